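"""Flow-cytometry event processing for on-the-fly reactive experiments.

Pipeline: generate or load per-event tables (forward scatter FSC, side
scatter SSC, named fluorescence channels), gate out debris and doublets,
spectrally deconvolve overlapping fluorophores, normalize to relative
promoter units (RPU), and classify events into genotypes by RPU thresholds.

The deconvolution model is linear: an event's expected channel vector is
``S @ x + a`` where ``S`` holds the per-unit spectral signature of each
fluorophore, ``x`` the fluorophore amounts, and ``a`` the per-channel
autofluorescence background. Unmixing is per-event ordinary least squares.

RPU normalization divides the FSC-normalized fluorophore amount by the
median FSC-normalized signal of a single-color control driven by the
strong constitutive pTDH3 promoter, so that control has median 1 RPU by
construction and expression levels become comparable across experiments.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde, theilslopes

__all__ = [
    "EventTable",
    "SpectralSignature",
    "GateConfig",
    "GateResult",
    "RpuReference",
    "GenotypeRule",
    "StrainPopulation",
    "PopulationSpec",
    "generate_events",
    "gate",
    "deconvolve",
    "DeconvolutionResult",
    "to_rpu",
    "RpuResult",
    "classify",
    "ClassificationResult",
    "rpu_reference_from_controls",
    "signature_from_controls",
    "process_events",
    "read_fcs",
]

_RESERVED = ("fsc", "ssc")


class EventTable:
    """Per-event cytometer measurements: FSC, SSC, and fluorescence channels.

    Wraps a DataFrame whose first two columns are ``fsc`` and ``ssc``
    (strictly positive scatter, arbitrary units) followed by uniquely named
    fluorescence channels (one column per detection channel).
    """

    def __init__(self, data: pd.DataFrame):
        for col in _RESERVED:
            if col not in data.columns:
                raise ValueError(f"event table must contain a {col!r} column")
        if data.columns.duplicated().any():
            raise ValueError("channel names must be unique")
        if len(data) and not (
            (data["fsc"] > 0).all() and (data["ssc"] > 0).all()
        ):
            raise ValueError("fsc and ssc must be strictly positive for every event")
        ordered = list(_RESERVED) + [c for c in data.columns if c not in _RESERVED]
        self._df = data.loc[:, ordered].reset_index(drop=True).astype(float)

    # -- container surface ---------------------------------------------------
    @property
    def n_events(self) -> int:
        return len(self._df)

    @property
    def channel_names(self) -> list[str]:
        return [c for c in self._df.columns if c not in _RESERVED]

    @property
    def fsc(self) -> np.ndarray:
        return self._df["fsc"].to_numpy()

    @property
    def ssc(self) -> np.ndarray:
        return self._df["ssc"].to_numpy()

    @property
    def channels(self) -> pd.DataFrame:
        return self._df[self.channel_names]

    def to_frame(self) -> pd.DataFrame:
        return self._df.copy()

    def subset(self, mask: np.ndarray) -> "EventTable":
        return EventTable(self._df.loc[np.asarray(mask)].reset_index(drop=True))

    def __len__(self) -> int:
        return self.n_events

    def __repr__(self) -> str:
        return f"EventTable(n_events={self.n_events}, channels={self.channel_names})"

    # -- delimited-text I/O --------------------------------------------------
    @classmethod
    def from_csv(cls, path: str, sep: str | None = None) -> "EventTable":
        if sep is None:
            sep = "\t" if os.fspath(path).endswith((".tsv", ".tab")) else ","
        return cls(pd.read_csv(path, sep=sep))

    def to_csv(self, path: str, sep: str | None = None) -> None:
        if sep is None:
            sep = "\t" if os.fspath(path).endswith((".tsv", ".tab")) else ","
        self._df.to_csv(path, sep=sep, index=False)


def read_fcs(path: str) -> EventTable:
    """Optional FCS 3.x ingestion, mapping $PnN names to channel columns.

    Requires the third-party ``fcsparser`` package; delimited text is the
    primary interface and this adapter is provided for convenience only.
    """
    try:
        import fcsparser  # type: ignore[import-not-found]
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading FCS files requires the optional 'fcsparser' package; "
            "export events as CSV/TSV instead"
        ) from exc
    _, df = fcsparser.parse(path)  # pragma: no cover - optional dependency
    df.columns = [c.lower() if c.lower() in _RESERVED else c for c in df.columns]
    return EventTable(df)  # pragma: no cover


@dataclass(frozen=True)
class SpectralSignature:
    """Spectral signatures of the fluorophores plus autofluorescence.

    ``matrix`` is (channels x fluorophores): expected intensity per unit
    fluorophore amount in each detection channel; ``autofluorescence`` is
    the per-channel expected background of a fluorophore-free cell. The
    matrix must have full column rank (fluorophores spectrally
    distinguishable), with all entries non-negative.
    """

    channel_names: tuple[str, ...]
    fluorophore_names: tuple[str, ...]
    matrix: np.ndarray
    autofluorescence: np.ndarray

    def __post_init__(self) -> None:
        S = np.asarray(self.matrix, dtype=float)
        a = np.asarray(self.autofluorescence, dtype=float)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))
        object.__setattr__(self, "fluorophore_names", tuple(self.fluorophore_names))
        object.__setattr__(self, "matrix", S)
        object.__setattr__(self, "autofluorescence", a)
        C, F = len(self.channel_names), len(self.fluorophore_names)
        if S.shape != (C, F):
            raise ValueError(f"matrix shape {S.shape} does not match ({C}, {F})")
        if a.shape != (C,):
            raise ValueError("autofluorescence must have one entry per channel")
        if (S < 0).any() or (a < 0).any():
            raise ValueError("signature entries must be non-negative")
        if np.linalg.matrix_rank(S) < F:
            raise ValueError(
                "signature matrix is rank-deficient: fluorophores "
                f"{_collinear_pair(S, self.fluorophore_names)} are collinear"
            )

    @classmethod
    def from_tsv(cls, path: str) -> "SpectralSignature":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "autofluorescence" not in df.columns:
            raise ValueError("signature file must contain an 'autofluorescence' column")
        fluors = [c for c in df.columns if c != "autofluorescence"]
        return cls(
            channel_names=tuple(df.index),
            fluorophore_names=tuple(fluors),
            matrix=df[fluors].to_numpy(),
            autofluorescence=df["autofluorescence"].to_numpy(),
        )

    def to_tsv(self, path: str) -> None:
        df = pd.DataFrame(self.matrix, index=list(self.channel_names),
                          columns=list(self.fluorophore_names))
        df["autofluorescence"] = self.autofluorescence
        df.to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def identity(cls, fluorophores: Sequence[str]) -> "SpectralSignature":
        """Identity mixing: one channel per fluorophore, no background."""
        n = len(fluorophores)
        return cls(
            channel_names=tuple(fluorophores),
            fluorophore_names=tuple(fluorophores),
            matrix=np.eye(n),
            autofluorescence=np.zeros(n),
        )


def _collinear_pair(S: np.ndarray, names: Sequence[str]) -> tuple[str, str]:
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    unit = S / norms
    gram = np.abs(unit.T @ unit)
    np.fill_diagonal(gram, 0.0)
    i, j = np.unravel_index(int(np.argmax(gram)), gram.shape)
    return (names[min(i, j)], names[max(i, j)])


# ---------------------------------------------------------------------------
# Synthetic event generation


@dataclass(frozen=True)
class StrainPopulation:
    """One strain's contribution to a synthetic sample.

    ``fluor_logmeans``/``fluor_logsds`` parameterize per-fluorophore
    lognormal expression in raw instrument units; fluorophores absent from
    the mapping are not expressed (amount 0).
    """

    name: str
    fraction: float
    fluor_logmeans: Mapping[str, float] = field(default_factory=dict)
    fluor_logsds: Mapping[str, float] = field(default_factory=dict)
    fsc_logmean: float = float(np.log(2000.0))
    fsc_logsd: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("strain fraction must lie in [0, 1]")
        if self.fsc_logsd < 0 or any(v < 0 for v in self.fluor_logsds.values()):
            raise ValueError("log-sds must be >= 0")


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for a synthetic cytometry sample with known ground truth.

    Emulates what the cytometer sees when the robot loads a diluted culture
    sample: a mixture of strains (lognormal size and expression), a debris
    fraction (events far below the cell-size mode), a doublet fraction
    (channel-wise sums of two cells measured as one event), and
    multiplicative measurement noise. Fully reproducible via ``seed``.
    """

    strains: tuple[StrainPopulation, ...]
    n_events: int
    doublet_fraction: float = 0.0
    debris_fraction: float = 0.0
    noise_sd: float = 0.1
    ssc_alpha: float = 2.4
    ssc_beta: float = 0.5
    ssc_logsd: float = 0.05
    default_fluor_logsd: float = 0.25
    debris_fsc_factor: float = 0.05
    debris_logsd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "strains", tuple(self.strains))
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        fracs = [s.fraction for s in self.strains]
        if self.strains and abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError("strain fractions must sum to 1")
        for frac in (self.doublet_fraction, self.debris_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("doublet/debris fractions must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _draw_singlets(
    spec: PopulationSpec,
    strain_idx: np.ndarray,
    sig: SpectralSignature,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Raw (noise-free) fsc, ssc and channel intensities for singlet draws."""
    n = strain_idx.size
    F = len(sig.fluorophore_names)
    amounts = np.zeros((n, F))
    fsc = np.empty(n)
    for si, strain in enumerate(spec.strains):
        sel = strain_idx == si
        m = int(np.count_nonzero(sel))
        if not m:
            continue
        fsc[sel] = np.exp(rng.normal(strain.fsc_logmean, strain.fsc_logsd, size=m))
        for fi, fluor in enumerate(sig.fluorophore_names):
            if fluor in strain.fluor_logmeans:
                sd = strain.fluor_logsds.get(fluor, spec.default_fluor_logsd)
                amounts[sel, fi] = np.exp(
                    rng.normal(strain.fluor_logmeans[fluor], sd, size=m)
                )
    ssc = np.exp(
        spec.ssc_alpha
        + spec.ssc_beta * np.log(fsc)
        + rng.normal(0.0, spec.ssc_logsd, size=n)
    )
    channels = amounts @ sig.matrix.T + sig.autofluorescence
    return fsc, ssc, channels


def generate_events(
    spec: PopulationSpec,
    signature: SpectralSignature | None = None,
) -> tuple[EventTable, np.ndarray]:
    """Synthesize an event table plus ground-truth labels.

    Labels are the strain name for singlets, ``"doublet"`` for coincident
    two-cell events (channel-wise sums of two sampled singlets) and
    ``"debris"`` for small non-cell particles. Channel intensities are
    ``S @ x + a`` perturbed by lognormal multiplicative noise of sd
    ``noise_sd``.
    """
    if signature is None:
        fluors = sorted({f for s in spec.strains for f in s.fluor_logmeans})
        signature = SpectralSignature.identity(fluors or ["blank"])
    rng = np.random.default_rng(spec.seed)
    n = spec.n_events
    cols = ["fsc", "ssc", *signature.channel_names]
    if n == 0:
        empty = pd.DataFrame({c: np.empty(0) for c in cols})
        return EventTable(empty), np.empty(0, dtype=object)
    if not spec.strains:
        raise ValueError("need at least one strain to generate events")

    u = rng.random(n)
    is_debris = u < spec.debris_fraction
    is_doublet = (~is_debris) & (u < spec.debris_fraction + spec.doublet_fraction)
    is_singlet = ~(is_debris | is_doublet)
    fractions = np.array([s.fraction for s in spec.strains])

    fsc = np.empty(n)
    ssc = np.empty(n)
    channels = np.empty((n, len(signature.channel_names)))
    labels = np.empty(n, dtype=object)

    k = int(np.count_nonzero(is_singlet))
    if k:
        idx = rng.choice(len(spec.strains), size=k, p=fractions)
        f, s, ch = _draw_singlets(spec, idx, signature, rng)
        fsc[is_singlet], ssc[is_singlet], channels[is_singlet] = f, s, ch
        labels[is_singlet] = np.array([spec.strains[i].name for i in idx], dtype=object)

    k = int(np.count_nonzero(is_doublet))
    if k:
        idx1 = rng.choice(len(spec.strains), size=k, p=fractions)
        idx2 = rng.choice(len(spec.strains), size=k, p=fractions)
        f1, s1, c1 = _draw_singlets(spec, idx1, signature, rng)
        f2, s2, c2 = _draw_singlets(spec, idx2, signature, rng)
        fsc[is_doublet] = f1 + f2
        ssc[is_doublet] = s1 + s2
        channels[is_doublet] = c1 + c2 - signature.autofluorescence  # one read, one background
        labels[is_doublet] = "doublet"

    k = int(np.count_nonzero(is_debris))
    if k:
        mode = float(np.mean([s.fsc_logmean for s in spec.strains]))
        f = np.exp(
            mode + np.log(spec.debris_fsc_factor)
            + rng.normal(0.0, spec.debris_logsd, size=k)
        )
        s = np.exp(
            spec.ssc_alpha + spec.ssc_beta * np.log(f)
            + rng.normal(0.0, spec.ssc_logsd, size=k)
        )
        fsc[is_debris], ssc[is_debris] = f, s
        channels[is_debris] = signature.autofluorescence
        labels[is_debris] = "debris"

    if spec.noise_sd > 0:
        channels = channels * np.exp(
            rng.normal(0.0, spec.noise_sd, size=channels.shape)
        )
    data = pd.DataFrame(np.column_stack([fsc, ssc, channels]), columns=cols)
    return EventTable(data), labels


# ---------------------------------------------------------------------------
# Gating


@dataclass(frozen=True)
class GateConfig:
    """Parameters of the size and doublet gates.

    ``size_threshold``: events whose log-FSC kernel-density value falls
    below this fraction of the density mode are removed (debris and
    dead/dying tails). ``doublet_threshold`` t maps to the
    (1 - t/10) quantile of the doublet-gate residuals. The KDE uses a
    fixed wide bandwidth (natural-log units) so a tight population sits
    near the smoothed mode.
    """

    size_threshold: float = 0.5
    doublet_threshold: float = 0.5
    kde_bandwidth: float = 0.6
    doublet_mad_factor: float = 3.5
    robust_fit_max_points: int = 1500

    def __post_init__(self) -> None:
        for name in ("size_threshold", "doublet_threshold"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.kde_bandwidth <= 0:
            raise ValueError("kde_bandwidth must be > 0")


@dataclass(frozen=True)
class GateResult:
    mask: np.ndarray
    n_removed_size: int
    n_removed_doublet: int
    warnings: tuple[str, ...] = ()


def gate(events: EventTable, config: GateConfig = GateConfig()) -> GateResult:
    """Keep-mask retaining intact single cells.

    Two sequential rules: (i) size gate -- drop events whose log-FSC
    kernel-density value is below ``size_threshold`` times the density
    mode; (ii) doublet gate -- on the size-kept events, fit a robust
    (Theil-Sen) line of log-SSC on log-FSC and drop events whose centered
    orthogonal residual magnitude exceeds
    max(quantile(1 - doublet_threshold/10), 3.5 x 1.4826 x MAD).
    The MAD floor makes re-gating clean data nearly a no-op while the
    quantile keeps the cut monotone in the named threshold.
    """
    n = events.n_events
    if n == 0:
        return GateResult(np.zeros(0, dtype=bool), 0, 0)
    if n < 3:
        return GateResult(
            np.ones(n, dtype=bool), 0, 0,
            warnings=(f"only {n} events: gating skipped, all kept",),
        )

    logf = np.log(events.fsc)
    spread = float(np.std(logf, ddof=1))
    if spread < 1e-12:
        keep_size = np.ones(n, dtype=bool)
    else:
        kde = gaussian_kde(logf, bw_method=config.kde_bandwidth / spread)
        dens = kde(logf)
        keep_size = dens >= config.size_threshold * dens.max()
    n_removed_size = int(np.count_nonzero(~keep_size))

    mask = keep_size.copy()
    kept_idx = np.flatnonzero(keep_size)
    if kept_idx.size >= 3:
        lf = logf[kept_idx]
        ls = np.log(events.ssc[kept_idx])
        if kept_idx.size > config.robust_fit_max_points:
            sub = np.linspace(0, kept_idx.size - 1, config.robust_fit_max_points).astype(int)
        else:
            sub = slice(None)
        slope, intercept, _, _ = theilslopes(ls[sub], lf[sub])
        res = (ls - intercept - slope * lf) / np.sqrt(1.0 + slope * slope)
        centered = res - np.median(res)
        mad = float(np.median(np.abs(centered)))
        cutoff = max(
            float(np.quantile(np.abs(centered), 1.0 - config.doublet_threshold / 10.0)),
            config.doublet_mad_factor * 1.4826 * mad,
        )
        keep_doublet = np.abs(centered) <= cutoff
        mask[kept_idx] = keep_doublet
    n_removed_doublet = int(np.count_nonzero(keep_size) - np.count_nonzero(mask))
    return GateResult(mask, n_removed_size, n_removed_doublet)


# ---------------------------------------------------------------------------
# Spectral deconvolution


@dataclass(frozen=True)
class DeconvolutionResult:
    amounts: pd.DataFrame
    residual_norm: np.ndarray


def deconvolve(
    events: EventTable,
    sig: SpectralSignature,
    nonnegative: bool = False,
) -> DeconvolutionResult:
    """Per-event fluorophore amounts by least-squares spectral unmixing.

    Solves ``min_x || S x + a - y ||`` for every event (unconstrained OLS
    by default; ``nonnegative=True`` switches to NNLS per event). Requires
    the event channels to match the signature channels exactly.
    """
    if list(events.channel_names) != list(sig.channel_names):
        raise ValueError(
            f"channel mismatch: events have {events.channel_names}, "
            f"signature has {list(sig.channel_names)}"
        )
    Y = events.channels.to_numpy()  # (n, C)
    B = (Y - sig.autofluorescence).T  # (C, n)
    if nonnegative:
        from scipy.optimize import nnls

        X = np.empty((len(sig.fluorophore_names), Y.shape[0]))
        for i in range(Y.shape[0]):
            X[:, i], _ = nnls(sig.matrix, B[:, i])
    else:
        X, *_ = np.linalg.lstsq(sig.matrix, B, rcond=None)
    residual = np.linalg.norm(sig.matrix @ X - B, axis=0)
    amounts = pd.DataFrame(X.T, columns=list(sig.fluorophore_names))
    return DeconvolutionResult(amounts=amounts, residual_norm=residual)


# ---------------------------------------------------------------------------
# RPU normalization


@dataclass(frozen=True)
class RpuReference:
    """Per-fluorophore median FSC-normalized amount of the pTDH3 control."""

    medians: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "medians", dict(self.medians))
        for fluor, value in self.medians.items():
            if not value > 0:
                raise ValueError(f"reference median for {fluor!r} must be > 0")

    def __getitem__(self, fluor: str) -> float:
        return self.medians[fluor]

    @classmethod
    def from_csv(cls, path: str) -> "RpuReference":
        df = pd.read_csv(path)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))

    def to_csv(self, path: str) -> None:
        pd.DataFrame(
            {"fluorophore": list(self.medians), "median": list(self.medians.values())}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class RpuResult:
    rpu: pd.DataFrame
    n_excluded: int
    included: np.ndarray


def to_rpu(
    amounts: pd.DataFrame,
    fsc: np.ndarray,
    ref: RpuReference,
) -> RpuResult:
    """Convert deconvolved amounts to relative promoter units.

    RPU(event, f) = (amount / FSC) / reference_median(f). Events with
    non-positive FSC are excluded and counted in ``n_excluded``.
    """
    fsc = np.asarray(fsc, dtype=float)
    if len(fsc) != len(amounts):
        raise ValueError("fsc and amounts must have the same length")
    ok = fsc > 0
    n_excluded = int(np.count_nonzero(~ok))
    denom = np.array([ref[f] for f in amounts.columns])
    rpu = amounts.loc[ok].to_numpy() / fsc[ok, None] / denom
    return RpuResult(
        rpu=pd.DataFrame(rpu, columns=amounts.columns),
        n_excluded=n_excluded,
        included=ok,
    )


def rpu_reference_from_controls(
    controls: Mapping[str, EventTable],
    sig: SpectralSignature,
    gate_config: GateConfig | None = GateConfig(),
) -> RpuReference:
    """Build the RPU reference from pTDH3 single-color control samples.

    For each fluorophore, the control table is gated, deconvolved, FSC
    normalized, and the median taken -- the median (not the mean) is used
    throughout the pipeline.
    """
    medians: dict[str, float] = {}
    for fluor, table in controls.items():
        if fluor not in sig.fluorophore_names:
            raise ValueError(f"unknown fluorophore {fluor!r} in controls")
        if gate_config is not None:
            table = table.subset(gate(table, gate_config).mask)
        dec = deconvolve(table, sig)
        medians[fluor] = float(np.median(dec.amounts[fluor].to_numpy() / table.fsc))
    return RpuReference(medians)


def signature_from_controls(
    controls: Mapping[str, EventTable],
    autofluorescence_control: EventTable,
    channel_names: Sequence[str] | None = None,
) -> SpectralSignature:
    """Estimate spectral signatures from single-color and blank controls.

    Autofluorescence is the per-channel median of the blank control (a
    single fixed vector, not per-event); each fluorophore's signature
    column is the per-channel median excess of its single-color control,
    rescaled to peak 1 so the fluorophore 'amount' unit is its brightest
    channel's intensity.
    """
    if channel_names is None:
        channel_names = autofluorescence_control.channel_names
    a = autofluorescence_control.channels[list(channel_names)].median().to_numpy()
    cols = []
    fluors = list(controls)
    for fluor in fluors:
        med = controls[fluor].channels[list(channel_names)].median().to_numpy()
        col = np.clip(med - a, 0.0, None)
        peak = col.max()
        if peak <= 0:
            raise ValueError(f"control for {fluor!r} shows no signal above background")
        cols.append(col / peak)
    return SpectralSignature(
        channel_names=tuple(channel_names),
        fluorophore_names=tuple(fluors),
        matrix=np.column_stack(cols),
        autofluorescence=a,
    )


# ---------------------------------------------------------------------------
# Genotype classification


@dataclass(frozen=True)
class GenotypeRule:
    """RPU-threshold predicates assigning each event to one genotype.

    ``rules`` maps a label to a list of ``(key, direction, threshold)``
    predicates (direction ``">"`` or ``"<"``), all of which must hold.
    Events matching no label, or more than one, are labeled
    ``"unassigned"``.
    """

    rules: tuple[tuple[str, tuple[tuple[str, str, float], ...]], ...]
    unassigned_label: str = "unassigned"

    def __post_init__(self) -> None:
        norm = tuple(
            (label, tuple((k, d, float(t)) for k, d, t in preds))
            for label, preds in self.rules
        )
        object.__setattr__(self, "rules", norm)
        labels = [label for label, _ in norm]
        if len(set(labels)) != len(labels):
            raise ValueError("genotype labels must be unique")
        for _, preds in norm:
            for _, d, _ in preds:
                if d not in (">", "<", ">=", "<="):
                    raise ValueError(f"unknown comparison direction {d!r}")

    @classmethod
    def threshold(
        cls, key: str, value: float, above: str, below: str
    ) -> "GenotypeRule":
        """Single-marker rule, e.g. 1 mCerulean RPU separating wild type
        (constitutive mCerulean) from the unmarked mutant."""
        return cls(rules=(
            (above, ((key, ">", value),)),
            (below, ((key, "<=", value),)),
        ))

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.rules] + [self.unassigned_label]

    def referenced_keys(self) -> set[str]:
        return {k for _, preds in self.rules for k, _, _ in preds}


@dataclass(frozen=True)
class ClassificationResult:
    labels: np.ndarray
    fractions: dict[str, float]
    counts: dict[str, int]


_OPS = {
    ">": np.greater,
    "<": np.less,
    ">=": np.greater_equal,
    "<=": np.less_equal,
}


def classify(rpu: pd.DataFrame, rules: GenotypeRule) -> ClassificationResult:
    """Assign each event exactly one genotype label from RPU predicates.

    Fractions cover every label including ``unassigned`` and sum to 1 (for
    a non-empty input); they are invariant under event permutation.
    """
    missing = rules.referenced_keys() - set(rpu.columns)
    if missing:
        raise ValueError(f"rules reference missing channels/fluorophores: {sorted(missing)}")
    n = len(rpu)
    match = np.zeros((n, len(rules.rules)), dtype=bool)
    for j, (_, preds) in enumerate(rules.rules):
        ok = np.ones(n, dtype=bool)
        for key, direction, thr in preds:
            ok &= _OPS[direction](rpu[key].to_numpy(), thr)
        match[:, j] = ok
    n_match = match.sum(axis=1)
    labels = np.full(n, rules.unassigned_label, dtype=object)
    unique = n_match == 1
    if unique.any():
        which = np.argmax(match[unique], axis=1)
        names = np.array([label for label, _ in rules.rules], dtype=object)
        labels[unique] = names[which]
    counts = {label: int(np.count_nonzero(labels == label)) for label in rules.labels}
    total = max(n, 1)
    fractions = {label: c / total for label, c in counts.items()}
    return ClassificationResult(labels=labels, fractions=fractions, counts=counts)


# ---------------------------------------------------------------------------
# Full pipeline


def process_events(
    events: EventTable,
    sig: SpectralSignature,
    ref: RpuReference,
    gate_config: GateConfig = GateConfig(),
    rules: GenotypeRule | None = None,
) -> pd.DataFrame:
    """Gate, deconvolve, and RPU-normalize an event table.

    Returns one row per retained event with ``fsc``, ``ssc``, the
    per-fluorophore RPU values, the deconvolution residual norm, and (when
    ``rules`` is given) a ``genotype`` column.
    """
    gated = events.subset(gate(events, gate_config).mask)
    dec = deconvolve(gated, sig)
    covered = [f for f in dec.amounts.columns if f in ref.medians]
    if not covered:
        raise ValueError("reference covers none of the signature's fluorophores")
    rpu = to_rpu(dec.amounts[covered], gated.fsc, ref)
    inc = rpu.included
    out = pd.DataFrame({
        "fsc": gated.fsc[inc],
        "ssc": gated.ssc[inc],
    })
    for fluor in rpu.rpu.columns:
        out[f"{fluor}_rpu"] = rpu.rpu[fluor].to_numpy()
    out["residual"] = dec.residual_norm[inc]
    if rules is not None:
        renamed = rpu.rpu.copy()
        result = classify(renamed, rules)
        out["genotype"] = result.labels
    return out
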