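"""Cytometry tests: synthetic generation, gating, spectral unmixing, RPU
normalization, genotype classification, and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from reacloop.cytometry import (
    EventTable,
    GateConfig,
    GenotypeRule,
    PopulationSpec,
    RpuReference,
    SpectralSignature,
    StrainPopulation,
    classify,
    deconvolve,
    gate,
    generate_events,
    process_events,
    to_rpu,
)

from conftest import AUTOFLUORESCENCE, CHANNELS, FLUOROPHORES, MATRIX, PTDH3_LEVEL


class TestGenerateEvents:
    def test_empty_spec_gives_empty_table(self, signature):
        strain = StrainPopulation("s", 1.0)
        events, labels = generate_events(
            PopulationSpec(strains=(strain,), n_events=0), signature
        )
        assert events.n_events == 0 and labels.size == 0

    def test_identity_mixing_returns_drawn_amounts(self):
        # One strain, zero noise, identity signature: channels equal the
        # lognormal fluorophore draws exactly.
        strain = StrainPopulation("s", 1.0, fluor_logmeans={"gfp": np.log(100.0)})
        spec = PopulationSpec(strains=(strain,), n_events=500, noise_sd=0.0, seed=3)
        events, labels = generate_events(spec)
        assert set(labels) == {"s"}
        values = events.channels["gfp"].to_numpy()
        assert np.all(values > 0)
        # draws are lognormal(log 100, default sd); check the median scale
        assert np.median(values) == pytest.approx(100.0, rel=0.1)

    def test_five_to_one_mixture_counts_in_binomial_interval(self, signature):
        wt = StrainPopulation("wt", 5.0 / 6.0, fluor_logmeans={"mCerulean": np.log(5000)})
        mut = StrainPopulation("mutant", 1.0 / 6.0)
        spec = PopulationSpec(strains=(wt, mut), n_events=12000, seed=0)
        _, labels = generate_events(spec, signature)
        n_wt = int(np.sum(labels == "wt"))
        lo = binom.ppf(0.005, 12000, 5.0 / 6.0)
        hi = binom.ppf(0.995, 12000, 5.0 / 6.0)
        assert lo <= n_wt <= hi

    def test_fraction_validation(self):
        with pytest.raises(ValueError):
            PopulationSpec(
                strains=(StrainPopulation("a", 0.6), StrainPopulation("b", 0.6)),
                n_events=10,
            )
        with pytest.raises(ValueError):
            PopulationSpec(strains=(StrainPopulation("a", 1.0),), n_events=-1)


class TestGate:
    def clean_spec(self, n=6000, seed=0, **kwargs):
        strain = StrainPopulation("s", 1.0, fluor_logmeans={"mCerulean": np.log(3000)})
        return PopulationSpec(strains=(strain,), n_events=n, seed=seed, **kwargs)

    def test_empty_table_empty_mask(self, signature):
        events, _ = generate_events(self.clean_spec(n=0), signature)
        assert gate(events).mask.size == 0

    def test_tiny_table_kept_with_warning(self, signature):
        events, _ = generate_events(self.clean_spec(n=2), signature)
        result = gate(events)
        assert result.mask.all() and result.warnings

    def test_clean_population_keeps_at_least_99_percent(self, signature):
        events, _ = generate_events(self.clean_spec(), signature)
        result = gate(events, GateConfig(size_threshold=0.5, doublet_threshold=0.5))
        assert result.mask.mean() >= 0.99

    def test_debris_and_doublet_removal_recall_precision(self, signature):
        spec = self.clean_spec(n=10000, doublet_fraction=0.05, debris_fraction=0.05)
        events, labels = generate_events(spec, signature)
        removed = ~gate(events).mask
        truly_bad = (labels == "doublet") | (labels == "debris")
        recall = (removed & truly_bad).sum() / truly_bad.sum()
        precision = (removed & truly_bad).sum() / removed.sum()
        assert recall >= 0.95
        assert precision >= 0.95

    def test_gating_is_idempotent_on_clean_data(self, signature):
        events, _ = generate_events(self.clean_spec(), signature)
        first = gate(events)
        kept = events.subset(first.mask)
        second = gate(kept)
        extra_removed = 1.0 - second.mask.mean()
        assert extra_removed < 0.01


class TestDeconvolve:
    def test_identity_signature_returns_channels(self):
        sig = SpectralSignature.identity(["a", "b"])
        df = pd.DataFrame(
            {"fsc": [100.0, 200.0], "ssc": [50.0, 60.0], "a": [3.0, 4.0], "b": [5.0, 6.0]}
        )
        result = deconvolve(EventTable(df), sig)
        np.testing.assert_allclose(result.amounts.to_numpy(), df[["a", "b"]].to_numpy())
        np.testing.assert_allclose(result.residual_norm, 0.0, atol=1e-12)

    def test_autofluorescence_only_event_maps_to_zero(self, signature):
        df = pd.DataFrame(
            [[100.0, 50.0, *AUTOFLUORESCENCE]], columns=["fsc", "ssc", *CHANNELS]
        )
        result = deconvolve(EventTable(df), signature)
        np.testing.assert_allclose(result.amounts.to_numpy(), 0.0, atol=1e-9)

    def test_recovers_known_mixture_exactly(self):
        # 3 channels x 2 fluorophores with 30% cross-talk.
        S = np.array([[1.0, 0.3], [0.3, 1.0], [0.1, 0.3]])
        a = np.array([5.0, 7.0, 3.0])
        sig = SpectralSignature(("c1", "c2", "c3"), ("f1", "f2"), S, a)
        x_true = np.array([[120.0, 40.0], [3.0, 900.0], [0.0, 55.0]])
        y = x_true @ S.T + a
        df = pd.DataFrame(
            np.column_stack([np.full(3, 100.0), np.full(3, 50.0), y]),
            columns=["fsc", "ssc", "c1", "c2", "c3"],
        )
        result = deconvolve(EventTable(df), sig)
        np.testing.assert_allclose(result.amounts.to_numpy(), x_true, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_normal_equations_oracle(self, seed):
        # random full-rank instances, <= 4 fluorophores and <= 6 channels
        rng = np.random.default_rng(seed)
        n_fluor = rng.integers(1, 5)
        n_chan = rng.integers(n_fluor, 7)
        S = rng.uniform(0.0, 1.0, size=(n_chan, n_fluor)) + np.eye(n_chan, n_fluor)
        a = rng.uniform(0.0, 10.0, size=n_chan)
        sig = SpectralSignature(
            tuple(f"c{i}" for i in range(n_chan)),
            tuple(f"f{i}" for i in range(n_fluor)),
            S,
            a,
        )
        y = rng.uniform(0.0, 1000.0, size=(50, n_chan))
        df = pd.DataFrame(
            np.column_stack([np.full(50, 100.0), np.full(50, 50.0), y]),
            columns=["fsc", "ssc", *sig.channel_names],
        )
        result = deconvolve(EventTable(df), sig)
        # brute-force per-event normal equations
        oracle = np.linalg.solve(S.T @ S, S.T @ (y - a).T).T
        np.testing.assert_allclose(result.amounts.to_numpy(), oracle, rtol=1e-9, atol=1e-9)

    def test_collinear_fluorophores_named_in_error(self):
        S = np.array([[1.0, 2.0], [0.5, 1.0], [0.2, 0.4]])
        with pytest.raises(ValueError, match="f1.*f2|collinear"):
            SpectralSignature(("c1", "c2", "c3"), ("f1", "f2"), S, np.zeros(3))


class TestToRpu:
    def test_reference_control_has_median_one(self, single_color_controls, signature, rpu_reference):
        table = single_color_controls["mNeonGreen"]
        table = table.subset(gate(table).mask)
        amounts = deconvolve(table, signature).amounts
        result = to_rpu(amounts, table.fsc, rpu_reference)
        assert result.rpu["mNeonGreen"].median() == pytest.approx(1.0, abs=1e-9)

    def test_double_signal_is_two_rpu(self):
        ref = RpuReference({"f": 2.0})
        amounts = pd.DataFrame({"f": [400.0]})
        result = to_rpu(amounts, np.array([100.0]), ref)
        assert result.rpu["f"].iloc[0] == pytest.approx(2.0)

    def test_scale_equivariance(self, rpu_reference):
        rng = np.random.default_rng(1)
        amounts = pd.DataFrame(
            rng.uniform(0, 1000, size=(100, 3)), columns=list(FLUOROPHORES)
        )
        fsc = rng.uniform(500, 5000, size=100)
        base = to_rpu(amounts, fsc, rpu_reference).rpu
        scaled_ref = RpuReference({k: 7.5 * v for k, v in rpu_reference.medians.items()})
        scaled = to_rpu(amounts * 7.5, fsc, scaled_ref).rpu
        np.testing.assert_allclose(scaled.to_numpy(), base.to_numpy(), rtol=1e-12)

    def test_autofluorescence_strain_near_zero_rpu(self, signature, rpu_reference):
        blank = StrainPopulation("auto", 1.0)
        events, _ = generate_events(
            PopulationSpec(strains=(blank,), n_events=5000, seed=2), signature
        )
        amounts = deconvolve(events, signature).amounts
        result = to_rpu(amounts, events.fsc, rpu_reference)
        assert result.rpu.median().abs().max() < 0.05

    def test_nonpositive_fsc_excluded_and_counted(self, rpu_reference):
        amounts = pd.DataFrame({f: [10.0, 20.0, 30.0] for f in FLUOROPHORES})
        result = to_rpu(amounts, np.array([100.0, 0.0, -5.0]), rpu_reference)
        assert result.n_excluded == 2
        assert len(result.rpu) == 1


class TestClassify:
    RULES = GenotypeRule.threshold("mCerulean", 1.0, above="wt", below="mutant")

    def test_all_above_threshold_labeled_wild_type(self):
        rpu = pd.DataFrame({"mCerulean": np.full(50, 1.5)})
        result = classify(rpu, self.RULES)
        assert result.fractions["wt"] == 1.0

    def test_all_below_threshold_labeled_mutant(self):
        rpu = pd.DataFrame({"mCerulean": np.full(50, 0.01)})
        assert classify(rpu, self.RULES).fractions["mutant"] == 1.0

    def test_missing_channel_is_an_input_error(self):
        with pytest.raises(ValueError, match="missing"):
            classify(pd.DataFrame({"mNeonGreen": [1.0]}), self.RULES)

    def test_fractions_sum_to_one_and_permutation_invariant(self):
        rng = np.random.default_rng(4)
        rpu = pd.DataFrame({"mCerulean": rng.uniform(0, 3, size=500)})
        base = classify(rpu, self.RULES)
        assert sum(base.fractions.values()) == pytest.approx(1.0)
        shuffled = rpu.sample(frac=1.0, random_state=5).reset_index(drop=True)
        assert classify(shuffled, self.RULES).fractions == base.fractions

    def test_five_to_one_mixture_recovered_within_1_percent(
        self, competition_mixture_spec, signature, rpu_reference
    ):
        events, labels = generate_events(competition_mixture_spec, signature)
        kept = gate(events)
        table = events.subset(kept.mask)
        amounts = deconvolve(table, signature).amounts
        rpu = to_rpu(amounts, table.fsc, rpu_reference)
        result = classify(rpu.rpu, self.RULES)
        truth = float(np.mean(labels == "wt"))
        assert result.fractions["wt"] == pytest.approx(truth, abs=0.01)


class TestPipeline:
    def test_end_to_end_recovers_strain_fractions_within_2_percent(
        self, competition_mixture_spec, signature, rpu_reference
    ):
        out = process_events(
            generate_events(competition_mixture_spec, signature)[0],
            signature,
            rpu_reference,
            rules=GenotypeRule.threshold("mCerulean", 1.0, above="wt", below="mutant"),
        )
        wt_fraction = float(np.mean(out["genotype"] == "wt"))
        assert wt_fraction == pytest.approx(1.0 / 6.0, abs=0.02)

    def test_event_table_roundtrip(self, tmp_path, signature):
        strain = StrainPopulation("s", 1.0, fluor_logmeans={"mCerulean": np.log(1000)})
        events, _ = generate_events(
            PopulationSpec(strains=(strain,), n_events=50, seed=7), signature
        )
        for name in ("events.csv", "events.tsv"):
            path = tmp_path / name
            events.to_csv(str(path))
            back = EventTable.from_csv(str(path))
            pd.testing.assert_frame_equal(back.to_frame(), events.to_frame())

    def test_signature_roundtrip(self, tmp_path, signature):
        path = tmp_path / "sig.tsv"
        signature.to_tsv(str(path))
        back = SpectralSignature.from_tsv(str(path))
        assert back.channel_names == signature.channel_names
        assert back.fluorophore_names == signature.fluorophore_names
        np.testing.assert_allclose(back.matrix, signature.matrix)
        np.testing.assert_allclose(back.autofluorescence, signature.autofluorescence)
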