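# Methods

This note documents the models, algorithms, default parameters and design
choices behind `reacloop`, and what its synthetic benchmarks do and do not
demonstrate about real data.

## Cytometry processing

**Event model.** An event is a row of (FSC, SSC, channel intensities), all
in arbitrary instrument units. The expected channel vector of a cell is
linear: `y = S x + a`, where `S` (channels × fluorophores) holds the
spectral signature of each fluorophore per unit amount, `x` the fluorophore
amounts, and `a` a single per-channel autofluorescence vector. `a` is
estimated as the per-channel *median* of a fluorophore-free control and
subtracted as a fixed vector, not per event; signature columns are the
median excess of single-color controls rescaled to peak 1, which fixes the
(arbitrary) amount unit per fluorophore.

**Gating.** Two sequential rules with the conventional defaults
`size_threshold = 0.5`, `doublet_threshold = 0.5`:

1. *Size gate.* Events whose log-FSC kernel-density value falls below
   `size_threshold` × the density mode are removed (debris, dead/dying
   tails). The KDE uses a **fixed wide bandwidth** (0.6 natural-log units,
   ≈ 0.26 decades; a `GateConfig` parameter) rather than a data-driven
   bandwidth. With a data-driven bandwidth a density-ratio cut at 0.5
   would always remove ~24% of even a perfectly clean Gaussian
   population; with a bandwidth wide relative to a healthy population's
   spread, a tight population sits near the smoothed mode (> 99% kept)
   while debris at a twentieth of the size mode is orders of magnitude
   below the cut.
2. *Doublet gate.* On size-kept events, a robust Theil–Sen line of
   log-SSC on log-FSC is fitted (subsampled to ≤ 1500 points, since the
   pairwise-slope estimator is quadratic in n) and events are removed when
   their centered orthogonal residual magnitude exceeds
   `max(q_{1−t/10}, 3.5 × 1.4826 × MAD)` with `t = doublet_threshold`.
   The quantile term makes the cut monotone in the named threshold; the
   MAD floor makes re-gating already-clean data nearly a no-op (< 1%
   additional removal) instead of always chopping a fixed 5%.

These rules are this package's reconstruction: only the two threshold
names and defaults are fixed by convention, the precise algorithm is a
design choice validated against the generator's ground-truth labels
(removal recall and precision ≥ 0.95 at 5% debris + 5% doublets).

**Deconvolution.** Per-event unconstrained ordinary least squares
`min_x ‖S x + a − y‖²`, solved for all events at once via `lstsq`; the
residual norm is returned per event. A non-negativity option (per-event
NNLS) exists but is off by default — unconstrained estimates preserve the
slightly negative values that arise from noise around zero, which keeps
medians unbiased. A rank-deficient signature raises an error naming the
most collinear fluorophore pair.

**RPU normalization.** `RPU = (amount / FSC) / median_ref`, where
`median_ref` is the median FSC-normalized deconvolved amount of a
single-color control driven by the strong constitutive pTDH3 promoter.
The control therefore has median 1 RPU by construction, and RPU is
invariant to joint rescaling of amounts and reference. Events with
non-positive FSC are excluded and counted.

**Genotyping.** RPU-threshold predicates per label (e.g. 1 mCerulean RPU
separating a marked wild type from an unmarked mutant). An event matching
no label, or more than one, is `unassigned`; fractions cover all labels
and sum to 1.

**Synthetic generator.** `PopulationSpec` draws per-strain lognormal FSC
(default log-mean ln 2000, log-sd 0.25) and lognormal fluorophore amounts,
mixes them through `S`, adds `a`, and applies multiplicative lognormal
channel noise (sd 0.1). SSC follows `log SSC = α + β log FSC + ε` with
β = 0.5: with β = 1, a doublet (the channel-wise sum of two cells read as
one event) would lie exactly on the singlet SSC–FSC line and be
geometrically undetectable, whereas β < 1 displaces it by ≈ (1−β)·ln 2,
which is what doublet gating exploits on real instruments via pulse
geometry. Debris sits at 5% of the FSC mode with autofluorescence-only
channels. The generator reproduces mixture fractions, spectral overlap,
coincidence and debris — it does **not** emulate detector saturation,
spillover spreading, time drift, or cell-cycle-correlated expression, so
passing tests demonstrate correctness of the processing algebra and
gating logic, not robustness to every instrument artifact.

## Light-driven expression model

Two-variable linear ODE for the EL222 blue-light induction circuit:

    dm/dt  = σ·L(t) − γm·m
    dFP/dt = km·m − γFP·FP,     L(t) ∈ {0, 1}

Defaults (jointly fitted values for the reporter circuit): γm = 2.09 h⁻¹
(mRNA half-life ≈ 20 min), σ = 0.64 RPU·h⁻¹, γFP = 0.475 h⁻¹ (protein
half-life 1.46 h, dominated by dilution at the turbidostat growth rate).
Because only `km·m` is observable from protein medians, `km` is tied to
`γm` by default; this fixes the dimensionless mRNA unit and makes the
remaining three parameters identifiable. The steady-state ceiling under
constant light is σ·km/(γm·γFP) = σ/γFP ≈ 1.35 RPU.

**Integration** is exact: the ODE is linear with piecewise-constant input,
so each constant-light segment is propagated with the closed-form matrix
exponential (scalar formulas; the `τ·e^{−γτ}` limit is used when
|γm − γFP| < 10⁻⁹ relative). No step-size error enters anywhere, including
inside optimization loops. Light programs are duty-cycled with period
30 min and the ON phase at the cycle start (**ON-first**); nothing forces
within-cycle placement, and at 30-min cycles versus 1/γm ≈ 29 min the
cycle-averaged response depends only weakly on it, but the choice is
fixed and documented here.

**Fitting** minimizes the summed squared FP residual over
(γm, σ, γFP) with bounds γ ∈ [10⁻³, 20] h⁻¹, σ ∈ [10⁻⁴, 20] RPU·h⁻¹, from
20 seeded log-uniform multi-starts (`scipy.optimize.least_squares`, TRF).
Each series is simulated from the dark steady state (0, 0). A parameter
whose Jacobian column vanishes at the optimum (e.g. σ under all-dark
programs) is unidentifiable; it is pinned to its lower bound and flagged
in the diagnostics rather than left wherever the optimizer started.

**State estimation** for control is hybrid: mRNA is an open-loop estimate
from simulating the full light history (initial state: dark steady state);
FP is set equal to the measurement; both are advanced by the data-arrival
delay (typically 10–15 min on hardware; 0 in the virtual loops) under the
actually applied light.

## Model-predictive control

**Light MPC.** Decision variable: 10 duty fractions (30-min cycles, 5 h
receding horizon). Objective: mean squared deviation of model-predicted FP
from the target, sampled every 6 min over the horizon — a smooth,
differentiable stand-in for "model-predicted distance to target".
Optimizer: bounded L-BFGS-B from a deterministic start list (previous plan
shifted by one cycle — the standard receding-horizon warm start — plus
constant 0 / 0.5 / 1 profiles and seeded uniform draws). Unreachable
targets saturate at the duty bounds and set a `saturated` flag instead of
erroring; if every start fails the previous plan is kept (fail-safe).
On 3-cycle horizons the planner matches exhaustive grid search (step
0.05) to within grid resolution; in closed loop on the noise-free plant it
holds any reachable target to < 2% after 10 h of hourly re-planning.

**Ratio control.** The steering map is a sigmoid in OD,
`Δµ(OD) = c0 − c1/(1 + e^{−(OD−c2)/c3})` (auxotroph minus prototroph,
h⁻¹), fitted by seeded multi-start least squares; the start list begins
with the flat degenerate model so constant data resolves deterministically
to c1 = 0. Composition dynamics use the two-strain identity
`d/dt log(r/(1−r)) = Δµ(OD(t))` — odds space rather than raw count
ratios, equivalent for two strains and numerically stable near 0 and 1 —
integrated exactly per constant-OD segment. The planner optimizes five
2-h OD setpoints in [0.1, 0.8] to minimize the squared ratio deviation at
block ends, with the same warm-start/fail-safe machinery. The "ratio" is
defined as the auxotroph fraction of events; the numerator is a parameter
of the loop builders. Under a +0.05 h⁻¹ unmodeled growth recovery of the
slow strain the loop shows the expected persistent undershoot of the
target — a model-mismatch signature, not a bug.

## Fitness inference

At steady state the two-strain odds grow exponentially at the growth-rate
difference, so Δµ is the OLS slope of log-odds versus time, with the
standard error from residual variance. "Linearity of the log ratio for at
least three points" marks steady state; it is operationalized as the
longest suffix window (≥ 3 usable points, both counts positive) whose
least-squares line has maximum absolute residual below 0.05 log units
(the tolerance is a parameter; "linear" is inherently a
qualitative criterion and needs an explicit operationalization). Under multinomial event sampling the estimator is
unbiased and its 1-σ interval covers the truth ≈ 68% when the design has
enough points (the SE uses normal OLS theory; with very few time points
the t-distribution correction and the heteroscedastic binomial variance
push 1-σ coverage a few points below 68%).

## Virtual turbidostat

State: per-strain biomass densities (OD units; OD is their sum), shared
histidine concentration h (µM), OD setpoint, 30 mL constant volume.
Dynamics per strain: `dX_i/dt = (µ_i − D)X_i`;
`dh/dt = D(h_in − h) − consumption`. The turbidostat law is the ideal
continuous hold: D is chosen each sub-step so the culture lands exactly on
the setpoint once reached (at steady state D equals the mean growth rate);
D = 0 below the setpoint. Integration is explicit Euler with ≤ 0.005 h
sub-steps; the discrete mass balance ΔOD = growth − dilution holds exactly
by construction.

**Growth law.** Prototrophs grow at constant µ_max (default 0.4 h⁻¹, the
observed 0.3–0.45 h⁻¹ range). Auxotroph growth is limited by *saturable
histidine transport*: uptake follows Monod kinetics in the external
concentration with the HIP1 transporter constant Km = 17 µM, and cells
carry an excess transport capacity ρ (default 8) relative to their growth
requirement, so

    µ_aux = µ_max · min(1, ρ·h/(Km + h)).

ρ = 1 recovers plain Monod growth — but plain Monod with Km = 17 µM
cannot reproduce the observed physiology: at 20 µM it would already halve
auxotroph growth (Δµ ≈ 0.18 h⁻¹ at *every* density), whereas the
experiments show near-zero fitness cost below OD 0.6. Excess transporter
capacity is the standard resolution: growth is unaffected until h falls
low enough that transport cannot cover demand, producing the sharp
transition. Consumption is `yield_q` µM per OD unit of growth for every
strain (prototrophs import available histidine in preference to
synthesizing it — this is what couples the residual concentration to total
density); at the held setpoint the flux balance gives
`h_ss = h_in − q·OD`. When demand would drive h negative, incoming
histidine is allocated to prototrophs first (they import only what is
available, growth unaffected) and auxotroph growth scales to the residual
flux — so for q·OD > h_in the auxotroph is fully growth-arrested. The
yield q = 28 µM/OD is a calibration (no measured value exists): it places
the arrest transition between OD 0.63 and 0.71 at 20 µM feed, giving
Δµ ≈ 0 below OD 0.6 and > 0.2 h⁻¹ at OD 0.8, and full arrest at every
setpoint ≥ 0.2 at 4 µM feed — the observed qualitative structure, which is
exactly what the simulator is asked to reproduce. No claim is made that q
or ρ are biologically measured values.

## Plate-reader protocol

Bookkeeping is pure conservation arithmetic on (volume, OD, antibiotic)
per well. Evaporation (true rate a state parameter, default 10 µL/h)
shrinks volume and concentrates solutes. Dilution trigger: median
blank-subtracted OD of the well group above threshold → add 100 µL media
(carrying each well's configured antibiotic concentration), mix, remove
`100 − E` µL with `E` = estimated evaporation since the last dilution —
volume returns exactly to nominal when the estimate matches the true
rate, and a rate mismatch accumulates linearly (both are tested). Removal
clamps at 0 with a warning when E ≥ 100 µL. After 10 h without dilution,
100 µL is added with no removal (the well is assumed nearly dry).
Treatments add 50 µL of dosed solution by conservation. OD cleaning
subtracts a cell-free blank and removes raw OD₆₀₀ readings > 3·10⁻³
within the first 2 h (an instrument artifact window; later readings are
kept). The trigger median is computed per configured well group (a plate row
in typical deployments). There is
deliberately no antibiotic pharmacodynamics: drug is tracked by
conservation only, and any growth response is a user-supplied function.

## Orchestrator

Instruments are in-process endpoints with a request/response contract
(status ok/error/unavailable, payload, timestamp) — the HTTP layer of a
deployed system is replaced by this contract with identical semantics, and
a thin HTTP adapter is an extension point, not part of this package.
The loop is discrete-time: advance every instrument exposing a `tick`
operation, then evaluate events (one-shot / periodic / on-data). Periodic
events fire at interval completions, never at t = 0, ties broken by
registration order. On-data cascades settle within the tick, each event
firing at most once per tick. Action steps may compute their parameters at
fire time (controller calls); the *concrete* parameters are logged, so the
JSON-lines log (ISO-8601 timestamps derived from the simulated clock plus
a sequence number) is complete: replaying the logged invocation sequence
against fresh instruments reproduces the final state bit-for-bit. An
error response aborts the remaining steps of that firing, is logged, and
the loop continues — the fail-safe behaviour an unattended overnight run
needs.

## Problem sizes used in the shipped benchmarks

Synthetic cytometry runs use 5 000–12 000 events (real acquisitions are
of the same order); fits use 3 series × 14 time points; closed-loop runs
are 10 h at hourly (light) or 2-h (ratio) cadence; statistical properties
use 200 seeded replicates. These sizes make every result exactly
reproducible from a seed while keeping the full suite fast.

## Known limitations

- The gating algorithm is this package's own design, validated against
  synthetic ground truth; deployed instruments use related but not
  identical rules, sharing the two named thresholds.
- The expression model ignores maturation delay, photobleaching, and
  cell-to-cell variability (it models the population median).
- The nutrient model's yield and transport capacity are calibrated, not
  measured; real Δµ(OD) values are not desk-reproducible, only the
  qualitative structure is claimed.
- Closed-loop tracking results are on a noise-free plant where model and
  plant coincide; real cells add process noise, measurement noise and
  model mismatch, so 2% tracking is an algorithmic property, not a
  biological prediction.
- No hardware drivers, no real network transport, no antibiotic kill
  model.
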