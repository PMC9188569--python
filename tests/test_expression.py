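"""Expression-model tests: exact integration, oracle equivalence, fitting,
and state estimation."""

import numpy as np
import pytest

from reacloop.expression import (
    ExpressionParams,
    ExpressionState,
    FitConfig,
    LightProgram,
    estimate_state,
    fit,
    simulate,
)

FIG_PARAMS = ExpressionParams(gamma_m=2.09, sigma=0.64, gamma_fp=0.475)


def onoff_program(pattern):
    """Full-ON/full-OFF blocks expressed as 30-min duty cycles."""
    duties = []
    for duration_h, on in pattern:
        duties += [1.0 if on else 0.0] * int(round(duration_h * 2))
    return LightProgram(tuple(duties))


def rk4_oracle(params, state0, light, t_end, dt=1e-4):
    """Brute-force explicit small-step integrator, aligned to light switches."""

    def deriv(t, y, L):
        m, fp = y
        return np.array(
            [params.sigma * L - params.gamma_m * m, params.k_m * m - params.gamma_fp * fp]
        )

    y = np.array([state0.mrna, state0.fp])
    t = state0.t
    for a, b, L in light.segments(t_stop=t_end):
        a, b = max(a, t), min(b, t_end)
        if b <= a:
            continue
        n = max(int(np.ceil((b - a) / dt)), 1)
        h = (b - a) / n
        for _ in range(n):
            k1 = deriv(t, y, L)
            k2 = deriv(t + h / 2, y + h / 2 * k1, L)
            k3 = deriv(t + h / 2, y + h / 2 * k2, L)
            k4 = deriv(t + h, y + h * k3, L)
            y = y + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += h
    return y


class TestSimulate:
    def test_dark_program_stays_at_zero(self):
        traj = simulate(
            FIG_PARAMS,
            ExpressionState(0, 0, 0),
            LightProgram((0.0,) * 10),
            np.linspace(0, 8, 50),
        )
        assert np.all(traj.mrna == 0) and np.all(traj.fp == 0)

    def test_protein_half_life_is_1_46_h(self):
        # Pure decay (sigma = 0): FP halves in ln2/gamma_fp = 1.46 h.
        p = ExpressionParams(gamma_m=2.09, sigma=0.0, gamma_fp=0.475)
        traj = simulate(p, ExpressionState(0.0, 1.0, 0.0), LightProgram(()), [1.46])
        assert traj.fp[0] == pytest.approx(0.5, abs=1e-3)

    def test_constant_light_reaches_sigma_over_gamma_fp(self):
        # With k_m = gamma_m the steady state under constant light is
        # sigma / gamma_fp (closed form).
        ss = FIG_PARAMS.sigma / FIG_PARAMS.gamma_fp
        traj = simulate(
            FIG_PARAMS, ExpressionState(0, 0, 0), LightProgram((1.0,) * 80), [40.0]
        )
        assert traj.fp[0] == pytest.approx(ss, abs=1e-6)

    def test_half_life_identities(self):
        # t_1/2 = ln2 / rate for both species, checked against simulate.
        p = ExpressionParams(gamma_m=2.0, sigma=0.0, gamma_fp=0.5, k_m=1e-9)
        traj = simulate(
            p, ExpressionState(1.0, 1.0, 0.0), LightProgram(()),
            [np.log(2) / 2.0, np.log(2) / 0.5],
        )
        assert traj.mrna[0] == pytest.approx(0.5, rel=1e-9)
        assert traj.fp[1] == pytest.approx(0.5, rel=1e-6)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_small_step_oracle(self, seed):
        rng = np.random.default_rng(seed)
        duties = tuple(rng.uniform(0, 1, size=6))
        program = LightProgram(duties, period_min=30.0)
        state0 = ExpressionState(rng.uniform(0, 0.3), rng.uniform(0, 1), 0.0)
        t_end = 3.5
        expected = rk4_oracle(FIG_PARAMS, state0, program, t_end, dt=1e-4)
        traj = simulate(FIG_PARAMS, state0, program, [t_end])
        assert traj.mrna[0] == pytest.approx(expected[0], rel=1e-6, abs=1e-12)
        assert traj.fp[0] == pytest.approx(expected[1], rel=1e-6, abs=1e-12)

    def test_superposition_fp_linear_in_sigma(self):
        program = LightProgram((0.7, 0.2, 1.0, 0.0, 0.5))
        times = np.linspace(0.1, 4, 17)
        base = simulate(
            ExpressionParams(2.0, 0.3, 0.5), ExpressionState(0, 0, 0), program, times
        ).fp
        scaled = simulate(
            ExpressionParams(2.0, 0.9, 0.5), ExpressionState(0, 0, 0), program, times
        ).fp
        np.testing.assert_allclose(scaled, 3.0 * base, rtol=1e-12)

    @pytest.mark.parametrize("seed", [3, 4])
    def test_monotone_in_duty_fractions(self, seed):
        rng = np.random.default_rng(seed)
        lo = rng.uniform(0, 0.6, size=8)
        hi = np.clip(lo + rng.uniform(0, 0.4, size=8), 0, 1)
        times = np.linspace(0.05, 5, 60)
        fp_lo = simulate(
            FIG_PARAMS, ExpressionState(0, 0, 0), LightProgram(tuple(lo)), times
        ).fp
        fp_hi = simulate(
            FIG_PARAMS, ExpressionState(0, 0, 0), LightProgram(tuple(hi)), times
        ).fp
        assert np.all(fp_hi >= fp_lo - 1e-12)

    def test_negative_initial_state_rejected(self):
        with pytest.raises(ValueError):
            ExpressionState(-0.1, 0.0, 0.0)


class TestFit:
    def make_dataset(self, params, programs, t_max=10.0, step=0.75):
        times = np.arange(0.0, t_max + 1e-9, step)
        return [
            (pr, times, simulate(params, ExpressionState(0, 0, 0), pr, times).fp)
            for pr in programs
        ]

    def test_recovers_generating_parameters(self):
        truth = ExpressionParams(gamma_m=1.0, sigma=0.5, gamma_fp=0.3)
        programs = [onoff_program([(2, 1), (6, 0)]), onoff_program([(1, 0), (4, 1), (3, 0)])]
        result = fit(self.make_dataset(truth, programs), FitConfig(n_starts=8))
        assert result.params.gamma_m == pytest.approx(1.0, rel=1e-4)
        assert result.params.sigma == pytest.approx(0.5, rel=1e-4)
        assert result.params.gamma_fp == pytest.approx(0.3, rel=1e-4)

    def test_recovers_characterization_parameters(self):
        # Three ON-OFF induction profiles, sampled at the 45-min cadence.
        programs = [
            onoff_program([(2, 1), (8, 0)]),
            onoff_program([(4, 1), (2, 0), (2, 1), (2, 0)]),
            onoff_program([(1, 0), (5, 1), (4, 0)]),
        ]
        result = fit(self.make_dataset(FIG_PARAMS, programs))
        assert result.params.gamma_m == pytest.approx(2.09, rel=5e-4)
        assert result.params.sigma == pytest.approx(0.64, rel=5e-4)
        assert result.params.gamma_fp == pytest.approx(0.475, rel=5e-4)

    def test_all_dark_data_flags_sigma_unidentifiable(self):
        programs = [onoff_program([(6, 0)])]
        data = self.make_dataset(ExpressionParams(1.0, 0.5, 0.3), programs, t_max=6)
        result = fit(data, FitConfig(n_starts=4))
        assert result.cost == pytest.approx(0.0, abs=1e-20)
        assert "sigma" in result.unidentifiable
        assert result.params.sigma == pytest.approx(1e-4)  # pinned to lower bound

    def test_noisy_fit_median_error_below_10_percent(self):
        # 5% multiplicative noise on the three-program characterization
        # design; median worst-parameter relative error over 20 replicates.
        programs = [
            onoff_program([(2, 1), (8, 0)]),
            onoff_program([(4, 1), (2, 0), (2, 1), (2, 0)]),
            onoff_program([(1, 0), (5, 1), (4, 0)]),
        ]
        clean = self.make_dataset(FIG_PARAMS, programs)
        truth = np.array([2.09, 0.64, 0.475])
        rng = np.random.default_rng(0)
        errors = []
        for _ in range(20):
            noisy = [
                (pr, t, y * rng.normal(1.0, 0.05, size=y.shape)) for pr, t, y in clean
            ]
            res = fit(noisy, FitConfig(n_starts=4, seed=1))
            fitted = np.array([res.params.gamma_m, res.params.sigma, res.params.gamma_fp])
            errors.append(np.abs(fitted / truth - 1.0).max())
        assert np.median(errors) < 0.10


class TestEstimateState:
    def test_all_dark_zero_measurement(self):
        state, warnings = estimate_state(
            0.0, LightProgram(()), FIG_PARAMS, t_sample=5.0, delay=0.0
        )
        assert state.mrna == 0.0 and state.fp == 0.0
        assert not warnings

    def test_long_light_history_gives_mrna_steady_state(self):
        program = LightProgram((1.0,) * 80)  # 40 h of constant light
        state, _ = estimate_state(
            1.0, program, FIG_PARAMS, t_sample=40.0, delay=0.0
        )
        assert state.mrna == pytest.approx(FIG_PARAMS.sigma / FIG_PARAMS.gamma_m, abs=1e-6)

    def test_delay_advance_consistent_with_simulate(self):
        program = LightProgram((0.8, 0.3, 1.0, 0.2, 0.6, 0.9))
        delay = 0.25
        est, _ = estimate_state(0.4, program, FIG_PARAMS, t_sample=2.0, delay=delay)
        pre, _ = estimate_state(0.4, program, FIG_PARAMS, t_sample=2.0, delay=0.0)
        direct = simulate(FIG_PARAMS, pre, program, [2.0 + delay]).final
        assert est.mrna == pytest.approx(direct.mrna, rel=1e-12)
        assert est.fp == pytest.approx(direct.fp, rel=1e-12)

    def test_negative_measurement_clipped_with_warning(self):
        state, warnings = estimate_state(
            -0.2, LightProgram(()), FIG_PARAMS, t_sample=1.0
        )
        assert state.fp == 0.0
        assert warnings
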