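import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad

from facelearn.ddm import (
    CELLS,
    ContrastSummary,
    DDMParams,
    contrast_drift_congruency,
    contrast_expression,
    ddm_log_likelihood,
    prob_upper,
    sample_first_passage,
    simulate_ddm,
    wiener_fpt_density,
)


def make_params(v=1.0, a=2.0, z=0.5, t0=0.3):
    return DDMParams(
        v={c: v for c in CELLS}, a={c: a for c in CELLS},
        z={"smile": z, "frown": z}, t0=t0,
    )


class TestDensity:
    def test_symmetry_no_drift(self):
        t = np.linspace(0.05, 6, 60)
        up = wiener_fpt_density(t, 0.0, 1.5, 0.5, "upper")
        lo = wiener_fpt_density(t, 0.0, 1.5, 0.5, "lower")
        np.testing.assert_allclose(up, lo, atol=1e-12)

    @pytest.mark.parametrize("v,a,z", [(0.5, 1.0, 0.5), (-1.0, 2.0, 0.3), (2.0, 0.8, 0.7)])
    def test_normalization_by_quadrature(self, v, a, z):
        total = sum(
            quad(lambda t: wiener_fpt_density(t, v, a, z, b), 1e-9, 60, limit=200)[0]
            for b in ("upper", "lower")
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize("v", [-1.5, -0.5, 0.5, 1.5])
    @pytest.mark.parametrize("z", [0.2, 0.5, 0.8])
    def test_choice_probability_closed_form(self, v, z):
        a = 1.5
        p_quad = quad(
            lambda t: wiener_fpt_density(t, v, a, z, "upper"), 1e-9, 80, limit=300
        )[0]
        assert p_quad == pytest.approx(prob_upper(v, a, z), abs=1e-3)

    def test_zero_drift_choice_probability_is_z(self):
        assert prob_upper(0.0, 2.0, 0.3) == pytest.approx(0.3)

    def test_reflection_identity_pointwise(self):
        t = np.linspace(0.01, 8, 200)
        for v, a, z in [(1.3, 1.7, 0.4), (-0.8, 2.5, 0.65), (0.0, 1.0, 0.2)]:
            lower = wiener_fpt_density(t, v, a, z, "lower")
            upper_reflected = wiener_fpt_density(t, -v, a, 1 - z, "upper")
            np.testing.assert_allclose(lower, upper_reflected, atol=1e-10)

    def test_series_regimes_agree(self):
        # small-time and large-time expansions must agree in the crossover
        # region: evaluate at two tolerances (changing the switch point)
        t = np.geomspace(0.01, 10, 100)
        d1 = wiener_fpt_density(t, 1.0, 2.0, 0.4, "lower", tol=1e-7)
        d2 = wiener_fpt_density(t, 1.0, 2.0, 0.4, "lower", tol=1e-12)
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            wiener_fpt_density(0.0, 1.0, 1.0, 0.5)
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, 1.0, -1.0, 0.5)
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, 1.0, 1.0, 1.5)
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, np.inf, 1.0, 0.5)
        with pytest.raises(ValueError):
            wiener_fpt_density(1.0, 1.0, 1.0, 0.5, boundary="sideways")


class TestSimulator:
    def test_symmetric_choice_rate(self):
        sim = simulate_ddm(0.0, 2.0, 0.5, 0.0, n=20_000, seed=1, dt=1e-3)
        p = (sim["boundary"] == "upper_smile").mean()
        assert p == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 20_000))

    def test_choice_rate_matches_closed_form(self):
        v, a, z = 1.0, 2.0, 0.5
        sim = simulate_ddm(v, a, z, 0.0, n=20_000, seed=2, dt=1e-3)
        p_true = prob_upper(v, a, z)
        se = np.sqrt(p_true * (1 - p_true) / 20_000)
        # Euler discretization at dt=1e-3 adds a small bias on top of MC error
        assert (sim["boundary"] == "upper_smile").mean() == pytest.approx(
            p_true, abs=3 * se + 0.01
        )

    def test_t0_shifts_rts(self):
        sim = simulate_ddm(1.0, 1.0, 0.5, 0.5, n=200, seed=3, dt=1e-3)
        assert (sim["rt_s"] > 0.5).all()

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_ddm(1.0, 1.0, 0.5, 0.0, n=0, seed=1)
        with pytest.raises(ValueError):
            simulate_ddm(1.0, 1.0, 0.5, 0.0, n=10, seed=1, dt=0.0)

    def test_nontermination_flagged(self):
        # near-zero drift, huge boundary, tiny horizon: walks get censored
        sim = simulate_ddm(0.0, 50.0, 0.5, 0.0, n=50, seed=4, dt=1e-3, horizon_s=0.5)
        assert sim.attrs["n_censored"] + len(sim) == 50
        assert sim.attrs["n_censored"] > 0


class TestInverseCdfSampler:
    def test_choice_proportions_match_closed_form(self, rng):
        v, a, z = 0.8, 1.6, 0.4
        rts, is_up = sample_first_passage(v, a, z, 0.2, n=20_000, rng=rng)
        p = prob_upper(v, a, z)
        assert is_up.mean() == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / 20_000))
        assert (rts > 0.2).all()

    def test_conditional_boundary(self, rng):
        rts, is_up = sample_first_passage(1.0, 2.0, 0.5, 0.0, n=100, rng=rng,
                                          boundary="lower")
        assert not is_up.any()

    def test_rt_distribution_matches_density(self, rng):
        from scipy import stats
        from scipy.integrate import cumulative_trapezoid

        v, a, z = 1.0, 2.0, 0.5
        rts, _ = sample_first_passage(v, a, z, 0.0, n=20_000, rng=rng)
        t = np.linspace(1e-4, 12, 6000)
        dens = wiener_fpt_density(t, v, a, z, "upper") + wiener_fpt_density(
            t, v, a, z, "lower"
        )
        cdf = cumulative_trapezoid(dens, t, initial=0)
        cdf /= cdf[-1]
        ks = stats.ks_1samp(rts, lambda x: np.interp(x, t, cdf))
        assert ks.statistic < 0.02


class TestLikelihood:
    def _obs(self, rt, response, target="smile", required="smile"):
        return pd.DataFrame(
            {
                "rt_s": rt,
                "response": response,
                "target_expression": target,
                "required_response": required,
            }
        )

    def test_symmetric_params_equal_boundaries(self):
        params = make_params(v=0.0, z=0.5, t0=0.1)
        up = ddm_log_likelihood(self._obs([1.0], ["smile"]), params)
        lo = ddm_log_likelihood(self._obs([1.0], ["frown"]), params)
        assert up == pytest.approx(lo, abs=1e-12)

    def test_rt_below_t0_gives_minus_inf(self):
        params = make_params(t0=0.5)
        assert ddm_log_likelihood(self._obs([0.4], ["smile"]), params) == -np.inf

    def test_reflection_identity_on_dataset(self, rng):
        v, a, z, t0 = 0.9, 1.8, 0.35, 0.2
        rts, is_up = sample_first_passage(v, a, z, t0, n=400, rng=rng)
        resp = np.where(is_up, "smile", "frown")
        obs = self._obs(rts, resp)
        p1 = DDMParams(
            v={c: v for c in CELLS}, a={c: a for c in CELLS},
            z={"smile": z, "frown": z}, t0=t0,
        )
        # swap all responses, negate v, mirror z
        obs_swapped = obs.copy()
        obs_swapped["response"] = np.where(resp == "smile", "frown", "smile")
        p2 = DDMParams(
            v={c: -v for c in CELLS}, a={c: a for c in CELLS},
            z={"smile": 1 - z, "frown": 1 - z}, t0=t0,
        )
        assert ddm_log_likelihood(obs, p1) == pytest.approx(
            ddm_log_likelihood(obs_swapped, p2), rel=1e-12
        )

    def test_grid_search_recovers_drift(self, rng):
        v_true, a, z, t0 = 1.2, 1.8, 0.5, 0.3
        rts, is_up = sample_first_passage(v_true, a, z, t0, n=5000, rng=rng)
        obs = self._obs(rts, np.where(is_up, "smile", "frown"))
        grid = np.arange(0.2, 2.3, 0.1)
        lls = [
            ddm_log_likelihood(obs, make_params(v=v, a=a, z=z, t0=t0)) for v in grid
        ]
        assert grid[int(np.argmax(lls))] == pytest.approx(v_true, abs=0.15)

    def test_param_validation(self):
        with pytest.raises(ValueError):
            make_params(a=-1.0)
        with pytest.raises(ValueError):
            make_params(z=1.0)
        with pytest.raises(ValueError):
            make_params(t0=-0.1)
        with pytest.raises(ValueError):
            make_params(v=np.inf)


class TestContrasts:
    def _draws(self, rng, n=4000):
        return rng.standard_normal((n, 4))

    def test_equal_magnitudes_give_zero(self):
        v = np.tile([1.0, -1.0, 1.0, -1.0], (1000, 1))
        out = contrast_drift_congruency(v)
        assert out["sum"].mean == 0.0
        assert out["mean"].mean == 0.0

    def test_injected_delta_recovered(self, rng):
        delta = 0.4
        base = 1.0 + 0.05 * rng.standard_normal((5000, 4))
        v = base.copy()
        v[:, :2] += delta  # congruent cells larger in magnitude
        out = contrast_drift_congruency(v)
        assert out["sum"].mean == pytest.approx(2 * delta, abs=0.01)
        assert out["mean"].mean == pytest.approx(delta, abs=0.005)

    def test_symmetric_posterior_centred_at_zero(self, rng):
        draws = {"v": 1.0 + 0.3 * rng.standard_normal((8000, 4))}
        out = contrast_expression(draws, "v_abs")
        assert out.mean == pytest.approx(0.0, abs=0.02)
        assert out.fraction_positive == pytest.approx(0.5, abs=0.05)

    def test_bias_contrast_shift(self, rng):
        z = 0.5 + 0.01 * rng.standard_normal((5000, 2))
        z[:, 0] += 0.03
        out = contrast_expression({"z": z}, "z")
        assert out.mean == pytest.approx(0.03, abs=0.002)

    def test_boundary_contrast_shift(self, rng):
        a = 2.0 + 0.02 * rng.standard_normal((5000, 4))
        a[:, [1, 3]] += 0.22  # frown-target cells higher
        out = contrast_expression({"a": a}, "a")
        assert out.mean == pytest.approx(-0.22, abs=0.005)

    def test_congruency_contrast_invariant_to_expression_relabel(self, rng):
        v = self._draws(rng)
        # smile<->frown relabel swaps cells within congruency levels
        relabelled = v[:, [1, 0, 3, 2]]
        a = contrast_drift_congruency(v)["sum"]
        b = contrast_drift_congruency(relabelled)["sum"]
        assert a.mean == pytest.approx(b.mean)
        assert a.cri_95 == pytest.approx(b.cri_95)

    def test_summary_format(self, rng):
        out = ContrastSummary.from_draws(rng.standard_normal(1000) + 0.77)
        d = out.to_dict()
        assert set(d) == {"mean", "cri_95", "fraction_positive"}
        assert d["cri_95"][0] < d["cri_95"][1]
        with pytest.raises(ValueError):
            ContrastSummary(mean=0.0, cri_95=(1.0, -1.0), fraction_positive=0.5)

    def test_unknown_parameter_rejected(self, rng):
        with pytest.raises(ValueError):
            contrast_expression({"v": self._draws(rng)}, "t0")
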