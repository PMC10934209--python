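import numpy as np
import pandas as pd
import pytest

import pahrisk as pr
from pahrisk.exposure import DistributionSpec, lognormal_from_moments
from pahrisk.montecarlo import (
    fit_distribution,
    percentiles,
    sensitivity,
    simulate_ilcr,
)

from conftest import make_factors

Z90 = 1.2815515655446004


class TestPercentiles:
    def test_hand_example(self):
        # linear interpolation on {1..100}
        result = percentiles(np.arange(1, 101), [10, 50, 90])
        assert result[10] == pytest.approx(10.9)
        assert result[50] == pytest.approx(50.5)
        assert result[90] == pytest.approx(90.1)

    def test_single_draw(self):
        result = percentiles([7.0], [10, 50, 90])
        assert set(result.values()) == {7.0}

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        a = percentiles(x, [10, 50, 90])
        b = percentiles(rng.permutation(x), [10, 50, 90])
        assert a == b

    def test_monotone_in_probs(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(size=1000)
        res = percentiles(x, [10, 50, 90])
        assert res[10] <= res[50] <= res[90]

    def test_probs_out_of_range(self):
        with pytest.raises(ValueError):
            percentiles([1.0, 2.0], [10, 105])

    def test_empty_draws(self):
        with pytest.raises(ValueError):
            percentiles([], [50])


class TestFitDistribution:
    def test_lognormal_selected_on_lognormal_data(self):
        rng = np.random.default_rng(42)
        draws = rng.lognormal(mean=-11.92, sigma=1.48, size=10_000)
        fits = fit_distribution(draws, ["normal", "lognormal", "uniform"])
        selected = [f for f in fits if f.selected]
        assert len(selected) == 1
        assert selected[0].family == "lognormal"
        assert selected[0].params["location"] == pytest.approx(-11.92, abs=0.05)
        assert selected[0].params["shape"] == pytest.approx(1.48, abs=0.05)

    def test_statistics_nonnegative(self):
        rng = np.random.default_rng(3)
        fits = fit_distribution(rng.uniform(1, 2, size=1000))
        assert all(f.ad_stat >= 0 and f.chi2_stat >= 0 for f in fits)

    def test_constant_samples_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_distribution(np.ones(100))

    def test_support_violation_is_explicit(self):
        rng = np.random.default_rng(4)
        samples = rng.normal(0.0, 1.0, size=200)  # contains negatives
        with pytest.raises(ValueError, match="admissible"):
            fit_distribution(samples, ["lognormal"])

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="20"):
            fit_distribution([1.0, 2.0, 3.0])

    def test_no_candidates(self):
        with pytest.raises(ValueError, match="candidate"):
            fit_distribution(np.arange(100.0), [])

    def test_family_recovery_rate(self):
        # parameter/family recovery across seeded repetitions
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            draws = rng.lognormal(mean=-11.92, sigma=1.48, size=10_000)
            fits = fit_distribution(draws, ["normal", "lognormal", "uniform"])
            best = next(f for f in fits if f.selected)
            hits += best.family == "lognormal"
        assert hits >= 95


class TestSensitivity:
    def test_single_stochastic_input(self):
        rng = np.random.default_rng(0)
        x = rng.lognormal(size=1000)
        inputs = pd.DataFrame({"teq": x, "bw": np.full(1000, 60.0)})
        shares = sensitivity(inputs, x * 2.0)
        assert shares["teq"] == pytest.approx(100.0)
        assert shares["bw"] == 0.0

    def test_abs_shares_sum_to_100(self):
        rng = np.random.default_rng(1)
        inputs = pd.DataFrame(
            {
                "a": rng.lognormal(0, 1.5, 2000),
                "b": rng.lognormal(0, 0.1, 2000),
                "c": rng.lognormal(0, 0.1, 2000),
            }
        )
        out = inputs["a"] * inputs["b"] / inputs["c"]
        shares = sensitivity(inputs, out)
        assert sum(abs(v) for v in shares.values()) == pytest.approx(100.0)

    def test_dominant_input_largest_and_denominator_negative(self):
        # brute-force qualitative check: CV 1.5 vs 0.1 vs 0.1
        rng = np.random.default_rng(2)
        n = 5000
        teq = rng.lognormal(0, 1.5, n)
        dr = rng.lognormal(0, 0.1, n)
        bw = rng.lognormal(0, 0.1, n)
        inputs = pd.DataFrame({"teq": teq, "dr": dr, "bw": bw})
        shares = sensitivity(inputs, teq * dr / bw)
        assert shares["teq"] > abs(shares["dr"])
        assert shares["teq"] > abs(shares["bw"])
        assert shares["teq"] > 0
        assert shares["bw"] < 0

    def test_duplicated_inputs_share_equally(self):
        rng = np.random.default_rng(3)
        x = rng.lognormal(size=2000)
        inputs = pd.DataFrame({"a": x, "b": x})
        shares = sensitivity(inputs, x**2)
        assert shares["a"] == pytest.approx(shares["b"])
        assert shares["a"] == pytest.approx(50.0, abs=1e-6)

    def test_monotone_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        a = rng.lognormal(0, 1, 1000)
        b = rng.lognormal(0, 0.5, 1000)
        out = a * b
        s1 = sensitivity(pd.DataFrame({"a": a, "b": b}), out)
        s2 = sensitivity(pd.DataFrame({"a": np.exp(a), "b": b * 1e6}), out)
        assert s1["a"] == pytest.approx(s2["a"])
        assert s1["b"] == pytest.approx(s2["b"])

    def test_constant_output_rejected(self):
        inputs = pd.DataFrame({"a": np.arange(20.0)})
        with pytest.raises(ValueError, match="constant"):
            sensitivity(inputs, np.ones(20))

    def test_too_few_draws(self):
        inputs = pd.DataFrame({"a": np.arange(5.0)})
        with pytest.raises(ValueError):
            sensitivity(inputs, np.arange(5.0))


class TestSimulateIlcr:
    def test_all_point_collapses(self, point_factors):
        result = simulate_ilcr(2.5e-5, point_factors, n=100, seed=9)
        assert result.sd == 0.0
        assert np.all(result.draws == result.draws[0])
        for v in result.percentiles.values():
            assert v == pytest.approx(2.5e-5)
        assert result.fitted is None
        assert result.sensitivity == {}

    def test_seed_determinism(self, point_factors):
        spec = DistributionSpec("lognormal", {"mean": 2e-5, "sd": 5.66e-5})
        a = simulate_ilcr(spec, point_factors, n=2000, seed=11)
        b = simulate_ilcr(spec, point_factors, n=2000, seed=11)
        c = simulate_ilcr(spec, point_factors, n=2000, seed=12)
        assert np.array_equal(a.draws, b.draws)
        assert a.percentiles == b.percentiles
        assert not np.array_equal(a.draws, c.draws)

    def test_seed_required(self, point_factors):
        with pytest.raises(ValueError, match="seed"):
            simulate_ilcr(1e-5, point_factors, n=100)

    def test_n_validation(self, point_factors):
        with pytest.raises(ValueError):
            simulate_ilcr(1e-5, point_factors, n=0, seed=1)

    def test_q90_matches_closed_form_within_bootstrap_se(self, point_factors):
        mean, sd = 2.00e-5, 5.66e-5
        spec = DistributionSpec("lognormal", {"mean": mean, "sd": sd})
        result = simulate_ilcr(spec, point_factors, n=10_000, seed=1)
        location, shape = lognormal_from_moments(mean, sd)
        closed = float(np.exp(location + Z90 * shape))
        # bootstrap SE of the sampled 90th percentile
        rng = np.random.default_rng(123)
        boot = [
            np.percentile(rng.choice(result.draws, result.n, replace=True), 90)
            for _ in range(200)
        ]
        se = float(np.std(boot))
        assert abs(result.percentiles[90.0] - closed) < 3 * se

    def test_large_n_convergence(self, point_factors):
        spec = DistributionSpec("lognormal", {"mean": 2.00e-5, "sd": 5.66e-5})
        result = simulate_ilcr(spec, point_factors, n=1_000_000, seed=5)
        location, shape = lognormal_from_moments(2.00e-5, 5.66e-5)
        for prob, z in ((10.0, -Z90), (50.0, 0.0), (90.0, Z90)):
            closed = float(np.exp(location + z * shape))
            assert result.percentiles[prob] == pytest.approx(closed, rel=5e-3)

    def test_output_lognormal_fit_recorded(self, point_factors):
        spec = DistributionSpec("lognormal", {"mean": 2e-5, "sd": 5.66e-5})
        result = simulate_ilcr(spec, point_factors, n=10_000, seed=2)
        assert result.fitted is not None
        assert result.fitted.family == "lognormal"
        location, shape = lognormal_from_moments(2e-5, 5.66e-5)
        assert result.fitted.params["location"] == pytest.approx(location, abs=0.05)
        assert result.fitted.params["shape"] == pytest.approx(shape, abs=0.05)

    def test_mixed_stochastic_sensitivity(self):
        factors = make_factors(
            dr=pr.DistributionSpec("lognormal", {"mean": 5.0, "sd": 0.5}),
            bw=pr.DistributionSpec("normal", {"mean": 60.0, "sd": 6.0},),
        )
        teq_spec = DistributionSpec("lognormal", {"mean": 1e-4, "sd": 1.5e-4})
        result = simulate_ilcr(teq_spec, factors, n=10_000, seed=7)
        shares = result.sensitivity
        assert sum(abs(v) for v in shares.values()) == pytest.approx(100.0)
        # teq has by far the largest CV -> dominant positive share
        assert shares["teq"] == max(shares.values())
        assert shares["teq"] > 50.0
        assert shares["bw"] < 0.0
        assert shares["ef"] == 0.0  # point input excluded

    def test_percentile_ordering(self, point_factors):
        spec = DistributionSpec("lognormal", {"mean": 1e-5, "sd": 2e-5})
        r = simulate_ilcr(spec, point_factors, n=5000, seed=3)
        assert r.percentiles[10.0] <= r.percentiles[50.0] <= r.percentiles[90.0]
        assert (r.draws >= 0).all()
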