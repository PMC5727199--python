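"""Barcode probability model, collision expectation and tumor-number solve."""

import numpy as np
import pandas as pd
import pytest

from tubahdr.calling import TumorCall
from tubahdr.collisions import (
    correct_sizes, exclude_frequent, expected_collisions, fit_frequencies,
    solve_total_tumors,
)
from tubahdr.design import ConfigError, InvalidInputError


class TestFitFrequencies:
    def test_uniform_pool_gives_equal_probabilities(self, design, uniform_pool):
        model = fit_frequencies(uniform_pool, design)
        assert len(model.p) == 24_576
        assert np.allclose(model.p.to_numpy(), 1 / 24_576)

    def test_free_parameter_count(self, design, pool):
        assert fit_frequencies(pool, design).free_parameters == 21

    def test_probabilities_sum_to_one(self, design, pool):
        model = fit_frequencies(pool, design)
        assert model.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_product_structure(self, design, pool):
        # p_i equals the product of fitted per-position frequencies
        # (per-position frequencies each sum to 1, so the products already
        # sum to 1 over the space and renormalization is a no-op)
        model = fit_frequencies(pool, design)
        for bc in (model.p.index[137], model.p.index[-1]):
            manual = np.prod([model.frequencies[b][n] for b, n in enumerate(bc)])
            assert model.p[bc] == pytest.approx(manual, rel=1e-9)


class TestExcludeFrequent:
    def test_fraction_zero_is_identity(self, design, pool):
        model = fit_frequencies(pool, design)
        out = exclude_frequent(model, pool.barcode_totals(), 0.0)
        assert out.p.equals(model.p)

    def test_exactly_ten_percent_excluded(self, design, uniform_pool):
        model = fit_frequencies(uniform_pool, design)
        observed = pd.Series(
            np.arange(100, 0, -1),
            index=[design.barcode_from_index(i) for i in range(100)])
        out = exclude_frequent(model, observed, 0.10)
        assert len(out.excluded) == 10
        # highest observed/p ratios go first
        assert set(out.excluded) == {design.barcode_from_index(i) for i in range(10)}

    def test_ties_broken_lexicographically(self, design, uniform_pool):
        model = fit_frequencies(uniform_pool, design)
        barcodes = sorted(design.barcode_from_index(i) for i in range(20))
        observed = pd.Series(5, index=barcodes)      # all tied
        out = exclude_frequent(model, observed, 0.10)
        assert sorted(out.excluded) == barcodes[:2]

    def test_renormalized_to_one(self, design, pool):
        model = fit_frequencies(pool, design)
        out = exclude_frequent(model, pool.barcode_totals(), 0.10)
        assert out.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert len(out.p) < len(model.p)

    def test_invalid_fraction(self, design, pool):
        model = fit_frequencies(pool, design)
        with pytest.raises(ConfigError):
            exclude_frequent(model, pool.barcode_totals(), 1.0)


class TestExpectedCollisions:
    def test_single_tumor_cannot_collide(self):
        for p in (0.0, 1e-4, 0.5, 1.0):
            assert expected_collisions(p, 1) == pytest.approx(0.0)

    def test_certain_barcode_three_tumors(self):
        assert expected_collisions(1.0, 3) == pytest.approx(2.0)

    def test_moderate_probability_closed_form(self):
        # C = Np + (1-p)^N - 1 = 0.999^1000 at p=1/1000, N=1000
        assert expected_collisions(1e-3, 1000) == pytest.approx(0.999 ** 1000)
        assert expected_collisions(1e-3, 1000) == pytest.approx(0.3677, abs=1e-4)

    def test_monte_carlo_multinomial_oracle(self, rng):
        """Mean collisions per barcode from brute-force multinomial draws."""
        n_tumors, n_barcodes, reps = 1000, 1000, 20_000
        p = np.full(n_barcodes, 1 / n_barcodes)
        excess = np.zeros(n_barcodes)
        sq = np.zeros(n_barcodes)
        for lo in range(0, reps, 2000):
            counts = rng.multinomial(n_tumors, p, size=2000)
            e = np.where(counts > 0, counts - 1, 0)
            excess += e.sum(axis=0)
            sq += (e.astype(float) ** 2).sum(axis=0)
        mc_mean = excess / reps
        expected = expected_collisions(p, n_tumors)
        var = sq / reps - mc_mean ** 2
        se = np.sqrt(var / reps)
        assert (np.abs(mc_mean - expected) <= 3 * se + 1e-12).mean() > 0.99
        # and the total matches tightly
        total_se = np.sqrt(var.sum() / reps)
        assert mc_mean.sum() == pytest.approx(expected.sum(),
                                              abs=3 * total_se)


class TestSolveTotalTumors:
    def test_zero_observed(self, design, uniform_pool):
        model = fit_frequencies(uniform_pool, design)
        est = solve_total_tumors(0, model)
        assert est.n_total == 0.0 and est.total_expected_collisions == 0.0

    def test_recovers_known_total_from_closed_form(self, design, uniform_pool):
        # expected distinct barcodes B(1 - (1-1/B)^N*) for N* = 3000
        model = fit_frequencies(uniform_pool, design)
        B = len(model.p)
        n_star = 3000
        n_obs = B * (1 - (1 - 1 / B) ** n_star)
        est = solve_total_tumors(n_obs, model)
        assert est.n_total == pytest.approx(n_star, abs=1e-3)

    def test_solver_consistency(self, design, pool):
        model = fit_frequencies(pool, design)
        est = solve_total_tumors(750, model)
        assert est.n_total - est.total_expected_collisions == pytest.approx(
            750, abs=1e-6)
        assert est.n_total >= est.n_observed

    def test_negligible_probabilities_limit(self):
        from tubahdr.collisions import BarcodeFrequencyModel
        from tubahdr.design import BarcodeDesign

        d = BarcodeDesign()
        p = pd.Series(np.full(10 ** 6, 1e-6),
                      index=[f"b{i}" for i in range(10 ** 6)])
        model = BarcodeFrequencyModel(d, [], p)
        est = solve_total_tumors(50, model)
        assert est.n_total - 50 < 0.01

    def test_observed_exceeding_space_errors(self, design, uniform_pool):
        model = fit_frequencies(uniform_pool, design)
        with pytest.raises(InvalidInputError):
            solve_total_tumors(30_000, model)

    def test_realized_collisions_match_model_across_scales(self, design, pool):
        """Multinomial simulations at N in {300, 3000} with the skewed
        fitted frequencies: mean realized collisions inside the central
        95% Monte-Carlo band of sum(C_i) at the true N."""
        model = fit_frequencies(pool, design)
        p = model.p.to_numpy()
        rng = np.random.default_rng(202)
        for n_true in (300, 3000):
            realized = []
            for lo in range(0, 200, 50):
                counts = rng.multinomial(n_true, p, size=50)
                realized.extend((n_true - (counts > 0).sum(axis=1)).tolist())
            expected = expected_collisions(p, n_true).sum()
            lo_q, hi_q = np.quantile(realized, [0.025, 0.975])
            assert lo_q <= expected <= hi_q
            se = np.std(realized, ddof=1) / np.sqrt(len(realized))
            assert np.mean(realized) == pytest.approx(expected, abs=3 * se)


class TestCorrectSizes:
    def _estimate(self, design, uniform_pool, n_obs=100):
        model = fit_frequencies(uniform_pool, design)
        return solve_total_tumors(n_obs, model)

    def test_zero_collision_leaves_size(self, design, uniform_pool):
        est = self._estimate(design, uniform_pool)
        est.c[:] = 0.0
        call = TumorCall("s", "G12D", est.c.index[0], 100, cells=4e5)
        kept, _ = correct_sizes([call], est)
        assert kept[0].cells == pytest.approx(4e5)

    def test_collision_of_one_halves_size(self, design, uniform_pool):
        est = self._estimate(design, uniform_pool)
        bc = est.c.index[5]
        est.c[bc] = 1.0
        call = TumorCall("s", "G12D", bc, 100, cells=4e5)
        kept, _ = correct_sizes([call], est)
        assert kept[0].cells == pytest.approx(2e5)
        assert kept[0].collision_factor == pytest.approx(2.0)

    def test_total_size_never_increases(self, design, pool, rng):
        model = fit_frequencies(pool, design)
        est = solve_total_tumors(500, model)
        barcodes = rng.choice(est.c.index.to_numpy(), size=50, replace=False)
        calls = [TumorCall("s", "G12D", bc, 10, cells=float(c))
                 for bc, c in zip(barcodes, rng.lognormal(12, 1, 50))]
        total_before = sum(c.cells for c in calls)
        kept, dropped = correct_sizes(calls, est)
        assert not dropped
        assert sum(c.cells for c in kept) <= total_before
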