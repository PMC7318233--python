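"""Tetrachoric estimator: contingency tables, ML oracle equivalence, repair."""

import warnings

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.tetrachoric import table_loglik


def grid_search_rho(table, step=1e-3):
    """Independent oracle: brute-force likelihood grid over rho."""
    grid = np.arange(-0.999, 0.999 + step / 2, step)
    lls = [table_loglik(table, r) for r in grid]
    return float(grid[int(np.argmax(lls))])


class TestPairTable:
    def test_enumeration(self):
        assert sn.pair_table([1, 1, 0, 0], [1, 0, 1, 0]) == (1, 1, 1, 1)

    def test_identical_vectors_have_no_discordance(self):
        x = np.array([1, 0, 1, 1, 0])
        a, b, c, d = sn.pair_table(x, x)
        assert (b, c) == (0, 0)
        assert a + d == len(x)

    def test_complementary_vectors_have_no_concordance(self):
        x = np.array([1, 0, 1, 0])
        a, b, c, d = sn.pair_table(x, 1 - x)
        assert (a, d) == (0, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            sn.pair_table([1, 0], [1, 0, 1])


class TestEstimator:
    def test_independence_table(self):
        rho, t1, t2 = sn.estimate_tetrachoric((25, 25, 25, 25))
        assert rho == pytest.approx(0.0, abs=1e-6)
        assert t1 == pytest.approx(0.0, abs=1e-12)
        assert t2 == pytest.approx(0.0, abs=1e-12)

    def test_perfect_agreement_with_zero_cell_correction(self):
        rho, _, _ = sn.estimate_tetrachoric((50, 0, 0, 50))
        assert rho > 0.95
        assert rho == pytest.approx(grid_search_rho((50, 0, 0, 50), 1e-4), abs=1e-3)

    def test_matches_grid_oracle(self):
        rho, _, _ = sn.estimate_tetrachoric((40, 10, 10, 40))
        assert rho == pytest.approx(grid_search_rho((40, 10, 10, 40), 1e-4), abs=1e-3)

    def test_sign_follows_odds_ratio(self, rng):
        """rho > 0 iff ad/bc > 1 (after the continuity correction)."""
        for _ in range(40):
            t = rng.integers(0, 40, size=4)
            ta, tb, tc, td = (int(v) for v in t)
            if min(ta + tb, tc + td, ta + tc, tb + td) == 0:
                continue  # degenerate margin: rho not identified
            a, b, c, d = (v + 0.5 for v in t)  # corrected counts
            odds = (a * d) / (b * c)
            if abs(np.log(odds)) < 1e-3:
                continue
            rho, *_ = sn.estimate_tetrachoric(tuple(int(v) for v in t))
            assert (rho > 0) == (odds > 1)

    def test_degenerate_margin_flagged(self):
        with pytest.warns(UserWarning, match="degenerate"):
            rho, t1, t2 = sn.estimate_tetrachoric((10, 0, 5, 0))
        assert rho == 0.0

    def test_consistency_on_simulated_data(self):
        """Estimate converges to the latent correlation (bias < 0.02 at n=50k)."""
        for target in (-0.5, 0.0, 0.3, 0.7):
            R = np.array([[1.0, target], [target, 1.0]])
            spec = sn.GeneratorSpec(
                n=50_000,
                prevalences=[0.6, 0.35],
                latent_correlation=R,
                seed=13,
                item_codes=("A", "B"),
            )
            m = sn.generate(spec)
            rho, *_ = sn.estimate_tetrachoric(sn.pair_table(m.values[:, 0], m.values[:, 1]))
            assert abs(rho - target) < 0.02


class TestCorrelationMatrix:
    def test_two_items_equal_scalar_estimate(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 2, size=(300, 2))
        est = sn.correlation_matrix(sn.SymptomMatrix(values, ("A", "B")))
        rho, t1, t2 = sn.estimate_tetrachoric(
            sn.pair_table(values[:, 0], values[:, 1])
        )
        assert est.rho[0, 1] == pytest.approx(rho, abs=1e-12)
        assert est.thresholds[0] == pytest.approx(t1, abs=1e-12)

    def test_symmetry_and_unit_diagonal(self, hub_chain_cohort):
        est = sn.correlation_matrix(hub_chain_cohort)
        np.testing.assert_array_equal(est.rho, est.rho.T)
        np.testing.assert_allclose(np.diag(est.rho), 1.0, atol=1e-12)

    def test_duplicated_items_trigger_psd_repair(self):
        # duplicated items push the smallest eigenvalue to 1 - 0.999 (the
        # rho bound); with a floor above that the repair contract activates
        rng = np.random.default_rng(0)
        base = rng.integers(0, 2, size=(200, 2))
        values = np.column_stack([base, base[:, 0], base[:, 0]])
        floor = 0.01
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = sn.correlation_matrix(
                sn.SymptomMatrix(values, ("A", "B", "C", "D")), eig_floor=floor
            )
        assert est.psd_repaired
        assert est.min_eigenvalue_before_repair < floor
        assert np.linalg.eigvalsh(est.rho).min() > 0
        np.testing.assert_allclose(np.diag(est.rho), 1.0, atol=1e-12)

    def test_clip_repair_fixes_indefinite_matrix(self):
        from symptomnet.tetrachoric import _clip_to_psd

        # violates the triangle inequality for correlations -> indefinite
        R = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(R).min() < 0
        fixed = _clip_to_psd(R, 1e-6)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
        np.testing.assert_allclose(np.diag(fixed), 1.0, atol=1e-12)
        np.testing.assert_allclose(fixed, fixed.T, atol=1e-12)

    def test_degenerate_item_zeroed(self):
        values = np.column_stack(
            [np.ones(50, dtype=int), np.random.default_rng(1).integers(0, 2, 50)]
        )
        with pytest.warns(UserWarning, match="degenerate"):
            est = sn.correlation_matrix(sn.SymptomMatrix(values, ("A", "B")))
        assert est.rho[0, 1] == 0.0
        assert est.degenerate_items == ("A",)


def test_estimator_matches_grid_oracle_on_random_tables(rng):
    """ML estimate equals the brute-force likelihood grid within 1e-3."""
    n_checked = 0
    while n_checked < 30:
        t = tuple(int(v) for v in rng.integers(1, 60, size=4))
        rho, *_ = sn.estimate_tetrachoric(t)
        if abs(rho) > 0.995:  # grid cannot localize the boundary
            continue
        assert rho == pytest.approx(grid_search_rho(t, 1e-3), abs=2e-3)
        n_checked += 1
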