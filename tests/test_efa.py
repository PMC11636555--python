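"""Tetrachoric estimation, principal factoring, retention and promax, each
checked against an independent route (closed forms, grid search, construction
oracles, and a frozen reference promax solution computed with R's stats::promax)."""

import warnings

import numpy as np
import pytest
from scipy import special, stats

from scpi.efa import (
    bvn_cdf,
    fit_efa,
    iterated_principal_factors,
    mask_loadings,
    polychoric_matrix,
    promax,
    retain_factors,
    smc,
    tetrachoric,
    tetrachoric_from_data,
    variance_explained,
)


def owen_bvn_cdf(h, k, rho):
    """Independent bivariate-normal CDF via Owen's T function (h, k != 0)."""
    assert h != 0 and k != 0
    r = np.sqrt(1 - rho**2)
    a_h = (k - rho * h) / (h * r)
    a_k = (h - rho * k) / (k * r)
    delta = 0.5 if h * k < 0 else 0.0
    return (0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
            - special.owens_t(h, a_h) - special.owens_t(k, a_k) - delta)


class TestBvnCdf:
    @pytest.mark.parametrize("h,k", [(-1.2, 0.7), (0.5, 0.5), (2.0, -1.5), (-0.3, -0.3)])
    @pytest.mark.parametrize("rho", [-0.95, -0.5, 0.3, 0.8, 0.999])
    def test_matches_owens_t_identity(self, h, k, rho):
        assert bvn_cdf(h, k, rho) == pytest.approx(owen_bvn_cdf(h, k, rho), abs=1e-10)

    def test_independence_factorizes(self):
        assert bvn_cdf(0.3, -1.1, 0.0) == pytest.approx(
            stats.norm.cdf(0.3) * stats.norm.cdf(-1.1))

    def test_median_point_closed_form(self):
        for rho in (-0.8, 0.25, 0.9):
            assert bvn_cdf(0.0, 0.0, rho) == pytest.approx(
                0.25 + np.arcsin(rho) / (2 * np.pi), abs=1e-12)


class TestTetrachoric:
    def test_independent_table_near_zero(self):
        res = tetrachoric(np.array([[25, 25], [25, 25]]))
        assert res.rho == pytest.approx(0.0, abs=1e-6)
        assert res.tau1 == pytest.approx(0.0) and res.tau2 == pytest.approx(0.0)

    def test_balanced_margins_closed_form(self):
        # with both thresholds at 0, rho = sin(2*pi*(p11 - 1/4))
        res = tetrachoric(np.array([[40, 10], [10, 40]]))
        assert res.rho == pytest.approx(np.sin(2 * np.pi * (0.40 - 0.25)), abs=1e-4)

    def test_matches_grid_search_oracle(self):
        tab = np.array([[40, 10], [10, 40]])
        res = tetrachoric(tab)
        taus = stats.norm.ppf([0.5, 0.5])
        grid = np.arange(-0.999, 0.9991, 0.001)

        def loglik(r):
            p00 = bvn_cdf(taus[0], taus[1], r)
            p = np.array([[p00, 0.5 - p00], [0.5 - p00, p00]])
            return float(np.sum(tab * np.log(np.clip(p, 1e-300, 1))))

        best = grid[np.argmax([loglik(r) for r in grid])]
        assert res.rho == pytest.approx(best, abs=0.005)

    def test_zero_cell_capped_with_warning(self):
        with pytest.warns(UserWarning, match="cap"):
            res = tetrachoric(np.array([[30, 0], [10, 30]]))
        assert res.at_cap and res.rho == pytest.approx(0.999)

    def test_zero_margin_degenerate(self):
        res = tetrachoric(np.array([[0, 0], [10, 30]]))
        assert res.degenerate and np.isnan(res.rho)

    def test_continuity_correction_tames_zero_cell(self):
        res = tetrachoric(np.array([[30, 0], [10, 30]]), continuity=True)
        assert not res.at_cap and 0 < res.rho < 0.999

    def test_consistent_under_threshold_model(self, rng):
        # plant a known latent correlation and recover it from binary data
        n, rho, t1, t2 = 50_000, 0.55, -0.4, 0.6
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        res = tetrachoric_from_data(z[:, 0] > t1, z[:, 1] > t2)
        assert res.rho == pytest.approx(rho, abs=0.03)
        assert res.tau1 == pytest.approx(t1, abs=0.03)
        assert res.tau2 == pytest.approx(t2, abs=0.03)

    def test_polychoric_matrix_shape_and_symmetry(self, big_cohort):
        from scpi.scoring import item_columns
        pm = polychoric_matrix(big_cohort[item_columns()])
        R = pm.rho
        assert R.shape == (6, 6)
        assert np.allclose(R, R.T) and np.allclose(np.diag(R), 1.0)
        assert (np.abs(R[~np.eye(6, dtype=bool)]) < 1).all()
        assert len(pm.diagnostics) == 15


class TestIteratedPrincipalFactors:
    @pytest.fixture()
    def construction(self):
        # orthogonal 2-factor model with 3 indicators per factor (identified)
        L = np.array([[0.8, 0.0], [0.7, 0.0], [0.6, 0.0],
                      [0.0, 0.75], [0.0, 0.65], [0.0, 0.55]])
        R = L @ L.T + np.diag(1 - np.sum(L**2, axis=1))
        return L, R

    def test_recovers_constructed_communalities(self, construction):
        L, R = construction
        _, h2, _, _, converged = iterated_principal_factors(R, 2)
        assert converged
        assert np.allclose(h2, np.sum(L**2, axis=1), atol=1e-4)

    def test_recovers_constructed_loadings_up_to_sign(self, construction):
        L, R = construction
        Lhat, _, _, _, _ = iterated_principal_factors(R, 2)
        # align columns by maximal absolute loading, then compare magnitudes
        got = np.abs(Lhat)
        want = np.abs(L)
        cols = [int(np.argmax(got[0])), int(np.argmax(got[3]))]
        assert np.allclose(got[:, cols], want, atol=1e-3)

    def test_identity_matrix_gives_zero_communalities(self):
        _, h2, _, _, _ = iterated_principal_factors(np.eye(6), 1)
        assert np.allclose(h2, 0.0, atol=1e-6)

    def test_fit_residual_not_worse_than_smc_start(self, construction):
        _, R = construction
        h2_0 = smc(R)
        R0 = R.copy()
        np.fill_diagonal(R0, h2_0)
        from scpi.efa import _principal_loadings
        L0 = _principal_loadings(R0, 2)
        off = ~np.eye(6, dtype=bool)
        res_start = np.abs((R - L0 @ L0.T)[off]).max()
        Lf, _, _, _, _ = iterated_principal_factors(R, 2)
        res_final = np.abs((R - Lf @ Lf.T)[off]).max()
        assert res_final <= res_start + 1e-12

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            iterated_principal_factors(np.array([[1, 0.5], [0.2, 1]]), 1)
        with pytest.raises(ValueError, match="unit diagonal"):
            iterated_principal_factors(np.array([[2.0, 0.1], [0.1, 2.0]]), 1)
        with pytest.raises(ValueError, match="factors"):
            iterated_principal_factors(np.eye(3), 3)


class TestRetention:
    def test_strict_kaiser_rule(self):
        k, _ = retain_factors([2.4, 1.7, 1.3, 0.3, 0.2, 0.1])
        assert k == 3
        k_id, scree = retain_factors(np.ones(6))
        assert k_id == 0
        assert list(scree.columns[:2]) == ["factor", "eigenvalue"]

    def test_scree_table_monotone(self):
        _, scree = retain_factors([2.4, 1.7, 1.3, 0.3, 0.2, 0.1])
        assert (np.diff(scree["eigenvalue"]) <= 0).all()
        assert scree["cumulative_share"].iloc[-1] == pytest.approx(1.0)


# frozen oracle: R 4.3 stats::promax(x, m=4) on the fixture below
PROMAX_INPUT = np.array([
    [0.769619, -0.041092, -0.083898],
    [0.931742, -0.149088, 0.090062],
    [0.098195, 0.734572, -0.280782],
    [0.321954, 0.644835, -0.055494],
    [0.179259, 0.099794, 0.600275],
    [0.070694, 0.100497, 0.649097],
])
PROMAX_REF_PATTERN = np.array([
    [0.774495, 0.053588, -0.093057],
    [0.948549, -0.072340, 0.050841],
    [-0.122209, 0.798519, -0.087787],
    [0.099468, 0.686828, 0.111486],
    [0.067999, -0.001752, 0.618089],
    [-0.043977, -0.021751, 0.666400],
])
PROMAX_REF_PHI = np.array([
    [1.0, 0.199017, 0.187586],
    [0.199017, 1.0, -0.018693],
    [0.187586, -0.018693, 1.0],
])


class TestPromax:
    def test_matches_reference_implementation(self):
        pattern, phi, _ = promax(PROMAX_INPUT, power=4)
        assert np.allclose(pattern, PROMAX_REF_PATTERN, atol=0.01)
        assert np.allclose(phi, PROMAX_REF_PHI, atol=0.01)

    def test_perfect_simple_structure_unchanged(self):
        L = np.array([[0.9, 0.0], [0.8, 0.0], [0.0, 0.7], [0.0, 0.6]])
        pattern, phi, _ = promax(L)
        # align columns/signs before comparing
        cols = [int(np.argmax(np.abs(pattern[0]))), int(np.argmax(np.abs(pattern[2])))]
        aligned = pattern[:, cols] * np.sign(np.diag(pattern[[0, 2]][:, cols]))
        assert np.allclose(aligned, L, atol=1e-6)
        assert np.allclose(phi, np.eye(2), atol=1e-6)

    def test_reconstruction_invariance(self):
        pattern, phi, _ = promax(PROMAX_INPUT)
        assert np.allclose(pattern @ phi @ pattern.T,
                           PROMAX_INPUT @ PROMAX_INPUT.T, atol=1e-8)

    def test_single_factor_is_noop(self):
        L = np.array([[0.8], [0.6], [0.4]])
        pattern, phi, _ = promax(L)
        assert np.allclose(pattern, L)
        assert phi.shape == (1, 1)


class TestFullCycle:
    def test_kaiser_retains_three_on_default_cohort(self, big_cohort):
        from scpi.scoring import item_columns
        sol = fit_efa(polychoric_matrix(big_cohort[item_columns()]))
        assert sol.n_factors == 3
        assert (np.diff(sol.eigenvalues) <= 1e-12).all()

    def test_within_factor_loading_products_recovered(self, big_cohort, calibrated_profile):
        """The within-factor tetrachorics identify loading products; those are
        recovered even where the individual split is weakly identified."""
        from scpi.scoring import item_columns
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = fit_efa(polychoric_matrix(big_cohort[item_columns()]))
        planted = np.abs(calibrated_profile.signed_loading_matrix)
        got = np.abs(sol.pattern)
        # map solution columns to planted columns via the dominant item pairs
        pairs = {0: (1, 2), 1: (4, 5), 2: (0, 3)}  # factor -> item rows
        for f, (i, j) in pairs.items():
            col = int(np.argmax(got[i]))
            assert np.argmax(got[j]) == col
            assert got[i, col] * got[j, col] == pytest.approx(
                planted[i, f] * planted[j, f], abs=0.08)

    def test_capability_and_resource_loadings_recovered(self, big_cohort, calibrated_profile):
        from scpi.scoring import item_columns
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = fit_efa(polychoric_matrix(big_cohort[item_columns()]))
        planted = np.abs(calibrated_profile.signed_loading_matrix)
        got = np.abs(sol.pattern)
        for i in (1, 2, 4, 5):   # 1b, 1c, 2b, 2c
            f = int(np.argmax(planted[i]))
            col = int(np.argmax(got[i]))
            assert got[i, col] == pytest.approx(planted[i, f], abs=0.10)

    def test_deterministic_given_matrix(self, big_cohort):
        from scpi.scoring import item_columns
        pm = polychoric_matrix(big_cohort[item_columns()])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = fit_efa(pm)
            b = fit_efa(pm)
        assert np.array_equal(a.pattern, b.pattern)
        assert np.array_equal(a.phi, b.phi)

    def test_rotation_preserves_communalities_and_fit(self, big_cohort):
        from scpi.scoring import item_columns
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = fit_efa(polychoric_matrix(big_cohort[item_columns()]))
        h2_rot = np.diag(sol.pattern @ sol.phi @ sol.pattern.T)
        assert np.allclose(h2_rot, sol.communalities, atol=1e-8)
        L = sol.loadings_unrotated
        assert np.allclose(sol.pattern @ sol.phi @ sol.pattern.T, L @ L.T, atol=1e-8)


class TestVarianceExplained:
    def test_construction_oracle(self):
        L = np.array([[0.8, 0.0], [0.7, 0.0], [0.6, 0.0],
                      [0.0, 0.75], [0.0, 0.65], [0.0, 0.55]])
        R = L @ L.T + np.diag(1 - np.sum(L**2, axis=1))
        sol = fit_efa(R, n_factors=2)
        ve = variance_explained(sol)
        assert ve["common_over_total"] == pytest.approx(
            np.mean(np.sum(L**2, axis=1)), abs=1e-4)

    def test_identity_input_zero_percent(self):
        sol = fit_efa(np.eye(6))
        assert sol.n_factors == 0
        assert variance_explained(sol)["common_over_total"] == pytest.approx(0.0)

    def test_all_conventions_reported(self, big_cohort):
        from scpi.scoring import item_columns
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = fit_efa(polychoric_matrix(big_cohort[item_columns()]))
        ve = variance_explained(sol)
        assert set(ve) == {"common_over_total", "retained_eigenvalues_over_total",
                           "structure_ss_over_total"}
        assert all(0 < v <= 1.5 for v in ve.values())


class TestMaskLoadings:
    def test_masks_sub_threshold_entries(self):
        tbl = mask_loadings(np.array([[0.89, 0.12, -0.03]]), 0.50, ("x",))
        assert list(tbl.iloc[0]) == ["0.89", "", ""]

    def test_threshold_zero_masks_nothing(self):
        tbl = mask_loadings(np.array([[0.2, -0.1]]), 0.0)
        assert (tbl != "").all().all()

    def test_fully_masked_row_warns(self):
        with pytest.warns(UserWarning, match="no loading"):
            mask_loadings(np.array([[0.2, 0.1]]), 0.5, ("weak",))
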