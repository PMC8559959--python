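import numpy as np
import pytest
from scipy import stats
from scipy.integrate import trapezoid

from flexcfdr.core import (
    CfdrSurface,
    cfdr_surface,
    flexible_cfdr,
    l_curve,
    left_censor,
    null_q_distribution,
    null_q_distribution_exact,
    point_level,
    spline_correct,
    v_value,
    _l_curves,
)
from flexcfdr.density import (
    abs_z_to_p,
    fit_reflected_kde,
    joint_tail_exact,
    p_to_abs_z,
    support_limits,
)
from flexcfdr.localfdr import LocalFdrFit, fit_local_fdr


def flat_fdr_fit(z_max=12.0):
    """A local-fdr fit that says 'everything is null' (fdr == 1)."""
    z = np.linspace(-z_max, z_max, 241)
    f = stats.norm.pdf(z)
    return LocalFdrFit(z_grid=z, f_marginal=f / trapezoid(f, z), pi0=1.0, fdr_curve=np.ones_like(z))


@pytest.fixture(scope="module")
def null_surface():
    """Surface fitted to pure-null independent (p, q) pairs."""
    rng = np.random.default_rng(21)
    n = 8_000
    z = np.abs(rng.standard_normal(n))
    q = rng.standard_normal(n)
    limits = support_limits(z, q)
    grid = fit_reflected_kde(z, q, limits, 201, 201)
    fdr_fit = fit_local_fdr(z)
    f0q, F0q, pi0 = null_q_distribution_exact(grid, fdr_fit)
    tail = joint_tail_exact(grid)
    return cfdr_surface(grid, tail, f0q, F0q, pi0)


class TestNullQDistribution:
    def test_flat_fdr_collapses_to_marginal(self, rng):
        z = np.abs(rng.standard_normal(2_000))
        q = rng.standard_normal(2_000)
        grid = fit_reflected_kde(z, q, support_limits(z, q), 101, 101)
        f0q, F0q, pi0 = null_q_distribution(grid, flat_fdr_fit())
        marginal = trapezoid(grid.f, grid.x, axis=0)
        marginal /= trapezoid(marginal, grid.y)
        assert np.max(np.abs(f0q - marginal)) < 1e-10
        assert pi0 == pytest.approx(1.0, abs=2e-3)
        assert np.all(np.diff(F0q) >= -1e-12)
        assert F0q[-1] == pytest.approx(1.0, abs=1e-6)

    def test_pi0_mass_bounded_by_one(self, rng):
        z = np.abs(rng.standard_normal(2_000))
        q = rng.standard_normal(2_000)
        grid = fit_reflected_kde(z, q, support_limits(z, q), 101, 101)
        fit = fit_local_fdr(z)
        for fn in (null_q_distribution, null_q_distribution_exact):
            _, _, pi0 = fn(grid, fit)
            assert pi0 <= 1 + 1e-6

    def test_independent_covariate_f0q_matches_empirical_cdf(self, rng):
        # with signal in p but q independent, Q | H0 has the marginal law of Q
        n = 10_000
        null = rng.random(n) < 0.9
        z = np.abs(np.where(null, rng.standard_normal(n), rng.normal(0, 3, n)))
        q = rng.standard_normal(n)
        grid = fit_reflected_kde(z, q, support_limits(z, q), 151, 151)
        f0q, F0q, _ = null_q_distribution_exact(grid, fit_local_fdr(z))
        emp = np.searchsorted(np.sort(q), grid.y) / n
        assert np.max(np.abs(F0q - emp)) < 0.05


class TestCfdrSurface:
    def test_corner_is_one(self, null_surface):
        assert null_surface.cfdr[0, -1] == pytest.approx(1.0, abs=1e-6)

    def test_null_surface_near_one_in_bulk(self, null_surface):
        s = null_surface
        bulk = s.joint_tail >= 0.01
        med = np.median(s.cfdr[bulk])
        assert 0.8 <= med <= 1.0

    def test_clamped_to_unit_interval(self, null_surface):
        assert np.all(null_surface.cfdr > 0)
        assert np.all(null_surface.cfdr <= 1)

    def test_covariate_uninformative_when_independent(self, null_surface):
        # for fixed z the surface should barely vary across q
        s = null_surface
        i = np.searchsorted(s.x, 1.0)
        row = s.cfdr_raw[i, :]
        keep = s.joint_tail[i, :] >= 0.01
        assert np.ptp(row[keep]) / np.median(row[keep]) < 0.1


class TestPointLevel:
    def test_trivial_corner(self, null_surface):
        assert point_level(null_surface, 1.0, null_surface.y[-1]) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_node_coincident_query(self, null_surface):
        s = null_surface
        i, j = 40, 77
        p = abs_z_to_p(s.x[i])
        assert point_level(s, p, s.y[j]) == pytest.approx(s.cfdr[i, j], rel=1e-9)

    def test_interpolation_matches_direct_evaluation(self, rng):
        # recompute the estimator at 50 random off-grid points from the
        # exact kernel integrals (numerator and denominator evaluated at the
        # point itself, not on the grid) and compare with bilinear
        # interpolation of the gridded surface at default resolution
        n = 4_000
        z = np.abs(rng.standard_normal(n))
        q = rng.standard_normal(n)
        grid = fit_reflected_kde(z, q, support_limits(z, q), 501, 501)
        fdr_fit = fit_local_fdr(z)
        f0q, F0q, pi0 = null_q_distribution_exact(grid, fdr_fit)
        s = cfdr_surface(grid, joint_tail_exact(grid), f0q, F0q, pi0)

        sp, sq = grid.bandwidths.sigma_p, grid.bandwidths.sigma_q
        from flexcfdr.localfdr import evaluate_fdr

        w = evaluate_fdr(fdr_fit, grid.x)
        kern = stats.norm.pdf((grid.x[None, :] - z[:, None]) / sp) + stats.norm.pdf(
            (grid.x[None, :] + z[:, None]) / sp
        )
        a = trapezoid(kern * w[None, :], grid.x, axis=1) / sp

        zq = rng.uniform(0.2, 2.8, 50)  # inside the data-supported region
        yq = rng.uniform(np.quantile(q, 0.05), np.quantile(q, 0.95), 50)
        interp = point_level(s, abs_z_to_p(zq), yq, mode="raw")
        # exact normalising constants match the gridded surface's
        f0q_norm = (a @ stats.norm.cdf((grid.y[-1] - q) / sq)) / n
        t_norm = np.mean(stats.norm.cdf((grid.y[-1] - q) / sq))
        for k in range(50):
            f0_at = (a @ stats.norm.cdf((yq[k] - q) / sq)) / n / f0q_norm
            t_at = (
                np.mean(
                    (
                        stats.norm.sf((zq[k] - z) / sp)
                        + stats.norm.sf((zq[k] + z) / sp)
                    )
                    * stats.norm.cdf((yq[k] - q) / sq)
                )
                / t_norm
            )
            direct = abs_z_to_p(zq[k]) * f0_at / t_at
            assert abs(interp[k] - direct) / direct < 0.02


class TestLCurve:
    def test_level_one_fills_strip(self, null_surface):
        assert np.all(l_curve(null_surface, 1.0).p_l == 1.0)

    def test_level_below_minimum_is_empty(self, null_surface):
        tiny = float(null_surface.cfdr.min()) * 0.5
        assert np.all(l_curve(null_surface, tiny).p_l == 0.0)

    def test_rightmost_crossing_on_nonmonotone_row(self):
        # constructed column that dips below the level, rises, dips again:
        # the boundary is the first (largest-p) crossing
        x = np.linspace(0, 10, 101)
        y = np.array([0.0, 1.0])
        col = np.ones(101)
        col[30:40] = 0.4   # first dip
        col[60:] = 0.2     # second dip
        mat = np.tile(col[:, None], (1, 2))
        pl = _l_curves(x, y, mat, np.array([0.5]))[0]
        # brute-force scan oracle
        px = abs_z_to_p(x)
        k = next(i for i in range(101) if col[i] <= 0.5)
        expected = px[k - 1] + (px[k] - px[k - 1]) * (col[k - 1] - 0.5) / (
            col[k - 1] - col[k]
        )
        assert pl[0] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(px[29], abs=px[29] - px[30])

    def test_level_validation(self, null_surface):
        with pytest.raises(ValueError):
            l_curve(null_surface, 0.0)
        with pytest.raises(ValueError):
            l_curve(null_surface, 1.5)


class TestVValue:
    def test_constant_boundary_integrates_to_constant(self, null_surface):
        s = null_surface
        curve = l_curve(s, 1.0)
        curve.p_l = np.full_like(curve.p_l, 0.37)
        assert v_value(s, curve) == pytest.approx(0.37, rel=1e-9)

    def test_full_strip_gives_one(self, null_surface):
        assert v_value(null_surface, l_curve(null_surface, 1.0)) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_matches_brute_force_region_integration(self, null_surface, rng):
        # independent scan-and-integrate oracle per level, on the monotone
        # surface used by the pipeline
        s = null_surface
        levels = np.sort(rng.uniform(s.cfdr_mono.min(), 1.0, 50))
        fast = trapezoid(
            _l_curves(s.x, s.y, s.cfdr_mono, levels) * s.f0q[None, :], s.y, axis=1
        )
        px = abs_z_to_p(s.x)
        for lev, vf in zip(levels, fast):
            pl = np.zeros(s.y.size)
            for j in range(s.y.size):
                col = s.cfdr_mono[:, j]
                hit = np.nonzero(col <= lev)[0]
                if hit.size == 0:
                    pl[j] = 0.0
                elif hit[0] == 0:
                    pl[j] = 1.0
                else:
                    k = hit[0]
                    pl[j] = px[k - 1] + (px[k] - px[k - 1]) * (col[k - 1] - lev) / (
                        col[k - 1] - col[k]
                    )
            oracle = trapezoid(pl * s.f0q, s.y)
            assert vf == pytest.approx(oracle, rel=1e-6)

    def test_nesting_monotonicity(self, null_surface, rng):
        s = null_surface
        levels = np.sort(rng.uniform(s.cfdr_mono.min(), 1.0, 40))
        pl = _l_curves(s.x, s.y, s.cfdr_mono, levels)
        assert np.all(np.diff(pl, axis=0) >= -1e-12)  # regions nest
        v = trapezoid(pl * s.f0q[None, :], s.y, axis=1)
        assert np.all(np.diff(v) >= -1e-12)


class TestLeftCensor:
    def test_dense_data_untouched(self, rng):
        q = rng.uniform(0, 1, 100_000)
        grid = np.linspace(0, 1, 501)
        censored, q_low, n = left_censor(q, grid, gridp=50)
        assert n == 0
        assert q_low == grid[0]
        assert censored is not q or np.array_equal(censored, q)

    def test_outliers_move_to_first_dense_cell(self, rng):
        q = np.concatenate([np.full(10, -10.0), rng.uniform(0, 1, 10_000)])
        grid = np.linspace(-10.55, 1.55, 501)
        censored, q_low, n = left_censor(q, grid, gridp=50)
        # exact counting oracle: first cell with >= 50 points; everything
        # to its left (the 10 outliers plus any bulk points in the sparse
        # partial cell) moves onto its edge
        counts, _ = np.histogram(q, bins=grid)
        expected_low = grid[np.nonzero(counts >= 50)[0][0]]
        assert q_low == expected_low
        assert n == np.sum(q < expected_low) and n >= 10
        assert np.all(censored >= q_low)
        assert np.all(censored[:10] == q_low)

    def test_unreachable_gridp_errors(self, rng):
        with pytest.raises(ValueError):
            left_censor(rng.uniform(0, 1, 30), np.linspace(0, 1, 11), gridp=50)


class TestSplineCorrect:
    def test_in_band_points_untouched(self, rng):
        q = rng.standard_normal(500)
        p = rng.uniform(0.01, 1, 500)
        v = p * 10 ** rng.uniform(-0.1, 0.1, 500)
        out, flags = spline_correct(p, q, v)
        assert not flags.any()
        assert np.array_equal(out, v)

    def test_inflated_outlier_mapped_back(self, rng):
        q = rng.standard_normal(1000)
        p = rng.uniform(0.01, 1, 1000)
        v = p.copy()           # trend: v == p, r == 0
        v[0] = p[0] * 1e-3     # one grossly inflated v (r = -3)
        out, flags = spline_correct(p, q, v)
        assert flags[0] and flags.sum() == 1
        # mapped back onto the (nearly flat) spline: v ~ p
        assert out[0] == pytest.approx(p[0], rel=0.1)

    def test_deflation_side_ignored_by_default_but_not_both(self, rng):
        q = rng.standard_normal(1000)
        p = rng.uniform(0.01, 1, 1000)
        p[0] = 1e-4
        v = p.copy()
        v[0] = 0.1  # conservative outlier: v 1000x larger than p
        _, flags = spline_correct(p, q, v, side="inflation")
        _, flags_both = spline_correct(p, q, v, side="both")
        assert not flags[0]
        assert flags_both[0]

    def test_corrected_values_stay_in_unit_interval(self, rng):
        q = rng.standard_normal(500)
        p = rng.uniform(0.5, 1, 500)
        v = p.copy()
        v[:5] = 1e-8
        out, _ = spline_correct(p, q, v)
        assert np.all((out > 0) & (out <= 1))

    def test_degenerate_covariate_skips(self, rng):
        p = rng.uniform(0.01, 1, 100)
        out, flags = spline_correct(p, np.zeros(100), p.copy())
        assert not flags.any()


class TestFlexibleCfdr:
    def test_informative_covariate_boosts_signal(self):
        # q tracks the true association: v should beat p on causal SNPs
        rng = np.random.default_rng(8)
        m = 4_000
        is_alt = rng.random(m) < 0.05
        z = np.abs(np.where(is_alt, rng.normal(0, 4, m), rng.standard_normal(m)))
        p = 2 * stats.norm.sf(z)
        q = -z + rng.standard_normal(m)  # strongly informative
        res = flexible_cfdr(p, q, grid_nx=151, grid_ny=151)
        # wholesale shift toward significance, measured on the log scale
        assert np.log10(res.v[is_alt]).mean() < np.log10(p[is_alt]).mean()

    def test_single_snp_errors(self):
        with pytest.raises(ValueError):
            flexible_cfdr(np.array([0.5]), np.array([0.0]))

    def test_rejects_invalid_inputs(self, rng):
        p = rng.uniform(0.01, 1, 100)
        q = rng.standard_normal(100)
        with pytest.raises(ValueError):
            flexible_cfdr(np.append(p, 0.0), np.append(q, 0.0))
        with pytest.raises(ValueError):
            flexible_cfdr(p, np.where(np.arange(100) == 3, np.nan, q))

    def test_shared_levels_share_v(self, rng):
        p = rng.uniform(1e-6, 1, 3_000)
        q = rng.standard_normal(3_000)
        res = flexible_cfdr(p, q, grid_nx=101, grid_ny=101, correct=False)
        order = np.argsort(res.level)
        assert np.all(np.diff(res.v[order]) >= -1e-12)

    def test_result_fields_aligned(self, rng):
        p = rng.uniform(1e-6, 1, 2_000)
        q = rng.standard_normal(2_000)
        res = flexible_cfdr(p, q, grid_nx=101, grid_ny=101)
        for arr in (res.v, res.level, res.censored, res.corrected, res.q_used):
            assert arr.shape == p.shape
        assert np.all((res.v > 0) & (res.v <= 1))
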