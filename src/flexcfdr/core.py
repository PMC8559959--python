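"""Conditional FDR surface, L-regions and v-values.

The estimated conditional FDR at a point (p, q) is

    cfdr(p, q) = p * Pr(Q <= q | H0) / Pr(P <= p, Q <= q)

where the joint probability comes from the reflected KDE of (|Z|, Q) and the
null covariate distribution Pr(Q <= q | H0) is obtained by weighting the
joint density with the local fdr Pr(H0 | Z = z) and integrating out Z.

Each observed pair is mapped to a "v-value": the probability, under the
null (P uniform, Q from its null law, independent), that a fresh pair falls
inside the L-region {(p', q') : cfdr(p', q') <= cfdr(p, q)}. v-values behave
like p-values and feed directly into Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import patsy
from scipy import stats
from scipy.integrate import cumulative_trapezoid, trapezoid

from .density import (
    DensityGrid,
    abs_z_to_p,
    bilinear_interpolate,
    fit_reflected_kde,
    joint_tail_exact,
    joint_tail_table,
    p_to_abs_z,
    support_limits,
)
from .localfdr import LocalFdrFit, evaluate_fdr, fit_local_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "CfdrSurface",
    "LCurve",
    "VValueResult",
    "null_q_distribution",
    "null_q_distribution_exact",
    "cfdr_surface",
    "point_level",
    "l_curve",
    "v_value",
    "left_censor",
    "spline_correct",
    "flexible_cfdr",
]

_TAIL_FLOOR = 1e-12
_V_FLOOR = 1e-300


@dataclass
class CfdrSurface:
    """Estimated cFDR on the (|Z|, Q) grid plus the null covariate law.

    ``cfdr`` is clamped to (0, 1] for reporting; ``cfdr_raw`` keeps the
    unclamped estimate, which is what L-curve levels are computed from so
    that distinct points in the high-p region keep distinct contours.
    """

    x: np.ndarray
    y: np.ndarray
    cfdr: np.ndarray
    cfdr_raw: np.ndarray
    cfdr_mono: np.ndarray
    f0q: np.ndarray
    F0q: np.ndarray
    pi0_mass: float
    joint_tail: np.ndarray


@dataclass
class LCurve:
    """Rightmost p-boundary of an L-region, one value per covariate node."""

    level: float
    p_l: np.ndarray


@dataclass
class VValueResult:
    v: np.ndarray
    level: np.ndarray
    censored: np.ndarray
    corrected: np.ndarray
    flipped: bool = False
    q_used: np.ndarray | None = None
    q_low: float | None = None
    surface: CfdrSurface | None = field(default=None, repr=False)


def null_q_distribution(grid: DensityGrid, fdr_fit: LocalFdrFit):
    """Null covariate density/CDF by local-fdr weighting of the joint KDE.

    g(x, y) = fdr(x) f(x, y) approximates the joint density of (|Z|, Q, H0);
    integrating out Z gives the (unnormalised) null covariate density and
    the total mass estimates Pr(H0).
    """
    w = evaluate_fdr(fdr_fit, grid.x)
    g = w[:, None] * grid.f
    f0q_raw = trapezoid(g, grid.x, axis=0)
    pi0_mass = float(trapezoid(f0q_raw, grid.y))
    if pi0_mass < 1e-6:
        raise ValueError("degenerate null: Pr(H0) mass below 1e-6")
    f0q = f0q_raw / pi0_mass
    F0q = cumulative_trapezoid(f0q, grid.y, initial=0.0)
    F0q /= F0q[-1]
    return f0q, F0q, pi0_mass


def null_q_distribution_exact(grid: DensityGrid, fdr_fit: LocalFdrFit):
    """Null covariate density/CDF from exact per-kernel integrals.

    Same estimator as :func:`null_q_distribution`, but each kernel's
    contribution is integrated in closed form in the covariate direction:
    kernel k gets the weight a_k = int fdr(x) K_sigma_p(x; z_k) dx (its null
    mass on the Z axis), and

        f0q(y) = sum_k a_k phi((y - q_k)/sigma_q) / (n sigma_q pi0)
        F0q(y) = sum_k a_k Phi((y - q_k)/sigma_q) / (n pi0)

    This matches the exact joint tail table node for node — in particular
    at the support edges, where grid quadrature returns an exact zero while
    the kernel tails do not, which would otherwise make the edge column of
    the cFDR surface degenerate.
    """
    if grid.fit_z is None or grid.fit_q is None:
        raise ValueError("grid does not carry its fitting sample")
    sp, sq = grid.bandwidths.sigma_p, grid.bandwidths.sigma_q
    zk, qk = grid.fit_z, grid.fit_q
    w = evaluate_fdr(fdr_fit, grid.x)
    # a_k = int_0^zmax fdr(x) [phi((x-z_k)/sp) + phi((x+z_k)/sp)]/sp dx
    kern = stats.norm.pdf((grid.x[None, :] - zk[:, None]) / sp) + stats.norm.pdf(
        (grid.x[None, :] + zk[:, None]) / sp
    )
    a = trapezoid(kern * w[None, :], grid.x, axis=1) / sp
    pi0_mass = float(np.mean(a))
    if pi0_mass < 1e-6:
        raise ValueError("degenerate null: Pr(H0) mass below 1e-6")
    dy = (grid.y[None, :] - qk[:, None]) / sq
    f0q = (a @ stats.norm.pdf(dy)) / (zk.size * sq)
    F0q = (a @ stats.norm.cdf(dy)) / zk.size
    F0q /= F0q[-1]
    f0q /= trapezoid(f0q, grid.y)
    return f0q, F0q, pi0_mass


def cfdr_surface(
    grid: DensityGrid,
    joint_tail: np.ndarray,
    f0q: np.ndarray,
    F0q: np.ndarray,
    pi0_mass: float,
) -> CfdrSurface:
    """Assemble the cFDR estimate ``p(x) F0q(y) / T(x, y)`` on the grid.

    Grid nodes where the joint tail T falls below a floor (empty corners of
    the support) inherit the value of the nearest valid node toward smaller
    x, preventing spurious spikes where the denominator vanishes.
    """
    p_x = abs_z_to_p(grid.x)
    t = np.asarray(joint_tail, dtype=float)
    raw = np.empty_like(t)
    valid = t >= _TAIL_FLOOR
    with np.errstate(divide="ignore", invalid="ignore"):
        raw[valid] = (p_x[:, None] * F0q[None, :])[valid] / t[valid]
    # T decreases in x, so invalid nodes form a suffix of each column: fill
    # down from the last valid node; columns with no valid node fall back to 1
    n_valid = valid.sum(axis=0)
    for j in np.nonzero(n_valid < grid.x.size)[0]:
        k = n_valid[j]
        raw[k:, j] = raw[k - 1, j] if k > 0 else 1.0
    raw = np.maximum(raw, _V_FLOOR)
    # monotone repair along z: the effective level of a point is the best
    # (smallest) cfdr achievable at any larger p on its covariate row, so a
    # point is rejected whenever a less significant point would be; this
    # also neutralises the estimator blowing up beyond the fitted data's Z
    # range, where the kernel tails die faster than the null
    mono = np.minimum.accumulate(raw, axis=0)
    return CfdrSurface(
        x=grid.x,
        y=grid.y,
        cfdr=np.minimum(raw, 1.0),
        cfdr_raw=raw,
        cfdr_mono=mono,
        f0q=f0q,
        F0q=F0q,
        pi0_mass=pi0_mass,
        joint_tail=t,
    )


def point_level(surface: CfdrSurface, p, q, mode: str = "clamped"):
    """cFDR level at observed pairs: bilinear interpolation at (|z(p)|, q).

    ``mode`` selects the matrix: "clamped" (reported cfdr), "raw"
    (unclamped), or "monotone" (running minimum along z — the level used
    for L-region construction)."""
    z = p_to_abs_z(p)
    mat = {
        "clamped": surface.cfdr,
        "raw": surface.cfdr_raw,
        "monotone": surface.cfdr_mono,
    }[mode]
    return bilinear_interpolate(surface.x, surface.y, mat, z, q)


def _l_curves(x, y, mat, levels) -> np.ndarray:
    """Rightmost p-boundary per covariate row for each level.

    For each column j the running minimum of ``mat`` along x is
    non-increasing, so the first node (scanning from x = 0, i.e. from p = 1
    downward) with cfdr <= level is found by binary search; the boundary is
    then linearly interpolated in p between the bracketing nodes. Returns a
    matrix of shape (len(levels), len(y)).
    """
    levels = np.asarray(levels, dtype=float)
    p_x = abs_z_to_p(x)
    m = np.minimum.accumulate(mat, axis=0)
    nx = x.size
    out = np.empty((levels.size, y.size))
    neg_levels = -levels
    for j in range(y.size):
        col_min = m[:, j]
        idx = np.searchsorted(-col_min, neg_levels, side="left")
        pl = np.zeros(levels.size)
        pl[idx == 0] = 1.0
        mid = (idx > 0) & (idx < nx)
        if np.any(mid):
            i = idx[mid]
            c0 = mat[i - 1, j]
            c1 = mat[i, j]
            p0 = p_x[i - 1]
            p1 = p_x[i]
            denom = c0 - c1
            frac = np.where(denom > 0, (c0 - levels[mid]) / np.where(denom > 0, denom, 1.0), 1.0)
            pl[mid] = p0 + (p1 - p0) * np.clip(frac, 0.0, 1.0)
        out[:, j] = pl
    return out


def l_curve(surface: CfdrSurface, level: float, raw: bool = False) -> LCurve:
    """L-curve of the region {cfdr <= level}: the rightmost (largest-p)
    crossing of the level in each covariate row of the clamped surface."""
    if not 0 < level <= (np.inf if raw else 1.0):
        raise ValueError("level must lie in (0, 1]")
    mat = surface.cfdr_raw if raw else surface.cfdr
    pl = _l_curves(surface.x, surface.y, mat, np.array([level]))[0]
    return LCurve(level=float(level), p_l=pl)


def v_value(surface: CfdrSurface, curve: LCurve) -> float:
    """Null mass of the L-region.

    Under the null P is uniform and independent of Q, so the inner integral
    over p is the boundary p_L(y) itself and v = int p_L(y) f0q(y) dy.
    """
    if curve.p_l.size != surface.y.size:
        raise ValueError("curve is not on the surface's covariate axis")
    v = float(trapezoid(curve.p_l * surface.f0q, surface.y))
    return min(max(v, _V_FLOOR), 1.0)


def left_censor(q: np.ndarray, y_grid: np.ndarray, gridp: int = 50):
    """Left-censor the covariate at the first well-populated grid cell.

    Counts data per cell of ``y_grid``; q_low is the left edge of the lowest
    cell holding at least ``gridp`` points, and every q < q_low is moved to
    q_low. Stabilises the KDE in the sparse left tail, where boundary cells
    would otherwise be estimated from a handful of points.
    """
    q = np.asarray(q, dtype=float)
    if gridp < 1:
        raise ValueError("gridp must be at least 1")
    counts, _ = np.histogram(q, bins=y_grid)
    dense = np.nonzero(counts >= gridp)[0]
    if dense.size == 0:
        raise ValueError(
            f"no grid cell holds {gridp} points; lower gridp or coarsen the grid"
        )
    q_low = float(y_grid[dense[0]])
    n_cens = int(np.sum(q < q_low))
    if n_cens:
        q = np.where(q < q_low, q_low, q)
    return q, q_low, n_cens


def spline_correct(p, q, v, dist_thr: float = 0.5, side: str = "inflation"):
    """Pull outlying v-values back to the p-q trend.

    Fits a natural cubic regression spline with 5 interior knots (at the
    1/6..5/6 quantiles of q) to r = log10(v/p) against q; points whose
    residual exceeds ``dist_thr`` are mapped back onto the spline,
    v -> p * 10^s(q), clamped to (0, 1]. Guards against artefactually
    inflated evidence where (p, q) is jointly sparse.

    ``side`` controls which deviations are corrected: "inflation" (default)
    corrects only v-values far below the trend — the direction that inflates
    significance; deflated v-values are merely conservative and are left
    alone. "both" corrects unsigned deviations.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    if not dist_thr > 0:
        raise ValueError("dist_thr must be positive")
    if side not in ("inflation", "both"):
        raise ValueError("side must be 'inflation' or 'both'")
    flags = np.zeros(p.size, dtype=bool)
    if np.unique(q).size < 7:
        logger.warning("fewer than 7 distinct covariate values; skipping spline correction")
        return v.copy(), flags
    r = np.log10(v / p)
    knots = np.quantile(q, [1 / 6, 2 / 6, 3 / 6, 4 / 6, 5 / 6])
    knots = np.unique(knots)
    design = np.asarray(
        patsy.dmatrix(
            "cr(q, knots=k, lower_bound=lb, upper_bound=ub)",
            {"q": q, "k": knots, "lb": float(q.min()), "ub": float(q.max())},
        )
    )
    beta, *_ = np.linalg.lstsq(design, r, rcond=None)
    s = design @ beta
    resid = r - s
    flags = (resid < -dist_thr) if side == "inflation" else (np.abs(resid) > dist_thr)
    v_out = v.copy()
    if np.any(flags):
        v_out[flags] = np.clip(p[flags] * 10.0 ** s[flags], _V_FLOOR, 1.0)
    return v_out, flags


def _align_sign(p, q, mask):
    """Negate q if Pearson cor(p, q) over ``mask`` is clearly negative, so
    small q always accompanies small p (positive stochastic monotonicity).

    The flip triggers only when the estimate is below minus two standard
    errors (-2/sqrt(n)): a covariate independent of p produces a correlation
    straddling zero, and flipping on that noise serves no purpose.
    """
    ps, qs = p[mask], q[mask]
    if ps.size < 3:
        raise ValueError("need at least 3 records to estimate the correlation")
    if np.std(qs) == 0:
        raise ValueError("covariate has zero variance on the alignment subset")
    r = float(np.corrcoef(ps, qs)[0, 1])
    if r < -2.0 / np.sqrt(ps.size):
        return -q, True
    return q, False


def _censor_grid(q: np.ndarray) -> np.ndarray:
    """Cell edges for the left-censoring count: cells one covariate
    bandwidth wide, so the count measures whether the KDE is locally
    supported by enough data (cells far narrower than a kernel say nothing
    about the reliability of the density estimate there)."""
    from .density import normal_reference_bandwidth

    lo, hi = float(np.min(q)), float(np.max(q))
    width = normal_reference_bandwidth(q)
    width = min(width, (hi - lo) / 10.0)
    n_cells = int(np.ceil((hi - lo) / width))
    return np.linspace(lo, hi, n_cells + 1)


def flexible_cfdr(
    p: np.ndarray,
    q: np.ndarray,
    indep: np.ndarray | None = None,
    *,
    gridp: int = 50,
    dist_thr: float = 0.5,
    grid_nx: int = 501,
    grid_ny: int = 501,
    locfdr_bins: int = 120,
    locfdr_df: int = 7,
    align_sign: bool = True,
    correct: bool = True,
    keep_surface: bool = False,
) -> VValueResult:
    """Map p-value/covariate pairs to v-values.

    Composes the full estimator: sign alignment, support construction,
    left-censoring, reflected KDE on the independent subset, local fdr fit,
    null covariate distribution, joint tail table, cFDR surface, per-pair
    L-curves and null-mass integration, and finally the sparse-region spline
    correction. SNPs sharing a cFDR level share an L-curve, so levels are
    deduplicated before the curve construction.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 1:
        raise ValueError("p and q must be 1-d arrays of equal length")
    if p.size < 10:
        raise ValueError("too few SNPs to fit the density estimates")
    if np.any(~np.isfinite(q)):
        raise ValueError("covariate contains non-finite values")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    if indep is None:
        indep = np.ones(p.size, dtype=bool)
    indep = np.asarray(indep, dtype=bool)
    if indep.shape != p.shape or not np.any(indep):
        raise ValueError("independence mask must flag at least one SNP")

    flipped = False
    if align_sign:
        q, flipped = _align_sign(p, q, indep)

    z = p_to_abs_z(p)
    limits = support_limits(z, q)
    q_cens, q_low, n_cens = left_censor(q, _censor_grid(q), gridp)
    censored = q < q_low
    if n_cens:
        logger.info("left-censored %d covariate values below %.4g", n_cens, q_low)

    grid = fit_reflected_kde(
        z[indep], q_cens[indep], limits, grid_nx=grid_nx, grid_ny=grid_ny
    )
    fdr_fit = fit_local_fdr(z[indep], n_bins=locfdr_bins, spline_df=locfdr_df)
    f0q, F0q, pi0_mass = null_q_distribution_exact(grid, fdr_fit)
    tail = joint_tail_exact(grid)
    surface = cfdr_surface(grid, tail, f0q, F0q, pi0_mass)

    levels = np.asarray(
        bilinear_interpolate(surface.x, surface.y, surface.cfdr_mono, z, q_cens)
    )
    uniq, inverse = np.unique(levels, return_inverse=True)
    pl_mat = _l_curves(surface.x, surface.y, surface.cfdr_mono, uniq)
    v_uniq = trapezoid(pl_mat * surface.f0q[None, :], surface.y, axis=1)
    v = np.clip(v_uniq[inverse], _V_FLOOR, 1.0)
    if np.any(~np.isfinite(v)):
        bad = np.nonzero(~np.isfinite(v))[0]
        raise RuntimeError(
            f"non-finite v-values at indices {bad[:10].tolist()}; "
            f"levels {levels[bad[:10]].tolist()}"
        )

    if correct:
        v, corrected = spline_correct(p, q_cens, v, dist_thr)
    else:
        corrected = np.zeros(p.size, dtype=bool)
    if np.any(corrected):
        logger.info("spline correction applied to %d SNPs", int(corrected.sum()))

    return VValueResult(
        v=v,
        level=levels,
        censored=censored,
        corrected=corrected,
        flipped=flipped,
        q_used=q_cens,
        q_low=q_low,
        surface=surface if keep_surface else None,
    )
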