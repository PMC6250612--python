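"""Density and second-order point-pattern statistics.

Implements the summary statistics used to classify cell arrangements in
follicles: per-region densities with Welch t-tests, Ripley's K function,
the pair correlation function g(r) by kernel estimation, pooled
(min/median/max across follicles) envelopes and Monte-Carlo CSR envelopes,
and the clustered / random / regular classification.

Under complete spatial randomness K(r) = pi r^2 and g(r) = 1; g > 1 at a
radius r signals clustering at that scale, g < 1 regularity/inhibition.
Edge effects on a bounded window bias the naive estimators downward; the
translation correction reweights each pair (i, j) by A / C(x_j - x_i),
where C(t) = area(W intersect (W + t)) is the set covariance of the window,
computed here on the binary mask by FFT autocorrelation so that irregular
(e.g. elliptical) windows are handled exactly.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal, stats

from .datatypes import PointPattern, RegionMask, SpatialCurve

__all__ = [
    "density",
    "ripley_k",
    "pair_correlation",
    "stoyan_bandwidth",
    "pooled_envelope",
    "csr_envelope",
    "classify_pattern",
    "compare_densities",
    "clark_evans_index",
    "default_r_grid",
]


def default_r_grid(r_max: float = 60.0, step: float = 1.0) -> np.ndarray:
    """Default radius grid: 1 um steps out to 60 um (resolves the 5-10 um scale)."""
    return np.arange(step, r_max + step / 2, step)


def density(pp: PointPattern) -> float:
    """Point density in cells per mm^2: n / window area."""
    area = pp.window.area_mm2
    if area <= 0:
        raise ValueError("window has zero area")
    return pp.n / area


def _set_covariance(window: RegionMask) -> np.ndarray:
    """C(t) = area(W ∩ (W+t)) on the pixel offset grid, cached on the mask."""
    if window._setcov_cache is None:
        m = window.mask.astype(float)
        cov = signal.fftconvolve(m, m[::-1, ::-1], mode="full")
        window._setcov_cache = np.maximum(cov, 0.0) * window.pixel_size**2
    return window._setcov_cache


def _pair_stats(pp: PointPattern, r_max: float, correction: str):
    """Upper-triangle pairwise distances <= r_max and translation weights.

    Returns (d, w): each unordered pair contributes one entry; weights are
    symmetric (C(-t) = C(t)), so ordered-pair sums are 2 * sum(w * ...).
    """
    pts = pp.points
    n = len(pts)
    diff = pts[None, :, :] - pts[:, None, :]
    dmat = np.hypot(diff[..., 0], diff[..., 1])
    iu = np.triu_indices(n, k=1)
    d = dmat[iu]
    keep = d <= r_max
    d = d[keep]
    if correction == "none":
        return d, np.ones_like(d)
    if correction != "translation":
        raise ValueError(f"unknown edge correction {correction!r}")
    dx = diff[..., 0][iu][keep]
    dy = diff[..., 1][iu][keep]
    cov = _set_covariance(pp.window)
    H, W = pp.window.shape
    p = pp.window.pixel_size
    rows = (H - 1) + dy / p
    cols = (W - 1) + dx / p
    c = ndimage.map_coordinates(cov, [rows, cols], order=1, mode="nearest")
    c = np.maximum(c, p**2)  # guard against vanishing overlap
    return d, pp.window.area_um2 / c


def ripley_k(
    pp: PointPattern,
    r_grid: np.ndarray | None = None,
    correction: str = "translation",
) -> SpatialCurve:
    """Ripley's K function estimate.

    K_hat(r) = (A / (n (n-1))) * sum_{i != j} w_ij 1[d_ij <= r], with w_ij = 1
    (no correction) or the translation weight A / C(x_j - x_i). K_hat is
    non-decreasing in r by construction. Requires n >= 2.
    """
    if pp.n < 2:
        raise ValueError("Ripley's K is undefined for fewer than 2 points")
    r = np.asarray(r_grid if r_grid is not None else default_r_grid(), dtype=float)
    d, w = _pair_stats(pp, float(r[-1]), correction)
    order = np.argsort(d)
    d_sorted, w_sorted = d[order], w[order]
    csum = np.concatenate([[0.0], np.cumsum(w_sorted)])
    idx = np.searchsorted(d_sorted, r, side="right")
    pair_sum = 2.0 * csum[idx]  # ordered pairs
    area = pp.window.area_um2
    k = area / (pp.n * (pp.n - 1)) * pair_sum
    return SpatialCurve(r=r, k=k, source="single", meta={"correction": correction, "n": pp.n})


def stoyan_bandwidth(pp: PointPattern) -> float:
    """Stoyan's rule of thumb: Epanechnikov half-width h = 0.15 / sqrt(lambda_hat),
    lambda_hat in points per um^2."""
    lam = pp.intensity_hat_um2
    if lam <= 0:
        raise ValueError("cannot set a bandwidth for an empty pattern")
    return 0.15 / np.sqrt(lam)


def pair_correlation(
    pp: PointPattern,
    r_grid: np.ndarray | None = None,
    bandwidth_rule: str = "stoyan",
    bandwidth: float | None = None,
    correction: str = "translation",
) -> SpatialCurve:
    """Kernel estimate of the pair correlation function g(r).

    g_hat(r) = sum_{i != j} w_ij kappa_h(r - d_ij) / (2 pi r lambda_hat^2 A),
    with an Epanechnikov kernel of half-width h (Stoyan's rule by default,
    or ``bandwidth_rule="fixed"`` with an explicit ``bandwidth``). Radii
    below h are kept but flagged unreliable (the kernel mass below r = 0 is
    not reflected). Requires n >= 2 and a grid excluding r = 0.
    """
    if pp.n < 2:
        raise ValueError("pair correlation is undefined for fewer than 2 points")
    r = np.asarray(r_grid if r_grid is not None else default_r_grid(), dtype=float)
    if np.any(r <= 0):
        raise ValueError("r grid must exclude r = 0")
    if bandwidth_rule == "stoyan":
        h = stoyan_bandwidth(pp)
    elif bandwidth_rule == "fixed":
        if bandwidth is None or bandwidth <= 0:
            raise ValueError("fixed bandwidth rule requires a positive bandwidth")
        h = float(bandwidth)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")

    d, w = _pair_stats(pp, float(r[-1]) + h, correction)
    # Epanechnikov kernel, vectorized over (grid, pairs)
    u = (r[:, None] - d[None, :]) / h
    kern = np.where(np.abs(u) < 1.0, 0.75 * (1.0 - u**2) / h, 0.0)
    pair_sum = 2.0 * kern @ w
    lam = pp.intensity_hat_um2
    area = pp.window.area_um2
    g = pair_sum / (2.0 * np.pi * r * lam**2 * area)
    return SpatialCurve(
        r=r,
        g=g,
        source="single",
        unreliable=r < h,
        meta={"bandwidth": h, "correction": correction, "n": pp.n},
    )


def pooled_envelope(curves: list[SpatialCurve]) -> SpatialCurve:
    """Pool curves from several follicles: pointwise median, min and max.

    This mirrors reporting one thick median line with a min/max envelope
    across the follicles of a group. All curves must share the radius grid
    exactly (no resampling).
    """
    if len(curves) < 2:
        raise ValueError("pooling needs at least 2 curves")
    r = curves[0].r
    for c in curves[1:]:
        if len(c.r) != len(r) or not np.allclose(c.r, r):
            raise ValueError("curves must share an identical r grid")
    use_g = curves[0].g is not None
    vals = np.vstack([(c.g if use_g else c.k) for c in curves])
    med = np.median(vals, axis=0)
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    return SpatialCurve(
        r=r.copy(),
        g=med if use_g else None,
        k=None if use_g else med,
        lo=lo,
        med=med,
        hi=hi,
        source="pooled_follicles",
        meta={"n_curves": len(curves)},
    )


def csr_envelope(
    pp: PointPattern,
    n_sim: int = 99,
    rank: int = 3,
    r_grid: np.ndarray | None = None,
    seed: int = 0,
    bandwidth_rule: str = "stoyan",
    bandwidth: float | None = None,
    correction: str = "translation",
) -> SpatialCurve:
    """Pointwise rank envelope of g under CSR, conditional on the observed n.

    Simulates ``n_sim`` binomial patterns (n points uniform in the window —
    conditioning on n tests arrangement, not abundance), estimates g for
    each with the same settings as the observed curve, and returns the
    rank-th smallest/largest value per radius as lo/hi with the median as
    med. The pointwise two-sided exceedance level is 2 * rank / (n_sim + 1).
    """
    if n_sim < 19:
        raise ValueError("need at least 19 simulations for a meaningful envelope")
    if not 1 <= rank <= n_sim // 2:
        raise ValueError("rank must lie in [1, n_sim // 2]")
    if pp.n < 2:
        raise ValueError("pair correlation is undefined for fewer than 2 points")
    r = np.asarray(r_grid if r_grid is not None else default_r_grid(), dtype=float)
    rng = np.random.default_rng(seed)
    from .synthetic import _uniform_in_window  # local to avoid import cycle

    sims = np.empty((n_sim, len(r)))
    for s in range(n_sim):
        pts = _uniform_in_window(rng, pp.window, pp.n)
        sim_pp = PointPattern(pts, pp.window, pp.cell_type)
        sims[s] = pair_correlation(
            sim_pp, r, bandwidth_rule=bandwidth_rule, bandwidth=bandwidth,
            correction=correction,
        ).g
    sims.sort(axis=0)
    lo = sims[rank - 1]
    hi = sims[n_sim - rank]
    med = np.median(sims, axis=0)
    return SpatialCurve(
        r=r,
        lo=lo,
        med=med,
        hi=hi,
        source="csr_sim",
        meta={
            "n_sim": n_sim,
            "rank": rank,
            "pointwise_level": 2.0 * rank / (n_sim + 1),
            "seed": seed,
        },
    )


def classify_pattern(
    curve: SpatialCurve,
    envelope: SpatialCurve,
    r_band: tuple[float, float] = (2.0, 20.0),
    min_run: int = 3,
) -> tuple[str, np.ndarray]:
    """Call a pattern clustered, csr or regular against a CSR envelope.

    ``clustered`` if g exits above the envelope on a contiguous run of at
    least ``min_run`` grid points within ``r_band``; ``regular`` likewise
    below; otherwise ``csr``. Returns the call and the radii of the
    excursion (empty for csr).
    """
    if envelope.source != "csr_sim":
        raise ValueError("classification requires a CSR simulation envelope")
    if curve.g is None:
        raise ValueError("curve must carry g values")
    if len(curve.r) != len(envelope.r) or not np.allclose(curve.r, envelope.r):
        raise ValueError("curve and envelope must share an identical r grid")
    lo_r, hi_r = r_band
    band = (curve.r >= lo_r) & (curve.r <= hi_r)
    if not band.any():
        raise ValueError("r_band does not intersect the radius grid")

    def _longest_run(flag: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(flag & band)
        if len(idx) == 0:
            return np.zeros(0, dtype=int)
        splits = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        best = max(splits, key=len)
        return best if len(best) >= min_run else np.zeros(0, dtype=int)

    up = _longest_run(curve.g > envelope.hi)
    down = _longest_run(curve.g < envelope.lo)
    if len(up) >= min_run and len(up) >= len(down):
        return "clustered", curve.r[up]
    if len(down) >= min_run:
        return "regular", curve.r[down]
    return "csr", np.zeros(0)


def compare_densities(
    group_a, group_b
) -> tuple[float, float, float, float]:
    """Welch two-sample two-sided t-test on per-follicle densities.

    Returns (t, p, mean_a, mean_b). Two groups with zero variance and equal
    means are non-informative; by convention t = 0, p = 1 in that case.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.0, 1.0, float(a.mean()), float(b.mean())
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), float(a.mean()), float(b.mean())


def clark_evans_index(pp: PointPattern) -> float:
    """Clark-Evans aggregation index: observed mean nearest-neighbor distance
    over the CSR expectation 1 / (2 sqrt(lambda)). Values < 1 indicate
    clustering, > 1 regularity. No edge correction (brute force)."""
    if pp.n < 2:
        raise ValueError("need at least 2 points")
    pts = pp.points
    diff = pts[None, :, :] - pts[:, None, :]
    d = np.hypot(diff[..., 0], diff[..., 1])
    np.fill_diagonal(d, np.inf)
    mean_nn = d.min(axis=1).mean()
    lam = pp.intensity_hat_um2
    return float(mean_nn * 2.0 * np.sqrt(lam))
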