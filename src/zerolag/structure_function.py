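"""Structure-function concordance, penalisation correlation, and mediation.

The analyses here connect functional connectivity estimates to the
structural connectome: per-participant rank concordance between a
functional adjacency matrix and the log-streamline-count matrix, the
correlation between phase-delay penalisation and streamline count, a
transmission-time proxy (tract length divided by HMOA, a conduction-speed
surrogate), and a percentile-bootstrap mediation analysis of the causal
chain structural strength -> transmission time -> phase-delay
penalisability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class LocationTestResult:
    statistic: float
    p_value: float
    p_corrected: float
    test_used: str              # "t" or "wilcoxon"
    normality_p: float
    n: int


@dataclass
class MediationResult:
    """Linear-model mediation paths with a percentile bootstrap CI.

    Paths follow the standard notation: a (X -> M), b (M -> Y given X),
    total effect c (Y ~ X), direct effect c' (X coefficient in Y ~ X + M);
    the indirect effect is a*b with c = c' + a*b holding exactly for the
    point estimates.
    """

    a: float
    b: float
    c: float
    c_prime: float
    indirect: float
    ci_low: float
    ci_high: float
    proportion_mediated: float       # nan when |c| is below tolerance
    n_boot: int
    n_obs: int


def _upper(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    iu = np.triu_indices(v.shape[0], k=1)
    return v[iu]


def structure_function_concordance(fc_matrix: np.ndarray,
                                   structural_log_count: np.ndarray) -> float:
    """Spearman rho between functional and log-count strict upper triangles.

    Returns NaN when either matrix is constant over its edges.
    """
    fc = _upper(fc_matrix)
    sc = _upper(structural_log_count)
    if fc.shape != sc.shape:
        raise ValueError("matrices must share region order and size")
    ok = ~(np.isnan(fc) | np.isnan(sc))
    fc, sc = fc[ok], sc[ok]
    if fc.size < 3 or np.allclose(fc, fc[0]) or np.allclose(sc, sc[0]):
        warnings.warn("constant input: concordance undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(fc, sc)
    return float(rho)


def group_location_test(values: np.ndarray, mu: float = 0.0,
                        alternative: str = "two-sided",
                        n_comparisons: int = 1,
                        normality_alpha: float = 0.05) -> LocationTestResult:
    """One-sample location test against mu with a normality screen.

    Shapiro-Wilk at ``normality_alpha`` selects between a one-sample t-test
    and the Wilcoxon signed-rank test; the raw p-value is Bonferroni
    corrected for the family size declared by the caller.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 5:
        raise ValueError("need at least 5 observations")
    if np.allclose(v, v[0]):
        warnings.warn("all values identical: location test degenerate",
                      stacklevel=2)
        return LocationTestResult(float("nan"), float("nan"), float("nan"),
                                  "degenerate", float("nan"), v.size)
    _, norm_p = stats.shapiro(v)
    if norm_p >= normality_alpha:
        stat, p = stats.ttest_1samp(v, mu, alternative=alternative)
        used = "t"
    else:
        stat, p = stats.wilcoxon(v - mu, alternative=alternative)
        used = "wilcoxon"
    return LocationTestResult(float(stat), float(p),
                              min(1.0, float(p) * n_comparisons), used,
                              float(norm_p), v.size)


def transmission_time_proxy(median_length_mm: np.ndarray,
                            median_hmoa: np.ndarray) -> np.ndarray:
    """Tract length / HMOA: a per-pair proxy of signal transmission time.

    HMOA proxies conduction speed (myelination correlates with nerve
    conduction velocity), so dividing tract length by it yields a relative
    transmission time in arbitrary units.  Pairs with HMOA <= 0 are excluded
    (NaN) -- elementwise on scalars or matrices.
    """
    length = np.asarray(median_length_mm, dtype=float)
    hmoa = np.asarray(median_hmoa, dtype=float)
    bad = hmoa <= 0
    if bad.any():
        warnings.warn(f"{int(bad.sum())} pair(s) with HMOA <= 0 excluded",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, length / np.where(bad, 1.0, hmoa))
    return float(out) if out.ndim == 0 else out


def penalisation_structure_correlation(penalisation_matrix: np.ndarray,
                                       streamline_count: np.ndarray) -> float:
    """Spearman rho between penalisation values and streamline counts,
    over region pairs with at least one streamline."""
    pen = _upper(penalisation_matrix)
    cnt = _upper(streamline_count)
    ok = (cnt >= 1) & ~np.isnan(pen)
    if ok.sum() < 10:
        warnings.warn(f"only {int(ok.sum())} eligible pairs with streamlines",
                      stacklevel=2)
    if ok.sum() < 3:
        return float("nan")
    rho, _ = stats.spearmanr(pen[ok], cnt[ok])
    return float(rho)


def transmission_fc_correlation(proxy: np.ndarray,
                                fc_matrix: np.ndarray) -> float:
    """Spearman rho between transmission-time proxy and connectivity strength
    over connected pairs (negative when quicker tracts connect stronger)."""
    pr = _upper(proxy)
    fc = _upper(fc_matrix)
    ok = ~(np.isnan(pr) | np.isnan(fc))
    if ok.sum() < 3:
        return float("nan")
    rho, _ = stats.spearmanr(pr[ok], fc[ok])
    return float(rho)


# ---------------------------------------------------------------------------
# mediation


def _slope(x: np.ndarray, y: np.ndarray, axis=-1):
    """OLS slope of y on x (with intercept), vectorised over leading axes."""
    xm = x.mean(axis=axis, keepdims=True)
    ym = y.mean(axis=axis, keepdims=True)
    xc = x - xm
    return ((xc * (y - ym)).sum(axis=axis)) / ((xc ** 2).sum(axis=axis))


def _two_predictor_coefs(x: np.ndarray, m: np.ndarray, y: np.ndarray):
    """Coefficients (b_x, b_m) of y ~ 1 + x + m, vectorised over leading axes."""
    xc = x - x.mean(axis=-1, keepdims=True)
    mc = m - m.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    sxx = (xc * xc).sum(axis=-1)
    smm = (mc * mc).sum(axis=-1)
    sxm = (xc * mc).sum(axis=-1)
    sxy = (xc * yc).sum(axis=-1)
    smy = (mc * yc).sum(axis=-1)
    det = sxx * smm - sxm ** 2
    bx = (smm * sxy - sxm * smy) / det
    bm = (sxx * smy - sxm * sxy) / det
    return bx, bm


_C_TOL = 1e-12


def mediation_bootstrap(x: np.ndarray, m: np.ndarray, y: np.ndarray,
                        n_boot: int = 1000,
                        seed: int | np.random.Generator = 0,
                        ci: float = 95.0) -> MediationResult:
    """Percentile-bootstrap mediation of X on Y through M (linear paths).

    Point estimates come from three OLS fits (Y~X for c; M~X for a;
    Y~X+M for c' and b); the unstandardised indirect effect a*b is
    recomputed on ``n_boot`` resamples of the observations and its CI taken
    at the (100-ci)/2 and (100+ci)/2 percentiles.  The proportion mediated
    a*b/c is NaN when |c| is below tolerance.
    """
    x = np.asarray(x, dtype=float).ravel()
    m = np.asarray(m, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = ~(np.isnan(x) | np.isnan(m) | np.isnan(y))
    x, m, y = x[ok], m[ok], y[ok]
    n = x.size
    if n < 30:
        raise ValueError("need at least 30 pair-level observations")
    if n_boot < 200:
        raise ValueError("need at least 200 bootstrap resamples")
    a = float(_slope(x, m))
    c = float(_slope(x, y))
    c_prime, b = _two_predictor_coefs(x, m, y)
    c_prime, b = float(c_prime), float(b)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, mb, yb = x[idx], m[idx], y[idx]
    ab = _slope(xb, mb)
    _, bb = _two_predictor_coefs(xb, mb, yb)
    indirect_boot = ab * bb
    lo, hi = np.percentile(indirect_boot, [(100 - ci) / 2, (100 + ci) / 2])
    indirect = a * b
    if abs(c) < _C_TOL:
        warnings.warn("total effect c ~ 0: proportion mediated undefined",
                      stacklevel=2)
        prop = float("nan")
    else:
        prop = indirect / c
    return MediationResult(a=a, b=b, c=c, c_prime=c_prime, indirect=indirect,
                           ci_low=float(lo), ci_high=float(hi),
                           proportion_mediated=prop, n_boot=n_boot, n_obs=n)
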