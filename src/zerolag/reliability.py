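"""Test-retest reliability: edgewise ICC(2,1) and whole-matrix consistency.

Absolute agreement between two epochs recorded minutes apart is quantified
per edge with the Shrout-Fleiss ICC(2,1) -- two-way random effects, absolute
agreement, single measurement -- with negative estimates clamped to 0.
Consistency of the whole adjacency matrix is the Spearman correlation of the
strict upper triangles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import build_matrices
from .spectral import BANDS
from .synthetic import Cohort

#: ICC interpretation bins (Koo & Li convention).
ICC_BINS = (
    (0.9, "excellent"), (0.75, "good"), (0.5, "moderate"), (0.0, "poor"),
)


def interpret_icc(value: float) -> str:
    for lo, label in ICC_BINS:
        if value >= lo:
            return label
    return "poor"


def icc_2_1(values_a: np.ndarray, values_b: np.ndarray,
            clamp_negative: bool = True) -> np.ndarray:
    """Vectorised ICC(2,1) across the trailing axes.

    ``values_a`` and ``values_b`` are measurement-1 and measurement-2 values
    with participants along axis 0 and any number of edge axes after; the
    ICC is computed independently per edge from the classical two-way ANOVA
    decomposition with k = 2 measurements.  Edges where either epoch has a
    missing (NaN) value in any participant are returned as NaN.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("epoch value arrays must have matching shapes")
    n = a.shape[0]
    if n < 3:
        raise ValueError("ICC(2,1) needs at least 3 participants")
    k = 2.0
    x = np.stack([a, b])                       # (2, n, ...)
    grand = x.mean(axis=(0, 1))
    row_mean = x.mean(axis=0)                  # per participant
    col_mean = x.mean(axis=1)                  # per measurement occasion
    ss_total = ((x - grand) ** 2).sum(axis=(0, 1))
    ss_rows = k * ((row_mean - grand) ** 2).sum(axis=0)
    ss_cols = n * ((col_mean - grand) ** 2).sum(axis=0)
    ss_err = ss_total - ss_rows - ss_cols
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + k * (ms_cols - ms_err) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        icc = (ms_rows - ms_err) / denom
    degenerate = denom <= 0
    if np.any(degenerate):
        warnings.warn("zero between-subject variance: ICC set to 0",
                      stacklevel=2)
        icc = np.where(degenerate, 0.0, icc)
    if clamp_negative:
        icc = np.clip(icc, 0.0, None)
    return icc


def consistency_spearman(matrix_a: np.ndarray, matrix_b: np.ndarray) -> float:
    """Spearman rho between the strict upper triangles of two matrices.

    Returns NaN (flagged sentinel) when either triangle is constant.
    """
    a = np.asarray(matrix_a, dtype=float)
    b = np.asarray(matrix_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square with matching shape")
    iu = np.triu_indices(a.shape[0], k=1)
    va, vb = a[iu], b[iu]
    ok = ~(np.isnan(va) | np.isnan(vb))
    va, vb = va[ok], vb[ok]
    if np.allclose(va, va[0]) or np.allclose(vb, vb[0]):
        warnings.warn("constant matrix: consistency undefined", stacklevel=2)
        return float("nan")
    rho, _ = stats.spearmanr(va, vb)
    return float(rho)


@dataclass
class ReliabilityResult:
    """Edgewise ICC matrices and per-participant consistency, one method/band."""

    method: str
    band: str
    icc: np.ndarray                   # (R, R) symmetric, clamped at 0
    median_icc: float
    consistency: np.ndarray           # per-participant Spearman rho
    interpretation: str


def reliability_by_band(cohort: Cohort,
                        methods=("coherence", "img_coh", "plv", "wpli",
                                 "aec", "orth_aec"),
                        bands=tuple(BANDS)) -> tuple[list[ReliabilityResult],
                                                     pd.DataFrame]:
    """Edgewise ICC(2,1) and consistency for every method x band.

    Connectivity matrices are computed for both epochs of each participant;
    edges with sentinel (NaN) values are dropped pairwise per edge (the edge
    is excluded for all participants).  Returns the per-combination results
    and a tidy summary table of median edgewise ICCs.
    """
    r = cohort.geometry.n_regions
    mats_a = {(m, b): [] for m in methods for b in bands}
    mats_b = {(m, b): [] for m in methods for b in bands}
    for epoch_a, epoch_b in cohort.epochs:
        for band in bands:
            out_a, _ = build_matrices(epoch_a, band, methods)
            out_b, _ = build_matrices(epoch_b, band, methods)
            for m in methods:
                mats_a[(m, band)].append(out_a[m].weights)
                mats_b[(m, band)].append(out_b[m].weights)
    results = []
    rows = []
    iu = np.triu_indices(r, k=1)
    for m in methods:
        for band in bands:
            a = np.stack(mats_a[(m, band)])      # (P, R, R)
            b = np.stack(mats_b[(m, band)])
            edge_ok = ~(np.isnan(a).any(axis=0) | np.isnan(b).any(axis=0))
            a = np.where(edge_ok, a, np.nan)
            b = np.where(edge_ok, b, np.nan)
            icc = icc_2_1(a, b)
            icc[~edge_ok] = np.nan
            np.fill_diagonal(icc, 0.0)
            vals = icc[iu]
            median = float(np.nanmedian(vals))
            cons = np.array([consistency_spearman(a[p], b[p])
                             for p in range(a.shape[0])])
            results.append(ReliabilityResult(
                method=m, band=band, icc=icc, median_icc=median,
                consistency=cons, interpretation=interpret_icc(median)))
            rows.append({"method": m, "band": band, "median_icc": median,
                         "mean_consistency": float(np.nanmean(cons)),
                         "interpretation": interpret_icc(median)})
    return results, pd.DataFrame(rows)
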