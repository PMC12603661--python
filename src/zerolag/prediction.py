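"""Delta-R^2 evaluation of connectivity-derived predictors.

The quantity of interest throughout is the change in out-of-sample R^2 when
a connectivity-derived predictor (mean strength, or normalised pathlength)
is added to a covariate-only baseline model: 10-fold cross-validation for
predicting current age over head circumference, leave-one-out
cross-validation for longitudinal working-memory change, permutation tests
for inclusive-versus-exclusive method contrasts, and an interaction screen
recommending age stratification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests


@dataclass
class DeltaR2Result:
    r2_model1: float
    r2_model2: float
    delta: float
    cv_scheme: str
    permutation_p: float | None = None
    fdr_p: float | None = None


def mean_strength(w: np.ndarray) -> float:
    """Mean of the strict-upper-triangle edge weights of a symmetric matrix."""
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("expected a square matrix")
    iu = np.triu_indices(w.shape[0], k=1)
    return float(np.nanmean(w[iu]))


def _pooled_oof_r2(y: np.ndarray, design: np.ndarray, folds) -> float:
    """Out-of-fold R^2 = 1 - SSE/SST on pooled held-out predictions."""
    pred = np.empty_like(y)
    for train, test in folds:
        coef, *_ = np.linalg.lstsq(design[train], y[train], rcond=None)
        pred[test] = design[test] @ coef
    sst = ((y - y.mean()) ** 2).sum()
    return float(1.0 - ((y - pred) ** 2).sum() / sst)


def _design(*columns: np.ndarray) -> np.ndarray:
    cols = [np.ones(columns[0].size)] + [np.asarray(c, float).ravel()
                                         for c in columns]
    return np.column_stack(cols)


def _kfold(n: int, k: int, seed: int) -> list:
    folds = list(KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n)))
    if any(len(test) < 2 for _, test in folds):
        raise ValueError("a fold has fewer than 2 observations")
    return folds


def cv_delta_r2(age: np.ndarray, head_circumference: np.ndarray,
                predictor: np.ndarray, k: int = 10,
                seed: int = 0) -> DeltaR2Result:
    """10-fold CV delta R^2 of a predictor over head circumference alone.

    The same fold assignment (a function of n, k and seed only) is used for
    both the covariate-only model and the augmented model, so the delta
    isolates the predictor's added value.
    """
    y = np.asarray(age, dtype=float).ravel()
    hc = np.asarray(head_circumference, dtype=float).ravel()
    pred = np.asarray(predictor, dtype=float).ravel()
    n = y.size
    if n < 3 * k:
        raise ValueError(f"need n >= 3k observations (n={n}, k={k})")
    if np.isnan(np.concatenate([y, hc, pred])).any():
        raise ValueError("missing covariates; exclude upstream")
    folds = _kfold(n, k, seed)
    r2_1 = _pooled_oof_r2(y, _design(hc), folds)
    r2_2 = _pooled_oof_r2(y, _design(hc, pred), folds)
    return DeltaR2Result(r2_1, r2_2, r2_2 - r2_1, cv_scheme=f"{k}-fold")


def permutation_delta_test(age: np.ndarray, hc: np.ndarray,
                           predictor_pairs: dict,
                           k: int = 10, n_perm: int = 1000,
                           seed: int = 0) -> pd.DataFrame:
    """Permutation test of inclusive-vs-exclusive delta-R^2 differences.

    ``predictor_pairs`` maps a label (e.g. ``("plv", "wpli", "alpha")``) to
    an ``(inclusive_predictor, exclusive_predictor)`` tuple.  The observed
    statistic per pair is delta_inclusive - delta_exclusive; its null
    distribution is obtained by permuting age while keeping both predictors
    and the folds fixed.  Two-sided p-values are Benjamini-Hochberg
    corrected across the declared family.
    """
    if not predictor_pairs:
        return pd.DataFrame(columns=["pair", "observed_diff", "p_raw",
                                     "p_fdr"])
    y = np.asarray(age, dtype=float).ravel()
    hc = np.asarray(hc, dtype=float).ravel()
    n = y.size
    folds = _kfold(n, k, seed)
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(n) for _ in range(n_perm)])

    def both_deltas(y_use):
        base = _pooled_oof_r2(y_use, _design(hc), folds)
        out = {}
        for label, (inc, exc) in predictor_pairs.items():
            d_inc = _pooled_oof_r2(y_use, _design(hc, inc), folds) - base
            d_exc = _pooled_oof_r2(y_use, _design(hc, exc), folds) - base
            out[label] = d_inc - d_exc
        return out

    observed = both_deltas(y)
    null = {label: np.empty(n_perm) for label in predictor_pairs}
    for p in range(n_perm):
        shuffled = both_deltas(y[perms[p]])
        for label in predictor_pairs:
            null[label][p] = shuffled[label]
    rows = []
    for label in predictor_pairs:
        obs = observed[label]
        p_val = (1.0 + np.sum(np.abs(null[label]) >= abs(obs))) / (n_perm + 1.0)
        rows.append({"pair": label, "observed_diff": obs, "p_raw": p_val})
    table = pd.DataFrame(rows)
    table["p_fdr"] = multipletests(table["p_raw"], method="fdr_bh")[1]
    return table


def loocv_delta_r2(outcome_change: np.ndarray, covariates: np.ndarray,
                   pathlength: np.ndarray) -> DeltaR2Result:
    """Leave-one-out CV delta R^2 of pathlength over a fixed covariate set.

    Uses the closed-form LOOCV residuals e_i / (1 - h_ii) of each linear
    model.  Raises on singular designs, naming the collinear columns.
    """
    y = np.asarray(outcome_change, dtype=float).ravel()
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != y.size:
        cov = cov.T
    pl = np.asarray(pathlength, dtype=float).ravel()
    if y.size < 10:
        raise ValueError("need at least 10 observations for LOOCV")

    def loocv_r2(design: np.ndarray) -> float:
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # identify offending columns by leave-one-column-out rank
            bad = [c for c in range(design.shape[1])
                   if np.linalg.matrix_rank(np.delete(design, c, axis=1)) == rank]
            raise ValueError(f"singular design; collinear columns: {bad}")
        coef, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        h = np.einsum("ij,jk,ik->i", design,
                      np.linalg.inv(design.T @ design), design)
        e_loo = resid / (1.0 - h)
        sst = ((y - y.mean()) ** 2).sum()
        return float(1.0 - (e_loo ** 2).sum() / sst)

    base = np.column_stack([np.ones(y.size), cov])
    r2_1 = loocv_r2(base)
    r2_2 = loocv_r2(np.column_stack([base, pl]))
    return DeltaR2Result(r2_1, r2_2, r2_2 - r2_1, cv_scheme="loocv")


@dataclass
class InteractionScreen:
    coefficient: float
    std_error: float
    p_value: float
    stratify: bool               # recommend age-stratified models


def interaction_screen(outcome_change: np.ndarray, pathlength: np.ndarray,
                       age: np.ndarray, alpha: float = 0.05) -> InteractionScreen:
    """GLM with a pathlength x age interaction over the pooled age range.

    A significant interaction indicates the pathlength-outcome slope differs
    across ages, recommending stratified (per-age-group) models.
    """
    y = np.asarray(outcome_change, dtype=float).ravel()
    pl = np.asarray(pathlength, dtype=float).ravel()
    a = np.asarray(age, dtype=float).ravel()
    design = sm.add_constant(np.column_stack([pl, a, pl * a]))
    fit = sm.OLS(y, design).fit()
    coef, se, p = fit.params[-1], fit.bse[-1], fit.pvalues[-1]
    return InteractionScreen(float(coef), float(se), float(p), bool(p < alpha))


def select_covariates_aic(y: np.ndarray, candidates: pd.DataFrame) -> list[str]:
    """Exhaustive AIC search over candidate covariate subsets (OLS fits).

    Returns the column names of the AIC-minimising subset (possibly empty);
    intended to be run once per age group and then frozen for all methods.
    """
    from itertools import combinations
    y = np.asarray(y, dtype=float).ravel()
    best_cols: tuple = ()
    best_aic = np.inf
    names = list(candidates.columns)
    for r in range(len(names) + 1):
        for cols in combinations(names, r):
            x = sm.add_constant(candidates[list(cols)].to_numpy()) if cols \
                else np.ones((y.size, 1))
            aic = sm.OLS(y, x).fit().aic
            if aic < best_aic:
                best_aic, best_cols = aic, cols
    return list(best_cols)
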