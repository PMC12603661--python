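"""Bivariate functional connectivity estimators and mean phase delays.

Six estimators are implemented in matched zero-phase-inclusive /
zero-phase-exclusive pairs:

================  =========================  =============================
inclusive         exclusive counterpart      source decomposition
================  =========================  =============================
coherence         imaginary coherency        Welch cross-spectra
PLV               wPLI                       Hilbert phases / cross-spectra
AEC               orthogonalised AEC         Hilbert envelopes
================  =========================  =============================

The exclusive variants suppress interactions whose cross-spectrum is real
(zero or pi phase lag), which removes signal-leakage artefact but also any
genuine zero-phase synchrony.  The mean phase delay tau_ij of a pair is the
circular mean of the instantaneous Hilbert phase differences over the epoch,
i.e. the angle of the complex resultant (1/N) sum_t exp(i * dtheta(t)).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .spectral import (AnalyticSeries, CrossSpectra, RegionTimeSeries,
                       analytic_signal, band_edges, bandpass_filter, welch_csd)

logger = logging.getLogger(__name__)

ESTIMATORS = ("coherence", "img_coh", "plv", "wpli", "aec", "orth_aec")
INCLUSIVE = ("coherence", "plv", "aec")
EXCLUSIVE = ("img_coh", "wpli", "orth_aec")
#: inclusive method -> methodologically corresponding exclusive method
METHOD_PAIRS = {"coherence": "img_coh", "plv": "wpli", "aec": "orth_aec"}

_RESULTANT_TOL = 1e-12
_AUTOSPEC_REL_TOL = 1e-12


@dataclass
class ConnectivityMatrix:
    """Symmetric non-negative edge weights for one estimator and band."""

    weights: np.ndarray
    method: str
    band: str
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("connectivity weights must be a square matrix")
        self.weights = w

    def upper_values(self) -> np.ndarray:
        """Strict-upper-triangle edge values (the canonical edge vector)."""
        iu = np.triu_indices(self.weights.shape[0], k=1)
        return self.weights[iu]


@dataclass
class PhaseDelayMatrix:
    """Circular-mean phase delays tau_ij in (-pi, pi] plus resultant lengths."""

    tau: np.ndarray
    resultant: np.ndarray
    band: str
    region_names: list[str] | None = None

    def abs_tau(self) -> np.ndarray:
        """|tau| wrapped into [0, pi] (sign carries no penalisation meaning)."""
        return np.abs(wrap_angle(self.tau))


def wrap_angle(theta: np.ndarray | float) -> np.ndarray | float:
    """Wrap angles into (-pi, pi]."""
    wrapped = np.mod(np.asarray(theta) + np.pi, 2 * np.pi) - np.pi
    return np.where(wrapped == -np.pi, np.pi, wrapped)


# ---------------------------------------------------------------------------
# phase delay and PLV


def mean_phase_delay(theta_i: np.ndarray,
                     theta_j: np.ndarray) -> tuple[float, float]:
    """Circular-mean phase delay tau and resultant length R of theta_i - theta_j.

    Returns ``(nan, R)`` when the resultant is numerically zero (perfectly
    balanced phase differences), for which a mean direction is undefined.
    """
    theta_i = np.asarray(theta_i, dtype=float)
    theta_j = np.asarray(theta_j, dtype=float)
    if theta_i.shape != theta_j.shape:
        raise ValueError("phase series must have equal length")
    z = np.exp(1j * (theta_i - theta_j)).mean()
    r = float(np.abs(z))
    if r < _RESULTANT_TOL:
        return float("nan"), r
    return float(np.angle(z)), r


def plv(theta_i: np.ndarray, theta_j: np.ndarray) -> float:
    """Phase locking value: length of the mean resultant of exp(i*dtheta)."""
    theta_i = np.asarray(theta_i, dtype=float)
    theta_j = np.asarray(theta_j, dtype=float)
    if theta_i.shape != theta_j.shape:
        raise ValueError("phase series must have equal length")
    return float(np.abs(np.exp(1j * (theta_i - theta_j)).mean()))


def _resultant_matrix(analytic: AnalyticSeries) -> np.ndarray:
    e = np.exp(1j * analytic.phase)
    return e @ e.conj().T / analytic.phase.shape[1]


def phase_delay_matrix(analytic: AnalyticSeries,
                       region_names: list[str] | None = None) -> PhaseDelayMatrix:
    """All-pairs circular-mean phase delays from Hilbert phases."""
    z = _resultant_matrix(analytic)
    r = np.abs(z)
    tau = np.angle(z)
    tau[r < _RESULTANT_TOL] = np.nan
    np.fill_diagonal(tau, 0.0)
    np.fill_diagonal(r, 1.0)
    return PhaseDelayMatrix(tau=tau, resultant=r, band=analytic.band,
                            region_names=region_names)


def plv_matrix(analytic: AnalyticSeries,
               region_names: list[str] | None = None) -> ConnectivityMatrix:
    w = np.abs(_resultant_matrix(analytic))
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, "plv", analytic.band, region_names)


# ---------------------------------------------------------------------------
# spectral estimators


def _band_average(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Mean over band bins, restricted to bins flagged valid per pair."""
    n = valid.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(valid, values, 0.0).sum(axis=-1) / n
    return np.where(n > 0, out, np.nan)


def _coherency_terms(csd: CrossSpectra, band):
    bins = csd.band_bins(band)
    if bins.size == 0:
        raise ValueError(f"no frequency bins fall inside band {band!r}")
    s = csd.mean_csd()[:, :, bins]
    auto = csd.psd()[:, bins]
    denom_sq = auto[:, None, :] * auto[None, :, :]
    valid = denom_sq > _AUTOSPEC_REL_TOL * max(denom_sq.max(), np.finfo(float).tiny)
    if not valid.all():
        warnings.warn("skipping frequency bins with (near-)zero autospectrum",
                      stacklevel=3)
    with np.errstate(invalid="ignore", divide="ignore"):
        coherency = s / np.sqrt(denom_sq)
    return coherency, valid


def coherence_matrix(csd: CrossSpectra, band,
                     region_names: list[str] | None = None) -> ConnectivityMatrix:
    """Band-averaged |coherency| for all pairs."""
    coherency, valid = _coherency_terms(csd, band)
    w = _band_average(np.abs(coherency), valid)
    np.fill_diagonal(w, 0.0)
    tag = band if isinstance(band, str) else csd.band
    return ConnectivityMatrix(w, "coherence", tag, region_names)


def imag_coherency_matrix(csd: CrossSpectra, band,
                          region_names: list[str] | None = None) -> ConnectivityMatrix:
    """Band-averaged |Im(coherency)| -- per-bin magnitude, then band mean."""
    coherency, valid = _coherency_terms(csd, band)
    w = _band_average(np.abs(coherency.imag), valid)
    np.fill_diagonal(w, 0.0)
    tag = band if isinstance(band, str) else csd.band
    return ConnectivityMatrix(w, "img_coh", tag, region_names)


def coherence(csd: CrossSpectra, pair: tuple[int, int], band) -> float:
    i, j = pair
    return float(coherence_matrix(csd, band).weights[i, j]) if i != j else 1.0


def imag_coherency(csd: CrossSpectra, pair: tuple[int, int], band) -> float:
    i, j = pair
    return float(imag_coherency_matrix(csd, band).weights[i, j]) if i != j else 0.0


def wpli_from_imag_segments(imag_values: np.ndarray) -> float:
    """wPLI from per-segment imaginary cross-spectrum values at one bin:
    |E{Im}| / E{|Im|}, defined as 0 when E{|Im|} = 0 (pure zero-lag)."""
    v = np.asarray(imag_values, dtype=float)
    den = np.abs(v).mean()
    if den == 0.0:
        logger.info("wPLI denominator E{|Im|} = 0 (pure zero-lag); returning 0")
        return 0.0
    return float(np.abs(v.mean()) / den)


def wpli_matrix(csd: CrossSpectra, band,
                region_names: list[str] | None = None) -> ConnectivityMatrix:
    """Weighted phase lag index, expectation over Welch segments, band mean."""
    bins = csd.band_bins(band)
    if bins.size == 0:
        raise ValueError(f"no frequency bins fall inside band {band!r}")
    if csd.n_segments < 2:
        warnings.warn("wPLI expectation over a single segment is degenerate "
                      "(value is 0 or 1 by construction)", stacklevel=2)
    z = csd.segments[:, :, bins]
    # E over segments of Im(S_ij) and |Im(S_ij)|, per pair per bin
    if z.shape[0] ** 2 * z.shape[1] * bins.size < 4_000_000:
        imag = np.imag(z[:, None, :, :] * z.conj()[None, :, :, :])
        num = np.abs(imag.mean(axis=2))
        den = np.abs(imag).mean(axis=2)
    else:  # large problems: loop rows to bound memory
        r = z.shape[0]
        num = np.empty((r, r, bins.size))
        den = np.empty((r, r, bins.size))
        for i in range(r):
            im = np.imag(z[i, None, :, :] * z.conj()[:, :, :])
            num[i] = np.abs(im.mean(axis=1))
            den[i] = np.abs(im).mean(axis=1)
    zero_den = den == 0.0
    if zero_den.any():
        off = zero_den.copy()
        off[np.arange(off.shape[0]), np.arange(off.shape[0]), :] = False
        if off.any():
            logger.info("wPLI: %d pair-bins with E{|Im|}=0 set to 0 by convention",
                        int(off.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(zero_den, 0.0, num / np.where(zero_den, 1.0, den))
    w = ratio.mean(axis=-1)
    np.fill_diagonal(w, 0.0)
    tag = band if isinstance(band, str) else csd.band
    return ConnectivityMatrix(w, "wpli", tag, region_names)


def wpli(csd: CrossSpectra, pair: tuple[int, int], band) -> float:
    i, j = pair
    return float(wpli_matrix(csd, band).weights[i, j])


# ---------------------------------------------------------------------------
# amplitude estimators


def aec(env_i: np.ndarray, env_j: np.ndarray) -> float:
    """|Pearson r| between two amplitude envelopes; nan if an envelope is flat."""
    env_i = np.asarray(env_i, dtype=float)
    env_j = np.asarray(env_j, dtype=float)
    if env_i.std() == 0.0 or env_j.std() == 0.0:
        warnings.warn("zero-variance envelope: AEC undefined", stacklevel=2)
        return float("nan")
    return float(np.abs(np.corrcoef(env_i, env_j)[0, 1]))


def aec_matrix(analytic: AnalyticSeries,
               region_names: list[str] | None = None) -> ConnectivityMatrix:
    env = analytic.envelope
    stds = env.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.abs(np.corrcoef(env))
    w[stds == 0.0, :] = np.nan
    w[:, stds == 0.0] = np.nan
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, "aec", analytic.band, region_names)


def _power_envelope(x: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Squared, log-transformed Hilbert envelope (rows = signals)."""
    a = analytic_signal(RegionTimeSeries(x, sampling_rate))
    return np.log(a.envelope ** 2 + 1e-300)


def _pearson_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation between matching rows of a and b."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    denom = np.sqrt((a ** 2).sum(axis=1) * (b ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a * b).sum(axis=1) / denom


_COLLINEAR_TOL = 1e-8


def orth_aec(x_i: np.ndarray, x_j: np.ndarray, sampling_rate: float) -> float:
    """Orthogonalised AEC of two band-limited signals.

    Each signal is orthogonalised to the other with a single epoch-wide OLS
    coefficient (the mild, time-domain form of leakage correction); power
    envelopes (squared, log-transformed Hilbert envelopes) of the reference
    and orthogonalised series are correlated in both directions and the two
    correlations averaged, reported as a magnitude.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    a_ij = float(x_i @ x_j) / float(x_j @ x_j)   # OLS slope of i on j
    a_ji = float(x_j @ x_i) / float(x_i @ x_i)
    res_i = x_i - a_ij * x_j                     # i orthogonalised to j
    res_j = x_j - a_ji * x_i
    if (np.linalg.norm(res_i) < _COLLINEAR_TOL * np.linalg.norm(x_i)
            or np.linalg.norm(res_j) < _COLLINEAR_TOL * np.linalg.norm(x_j)):
        warnings.warn("collinear signals: orthogonalised residual is null, "
                      "orthAEC set to 0", stacklevel=2)
        return 0.0
    p = _power_envelope(np.vstack([x_i, x_j, res_i, res_j]), sampling_rate)
    r1 = float(np.corrcoef(p[0], p[3])[0, 1])    # i vs j_perp_i
    r2 = float(np.corrcoef(p[1], p[2])[0, 1])    # j vs i_perp_j
    return abs((r1 + r2) / 2.0)


def orth_aec_matrix(ts: RegionTimeSeries,
                    region_names: list[str] | None = None) -> ConnectivityMatrix:
    """All-pairs orthogonalised AEC (column-batched residual Hilberts)."""
    x = ts.data
    r, _ = x.shape
    norms_sq = (x ** 2).sum(axis=1)
    p_ref = _power_envelope(x, ts.sampling_rate)
    # c[i, j] = corr(power envelope of j, power envelope of i orthogonalised to j)
    c = np.zeros((r, r))
    collinear = np.zeros((r, r), dtype=bool)
    for j in range(r):
        a = (x @ x[j]) / norms_sq[j]             # OLS slopes of every i on j
        resid = x - a[:, None] * x[j]
        rn = np.linalg.norm(resid, axis=1)
        bad = rn < _COLLINEAR_TOL * np.sqrt(norms_sq)
        collinear[:, j] |= bad
        p_res = _power_envelope(resid, ts.sampling_rate)
        c[:, j] = _pearson_rows(np.broadcast_to(p_ref[j], p_res.shape), p_res)
    w = np.abs((c + c.T) / 2.0)
    mask = collinear | collinear.T
    if mask[np.triu_indices(r, k=1)].any():
        warnings.warn("collinear region pairs: orthAEC set to 0", stacklevel=2)
    w[mask] = 0.0
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(w, "orth_aec", ts.band, region_names)


# ---------------------------------------------------------------------------
# orchestration


def build_matrices(epoch: RegionTimeSeries,
                   band: str | tuple[float, float],
                   methods=ESTIMATORS,
                   segment_seconds: float = 2.0,
                   overlap_fraction: float = 0.5,
                   ) -> tuple[dict[str, ConnectivityMatrix], PhaseDelayMatrix]:
    """Filter an epoch to a band and evaluate the requested estimators.

    Returns the estimator matrices keyed by method name together with the
    mean-phase-delay matrix of the band-filtered signals.  Broadband input is
    filtered here; input already tagged with a band is used as-is.
    """
    unknown = set(methods) - set(ESTIMATORS)
    if unknown:
        raise ValueError(f"unknown estimators: {sorted(unknown)}")
    ts = bandpass_filter(epoch, band) if epoch.band == "broadband" else epoch
    names = ts.region_names
    analytic = analytic_signal(ts)
    tau = phase_delay_matrix(analytic, names)
    out: dict[str, ConnectivityMatrix] = {}
    if {"coherence", "img_coh", "wpli"} & set(methods):
        csd = welch_csd(ts, segment_seconds, overlap_fraction)
        if "coherence" in methods:
            out["coherence"] = coherence_matrix(csd, band, names)
        if "img_coh" in methods:
            out["img_coh"] = imag_coherency_matrix(csd, band, names)
        if "wpli" in methods:
            out["wpli"] = wpli_matrix(csd, band, names)
    if "plv" in methods:
        out["plv"] = plv_matrix(analytic, names)
    if "aec" in methods:
        out["aec"] = aec_matrix(analytic, names)
    if "orth_aec" in methods:
        out["orth_aec"] = orth_aec_matrix(ts, names)
    return out, tau
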