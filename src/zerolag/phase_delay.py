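"""Near-zero phase-delay classification, leakage plateau, penalisation scale.

Signal leakage produces artefactual connectivity at exactly zero phase lag
and decays with Euclidean distance between sources, whereas genuine
zero-phase synchrony does not.  This module (i) classifies pair delays as
near-zero (within a threshold of 0 or +/-pi, the two lags that
phase-exclusive estimators suppress), (ii) profiles the near-zero proportion
against centroid distance and locates the distance beyond which the profile
is flat -- where leakage is likely negligible, (iii) provides the conduction
-delay worked values and the [0, 1] penalisation scale quantifying how hard
a given mean delay is down-weighted by zero-phase-exclusive estimators, and
(iv) runs the homotopic versus heterotopic interhemispheric contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .connectivity import wrap_angle
from .synthetic import RegionGeometry

NEAR_ZERO_THRESHOLD = 0.3   # radians from 0 or +/-pi


@dataclass
class NearZeroClassification:
    """Boolean near-zero mask and circular distance to the nearest of {0, pi}."""

    mask: np.ndarray            # True where near-zero (or near +/-pi)
    distance: np.ndarray        # radians to nearest of {0, pi}, in [0, pi/2]
    threshold: float


@dataclass
class DistanceProfile:
    """Proportion of near-zero pairs per Euclidean-distance bin."""

    bin_edges: np.ndarray       # (n_bins + 1,), mm
    proportion: np.ndarray      # (n_bins,), nan where the bin is empty
    counts: np.ndarray          # pooled pair observations per bin

    @property
    def bin_centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_mm": self.bin_edges[:-1], "bin_hi_mm": self.bin_edges[1:],
            "proportion_near_zero": self.proportion, "n_pairs": self.counts,
        })


@dataclass
class PlateauResult:
    """Leakage-negligibility distance and the flatness-test trace."""

    distance_mm: float | None    # smallest flat suffix start; None = no plateau
    trace: pd.DataFrame          # per-candidate start: rho, p, flat flag
    alpha: float


@dataclass
class HomotopicContrast:
    """Chi-squared contrast of near-zero proportions, homotopic vs heterotopic."""

    statistic: float
    dof: int
    p_value: float
    table: np.ndarray            # 2x2 [near, other] x [homotopic, heterotopic]
    n_per_group: int
    heterotopic_pairs: list = field(default_factory=list)


def distance_to_zero_or_pi(tau: np.ndarray) -> np.ndarray:
    """Circular distance from each delay to the nearest of {0, +/-pi}."""
    a = np.abs(wrap_angle(np.asarray(tau, dtype=float)))
    return np.minimum(a, np.pi - a)


def near_zero_mask(tau: np.ndarray,
                   threshold: float = NEAR_ZERO_THRESHOLD) -> NearZeroClassification:
    """Classify delays within ``threshold`` radians of 0 or +/-pi as near-zero."""
    if not 0.0 < threshold < np.pi / 2:
        raise ValueError("threshold must lie in (0, pi/2)")
    dist = distance_to_zero_or_pi(tau)
    return NearZeroClassification(mask=dist < threshold, distance=dist,
                                  threshold=threshold)


def circle_fraction(threshold: float) -> float:
    """Percent of the unit circle within ``threshold`` radians of 0 or +/-pi."""
    if not 0.0 < threshold <= np.pi / 2:
        raise ValueError("threshold must lie in (0, pi/2]")
    return 100.0 * (4.0 * threshold) / (2.0 * np.pi)


def conduction_phase_delay(length_mm: float, velocity_mps: float,
                           synaptic_delay_s: float, freq_hz: float) -> float:
    """Phase delay (rad, unwrapped) implied by axonal conduction + synapse:
    2*pi*f*(L/v + d)."""
    if velocity_mps <= 0:
        raise ValueError("conduction velocity must be positive")
    if length_mm < 0 or synaptic_delay_s < 0 or freq_hz < 0:
        raise ValueError("length, delay and frequency must be non-negative")
    return 2.0 * np.pi * freq_hz * (length_mm / 1000.0 / velocity_mps
                                    + synaptic_delay_s)


def penalisation_value(tau):
    """[0, 1] score of how hard a mean delay is penalised by zero-phase-
    exclusive estimators: ||tau| - pi/2| / (pi/2), with |tau| wrapped to
    [0, pi].  1 at 0 and +/-pi, 0 at +/-pi/2; elementwise on arrays."""
    a = np.abs(wrap_angle(np.asarray(tau, dtype=float)))
    out = np.abs(a - np.pi / 2.0) / (np.pi / 2.0)
    return float(out) if np.isscalar(tau) else out


def imgcoh_attenuation(phi) -> float | np.ndarray:
    """Percent reduction of a noiseless pair's strength by ImgCoh (or wPLI)
    relative to coherence at constant phase offset phi: 100 * (1 - |sin phi|)."""
    out = 100.0 * (1.0 - np.abs(np.sin(np.asarray(phi, dtype=float))))
    return float(out) if np.isscalar(phi) else out


# ---------------------------------------------------------------------------
# distance profile and plateau


def proportion_vs_distance(tau_matrices,
                           geometry: RegionGeometry,
                           bin_width_mm: float = 10.0,
                           threshold: float = NEAR_ZERO_THRESHOLD,
                           ) -> DistanceProfile:
    """Pool pairs across participants into distance bins; near-zero fraction.

    ``tau_matrices`` is an iterable of (R, R) mean-phase-delay matrices with
    region order matching ``geometry``.  Empty bins are reported with count 0
    and proportion NaN.
    """
    d = geometry.distance_matrix()
    iu = np.triu_indices(geometry.n_regions, k=1)
    dist = d[iu]
    edges = np.arange(0.0, dist.max() + bin_width_mm, bin_width_mm)
    n_bins = len(edges) - 1
    near = np.zeros(n_bins)
    total = np.zeros(n_bins)
    which = np.clip(np.digitize(dist, edges) - 1, 0, n_bins - 1)
    for tau in tau_matrices:
        tau = np.asarray(tau)
        if tau.shape != d.shape:
            raise ValueError("tau matrix shape does not match geometry")
        cls = near_zero_mask(tau[iu], threshold)
        ok = ~np.isnan(tau[iu])
        np.add.at(near, which[ok], cls.mask[ok])
        np.add.at(total, which[ok], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prop = np.where(total > 0, near / np.maximum(total, 1), np.nan)
    return DistanceProfile(bin_edges=edges, proportion=prop,
                           counts=total.astype(int))


def leakage_negligible_distance(profile: DistanceProfile,
                                flatness_alpha: float = 0.05,
                                min_suffix_bins: int = 5,
                                min_count_fraction: float = 0.05,
                                tail_tolerance: float = 0.05) -> PlateauResult:
    """Smallest distance beyond which the near-zero proportion is flat.

    A candidate start bin opens a flat suffix when, over the bins at or
    beyond it: (i) there is no *material* decreasing trend -- a trend counts
    only when the Spearman rank correlation between bin distance and
    proportion is significantly negative at ``flatness_alpha`` AND the
    count-weighted least-squares fit declines by more than
    ``tail_tolerance`` across the suffix (practical equivalence: with
    enough pooled pairs a rank test flags arbitrarily small declines that a
    graphical reading would call flat) -- and (ii) the start bin's own
    proportion lies within ``tail_tolerance`` of the count-weighted mean of
    the later bins (so a still-elevated bin cannot open the plateau merely
    because a rank test over few bins is underpowered).  Returns the left
    edge of the first such suffix, or a ``None`` sentinel when no suffix of
    at least ``min_suffix_bins`` bins qualifies.  Bins holding fewer than
    ``min_count_fraction`` of the best-populated bin's pair count are
    excluded from the scan: their binomial noise swamps any trend.  The
    result is invariant to uniform rescaling of pair counts.
    """
    counts_ok = profile.counts >= min_count_fraction * profile.counts.max()
    ok = ~np.isnan(profile.proportion) & counts_ok
    if ok.sum() < min_suffix_bins:
        raise ValueError(f"need at least {min_suffix_bins} well-populated bins")
    centers = profile.bin_centers[ok]
    props = profile.proportion[ok]
    weights = profile.counts[ok].astype(float)
    edges = profile.bin_edges[:-1][ok]
    rows = []
    found: float | None = None
    for start in range(len(centers) - min_suffix_bins + 1):
        x, y = centers[start:], props[start:]
        if np.allclose(y, y[0]):
            rho, p = 0.0, 1.0        # perfectly flat: no trend by definition
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", stats.ConstantInputWarning)
                rho, p = stats.spearmanr(x, y)
            if np.isnan(rho):
                rho, p = 0.0, 1.0
        tail = float(np.average(y[1:], weights=weights[start + 1:]))
        level_ok = y[0] <= tail + tail_tolerance
        slope = np.polyfit(x, y, 1, w=np.sqrt(weights[start:]))[0]
        fitted_decline = max(0.0, -slope * (x[-1] - x[0]))
        material_trend = (rho < 0 and p < flatness_alpha
                          and fitted_decline > tail_tolerance)
        flat = level_ok and not material_trend
        rows.append({"start_mm": edges[start], "n_bins": len(x),
                     "rho": rho, "p": p, "tail_level": tail,
                     "fitted_decline": fitted_decline, "flat": flat})
        if flat and found is None:
            found = float(edges[start])
    trace = pd.DataFrame(rows)
    return PlateauResult(distance_mm=found, trace=trace, alpha=flatness_alpha)


# ---------------------------------------------------------------------------
# homotopic contrast


def homotopic_contrast(masks,
                       geometry: RegionGeometry,
                       n_heterotopic_pairs: int | None = None,
                       seed: int = 0) -> HomotopicContrast:
    """Pearson chi-squared contrast of near-zero proportions.

    ``masks`` is an iterable of per-participant boolean near-zero matrices.
    Homotopic interhemispheric pairs are compared against an equally sized
    random sample (without replacement) of heterotopic interhemispheric
    pairs, pooling participant x pair observations into a 2x2 table.
    """
    masks = [np.asarray(m, dtype=bool) for m in masks]
    hp = geometry.homotopic_pairs()
    if not hp:
        raise ValueError("geometry defines no homotopic pairs")
    het = geometry.heterotopic_interhemispheric_pairs()
    k = n_heterotopic_pairs if n_heterotopic_pairs is not None else len(hp)
    if k > len(het):
        raise ValueError(f"requested {k} heterotopic pairs, only {len(het)} exist")
    rng = np.random.default_rng(seed)
    chosen = [het[i] for i in rng.choice(len(het), size=k, replace=False)]
    hi, hj = np.array([p[0] for p in hp]), np.array([p[1] for p in hp])
    gi, gj = np.array([p[0] for p in chosen]), np.array([p[1] for p in chosen])
    near_h = other_h = near_g = other_g = 0
    for m in masks:
        vh = m[hi, hj]
        vg = m[gi, gj]
        near_h += int(vh.sum())
        other_h += int((~vh).sum())
        near_g += int(vg.sum())
        other_g += int((~vg).sum())
    table = np.array([[near_h, other_h], [near_g, other_g]])
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        warnings.warn("chi-squared expected cell count < 5; reporting anyway",
                      stacklevel=2)
    if table[0].sum() != table[1].sum():
        warnings.warn("unequal pooled observations between groups", stacklevel=2)
    if (table.sum(axis=0) == 0).any():
        # degenerate: one outcome never observed -> proportions identical
        chi2, p, dof = 0.0, 1.0, 1
    else:
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return HomotopicContrast(statistic=float(chi2), dof=int(dof),
                             p_value=float(p), table=table,
                             n_per_group=int(table[0].sum()),
                             heterotopic_pairs=chosen)
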