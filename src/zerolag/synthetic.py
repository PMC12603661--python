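"""Synthetic cohort generator: geometry, connectomes, coupled epochs, outcomes.

The generator encodes the biology the downstream analyses assume, so the
whole pipeline can be exercised and validated without access-controlled EEG:

* a bilateral region layout with mirror-image homotopic partners,
* a structural connectome whose streamline counts decay with distance and
  are boosted across homotopic pairs, with tract lengths >= the straight-line
  distance and a microstructure measure (HMOA) coupled to streamline count,
* narrowband coupled oscillators in which a structurally connected
  follower region receives the leader's oscillation delayed by
  ``tract_length / velocity + synaptic_delay``, with conduction velocity
  proportional to HMOA -- so stronger/faster tracts plant phase delays
  closer to zero (the causal chain the mediation analysis must recover),
* homotopic pairs additionally share a zero-lag driver (a stand-in for
  resonance-induced synchrony),
* zero-lag signal leakage applied as a row-normalised Gaussian mixing
  matrix over centroid distance,
* paired test-retest epochs (identical coupling structure, independent
  noise) and covariate-linked outcomes: coupling strength rises with age,
  head circumference follows a saturating growth curve, and the change in
  working-memory errors is planted on the normalised pathlength of the
  participant's expected-coherence network over the working-memory
  subnetwork (the noise-free limit of what the estimation pipeline
  measures), with planted effect sizes recorded for recovery tests.

All randomness flows from one master seed through ``numpy.random.SeedSequence``
spawning, in a fixed order, so identical specs give bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .network import default_swm_rois, normalized_pathlength, subnetwork
from .spectral import RegionTimeSeries, band_edges

#: Desikan-Killiany cortical region base names (34 per hemisphere).
DK_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
)


@dataclass
class RegionGeometry:
    """Region labels, hemispheres, centroids (mm) and homotopic partnering."""

    names: list[str]
    hemisphere: np.ndarray          # 'L' or 'R' per region
    lobe: list[str]
    centroids: np.ndarray           # (R, 3) mm; x = 0 is the midline
    homotopic_partner: np.ndarray   # partner region index per region

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def distance_matrix(self) -> np.ndarray:
        diff = self.centroids[:, None, :] - self.centroids[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=-1))

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """Each mirror-image pair once, as (i, j) with i < j."""
        return [(i, int(j)) for i, j in enumerate(self.homotopic_partner)
                if i < j]

    def heterotopic_interhemispheric_pairs(self) -> list[tuple[int, int]]:
        """All cross-hemisphere pairs that are not homotopic partners."""
        out = []
        for i in range(self.n_regions):
            for j in range(i + 1, self.n_regions):
                if (self.hemisphere[i] != self.hemisphere[j]
                        and self.homotopic_partner[i] != j):
                    out.append((i, j))
        return out


def _lobe_of(y: float, z: float) -> str:
    if y > 15:
        return "frontal"
    if y < -55:
        return "occipital"
    return "parietal" if z > 15 else "temporal"


def make_geometry(n_regions: int = 68, seed: int = 0) -> RegionGeometry:
    """Bilateral layout with mirrored homotopic centroids.

    Left-hemisphere regions occupy indices ``0 .. n/2 - 1`` and their
    homotopic partners ``n/2 .. n - 1`` in the same order; centroids of a
    pair are mirror images in the x = 0 plane.
    """
    if n_regions < 4 or n_regions % 2:
        raise ValueError("n_regions must be an even count >= 4")
    half = n_regions // 2
    rng = np.random.default_rng(seed)
    for _ in range(100):
        x = rng.uniform(10.0, 55.0, half)
        y = rng.uniform(-68.0, 68.0, half)
        z = rng.uniform(-35.0, 50.0, half)
        right = np.column_stack([x, y, z])
        d = np.sqrt(((right[:, None] - right[None, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        if d.min() > 4.0:       # keep centroids comfortably distinct
            break
    left = right * np.array([-1.0, 1.0, 1.0])
    centroids = np.vstack([left, right])
    base = list(DK_REGIONS) if half == len(DK_REGIONS) else [
        f"region{k:02d}" for k in range(half)]
    names = [f"lh-{b}" for b in base] + [f"rh-{b}" for b in base]
    hemisphere = np.array(["L"] * half + ["R"] * half)
    partner = np.concatenate([np.arange(half) + half, np.arange(half)])
    lobe = [_lobe_of(c[1], c[2]) for c in centroids]
    return RegionGeometry(names=names, hemisphere=hemisphere, lobe=lobe,
                          centroids=centroids, homotopic_partner=partner)


# ---------------------------------------------------------------------------
# structural connectome


@dataclass
class StructuralConnectomeParams:
    """Generative knobs for the synthetic tractography tables."""

    amplitude: float = 300.0       # expected streamline count at zero distance
    decay_mm: float = 12.0         # exponential distance decay of counts
    homotopic_boost: float = 60.0  # multiplicative count boost, homotopic pairs
    tortuosity_sd: float = 0.15    # tract length = distance * (1 + |N(0, sd)|)
    hmoa_base: float = 0.02
    hmoa_slope: float = 0.06       # HMOA rises with normalised log count
    hmoa_noise: float = 0.15       # lognormal sd of HMOA noise
    poisson_noise: bool = True     # draw counts ~ Poisson(mean) vs round(mean)


@dataclass
class StructuralConnectome:
    """Per-pair streamline count, normalised log count, length and HMOA."""

    streamline_count: np.ndarray   # (R, R) non-negative, symmetric, 0 diag
    norm_log_count: np.ndarray     # log(1 + count) scaled to max 1
    median_length: np.ndarray      # mm, 0 where unconnected
    median_hmoa: np.ndarray        # > 0 where connected, 0 elsewhere
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        for m in (self.streamline_count, self.norm_log_count,
                  self.median_length, self.median_hmoa):
            if not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
                raise ValueError("connectome matrices must be symmetric with "
                                 "zero diagonal")
        if np.any(self.streamline_count < 0):
            raise ValueError("streamline counts must be non-negative")

    @property
    def connected(self) -> np.ndarray:
        return self.streamline_count >= 1


def normalised_log_count(counts: np.ndarray) -> np.ndarray:
    """log(1 + count), scaled so the strongest edge equals 1."""
    logc = np.log1p(np.asarray(counts, dtype=float))
    peak = logc.max()
    return logc / peak if peak > 0 else logc


def make_structural_connectome(geometry: RegionGeometry,
                               params: StructuralConnectomeParams | None = None,
                               seed: int | np.random.Generator = 0,
                               ) -> StructuralConnectome:
    """Distance-decaying streamline counts with a homotopic boost.

    Median tract length is the centroid distance times a tortuosity factor
    >= 1, and median HMOA increases with normalised log count (plus
    lognormal noise), so count and HMOA are positively rank-correlated.
    """
    params = params or StructuralConnectomeParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    d = geometry.distance_matrix()
    n = geometry.n_regions
    mean = params.amplitude * np.exp(-d / params.decay_mm)
    for i, j in geometry.homotopic_pairs():
        mean[i, j] *= params.homotopic_boost
        mean[j, i] = mean[i, j]
    iu = np.triu_indices(n, k=1)
    counts = np.zeros((n, n))
    vals = rng.poisson(mean[iu]).astype(float) if params.poisson_noise \
        else np.round(mean[iu])
    counts[iu] = vals
    counts = counts + counts.T
    connected = counts >= 1

    tort = np.zeros((n, n))
    tort[iu] = 1.0 + np.abs(rng.normal(0.0, params.tortuosity_sd, iu[0].size))
    tort = tort + tort.T
    length = np.where(connected, d * tort, 0.0)

    nlc = normalised_log_count(counts)
    hmoa = np.zeros((n, n))
    noise = np.exp(rng.normal(0.0, params.hmoa_noise, iu[0].size))
    hmoa[iu] = (params.hmoa_base + params.hmoa_slope * nlc[iu]) * noise
    hmoa = hmoa + hmoa.T
    hmoa = np.where(connected, hmoa, 0.0)

    return StructuralConnectome(streamline_count=counts, norm_log_count=nlc,
                                median_length=length, median_hmoa=hmoa,
                                region_names=list(geometry.names))


# ---------------------------------------------------------------------------
# coupled oscillator epochs


@dataclass
class SyntheticCohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults follow the emulated study: 68 regions, 153 participants,
    20-second epochs at 250 Hz, 4.5 m/s conduction velocity and 0.75 ms
    synaptic delay.  SNR and coupling magnitudes are calibration choices of
    the generator, not estimates of any real dataset.
    """

    n_regions: int = 68
    n_participants: int = 153
    sampling_rate: float = 250.0       # Hz
    epoch_seconds: float = 20.0
    conduction_velocity: float = 4.5   # m/s along white-matter tracts
    synaptic_delay: float = 0.00075    # s
    leakage_sigma: float = 20.0        # mm; 0 disables leakage mixing
    coupling_strength_range: tuple[float, float] = (0.5, 1.5)
    seed: int = 0
    # calibration choices (documented in the methods note)
    coupling_strength: float = 1.0     # global gain on directed coupling
    noise_level: float = 0.5           # broadband noise sd per unit-sd source
    homotopic_gain: float = 2.2        # zero-lag shared-driver gain
    zero_lag_fraction: float = 0.5     # fraction of regions in resonance-like
    zero_lag_gain: float = 1.5         # distance-independent zero-lag pairs
    hmoa_reference: float = 0.05       # HMOA mapping to nominal velocity
    osc_bands: tuple = ("theta", "alpha")
    age_coupling_slope: float = 1.0    # coupling gain rise over the age range
    coupling_individual_sd: float = 0.25  # age-independent per-person gain sd
    swm_beta: float = 8.0              # errors change per SD of true pathlength
    swm_noise: float = 2.0             # residual sd of the outcome change

    def __post_init__(self) -> None:
        positive = ("sampling_rate", "epoch_seconds", "conduction_velocity",
                    "hmoa_reference")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.synaptic_delay < 0 or self.leakage_sigma < 0:
            raise ValueError("synaptic_delay and leakage_sigma must be >= 0")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


def _narrowband_noise(rng: np.random.Generator, n_rows: int, n_samples: int,
                      fs: float, band) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise rows (filtered white noise)."""
    lo, hi = band_edges(band)
    taps = sps.firwin(251, [lo, hi], window="hamming", pass_zero=False, fs=fs)
    x = sps.fftconvolve(rng.standard_normal((n_rows, n_samples)),
                        taps[None, :], mode="same", axes=1)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def transmission_delays(connectome: StructuralConnectome,
                        spec: SyntheticCohortSpec) -> np.ndarray:
    """Planted pair delays in seconds: length / (v * hmoa/hmoa_ref) + synaptic.

    Zero where unconnected.  Conduction velocity scales with HMOA so
    microstructurally stronger tracts transmit faster.
    """
    connected = connectome.connected
    v_eff = spec.conduction_velocity * np.where(
        connected, connectome.median_hmoa / spec.hmoa_reference, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dt = (connectome.median_length / 1000.0) / v_eff + spec.synaptic_delay
    return np.where(connected, dt, 0.0)


def leakage_matrix(geometry: RegionGeometry, sigma_mm: float) -> np.ndarray:
    """Row-normalised Gaussian leakage mixing over centroid distance.

    ``sigma_mm`` is the width of each region's spatial mixing kernel.  Two
    regions additionally share mid-lying sources, so the pair-level
    artefact kernel is somewhat wider (by up to sqrt(2)); artefactual
    zero-lag coupling between a pair is negligible beyond roughly three to
    four sigma of separation.
    """
    if sigma_mm == 0:
        return np.eye(geometry.n_regions)
    d = geometry.distance_matrix()
    m = np.exp(-d ** 2 / (2.0 * sigma_mm ** 2))
    return m / m.sum(axis=1, keepdims=True)


def draw_zero_lag_pairs(n_regions: int, fraction: float,
                        rng: np.random.Generator) -> list[tuple[int, int]]:
    """Distance-independent resonance-like zero-lag pairs (a random matching).

    ``fraction`` is the fraction of regions participating; each region gets
    at most one extra zero-lag partner (besides its homotopic one), keeping
    the number of strong shared drivers per region bounded.
    """
    k = int(fraction * n_regions) // 2
    perm = rng.permutation(n_regions)
    return [tuple(sorted((int(perm[2 * i]), int(perm[2 * i + 1]))))
            for i in range(k)]


def coupling_gains(connectome: StructuralConnectome,
                   spec: SyntheticCohortSpec,
                   rng: np.random.Generator) -> np.ndarray:
    """Per-pair coupling gains: global strength x norm-log count x jitter."""
    n = connectome.streamline_count.shape[0]
    lo, hi = spec.coupling_strength_range
    iu = np.triu_indices(n, k=1)
    jitter = np.zeros((n, n))
    jitter[iu] = rng.uniform(lo, hi, iu[0].size)
    jitter = jitter + jitter.T
    gains = spec.coupling_strength * connectome.norm_log_count * jitter
    return np.where(connectome.connected, gains, 0.0)


@dataclass
class CouplingStructure:
    """One participant's coupling: fixed across their test-retest epochs.

    Individual differences in every gain (directed coupling, homotopic and
    resonance-like zero-lag drivers) are what make edgewise test-retest
    reliability meaningful: the structure is identical between a
    participant's two epochs while the oscillatory noise is independent.
    """

    gains: np.ndarray                       # (R, R) directed coupling gains
    homotopic_gains: np.ndarray             # per homotopic pair
    zero_lag_pairs: list[tuple[int, int]]
    zero_lag_gains: np.ndarray              # per zero-lag pair


def draw_coupling(geometry: RegionGeometry,
                  connectome: StructuralConnectome,
                  spec: SyntheticCohortSpec,
                  rng: np.random.Generator) -> CouplingStructure:
    """Draw a participant's full coupling structure (all gains jittered)."""
    lo, hi = spec.coupling_strength_range
    gains = coupling_gains(connectome, spec, rng)
    hp = geometry.homotopic_pairs()
    homotopic_gains = spec.homotopic_gain * rng.uniform(0.75, 1.25, len(hp))
    zl = draw_zero_lag_pairs(geometry.n_regions, spec.zero_lag_fraction, rng)
    zero_lag_gains = spec.zero_lag_gain * rng.uniform(0.75, 1.25, len(zl))
    return CouplingStructure(gains=gains, homotopic_gains=homotopic_gains,
                             zero_lag_pairs=zl, zero_lag_gains=zero_lag_gains)


def simulate_epoch(geometry: RegionGeometry,
                   connectome: StructuralConnectome,
                   spec: SyntheticCohortSpec,
                   band="alpha",
                   seed: int | np.random.Generator = 0,
                   coupling: CouplingStructure | None = None,
                   ) -> RegionTimeSeries:
    """One multichannel epoch of coupled narrowband oscillators plus leakage.

    ``band`` may be a band name, an explicit (lo, hi) tuple, or a sequence
    of bands whose oscillatory components are summed.  ``coupling`` fixes
    the participant's full coupling structure (used to give test-retest
    epoch pairs an identical structure); when omitted it is drawn here.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bands = [band] if isinstance(band, str) or (
        len(band) == 2 and isinstance(band[0], (int, float))) else list(band)
    fs = spec.sampling_rate
    n_samples = int(round(spec.epoch_seconds * fs))
    for b in bands:
        lo, hi = band_edges(b)
        if not (1.0 <= lo < hi < fs / 2):
            raise ValueError(f"band {b!r} outside [1, Nyquist) at fs={fs}")
    dt = transmission_delays(connectome, spec)
    if dt.max() >= spec.epoch_seconds:
        raise ValueError("planted transmission delay exceeds epoch length")
    d_samp = np.round(dt * fs).astype(int)
    buffer = int(d_samp.max())
    r = geometry.n_regions
    if coupling is None:
        coupling = draw_coupling(geometry, connectome, spec, rng)
    gains = coupling.gains
    hp = geometry.homotopic_pairs()
    x = np.zeros((r, n_samples))
    iu = np.triu_indices(r, k=1)
    coupled = [(int(i), int(j)) for i, j in zip(*iu) if gains[i, j] > 0]
    scale = 1.0 / np.sqrt(len(bands))
    for b in bands:
        src = _narrowband_noise(rng, r, n_samples + buffer, fs, b)
        x += scale * src[:, buffer:]
        # directed coupling: follower j receives leader i delayed by dt_ij
        for i, j in coupled:
            lag = d_samp[i, j]
            x[j] += scale * gains[i, j] * src[i, buffer - lag:
                                             n_samples + buffer - lag]
        drivers = _narrowband_noise(rng, len(hp), n_samples, fs, b)
        for k, (i, j) in enumerate(hp):     # shared zero-lag driver
            x[i] += scale * coupling.homotopic_gains[k] * drivers[k]
            x[j] += scale * coupling.homotopic_gains[k] * drivers[k]
        if coupling.zero_lag_pairs:
            zdrivers = _narrowband_noise(rng, len(coupling.zero_lag_pairs),
                                         n_samples, fs, b)
            for k, (i, j) in enumerate(coupling.zero_lag_pairs):
                x[i] += scale * coupling.zero_lag_gains[k] * zdrivers[k]
                x[j] += scale * coupling.zero_lag_gains[k] * zdrivers[k]
    x += spec.noise_level * rng.standard_normal((r, n_samples))
    observed = leakage_matrix(geometry, spec.leakage_sigma) @ x
    return RegionTimeSeries(observed, fs, band="broadband",
                            region_names=list(geometry.names))


# ---------------------------------------------------------------------------
# cohort


@dataclass
class Cohort:
    """A simulated cohort: geometry, connectomes, paired epochs, covariates."""

    spec: SyntheticCohortSpec
    geometry: RegionGeometry
    connectomes: list[StructuralConnectome]
    epochs: list[tuple[RegionTimeSeries, RegionTimeSeries]]
    table: pd.DataFrame
    couplings: list = field(default_factory=list)
    planted: dict = field(default_factory=dict)

    @property
    def n_participants(self) -> int:
        return len(self.epochs)


def _head_circumference(age: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Saturating (logistic) growth curve, cm, plus measurement noise."""
    return 45.0 + 12.0 / (1.0 + np.exp(-(age - 6.0) / 4.0)) + rng.normal(0, 1.0, age.shape)


def expected_coherence(geometry: RegionGeometry,
                       spec: SyntheticCohortSpec,
                       coupling: CouplingStructure,
                       bias_floor: float = 0.2) -> np.ndarray:
    """Noise-free limit of the measured coherence matrix for one participant.

    The generative model is linear in its components (sources, zero-lag
    drivers, broadband noise), so the expected band coherence follows from
    the Gram matrix of the component weights after leakage mixing: narrowband
    time shifts rotate a component's phase without reducing its within-band
    coherence.  ``bias_floor`` models the finite-sample positive bias of the
    Welch coherence estimator (roughly 1/sqrt(n_segments)); measured
    matrices approach this expectation as the epoch grows.  Used to plant
    outcomes on quantities the estimation pipeline can actually recover.
    """
    r = geometry.n_regions
    hp = geometry.homotopic_pairs()
    # component weight matrix: sources, homotopic drivers, zero-lag drivers
    s = np.eye(r)
    iu = np.triu_indices(r, k=1)
    for i, j in zip(*iu):
        if coupling.gains[i, j] > 0:
            s[j, i] += coupling.gains[i, j]      # follower j carries leader i
    d = np.zeros((r, len(hp)))
    for k, (i, j) in enumerate(hp):
        d[i, k] = d[j, k] = coupling.homotopic_gains[k]
    z = np.zeros((r, len(coupling.zero_lag_pairs)))
    for k, (i, j) in enumerate(coupling.zero_lag_pairs):
        z[i, k] = z[j, k] = coupling.zero_lag_gains[k]
    sigma = s @ s.T + d @ d.T + z @ z.T + spec.noise_level ** 2 * np.eye(r)
    m = leakage_matrix(geometry, spec.leakage_sigma)
    sigma = m @ sigma @ m.T
    denom = np.sqrt(np.outer(np.diag(sigma), np.diag(sigma)))
    coh = np.abs(sigma) / denom
    coh = np.sqrt(coh ** 2 + bias_floor ** 2 * (1 - coh ** 2))
    np.fill_diagonal(coh, 0.0)
    return coh


def true_coupling_network(coupling: CouplingStructure,
                          geometry: RegionGeometry) -> np.ndarray:
    """Symmetric ground-truth functional network: all planted couplings."""
    w = coupling.gains.copy()
    for k, (i, j) in enumerate(geometry.homotopic_pairs()):
        w[i, j] += coupling.homotopic_gains[k]
        w[j, i] = w[i, j]
    for k, (i, j) in enumerate(coupling.zero_lag_pairs):
        w[i, j] += coupling.zero_lag_gains[k]
        w[j, i] = w[i, j]
    return w


def _true_pathlength(coupling: CouplingStructure, geometry: RegionGeometry,
                     spec: SyntheticCohortSpec,
                     rng: np.random.Generator) -> float:
    """Planted normalised pathlength: the expected-coherence network's L'
    on the working-memory subnetwork (all regions when not the 68-region
    layout).  50 null surrogates suffice at generation time because only
    the between-subject ordering of the planted values matters."""
    w = expected_coherence(geometry, spec, coupling)
    if geometry.n_regions == 68:
        w = subnetwork(w, geometry.names, default_swm_rois())
    return normalized_pathlength(w, n_null=50, seed=rng).normalized


def simulate_cohort(spec: SyntheticCohortSpec,
                    connectome_params: StructuralConnectomeParams | None = None,
                    ) -> Cohort:
    """Generate the full synthetic cohort from one master seed.

    Per participant: an age-dependent coupling gain, a private structural
    connectome draw, two epochs with identical coupling structure and
    independent noise, and covariates/outcomes with planted effect sizes
    recorded in ``Cohort.planted`` for recovery tests.
    """
    if spec.n_participants < 10:
        raise ValueError("a cohort needs at least 10 participants")
    master = np.random.SeedSequence(spec.seed)
    geom_ss, cov_ss, part_ss = master.spawn(3)
    geometry = make_geometry(spec.n_regions, seed=np.random.default_rng(geom_ss).integers(2**31))
    cov_rng = np.random.default_rng(cov_ss)
    n = spec.n_participants
    age = cov_rng.uniform(6.0, 31.0, n)
    head = _head_circumference(age, cov_rng)
    interval = cov_rng.uniform(12.0, 30.0, n)
    swm_t1 = np.maximum(0, np.round(30.0 - 0.8 * age + cov_rng.normal(0, 3.0, n)))

    connectomes: list[StructuralConnectome] = []
    epochs: list[tuple[RegionTimeSeries, RegionTimeSeries]] = []
    couplings: list[CouplingStructure] = []
    path_true = np.empty(n)
    part_children = part_ss.spawn(n)
    for p in range(n):
        rng = np.random.default_rng(part_children[p])
        conn = make_structural_connectome(geometry, connectome_params, seed=rng)
        # global coupling increases with age (maturation of connectivity);
        # the multiplier scales every gain so measured strength and (through
        # the saturation of the estimators) pathlength both carry the signal
        gain_mult = (1.0 - spec.age_coupling_slope / 2.0
                     + spec.age_coupling_slope * (age[p] - 6.0) / 25.0
                     + rng.normal(0.0, spec.coupling_individual_sd))
        gain_mult = max(gain_mult, 0.2)
        spec_p = replace(spec,
                         coupling_strength=spec.coupling_strength * gain_mult,
                         homotopic_gain=spec.homotopic_gain * gain_mult,
                         zero_lag_gain=spec.zero_lag_gain * gain_mult)
        coupling = draw_coupling(geometry, conn, spec_p, rng)
        a = simulate_epoch(geometry, conn, spec_p, spec.osc_bands, rng,
                           coupling=coupling)
        b = simulate_epoch(geometry, conn, spec_p, spec.osc_bands, rng,
                           coupling=coupling)
        path_true[p] = _true_pathlength(coupling, geometry, spec_p, rng)
        connectomes.append(conn)
        epochs.append((a, b))
        couplings.append(coupling)

    z_path = (path_true - path_true.mean()) / max(path_true.std(), 1e-12)
    delta = (spec.swm_beta * z_path - 0.15 * (age - age.mean())
             + cov_rng.normal(0, spec.swm_noise, n))
    swm_t2 = np.maximum(0, np.round(swm_t1 + delta))

    table = pd.DataFrame({
        "participant_id": [f"sub-{p:03d}" for p in range(n)],
        "age": age,
        "head_circumference": head,
        "swm_errors_t1": swm_t1.astype(int),
        "swm_errors_t2": swm_t2.astype(int),
        "t2_t1_interval": interval,
    })
    planted = {
        "swm_beta": spec.swm_beta,
        "true_pathlength": path_true,
        "age_coupling_slope": spec.age_coupling_slope,
    }
    return Cohort(spec=spec, geometry=geometry, connectomes=connectomes,
                  epochs=epochs, table=table, couplings=couplings,
                  planted=planted)
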