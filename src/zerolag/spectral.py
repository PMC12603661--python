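"""Shared signal core: band filtering, analytic signal, Welch cross-spectra.

All connectivity estimators downstream consume one of three objects built
here from a region-by-time block:

* :class:`RegionTimeSeries` -- the raw or band-filtered multichannel block,
* :class:`AnalyticSeries`   -- Hilbert phases and amplitude envelopes,
* :class:`CrossSpectra`     -- segment-wise windowed rFFTs (Welch), kept
  per segment because the wPLI expectation operator runs over segments.

Filtering follows the EEG convention of sequential high-pass then low-pass
FIR filters (order 250, Hamming window) applied forward and backward so the
net phase response is zero, with 500 samples of reflect padding prepended
and appended around both filtering and the Hilbert transform to suppress
edge transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

#: Conventional EEG frequency bands, Hz (inclusive lower, exclusive-ish upper
#: edge used as FIR cutoffs; band-bin selection is inclusive on both edges).
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "low_beta": (13.0, 20.0),
    "high_beta": (20.0, 32.0),
}

FILTER_ORDER = 250     # FIR order per filter (numtaps = order + 1)
PAD_SAMPLES = 500      # reflect padding around filtering / Hilbert


def band_edges(band: str | tuple[float, float]) -> tuple[float, float]:
    """Resolve a band name or explicit (lo, hi) tuple to edge frequencies."""
    if isinstance(band, str):
        try:
            return BANDS[band]
        except KeyError:
            raise ValueError(
                f"unknown band {band!r}; known bands: {sorted(BANDS)}"
            ) from None
    lo, hi = float(band[0]), float(band[1])
    return lo, hi


@dataclass
class RegionTimeSeries:
    """Region-by-sample numeric block with its sampling rate and band tag."""

    data: np.ndarray            # (n_regions, n_samples)
    sampling_rate: float        # Hz
    band: str = "broadband"
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class AnalyticSeries:
    """Instantaneous phase (wrapped to (-pi, pi]) and amplitude envelope."""

    phase: np.ndarray           # (n_regions, n_samples), radians
    envelope: np.ndarray        # (n_regions, n_samples), >= 0
    sampling_rate: float
    band: str = "broadband"


@dataclass
class CrossSpectra:
    """Welch segment spectra for all regions, with per-segment terms kept.

    ``segments`` holds the scaled windowed rFFT of every Welch segment,
    shape (n_regions, n_segments, n_freqs); cross-spectral densities are
    formed lazily as ``Z_i * conj(Z_j)`` so both the segment-averaged CSD
    (coherence, ImgCoh) and the segment-wise imaginary parts (wPLI) come
    from the same decomposition.
    """

    freqs: np.ndarray                 # (n_freqs,), Hz
    segments: np.ndarray              # (n_regions, n_segments, n_freqs) complex
    sampling_rate: float
    band: str = "broadband"
    _mean_csd: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_segments(self) -> int:
        return self.segments.shape[1]

    def mean_csd(self) -> np.ndarray:
        """Segment-averaged cross-spectral density, (R, R, F) complex."""
        if self._mean_csd is None:
            z = self.segments
            self._mean_csd = np.einsum("isf,jsf->ijf", z, z.conj()) / self.n_segments
        return self._mean_csd

    def psd(self) -> np.ndarray:
        """Segment-averaged autospectra, (R, F) real non-negative."""
        return (np.abs(self.segments) ** 2).mean(axis=1)

    def band_bins(self, band: str | tuple[float, float]) -> np.ndarray:
        lo, hi = band_edges(band)
        return np.flatnonzero((self.freqs >= lo) & (self.freqs <= hi))


# ---------------------------------------------------------------------------
# filtering


def _fir_kernel(cutoff, fs: float, pass_zero) -> np.ndarray:
    return sps.firwin(FILTER_ORDER + 1, cutoff, window="hamming",
                      pass_zero=pass_zero, fs=fs)


def _two_pass(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    # forward+backward application of a linear-phase FIR == single
    # convolution with taps * reversed taps (|H|^2, zero phase)
    kernel = np.convolve(taps, taps[::-1])
    return sps.fftconvolve(data, kernel[None, :], mode="same", axes=1)


def _reflect_pad(data: np.ndarray, pad: int) -> np.ndarray:
    if data.shape[1] <= pad:
        raise ValueError(
            f"need more than {pad} samples for {pad}-sample reflect padding; "
            f"got {data.shape[1]}"
        )
    return np.pad(data, ((0, 0), (pad, pad)), mode="reflect")


def bandpass_filter(ts: RegionTimeSeries,
                    band: str | tuple[float, float]) -> RegionTimeSeries:
    """Zero-phase FIR band-pass: high-pass then low-pass, two-pass each.

    Each filter is an order-250 Hamming-window FIR applied forward and
    backward (so the amplitude response is squared and the phase response is
    exactly zero); 500 reflect-padded samples are prepended/appended before
    filtering and stripped afterwards.
    """
    lo, hi = band_edges(band)
    nyq = ts.sampling_rate / 2.0
    if not (0.0 < lo < hi):
        raise ValueError(f"band edges must satisfy 0 < lo < hi, got ({lo}, {hi})")
    if hi >= nyq:
        raise ValueError(f"upper band edge {hi} Hz >= Nyquist {nyq} Hz")
    if ts.n_samples < 2 * FILTER_ORDER:
        raise ValueError(
            f"need at least {2 * FILTER_ORDER} samples to filter, got {ts.n_samples}"
        )
    padded = _reflect_pad(ts.data, PAD_SAMPLES)
    out = _two_pass(padded, _fir_kernel(lo, ts.sampling_rate, pass_zero=False))
    out = _two_pass(out, _fir_kernel(hi, ts.sampling_rate, pass_zero=True))
    out = out[:, PAD_SAMPLES:-PAD_SAMPLES]
    tag = band if isinstance(band, str) else f"{lo:g}-{hi:g}Hz"
    return RegionTimeSeries(out, ts.sampling_rate, band=tag,
                            region_names=ts.region_names)


def analytic_signal(ts: RegionTimeSeries) -> AnalyticSeries:
    """Hilbert phases and envelopes, with reflect padding applied/stripped."""
    padded = _reflect_pad(ts.data, PAD_SAMPLES)
    z = sps.hilbert(padded, axis=1)[:, PAD_SAMPLES:-PAD_SAMPLES]
    return AnalyticSeries(phase=np.angle(z), envelope=np.abs(z),
                          sampling_rate=ts.sampling_rate, band=ts.band)


# ---------------------------------------------------------------------------
# Welch cross-spectral estimation


def welch_csd(ts: RegionTimeSeries,
              segment_seconds: float = 2.0,
              overlap_fraction: float = 0.5,
              window: str = "hann") -> CrossSpectra:
    """Segment-wise windowed rFFTs on a Welch grid (Hann, 50% overlap).

    Scaling matches the scipy density convention (``scipy.signal.csd`` with
    ``detrend=False``): segment spectra are scaled so that
    ``mean_j |Z_i|^2`` equals the one-sided cross-spectral density, hence
    ``sum(psd) * df`` approximates the time-domain variance (Parseval).
    """
    fs = ts.sampling_rate
    nperseg = int(round(segment_seconds * fs))
    if nperseg > ts.n_samples:
        raise ValueError(
            f"segment of {nperseg} samples exceeds epoch of {ts.n_samples}"
        )
    if not 0 <= overlap_fraction < 1:
        raise ValueError("overlap_fraction must be in [0, 1)")
    hop = max(1, int(round(nperseg * (1.0 - overlap_fraction))))
    starts = np.arange(0, ts.n_samples - nperseg + 1, hop)
    if len(starts) < 2:
        warnings.warn(
            "fewer than 2 Welch segments: the wPLI expectation over segments "
            "is undefined (zero variability)", stacklevel=2,
        )
    win = sps.get_window(window, nperseg, fftbins=True)
    # (R, S, nperseg) strided view of the segment grid
    segs = np.stack([ts.data[:, s:s + nperseg] for s in starts], axis=1)
    z = np.fft.rfft(segs * win, axis=2)
    # one-sided density scaling; interior bins doubled (power is |Z|^2)
    scale = np.sqrt(1.0 / (fs * (win ** 2).sum()))
    z = z * scale
    nf = z.shape[2]
    interior = np.ones(nf)
    interior[1:] = np.sqrt(2.0)
    if nperseg % 2 == 0:
        interior[-1] = 1.0          # Nyquist bin is not doubled
    z = z * interior
    freqs = np.fft.rfftfreq(nperseg, d=1.0 / fs)
    return CrossSpectra(freqs=freqs, segments=z, sampling_rate=fs, band=ts.band)
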