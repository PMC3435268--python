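"""Spectral estimators: Hann PSD snapshots, Morlet dynamic spectra, and
Butterworth+Hilbert analytic band signals.

Conventions
-----------
* PSD snapshots are taper-power-corrected densities in uV^2/Hz on a grid
  with resolution 1/T for epoch duration T.
* The Morlet kernel at frequency f has Gaussian envelope
  sigma_t = cycles / (2*pi*f) and is normalized so that a unit-amplitude
  tone at f yields |X| = 1 (analytic-amplitude convention).  Power densities
  are recovered via the kernel's equivalent noise bandwidth.
* Analytic bands use zero-phase (forward-backward) Butterworth filtering so
  that phase 0 coincides with the surface-positive peak of the band-passed
  potential.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .data_model import EpochSet, RecordingSession
from .errors import ParameterError, ValidationError


@dataclass
class SpectralSnapshot:
    """Per-epoch Hann periodograms on a common frequency grid."""

    frequencies: np.ndarray          # (n_freq,) Hz
    power: np.ndarray                # (n_epochs, n_freq) uV^2/Hz
    labels: np.ndarray               # (n_epochs,) condition labels
    epoch_duration_s: float

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=np.float64))
        self.labels = np.asarray(self.labels, dtype=object)
        if self.power.shape != (len(self.labels), len(self.frequencies)):
            raise ValidationError("power matrix shape mismatch")
        if (self.power < 0).any():
            raise ValidationError("negative spectral power")

    def select(self, label) -> "SpectralSnapshot":
        mask = self.labels == label
        return SpectralSnapshot(self.frequencies, self.power[mask],
                                self.labels[mask], self.epoch_duration_s)


@dataclass
class DynamicSpectrum:
    """Complex Morlet coefficients X(f, t) for every sample."""

    frequencies: np.ndarray          # (n_freq,) Hz
    coefficients: np.ndarray         # (n_freq, n_samples) complex
    rate: float
    cycles: int
    enbw: np.ndarray                 # (n_freq,) equivalent noise bandwidth, Hz
    edge: np.ndarray = field(default=None)  # (n_freq, n_samples) bool

    def __post_init__(self):
        if self.edge is None:
            self.edge = np.zeros(self.coefficients.shape, dtype=bool)

    def power_density(self) -> np.ndarray:
        """|X|^2 scaled to a one-sided PSD estimate (uV^2/Hz)."""
        return np.abs(self.coefficients) ** 2 / self.enbw[:, None]

    def phase(self) -> np.ndarray:
        return np.angle(self.coefficients)

    def valid_mask(self) -> np.ndarray:
        """Samples clear of the edge region at *every* frequency."""
        return ~self.edge.any(axis=0)


@dataclass
class AnalyticBand:
    """Band-passed signal and its Hilbert analytic extension."""

    band: tuple[float, float]
    values: np.ndarray               # complex z(t) = a(t) e^{i phi(t)}
    rate: float
    order: int

    @property
    def amplitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


# ---------------------------------------------------------------------------
# Hann PSD snapshots
# ---------------------------------------------------------------------------

def band_mask(frequencies, bands) -> np.ndarray:
    """Boolean mask of grid points falling inside any of ``bands``."""
    frequencies = np.asarray(frequencies)
    mask = np.zeros(len(frequencies), dtype=bool)
    for lo, hi in bands:
        mask |= (frequencies >= lo) & (frequencies <= hi)
    return mask


def psd_snapshots(session: RecordingSession, epochs: EpochSet,
                  channel: int | str = 0,
                  fmin: float = 0.0, fmax: float | None = None,
                  omit_bands=()) -> SpectralSnapshot:
    """Hann-tapered periodogram of each epoch of one channel.

    ``omit_bands`` drops grid points inside the given (lo, hi) intervals,
    e.g. line-noise bands.
    """
    if isinstance(channel, str):
        channel = session.channel_index(channel)
    epochs.check_within(session.n_samples)
    if len(epochs) == 0:
        raise ValidationError("no epochs")
    x = session.samples[channel]
    n = epochs.duration
    segs = np.stack([x[s:s + n] for s in epochs.starts])
    freqs, power = sps.periodogram(segs, fs=session.rate, window="hann",
                                   detrend="constant", axis=-1)
    keep = np.ones(len(freqs), dtype=bool)
    if fmax is None:
        fmax = session.rate / 2
    keep &= (freqs >= fmin) & (freqs <= fmax)
    if len(omit_bands):
        keep &= ~band_mask(freqs, omit_bands)
    return SpectralSnapshot(freqs[keep], power[:, keep], epochs.labels,
                            n / session.rate)


# ---------------------------------------------------------------------------
# Morlet dynamic spectrum
# ---------------------------------------------------------------------------

def _morlet_rows(x, grid, rate: float, cycles: int):
    """Yield (row index, complex coefficients, enbw) per grid frequency.

    Implemented as one shared forward FFT of the reflect-padded signal
    followed by per-frequency multiplication with the wavelet's analytic
    frequency response (a Gaussian of width 1/(2*pi*sigma_t) centered at
    +f, peak-normalized to 2 so a unit cosine yields |X| = 1).
    """
    from scipy.fft import fft, ifft, next_fast_len

    x = np.asarray(x, dtype=np.float64)
    grid = np.atleast_1d(np.asarray(grid, dtype=np.float64))
    n = len(x)
    sigma_max = cycles / (2 * np.pi * grid.min())
    pad = min(int(np.ceil(4 * sigma_max * rate)), n - 1)
    xp = np.concatenate([x[pad:0:-1], x, x[-2:-2 - pad:-1]]) if pad \
        else x
    nfft = next_fast_len(len(xp))
    spec = fft(xp, n=nfft)
    nu = np.fft.fftfreq(nfft, d=1.0 / rate)
    dnu = rate / nfft
    for i, f in enumerate(grid):
        sigma = cycles / (2 * np.pi * f)
        h = 2.0 * np.exp(-2 * np.pi ** 2 * sigma ** 2 * (nu - f) ** 2)
        row = ifft(spec * h)[pad:pad + n]
        enbw = float(np.sum(h * h) * dnu / 2.0)
        yield i, row, enbw


def morlet_spectrogram(x, grid, rate: float, cycles: int = 5,
                       edge_cycles: float | None = None) -> DynamicSpectrum:
    """Convolve ``x`` with unit-response Morlet wavelets at each frequency.

    Edges are handled by reflect-padding; samples within ``edge_cycles``
    (default: the cycles parameter) cycles of either end are flagged in
    ``edge`` and should be excluded from phase-conditioned averages.
    """
    x = np.asarray(x, dtype=np.float64)
    grid = np.atleast_1d(np.asarray(grid, dtype=np.float64))
    nyq = rate / 2
    if (grid <= 0).any() or (grid >= nyq).any():
        raise ParameterError(f"frequencies must lie in (0, {nyq}) Hz")
    if edge_cycles is None:
        edge_cycles = cycles
    n = len(x)
    coeffs = np.empty((len(grid), n), dtype=np.complex128)
    edge = np.zeros((len(grid), n), dtype=bool)
    enbw = np.empty(len(grid))
    for i, row, bw in _morlet_rows(x, grid, rate, cycles):
        coeffs[i] = row
        enbw[i] = bw
        n_edge = min(n, int(np.ceil(edge_cycles * rate / grid[i])))
        edge[i, :n_edge] = True
        edge[i, n - n_edge:] = True
    return DynamicSpectrum(grid, coeffs, rate, cycles, enbw, edge)


def morlet_log_power_projection(x, grid, rate: float, weights,
                                cycles: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Weighted sum over frequencies of mean-removed log wavelet power.

    Memory-light equivalent of projecting the normalized log dynamic
    spectrum onto ``weights`` without materializing the full coefficient
    matrix.  Returns (projection, valid mask).
    """
    x = np.asarray(x, dtype=np.float64)
    grid = np.atleast_1d(np.asarray(grid, dtype=np.float64))
    nyq = rate / 2
    if (grid <= 0).any() or (grid >= nyq).any():
        raise ParameterError(f"frequencies must lie in (0, {nyq}) Hz")
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != grid.shape:
        raise ParameterError("one weight per grid frequency required")
    n = len(x)
    out = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    for i, row, _ in _morlet_rows(x, grid, rate, cycles):
        logp = np.log(row.real ** 2 + row.imag ** 2 + np.finfo(float).tiny)
        out += weights[i] * (logp - logp.mean())
        n_edge = min(n, int(np.ceil(cycles * rate / grid[i])))
        valid[:n_edge] = False
        valid[n - n_edge:] = False
    return out, valid


# ---------------------------------------------------------------------------
# Analytic band (Butterworth + Hilbert)
# ---------------------------------------------------------------------------

def analytic_band(x, band, rate: float, order: int = 3) -> AnalyticBand:
    """Zero-phase band-pass then Hilbert analytic signal.

    The forward-backward filter doubles the effective order but keeps the
    band-passed trace phase-aligned with the input, so phase 0 marks the
    surface-positive peak of the rhythm.
    """
    lo, hi = band
    nyq = rate / 2
    if not (0 < lo < hi < nyq):
        raise ParameterError(f"band {band} must lie inside (0, {nyq}) Hz")
    x = np.asarray(x, dtype=np.float64)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=rate, output="sos")
    filtered = sps.sosfiltfilt(sos, x)
    return AnalyticBand((float(lo), float(hi)), sps.hilbert(filtered),
                        float(rate), order)


def butter_band_gain(band, freq: float, rate: float, order: int = 3) -> float:
    """Amplitude gain of the zero-phase band-pass filter at ``freq``."""
    sos = sps.butter(order, list(band), btype="bandpass", fs=rate,
                     output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=rate)
    return float(np.abs(h[0]) ** 2)  # forward-backward squares the response
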