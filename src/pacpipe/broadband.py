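"""Decoupling of the power spectrum into broadband and rhythmic components,
and extraction of the broadband timecourse.

An ensemble of per-epoch PSDs is normalized by its geometric-mean spectrum
and log-transformed; eigen-decomposition of the resulting inter-frequency
covariation yields "principal spectral components" (PSCs).  The first PSC
carries spectrum-wide (broadband) covariation and approximates the log of
the time-varying coefficient of a power-law spectrum; lower components
(by default the 2nd-4th) carry band-limited rhythms.  Projecting a dynamic
(wavelet) spectrum onto the first PSC gives the broadband timecourse used
in all coupling analyses.  A 65-135 Hz band-power envelope is available as
a cheap approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .errors import ParameterError, ValidationError
from .spectral import (DynamicSpectrum, SpectralSnapshot, analytic_band,
                       morlet_log_power_projection)
from scipy import signal as sps


@dataclass
class PSCDecomposition:
    """Eigen-structure of normalized log-PSD covariation across frequencies."""

    frequencies: np.ndarray      # (n_freq,)
    eigenvalues: np.ndarray      # (n_comp,) descending
    eigenvectors: np.ndarray     # (n_freq, n_comp), orthonormal columns
    mean_log: np.ndarray         # (n_freq,) ensemble mean log-spectrum
    projections: np.ndarray      # (n_epochs, n_comp) epoch scores
    labels: np.ndarray           # (n_epochs,) epoch condition labels
    epoch_duration_s: float

    @property
    def n_components(self) -> int:
        return self.eigenvectors.shape[1]

    def variance_explained(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


@dataclass
class BroadbandTrace:
    """Z-scored log-broadband series plus its display variant.

    ``values`` is the z-scored series used for every coupling computation;
    ``raw`` is the same series before z-scoring (log units), needed for
    modulation-depth recovery; ``display`` is the smoothed and exponentiated
    variant used only for illustration.
    """

    values: np.ndarray           # z-units
    raw: np.ndarray              # log units, unsmoothed
    rate: float
    source: str                  # "psc" | "bandpower"
    display: np.ndarray = None
    valid: np.ndarray = field(default=None)  # samples safe for averaging

    def __post_init__(self):
        if self.valid is None:
            self.valid = np.ones(len(self.values), dtype=bool)
        if self.display is None:
            self.display = np.exp(_zscore(
                gaussian_filter1d(self.raw, sigma=0.05 * self.rate)))


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return x - x.mean()
    return (x - x.mean()) / sd


# ---------------------------------------------------------------------------
# PSC decomposition of spectral snapshots
# ---------------------------------------------------------------------------

def psc_decompose(snapshots: SpectralSnapshot) -> PSCDecomposition:
    """Eigen-decomposition of normalized log-PSD covariation.

    Each epoch's PSD is divided by the ensemble geometric-mean spectrum and
    log-transformed (equivalently: the per-frequency mean log-power is
    subtracted), then an SVD of the epoch-by-frequency matrix yields the
    eigenvalues/eigenvectors of the inter-frequency second-moment matrix.
    Components are ordered by eigenvalue; each eigenvector's sign is fixed
    so its mean weight is non-negative ("broadband up" is positive).
    """
    P = snapshots.power
    if P.shape[0] < 2 or P.shape[1] < 2:
        raise ValidationError("need >= 2 epochs and >= 2 frequencies")
    if (P <= 0).any():
        raise ValidationError("log-decomposition requires strictly positive power")
    logp = np.log(P)
    mean_log = logp.mean(axis=0)
    X = logp - mean_log
    if np.allclose(X, 0):
        raise ValidationError("constant spectra: degenerate decomposition")
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    eigvals = s ** 2 / X.shape[0]
    eigvecs = vt.T
    sign = np.where(eigvecs.sum(axis=0) >= 0, 1.0, -1.0)
    eigvecs = eigvecs * sign
    proj = X @ eigvecs
    return PSCDecomposition(snapshots.frequencies.copy(), eigvals, eigvecs,
                            mean_log, proj, snapshots.labels.copy(),
                            snapshots.epoch_duration_s)


def reconstruct_spectra(decomp: PSCDecomposition,
                        included) -> SpectralSnapshot:
    """Rebuild per-epoch spectra from a subset of PSCs (0-based indices).

    An empty index set returns the ensemble geometric-mean spectrum for
    every epoch.  Using all components reproduces the input exactly.
    """
    included = np.asarray(sorted(set(int(i) for i in included)), dtype=int)
    if len(included) and (included.min() < 0
                          or included.max() >= decomp.n_components):
        raise ParameterError(
            f"component indices out of range 0..{decomp.n_components - 1}")
    n_epochs = decomp.projections.shape[0]
    if len(included) == 0:
        X = np.zeros((n_epochs, len(decomp.frequencies)))
    else:
        X = decomp.projections[:, included] @ decomp.eigenvectors[:, included].T
    power = np.exp(X + decomp.mean_log)
    return SpectralSnapshot(decomp.frequencies.copy(), power,
                            decomp.labels.copy(), decomp.epoch_duration_s)


def rhythm_component_indices(decomp: PSCDecomposition,
                             rhythm=(1, 2, 3)) -> np.ndarray:
    """All component indices except the given rhythm set (default 2nd-4th)."""
    rhythm = set(int(i) for i in rhythm)
    return np.array([i for i in range(decomp.n_components)
                     if i not in rhythm], dtype=int)


# ---------------------------------------------------------------------------
# Broadband timecourses
# ---------------------------------------------------------------------------

def broadband_timecourse(dyn: DynamicSpectrum,
                         decomp: PSCDecomposition) -> BroadbandTrace:
    """Project the normalized log dynamic spectrum onto the first PSC.

    The per-sample log wavelet power at each frequency is normalized by its
    time mean (geometric-mean normalization, mirroring the snapshot
    decomposition), projected onto the first eigenvector, and z-scored.
    Smoothing and exponentiation appear only in the display variant.
    """
    if (len(dyn.frequencies) != len(decomp.frequencies)
            or not np.allclose(dyn.frequencies, decomp.frequencies)):
        raise ValidationError("dynamic-spectrum grid does not match decomposition")
    logp = np.log(dyn.power_density() + np.finfo(float).tiny)
    logp -= logp.mean(axis=1, keepdims=True)
    raw = decomp.eigenvectors[:, 0] @ logp
    return BroadbandTrace(values=_zscore(raw), raw=raw, rate=dyn.rate,
                          source="psc", valid=dyn.valid_mask())


def psc_broadband(signal_1d, rate: float, decomp: PSCDecomposition,
                  cycles: int = 5) -> BroadbandTrace:
    """Morlet log-power projection onto the first PSC, without materializing
    the full dynamic spectrum (memory-light equivalent of
    :func:`broadband_timecourse` after :func:`morlet_spectrogram`)."""
    raw, valid = morlet_log_power_projection(
        signal_1d, decomp.frequencies, rate, decomp.eigenvectors[:, 0],
        cycles)
    return BroadbandTrace(values=_zscore(raw), raw=raw, rate=float(rate),
                          source="psc", valid=valid)


def bandpower_broadband(x, rate: float, band=(65.0, 135.0),
                        line_noise_hz: float = 60.0,
                        line_halfwidth_hz: float = 3.0,
                        order: int = 3) -> BroadbandTrace:
    """Log analytic amplitude of a high-frequency band, z-scored.

    Approximates the PSC broadband trace with the 65-135 Hz envelope.
    Line-noise harmonics inside the band are removed with zero-phase
    Butterworth band-stop filters (a notch has a true zero at its center
    frequency, so an injected line tone contributes nothing).
    """
    lo, hi = band
    nyq = rate / 2
    if not (0 < lo < hi < nyq):
        raise ParameterError(f"band {band} must lie inside (0, {nyq}) Hz")
    filtered = analytic_band(x, band, rate, order=order).values.real
    f = line_noise_hz
    while f < hi:
        if f > lo:
            stop = (max(f - line_halfwidth_hz, lo + 1e-6),
                    min(f + line_halfwidth_hz, hi - 1e-6))
            sos = sps.butter(order, list(stop), btype="bandstop", fs=rate,
                             output="sos")
            filtered = sps.sosfiltfilt(sos, filtered)
        f += line_noise_hz
    amp = np.abs(sps.hilbert(filtered))
    raw = np.log(amp + np.finfo(float).tiny)
    return BroadbandTrace(values=_zscore(raw), raw=raw, rate=float(rate),
                          source="bandpower")
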