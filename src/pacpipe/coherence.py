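"""Seed-referenced complex phase coherence and its phase-lag projection.

The coherence between a seed channel and every other channel is the
two-stage average of e^{i(phi_seed - phi_j)}: mean over time within each
rest epoch, then unweighted complex mean across epochs.  Keeping the
complex value (rather than its magnitude) exposes re-referencing artifacts:
a strong rhythm shared by part of the array leaks into the other channels
through the common average with a pi phase shift, which shows up as
negative projected coherence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import EpochSet, RecordingSession
from .errors import ParameterError, ValidationError
from .spectral import analytic_band
from .stats import signed_r2


@dataclass
class SeedSelection:
    """Chosen seed channel and the statistic behind the choice."""

    channel: int                 # row index
    channel_id: str
    statistic: float             # signed r^2 of broadband, movement vs rest
    low_confidence: bool         # no meaningful movement response anywhere


@dataclass
class PhaseCoherenceMap:
    """Per-channel complex coherence with a seed channel."""

    seed: int
    band: tuple[float, float]
    gamma: np.ndarray            # (n_channels,) complex; NaN for excluded
    n_epochs: int
    channel_ids: np.ndarray

    def __post_init__(self):
        finite = np.isfinite(self.gamma)
        if (np.abs(self.gamma[finite]) > 1 + 1e-9).any():
            raise ValidationError("|coherence| cannot exceed 1")


def epoch_means(trace: np.ndarray, epochs: EpochSet) -> np.ndarray:
    """Mean of a per-sample trace within each epoch window."""
    return np.array([trace[s:s + epochs.duration].mean()
                     for s in epochs.starts])


def select_seed(session: RecordingSession, broadband: np.ndarray,
                movement_epochs: EpochSet, rest_epochs: EpochSet,
                min_stat: float = 0.05) -> SeedSelection:
    """Channel whose broadband shows the strongest movement-vs-rest change.

    ``broadband`` is (n_channels, n_samples) of z-scored broadband traces.
    Ties break toward the lowest row index.  If no channel reaches
    ``min_stat`` the selection is flagged low-confidence.
    """
    if len(movement_epochs) == 0:
        raise ParameterError("no movement epochs")
    if len(rest_epochs) == 0:
        raise ParameterError("no rest epochs")
    included = session.included_indices()
    stats = np.full(session.n_channels, -np.inf)
    for i in included:
        a = epoch_means(broadband[i], movement_epochs)
        b = epoch_means(broadband[i], rest_epochs)
        stats[i] = signed_r2(a, b)
    best = int(np.argmax(stats))  # argmax returns the first (lowest) index
    return SeedSelection(best, str(session.channels["id"].iloc[best]),
                         float(stats[best]), stats[best] < min_stat)


def phase_coherence_map(session: RecordingSession, seed: int | str,
                        band=(12.0, 20.0), epochs: EpochSet | None = None,
                        order: int = 3) -> PhaseCoherenceMap:
    """Two-stage complex phase coherence of every channel with the seed.

    The session is expected to be re-referenced already (CAR).  ``epochs``
    defaults to 1-s windows centered on the session's rest events.
    """
    if isinstance(seed, str):
        seed = session.channel_index(seed)
    seed = int(seed)
    if bool(session.channels["excluded"].iloc[seed]):
        raise ParameterError("seed channel is excluded")
    if epochs is None:
        epochs = EpochSet.around_events(session, "rest", 1.0)
    if len(epochs) == 0:
        raise ParameterError("need at least one epoch")
    epochs.check_within(session.n_samples)

    phases = np.empty_like(session.samples)
    included = session.included_indices()
    for i in included:
        phases[i] = analytic_band(session.samples[i], band, session.rate,
                                  order=order).phase
    gamma = np.full(session.n_channels, np.nan + 0j, dtype=complex)
    for i in included:
        per_epoch = []
        for s in epochs.starts:
            dphi = phases[seed, s:s + epochs.duration] \
                 - phases[i, s:s + epochs.duration]
            per_epoch.append(np.exp(1j * dphi).mean())
        gamma[i] = np.mean(per_epoch)
    return PhaseCoherenceMap(seed, (float(band[0]), float(band[1])), gamma,
                             len(epochs),
                             session.channels["id"].to_numpy())


def project_coherence(cmap: PhaseCoherenceMap) -> np.ndarray:
    """Project every coherence onto the phase of the strongest non-seed site.

    Returns Re(gamma_j * e^{-i psi*}) where psi* is the phase of the
    maximum-|gamma| channel other than the seed (whose self-coherence is
    trivially 1).
    """
    mags = np.abs(cmap.gamma)
    mags[cmap.seed] = -np.inf
    mags[~np.isfinite(np.abs(cmap.gamma))] = -np.inf
    best = int(np.argmax(mags))
    if not np.isfinite(mags[best]):
        raise ParameterError("coherence map has no non-seed channels")
    psi = np.angle(cmap.gamma[best])
    return np.real(cmap.gamma * np.exp(-1j * psi))
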