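"""Synthetic session generator with the statistical structure the analysis
assumes: 1/f^chi broadband whose envelope is modulated by the phase of an
imposed rhythm, rhythm amplitude and coupling that drop during movement
trials, a cued finger-movement task (2 s movement / 2 s rest), and
channel-specific broadband gains per finger.

Positive and negative controls for the whole pipeline are built from these
pieces: colored noise and random walks must show no coupling, while
embedded modulation must be recovered with the imposed depth and phase.

Randomness is organized in named substreams derived from the config seed
(task order, finger traces, per-channel noise, ...) so every piece is
bit-reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .data_model import (RecordingSession, empty_events, make_channel_table)
from .errors import ParameterError

FINGERS = ("thumb", "index", "middle", "ring", "little")

# substream tags (mixed with the config seed)
_TASK, _TRACES, _PHASES, _CHANNEL0 = 0, 1, 2, 100


def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag]))


@dataclass
class RhythmSpec:
    """A band-limited rhythm added to a subset of channels."""

    band: tuple[float, float] = (12.0, 20.0)
    amplitude: float = 1.0
    movement_multiplier: float = 1.0
    channels: tuple[int, ...] | None = None   # None = all channels
    shared_phase: bool = True

    @property
    def frequency(self) -> float:
        return 0.5 * (self.band[0] + self.band[1])


@dataclass
class CouplingSpec:
    """Phase-amplitude coupling of one channel's broadband to one rhythm."""

    channel: int = 0
    rhythm: int = 0
    depth: float = 0.5                        # d in [0, 1]
    phase0: float = 0.0                       # preferred phase in (-pi, pi]
    movement_multiplier: float = 1.0


@dataclass
class TaskSpec:
    """Cued finger-movement task: interleaved movement and rest trials."""

    fingers: tuple[str, ...] = FINGERS
    cues_per_finger: int = 30
    movement_s: float = 2.0
    rest_s: float = 2.0
    flexions: tuple[int, int] = (2, 5)        # flexions per movement trial


@dataclass
class SomatotopySpec:
    """Finger -> channel map with a broadband gain during that finger's trials."""

    mapping: dict[str, int] = field(default_factory=dict)
    gain: float = 2.0
    lead_s: float = 0.075                     # gain onset lead before trace


@dataclass
class SyntheticConfig:
    n_channels: int = 4
    rate: float = 1000.0
    duration_s: float = 60.0                  # used when task is None
    chi: float | tuple[float, ...] = 2.0
    rhythms: list[RhythmSpec] = field(default_factory=list)
    couplings: list[CouplingSpec] = field(default_factory=list)
    task: TaskSpec | None = None
    somatotopy: SomatotopySpec | None = None
    broadband_scale: float = 1.0
    noise_floor: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if np.isscalar(self.chi):
            self.chi = tuple([float(self.chi)] * self.n_channels)
        if len(self.chi) != self.n_channels:
            raise ParameterError("need one chi per channel")
        nyq = self.rate / 2
        for r in self.rhythms:
            if not (0 < r.band[0] < r.band[1] < nyq):
                raise ParameterError(f"rhythm band {r.band} outside (0, {nyq})")
            if r.channels is not None and any(
                    not 0 <= c < self.n_channels for c in r.channels):
                raise ParameterError("rhythm channel subset out of range")
        for c in self.couplings:
            if not 0.0 <= c.depth <= 1.0:
                raise ParameterError("coupling depth must be in [0, 1]")
            if not 0 <= c.channel < self.n_channels:
                raise ParameterError("coupling channel out of range")
            if not 0 <= c.rhythm < len(self.rhythms):
                raise ParameterError("coupling refers to a missing rhythm")
        if self.somatotopy is not None:
            for f, ch in self.somatotopy.mapping.items():
                if not 0 <= ch < self.n_channels:
                    raise ParameterError(f"somatotopy channel {ch} out of range")


# ---------------------------------------------------------------------------
# Noise primitives
# ---------------------------------------------------------------------------

def make_colored_noise(n: int, chi: float, rate: float = 1.0,
                       seed=None, rng=None) -> np.ndarray:
    """Gaussian series with expected PSD proportional to 1/f^chi, unit variance.

    Spectral synthesis: white Gaussian noise is shaped in the frequency
    domain by f^(-chi/2) (DC removed), inverse-transformed, and rescaled to
    unit variance.  chi = 0 reduces to white noise.
    """
    if n < 2:
        raise ParameterError("need n >= 2")
    if chi < 0:
        raise ParameterError("chi must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    spec[0] = 0.0
    if chi > 0:
        spec[1:] = spec[1:] * freqs[1:] ** (-chi / 2.0)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def make_random_walk(n: int, seed=None, rng=None) -> np.ndarray:
    """Cumulative sum of unit white noise (PSD slope about -2)."""
    if n < 2:
        raise ParameterError("need n >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    return np.cumsum(rng.standard_normal(n))


# ---------------------------------------------------------------------------
# Task layout
# ---------------------------------------------------------------------------

def build_task(config: SyntheticConfig) -> pd.DataFrame:
    """Trial table (start sample, finger) for the config's task, or empty.

    The interleaving order depends only on the config seed.
    """
    if config.task is None:
        return pd.DataFrame({"start": pd.Series(dtype=np.int64),
                             "finger": pd.Series(dtype=str)})
    task = config.task
    rng = _stream(config.seed, _TASK)
    order = np.repeat(np.arange(len(task.fingers)), task.cues_per_finger)
    order = rng.permutation(order)
    trial_len = int(round((task.movement_s + task.rest_s) * config.rate))
    starts = np.arange(len(order), dtype=np.int64) * trial_len
    return pd.DataFrame({"start": starts,
                         "finger": [task.fingers[i] for i in order]})


def _n_samples(config: SyntheticConfig) -> int:
    if config.task is None:
        return int(round(config.duration_s * config.rate))
    task = config.task
    per = int(round((task.movement_s + task.rest_s) * config.rate))
    return per * task.cues_per_finger * len(task.fingers)


def _movement_masks(config: SyntheticConfig, trials: pd.DataFrame,
                    n: int) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """(any-movement mask, per-finger movement-trial masks)."""
    any_mask = np.zeros(n, dtype=bool)
    finger_masks = {}
    if config.task is None:
        return any_mask, finger_masks
    mlen = int(round(config.task.movement_s * config.rate))
    for f in config.task.fingers:
        finger_masks[f] = np.zeros(n, dtype=bool)
    for start, finger in zip(trials["start"], trials["finger"]):
        any_mask[start:start + mlen] = True
        finger_masks[finger][start:start + mlen] = True
    return any_mask, finger_masks


def _finger_traces(config: SyntheticConfig, trials: pd.DataFrame, n: int):
    """Smoothed pulse trains (2-5 flexions per movement trial) + ground truth."""
    traces = {}
    truth_rows = []
    if config.task is None:
        return traces, truth_rows
    task = config.task
    rng = _stream(config.seed, _TRACES)
    rate = config.rate
    mlen = task.movement_s
    sigma = 0.06 * rate                        # pulse width ~60 ms SD
    t = np.arange(n)
    for f in task.fingers:
        traces[f] = np.zeros(n)
    lo, hi = task.flexions
    for start, finger in zip(trials["start"], trials["finger"]):
        k = int(rng.integers(lo, hi + 1))
        centers = start + ((np.arange(k) + 0.5) / k * mlen * rate).astype(int)
        for c in centers:
            lo_i = max(0, int(c - 5 * sigma))
            hi_i = min(n, int(c + 5 * sigma))
            traces[finger][lo_i:hi_i] += np.exp(
                -(t[lo_i:hi_i] - c) ** 2 / (2 * sigma ** 2))
            init = max(0, int(c - 2 * sigma))
            term = min(n - 1, int(c + 2 * sigma))
            truth_rows += [("movement_init", finger, init),
                           ("movement_peak", finger, int(c)),
                           ("movement_term", finger, term)]
    return traces, truth_rows


def _rest_events(config: SyntheticConfig, trials: pd.DataFrame,
                 n: int) -> list[tuple[str, str, int]]:
    """Rest markers on a 1-s grid (centers of 1-s epochs tiling rest time)."""
    rate = config.rate
    rows = []
    if config.task is None:
        centers = np.arange(0.5 * rate, n, rate).astype(int)
        return [("rest", "none", int(c)) for c in centers if c < n]
    mlen = int(round(config.task.movement_s * rate))
    rlen = int(round(config.task.rest_s * rate))
    for start in trials["start"]:
        r0 = start + mlen
        centers = np.arange(r0 + 0.5 * rate, r0 + rlen, rate).astype(int)
        rows += [("rest", "none", int(c)) for c in centers if c < n]
    return rows


# ---------------------------------------------------------------------------
# Session assembly
# ---------------------------------------------------------------------------

def make_session(config: SyntheticConfig) -> RecordingSession:
    """Generate a session with imposed rhythms, coupling, and task structure.

    Per channel: colored-noise broadband whose component above twice each
    coupled rhythm's top frequency is amplitude-scaled by
    ``1 + d(t) cos(phase - phi0)`` (only spectral elements above ~2x the
    rhythm frequency can track its phase), plus the rhythms themselves,
    plus a white noise floor.  Rhythm amplitudes and coupling depths are
    multiplied by their movement multipliers inside movement trials; the
    somatotopic channel's broadband is raised during its finger's trials
    with a small onset lead.  The modulation phase is the clean generated
    rhythm phase, so ground truth is exact.
    """
    n = _n_samples(config)
    rate = config.rate
    trials = build_task(config)
    any_move, finger_masks = _movement_masks(config, trials, n)
    traces, truth_rows = _finger_traces(config, trials, n)

    # rhythms: clean phase series theta(t) per spec, shared or per-channel
    t = np.arange(n) / rate
    phase_rng = _stream(config.seed, _PHASES)
    rhythm_phases = []                       # (n_rhythms,) or per-channel dict
    for r in config.rhythms:
        if r.shared_phase:
            offs = {c: phase_rng.uniform(-np.pi, np.pi)
                    for c in [None]}         # one shared offset
        else:
            offs = {c: phase_rng.uniform(-np.pi, np.pi)
                    for c in range(config.n_channels)}
        rhythm_phases.append(offs)

    def rhythm_phase(ri: int, channel: int) -> np.ndarray:
        r = config.rhythms[ri]
        offs = rhythm_phases[ri]
        off = offs[None] if r.shared_phase else offs[channel]
        theta = 2 * np.pi * r.frequency * t + off
        return np.angle(np.exp(1j * theta))  # wrap to (-pi, pi]

    samples = np.empty((config.n_channels, n))
    soma = config.somatotopy
    for ch in range(config.n_channels):
        rng = _stream(config.seed, _CHANNEL0 + ch)
        bb = make_colored_noise(n, config.chi[ch], rate, rng=rng)
        # impose couplings on the >2x-rhythm component of the broadband
        for spec in config.couplings:
            if spec.channel != ch:
                continue
            r = config.rhythms[spec.rhythm]
            cutoff = min(2.0 * r.band[1], 0.9 * rate / 2)
            sos = sps.butter(4, cutoff, btype="highpass", fs=rate,
                             output="sos")
            high = sps.sosfiltfilt(sos, bb)
            low = bb - high
            d = spec.depth * np.where(any_move, spec.movement_multiplier, 1.0)
            phi = rhythm_phase(spec.rhythm, ch)
            bb = low + high * (1.0 + d * np.cos(phi - spec.phase0))
        # somatotopic broadband gain with onset lead
        if soma is not None:
            for finger, target in soma.mapping.items():
                if target != ch or finger not in finger_masks:
                    continue
                lead = int(round(soma.lead_s * rate))
                mask = finger_masks[finger]
                shifted = np.zeros(n, dtype=bool)
                shifted[:n - lead] = mask[lead:] if lead else mask
                shifted |= mask
                bb = bb * np.where(shifted, soma.gain, 1.0)
        x = config.broadband_scale * bb
        for ri, r in enumerate(config.rhythms):
            if r.channels is not None and ch not in r.channels:
                continue
            amp = r.amplitude * np.where(any_move, r.movement_multiplier, 1.0)
            x = x + amp * np.cos(rhythm_phase(ri, ch))
        x = x + config.noise_floor * rng.standard_normal(n)
        samples[ch] = x

    event_rows = truth_rows + _rest_events(config, trials, n)
    if config.task is not None:
        mstart = trials["start"].to_numpy()
        event_rows += [("cue", f, int(s))
                       for s, f in zip(mstart, trials["finger"])]
    if event_rows:
        events = pd.DataFrame(event_rows,
                              columns=["label", "effector", "sample"])
        events = events.sort_values("sample", kind="stable")
        events = events.reset_index(drop=True)
        events["sample"] = events["sample"].astype(np.int64)
    else:
        events = empty_events()

    channels = make_channel_table([f"ch{i}" for i in range(config.n_channels)])
    return RecordingSession(samples, rate, channels, events, traces)
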