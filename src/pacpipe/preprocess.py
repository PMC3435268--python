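"""Re-referencing, channel rejection, and event construction.

Common average referencing (CAR) subtracts the instantaneous mean of the
included channels from each included channel; excluded channels pass
through untouched but keep their flag.  CAR is idempotent.

Movement events are detected on z-scored finger traces with a declared
threshold convention: initiation is an upward crossing of +0.5 SD, the peak
is the local maximum of the excursion, termination the downward crossing.
Rest events are drawn uniformly from samples at least 500 ms from any
movement initiation/termination and at least 250 ms from any other rest
event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import RecordingSession, empty_events
from .errors import ValidationError


def common_average_reference(session: RecordingSession,
                             excluded=()) -> RecordingSession:
    """Subtract the instantaneous mean of included channels.

    ``excluded`` may contain channel ids (str) or row indices; they are
    flagged in the returned session's channel table in addition to any
    pre-existing flags.
    """
    out = session.copy()
    flags = out.channels["excluded"].to_numpy(dtype=bool)
    for ch in excluded:
        idx = out.channel_index(ch) if isinstance(ch, str) else int(ch)
        flags[idx] = True
    included = np.flatnonzero(~flags)
    if len(included) == 0:
        raise ValidationError("all channels excluded: cannot re-reference")
    mean = out.samples[included].mean(axis=0)
    out.samples[included] -= mean
    out.channels["excluded"] = flags
    return out


def auto_exclude(session: RecordingSession, amplitude_sd: float = 10.0,
                 flat_tol: float = 1e-12) -> list[str]:
    """Channels violating the automatic rejection rule.

    A channel is rejected when flat (SD below ``flat_tol``) or when any
    sample deviates from its mean by more than ``amplitude_sd`` standard
    deviations.  Returns channel ids; flags are left to the caller.
    """
    bad = []
    for i in range(session.n_channels):
        x = session.samples[i]
        sd = x.std()
        if sd < flat_tol or np.abs(x - x.mean()).max() > amplitude_sd * sd:
            bad.append(str(session.channels["id"].iloc[i]))
    return bad


@dataclass
class EventRules:
    """Thresholds for movement detection and rest-event placement."""

    threshold_sd: float = 0.5
    rest_margin_s: float = 0.5      # min distance to movement init/term
    rest_spacing_s: float = 0.25    # min distance between rest events
    max_rest_events: int = 250
    glove_lag_s: float = 0.0        # shift applied to movement markers
    seed: int = 0


def _detect_flexions(trace: np.ndarray, threshold_sd: float):
    """(init, peak, term) triples from threshold crossings of a z-scored trace."""
    sd = trace.std()
    if sd == 0:
        return []
    z = (trace - trace.mean()) / sd
    above = z > threshold_sd
    d = np.diff(above.astype(np.int8))
    ups = np.flatnonzero(d == 1) + 1
    downs = np.flatnonzero(d == -1) + 1
    triples = []
    for up in ups:
        later = downs[downs > up]
        if len(later) == 0:
            continue  # flexion never terminates within the record
        down = later[0]
        peak = up + int(np.argmax(z[up:down]))
        triples.append((up, peak, down))
    return triples


def build_events(session: RecordingSession,
                 rules: EventRules | None = None) -> pd.DataFrame:
    """Movement (init/peak/term per flexion) and rest events from finger traces."""
    if not session.finger_traces:
        raise ValidationError("session has no finger traces")
    rules = rules or EventRules()
    rate = session.rate
    lag = int(round(rules.glove_lag_s * rate))
    rows = []
    for finger, trace in session.finger_traces.items():
        for init, peak, term in _detect_flexions(trace, rules.threshold_sd):
            for label, s in (("movement_init", init), ("movement_peak", peak),
                             ("movement_term", term)):
                s = min(max(s - lag, 0), session.n_samples - 1)
                rows.append((label, finger, s))
    move_df = pd.DataFrame(rows, columns=["label", "effector", "sample"]) \
        if rows else empty_events()

    # rest events: uniform draws from the allowed set, thinning as we go
    margin = int(round(rules.rest_margin_s * rate))
    spacing = int(round(rules.rest_spacing_s * rate))
    allowed = np.ones(session.n_samples, dtype=bool)
    for label in ("movement_init", "movement_term"):
        for s in move_df.loc[move_df["label"] == label, "sample"]:
            allowed[max(0, s - margin):s + margin + 1] = False
    rng = np.random.default_rng(rules.seed)
    rest = []
    candidates = np.flatnonzero(allowed)
    while len(candidates) and len(rest) < rules.max_rest_events:
        s = int(rng.choice(candidates))
        rest.append(s)
        allowed[max(0, s - spacing):s + spacing + 1] = False
        candidates = np.flatnonzero(allowed)
    if not rest and rules.max_rest_events > 0:
        warnings.warn("rest-event rules unsatisfiable: empty rest set",
                      stacklevel=2)
    rest_df = pd.DataFrame({"label": "rest", "effector": "none",
                            "sample": sorted(rest)}) if rest else empty_events()
    events = pd.concat([move_df, rest_df], ignore_index=True)
    events["sample"] = events["sample"].astype(np.int64)
    return events.sort_values("sample", kind="stable").reset_index(drop=True)
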