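"""Domain types, session container I/O, and validation.

The root input of every analysis stage is a :class:`RecordingSession`:
multichannel surface-potential samples at a fixed rate, a channel metadata
table, an event table, and (optionally) per-digit position traces.  Sessions
round-trip bit-exactly through an HDF5 container and can be imported from
EDF/EDF+ files or plain delimited numeric tables.

Sample indexing is 0-based; epoch windows are half-open
``[start, start + duration)``.  Event times are stored as integer sample
indices, never as seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError

EVENT_LABELS = ("movement_init", "movement_peak", "movement_term", "rest", "cue")
EFFECTORS = ("thumb", "index", "middle", "ring", "little", "none")

_CHANNEL_COLUMNS = ["id", "region", "excluded"]
_EVENT_COLUMNS = ["label", "effector", "sample"]


def empty_events() -> pd.DataFrame:
    """An event table with the right schema and zero rows."""
    return pd.DataFrame({"label": pd.Series(dtype=str),
                         "effector": pd.Series(dtype=str),
                         "sample": pd.Series(dtype=np.int64)})


def make_channel_table(ids, regions=None, excluded=None) -> pd.DataFrame:
    """Build a channel metadata table from parallel sequences."""
    ids = list(ids)
    n = len(ids)
    return pd.DataFrame({
        "id": [str(i) for i in ids],
        "region": list(regions) if regions is not None else ["unknown"] * n,
        "excluded": np.asarray(excluded, dtype=bool) if excluded is not None
                    else np.zeros(n, dtype=bool),
    })


@dataclass
class RecordingSession:
    """Multichannel potential recording plus channel/event metadata.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Potential in microvolts, regularly sampled.
    rate : float
        Sampling rate in samples/s; must be > 0.
    channels : DataFrame with columns ``id``, ``region``, ``excluded``
        One row per channel, aligned with the rows of ``samples``.
    events : DataFrame with columns ``label``, ``effector``, ``sample``
        Task markers; ``sample`` is a 0-based index into the record.
    finger_traces : dict[str, ndarray], optional
        Per-digit position traces (arbitrary units), same length as the
        record.
    """

    samples: np.ndarray
    rate: float
    channels: pd.DataFrame
    events: pd.DataFrame = field(default_factory=empty_events)
    finger_traces: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        self.events = self.events.reset_index(drop=True)
        self.channels = self.channels.reset_index(drop=True)
        self.finger_traces = {k: np.asarray(v, dtype=np.float64)
                              for k, v in self.finger_traces.items()}
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.samples.ndim != 2:
            raise ValidationError("samples must be 2-D (channels x time)")
        if not np.isfinite(self.rate) or self.rate <= 0:
            raise ValidationError(f"rate must be > 0, got {self.rate}")
        n_ch, n_samp = self.samples.shape
        if list(self.channels.columns) != _CHANNEL_COLUMNS:
            raise ValidationError(
                f"channel table must have columns {_CHANNEL_COLUMNS}")
        if len(self.channels) != n_ch:
            raise ValidationError(
                f"channel table has {len(self.channels)} rows for "
                f"{n_ch} channels")
        if self.channels["id"].duplicated().any():
            raise ValidationError("duplicate channel ids")
        if list(self.events.columns) != _EVENT_COLUMNS:
            raise ValidationError(
                f"event table must have columns {_EVENT_COLUMNS}")
        if len(self.events):
            bad = set(self.events["label"]) - set(EVENT_LABELS)
            if bad:
                raise ValidationError(f"unknown event labels: {sorted(bad)}")
            bad = set(self.events["effector"]) - set(EFFECTORS)
            if bad:
                raise ValidationError(f"unknown effectors: {sorted(bad)}")
            idx = np.asarray(self.events["sample"], dtype=np.int64)
            if idx.min() < 0 or idx.max() >= n_samp:
                raise ValidationError(
                    "event sample index outside record "
                    f"[0, {n_samp}): {idx.min()}..{idx.max()}")
        for name, trace in self.finger_traces.items():
            if trace.shape != (n_samp,):
                raise ValidationError(
                    f"finger trace {name!r} length {trace.shape} != "
                    f"record length {n_samp}")

    # -- convenience ------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def included_indices(self) -> np.ndarray:
        """Row indices of channels not flagged as excluded."""
        return np.flatnonzero(~self.channels["excluded"].to_numpy(dtype=bool))

    def channel_index(self, channel_id: str) -> int:
        rows = np.flatnonzero(self.channels["id"].to_numpy() == str(channel_id))
        if len(rows) == 0:
            raise KeyError(f"no channel with id {channel_id!r}")
        return int(rows[0])

    def events_of(self, label: str, effector: str | None = None) -> np.ndarray:
        """Sample indices of events with the given label (and effector)."""
        mask = self.events["label"] == label
        if effector is not None:
            mask &= self.events["effector"] == effector
        return self.events.loc[mask, "sample"].to_numpy(dtype=np.int64)

    def copy(self) -> "RecordingSession":
        return RecordingSession(
            samples=self.samples.copy(),
            rate=self.rate,
            channels=self.channels.copy(),
            events=self.events.copy(),
            finger_traces={k: v.copy() for k, v in self.finger_traces.items()},
        )


@dataclass
class EpochSet:
    """Uniform-duration, half-open analysis windows ``[start, start+duration)``.

    ``starts`` and ``labels`` are parallel arrays; ``duration`` is in samples
    and constant within a set (default 1 s at the session rate).
    """

    starts: np.ndarray
    duration: int
    labels: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.duration = int(self.duration)
        if self.duration <= 0:
            raise ValidationError("epoch duration must be positive")
        if self.starts.shape != self.labels.shape:
            raise ValidationError("starts and labels must be parallel")

    def __len__(self) -> int:
        return len(self.starts)

    def check_within(self, n_samples: int) -> None:
        if len(self.starts) and (self.starts.min() < 0
                                 or (self.starts + self.duration).max() > n_samples):
            raise ValidationError("epoch window outside record")

    def select(self, label) -> "EpochSet":
        mask = self.labels == label
        return EpochSet(self.starts[mask], self.duration, self.labels[mask])

    @classmethod
    def around_events(cls, session: RecordingSession, label: str,
                      duration_s: float = 1.0,
                      effector: str | None = None) -> "EpochSet":
        """Windows centered on each event of the given label.

        Windows that would extend past either end of the record are dropped.
        """
        dur = int(round(duration_s * session.rate))
        centers = session.events_of(label, effector)
        starts = centers - dur // 2
        ok = (starts >= 0) & (starts + dur <= session.n_samples)
        starts = starts[ok]
        return cls(starts, dur, np.array([label] * len(starts), dtype=object))


@dataclass
class PipelineConfig:
    """Analysis-wide numeric conventions and defaults.

    The defaults record the conventions used throughout: 1 s spectral
    snapshots, 1-50 Hz palette grid, 5-cycle wavelets, a 12-20 Hz beta band
    and 4-8 Hz theta band, K=24 phase bins, and a 65-135 Hz band-power
    approximation of broadband.
    """

    epoch_duration_s: float = 1.0
    psd_fmin: float = 1.0
    psd_fmax: float = 200.0
    palette_fmin: float = 1.0
    palette_fmax: float = 50.0
    palette_fstep: float = 1.0
    wavelet_cycles: int = 5
    beta_band: tuple[float, float] = (12.0, 20.0)
    theta_band: tuple[float, float] = (4.0, 8.0)
    phase_bins: int = 24
    line_noise_hz: float = 60.0
    line_noise_halfwidth_hz: float = 3.0
    broadband_band: tuple[float, float] = (65.0, 135.0)
    broadband_source: str = "psc"           # "psc" | "bandpower"
    trial_movement_s: float = 2.0
    trial_rest_s: float = 2.0
    filter_order: int = 3
    n_permutations: int = 1_000_000
    seed: int = 0

    def __post_init__(self):
        for name in ("beta_band", "theta_band", "broadband_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"{name} must be ordered low < high")
            setattr(self, name, (float(lo), float(hi)))
        if self.phase_bins < 4 or self.phase_bins % 2:
            raise ValidationError("phase_bins must be even and >= 4")
        if not (0 < self.psd_fmin < self.psd_fmax):
            raise ValidationError("psd grid must be strictly increasing")
        if not (0 < self.palette_fmin < self.palette_fmax):
            raise ValidationError("palette grid must be strictly increasing")
        if self.palette_fstep <= 0:
            raise ValidationError("palette_fstep must be positive")
        if self.broadband_source not in ("psc", "bandpower"):
            raise ValidationError("broadband_source must be 'psc' or 'bandpower'")

    @property
    def palette_grid(self) -> np.ndarray:
        return np.arange(self.palette_fmin, self.palette_fmax + 1e-9,
                         self.palette_fstep)

    def line_noise_bands(self, fmax: float) -> list[tuple[float, float]]:
        """Exclusion bands around the line-noise base frequency and harmonics."""
        bands = []
        f = self.line_noise_hz
        while f - self.line_noise_halfwidth_hz < fmax:
            bands.append((f - self.line_noise_halfwidth_hz,
                          f + self.line_noise_halfwidth_hz))
            f += self.line_noise_hz
        return bands

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        for key in ("beta_band", "theta_band", "broadband_band"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


# ---------------------------------------------------------------------------
# Session I/O
# ---------------------------------------------------------------------------

def save_session(session: RecordingSession, path) -> None:
    """Write a session to the native HDF5 container.

    Layout: ``/samples`` (channels x time, float64), ``/rate`` scalar,
    ``/channels`` and ``/events`` as column datasets, ``/finger_traces/<digit>``.
    Round-trips bit-exactly through :func:`load_session`.
    """
    session.validate()
    with h5py.File(path, "w") as f:
        f.create_dataset("samples", data=session.samples)
        f.create_dataset("rate", data=float(session.rate))
        g = f.create_group("channels")
        g.create_dataset("id", data=np.array(session.channels["id"], dtype="S"))
        g.create_dataset("region",
                         data=np.array(session.channels["region"], dtype="S"))
        g.create_dataset("excluded",
                         data=session.channels["excluded"].to_numpy(dtype=bool))
        g = f.create_group("events")
        g.create_dataset("label",
                         data=np.array(session.events["label"], dtype="S"))
        g.create_dataset("effector",
                         data=np.array(session.events["effector"], dtype="S"))
        g.create_dataset("sample",
                         data=session.events["sample"].to_numpy(dtype=np.int64))
        g = f.create_group("finger_traces")
        for name, trace in session.finger_traces.items():
            g.create_dataset(name, data=trace)


def _decode(arr) -> list[str]:
    return [x.decode() if isinstance(x, bytes) else str(x) for x in arr]


def _load_container(path) -> RecordingSession:
    with h5py.File(path, "r") as f:
        samples = f["samples"][()]
        rate = float(f["rate"][()])
        channels = pd.DataFrame({
            "id": _decode(f["channels/id"][()]),
            "region": _decode(f["channels/region"][()]),
            "excluded": f["channels/excluded"][()].astype(bool),
        })
        events = pd.DataFrame({
            "label": _decode(f["events/label"][()]),
            "effector": _decode(f["events/effector"][()]),
            "sample": f["events/sample"][()].astype(np.int64),
        })
        if not len(events):
            events = empty_events()
        traces = {name: f["finger_traces"][name][()]
                  for name in f.get("finger_traces", {})}
    return RecordingSession(samples, rate, channels, events, traces)


def _load_table(path, rate: float, events_path=None) -> RecordingSession:
    """Delimited numeric table: one column per channel, header row of ids."""
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # noqa: BLE001 - wrap any parse failure
        raise FormatError(f"cannot parse table {path}: {exc}") from exc
    if df.shape[1] < 1 or not len(df):
        raise FormatError(f"table {path} has no data")
    try:
        samples = df.to_numpy(dtype=np.float64).T
    except ValueError as exc:
        raise FormatError(f"non-numeric values in table {path}") from exc
    events = empty_events()
    if events_path is not None:
        events = load_events_csv(events_path)
    return RecordingSession(samples, rate,
                            make_channel_table(df.columns), events)


def load_events_csv(path) -> pd.DataFrame:
    """Event table CSV with columns label, effector, sample."""
    df = pd.read_csv(path)
    if list(df.columns) != _EVENT_COLUMNS:
        raise FormatError(
            f"event CSV must have columns {_EVENT_COLUMNS}, got "
            f"{list(df.columns)}")
    df["sample"] = df["sample"].astype(np.int64)
    return df


def save_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False)


def load_session(path, format: str = "container", rate: float | None = None,
                 events_path=None) -> RecordingSession:
    """Load a validated session from ``path``.

    Parameters
    ----------
    format : {"container", "edf", "table"}
        ``container`` is the native HDF5 layout written by
        :func:`save_session`; ``edf`` reads EDF/EDF+ (units converted to uV
        where the header declares mV or V); ``table`` reads a delimited
        numeric table (requires ``rate``).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format == "container":
        try:
            return _load_container(path)
        except (OSError, KeyError) as exc:
            raise FormatError(f"cannot read container {path}: {exc}") from exc
    if format == "edf":
        from ._edf import read_edf
        samples, rate_edf, ids = read_edf(path)
        events = load_events_csv(events_path) if events_path else empty_events()
        return RecordingSession(samples, rate_edf,
                                make_channel_table(ids), events)
    if format == "table":
        if rate is None:
            raise ValidationError("table format requires an explicit rate")
        return _load_table(path, rate, events_path)
    raise ValidationError(f"unknown format {format!r}")
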