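"""Minimal EDF/EDF+ reader (and writer, used by the test suite).

Implements the plain continuous-recording subset of the format: a 256-byte
fixed header, 256 bytes per signal of field headers, then data records of
little-endian int16 samples.  Annotation channels ("EDF Annotations") are
skipped.  All retained signals must share one sampling rate.
"""

from __future__ import annotations

import numpy as np

from .errors import FormatError

_UNIT_TO_UV = {"uv": 1.0, "\xb5v": 1.0, "mv": 1e3, "v": 1e6, "": 1.0}


def _field(raw: bytes, start: int, width: int) -> str:
    return raw[start:start + width].decode("ascii", errors="replace").strip()


def read_edf(path):
    """Read an EDF file -> (samples uV (n_signals, n_samples), rate, labels)."""
    with open(path, "rb") as f:
        raw = f.read()
    if len(raw) < 256:
        raise FormatError(f"{path}: too short for an EDF header")
    try:
        n_records = int(_field(raw, 236, 8))
        record_dur = float(_field(raw, 244, 8))
        ns = int(_field(raw, 252, 4))
    except ValueError as exc:
        raise FormatError(f"{path}: malformed EDF header") from exc
    if ns <= 0 or record_dur <= 0 or n_records < 0:
        raise FormatError(f"{path}: inconsistent EDF header")
    header_len = 256 + ns * 256
    if len(raw) < header_len:
        raise FormatError(f"{path}: truncated signal headers")

    def sig_field(offset, width, i):
        return _field(raw, 256 + offset * ns + i * width, width)

    labels, units, pmin, pmax, dmin, dmax, spr = [], [], [], [], [], [], []
    for i in range(ns):
        labels.append(sig_field(0, 16, i))
        units.append(sig_field(96, 8, i))
        try:
            pmin.append(float(sig_field(104, 8, i)))
            pmax.append(float(sig_field(112, 8, i)))
            dmin.append(int(sig_field(120, 8, i)))
            dmax.append(int(sig_field(128, 8, i)))
            spr.append(int(sig_field(216, 8, i)))
        except ValueError as exc:
            raise FormatError(f"{path}: malformed signal header {i}") from exc

    keep = [i for i in range(ns) if labels[i] != "EDF Annotations"]
    if not keep:
        raise FormatError(f"{path}: no data signals")
    rates = {spr[i] / record_dur for i in keep}
    if len(rates) != 1:
        raise FormatError(f"{path}: signals have mixed sampling rates")
    rate = rates.pop()

    rec_len = sum(spr)
    data = np.frombuffer(raw, dtype="<i2", offset=header_len)
    if len(data) < n_records * rec_len:
        raise FormatError(f"{path}: truncated data records")
    data = data[:n_records * rec_len].reshape(n_records, rec_len)

    offsets = np.concatenate([[0], np.cumsum(spr)])
    out = np.empty((len(keep), n_records * spr[keep[0]]), dtype=np.float64)
    for row, i in enumerate(keep):
        dig = data[:, offsets[i]:offsets[i + 1]].reshape(-1).astype(np.float64)
        if dmax[i] == dmin[i]:
            raise FormatError(f"{path}: degenerate digital range, signal {i}")
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (dig - dmin[i]) * gain + pmin[i]
        scale = _UNIT_TO_UV.get(units[i].lower())
        if scale is None:
            raise FormatError(f"{path}: unknown unit {units[i]!r}, signal {i}")
        out[row] = phys * scale
    return out, rate, [labels[i] for i in keep]


def write_edf(path, samples, rate, labels=None, unit="uV") -> None:
    """Write float samples (uV) as a plain EDF file with 1-s records.

    Quantizes to the int16 range over each signal's observed span; intended
    for fixtures and interchange, not archival fidelity.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=np.float64))
    ns, n = samples.shape
    spr = int(round(rate))
    if spr != rate:
        raise FormatError("EDF writer requires an integer rate")
    n_records = n // spr
    if n_records * spr != n:
        raise FormatError("record length must be a multiple of the rate")
    if labels is None:
        labels = [f"ch{i}" for i in range(ns)]

    def pad(s, w):
        b = str(s).encode("ascii")[:w]
        return b + b" " * (w - len(b))

    hdr = b"".join([
        pad("0", 8), pad("X", 80), pad("X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(256 + ns * 256, 8), pad("", 44),
        pad(n_records, 8), pad("1", 8), pad(ns, 4),
    ])
    pmins = samples.min(axis=1)
    pmaxs = samples.max(axis=1)
    span = np.where(pmaxs > pmins, pmaxs - pmins, 1.0)
    fields = []
    for vals, width in [
        (labels, 16), (["" for _ in range(ns)], 80), ([unit] * ns, 8),
        ([f"{v:.8g}"[:8] for v in pmins], 8),
        ([f"{v:.8g}"[:8] for v in pmaxs], 8),
        (["-32768"] * ns, 8), (["32767"] * ns, 8),
        (["" for _ in range(ns)], 80), ([str(spr)] * ns, 8),
        (["" for _ in range(ns)], 32),
    ]:
        fields.append(b"".join(pad(v, width) for v in vals))
    hdr += b"".join(fields)

    dig = np.empty_like(samples)
    for i in range(ns):
        dig[i] = (samples[i] - pmins[i]) / span[i] * 65535.0 - 32768.0
    dig16 = np.clip(np.round(dig), -32768, 32767).astype("<i2")
    records = dig16.reshape(ns, n_records, spr).transpose(1, 0, 2)
    with open(path, "wb") as f:
        f.write(hdr)
        f.write(records.tobytes())
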