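"""Minimal European Data Format (EDF) container I/O.

Implements the plain 16-bit EDF spec (Kemp et al. 1992): fixed-width ASCII
header, one header block per signal, and data records of little-endian
int16 samples. Mixed per-channel sampling rates are supported through the
per-signal samples-per-record field, which is what the 400 Hz EEG /
2 kHz LFP recordings require. EDF+ annotations are out of scope.

The recording-identification field carries the ZT anchor of the recording
start as ``ZTSEC=<seconds>`` so that a write/read round trip preserves it.
"""
from __future__ import annotations

import datetime
import re
from dataclasses import dataclass

import numpy as np

_DIG_MAX = 32767
_DIG_MIN = -32767


@dataclass
class EdfSignal:
    label: str
    sampling_rate: float
    data: np.ndarray
    physical_dim: str = "uV"
    prefilter: str = ""


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"EDF header field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def _num(value: float, width: int) -> bytes:
    # Format so that the written (truncated-precision) value is also the one
    # used for scaling: callers must re-parse before quantizing.
    for prec in range(6, 0, -1):
        s = f"{value:.{prec}g}"
        if len(s) <= width:
            return _field(s, width)
    raise ValueError(f"cannot format {value} in {width} bytes")


def write_edf(path, signals: list[EdfSignal], zt_start_s: float = 0.0,
              record_s: float = 1.0) -> None:
    """Write signals to ``path`` as plain EDF.

    Each signal's ``sampling_rate * record_s`` must be an integer and all
    signals must share a common duration that is a whole number of records.
    Samples are quantized to the 16-bit digital range with a symmetric
    physical range, so the round-trip error is at most half a quantization
    step per sample.
    """
    if not signals:
        raise ValueError("no signals to write")
    durations = {round(s.data.size / s.sampling_rate, 9) for s in signals}
    if len(durations) > 1:
        raise ValueError(f"signals have mismatched durations: {sorted(durations)} s")
    duration = durations.pop()
    n_records = duration / record_s
    if abs(n_records - round(n_records)) > 1e-9:
        raise ValueError(
            f"duration {duration} s is not a whole number of {record_s} s records"
        )
    n_records = int(round(n_records))
    spr = []
    for s in signals:
        n = s.sampling_rate * record_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"signal {s.label!r}: rate {s.sampling_rate} Hz does not give an "
                f"integer sample count per {record_s} s record"
            )
        spr.append(int(round(n)))

    ns = len(signals)
    header_bytes = 256 * (1 + ns)
    now = datetime.date(2000, 1, 1)
    rec_id = f"Startdate 01.JAN.2000 ZTSEC={zt_start_s:g}"

    head = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field(rec_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field("00.00.00", 8),
        _field(str(header_bytes), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _num(record_s, 8),
        _field(str(ns), 4),
    ])

    phys_ranges = []
    for s in signals:
        pm = float(np.max(np.abs(s.data))) if s.data.size else 0.0
        pm = max(pm, 1.0)
        # re-parse the truncated representation so scaling matches the header
        pm = float(_num(pm * 1.000001, 8).decode().strip())
        phys_ranges.append(pm)

    cols = []
    cols.append(b"".join(_field(s.label, 16) for s in signals))
    cols.append(b"".join(_field("", 80) for _ in signals))
    cols.append(b"".join(_field(s.physical_dim, 8) for s in signals))
    cols.append(b"".join(_num(-pm, 8) for pm in phys_ranges))
    cols.append(b"".join(_num(pm, 8) for pm in phys_ranges))
    cols.append(b"".join(_field(str(_DIG_MIN), 8) for _ in signals))
    cols.append(b"".join(_field(str(_DIG_MAX), 8) for _ in signals))
    cols.append(b"".join(_field(s.prefilter, 80) for s in signals))
    cols.append(b"".join(_field(str(n), 8) for n in spr))
    cols.append(b"".join(_field("", 32) for _ in signals))

    digitized = []
    for s, pm in zip(signals, phys_ranges):
        d = np.clip(np.round(np.asarray(s.data, dtype=np.float64) / pm * _DIG_MAX),
                    _DIG_MIN, _DIG_MAX).astype("<i2")
        digitized.append(d.reshape(n_records, -1))
    interleaved = (digitized[0] if len(digitized) == 1
                   else np.hstack(digitized))

    with open(path, "wb") as fh:
        fh.write(head)
        fh.write(b"".join(cols))
        fh.write(interleaved.tobytes())


def read_edf(path) -> tuple[list[EdfSignal], float]:
    """Read a plain EDF file; returns (signals, zt_start_s)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        rec_id = head[88:168].decode("ascii", errors="replace")
        n_records = int(head[236:244].decode().strip())
        record_s = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())

        sig_head = fh.read(256 * ns)
        # per-signal header fields are stored column-major (all labels, then
        # all transducers, ...)
        off = 0
        widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
        cols = []
        for w in widths:
            cols.append([sig_head[off + i * w: off + (i + 1) * w].decode().strip()
                         for i in range(ns)])
            off += ns * w
        labels, _, dims, pmin, pmax, dmin, dmax, prefilter, spr, _ = cols
        pmin = [float(v) for v in pmin]
        pmax = [float(v) for v in pmax]
        dmin = [int(v) for v in dmin]
        dmax = [int(v) for v in dmax]
        spr = [int(v) for v in spr]

        raw = np.frombuffer(fh.read(), dtype="<i2")

    per_record = sum(spr)
    if raw.size < per_record * n_records:
        raise ValueError(f"{path}: data section shorter than header promises")
    raw = raw[: per_record * n_records].reshape(n_records, per_record)

    signals = []
    start = 0
    for i in range(ns):
        stop = start + spr[i]
        dig = raw[:, start:stop].reshape(-1).astype(np.float64)
        scale = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (dig - dmin[i]) * scale + pmin[i]
        signals.append(EdfSignal(
            label=labels[i],
            sampling_rate=spr[i] / record_s,
            data=phys,
            physical_dim=dims[i],
            prefilter=prefilter[i],
        ))
        start = stop

    m = re.search(r"ZTSEC=([-\d.eE+]+)", rec_id)
    zt_start_s = float(m.group(1)) if m else 0.0
    return signals, zt_start_s
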