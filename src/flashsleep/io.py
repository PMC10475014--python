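"""File I/O: European Data Format (EDF) signals and the study's CSV tables.

EDF *reading* goes through mne.  Writing uses a minimal EDF(+)-compatible
writer implemented here (16-bit samples, 1-s data records, fixed header
date), sufficient for archiving simulated PSG channels; the mne reader
round-trips it, which the test suite uses as an independent check of the
writer.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .spectral import PsgSignal

_EDF_DIG_MAX = 32767


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field {text!r} exceeds {width} bytes")
    return b.ljust(width)


def write_edf(path, signals: Sequence[PsgSignal]) -> None:
    """Write channels to an EDF file (int16, 1-second data records).

    All signals must share an integer sampling rate and a common length; a
    tail shorter than one record is dropped with a warning.  Physical units
    are microvolts; each channel is scaled symmetrically to its own maximum
    absolute value.
    """
    if not signals:
        raise ValueError("no signals to write")
    fs = signals[0].fs
    if any(s.fs != fs for s in signals):
        raise ValueError("all signals must share one sampling rate")
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(fs)
    n = min(len(s.samples) for s in signals)
    if any(len(s.samples) != n for s in signals):
        warnings.warn("signals differ in length; truncating to shortest")
    n_records = n // fs
    if n_records < 1:
        raise ValueError("signals shorter than one 1-s record")
    if n_records * fs != n:
        warnings.warn(f"dropping {n - n_records * fs} samples "
                      "beyond the last whole second")

    headers = [b"0".ljust(8), _pad("X X X X", 80), _pad("Startdate X", 80),
               _pad("01.01.01", 8), _pad("00.00.00", 8),
               _pad(str(256 * (len(signals) + 1)), 8), _pad("", 44),
               _pad(str(n_records), 8), _pad("1", 8),
               _pad(str(len(signals)), 4)]

    phys_max = []
    for s in signals:
        m = float(np.max(np.abs(s.samples[: n_records * fs]))) if n else 0.0
        # round up to one decimal so the header field is short and the
        # quantization gain is exactly representable in ASCII
        phys_max.append(max(1.0, math.ceil(m * 10.0) / 10.0))

    def field(fmt, width):
        return b"".join(_pad(fmt(s, p), width) for s, p in zip(signals, phys_max))

    headers += [
        field(lambda s, p: s.channel, 16),
        field(lambda s, p: "", 80),          # transducer
        field(lambda s, p: "uV", 8),
        field(lambda s, p: f"{-p:g}", 8),    # physical min
        field(lambda s, p: f"{p:g}", 8),     # physical max
        field(lambda s, p: str(-_EDF_DIG_MAX), 8),
        field(lambda s, p: str(_EDF_DIG_MAX), 8),
        field(lambda s, p: "", 80),          # prefiltering
        field(lambda s, p: str(fs), 8),      # samples per record
        field(lambda s, p: "", 32),
    ]

    digital = [
        np.clip(np.round(s.samples[: n_records * fs] / p * _EDF_DIG_MAX),
                -_EDF_DIG_MAX, _EDF_DIG_MAX).astype("<i2")
        for s, p in zip(signals, phys_max)
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        fh.write(b"".join(headers))
        for r in range(n_records):
            for d in digital:
                fh.write(d[r * fs:(r + 1) * fs].tobytes())


def read_edf(
    path,
    channels: Optional[Sequence[str]] = None,
    start_time: float = 0.0,
) -> list[PsgSignal]:
    """Read EDF channels (case-insensitive label match) as microvolt signals."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    available = {name.upper(): name for name in raw.ch_names}
    if channels is None:
        wanted = list(raw.ch_names)
    else:
        missing = [c for c in channels if c.upper() not in available]
        if missing:
            raise ValueError(
                f"channel(s) {missing} absent from {path}; "
                f"file has {raw.ch_names}"
            )
        wanted = [available[c.upper()] for c in channels]
    data = raw.get_data(picks=wanted, units="uV")
    fs = float(raw.info["sfreq"])
    return [
        PsgSignal(channel=name, fs=fs, samples=row, start_time=start_time)
        for name, row in zip(wanted, data)
    ]


def clock_to_hours(text: str) -> float:
    """Parse 'HH:MM' (24-h clock) to decimal hours."""
    parts = text.strip().split(":")
    if len(parts) != 2:
        raise ValueError(f"clock time {text!r} is not HH:MM")
    h, m = int(parts[0]), int(parts[1])
    if not (0 <= h < 24 and 0 <= m < 60):
        raise ValueError(f"clock time {text!r} out of range")
    return h + m / 60.0


def wrap_relative(clock_h: float, hson_h: float) -> float:
    """Map a clock time to continuous hours relative to HSOn, in [-12, 12).

    Samples up to 12 h before habitual sleep onset belong to that night's
    day; later clock times wrap to the hours after sleep onset.
    """
    return (clock_h - hson_h + 12.0) % 24.0 - 12.0
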