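"""Shared fixtures: deterministic signals and a minimal EDF writer."""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pytest

from tfmra import Segment

FS = 256.0


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def tone_segment() -> Segment:
    n = np.arange(256)
    return Segment(np.cos(2 * np.pi * 32 * n / FS), FS, 1.0)


@pytest.fixture
def chirp_segment() -> Segment:
    from scipy.signal import chirp

    t = np.arange(256) / FS
    return Segment(chirp(t, f0=10, t1=1.0, f1=50), FS, 1.0)


def write_minimal_edf(path: Path, data: np.ndarray, fs: float,
                      channel_names: list[str]) -> None:
    """Write a small single-record EDF file (synthetic test fixture).

    Implements just enough of the EDF header + 16-bit sample encoding for a
    reader to parse one data record; physical range is set so integer
    quantization error stays below 0.01 uV for the amplitudes used here.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    ns, n_samples = data.shape
    assert len(channel_names) == ns
    record_s = n_samples / fs
    phys_min, phys_max = -500.0, 500.0
    dig_min, dig_max = -32768, 32767

    def pad(text: str, width: int) -> bytes:
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.20", 8), pad("00.00.00", 8),
        pad(str(256 + ns * 256), 8), pad("", 44), pad("1", 8),
        pad(f"{record_s:g}", 8), pad(str(ns), 4),
    ])
    header += b"".join(pad(name, 16) for name in channel_names)
    header += b"".join(pad("AgAgCl electrode", 80) for _ in range(ns))
    header += b"".join(pad("uV", 8) for _ in range(ns))
    header += b"".join(pad(f"{phys_min:g}", 8) for _ in range(ns))
    header += b"".join(pad(f"{phys_max:g}", 8) for _ in range(ns))
    header += b"".join(pad(str(dig_min), 8) for _ in range(ns))
    header += b"".join(pad(str(dig_max), 8) for _ in range(ns))
    header += b"".join(pad("", 80) for _ in range(ns))
    header += b"".join(pad(str(n_samples), 8) for _ in range(ns))
    header += b"".join(pad("", 32) for _ in range(ns))

    gain = (dig_max - dig_min) / (phys_max - phys_min)
    body = b""
    for ch in range(ns):
        dig = np.round((data[ch] - phys_min) * gain + dig_min).astype("<i2")
        body += struct.pack(f"<{n_samples}h", *dig)
    path.write_bytes(header + body)
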