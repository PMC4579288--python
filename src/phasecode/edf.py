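"""EDF interoperability: a minimal writer plus an MNE-backed reader.

EDF (European Data Format) stores 16-bit integer samples with per-signal
physical scaling in a plain ASCII header. Writing uses a deliberately
small implementation of the published format (single data record layout);
reading goes through :func:`mne.io.read_raw_edf`, so the round trip is
checked against an independent parser. Quantization to 16 bits limits
amplitude fidelity to ~1e-5 of the signal range, which is far below the
noise floor of any recording this package analyzes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["write_edf", "read_edf"]


def _ascii8(value: float) -> str:
    """Shortest %g rendering of ``value`` that fits the 8-char EDF field."""
    for precision in range(7, 0, -1):
        s = f"{value:.{precision}g}"
        if len(s) <= 8:
            return s
    raise ValueError(f"cannot render {value} in 8 ASCII characters")


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"EDF header field too long: {text!r} > {width}")
    return b.ljust(width)


def write_edf(
    signals: np.ndarray,
    rate: float,
    path,
    channel_names=None,
    physical_dim: str = "uV",
    scale: float = 1e6,
) -> Path:
    """Write one or more channels to an EDF file.

    ``signals`` is (n_samples,) or (n_channels, n_samples) in volts;
    samples are stored as microvolts (``scale``) in 1-second data records
    (a final shorter record is used when the length does not divide).
    """
    signals = np.atleast_2d(np.asarray(signals, dtype=float)) * scale
    n_ch, n = signals.shape
    if channel_names is None:
        channel_names = [f"ch{i}" for i in range(n_ch)]
    ns_rec = int(rate) if n % int(rate) == 0 else n
    n_records = n // ns_rec
    duration = ns_rec / rate

    phys_min = signals.min(axis=1)
    phys_max = signals.max(axis=1)
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    path = Path(path)
    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate 01-JAN-2000 X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad(_ascii8(duration), 8),
            _pad(str(n_ch), 4),
        ]
    )

    def field(values, width):
        return b"".join(_pad(str(v)[:width], width) for v in values)

    header += field(channel_names, 16)
    header += field([""] * n_ch, 80)
    header += field([physical_dim] * n_ch, 8)
    header += field([_ascii8(v) for v in phys_min], 8)
    header += field([_ascii8(v) for v in phys_max], 8)
    header += field([dig_min] * n_ch, 8)
    header += field([dig_max] * n_ch, 8)
    header += field([""] * n_ch, 80)
    header += field([ns_rec] * n_ch, 8)
    header += field([""] * n_ch, 32)

    # re-read the rounded header values so digital samples invert exactly
    pmin = np.array([float(_ascii8(v)) for v in phys_min])
    pmax = np.array([float(_ascii8(v)) for v in phys_max])
    gain = (pmax - pmin) / (dig_max - dig_min)
    digital = np.round((signals - pmin[:, None]) / gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            sl = slice(rec * ns_rec, (rec + 1) * ns_rec)
            for ch in range(n_ch):
                fh.write(digital[ch, sl].tobytes())
    return path


def read_edf(path) -> tuple[np.ndarray, float]:
    """Read an EDF file via MNE; returns (signals in volts, sampling rate)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return raw.get_data(), float(raw.info["sfreq"])
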