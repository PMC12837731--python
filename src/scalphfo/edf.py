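"""European Data Format (EDF) input/output.

Reading goes through MNE.  Writing uses a small self-contained EDF
encoder (16-bit samples, one-second data records, standard 10-20 channel
labels) sufficient for the synthetic recordings this package produces;
it is not a general-purpose EDF+ writer (no annotations channel, no
discontinuous records).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .core import DataError, EegRecording

_HDR = 256


def _field(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise DataError(f"EDF header field too long: {text!r}")
    return b.ljust(width)


def write_edf(recording: EegRecording, path) -> None:
    """Write a recording as 16-bit EDF with one-second data records.

    The tail of the signal is zero-padded to a whole record.  Physical
    scaling is chosen per channel from the data range.
    """
    fs = recording.sfreq
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise DataError("EDF writer requires an integer sampling rate")
    nch = recording.n_channels
    n_records = int(np.ceil(recording.n_samples / spr))
    data = np.zeros((nch, n_records * spr))
    data[:, : recording.n_samples] = recording.data

    phys_max = np.maximum(np.abs(data).max(axis=1), 1e-6)
    dig_max = 32767
    gains = phys_max / dig_max

    head = b"".join(
        [
            _field("0", 8),
            _field("X X X X", 80),            # local patient id (anonymous)
            _field("Startdate X X X X", 80),  # local recording id
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(str(_HDR * (1 + nch)), 8),
            _field("", 44),
            _field(str(n_records), 8),
            _field("1", 8),                   # record duration, seconds
            _field(str(nch), 4),
        ]
    )
    labels = b"".join(_field(ch, 16) for ch in recording.channels)
    transducer = b"".join(_field("AgAgCl electrode", 80) for _ in range(nch))
    dim = b"".join(_field("uV", 8) for _ in range(nch))
    pmin = b"".join(_field(f"{-m:.6g}"[:8], 8) for m in phys_max)
    pmax = b"".join(_field(f"{m:.6g}"[:8], 8) for m in phys_max)
    dmin = b"".join(_field(str(-dig_max), 8) for _ in range(nch))
    dmax = b"".join(_field(str(dig_max), 8) for _ in range(nch))
    prefilt = b"".join(_field("", 80) for _ in range(nch))
    nsamp = b"".join(_field(str(spr), 8) for _ in range(nch))
    reserved = b"".join(_field("", 32) for _ in range(nch))

    digital = np.round(data / gains[:, None]).clip(-dig_max, dig_max).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(head + labels + transducer + dim + pmin + pmax
                 + dmin + dmax + prefilt + nsamp + reserved)
        for r in range(n_records):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path, min_sfreq: float | None = None) -> EegRecording:
    """Load an EDF file into an :class:`EegRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(Path(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    if min_sfreq is not None and fs < min_sfreq:
        raise DataError(
            f"sampling rate {fs} Hz below required {min_sfreq} Hz"
        )
    return EegRecording(
        data=raw.get_data() * 1e6,  # MNE returns volts
        sfreq=fs,
        channels=list(raw.ch_names),
    )
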