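"""Minimal single-channel EDF / BDF writer.

Both formats share the 256-byte fixed header plus one 256-byte signal header;
EDF stores little-endian int16 samples, BDF (the BioSemi 24-bit variant)
little-endian 3-byte two's-complement integers.  Records are 1 s long; the
final partial record, if any, is padded with the physical value 0 (readers
will therefore report a duration rounded up to a whole second).

Reading is delegated to ``mne`` (see :func:`vims_hrv.preprocessing.read_ecg`);
this writer exists because the study's acquisition chain persisted ``.bdf``
files and round-trip tests need files to read.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import ParameterError


def _pad_field(value: str, width: int) -> bytes:
    b = value.encode("ascii")
    if len(b) > width:
        raise ParameterError(f"header field too long: {value!r} > {width} bytes")
    return b.ljust(width)


def write_edf(
    path: str | Path,
    samples_uv: np.ndarray,
    fs: float,
    kind: str = "edf",
    channel_label: str = "ECG",
) -> None:
    """Write a single-channel recording in microvolts.

    ``fs`` must be a positive integer (samples per 1 s data record).
    """
    samples = np.asarray(samples_uv, dtype=float)
    if samples.ndim != 1 or samples.size == 0:
        raise ParameterError("samples must be a non-empty 1-D array")
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ParameterError("fs must be a positive integer for EDF/BDF records")
    fs = int(round(fs))
    if kind not in ("edf", "bdf"):
        raise ParameterError(f"kind must be 'edf' or 'bdf', got {kind!r}")

    n_records = int(np.ceil(samples.size / fs))
    padded = np.zeros(n_records * fs)
    padded[: samples.size] = samples

    phys_min = float(np.floor(min(padded.min(), -1.0)))
    phys_max = float(np.ceil(max(padded.max(), 1.0)))
    if kind == "edf":
        dig_min, dig_max = -32768, 32767
    else:
        dig_min, dig_max = -8388608, 8388607
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.round((padded - phys_min) * gain + dig_min).astype(np.int64)
    digital = np.clip(digital, dig_min, dig_max)

    header = bytearray()
    if kind == "edf":
        header += _pad_field("0", 8)
    else:
        header += b"\xffBIOSEMI"
    header += _pad_field("X X X X", 80)                  # patient id
    header += _pad_field("Startdate X X X X", 80)        # recording id
    header += _pad_field("01.01.00", 8)                  # start date
    header += _pad_field("00.00.00", 8)                  # start time
    header += _pad_field(str(256 * 2), 8)                # header bytes
    header += _pad_field("24BIT" if kind == "bdf" else "", 44)
    header += _pad_field(str(n_records), 8)
    header += _pad_field("1", 8)                         # record duration (s)
    header += _pad_field("1", 4)                         # number of signals

    header += _pad_field(channel_label, 16)
    header += _pad_field("AgAgCl electrode", 80)
    header += _pad_field("uV", 8)
    header += _pad_field(f"{phys_min:g}", 8)
    header += _pad_field(f"{phys_max:g}", 8)
    header += _pad_field(str(dig_min), 8)
    header += _pad_field(str(dig_max), 8)
    header += _pad_field("", 80)                         # prefiltering
    header += _pad_field(str(fs), 8)                     # samples per record
    header += _pad_field("", 32)                         # reserved

    if kind == "edf":
        body = digital.astype("<i2").tobytes()
    else:
        d = digital.astype("<i4")
        raw = d.view(np.uint8).reshape(-1, 4)
        body = raw[:, :3].tobytes()                      # little-endian 24-bit

    Path(path).write_bytes(bytes(header) + body)
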