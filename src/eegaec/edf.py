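"""EDF reading and writing for sensor recordings.

Reading goes through :func:`mne.io.read_raw_edf`.  Writing uses a small
built-in EDF encoder (16-bit, one-second data records, a common physical
range across channels) sufficient for round-tripping synthetic cohorts;
values survive the trip to within the 16-bit quantization step.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import scipy.signal

from .core import SensorRecording


def _pad_ascii(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path, recording: SensorRecording, physical_dim: str = "uV") -> None:
    """Write a recording as EDF with 1-second data records.

    The sampling rate must be a positive integer; a trailing partial second
    is zero-padded.  One shared symmetric physical range covering the data
    is used for all channels.
    """
    fs = recording.fs
    if fs <= 0 or abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    data = recording.data
    n_ch, n_samp = data.shape
    n_rec = int(np.ceil(n_samp / fs))
    padded = np.zeros((n_ch, n_rec * fs))
    padded[:, :n_samp] = data

    pmax = float(np.max(np.abs(padded)))
    pmax = pmax if pmax > 0 else 1.0
    # use the limits exactly as they will be printed in the header, so the
    # decoding affine matches the encoding one
    pmax = float(f"{pmax * 1.0001:.6g}"[:8])
    pmin = -pmax
    dmin, dmax = -32768, 32767
    slope = (pmax - pmin) / (dmax - dmin)
    digital = np.clip(
        np.round((padded - pmin) / slope + dmin), dmin, dmax
    ).astype("<i2")

    start = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad_ascii("0", 8),
            _pad_ascii("X X X X", 80),
            _pad_ascii("Synthetic EEG", 80),
            _pad_ascii(start.strftime("%d.%m.%y"), 8),
            _pad_ascii(start.strftime("%H.%M.%S"), 8),
            _pad_ascii(str(256 * (1 + n_ch)), 8),
            _pad_ascii("", 44),
            _pad_ascii(str(n_rec), 8),
            _pad_ascii("1", 8),
            _pad_ascii(str(n_ch), 4),
        ]
    )
    fields = [
        (16, recording.ch_names),
        (80, ["" for _ in range(n_ch)]),  # transducer
        (8, [physical_dim] * n_ch),
        (8, [f"{pmin:.6g}" for _ in range(n_ch)]),
        (8, [f"{pmax:.6g}" for _ in range(n_ch)]),
        (8, [str(dmin)] * n_ch),
        (8, [str(dmax)] * n_ch),
        (80, ["" for _ in range(n_ch)]),  # prefiltering
        (8, [str(fs)] * n_ch),
        (32, ["" for _ in range(n_ch)]),  # reserved
    ]
    sig_header = b"".join(
        b"".join(_pad_ascii(v, width) for v in values) for width, values in fields
    )

    with open(path, "wb") as fh:
        fh.write(header + sig_header)
        for r in range(n_rec):
            block = digital[:, r * fs : (r + 1) * fs]
            fh.write(block.tobytes())


def _edf_channel_rates(path) -> list[float]:
    """Per-channel sampling rates from the EDF header (samples per record
    divided by record duration)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise ValueError(f"{path}: truncated EDF header")
        try:
            rec_dur = float(head[244:252])
            n_ch = int(head[252:256])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed EDF header") from exc
        sig = fh.read(256 * n_ch)
        if len(sig) < 256 * n_ch:
            raise ValueError(f"{path}: truncated EDF signal headers")
    off = n_ch * (16 + 80 + 8 + 8 + 8 + 8 + 8 + 80)
    rates = []
    for i in range(n_ch):
        field_ = sig[off + 8 * i : off + 8 * (i + 1)]
        rates.append(int(field_) / rec_dur)
    return rates


def read_recording(
    path,
    highpass_hz: float | None = None,
    notch_hz: float | None = None,
) -> SensorRecording:
    """Read an EDF file into a SensorRecording (values in microvolts).

    Optional basic preprocessing: a zero-phase 4th-order Butterworth
    high-pass (e.g. 1 Hz to remove drift) and a notch at the line frequency
    (e.g. 50 Hz), both applied after loading.
    """
    import mne

    rates = _edf_channel_rates(path)
    if len(set(rates)) > 1:
        raise ValueError(
            f"{path}: channels carry inconsistent sampling rates {sorted(set(rates))}"
        )
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data() * 1e6  # mne scales EEG to volts; recover microvolts
    if highpass_hz:
        sos = scipy.signal.butter(4, highpass_hz, btype="highpass", fs=fs, output="sos")
        data = scipy.signal.sosfiltfilt(sos, data, axis=-1)
    if notch_hz:
        b, a = scipy.signal.iirnotch(notch_hz, Q=30.0, fs=fs)
        data = scipy.signal.filtfilt(b, a, data, axis=-1)
    return SensorRecording(
        data,
        fs,
        ch_names=list(raw.ch_names),
        meta={"path": str(Path(path))},
    )
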