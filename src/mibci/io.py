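"""Reading and writing recordings: 16-bit EDF, plain CSV, JSON marker sidecars.

The EDF writer/reader implement the standard European Data Format (ASCII
header, 16-bit little-endian samples, per-channel physical scaling) with
1-second data records.  Cue markers travel in a JSON sidecar
``<name>.markers.json`` — ``{"subject", "fs", "markers": [{onset_s, class,
level, session}, ...]}`` — for both formats, which keeps the signal files
format-pure and the markers human-readable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import Marker, Recording

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(recording: Recording, path: str | Path) -> Path:
    """Write a 16-bit EDF file with 1-second data records.

    Physical min/max are set per channel from the data, so quantization error
    is at most (phys range) / 2^16 per sample. The last record is zero-padded
    when the duration is not a whole number of seconds. Requires an integer
    sampling rate.
    """
    path = Path(path)
    fs = recording.fs
    if fs != int(fs):
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(fs)  # samples per 1-s record
    n_sig = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / spr))

    data = np.zeros((n_sig, n_rec * spr))
    data[:, : recording.n_samples] = recording.data
    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin <= 0
    pmin[flat] -= 1.0
    pmax[flat] += 1.0

    header = b"".join([
        _ascii("0", 8),
        _ascii(recording.subject, 80),
        _ascii("mibci synthetic recording", 80),
        _ascii("01.01.00", 8),
        _ascii("00.00.00", 8),
        _ascii(256 * (1 + n_sig), 8),
        _ascii("", 44),
        _ascii(n_rec, 8),
        _ascii(1, 8),
        _ascii(n_sig, 4),
    ])
    fields = [
        (16, [lab for lab in recording.channel_labels]),
        (80, ["" for _ in range(n_sig)]),  # transducer
        (8, ["uV" for _ in range(n_sig)]),
        (8, [f"{v:.6g}"[:8] for v in pmin]),
        (8, [f"{v:.6g}"[:8] for v in pmax]),
        (8, [str(_DIG_MIN) for _ in range(n_sig)]),
        (8, [str(_DIG_MAX) for _ in range(n_sig)]),
        (80, ["" for _ in range(n_sig)]),  # prefiltering
        (8, [str(spr) for _ in range(n_sig)]),
        (32, ["" for _ in range(n_sig)]),
    ]
    sig_header = b"".join(
        b"".join(_ascii(v, width) for v in values) for width, values in fields
    )
    # re-read the rounded physical limits so scaling matches what the header says
    pmin_h = np.array([float(f"{v:.6g}"[:8]) for v in pmin])
    pmax_h = np.array([float(f"{v:.6g}"[:8]) for v in pmax])
    gain = (_DIG_MAX - _DIG_MIN) / (pmax_h - pmin_h)
    digital = np.round((data - pmin_h[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(sig_header)
        for r in range(n_rec):
            f.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read a 16-bit EDF file written by :func:`write_edf` (or compatible)."""
    path = Path(path)
    with open(path, "rb") as f:
        head = f.read(256)
        subject = head[8:88].decode("ascii").strip()
        n_rec = int(head[236:244])
        rec_dur = float(head[244:252])
        n_sig = int(head[252:256])
        sig = f.read(256 * n_sig)

        def field(offset_per_sig: int, width: int) -> list[str]:
            base = offset_per_sig * n_sig
            return [
                sig[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(n_sig)
            ]

        labels = field(0, 16)
        pmin = np.array([float(v) for v in field(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in field(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in field(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in field(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in field(16 + 80 + 8 + 8 + 8 + 8 + 8 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("mixed per-signal rates are not supported")
        spr0 = spr[0]
        raw = np.frombuffer(f.read(), dtype="<i2")
    raw = raw[: n_rec * n_sig * spr0].reshape(n_rec, n_sig, spr0)
    digital = np.moveaxis(raw, 1, 0).reshape(n_sig, n_rec * spr0).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (digital - dmin[:, None]) * gain[:, None] + pmin[:, None]
    fs = spr0 / rec_dur
    return Recording(data=data, fs=fs, channel_labels=labels, subject=subject)


def write_csv(recording: Recording, path: str | Path) -> Path:
    """Plain CSV: one column per channel, header row = channel labels."""
    path = Path(path)
    pd.DataFrame(recording.data.T, columns=recording.channel_labels).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def read_csv_recording(path: str | Path, fs: float) -> Recording:
    """Read a CSV written by :func:`write_csv`; the rate comes from the sidecar."""
    df = pd.read_csv(path)
    return Recording(data=df.to_numpy().T, fs=fs,
                     channel_labels=[str(c) for c in df.columns])


def write_markers(recording: Recording, path: str | Path) -> Path:
    """JSON sidecar with cue markers and the sampling rate."""
    path = Path(path)
    payload = {
        "subject": recording.subject,
        "fs": recording.fs,
        "markers": [
            {
                "onset_s": m.onset / recording.fs,
                "class": m.label,
                "level": m.level,
                "session": m.session,
            }
            for m in recording.markers
        ],
    }
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_markers(path: str | Path) -> tuple[list[Marker], float, str]:
    """Parse a marker sidecar; returns (markers, fs, subject)."""
    d = json.loads(Path(path).read_text())
    fs = float(d["fs"])
    markers = [
        Marker(onset=int(round(m["onset_s"] * fs)), label=m["class"],
               level=int(m["level"]), session=m["session"])
        for m in d["markers"]
    ]
    return markers, fs, d.get("subject", "sub-01")


def save_recording(recording: Recording, directory: str | Path, name: str,
                   fmt: str = "edf") -> tuple[Path, Path]:
    """Write ``<name>.<fmt>`` plus the ``<name>.markers.json`` sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if fmt == "edf":
        sig = write_edf(recording, directory / f"{name}.edf")
    elif fmt == "csv":
        sig = write_csv(recording, directory / f"{name}.csv")
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'edf' or 'csv')")
    side = write_markers(recording, directory / f"{name}.markers.json")
    return sig, side


def load_recording(path: str | Path) -> Recording:
    """Load a signal file (.edf or .csv) and its marker sidecar if present."""
    path = Path(path)
    sidecar = path.with_suffix("").with_suffix("")  # strip one suffix
    sidecar = path.parent / (path.stem + ".markers.json")
    markers: list[Marker] = []
    fs = None
    subject = "sub-01"
    if sidecar.exists():
        markers, fs, subject = read_markers(sidecar)
    if path.suffix == ".edf":
        rec = read_edf(path)
    elif path.suffix == ".csv":
        if fs is None:
            raise ValueError("CSV recordings need a marker sidecar carrying fs")
        rec = read_csv_recording(path, fs)
    else:
        raise ValueError(f"unknown recording format {path.suffix!r}")
    rec.markers = markers
    rec.subject = subject
    # container invariants are re-checked on construction only; validate onsets
    if any(m.onset >= rec.n_samples for m in markers):
        raise ValueError("marker onsets exceed the recording length")
    return rec
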