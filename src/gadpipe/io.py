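"""Recording import/export: EDF and plain delimited text.

EDF reading uses :mod:`mne` when available.  EDF writing is a minimal
self-contained implementation of the classic 16-bit EDF layout (one data
record per second), sufficient for exporting synthetic cohorts that other
EEG toolboxes can read; quantisation error is bounded by the physical range
divided by 2^15.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .preprocess import Recording


# ---------------------------------------------------------------------------
# plain-text fixtures
# ---------------------------------------------------------------------------


def write_text_recording(rec: Recording, path) -> None:
    """Write channels x samples TSV with a channel-name header plus a JSON
    sidecar (``<path>.json``) carrying fs, subject id and group."""
    path = Path(path)
    header = "\t".join(rec.channels)
    np.savetxt(path, rec.data.T, delimiter="\t", header=header, comments="")
    sidecar = {"fs": rec.fs, "subject_id": rec.subject_id, "group": rec.group}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_text_recording(path) -> Recording:
    path = Path(path)
    with open(path) as fh:
        channels = tuple(fh.readline().rstrip("\n").split("\t"))
    data = np.loadtxt(path, delimiter="\t", skiprows=1).T
    if data.ndim == 1:
        data = data[None, :]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return Recording(
        data=data,
        fs=float(meta["fs"]),
        channels=channels,
        subject_id=meta.get("subject_id", ""),
        group=meta.get("group", ""),
    )


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: Recording, path) -> None:
    """Write a recording as 16-bit EDF with 1-second data records.

    The sampling rate must be an integer; a trailing partial second is
    dropped.  Physical min/max are set symmetrically from the data so the
    quantisation step is ``2 * max|x| / (2^16 - 2)``.
    """
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_rec = rec.n_samples // fs
    if n_rec < 1:
        raise ValueError("recording shorter than one EDF data record")
    data = rec.data[:, : n_rec * fs]
    ns = data.shape[0]

    phys_max = float(np.max(np.abs(data)))
    phys_max = phys_max if phys_max > 0 else 1.0
    dig_max, dig_min = 32767, -32767
    scale = dig_max / phys_max
    digital = np.clip(np.round(data * scale), dig_min, dig_max).astype("<i2")

    hdr = b""
    hdr += _edf_field("0", 8)
    hdr += _edf_field(f"{rec.subject_id or 'X'} {rec.group or 'X'}", 80)
    hdr += _edf_field("Startdate X", 80)
    hdr += _edf_field("01.01.00", 8)
    hdr += _edf_field("00.00.00", 8)
    hdr += _edf_field(256 * (ns + 1), 8)
    hdr += _edf_field("", 44)
    hdr += _edf_field(n_rec, 8)
    hdr += _edf_field(1, 8)  # record duration, seconds
    hdr += _edf_field(ns, 4)

    def per_signal(value, width):
        return b"".join(_edf_field(value(ch) if callable(value) else value, width)
                        for ch in rec.channels)

    hdr += per_signal(lambda ch: ch, 16)          # label
    hdr += per_signal("", 80)                     # transducer
    hdr += per_signal("uV", 8)                    # physical dimension
    hdr += per_signal(f"{-phys_max:.6g}"[:8], 8)  # physical minimum
    hdr += per_signal(f"{phys_max:.6g}"[:8], 8)   # physical maximum
    hdr += per_signal(dig_min, 8)
    hdr += per_signal(dig_max, 8)
    hdr += per_signal("", 80)                     # prefiltering
    hdr += per_signal(fs, 8)                      # samples per record
    hdr += per_signal("", 32)                     # reserved

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            fh.write(digital[:, r * fs : (r + 1) * fs].tobytes())


def read_edf(path, subject_id: str = "", group: str = "") -> Recording:
    """Read an EDF recording via mne (optional dependency)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return Recording(
        data=raw.get_data(),
        fs=float(raw.info["sfreq"]),
        channels=tuple(raw.ch_names),
        subject_id=subject_id,
        group=group,
    )


def export_cohort_edf(recordings, out_dir, seed: int | None = None) -> Path:
    """Write one EDF per subject plus a plain-text manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lines = ["subject_id\tgroup\tfile\tseed"]
    for rec in recordings:
        fname = f"{rec.subject_id}.edf"
        write_edf(rec, out_dir / fname)
        lines.append(f"{rec.subject_id}\t{rec.group}\t{fname}\t{seed}")
    manifest = out_dir / "manifest.tsv"
    manifest.write_text("\n".join(lines) + "\n")
    return manifest
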