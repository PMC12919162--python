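"""Cohort and artifact I/O.

The primary interchange format is a directory of per-subject CSV
matrices (rows = samples, columns = channels) plus a JSON manifest
carrying subject IDs, labels, the sampling rate and the montage.  A
minimal EDF writer (16-bit, one-second data records) is provided for
interoperability with standard EEG tooling; EDF/BDF reading goes
through MNE when it is available.
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import EpochSet, Recording

__all__ = [
    "write_csv_cohort",
    "read_csv_cohort",
    "write_edf",
    "write_edf_cohort",
    "read_edf",
    "save_epochset",
    "load_epochset",
]


# ---------------------------------------------------------------------------
# CSV + manifest


def write_csv_cohort(recordings: list[Recording], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in recordings:
        fname = f"{rec.subject_id}.csv"
        pd.DataFrame(rec.data.T, columns=rec.channel_names).to_csv(
            outdir / fname, index=False
        )
        manifest.append(
            {
                "file": fname,
                "subject_id": rec.subject_id,
                "label": rec.label,
                "fs": rec.fs,
                "montage": list(rec.channel_names),
            }
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def read_csv_cohort(indir: str | Path) -> list[Recording]:
    indir = Path(indir)
    with open(indir / "manifest.json") as fh:
        manifest = json.load(fh)
    recs = []
    for entry in manifest:
        df = pd.read_csv(indir / entry["file"])
        recs.append(
            Recording(
                data=df[entry["montage"]].to_numpy().T,
                fs=float(entry["fs"]),
                channel_names=list(entry["montage"]),
                subject_id=entry["subject_id"],
                label=entry["label"],
            )
        )
    return recs


# ---------------------------------------------------------------------------
# EDF (16-bit, one-second records)


def _pad(s: str, n: int) -> bytes:
    return s.encode("ascii")[:n].ljust(n)


def write_edf(rec: Recording, path: str | Path) -> Path:
    """Write one recording as EDF with one-second data records.

    Samples beyond the last whole second are dropped (EDF stores an
    integer number of fixed-duration records).
    """
    path = Path(path)
    n_ch = rec.data.shape[0]
    spr = int(round(rec.fs))  # samples per record
    n_rec = rec.data.shape[1] // spr
    if n_rec == 0:
        raise ValueError("recording shorter than one EDF data record")
    data = rec.data[:, : n_rec * spr]

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    span = np.where(pmax - pmin <= 0, 1.0, pmax - pmin)
    dmin, dmax = -32768, 32767
    scaled = (data - pmin[:, None]) / span[:, None] * (dmax - dmin) + dmin
    digital = np.clip(np.round(scaled), dmin, dmax).astype("<i2")

    now = datetime(2000, 1, 1)
    header = b"".join(
        [
            _pad("0", 8),
            _pad(rec.subject_id, 80),
            _pad(f"Startdate 01-JAN-2000 {rec.label}", 80),
            _pad(now.strftime("%d.%m.%y"), 8),
            _pad(now.strftime("%H.%M.%S"), 8),
            _pad(str(256 * (1 + n_ch)), 8),
            _pad("", 44),
            _pad(str(n_rec), 8),
            _pad("1", 8),
            _pad(str(n_ch), 4),
        ]
    )
    sig = b"".join(
        [
            b"".join(_pad(c, 16) for c in rec.channel_names),
            b"".join(_pad("AgAgCl electrode", 80) for _ in range(n_ch)),
            b"".join(_pad("uV", 8) for _ in range(n_ch)),
            b"".join(_pad(f"{pmin[i]:.6g}"[:8], 8) for i in range(n_ch)),
            b"".join(_pad(f"{pmax[i] if pmax[i] > pmin[i] else pmin[i] + 1:.6g}"[:8], 8)
                     for i in range(n_ch)),
            b"".join(_pad(str(dmin), 8) for _ in range(n_ch)),
            b"".join(_pad(str(dmax), 8) for _ in range(n_ch)),
            b"".join(_pad("", 80) for _ in range(n_ch)),
            b"".join(_pad(str(spr), 8) for _ in range(n_ch)),
            b"".join(_pad("", 32) for _ in range(n_ch)),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]
            fh.write(block.tobytes())
    return path


def write_edf_cohort(recordings: list[Recording], outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in recordings:
        fname = f"{rec.subject_id}.edf"
        write_edf(rec, outdir / fname)
        manifest.append(
            {
                "file": fname,
                "subject_id": rec.subject_id,
                "label": rec.label,
                "fs": rec.fs,
                "montage": list(rec.channel_names),
            }
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


def read_edf(
    path: str | Path, subject_id: str | None = None, label: str = "HC"
) -> Recording:
    """Read an EDF/BDF file through MNE into a Recording (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE uses volts internally
    return Recording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        subject_id=subject_id or Path(path).stem,
        label=label,
    )


# ---------------------------------------------------------------------------
# epoch tensors


def save_epochset(eps: EpochSet, prefix: str | Path) -> None:
    prefix = str(prefix)
    np.save(f"{prefix}.npy", eps.epochs)
    meta = {
        "fs": eps.fs,
        "channel_names": eps.channel_names,
        "subject_ids": eps.subject_ids.tolist(),
        "labels": eps.labels.tolist(),
        "is_augmented": eps.is_augmented.tolist(),
        "flags": sorted(eps.flags),
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh)


def load_epochset(prefix: str | Path) -> EpochSet:
    prefix = str(prefix)
    epochs = np.load(f"{prefix}.npy")
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    return EpochSet(
        epochs=epochs,
        fs=meta["fs"],
        channel_names=meta["channel_names"],
        subject_ids=np.array(meta["subject_ids"]),
        labels=np.array(meta["labels"]),
        is_augmented=np.array(meta["is_augmented"], dtype=bool),
        flags=set(meta["flags"]),
    )
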