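"""File formats: ABR traces as TSV + JSON sidecar, micrographs as PNG + JSON.

Trace layout: ``<name>.tsv`` with columns ``time_ms`` (relative to stimulus
onset) and ``voltage_uV``, next to ``<name>.json`` holding
``{subject, group, freq_khz, intensity_db, sampling_rate, onset_index}``.
A cohort directory additionally carries ``manifest.csv`` listing every trace
and ``truth.csv`` with the ground-truth thresholds.  Micrographs are 8-bit
grayscale PNGs with a JSON sidecar and an optional ``*_mask.png``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from PIL import Image

from .abr_features import ABRRecording, IntensitySeries
from .densitometry import MicrographField
from .errors import InputError
from .synthetic_data import CohortDataset, HistologyCohort


def _trace_name(rec: ABRRecording) -> str:
    return f"{rec.subject}_f{rec.freq_khz:g}kHz_i{rec.intensity_db:g}dB"


def write_recording(rec: ABRRecording, directory: Path, name: Optional[str] = None) -> Path:
    """Write one trace as TSV plus JSON sidecar; returns the TSV path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    name = name or _trace_name(rec)
    tsv = directory / f"{name}.tsv"
    df = pd.DataFrame({"time_ms": rec.time_ms, "voltage_uV": rec.samples})
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    meta = {
        "subject": rec.subject, "group": rec.group,
        "freq_khz": rec.freq_khz, "intensity_db": rec.intensity_db,
        "sampling_rate": rec.sampling_rate, "onset_index": rec.onset_index,
    }
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=2))
    return tsv


def read_recording(tsv_path: Path) -> ABRRecording:
    """Read a trace written by :func:`write_recording` (or the documented CSV layout)."""
    tsv_path = Path(tsv_path)
    sidecar = tsv_path.with_suffix(".json")
    if not sidecar.exists():
        raise InputError(f"missing metadata sidecar for {tsv_path.name}")
    meta = json.loads(sidecar.read_text())
    sep = "\t" if tsv_path.suffix == ".tsv" else ","
    df = pd.read_csv(tsv_path, sep=sep)
    if "voltage_uV" not in df.columns:
        raise InputError(f"{tsv_path.name} lacks a voltage_uV column")
    return ABRRecording(
        samples=df["voltage_uV"].to_numpy(),
        sampling_rate=float(meta["sampling_rate"]),
        onset_index=int(meta["onset_index"]),
        freq_khz=float(meta["freq_khz"]),
        intensity_db=float(meta["intensity_db"]),
        subject=str(meta.get("subject", "")),
        group=str(meta.get("group", "")),
    )


def write_cohort(dataset: CohortDataset, directory: Path) -> Path:
    """Write every trace of a cohort plus manifest and ground-truth tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for (group, subject, freq), series in dataset.series.items():
        for rec in series.recordings:
            path = write_recording(rec, directory)
            rows.append({
                "file": path.name, "group": group, "subject": subject,
                "freq_khz": freq, "intensity_db": rec.intensity_db,
            })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    dataset.truth.to_csv(directory / "truth.csv", index=False, float_format="%.6g")
    return manifest


def read_cohort(directory: Path) -> Dict[Tuple[str, str, float], IntensitySeries]:
    """Read a cohort directory back into per-(group, subject, frequency) series."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise InputError(f"no manifest.csv under {directory}")
    df = pd.read_csv(manifest)
    out: Dict[Tuple[str, str, float], List[ABRRecording]] = {}
    for _, row in df.iterrows():
        rec = read_recording(directory / row["file"])
        out.setdefault((row["group"], row["subject"], float(row["freq_khz"])), []).append(rec)
    return {
        key: IntensitySeries(sorted(recs, key=lambda r: -r.intensity_db))
        for key, recs in out.items()
    }


def write_micrograph(fld: MicrographField, directory: Path, name: str,
                     save_mask: bool = False) -> Path:
    """Write a field as 8-bit grayscale PNG + JSON sidecar (+ optional mask PNG)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{name}.png"
    Image.fromarray(np.asarray(fld.pixels, dtype=np.uint8), mode="L").save(png)
    meta = {
        "subject": fld.subject, "group": fld.group,
        "subdivision": fld.subdivision, "position": fld.position,
        "pixel_size_um": fld.pixel_size_um, "is_inverted": fld.is_inverted,
    }
    (directory / f"{name}.json").write_text(json.dumps(meta, indent=2))
    if save_mask and fld.truth_mask is not None:
        mask_img = (fld.truth_mask.astype(np.uint8)) * 255
        Image.fromarray(mask_img, mode="L").save(directory / f"{name}_mask.png")
    return png


def read_micrograph(png_path: Path) -> MicrographField:
    """Read a field PNG (+ sidecar + mask if present) back into memory."""
    png_path = Path(png_path)
    img = np.asarray(Image.open(png_path).convert("L"))
    sidecar = png_path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    mask_path = png_path.with_name(png_path.stem + "_mask.png")
    mask = None
    if mask_path.exists():
        mask = np.asarray(Image.open(mask_path).convert("L")) > 127
    return MicrographField(
        pixels=img,
        subdivision=meta.get("subdivision", "AVCN"),
        position=meta.get("position", "middle"),
        subject=meta.get("subject", ""),
        group=meta.get("group", ""),
        pixel_size_um=meta.get("pixel_size_um"),
        truth_mask=mask,
        is_inverted=bool(meta.get("is_inverted", True)),
    )


def write_histology_cohort(cohort: HistologyCohort, directory: Path,
                           save_masks: bool = False) -> Path:
    """Write every field of a histology cohort plus manifest and truth tables."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    counters: Dict[Tuple[str, str], int] = {}
    for fld in cohort.fields:
        key = (fld.subject, fld.position)
        counters[key] = counters.get(key, 0) + 1
        name = f"{fld.subject}_{fld.subdivision}_s{counters[key]:02d}_{fld.position}"
        path = write_micrograph(fld, directory, name, save_mask=save_masks)
        rows.append({
            "file": path.name, "group": fld.group, "subject": fld.subject,
            "subdivision": fld.subdivision, "position": fld.position,
        })
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    cohort.truth.to_csv(directory / "truth.csv", index=False, float_format="%.6g")
    return manifest


def write_table(df: pd.DataFrame, path: Path, provenance: Optional[str] = None,
                index: bool = False) -> Path:
    """Write a CSV table, optionally prefixed with a ``#`` provenance header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if provenance:
            fh.write(f"# {provenance}\n")
        df.to_csv(fh, index=index, float_format="%.6g")
    return path


def read_table(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
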