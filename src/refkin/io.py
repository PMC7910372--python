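"""File I/O: TAC tables (CSV), NIfTI volumes, label legends, cohort manifests.

TAC tables are plain CSV with a header row ``frame_start_s,frame_end_s``
followed by one column per region; frame times in seconds, activities in
kBq/mL, "." decimal separator. Images are NIfTI-1 (.nii/.nii.gz) with the
label legend as a JSON sidecar mapping integer label to region name.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .tac import (
    TAC,
    DynamicImage,
    FrameSchedule,
    LabelVolume,
    ScanRecord,
    ScheduleError,
)

__all__ = [
    "read_tac_table",
    "write_tac_table",
    "read_dynamic_nifti",
    "write_dynamic_nifti",
    "read_label_nifti",
    "write_label_nifti",
    "write_parametric_nifti",
    "read_cohort",
    "write_cohort",
]

_TIME_COLS = ("frame_start_s", "frame_end_s")


def read_tac_table(path) -> dict[str, TAC]:
    """Read a TAC CSV into a mapping of region name to :class:`TAC`.

    All TACs in one file share a single validated frame schedule.
    """
    df = pd.read_csv(path)
    for col in _TIME_COLS:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    regions = [c for c in df.columns if c not in _TIME_COLS]
    if not regions:
        raise ValueError(f"{path}: no region columns found")
    try:
        schedule = FrameSchedule(
            start_s=df["frame_start_s"].to_numpy(),
            end_s=df["frame_end_s"].to_numpy(),
        )
    except ScheduleError as exc:
        raise ScheduleError(f"{path}: {exc}") from exc
    return {
        r: TAC(schedule=schedule, values=df[r].to_numpy(), region=r) for r in regions
    }


def write_tac_table(path, tacs: dict[str, TAC]) -> None:
    """Write named TACs (sharing one schedule) to CSV; full float precision."""
    schedules = {t.schedule for t in tacs.values()}
    if len(schedules) != 1:
        raise ValueError("all TACs in one table must share a schedule")
    schedule = schedules.pop()
    df = pd.DataFrame(
        {"frame_start_s": schedule.start_s, "frame_end_s": schedule.end_s}
    )
    for name, tac in tacs.items():
        df[name] = tac.values
    df.to_csv(path, index=False, float_format="%.17g")


def write_dynamic_nifti(path, img: DynamicImage) -> None:
    affine = np.diag([*img.voxel_size_mm, 1.0])
    nib.save(nib.Nifti1Image(img.voxels.astype(np.float32), affine), str(path))
    sidecar = {
        "frame_start_s": img.schedule.start_s.tolist(),
        "frame_end_s": img.schedule.end_s.tolist(),
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar))


def read_dynamic_nifti(path, schedule: FrameSchedule | None = None) -> DynamicImage:
    """Read a 4-D NIfTI; frame timing from ``schedule`` or the JSON sidecar."""
    nii = nib.load(str(path))
    if schedule is None:
        sidecar = Path(str(path) + ".json")
        if not sidecar.exists():
            raise ValueError(f"no schedule given and no sidecar {sidecar}")
        meta = json.loads(sidecar.read_text())
        schedule = FrameSchedule(
            start_s=np.asarray(meta["frame_start_s"]),
            end_s=np.asarray(meta["frame_end_s"]),
        )
    voxel_size = np.asarray(nii.header.get_zooms()[:3], dtype=float)
    return DynamicImage(
        voxels=np.asanyarray(nii.dataobj, dtype=float),
        voxel_size_mm=voxel_size,
        schedule=schedule,
    )


def write_label_nifti(path, labels: LabelVolume, voxel_size_mm) -> None:
    affine = np.diag([*np.asarray(voxel_size_mm, dtype=float), 1.0])
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int16), affine), str(path))
    legend = {str(k): v for k, v in labels.legend.items()}
    Path(str(path) + ".json").write_text(json.dumps(legend))


def read_label_nifti(path) -> LabelVolume:
    nii = nib.load(str(path))
    legend_path = Path(str(path) + ".json")
    if not legend_path.exists():
        raise ValueError(f"label volume {path} has no legend sidecar")
    legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return LabelVolume(labels=np.asanyarray(nii.dataobj), legend=legend)


def write_parametric_nifti(path, values: np.ndarray, voxel_size_mm, meta: dict) -> None:
    """Write a 3-D parameter map (NaN = failed/out-of-mask) plus JSON sidecar."""
    affine = np.diag([*np.asarray(voxel_size_mm, dtype=float), 1.0])
    nib.save(nib.Nifti1Image(values.astype(np.float32), affine), str(path))
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def write_cohort(records: list[ScanRecord], out_dir) -> Path:
    """Write one TAC CSV per scan plus a manifest CSV; returns manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        fname = f"{rec.subject_id}_{rec.session}.csv"
        write_tac_table(out / fname, rec.tacs)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "genotype": rec.genotype,
                "session": rec.session,
                "file": fname,
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path) -> list[ScanRecord]:
    manifest = Path(manifest_path)
    df = pd.read_csv(manifest)
    records = []
    for row in df.itertuples():
        tacs = read_tac_table(manifest.parent / row.file)
        records.append(
            ScanRecord(
                subject_id=str(row.subject_id),
                genotype=str(row.genotype),
                session=str(row.session),
                tacs=tacs,
            )
        )
    return records
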