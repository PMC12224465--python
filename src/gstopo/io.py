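"""On-disk formats: NIfTI-1 volumes, motion parameter text, TSV tables, JSON
manifests.  Arrays round-trip bit-exactly (dtype-preserving NIfTI reads)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import BoldRun, CouplingAtlas, Phenotype
from .exceptions import FormatError

__all__ = [
    "save_nifti", "load_nifti", "write_motion", "read_motion",
    "write_participants", "read_participants", "write_cohort", "read_cohort",
    "sha256_of",
]

_PARTICIPANT_COLS = ["subject_id", "age", "sex", "mean_fd", "scan_start", "sleep_score"]


def save_nifti(data: np.ndarray, path, voxel_size: float = 3.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    """Load a NIfTI volume preserving the on-disk dtype; returns (data, voxel mm)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    voxel = float(img.header.get_zooms()[0])
    return data, voxel


def write_motion(motion_params: np.ndarray, path) -> None:
    np.savetxt(str(path), motion_params, fmt="%.10e")


def read_motion(path) -> np.ndarray:
    try:
        m = np.loadtxt(str(path))
    except ValueError as e:
        raise FormatError(f"unparseable motion file {path}: {e}") from None
    m = np.atleast_2d(m)
    if m.shape[1] != 6:
        raise FormatError(f"motion file {path} has {m.shape[1]} columns, expected 6")
    return m


def write_participants(phenotypes: list[Phenotype], path) -> None:
    pd.DataFrame([
        dict(subject_id=p.subject_id, age=p.age, sex=p.sex, mean_fd=p.mean_fd,
             scan_start=p.scan_start, sleep_score=p.sleep_score)
        for p in phenotypes
    ]).to_csv(path, sep="\t", index=False)


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _PARTICIPANT_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"participants table missing columns: {missing}")
    for col in ("age", "mean_fd", "scan_start"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise FormatError(f"participants table: missing {col} in row(s) "
                              f"{bad.tolist()}")
    return df


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_cohort(runs: list[BoldRun], phenotypes: list[Phenotype], out_dir,
                 atlas: CouplingAtlas | None = None,
                 params: dict | None = None) -> dict:
    """Write one NIfTI + motion file per subject, a participants TSV, the
    atlas volumes, and a JSON manifest of generator parameters/hashes."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise FormatError(f"cannot create output directory {out}: {e}") from None
    files: dict[str, str] = {}
    for run in runs:
        bold = out / f"{run.phenotype_ref}_bold.nii.gz"
        save_nifti(run.data, bold, voxel_size=run.voxel_size)
        motion = out / f"{run.phenotype_ref}_motion.txt"
        write_motion(run.motion_params, motion)
        files[bold.name] = sha256_of(bold)
        files[motion.name] = sha256_of(motion)
    write_participants(phenotypes, out / "participants.tsv")
    files["participants.tsv"] = sha256_of(out / "participants.tsv")
    # FD traces, one column per frame index, so cohorts round-trip fully
    np.savetxt(out / "fd_traces.txt", np.stack([p.fd_trace for p in phenotypes]),
               fmt="%.10e")
    if atlas is not None:
        save_nifti(atlas.labels, out / "atlas_labels.nii.gz", atlas.voxel_size)
        save_nifti(atlas.gm_probability, out / "atlas_gm.nii.gz", atlas.voxel_size)
        atlas.region_table.to_csv(out / "atlas_regions.tsv", sep="\t", index=False)
    manifest = {
        "n_subjects": len(runs),
        "t_frames": runs[0].t_frames if runs else 0,
        "tr": runs[0].tr if runs else None,
        "voxel_size": runs[0].voxel_size if runs else None,
        "params": params or {},
        "files": files,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_cohort(out_dir) -> tuple[list[BoldRun], list[Phenotype],
                                  CouplingAtlas | None, dict]:
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    df = read_participants(out / "participants.tsv")
    traces = np.atleast_2d(np.loadtxt(out / "fd_traces.txt"))
    phenotypes = []
    for i, row in df.iterrows():
        phenotypes.append(Phenotype(
            subject_id=row.subject_id, age=float(row.age), sex=int(row.sex),
            mean_fd=float(traces[i].mean()), fd_trace=traces[i],
            scan_start=float(row.scan_start), sleep_score=int(row.sleep_score)))
    ages = np.array([p.age for p in phenotypes])
    if ages.std() > 0:
        for p in phenotypes:
            p.age_z = float((p.age - ages.mean()) / ages.std())
    runs = []
    for p in phenotypes:
        data, voxel = load_nifti(out / f"{p.subject_id}_bold.nii.gz")
        motion = read_motion(out / f"{p.subject_id}_motion.txt")
        runs.append(BoldRun(data=data, tr=float(manifest["tr"]), voxel_size=voxel,
                            motion_params=motion, phenotype_ref=p.subject_id))
    atlas = None
    if (out / "atlas_labels.nii.gz").exists():
        labels, voxel = load_nifti(out / "atlas_labels.nii.gz")
        gm, _ = load_nifti(out / "atlas_gm.nii.gz")
        table = pd.read_csv(out / "atlas_regions.tsv", sep="\t")
        atlas = CouplingAtlas(labels=labels, region_table=table,
                              gm_probability=gm, voxel_size=voxel)
    return runs, phenotypes, atlas, manifest
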