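"""Readers and writers for the pipeline's on-disk artifacts.

Formats: BOLD and masks as 4-D/3-D NIfTI with a JSON sidecar carrying
TR, voxel list and mask labels; EEG as HDF5 (samples + header
attributes); EFP weight models and run manifests as JSON; EFP
time-courses, ratings and events as TSV.  Every writer is matched by a
reader that reproduces the in-memory object exactly (floats to full
precision, labels and integers exactly), which the round-trip tests
assert.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd

from .datasets import BOLDDataset
from .efp import EEGRecording, EFPTimecourse
from .reactivity import RatingTrace

__all__ = [
    "save_eeg", "load_eeg",
    "save_bold", "load_bold",
    "save_efp_timecourse", "load_efp_timecourse",
    "save_ratings", "load_ratings",
    "save_json", "load_json",
]


# ---------------------------------------------------------------------------
# EEG (HDF5)
# ---------------------------------------------------------------------------

def save_eeg(rec: EEGRecording, path) -> None:
    with h5py.File(path, "w") as fh:
        ds = fh.create_dataset("samples", data=rec.samples)
        ds.attrs["fs"] = rec.fs
        ds.attrs["channel_labels"] = json.dumps(list(rec.channel_labels))
        ds.attrs["reference"] = rec.reference
        fh.attrs["format"] = "efpcouple-eeg-v1"


def load_eeg(path) -> EEGRecording:
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("format") != "efpcouple-eeg-v1":
            raise ValueError(f"incompatible EEG file format in {path}")
        ds = fh["samples"]
        return EEGRecording(
            samples=ds[()],
            fs=float(ds.attrs["fs"]),
            channel_labels=json.loads(ds.attrs["channel_labels"]),
            reference=str(ds.attrs["reference"]),
        )


# ---------------------------------------------------------------------------
# BOLD (NIfTI + JSON sidecar)
# ---------------------------------------------------------------------------

def save_bold(bold: BOLDDataset, prefix) -> tuple[Path, Path]:
    """Write ``<prefix>.nii`` (dense 4-D grid) and ``<prefix>.json``.

    The sidecar records TR, the flat voxel list (lattice coordinates in
    dataset order), spacing, origin and the named masks, so the flat
    ``voxels x volumes`` matrix is reconstructed exactly on load.
    """
    prefix = Path(prefix)
    dims = bold.voxel_coords.max(axis=0) + 1
    grid = np.zeros((*dims, bold.n_volumes), dtype=np.float64)
    i, j, k = bold.voxel_coords.T
    grid[i, j, k, :] = bold.data
    affine = np.diag([*bold.spacing, 1.0])
    affine[:3, 3] = bold.origin
    img = nib.Nifti1Image(grid, affine)
    img.header["pixdim"][4] = bold.tr
    nii_path = prefix.with_suffix(".nii")
    nib.save(img, nii_path)
    sidecar = {
        "format": "efpcouple-bold-v1",
        "tr": bold.tr,
        "subject_id": bold.subject_id,
        "voxel_coords": bold.voxel_coords.tolist(),
        "spacing": bold.spacing.tolist(),
        "origin": bold.origin.tolist(),
        "masks": {k2: v.tolist() for k2, v in bold.masks.items()},
    }
    json_path = prefix.with_suffix(".json")
    json_path.write_text(json.dumps(sidecar))
    return nii_path, json_path


def load_bold(prefix) -> BOLDDataset:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    if meta.get("format") != "efpcouple-bold-v1":
        raise ValueError(f"incompatible BOLD sidecar format for {prefix}")
    grid = np.asarray(nib.load(prefix.with_suffix(".nii")).dataobj, dtype=np.float64)
    coords = np.asarray(meta["voxel_coords"], dtype=int)
    i, j, k = coords.T
    return BOLDDataset(
        data=grid[i, j, k, :],
        tr=float(meta["tr"]),
        voxel_coords=coords,
        spacing=np.asarray(meta["spacing"], dtype=float),
        origin=np.asarray(meta["origin"], dtype=float),
        masks={k2: np.asarray(v, dtype=int) for k2, v in meta["masks"].items()},
        subject_id=str(meta["subject_id"]),
    )


# ---------------------------------------------------------------------------
# EFP time-course (TSV)
# ---------------------------------------------------------------------------

def save_efp_timecourse(efp: EFPTimecourse, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# model: {efp.model_name}\n")
        fh.write(f"# dt_s: {efp.dt!r}\n")
        fh.write(f"# t0_s: {efp.t0!r}\n")
        fh.write(f"# warmup_steps: {efp.warmup_steps}\n")
        pd.DataFrame({"time_s": efp.times, "value": efp.values}).to_csv(
            fh, sep="\t", index=False, float_format="%.17g"
        )


def load_efp_timecourse(path) -> EFPTimecourse:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, val = line[1:].partition(":")
            meta[key.strip()] = val.strip()
    df = pd.read_csv(path, sep="\t", comment="#", float_precision="round_trip")
    return EFPTimecourse(
        values=df["value"].to_numpy(),
        dt=float(meta.get("dt_s", 1.5)),
        t0=float(meta.get("t0_s", 12.0)),
        model_name=meta.get("model", "efp"),
        warmup_steps=int(meta.get("warmup_steps", 0)),
    )


# ---------------------------------------------------------------------------
# ratings (long TSV)
# ---------------------------------------------------------------------------

def save_ratings(traces: dict, path, subject_id: str = "") -> None:
    """Write ``{scene: RatingTrace}`` as a long (subject, scene, time, value) TSV."""
    rows = []
    for scene in sorted(traces):
        tr = traces[scene]
        for t, v in zip(tr.t, tr.values):
            rows.append((tr.subject_id or subject_id, scene, t, v))
    pd.DataFrame(rows, columns=["subject", "scene", "time_s", "value"]).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def load_ratings(path) -> dict:
    """Read a ratings TSV back into ``{(subject, scene): RatingTrace}``."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    df["subject"] = df["subject"].fillna("")
    out = {}
    for (subj, scene), grp in df.groupby(["subject", "scene"]):
        out[(str(subj), str(scene))] = RatingTrace(
            t=grp["time_s"].to_numpy(),
            values=grp["value"].to_numpy(),
            scene=str(scene),
            subject_id=str(subj),
        )
    return out


# ---------------------------------------------------------------------------
# generic JSON
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=1))


def load_json(path):
    return json.loads(Path(path).read_text())
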