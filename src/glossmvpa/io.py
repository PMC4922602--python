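"""Serialization: NIfTI volumes, TSV tables, PNG stimuli.

BOLD runs are written as 4-D NIfTI-1 volumes on the toy brain's grid with
the voxel size in the affine, together with BIDS-style events TSVs and ROI
label volumes.  Pattern sets round-trip through TSV (one row per pattern,
label/run columns first) with a JSON sidecar of provenance.  Stereo pairs
are written as ``<stem>_L.png`` / ``<stem>_R.png`` plus an optional
side-by-side cross-fuse image and an NPZ archive of the per-pixel surface
points and lookup directions used by correspondence tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from PIL import Image

from .preprocess import PatternSet, PreprocessParams
from .simulate import BoldDataset
from .stimulus import StereoPair

__all__ = [
    "save_bold_nifti",
    "save_events",
    "save_pattern_set",
    "load_pattern_set",
    "save_stereo_pair",
    "save_image",
]


def _affine(brain) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = brain.voxel_size
    return aff


def save_bold_nifti(dataset: BoldDataset, out_dir: str | Path, stem: str | None = None) -> list[Path]:
    """Write one 4-D NIfTI per run plus mask/ROI volumes and events TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = stem or dataset.subject
    brain = dataset.brain
    aff = _affine(brain)
    paths = []
    for r, data in enumerate(dataset.runs):
        vol = np.zeros((*brain.shape, data.shape[1]), dtype=np.float32)
        vol[brain.ijk[:, 0], brain.ijk[:, 1], brain.ijk[:, 2], :] = data
        img = nib.Nifti1Image(vol, aff)
        img.header.set_zooms((*brain.voxel_size, dataset.design.tr))
        p = out / f"{stem}_run-{r + 1:02d}_bold.nii"
        nib.save(img, p)
        paths.append(p)
        save_events(dataset, r, out / f"{stem}_run-{r + 1:02d}_events.tsv")
    mask = nib.Nifti1Image(brain.mask_volume().astype(np.uint8), aff)
    nib.save(mask, out / f"{stem}_mask.nii")
    roi_codes = {name: i + 1 for i, name in enumerate(brain.roi_names)}
    roi_vals = np.array([roi_codes.get(r, 0) for r in brain.roi], dtype=float)
    roi_img = nib.Nifti1Image(brain.embed(roi_vals, fill=0.0).astype(np.int16), aff)
    nib.save(roi_img, out / f"{stem}_rois.nii")
    (out / f"{stem}_rois.json").write_text(json.dumps(roi_codes, indent=1))
    return paths


def save_events(dataset: BoldDataset, run: int, path: str | Path) -> Path:
    path = Path(path)
    dataset.design.events(run).to_csv(path, sep="\t", index=False)
    return path


def save_pattern_set(pset: PatternSet, path: str | Path, provenance: dict | None = None) -> Path:
    """TSV of patterns (label/run columns then voxel columns) + JSON sidecar."""
    path = Path(path)
    df = pd.DataFrame(pset.patterns, columns=[f"v{int(v)}" for v in pset.voxels])
    df.insert(0, "run", pset.runs)
    df.insert(0, "label", pset.labels)
    df.to_csv(path, sep="\t", index=False)
    meta = {
        "roi": pset.roi,
        "subject": pset.subject,
        "voxels": [int(v) for v in pset.voxels],
        "params": {
            "qc_threshold": pset.params.qc_threshold,
            "k_voxels": pset.params.k_voxels,
            "shift_s": pset.params.shift_s,
            "block_trs": pset.params.block_trs,
            "normalization": pset.params.normalization,
        },
    }
    if provenance:
        meta["provenance"] = provenance
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))
    return path


def load_pattern_set(path: str | Path) -> PatternSet:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    meta = json.loads(path.with_suffix(".json").read_text())
    vox_cols = [c for c in df.columns if c.startswith("v")]
    return PatternSet(
        patterns=df[vox_cols].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=object),
        runs=df["run"].to_numpy(dtype=int),
        voxels=np.asarray(meta["voxels"], dtype=int),
        roi=meta.get("roi", ""),
        subject=meta.get("subject", ""),
        params=PreprocessParams(**meta["params"]),
    )


def _to_uint8(img: np.ndarray) -> np.ndarray:
    return (np.clip(img, 0.0, 1.0) * 255.0).round().astype(np.uint8)


def save_image(img: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    Image.fromarray(_to_uint8(img)).save(path)
    return path


def save_stereo_pair(pair: StereoPair, out_dir: str | Path, stem: str,
                     cross_fuse: bool = True, save_meta: bool = True) -> dict[str, Path]:
    """Write ``<stem>_L.png``, ``<stem>_R.png`` (+ cross-fuse, meta NPZ)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "left": save_image(pair.left, out / f"{stem}_L.png"),
        "right": save_image(pair.right, out / f"{stem}_R.png"),
    }
    if cross_fuse:
        gap = np.ones((pair.left.shape[0], 8, 3))
        side = np.concatenate([pair.right, gap, pair.left], axis=1)  # cross-eyed fusion
        paths["cross_fuse"] = save_image(side, out / f"{stem}_crossfuse.png")
    if save_meta:
        arrays = {}
        for eye in ("left", "right"):
            for key in ("hit", "point", "normal", "lookup"):
                arrays[f"{eye}_{key}"] = pair.meta[eye][key]
        p = out / f"{stem}_meta.npz"
        np.savez_compressed(p, condition=pair.condition, **arrays)
        paths["meta"] = p
    return paths
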