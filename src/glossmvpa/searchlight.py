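"""Moving-sphere (searchlight) decoding and group cluster inference.

An 8-mm-radius sphere is centered on every in-mask voxel (anisotropic
2.5 x 2.5 x 3 mm voxels respected); the patterns restricted to the sphere's
in-mask voxels are decoded with the same leave-one-run-out SVM as the ROI
analysis — without the top-250 voxel selection, since the sphere itself is
the feature set — and the accuracy is written at the center voxel.  Group
maps are tested per voxel against chance (0.5, one-tailed one-sample t);
supra-threshold voxels form 26-connected clusters and clusters below a
minimum extent (4 voxels ~ 25 mm^2 in-plane) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from scipy import ndimage
from scipy import stats as sps

from ._fast_svm import svm_decision
from .decoding import Contrast, SVM_C
from .preprocess import PatternSet, PreprocessParams, extract_patterns, qc_runs
from .simulate import BoldDataset, ToyBrain

__all__ = [
    "SearchlightParams",
    "AccuracyMap",
    "sphere_neighborhoods",
    "searchlight_map",
    "group_cluster_threshold",
]


@dataclass(frozen=True)
class SearchlightParams:
    radius_mm: float = 8.0
    cluster_min_voxels: int = 4  # volumetric analogue of a 25 mm^2 surface criterion
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("radius must be positive")


@dataclass
class AccuracyMap:
    """Center-assigned accuracy per in-mask voxel, on the brain's grid."""

    values: np.ndarray  # (n_voxels,) accuracy in [0, 1]
    brain: ToyBrain
    subject: str = ""
    contrast: str = ""

    def volume(self) -> np.ndarray:
        return self.brain.embed(self.values)


def sphere_neighborhoods(brain: ToyBrain, params: SearchlightParams | None = None
                         ) -> list[np.ndarray]:
    """For each in-mask voxel, indices of in-mask voxels within the sphere.

    Distances are center-to-center in mm, so the anisotropic voxel size
    shapes the neighborhood; the center voxel is always included.
    """
    params = params or SearchlightParams()
    vs = np.asarray(brain.voxel_size)
    if params.radius_mm <= vs.max():
        raise ValueError("radius must exceed the largest voxel dimension")
    reach = np.floor(params.radius_mm / vs).astype(int)
    offs = []
    for di in range(-reach[0], reach[0] + 1):
        for dj in range(-reach[1], reach[1] + 1):
            for dk in range(-reach[2], reach[2] + 1):
                d2 = (di * vs[0]) ** 2 + (dj * vs[1]) ** 2 + (dk * vs[2]) ** 2
                if d2 <= params.radius_mm**2:
                    offs.append((di, dj, dk))
    offsets = np.asarray(offs)

    # grid -> stored-voxel index lookup
    lut = np.full(brain.shape, -1, dtype=int)
    lut[brain.ijk[:, 0], brain.ijk[:, 1], brain.ijk[:, 2]] = np.arange(brain.n_voxels)
    shape = np.asarray(brain.shape)
    neighborhoods = []
    for center in brain.ijk:
        pts = center[None, :] + offsets
        ok = np.all((pts >= 0) & (pts < shape[None, :]), axis=1)
        idx = lut[pts[ok, 0], pts[ok, 1], pts[ok, 2]]
        neighborhoods.append(np.sort(idx[idx >= 0]))
    return neighborhoods


def searchlight_map(dataset: BoldDataset, contrast: Contrast,
                    params: SearchlightParams | None = None,
                    preprocess: PreprocessParams | None = None,
                    balance: bool = True) -> AccuracyMap:
    """Leave-one-run-out decoding accuracy at every in-mask voxel.

    Patterns are extracted once for the whole volume (QC-retained runs,
    z-scoring, 4-s shift, 8-TR block averages); per center the neighborhood
    columns are re-normalized (per-pattern mean over the sphere's voxels)
    and decoded.  No minimum neighborhood size is enforced.
    """
    params = params or SearchlightParams()
    preprocess = preprocess or PreprocessParams()
    retained, _ = qc_runs(dataset, preprocess)
    pset = extract_patterns(
        dataset, np.arange(dataset.brain.n_voxels), params=preprocess, runs=retained,
        roi="searchlight",
    )
    mask, y = contrast.binarize(pset.labels)
    rows = np.where(mask)[0]
    runs = pset.runs[rows]
    X_all = pset.patterns[rows]
    uniq_runs = np.unique(runs)

    neighborhoods = sphere_neighborhoods(dataset.brain, params)
    values = np.empty(dataset.brain.n_voxels)
    with sklearn.config_context(assume_finite=True):
        for v, nb in enumerate(neighborhoods):
            X = X_all[:, nb]
            X = X - X.mean(axis=1, keepdims=True)
            G = X @ X.T
            correct = total = 0
            for r in uniq_runs:
                te = runs == r
                tr = ~te
                yt, ye = y[tr], y[te]
                if ye.all() or (~ye).all() or yt.all() or (~yt).all():
                    continue
                dec = svm_decision(G[np.ix_(tr, tr)], yt, G[np.ix_(te, tr)],
                                   balance=balance, C=SVM_C)
                correct += int(np.sum((dec >= 0.0) == ye))
                total += int(te.sum())
            values[v] = correct / total if total else np.nan
    return AccuracyMap(values=values, brain=dataset.brain,
                       subject=dataset.subject, contrast=contrast.name)


def group_cluster_threshold(maps: list[AccuracyMap], params: SearchlightParams | None = None
                            ) -> tuple[np.ndarray, pd.DataFrame]:
    """Group t map vs chance with cluster-extent thresholding.

    Returns (thresholded t volume with NaN outside surviving clusters, a
    cluster table with size, peak t and peak grid location).  All maps must
    share one grid.
    """
    params = params or SearchlightParams()
    if len(maps) < 2:
        raise ValueError("group inference needs >= 2 subjects")
    brain = maps[0].brain
    for m in maps[1:]:
        if m.brain.shape != brain.shape or len(m.values) != len(maps[0].values):
            raise ValueError("accuracy maps are on different grids")

    data = np.stack([m.values for m in maps], axis=0)  # (subjects, voxels)
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    n = data.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean - 0.5) / (sd / np.sqrt(n))
    # zero across-subject variance (e.g. ceiling accuracy in every subject):
    # identical off-chance values are decisively significant, not undefined
    const = sd == 0
    t = np.where(const, np.sign(mean - 0.5) * np.inf, t)
    t = np.where(const & (mean == 0.5), 0.0, t)
    t = np.where(np.isnan(t), 0.0, t)
    p = sps.t.sf(t, df=n - 1)  # one-tailed, above chance
    sig = p < params.alpha

    sig_vol = brain.embed(sig.astype(float), fill=0.0) > 0.5
    labeled, n_clusters = ndimage.label(sig_vol, structure=np.ones((3, 3, 3), dtype=int))
    t_vol = brain.embed(t, fill=np.nan)

    rows = []
    keep_vol = np.full(brain.shape, np.nan)
    for c in range(1, n_clusters + 1):
        members = labeled == c
        size = int(members.sum())
        if size < params.cluster_min_voxels:
            continue
        tc = np.where(members, t_vol, -np.inf)
        peak = np.unravel_index(np.argmax(tc), tc.shape)
        rows.append({"cluster": len(rows) + 1, "n_voxels": size,
                     "peak_t": float(t_vol[peak]), "peak_i": peak[0],
                     "peak_j": peak[1], "peak_k": peak[2]})
        keep_vol[members] = t_vol[members]
    table = pd.DataFrame(rows, columns=["cluster", "n_voxels", "peak_t",
                                        "peak_i", "peak_j", "peak_k"])
    return keep_vol, table
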