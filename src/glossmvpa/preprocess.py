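"""Run QC, voxel selection and block-pattern extraction.

The chain mirrors a standard block-design MVPA pipeline: exclude runs whose
global-signal percent variance exceeds 0.23; within each ROI rank voxels by
the t contrast "all experimental conditions vs fixation" (on time windows
shifted 4 s for the hemodynamic delay) and keep the top 250 (or all voxels
with t > 0 if fewer); z-score each voxel's time course per run; average the
8 in-block TRs into one pattern per block; and subtract each pattern's
across-voxel mean to remove condition/run baseline offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .simulate import BoldDataset

__all__ = ["PreprocessParams", "PatternSet", "qc_runs", "select_voxels", "extract_patterns"]


@dataclass(frozen=True)
class PreprocessParams:
    qc_threshold: float = 0.23     # percent-variance cutoff for run exclusion
    k_voxels: int = 250            # voxels kept per ROI
    shift_s: float = 4.0           # hemodynamic shift applied to block windows
    block_trs: int = 8             # TRs averaged per block
    normalization: str = "pattern_mean"  # or "voxel_run_mean"

    def __post_init__(self) -> None:
        if self.k_voxels < 1:
            raise ValueError("k_voxels must be >= 1")
        if self.normalization not in ("pattern_mean", "voxel_run_mean"):
            raise ValueError("normalization must be 'pattern_mean' or 'voxel_run_mean'")

    def shift_trs(self, tr: float) -> int:
        n = self.shift_s / tr
        if not np.isclose(n, round(n)):
            raise ValueError("shift must be an integer multiple of TR")
        return int(round(n))


@dataclass
class PatternSet:
    """Block-level multivoxel patterns: the classifier's currency."""

    patterns: np.ndarray          # (n_patterns, n_voxels), z-units
    labels: np.ndarray            # condition per pattern
    runs: np.ndarray              # run index per pattern
    voxels: np.ndarray            # dataset voxel indices (feature order)
    roi: str = ""
    subject: str = ""
    params: PreprocessParams = field(default_factory=PreprocessParams)

    def __post_init__(self) -> None:
        n = len(self.patterns)
        if not (len(self.labels) == len(self.runs) == n):
            raise ValueError("patterns, labels and runs must align")

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def select(self, mask: np.ndarray) -> "PatternSet":
        """Row-subset (patterns) by boolean mask or index array."""
        return replace(self, patterns=self.patterns[mask], labels=self.labels[mask],
                       runs=self.runs[mask])

    def restrict_voxels(self, cols: np.ndarray) -> "PatternSet":
        """Column-subset (features), re-applying per-pattern mean removal."""
        pat = self.patterns[:, cols].copy()
        if self.params.normalization == "pattern_mean":
            pat -= pat.mean(axis=1, keepdims=True)
        return replace(self, patterns=pat, voxels=self.voxels[cols])


def qc_runs(dataset: BoldDataset, params: PreprocessParams | None = None
            ) -> tuple[list[int], pd.DataFrame]:
    """Exclude runs with excessive global-signal variance.

    The QC statistic per run is the variance of the whole-brain mean time
    course expressed in percent signal change about its own mean.  Returns
    (retained run indices, report table).
    """
    params = params or PreprocessParams()
    if dataset.n_runs < 1:
        raise ValueError("dataset has no runs")
    rows = []
    retained = []
    for r in range(dataset.n_runs):
        g = dataset.global_signal(r)
        pct = 100.0 * (g - g.mean()) / g.mean()
        var = float(pct.var(ddof=1))
        keep = var <= params.qc_threshold
        rows.append({"run": r, "global_signal_pct_variance": var, "retained": keep})
        if keep:
            retained.append(r)
    report = pd.DataFrame(rows)
    if not retained:
        raise ValueError(
            "all runs excluded by QC; review the qc_threshold "
            f"(={params.qc_threshold}) against the report"
        )
    return retained, report


def _window_indices(dataset: BoldDataset, run: int, shift_trs: int, block_trs: int,
                    trial_types: str) -> tuple[np.ndarray, list[np.ndarray]]:
    """Shifted TR windows per block; returns (all TR indices, per-block windows)."""
    ev = dataset.design.block_onset_trs(run, trial_types=trial_types)
    n = dataset.design.n_trs_per_run
    windows = []
    for _, row in ev.iterrows():
        start = int(row["onset_tr"]) + shift_trs
        w = np.arange(start, min(start + block_trs, n))
        windows.append(w)
    flat = np.concatenate(windows) if windows else np.array([], dtype=int)
    return flat, windows


def select_voxels(dataset: BoldDataset, roi: str, params: PreprocessParams | None = None,
                  runs: list[int] | None = None) -> np.ndarray:
    """Rank ROI voxels by the all-experimental-vs-fixation t contrast.

    Returns the ``k_voxels`` highest-t voxel indices (into the dataset's
    voxel axis); if fewer than k have t > 0, returns exactly the positive-t
    voxels.  The contrast never sees the condition labels, so selection is
    orthogonal to any decoded distinction.
    """
    params = params or PreprocessParams()
    roi_idx = dataset.brain.roi_indices(roi)
    if runs is None:
        runs = list(range(dataset.n_runs))
    shift = params.shift_trs(dataset.design.tr)

    exp_vals, fix_vals = [], []
    for r in runs:
        exp_trs, _ = _window_indices(dataset, r, shift, params.block_trs, "experimental")
        fix_trs, _ = _window_indices(dataset, r, shift, params.block_trs, "fixation")
        exp_vals.append(dataset.runs[r][np.ix_(roi_idx, exp_trs)])
        fix_vals.append(dataset.runs[r][np.ix_(roi_idx, fix_trs)])
    a = np.concatenate(exp_vals, axis=1)
    b = np.concatenate(fix_vals, axis=1)
    # pooled-variance two-sample t per voxel
    na, nb = a.shape[1], b.shape[1]
    va = a.var(axis=1, ddof=1)
    vb = b.var(axis=1, ddof=1)
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    sp = np.where(sp == 0, np.finfo(float).tiny, sp)
    t = (a.mean(axis=1) - b.mean(axis=1)) / (sp * np.sqrt(1.0 / na + 1.0 / nb))

    order = np.argsort(-t, kind="stable")
    if len(roi_idx) >= params.k_voxels and (t > 0).sum() >= params.k_voxels:
        chosen = order[: params.k_voxels]
    else:
        chosen = order[t[order] > 0]
        if len(chosen) == 0:
            chosen = order[: min(params.k_voxels, len(order))]
    return roi_idx[chosen]


def extract_patterns(dataset: BoldDataset, voxels: np.ndarray,
                     params: PreprocessParams | None = None,
                     runs: list[int] | None = None,
                     roi: str = "", subject: str | None = None) -> PatternSet:
    """Turn run time series into one labeled pattern per experimental block.

    Per run and voxel the full time course is z-scored; each block's 8
    shifted TRs are averaged into one value per voxel; then each pattern's
    across-voxel mean is removed (default) or, behind the
    ``voxel_run_mean`` switch, each voxel's across-block mean per run.
    """
    params = params or PreprocessParams()
    voxels = np.asarray(voxels)
    if len(voxels) == 0:
        raise ValueError("voxel list is empty")
    if runs is None:
        runs = list(range(dataset.n_runs))
    if len(runs) < 2:
        raise ValueError("need >= 2 retained runs for cross-validation downstream")
    shift = params.shift_trs(dataset.design.tr)

    pats, labels, run_ids = [], [], []
    for r in runs:
        data = dataset.runs[r][voxels]
        mu = data.mean(axis=1, keepdims=True)
        sd = data.std(axis=1, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        z = (data - mu) / sd
        ev = dataset.design.block_onset_trs(r, trial_types="experimental")
        _, windows = _window_indices(dataset, r, shift, params.block_trs, "experimental")
        block_pats = np.stack([z[:, w].mean(axis=1) for w in windows], axis=0)
        if params.normalization == "voxel_run_mean":
            block_pats = block_pats - block_pats.mean(axis=0, keepdims=True)
        else:
            block_pats = block_pats - block_pats.mean(axis=1, keepdims=True)
        pats.append(block_pats)
        labels.extend(ev["trial_type"].tolist())
        run_ids.extend([r] * len(ev))

    return PatternSet(
        patterns=np.concatenate(pats, axis=0),
        labels=np.asarray(labels, dtype=object),
        runs=np.asarray(run_ids, dtype=int),
        voxels=voxels,
        roi=roi,
        subject=subject if subject is not None else dataset.subject,
        params=params,
    )
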