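"""Synthetic multi-run BOLD data with controllable representational structure.

The generator emulates the measurement the decoding pipeline analyzes: a
block-design voxel time series on a toy voxel grid (2.5 x 2.5 x 3 mm, as
acquired) with ellipsoidal ROIs.  Voxels are assigned to latent neural
populations implementing the shared-subpopulation hypothesis for gloss
coding:

- ``shared_gloss``     responds to {mirror, anti_mirror, glossy} — gloss
                       regardless of cue type.
- ``mono_gloss_only``  responds to {glossy} — monocular gloss cues only.
- ``bino_gloss_only``  responds to {mirror, anti_mirror}.
- ``structure``        responds to {mirror, anti_mirror, painted} — the
                       stereoscopically curved conditions — so painted vs
                       flat is decodable while [mirror & anti-mirror] vs
                       painted is not.

Each voxel in a population carries a fixed Gaussian response weight
(zero-mean across voxels, scaled by the population amplitude in percent
signal change), so responses survive the pipeline's per-pattern mean
subtraction as multivoxel patterns rather than uniform offsets.
Hemodynamics are a 4-s delayed boxcar with a 1-TR linear ramp; noise is
i.i.d. Gaussian per voxel and TR (optional AR(1)).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .design import ExperimentDesign

__all__ = [
    "ToyBrain",
    "EffectModel",
    "BoldDataset",
    "make_toy_brain",
    "simulate_subject",
    "inject_global_drift",
    "POPULATIONS",
]

BASELINE = 100.0  # arbitrary BOLD units; signals/noise are in % of this

POPULATIONS: dict[str, frozenset[str]] = {
    "shared_gloss": frozenset({"mirror", "anti_mirror", "glossy"}),
    "mono_gloss_only": frozenset({"glossy"}),
    "bino_gloss_only": frozenset({"mirror", "anti_mirror"}),
    "structure": frozenset({"mirror", "anti_mirror", "painted"}),
}


@dataclass(frozen=True)
class ToyBrain:
    """Voxel grid with ellipsoidal ROIs inside a box-shaped 'brain'.

    Only in-mask voxels are simulated/stored; ``ijk`` maps each stored
    voxel back to the grid so volumes can be reassembled for NIfTI export
    and searchlight geometry.
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]  # mm
    ijk: np.ndarray  # (n_voxels, 3) int grid coordinates of in-mask voxels
    roi: np.ndarray  # (n_voxels,) str label, "" = background

    @property
    def n_voxels(self) -> int:
        return len(self.ijk)

    @property
    def roi_names(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.roi) - {""}))

    def roi_indices(self, name: str) -> np.ndarray:
        idx = np.where(self.roi == name)[0]
        if len(idx) == 0:
            raise KeyError(f"ROI {name!r} has no voxels")
        return idx

    def mask_volume(self) -> np.ndarray:
        vol = np.zeros(self.shape, dtype=bool)
        vol[self.ijk[:, 0], self.ijk[:, 1], self.ijk[:, 2]] = True
        return vol

    def embed(self, values: np.ndarray, fill: float = np.nan) -> np.ndarray:
        """Scatter per-voxel values into a full grid volume."""
        vol = np.full(self.shape, fill, dtype=float)
        vol[self.ijk[:, 0], self.ijk[:, 1], self.ijk[:, 2]] = values
        return vol


def make_toy_brain(
    n_rois: int = 3,
    roi_radius_mm: float = 11.0,
    voxel_size: tuple[float, float, float] = (2.5, 2.5, 3.0),
    background_voxels: int = 300,
    seed: int = 0,
) -> ToyBrain:
    """Build a toy brain of spherical ROIs on a shared grid.

    ROIs (named ``ROI1`` ... ``ROIn``) are balls of ``roi_radius_mm``
    placed on a ring, far enough apart not to touch; an 11-mm ball holds
    ~300 voxels at the 2.5 x 2.5 x 3 mm grid, comfortably above the
    pipeline's 250-voxel selection.  A seeded random sample of background
    voxels surrounds them so whole-brain QC statistics are meaningful.
    """
    vs = np.asarray(voxel_size)
    ring_r = max(2.2 * roi_radius_mm, roi_radius_mm * n_rois * 0.75)
    half_xy = ring_r + roi_radius_mm + 2 * vs[0]
    half_z = roi_radius_mm + 2 * vs[2]
    shape = (
        int(np.ceil(2 * half_xy / vs[0])) + 1,
        int(np.ceil(2 * half_xy / vs[1])) + 1,
        int(np.ceil(2 * half_z / vs[2])) + 1,
    )
    center = (np.asarray(shape) - 1) / 2.0
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    coords = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    mm = (coords - center) * vs

    roi_label = np.full(len(coords), "", dtype=object)
    angles = 2 * np.pi * np.arange(n_rois) / max(n_rois, 1)
    for r in range(n_rois):
        c = np.array([ring_r * np.cos(angles[r]), ring_r * np.sin(angles[r]), 0.0])
        d2 = np.sum((mm - c) ** 2, axis=1)
        inside = d2 <= roi_radius_mm**2
        roi_label[inside] = f"ROI{r + 1}"

    in_roi = roi_label != ""
    rng = np.random.default_rng(seed)
    bg_candidates = np.where(~in_roi)[0]
    bg = rng.choice(bg_candidates, size=min(background_voxels, len(bg_candidates)), replace=False)
    keep = np.zeros(len(coords), dtype=bool)
    keep[in_roi] = True
    keep[bg] = True
    return ToyBrain(
        shape=shape,
        voxel_size=tuple(float(v) for v in vs),
        ijk=coords[keep].astype(int),
        roi=np.asarray(roi_label[keep], dtype=object),
    )


@dataclass(frozen=True)
class EffectModel:
    """Population mixture and signal strength for one ROI.

    Fractions are of the ROI's voxels; amplitudes are the SD of the
    per-voxel response weights in percent signal change.  The remainder
    (1 - sum of fractions) of voxels is null.  ``noise_sd`` is the i.i.d.
    noise SD in percent; ``hrf_lag_s`` the hemodynamic delay applied to
    every condition regressor.
    """

    f_shared_gloss: float = 0.0
    f_mono_gloss_only: float = 0.0
    f_bino_gloss_only: float = 0.0
    f_structure: float = 0.0
    amp_shared_gloss: float = 0.0
    amp_mono_gloss_only: float = 0.0
    amp_bino_gloss_only: float = 0.0
    amp_structure: float = 0.0
    amp_bino_scale: float = 1.0  # scales shared-gloss response to binocular conditions
    noise_sd: float = 1.0
    hrf_lag_s: float = 4.0
    ar1: float = 0.0

    def __post_init__(self) -> None:
        fracs = self.fractions
        if any(f < 0 for f in fracs.values()):
            raise ValueError("population fractions must be nonnegative")
        if sum(fracs.values()) > 1.0 + 1e-12:
            raise ValueError("population fractions must sum to <= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        amps = (self.amp_shared_gloss, self.amp_mono_gloss_only,
                self.amp_bino_gloss_only, self.amp_structure)
        if any(a < 0 for a in amps):
            raise ValueError("amplitudes must be >= 0")

    @property
    def fractions(self) -> dict[str, float]:
        return {
            "shared_gloss": self.f_shared_gloss,
            "mono_gloss_only": self.f_mono_gloss_only,
            "bino_gloss_only": self.f_bino_gloss_only,
            "structure": self.f_structure,
        }

    @property
    def amplitudes(self) -> dict[str, float]:
        return {
            "shared_gloss": self.amp_shared_gloss,
            "mono_gloss_only": self.amp_mono_gloss_only,
            "bino_gloss_only": self.amp_bino_gloss_only,
            "structure": self.amp_structure,
        }


NULL_MODEL = EffectModel()


@dataclass
class BoldDataset:
    """Per-subject multi-run voxel time series plus ground truth."""

    design: ExperimentDesign
    brain: ToyBrain
    runs: list[np.ndarray] = field(repr=False)  # each (n_voxels, n_trs)
    truth: dict = field(repr=False)
    seed: int = 0
    subject: str = "sub-01"

    def __post_init__(self) -> None:
        for r, data in enumerate(self.runs):
            if data.shape != (self.brain.n_voxels, self.design.n_trs_per_run):
                raise ValueError(
                    f"run {r}: data shape {data.shape} does not match brain/design "
                    f"({self.brain.n_voxels} voxels x {self.design.n_trs_per_run} TRs)"
                )

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def global_signal(self, run: int) -> np.ndarray:
        """Whole-brain mean time course of one run."""
        return self.runs[run].mean(axis=0)


def condition_regressor(design: ExperimentDesign, run: int, condition: str,
                        hrf_lag_s: float = 4.0) -> np.ndarray:
    """Boxcar for one condition, delayed by the hemodynamic lag and smoothed
    by a 1-TR linear ramp, sampled on the TR grid."""
    n = design.n_trs_per_run
    box = np.zeros(n + 2)
    lag_trs = int(round(hrf_lag_s / design.tr))
    if not np.isclose(lag_trs * design.tr, hrf_lag_s):
        raise ValueError("hrf lag must be an integer multiple of TR")
    ev = design.block_onset_trs(run)
    for _, row in ev.iterrows():
        if row["trial_type"] != condition:
            continue
        start = row["onset_tr"] + lag_trs
        box[start:start + design.block_len_trs] = 1.0
    # 1-TR ramp: average of current and previous sample
    reg = 0.5 * (box + np.roll(box, 1))
    return reg[:n]


def _normalize_models(brain: ToyBrain, model) -> dict[str, EffectModel]:
    if isinstance(model, EffectModel):
        return {name: model for name in brain.roi_names}
    models = dict(model)
    unknown = set(models) - set(brain.roi_names)
    if unknown:
        raise ValueError(f"models reference undefined ROIs: {sorted(unknown)}")
    return models


def assign_populations(brain: ToyBrain, model: EffectModel | Mapping[str, EffectModel],
                       seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw the latent (population, weight) assignment for one subject.

    The assignment is a property of the subject's cortex, not of a
    scanning session: pass the same assignment to ``simulate_subject`` for
    both sessions so cross-session transfer sees the same voxels carrying
    the shared-gloss code.
    """
    models = _normalize_models(brain, model)
    rng = np.random.default_rng(seed)
    population = np.full(brain.n_voxels, "null", dtype=object)
    weights = np.zeros(brain.n_voxels)
    for name, m in models.items():
        idx = rng.permutation(brain.roi_indices(name))
        pos = 0
        for pop, frac in m.fractions.items():
            k = int(round(frac * len(idx)))
            sel = idx[pos:pos + k]
            population[sel] = pop
            weights[sel] = m.amplitudes[pop] * rng.standard_normal(k)
            pos += k
    return population, weights


def simulate_subject(
    design: ExperimentDesign,
    model: EffectModel | Mapping[str, EffectModel],
    seed: int,
    brain: ToyBrain | None = None,
    subject: str = "sub-01",
    assignment: tuple[np.ndarray, np.ndarray] | None = None,
) -> BoldDataset:
    """Simulate one subject's multi-run dataset.

    ``model`` is a single EffectModel applied to every ROI or a mapping
    ROI name -> EffectModel; background voxels are always null.  The same
    (design, model, seed, brain) always yields a bit-identical dataset.
    ``assignment`` (from :func:`assign_populations`) fixes the per-voxel
    population structure across sessions of the same subject; when absent
    it is drawn from ``seed``.
    """
    if brain is None:
        brain = make_toy_brain()
    models = _normalize_models(brain, model)

    rng = np.random.default_rng(seed)
    n_vox = brain.n_voxels
    if assignment is None:
        population, weights = assign_populations(brain, models, int(rng.integers(2**31)))
    else:
        population, weights = assignment
        if len(population) != n_vox or len(weights) != n_vox:
            raise ValueError("assignment does not match the brain's voxel count")

    # noise / lag parameters may differ per ROI; background follows the
    # first model (or defaults when no ROI models exist)
    default_m = next(iter(models.values())) if models else NULL_MODEL
    noise_sd = np.full(n_vox, default_m.noise_sd)
    for name, m in models.items():
        noise_sd[brain.roi_indices(name)] = m.noise_sd

    runs = []
    for r in range(design.n_runs):
        data = np.full((n_vox, design.n_trs_per_run), BASELINE)
        for name, m in models.items():
            roi_idx = brain.roi_indices(name)
            for pop, cond_set in POPULATIONS.items():
                members = roi_idx[population[roi_idx] == pop]
                if len(members) == 0:
                    continue
                reg = np.zeros(design.n_trs_per_run)
                for cond in cond_set:
                    if cond in design.conditions:
                        scale = (m.amp_bino_scale
                                 if pop == "shared_gloss" and cond in ("mirror", "anti_mirror")
                                 else 1.0)
                        reg = reg + scale * condition_regressor(design, r, cond, m.hrf_lag_s)
                data[members] += weights[members][:, None] * reg[None, :]
        noise = rng.standard_normal((n_vox, design.n_trs_per_run)) * noise_sd[:, None]
        if default_m.ar1 > 0:
            phi = default_m.ar1
            for t in range(1, noise.shape[1]):
                noise[:, t] += phi * noise[:, t - 1]
        data = data + noise
        runs.append(data)

    truth = {"population": population, "weights": weights, "models": models}
    return BoldDataset(design=design, brain=brain, runs=runs, truth=truth,
                       seed=seed, subject=subject)


def inject_global_drift(dataset: BoldDataset, run: int, amplitude_pct: float,
                        period_s: float = 80.0) -> BoldDataset:
    """Return a copy with a slow sinusoidal drift added to every voxel of one run.

    ``amplitude_pct`` is the sine amplitude in percent of baseline; a 1%
    drift contributes ~0.5 to the global-signal percent variance, well over
    the 0.23 QC threshold, while 0.01% is far below it.
    """
    if amplitude_pct < 0:
        raise ValueError("amplitude_pct must be >= 0")
    if not (0 <= run < dataset.n_runs):
        raise ValueError(f"run index {run} out of range (0..{dataset.n_runs - 1})")
    new_runs = [r.copy() for r in dataset.runs]
    t = np.arange(dataset.design.n_trs_per_run) * dataset.design.tr
    drift = (BASELINE * amplitude_pct / 100.0) * np.sin(2 * np.pi * t / period_s)
    new_runs[run] = new_runs[run] + drift[None, :]
    out = replace(dataset, runs=new_runs, truth=copy.copy(dataset.truth))
    return out
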