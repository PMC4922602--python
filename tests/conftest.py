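"""Shared fixtures: small rendering scenes and simulated null cohorts.

The expensive objects (12-subject null cohorts and their 1,000-rep
permutation nulls) are session-scoped so the boundary, bias and index
checks all reuse one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from glossmvpa.decoding import CONTRASTS
from glossmvpa.design import RUN_RANGES, make_design
from glossmvpa.envmaps import make_envmap
from glossmvpa.preprocess import PreprocessParams, extract_patterns, qc_runs, select_voxels
from glossmvpa.simulate import EffectModel, make_toy_brain, simulate_subject
from glossmvpa.stimulus import Scene, make_potato


def build_null_cohort(session: str, seed: int, n_subjects: int = 12,
                      roi_radius_mm: float = 14.5, n_rois: int = 1):
    """Null subjects through the full pipeline.

    Returns a list of PatternSets (one per subject) when ``n_rois == 1``,
    else a dict ROI name -> list of PatternSets.
    """
    brain = make_toy_brain(n_rois=n_rois, roi_radius_mm=roi_radius_mm)
    rng = np.random.default_rng(seed)
    lo, hi = RUN_RANGES[session]
    params = PreprocessParams()
    by_roi: dict[str, list] = {roi: [] for roi in brain.roi_names}
    for s in range(n_subjects):
        design = make_design(session, int(rng.integers(lo, hi + 1)),
                             seed=int(rng.integers(2**31)))
        ds = simulate_subject(design, EffectModel(noise_sd=1.0),
                              seed=int(rng.integers(2**31)), brain=brain,
                              subject=f"sub-{s + 1:02d}")
        retained, _ = qc_runs(ds, params)
        for roi in brain.roi_names:
            vox = select_voxels(ds, roi, params, runs=retained)
            by_roi[roi].append(extract_patterns(ds, vox, params, runs=retained, roi=roi))
    if n_rois == 1:
        return by_roi["ROI1"]
    return by_roi


@pytest.fixture(scope="session")
def null_bino_cohort():
    """12 binocular null subjects, two ROIs each (dict ROI -> PatternSets)."""
    return build_null_cohort("binocular", seed=202401, n_rois=2)


@pytest.fixture(scope="session")
def null_mono_cohort():
    return build_null_cohort("nonstereoscopic", seed=202402, n_rois=2)


@pytest.fixture(scope="session")
def cv_null_distributions(null_bino_cohort, null_mono_cohort):
    """The five 1,000-rep permutation-null analyses, ROI-averaged over the
    two simulated ROIs: (averaged threshold, per-ROI NullDistributions)."""
    from glossmvpa.stats import roi_averaged_threshold

    out = {}
    for key, cohort, cname, seed in (
        ("mirror_anti_vs_painted", null_bino_cohort, "mirror_anti_vs_painted", 11),
        ("mirror_vs_anti", null_bino_cohort, "mirror_vs_anti", 12),
        ("painted_vs_flat", null_bino_cohort, "painted_vs_flat", 13),
        ("glossy_vs_matte", null_mono_cohort, "glossy_vs_matte", 15),
    ):
        avg, nulls = roi_averaged_threshold(cohort, CONTRASTS[cname], n_reps=1000,
                                            seed=seed)
        out[key] = (avg, nulls)
    avg, nulls = roi_averaged_threshold(
        null_bino_cohort, CONTRASTS["mirror_anti_vs_painted"], n_reps=1000, seed=14,
        transfer_with=CONTRASTS["flat_vs_painted"])
    out["transfer_MAvsP_to_FvsP"] = (avg, nulls)
    return out


@pytest.fixture(scope="session")
def scene():
    """Small-resolution scene shared by the renderer tests."""
    return Scene(potato=make_potato(seed=1, amplitude=0.12),
                 env=make_envmap("blobs", seed=0), image_px=48)
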