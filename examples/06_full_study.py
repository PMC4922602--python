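"""Run the whole analysis matrix on a small simulated cohort.

Writes QC, decoding, index, threshold, group-test and transfer tables plus
figures under ``study_out/``.  The same pipeline scales to the full
12-subject, 1,000-permutation configuration (see study_config.yaml); this
example uses 4 subjects and 150 permutations to finish in a few minutes.
"""

from glossmvpa import StudyConfig, run_study
from glossmvpa.study import GLOSS_TRANSFER_MODEL, STRUCTURE_MODEL
from glossmvpa.simulate import EffectModel

config = StudyConfig(
    seed=7,
    n_subjects=4,
    rois={"ROI1": GLOSS_TRANSFER_MODEL,   # shared-subpopulation gloss coding
          "ROI2": STRUCTURE_MODEL,        # 3-D structure coding
          "ROI3": EffectModel()},         # null control region
    n_permutations=150,
)
result = run_study(config, out_dir="study_out", render_examples=True)

print(result.group[["roi", "analysis", "mean", "t", "significant"]]
      .to_string(index=False))
print("\nPermutation boundaries (95%):")
print(result.thresholds.to_string(index=False))
print("\nTables and figures written to study_out/ — ROI1 should decode the gloss",
      "contrasts and transfer monocular->binocular; ROI2 should decode",
      "painted-vs-flat; ROI3 should stay silent.")
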