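# Full-scale study configuration for the command-line interface:
#   glossmvpa all --config examples/study_config.yaml --out study_full
# 12 subjects, three ROIs, 1,000 label shuffles per null. Expect a multi-hour
# run on one core; lower n_permutations / n_subjects for a quick look.
seed: 2024
n_subjects: 12
roi_radius_mm: 14.5
n_permutations: 1000
searchlight_contrast: mirror_anti_vs_painted
rois:
  ROI1:   # shared-subpopulation gloss region (transfer asymmetry emerges here)
    f_shared_gloss: 0.05
    f_mono_gloss_only: 0.20
    f_bino_gloss_only: 0.50
    amp_shared_gloss: 0.15
    amp_mono_gloss_only: 0.15
    amp_bino_gloss_only: 0.40
    noise_sd: 1.0
  ROI2:   # 3-D structure region
    f_structure: 0.3
    amp_structure: 0.3
    noise_sd: 1.0
  ROI3: {}   # null control (noise only)
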