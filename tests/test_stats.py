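"""d', indices, permutation machinery and group tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from glossmvpa.decoding import CONTRASTS
from glossmvpa.preprocess import PatternSet
from glossmvpa.stats import (NullDistribution, compare_indices_anova, compute_indices,
                             dprime, group_test, index_permutation_null, permutation_null,
                             roi_averaged_threshold)


class TestDprime:
    def test_symmetric_confusion_gives_zero(self):
        assert dprime(10, 10, 10, 10) == 0.0
        assert dprime(7, 21, 7, 21) == 0.0  # H == F at 25%

    def test_perfect_performance_with_clipping(self):
        # 28/28 hits and 28/28 correct rejections: rates clip to 55/56
        expected = 2.0 * norm.ppf(55.0 / 56.0)
        assert np.isclose(dprime(28, 0, 0, 28), expected)
        assert np.isclose(expected, 4.2003, atol=5e-4)

    def test_zero_class_rejected(self):
        with pytest.raises(ValueError):
            dprime(0, 0, 5, 5)

    @settings(derandomize=True, max_examples=50)
    @given(st.tuples(st.integers(0, 30), st.integers(0, 30),
                     st.integers(0, 30), st.integers(0, 30)))
    def test_antisymmetric_under_true_label_swap(self, counts):
        h, m, fa, cr = counts
        if h + m == 0 or fa + cr == 0:
            return
        # swapping the true labels (predictions fixed) negates d'
        assert np.isclose(dprime(fa, cr, h, m), -dprime(h, m, fa, cr), atol=1e-12)


class TestIndices:
    def test_equal_dprimes_give_zero_indices(self):
        idx = compute_indices({"mirror_anti_vs_painted": 0.7, "mirror_vs_anti": 0.7,
                               "painted_vs_flat": 0.7})
        assert idx == {"gloss_index": 0.0, "structure_index": 0.0}

    def test_arithmetic(self):
        idx = compute_indices({"mirror_anti_vs_painted": 1.0, "mirror_vs_anti": 0.2,
                               "painted_vs_flat": 0.8})
        assert np.isclose(idx["gloss_index"], 0.8)
        assert np.isclose(idx["structure_index"], 0.6)

    def test_missing_contrast_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_indices({"mirror_vs_anti": 0.1})


class TestGroupTest:
    def test_all_at_baseline_not_significant(self):
        res = group_test(np.full(12, 0.53), baseline=0.53, n_rois=15)
        assert res["t"] == 0.0 and not res["significant"]

    def test_one_sd_shift_gives_sqrt_n_t(self):
        rng = np.random.default_rng(0)
        z = rng.standard_normal(12)
        z = (z - z.mean()) / z.std(ddof=1)  # exactly unit sample SD, zero mean
        res = group_test(0.5 + 1.0 + z, baseline=0.5, n_rois=1)
        assert np.isclose(res["t"], np.sqrt(12), atol=1e-10)  # ~3.464

    def test_bonferroni_threshold(self):
        res = group_test(np.array([0.5, 0.6, 0.7]), baseline=0.5, n_rois=15)
        assert np.isclose(res["alpha_corrected"], 0.05 / 15)

    def test_accepts_null_distribution_baseline(self):
        nd = NullDistribution(reps=np.linspace(0.45, 0.55, 1000))
        res = group_test(np.full(6, 0.8), baseline=nd, n_rois=1)
        assert res["baseline"] == nd.threshold_95
        assert res["significant"]

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            group_test(np.array([0.6]), 0.5)


def _noise_psets(n_subjects, n_runs=3, n_vox=20, seed=0,
                 conds=("mirror", "anti_mirror", "painted", "flat")):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        labels = np.concatenate([rng.permutation(np.repeat(conds, 4))
                                 for _ in range(n_runs)])
        out.append(PatternSet(
            patterns=rng.standard_normal((16 * n_runs, n_vox)),
            labels=labels.astype(object),
            runs=np.repeat(np.arange(n_runs), 16),
            voxels=np.arange(n_vox)))
    return out


class TestPermutationNull:
    def test_deterministic_given_seed(self):
        psets = _noise_psets(2, seed=1)
        a = permutation_null(psets, CONTRASTS["mirror_vs_anti"], n_reps=100, seed=5)
        b = permutation_null(psets, CONTRASTS["mirror_vs_anti"], n_reps=100, seed=5)
        assert np.array_equal(a.reps, b.reps)
        assert a.threshold_95 == np.percentile(a.reps, 95)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError, match="100"):
            permutation_null(_noise_psets(2), CONTRASTS["mirror_vs_anti"], n_reps=50)

    def test_absent_conditions_rejected(self):
        psets = _noise_psets(2, conds=("glossy", "matte", "rough", "textured"))
        with pytest.raises(ValueError, match="absent"):
            permutation_null(psets, CONTRASTS["mirror_vs_anti"], n_reps=100)

    def test_threshold_scales_inverse_sqrt_subjects(self):
        """Group-mean null width shrinks as 1/sqrt(n): checked at n=3,12,48."""
        margins = {}
        for n in (3, 12, 48):
            nd = permutation_null(_noise_psets(n, seed=n), CONTRASTS["mirror_vs_anti"],
                                  n_reps=250, seed=7)
            margins[n] = nd.threshold_95 - 0.5
        r12 = margins[3] / margins[12]
        r48 = margins[12] / margins[48]
        assert 2.0 * 0.7 < r12 < 2.0 / 0.7
        assert 2.0 * 0.7 < r48 < 2.0 / 0.7

    def test_convergence_100_vs_1000_reps(self):
        psets = _noise_psets(6, seed=2)
        a = permutation_null(psets, CONTRASTS["painted_vs_flat"], n_reps=100, seed=3)
        b = permutation_null(psets, CONTRASTS["painted_vs_flat"], n_reps=1000, seed=3)
        assert abs(a.threshold_95 - b.threshold_95) < 0.005

    def test_roi_averaged_threshold(self):
        by_roi = {"A": _noise_psets(3, seed=4), "B": _noise_psets(3, seed=5)}
        avg, nulls = roi_averaged_threshold(by_roi, CONTRASTS["mirror_vs_anti"],
                                            n_reps=100, seed=1)
        assert set(nulls) == {"A", "B"}
        assert np.isclose(avg, np.mean([nulls["A"].threshold_95, nulls["B"].threshold_95]))

    def test_index_null_reps_and_determinism(self):
        psets = _noise_psets(2, seed=6)
        a = index_permutation_null(psets, n_reps=100, seed=9)
        b = index_permutation_null(psets, n_reps=100, seed=9)
        assert set(a) == {"gloss_index", "structure_index"}
        assert all(np.array_equal(a[k].reps, b[k].reps) for k in a)
        assert all(len(a[k].reps) == 100 for k in a)


def _index_table(rng, n_subj=12, n_roi=15, effect=0.0, effect_roi="roi01", noise=0.3):
    rows = []
    for s in range(n_subj):
        for r in range(n_roi):
            roi = f"roi{r + 1:02d}"
            for index in ("gloss_index", "structure_index"):
                v = rng.normal(0, noise)
                if index == "gloss_index" and roi == effect_roi:
                    v += effect
                rows.append({"subject": f"s{s}", "roi": roi, "index": index, "value": v})
    return pd.DataFrame(rows)


class TestIndicesAnova:
    def test_degrees_of_freedom_for_2x15_design(self):
        table = _index_table(np.random.default_rng(0))
        res = compare_indices_anova(table)
        inter = res["anova"].loc["index:roi"]
        assert (inter["df_num"], inter["df_den"]) == (14.0, 154.0)
        assert res["anova"].loc["index", "df_den"] == 11.0

    def test_constant_table_gives_zero_f(self):
        table = _index_table(np.random.default_rng(0), noise=0.0)
        table["value"] = 0.42
        res = compare_indices_anova(table)
        assert (res["anova"]["F"] == 0.0).all()
        assert len(res["tukey"]) == 0

    def test_incomplete_table_rejected(self):
        table = _index_table(np.random.default_rng(0)).iloc[:-1]
        with pytest.raises(ValueError, match="incomplete"):
            compare_indices_anova(table)

    def test_interaction_power_for_localized_effect(self):
        """One ROI's gloss index shifted by 2x the noise SD: the index-by-ROI
        interaction should be detected in the overwhelming majority of runs."""
        rng = np.random.default_rng(1)
        pvals = []
        n_sims = 25
        for _ in range(n_sims):
            table = _index_table(rng, effect=0.6, noise=0.3)
            res = compare_indices_anova(table)
            pvals.append(res["anova"].loc["index:roi", "p"])
        pvals = np.asarray(pvals)
        # power ~0.75 at this effect size (12 subjects, 15 ROIs); far above
        # the 5% false-positive rate and typically decisive
        assert np.mean(pvals < 0.05) > 0.5
        assert np.median(pvals) < 0.05

    def test_tukey_flags_the_shifted_cell(self):
        rng = np.random.default_rng(2)
        table = _index_table(rng, effect=3.0, noise=0.2, n_roi=3)
        res = compare_indices_anova(table)
        tk = res["tukey"]
        hit = tk[(tk.group1.str.contains("gloss_index\\|roi01"))
                 | (tk.group2.str.contains("gloss_index\\|roi01"))]
        assert hit.reject.astype(bool).any()
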