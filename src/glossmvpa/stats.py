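"""Signal-detection indices, permutation nulls and group-level tests.

Decoding accuracy is converted to d' from fold-pooled confusion counts
(z(H) - z(F) with 1/(2N) rate clipping).  Two difference indices normalize
decoding of material vs depth structure by the mirror-vs-anti-mirror
baseline:

    gloss_index     = d'([mirror & anti-mirror] vs painted) - d'(mirror vs anti-mirror)
    structure_index = d'(painted vs flat)                   - d'(mirror vs anti-mirror)

Group-level inference uses permutation nulls: condition labels are shuffled
within each run independently for every subject, the full decoding
computation is re-run, and the across-subject mean is recorded per
repetition; the one-tailed 95th percentile of those group means is the
significance boundary (optionally averaged across ROIs).  The permutation
engine precomputes each subject's linear-kernel Gram matrix once, so the
SVM refits inside the shuffle loop cost well under a millisecond each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import sklearn
from scipy import stats as sps

from ._fast_svm import svm_decision
from .decoding import Contrast, SVM_C
from .preprocess import PatternSet

__all__ = [
    "dprime",
    "compute_indices",
    "NullDistribution",
    "permutation_null",
    "transfer_permutation_null",
    "index_permutation_null",
    "roi_averaged_threshold",
    "group_test",
    "compare_indices_anova",
]


# ---------------------------------------------------------------------------
# d' and indices
# ---------------------------------------------------------------------------

def dprime(hits: int, misses: int, false_alarms: int, correct_rejections: int) -> float:
    """Sensitivity d' = z(H) - z(F) from pooled confusion counts.

    Hit and false-alarm rates are clipped to [1/(2N), 1 - 1/(2N)] with N
    the per-class test count, so perfect performance stays finite.
    """
    n_pos = hits + misses
    n_neg = false_alarms + correct_rejections
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one test pattern per class for d'")
    H = np.clip(hits / n_pos, 1.0 / (2 * n_pos), 1.0 - 1.0 / (2 * n_pos))
    F = np.clip(false_alarms / n_neg, 1.0 / (2 * n_neg), 1.0 - 1.0 / (2 * n_neg))
    return float(sps.norm.ppf(H) - sps.norm.ppf(F))


def dprime_from_accuracy(accuracy: float, n_per_class: int) -> float:
    """Alternative convention: d' = 2 z(accuracy), with the same clipping."""
    a = np.clip(accuracy, 1.0 / (2 * n_per_class), 1.0 - 1.0 / (2 * n_per_class))
    return float(2.0 * sps.norm.ppf(a))


def compute_indices(dprimes: dict[str, float]) -> dict[str, float]:
    """Gloss and 3D-structure indices from the three binocular contrasts."""
    needed = {"mirror_anti_vs_painted", "mirror_vs_anti", "painted_vs_flat"}
    missing = needed - set(dprimes)
    if missing:
        raise ValueError(f"missing contrasts for indices: {sorted(missing)}")
    return {
        "gloss_index": dprimes["mirror_anti_vs_painted"] - dprimes["mirror_vs_anti"],
        "structure_index": dprimes["painted_vs_flat"] - dprimes["mirror_vs_anti"],
    }


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

@dataclass
class NullDistribution:
    """Per-repetition group means and the one-tailed 95% boundary."""

    reps: np.ndarray
    scope: str = "per-ROI"
    statistic: str = "accuracy"

    @property
    def n_reps(self) -> int:
        return len(self.reps)

    @property
    def threshold_95(self) -> float:
        return float(np.percentile(self.reps, 95))

    @property
    def mean(self) -> float:
        return float(np.mean(self.reps))


class _SubjectEngine:
    """Precomputed Gram matrix + bookkeeping for fast relabeled decoding."""

    def __init__(self, pset: PatternSet):
        X = np.ascontiguousarray(pset.patterns, dtype=np.float64)
        self.gram = X @ X.T
        self.labels = np.asarray(pset.labels, dtype=object)
        self.runs = np.asarray(pset.runs)
        self.run_rows = {int(r): np.where(self.runs == r)[0] for r in np.unique(self.runs)}

    def shuffle_labels(self, rng: np.random.Generator,
                       conditions: "set[str] | None" = None) -> np.ndarray:
        """Condition labels permuted within each run independently.

        With ``conditions`` given, only blocks of those conditions exchange
        labels (the exchangeability unit of a test restricted to them);
        otherwise all labels in the run are shuffled.
        """
        lab = self.labels.copy()
        for rows in self.run_rows.values():
            if conditions is not None:
                rows = rows[np.isin(lab[rows], sorted(conditions))]
            lab[rows] = lab[rows][rng.permutation(len(rows))]
        return lab

    def cv_confusion(self, labels: np.ndarray, contrast: Contrast,
                     balance: bool = True) -> tuple[int, int, int, int]:
        """Leave-one-run-out confusion counts under the given labels."""
        mask, y = contrast.binarize(labels)
        rows = np.where(mask)[0]
        runs = self.runs[rows]
        G = self.gram[np.ix_(rows, rows)]
        h = m = fa = cr = 0
        for r in np.unique(runs):
            te = runs == r
            tr = ~te
            yt, ye = y[tr], y[te]
            if ye.all() or (~ye).all() or yt.all() or (~yt).all():
                continue
            dec = svm_decision(G[np.ix_(tr, tr)], yt, G[np.ix_(te, tr)],
                               balance=balance, C=SVM_C)
            pred = dec >= 0.0
            h += int(np.sum(pred & ye))
            m += int(np.sum(~pred & ye))
            fa += int(np.sum(pred & ~ye))
            cr += int(np.sum(~pred & ~ye))
        return h, m, fa, cr

    def cv_accuracy(self, labels: np.ndarray, contrast: Contrast, balance: bool = True) -> float:
        """Balanced (macro-averaged) accuracy; equals plain accuracy for
        equal test-class counts."""
        h, m, fa, cr = self.cv_confusion(labels, contrast, balance)
        if h + m == 0 or fa + cr == 0:
            return np.nan
        return 0.5 * (h / (h + m) + cr / (fa + cr))

    def cv_accuracy_shuffled(self, rng: np.random.Generator, contrast: Contrast,
                             balance: bool = True, granularity: str = "per_fold") -> float:
        """Balanced CV accuracy with within-run shuffles of the contrast labels.

        ``granularity='per_fold'`` redraws the shuffle for every
        cross-validation fold ("shuffling labels per test");
        ``'per_rep'`` draws one shuffle and reruns the whole CV on it.
        Only the labels of the contrast's own conditions exchange, so the
        participating blocks are fixed and the Gram submatrix is reused.
        """
        mask, y0 = contrast.binarize(self.labels)
        rows = np.where(mask)[0]
        runs = self.runs[rows]
        G = self.gram[np.ix_(rows, rows)]
        run_local = {r: np.where(runs == r)[0] for r in np.unique(runs)}

        def draw() -> np.ndarray:
            y = y0.copy()
            for rr in run_local.values():
                y[rr] = y[rr][rng.permutation(len(rr))]
            return y

        if granularity == "per_rep":
            y_shared = draw()
        elif granularity != "per_fold":
            raise ValueError("granularity must be 'per_fold' or 'per_rep'")
        h = m = fa = cr = 0
        for r in run_local:
            y = draw() if granularity == "per_fold" else y_shared
            te = runs == r
            tr = ~te
            yt, ye = y[tr], y[te]
            if ye.all() or (~ye).all() or yt.all() or (~yt).all():
                continue
            dec = svm_decision(G[np.ix_(tr, tr)], yt, G[np.ix_(te, tr)],
                               balance=balance, C=SVM_C)
            pred = dec >= 0.0
            h += int(np.sum(pred & ye))
            m += int(np.sum(~pred & ye))
            fa += int(np.sum(pred & ~ye))
            cr += int(np.sum(~pred & ~ye))
        if h + m == 0 or fa + cr == 0:
            return np.nan
        return 0.5 * (h / (h + m) + cr / (fa + cr))


class _TransferEngine:
    """Cross-pattern-set Gram blocks for fast relabeled transfer decoding."""

    def __init__(self, train_set: PatternSet, test_set: PatternSet):
        Xtr = np.ascontiguousarray(train_set.patterns, dtype=np.float64)
        Xte = np.ascontiguousarray(test_set.patterns, dtype=np.float64)
        self.gram_tt = Xtr @ Xtr.T
        self.gram_et = Xte @ Xtr.T
        self.train = _SubjectEngine.__new__(_SubjectEngine)
        self.train.labels = np.asarray(train_set.labels, dtype=object)
        self.train.runs = np.asarray(train_set.runs)
        self.train.run_rows = {int(r): np.where(self.train.runs == r)[0]
                               for r in np.unique(self.train.runs)}
        self.test = _SubjectEngine.__new__(_SubjectEngine)
        self.test.labels = np.asarray(test_set.labels, dtype=object)
        self.test.runs = np.asarray(test_set.runs)
        self.test.run_rows = {int(r): np.where(self.test.runs == r)[0]
                              for r in np.unique(self.test.runs)}

    def accuracy(self, labels_train: np.ndarray, labels_test: np.ndarray,
                 train_c: Contrast, test_c: Contrast, balance: bool = True) -> float:
        tr_mask, y_tr = train_c.binarize(labels_train)
        te_mask, y_te = test_c.binarize(labels_test)
        tr = np.where(tr_mask)[0]
        te = np.where(te_mask)[0]
        dec = svm_decision(self.gram_tt[np.ix_(tr, tr)], y_tr,
                           self.gram_et[np.ix_(te, tr)], balance=balance, C=SVM_C)
        pred = dec >= 0.0
        tpr = float(np.mean(pred[y_te]))
        tnr = float(np.mean(~pred[~y_te]))
        return 0.5 * (tpr + tnr)


def permutation_null(psets: list[PatternSet], contrast: Contrast, n_reps: int = 1000,
                     seed: int = 0, balance: bool = True,
                     granularity: str = "per_fold",
                     shuffle_scope: str = "contrast") -> NullDistribution:
    """Group-level permutation null for leave-one-run-out decoding accuracy.

    Per repetition and subject, condition labels are shuffled within each
    run among the blocks of the tested conditions (their exchangeability
    unit) and the CV is re-run; the across-subject mean balanced accuracy
    is recorded per repetition.  ``granularity='per_fold'`` (default)
    redraws the shuffle independently for every cross-validation fold —
    "shuffling labels per test" — which keeps folds decorrelated;
    ``'per_rep'`` uses one shuffle for the whole CV, whose fold-shared
    labels widen the null slightly.  ``shuffle_scope='all'`` instead
    permutes all condition labels in the run with one draw per repetition
    (also randomizing which blocks enter the contrast).  ``n_reps`` must
    be >= 100 for a stable 95th percentile.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    for p in psets:
        if not (contrast.conditions <= set(np.unique(p.labels))):
            raise ValueError(f"contrast {contrast.name} conditions absent from a pattern set")
    rng = np.random.default_rng(seed)
    engines = [_SubjectEngine(p) for p in psets]
    reps = np.empty(n_reps)
    with sklearn.config_context(assume_finite=True):
        for i in range(n_reps):
            if shuffle_scope == "all":
                accs = [e.cv_accuracy(e.shuffle_labels(rng), contrast, balance)
                        for e in engines]
            else:
                accs = [e.cv_accuracy_shuffled(rng, contrast, balance, granularity)
                        for e in engines]
            reps[i] = np.mean(accs)
    return NullDistribution(reps=reps, statistic=f"accuracy[{contrast.name}]")


def transfer_permutation_null(train_sets: list[PatternSet], test_sets: list[PatternSet],
                              train_contrast: Contrast, test_contrast: Contrast,
                              n_reps: int = 1000, seed: int = 0,
                              balance: bool = True) -> NullDistribution:
    """Permutation null for transfer decoding (train once, test once).

    Training and test labels are shuffled within-run *independently*: any
    block shared between the two sets (e.g. painted blocks in the
    within-session transfer) would otherwise keep its training label at
    test and be memorized by the classifier, biasing the null above 0.5.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    if len(train_sets) != len(test_sets):
        raise ValueError("need one training and one test set per subject")
    rng = np.random.default_rng(seed)
    engines = [_TransferEngine(a, b) for a, b in zip(train_sets, test_sets)]
    reps = np.empty(n_reps)
    with sklearn.config_context(assume_finite=True):
        for i in range(n_reps):
            accs = []
            for e in engines:
                lab_tr = e.train.shuffle_labels(rng, train_contrast.conditions)
                lab_te = e.test.shuffle_labels(rng, test_contrast.conditions)
                accs.append(e.accuracy(lab_tr, lab_te, train_contrast, test_contrast, balance))
            reps[i] = np.mean(accs)
    return NullDistribution(
        reps=reps, statistic=f"transfer[{train_contrast.name}->{test_contrast.name}]"
    )


def index_permutation_null(psets: list[PatternSet], n_reps: int = 1000, seed: int = 0,
                           ) -> dict[str, NullDistribution]:
    """Permutation nulls of the gloss and 3D-structure indices.

    The shuffles follow the same "per test" granularity as the accuracy
    nulls — a fresh within-run permutation of *all* condition labels for
    every cross-validation fold — and within each fold the *same* shuffled
    assignment feeds all three contrasts, so the shared
    mirror-vs-anti-mirror baseline stays correlated with the other d'
    terms, shrinking the difference null exactly as a shared-term
    subtraction should.
    """
    from .decoding import CONTRASTS

    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    rng = np.random.default_rng(seed)
    engines = [_SubjectEngine(p) for p in psets]
    names = ("mirror_anti_vs_painted", "mirror_vs_anti", "painted_vs_flat")
    contrasts = {name: CONTRASTS[name] for name in names}
    gloss = np.empty(n_reps)
    structure = np.empty(n_reps)
    with sklearn.config_context(assume_finite=True):
        for i in range(n_reps):
            g_subj, s_subj = [], []
            for e in engines:
                conf = {name: [0, 0, 0, 0] for name in names}
                for r in e.run_rows:
                    lab = e.shuffle_labels(rng)
                    for name, c in contrasts.items():
                        mask, y = c.binarize(lab)
                        rows = np.where(mask)[0]
                        runs_c = e.runs[rows]
                        te = runs_c == r
                        tr = ~te
                        yt, ye = y[tr], y[te]
                        if ye.all() or (~ye).all() or yt.all() or (~yt).all():
                            continue
                        G = e.gram[np.ix_(rows, rows)]
                        dec = svm_decision(G[np.ix_(tr, tr)], yt, G[np.ix_(te, tr)],
                                           C=SVM_C)
                        pred = dec >= 0.0
                        acc = conf[name]
                        acc[0] += int(np.sum(pred & ye))
                        acc[1] += int(np.sum(~pred & ye))
                        acc[2] += int(np.sum(pred & ~ye))
                        acc[3] += int(np.sum(~pred & ~ye))
                dps = {name: dprime(*conf[name]) for name in names}
                idx = compute_indices(dps)
                g_subj.append(idx["gloss_index"])
                s_subj.append(idx["structure_index"])
            gloss[i] = np.mean(g_subj)
            structure[i] = np.mean(s_subj)
    return {
        "gloss_index": NullDistribution(reps=gloss, statistic="gloss_index"),
        "structure_index": NullDistribution(reps=structure, statistic="structure_index"),
    }


def roi_averaged_threshold(psets_by_roi: dict[str, list[PatternSet]], contrast: Contrast,
                           n_reps: int = 1000, seed: int = 0, balance: bool = True,
                           transfer_with: Contrast | None = None,
                           ) -> tuple[float, dict[str, NullDistribution]]:
    """Per-ROI permutation nulls and the across-ROI average of their 95% boundaries.

    With ``transfer_with`` set, the null is the within-session transfer
    null trained on ``contrast`` and tested on ``transfer_with``.
    Each ROI gets an independent seed derived from ``seed``.
    """
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
             np.random.SeedSequence(seed).spawn(len(psets_by_roi))]
    nulls: dict[str, NullDistribution] = {}
    for (roi, psets), s in zip(psets_by_roi.items(), seeds):
        if transfer_with is None:
            nulls[roi] = permutation_null(psets, contrast, n_reps=n_reps, seed=s, balance=balance)
        else:
            nulls[roi] = transfer_permutation_null(psets, psets, contrast, transfer_with,
                                                   n_reps=n_reps, seed=s, balance=balance)
    avg = float(np.mean([n.threshold_95 for n in nulls.values()]))
    return avg, nulls


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def group_test(values: np.ndarray, baseline: "float | NullDistribution",
               n_rois: int = 1) -> dict:
    """One-sample t test of per-subject statistics against a baseline.

    One-tailed (greater); Bonferroni-corrected across ``n_rois`` regions:
    significant iff p < 0.05 / n_rois.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("group test needs >= 2 subjects")
    b = baseline.threshold_95 if isinstance(baseline, NullDistribution) else float(baseline)
    if np.ptp(values) == 0:  # degenerate: identical subject values (e.g. ceiling)
        if values[0] == b:
            t, p = 0.0, 1.0
        else:
            t = np.inf if values[0] > b else -np.inf
            p = 0.0 if values[0] > b else 1.0
    else:
        res = sps.ttest_1samp(values, popmean=b, alternative="greater")
        t, p = float(res.statistic), float(res.pvalue)
    return {"t": t, "p": p, "significant": bool(p < 0.05 / n_rois),
            "alpha_corrected": 0.05 / n_rois, "baseline": b, "n": len(values)}


def compare_indices_anova(table: pd.DataFrame) -> dict:
    """2 (index) x n-ROI repeated-measures ANOVA with Tukey HSD post hocs.

    ``table`` is long-format with columns subject, roi, index, value and a
    complete subject x roi x index grid (no imputation is attempted).
    Returns the ANOVA table (F, df, p per effect) and the full pairwise
    Tukey decision table over index-by-ROI cell means.
    """
    from statsmodels.stats.anova import AnovaRM
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    required = {"subject", "roi", "index", "value"}
    if not required <= set(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    counts = table.groupby(["subject", "roi", "index"]).size()
    if (counts != 1).any() or len(counts) != (
        table["subject"].nunique() * table["roi"].nunique() * table["index"].nunique()
    ):
        raise ValueError("incomplete subject x roi x index table; no imputation performed")

    n_s = table["subject"].nunique()
    n_r = table["roi"].nunique()
    n_i = table["index"].nunique()
    if np.ptp(table["value"].to_numpy()) == 0:
        # constant data: every effect SS is 0; report F = 0, p = 1 outright
        # (the 0/0 ratio inside the fit is numerically meaningless)
        anova = pd.DataFrame(
            {"F": 0.0,
             "df_num": [float(n_i - 1), float(n_r - 1), float((n_i - 1) * (n_r - 1))],
             "df_den": [float((n_i - 1) * (n_s - 1)), float((n_r - 1) * (n_s - 1)),
                        float((n_i - 1) * (n_r - 1) * (n_s - 1))],
             "p": 1.0},
            index=pd.Index(["index", "roi", "index:roi"]),
        )
    else:
        aov = AnovaRM(table, depvar="value", subject="subject",
                      within=["index", "roi"]).fit()
        anova = aov.anova_table.rename(
            columns={"F Value": "F", "Num DF": "df_num", "Den DF": "df_den", "Pr > F": "p"}
        )
        anova["F"] = anova["F"].fillna(0.0)
        anova["p"] = anova["p"].fillna(1.0)

    cells = table["index"].astype(str) + "|" + table["roi"].astype(str)
    if np.allclose(table["value"].var(), 0):
        tukey = pd.DataFrame(columns=["group1", "group2", "meandiff", "p-adj", "reject"])
    else:
        res = pairwise_tukeyhsd(endog=table["value"].to_numpy(), groups=cells.to_numpy())
        tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return {"anova": anova, "tukey": tukey}
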