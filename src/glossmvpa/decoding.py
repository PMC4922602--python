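"""Linear SVM decoding with leave-one-run-out cross-validation.

Wraps a linear support-vector classifier (libsvm via scikit-learn, C = 1)
with the bookkeeping the block-design analyses need: binary contrasts over
condition sets, class-weight balancing for unequal class sizes (the 2-vs-1
contrast), per-run fold construction that never leaks a test run into
training, fold-pooled confusion counts, and cross-decoding transfer where a
model trained on one contrast is tested on another via an explicit
positive-to-positive class mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

from .preprocess import PatternSet

__all__ = [
    "Contrast",
    "CONTRASTS",
    "DecodingResult",
    "LinearDecoder",
    "train_classifier",
    "cross_validate",
    "transfer_decode",
]

SVM_C = 1.0  # soft-margin cost; fixed for reproducibility


@dataclass(frozen=True)
class Contrast:
    """Binary contrast between two disjoint condition sets.

    ``positive`` is treated as the signal class for confusion counts; in
    the gloss contrasts it is the glossy-looking side.
    """

    name: str
    positive: frozenset[str]
    negative: frozenset[str]

    def __post_init__(self) -> None:
        if not self.positive or not self.negative:
            raise ValueError("both class sets must be nonempty")
        if self.positive & self.negative:
            raise ValueError("class sets must be disjoint")

    @property
    def conditions(self) -> frozenset[str]:
        return self.positive | self.negative

    def binarize(self, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(row mask of involved conditions, boolean y with True = positive)."""
        labels = np.asarray(labels)
        mask = np.isin(labels, sorted(self.conditions))
        y = np.isin(labels[mask], sorted(self.positive))
        return mask, y


def _c(name: str, pos, neg) -> Contrast:
    return Contrast(name, frozenset(pos), frozenset(neg))


CONTRASTS: dict[str, Contrast] = {
    "mirror_anti_vs_painted": _c("mirror_anti_vs_painted", {"mirror", "anti_mirror"}, {"painted"}),
    "mirror_vs_anti": _c("mirror_vs_anti", {"mirror"}, {"anti_mirror"}),
    "painted_vs_flat": _c("painted_vs_flat", {"painted"}, {"flat"}),
    "glossy_vs_matte": _c("glossy_vs_matte", {"glossy"}, {"matte"}),
    "flat_vs_painted": _c("flat_vs_painted", {"flat"}, {"painted"}),
}


@dataclass
class DecodingResult:
    """Accuracy plus signal-detection confusion counts (positive = signal)."""

    accuracy: float
    fold_accuracies: list[float]
    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int
    n_train: list[int] = field(default_factory=list)
    n_test: list[int] = field(default_factory=list)
    fold_runs: list[int] = field(default_factory=list)
    contrast: str = ""

    @property
    def n_total(self) -> int:
        return self.hits + self.misses + self.false_alarms + self.correct_rejections

    @property
    def balanced_accuracy(self) -> float:
        """Macro-averaged accuracy, (hit rate + correct-rejection rate) / 2.

        Equals ``accuracy`` whenever the test classes are equally frequent;
        for the 2-vs-1 contrast it removes the majority-class prediction
        bias a max-margin classifier keeps even with balanced training
        weights, so shuffled-label nulls center on 0.5.
        """
        tpr = self.hits / (self.hits + self.misses)
        tnr = self.correct_rejections / (self.false_alarms + self.correct_rejections)
        return 0.5 * (tpr + tnr)

    def __post_init__(self) -> None:
        n_correct = self.hits + self.correct_rejections
        if self.n_total and not np.isclose(self.accuracy, n_correct / self.n_total):
            raise ValueError("accuracy inconsistent with confusion counts")


class LinearDecoder:
    """Maximum-margin linear separator with optional class balancing.

    Thin wrapper over sklearn's libsvm SVC (linear kernel).  Predictions
    use decision value >= 0 -> positive class, making the measure-zero tie
    deterministic.
    """

    def __init__(self, balance: bool = True, C: float = SVM_C):
        self.balance = balance
        self.C = C
        self._svc: SVC | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "LinearDecoder":
        y = np.asarray(y, dtype=bool)
        if len(np.unique(y)) < 2:
            raise ValueError("training data contains a single class")
        self._svc = SVC(kernel="linear", C=self.C,
                        class_weight="balanced" if self.balance else None)
        self._svc.fit(X, y)
        return self

    @property
    def weights(self) -> np.ndarray:
        return np.asarray(self._svc.coef_).ravel()

    @property
    def bias(self) -> float:
        return float(self._svc.intercept_[0])

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self._svc.decision_function(X)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.decision(X) >= 0.0


def train_classifier(X: np.ndarray, y: np.ndarray, balance: bool = True) -> LinearDecoder:
    """Fit the linear SVM on patterns ``X`` with boolean labels ``y``."""
    return LinearDecoder(balance=balance).fit(X, y)


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[int, int, int, int]:
    hits = int(np.sum(y_pred & y_true))
    misses = int(np.sum(~y_pred & y_true))
    fas = int(np.sum(y_pred & ~y_true))
    crs = int(np.sum(~y_pred & ~y_true))
    return hits, misses, fas, crs


def cross_validate(pset: PatternSet, contrast: Contrast, balance: bool = True) -> DecodingResult:
    """Leave-one-run-out decoding of one contrast.

    Each retained run serves once as the test fold; the model is trained on
    every other run's patterns of the contrast conditions.  A fold whose
    test run lacks one of the classes is skipped with a warning; accuracy
    and confusion counts are pooled over the remaining folds.
    """
    mask, y_all = contrast.binarize(pset.labels)
    X = pset.patterns[mask]
    y = y_all
    runs = pset.runs[mask]
    uniq = np.unique(runs)
    if len(uniq) < 2:
        raise ValueError("cross-validation needs >= 2 runs")

    folds, accs, ntr, nte = [], [], [], []
    h = m = fa = cr = 0
    for r in uniq:
        te = runs == r
        tr = ~te
        if len(np.unique(y[te])) < 2:
            warnings.warn(f"run {r} lacks a class for contrast {contrast.name}; fold skipped",
                          stacklevel=2)
            continue
        model = train_classifier(X[tr], y[tr], balance=balance)
        pred = model.predict(X[te])
        hh, mm, ff, cc = _confusion(y[te], pred)
        h += hh; m += mm; fa += ff; cr += cc
        accs.append(float((hh + cc) / te.sum()))
        folds.append(int(r))
        ntr.append(int(tr.sum()))
        nte.append(int(te.sum()))
    if not folds:
        raise ValueError(f"all folds skipped for contrast {contrast.name}")
    total = h + m + fa + cr
    return DecodingResult(
        accuracy=(h + cr) / total, fold_accuracies=accs,
        hits=h, misses=m, false_alarms=fa, correct_rejections=cr,
        n_train=ntr, n_test=nte, fold_runs=folds, contrast=contrast.name,
    )


def transfer_cross_validate(pset: PatternSet, train_contrast: Contrast,
                            test_contrast: Contrast, balance: bool = True) -> DecodingResult:
    """Within-session transfer without leakage: leave-one-run-out folds.

    For each run r the model is trained on the *other* runs' patterns of
    ``train_contrast`` and tested on run r's patterns of ``test_contrast``,
    so a condition shared by both contrasts (painted, in the within-session
    analyses) never appears in both training and test with its identity
    intact.  Results are pooled over folds as in :func:`cross_validate`.
    """
    tr_mask, y_tr_all = train_contrast.binarize(pset.labels)
    te_mask, y_te_all = test_contrast.binarize(pset.labels)
    tr_rows = np.where(tr_mask)[0]
    te_rows = np.where(te_mask)[0]
    uniq = np.unique(pset.runs)
    if len(uniq) < 2:
        raise ValueError("cross-validated transfer needs >= 2 runs")
    h = m = fa = cr = 0
    accs, ntr, nte, folds = [], [], [], []
    for r in uniq:
        tr = tr_rows[pset.runs[tr_rows] != r]
        te = te_rows[pset.runs[te_rows] == r]
        y_tr = y_tr_all[pset.runs[tr_rows] != r]
        y_te = y_te_all[pset.runs[te_rows] == r]
        if len(te) == 0 or len(np.unique(y_te)) < 2 or len(np.unique(y_tr)) < 2:
            warnings.warn(f"run {r} lacks a class for transfer; fold skipped", stacklevel=2)
            continue
        model = train_classifier(pset.patterns[tr], y_tr, balance=balance)
        pred = model.predict(pset.patterns[te])
        hh, mm, ff, cc = _confusion(y_te, pred)
        h += hh; m += mm; fa += ff; cr += cc
        accs.append(float((hh + cc) / len(te)))
        ntr.append(len(tr)); nte.append(len(te)); folds.append(int(r))
    if not folds:
        raise ValueError("all transfer folds skipped")
    total = h + m + fa + cr
    return DecodingResult(
        accuracy=(h + cr) / total, fold_accuracies=accs,
        hits=h, misses=m, false_alarms=fa, correct_rejections=cr,
        n_train=ntr, n_test=nte, fold_runs=folds,
        contrast=f"{train_contrast.name}->{test_contrast.name}[cv]",
    )


def transfer_decode(train_set: PatternSet, train_contrast: Contrast,
                    test_set: PatternSet, test_contrast: Contrast,
                    balance: bool = True) -> DecodingResult:
    """Train on one contrast, test once on another (cross-decoding).

    The test contrast's positive class is mapped onto the training
    contrast's positive class (glossy <-> glossy); both pattern sets must
    share an identical voxel list so features stay aligned.
    """
    if len(train_set.voxels) != len(test_set.voxels) or np.any(
        np.asarray(train_set.voxels) != np.asarray(test_set.voxels)
    ):
        raise ValueError("train and test sets use different voxel lists; "
                         "select voxels once and apply to both sessions")
    tr_mask, y_tr = train_contrast.binarize(train_set.labels)
    te_mask, y_te = test_contrast.binarize(test_set.labels)
    model = train_classifier(train_set.patterns[tr_mask], y_tr, balance=balance)
    pred = model.predict(test_set.patterns[te_mask])
    h, m, fa, cr = _confusion(y_te, pred)
    total = h + m + fa + cr
    return DecodingResult(
        accuracy=(h + cr) / total, fold_accuracies=[(h + cr) / total],
        hits=h, misses=m, false_alarms=fa, correct_rejections=cr,
        n_train=[int(tr_mask.sum())], n_test=[int(te_mask.sum())], fold_runs=[-1],
        contrast=f"{train_contrast.name}->{test_contrast.name}",
    )
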