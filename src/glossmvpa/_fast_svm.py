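"""Low-overhead precomputed-kernel linear SVM for permutation loops.

Permutation nulls refit the same small SVM tens of thousands of times; the
public ``SVC`` entry point spends ~90% of each call on input validation.
This module calls scikit-learn's bundled libsvm solver directly and forms
the decision values explicitly:

    decision(x) = -( K(x, SV) @ dual_coef + intercept )

(the leading minus reproduces sklearn's binary-class sign convention, where
positive decision values mean the second class, here ``True``).  At import
the fast path is verified against ``SVC`` on a small random problem; if the
low-level interface ever changes, everything transparently falls back to
the public API.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import SVC

SVM_EPS = 1e-3  # libsvm default stopping tolerance, kept identical in both paths

try:  # pragma: no cover - exercised via the calibration below
    from sklearn.svm import _libsvm

    _libsvm.set_verbosity_wrap(0)
except ImportError:  # pragma: no cover
    _libsvm = None


def _class_weights(y: np.ndarray, balance: bool) -> np.ndarray:
    """Per-class C multipliers in [False, True] order (libsvm label order)."""
    if not balance:
        return np.ones(2)
    n = len(y)
    n_pos = int(np.sum(y))
    return np.array([n / (2.0 * (n - n_pos)), n / (2.0 * n_pos)])


def _decision_fast(G_train: np.ndarray, y_train: np.ndarray, K_test: np.ndarray,
                   balance: bool, C: float) -> np.ndarray:
    out = _libsvm.fit(
        np.ascontiguousarray(G_train, dtype=np.float64),
        y_train.astype(np.float64),
        svm_type=0,
        kernel="precomputed",
        C=C,
        tol=SVM_EPS,
        class_weight=_class_weights(y_train, balance),
    )
    support, sv_coef, intercept = out[0], out[3], out[4]
    return -(K_test[:, support] @ sv_coef.ravel() + intercept[0])


def _decision_public(G_train: np.ndarray, y_train: np.ndarray, K_test: np.ndarray,
                     balance: bool, C: float) -> np.ndarray:
    svc = SVC(kernel="precomputed", C=C, tol=SVM_EPS,
              class_weight="balanced" if balance else None)
    svc.fit(G_train, y_train)
    return svc.decision_function(K_test)


def _calibrate() -> bool:
    if _libsvm is None:
        return False
    rng = np.random.default_rng(12345)
    X = rng.standard_normal((24, 10))
    y = np.arange(24) % 3 != 0  # imbalanced 2:1
    G = X @ X.T
    K = rng.standard_normal((5, 10)) @ X.T
    try:
        for balance in (True, False):
            a = _decision_fast(G, y, K, balance, 1.0)
            b = _decision_public(G, y, K, balance, 1.0)
            if not np.allclose(a, b, atol=1e-8):
                return False
    except Exception:
        return False
    return True


FAST_PATH = _calibrate()


def svm_decision(G_train: np.ndarray, y_train: np.ndarray, K_test: np.ndarray,
                 balance: bool = True, C: float = 1.0) -> np.ndarray:
    """Decision values for test rows; >= 0 means the positive (True) class.

    ``G_train`` is the train x train linear Gram matrix, ``K_test`` the
    test x train block, ``y_train`` boolean labels with both classes
    present.
    """
    if FAST_PATH:
        return _decision_fast(G_train, y_train, K_test, balance, C)
    return _decision_public(G_train, y_train, K_test, balance, C)
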