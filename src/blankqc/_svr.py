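"""Thin epsilon-SVR wrapper used by the drift-correction grid search.

The leave-one-out grid search refits thousands of tiny (n <= ~30) RBF
support-vector regressions per feature.  ``sklearn.svm.SVR`` spends almost
all of its time in per-call validation at that size, so this module calls
the bundled libsvm solver directly; predictions are identical to
``SVR(kernel="rbf")`` (asserted in the test suite).  Only what the grid
search needs is exposed: fit on 1-D run orders, predict at run orders.
"""

from __future__ import annotations

import numpy as np
from sklearn.svm import _libsvm as libsvm

libsvm.set_verbosity_wrap(0)

_RBF = "rbf"
_EPS_SVR = 3  # libsvm svm_type code for epsilon-SVR


class SvrFitError(RuntimeError):
    """libsvm failed to produce a usable model."""


def svr_fit(orders: np.ndarray, values: np.ndarray, C: float, epsilon: float,
            gamma: float, tol: float = 1e-3):
    """Fit epsilon-SVR with RBF kernel k(t,t') = exp(-gamma (t-t')^2)."""
    X = np.ascontiguousarray(np.asarray(orders, dtype=np.float64).reshape(-1, 1))
    y = np.ascontiguousarray(np.asarray(values, dtype=np.float64))
    try:
        out = libsvm.fit(
            X, y, svm_type=_EPS_SVR, kernel=_RBF,
            gamma=float(gamma), C=float(C), epsilon=float(epsilon), tol=tol,
        )
    except Exception as exc:  # pragma: no cover - solver failure path
        raise SvrFitError(str(exc)) from exc
    support, sv, n_sv, coef, intercept = out[0], out[1], out[2], out[3], out[4]
    return {"support": support, "sv": sv, "n_sv": n_sv, "coef": coef,
            "intercept": intercept, "gamma": float(gamma)}


def svr_predict(model: dict, orders: np.ndarray) -> np.ndarray:
    """Evaluate a fitted model at run orders (manual RBF expansion).

    f(t) = sum_i coef_i exp(-gamma (t - sv_i)^2) + b, with libsvm's sign
    convention (b = -rho already folded into ``intercept``).
    """
    t = np.asarray(orders, dtype=np.float64).reshape(-1, 1)
    sv = np.asarray(model["sv"], dtype=np.float64).reshape(1, -1)
    coef = np.asarray(model["coef"], dtype=np.float64).ravel()
    K = np.exp(-model["gamma"] * (t - sv) ** 2)
    return K @ coef + float(np.asarray(model["intercept"]).ravel()[0])
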