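"""Independent oracles shared by the unit and acceptance suites.

These deliberately avoid the package's own solver paths: the quadratic
program goes through scipy's SLSQP on the explicit monotone-cone
constraints, and the isotonic route goes through scikit-learn.
"""

import numpy as np
from scipy.optimize import LinearConstraint, minimize
from sklearn.isotonic import IsotonicRegression


def staircase_objective(I, labels, weights, lam):
    I = np.asarray(I, dtype=float)
    return float(-(np.asarray(weights) * np.asarray(labels) * I).sum() + lam * (I * I).sum())


def qp_oracle(labels, weights, lam):
    """Constrained quadratic minimization over the monotone cone, I_1 = 0."""
    P = len(labels)
    A = np.zeros((P - 1, P))
    for k in range(P - 1):
        A[k, k], A[k, k + 1] = -1.0, 1.0
    cons = [
        LinearConstraint(A, 0.0, np.inf),
        LinearConstraint(np.eye(P)[0], 0.0, 0.0),
    ]
    res = minimize(
        staircase_objective,
        x0=np.zeros(P),
        args=(np.asarray(labels, float), np.asarray(weights, float), lam),
        constraints=cons,
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-14},
    )
    return res.x


def isotonic_oracle(labels, weights, lam):
    """Weighted isotonic regression of y·w/(2λ) for positions ≥ 2, clipped at 0."""
    labels = np.asarray(labels, float)
    P = len(labels)
    targets = labels * np.asarray(weights, float) / (2 * lam)
    out = np.zeros(P)
    if P > 1:
        iso = IsotonicRegression(increasing=True)
        fit = iso.fit_transform(np.arange(P - 1), targets[1:])
        out[1:] = np.maximum(fit, 0.0)
    return out


def kkt_ok(I, labels, weights, lam, tol=1e-8):
    """Stationarity: each step is flat or its tail sum of (y·w − 2λI) vanishes."""
    resid = np.asarray(labels) * np.asarray(weights) - 2 * lam * np.asarray(I)
    for k in range(1, len(I)):
        step = I[k] - I[k - 1]
        tail = resid[k:].sum()
        if step > tol and abs(tail) > tol:
            return False
        if step < -tol:
            return False
    return True
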