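"""Batched linear SVM solver for pairwise decoding.

Solves the same convex problem as liblinear's default classifier
(L2-regularized squared-hinge SVM with a regularized intercept,
``intercept_scaling = 1``) by dual coordinate descent, compiled with numba
so that the hundreds of thousands of tiny fits needed for a full pairwise
decoding RDM run in seconds.  Agreement with ``sklearn.svm.LinearSVC`` on
the same problems is asserted by the test suite.

All loops are deterministic (cyclic coordinate order), so results are
bit-reproducible and independent of scheduling.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _fit_weights(Xtr, ytr, C, max_epochs, tol):
    """Train squared-hinge dual CD on (Xtr, ytr); return the weight vector.

    Features must already include any intercept column.  ytr in {-1, +1}.
    """
    n, d = Xtr.shape
    diag = 1.0 / (2.0 * C)
    qd = np.empty(n)
    for i in range(n):
        s = diag
        for j in range(d):
            s += Xtr[i, j] * Xtr[i, j]
        qd[i] = s
    alpha = np.zeros(n)
    w = np.zeros(d)
    for _ in range(max_epochs):
        max_viol = 0.0
        for i in range(n):
            g = -1.0 + diag * alpha[i]
            for j in range(d):
                g += ytr[i] * w[j] * Xtr[i, j]
            if alpha[i] == 0.0:
                pg = min(g, 0.0)
            else:
                pg = g
            if abs(pg) > max_viol:
                max_viol = abs(pg)
            if pg != 0.0:
                a_new = alpha[i] - g / qd[i]
                if a_new < 0.0:
                    a_new = 0.0
                delta = a_new - alpha[i]
                if delta != 0.0:
                    alpha[i] = a_new
                    for j in range(d):
                        w[j] += delta * ytr[i] * Xtr[i, j]
        if max_viol < tol:
            break
    return w


@njit(cache=True)
def _fit_predict(Xtr, ytr, Xte, C, max_epochs, tol):
    """Fit on (Xtr, ytr) and return sign predictions for Xte."""
    d = Xtr.shape[1]
    w = _fit_weights(Xtr, ytr, C, max_epochs, tol)
    m = Xte.shape[0]
    pred = np.empty(m)
    for i in range(m):
        s = 0.0
        for j in range(d):
            s += w[j] * Xte[i, j]
        pred[i] = 1.0 if s >= 0.0 else -1.0
    return pred


@njit(cache=True)
def pair_accuracy_timecourse(X, y, fold_assign, n_folds, C, max_epochs, tol):
    """Mean cross-validated accuracy per timepoint for one condition pair.

    Parameters
    ----------
    X : (n_trials, n_channels, n_timepoints) float64
    y : (n_trials,) float64 in {-1, +1}
    fold_assign : (n_repeats, n_trials) int64, fold id per trial per repeat
    n_folds : int
    C : regularization constant
    max_epochs, tol : dual CD stopping rule

    Returns
    -------
    (n_timepoints,) mean held-out accuracy over repeats x folds.

    Features at each timepoint are the channel vector, z-scored with
    training-fold statistics only, plus a constant intercept column.
    """
    n, nch, nt = X.shape
    n_repeats = fold_assign.shape[0]
    acc = np.zeros(nt)
    d = nch + 1
    Xtr = np.empty((n, d))
    Xte = np.empty((n, d))
    ytr = np.empty(n)
    yte = np.empty(n)
    mu = np.empty(nch)
    sd = np.empty(nch)
    n_eval = 0
    for r in range(n_repeats):
        for f in range(n_folds):
            ntr = 0
            nte = 0
            for i in range(n):
                if fold_assign[r, i] == f:
                    nte += 1
                else:
                    ntr += 1
            for t in range(nt):
                # gather train/test rows for this timepoint
                a = 0
                b = 0
                for i in range(n):
                    if fold_assign[r, i] == f:
                        for ch in range(nch):
                            Xte[b, ch] = X[i, ch, t]
                        yte[b] = y[i]
                        b += 1
                    else:
                        for ch in range(nch):
                            Xtr[a, ch] = X[i, ch, t]
                        ytr[a] = y[i]
                        a += 1
                # z-score with training statistics only
                for ch in range(nch):
                    s = 0.0
                    for i in range(ntr):
                        s += Xtr[i, ch]
                    m = s / ntr
                    s2 = 0.0
                    for i in range(ntr):
                        diff = Xtr[i, ch] - m
                        s2 += diff * diff
                    v = np.sqrt(s2 / ntr)
                    if v == 0.0:
                        v = 1.0
                    mu[ch] = m
                    sd[ch] = v
                for i in range(ntr):
                    for ch in range(nch):
                        Xtr[i, ch] = (Xtr[i, ch] - mu[ch]) / sd[ch]
                    Xtr[i, nch] = 1.0
                for i in range(nte):
                    for ch in range(nch):
                        Xte[i, ch] = (Xte[i, ch] - mu[ch]) / sd[ch]
                    Xte[i, nch] = 1.0
                pred = _fit_predict(
                    Xtr[:ntr], ytr[:ntr], Xte[:nte], C, max_epochs, tol
                )
                correct = 0
                for i in range(nte):
                    if pred[i] == yte[i]:
                        correct += 1
                acc[t] += correct / nte
            n_eval += 1
    return acc / n_eval


def fit_single(Xtr, ytr, C=1.0, max_epochs=5000, tol=1e-8):
    """Fit one problem and return ``(coef, intercept)``.

    Appends an intercept column; no feature scaling.  Used by the tests to
    compare weights/predictions against ``sklearn.svm.LinearSVC``.
    """
    Xtr = np.ascontiguousarray(
        np.column_stack([Xtr, np.ones(len(Xtr))]), dtype=np.float64
    )
    ytr = np.asarray(ytr, dtype=np.float64)
    w = _fit_weights(Xtr, ytr, C, max_epochs, tol)
    return w[:-1], w[-1]
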