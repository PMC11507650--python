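"""Compiled inner loop for subset-wise PLS cross-validation.

BOSS evaluates on the order of 10^4-10^5 bootstrap sub-models per run;
the k-fold NIPALS evaluation of one variable subset is therefore
compiled with numba.  The math is identical to
:func:`crabspec.pls.rmsecv` restricted to a fixed fold assignment (a
unit test asserts the two paths agree).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["cv_rmse_path"]

_TINY = 1e-12


@njit(cache=True)
def cv_rmse_path(Xs, y, fold_ids, n_folds, max_comps):  # pragma: no cover - compiled
    """RMSECV per component count 1..max_comps under a fixed fold layout.

    Parameters: Xs (n, m) variable-subset matrix, y (n,) response,
    fold_ids (n,) fold membership 0..n_folds-1.  Returns (max_comps,)
    RMSE values; exhausted deflation repeats the last usable count.
    """
    n, m = Xs.shape
    preds = np.zeros((max_comps, n))
    for f in range(n_folds):
        n_te = 0
        for i in range(n):
            if fold_ids[i] == f:
                n_te += 1
        n_tr = n - n_te
        Xtr = np.empty((n_tr, m))
        ytr = np.empty(n_tr)
        te_idx = np.empty(n_te, dtype=np.int64)
        a = 0
        b_i = 0
        for i in range(n):
            if fold_ids[i] == f:
                te_idx[b_i] = i
                b_i += 1
            else:
                Xtr[a] = Xs[i]
                ytr[a] = y[i]
                a += 1

        x_mean = np.zeros(m)
        for i in range(n_tr):
            x_mean += Xtr[i]
        x_mean /= n_tr
        y_mean = ytr.mean()
        Xd = Xtr - x_mean
        yd = ytr - y_mean

        Rt = np.zeros((max_comps, m))
        Pt = np.zeros((max_comps, m))
        coef = np.zeros(m)
        Xte = Xs[te_idx] - x_mean
        k_eff = 0
        for k in range(max_comps):
            w = Xd.T @ yd
            nw = np.sqrt((w * w).sum())
            if nw < _TINY:
                break
            w = w / nw
            t = Xd @ w
            tt = (t * t).sum()
            if tt < _TINY:
                break
            pk = (Xd.T @ t) / tt
            qk = (t @ yd) / tt
            Xd -= np.outer(t, pk)
            yd = yd - qk * t
            r = w.copy()
            for j in range(k):
                dot = 0.0
                for i in range(m):
                    dot += Pt[j, i] * w[i]
                for i in range(m):
                    r[i] -= dot * Rt[j, i]
            Rt[k] = r
            Pt[k] = pk
            coef = coef + qk * r
            yhat = y_mean + Xte @ coef
            for j in range(n_te):
                preds[k, te_idx[j]] = yhat[j]
            k_eff = k + 1
        for k in range(k_eff, max_comps):
            for j in range(n_te):
                preds[k, te_idx[j]] = preds[k_eff - 1, te_idx[j]] if k_eff else y_mean

    rmse = np.empty(max_comps)
    for k in range(max_comps):
        s = 0.0
        for i in range(n):
            e = preds[k, i] - y[i]
            s += e * e
        rmse[k] = np.sqrt(s / n)
    return rmse
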