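"""Independent brute-force oracles used across the test modules.

Everything here is deliberately naive (enumeration, dense matrices,
direct likelihood evaluation) and shares no code with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment


def group_ss(Y: np.ndarray) -> float:
    return float(((Y - Y.mean(axis=0)) ** 2).sum()) if len(Y) else 0.0


def brute_numeric_split(values, Y, min_leaf=1):
    """Best threshold by direct evaluation of every midpoint."""
    values = np.asarray(values, float)
    Y = np.asarray(Y, float)
    parent = group_ss(Y)
    best = None
    for t in sorted(set((a + b) / 2 for a, b in itertools.pairwise(sorted(set(values))))):
        mask = values < t
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            continue
        red = parent - group_ss(Y[mask]) - group_ss(Y[~mask])
        if best is None or red > best[1] + 1e-12:
            best = (t, red)
    return best


def brute_categorical_split(levels, Y, min_leaf=1):
    """Best level partition by enumerating every proper subset."""
    levels = np.asarray(levels, object)
    Y = np.asarray(Y, float)
    uniq = sorted(set(levels))
    parent = group_ss(Y)
    best = None
    for r in range(1, len(uniq)):
        for combo in itertools.combinations(uniq, r):
            mask = np.isin(levels, combo)
            if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
                continue
            red = parent - group_ss(Y[mask]) - group_ss(Y[~mask])
            left = frozenset(combo) if uniq[0] in combo else frozenset(set(uniq) - set(combo))
            if best is None or red > best[1] + 1e-12:
                best = (left, red)
    return best


def reml_negloglik(sigma2s, Zs, y):
    """-2/2 * restricted log-likelihood by direct dense-V evaluation.

    ``sigma2s``: variances for each Z in ``Zs`` plus the residual (last).
    Intercept-only fixed effects.
    """
    n = len(y)
    X = np.ones((n, 1))
    V = sigma2s[-1] * np.eye(n)
    for Z, s in zip(Zs, sigma2s[:-1]):
        V += s * (Z @ Z.T)
    Vi = np.linalg.inv(V)
    _, sld = np.linalg.slogdet(V)
    M = X.T @ Vi @ X
    beta = np.linalg.solve(M, X.T @ Vi @ y)
    r = y - X @ beta
    return 0.5 * (sld + np.linalg.slogdet(M)[1] + r @ Vi @ r)


def dummies(labels) -> np.ndarray:
    return pd.get_dummies(pd.Series(labels)).to_numpy(float)


def matching_accuracy(truth_labels, found_labels) -> float:
    """Fraction of rows matched to their planted group under the best
    one-to-one leaf-to-group matching (Hungarian algorithm)."""
    ct = pd.crosstab(pd.Series(truth_labels), pd.Series(list(found_labels))).to_numpy()
    r, c = linear_sum_assignment(-ct)
    return ct[r, c].sum() / ct.sum()


def ls_means_prediction_oracle(df, population, treatment, value):
    """LS means via the raw normal equations (min-norm lstsq on the full
    overparameterized dummy design); predictions are unique even though
    coefficients are not."""
    P = dummies(df[population])
    T = dummies(df[treatment])
    X = np.column_stack([np.ones(len(df)), P, T])
    beta, *_ = np.linalg.lstsq(X, df[value].to_numpy(float), rcond=None)
    n_pop, n_trt = P.shape[1], T.shape[1]
    pops = sorted(df[population].unique())
    out = {}
    for i, p in enumerate(pops):
        preds = []
        for j in range(n_trt):
            x = np.zeros(1 + n_pop + n_trt)
            x[0] = 1
            x[1 + i] = 1
            x[1 + n_pop + j] = 1
            preds.append(x @ beta)
        out[p] = float(np.mean(preds))
    return pd.Series(out)
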