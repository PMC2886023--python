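"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — dense covariance algebra, exact
rational enumeration, direct recursion — and shares no code with the
implementation paths it checks.
"""

from __future__ import annotations

import math
from fractions import Fraction
from functools import lru_cache

import numpy as np


# --------------------------------------------------------------------------
# dense mixed-model oracle
# --------------------------------------------------------------------------

def dense_designs(obs):
    """Dense W (comparison-group indicators) and Z_k blocks for the
    normalization model, built straight from the observation table."""
    import pandas as pd

    def codes(s):
        c = pd.Categorical(s)
        return np.asarray(c.codes), len(c.categories), list(c.categories)

    n = len(obs)
    ckey = (obs["array_id"].astype(str) + "|" + obs["block_id"].astype(str)
            + "|" + obs["dye"].astype(str))
    c, nc, _ = codes(ckey)
    W = np.zeros((n, nc))
    W[np.arange(n), c] = 1.0

    g, ng, genes = codes(obs["gene_id"])
    Zs, level_info = [], []
    for cols in (None, "array_id", "dye", "flock_id", "treatment_id"):
        if cols is None:
            f, nf = np.zeros(n, dtype=int), 1
            levels = [None]
        else:
            f, nf, levels = codes(obs[cols])
        Z = np.zeros((n, ng * nf))
        Z[np.arange(n), g * nf + f] = 1.0
        Zs.append(Z)
        level_info.append((genes, levels))
    y = obs["log2_intensity"].to_numpy(dtype=float)
    return y, W, Zs, level_info


def dense_V(Zs, variances, sigma2_e):
    n = Zs[0].shape[0]
    V = sigma2_e * np.eye(n)
    for Z, s2 in zip(Zs, variances):
        V += s2 * (Z @ Z.T)
    return V


def gls_solutions(y, W, Zs, variances, sigma2_e, K=None):
    """BLUE of the fixed part and BLUPs u_k = G_k Z_k' P y on the dense V.

    ``K`` optionally supplies a covariance structure matrix per term
    (defaults to identity): cov(u_k) = variances[k] * K[k].
    """
    if K is None:
        K = [np.eye(Z.shape[1]) for Z in Zs]
    n = len(y)
    V = sigma2_e * np.eye(n)
    for Z, s2, Kk in zip(Zs, variances, K):
        V += s2 * (Z @ Kk @ Z.T)
    Vi = np.linalg.inv(V)
    WVW = W.T @ Vi @ W
    b = np.linalg.solve(WVW, W.T @ Vi @ y)
    P = Vi - Vi @ W @ np.linalg.inv(WVW) @ W.T @ Vi
    us = [s2 * Kk @ Z.T @ (P @ y) for Z, s2, Kk in zip(Zs, variances, K)]
    return b, us


def dense_reml_loglik(y, W, Zs, variances, sigma2_e, K=None):
    """Textbook restricted log-likelihood on the dense covariance."""
    if K is None:
        K = [np.eye(Z.shape[1]) for Z in Zs]
    n, p = W.shape
    V = sigma2_e * np.eye(n)
    for Z, s2, Kk in zip(Zs, variances, K):
        V += s2 * (Z @ Kk @ Z.T)
    Vi = np.linalg.inv(V)
    WVW = W.T @ Vi @ W
    P = Vi - Vi @ W @ np.linalg.inv(WVW) @ W.T @ Vi
    _, l1 = np.linalg.slogdet(V)
    _, l2 = np.linalg.slogdet(WVW)
    return -0.5 * (l1 + l2 + float(y @ P @ y) + (n - p) * np.log(2 * np.pi))


# --------------------------------------------------------------------------
# pedigree oracle: direct recursion of the tabular rules
# --------------------------------------------------------------------------

def kinship_recursive(pedigree_rows):
    """Relationship coefficients by direct recursion.

    ``pedigree_rows`` is a list of (animal, sire, dam) with '0' for unknown;
    returns a dict-backed function a(x, y).
    """
    parents = {a: (s, d) for a, s, d in pedigree_rows}
    order = {a: i for i, (a, _, _) in enumerate(pedigree_rows)}

    @lru_cache(maxsize=None)
    def a(x, y):
        if x == "0" or y == "0":
            return 0.0
        if order[x] < order[y]:
            x, y = y, x
        s, d = parents[x]
        if x == y:
            return 1.0 + 0.5 * a(s, d) if s != "0" and d != "0" else 1.0
        return 0.5 * (a(s, y) + a(d, y))

    return a


# --------------------------------------------------------------------------
# exact-test oracles (rational arithmetic)
# --------------------------------------------------------------------------

def hwe_exact_enumeration(n_AA, n_Aa, n_aa):
    """HWE exact p by enumerating every genotype table with the observed
    allele counts, using exact rational probabilities."""
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa
    n_A = 2 * n - n_a
    rare = min(n_A, n_a)
    if rare == 0:
        return 1.0

    def table_weight(het):
        hom_rare = (rare - het) // 2
        hom_common = n - het - hom_rare
        if hom_rare < 0 or hom_common < 0:
            return None
        return (Fraction(math.factorial(n),
                         math.factorial(het) * math.factorial(hom_rare)
                         * math.factorial(hom_common)) * 2 ** het)

    weights = {}
    for het in range(rare % 2, rare + 1, 2):
        w = table_weight(het)
        if w is not None:
            weights[het] = w
    total = sum(weights.values())
    obs_het = n_Aa
    p_obs = weights[obs_het]
    p = sum(w for w in weights.values() if w <= p_obs)
    return float(Fraction(p, total))


def hypergeom_upper_tail(k, N, K, n):
    """P[X >= k] for X ~ Hypergeometric(N, K, n), exact rationals."""
    total = math.comb(N, n)
    s = sum(math.comb(K, j) * math.comb(N - K, n - j)
            for j in range(k, min(K, n) + 1))
    return float(Fraction(s, total))
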