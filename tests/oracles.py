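"""Independently coded brute-force oracles used by the unit and
equivalence tests. Each oracle reimplements a computation from first
principles (normal equations, exhaustive enumeration, closed forms) and is
deliberately kept separate from the package's own code paths."""

import itertools
import math

import numpy as np
from scipy import stats


def ols_oracle(X, y):
    """Full OLS by explicit normal equations: beta, se, t, p."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    dof = len(y) - X.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df=dof)
    return beta, se, t, p


def tmm_oracle(counts, ref_col, obs_col):
    """Step-by-step TMM factor of column obs against column ref.

    Written directly from the recipe: doubly-positive genes, M/A values on
    library-scaled proportions, drop the 30% M and 5% A tails, inverse
    delta-method weights, 2**weighted-mean.
    """
    obs = np.asarray(counts[:, obs_col], float)
    ref = np.asarray(counts[:, ref_col], float)
    No, Nr = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep], ref[keep]
    M = np.log2((o / No) / (r / Nr))
    A = 0.5 * np.log2((o / No) * (r / Nr))
    w = (No - o) / (No * o) + (Nr - r) / (Nr * r)
    n = len(M)
    loM = math.floor(n * 0.30) + 1
    hiM = n + 1 - loM
    loA = math.floor(n * 0.05) + 1
    hiA = n + 1 - loA
    order_m = {idx: rank + 1 for rank, idx in enumerate(np.argsort(M, kind="stable"))}
    order_a = {idx: rank + 1 for rank, idx in enumerate(np.argsort(A, kind="stable"))}
    sel = [i for i in range(n)
           if loM <= order_m[i] <= hiM and loA <= order_a[i] <= hiA]
    num = sum(M[i] / w[i] for i in sel)
    den = sum(1.0 / w[i] for i in sel)
    return 2.0 ** (num / den)


def int_oracle(values, c=0.375):
    """Inverse normal transform by explicit rank formula."""
    values = np.asarray(values, float)
    n = len(values)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    # average ties
    for v in np.unique(values):
        m = values == v
        ranks[m] = ranks[m].mean()
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def m_eff_oracle(dosages, block=200, share=0.99):
    """Effective tests by explicit per-block eigen cumulative scan."""
    m = dosages.shape[1]
    total = 0
    for s in range(0, m, block):
        D = dosages[:, s:s + block].astype(float)
        D = D[:, D.std(axis=0) > 0]
        if D.shape[1] == 0:
            continue
        C = np.corrcoef(D.T) if D.shape[1] > 1 else np.ones((1, 1))
        ev = sorted(np.linalg.eigvalsh(np.atleast_2d(C)), reverse=True)
        ev = [max(e, 0) for e in ev]
        cum, k = 0.0, 0
        tot = sum(ev)
        for e in ev:
            cum += e
            k += 1
            if cum / tot >= share:
                break
        total += k
    return max(total, 1)


def bh_oracle(pvals):
    """Benjamini-Hochberg q-values by the step-up definition."""
    p = np.asarray(pvals, float)
    n = len(p)
    order = np.argsort(p)
    q = np.empty(n)
    prev = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, p[i] * n / rank_from_top)
        q[i] = val
        prev = val
    return q


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    probs = {}
    for x in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        probs[x] = (math.comb(col1, x) * math.comb(n - col1, row1 - x)
                    / math.comb(n, row1))
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


def labf_oracle(z, V, W):
    r = W / (V + W)
    return 0.5 * math.log(1 - r) + 0.5 * r * z * z


def coloc_oracle(l1, l2, p1, pc):
    """Exhaustive configuration enumeration in plain probability space.

    Works for small regions where exp(labf) does not overflow.
    """
    bf1 = [math.exp(v) for v in l1]
    bf2 = [math.exp(v) for v in l2]
    m = len(bf1)
    mass = {"null": 1.0, "trait1_only": 0.0, "trait2_only": 0.0,
            "both_distinct": 0.0, "both_shared": 0.0}
    for i in range(m):
        mass["trait1_only"] += p1 * bf1[i]
        mass["trait2_only"] += p1 * bf2[i]
        mass["both_shared"] += p1 * pc * bf1[i] * bf2[i]
        for j in range(m):
            if i != j:
                mass["both_distinct"] += p1 * p1 * (1 - pc) * bf1[i] * bf2[j]
    total = sum(mass.values())
    return {k: v / total for k, v in mass.items()}


def nb_mean_var(draws):
    return float(np.mean(draws)), float(np.var(draws))


def storey_pi1_oracle(p, lambdas=None):
    p = np.asarray(p, float)
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0 = [np.mean(p > lam) / (1 - lam) for lam in lambdas]
    coef = np.polyfit(lambdas, pi0, 3)
    val = np.polyval(coef, lambdas[-1])
    return 1.0 - min(max(val, 0.0), 1.0)
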