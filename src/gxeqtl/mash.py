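"""Empirical-Bayes multivariate shrinkage of eQTL effects across contexts.

Effect estimates (Bhat) and standard errors (Shat) for each gene-SNP pair
across R contexts (cell type x condition combinations) are modeled with a
mixture-of-multivariate-normals prior,

    b_j ~ sum_{k,l} pi_{kl} N(0, omega_l^2 U_k)   (plus a point mass at 0),
    Bhat_j | b_j ~ N(b_j, S_j V S_j),

with canonical covariance components (identity, per-context singletons,
equal effects) and data-driven components (empirical covariance and low-rank
PCA reconstruction of the strong-set z-scores) on a multiplicative scale
grid. Mixture weights are estimated by EM on a random set of LD-independent
pairs; posterior means, standard deviations and the local false sign rate
(lfsr) are computed for the strong set.

The lfsr of effect b in one context is
min{P(b >= 0 | data), P(b <= 0 | data)}, with posterior point mass at zero
counted on both sides, so lfsr = 1 when all mass sits at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .simgen import GenotypePanel

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class EffectMatrix:
    """Per gene-SNP pair effect estimates across contexts."""

    pairs: pd.DataFrame       # gene, snp
    Bhat: np.ndarray          # pairs x R
    Shat: np.ndarray          # pairs x R (> 0 where observed)
    contexts: list[str]
    mask: np.ndarray | None = None  # True where observed; None = complete

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = np.isfinite(self.Bhat) & np.isfinite(self.Shat)
        obs = self.mask
        if np.any(self.Shat[obs] <= 0):
            raise ValueError("Shat must be positive where observed")

    @property
    def Z(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.mask, self.Bhat / self.Shat, np.nan)


@dataclass
class PriorSpec:
    V: np.ndarray                       # residual correlation, R x R
    Ulist: dict[str, np.ndarray]        # component covariances (unit scale)
    grid: np.ndarray                    # omega scales
    pi: np.ndarray | None = None        # weights over [null] + (U, omega)
    component_names: list[str] = field(default_factory=list)

    def components(self) -> list[tuple[str, np.ndarray]]:
        """Expanded component list: the null plus every (U, omega) pair."""
        R = self.V.shape[0]
        comps = [("null", np.zeros((R, R)))]
        for name, U in self.Ulist.items():
            for w in self.grid:
                comps.append((f"{name};omega={w:.6g}", (w ** 2) * U))
        return comps


# ---------------------------------------------------------------------------
# LD pruning and the random / strong sets
# ---------------------------------------------------------------------------

def ld_prune(panel: GenotypePanel, window: int = 50, step: int = 5,
             r2_threshold: float = 0.2) -> list[str]:
    """Greedy sliding-window LD pruning (window 50 SNPs, step 5, r^2 0.2).

    Within each window, for any surviving pair with r^2 > threshold the SNP
    with lower MAF is removed (tie: the higher position); the window then
    advances by ``step`` SNPs.
    """
    D = panel.dosages.astype(float)
    m = D.shape[1]
    maf = panel.snps["maf"].to_numpy()
    pos = panel.snps["pos"].to_numpy()
    removed = np.zeros(m, dtype=bool)
    start = 0
    while start < m:
        idx = [j for j in range(start, min(start + window, m)) if not removed[j]]
        if len(idx) > 1:
            sub = D[:, idx]
            sd = sub.std(axis=0)
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(sub, rowvar=False)
            changed = True
            while changed:
                changed = False
                for a in range(len(idx)):
                    ja = idx[a]
                    if removed[ja] or sd[a] == 0:
                        continue
                    for b in range(a + 1, len(idx)):
                        jb = idx[b]
                        if removed[jb] or sd[b] == 0:
                            continue
                        r = corr[a, b]
                        if r * r > r2_threshold:
                            if maf[ja] > maf[jb]:
                                drop = jb
                            elif maf[jb] > maf[ja]:
                                drop = ja
                            else:
                                drop = ja if pos[ja] > pos[jb] else jb
                            removed[drop] = True
                            changed = True
        if start + window >= m:
            break
        start += step
    return [s for j, s in enumerate(panel.snp_ids) if not removed[j]]


def build_strong_set(results_by_context: dict[str, pd.DataFrame],
                     seed: int = 0) -> pd.DataFrame:
    """Top pair per gene: smallest nominal p across all contexts.

    Exact ties are broken by a seeded uniform draw.
    """
    rng = np.random.default_rng(seed)
    stacked = pd.concat(
        [df.assign(context=ctx) for ctx, df in results_by_context.items()],
        ignore_index=True)
    rows = []
    for gene, grp in stacked.groupby("gene", sort=False):
        pmin = grp["p"].min()
        best = grp.loc[grp["p"] == pmin, "snp"].unique()
        snp = best[0] if len(best) == 1 else str(rng.choice(np.sort(best)))
        rows.append({"gene": gene, "snp": snp, "p_min": pmin})
    return pd.DataFrame(rows)


def assemble_effects(results_by_context: dict[str, pd.DataFrame],
                     pairs: pd.DataFrame) -> EffectMatrix:
    """Collect Bhat/Shat for the given (gene, snp) pairs across contexts."""
    contexts = list(results_by_context)
    key = pairs["gene"] + "|" + pairs["snp"]
    B = np.full((len(pairs), len(contexts)), np.nan)
    S = np.full((len(pairs), len(contexts)), np.nan)
    for r, ctx in enumerate(contexts):
        df = results_by_context[ctx]
        idx = (df["gene"] + "|" + df["snp"]).to_numpy()
        lut_b = pd.Series(df["beta"].to_numpy(), index=idx)
        lut_s = pd.Series(df["se"].to_numpy(), index=idx)
        present = key.isin(lut_b.index)
        B[present.to_numpy(), r] = lut_b.loc[key[present]].to_numpy()
        S[present.to_numpy(), r] = lut_s.loc[key[present]].to_numpy()
    return EffectMatrix(pairs=pairs[["gene", "snp"]].reset_index(drop=True),
                        Bhat=B, Shat=S, contexts=contexts)


# ---------------------------------------------------------------------------
# residual correlation
# ---------------------------------------------------------------------------

def estimate_null_correlation(Z: np.ndarray, z_max: float = 2.0,
                              max_condition: float = 1e6) -> np.ndarray:
    """Residual correlation V from near-null rows (max |z| < 2).

    Ridge-regularized toward the identity until the condition number is at
    most ``max_condition``; unit diagonal enforced. Falls back to the
    identity (with a warning) when fewer than 20 rows qualify.
    """
    Z = np.asarray(Z, float)
    R = Z.shape[1]
    if R == 1:
        return np.ones((1, 1))
    complete = np.isfinite(Z).all(axis=1)
    rows = Z[complete]
    rows = rows[np.abs(rows).max(axis=1) < z_max]
    if rows.shape[0] < 20:
        warnings.warn("fewer than 20 near-null rows; using identity correlation")
        return np.eye(R)
    V = np.corrcoef(rows, rowvar=False)
    V = np.atleast_2d(V)
    eps = 0.0
    while np.linalg.cond(V) > max_condition:
        eps = max(eps * 2, 1e-4)
        V = (1 - eps) * V + eps * np.eye(R)
    np.fill_diagonal(V, 1.0)
    return 0.5 * (V + V.T)


# ---------------------------------------------------------------------------
# covariance components and the scale grid
# ---------------------------------------------------------------------------

def canonical_covariances(R: int) -> dict[str, np.ndarray]:
    U = {"identity": np.eye(R), "equal_effects": np.ones((R, R))}
    for r in range(R):
        e = np.zeros((R, R))
        e[r, r] = 1.0
        U[f"singleton_{r}"] = e
    return U


def data_driven_covariances(Z_strong: np.ndarray, n_pcs: int = 5
                            ) -> dict[str, np.ndarray]:
    """Empirical covariance and rank-k PCA reconstruction of strong z-scores."""
    Z = Z_strong[np.isfinite(Z_strong).all(axis=1)]
    R = Z.shape[1]
    out: dict[str, np.ndarray] = {}
    if Z.shape[0] >= 2:
        emp = Z.T @ Z / Z.shape[0]
        out["empirical"] = _psd(emp)
        ev, evec = np.linalg.eigh(emp)
        order = np.argsort(ev)[::-1]
        k = min(n_pcs, R)
        lead = evec[:, order[:k]] * np.sqrt(np.clip(ev[order[:k]], 0, None))
        out[f"pca_rank{k}"] = _psd(lead @ lead.T)
    return {name: _normalize_cov(U) for name, U in out.items()}


def _psd(U: np.ndarray) -> np.ndarray:
    ev, evec = np.linalg.eigh(0.5 * (U + U.T))
    return (evec * np.clip(ev, 0, None)) @ evec.T


def _normalize_cov(U: np.ndarray) -> np.ndarray:
    m = np.max(np.diag(U))
    return U / m if m > 0 else U


def default_grid(Bhat: np.ndarray, Shat: np.ndarray) -> np.ndarray:
    """omega grid from min(Shat)/10 to 2 max|Bhat| in sqrt(2) steps."""
    obs = np.isfinite(Shat) & (Shat > 0)
    lo = np.nanmin(Shat[obs]) / 10.0
    hi = 2.0 * np.nanmax(np.abs(Bhat[np.isfinite(Bhat)]))
    hi = max(hi, lo * 2)
    n = int(np.ceil(2 * np.log2(hi / lo))) + 1
    return lo * np.sqrt(2.0) ** np.arange(n)


def build_prior(effects: EffectMatrix, strong: EffectMatrix | None = None,
                n_pcs: int = 5) -> PriorSpec:
    V = estimate_null_correlation(effects.Z)
    R = len(effects.contexts)
    U = canonical_covariances(R)
    if strong is not None:
        U.update(data_driven_covariances(strong.Z, n_pcs=n_pcs))
    grid = default_grid(effects.Bhat, effects.Shat)
    return PriorSpec(V=V, Ulist=U, grid=grid)


# ---------------------------------------------------------------------------
# likelihood, EM, posterior
# ---------------------------------------------------------------------------

def _pattern_groups(mask: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group row indices by identical observation patterns."""
    keys = [tuple(np.flatnonzero(m)) for m in mask]
    groups: dict[tuple, list[int]] = {}
    for i, k in enumerate(keys):
        groups.setdefault(k, []).append(i)
    return [(np.array(k, int), np.array(v, int)) for k, v in groups.items() if len(k)]


def loglik_matrix(effects: EffectMatrix, prior: PriorSpec) -> np.ndarray:
    """Log-likelihood of each pair under each mixture component.

    For pair j and component with prior covariance P (on observed contexts
    o): Bhat_j[o] ~ N(0, P[o,o] + S_j V S_j [o,o]). Missing contexts are
    marginalized out of the multivariate normal.
    """
    comps = prior.components()
    J = effects.Bhat.shape[0]
    L = np.full((J, len(comps)), -np.inf)
    for obs, rows in _pattern_groups(effects.mask):
        B = effects.Bhat[np.ix_(rows, obs)]
        S = effects.Shat[np.ix_(rows, obs)]
        Vo = prior.V[np.ix_(obs, obs)]
        SVS = Vo[None, :, :] * S[:, :, None] * S[:, None, :]
        d = len(obs)
        for c, (_, P) in enumerate(comps):
            Sig = SVS + P[np.ix_(obs, obs)][None, :, :]
            sign, logdet = np.linalg.slogdet(Sig)
            if np.any(sign <= 0):
                raise FloatingPointError(
                    f"non-positive-definite covariance in component {comps[c][0]}")
            x = np.linalg.solve(Sig, B[:, :, None])[:, :, 0]
            quad = np.einsum("jr,jr->j", B, x)
            L[rows, c] = -0.5 * (d * _LOG2PI + logdet + quad)
    return L


def fit_weights_em(effects: EffectMatrix, prior: PriorSpec, tol: float = 1e-8,
                   max_iter: int = 1000) -> PriorSpec:
    """EM for the mixture weights pi from a uniform start.

    Only the weights are free, so the per-component log-likelihood matrix
    is fixed and each iteration is a responsibility average. The
    log-likelihood is asserted to be nondecreasing.
    """
    L = loglik_matrix(effects, prior)
    if not np.isfinite(L).all():
        bad = np.where(~np.isfinite(L).any(axis=0))[0]
        names = [prior.components()[c][0] for c in bad]
        raise FloatingPointError(f"non-finite likelihood for components {names}")
    C = L.shape[1]
    pi = np.full(C, 1.0 / C)
    last = -np.inf
    for _ in range(max_iter):
        logw = np.log(np.maximum(pi, 1e-300))[None, :] + L
        ll_rows = logsumexp(logw, axis=1)
        ll = float(ll_rows.sum())
        assert ll >= last - 1e-6, "EM log-likelihood decreased"
        resp = np.exp(logw - ll_rows[:, None])
        pi = resp.mean(axis=0)
        if ll - last < tol and np.isfinite(last):
            break
        last = ll
    fitted = PriorSpec(V=prior.V, Ulist=prior.Ulist, grid=prior.grid, pi=pi,
                       component_names=[n for n, _ in prior.components()])
    return fitted


@dataclass
class PosteriorEffects:
    pairs: pd.DataFrame
    contexts: list[str]
    mean: np.ndarray      # pairs x R posterior mean
    sd: np.ndarray        # pairs x R posterior SD
    lfsr: np.ndarray      # pairs x R local false sign rate

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r, ctx in enumerate(self.contexts):
            rows.append(pd.DataFrame({
                "gene": self.pairs["gene"], "snp": self.pairs["snp"],
                "context": ctx, "mean": self.mean[:, r], "sd": self.sd[:, r],
                "lfsr": self.lfsr[:, r]}))
        return pd.concat(rows, ignore_index=True)


def posterior(effects: EffectMatrix, prior: PriorSpec,
              sign_tol: float = 1e-12) -> PosteriorEffects:
    """Mixture posterior mean, SD, and lfsr per pair and context.

    Per component with prior covariance P, the conjugate posterior on the
    full coordinate set given the observed contexts o is
    N(P[:,o] Sig_o^-1 Bhat_o, P - P[:,o] Sig_o^-1 P[o,:]) with
    Sig_o = P[o,o] + S V S [o,o]; unobserved contexts are therefore handled
    by marginalization. The lfsr accumulates per-component positive,
    negative and point-zero sign masses.
    """
    if prior.pi is None:
        raise ValueError("prior weights not fitted; run fit_weights_em first")
    comps = prior.components()
    J, R = effects.Bhat.shape
    L = loglik_matrix(effects, prior)
    logw = np.log(np.maximum(prior.pi, 1e-300))[None, :] + L
    resp = np.exp(logw - logsumexp(logw, axis=1)[:, None])

    mean = np.zeros((J, R))
    second = np.zeros((J, R))   # E[b^2]
    pos = np.zeros((J, R))
    neg = np.zeros((J, R))
    zero = np.zeros((J, R))

    for obs, rows in _pattern_groups(effects.mask):
        B = effects.Bhat[np.ix_(rows, obs)]
        S = effects.Shat[np.ix_(rows, obs)]
        Vo = prior.V[np.ix_(obs, obs)]
        SVS = Vo[None, :, :] * S[:, :, None] * S[:, None, :]
        for c, (_, P) in enumerate(comps):
            w = resp[rows, c][:, None]
            if np.all(w < 1e-300):
                continue
            if np.allclose(P, 0):
                zero[rows] += w
                continue
            Sig = SVS + P[np.ix_(obs, obs)][None, :, :]
            X = np.linalg.solve(Sig, B[:, :, None])[:, :, 0]       # Sig^-1 B
            m = X @ P[obs, :]                                      # rows x R
            Y = np.linalg.solve(Sig, np.broadcast_to(
                P[np.ix_(obs, np.arange(R))], (len(rows), len(obs), R)).copy())
            var = np.diag(P)[None, :] - np.einsum(
                "or,jor->jr", P[np.ix_(obs, np.arange(R))], Y)
            var = np.clip(var, 0.0, None)
            sd = np.sqrt(var)
            mean[rows] += w * m
            second[rows] += w * (var + m ** 2)
            point = sd < sign_tol
            with np.errstate(divide="ignore", invalid="ignore"):
                p_pos = np.where(point, (m > sign_tol).astype(float),
                                 stats.norm.sf(-m / np.maximum(sd, sign_tol)))
                p_neg = np.where(point, (m < -sign_tol).astype(float),
                                 stats.norm.cdf(-m / np.maximum(sd, sign_tol)))
            p_zero = np.where(point & (np.abs(m) <= sign_tol), 1.0,
                              np.clip(1.0 - p_pos - p_neg, 0.0, None))
            pos[rows] += w * p_pos
            neg[rows] += w * p_neg
            zero[rows] += w * p_zero
    sd_out = np.sqrt(np.clip(second - mean ** 2, 0.0, None))
    lfsr = 1.0 - np.maximum(pos, neg)
    lfsr = np.clip(lfsr, 0.0, 1.0)
    return PosteriorEffects(pairs=effects.pairs, contexts=effects.contexts,
                            mean=mean, sd=sd_out, lfsr=lfsr)


# ---------------------------------------------------------------------------
# sharing by magnitude
# ---------------------------------------------------------------------------

def sharing_by_magnitude(post: PosteriorEffects, c1: str, c2: str,
                         lfsr_cut: float = 0.1, factor: float = 1.5
                         ) -> pd.DataFrame:
    """Pairwise sharing: same sign and magnitudes within ``factor``.

    Restricted to pairs significant (lfsr < cut) in either context; a zero
    posterior mean in one context is never shared (infinite ratio).
    """
    i1, i2 = post.contexts.index(c1), post.contexts.index(c2)
    m1, m2 = post.mean[:, i1], post.mean[:, i2]
    sig = (post.lfsr[:, i1] < lfsr_cut) | (post.lfsr[:, i2] < lfsr_cut)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(np.abs(m1), np.abs(m2)) / np.minimum(np.abs(m1),
                                                                np.abs(m2))
    shared = sig & (np.sign(m1) == np.sign(m2)) & (m1 != 0) & (ratio <= factor)
    return pd.DataFrame({"gene": post.pairs["gene"], "snp": post.pairs["snp"],
                         "significant": sig, "ratio": ratio, "shared": shared})
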