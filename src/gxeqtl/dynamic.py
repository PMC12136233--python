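"""Dynamic eQTL mapping along differentiation pseudotime.

Bin-level pseudobulk expression E_ct for donor c in pseudotime bin t is
regressed on a 28-column design,

    E_ct ~ N(mu + b1 G_c + b2 gPC_c1 + b3 gPC_c2 + b4 S_c + b5 tau
             + b6 PC_c1 + ... + b15 PC_c10
             + b16 PC_c1 tau + ... + b25 PC_c10 tau
             + b26 S_c tau + b27 G_c tau, sigma^2),

where tau is the bin median pseudotime, S is donor sex, gPC are genotype
PCs (population structure, no pseudotime interaction), and PC_1..10 are
cell-line expression PCs from a NIPALS PCA that tolerates the missing
donor-by-bin blocks. The genotype-by-pseudotime coefficient b27 is the
dynamic-eQTL test; significance combines the effective-number-of-tests
correction per gene with a genome-wide Benjamini-Hochberg cutoff rule, and
significant calls are classified early / late / switch from the predicted
effects at the trajectory endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cis_eqtl import effective_tests
from .simgen import GenotypePanel

# ---------------------------------------------------------------------------
# NIPALS PCA with missing data
# ---------------------------------------------------------------------------

def nipals_pca(X: np.ndarray, n_pcs: int = 10, tol: float = 1e-8,
               max_iter: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """NIPALS principal components of a matrix with missing entries.

    Rows are observations (donors), columns features (gene x bin
    expression). Missing entries (NaN) are simply skipped in every inner
    product. Columns are mean-centered on their observed entries.
    Initialization is the first column with any observed value, so the
    result is deterministic. Returns (scores, loadings) with shapes
    (n, n_pcs) and (p, n_pcs).
    """
    X = np.array(X, dtype=float)
    n, p = X.shape
    obs = np.isfinite(X)
    if np.any(obs.sum(axis=1) < 2):
        raise ValueError("each observation must have >= 2 observed features")
    mu = np.nanmean(X, axis=0)
    Xc = np.where(obs, X - mu, 0.0)
    n_pcs = min(n_pcs, n, p)
    T = np.zeros((n, n_pcs))
    P = np.zeros((p, n_pcs))
    for a in range(n_pcs):
        j0 = int(np.argmax(obs.any(axis=0)))
        t = Xc[:, j0].copy()
        if np.all(t == 0):
            t = Xc[:, int(np.argmax((Xc ** 2).sum(axis=0)))].copy()
        converged = False
        for _ in range(max_iter):
            denom_p = (obs * t[:, None] ** 2).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                pvec = np.where(denom_p > 0, (Xc * t[:, None]).sum(axis=0) / denom_p, 0.0)
            norm = np.linalg.norm(pvec)
            if norm == 0:
                break
            pvec /= norm
            denom_t = (obs * pvec[None, :] ** 2).sum(axis=1)
            t_new = np.where(denom_t > 0, (Xc * pvec[None, :]).sum(axis=1) / denom_t, 0.0)
            if np.linalg.norm(t_new - t) < tol * max(1.0, np.linalg.norm(t_new)):
                t = t_new
                converged = True
                break
            t = t_new
        if not converged:
            warnings.warn(f"NIPALS component {a + 1} did not converge; "
                          "using last iterate")
        T[:, a] = t
        P[:, a] = pvec
        Xc = Xc - np.where(obs, np.outer(t, pvec), 0.0)
    return T, P


def cell_line_pcs(pb_bins, n_pcs: int = 10) -> pd.DataFrame:
    """Donor scores from NIPALS PCA of the donor x (gene, bin) matrix.

    The input is bin-level pseudobulk (normalized expression indexed by
    donor x bin samples); a donor absent from a bin contributes missing
    values for that bin's features.
    """
    expr = pb_bins.expression
    meta = pb_bins.samples
    donors = sorted(meta["donor"].unique())
    bins = sorted(meta["bin"].unique())
    blocks = []
    for b in bins:
        cols = meta.index[meta["bin"] == b]
        sub = expr[cols]
        sub.columns = meta.loc[cols, "donor"]
        blocks.append(sub.T.reindex(donors))
    X = pd.concat(blocks, axis=1)
    scores, _ = nipals_pca(X.to_numpy(), n_pcs=n_pcs)
    return pd.DataFrame(scores, index=donors,
                        columns=[f"PC{i+1}" for i in range(scores.shape[1])])


# ---------------------------------------------------------------------------
# the interaction model
# ---------------------------------------------------------------------------

@dataclass
class DynamicFit:
    results: pd.DataFrame    # gene, snp, beta_g, beta27, se27, t27, p
    tau_range: tuple[float, float]
    design_columns: list[str]


def _design(G: np.ndarray, tau: np.ndarray, sex: np.ndarray, gpc: np.ndarray,
            pcs: np.ndarray) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(tau), G, gpc[:, 0], gpc[:, 1], sex, tau]
    names = ["intercept", "G", "gPC1", "gPC2", "sex", "tau"]
    for k in range(pcs.shape[1]):
        cols.append(pcs[:, k])
        names.append(f"PC{k+1}")
    for k in range(pcs.shape[1]):
        cols.append(pcs[:, k] * tau)
        names.append(f"PC{k+1}xTau")
    cols.append(sex * tau)
    names.append("sexxTau")
    cols.append(G * tau)
    names.append("GxTau")
    return np.column_stack(cols), names


def fit_dynamic(pb_bins, panel: GenotypePanel, tss: pd.DataFrame,
                pcs: pd.DataFrame | None = None, gpcs: pd.DataFrame | None = None,
                window: int = 100_000, n_pcs: int = 10,
                weights: np.ndarray | None = None) -> DynamicFit:
    """Fit the genotype-by-pseudotime interaction model for every cis pair.

    ``pb_bins`` is a normalized donor x bin PseudobulkMatrix whose samples
    table carries donor, bin and tau (bin median pseudotime). Plain OLS by
    default; ``weights`` enables optional weighted least squares.
    """
    from .cis_eqtl import genotype_pcs

    meta = pb_bins.samples
    expr = pb_bins.expression
    donors_all = [d for d in panel.donors if d in set(meta["donor"])]
    if pcs is None:
        pcs = cell_line_pcs(pb_bins, n_pcs=n_pcs)
    if gpcs is None:
        gpcs = genotype_pcs(panel, n_pcs=2)

    donor_arr = meta["donor"].to_numpy()
    tau = meta["tau"].to_numpy().astype(float)
    didx = np.array([panel.donors.index(d) for d in donor_arr])
    sex = (panel.sex[didx].astype(float) if panel.sex is not None
           else np.zeros(len(didx)))
    gpc = gpcs.loc[donor_arr].to_numpy().astype(float)
    pc = pcs.reindex(donor_arr).to_numpy().astype(float)

    tss_map = tss.set_index("gene")["tss"]
    snp_pos = panel.snps["pos"].to_numpy()
    rows = []
    names = None
    for gene in expr.index:
        if gene not in tss_map.index:
            continue
        y_all = expr.loc[gene].to_numpy().astype(float)
        ok = np.isfinite(y_all)
        in_cis = np.abs(snp_pos - tss_map.loc[gene]) <= window
        for j in np.where(in_cis)[0]:
            G = panel.dosages[didx, j].astype(float)
            X, names = _design(G[ok], tau[ok], sex[ok], gpc[ok], pc[ok])
            y = y_all[ok]
            if weights is not None:
                w = np.sqrt(weights[ok])
                Xw, yw = X * w[:, None], y * w
            else:
                Xw, yw = X, y
            beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
            if rank < X.shape[1]:
                _, Rr = np.linalg.qr(Xw)
                bad = [names[i] for i in range(X.shape[1])
                       if abs(Rr[i, i]) < 1e-8 * abs(Rr[0, 0])]
                raise np.linalg.LinAlgError(
                    f"rank-deficient design for {gene}; collinear columns: {bad}")
            resid = yw - Xw @ beta
            dof = len(y) - X.shape[1]
            sigma2 = resid @ resid / dof
            XtX_inv = np.linalg.inv(Xw.T @ Xw)
            se27 = np.sqrt(sigma2 * XtX_inv[-1, -1])
            t27 = beta[-1] / se27
            p = 2 * stats.t.sf(abs(t27), df=dof)
            rows.append((gene, panel.snps.iloc[j]["snp"], beta[1], beta[-1],
                         se27, t27, p))
    res = pd.DataFrame(rows, columns=["gene", "snp", "beta_g", "beta27",
                                      "se27", "t27", "p"])
    return DynamicFit(results=res, tau_range=(float(tau.min()), float(tau.max())),
                      design_columns=names or [])


# ---------------------------------------------------------------------------
# significance: eigenMT + BH with the cutoff rule
# ---------------------------------------------------------------------------

def dynamic_significance(fit: DynamicFit, panel: GenotypePanel,
                         fdr: float = 0.1) -> pd.DataFrame:
    """Flag significant dynamic pairs with the genome-wide cutoff rule.

    Per gene, the interaction p-values are corrected by the effective
    number of tests; Benjamini-Hochberg runs on the per-gene minima. The
    significance cutoff is the corrected p-value of the gene whose BH
    q-value is closest to ``fdr`` from below (i.e. the largest corrected
    minimum among genes with q <= fdr), and every pair -- not only the top
    pair -- with corrected p at or below that cutoff is retained.
    """
    res = fit.results.copy()
    snp_index = {s: j for j, s in enumerate(panel.snp_ids)}
    adj = []
    for gene, grp in res.groupby("gene", sort=False):
        js = [snp_index[s] for s in grp["snp"]]
        m_eff = effective_tests(panel.dosages[:, js])
        adj.append(pd.Series(np.minimum(1.0, grp["p"] * m_eff), index=grp.index))
    res["p_eigenmt"] = pd.concat(adj)

    gene_min = res.groupby("gene")["p_eigenmt"].min()
    _, q, _, _ = multipletests(gene_min.to_numpy(), method="fdr_bh")
    qser = pd.Series(q, index=gene_min.index)
    passing = qser[qser <= fdr]
    if passing.empty:
        res["significant"] = False
        return res
    # boundary gene: the passing gene whose corrected p sits closest to the
    # genome-wide threshold, i.e. the largest corrected minimum that still
    # satisfies q <= fdr
    cutoff_gene = gene_min.loc[passing.index].idxmax()
    cutoff = float(gene_min.loc[cutoff_gene])
    res["significant"] = res["p_eigenmt"] <= cutoff
    return res


# ---------------------------------------------------------------------------
# classification and replication
# ---------------------------------------------------------------------------

def endpoint_effects(beta_g: float, beta27: float,
                     tau_range: tuple[float, float]) -> tuple[float, float]:
    """Predicted genotype effect at the trajectory endpoints."""
    return beta_g + beta27 * tau_range[0], beta_g + beta27 * tau_range[1]


def classify_dynamic(e_start: float, e_end: float,
                     switch_threshold: float = 1.0) -> str:
    """Early / late / switch from the endpoint effects.

    Same sign: early when the magnitude decreases, late when it increases
    (an exact tie is labeled late). Sign reversal is a switch only when
    both endpoint magnitudes exceed ``switch_threshold``; otherwise it
    falls back to the magnitude comparison.
    """
    if np.sign(e_start) != np.sign(e_end) and e_start != 0 and e_end != 0:
        if abs(e_start) > switch_threshold and abs(e_end) > switch_threshold:
            return "switch"
    return "early" if abs(e_end) < abs(e_start) else "late"


def classify_calls(res: pd.DataFrame, tau_range: tuple[float, float],
                   switch_threshold: float = 1.0) -> pd.DataFrame:
    out = res.copy()
    e0, e1 = endpoint_effects(out["beta_g"].to_numpy(), out["beta27"].to_numpy(),
                              tau_range)
    out["e_start"], out["e_end"] = e0, e1
    out["class"] = [classify_dynamic(a, b, switch_threshold)
                    for a, b in zip(e0, e1)]
    return out


def pi1(pvalues: np.ndarray, lambdas: np.ndarray | None = None) -> float:
    """Storey's pi1 replication estimate.

    pi0(lambda) = #{p > lambda} / (n (1 - lambda)) on the grid
    lambda = 0.05, 0.10, ..., 0.95; a cubic polynomial smoother is
    evaluated at the largest lambda and clamped to [0, 1]; pi1 = 1 - pi0.
    """
    p = np.asarray(pvalues, float)
    if len(p) < 50:
        raise ValueError("pi1 requires >= 50 p-values")
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(p > lam).mean() / (1 - lam) for lam in lambdas])
    coef = np.polyfit(lambdas, pi0_l, deg=3)
    pi0 = float(np.clip(np.polyval(coef, lambdas[-1]), 0.0, 1.0))
    return 1.0 - pi0
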