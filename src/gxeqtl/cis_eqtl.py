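"""Per-context cis-eQTL mapping with covariates and gene-level correction.

Linear regression of inverse-normal expression on allelic dosage within a
+/-100 kb window around each gene's TSS, with sex, two genotype principal
components, and data-selected expression PCs as covariates; gene-level
multiple testing by the effective-number-of-tests (eigen-decomposition)
correction; genome-wide Benjamini-Hochberg FDR on the per-gene corrected
minima.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simgen import GenotypePanel, passes_snp_filters

log = logging.getLogger(__name__)


@dataclass
class CovariateSet:
    """Design covariates for one mapping context (no intercept column)."""

    matrix: pd.DataFrame        # samples x covariates
    n_expression_pcs: int
    dropped: list[str] = field(default_factory=list)  # pruned by R^2 > 0.9


# ---------------------------------------------------------------------------
# genotype PCs (population structure), computed once on the full panel
# ---------------------------------------------------------------------------

def genotype_pcs(panel: GenotypePanel, n_pcs: int = 2) -> pd.DataFrame:
    X = panel.dosages.astype(float)
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = u[:, :n_pcs] * s[:n_pcs]
    return pd.DataFrame(pcs, index=panel.donors,
                        columns=[f"gPC{i+1}" for i in range(n_pcs)])


# ---------------------------------------------------------------------------
# expression PC selection
# ---------------------------------------------------------------------------

def _pc_variances(mat: np.ndarray) -> np.ndarray:
    x = mat - mat.mean(axis=0)
    s = np.linalg.svd(x, compute_uv=False)
    return s ** 2 / (mat.shape[0] - 1)


def select_expression_pcs(expr: pd.DataFrame, method: str = "parallel",
                          n_permutations: int = 30, seed: int = 0,
                          max_pcs: int | None = None,
                          other_covariates: pd.DataFrame | None = None,
                          r2_prune: float = 0.9) -> CovariateSet:
    """Choose the number of expression PCs by parallel analysis or the elbow.

    Parallel analysis (Buja-Eyuboglu): K = number of leading PCs whose
    variance exceeds the 95th percentile of the same-rank variances under
    ``n_permutations`` independent within-gene permutations; counting stops
    at the first failure. The elbow takes the PC maximizing the distance to
    the chord through the first and last eigenvalue. Non-PC covariates with
    R^2 > 0.9 against any selected PC are dropped.
    """
    if expr.shape[1] < 10:
        raise ValueError("PC selection requires >= 10 samples")
    mat = expr.to_numpy().T  # samples x genes
    var = _pc_variances(mat)
    n_comp = len(var)
    if method == "parallel":
        rng = np.random.default_rng(seed)
        perm_vars = np.empty((n_permutations, n_comp))
        for b in range(n_permutations):
            perm = np.empty_like(mat)
            for j in range(mat.shape[1]):
                perm[:, j] = rng.permutation(mat[:, j])
            perm_vars[b] = _pc_variances(perm)
        thresh = np.quantile(perm_vars, 0.95, axis=0)
        k = 0
        while k < n_comp and var[k] > thresh[k]:
            k += 1
    elif method == "elbow":
        x = np.arange(n_comp, dtype=float)
        y = var
        p0, p1 = np.array([x[0], y[0]]), np.array([x[-1], y[-1]])
        chord = p1 - p0
        chord = chord / np.linalg.norm(chord)
        rel = np.column_stack([x, y]) - p0
        dist = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
        k = int(np.argmax(dist))
    else:
        raise ValueError(f"unknown method {method!r}")
    if max_pcs is not None:
        k = min(k, max_pcs)

    x = mat - mat.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = pd.DataFrame(u[:, :k] * s[:k], index=expr.columns,
                       columns=[f"ePC{i+1}" for i in range(k)])
    dropped: list[str] = []
    cov = pcs
    if other_covariates is not None:
        other = other_covariates.loc[expr.columns]
        keep_cols = []
        for c in other.columns:
            r2max = 0.0
            v = other[c].to_numpy().astype(float)
            if np.std(v) > 0:
                for p in pcs.columns:
                    r = np.corrcoef(v, pcs[p].to_numpy())[0, 1]
                    r2max = max(r2max, r * r)
            if r2max > r2_prune:
                dropped.append(c)
            else:
                keep_cols.append(c)
        cov = pd.concat([other[keep_cols], pcs], axis=1)
    return CovariateSet(matrix=cov, n_expression_pcs=k, dropped=dropped)


# ---------------------------------------------------------------------------
# cis mapping
# ---------------------------------------------------------------------------

def _residualize(Y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Project out columns of C (with intercept) from the columns of Y."""
    Q, _ = np.linalg.qr(C)
    return Y - Q @ (Q.T @ Y)


def map_cis(expr: pd.DataFrame, panel: GenotypePanel, tss: pd.DataFrame,
            covariates: CovariateSet | pd.DataFrame | None = None,
            window: int = 100_000, donors: list[str] | None = None
            ) -> pd.DataFrame:
    """OLS cis-eQTL scan: every SNP within ``window`` of each gene's TSS.

    Expression columns are donor ids; the panel is subset and SNPs failing
    the MAF/homozygote filters within this donor subset are skipped.
    Returns all nominal results (gene, snp, beta, se, t, p, n).
    """
    if donors is None:
        donors = [d for d in expr.columns if d in set(panel.donors)]
    expr = expr[donors]
    sub = panel.subset_donors(donors)
    n = len(donors)

    if covariates is None:
        C = np.ones((n, 1))
        p_cov = 0
    else:
        cmat = covariates.matrix if isinstance(covariates, CovariateSet) else covariates
        cmat = cmat.loc[donors]
        C = np.column_stack([np.ones(n), cmat.to_numpy().astype(float)])
        p_cov = cmat.shape[1]
    dof = n - p_cov - 2  # intercept + covariates + genotype
    if dof < 1:
        raise ValueError("not enough samples for the covariate design")

    # residualize once (Frisch-Waugh): identical estimates to the full OLS
    Y = _residualize(expr.to_numpy().T, C)          # samples x genes
    keep = np.array([passes_snp_filters(sub.dosages[:, j])
                     for j in range(sub.dosages.shape[1])])
    G = _residualize(sub.dosages.astype(float), C)  # samples x snps

    tss_map = tss.set_index("gene")["tss"]
    results = []
    snp_pos = sub.snps["pos"].to_numpy()
    gg = (G ** 2).sum(axis=0)
    for gi, gene in enumerate(expr.index):
        if gene not in tss_map.index:
            continue
        t0 = tss_map.loc[gene]
        in_cis = np.abs(snp_pos - t0) <= window
        js = np.where(in_cis & keep)[0]
        if len(js) == 0:
            continue
        y = Y[:, gi]
        g = G[:, js]
        denom = gg[js]
        zero = denom <= 1e-12
        if zero.any():
            log.info("gene %s: %d SNPs with zero genotype variance skipped",
                     gene, int(zero.sum()))
            js = js[~zero]
            g = g[:, ~zero]
            denom = denom[~zero]
            if len(js) == 0:
                continue
        beta = (g.T @ y) / denom
        rss = (y ** 2).sum() - beta ** 2 * denom
        rss = np.maximum(rss, 0.0)
        se = np.sqrt(rss / dof / denom)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = beta / se
        pval = 2 * stats.t.sf(np.abs(tval), df=dof)
        for k, j in enumerate(js):
            results.append((gene, sub.snps.iloc[j]["snp"], sub.snps.iloc[j]["chrom"],
                            int(sub.snps.iloc[j]["pos"]), n, beta[k], se[k],
                            tval[k], pval[k]))
    return pd.DataFrame(results, columns=["gene", "snp", "chrom", "pos", "n",
                                          "beta", "se", "t", "p"])


# ---------------------------------------------------------------------------
# eigenMT-style effective number of tests
# ---------------------------------------------------------------------------

def effective_tests(dosages: np.ndarray, block_size: int = 200,
                    var_explained: float = 0.99) -> int:
    """Effective number of independent tests among cis SNPs.

    SNPs are split into consecutive blocks of <= ``block_size``; in each
    block the eigenvalues of the SNP correlation matrix are sorted
    descending and the block contributes the smallest k whose cumulative
    share reaches ``var_explained``; the gene total is the sum over blocks.
    """
    m = dosages.shape[1]
    if m == 0:
        raise ValueError("effective_tests requires >= 1 SNP")
    total = 0
    for start in range(0, m, block_size):
        block = dosages[:, start:start + block_size].astype(float)
        sd = block.std(axis=0)
        block = block[:, sd > 0]
        if block.shape[1] == 0:
            continue
        corr = np.corrcoef(block, rowvar=False)
        corr = np.atleast_2d(corr)
        ev = np.sort(np.linalg.eigvalsh(corr))[::-1]
        ev = np.clip(ev, 0, None)
        share = np.cumsum(ev) / ev.sum()
        total += int(np.searchsorted(share, var_explained) + 1)
    return max(total, 1)


def eigen_mt(results: pd.DataFrame, panel: GenotypePanel,
             donors: list[str] | None = None, block_size: int = 200,
             var_explained: float = 0.99) -> pd.DataFrame:
    """Per-gene corrected p: p_eigenMT = min(1, p_top * M_eff)."""
    sub = panel if donors is None else panel.subset_donors(donors)
    snp_index = {s: j for j, s in enumerate(sub.snp_ids)}
    out = []
    for gene, grp in results.groupby("gene", sort=False):
        js = [snp_index[s] for s in grp["snp"]]
        m_eff = effective_tests(sub.dosages[:, js], block_size, var_explained)
        p_top = grp["p"].min()
        out.append((gene, len(js), m_eff, min(1.0, p_top * m_eff)))
    return pd.DataFrame(out, columns=["gene", "m_tests", "m_eff", "p_eigenmt"])


def gene_fdr(gene_p: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Benjamini-Hochberg q-values on per-gene corrected p; eGene = q <= alpha."""
    out = gene_p.copy()
    _, q, _, _ = multipletests(out["p_eigenmt"].to_numpy(), method="fdr_bh")
    out["q"] = q
    out["egene"] = out["q"] <= alpha
    return out


def map_context(expr: pd.DataFrame, panel: GenotypePanel, tss: pd.DataFrame,
                covariates: CovariateSet | None = None, window: int = 100_000,
                alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-context scan: nominal results plus gene-level calls."""
    res = map_cis(expr, panel, tss, covariates, window=window)
    donors = [d for d in expr.columns if d in set(panel.donors)]
    genes = eigen_mt(res, panel, donors=donors)
    genes = gene_fdr(genes, alpha=alpha)
    return res, genes
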