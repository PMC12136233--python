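"""Locus- and gene-level comparisons of response vs. non-response eQTLs.

TSS-distance profiles, candidate cis-regulatory element (cCRE) category
enrichment by Fisher's exact test, cross-treatment combination of odds
ratios, gene-feature comparisons (TSS counts, cumulative enhancer length,
pLI constraint), and QQ-style GWAS signal enrichment.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio

CATEGORY_PRECEDENCE = ("PLS", "pELS", "dELS")


# ---------------------------------------------------------------------------
# TSS distances and category assignment
# ---------------------------------------------------------------------------

def tss_distance(pairs: pd.DataFrame, snps: pd.DataFrame, tss: pd.DataFrame,
                 bin_width: int = 5000) -> pd.DataFrame:
    """Signed distance snp_pos - tss_pos of each pair's own eGene.

    Positive = SNP downstream of (greater coordinate than) the TSS.
    ``bin_width`` controls the reporting histogram bin assignment.
    """
    pos = snps.set_index("snp")["pos"]
    t = tss.set_index("gene")["tss"]
    out = pairs.copy()
    known = out["gene"].isin(t.index) & out["snp"].isin(pos.index)
    skipped = int((~known).sum())
    if skipped:
        warnings.warn(f"{skipped} pairs skipped (missing TSS or SNP position)")
    out = out[known].copy()
    out["distance"] = pos.loc[out["snp"]].to_numpy() - t.loc[out["gene"]].to_numpy()
    out["distance_bin"] = (np.floor(out["distance"] / bin_width) * bin_width).astype(int)
    return out


def assign_categories(snps: pd.DataFrame, cres: pd.DataFrame) -> pd.Series:
    """Map each SNP to at most one cCRE category (precedence PLS > pELS > dELS).

    Intervals are BED half-open 0-based; SNP positions are 1-based, so a
    SNP at position p overlaps [start, end) when start < p <= end.
    """
    cats = pd.Series("none", index=snps["snp"].to_numpy())
    rank = {c: i for i, c in enumerate(CATEGORY_PRECEDENCE)}
    for chrom, sub in snps.groupby("chrom"):
        intervals = cres[cres["chrom"] == chrom]
        if intervals.empty:
            continue
        starts = intervals["start"].to_numpy()
        ends = intervals["end"].to_numpy()
        labels = intervals["category"].to_numpy()
        for snp, p in zip(sub["snp"], sub["pos"]):
            hit = (starts < p) & (p <= ends)
            if hit.any():
                found = [l for l in labels[hit] if l in rank]
                if found:
                    cats.loc[snp] = min(found, key=lambda l: rank[l])
                elif cats.loc[snp] == "none":
                    cats.loc[snp] = "other"
    return cats


# ---------------------------------------------------------------------------
# Fisher enrichment
# ---------------------------------------------------------------------------

def fisher_enrichment(snp_set: set, background: set, annotated: set
                      ) -> tuple[float, float, bool]:
    """2x2 Fisher test of a SNP set against a background for one category.

    Table: (in set x in category). Returns (odds ratio, two-sided p,
    zero_margin_flag); with a zero margin the conditional MLE is undefined
    and the Haldane-corrected sample odds ratio is reported instead.
    """
    snp_set = set(snp_set) & set(background)
    rest = set(background) - snp_set
    a = len(snp_set & annotated)
    b = len(snp_set - annotated)
    c = len(rest & annotated)
    d = len(rest - annotated)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    zero_margin = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if a * d == 0 or b * c == 0:
        or_hat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        flagged = True
    else:
        or_hat = _odds_ratio(table, kind="conditional").statistic
        flagged = zero_margin
    return float(or_hat), float(p), flagged


def cre_enrichment(snp_sets: dict[str, set], background: set,
                   categories: pd.Series) -> pd.DataFrame:
    """Fisher enrichment of each SNP set in each cCRE category."""
    rows = []
    for cat in list(CATEGORY_PRECEDENCE):
        annotated = set(categories.index[categories == cat])
        for name, sset in snp_sets.items():
            or_hat, p, flagged = fisher_enrichment(sset, background, annotated)
            rows.append({"set": name, "category": cat, "odds_ratio": or_hat,
                         "p": p, "zero_margin": flagged})
    return pd.DataFrame(rows)


def combine_across_treatments(ors: np.ndarray, ps: np.ndarray
                              ) -> tuple[float, float]:
    """OR_average (arithmetic mean) and P_combined (Fisher's method)."""
    ors = np.asarray(ors, float)
    ps = np.asarray(ps, float)
    if len(ors) == 1:
        return float(ors[0]), float(ps[0])
    tiny = np.finfo(float).tiny
    if (ps <= 0).any():
        warnings.warn("zero p-value clipped to smallest positive float")
        ps = np.clip(ps, tiny, 1.0)
    chi2 = -2.0 * np.log(ps).sum()
    p_comb = stats.chi2.sf(chi2, df=2 * len(ps))
    return float(ors.mean()), float(p_comb)


# ---------------------------------------------------------------------------
# gene-level features
# ---------------------------------------------------------------------------

def gene_feature_tests(features: pd.DataFrame, response_genes: set,
                       nonresponse_genes: set, pli_cut: float = 0.9,
                       n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Compare gene-level features between response and non-response eGenes.

    pLI: Fisher test on high-pLI (> 0.9) membership; continuous features
    (tss_count, enhancer length): two-sided rank-sum test, with group
    means and seeded bootstrap SDs.
    """
    if not response_genes or not nonresponse_genes:
        raise ValueError("both gene sets must be non-empty")
    rng = np.random.default_rng(seed)
    f = features.set_index("gene")
    resp = f.loc[f.index.intersection(list(response_genes))]
    nonr = f.loc[f.index.intersection(list(nonresponse_genes))]
    rows = []

    def boot_sd(x: np.ndarray, statistic) -> float:
        if len(x) == 0:
            return np.nan
        vals = [statistic(rng.choice(x, size=len(x), replace=True))
                for _ in range(n_boot)]
        return float(np.std(vals))

    for col in ("tss_count", "cumulative_enhancer_length"):
        if col not in f.columns:
            continue
        a, b = resp[col].dropna().to_numpy(), nonr[col].dropna().to_numpy()
        if np.array_equal(np.sort(a), np.sort(b)):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append({"feature": col, "test": "ranksum",
                     "response_mean": float(a.mean()),
                     "nonresponse_mean": float(b.mean()),
                     "response_sd": boot_sd(a, np.mean),
                     "nonresponse_sd": boot_sd(b, np.mean),
                     "statistic": np.nan, "p": p})
    if "pli" in f.columns:
        a_hi = int((resp["pli"] > pli_cut).sum())
        a_lo = int((resp["pli"] <= pli_cut).sum())
        b_hi = int((nonr["pli"] > pli_cut).sum())
        b_lo = int((nonr["pli"] <= pli_cut).sum())
        table = np.array([[a_hi, a_lo], [b_hi, b_lo]])
        or_hat, p = stats.fisher_exact(table, alternative="two-sided")
        frac_a = (resp["pli"] > pli_cut).to_numpy().astype(float)
        frac_b = (nonr["pli"] > pli_cut).to_numpy().astype(float)
        rows.append({"feature": "pli_gt_0.9", "test": "fisher",
                     "response_mean": float(frac_a.mean()),
                     "nonresponse_mean": float(frac_b.mean()),
                     "response_sd": boot_sd(frac_a, np.mean),
                     "nonresponse_sd": boot_sd(frac_b, np.mean),
                     "statistic": float(or_hat), "p": float(p)})
    return pd.DataFrame(rows)


def gene_set_fisher(test_genes: set, universe: set, category_genes: set
                    ) -> tuple[float, float]:
    """Generic gene-set enrichment Fisher test within a tested universe."""
    or_hat, p, _ = fisher_enrichment(test_genes, universe, set(category_genes))
    return or_hat, p


# ---------------------------------------------------------------------------
# QQ enrichment of GWAS signal
# ---------------------------------------------------------------------------

def qq_enrichment(gwas_p: pd.DataFrame, snp_categories: dict[str, set],
                  min_snps: int = 10) -> pd.DataFrame:
    """Observed vs. expected -log10 GWAS p quantiles per SNP category.

    Ties order deterministically by (p, snp id). The per-category summary
    is the mean observed - expected difference.
    """
    lut = gwas_p.set_index("snp")["p"]
    out = []
    for name, snps in snp_categories.items():
        present = sorted(s for s in snps if s in lut.index)
        if len(present) < min_snps:
            warnings.warn(f"category {name!r} has < {min_snps} SNPs; skipped")
            continue
        sub = pd.DataFrame({"snp": present, "p": lut.loc[present].to_numpy()})
        sub = sub.sort_values(["p", "snp"]).reset_index(drop=True)
        n = len(sub)
        expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
        observed = -np.log10(np.clip(sub["p"].to_numpy(), 1e-300, 1.0))
        out.append(pd.DataFrame({
            "category": name, "snp": sub["snp"], "expected": expected,
            "observed": observed}))
    if not out:
        return pd.DataFrame(columns=["category", "snp", "expected", "observed"])
    return pd.concat(out, ignore_index=True)


def qq_summary(qq: pd.DataFrame) -> pd.DataFrame:
    return (qq.assign(diff=qq["observed"] - qq["expected"])
            .groupby("category")["diff"].mean().rename("mean_obs_minus_exp")
            .reset_index())
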