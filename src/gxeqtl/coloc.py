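"""Two-trait Bayesian colocalization with Wakefield approximate Bayes factors.

Under a single causal variant per trait, every causal configuration in a
region of m SNPs is enumerated: the null; trait 1 alone at SNP i (prior
p1 per SNP); trait 2 alone at SNP j (p1); both traits at distinct SNPs
i != j (prior p1^2 (1 - pc) per ordered pair); and both traits sharing SNP
i (prior p1 * pc per SNP). Configuration likelihoods are products of
per-SNP Wakefield approximate Bayes factors and posteriors are normalized
in log space. PP_regional is the posterior mass on "both traits
associated" (shared + distinct); PP_alignment is the shared share of that
mass. The default priors are p1 = 1e-4 and conditional colocalization
prior pc = 0.025; a region is called colocalized when PP_regional > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist


@dataclass
class RegionSummary:
    """Per-SNP z and variance for the two traits in one region."""

    snps: list[str]
    z1: np.ndarray
    V1: np.ndarray   # se^2 of trait-1 effect estimates
    z2: np.ndarray
    V2: np.ndarray
    region: str = "region"

    def __post_init__(self) -> None:
        m = len(self.snps)
        if m < 2:
            raise ValueError("region must contain >= 2 SNPs")
        for arr in (self.z1, self.V1, self.z2, self.V2):
            if len(arr) != m:
                raise ValueError("summary arrays must match the SNP list")
            if not np.isfinite(arr).all():
                raise ValueError("z and V must be finite")
        if np.any(self.V1 <= 0) or np.any(self.V2 <= 0):
            raise ValueError("V must be positive")

    @classmethod
    def from_summary_stats(cls, eqtl: pd.DataFrame, gwas: pd.DataFrame,
                           region: str = "region") -> "RegionSummary":
        merged = eqtl.merge(gwas, on="snp", suffixes=("_1", "_2"))
        return cls(
            snps=merged["snp"].tolist(),
            z1=(merged["beta_1"] / merged["se_1"]).to_numpy(),
            V1=(merged["se_1"] ** 2).to_numpy(),
            z2=(merged["beta_2"] / merged["se_2"]).to_numpy(),
            V2=(merged["se_2"] ** 2).to_numpy(),
            region=region,
        )


@dataclass
class ColocResult:
    region: str
    pp_regional: float
    pp_alignment: float
    pp: float
    candidate_snp: str
    posteriors: dict
    colocalized: bool = False


def wakefield_labf(z: np.ndarray, V: np.ndarray, W: float = 0.15 ** 2
                   ) -> np.ndarray:
    """Log Wakefield approximate Bayes factor for one SNP association.

    labf = 0.5 log(1 - r) + 0.5 r z^2 with r = W / (V + W); the prior
    effect variance W defaults to 0.15^2 (quantitative traits).
    """
    z = np.asarray(z, float)
    V = np.asarray(V, float)
    if np.any(V <= 0):
        raise ValueError("V must be positive")
    r = W / (V + W)
    return 0.5 * np.log1p(-r) + 0.5 * r * z ** 2


def coloc_two_traits(region: RegionSummary, p1: float = 1e-4,
                     pc: float = 0.025, W: float = 0.15 ** 2) -> ColocResult:
    """Enumerate the five configuration classes and normalize in log space."""
    m = len(region.snps)
    if p1 * m >= 1:
        raise ValueError(f"p1 * n_snps = {p1 * m:.3g} >= 1: inconsistent prior")
    l1 = wakefield_labf(region.z1, region.V1, W)
    l2 = wakefield_labf(region.z2, region.V2, W)

    log_p1 = np.log(p1)
    # class log-masses (prior x likelihood), aggregated over configurations
    log_null = 0.0
    log_t1 = log_p1 + logsumexp(l1)
    log_t2 = log_p1 + logsumexp(l2)
    both = logsumexp(l1) + logsumexp(l2)           # sum over all (i, j)
    diag = logsumexp(l1 + l2)                      # sum over i == j
    with np.errstate(divide="ignore"):
        if diag >= both:                            # m == 1 style degeneracy
            log_offdiag = -np.inf
        else:
            log_offdiag = both + np.log1p(-np.exp(diag - both))
    log_distinct = 2 * log_p1 + np.log1p(-pc) + log_offdiag
    log_shared = log_p1 + np.log(pc) + diag

    logs = np.array([log_null, log_t1, log_t2, log_distinct, log_shared])
    total = logsumexp(logs)
    post = np.exp(logs - total)
    names = ["null", "trait1_only", "trait2_only", "both_distinct", "both_shared"]
    posteriors = dict(zip(names, post))

    pp_regional = posteriors["both_distinct"] + posteriors["both_shared"]
    denom = pp_regional
    pp_alignment = posteriors["both_shared"] / denom if denom > 0 else 0.0
    candidate = region.snps[int(np.argmax(l1 + l2))]
    return ColocResult(region=region.region, pp_regional=float(pp_regional),
                       pp_alignment=float(pp_alignment),
                       pp=float(pp_regional * pp_alignment),
                       candidate_snp=candidate, posteriors=posteriors)


def call_coloc(results: list[ColocResult], threshold: float = 0.5,
               use_product: bool = False) -> pd.DataFrame:
    """Flag colocalized regions: PP_regional > threshold (strict).

    ``use_product`` switches the rule to the full product
    PP_regional * PP_alignment.
    """
    rows = []
    for r in results:
        stat = r.pp if use_product else r.pp_regional
        r.colocalized = bool(stat > threshold)
        rows.append({"region": r.region, "pp_regional": r.pp_regional,
                     "pp_alignment": r.pp_alignment, "pp": r.pp,
                     "candidate_snp": r.candidate_snp,
                     "colocalized": r.colocalized})
    return pd.DataFrame(rows, columns=["region", "pp_regional", "pp_alignment",
                                       "pp", "candidate_snp", "colocalized"])


def coloc_rate_summary(calls: pd.DataFrame, classes: pd.Series,
                       conf: float = 0.95) -> pd.DataFrame:
    """Proportion of colocalized regions per eQTL class, with exact
    (Clopper-Pearson) binomial confidence intervals."""
    df = calls.copy()
    df["class"] = classes.reindex(df["region"]).to_numpy()
    rows = []
    for cls, grp in df.groupby("class", dropna=False):
        n = len(grp)
        k = int(grp["colocalized"].sum())
        if n == 0:
            rows.append({"class": cls, "n": 0, "colocalized": 0,
                         "proportion": np.nan, "ci_lo": np.nan, "ci_hi": np.nan})
            continue
        alpha = 1 - conf
        lo = beta_dist.ppf(alpha / 2, k, n - k + 1) if k > 0 else 0.0
        hi = beta_dist.ppf(1 - alpha / 2, k + 1, n - k) if k < n else 1.0
        rows.append({"class": cls, "n": n, "colocalized": k,
                     "proportion": k / n, "ci_lo": float(lo), "ci_hi": float(hi)})
    return pd.DataFrame(rows)
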