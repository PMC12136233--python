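"""Synthetic data generation with planted regulatory effects.

Emulates a heterogeneous differentiating culture (HDC) eQTL study design:
donors x treatment conditions x cell types, single cells with
negative-binomial counts, biallelic genotypes in Hardy-Weinberg
equilibrium, differentiation pseudotime on a subset of cells, candidate
cis-regulatory elements around gene TSSs, and GWAS summary statistics for
colocalization. Every planted effect is recorded in a machine-readable
truth table so downstream stages have a recovery target.

Genetic effects act on the log mean of cell-level counts:

    log mu = a_g + (beta + gamma_context + delta * tau) * G
             + b_sex * sex + b_pop * pop + u_donor

where G is the allelic dosage of the gene's causal SNP, gamma_context is
an additive context modulation (response eQTLs), delta is the
genotype-by-pseudotime slope (dynamic eQTLs), and u_donor is a per
donor-gene random intercept.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_CONDITIONS = ("control", "nicotine", "caffeine", "ethanol")

# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate a desk-scale version of the HDC design: donors with
    genotypes in HWE (MAF >= 0.05), one cell type observed under a control
    and three treatment arms, ~tens of cells per donor and context, and a
    differentiation trajectory covered by pseudotime in [0, 1].
    """

    n_donors: int = 50
    n_genes: int = 50
    n_snps_per_gene: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    contexts: tuple[tuple[str, str], ...] = tuple(
        ("progenitor", cond) for cond in DEFAULT_CONDITIONS
    )
    cells_per_donor_context: int = 20
    nb_dispersion: float = 10.0
    effect_grid: tuple[float, ...] = (0.5, 1.0)
    response_fraction: float = 0.2
    dynamic_fraction: float = 0.1
    seed: int = 0
    # secondary knobs -------------------------------------------------------
    ld_copy_prob: float = 0.3      # adjacent-SNP haplotype copying rate
    block_dropout: float = 0.0     # probability a donor x context block is absent
    trajectory_fraction: float = 1.0  # fraction of cells on the trajectory
    pseudotime_mixture: tuple[float, ...] | None = None  # Beta mixture weights
    baseline_log_mean: tuple[float, float] = (math.log(0.5), math.log(5.0))
    sex_effect: float = 0.1
    pop_effect: float = 0.1
    donor_sd: float = 0.1
    batch_effect: float = 0.05
    response_multiplier: float = 3.0  # fold change planted in treated arms
    dynamic_slope: float = 1.0        # delta, log-expression per allele per unit tau

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.05 <= lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within [0.05, 0.5], got {self.maf_range}")
        for name in ("response_fraction", "dynamic_fraction", "block_dropout",
                     "trajectory_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_donors < 4:
            raise ValueError("n_donors must be >= 4")
        if not self.contexts:
            raise ValueError("contexts must be non-empty")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GenotypePanel:
    """Donor x SNP dosage matrix with SNP coordinates and allele frequency."""

    donors: list[str]
    snps: pd.DataFrame  # columns: snp, chrom, pos (1-based), ref, alt, maf, gene
    dosages: np.ndarray  # shape (n_donors, n_snps), values in {0, 1, 2}
    sex: np.ndarray | None = None        # 0/1 per donor
    population: np.ndarray | None = None  # 0/1 per donor

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.donors), len(self.snps)):
            raise ValueError("dosage matrix shape does not match donors x snps")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in {0, 1, 2}")

    @property
    def snp_ids(self) -> np.ndarray:
        return self.snps["snp"].to_numpy()

    def dosage_of(self, snp: str) -> np.ndarray:
        j = self.snps.index[self.snps["snp"] == snp]
        if len(j) == 0:
            raise KeyError(f"unknown SNP {snp!r}")
        return self.dosages[:, j[0]]

    def subset_donors(self, donors: Sequence[str]) -> "GenotypePanel":
        idx = [self.donors.index(d) for d in donors]
        return GenotypePanel(
            donors=list(donors),
            snps=self.snps.copy(),
            dosages=self.dosages[idx],
            sex=None if self.sex is None else self.sex[idx],
            population=None if self.population is None else self.population[idx],
        )


@dataclass
class TruthTable:
    """Planted generator parameters and the derived response/dynamic flags.

    ``effects`` holds one row per (gene, context) with the realized additive
    genetic effect in that context; ``pairs`` holds the per-gene causal SNP,
    base effect and pseudotime slope delta.
    """

    pairs: pd.DataFrame    # gene, snp, base_effect, delta, is_response, is_dynamic
    effects: pd.DataFrame  # gene, snp, cell_type, condition, effect

    @staticmethod
    def recompute_flags(effects: pd.DataFrame, pairs: pd.DataFrame,
                        factor: float = 1.5) -> pd.DataFrame:
        """Re-derive is_response / is_dynamic from the stored parameters.

        A pair is a response pair when, within any cell type, the context
        effects change sign or the max/min magnitude ratio exceeds
        ``factor``; dynamic when delta != 0.
        """
        flags = []
        for gene, grp in effects.groupby("gene", sort=False):
            is_resp = False
            for _, sub in grp.groupby("cell_type", sort=False):
                e = sub["effect"].to_numpy()
                if np.any(e != 0):
                    if np.nanmax(e) > 0 and np.nanmin(e) < 0:
                        is_resp = True
                    else:
                        mags = np.abs(e)
                        lo = mags.min()
                        hi = mags.max()
                        if lo == 0 or hi / lo > factor:
                            is_resp = True
            flags.append((gene, is_resp))
        out = pairs.merge(pd.DataFrame(flags, columns=["gene", "is_response_rc"]),
                          on="gene", how="left")
        out["is_dynamic_rc"] = out["delta"] != 0
        return out


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def _homozygote_count(dosage_col: np.ndarray) -> int:
    return int(np.sum(dosage_col == 0) + np.sum(dosage_col == 2))


def passes_snp_filters(dosage_col: np.ndarray, min_maf: float = 0.05,
                       min_hom: int = 2) -> bool:
    """MAF >= 0.05 and at least 2 homozygote carriers (dosage 0 or 2)."""
    af = dosage_col.mean() / 2.0
    maf = min(af, 1.0 - af)
    return maf >= min_maf and _homozygote_count(dosage_col) >= min_hom


def simulate_genotypes(config: SimConfig, rng: np.random.Generator | None = None,
                       max_tries: int = 50) -> GenotypePanel:
    """Simulate a biallelic dosage panel in HWE with LD and the study filters.

    Per SNP an allele frequency p ~ Uniform(maf_range) is drawn; haplotypes
    are generated with adjacent-SNP copying at rate ``ld_copy_prob`` so
    nearby SNPs are correlated; dosage = sum of two haplotypes, i.e.
    Binomial(2, p) marginally. SNPs failing the MAF >= 0.05 or
    >= 2-homozygote filter are regenerated up to ``max_tries`` times and
    dropped otherwise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_donors
    rows = []
    cols = []
    for g in range(config.n_genes):
        gene = f"gene{g:04d}"
        chrom = "chr1"
        tss = 1_000_000 * (g + 1)
        positions = np.sort(rng.integers(tss - 100_000, tss + 100_000,
                                         size=config.n_snps_per_gene))
        prev_hap = None
        for j, pos in enumerate(positions):
            for attempt in range(max_tries):
                p = rng.uniform(*config.maf_range)
                fresh = (rng.random((n, 2)) < p).astype(np.int8)
                if prev_hap is not None and config.ld_copy_prob > 0:
                    copy = rng.random((n, 2)) < config.ld_copy_prob
                    hap = np.where(copy, prev_hap, fresh)
                else:
                    hap = fresh
                dosage = hap.sum(axis=1)
                if passes_snp_filters(dosage):
                    prev_hap = hap
                    cols.append(dosage)
                    rows.append({
                        "snp": f"{chrom}:{pos}:A_G_{g}_{j}",
                        "chrom": chrom,
                        "pos": int(pos),
                        "ref": "A",
                        "alt": "G",
                        "maf": float(min(dosage.mean() / 2, 1 - dosage.mean() / 2)),
                        "gene": gene,
                    })
                    break
            # else: dropped after max_tries (recorded implicitly by absence)
    if not rows:
        raise ValueError(
            "no SNP passed the MAF >= 0.05 / >= 2 homozygotes filters; "
            "panel is empty")
    snps = pd.DataFrame(rows).reset_index(drop=True)
    dosages = np.column_stack(cols).astype(np.int8)
    donors = [f"donor{i:03d}" for i in range(n)]
    sex = rng.integers(0, 2, size=n).astype(np.int8)
    population = (np.arange(n) >= n // 2).astype(np.int8)
    return GenotypePanel(donors=donors, snps=snps, dosages=dosages,
                         sex=sex, population=population)


def gene_tss_table(panel: GenotypePanel) -> pd.DataFrame:
    """TSS coordinates implied by the simulated gene layout (1-based)."""
    genes = panel.snps["gene"].unique()
    rows = [{"gene": g, "chrom": "chr1",
             "tss": 1_000_000 * (int(g.replace("gene", "")) + 1)} for g in genes]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth table
# ---------------------------------------------------------------------------

def make_truth(config: SimConfig, panel: GenotypePanel,
               rng: np.random.Generator | None = None,
               dynamic_condition: str | None = None) -> TruthTable:
    """Assign each gene a causal cis-SNP and planted effect structure.

    With probability ``response_fraction`` the gene's effect is modulated in
    the treated arms (multiplied by ``response_multiplier`` or sign-flipped);
    with probability ``dynamic_fraction`` the effect carries a
    genotype-by-pseudotime slope delta; otherwise the effect is constant
    across contexts. A zero base effect (null gene) occurs for genes not
    assigned an effect from ``effect_grid``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    genes = list(panel.snps["gene"].unique())
    cell_types = sorted({ct for ct, _ in config.contexts})
    conditions = [cond for _, cond in config.contexts]
    pair_rows = []
    eff_rows = []
    for gene in genes:
        snp_pool = panel.snps.loc[panel.snps["gene"] == gene, "snp"].to_numpy()
        snp = str(rng.choice(snp_pool))
        base = float(rng.choice(config.effect_grid)) * (1 if rng.random() < 0.5 else -1)
        u = rng.random()
        is_response = u < config.response_fraction
        is_dynamic = config.response_fraction <= u < (
            config.response_fraction + config.dynamic_fraction)
        delta = float(config.dynamic_slope * np.sign(base)) if is_dynamic else 0.0
        sign_flip = is_response and rng.random() < 0.3
        for ct, cond in config.contexts:
            if not is_response or cond == "control":
                effect = base
            elif sign_flip:
                effect = -base
            else:
                effect = base * config.response_multiplier
            eff_rows.append({"gene": gene, "snp": snp, "cell_type": ct,
                             "condition": cond, "effect": effect})
        pair_rows.append({"gene": gene, "snp": snp, "base_effect": base,
                          "delta": delta,
                          "delta_condition": dynamic_condition or "",
                          "is_response": bool(is_response),
                          "is_dynamic": bool(is_dynamic)})
    return TruthTable(pairs=pd.DataFrame(pair_rows), effects=pd.DataFrame(eff_rows))


# ---------------------------------------------------------------------------
# cells and counts
# ---------------------------------------------------------------------------

def simulate_cells(config: SimConfig, panel: GenotypePanel,
                   rng: np.random.Generator | None = None,
                   dropout: float | None = None) -> pd.DataFrame:
    """Cell-level metadata table: donor, condition, cell type, pseudotime.

    Each donor contributes ``cells_per_donor_context`` cells per
    (cell type, condition) context; whole donor x context blocks are absent
    with probability ``dropout`` to exercise missing-data paths. Cells on
    the trajectory receive pseudotime tau in [0, 1], uniform by default or
    from a Beta mixture when ``pseudotime_mixture`` is set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    if dropout is None:
        dropout = config.block_dropout
    rows = []
    cid = 0
    for d_idx, donor in enumerate(panel.donors):
        for ct, cond in config.contexts:
            if dropout > 0 and rng.random() < dropout:
                continue
            k = config.cells_per_donor_context
            on_traj = rng.random(k) < config.trajectory_fraction
            if config.pseudotime_mixture is None:
                tau = rng.uniform(0.0, 1.0, size=k)
            else:
                w = np.asarray(config.pseudotime_mixture, float)
                w = w / w.sum()
                comp = rng.choice(len(w), size=k, p=w)
                # components are Beta(1,3), Beta(3,1), Beta(2,2), ...
                shapes = [(1, 3), (3, 1), (2, 2), (5, 5)]
                tau = np.array([rng.beta(*shapes[c % len(shapes)]) for c in comp])
            batch = "batch1" if d_idx < len(panel.donors) // 2 else "batch2"
            for i in range(k):
                rows.append({
                    "cell_id": f"cell{cid:07d}",
                    "donor": donor,
                    "condition": cond,
                    "cell_type": ct,
                    "batch": batch,
                    "trajectory": "traj1" if on_traj[i] else "",
                    "pseudotime": float(tau[i]) if on_traj[i] else np.nan,
                    "n_genes_detected": int(rng.integers(800, 9000)),
                    "pct_mito": float(rng.uniform(0, 20)),
                })
                cid += 1
    return pd.DataFrame(rows)


def simulate_counts(cells: pd.DataFrame, panel: GenotypePanel, truth: TruthTable,
                    config: SimConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Gene x cell negative-binomial count matrix with planted effects.

    Counts are generated at cell level so pseudobulk aggregation and the
    cell-count filters are exercised end to end. The NB dispersion is
    ``config.nb_dispersion`` (size parameter; variance = mu + mu^2/size).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    unknown = set(cells["donor"]) - set(panel.donors)
    if unknown:
        raise ValueError(f"cells reference donors absent from panel: {sorted(unknown)[:5]}")
    donor_idx = np.array([panel.donors.index(d) for d in cells["donor"]])
    genes = truth.pairs["gene"].to_numpy()
    n_genes, n_cells = len(genes), len(cells)

    base_rng = np.random.default_rng(config.seed + 4)
    a_g = base_rng.uniform(*config.baseline_log_mean, size=n_genes)
    u = base_rng.normal(0.0, config.donor_sd, size=(n_genes, len(panel.donors)))

    snp_col = np.array([int(np.where(panel.snp_ids == s)[0][0])
                        for s in truth.pairs["snp"]])
    G = panel.dosages[:, snp_col].T.astype(float)          # genes x donors
    G_cell = G[:, donor_idx]                               # genes x cells

    # per-(gene, context) effect lookup
    ctx_key = (cells["cell_type"] + "|" + cells["condition"]).to_numpy()
    eff = truth.effects.copy()
    eff["ctx"] = eff["cell_type"] + "|" + eff["condition"]
    eff_wide = eff.pivot(index="gene", columns="ctx", values="effect").loc[genes]
    ctx_codes, ctx_uniq = pd.factorize(ctx_key)
    eff_mat = eff_wide[ctx_uniq].to_numpy()                # genes x uniq contexts
    effect_cell = eff_mat[:, ctx_codes]                    # genes x cells

    tau = np.nan_to_num(cells["pseudotime"].to_numpy(), nan=0.0)
    delta = truth.pairs["delta"].to_numpy()[:, None].astype(float)
    if "delta_condition" in truth.pairs.columns:
        # a non-empty delta_condition restricts the pseudotime slope to
        # cells of that condition (treatment-only dynamic effects)
        dcond = truth.pairs["delta_condition"].fillna("").to_numpy()
        cond_cell = cells["condition"].to_numpy()
        active = np.ones((n_genes, n_cells))
        for gi, dc in enumerate(dcond):
            if dc:
                active[gi] = (cond_cell == dc).astype(float)
        delta = delta * active
    sex_cell = panel.sex[donor_idx][None, :]
    pop_cell = panel.population[donor_idx][None, :]
    batch_cell = (cells["batch"] == "batch2").to_numpy(int)[None, :]

    log_mu = (a_g[:, None]
              + (effect_cell + delta * tau[None, :]) * G_cell
              + config.sex_effect * sex_cell
              + config.pop_effect * pop_cell
              + config.batch_effect * batch_cell
              + u[:, donor_idx])
    mu = np.exp(log_mu)
    size = config.nb_dispersion
    if np.isinf(size):
        counts = rng.poisson(mu)
    else:
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    return pd.DataFrame(counts, index=genes, columns=cells["cell_id"].to_numpy())


# ---------------------------------------------------------------------------
# cis-regulatory elements
# ---------------------------------------------------------------------------

def categorize_tss_distance(d: float) -> str:
    """cCRE category from center-to-TSS distance: promoter-like within
    200 bp, proximal enhancer within 2 kb (closed boundary), distal beyond."""
    if d <= 200:
        return "PLS"
    if d <= 2000:
        return "pELS"
    return "dELS"


def simulate_cres(gene_tss: pd.DataFrame, rng: np.random.Generator | None = None,
                  n_background: int = 200, width: int = 300,
                  enrichment_spec: dict | None = None, seed: int = 0) -> pd.DataFrame:
    """BED-style cCRE intervals labeled {PLS, pELS, dELS, other}.

    Labels follow the distance rules: promoter-like (PLS) when the interval
    center is within 200 bp of a TSS, TSS-proximal enhancer (pELS) within
    2 kb (closed boundary, <= 2000 bp), TSS-distal enhancer (dELS) beyond.
    ``enrichment_spec`` maps category -> list of SNP positions to cover with
    an interval of that category (planted enrichment). Intervals are BED
    half-open, 0-based; identical duplicates are removed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    tss_pos = gene_tss.set_index("gene")["tss"]
    rows = []

    def categorize(center: float, chrom: str) -> str:
        return categorize_tss_distance(np.abs(tss_pos.to_numpy() - center).min())

    for _, g in gene_tss.iterrows():
        tss = g["tss"]
        # one promoter element, a proximal and a couple of distal enhancers
        for offset in (0, 1500, -5000, 20000):
            center = tss + offset
            start = int(center - width // 2)
            rows.append({"chrom": g["chrom"], "start": start, "end": start + width,
                         "category": categorize(center, g["chrom"])})
    span = (int(gene_tss["tss"].min()) - 200_000, int(gene_tss["tss"].max()) + 200_000)
    for _ in range(n_background):
        center = int(rng.integers(*span))
        start = center - width // 2
        rows.append({"chrom": "chr1", "start": start, "end": start + width,
                     "category": categorize(center, "chr1")})
    if enrichment_spec:
        for category, positions in enrichment_spec.items():
            for pos in positions:
                start = int(pos) - width // 2
                rows.append({"chrom": "chr1", "start": start, "end": start + width,
                             "category": category})
    out = pd.DataFrame(rows).drop_duplicates().reset_index(drop=True)
    return out.sort_values(["chrom", "start"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# GWAS summary statistics
# ---------------------------------------------------------------------------

def simulate_gwas(panel: GenotypePanel, snps: Sequence[str], mode: str,
                  causal_snp: str | None = None, beta: float = 0.3,
                  n_gwas: int = 2000, rng: np.random.Generator | None = None,
                  seed: int = 0, ld_copy_prob: float | None = None) -> pd.DataFrame:
    """Per-SNP GWAS summary statistics from an explicit causal model.

    A cohort of ``n_gwas`` individuals is simulated with the same
    haplotype-copying LD process as the panel (allele frequencies taken
    from the panel MAFs); the quantitative trait is
    beta * G_causal + N(0, 1). Marginal per-SNP OLS gives (beta, se, p).

    mode: 'shared' (causal SNP = ``causal_snp``), 'distinct' (a different
    SNP in the region), or 'null' (no causal SNP).
    """
    if mode not in {"shared", "distinct", "null"}:
        raise ValueError(f"unknown mode {mode!r}")
    if len(snps) < 2:
        raise ValueError("region must contain >= 2 SNPs")
    if rng is None:
        rng = np.random.default_rng(seed)
    sub = panel.snps.set_index("snp").loc[list(snps)]
    freqs = sub["maf"].to_numpy()
    copy_prob = 0.3 if ld_copy_prob is None else ld_copy_prob
    n_snps = len(snps)
    hap = np.empty((n_gwas, 2, n_snps), dtype=np.int8)
    hap[:, :, 0] = rng.random((n_gwas, 2)) < freqs[0]
    for j in range(1, n_snps):
        fresh = (rng.random((n_gwas, 2)) < freqs[j]).astype(np.int8)
        copy = rng.random((n_gwas, 2)) < copy_prob
        hap[:, :, j] = np.where(copy, hap[:, :, j - 1], fresh)
    G = hap.sum(axis=1).astype(float)  # n_gwas x n_snps

    snps = list(snps)
    if mode == "null":
        y = rng.normal(size=n_gwas)
    else:
        if mode == "shared":
            if causal_snp is None:
                raise ValueError("shared mode requires causal_snp")
            c = snps.index(causal_snp)
        else:
            pool = [j for j, s in enumerate(snps) if s != causal_snp]
            c = int(rng.choice(pool))
        y = beta * G[:, c] + rng.normal(size=n_gwas)

    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    ss = (Gc ** 2).sum(axis=0)
    ss[ss == 0] = np.nan
    bhat = Gc.T @ yc / ss
    resid_var = np.array([
        np.sum((yc - bhat[j] * Gc[:, j]) ** 2) / (n_gwas - 2) for j in range(n_snps)])
    se = np.sqrt(resid_var / ss)
    from scipy import stats
    t = bhat / se
    p = 2 * stats.t.sf(np.abs(t), df=n_gwas - 2)
    return pd.DataFrame({
        "snp": snps,
        "chrom": sub["chrom"].to_numpy(),
        "pos": sub["pos"].to_numpy(),
        "beta": bhat,
        "se": se,
        "p": p,
        "n": n_gwas,
    })


# ---------------------------------------------------------------------------
# file export (flat text formats only)
# ---------------------------------------------------------------------------

def write_dosage_tsv(panel: GenotypePanel, path) -> None:
    df = pd.DataFrame(panel.dosages.T, index=panel.snp_ids, columns=panel.donors)
    df.index.name = "snp"
    df.to_csv(path, sep="\t")


def read_dosage_tsv(path, snp_table: pd.DataFrame | None = None) -> GenotypePanel:
    """Load a donor x SNP panel from a dosage TSV written by this module."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    dosages = df.to_numpy().T.astype(np.int8)
    if snp_table is None:
        snps = []
        for s in df.index:
            chrom, pos = s.split(":")[:2]
            snps.append({"snp": s, "chrom": chrom, "pos": int(pos),
                         "ref": "A", "alt": "G",
                         "maf": np.nan, "gene": ""})
        snp_table = pd.DataFrame(snps)
    snp_table = snp_table.copy()
    af = dosages.mean(axis=0) / 2
    snp_table["maf"] = np.minimum(af, 1 - af)
    return GenotypePanel(donors=list(df.columns), snps=snp_table,
                         dosages=dosages)


def read_vcf(path) -> GenotypePanel:
    """Load a biallelic VCF into a dosage panel (cyvcf2)."""
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    donors = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        gts = np.asarray(var.gt_types)  # 0=hom-ref, 1=het, 3=hom-alt
        dosage = np.where(gts == 3, 2, np.where(gts == 1, 1, 0)).astype(np.int8)
        cols.append(dosage)
        af = dosage.mean() / 2
        rows.append({"snp": var.ID or f"{var.CHROM}:{var.POS}",
                     "chrom": var.CHROM, "pos": var.POS,
                     "ref": var.REF, "alt": var.ALT[0] if var.ALT else ".",
                     "maf": float(min(af, 1 - af)), "gene": ""})
    return GenotypePanel(donors=donors, snps=pd.DataFrame(rows),
                         dosages=np.column_stack(cols))


def write_counts_mtx(counts: pd.DataFrame, out_dir) -> None:
    """Counts as MatrixMarket text plus gene/cell sidecar TSVs."""
    from pathlib import Path

    from scipy import io as spio
    from scipy import sparse
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "counts.mtx", sparse.csr_matrix(counts.to_numpy()))
    pd.Series(counts.index, name="gene").to_csv(out / "genes.tsv", sep="\t",
                                                index=False)
    pd.Series(counts.columns, name="cell_id").to_csv(out / "cells_index.tsv",
                                                     sep="\t", index=False)


def write_vcf(panel: GenotypePanel, path) -> None:
    """Minimal VCF 4.2 with GT fields derived from dosage (unphased)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=gxeqtl-simgen\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=chr1>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.donors) + "\n")
        for j, row in panel.snps.iterrows():
            gts = "\t".join(gt_map[int(d)] for d in panel.dosages[:, j])
            fh.write(f"{row['chrom']}\t{row['pos']}\t{row['snp']}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")


def write_bed(cres: pd.DataFrame, path) -> None:
    cres[["chrom", "start", "end", "category"]].to_csv(
        path, sep="\t", header=False, index=False)


def simulate_all(config: SimConfig) -> dict:
    """Run the full generator; returns panel, cells, counts, truth, tss, cres."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_genotypes(config, rng=np.random.default_rng(config.seed))
    truth = make_truth(config, panel)
    cells = simulate_cells(config, panel)
    counts = simulate_counts(cells, panel, truth, config)
    tss = gene_tss_table(panel)
    cres = simulate_cres(tss, seed=config.seed + 5)
    return {"panel": panel, "truth": truth, "cells": cells, "counts": counts,
            "tss": tss, "cres": cres}
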