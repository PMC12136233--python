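"""Pseudobulk aggregation, filtering, TMM normalization and rank transforms.

Cell-level counts are summed within samples (donor x condition x cell type,
or donor x pseudotime bin), filtered with the study's cell/donor/gene
thresholds, scaled with trimmed-mean-of-M-values (TMM) factors, log
transformed, and inverse normal transformed across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------


@dataclass
class PseudobulkMatrix:
    counts: pd.DataFrame          # genes x samples, raw aggregated counts
    samples: pd.DataFrame         # per-sample metadata incl. n_cells
    expression: pd.DataFrame | None = None  # normalized (log / INT) matrix
    tmm: pd.Series | None = None  # per-sample scaling factor
    filter_report: dict = field(default_factory=dict)

    def copy(self) -> "PseudobulkMatrix":
        return PseudobulkMatrix(
            counts=self.counts.copy(),
            samples=self.samples.copy(),
            expression=None if self.expression is None else self.expression.copy(),
            tmm=None if self.tmm is None else self.tmm.copy(),
            filter_report=dict(self.filter_report),
        )


@dataclass
class PseudotimeBinning:
    trajectory: str
    bins: pd.DataFrame      # bin, tau_lo, tau_hi, n_cells, n_donors, tau_median
    cell_bins: pd.Series    # cell_id -> bin label


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

def aggregate(counts: pd.DataFrame, cells: pd.DataFrame,
              group_keys: list[str]) -> PseudobulkMatrix:
    """Sum gene counts over cells sharing ``group_keys``; empty groups absent."""
    missing = [k for k in group_keys if k not in cells.columns]
    if missing:
        raise KeyError(f"group keys absent from cell metadata: {missing}")
    cells = cells.set_index("cell_id").loc[counts.columns].reset_index()
    sample_id = cells[group_keys].astype(str).agg("|".join, axis=1).to_numpy()
    codes, uniq = pd.factorize(sample_id)
    mat = np.zeros((counts.shape[0], len(uniq)), dtype=np.int64)
    np.add.at(mat.T, codes, counts.to_numpy().T)
    agg = pd.DataFrame(mat, index=counts.index, columns=uniq)
    meta_rows = []
    for u in uniq:
        sel = cells.loc[sample_id == u]
        row = {k: sel.iloc[0][k] for k in group_keys}
        row["sample"] = u
        row["n_cells"] = len(sel)
        meta_rows.append(row)
    samples = pd.DataFrame(meta_rows).set_index("sample")
    return PseudobulkMatrix(counts=agg, samples=samples)


def nonzero_cells_per_gene(counts: pd.DataFrame, cells: pd.DataFrame,
                           by: str) -> pd.DataFrame:
    """Per gene x level-of-``by``: number of cells with a nonzero count."""
    cells = cells.set_index("cell_id").loc[counts.columns]
    codes, uniq = pd.factorize(cells[by].to_numpy())
    nz = counts.to_numpy() > 0
    out = np.zeros((counts.shape[0], len(uniq)), dtype=np.int64)
    np.add.at(out.T, codes, nz.T)
    return pd.DataFrame(out, index=counts.index, columns=uniq)


def filter_eqtl(pb: PseudobulkMatrix, counts: pd.DataFrame | None = None,
                cells: pd.DataFrame | None = None,
                min_cells_per_sample: int = 3,
                min_donors_per_celltype: int = 10,
                min_nonzero_cells_per_condition: int = 5,
                min_donors_with_reads: int = 2,
                min_reads: int = 3) -> PseudobulkMatrix:
    """Apply the eQTL-stage sample and gene filters.

    Samples with fewer than 3 cells are removed; cell types kept only when
    >= 10 donors remain; genes kept only with >= 5 cells with nonzero reads
    in every condition (requires the cell-level matrix) and >= 2 donors
    with >= 3 aggregated reads. A per-rule removal report is attached.
    """
    report: dict[str, int] = {}
    out = pb.copy()

    keep = out.samples["n_cells"] >= min_cells_per_sample
    report["samples_too_few_cells"] = int((~keep).sum())
    out.samples = out.samples.loc[keep]
    out.counts = out.counts.loc[:, out.samples.index]

    if "cell_type" in out.samples.columns and "donor" in out.samples.columns:
        donors_per_ct = out.samples.groupby("cell_type")["donor"].nunique()
        bad_ct = donors_per_ct[donors_per_ct < min_donors_per_celltype].index
        report["cell_types_too_few_donors"] = len(bad_ct)
        keep = ~out.samples["cell_type"].isin(bad_ct)
        out.samples = out.samples.loc[keep]
        out.counts = out.counts.loc[:, out.samples.index]

    gene_keep = pd.Series(True, index=out.counts.index)
    if counts is not None and cells is not None and "condition" in cells.columns:
        cells_used = cells[cells["cell_id"].isin(counts.columns)]
        nz = nonzero_cells_per_gene(counts[cells_used["cell_id"]], cells_used,
                                    by="condition")
        gene_keep &= (nz >= min_nonzero_cells_per_condition).all(axis=1)
    report["genes_failing_nonzero_cells"] = int((~gene_keep).sum())

    if "donor" in out.samples.columns:
        donor_codes, donor_uniq = pd.factorize(out.samples["donor"].to_numpy())
        per_donor = np.zeros((out.counts.shape[0], len(donor_uniq)))
        np.add.at(per_donor.T, donor_codes, out.counts.to_numpy().T)
        enough = (per_donor >= min_reads).sum(axis=1) >= min_donors_with_reads
        before = gene_keep.sum()
        gene_keep &= pd.Series(enough, index=out.counts.index)
        report["genes_failing_donor_reads"] = int(before - gene_keep.sum())

    out.counts = out.counts.loc[gene_keep]
    if out.counts.shape[0] == 0:
        raise ValueError("all genes removed by the eQTL-stage gene filters")
    out.filter_report = report
    return out


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, logratio_trim: float = 0.30,
              sum_trim: float = 0.05) -> float:
    """TMM factor of one sample against the reference.

    Doubly-positive genes only; M = log2 ratio of library-scaled
    proportions, A = average log2 abundance; trim 30% of M tails and 5% of
    A tails; factor = 2 ** (precision-weighted mean of remaining M).
    """
    n_obs, n_ref = obs.sum(), ref.sum()
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        warnings.warn("sample shares no positive genes with reference; factor 1")
        return 1.0
    o, r = obs[pos].astype(float), ref[pos].astype(float)
    p_o, p_r = o / n_obs, r / n_ref
    M = np.log2(p_o / p_r)
    A = 0.5 * np.log2(p_o * p_r)
    w = (n_obs - o) / (n_obs * o) + (n_ref - r) / (n_ref * r)
    n = len(M)
    lo_m = int(np.floor(n * logratio_trim)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * sum_trim)) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(M, method="ordinal")
    rank_a = stats.rankdata(A, method="ordinal")
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any() or not np.isfinite(M[keep]).all():
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, reference: str | None = None) -> pd.Series:
    """Per-sample TMM scaling factors, normalized to geometric mean 1.

    The reference sample is the one whose upper-quartile (of library-scaled
    counts) is closest to the mean upper-quartile, unless given explicitly.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires >= 2 samples")
    lib = counts.sum(axis=0).to_numpy().astype(float)
    if (lib == 0).any():
        raise ValueError("zero library size")
    if reference is None:
        uq = np.array([np.quantile(counts.iloc[:, j].to_numpy() / lib[j], 0.75)
                       for j in range(counts.shape[1])])
        ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_j = counts.columns.get_loc(reference)
    ref = counts.iloc[:, ref_j].to_numpy()
    raw = np.array([_tmm_pair(counts.iloc[:, j].to_numpy(), ref)
                    for j in range(counts.shape[1])])
    raw = raw / np.exp(np.mean(np.log(raw)))
    return pd.Series(raw, index=counts.columns, name="tmm")


def log_normalize(counts: pd.DataFrame, tmm: pd.Series,
                  pseudocount: float = 0.5, scale: float = 1e4) -> pd.DataFrame:
    """Natural-log expression after library-size x TMM scaling."""
    eff_lib = counts.sum(axis=0) * tmm
    return np.log(counts / eff_lib * scale + pseudocount)


# ---------------------------------------------------------------------------
# inverse normal transform
# ---------------------------------------------------------------------------

def inverse_normal(row: np.ndarray, c: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform with the Blom offset c = 3/8.

    value_i = Phi^-1((rank_i - c) / (n - 2c + 1)); ties get average ranks.
    A constant row maps to all zeros (with a warning).
    """
    x = np.asarray(row, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("inverse normal transform requires >= 3 samples")
    if np.all(x == x[0]):
        warnings.warn("constant row in inverse normal transform; returning zeros")
        return np.zeros(n)
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - c) / (n - 2 * c + 1))


def int_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Row-wise inverse normal transform of a genes x samples matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = np.vstack([inverse_normal(expr.iloc[i].to_numpy())
                         for i in range(expr.shape[0])])
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def normalize(pb: PseudobulkMatrix, transform: str = "int") -> PseudobulkMatrix:
    """TMM + log, optionally followed by the inverse normal transform."""
    out = pb.copy()
    out.tmm = tmm_factors(out.counts)
    logx = log_normalize(out.counts, out.tmm)
    out.expression = int_matrix(logx) if transform == "int" else logx
    return out


# ---------------------------------------------------------------------------
# pseudotime binning
# ---------------------------------------------------------------------------

def _merge_sweep(bins: list[dict], too_few) -> list[dict]:
    """Left-to-right merge of deficient bins into the next; last into prev."""
    changed = True
    while changed and len(bins) > 1:
        changed = False
        for i in range(len(bins) - 1):
            if too_few(bins[i]):
                nxt = bins[i + 1]
                nxt["cells"] = bins[i]["cells"] + nxt["cells"]
                nxt["tau_lo"] = bins[i]["tau_lo"]
                del bins[i]
                changed = True
                break
        else:
            if too_few(bins[-1]):
                prev = bins[-2]
                prev["cells"] = prev["cells"] + bins[-1]["cells"]
                prev["tau_hi"] = bins[-1]["tau_hi"]
                del bins[-1]
                changed = True
    return bins


def bin_pseudotime(cells: pd.DataFrame, trajectory: str, n_bins: int = 15,
                   min_cells: int = 100, min_donors: int = 20,
                   min_cells_per_donor: int = 5) -> PseudotimeBinning:
    """Equal-range pseudotime bins with the study's merge rules.

    (1) donors with < 5 cells on the trajectory are removed; (2) ``n_bins``
    bins of equal pseudotime range; (3) bins with fewer than
    min(``min_cells``, total/n_bins) cells are merged left-to-right into
    the next bin (a deficient final bin merges into the previous one);
    (4) the same sweep enforces >= ``min_donors`` donors per bin. Bin
    medians are recomputed after merging.
    """
    tc = cells[(cells["trajectory"] == trajectory) & cells["pseudotime"].notna()].copy()
    if tc.empty:
        raise ValueError(f"no cells on trajectory {trajectory!r}")
    donor_counts = tc.groupby("donor")["cell_id"].count()
    good_donors = donor_counts[donor_counts >= min_cells_per_donor].index
    tc = tc[tc["donor"].isin(good_donors)]
    if tc["donor"].nunique() < min_donors:
        raise ValueError(
            f"trajectory {trajectory!r}: fewer than {min_donors} donors after "
            "the per-donor cell filter")

    tau = tc["pseudotime"].to_numpy()
    lo, hi = tau.min(), tau.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.searchsorted(edges, tau, side="right") - 1, 0, n_bins - 1)
    bins = []
    for b in range(n_bins):
        members = tc.index[idx == b].tolist()
        bins.append({"tau_lo": edges[b], "tau_hi": edges[b + 1], "cells": members})
    bins = [b for b in bins if len(b["cells"]) > 0] or bins[:1]

    cell_thresh = min(min_cells, len(tc) // n_bins)
    bins = _merge_sweep(bins, lambda b: len(b["cells"]) < cell_thresh)
    bins = _merge_sweep(
        bins, lambda b: tc.loc[b["cells"], "donor"].nunique() < min_donors)

    if len(bins) < 2:
        raise ValueError(
            f"trajectory {trajectory!r}: fewer than 2 bins after merging")

    rows = []
    cell_bin = pd.Series(index=tc["cell_id"].to_numpy(), dtype=object)
    for b, binfo in enumerate(bins):
        sub = tc.loc[binfo["cells"]]
        label = f"bin{b:02d}"
        rows.append({
            "bin": label,
            "tau_lo": binfo["tau_lo"],
            "tau_hi": binfo["tau_hi"],
            "n_cells": len(sub),
            "n_donors": sub["donor"].nunique(),
            "tau_median": float(sub["pseudotime"].median()),
        })
        cell_bin.loc[sub["cell_id"].to_numpy()] = label
    bins_df = pd.DataFrame(rows)
    if not bins_df["tau_median"].is_monotonic_increasing:
        # equal-range bins on sorted tau: medians are increasing by
        # construction; guard against pathological duplicates
        warnings.warn("bin medians not strictly increasing")
    return PseudotimeBinning(trajectory=trajectory, bins=bins_df, cell_bins=cell_bin)


def aggregate_bins(counts: pd.DataFrame, cells: pd.DataFrame,
                   binning: PseudotimeBinning) -> PseudobulkMatrix:
    """Donor x pseudotime-bin pseudobulk for one trajectory."""
    tc = cells[cells["cell_id"].isin(binning.cell_bins.index)].copy()
    tc["bin"] = binning.cell_bins.loc[tc["cell_id"]].to_numpy()
    pb = aggregate(counts[tc["cell_id"]], tc, ["donor", "bin"])
    tau = binning.bins.set_index("bin")["tau_median"]
    pb.samples["tau"] = tau.loc[pb.samples["bin"]].to_numpy()
    return pb


def normalize_bins(pb: PseudobulkMatrix, transform: str = "int") -> PseudobulkMatrix:
    """Normalize bin-level pseudobulk within each bin across donors."""
    out = pb.copy()
    tmm_all = pd.Series(1.0, index=out.counts.columns)
    expr = pd.DataFrame(np.nan, index=out.counts.index, columns=out.counts.columns)
    for b, sub in out.samples.groupby("bin"):
        cols = sub.index
        if len(cols) < 2:
            continue
        tmm = tmm_factors(out.counts[cols])
        tmm_all.loc[cols] = tmm
        logx = log_normalize(out.counts[cols], tmm)
        expr[cols] = int_matrix(logx) if transform == "int" else logx
    out.tmm = tmm_all
    out.expression = expr
    return out
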