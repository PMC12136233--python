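"""Response vs. standard (non-response) eQTL calls from posterior effects.

A gene-SNP pair is a significant eQTL in a cell type and treatment when its
lfsr is below 0.1 in the control or the treatment context. Among significant
pairs, a response eQTL changes effect size by more than a factor of 1.5
between control and treatment (sign flips count as response regardless of
the ratio); otherwise the pair is a standard, non-response eQTL. A response
eGene is a gene with at least one response eQTL; a non-response eGene has at
least one eQTL but no response eQTL.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .mash import PosteriorEffects


def _context_name(cell_type: str, condition: str) -> str:
    return f"{cell_type}|{condition}"


def call_response(post: PosteriorEffects, lfsr_cut: float = 0.1,
                  factor: float = 1.5, control: str = "control") -> pd.DataFrame:
    """Classify each pair x cell type x treatment.

    Contexts are named ``cell_type|condition``; every treatment context must
    have a matching control context in the same cell type.
    """
    ctx = pd.DataFrame(
        [c.split("|") for c in post.contexts], columns=["cell_type", "condition"])
    ctx["index"] = np.arange(len(post.contexts))
    treatments = ctx[ctx["condition"] != control]
    missing = []
    for _, row in treatments.iterrows():
        if not ((ctx["cell_type"] == row["cell_type"])
                & (ctx["condition"] == control)).any():
            missing.append(_context_name(row["cell_type"], control))
    if missing:
        raise ValueError(f"missing control contexts: {sorted(set(missing))}")

    rows = []
    for _, row in treatments.iterrows():
        it = int(row["index"])
        ic = int(ctx.loc[(ctx["cell_type"] == row["cell_type"])
                         & (ctx["condition"] == control), "index"].iloc[0])
        mc, mt = post.mean[:, ic], post.mean[:, it]
        lc, lt = post.lfsr[:, ic], post.lfsr[:, it]
        sig = (lc < lfsr_cut) | (lt < lfsr_cut)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.maximum(np.abs(mc), np.abs(mt)) / np.minimum(
                np.abs(mc), np.abs(mt))
        sign_flip = np.sign(mc) * np.sign(mt) < 0
        zero_one_side = (mc == 0) ^ (mt == 0)
        is_resp = sig & (sign_flip | zero_one_side | (ratio > factor))
        cls = np.where(~sig, "not_significant",
                       np.where(is_resp, "response", "non_response"))
        rows.append(pd.DataFrame({
            "gene": post.pairs["gene"], "snp": post.pairs["snp"],
            "cell_type": row["cell_type"], "treatment": row["condition"],
            "significant_control": lc < lfsr_cut,
            "significant_treatment": lt < lfsr_cut,
            "mean_control": mc, "mean_treatment": mt,
            "fold_change": ratio, "class": cls}))
    return pd.concat(rows, ignore_index=True)


def egene_rollup(calls: pd.DataFrame) -> pd.DataFrame:
    """Per gene x treatment: response eGene if any response eQTL, else
    non-response eGene if any eQTL, else not significant."""
    rows = []
    for (gene, trt), grp in calls.groupby(["gene", "treatment"], sort=False):
        if (grp["class"] == "response").any():
            cls = "response"
        elif (grp["class"] == "non_response").any():
            cls = "non_response"
        else:
            cls = "not_significant"
        rows.append({"gene": gene, "treatment": trt, "egene_class": cls})
    return pd.DataFrame(rows)


def summarize_by_context(calls: pd.DataFrame) -> pd.DataFrame:
    """Deterministic counts of each class per cell type x treatment."""
    classes = ["response", "non_response", "not_significant"]
    if calls.empty:
        return pd.DataFrame(columns=["cell_type", "treatment"] + classes)
    out = (calls.groupby(["cell_type", "treatment", "class"], sort=True)
           .size().unstack("class", fill_value=0).reset_index())
    for c in classes:
        if c not in out.columns:
            out[c] = 0
    return out[["cell_type", "treatment"] + classes]
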