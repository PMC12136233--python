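"""Pipeline orchestration: simulate -> pseudobulk -> map -> shrink ->
response / dynamic -> enrich / coloc, driven by a single configuration.

Stages exchange flat text files (TSV / VCF / BED / JSON) so each stage is
independently runnable and inspectable; a run manifest records the config
hash, seed, and per-stage row counts. Every output table carries a header
comment naming the producing stage, config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cis_eqtl, coloc, dynamic, enrichment, mash, pseudobulk, response, simgen

log = logging.getLogger("gxeqtl")

STAGES = ["simulate", "pseudobulk", "map", "mash", "response", "dynamic",
          "enrich", "coloc"]


@dataclass
class RunConfig:
    """All stage thresholds in one place, mirroring module defaults."""

    seed: int = 0
    out_dir: str = "gxeqtl_run"
    window: int = 100_000
    maf: float = 0.05
    lfsr: float = 0.1
    factor: float = 1.5
    fdr: float = 0.1
    n_bins: int = 15
    p1: float = 1e-4
    pc: float = 0.025
    coloc_threshold: float = 0.5
    alpha: float = 0.05
    n_expression_pcs: int | None = None   # None = parallel analysis
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self) -> None:
        if not 0 <= self.lfsr <= 1:
            raise ValueError(f"lfsr must be in [0, 1], got {self.lfsr}")
        if not 0 <= self.fdr <= 1:
            raise ValueError(f"fdr must be in [0, 1], got {self.fdr}")
        if self.factor < 1:
            raise ValueError("factor must be >= 1")
        if not 0 < self.p1 < 1 or not 0 < self.pc < 1:
            raise ValueError("priors p1, pc must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_tsv(df: pd.DataFrame, path: Path, stage: str, cfg: RunConfig,
               index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# stage={stage} config_hash={cfg.config_hash()} seed={cfg.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run manifest."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "stages": {}}
    current = "simulate"
    try:
        # -- simulate -----------------------------------------------------
        sim_cfg = simgen.SimConfig(seed=cfg.seed, **cfg.sim)
        data = simgen.simulate_all(sim_cfg)
        panel, cells, counts, truth, tss = (
            data["panel"], data["cells"], data["counts"], data["truth"],
            data["tss"])
        simgen.write_dosage_tsv(panel, out / "dosages.tsv")
        simgen.write_vcf(panel, out / "genotypes.vcf")
        simgen.write_bed(data["cres"], out / "cres.bed")
        _write_tsv(cells, out / "cells.tsv", "simulate", cfg)
        _write_tsv(truth.pairs, out / "truth_pairs.tsv", "simulate", cfg)
        _write_tsv(truth.effects, out / "truth_effects.tsv", "simulate", cfg)
        _write_tsv(tss, out / "tss.tsv", "simulate", cfg)
        manifest["stages"]["simulate"] = {
            "n_snps": int(panel.dosages.shape[1]), "n_cells": len(cells),
            "n_genes": counts.shape[0]}

        # -- pseudobulk ---------------------------------------------------
        current = "pseudobulk"
        pb = pseudobulk.aggregate(counts, cells,
                                  ["donor", "cell_type", "condition"])
        pb = pseudobulk.filter_eqtl(pb, counts=counts, cells=cells)
        contexts = sorted({(r["cell_type"], r["condition"])
                           for _, r in pb.samples.iterrows()})
        _write_tsv(pb.counts, out / "pseudobulk_counts.tsv", "pseudobulk", cfg,
                   index=True)
        _write_tsv(pb.samples.reset_index(), out / "pseudobulk_samples.tsv",
                   "pseudobulk", cfg)
        (out / "filter_report.txt").write_text(
            "\n".join(f"{k}\t{v}" for k, v in pb.filter_report.items()) + "\n")
        manifest["stages"]["pseudobulk"] = {
            "n_samples": pb.counts.shape[1], "n_genes": pb.counts.shape[0],
            "filter_report": pb.filter_report}

        # -- per-context mapping -----------------------------------------
        current = "map"
        gpcs = cis_eqtl.genotype_pcs(panel)
        results_by_context: dict[str, pd.DataFrame] = {}
        # normalization spans all conditions within a cell type so that
        # effect-size ratios between conditions stay on a common scale
        norm_by_ct: dict[str, pseudobulk.PseudobulkMatrix] = {}
        for ct in sorted({c for c, _ in contexts}):
            cols = pb.samples.index[pb.samples["cell_type"] == ct]
            sub = pseudobulk.PseudobulkMatrix(counts=pb.counts[cols],
                                              samples=pb.samples.loc[cols])
            norm_by_ct[ct] = pseudobulk.normalize(sub)
        for ct, cond in contexts:
            norm = norm_by_ct[ct]
            cols = norm.samples.index[norm.samples["condition"] == cond]
            expr = norm.expression[cols].copy()
            expr.columns = norm.samples.loc[cols, "donor"]
            donors = list(expr.columns)
            other = pd.DataFrame({
                "sex": panel.sex[[panel.donors.index(d) for d in donors]]},
                index=donors)
            other = pd.concat([other, gpcs.loc[donors]], axis=1)
            cov = cis_eqtl.select_expression_pcs(
                expr, seed=cfg.seed, other_covariates=other,
                max_pcs=cfg.n_expression_pcs)
            res = cis_eqtl.map_cis(expr, panel, tss, cov, window=cfg.window)
            results_by_context[f"{ct}|{cond}"] = res
            _write_tsv(res, out / f"assoc_{ct}_{cond}.tsv", "map", cfg)
        manifest["stages"]["map"] = {
            ctx: len(df) for ctx, df in results_by_context.items()}

        # -- multivariate shrinkage --------------------------------------
        current = "mash"
        pruned = mash.ld_prune(panel)
        strong_pairs = mash.build_strong_set(results_by_context, seed=cfg.seed)
        strong = mash.assemble_effects(results_by_context, strong_pairs)
        rng = np.random.default_rng(cfg.seed)
        rand_df = pd.concat(results_by_context.values())
        rand_df = rand_df[rand_df["snp"].isin(pruned)][["gene", "snp"]]
        rand_df = rand_df.drop_duplicates().reset_index(drop=True)
        if len(rand_df) > 2000:
            rand_df = rand_df.iloc[rng.choice(len(rand_df), 2000, replace=False)]
        random_set = mash.assemble_effects(results_by_context, rand_df)
        prior = mash.build_prior(random_set, strong=strong)
        fitted = mash.fit_weights_em(random_set, prior)
        post = mash.posterior(strong, fitted)
        _write_tsv(post.to_frame(), out / "posterior.tsv", "mash", cfg)
        (out / "prior.json").write_text(json.dumps({
            "V": fitted.V.tolist(), "grid": fitted.grid.tolist(),
            "pi": fitted.pi.tolist(), "components": fitted.component_names,
        }, indent=1))
        manifest["stages"]["mash"] = {"n_strong": len(strong_pairs),
                                      "n_random": len(rand_df),
                                      "n_components": len(fitted.pi)}

        # -- response calls ----------------------------------------------
        current = "response"
        calls = response.call_response(post, lfsr_cut=cfg.lfsr,
                                       factor=cfg.factor)
        summary = response.summarize_by_context(calls)
        egenes = response.egene_rollup(calls)
        _write_tsv(calls, out / "response_calls.tsv", "response", cfg)
        _write_tsv(summary, out / "response_summary.tsv", "response", cfg)
        _write_tsv(egenes, out / "response_egenes.tsv", "response", cfg)
        manifest["stages"]["response"] = {
            "n_response": int((calls["class"] == "response").sum()),
            "n_non_response": int((calls["class"] == "non_response").sum())}

        # -- dynamic eQTLs ------------------------------------------------
        current = "dynamic"
        dyn_rows = []
        for cond in sorted(cells["condition"].unique()):
            sub_cells = cells[cells["condition"] == cond]
            try:
                binning = pseudobulk.bin_pseudotime(sub_cells, "traj1",
                                                    n_bins=cfg.n_bins)
                pbb = pseudobulk.aggregate_bins(counts, sub_cells, binning)
                pbb = pseudobulk.normalize_bins(pbb)
                fit = dynamic.fit_dynamic(pbb, panel, tss)
                dyn = dynamic.dynamic_significance(fit, panel, fdr=cfg.fdr)
                dyn = dynamic.classify_calls(dyn, fit.tau_range)
                dyn.insert(0, "condition", cond)
                dyn.insert(0, "trajectory", "traj1")
                dyn_rows.append(dyn)
            except ValueError as exc:
                log.warning("dynamic stage skipped for %s: %s", cond, exc)
        if dyn_rows:
            dyn_all = pd.concat(dyn_rows, ignore_index=True)
            _write_tsv(dyn_all, out / "dynamic_calls.tsv", "dynamic", cfg)
            manifest["stages"]["dynamic"] = {
                "n_pairs": len(dyn_all),
                "n_significant": int(dyn_all["significant"].sum())}
        else:
            manifest["stages"]["dynamic"] = {"skipped": "no usable trajectory"}

        # -- enrichment ---------------------------------------------------
        current = "enrich"
        cats = enrichment.assign_categories(panel.snps, data["cres"])
        resp_snps = set(calls.loc[calls["class"] == "response", "snp"])
        nonresp_snps = set(calls.loc[calls["class"] == "non_response", "snp"])
        background = set(pd.concat(results_by_context.values())["snp"])
        enr = enrichment.cre_enrichment(
            {"response": resp_snps, "non_response": nonresp_snps},
            background, cats)
        _write_tsv(enr, out / "cre_enrichment.tsv", "enrich", cfg)
        manifest["stages"]["enrich"] = {"n_tests": len(enr)}

        # -- colocalization ----------------------------------------------
        current = "coloc"
        coloc_rows = []
        sig_genes = egenes.loc[egenes["egene_class"] != "not_significant",
                               "gene"].unique()[:10]
        for gene in sig_genes:
            snps = panel.snps.loc[panel.snps["gene"] == gene, "snp"].tolist()
            if len(snps) < 2:
                continue
            causal = truth.pairs.set_index("gene").loc[gene, "snp"]
            gwas = simgen.simulate_gwas(panel, snps, mode="shared",
                                        causal_snp=causal,
                                        seed=cfg.seed + hash(gene) % 10000)
            ctx0 = next(iter(results_by_context))
            eqtl_df = results_by_context[ctx0]
            eqtl_sub = eqtl_df[(eqtl_df["gene"] == gene)
                               & eqtl_df["snp"].isin(snps)]
            if len(eqtl_sub) < 2:
                continue
            region = coloc.RegionSummary.from_summary_stats(
                eqtl_sub[["snp", "beta", "se"]],
                gwas[["snp", "beta", "se"]], region=gene)
            coloc_rows.append(coloc.coloc_two_traits(region, p1=cfg.p1,
                                                     pc=cfg.pc))
        cdf = coloc.call_coloc(coloc_rows, threshold=cfg.coloc_threshold)
        _write_tsv(cdf, out / "coloc.tsv", "coloc", cfg)
        manifest["stages"]["coloc"] = {"n_regions": len(cdf)}
    except Exception:
        log.error("pipeline failed in stage %r", current)
        (out / "manifest.partial.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["n_stages"] = len(manifest["stages"])
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
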