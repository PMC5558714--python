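"""End-to-end orchestration: simulate (optional) -> filter -> neighbors ->
specificity -> differential expression -> selection scan -> GWAS overlap.

One declarative config (YAML-style nested keys) drives the run; the global
seed is propagated to every stochastic stage, so re-running an identical
config reproduces byte-identical outputs. Stages whose inputs are absent
are skipped with an explicit notice in the report.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, gtf, gwas, neighbors, popgen, simulate, specificity
from . import transcripts as tx
from .models import ExpressionMatrix, SnpGenotypePanel, ValidationError, \
    loci_to_dataframe

log = logging.getLogger("lincscan")

STAGES = ("simulate", "filter", "neighbors", "specificity", "de", "scan",
          "gwas")


@dataclass
class RunReport:
    stages: dict = field(default_factory=dict)  # stage -> status/counts
    outputs: dict = field(default_factory=dict)  # stage -> {name: path}
    params: dict = field(default_factory=dict)

    def record(self, stage: str, status: str, **counts) -> None:
        self.stages[stage] = {"status": status, **counts}
        log.info("[%s] %s %s", stage, status, counts or "")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"stages": self.stages, "outputs": self.outputs,
                       "params": self.params}, fh, indent=1, default=str)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return cfg


def validate_config(cfg: dict) -> list[str]:
    """Returns a list of problems (empty = valid). Referenced input paths
    must resolve unless the simulate stage will create them."""
    problems = []
    if not cfg.get("outdir"):
        problems.append("outdir missing")
    sim_on = (cfg.get("simulate") or {}).get("enabled", True)
    if not sim_on:
        for key, p in (cfg.get("inputs") or {}).items():
            if p and not Path(p).exists():
                problems.append(f"input {key!r}: {p} does not exist")
        if not cfg.get("inputs"):
            problems.append("simulate disabled but no inputs given")
    return problems


def _sim_config(cfg: dict) -> simulate.SimConfig:
    overrides = {k: v for k, v in (cfg.get("simulate") or {}).items()
                 if k != "enabled"}
    overrides.setdefault("seed", cfg.get("seed", 0))
    return simulate.SimConfig(**overrides)


def run_pipeline(cfg: dict) -> RunReport:
    problems = validate_config(cfg)
    if problems:
        raise ValidationError("; ".join(problems))
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(params=cfg)
    seed = int(cfg.get("seed", 0))

    # --- stage: simulate / load inputs -------------------------------------
    sim_on = (cfg.get("simulate") or {}).get("enabled", True)
    truth = None
    if sim_on:
        sc = _sim_config(cfg)
        sc.seed = seed if "seed" not in (cfg.get("simulate") or {}) else sc.seed
        loci, transcripts = simulate.generate_annotation(sc)
        known_ref, known_ids = simulate.generate_known_reference(
            sc, loci, transcripts)
        cpc_df, hits_df = simulate.generate_attribute_tables(sc, transcripts)
        matrix, expr_truth = simulate.generate_expression(sc, loci)
        panel, pop_truth = simulate.generate_genotypes(sc)
        gwas_cfg = cfg.get("gwas") or {}
        gwas_table, gwas_truth = simulate.generate_gwas_table(
            sc, loci, n_snps=gwas_cfg.get("n_snps", 60),
            n_in_locus=gwas_cfg.get("n_in_locus", 10))
        truth = simulate.merge_truths(expr_truth, pop_truth, gwas_truth)
        truth.known_linc_ids = known_ids

        ind = outdir / "inputs"
        ind.mkdir(exist_ok=True)
        gtf.write_transcripts(transcripts, ind / "assembly.gtf")
        gtf.write_transcripts(known_ref, ind / "known_lncrna.gtf")
        cpc_df.to_csv(ind / "cpc_scores.tsv", sep="\t", index=False)
        hits_df.to_csv(ind / "homology_hits.tsv", sep="\t", index=False)
        matrix.to_tsv(ind / "expression.tsv", ind / "sample_map.tsv")
        panel.to_tsv(ind / "panel.tsv")
        gwas_table.to_csv(ind / "gwas_snps.tsv", sep="\t", index=False)
        truth.to_json(ind / "ground_truth.json")
        report.record("simulate", "complete", n_loci=len(loci),
                      n_transcripts=len(transcripts), n_snps=len(panel))
    else:
        inputs = cfg["inputs"]
        transcripts = gtf.read_transcripts(inputs["gtf"])
        loci = gtf.read_loci(inputs["gtf"], biotype="lincRNA_candidate")
        if inputs.get("pc_gtf"):
            loci += gtf.read_loci(inputs["pc_gtf"], biotype="protein_coding")
        if inputs.get("cpc"):
            gtf.attach_attributes(transcripts,
                                  cpc=gtf.read_cpc_scores(inputs["cpc"]))
        if inputs.get("hits"):
            gtf.attach_attributes(
                transcripts, hits=gtf.read_homology_hits(inputs["hits"]))
        known_ref = (gtf.read_transcripts(inputs["known_gtf"])
                     if inputs.get("known_gtf") else [])
        matrix = (ExpressionMatrix.from_tsv(inputs["expr"],
                                            inputs["sample_map"])
                  if inputs.get("expr") else None)
        panel = (SnpGenotypePanel.from_tsv(inputs["panel"])
                 if inputs.get("panel") else None)
        gwas_table = (gwas.read_gwas_table(inputs["gwas"])
                      if inputs.get("gwas") else None)
        report.record("simulate", "skipped (inputs supplied)")

    # --- stage: filter + novelty -------------------------------------------
    fcfg = cfg.get("filter") or {}
    linc_tx = [t for t in transcripts
               if t.gene_id is None or not t.gene_id.startswith("pc_")]
    linc_loci_all = [l for l in loci if l.biotype == "lincRNA_candidate"]
    thresholds = tx.FilterThresholds(**{k: v for k, v in fcfg.items()
                                        if k in tx.FilterThresholds.__annotations__})
    retained, rejlog = tx.filter_candidates(linc_tx, thresholds,
                                            loci=linc_loci_all)
    retained_ids = {t.id for t in retained}
    linc_loci = [l for l in linc_loci_all
                 if any(t in retained_ids for t in l.transcript_ids)]
    codes = {t.id: tx.classify_class_code(
        t, known_ref, fcfg.get("runon_distance", 2000))[0] for t in retained}
    callable_loci = [
        simulate.GeneLocus(  # locus restricted to retained members
            id=l.id, chrom=l.chrom, start=l.start, end=l.end,
            biotype=l.biotype,
            transcript_ids=[t for t in l.transcript_ids if t in retained_ids])
        for l in linc_loci]
    known, novel = tx.call_novel(callable_loci, codes)
    summary = (tx.summarize_transcripts(retained) if retained else
               {"median_length": float("nan"), "mean_exon_count": float("nan")})
    gtf.write_transcripts(retained, outdir / "retained_lincrnas.gtf")
    rejlog.to_csv(outdir / "rejection_log.tsv", sep="\t", index=False)
    pd.Series(codes, name="class_code").to_csv(
        outdir / "class_codes.tsv", sep="\t", index_label="transcript_id")
    loci_to_dataframe(novel).to_csv(outdir / "novel_loci.tsv", sep="\t",
                                    index=False)
    report.record("filter", "complete", n_retained=len(retained),
                  n_rejected=len(rejlog), n_loci=len(linc_loci),
                  n_novel=len(novel), n_known=len(known),
                  median_length=summary["median_length"],
                  mean_exon_count=summary["mean_exon_count"])

    pc_loci = [l for l in loci if l.biotype == "protein_coding"]

    # --- stage: neighbors ---------------------------------------------------
    ncfg = cfg.get("neighbors") or {}
    if matrix is not None and pc_loci:
        pairs = neighbors.closest_genes(linc_loci, pc_loci)
        neighbors.pairs_to_dataframe(pairs).to_csv(
            outdir / "neighbor_pairs.tsv", sep="\t", index=False)
        tissue_samples = [s for s, g in matrix.groups.items()
                          if not str(g).startswith("cond_")]
        tissue_matrix = ExpressionMatrix(matrix.values[tissue_samples],
                                         matrix.groups[tissue_samples])
        try:
            corr = neighbors.correlation_comparison(
                tissue_matrix, pairs, pc_loci,
                window=ncfg.get("window", 20_000), seed=seed)
            with open(outdir / "correlation_report.json", "w") as fh:
                json.dump({"n_pairs": corr.n_pairs, "tests": corr.tests,
                           "mean_pcc": {
                               "linc_neighbor": float(np.mean(corr.pcc_linc_neighbor)),
                               "pc_neighbor": float(np.mean(corr.pcc_pc_neighbor)),
                               "random": float(np.mean(corr.pcc_random))}},
                          fh, indent=1)
            report.record("neighbors", "complete", n_pairs=len(pairs),
                          n_corr_pairs=corr.n_pairs)
        except ValidationError as err:
            report.record("neighbors", f"partial ({err})", n_pairs=len(pairs))
    else:
        report.record("neighbors", "skipped (no expression or coding loci)")

    # --- stage: specificity -------------------------------------------------
    if matrix is not None:
        tissue_samples = [s for s, g in matrix.groups.items()
                          if not str(g).startswith("cond_")]
        tmat = ExpressionMatrix(matrix.values[tissue_samples],
                                matrix.groups[tissue_samples])
        calls_tsi = specificity.call_specific(tmat, method="tsi")
        calls_mr = specificity.call_specific(tmat, method="minratio")
        calls_tsi.to_csv(outdir / "specific_tsi.tsv", sep="\t",
                         index_label="gene_id")
        calls_mr.to_csv(outdir / "specific_minratio.tsv", sep="\t",
                        index_label="gene_id")
        report.record(
            "specificity", "complete", n_tsi=len(calls_tsi),
            n_minratio=len(calls_mr),
            minratio_in_tsi_fraction=specificity.containment_fraction(
                calls_mr.index, calls_tsi.index))
    else:
        report.record("specificity", "skipped (no expression)")

    # --- stage: differential expression ------------------------------------
    dcfg = cfg.get("de") or {}
    cond_a = dcfg.get("group_a", "cond_a")
    cond_b = dcfg.get("group_b", "cond_b")
    if matrix is not None and cond_a in set(matrix.groups) \
            and cond_b in set(matrix.groups):
        de = diffexpr.de_test(matrix, cond_a, cond_b,
                              alpha=dcfg.get("alpha", 0.05))
        de.to_csv(outdir / "de_results.tsv", sep="\t", index_label="gene_id")
        counts = {"n_de": int(de["is_de"].sum())}
        if truth is not None and truth.de_genes:
            rec = diffexpr.de_recovery_report(
                de, truth.de_genes.get(f"{cond_a}|{cond_b}", []))
            counts.update({k: rec[k] for k in
                           ("sensitivity", "false_discovery_fraction")})
        report.record("de", "complete", **counts)
    else:
        report.record("de", "skipped (condition groups absent)")

    # --- stage: selection scan ----------------------------------------------
    scfg = cfg.get("scan") or {}
    if panel is not None:
        lengths = None
        if sim_on:
            lengths = {f"chr{i + 1}": sc.chrom_length_bp
                       for i in range(sc.n_chromosomes)}
        win = popgen.window_scan(
            panel, window_bp=scfg.get("window", 50_000),
            step_bp=scfg.get("step", 25_000),
            min_snps=scfg.get("min_snps", 10), chrom_lengths=lengths)
        hp_win = popgen.window_scan(
            panel, window_bp=scfg.get("hp_window", 40_000),
            step_bp=scfg.get("hp_step", 20_000),
            min_snps=scfg.get("min_snps", 10), chrom_lengths=lengths)
        top = scfg.get("top", 0.05)
        flags_fst = popgen.call_top_windows(win, "fst", top)
        flags_dpi = popgen.call_top_windows(win, "delta_pi", top)
        flags_hp = popgen.call_top_windows(hp_win, "hp", top)
        sets = popgen.combine_candidate_sets(
            popgen.loci_in_candidates(win, flags_fst, linc_loci),
            popgen.loci_in_candidates(win, flags_dpi, linc_loci),
            popgen.loci_in_candidates(hp_win, flags_hp, linc_loci))
        win.assign(top_fst=flags_fst, top_delta_pi=flags_dpi).to_csv(
            outdir / "windows.tsv", sep="\t", index=False)
        hp_win.assign(top_hp=flags_hp).to_csv(outdir / "hp_windows.tsv",
                                              sep="\t", index=False)
        with open(outdir / "candidate_sets.json", "w") as fh:
            json.dump(sets.summary(), fh, indent=1)
        pd.DataFrame(sorted(sets.union), columns=["locus_id"]).to_csv(
            outdir / "selected_lincrnas.tsv", sep="\t", index=False)
        report.record("scan", "complete", **sets.summary())
    else:
        report.record("scan", "skipped (no genotype panel)")

    # --- stage: GWAS overlap -------------------------------------------------
    gcfg = cfg.get("gwas") or {}
    if gwas_table is not None:
        res = gwas.snps_in_loci(gwas_table, linc_loci)
        res["assignments"].to_csv(outdir / "gwas_assignments.tsv", sep="\t",
                                  index=False)
        frac = gwas.array_fraction(len(gwas_table[["chrom", "pos"]]
                                       .drop_duplicates()),
                                   gcfg.get("array_size", 580_954))
        with open(outdir / "gwas_summary.json", "w") as fh:
            json.dump({"n_snps_in": res["n_snps_in"],
                       "n_loci_hit": res["n_loci_hit"], **frac}, fh, indent=1)
        report.record("gwas", "complete", n_snps_in=res["n_snps_in"],
                      n_loci_hit=res["n_loci_hit"])
    else:
        report.record("gwas", "skipped (no GWAS table)")

    report.to_json(outdir / "run_report.json")
    return report
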