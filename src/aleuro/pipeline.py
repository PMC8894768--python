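"""Candidate-prioritization funnel and end-to-end orchestration.

The funnel reproduces the study's prioritization logic on any inputs:

    detected co-IP proteins
      -> high/medium confidence tier
        -> CS(AL) > cs_threshold (preferential aleurone expression)
          -> optional annotation-category filter (manual curation stands in
             as a supplied category map, not automated judgment)

``run_all`` wires the synthetic generators through every analysis stage
with one seed and writes all stage outputs plus a machine-readable manifest
(seed, thresholds, package versions, per-stage row counts) sufficient to
reproduce the run exactly.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from aleuro import __version__
from aleuro.containers import SimConfig
from aleuro.coip import run_coip
from aleuro.deg import deg_overlap_summary, run_deg
from aleuro.expression import (class_fraction, compute_tpm, cs_score_table,
                               summarize_expression)
from aleuro.go import GoDag, term_enrichment
from aleuro.synthio import (simulate_go_universe, simulate_proteomics_ip,
                            simulate_qpcr_ct, simulate_rnaseq_counts,
                            simulate_tonoplast_profile, write_go,
                            write_profile, write_proteomics, write_qpcr,
                            write_rnaseq)


@dataclass
class PipelineConfig:
    """Thresholds and design of a full run; all thresholds surfaced here."""

    seed: int = 0
    alpha: float = 0.05
    min_fold: float = 2.0
    cs_threshold: float = 0.5
    deg_timepoints: tuple = (18, 22)
    sim: dict = field(default_factory=dict)  # SimConfig overrides

    def __post_init__(self):
        if self.alpha <= 0 or self.min_fold <= 0 or self.cs_threshold <= 0:
            raise ValueError("thresholds must be positive")

    def sim_config(self) -> SimConfig:
        d = dict(self.sim)
        d["seed"] = self.seed
        return SimConfig.from_dict(d)


def simulate_study(config: SimConfig):
    """Coupled transcriptome + proteome simulation for funnel recovery.

    Proteins are mapped onto the gene universe; planted tonoplast proteins
    are assigned to AL-up differentially expressed genes (so their CS(AL)
    truth is ``2^effect / (2^effect + 1)``, 0.8 at the default effect of 2),
    while background proteins map to non-DE genes.
    """
    cm, truth_rna = simulate_rnaseq_counts(config)
    prot, truth_prot = simulate_proteomics_ip(config)
    rng = np.random.default_rng([int(config.seed), 17])

    proteins = sorted(set(prot["protein"]))
    tono = sorted(truth_prot.tonoplast_proteins)
    others = [p for p in proteins if p not in truth_prot.tonoplast_proteins]
    al_up = sorted(g for g, fc in truth_rna.de_genes.items() if fc > 0)
    non_de = sorted(set(cm.genes) - set(truth_rna.de_genes))
    if len(al_up) < len(tono):
        raise ValueError(
            f"need >= {len(tono)} AL-up DE genes to anchor the planted "
            f"tonoplast proteins, have {len(al_up)}; raise de_fraction or "
            "n_genes")
    if len(non_de) < len(others):
        raise ValueError("gene universe too small for background proteins")
    gene_map = {}
    for p, g in zip(tono, rng.choice(al_up, len(tono), replace=False)):
        gene_map[p] = g
    for p, g in zip(others, rng.choice(non_de, len(others), replace=False)):
        gene_map[p] = g
    return {"counts": cm, "truth_rna": truth_rna, "proteomics": prot,
            "truth_prot": truth_prot, "protein_gene_map": gene_map}


def run_candidate_funnel(tiers: pd.DataFrame, cs_table: pd.DataFrame,
                         protein_gene_map: dict,
                         cs_threshold: float = 0.5,
                         category_map: dict | None = None,
                         categories_keep=None,
                         deg_genes=None):
    """Apply the tier -> CS -> category funnel.

    Parameters
    ----------
    tiers
        Output of :func:`aleuro.coip.run_coip` (per-protein tier table).
    cs_table
        Output of :func:`aleuro.expression.cs_score_table` (per-gene CS).
    protein_gene_map
        protein id -> gene id; proteins without a mapped gene or with an
        undefined CS fail the CS stage.
    category_map, categories_keep
        Optional protein -> annotation category map and the categories to
        retain (the curation stage); skipped when either is None.
    deg_genes
        Optional set of final DEG gene ids, recorded as evidence.

    Returns
    -------
    (candidates, funnel)
        ``candidates``: per-candidate evidence rows for proteins surviving
        all stages; ``funnel``: stage names and counts (non-increasing).
    """
    stages = []
    detected = tiers.index[tiers["detected"]]
    stages.append(("detected", len(detected)))

    hm = [p for p in detected if tiers.loc[p, "tier"] in ("high", "medium")]
    stages.append(("high_medium_tier", len(hm)))

    cs_pass = []
    for p in hm:
        g = protein_gene_map.get(p)
        if g is None or g not in cs_table.index:
            continue
        row = cs_table.loc[g]
        if bool(row["defined"]) and float(row["cs_al"]) > cs_threshold:
            cs_pass.append(p)
    stages.append((f"cs_al_gt_{cs_threshold}", len(cs_pass)))

    final = cs_pass
    if category_map is not None and categories_keep is not None:
        keep = set(categories_keep)
        final = [p for p in cs_pass if category_map.get(p) in keep]
        stages.append(("annotation_category", len(final)))

    deg_genes = set(deg_genes or ())
    rows = []
    fd_cols = [c for c in tiers.columns if c.startswith("fd_")]
    for p in final:
        g = protein_gene_map[p]
        row = {"protein": p, "gene": g, "tier": tiers.loc[p, "tier"],
               "cs_al": float(cs_table.loc[g, "cs_al"]),
               "is_deg": g in deg_genes}
        for c in fd_cols:
            row[c] = float(tiers.loc[p, c])
        if category_map is not None:
            row["category"] = category_map.get(p)
        rows.append(row)
    candidates = pd.DataFrame(rows)
    funnel = pd.DataFrame(stages, columns=["stage", "count"])
    return candidates, funnel


def run_all(config: PipelineConfig, outdir: str) -> dict:
    """Execute simulate -> expression -> deg -> coip -> goenrich -> funnel.

    Writes every stage's tables under ``outdir`` and returns the manifest
    (also written as ``manifest.json``).  Outputs carry no timestamps, so a
    fixed seed reproduces the run byte for byte.
    """
    os.makedirs(outdir, exist_ok=True)
    sim = config.sim_config()
    manifest = {"package_version": __version__, "seed": config.seed,
                "thresholds": {"alpha": config.alpha,
                               "min_fold": config.min_fold,
                               "cs_threshold": config.cs_threshold},
                "sim_config": sim.to_dict(), "stages": {}}

    def _log(stage, **counts):
        manifest["stages"][stage] = counts

    # --- simulate ---
    study = simulate_study(sim)
    cm = study["counts"]
    write_rnaseq(cm, study["truth_rna"], os.path.join(outdir, "rnaseq"))
    write_proteomics(study["proteomics"], study["truth_prot"],
                     os.path.join(outdir, "coip"))
    ann, edges, go_study, truth_go = simulate_go_universe(sim)
    write_go(ann, edges, go_study, truth_go, os.path.join(outdir, "go"))
    profile, truth_prof = simulate_tonoplast_profile(sim)
    write_profile(profile, truth_prof, os.path.join(outdir, "imaging"))
    ct, truth_q = simulate_qpcr_ct(sim)
    write_qpcr(ct, truth_q, os.path.join(outdir, "qpcr"))
    pd.DataFrame(sorted(study["protein_gene_map"].items()),
                 columns=["protein", "gene"]).to_csv(
        os.path.join(outdir, "coip", "protein_gene_map.tsv"),
        sep="\t", index=False)
    _log("simulate", n_genes=int(cm.counts.shape[0]),
         n_samples=int(cm.counts.shape[1]),
         n_proteins=len(set(study["proteomics"]["protein"])))

    # --- expression ---
    tpm = summarize_expression(compute_tpm(cm))
    cs = cs_score_table(tpm)
    fractions = class_fraction(tpm,
                               study["truth_rna"].expression_class_map)
    exp_dir = os.path.join(outdir, "expression")
    os.makedirs(exp_dir, exist_ok=True)
    tpm.tpm.to_csv(os.path.join(exp_dir, "tpm.tsv"), sep="\t")
    flat = tpm.mean_tpm.copy()
    flat.columns = [f"{t}_{tp}" for t, tp in flat.columns]
    flat.to_csv(os.path.join(exp_dir, "mean_tpm.tsv"), sep="\t")
    cs.to_csv(os.path.join(exp_dir, "cs_scores.tsv"), sep="\t")
    fractions.to_csv(os.path.join(exp_dir, "class_fractions.tsv"),
                     sep="\t", index=False)
    _log("expression", n_genes=int(tpm.tpm.shape[0]),
         n_defined_cs=int(cs["defined"].sum()))

    # --- deg ---
    deg_dir = os.path.join(outdir, "deg")
    os.makedirs(deg_dir, exist_ok=True)
    per_tp = {}
    for tp in config.deg_timepoints:
        rec = run_deg(cm, tp, tpm=tpm, alpha=config.alpha,
                      min_fold=config.min_fold)
        rec.to_csv(os.path.join(deg_dir, f"deg_t{tp}.tsv"), sep="\t")
        per_tp[tp] = rec
    summary = deg_overlap_summary(per_tp)
    summary.to_csv(os.path.join(deg_dir, "summary.tsv"), sep="\t",
                   index=False)
    deg_genes = set().union(*(set(r.index[r["deg"]])
                              for r in per_tp.values()))
    _log("deg", **{f"n_deg_t{tp}": int(r["deg"].sum())
                   for tp, r in per_tp.items()})

    # --- coip ---
    tiers, enrich = run_coip(
        study["proteomics"],
        predicted=study["truth_prot"].tonoplast_proteins,
        universe_size=sim.n_genes)
    tiers.to_csv(os.path.join(outdir, "coip", "tiers.tsv"), sep="\t")
    with open(os.path.join(outdir, "coip", "enrichment.json"), "w") as fh:
        json.dump({"table": enrich.table, "odds_ratio": enrich.odds_ratio,
                   "p": enrich.p}, fh, indent=1)
    _log("coip", n_detected=int(tiers["detected"].sum()),
         n_high=int((tiers["tier"] == "high").sum()),
         n_medium=int((tiers["tier"] == "medium").sum()),
         n_low=int((tiers["tier"] == "low").sum()))

    # --- go enrichment on the high/medium gene set ---
    dag = GoDag.from_tables(ann, edges)
    hm_prot = tiers.index[tiers["tier"].isin(["high", "medium"])]
    hm_genes = {study["protein_gene_map"][p] for p in hm_prot}
    annotated = set(ann["gene"])
    go_study_set = sorted(hm_genes & annotated) or sorted(go_study)
    go_res = term_enrichment(dag, go_study_set, mode="weight01")
    go_res.to_csv(os.path.join(outdir, "go", "enrichment.tsv"), sep="\t")
    _log("goenrich", n_terms=len(go_res), n_study_genes=len(go_study_set))

    # --- funnel ---
    candidates, funnel = run_candidate_funnel(
        tiers, cs, study["protein_gene_map"],
        cs_threshold=config.cs_threshold, deg_genes=deg_genes)
    candidates.to_csv(os.path.join(outdir, "candidates.tsv"), sep="\t",
                      index=False)
    funnel.to_csv(os.path.join(outdir, "funnel.tsv"), sep="\t", index=False)
    _log("funnel", **{s: int(c) for s, c in
                      funnel.itertuples(index=False, name=None)})

    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
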