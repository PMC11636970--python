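"""End-to-end orchestration: simulate -> filter -> diversity -> LDA screen
-> metabolite screen -> networks -> cross-omics integration -> random
forest -> single-cell scoring, from a single config, with a run manifest
recording seeds, paths and the record counts surviving each stage."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import classifier, differential, ecology, integration, io, network, singlecell
from .config import Config
from .simulate import (generate_cells, generate_metabolome, generate_microbiome,
                       make_gene_sets, substream)
from .tables import SampleMetadata

log = logging.getLogger("keloidomics.pipeline")

STAGES = ["simulate", "ecology", "lefse", "metab-diff", "network",
          "integrate", "classify", "score-cells"]


@dataclass
class RunManifest:
    config: dict
    seeds: Dict[str, int] = field(default_factory=dict)
    outputs: Dict[str, Dict[str, str]] = field(default_factory=dict)
    counts: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def record(self, stage: str, outputs: Dict[str, str], counts: Dict[str, float]) -> None:
        self.outputs[stage] = outputs
        self.counts[stage] = {k: (float(v) if isinstance(v, float) else v)
                              for k, v in counts.items()}

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seeds": self.seeds,
             "outputs": self.outputs, "counts": self.counts},
            indent=2, default=str))


def _stage_seed(master: int, name: str) -> int:
    return int(substream(master, f"stage-{name}").integers(2**31 - 1))


def run_all(cfg: Config, outdir) -> RunManifest:
    """Execute every stage in dependency order on synthetic data and write
    a TSV bundle, a manifest JSON and a markdown summary to ``outdir``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    from dataclasses import asdict
    man = RunManifest(config=asdict(cfg))
    sim = cfg.sim
    master = int(cfg.seed)
    man.seeds = {st: _stage_seed(master, st) for st in STAGES}

    # --- simulate ---------------------------------------------------------
    tab, meta, truth = generate_microbiome(
        n_mk=sim["n_mk"], n_ns=sim["n_ns"], n_taxa=sim["n_taxa"],
        n_diff=sim["n_diff"], effect_log2fc=sim["effect_log2fc"],
        n_modules=sim["n_modules"], module_size=sim["module_size"],
        module_rho=sim["module_rho"], seed=man.seeds["simulate"])
    plasma = generate_metabolome(meta, truth, n_mets=sim["n_mets_plasma"],
                                 n_diff=sim["n_diff_mets"], n_cross=sim["n_cross"],
                                 compartment="plasma", coupling_rho=sim["coupling_rho"],
                                 seed=man.seeds["simulate"])
    tissue = generate_metabolome(meta, truth, n_mets=sim["n_mets_tissue"],
                                 n_diff=sim["n_diff_mets"], n_cross=0,
                                 compartment="tissue", coupling_rho=sim["coupling_rho"],
                                 seed=man.seeds["simulate"] + 1)
    io.write_abundance_table(tab, out / "taxa.tsv")
    io.write_metadata(meta, out / "metadata.tsv")
    io.write_metabolite_matrix(plasma, out / "plasma.tsv")
    io.write_metabolite_matrix(tissue, out / "tissue.tsv")
    (out / "truth.json").write_text(json.dumps({
        "differential_taxa": truth.differential_taxa,
        "module_assignments": truth.module_assignments,
        "cross_links": truth.cross_links,
        "differential_metabolites": truth.differential_metabolites,
        "seed": truth.seed}, indent=2))
    man.record("simulate",
               {"taxa": "taxa.tsv", "metadata": "metadata.tsv",
                "plasma": "plasma.tsv", "tissue": "tissue.tsv", "truth": "truth.json"},
               {"samples": len(tab.sample_ids), "taxa": len(tab.feature_ids),
                "plasma_mets": len(plasma.metabolite_ids),
                "tissue_mets": len(tissue.metabolite_ids)})

    # --- ecology ----------------------------------------------------------
    filtered = ecology.prevalence_filter(tab, cfg.min_abund, cfg.min_prev)
    div = ecology.alpha_diversity(filtered)
    dmat = ecology.bray_curtis(tab)
    ord_res = ecology.pcoa(dmat, n_axes=2, cailliez=cfg.cailliez)
    r_stat, p_anosim = ecology.anosim(dmat, meta.group, n_perm=cfg.anosim_perm,
                                      seed=man.seeds["ecology"])
    tree = ecology.upgma_tree(dmat)
    venn = ecology.shared_feature_counts(tab, meta)
    div.table.to_csv(out / "diversity.tsv", sep="\t")
    ord_res.coordinates.to_csv(out / "pcoa.tsv", sep="\t")
    (out / "tree.nwk").write_text(tree + "\n")
    venn.to_csv(out / "venn.tsv", sep="\t")
    man.record("ecology",
               {"diversity": "diversity.tsv", "pcoa": "pcoa.tsv", "tree": "tree.nwk",
                "venn": "venn.tsv"},
               {"features_after_filter": len(filtered.feature_ids),
                "anosim_R": float(r_stat), "anosim_p": float(p_anosim)})

    # --- LEfSe-style screen ----------------------------------------------
    screen_tab = filtered.normalize() if cfg.renorm_pathways else filtered
    lda_calls = differential.lda_effect_size(
        screen_tab, meta, alpha=cfg.lda_alpha, n_boot=cfg.lda_n_boot,
        boot_frac=cfg.lda_boot_frac, ridge=cfg.lda_ridge,
        lda_cut=cfg.lda_cut_taxa, seed=man.seeds["lefse"])
    lda_calls.table.to_csv(out / "lda_calls.tsv", sep="\t")
    man.record("lefse", {"calls": "lda_calls.tsv"},
               {"significant": int(lda_calls.table["significant"].sum())})

    # --- metabolite screen -------------------------------------------------
    met_calls = {}
    for name, mat in (("plasma", plasma), ("tissue", tissue)):
        calls = differential.oplsda_vip(mat, meta, n_ortho=cfg.n_ortho,
                                        vip_cut=cfg.vip_cut, fdr_cut=cfg.fdr_cut,
                                        vip_mode=cfg.vip_mode, welch=cfg.welch)
        calls.table.to_csv(out / f"met_calls_{name}.tsv", sep="\t")
        met_calls[name] = calls
    man.record("metab-diff",
               {name: f"met_calls_{name}.tsv" for name in met_calls},
               {f"significant_{n}": int(c.table["significant"].sum())
                for n, c in met_calls.items()})

    # --- per-group networks -------------------------------------------------
    nets = {}
    for g in ("MK", "NS"):
        sub = filtered.subset_samples(meta.ids_in(g))
        nets[g] = network.finalize_network(
            sub, cfg.corr_p, cfg.corr_r, cfg.top_edges, cfg.zi_cut, cfg.pi_cut,
            seed=cfg.module_seed, weighted=cfg.weighted_degree)
        io.write_network(nets[g], out / f"network_{g}.tsv", "edge_tsv")
        io.write_network(nets[g], out / f"network_{g}.graphml", "graphml")
    comp = network.compare_networks(nets["MK"], nets["NS"])
    (out / "network_comparison.json").write_text(json.dumps({
        "shared_core": comp.shared_core, "edge_counts": comp.edge_counts}, indent=2))
    man.record("network",
               {g: f"network_{g}.tsv" for g in nets} | {"comparison": "network_comparison.json"},
               {f"{g}_{s}": comp.edge_counts[g][s] for g in nets for s in ("pos", "neg")}
               | {f"{g}_core": len([n for n, c in nets[g].nodes(data="category")
                                    if c == "connector"]) for g in nets})

    # --- integration --------------------------------------------------------
    block = integration.crossblock_correlate(plasma.data, tab.data)
    selected = integration.select_highly_associated(
        block, k=cfg.top_metabolites, min_abs_rho=cfg.min_abs_rho)
    block.to_long().to_csv(out / "cross_plasma_taxa.tsv", sep="\t", index=False)
    (out / "selected_metabolites.txt").write_text("\n".join(selected) + "\n")
    man.record("integrate",
               {"block": "cross_plasma_taxa.tsv", "selected": "selected_metabolites.txt"},
               {"displayed": int(block.display_mask.to_numpy().sum()),
                "selected": len(selected)})

    # --- classifier ---------------------------------------------------------
    reports = {}
    layers = {"taxa": filtered.data, "plasma": plasma.data, "tissue": tissue.data}
    for layer, feats in layers.items():
        rep = classifier.classify_layer(
            feats, meta, layer=layer, train_frac=cfg.split, top_k=cfg.top_k,
            n_trees=cfg.n_trees, n_repeats=cfg.n_repeats, n_boot=cfg.n_boot_auc,
            seed=man.seeds["classify"], roc_on=cfg.roc_on,
            importance_estimator=cfg.importance_estimator)
        (out / f"classifier_{layer}.json").write_text(json.dumps(rep.to_dict(), indent=2))
        pd.DataFrame(rep.roc_points, columns=["fpr", "tpr"]).to_csv(
            out / f"roc_{layer}.tsv", sep="\t", index=False)
        reports[layer] = rep
    man.record("classify",
               {layer: f"classifier_{layer}.json" for layer in reports},
               {f"auc_{layer}": float(r.auc) for layer, r in reports.items()})

    # --- single cell --------------------------------------------------------
    sets = make_gene_sets(sim["n_sets"], sim["set_size"], sim["n_genes"],
                          seed=man.seeds["score-cells"])
    clusters = [f"C{i+1}" for i in range(sim["n_clusters"])]
    active_map = {list(sets.sets)[0]: clusters[:1]}
    cm, cell_truth = generate_cells(sim["n_cells_per_cluster"], clusters,
                                    sim["n_genes"], sets, active_map,
                                    sim["activity_fc"], seed=man.seeds["score-cells"])
    cm_qc = singlecell.qc_filter(cm, cfg.umi_min, cfg.umi_max)
    scores = singlecell.pathway_score(cm_qc, sets, top_frac=cfg.top_frac)
    cmp_tab = singlecell.cluster_score_compare(scores, cm_qc.cluster)
    scores.scores.to_csv(out / "cell_scores.tsv", sep="\t")
    cmp_tab.to_csv(out / "cluster_scores.tsv", sep="\t")
    man.record("score-cells",
               {"scores": "cell_scores.tsv", "clusters": "cluster_scores.tsv"},
               {"cells_in": len(cm.cell_ids), "cells_kept": len(cm_qc.cell_ids),
                "sets": len(scores.set_names)})

    man.save(out / "manifest.json")
    _write_summary(man, out / "summary.md")
    log.info("run complete: %s", out)
    return man


def _write_summary(man: RunManifest, path) -> None:
    lines = ["# Pipeline run summary", ""]
    for stage in STAGES:
        if stage not in man.counts:
            continue
        lines.append(f"## {stage}")
        for k, v in man.counts[stage].items():
            lines.append(f"- {k}: {v}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
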