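"""Pipeline configuration: every threshold in one place, with defaults
matching the study design the pipeline re-implements.

All abundance thresholds are fractions of 1 (a 0.01% detection floor is
``min_abund=1e-4``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class Config:
    # community filtering
    min_abund: float = 1e-4      # minimum relative abundance (fraction)
    min_prev: float = 0.10       # minimum prevalence (fraction of samples)
    renorm_pathways: bool = False  # renormalize pathway tables before LDA screening

    # co-occurrence network
    corr_p: float = 0.05
    corr_r: float = 0.3
    top_edges: int = 200
    zi_cut: float = 2.5
    pi_cut: float = 0.62
    module_seed: int = 0
    weighted_degree: bool = False

    # differential screening
    lda_alpha: float = 0.05
    lda_cut_taxa: float = 2.5
    lda_cut_path: float = 3.0
    lda_n_boot: int = 30
    lda_boot_frac: float = 2.0 / 3.0
    lda_ridge: float = 1e-3
    vip_cut: float = 1.0
    fdr_cut: float = 0.05
    n_ortho: int = 1
    vip_mode: str = "pred"       # "pred" | "all"
    welch: bool = False

    # ecology
    anosim_perm: int = 999
    cailliez: bool = False

    # integration
    top_metabolites: int = 50
    min_abs_rho: float = 0.0

    # classifier
    split: float = 0.7
    top_k: int = 5
    n_trees: int = 500
    n_repeats: int = 10
    n_boot_auc: int = 2000
    importance_estimator: str = "oob"  # "oob" (per-tree MDA) | "test"
    roc_on: str = "test"         # "test" | "all"

    # single cell
    umi_min: int = 200
    umi_max: int = 6000
    top_frac: float = 0.05

    # synthetic data (defaults mirror the study cohort: 56 MK / 60 NS, 149 taxa)
    sim: dict = field(default_factory=lambda: {
        "n_mk": 56, "n_ns": 60, "n_taxa": 149, "n_diff": 10,
        "effect_log2fc": 2.0, "n_modules": 4, "module_size": 5,
        "module_rho": 0.8,
        "n_mets_plasma": 780, "n_mets_tissue": 882, "n_diff_mets": 20,
        "n_cross": 10, "coupling_rho": 0.9,
        "n_cells_per_cluster": 60, "n_clusters": 6, "n_genes": 1000,
        "n_sets": 4, "set_size": 30, "activity_fc": 4.0,
    })

    seed: int = 0

    @classmethod
    def load(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key == "sim":
                cfg.sim.update(val)
            else:
                setattr(cfg, key, val)
        return cfg

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
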