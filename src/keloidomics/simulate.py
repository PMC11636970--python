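"""Synthetic two-group multiomics data with planted, known ground truth.

Every downstream stage of the pipeline (diversity, LDA screening, OPLS-DA
VIP calling, co-occurrence networks, cross-omics correlation, random-forest
discrimination, single-cell pathway scoring) is validated by recovering
signal planted here.  Signals are planted on absolute log-scale abundances
and the samples are then closed to sum 1, accepting the compositional
distortion a relative-abundance profiler would introduce.

One master seed derives independent named substreams, so adding a generator
call never perturbs the draws of an earlier one.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .singlecell import CellMatrix
from .tables import (
    AbundanceTable,
    Compartment,
    FeatureKind,
    GeneSetCollection,
    MetabMode,
    MetaboliteMatrix,
    SampleMetadata,
)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG stream keyed by (master seed, purpose name)."""
    key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


@dataclass
class SyntheticTruth:
    """Everything that was planted, so recovery can be measured exactly."""

    seed: int
    differential_taxa: List[Tuple[str, float, str]] = field(default_factory=list)
    module_assignments: Dict[str, int] = field(default_factory=dict)
    cross_links: List[Tuple[str, str, int]] = field(default_factory=list)
    differential_metabolites: Dict[str, List[Tuple[str, float, str]]] = field(default_factory=dict)
    informative_cell_sets: List[Tuple[str, List]] = field(default_factory=list)
    #: log-scale taxon signals before closure (samples x taxa); the handle
    #: the metabolome generator couples to
    taxon_latents: Optional[pd.DataFrame] = None

    def diff_taxon_ids(self) -> List[str]:
        return [t for t, _, _ in self.differential_taxa]

    def diff_metabolite_ids(self, compartment: str) -> List[str]:
        return [m for m, _, _ in self.differential_metabolites.get(str(compartment), [])]


def generate_microbiome(n_mk: int = 56, n_ns: int = 60, n_taxa: int = 149,
                        n_diff: int = 10, effect_log2fc: float = 2.0,
                        n_modules: int = 4, module_size: int = 5,
                        module_rho: float = 0.8, seed: int = 0,
                        ) -> Tuple[AbundanceTable, SampleMetadata, SyntheticTruth]:
    """Two-group compositional taxon table with planted differential taxa
    and planted correlation modules.

    Baseline log-abundances are Gaussian per taxon (log-normal abundances);
    the planted differential taxa are shifted by ``effect_log2fc * log 2``
    in their enriched group; taxa of a planted module share a latent
    Gaussian factor with loading ``sqrt(module_rho)`` so within-module
    pairwise correlation is approximately ``module_rho``.  Rows are closed
    to sum 1 at the end.
    """
    if n_diff > n_taxa:
        raise ValueError("n_diff cannot exceed n_taxa")
    if n_modules * module_size > n_taxa:
        raise ValueError("module taxa exceed n_taxa")
    if n_diff > 0 and effect_log2fc == 0:
        raise ValueError("effect_log2fc must be nonzero when planting differential taxa")
    if not 0 < module_rho < 1:
        raise ValueError("module_rho must be in (0, 1)")

    rng = substream(seed, "microbiome")
    n = n_mk + n_ns
    samples = [f"MK{i+1:03d}" for i in range(n_mk)] + [f"NS{i+1:03d}" for i in range(n_ns)]
    groups = np.array(["MK"] * n_mk + ["NS"] * n_ns)
    taxa = [f"s__Taxon{j+1:04d}" for j in range(n_taxa)]
    names = [t[3:] for t in taxa]

    truth = SyntheticTruth(seed=int(seed))

    mu = rng.normal(0.0, 1.5, size=n_taxa)          # taxon-level baseline
    noise = rng.normal(0.0, 1.0, size=(n, n_taxa))  # sample-level variation
    x = mu[None, :] + noise

    # planted correlation modules on a contiguous block of taxa
    order = rng.permutation(n_taxa)
    mod_taxa = order[: n_modules * module_size]
    for m in range(n_modules):
        members = mod_taxa[m * module_size: (m + 1) * module_size]
        factor = rng.normal(0.0, 1.0, size=n)
        lam = np.sqrt(module_rho)
        x[:, members] = (mu[members][None, :]
                         + lam * factor[:, None]
                         + np.sqrt(1.0 - module_rho) * noise[:, members])
        for j in members:
            truth.module_assignments[names[j]] = m

    # planted differential taxa, disjoint from the modules when possible
    free = [j for j in order[n_modules * module_size:]]
    pool = free if len(free) >= n_diff else list(order)
    diff = rng.choice(pool, size=n_diff, replace=False) if n_diff else np.array([], dtype=int)
    shift = np.log(2.0) * effect_log2fc
    for j in diff:
        enriched = "MK" if rng.random() < 0.5 else "NS"
        x[groups == enriched, j] += shift
        truth.differential_taxa.append((names[j], float(effect_log2fc), enriched))

    abund = np.exp(x)
    abund /= abund.sum(axis=1, keepdims=True)

    df = pd.DataFrame(abund, index=samples, columns=names)
    rank = pd.Series("species", index=names)
    tab = AbundanceTable(df, FeatureKind.taxon, rank=rank, normalized=True)
    meta = SampleMetadata(pd.Series(groups, index=samples))
    truth.taxon_latents = pd.DataFrame(x, index=samples, columns=names)
    return tab, meta, truth


def generate_metabolome(meta: SampleMetadata, truth: SyntheticTruth,
                        n_mets: int = 780, n_diff: int = 20, n_cross: int = 10,
                        compartment: str = "plasma", coupling_rho: float = 0.9,
                        seed: int = 0, effect_log2fc: float = 1.0,
                        ) -> MetaboliteMatrix:
    """Log-normal metabolite intensities coupled to the microbiome.

    ``n_diff`` metabolites are shifted between groups by
    ``effect_log2fc * log 2`` on the log scale; ``n_cross`` metabolites are
    linearly coupled (correlation ``coupling_rho``) to the log-scale latent
    signal of randomly chosen taxa.  Planted identities are appended to
    ``truth``.
    """
    compartment = Compartment(compartment).value
    if n_cross > n_mets:
        raise ValueError("n_cross cannot exceed n_mets")
    if truth.taxon_latents is None:
        raise ValueError("truth carries no microbiome latent factors")

    rng = substream(seed, f"metabolome-{compartment}")
    samples = meta.sample_ids
    latents = truth.taxon_latents.loc[samples]
    groups = meta.labels_for(samples)
    n = len(samples)
    prefix = "P" if compartment == "plasma" else "T"
    mets = [f"{prefix}_met{j+1:04d}" for j in range(n_mets)]

    mu = rng.normal(11.5, 1.5, size=n_mets)          # log intensity baselines
    sd = 0.5
    z = rng.normal(0.0, 1.0, size=(n, n_mets))

    order = rng.permutation(n_mets)
    cross_idx = order[:n_cross]
    diff_idx = order[n_cross: n_cross + n_diff]

    taxa = list(latents.columns)
    for j in cross_idx:
        t = taxa[rng.integers(len(taxa))]
        lat = latents[t].to_numpy()
        lat = (lat - lat.mean()) / lat.std()
        sign = 1 if rng.random() < 0.5 else -1
        z[:, j] = sign * coupling_rho * lat + np.sqrt(1 - coupling_rho**2) * z[:, j]
        truth.cross_links.append((t, mets[j], sign))

    calls = truth.differential_metabolites.setdefault(compartment, [])
    for j in diff_idx:
        enriched = "MK" if rng.random() < 0.5 else "NS"
        z[groups == enriched, j] += np.log(2.0) * effect_log2fc / sd
        calls.append((mets[j], float(effect_log2fc), enriched))

    vals = np.exp(mu[None, :] + sd * z)
    df = pd.DataFrame(vals, index=samples, columns=mets)
    return MetaboliteMatrix(df, Compartment(compartment), MetabMode.untargeted)


def make_gene_sets(n_sets: int = 4, set_size: int = 30, n_genes: int = 1000,
                   seed: int = 0) -> GeneSetCollection:
    """Disjoint synthetic metabolic gene sets over the gene universe."""
    if n_sets * set_size > n_genes:
        raise ValueError("gene sets exceed the gene universe")
    rng = substream(seed, "genesets")
    genes = [f"g{j+1:04d}" for j in range(n_genes)]
    order = rng.permutation(n_genes)
    sets = {}
    for s in range(n_sets):
        idx = order[s * set_size: (s + 1) * set_size]
        sets[f"pathway_{s+1}"] = [genes[i] for i in sorted(idx)]
    return GeneSetCollection(sets)


def generate_cells(n_cells_per_cluster: int = 60, clusters: Optional[List[str]] = None,
                   n_genes: int = 1000, sets: Optional[GeneSetCollection] = None,
                   active_map: Optional[Dict[str, List[str]]] = None,
                   activity_fc: float = 4.0, seed: int = 0,
                   ) -> Tuple[CellMatrix, SyntheticTruth]:
    """Negative-binomial UMI counts with planted pathway activity.

    Genes of a set named in ``active_map`` are upregulated by
    ``activity_fc`` in the mapped clusters.  Per-cell size factors vary over
    an order of magnitude so the UMI-total QC gate removes real cells.
    """
    if activity_fc <= 1:
        raise ValueError("activity_fc must exceed 1")
    clusters = clusters if clusters is not None else [f"C{i+1}" for i in range(6)]
    sets = sets if sets is not None else make_gene_sets(n_genes=n_genes, seed=seed)
    active_map = active_map or {}

    genes = [f"g{j+1:04d}" for j in range(n_genes)]
    universe = set(genes)
    for name, members in sets:
        missing = set(members) - universe
        if missing:
            raise ValueError(f"gene set {name!r} has genes outside the universe")
    for name in active_map:
        if name not in sets.sets:
            raise ValueError(f"active_map names unknown set {name!r}")

    rng = substream(seed, "cells")
    gene_mean = np.exp(rng.normal(-0.3, 1.0, size=n_genes))
    gene_pos = {g: i for i, g in enumerate(genes)}

    rows, labels = [], []
    truth = SyntheticTruth(seed=int(seed))
    for name, active in active_map.items():
        truth.informative_cell_sets.append((name, list(active)))

    for c in clusters:
        boost = np.ones(n_genes)
        for name, active in active_map.items():
            if c in active:
                idx = [gene_pos[g] for g in sets[name]]
                boost[idx] = activity_fc
        for _ in range(n_cells_per_cluster):
            size = np.exp(rng.normal(0.0, 1.0))     # heavy-tailed library sizes
            m = size * gene_mean * boost
            r = 2.0                                  # NB dispersion
            counts = rng.negative_binomial(r, r / (r + m))
            rows.append(sp.csr_matrix(counts))
            labels.append(c)

    counts = sp.vstack(rows).tocsr()
    cell_ids = [f"cell{i+1:05d}" for i in range(counts.shape[0])]
    cm = CellMatrix(cell_ids, genes, counts,
                    cluster=pd.Series(labels, index=cell_ids))
    return cm, truth
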