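"""Single-cell QC and rank-based metabolic pathway activity scoring.

Cells are rows of a sparse UMI-count matrix.  Pathway activity is scored
per cell with a rank-AUC statistic (AUCell-style): genes are ranked by
descending count and the score is the normalized area under the recovery
curve of the set's genes within the top fraction of the ranking, so it is
invariant to library size and any monotone rescaling of a cell's counts.
Upstream steps that need raw-data context (doublet removal, variable-gene
selection, embedding, clustering) are consumed as precomputed labels.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata

from .tables import GeneSetCollection, ValidationError

log = logging.getLogger("keloidomics.singlecell")


@dataclass
class CellMatrix:
    """Cells x genes sparse non-negative integer UMI counts with optional
    per-cell cluster and disease-group annotations."""

    cell_ids: List[str]
    gene_ids: List[str]
    counts: sp.csr_matrix
    cluster: Optional[pd.Series] = None   # cell -> cluster id
    group: Optional[pd.Series] = None     # cell -> keloid | normal

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValidationError("counts shape does not match id lists")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("duplicate cell ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("counts must be non-negative")

    @property
    def total_umi(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()


@dataclass
class PathwayScoreTable:
    """Per-cell activity scores in [0, 1], one column per gene set."""

    scores: pd.DataFrame  # cells x sets

    @property
    def cell_ids(self) -> List[str]:
        return list(self.scores.index)

    @property
    def set_names(self) -> List[str]:
        return list(self.scores.columns)


def qc_filter(cm: CellMatrix, umi_min: int = 200, umi_max: int = 6000) -> CellMatrix:
    """Keep cells with umi_min <= total UMI <= umi_max (both inclusive:
    the rule removes cells with totals strictly below the floor or strictly
    above the ceiling).  Genes are untouched."""
    totals = cm.total_umi
    keep = (totals >= umi_min) & (totals <= umi_max)
    if not keep.any():
        log.warning("QC filter removed every cell (umi_min=%d, umi_max=%d)",
                    umi_min, umi_max)
    idx = np.flatnonzero(keep)
    cells = [cm.cell_ids[i] for i in idx]
    cluster = cm.cluster.iloc[idx] if cm.cluster is not None else None
    group = cm.group.iloc[idx] if cm.group is not None else None
    log.info("QC filter: %d of %d cells kept", len(cells), len(cm.cell_ids))
    return CellMatrix(cells, list(cm.gene_ids), cm.counts[idx], cluster, group)


def pathway_score(cm: CellMatrix, sets: GeneSetCollection,
                  top_frac: float = 0.05) -> PathwayScoreTable:
    """Rank-AUC activity score of each gene set in each cell.

    Per cell, genes are ranked by descending count (ties share the average
    rank).  The raw score is the area under the recovery curve of the set's
    detected genes within the top ``ceil(top_frac * n_genes)`` ranks,
    normalized by the maximal attainable area so the score lies in [0, 1].
    Set genes with zero counts never count as recovered; a cell detecting
    no set gene scores 0.
    """
    if not 0 < top_frac < 1:
        raise ValueError("top_frac must be in (0, 1)")
    n_genes = len(cm.gene_ids)
    top = math.ceil(top_frac * n_genes)
    gene_pos = {g: i for i, g in enumerate(cm.gene_ids)}

    usable: Dict[str, np.ndarray] = {}
    for name, genes in sets:
        idx = np.array([gene_pos[g] for g in genes if g in gene_pos], dtype=int)
        if idx.size == 0:
            log.warning("gene set %s has no genes in the matrix; skipped", name)
            continue
        usable[name] = idx

    dense = np.asarray(cm.counts.todense(), dtype=float)
    # rank 1 = highest count; ties get the average rank
    ranks = rankdata(-dense, axis=1, method="average")

    # max attainable area: all s detected genes packed into the top s ranks
    def _max_area(s: int) -> float:
        s = min(s, top)
        return s * (s + 1) / 2 + (top - s) * s

    out = {}
    for name, idx in usable.items():
        r = ranks[:, idx]                     # cells x set genes
        detected = dense[:, idx] > 0
        r = np.where(detected, r, np.inf)     # undetected genes never recover
        # area under the step recovery curve over positions 1..top:
        # a gene recovered at (ceil of) rank r contributes (top - ceil(r) + 1);
        # the denominator is the area when the whole set tops the ranking,
        # so the score depends only on the multiset of set-gene ranks
        contrib = np.where(r <= top, top - np.ceil(np.minimum(r, top)) + 1, 0.0)
        raw = contrib.sum(axis=1)
        score = np.where(detected.any(axis=1), raw / _max_area(idx.size), 0.0)
        out[name] = np.clip(score, 0.0, 1.0)

    return PathwayScoreTable(pd.DataFrame(out, index=cm.cell_ids))


def cluster_score_compare(ps: PathwayScoreTable, cluster: pd.Series,
                          min_cells: int = 3) -> pd.DataFrame:
    """Per-cluster mean score per set, the top-scoring cluster, and a
    rank-sum p-value for top cluster vs all other cells.

    Clusters with fewer than ``min_cells`` cells are excluded from testing
    (their means are still reported).
    """
    from .differential import rank_sum_test

    cluster = cluster.reindex(ps.cell_ids)
    labels = cluster.to_numpy()
    uniq = pd.unique(cluster.dropna())
    if len(uniq) < 2:
        raise ValueError("need at least two clusters to compare")
    sizes = {c: int((labels == c).sum()) for c in uniq}
    testable = [c for c in uniq if sizes[c] >= min_cells]
    for c in uniq:
        if sizes[c] < min_cells:
            log.warning("cluster %s has %d (<%d) cells; excluded from testing",
                        c, sizes[c], min_cells)

    rows = []
    for name in ps.set_names:
        vals = ps.scores[name].to_numpy()
        means = {c: float(vals[labels == c].mean()) for c in uniq}
        # top cluster among testable ones; ties broken by cluster id
        top = sorted(testable, key=lambda c: (-means[c], str(c)))[0]
        in_top = labels == top
        _, p = rank_sum_test(vals[in_top], vals[~in_top & pd.notna(labels)])
        row = {"set": name, "top_cluster": top, "p_top_vs_rest": p}
        row.update({f"mean_{c}": means[c] for c in uniq})
        rows.append(row)
    return pd.DataFrame(rows).set_index("set")
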