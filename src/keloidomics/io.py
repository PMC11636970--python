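"""Readers and writers for the tabular formats the pipeline consumes.

Abundance profiles follow the MetaPhlAn/HUMAnN dialect: tab-separated,
first column a feature id (optionally a pipe-delimited taxonomy string with
rank prefixes such as ``s__``), remaining columns samples.  Networks go out
as edge TSV or GraphML; single-cell matrices as MatrixMarket triplets with
side files of gene and cell names.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import List, Optional, Tuple

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .tables import (
    AbundanceTable,
    Compartment,
    FeatureKind,
    FormatError,
    GeneSetCollection,
    MetabMode,
    MetaboliteMatrix,
    Rank,
    RANK_PREFIXES,
    SampleMetadata,
    ValidationError,
)

log = logging.getLogger("keloidomics.io")


def parse_taxonomy_id(raw: str) -> Tuple[str, Rank]:
    """Split a MetaPhlAn-style lineage into (leaf name, rank).

    ``k__Bacteria|s__Bacteroides_plebeius`` -> (``Bacteroides_plebeius``,
    species).  Ids without a recognised prefix come back rank-unknown and
    unchanged, so the parse is lossless.
    """
    leaf = raw.split("|")[-1]
    for prefix, rank in RANK_PREFIXES.items():
        if leaf.startswith(prefix):
            return leaf[len(prefix):], rank
    return raw, Rank.unknown


def read_abundance_table(path, kind: FeatureKind = FeatureKind.taxon,
                         transpose: bool = False) -> AbundanceTable:
    """Read a tab-separated abundance profile into a normalized table.

    Rows are features, columns samples (``transpose=True`` for the
    samples-in-rows dialect).  Values are renormalized per sample to sum 1.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if raw.isna().any().any():
        row = raw.index[raw.isna().any(axis=1)][0]
        # +2: header line plus 1-based numbering
        line_no = list(raw.index).index(row) + 2
        raise FormatError(f"{path.name}: malformed row length at line {line_no} ({row!r})")
    if transpose:
        raw = raw.T
    names, ranks = [], []
    for fid in raw.index:
        name, rank = parse_taxonomy_id(str(fid))
        names.append(name)
        ranks.append(rank)
    df = raw.T.astype(float)
    df.columns = names
    if np.any(df.to_numpy() < 0):
        raise ValidationError(f"{path.name}: negative abundance value")
    rank = pd.Series(ranks, index=names)
    tab = AbundanceTable(df, feature_kind=kind, rank=rank).normalize()
    log.info("read %s: %d samples x %d features", path.name, *tab.data.shape)
    return tab


def write_abundance_table(tab: AbundanceTable, path) -> None:
    tab.data.T.to_csv(path, sep="\t", index_label="feature_id")


def read_metabolite_matrix(path, compartment, mode=MetabMode.untargeted,
                           transpose: bool = False) -> MetaboliteMatrix:
    """Read a CSV/TSV metabolite matrix (samples in rows by default)."""
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep, index_col=0).astype(float)
    if transpose:
        df = df.T
    return MetaboliteMatrix(df, Compartment(compartment), MetabMode(mode))


def write_metabolite_matrix(mat: MetaboliteMatrix, path) -> None:
    mat.data.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "group" not in df.columns:
        raise FormatError(f"{Path(path).name}: expected a 'group' column")
    return SampleMetadata(df["group"])


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.group.rename("group").to_csv(path, sep="\t", index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name, description, genes...).

    The description field is discarded; duplicate genes within a set are
    dropped with a logged warning.
    """
    sets = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{Path(path).name}: line {i} has fewer than 3 fields")
            name, genes = fields[0], fields[2:]
            seen, uniq = set(), []
            for g in genes:
                if g in seen:
                    log.warning("gene set %s: duplicate gene %s dropped", name, g)
                else:
                    seen.add(g)
                    uniq.append(g)
            sets[name] = uniq
    return GeneSetCollection(sets)


def write_gmt(sets: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets:
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# networks

_EDGE_COLS = ["source", "target", "rho", "p", "sign"]
_NODE_ATTRS = ["module", "Zi", "Pi", "category"]


def write_network(net: nx.Graph, path, format: str = "edge_tsv") -> None:
    """Write a finalized co-occurrence network.

    ``edge_tsv`` holds one row per edge (source, target, rho, p, sign);
    ``graphml`` additionally carries the node attributes module, Zi, Pi and
    category so a round-trip read reproduces the graph exactly.
    """
    if format == "edge_tsv":
        rows = [
            {"source": u, "target": v, "rho": d["rho"], "p": d["p"], "sign": d["sign"]}
            for u, v, d in net.edges(data=True)
        ]
        pd.DataFrame(rows, columns=_EDGE_COLS).to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(net, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> nx.Graph:
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for row in df.itertuples(index=False):
            g.add_edge(str(row.source), str(row.target),
                       rho=float(row.rho), p=float(row.p), sign=str(row.sign))
        return g
    if format == "graphml":
        return nx.read_graphml(path)
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# single cell

def read_cell_matrix(mtx_path, genes_path, barcodes_path,
                     clusters_path: Optional[str] = None):
    """Read MatrixMarket counts (genes x cells, 10x convention) plus name
    files; returns a :class:`~keloidomics.singlecell.CellMatrix`."""
    from .singlecell import CellMatrix  # local import avoids a cycle

    counts = sp.csr_matrix(scipy.io.mmread(mtx_path)).T  # -> cells x genes
    genes = [l.strip() for l in open(genes_path) if l.strip()]
    cells = [l.strip() for l in open(barcodes_path) if l.strip()]
    cluster = None
    if clusters_path is not None:
        s = pd.read_csv(clusters_path, sep="\t", index_col=0).iloc[:, 0]
        cluster = s.reindex(cells)
    return CellMatrix(cell_ids=cells, gene_ids=genes, counts=counts, cluster=cluster)


def write_cell_matrix(cm, mtx_path, genes_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(mtx_path), sp.coo_matrix(cm.counts.T))
    Path(genes_path).write_text("\n".join(cm.gene_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(cm.cell_ids) + "\n")
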