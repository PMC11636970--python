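"""Cross-omics correlation blocks.

Each block pairs two omics layers (tissue vs plasma metabolites, plasma
metabolites vs microbial pathways, plasma metabolites vs taxa) on their
shared samples, computes all pairwise Spearman correlations, applies a
Benjamini-Hochberg correction across the whole block, and masks the
display at p < 0.05 (the heatmap rule).  "Highly associated" rows are the
top-k by their strongest masked |rho|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd

from .differential import bh_fdr
from .network import spearman_cross

log = logging.getLogger("keloidomics.integration")


@dataclass
class CrossBlockResult:
    rho: pd.DataFrame     # rows x cols
    p: pd.DataFrame
    q: pd.DataFrame       # BH across the whole block
    display_mask: pd.DataFrame  # p < 0.05

    @property
    def row_ids(self) -> List[str]:
        return list(self.rho.index)

    @property
    def col_ids(self) -> List[str]:
        return list(self.rho.columns)

    def to_long(self) -> pd.DataFrame:
        """Long-format (row, col, rho, p, q, displayed) table."""
        out = []
        for r in self.rho.index:
            for c in self.rho.columns:
                out.append((r, c, self.rho.at[r, c], self.p.at[r, c],
                            self.q.at[r, c], bool(self.display_mask.at[r, c])))
        return pd.DataFrame(out, columns=["row", "col", "rho", "p", "q", "displayed"])


def crossblock_correlate(a: pd.DataFrame, b: pd.DataFrame,
                         display_p: float = 0.05) -> CrossBlockResult:
    """Spearman rho/p for every (column of a, column of b) pair over the
    intersection of their sample ids; BH q over all pairs in the block.

    ``a`` rows become the block's rows, ``b`` columns its columns.
    """
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} shared samples; need >=5")
    a, b = a.loc[shared], b.loc[shared]
    rho, p = spearman_cross(a, b)
    q = bh_fdr(p.ravel()).reshape(p.shape)
    rows, cols = list(a.columns), list(b.columns)
    log.info("cross block: %d x %d pairs on %d shared samples, %d displayed",
             len(rows), len(cols), len(shared), int((p < display_p).sum()))
    return CrossBlockResult(
        pd.DataFrame(rho, index=rows, columns=cols),
        pd.DataFrame(p, index=rows, columns=cols),
        pd.DataFrame(q, index=rows, columns=cols),
        pd.DataFrame(p < display_p, index=rows, columns=cols),
    )


def select_highly_associated(res: CrossBlockResult, k: int = 50,
                             min_abs_rho: float = 0.0) -> List[str]:
    """Rows ranked by the maximum |rho| over their displayed cells; rows
    with no displayed cell or a best |rho| below ``min_abs_rho`` are
    ineligible.  Returns at most k row ids, ties broken by row id."""
    if k <= 0:
        raise ValueError("k must be positive")
    absr = res.rho.abs().where(res.display_mask)
    best = absr.max(axis=1)
    eligible = best.dropna()
    eligible = eligible[eligible >= min_abs_rho]
    ranked = sorted(eligible.items(), key=lambda kv: (-kv[1], kv[0]))
    return [r for r, _ in ranked[:k]]
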