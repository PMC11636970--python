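"""Community ecology: prevalence filtering, alpha/beta diversity,
principal-coordinate ordination, ANOSIM group separation, average-linkage
clustering, and shared-feature (Venn) counts.

Conventions: Shannon uses the natural log; Simpson is the Gini-Simpson
index 1 - sum(p^2); Chao1 is always the bias-corrected form
S_obs + F1(F1-1)/(2(F2+1)) so it stays defined when no doubletons exist;
the ANOSIM p-value uses the add-one permutation estimator so it can never
be exactly zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .tables import AbundanceTable, Rank, SampleMetadata, ValidationError

log = logging.getLogger("keloidomics.ecology")


def prevalence_filter(tab: AbundanceTable, min_abund: float = 1e-4,
                      min_prev: float = 0.10) -> AbundanceTable:
    """Keep features with abundance >= min_abund in >= ceil(min_prev * n)
    samples (both comparisons inclusive).  Samples are untouched and the
    surviving fractions are NOT renormalized."""
    if not 0 < min_abund < 1:
        raise ValueError("min_abund must be in (0, 1)")
    if not 0 < min_prev <= 1:
        raise ValueError("min_prev must be in (0, 1]")
    n = len(tab.sample_ids)
    need = math.ceil(min_prev * n)
    hits = (tab.values >= min_abund).sum(axis=0)
    keep = [f for f, h in zip(tab.feature_ids, hits) if h >= need]
    if not keep:
        log.warning("prevalence filter removed every feature")
    log.info("prevalence filter: %d of %d features kept (>=%g in >=%d samples)",
             len(keep), len(tab.feature_ids), min_abund, need)
    return tab.subset_features(keep)


@dataclass
class DiversityResult:
    """Per-sample alpha diversity (Chao1 only when integer counts given)."""
    table: pd.DataFrame  # columns: shannon, simpson, optionally chao1


def _chao1(counts: np.ndarray) -> float:
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def alpha_diversity(tab: AbundanceTable,
                    counts: Optional[np.ndarray] = None) -> DiversityResult:
    """Shannon (-sum p ln p), Gini-Simpson (1 - sum p^2) from fractions and,
    when an integer count matrix is supplied, bias-corrected Chao1."""
    vals = tab.values
    sums = vals.sum(axis=1)
    if np.any(sums <= 0):
        bad = tab.data.index[sums <= 0][0]
        raise ValidationError(f"sample {bad!r} is all-zero; diversity undefined")
    p = vals / sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        shannon = -np.nansum(np.where(p > 0, p * np.log(p), 0.0), axis=1)
    simpson = 1.0 - (p**2).sum(axis=1)
    out = pd.DataFrame({"shannon": shannon, "simpson": simpson}, index=tab.sample_ids)
    if counts is not None:
        counts = np.asarray(counts)
        if counts.shape != vals.shape:
            raise ValueError("counts matrix shape mismatch")
        if not np.allclose(counts, np.round(counts)):
            raise ValidationError("Chao1 requires integer counts")
        out["chao1"] = [_chao1(row) for row in counts]
    return DiversityResult(out)


def bray_curtis(tab: AbundanceTable) -> pd.DataFrame:
    """Bray-Curtis dissimilarity d(x,y) = sum|x-y| / sum(x+y) for every
    sample pair."""
    if len(tab.sample_ids) < 2:
        raise ValueError("need at least two samples")
    vals = tab.values
    zero = vals.sum(axis=1) == 0
    if zero.sum() >= 2:
        raise ValidationError("distance undefined between all-zero samples")
    d = squareform(pdist(vals, metric="braycurtis"))
    return pd.DataFrame(d, index=tab.sample_ids, columns=tab.sample_ids)


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame       # samples x axes
    eigenvalues: np.ndarray         # non-increasing, positive part
    proportion_explained: np.ndarray


def pcoa(d: pd.DataFrame, n_axes: int = 2, cailliez: bool = False) -> OrdinationResult:
    """Principal-coordinate analysis by Gower double-centering of -d^2/2.

    Axes are ordered by eigenvalue and scaled by sqrt(eigenvalue); negative
    eigenvalues are dropped from the proportion-explained denominator (an
    optional Cailliez correction removes them instead).
    """
    dm = np.asarray(d, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T) or np.any(np.diag(dm) != 0):
        raise ValueError("expected a symmetric zero-diagonal distance matrix")
    if cailliez:
        dm = _cailliez(dm)
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    n_pos = int(pos.sum())
    if n_axes > n_pos:
        log.warning("requested %d axes but only %d positive eigenvalues", n_axes, n_pos)
        n_axes = max(n_pos, 0)
    lam = evals[:n_axes]
    coords = evecs[:, :n_axes] * np.sqrt(lam)[None, :]
    denom = evals[pos].sum() if n_pos else 1.0
    prop = lam / denom
    cols = [f"PCo{i+1}" for i in range(n_axes)]
    idx = d.index if isinstance(d, pd.DataFrame) else range(n)
    return OrdinationResult(pd.DataFrame(coords, index=idx, columns=cols), lam, prop)


def _cailliez(dm: np.ndarray) -> np.ndarray:
    """Smallest additive constant making the distances Euclidean."""
    n = dm.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    d1 = -0.5 * j @ (dm**2) @ j
    d2 = -0.5 * j @ dm @ j
    top = np.hstack([np.zeros((n, n)), 2 * d1])
    bot = np.hstack([-np.eye(n), -4 * d2])
    c = np.max(np.real(np.linalg.eigvals(np.vstack([top, bot]))))
    out = dm + c
    np.fill_diagonal(out, 0.0)
    return out


def anosim(d: pd.DataFrame, groups, n_perm: int = 999,
           seed: int = 0) -> Tuple[float, float]:
    """Analysis of similarities on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (N(N-1)/4)
    with N the number of samples; the p-value is the add-one permutation
    estimator (1 + #{R* >= R}) / (1 + n_perm), so p is never 0 and the
    smallest attainable value with 999 permutations is 0.001.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be at least 99")
    labels = np.asarray(pd.Series(groups).loc[list(d.index)]
                        if isinstance(groups, (pd.Series, dict)) else groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise ValueError("need >=2 groups with >=2 samples each")
    dm = np.asarray(d, dtype=float)
    n = dm.shape[0]
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dm[iu])
    denom = n * (n - 1) / 4.0

    def stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    r_obs = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= r_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r_obs), float(p)


def upgma_tree(d: pd.DataFrame) -> str:
    """Average-linkage (UPGMA) clustering; returns an ultrametric newick
    string with branch lengths.  Tied merge candidates are broken by the
    lexicographic order of the clusters' smallest leaf names, so the output
    is deterministic."""
    names = list(d.index)
    if len(names) < 2:
        raise ValueError("need at least two samples")
    dm = {frozenset((a, b)): float(d.loc[a, b]) for i, a in enumerate(names)
          for b in names[i + 1:]}
    # cluster state: representative smallest leaf -> (newick, size, height)
    active = {nm: (nm, 1, 0.0) for nm in names}
    while len(active) > 1:
        reps = sorted(active)
        best = None
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                key = (dm[frozenset((a, b))], a, b)
                if best is None or key < best:
                    best = key
        dist, a, b = best
        (nwk_a, sz_a, h_a), (nwk_b, sz_b, h_b) = active[a], active[b]
        h = dist / 2.0
        merged = f"({nwk_a}:{h - h_a:.10g},{nwk_b}:{h - h_b:.10g})"
        for c in reps:
            if c in (a, b):
                continue
            dnew = (sz_a * dm[frozenset((a, c))] + sz_b * dm[frozenset((b, c))]) / (sz_a + sz_b)
            dm[frozenset((a, c))] = dnew
        del active[b]
        active[a] = (merged, sz_a + sz_b, h)
    (nwk, _, _), = active.values()
    return nwk + ";"


def shared_feature_counts(tab: AbundanceTable, meta: SampleMetadata
                          ) -> pd.DataFrame:
    """Per-rank counts of features shared between the two groups and unique
    to each (presence = abundance > 0 in at least one sample of a group)."""
    ranks = tab.rank if tab.rank is not None else pd.Series(
        Rank.unknown, index=tab.feature_ids)
    vals = tab.data
    present = {}
    for g in ("MK", "NS"):
        ids = [s for s in meta.ids_in(g) if s in vals.index]
        present[g] = (vals.loc[ids] > 0).any(axis=0)
    ranks = pd.Series(ranks, index=tab.feature_ids).map(
        lambda r: getattr(r, "value", None) or str(r))
    rows = []
    for rk in pd.unique(ranks):
        feats = ranks.index[ranks == rk]
        mk, ns = present["MK"].loc[feats], present["NS"].loc[feats]
        rows.append({
            "rank": rk,
            "shared": int((mk & ns).sum()),
            "MK_only": int((mk & ~ns).sum()),
            "NS_only": int((~mk & ns).sum()),
        })
    return pd.DataFrame(rows).set_index("rank")
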