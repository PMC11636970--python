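"""Two-class feature screening.

Taxa and pathways are screened LEfSe-style: a per-feature rank-sum test
gates features at p < alpha, then a bootstrapped one-dimensional Fisher
discriminant converts group separation into a log10 effect size (the "LDA
score"); the call rule is p < alpha AND score >= cut (2.5 for taxa, 3 for
pathways by default).  Metabolites are screened with an OPLS-DA model: VIP
on the predictive component plus a Student's t-test with Benjamini-
Hochberg correction; the call rule is VIP > 1 AND q < 0.05.

The LEfSe subclass stage is omitted: the design is a plain two-group
comparison (MK vs NS) with no subclass structure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import AbundanceTable, MetaboliteMatrix, SampleMetadata, ValidationError

log = logging.getLogger("keloidomics.differential")


# ---------------------------------------------------------------------------
# elementary tests

def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Wilcoxon-Mann-Whitney two-sided test.

    Exact enumeration when the pooled sample size is <= 12 and tie-free;
    otherwise the tie-corrected normal approximation (no continuity
    correction, so identical samples give p = 1 exactly).
    Returns (U statistic for x, two-sided p).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    if x.size + y.size <= 12 and tie_free:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def student_t_test(x: Sequence[float], y: Sequence[float],
                   welch: bool = False) -> Tuple[float, float, bool]:
    """Student's pooled-variance t-test (Welch by flag).

    Returns (t, two-sided p, degenerate).  With zero pooled variance the
    result is degenerate: p = 1 for equal means, p = 0 otherwise.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least two observations")
    sx, sy = x.var(ddof=1), y.var(ddof=1)
    if sx == 0 and sy == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0, True
        return math.inf, 0.0, True
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p), False


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# LEfSe-style LDA effect size

@dataclass
class FeatureCallTable:
    """Per-feature screening statistics and significance calls."""

    table: pd.DataFrame
    # columns: mean_MK, mean_NS, p_value, q_value, lda_score?, vip?,
    #          enriched_group, significant

    def significant_ids(self) -> List[str]:
        return list(self.table.index[self.table["significant"]])


def _fisher_direction(xa: np.ndarray, xb: np.ndarray, ridge: float) -> np.ndarray:
    """One-dimensional Fisher LDA direction with the pooled within-class
    covariance shrunk by a ridge relative to its mean variance."""
    ma, mb = xa.mean(axis=0), xb.mean(axis=0)
    ca = np.cov(xa, rowvar=False, ddof=1) if xa.shape[0] > 1 else np.zeros((xa.shape[1],) * 2)
    cb = np.cov(xb, rowvar=False, ddof=1) if xb.shape[0] > 1 else np.zeros((xb.shape[1],) * 2)
    sw = np.atleast_2d((ca + cb) / 2.0)
    mean_var = np.trace(sw) / sw.shape[0]
    sw = sw + ridge * max(mean_var, 1e-12) * np.eye(sw.shape[0])
    return np.linalg.solve(sw, ma - mb)


def lda_effect_size(tab: AbundanceTable, meta: SampleMetadata,
                    alpha: float = 0.05, n_boot: int = 30,
                    boot_frac: float = 2.0 / 3.0, ridge: float = 1e-3,
                    lda_cut: float = 2.5, seed: int = 0) -> FeatureCallTable:
    """LEfSe-style two-stage screen of an abundance table.

    Stage 1 keeps features whose rank-sum p < alpha.  Stage 2 bootstraps a
    Fisher discriminant over the surviving features (values scaled to a
    per-sample sum of 1e6, the LEfSe convention) and converts the class
    separation into score = log10(1 + mean bootstrap effect).  A feature is
    significant when p < alpha AND score >= lda_cut.
    """
    samples = [s for s in tab.sample_ids if s in meta.group.index]
    labels = meta.labels_for(samples)
    vals = tab.data.loc[samples].to_numpy(dtype=float)
    sums = vals.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValidationError("all-zero sample in abundance table")
    x = vals / sums * 1e6
    feats = tab.feature_ids
    a, b = labels == "MK", labels == "NS"
    na, nb = int(a.sum()), int(b.sum())
    ba, bb = math.ceil(boot_frac * na), math.ceil(boot_frac * nb)
    if min(ba, bb) < 3:
        raise ValueError("a class has fewer than 3 samples after bootstrap sizing")

    stat = np.empty(len(feats))
    pvec = np.empty(len(feats))
    for j in range(len(feats)):
        stat[j], pvec[j] = rank_sum_test(x[a, j], x[b, j])
    qvec = bh_fdr(pvec)
    keep = np.flatnonzero(pvec < alpha)
    log.info("LDA stage 1: %d of %d features pass p<%g", keep.size, len(feats), alpha)

    score = np.full(len(feats), np.nan)
    if keep.size:
        rng = np.random.default_rng(seed)
        xa_all, xb_all = x[a][:, keep], x[b][:, keep]
        effects = np.zeros((n_boot, keep.size))
        for bi in range(n_boot):
            ia = rng.integers(na, size=ba)
            ib = rng.integers(nb, size=bb)
            xa, xb = xa_all[ia], xb_all[ib]
            w = _fisher_direction(xa, xb, ridge)
            ma, mb = xa.mean(axis=0), xb.mean(axis=0)
            wnorm = np.linalg.norm(w)
            proj_gap = abs(float(w @ ma - w @ mb)) / wnorm if wnorm > 0 else 0.0
            effects[bi] = (np.abs(ma - mb) + np.abs(w) * proj_gap) / 2.0
        score[keep] = np.log10(1.0 + effects.mean(axis=0))

    mean_mk = x[a].mean(axis=0)
    mean_ns = x[b].mean(axis=0)
    enriched = np.where(mean_mk >= mean_ns, "MK", "NS")
    significant = (pvec < alpha) & (np.nan_to_num(score, nan=-np.inf) >= lda_cut)
    df = pd.DataFrame({
        "mean_MK": mean_mk, "mean_NS": mean_ns,
        "p_value": pvec, "q_value": qvec, "lda_score": score,
        "enriched_group": enriched, "significant": significant,
    }, index=feats)
    log.info("LDA calls: %d significant at score>=%g", int(significant.sum()), lda_cut)
    return FeatureCallTable(df)


# ---------------------------------------------------------------------------
# OPLS-DA + VIP

@dataclass
class OPLSModel:
    w_pred: np.ndarray       # predictive weights (unit norm)
    t_pred: np.ndarray       # predictive scores
    w_ortho: np.ndarray      # (n_ortho, J) orthogonal weights
    t_ortho: np.ndarray      # (n, n_ortho) orthogonal scores
    features: List[str]


def _opls_fit(x: np.ndarray, y: np.ndarray, n_ortho: int) -> OPLSModel:
    """Orthogonal-filtering NIPALS: remove y-orthogonal variation from X,
    then fit one predictive PLS component."""
    xr = x.copy()
    w_os, t_os = [], []
    for _ in range(n_ortho):
        w = xr.T @ y / (y @ y)
        w /= np.linalg.norm(w)
        t = xr @ w
        p = xr.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        norm = np.linalg.norm(w_o)
        if norm < 1e-12:
            break
        w_o /= norm
        t_o = xr @ w_o
        p_o = xr.T @ t_o / (t_o @ t_o)
        xr = xr - np.outer(t_o, p_o)
        w_os.append(w_o)
        t_os.append(t_o)
    w = xr.T @ y / (y @ y)
    w /= np.linalg.norm(w)
    t = xr @ w
    return OPLSModel(w, t,
                     np.array(w_os) if w_os else np.empty((0, x.shape[1])),
                     np.column_stack(t_os) if t_os else np.empty((x.shape[0], 0)),
                     [])


def _vip(model: OPLSModel, y: np.ndarray, mode: str = "pred") -> np.ndarray:
    """Variable importance in projection.

    ``pred`` restricts to the predictive component, where the multi-
    component formula collapses to sqrt(J) * |w| / ||w|| and mean(VIP^2)=1
    exactly.  ``all`` includes the orthogonal components weighted by their
    (near-zero) explained y-variance.
    """
    j = model.w_pred.size
    if mode == "pred" or model.w_ortho.shape[0] == 0:
        w = model.w_pred / np.linalg.norm(model.w_pred)
        return math.sqrt(j) * np.abs(w)
    comps = [(model.w_pred, model.t_pred)] + [
        (model.w_ortho[i], model.t_ortho[:, i]) for i in range(model.w_ortho.shape[0])]
    ssy, wsq = [], []
    for w, t in comps:
        q = (y @ t) / (t @ t)
        ssy.append(q * q * (t @ t))
        wn = w / np.linalg.norm(w)
        wsq.append(wn**2)
    ssy = np.asarray(ssy)
    wsq = np.asarray(wsq)
    return np.sqrt(j * (ssy @ wsq) / ssy.sum())


def oplsda_vip(mets: MetaboliteMatrix, meta: SampleMetadata, n_ortho: int = 1,
               vip_cut: float = 1.0, fdr_cut: float = 0.05,
               vip_mode: str = "pred", welch: bool = False) -> FeatureCallTable:
    """OPLS-DA screen of a metabolite matrix: VIP > vip_cut AND BH q <
    fdr_cut from a per-feature Student's t-test.

    Features are centered and unit-variance scaled; zero-variance features
    are excluded with a warning.  y is the class label encoded +/-1.
    """
    samples = [s for s in mets.sample_ids if s in meta.group.index]
    labels = meta.labels_for(samples)
    a, b = labels == "MK", labels == "NS"
    if min(a.sum(), b.sum()) < 3:
        raise ValueError("need at least 3 samples per class")
    data = mets.data.loc[samples]
    sd = data.std(ddof=1)
    dropped = list(sd.index[sd == 0])
    if dropped:
        log.warning("%d zero-variance metabolites excluded", len(dropped))
        data = data.drop(columns=dropped)
    x = ((data - data.mean()) / data.std(ddof=1)).to_numpy(dtype=float)
    y = np.where(a, 1.0, -1.0)
    y = y - y.mean()

    model = _opls_fit(x, y, n_ortho)
    vip = _vip(model, y, vip_mode)

    feats = list(data.columns)
    pvec = np.empty(len(feats))
    for jx in range(len(feats)):
        _, pvec[jx], _ = student_t_test(data.iloc[:, jx][a], data.iloc[:, jx][b],
                                        welch=welch)
    qvec = bh_fdr(pvec)
    mean_mk = data[a].mean().to_numpy()
    mean_ns = data[b].mean().to_numpy()
    enriched = np.where(mean_mk >= mean_ns, "MK", "NS")
    significant = (vip > vip_cut) & (qvec < fdr_cut)
    df = pd.DataFrame({
        "mean_MK": mean_mk, "mean_NS": mean_ns,
        "p_value": pvec, "q_value": qvec, "vip": vip,
        "enriched_group": enriched, "significant": significant,
    }, index=feats)
    log.info("OPLS-DA calls: %d significant (VIP>%g, q<%g)",
             int(significant.sum()), vip_cut, fdr_cut)
    return FeatureCallTable(df)


# ---------------------------------------------------------------------------
# set enrichment & calibration curves

@dataclass
class EnrichmentResult:
    set_name: str
    k_hits: int
    set_size: int
    n_selected: int
    n_universe: int
    p_value: float
    q_value: float


def set_enrichment(selected: Sequence[str], universe: Sequence[str],
                   annotation: Dict[str, Sequence[str]]) -> List[EnrichmentResult]:
    """Hypergeometric upper-tail over-representation per set, BH across
    sets.  The background is the full universe of detected features."""
    universe = list(dict.fromkeys(universe))
    if not universe:
        raise ValueError("empty universe")
    uset = set(universe)
    sel = set(selected)
    if not sel <= uset:
        raise ValueError("selected features must be a subset of the universe")
    names, pvals, rows = [], [], []
    for name, members in annotation.items():
        in_uni = uset & set(members)
        k = len(sel & in_uni)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_uni), len(sel)))
        names.append(name)
        pvals.append(min(p, 1.0))
        rows.append((name, k, len(in_uni), len(sel), len(universe)))
    qvals = bh_fdr(pvals) if pvals else []
    return [EnrichmentResult(n, k, ssz, nsel, nuni, p, q)
            for (n, k, ssz, nsel, nuni), p, q in zip(rows, pvals, qvals)]


def standard_curve_quantify(calibration: Sequence[Tuple[float, float]],
                            responses: Sequence[float]
                            ) -> Tuple[np.ndarray, np.ndarray]:
    """Concentrations from instrument responses via an OLS standard curve
    response = a * conc + b.  Returns (concentrations, extrapolated flags)
    where a flag marks responses outside the calibrated response range."""
    cal = np.asarray(calibration, dtype=float)
    if cal.shape[0] < 2 or np.unique(cal[:, 0]).size < 2:
        raise ValueError("need >=2 calibration points with distinct concentrations")
    conc, resp = cal[:, 0], cal[:, 1]
    a, b = np.polyfit(conc, resp, 1)
    if abs(a) <= 1e-12 * max(1.0, abs(b)):
        raise ValueError("flat calibration curve: concentration not identifiable")
    r = np.asarray(responses, dtype=float)
    est = (r - b) / a
    lo, hi = resp.min(), resp.max()
    flags = (r < lo) | (r > hi)
    return est, flags
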