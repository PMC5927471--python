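"""Statistical contrasts on network summaries.

The comparisons mirror common longitudinal microbiome designs: are
network structures more similar within a subject (or family) than
between subjects; do groups of samples (diet, BMI class, skin
micro-environment) differ in network dissimilarity or average
centrality?

Implemented tests:

* ANOSIM (Clarke's R) with label permutation on a fixed dissimilarity
  matrix; ``R = (rb - rw) / (M/2)`` with rb / rw the mean between- and
  within-group ranks of the n(n-1)/2 pairwise dissimilarities.
* Paired Wilcoxon signed-rank, exact (mid-ranked ties, zeros dropped)
  up to n = 25 and normal approximation above.
* One-way ANOVA with post hoc Tukey HSD (adjusted p-values and 95%
  confidence intervals per pair).
* Holm step-down multiple-testing correction.
* Nonmetric multidimensional scaling (NMDS) ordination of a
  dissimilarity matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import MDS
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger("phagenet")


@dataclass(frozen=True)
class StatResult:
    """One statistical test outcome."""

    name: str
    statistic: float
    p_value: float
    n: int
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r(ranks: np.ndarray, same_group: np.ndarray) -> float:
    m = len(ranks)
    rw = ranks[same_group].mean()
    rb = ranks[~same_group].mean()
    return float((rb - rw) / (m / 2.0))


def anosim(dist: pd.DataFrame, groups: Mapping[str, str] | Sequence[str],
           n_perm: int = 999, seed: int = 0) -> StatResult:
    """Analysis of similarity on a sample dissimilarity matrix.

    ``groups`` maps sample id to group label (or lists labels in matrix
    order).  The p-value is the permutation tail probability
    ``(1 + #{R_perm >= R_obs}) / (n_perm + 1)``; group labels are
    permuted while the distance matrix stays fixed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(dist.index)
    if isinstance(groups, Mapping):
        labels = np.array([groups[s] for s in ids])
    else:
        labels = np.asarray(list(groups))
        if len(labels) != len(ids):
            raise ValueError("one group label per sample required")
    if len(np.unique(labels)) < 2:
        raise ValueError("ANOSIM needs >= 2 groups")
    D = dist.to_numpy(dtype=float)
    iu = np.triu_indices(len(ids), k=1)
    ranks = stats.rankdata(D[iu])
    same = np.equal.outer(labels, labels)[iu]
    r_obs = _anosim_r(ranks, same)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        same_p = np.equal.outer(perm, perm)[iu]
        if _anosim_r(ranks, same_p) >= r_obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return StatResult(name="anosim", statistic=r_obs, p_value=p,
                      n=len(ids), n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Paired Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided signed-rank p with mid-ranked ties.

    Ranks of |d| are doubled to integers; the null distribution of the
    positive-rank sum is built by the standard generating-function DP
    over all 2^n sign assignments.
    """
    ranks = stats.rankdata(np.abs(d))
    r2 = np.round(2 * ranks).astype(int)
    w_pos = int(r2[d > 0].sum())
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = 0.5 * (dist + shifted)
    cdf = float(dist[:w_pos + 1].sum())
    sf = float(dist[w_pos:].sum())
    return min(1.0, 2.0 * min(cdf, sf))


def paired_wilcoxon(x: Sequence[float], y: Sequence[float],
                    exact_max_n: int = 25) -> StatResult:
    """Two-sided paired Wilcoxon signed-rank test.

    Zero differences are dropped; the exact distribution (ties
    mid-ranked) is enumerated up to ``exact_max_n`` non-zero pairs and
    the tie-corrected normal approximation is used above.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    d = x - y
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("degenerate Wilcoxon input: all differences zero")
    if len(d) <= exact_max_n:
        p = _exact_signed_rank_p(d)
        method = "exact"
    else:
        p = float(stats.wilcoxon(d, method="approx",
                                 correction=True).pvalue)
        method = "approx"
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    logger.debug("paired Wilcoxon (%s): n=%d W+=%.1f p=%.4g",
                 method, len(d), w_pos, p)
    return StatResult(name=f"wilcoxon_{method}", statistic=w_pos,
                      p_value=p, n=len(d))


# ---------------------------------------------------------------------------
# Intra- vs inter-unit dissimilarity contrast
# ---------------------------------------------------------------------------

def intra_inter_contrast(dist: pd.DataFrame, design: pd.DataFrame,
                         level: str = "subject",
                         site_stratum: str | None = None,
                         ) -> tuple[pd.DataFrame, StatResult]:
    """Within-unit vs between-unit network dissimilarity, paired by unit.

    For every unit (subject or family) with >= 2 timepoints:
    *intra* is the mean dissimilarity among that unit's own samples
    across time, and *inter* is the mean dissimilarity between the
    unit's samples and all other units' samples (restricted to the same
    stratum when ``site_stratum`` names a design column).  The paired
    (intra, inter) values are compared by a two-sided paired Wilcoxon
    signed-rank test.
    """
    if level not in design.columns:
        raise ValueError(f"design has no {level!r} column")
    design = design.set_index("sample_id") if "sample_id" in design.columns \
        else design
    rows = []
    for unit, sub in design.groupby(level):
        unit_samples = [s for s in sub.index if s in dist.index]
        if len(unit_samples) < 2:
            continue
        intra_vals = [dist.loc[a, b]
                      for i, a in enumerate(unit_samples)
                      for b in unit_samples[i + 1:]]
        inter_vals = []
        for a in unit_samples:
            stratum = design.loc[a, site_stratum] if site_stratum else None
            for b in dist.index:
                if design.loc[b, level] == unit:
                    continue
                if site_stratum and design.loc[b, site_stratum] != stratum:
                    continue
                inter_vals.append(dist.loc[a, b])
        if not inter_vals:
            continue
        rows.append({level: unit,
                     "intra": float(np.mean(intra_vals)),
                     "inter": float(np.mean(inter_vals))})
    if not rows:
        raise ValueError("no unit has repeated sampling")
    table = pd.DataFrame(rows)
    result = paired_wilcoxon(table["intra"], table["inter"])
    return table, result


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

def nmds(dist: pd.DataFrame, dims: int = 2, restarts: int = 4,
         seed: int = 0, max_iter: int = 300,
         ) -> tuple[pd.DataFrame, float]:
    """Nonmetric MDS ordination of a dissimilarity matrix.

    Runs SMACOF with ``restarts`` random initializations and returns the
    best embedding plus its normalized stress (Kruskal stress-1 style;
    0 is a perfect rank-order fit).
    """
    if dims < 1:
        raise ValueError("dims must be >= 1")
    try:  # scikit-learn >= 1.9 parameter names
        mds = MDS(n_components=dims, metric_mds=False, metric="precomputed",
                  init="random", n_init=restarts, random_state=seed,
                  max_iter=max_iter, normalized_stress=True)
    except TypeError:
        mds = MDS(n_components=dims, metric=False,
                  dissimilarity="precomputed", n_init=restarts,
                  random_state=seed, max_iter=max_iter,
                  normalized_stress=True)
    coords = mds.fit_transform(dist.to_numpy(dtype=float))
    frame = pd.DataFrame(coords, index=dist.index,
                         columns=[f"NMDS{i + 1}" for i in range(dims)])
    return frame, float(mds.stress_)


# ---------------------------------------------------------------------------
# ANOVA + Tukey, Holm
# ---------------------------------------------------------------------------

def anova_tukey(values: Sequence[float], groups: Sequence[str],
                alpha: float = 0.05) -> dict:
    """One-way ANOVA with post hoc Tukey HSD.

    Returns the ANOVA F and p plus a per-pair table with the mean
    difference, Tukey-adjusted p and the (1 - alpha) confidence
    interval for each of the k(k-1)/2 group pairs.
    """
    values = np.asarray(list(values), dtype=float)
    labels = np.asarray(list(groups))
    if len(values) != len(labels):
        raise ValueError("values and groups must align")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs >= 2 values")
    f_stat, p = stats.f_oneway(*[values[labels == g] for g in uniq])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(tukey.summary().data[1:],
                         columns=tukey.summary().data[0])
    table = table.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    return {"anova": StatResult(name="anova", statistic=float(f_stat),
                                p_value=float(p), n=len(values)),
            "tukey": table}


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    m = len(p)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted
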