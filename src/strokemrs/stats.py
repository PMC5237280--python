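"""Univariate follow-up statistics for selected spectral features.

Distribution checks (Lilliefors-corrected Kolmogorov-Smirnov, Levene),
the Kruskal-Wallis omnibus test across the three classes, Dunn's
rank-based post-hoc pairwise z tests with Bonferroni adjustment, and
median/IQR summaries of the normalized peak heights.

Percentile convention matters for reproducing interquartile ranges:
linear interpolation between order statistics (R/NumPy type 7) is the
default; the type-6 (Weibull) rule used by some commercial packages is
available via `percentile_method="weibull"`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.stats
from statsmodels.stats.diagnostic import lilliefors

from .core import Cohort

__all__ = [
    "FeatureSummary",
    "normality_check",
    "kruskal_wallis",
    "posthoc_pairwise",
    "summarize_feature",
]


@dataclass
class FeatureSummary:
    datapoint_index: int
    ppm: float
    per_class: dict  # class -> (median, q25, q75) or None for an empty class
    kw_h: float
    kw_p: float
    posthoc: list  # [((class_a, class_b), adjusted_p)]


def normality_check(groups: dict) -> dict:
    """Lilliefors KS p-value per group plus a Levene p across groups.

    Groups with fewer than 3 values are skipped with a warning.  Returns
    {"ks": {group: p}, "levene": p}.
    """
    ks = {}
    usable = []
    for name, vals in groups.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 3:
            warnings.warn(f"group {name!r} has <3 values; normality check skipped")
            continue
        if np.ptp(vals) == 0:
            ks[name] = 0.0  # a point mass is maximally non-normal
        else:
            _, p = lilliefors(vals, dist="norm")
            ks[name] = float(p)
        usable.append(vals)
    levene_p = float("nan")
    if len(usable) >= 2:
        _, levene_p = scipy.stats.levene(*usable)
    return {"ks": ks, "levene": float(levene_p)}


def kruskal_wallis(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with its chi-square p-value."""
    arrays = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(arrays) < 2:
        raise ValueError("kruskal_wallis needs at least 2 non-empty groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = scipy.stats.kruskal(*arrays)
    return float(h), float(p)


def posthoc_pairwise(groups: dict, adjust: str = "bonferroni") -> list:
    """Dunn's rank-based pairwise z tests after a Kruskal-Wallis omnibus.

    Returns [((name_a, name_b), adjusted_p)] for every pair; two-sided
    p-values are Bonferroni-multiplied by the number of pairs (capped
    at 1).
    """
    names = [n for n, v in groups.items() if len(v) > 0]
    if len(names) < 2:
        raise ValueError("posthoc_pairwise needs at least 2 non-empty groups")
    arrays = {n: np.asarray(groups[n], dtype=float) for n in names}
    pooled = np.concatenate([arrays[n] for n in names])
    N = pooled.size
    ranks = scipy.stats.rankdata(pooled)
    mean_rank, start = {}, 0
    for n in names:
        k = arrays[n].size
        mean_rank[n] = ranks[start : start + k].mean()
        start += k
    # tie correction to the rank variance
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        se = np.sqrt(base_var * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        if se == 0:
            p = 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / se
            p = 2.0 * scipy.stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p = min(1.0, p * m)
        elif adjust is not None and adjust != "none":
            raise ValueError(f"unknown adjustment {adjust!r}")
        out.append(((a, b), float(p)))
    return out


def summarize_feature(
    cohort: Cohort,
    datapoint_index: int,
    percentile_method: str = "linear",
) -> FeatureSummary:
    """Median (IQR) per class of one datapoint's normalized heights,
    with the Kruskal-Wallis omnibus and Dunn post-hoc results."""
    groups = {
        c: np.array(
            [r.intensities[datapoint_index] for r in cohort.records if r.label == c]
        )
        for c in cohort.class_labels
    }
    per_class = {}
    for c, vals in groups.items():
        if vals.size == 0:
            per_class[c] = None
            continue
        q25, med, q75 = np.quantile(vals, [0.25, 0.5, 0.75], method=percentile_method)
        per_class[c] = (float(med), float(q25), float(q75))
    nonempty = [v for v in groups.values() if v.size > 0]
    if len(nonempty) >= 2:
        h, p = kruskal_wallis(nonempty)
        post = posthoc_pairwise({c: v for c, v in groups.items() if v.size > 0})
    else:
        h, p, post = float("nan"), float("nan"), []
    ppm = float(cohort.axis[datapoint_index])
    return FeatureSummary(datapoint_index, ppm, per_class, h, p, post)
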