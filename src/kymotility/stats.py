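"""Hierarchical superplot aggregation and the nonparametric statistics battery.

The battery mirrors a common workflow for grouped single-molecule data:
each group is first screened for normality with the D'Agostino–Pearson K²
omnibus test.  If every group passes, pairwise two-tailed independent
t-tests are used; otherwise a Kruskal–Wallis H omnibus test is followed by
Conover–Iman (or Dunn) pairwise post hoc tests.  Pairwise p values are
corrected with Holm–Bonferroni.

Statistics default to per-microtubule values; aggregation supports the
track -> microtubule -> movie -> experiment hierarchy so that superplots
can show individual microtubules alongside per-experiment means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps
from statsmodels.stats.multitest import multipletests

from kymotility.io_model import ExperimentManifest

__all__ = [
    "SuperplotSummary",
    "TestResult",
    "PairwiseResult",
    "aggregate",
    "directionality_proportions",
    "dagostino_pearson",
    "kruskal_wallis",
    "conover_posthoc",
    "dunn_posthoc",
    "holm_bonferroni",
    "motility_battery",
    "CLASS_LABELS",
]

CLASS_LABELS = ("minus", "plus", "static", "bidirectional")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    df: float | None = None
    p_adjusted: float | None = None


@dataclass(frozen=True)
class PairwiseResult:
    """Pairwise post hoc matrices (index/columns are group names)."""

    statistic: pd.DataFrame
    pvalue: pd.DataFrame
    method: str
    df: float | None = None

    def pairs(self) -> list[tuple[str, str]]:
        names = list(self.pvalue.index)
        return list(combinations(names, 2))

    def flat_pvalues(self) -> pd.Series:
        """Upper-triangle raw p values keyed by (group_a, group_b)."""
        return pd.Series({(a, b): self.pvalue.loc[a, b] for a, b in self.pairs()})


@dataclass(frozen=True)
class SuperplotSummary:
    """Hierarchical summary of one metric.

    ``values`` are the raw per-unit values (typically per microtubule);
    ``group_means`` are their means within each group at the requested
    level (typically per experiment).  Pooled order statistics describe the
    raw values: median, quartiles, and the 10th/90th percentiles used as
    whisker bounds.
    """

    level: str
    values: pd.Series = field(repr=False)
    group_means: pd.Series = field(repr=False)
    pooled_median: float = 0.0
    quartile1: float = 0.0
    quartile3: float = 0.0
    p10: float = 0.0
    p90: float = 0.0

    @property
    def n_values(self) -> int:
        return int(self.values.size)

    @property
    def n_groups(self) -> int:
        return int(self.group_means.size)


def aggregate(
    values: Mapping[str, float] | pd.Series,
    manifest: ExperimentManifest,
    level: str = "experiment",
) -> SuperplotSummary:
    """Summarize per-unit values at a grouping level of the manifest.

    *values* is keyed by track id (or context id when the values are
    already per microtubule — context ids are resolved through the
    manifest's context column).  Any key that does not map through the
    manifest raises ``KeyError`` naming the orphan.
    """
    s = pd.Series(values, dtype=float)
    tbl = manifest.table
    col = {"condition": "condition", "experiment": "experiment_id", "movie": "movie_id", "mt": "context_id", "microtubule": "context_id"}
    if level not in col:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(col)}")
    if s.index.isin(tbl["track_id"]).all():
        key = tbl.drop_duplicates("track_id").set_index("track_id")[col[level]]
    elif s.index.isin(tbl["context_id"]).all():
        key = tbl.drop_duplicates("context_id").set_index("context_id")[col[level]]
    else:
        orphans = s.index[~(s.index.isin(tbl["track_id"]) | s.index.isin(tbl["context_id"]))]
        raise KeyError(f"value id(s) {list(orphans[:5])} not mapped by the manifest")
    groups = key.loc[s.index]
    group_means = s.groupby(groups.values).mean()
    q1, med, q3 = np.percentile(s, [25, 50, 75])
    p10, p90 = np.percentile(s, [10, 90])
    return SuperplotSummary(
        level=level,
        values=s,
        group_means=group_means,
        pooled_median=float(med),
        quartile1=float(q1),
        quartile3=float(q3),
        p10=float(p10),
        p90=float(p90),
    )


def directionality_proportions(
    labels: Mapping[str, str] | pd.Series | Sequence[str],
    manifest: ExperimentManifest | None = None,
) -> pd.DataFrame:
    """Per-class pooled counts and fractions plus per-experiment mean ± s.d.

    Pooled fractions (count / total) and per-experiment means generally
    differ; both are reported, explicitly labeled.  Without a manifest all
    tracks are treated as one experiment.  Returns a DataFrame indexed by
    class label with columns ``count``, ``pooled_fraction``,
    ``experiment_mean_fraction``, ``experiment_sd_fraction``.
    """
    if isinstance(labels, (pd.Series, Mapping)):
        s = pd.Series(labels, dtype=str)
    else:
        s = pd.Series(list(labels), dtype=str)
    bad = set(s) - set(CLASS_LABELS)
    if bad:
        raise ValueError(f"unknown class label(s) {sorted(bad)}")
    if manifest is not None:
        exp = manifest.group_of(list(s.index), "experiment")
        exp.index = s.index
    else:
        exp = pd.Series("experiment_1", index=s.index)
    df = pd.DataFrame({"label": s.values, "experiment": exp.values})
    counts = df["label"].value_counts().reindex(CLASS_LABELS, fill_value=0)
    total = int(counts.sum())
    per_exp = (
        df.groupby("experiment")["label"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=CLASS_LABELS, fill_value=0.0)
    )
    mean = per_exp.mean(axis=0)
    sd = per_exp.std(axis=0, ddof=1).fillna(0.0)
    return pd.DataFrame(
        {
            "count": counts.astype(int),
            "pooled_fraction": counts / total if total else 0.0,
            "experiment_mean_fraction": mean,
            "experiment_sd_fraction": sd,
        }
    )


def dagostino_pearson(sample: Sequence[float], min_n: int = 20, force: bool = False) -> TestResult:
    """D'Agostino–Pearson K² omnibus normality test.

    Combines the skewness and kurtosis z-scores as K² = z₁² + z₂², referred
    to a χ² distribution with 2 degrees of freedom.  The z transforms are
    the standard small-sample normalizations of √b₁ and b₂.  Samples
    smaller than *min_n* are refused by default (the omnibus approximation
    is unreliable there); pass ``force=True`` to proceed with a warning.
    """
    x = np.asarray(sample, dtype=float)
    n = x.size
    if n < min_n:
        if not force:
            raise ValueError(f"sample size {n} < {min_n}; K² omnibus test refused (use force=True)")
        warnings.warn(f"K² omnibus test on small sample (n={n}) is unreliable", stacklevel=2)
    if n < 8:
        raise ValueError("K² needs n >= 8 for the kurtosis z transform")
    mu = x.mean()
    m2 = np.mean((x - mu) ** 2)
    if m2 == 0:
        raise ValueError("constant sample: skewness/kurtosis undefined")
    m3 = np.mean((x - mu) ** 3)
    m4 = np.mean((x - mu) ** 4)

    # skewness z (D'Agostino's transform of g1 = m3 / m2^1.5)
    g1 = m3 / m2**1.5
    y = g1 * math.sqrt((n + 1) * (n + 3) / (6.0 * (n - 2)))
    beta2 = 3.0 * (n**2 + 27 * n - 70) * (n + 1) * (n + 3) / ((n - 2.0) * (n + 5) * (n + 7) * (n + 9))
    w2 = -1.0 + math.sqrt(2.0 * (beta2 - 1.0))
    delta = 1.0 / math.sqrt(0.5 * math.log(w2))
    alpha = math.sqrt(2.0 / (w2 - 1.0))
    y = y / alpha
    z1 = delta * math.log(y + math.sqrt(y * y + 1.0))

    # kurtosis z (Anscombe–Glynn transform of b2 = m4 / m2^2)
    b2 = m4 / m2**2
    e_b2 = 3.0 * (n - 1) / (n + 1.0)
    var_b2 = 24.0 * n * (n - 2) * (n - 3) / ((n + 1.0) ** 2 * (n + 3) * (n + 5))
    xx = (b2 - e_b2) / math.sqrt(var_b2)
    sqrt_beta1 = (
        6.0 * (n * n - 5 * n + 2) / ((n + 7.0) * (n + 9))
        * math.sqrt(6.0 * (n + 3) * (n + 5) / (n * (n - 2.0) * (n - 3)))
    )
    a = 6.0 + 8.0 / sqrt_beta1 * (2.0 / sqrt_beta1 + math.sqrt(1.0 + 4.0 / sqrt_beta1**2))
    denom = 1.0 + xx * math.sqrt(2.0 / (a - 4.0))
    term = (1.0 - 2.0 / a) / denom
    z2 = ((1.0 - 2.0 / (9.0 * a)) - np.sign(term) * abs(term) ** (1.0 / 3.0)) / math.sqrt(2.0 / (9.0 * a))

    k2 = z1 * z1 + z2 * z2
    p = float(sps.chi2.sf(k2, 2))
    return TestResult(statistic=float(k2), p=p, method="dagostino_pearson_k2", df=2)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H test (χ² approximation, k−1 df)."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrs):
        raise ValueError("every group needs >= 1 value")
    pooled = np.concatenate(arrs)
    if np.all(pooled == pooled[0]):
        # every value identical: no evidence of any difference
        return TestResult(statistic=0.0, p=1.0, method="kruskal_wallis_h", df=len(arrs) - 1)
    h, p = sps.kruskal(*arrs)
    return TestResult(statistic=float(h), p=float(p), method="kruskal_wallis_h", df=len(arrs) - 1)


def _ranked(groups: Mapping[str, Sequence[float]]) -> tuple[list[str], list[np.ndarray], np.ndarray]:
    names = list(groups)
    arrs = [np.asarray(groups[k], dtype=float) for k in names]
    if any(a.size == 0 for a in arrs):
        empty = [k for k, a in zip(names, arrs) if a.size == 0]
        raise ValueError(f"empty group(s): {empty}")
    ranks = sps.rankdata(np.concatenate(arrs))  # mid-ranks for ties
    return names, arrs, ranks


def _as_group_dict(groups) -> Mapping[str, Sequence[float]]:
    if isinstance(groups, Mapping):
        return groups
    return {f"group_{i + 1}": g for i, g in enumerate(groups)}


def conover_posthoc(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> PairwiseResult:
    """Conover–Iman pairwise comparisons on pooled ranks after Kruskal–Wallis.

    The pairwise statistic is a t statistic on rank means with the pooled
    rank variance S² and the (N−1−H)/(N−k) shrinkage term, referred to a t
    distribution with N−k degrees of freedom; ties enter through the
    mid-ranks and the tie-corrected H.  Raw two-sided p values are
    returned; apply :func:`holm_bonferroni` for the family correction.
    """
    gd = _as_group_dict(groups)
    names, arrs, ranks = _ranked(gd)
    sizes = np.array([a.size for a in arrs])
    n_total = int(sizes.sum())
    k = len(names)
    if n_total - k <= 0:
        raise ValueError("need more observations than groups")
    bounds = np.cumsum(sizes)[:-1]
    rank_groups = np.split(ranks, bounds)
    rank_means = np.array([r.mean() for r in rank_groups])
    h = kruskal_wallis(arrs).statistic
    s2 = (np.sum(ranks**2) - n_total * (n_total + 1.0) ** 2 / 4.0) / (n_total - 1.0)
    df = n_total - k
    stat = pd.DataFrame(0.0, index=names, columns=names)
    pval = pd.DataFrame(1.0, index=names, columns=names)
    var_scale = s2 * (n_total - 1.0 - h) / df
    for i, j in combinations(range(k), 2):
        if s2 == 0.0:  # all values identical
            t = 0.0
        else:
            se = math.sqrt(var_scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
            diff = rank_means[i] - rank_means[j]
            t = math.inf * np.sign(diff) if se == 0.0 else diff / se
        if t == 0.0:
            p = 1.0
        elif math.isfinite(t):
            p = float(2.0 * sps.t.sf(abs(t), df))
        else:
            p = 0.0
        stat.iloc[i, j] = t
        stat.iloc[j, i] = -t
        pval.iloc[i, j] = pval.iloc[j, i] = min(p, 1.0)
    return PairwiseResult(statistic=stat, pvalue=pval, method="conover_iman", df=df)


def dunn_posthoc(groups: Mapping[str, Sequence[float]] | Sequence[Sequence[float]]) -> PairwiseResult:
    """Dunn's pairwise z comparisons on pooled ranks, with tie correction.

    z = (R̄ᵢ − R̄ⱼ) / √[(N(N+1)/12 − ΣT/(12(N−1))) (1/nᵢ + 1/nⱼ)] where
    ΣT sums t³−t over tied groups.  Raw two-sided p values are returned.
    """
    gd = _as_group_dict(groups)
    names, arrs, ranks = _ranked(gd)
    sizes = np.array([a.size for a in arrs])
    n_total = int(sizes.sum())
    k = len(names)
    bounds = np.cumsum(sizes)[:-1]
    rank_groups = np.split(ranks, bounds)
    rank_means = np.array([r.mean() for r in rank_groups])
    _, counts = np.unique(np.concatenate(arrs), return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    var_term = n_total * (n_total + 1.0) / 12.0 - tie_sum / (12.0 * (n_total - 1.0))
    stat = pd.DataFrame(0.0, index=names, columns=names)
    pval = pd.DataFrame(1.0, index=names, columns=names)
    for i, j in combinations(range(k), 2):
        if var_term <= 0.0:  # all values identical
            z = 0.0
        else:
            se = math.sqrt(var_term * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (rank_means[i] - rank_means[j]) / se
        p = 1.0 if z == 0.0 else float(2.0 * sps.norm.sf(abs(z)))
        stat.iloc[i, j] = z
        stat.iloc[j, i] = -z
        pval.iloc[i, j] = pval.iloc[j, i] = min(p, 1.0)
    return PairwiseResult(statistic=stat, pvalue=pval, method="dunn", df=None)


def holm_bonferroni(p_values: Sequence[float]) -> np.ndarray:
    """Holm–Bonferroni step-down adjusted p values (capped at 1, monotone)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def motility_battery(
    groups: Mapping[str, Sequence[float]],
    gate_alpha: float = 0.05,
    posthoc: str = "conover",
    min_n_normality: int = 20,
) -> dict:
    """Full decision-tree comparison of >= 2 experimental groups.

    Each group is screened with the K² normality test at *gate_alpha*; if
    every group is consistent with normality, pairwise two-tailed
    independent t-tests are used, otherwise Kruskal–Wallis followed by the
    chosen post hoc.  Pairwise p values are Holm–Bonferroni corrected in
    one family across all pairs.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    normality: dict[str, TestResult | None] = {}
    for name, vals in groups.items():
        try:
            normality[name] = dagostino_pearson(vals, min_n=min_n_normality)
        except ValueError:
            # too small or degenerate for the omnibus test: fall through to
            # the nonparametric branch
            normality[name] = None
    all_normal = all(r is not None and r.p >= gate_alpha for r in normality.values())

    names = list(groups)
    if all_normal:
        omnibus = None
        recs = []
        for a, b in combinations(names, 2):
            t, p = sps.ttest_ind(np.asarray(groups[a], float), np.asarray(groups[b], float))
            recs.append(((a, b), float(t), float(p)))
        method = "t_test_independent"
        pairwise = None
    else:
        omnibus = kruskal_wallis([groups[n] for n in names])
        fn = {"conover": conover_posthoc, "dunn": dunn_posthoc}[posthoc]
        pairwise = fn(groups)
        recs = [((a, b), float(pairwise.statistic.loc[a, b]), float(pairwise.pvalue.loc[a, b])) for a, b in combinations(names, 2)]
        method = pairwise.method
    raw = np.array([r[2] for r in recs])
    adj = holm_bonferroni(raw)
    comparisons = [
        TestResult(statistic=s, p=p, p_adjusted=float(pa), method=method)
        for (_, s, p), pa in zip(recs, adj)
    ]
    return {
        "normality": normality,
        "all_normal": all_normal,
        "omnibus": omnibus,
        "pairwise": pairwise,
        "pairs": [r[0] for r in recs],
        "comparisons": comparisons,
        "method": method,
    }
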