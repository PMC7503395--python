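"""Replicate-aware group comparisons with a normality-gated test branch.

The pipeline mirrors common practice in developmental electrophysiology:
each group is first tested for normality (Shapiro-Wilk); if every group
passes, groups are compared with one-way ANOVA followed by Bonferroni-
corrected pairwise t tests, otherwise with Kruskal-Wallis followed by
Dunn's test (Bonferroni-adjusted). The unit of analysis is configurable:
individual cells as biological replicates (electrophysiology) or per-animal
means of technical replicates (AIS morphometry).

Dunn's test is implemented here directly (rank sums with tie correction)
since it is a short closed-form z-test on the pooled ranks.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import AismatureWarning, InsufficientDataError, ParameterError

__all__ = [
    "GroupedMeasurements",
    "GroupComparison",
    "summarize_replicates",
    "compare_groups",
    "dunn_test",
    "significance_stars",
    "render_summary",
]


@dataclass
class GroupedMeasurements:
    """Values per group, tagged with the animal each came from.

    ``groups`` maps a group label to a list of ``(animal_id, value)``.
    ``replicate_mode``: ``'cell_as_unit'`` treats every measurement as an
    independent biological replicate; ``'animal_mean_as_unit'`` averages the
    technical replicates within each animal first.
    """

    groups: dict
    replicate_mode: str = "cell_as_unit"

    def __post_init__(self) -> None:
        if self.replicate_mode not in ("cell_as_unit", "animal_mean_as_unit"):
            raise ParameterError(f"unknown replicate_mode {self.replicate_mode!r}")
        for label, pairs in self.groups.items():
            for _, v in pairs:
                if not np.isfinite(v):
                    raise ParameterError(f"non-finite value in group {label!r}")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str, value_col: str,
                   animal_col: str = "animal_id",
                   replicate_mode: str = "cell_as_unit") -> "GroupedMeasurements":
        groups = {}
        for label, sub in df.groupby(group_col, sort=False):
            groups[label] = list(zip(sub[animal_col], sub[value_col].astype(float)))
        return cls(groups=groups, replicate_mode=replicate_mode)

    def values(self, label) -> np.ndarray:
        return np.array([v for _, v in self.groups[label]], dtype=float)


@dataclass
class GroupComparison:
    omnibus_test: str  # 'anova' or 'kruskal_wallis'
    omnibus_p: float
    omnibus_stat: float
    posthoc_method: str | None  # 'bonferroni' (pairwise t) or 'dunn'
    pairwise_p: pd.DataFrame | None
    summaries: pd.DataFrame
    normality_p: dict
    alpha: float = 0.05

    def significant_pairs(self, alpha: float | None = None) -> list:
        if self.pairwise_p is None:
            return []
        a = self.alpha if alpha is None else alpha
        out = []
        labels = list(self.pairwise_p.index)
        for i, gi in enumerate(labels):
            for gj in labels[i + 1:]:
                if self.pairwise_p.loc[gi, gj] < a:
                    out.append((gi, gj))
        return out


def summarize_replicates(data: GroupedMeasurements) -> GroupedMeasurements:
    """Collapse technical replicates per the declared replicate mode.

    ``animal_mean_as_unit``: one value per animal (mean of its measurements);
    ``cell_as_unit``: identity. Animals with zero measurements are excluded
    with a warning.
    """
    if data.replicate_mode == "cell_as_unit":
        return data
    groups = {}
    for label, pairs in data.groups.items():
        by_animal: dict = {}
        for animal, v in pairs:
            by_animal.setdefault(animal, []).append(v)
        collapsed = []
        for animal, vals in by_animal.items():
            if not vals:
                warnings.warn(f"animal {animal} has no measurements; excluded",
                              AismatureWarning, stacklevel=2)
                continue
            collapsed.append((animal, float(np.mean(vals))))
        groups[label] = collapsed
    return GroupedMeasurements(groups=groups, replicate_mode="cell_as_unit")


def dunn_test(samples: list, labels: list) -> pd.DataFrame:
    """Dunn's multiple-comparison test on pooled ranks, Bonferroni-adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values
    multiplied by the number of pairs (capped at 1).
    """
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for s in samples:
        mean_ranks.append(ranks[start:start + len(s)].mean())
        sizes.append(len(s))
        start += len(s)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(samples)
    m = k * (k - 1) // 2
    p = pd.DataFrame(np.eye(len(labels)) * 0 + np.nan, index=labels, columns=labels)
    np.fill_diagonal(p.values, 1.0)
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        raw = 2.0 * sps.norm.sf(abs(z))
        adj = min(1.0, raw * m)
        p.iloc[i, j] = p.iloc[j, i] = adj
    return p


def _pairwise_t_bonferroni(samples: list, labels: list) -> pd.DataFrame:
    k = len(samples)
    m = k * (k - 1) // 2
    p = pd.DataFrame(np.full((k, k), np.nan), index=labels, columns=labels)
    np.fill_diagonal(p.values, 1.0)
    for i, j in itertools.combinations(range(k), 2):
        raw = sps.ttest_ind(samples[i], samples[j], equal_var=True).pvalue
        adj = min(1.0, float(raw) * m)
        p.iloc[i, j] = p.iloc[j, i] = adj
    return p


def compare_groups(
    data: GroupedMeasurements,
    alpha: float = 0.05,
    *,
    posthoc_always: bool = False,
) -> GroupComparison:
    """Normality-gated omnibus test plus (gated) post hoc pairwise comparisons.

    Shapiro-Wilk per group; all groups normal (p > alpha) -> one-way ANOVA
    and Bonferroni-corrected pairwise t tests; any group non-normal ->
    Kruskal-Wallis and Dunn's test. Post hoc p-values are computed only when
    the omnibus test is significant, unless ``posthoc_always`` is set.
    """
    data = summarize_replicates(data)
    labels = list(data.groups.keys())
    if len(labels) < 2:
        raise InsufficientDataError("need >= 2 groups")
    samples = [data.values(lbl) for lbl in labels]
    for lbl, s in zip(labels, samples):
        if s.size < 3:
            raise InsufficientDataError(f"group {lbl!r} has n = {s.size} < 3")

    normality_p = {}
    for lbl, s in zip(labels, samples):
        if np.ptp(s) == 0:
            normality_p[lbl] = 0.0  # degenerate: constant sample is not normal
        else:
            normality_p[lbl] = float(sps.shapiro(s).pvalue)
    all_normal = all(p > alpha for p in normality_p.values())

    if all_normal:
        stat, p_omni = sps.f_oneway(*samples)
        test, posthoc = "anova", "bonferroni"
    else:
        try:
            stat, p_omni = sps.kruskal(*samples)
        except ValueError:  # all values identical across every group
            stat, p_omni = 0.0, 1.0
        test, posthoc = "kruskal_wallis", "dunn"
    if np.isnan(p_omni):
        p_omni = 1.0

    pairwise = None
    if posthoc_always or p_omni < alpha:
        if posthoc == "bonferroni":
            pairwise = _pairwise_t_bonferroni(samples, labels)
        else:
            pairwise = dunn_test(samples, labels)

    summaries = pd.DataFrame(
        {
            "group": labels,
            "n": [s.size for s in samples],
            "mean": [s.mean() for s in samples],
            "sd": [s.std(ddof=1) if s.size > 1 else 0.0 for s in samples],
            "median": [np.median(s) for s in samples],
            "q1": [np.percentile(s, 25) for s in samples],
            "q3": [np.percentile(s, 75) for s in samples],
            "min": [s.min() for s in samples],
            "max": [s.max() for s in samples],
        }
    ).set_index("group")

    return GroupComparison(
        omnibus_test=test,
        omnibus_p=float(p_omni),
        omnibus_stat=float(stat),
        posthoc_method=posthoc if pairwise is not None else None,
        pairwise_p=pairwise,
        summaries=summaries,
        normality_p=normality_p,
        alpha=alpha,
    )


def significance_stars(p: float) -> str:
    """Figure-legend star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def render_summary(cmp: GroupComparison, style: str = "box") -> pd.DataFrame:
    """Flat report table: per-group summaries plus starred pairwise comparisons.

    ``style='box'`` reports median [q1, q3] min-max per group (box-plot
    convention); ``style='xy'`` reports mean +/- SD.
    """
    if style not in ("box", "xy"):
        raise ParameterError("style must be 'box' or 'xy'")
    rows = []
    for lbl, s in cmp.summaries.iterrows():
        if style == "box":
            desc = (f"{s['median']:.4g} [{s['q1']:.4g}, {s['q3']:.4g}] "
                    f"({s['min']:.4g}-{s['max']:.4g})")
        else:
            desc = f"{s['mean']:.4g} +/- {s['sd']:.4g}"
        rows.append({"kind": "group", "item": lbl, "n": int(s["n"]),
                     "value": desc, "p": np.nan, "stars": ""})
    rows.append({"kind": "omnibus", "item": cmp.omnibus_test, "n": int(cmp.summaries["n"].sum()),
                 "value": f"stat={cmp.omnibus_stat:.4g}", "p": cmp.omnibus_p,
                 "stars": significance_stars(cmp.omnibus_p)})
    if cmp.pairwise_p is not None:
        labels = list(cmp.pairwise_p.index)
        for i, gi in enumerate(labels):
            for gj in labels[i + 1:]:
                p = float(cmp.pairwise_p.loc[gi, gj])
                rows.append({"kind": "pairwise", "item": f"{gi} vs {gj}",
                             "n": np.nan, "value": cmp.posthoc_method,
                             "p": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)
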