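"""DEG filtering between subtypes and Kaplan-Meier / log-rank validation.

The survival-signature stage first reduces the gene universe to the genes
differentially expressed between two sample clusters (two-sample t test at
a strict alpha, 0.001 by default), feeds them to the selection methods, and
finally validates the aggregated signature on an independent cohort:
samples are clustered on the signature genes (complete linkage, Pearson
distance), and differences in survival between the resulting subtypes are
assessed with Kaplan-Meier curves and the log-rank test.  The estimator and
test are delegated to lifelines; this module adapts them to the pipeline's
types and conventions (events precede censorings at tied times).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster
from scipy.stats import ttest_ind

from .core_io import ExpressionDataset, SurvivalTable
from .cluster_boot import hcluster

__all__ = ["KmCurve", "t_test_deg", "kaplan_meier", "logrank_test", "validate_signature"]


@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival curve for one group."""

    group: str
    times: np.ndarray  # event-time grid (starts at 0)
    survival: np.ndarray  # S(t) at those times
    at_risk: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.size and not np.isclose(s[0], 1.0):
            raise ValueError("S(0) must be 1")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival estimates must be non-increasing")


def t_test_deg(
    dataset: ExpressionDataset,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.001,
    welch: bool = False,
) -> list[tuple[str, float, float]]:
    """Per-gene two-sided two-sample t test between two sample groups.

    Pooled-variance (Student) t by default; ``welch=True`` switches to the
    unequal-variance form.  Genes with p < alpha are returned sorted by p
    ascending (ties by gene id).  A gene with zero pooled variance and zero
    mean difference gets p = 1.
    """
    ids_a, ids_b = list(group_a), list(group_b)
    if len(ids_a) < 2 or len(ids_b) < 2:
        raise ValueError("both groups need >= 2 samples")
    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    Xa = dataset.values[:, [pos[s] for s in ids_a]]
    Xb = dataset.values[:, [pos[s] for s in ids_b]]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = ttest_ind(Xa, Xb, axis=1, equal_var=not welch)
    # degenerate genes: zero variance in both groups and equal means -> p = 1
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    hits = [
        (g, float(ti), float(pi))
        for g, ti, pi in zip(dataset.gene_ids, t, p)
        if pi < alpha
    ]
    return sorted(hits, key=lambda r: (r[2], r[0]))


def kaplan_meier(table: SurvivalTable, group: str | None = None) -> KmCurve:
    """Product-limit survival estimate for one group (or the whole table)."""
    if group is not None:
        if table.group is None:
            raise ValueError("table has no group column")
        mask = np.array([g == group for g in table.group])
        if not mask.any():
            raise ValueError(f"group {group!r} is empty")
        times, events = table.time[mask], table.event[mask]
    else:
        times, events = table.time, table.event
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index).to_numpy(dtype=float)
    return KmCurve(group or "all", grid, surv, at_risk)


def logrank_test(table: SurvivalTable, groups: Sequence[str] | None = None) -> tuple[float, int, float]:
    """Log-rank comparison of survival across groups: (chi_square, df, p).

    Uses the observed-minus-expected construction at each distinct event
    time under the hypergeometric model; chi-square with (#groups - 1)
    degrees of freedom.
    """
    if table.group is None:
        raise ValueError("table has no group column")
    grp = np.asarray(table.group)
    if groups is not None:
        mask = np.isin(grp, list(groups))
        tab = SurvivalTable(
            tuple(np.asarray(table.sample_ids)[mask]),
            table.time[mask],
            table.event[mask],
            tuple(grp[mask]),
        )
    else:
        tab = table
    labels = np.asarray(tab.group)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need >= 2 non-empty groups")
    if tab.event.sum() == 0:
        raise ValueError("no observed events; log-rank is undefined")
    res = multivariate_logrank_test(tab.time, labels, tab.event)
    df = int(uniq.size - 1)
    return float(res.test_statistic), df, float(res.p_value)


def validate_signature(
    signature: Sequence[str],
    dataset: ExpressionDataset,
    table: SurvivalTable,
    n_clusters: int = 3,
    alpha: float = 0.05,
) -> dict:
    """Cluster an independent cohort on the signature genes and test survival.

    The dataset is restricted to the signature genes present, samples are
    clustered by complete-linkage on Pearson distance and cut into
    ``n_clusters`` subtypes, and survival differences across subtypes are
    assessed by the log-rank test with per-subtype KM curves.
    """
    present = [g for g in signature if g in set(dataset.gene_ids)]
    if not present:
        raise ValueError("no signature gene present in the dataset")
    if n_clusters >= dataset.n_samples:
        raise ValueError(
            "n_clusters must be smaller than the sample count "
            "(singleton clusters leave the log-rank test undefined)"
        )
    sub = dataset.subset_genes(sorted(present))
    tree = hcluster(sub, "complete", "pearson")
    assignment = fcluster(tree.linkage_matrix, t=n_clusters, criterion="maxclust")
    groups = tuple(f"C{a}" for a in assignment)
    sub_table = table.subset(sub.sample_ids).with_group(groups)
    chi2, df, p = logrank_test(sub_table)
    curves = {g: kaplan_meier(sub_table, g) for g in sorted(set(groups))}
    return {
        "assignment": {s: g for s, g in zip(sub.sample_ids, groups)},
        "chi_square": chi2,
        "df": df,
        "p_value": p,
        "significant": bool(p < alpha),
        "curves": curves,
        "signature_genes_used": sorted(present),
    }
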