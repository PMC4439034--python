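"""Hierarchical sample clustering with bootstrap and multiscale-bootstrap support.

Samples are clustered agglomeratively on 1 - Pearson correlation of their
expression profiles (or Euclidean distance).  Cluster uncertainty follows
the two-level convention: the ordinary bootstrap probability (BP) of an
internal node is the fraction of gene-resampled dendrograms containing
exactly the same sample set, and the approximately unbiased (AU) p-value
corrects BP's bias via multiscale bootstrap — resampling ceil(r * n_genes)
genes at several ratios r spanning 1, fitting the probit-transformed BP
curve z_r = Phi^-1(1 - BP_r) to v*sqrt(r) + c/sqrt(r) by weighted least
squares, and reporting AU = 1 - Phi(v - c).  Nodes with AU above a
threshold (0.95 by convention) are the well-supported clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from scipy.stats import norm

from .core_io import ExpressionDataset
from .evaluation import sample_distance_matrix

__all__ = [
    "ClusterNode",
    "ClusterTree",
    "hcluster",
    "fit_au",
    "bootstrap_support",
    "highlight_clusters",
]

DEFAULT_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


@dataclass(frozen=True)
class ClusterNode:
    """One internal dendrogram node: its sample set, merge height, support."""

    members: frozenset[str]
    height: float
    bp: float | None = None
    au: float | None = None
    v: float | None = None
    c: float | None = None
    degenerate_fit: bool = False
    bp_per_scale: tuple[float, ...] | None = None


@dataclass(frozen=True)
class ClusterTree:
    """Dendrogram over samples with optional per-node BP / AU support."""

    sample_ids: tuple[str, ...]
    linkage_matrix: np.ndarray
    nodes: tuple[ClusterNode, ...]
    linkage_method: str = "complete"
    distance: str = "pearson"
    n_boot: int | None = None
    scales: tuple[float, ...] = ()

    @property
    def has_support(self) -> bool:
        return all(n.bp is not None for n in self.nodes)


def _internal_node_sets(Z: np.ndarray, sample_ids: Sequence[str]) -> list[tuple[frozenset, float]]:
    n = len(sample_ids)
    sets: dict[int, frozenset] = {i: frozenset([sample_ids[i]]) for i in range(n)}
    out = []
    for k, (a, b, h, _) in enumerate(Z):
        merged = sets[int(a)] | sets[int(b)]
        sets[n + k] = merged
        out.append((merged, float(h)))
    return out


def hcluster(
    dataset: ExpressionDataset,
    linkage_method: str = "complete",
    distance: str = "pearson",
) -> ClusterTree:
    """Agglomerative dendrogram over samples (supports unset).

    Pearson distance = 1 - correlation of sample profiles; a zero-variance
    sample profile is an error (its correlation is undefined).  Ties in the
    distance matrix are resolved by scipy's deterministic merge order, which
    follows sample-id (column) order.
    """
    if dataset.n_samples < 2:
        raise ValueError("need >= 2 samples to cluster")
    if linkage_method not in ("complete", "average", "single", "ward"):
        raise ValueError(f"unknown linkage {linkage_method!r}")
    try:
        D = sample_distance_matrix(dataset.values, distance)
    except ValueError as exc:
        if "zero-variance" in str(exc):
            # name the sample, not just the column
            sd = dataset.values.std(axis=0)
            bad = dataset.sample_ids[int(np.argmax(sd == 0))]
            raise ValueError(f"sample {bad!r} has zero variance under pearson distance") from None
        raise
    if linkage_method == "ward":
        Z = linkage(dataset.values.T, method="ward")
    else:
        Z = linkage(squareform(D, checks=False), method=linkage_method)
    nodes = tuple(
        ClusterNode(members=m, height=h) for m, h in _internal_node_sets(Z, dataset.sample_ids)
    )
    return ClusterTree(dataset.sample_ids, Z, nodes, linkage_method, distance)


def fit_au(
    bps: np.ndarray, scales: Sequence[float], n_boot: int
) -> tuple[float, float | None, float | None, bool]:
    """Multiscale fit of per-scale bootstrap proportions -> (au, v, c, degenerate).

    z_r = Phi^-1(1 - BP_r) is regressed on (sqrt(r), 1/sqrt(r)) by weighted
    least squares with binomial delta-method weights
    n_boot * phi(z_r)^2 / (BP_r (1 - BP_r)); au = 1 - Phi(v - c).  BP values
    are clipped to [1/(2 n_boot), 1 - 1/(2 n_boot)] before the probit; a node
    with BP in {0, 1} at every scale is unfittable and returns au = BP(1)
    with the degenerate flag set.
    """
    bps = np.asarray(bps, dtype=float)
    scales = np.asarray(scales, dtype=float)
    r1 = int(np.argmin(np.abs(scales - 1.0)))
    if np.all((bps == 0) | (bps == 1)):
        return float(bps[r1]), None, None, True
    clipped = np.clip(bps, 1.0 / (2 * n_boot), 1.0 - 1.0 / (2 * n_boot))
    z = norm.ppf(1.0 - clipped)
    w = n_boot * norm.pdf(z) ** 2 / (clipped * (1.0 - clipped))
    X = np.stack([np.sqrt(scales), 1.0 / np.sqrt(scales)], axis=1)
    sw = np.sqrt(w)[:, None]
    beta, *_ = np.linalg.lstsq(sw * X, np.sqrt(w) * z, rcond=None)
    v, c = float(beta[0]), float(beta[1])
    return float(1.0 - norm.cdf(v - c)), v, c, False


def bootstrap_support(
    dataset: ExpressionDataset,
    tree: ClusterTree,
    n_boot: int = 1000,
    scales: Sequence[float] = DEFAULT_SCALES,
    seed: int = 0,
) -> ClusterTree:
    """Attach BP and multiscale-AU support to every internal node.

    For each scale r, ``n_boot`` resamples of ceil(r * n_genes) genes are
    drawn with replacement, the samples are reclustered, and BP_r(node) is
    the fraction of replicates whose dendrogram contains the identical
    sample set.  ``bp`` is BP at r = 1; the AU p-value comes from the WLS
    fit of z_r = Phi^-1(1 - BP_r) to v*sqrt(r) + c/sqrt(r) with binomial
    delta-method weights, au = 1 - Phi(v - c).  Nodes whose BP is 0 or 1 at
    every scale cannot be fitted and fall back to au = bp with a
    degenerate-fit flag.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100 (the multiscale fit is unstable below)")
    scales = tuple(float(r) for r in scales)
    if 1.0 not in scales:
        raise ValueError("scales must include 1.0 (ordinary bootstrap)")
    rng = np.random.default_rng(seed)
    n_genes = dataset.n_genes
    node_sets = [node.members for node in tree.nodes]
    counts = np.zeros((len(node_sets), len(scales)))
    for si, r in enumerate(scales):
        size = math.ceil(r * n_genes)
        for _ in range(n_boot):
            idx = rng.integers(0, n_genes, size=size)
            values = dataset.values[idx]
            try:
                D = sample_distance_matrix(values, tree.distance)
            except ValueError:
                continue  # a degenerate resample (zero-variance profile) is skipped
            if tree.linkage_method == "ward":
                Z = linkage(values.T, method="ward")
            else:
                Z = linkage(squareform(D, checks=False), method=tree.linkage_method)
            rep_sets = {m for m, _ in _internal_node_sets(Z, dataset.sample_ids)}
            for ni, members in enumerate(node_sets):
                if members in rep_sets:
                    counts[ni, si] += 1
    bp_all = counts / n_boot
    r1 = scales.index(1.0)
    new_nodes = []
    for ni, node in enumerate(tree.nodes):
        bps = bp_all[ni]
        bp = float(bps[r1])
        au, v, c, degenerate = fit_au(bps, scales, n_boot)
        new_nodes.append(
            replace(node, bp=bp, au=au, v=v, c=c, degenerate_fit=degenerate,
                    bp_per_scale=tuple(float(b) for b in bps))
        )
    return ClusterTree(
        tree.sample_ids,
        tree.linkage_matrix,
        tuple(new_nodes),
        tree.linkage_method,
        tree.distance,
        n_boot=n_boot,
        scales=scales,
    )


def highlight_clusters(tree: ClusterTree, threshold: float = 0.95) -> list[frozenset[str]]:
    """Maximal internal nodes with AU above the threshold, outermost first.

    The root (all samples) is excluded — it is trivially present in every
    replicate — so when every node passes, the two children of the root are
    the maximal proper clusters returned.  No returned set contains another.
    """
    if not tree.has_support:
        raise ValueError("bootstrap support has not been computed")
    all_samples = frozenset(tree.sample_ids)
    passing = [
        n for n in tree.nodes if n.members != all_samples and (n.au or 0.0) > threshold
    ]
    # keep only maximal sets (not contained in another passing set)
    passing.sort(key=lambda n: -len(n.members))
    out: list[frozenset[str]] = []
    for n in passing:
        if not any(n.members < kept for kept in out):
            out.append(n.members)
    return out
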