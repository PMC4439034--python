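"""Prefiltering, ortholog integration and moving-average trend smoothing.

The fold-change prefilter keeps genes showing at least a given fold
regulation (|M| >= log2(fold)) in at least a given fraction of samples —
the "two-fold in 20% of samples" rule that reduces an array to the
deregulated gene universe.  Cross-species integration joins two expression
matrices on an ortholog map, and the smoothing step replaces each gene's
stage-ordered series by its weighted moving average (the trend component of
a time-course decomposition), which stabilizes downstream selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_io import ExpressionDataset, HomologMap

__all__ = ["SmoothingSpec", "fold_change_filter", "map_orthologs", "smooth_trend"]


@dataclass(frozen=True)
class SmoothingSpec:
    """Moving-average window over the stage-ordered sample series.

    ``window`` defaults to 4, one disease stage's worth of replicates;
    ``weights`` (optional) must be non-negative, length ``window`` and sum
    to 1 — uniform when omitted.
    """

    window: int = 4
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.weights is not None:
            w = tuple(float(x) for x in self.weights)
            object.__setattr__(self, "weights", w)
            if len(w) != self.window:
                raise ValueError("weights length must equal window")
            if any(x < 0 for x in w):
                raise ValueError("weights must be non-negative")
            if not math.isclose(sum(w), 1.0, rel_tol=0, abs_tol=1e-9):
                raise ValueError("weights must sum to 1")


def fold_change_filter(
    dataset: ExpressionDataset, fold_threshold: float = 2.0, sample_fraction: float = 0.20
) -> ExpressionDataset:
    """Keep genes with |M| >= log2(fold_threshold) in enough samples.

    "Enough" is ``ceil(sample_fraction * n_samples)`` — the boundary is
    inclusive on both the fold change and the sample count ("or more").
    Gene order is preserved.  Raises if no gene survives.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must be > 1")
    if not (0 < sample_fraction <= 1):
        raise ValueError("sample_fraction must be in (0, 1]")
    cut = np.log2(fold_threshold)
    need = math.ceil(sample_fraction * dataset.n_samples)
    hits = (np.abs(dataset.values) >= cut).sum(axis=1)
    keep = [g for g, h in zip(dataset.gene_ids, hits) if h >= need]
    if not keep:
        raise ValueError(
            f"fold_change_filter removed all genes (fold={fold_threshold}, "
            f"fraction={sample_fraction}); relax the threshold"
        )
    return dataset.subset_genes(keep)


def map_orthologs(
    a: ExpressionDataset, b: ExpressionDataset, homolog_map: HomologMap
) -> ExpressionDataset:
    """Join two datasets on ortholog pairs present in both.

    Output rows are the ortholog pairs (gene id ``"a_id|b_id"``) whose both
    members exist; columns are the samples of ``a`` followed by those of
    ``b``.  One-to-many pairs are kept as separate rows.  Labels are merged
    when both inputs carry them.
    """
    if a.n_genes == 0 or b.n_genes == 0:
        raise ValueError("both datasets must be non-empty")
    pos_a = {g: i for i, g in enumerate(a.gene_ids)}
    pos_b = {g: i for i, g in enumerate(b.gene_ids)}
    rows = []
    gene_ids = []
    for ga, gb in homolog_map.pairs:
        ia, ib = pos_a.get(ga), pos_b.get(gb)
        if ia is None or ib is None:
            continue
        gene_ids.append(f"{ga}|{gb}")
        rows.append(np.concatenate([a.values[ia], b.values[ib]]))
    if not rows:
        raise ValueError("no ortholog pair present in both datasets")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValueError(f"sample ids shared between datasets: {sorted(overlap)[:5]}")
    labels = None
    if a.labels is not None and b.labels is not None:
        labels = {**a.labels, **b.labels}
    return ExpressionDataset(
        tuple(gene_ids), a.sample_ids + b.sample_ids, np.vstack(rows), labels
    )


def smooth_trend(
    dataset: ExpressionDataset,
    spec: SmoothingSpec = SmoothingSpec(),
    sample_order: Sequence[str] | None = None,
) -> ExpressionDataset:
    """Replace each gene's stage-ordered series by its weighted moving average.

    ``sample_order`` is a permutation of the sample ids reflecting disease
    progression (default: current column order).  The window is centred
    (left-biased by one for even windows); at the series edges the window is
    truncated and its weights renormalized, so no data is invented beyond
    the ends.  Output keeps the dataset's original column order.
    """
    order = list(sample_order) if sample_order is not None else list(dataset.sample_ids)
    if sorted(order) != sorted(dataset.sample_ids):
        raise ValueError("sample_order must be a permutation of the sample ids")
    n = dataset.n_samples
    w = spec.window
    if w > n:
        raise ValueError(f"smoothing window {w} exceeds sample count {n}")
    weights = np.asarray(spec.weights if spec.weights is not None else [1.0 / w] * w)

    pos = {s: i for i, s in enumerate(dataset.sample_ids)}
    perm = np.array([pos[s] for s in order])
    X = dataset.values[:, perm]

    left = (w - 1) // 2
    out = np.empty_like(X)
    for j in range(n):
        start = j - left  # nominal window start; clipped at the series ends
        lo, hi = max(0, start), min(n, start + w)
        ww = weights[lo - start : hi - start]
        ww = ww / ww.sum()
        out[:, j] = X[:, lo:hi] @ ww

    # restore the dataset's own column order
    inv = np.empty_like(perm)
    inv[np.arange(n)] = perm
    restored = np.empty_like(out)
    restored[:, perm] = out
    return ExpressionDataset(dataset.gene_ids, dataset.sample_ids, restored, dataset.labels)
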