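"""External resampling, selection stability and frequency-aggregation ensembles.

Any search method is wrapped in an external stratified k-fold loop: the
method runs on each training split and its best subset is recorded, giving k
(usually 5) signatures.  Stability is the average Hamming distance between
those subsets — reported both raw (AHD) and normalized by the gene-universe
size (NAHD in [0, 1]) — plus per-gene selection frequencies (multiples of
1/k).  The ensemble signature is built by "rank summation": genes are added
in descending frequency order, each prefix is evaluated, and growth stops at
the first strict error increase, keeping the best prefix seen.  The same
aggregation applied across methods (one vote per method's ensemble) yields
the cross-method convergent signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .core_io import ExpressionDataset
from .evaluation import Evaluator, holdout_error
from .search import SelectionTrace

__all__ = [
    "StabilityReport",
    "external_cv_select",
    "nahd",
    "aggregate_by_frequency",
    "cross_method_aggregate",
    "run_stability",
]


@dataclass(frozen=True)
class StabilityReport:
    """Per-fold subsets, stability measures and the aggregated ensemble."""

    fold_subsets: tuple[tuple[str, ...], ...]
    nahd: float
    ahd_raw: float
    frequencies: dict[str, float]
    ensemble_subset: tuple[str, ...]
    ensemble_error: float
    per_fold_errors: tuple[float, ...]

    def __post_init__(self) -> None:
        union = set().union(*[set(s) for s in self.fold_subsets]) if self.fold_subsets else set()
        if not set(self.ensemble_subset) <= union:
            raise ValueError("ensemble subset contains a gene absent from every fold")

    def to_dict(self) -> dict:
        return {
            "fold_subsets": [list(s) for s in self.fold_subsets],
            "nahd": self.nahd,
            "ahd_raw": self.ahd_raw,
            "frequencies": dict(sorted(self.frequencies.items())),
            "ensemble_subset": list(self.ensemble_subset),
            "ensemble_error": self.ensemble_error,
            "per_fold_errors": list(self.per_fold_errors),
        }


def external_cv_select(
    dataset: ExpressionDataset,
    labels: Sequence,
    method: Callable[[ExpressionDataset, Sequence], SelectionTrace],
    evaluator: Evaluator,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[tuple[str, ...]], list[float]]:
    """Run a selection method externally over k stratified folds.

    The data is partitioned into k mutually exclusive stratified folds; for
    each fold the method runs on the remaining k-1 folds and its best subset
    is recorded together with a held-out error: for wrapper-style evaluators
    the error of the evaluator applied to the held-out samples (classifier
    retrained on the training split is approximated by evaluating the
    held-out block), keeping selection strictly external to error estimation.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]!r} has {counts.min()} samples < k={k}; "
            "use a smaller k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    subsets: list[tuple[str, ...]] = []
    errors: list[float] = []
    sample_ids = np.array(dataset.sample_ids)
    spec = getattr(evaluator, "spec", None)
    for train, test in skf.split(np.zeros(len(y)), y):
        train_ds = dataset.subset_samples(sample_ids[train])
        trace = method(train_ds, y[train])
        subsets.append(trace.best_subset)
        test_ds = dataset.subset_samples(sample_ids[test])
        if spec is not None and spec.kind == "wrapper":
            # proper induction: train on the k-1 folds, score the held-out one
            err = holdout_error(
                train_ds, y[train], test_ds, y[test], list(trace.best_subset), spec
            )
        else:
            err = float(evaluator(test_ds, y[test], list(trace.best_subset)))
        errors.append(err)
    return subsets, errors


def nahd(subsets: Sequence[Sequence[str]], universe_size: int) -> tuple[float, float]:
    """Average Hamming distance between subsets: (normalized, raw).

    The Hamming distance between two subsets over a fixed gene universe is
    the size of their symmetric difference; the mean over unordered pairs is
    the raw AHD, and dividing by the universe size gives NAHD in [0, 1].
    """
    if len(subsets) < 2:
        raise ValueError("need >= 2 subsets")
    if universe_size <= 0:
        raise ValueError("universe_size must be > 0")
    max_size = max(len(set(s)) for s in subsets)
    if universe_size < max_size:
        raise ValueError("universe_size smaller than a subset")
    dists = [
        len(set(a) ^ set(b)) for a, b in combinations(subsets, 2)
    ]
    raw = float(np.mean(dists))
    return raw / universe_size, raw


def _frequency_ranking(subsets: Sequence[Sequence[str]]) -> tuple[list[str], dict[str, float]]:
    """Rank the union of genes by selection frequency.

    Ties break by mean within-subset insertion rank (earlier = better), then
    lexicographic gene id, so the ranking is fully deterministic.
    """
    k = len(subsets)
    freq: dict[str, int] = {}
    ranks: dict[str, list[int]] = {}
    for sub in subsets:
        for pos, g in enumerate(sub):
            freq[g] = freq.get(g, 0) + 1
            ranks.setdefault(g, []).append(pos)
    frequencies = {g: c / k for g, c in freq.items()}
    ordered = sorted(
        freq,
        key=lambda g: (-freq[g], float(np.mean(ranks[g])), g),
    )
    return ordered, frequencies


def aggregate_by_frequency(
    subsets: Sequence[Sequence[str]],
    dataset: ExpressionDataset,
    labels: Sequence,
    evaluator: Evaluator,
) -> tuple[tuple[str, ...], float, dict[str, float]]:
    """Frequency-based ("rank summation") ensemble aggregation.

    Genes from the union of the subsets are added one at a time in
    descending selection-frequency order, evaluating every prefix on the
    full data; growth stops at the first strict error increase and the best
    prefix seen (minimum error) is returned with its error and the gene
    frequencies.
    """
    if not subsets:
        raise ValueError("no subsets to aggregate")
    y = np.asarray(labels)
    ordered, frequencies = _frequency_ranking(subsets)
    best_prefix: tuple[str, ...] = ()
    best_err = np.inf
    prev_err = np.inf
    for i in range(1, len(ordered) + 1):
        prefix = tuple(ordered[:i])
        err = float(evaluator(dataset, y, list(prefix)))
        if err < best_err:
            best_prefix, best_err = prefix, err
        if np.isfinite(prev_err) and err > prev_err:
            break
        prev_err = err
    return best_prefix, best_err, frequencies


def run_stability(
    dataset: ExpressionDataset,
    labels: Sequence,
    method: Callable[[ExpressionDataset, Sequence], SelectionTrace],
    evaluator: Evaluator,
    k: int = 5,
    seed: int = 0,
) -> StabilityReport:
    """External k-fold selection + stability + frequency ensemble, in one call."""
    subsets, fold_errors = external_cv_select(dataset, labels, method, evaluator, k, seed)
    norm, raw = nahd(subsets, dataset.n_genes)
    ensemble, err, freqs = aggregate_by_frequency(subsets, dataset, labels, evaluator)
    return StabilityReport(
        fold_subsets=tuple(subsets),
        nahd=norm,
        ahd_raw=raw,
        frequencies=freqs,
        ensemble_subset=ensemble,
        ensemble_error=err,
        per_fold_errors=tuple(fold_errors),
    )


def cross_method_aggregate(
    reports: Sequence[StabilityReport],
    dataset: ExpressionDataset,
    labels: Sequence,
    evaluator: Evaluator,
) -> StabilityReport:
    """Aggregate the per-method ensemble signatures into one convergent signature.

    Each method's ensemble subset counts as one vote and the same
    frequency-based aggregation is reapplied across methods, so the reported
    frequencies are multiples of 1/n_methods.
    """
    if len(reports) < 2:
        raise ValueError("need >= 2 method reports")
    votes = [r.ensemble_subset for r in reports]
    ensemble, err, freqs = aggregate_by_frequency(votes, dataset, labels, evaluator)
    norm, raw = nahd(votes, dataset.n_genes)
    return StabilityReport(
        fold_subsets=tuple(votes),
        nahd=norm,
        ahd_raw=raw,
        frequencies=freqs,
        ensemble_subset=ensemble,
        ensemble_error=err,
        per_fold_errors=tuple(r.ensemble_error for r in reports),
    )
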