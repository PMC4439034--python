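"""Information-theoretic and univariate relevance scores.

These primitives underlie every search strategy: expression vectors are
discretized (equal-frequency by default, or at the natural +/-1 two-fold cut
of log2 ratios), mutual information is the plug-in estimate in bits, and
redundancy of a gene subset is measured either as average pairwise MI or as
average pairwise GO-term set overlap (Jaccard).  The univariate scores are
the one-way ANOVA F statistic, a Golub-style signal-to-noise margin (GS1)
and the between/within sum-of-squares ratio (GS2); for all three, higher
means more class-relevant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .core_io import ExpressionDataset

__all__ = [
    "DiscretizationSpec",
    "GeneAnnotation",
    "discretize",
    "discretize_matrix",
    "entropy",
    "mutual_information",
    "normalized_mi",
    "mi_redundancy",
    "go_redundancy",
    "univariate_scores",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DiscretizationSpec:
    """How continuous expression values are binned before MI estimation."""

    n_bins: int = 3
    strategy: str = "equal_frequency"  # or "sign_threshold"

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.strategy not in ("equal_frequency", "sign_threshold"):
            raise ValueError(f"unknown discretization strategy {self.strategy!r}")
        if self.strategy == "sign_threshold" and self.n_bins != 3:
            raise ValueError("sign_threshold discretization is defined for 3 bins")


@dataclass(frozen=True)
class GeneAnnotation:
    """Mapping gene_id -> set of GO term ids (term sets may be empty)."""

    terms: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        terms = {str(g): frozenset(str(t) for t in ts) for g, ts in self.terms.items()}
        for g, ts in terms.items():
            if any(not t for t in ts):
                raise ValueError(f"empty GO term id for gene {g!r}")
        object.__setattr__(self, "terms", terms)

    def get(self, gene_id: str) -> frozenset[str]:
        return self.terms.get(gene_id, frozenset())


def discretize(values: Sequence[float], spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Bin a numeric vector into integer bin indices.

    Equal-frequency: elements are assigned by stable-sorted rank so that bin
    sizes differ by at most one when values are distinct; ties keep their
    input order and may straddle a quantile boundary.  A constant vector maps
    to a single bin 0.  Sign-threshold (3 bins): M <= -1, -1 < M < 1, M >= 1.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("cannot discretize an empty vector")
    if spec.strategy == "sign_threshold":
        bins = np.full(x.shape, 1, dtype=int)
        bins[x <= -1.0] = 0
        bins[x >= 1.0] = 2
        return bins
    if np.all(x == x[0]):
        return np.zeros(x.shape, dtype=int)
    order = np.argsort(x, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(x.size)
    return (ranks * spec.n_bins) // x.size


def discretize_matrix(values: np.ndarray, spec: DiscretizationSpec = DiscretizationSpec()) -> np.ndarray:
    """Discretize each row (gene) of a matrix across its columns (samples)."""
    return np.vstack([discretize(row, spec) for row in np.atleast_2d(values)])


def _as_codes(v: Sequence) -> np.ndarray:
    arr = np.asarray(v)
    _, codes = np.unique(arr, return_inverse=True)
    return codes


def entropy(x: Sequence) -> float:
    """Shannon entropy of the empirical distribution, in bits."""
    codes = _as_codes(x)
    p = np.bincount(codes).astype(float)
    p = p[p > 0] / codes.size
    return float(-(p * np.log2(p)).sum())


def mutual_information(x: Sequence, y: Sequence) -> float:
    """Plug-in mutual information (bits) of two discrete vectors."""
    cx, cy = _as_codes(x), _as_codes(y)
    if cx.size != cy.size:
        raise ValueError(f"length mismatch: {cx.size} vs {cy.size}")
    if cx.size < 2:
        raise ValueError("need at least 2 observations")
    joint = np.zeros((cx.max() + 1, cy.max() + 1))
    np.add.at(joint, (cx, cy), 1.0)
    return _mi_from_joint(joint)


def _mi_from_joint(joint: np.ndarray) -> float:
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    ratio = np.where(mask, p / np.where(mask, px * py, 1.0), 1.0)
    return float(np.maximum((p * np.log2(np.where(mask, ratio, 1.0))).sum(), 0.0))


def normalized_mi(x: Sequence, y: Sequence) -> float:
    """I(x;y) / sqrt(H(x) H(y)); 0 by convention when either entropy is 0."""
    hx, hy = entropy(x), entropy(y)
    if hx <= 0 or hy <= 0:
        return 0.0
    return float(min(mutual_information(x, y) / np.sqrt(hx * hy), 1.0))


def mi_redundancy(
    subset: Sequence[str],
    dataset: ExpressionDataset,
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> float:
    """Average pairwise MI (bits) among a gene subset, discretized per gene."""
    if len(subset) < 2:
        raise ValueError("mi_redundancy needs a subset of >= 2 genes")
    idx = dataset.gene_index(subset)
    codes = discretize_matrix(dataset.values[idx], disc)
    vals = [mutual_information(codes[i], codes[j]) for i, j in combinations(range(len(subset)), 2)]
    return float(np.mean(vals))


def go_redundancy(subset: Sequence[str], ann: GeneAnnotation) -> float:
    """Average pairwise Jaccard similarity of GO term sets over a subset.

    A pair where both term sets are empty contributes 0 (no evidence of
    functional relatedness).
    """
    if len(subset) < 2:
        raise ValueError("go_redundancy needs a subset of >= 2 genes")
    sims = []
    for a, b in combinations(subset, 2):
        ta, tb = ann.get(a), ann.get(b)
        union = ta | tb
        sims.append(len(ta & tb) / len(union) if union else 0.0)
    return float(np.mean(sims))


def univariate_scores(
    dataset: ExpressionDataset,
    labels: Sequence | None = None,
    score_id: str = "f",
) -> dict[str, float]:
    """Per-gene class-relevance scores: ``f`` (ANOVA F), ``gs1``, ``gs2``.

    gs1 is the maximum over class pairs of |mu_i - mu_j| / (s_i + s_j)
    (signal-to-noise margin); gs2 is BSS/WSS; f the one-way ANOVA statistic.
    Denominators receive epsilon = 1e-12 so zero-variance degenerate classes
    are handled rather than erroring.
    """
    if labels is None:
        labels = dataset.label_vector()
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need >= 2 classes")
    X = dataset.values  # genes x samples
    n = X.shape[1]
    k = classes.size
    means = np.stack([X[:, y == c].mean(axis=1) for c in classes], axis=1)  # genes x k
    sds = np.stack([X[:, y == c].std(axis=1, ddof=1) if (y == c).sum() > 1 else np.zeros(X.shape[0]) for c in classes], axis=1)
    counts = np.array([(y == c).sum() for c in classes], dtype=float)
    grand = X.mean(axis=1, keepdims=True)
    bss = ((means - grand) ** 2 * counts).sum(axis=1)
    wss = np.zeros(X.shape[0])
    for ci, c in enumerate(classes):
        wss += ((X[:, y == c] - means[:, ci : ci + 1]) ** 2).sum(axis=1)

    if score_id == "f":
        if np.any(counts < 2):
            raise ValueError("F score needs >= 2 samples per class")
        score = (bss / (k - 1)) / (wss / (n - k) + _EPS)
    elif score_id == "gs2":
        score = bss / (wss + _EPS)
    elif score_id == "gs1":
        score = np.zeros(X.shape[0])
        for i, j in combinations(range(k), 2):
            cand = np.abs(means[:, i] - means[:, j]) / (sds[:, i] + sds[:, j] + _EPS)
            score = np.maximum(score, cand)
    else:
        raise ValueError(f"unknown score_id {score_id!r} (use f|gs1|gs2)")
    return {g: float(s) for g, s in zip(dataset.gene_ids, score)}
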