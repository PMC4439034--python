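"""Search strategies over gene subsets.

Four families, mirroring the selection grid of the framework:

* **RFE** — backward elimination from the full gene universe.  At each
  iteration every gene g receives a coefficient I(g): with g excluded, every
  sample becomes the discretized vector of the remaining genes, and I(g) is
  the sum of sample-by-sample mutual information over between-class sample
  pairs minus the sum over within-class pairs.  A gene whose exclusion
  leaves the best separation (largest I) is the least needed, so the m
  genes with the largest coefficient are dropped each iteration.
  Redundancy-aware variants form "coefficient II" by adding the gene's
  average pairwise MI with the subset (RFE_MR) or its average GO-term
  similarity (MinR_MinGO) — pushing redundant genes toward removal — while
  MaxR_MaxGO subtracts the GO similarity, protecting co-functional genes.
* **MRMR** — forward search scoring each candidate by normalized MI with
  the class divided by its average MI with the already-selected genes.
* **Univariate forward** — genes ranked once by GS1 / GS2 / F and added
  greedily in rank order.
* **GA** — a genetic algorithm over fixed-length gene subsets with elitism,
  roulette-wheel selection, uniform crossover and replace-with-unused-gene
  mutation.

Each run returns a :class:`SelectionTrace`; the selected signature is the
evaluated subset with the minimum error.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .core_io import ExpressionDataset
from .evaluation import Evaluator, EvaluatorSpec, make_evaluator
from .metrics import (
    DiscretizationSpec,
    GeneAnnotation,
    discretize_matrix,
    go_redundancy,
    mutual_information,
    normalized_mi,
    univariate_scores,
)

__all__ = [
    "SelectionTrace",
    "RfeSpec",
    "GaSpec",
    "rfe_coefficient",
    "rfe_search",
    "mrmr_search",
    "univariate_forward_search",
    "ga_search",
    "METHOD_IDS",
    "method_runner",
]

_EPS_RED = 1e-6  # MRMR redundancy floor for the empty selection


@dataclass(frozen=True)
class SelectionTrace:
    """Ordered record of evaluated candidate subsets and their errors."""

    steps: tuple[tuple[tuple[str, ...], float], ...]
    best_subset: tuple[str, ...] = ()
    best_error: float = float("nan")

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a trace needs at least one step")
        keys = [frozenset(s) for s, _ in self.steps]
        if len(set(keys)) != len(keys):
            raise ValueError("subsets within a trace must be distinct")
        errors = [e for _, e in self.steps]
        # among equal-error iterates keep the first: the most parsimonious
        # subset (forward searches stop growing once the minimum is reached;
        # backward elimination keeps the largest surviving set on a plateau)
        best_i = int(np.argmin(errors))
        object.__setattr__(self, "best_subset", tuple(self.steps[best_i][0]))
        object.__setattr__(self, "best_error", float(errors[best_i]))


@dataclass(frozen=True)
class RfeSpec:
    """Backward-elimination schedule and redundancy handling.

    ``m`` genes are removed per iteration; ``x`` first-pass and ``y``
    refinement iterations bound the total schedule.  ``redundancy_mode`` is
    none | mi | go_min | go_max with weight ``redundancy_weight``.
    """

    m: int = 5
    x: int = 50
    y: int = 10
    redundancy_mode: str = "none"
    redundancy_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.m < 1 or self.x < 1 or self.y < 0:
            raise ValueError("need m >= 1, x >= 1, y >= 0")
        if self.redundancy_mode not in ("none", "mi", "go_min", "go_max"):
            raise ValueError(f"unknown redundancy_mode {self.redundancy_mode!r}")
        if self.redundancy_weight < 0:
            raise ValueError("redundancy_weight must be >= 0")


@dataclass(frozen=True)
class GaSpec:
    """Genetic-algorithm parameters over fixed-length gene subsets."""

    population_size: int = 20
    chromosome_length: int = 70
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    elitism_count: int = 1
    max_generations: int = 100
    slope_threshold: float = 0.05
    slope_window: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        if self.population_size < 1 or self.chromosome_length < 1:
            raise ValueError("population and chromosome sizes must be >= 1")


# ---------------------------------------------------------------------------
# RFE
# ---------------------------------------------------------------------------


def rfe_coefficient(
    dataset: ExpressionDataset,
    labels: Sequence,
    excluded_gene: str,
    current_subset: Sequence[str],
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> float:
    """Coefficient I of one gene: reference (pair-enumeration) implementation.

    With ``excluded_gene`` removed from ``current_subset``, every sample is
    the discretized vector of the remaining genes; the coefficient is
    sum of MI over between-class sample pairs minus sum over within-class
    pairs.
    """
    if excluded_gene not in set(current_subset):
        raise ValueError("excluded_gene must belong to current_subset")
    if len(current_subset) < 2:
        raise ValueError("current_subset must have >= 2 genes")
    keep = [g for g in current_subset if g != excluded_gene]
    idx = dataset.gene_index(keep)
    codes = discretize_matrix(dataset.values[idx], disc)
    y = np.asarray(labels)
    total = 0.0
    n = dataset.n_samples
    for i in range(n):
        for j in range(i + 1, n):
            mi = mutual_information(codes[:, i], codes[:, j])
            total += mi if y[i] != y[j] else -mi
    return float(total)


def _rfe_coefficients_all(
    codes: np.ndarray, y: np.ndarray, n_bins: int
) -> np.ndarray:
    """Vectorized coefficient I for every gene of a discretized subset.

    ``codes`` is genes x samples with integer bins in [0, n_bins).  For each
    sample pair the 3x3 joint table over genes is computed once; excluding a
    gene is a single-cell decrement, so all G leave-one-out MIs come from
    adjusting that table.
    """
    G, n = codes.shape
    B = n_bins
    B2 = B * B
    rindex = np.arange(B2) // B
    sindex = np.arange(B2) % B
    coeff = np.zeros(G)
    gidx = np.arange(G)
    m = G - 1  # observations per leave-one-out table
    for i in range(n):
        for j in range(i + 1, n):
            cells = codes[:, i] * B + codes[:, j]
            N = np.bincount(cells, minlength=B2).astype(float)
            Nr = N.reshape(B, B).sum(axis=1)
            Nc = N.reshape(B, B).sum(axis=0)
            C = np.tile(N, (G, 1))
            C[gidx, cells] -= 1.0
            R = np.tile(Nr, (G, 1))
            R[gidx, codes[:, i]] -= 1.0
            S = np.tile(Nc, (G, 1))
            S[gidx, codes[:, j]] -= 1.0
            Rexp = R[:, rindex]
            Sexp = S[:, sindex]
            pos = C > 0
            ratio = np.where(pos, C * m / np.where(pos, Rexp * Sexp, 1.0), 1.0)
            mi = np.maximum((np.where(pos, C * np.log2(ratio), 0.0)).sum(axis=1) / m, 0.0)
            coeff += mi if y[i] != y[j] else -mi
    return coeff


def rfe_search(
    dataset: ExpressionDataset,
    labels: Sequence,
    spec: RfeSpec,
    evaluator: Evaluator,
    disc: DiscretizationSpec = DiscretizationSpec(),
    annotation: GeneAnnotation | None = None,
) -> SelectionTrace:
    """Backward recursive elimination; returns the minimum-error trace.

    Stops when <= m genes remain or the x + y iteration budget is spent.
    Redundancy modes fold a second term into the removal score: ``mi`` and
    ``go_min`` add the gene's average pairwise redundancy with the subset
    (redundant genes removed sooner), ``go_max`` subtracts it (co-functional
    genes protected).
    """
    y = np.asarray(labels)
    current = list(dataset.gene_ids)
    if len(current) <= spec.m:
        raise ValueError("n_genes must exceed m")
    if spec.redundancy_mode in ("go_min", "go_max") and annotation is None:
        raise ValueError("GO redundancy modes require a GeneAnnotation")
    codes_full = discretize_matrix(dataset.values, disc)
    pos = {g: i for i, g in enumerate(dataset.gene_ids)}
    steps: list[tuple[tuple[str, ...], float]] = []
    max_iter = spec.x + spec.y
    for iteration in range(max_iter + 1):
        try:
            err = evaluator(dataset, y, current)
        except Exception as exc:
            raise RuntimeError(f"evaluator failed at RFE iteration {iteration}") from exc
        steps.append((tuple(current), float(err)))
        if len(current) <= spec.m or iteration >= max_iter:
            break
        codes = codes_full[[pos[g] for g in current]]
        coeff = _rfe_coefficients_all(codes, y, disc.n_bins)
        if spec.redundancy_mode != "none":
            red = _subset_redundancy(current, codes, annotation, spec.redundancy_mode)
            # adding redundancy pushes redundant genes toward removal (mi/go_min);
            # go_max subtracts it, protecting co-functional genes instead
            sign = -1.0 if spec.redundancy_mode == "go_max" else 1.0
            coeff = coeff + sign * spec.redundancy_weight * red
        # a gene whose exclusion leaves the best separation is least needed:
        # the m largest coefficients are the "worst" genes and are removed
        order = np.argsort(-coeff, kind="stable")
        drop = {current[k] for k in order[: spec.m]}
        current = [g for g in current if g not in drop]
    return SelectionTrace(tuple(steps))


def _subset_redundancy(
    subset: list[str],
    codes: np.ndarray,
    annotation: GeneAnnotation | None,
    mode: str,
) -> np.ndarray:
    """Per-gene average pairwise redundancy with the rest of the subset."""
    G = len(subset)
    red = np.zeros(G)
    if mode == "mi":
        for a in range(G):
            vals = [
                mutual_information(codes[a], codes[b]) for b in range(G) if b != a
            ]
            red[a] = np.mean(vals) if vals else 0.0
    else:
        for a in range(G):
            ta = annotation.get(subset[a])
            sims = []
            for b in range(G):
                if b == a:
                    continue
                tb = annotation.get(subset[b])
                union = ta | tb
                sims.append(len(ta & tb) / len(union) if union else 0.0)
            red[a] = np.mean(sims) if sims else 0.0
    return red


# ---------------------------------------------------------------------------
# MRMR
# ---------------------------------------------------------------------------


def mrmr_search(
    dataset: ExpressionDataset,
    labels: Sequence,
    disc: DiscretizationSpec = DiscretizationSpec(),
    evaluator: Evaluator | None = None,
    max_iter: int = 30,
) -> SelectionTrace:
    """Forward minimum-redundancy maximum-relevance search.

    Candidate score = NMI(gene, class) / mean MI(gene, selected genes); the
    redundancy denominator is floored at 1e-6 bits, so the first pick is the
    max-relevance gene.  Each grown prefix is evaluated; the trace's best
    subset is the minimum-error prefix.
    """
    if max_iter > dataset.n_genes:
        raise ValueError("max_iter cannot exceed the number of genes")
    y = np.asarray(labels)
    codes = discretize_matrix(dataset.values, disc)
    relevance = np.array([normalized_mi(codes[g], y) for g in range(dataset.n_genes)])
    selected: list[int] = []
    steps: list[tuple[tuple[str, ...], float]] = []
    mi_cache: dict[tuple[int, int], float] = {}

    def pair_mi(a: int, b: int) -> float:
        key = (min(a, b), max(a, b))
        if key not in mi_cache:
            mi_cache[key] = mutual_information(codes[a], codes[b])
        return mi_cache[key]

    for _ in range(max_iter):
        best_g, best_c = None, -np.inf
        for g in range(dataset.n_genes):
            if g in selected:
                continue
            if selected:
                red = float(np.mean([pair_mi(g, s) for s in selected]))
            else:
                red = _EPS_RED
            c = relevance[g] / max(red, _EPS_RED)
            # deterministic tie-break: higher coefficient, then lexicographic id
            if c > best_c or (c == best_c and best_g is not None
                              and dataset.gene_ids[g] < dataset.gene_ids[best_g]):
                best_g, best_c = g, c
        selected.append(best_g)
        prefix = tuple(dataset.gene_ids[s] for s in selected)
        err = evaluator(dataset, y, list(prefix))
        steps.append((prefix, float(err)))
    return SelectionTrace(tuple(steps))


def mrmr_coefficients(
    dataset: ExpressionDataset,
    labels: Sequence,
    selected: Sequence[str],
    disc: DiscretizationSpec = DiscretizationSpec(),
) -> dict[str, float]:
    """MRMR coefficient of every unselected gene given the current selection.

    Exposed separately so the step arithmetic can be checked directly.
    """
    y = np.asarray(labels)
    codes = discretize_matrix(dataset.values, disc)
    sel_idx = list(dataset.gene_index(selected)) if selected else []
    out = {}
    for g, gid in enumerate(dataset.gene_ids):
        if gid in set(selected):
            continue
        rel = normalized_mi(codes[g], y)
        if sel_idx:
            red = float(np.mean([mutual_information(codes[g], codes[s]) for s in sel_idx]))
        else:
            red = _EPS_RED
        out[gid] = rel / max(red, _EPS_RED)
    return out


# ---------------------------------------------------------------------------
# Univariate forward selection
# ---------------------------------------------------------------------------


def univariate_forward_search(
    dataset: ExpressionDataset,
    labels: Sequence,
    score_id: str = "f",
    evaluator: Evaluator | None = None,
    max_iter: int = 30,
) -> SelectionTrace:
    """Rank genes once by a univariate score and grow prefixes greedily."""
    y = np.asarray(labels)
    scores = univariate_scores(dataset, y, score_id)
    ranked = sorted(scores, key=lambda g: (-scores[g], g))
    steps: list[tuple[tuple[str, ...], float]] = []
    for k in range(1, min(max_iter, len(ranked)) + 1):
        prefix = tuple(ranked[:k])
        err = evaluator(dataset, y, list(prefix))
        steps.append((prefix, float(err)))
    return SelectionTrace(tuple(steps))


# ---------------------------------------------------------------------------
# Genetic algorithm
# ---------------------------------------------------------------------------


def ga_search(
    dataset: ExpressionDataset,
    labels: Sequence,
    spec: GaSpec,
    evaluator: Evaluator,
) -> SelectionTrace:
    """Genetic-algorithm subset search (fixed-length chromosomes).

    Fitness = 1 - evaluation error.  Elitism copies the best chromosomes
    intact; roulette-wheel selection fills the rest; parent pairs undergo
    uniform crossover with probability ``crossover_prob`` (position swaps
    that would duplicate a gene inside a child are skipped); mutation
    replaces a position with a uniformly drawn unused gene.  The run stops
    once the generation count exceeds ``max_generations`` and the
    least-squares slope of the per-generation minimum error over the last
    ``slope_window`` generations is below ``slope_threshold`` in magnitude
    (with a hard cap at 4x max_generations as a safety valve).
    """
    n_genes = dataset.n_genes
    L = spec.chromosome_length
    if L > n_genes:
        raise ValueError("chromosome_length cannot exceed n_genes")
    rng = np.random.default_rng(spec.seed)
    y = np.asarray(labels)
    gene_ids = dataset.gene_ids

    cache: dict[frozenset, float] = {}
    steps: list[tuple[tuple[str, ...], float]] = []

    def evaluate(chrom: np.ndarray, generation: int) -> float:
        key = frozenset(chrom.tolist())
        if key not in cache:
            subset = [gene_ids[i] for i in chrom]
            err = float(evaluator(dataset, y, subset))
            if not np.isfinite(err):
                raise RuntimeError(f"non-finite fitness at generation {generation}")
            cache[key] = err
            steps.append((tuple(subset), err))
        return cache[key]

    pop = [rng.choice(n_genes, size=L, replace=False) for _ in range(spec.population_size)]
    history: list[float] = []
    generation = 0
    hard_cap = 4 * spec.max_generations
    while True:
        errors = np.array([evaluate(c, generation) for c in pop])
        history.append(float(errors.min()))
        generation += 1
        if generation > spec.max_generations and len(history) >= spec.slope_window:
            recent = np.array(history[-spec.slope_window:])
            slope = np.polyfit(np.arange(len(recent)), recent, 1)[0]
            if abs(slope) < spec.slope_threshold:
                break
        if generation >= hard_cap:
            break
        # elitism
        order = np.argsort(errors, kind="stable")
        elite = [pop[i].copy() for i in order[: spec.elitism_count]]
        # roulette wheel on fitness = 1 - error (shifted to be positive)
        fitness = 1.0 - errors
        w = fitness - fitness.min() + 1e-9
        probs = w / w.sum()
        n_offspring = spec.population_size - spec.elitism_count
        parents = [pop[i] for i in rng.choice(len(pop), size=n_offspring, p=probs)]
        children: list[np.ndarray] = []
        for a in range(0, n_offspring - 1, 2):
            p1, p2 = parents[a].copy(), parents[a + 1].copy()
            if rng.random() < spec.crossover_prob:
                s1, s2 = set(p1.tolist()), set(p2.tolist())
                for pos_i in range(L):
                    if rng.random() < 0.5:
                        g1, g2 = int(p1[pos_i]), int(p2[pos_i])
                        if g2 not in s1 and g1 not in s2:
                            p1[pos_i], p2[pos_i] = g2, g1
                            s1.discard(g1); s1.add(g2)
                            s2.discard(g2); s2.add(g1)
            children.extend([p1, p2])
        if len(children) < n_offspring:  # odd slot: pass the last parent through
            children.append(parents[-1].copy())
        for chrom in children:
            in_use = set(chrom.tolist())
            for pos_i in range(L):
                if rng.random() < spec.mutation_prob:
                    unused = np.setdiff1d(np.arange(n_genes), list(in_use))
                    if unused.size:
                        new_gene = int(rng.choice(unused))
                        in_use.discard(int(chrom[pos_i]))
                        in_use.add(new_gene)
                        chrom[pos_i] = new_gene
        pop = elite + children[:n_offspring]
    return SelectionTrace(tuple(steps))


# ---------------------------------------------------------------------------
# Method registry (the selection grid)
# ---------------------------------------------------------------------------

METHOD_IDS = (
    "rfe",
    "rfe_mr",
    "rfe_svm",
    "rfe_nb",
    "rfe_bn",
    "mrmr",
    "ga",
    "gs1",
    "gs2",
    "ftest",
    "rfe_minr_mingo",
    "rfe_maxr_maxgo",
)


def method_runner(
    method_id: str,
    evaluator: Evaluator | None = None,
    seed: int = 0,
    rfe_spec: RfeSpec | None = None,
    ga_spec: GaSpec | None = None,
    disc: DiscretizationSpec = DiscretizationSpec(),
    annotation: GeneAnnotation | None = None,
    max_iter: int = 30,
) -> Callable[[ExpressionDataset, Sequence], SelectionTrace]:
    """Bind a selection-grid method id into a ``(dataset, labels) -> trace`` callable.

    When ``evaluator`` is omitted, the grid's default pairing applies:
    wrapper CV of the matching classifier for rfe_svm / rfe_nb / rfe_bn
    (k = 5), 10-fold SVM wrapper for the univariate hybrids (gs1 / gs2 /
    ftest), and the distance-matrix criterion for the rest.
    """
    if method_id not in METHOD_IDS:
        raise ValueError(f"unknown method {method_id!r}; valid: {METHOD_IDS}")

    if evaluator is None:
        if method_id in ("rfe_svm", "rfe_nb", "rfe_bn"):
            clf = {"rfe_svm": "svm", "rfe_nb": "nb_gauss", "rfe_bn": "bayes_net"}[method_id]
            evaluator = make_evaluator(
                EvaluatorSpec(kind="wrapper", classifier_id=clf, k_folds=5, seed=seed)
            )
        elif method_id in ("gs1", "gs2", "ftest"):
            evaluator = make_evaluator(
                EvaluatorSpec(kind="wrapper", classifier_id="svm", k_folds=10, seed=seed)
            )
        else:
            evaluator = make_evaluator(EvaluatorSpec(kind="distance_matrix", seed=seed))

    def run(dataset: ExpressionDataset, labels: Sequence) -> SelectionTrace:
        if method_id.startswith("rfe"):
            mode = {
                "rfe_mr": "mi",
                "rfe_minr_mingo": "go_min",
                "rfe_maxr_maxgo": "go_max",
            }.get(method_id, "none")
            if rfe_spec is not None:
                spec = replace(rfe_spec, redundancy_mode=mode)
            else:
                spec = RfeSpec(m=max(1, dataset.n_genes // 15), redundancy_mode=mode)
            return rfe_search(dataset, labels, spec, evaluator, disc, annotation)
        if method_id == "mrmr":
            return mrmr_search(dataset, labels, disc, evaluator, min(max_iter, dataset.n_genes))
        if method_id == "ga":
            spec = ga_spec or GaSpec(
                chromosome_length=min(70, dataset.n_genes), seed=seed
            )
            return ga_search(dataset, labels, spec, evaluator)
        score = {"gs1": "gs1", "gs2": "gs2", "ftest": "f"}[method_id]
        return univariate_forward_search(dataset, labels, score, evaluator, max_iter)

    return run
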