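"""Hypergeometric over-representation of gene sets in selected subsets.

A selected subset of size n drawn from a universe of N genes is tested
against each gene set (restricted to the universe): the p-value is the
upper tail P(X >= overlap) of the hypergeometric distribution.  Following
the framework's convention, tests are reported at a raw p < alpha cut with
no multiple-testing correction (a Benjamini-Hochberg option exists but is
off by default), and repeating the test over the k selection runs gives a
pathway signature: per-set mean p, SD of p, and the frequency of runs in
which the set was significant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import hypergeom

from .core_io import GeneSetCollection

__all__ = [
    "PathwaySignature",
    "hypergeometric_p",
    "enrich_subset",
    "pathway_signature",
]


@dataclass(frozen=True)
class PathwaySignature:
    """Per-pathway stability rows: (set_name, mean_p, sd_p, frequency)."""

    rows: tuple[tuple[str, float, float, int], ...]
    n_runs: int

    def __post_init__(self) -> None:
        for name, mean_p, _sd, freq in self.rows:
            if not (0 <= mean_p <= 1):
                raise ValueError(f"mean_p out of [0,1] for {name!r}")
            if not (0 <= freq <= self.n_runs):
                raise ValueError(f"frequency out of range for {name!r}")

    def to_rows(self) -> list[dict]:
        return [
            {"set_name": n, "mean_p": m, "sd_p": s, "frequency": f}
            for n, m, s, f in self.rows
        ]


def hypergeometric_p(
    overlap: int, subset_size: int, set_size_in_universe: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts members of the gene set among ``subset_size`` draws without
    replacement from a universe of ``universe_size`` genes of which
    ``set_size_in_universe`` belong to the set.
    """
    if overlap < 0 or subset_size < 0 or set_size_in_universe < 0 or universe_size <= 0:
        raise ValueError("counts must be non-negative (universe positive)")
    if subset_size > universe_size or set_size_in_universe > universe_size:
        raise ValueError("subset/set size exceeds the universe")
    if overlap > min(subset_size, set_size_in_universe):
        raise ValueError("overlap exceeds subset or set size")
    # sf(k) = P(X > k), so P(X >= overlap) = sf(overlap - 1)
    return float(hypergeom.sf(overlap - 1, universe_size, set_size_in_universe, subset_size))


def enrich_subset(
    subset: Sequence[str],
    collection: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> list[tuple[str, float]]:
    """Test every gene set for over-representation in ``subset``.

    Set membership is intersected with the universe before testing; results
    with p < alpha are returned sorted ascending by p (ties by set name).
    ``bh_correct=True`` applies Benjamini-Hochberg before thresholding.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sub = set(subset)
    if not sub <= uni:
        raise ValueError("subset must be contained in the universe")
    names, ps = [], []
    for name, members in collection.sets.items():
        members_u = set(members) & uni
        if not members_u:
            continue
        overlap = len(sub & members_u)
        p = hypergeometric_p(overlap, len(sub), len(members_u), len(uni))
        names.append(name)
        ps.append(p)
    ps = np.asarray(ps)
    if bh_correct and len(ps):
        order = np.argsort(ps)
        m = len(ps)
        adj = np.empty(m)
        prev = 1.0
        for rank_i, idx in enumerate(order[::-1]):
            i = m - rank_i  # rank from 1..m, descending walk
            prev = min(prev, ps[idx] * m / i)
            adj[idx] = prev
        ps = adj
    hits = [(n, float(p)) for n, p in zip(names, ps) if p < alpha]
    return sorted(hits, key=lambda t: (t[1], t[0]))


def pathway_signature(
    run_subsets: Sequence[Sequence[str]],
    collection: GeneSetCollection,
    universe: Sequence[str],
    alpha: float = 0.05,
) -> PathwaySignature:
    """Pathway-level stability across selection runs.

    Per set: the hypergeometric p in each run, its mean and (population) SD,
    and the frequency = number of runs with p < alpha.  Sets never
    significant in any run are omitted.
    """
    if not run_subsets:
        raise ValueError("need >= 1 run")
    uni = set(universe)
    per_set: dict[str, list[float]] = {}
    for sub in run_subsets:
        sub_set = set(sub) & uni
        for name, members in collection.sets.items():
            members_u = set(members) & uni
            if not members_u:
                continue
            p = hypergeometric_p(len(sub_set & members_u), len(sub_set), len(members_u), len(uni))
            per_set.setdefault(name, []).append(p)
    rows = []
    for name, ps in per_set.items():
        freq = int(sum(p < alpha for p in ps))
        if freq == 0:
            continue
        rows.append((name, float(np.mean(ps)), float(np.std(ps)), freq))
    rows.sort(key=lambda r: (-r[3], r[1], r[0]))
    return PathwaySignature(tuple(rows), n_runs=len(run_subsets))
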