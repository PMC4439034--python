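"""Synthetic microarray-style data with the structure the pipeline assumes.

The generator emulates the regimes of a staged liver-disease study without
any array data: ordered disease stages (e.g. steatosis -> NASH -> HCC) with
a planted set of "progression" genes whose class means step monotonically on
the log2-ratio scale, blocks of redundant genes that are noisy copies of
planted ones (controllable within-block Pearson correlation), pathway
collections enriched for the planted genes, and two latent tumor subtypes
with exponentially distributed event times whose rates differ by a known
hazard ratio.  Everything is driven by one integer seed and is bit-
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .core_io import ExpressionDataset, GeneSetCollection, SurvivalTable

__all__ = ["SimulationSpec", "generate_progression", "generate_survival", "generate_genesets"]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults mirror the scale of the study this pipeline targets: ~500 genes
    surviving a fold-change prefilter, 3 ordered disease stages with a
    handful of replicates each, log2 effect of one unit (two-fold) per stage
    step over noise with SD 0.5, and a survival arm with hazard ratio 4
    between latent subtypes.
    """

    n_genes: int = 500
    n_samples_per_class: int = 5
    classes: tuple[str, ...] = ("steatosis", "NASH", "HCC")
    n_informative: int = 20
    effect_size: float = 1.0
    n_redundant_blocks: int = 4
    block_size: int = 5
    block_correlation: float = 0.8
    noise_sd: float = 0.5
    n_pathways: int = 20
    pathway_size: int = 15
    enriched_fraction: float = 0.8
    max_sets_per_gene: int = 3
    hazard_ratio: float = 4.0
    baseline_hazard: float = 1.0 / 365.0  # events per day: median survival ~1 year
    censor_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant_blocks * self.block_size > self.n_genes:
            raise ValueError("informative + redundant genes exceed n_genes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not (0 <= self.block_correlation < 1):
            raise ValueError("block_correlation must be in [0, 1)")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        if not (0 <= self.censor_fraction < 1):
            raise ValueError("censor_fraction must be in [0, 1)")
        if len(self.classes) < 2:
            raise ValueError("need >= 2 ordered classes")


def generate_progression(spec: SimulationSpec) -> tuple[ExpressionDataset, list[str]]:
    """Simulate an ordered-stage expression dataset with planted signature genes.

    Informative genes step by ``effect_size`` per stage (centred so M values
    stay symmetric around 0 across the time course); each redundant block is
    ``rho * source + sqrt(1 - rho^2) * noise`` around a randomly chosen
    informative source gene; all remaining genes are N(0, noise_sd^2) noise.

    Returns the labelled dataset and the list of planted informative gene ids.
    """
    rng = np.random.default_rng(spec.seed)
    k = len(spec.classes)
    n = spec.n_samples_per_class * k
    sample_ids = tuple(
        f"{c}_{r + 1}" for c in spec.classes for r in range(spec.n_samples_per_class)
    )
    labels = {s: s.rsplit("_", 1)[0] for s in sample_ids}
    stage = np.repeat(np.arange(k), spec.n_samples_per_class).astype(float)

    gene_ids = tuple(f"g{i:04d}" for i in range(spec.n_genes))
    values = rng.normal(0.0, spec.noise_sd, size=(spec.n_genes, n))

    # Informative genes follow monotone stage profiles with gene-specific
    # onset: a linear ramp stepping by effect_size at every stage boundary,
    # or a single effect_size step at one boundary (genes deregulate at
    # different points of the disease course).  Signs alternate, so the
    # planted set is jointly informative rather than one shared pattern.
    info_idx = np.arange(spec.n_informative)
    signs = np.where(info_idx % 2 == 0, 1.0, -1.0)
    onsets = [None] + list(range(1, k))  # None = linear ramp
    for j in info_idx:
        onset = onsets[(j // 2) % len(onsets)]
        if onset is None:
            cum = np.arange(k, dtype=float)
        else:
            cum = np.where(np.arange(k) >= onset, 1.0, 0.0)
        profile = spec.effect_size * (cum - cum.mean())
        values[j] += signs[j] * profile[stage.astype(int)]

    # redundant blocks: noisy copies of randomly chosen informative genes
    pos = spec.n_informative
    rho = spec.block_correlation
    for _ in range(spec.n_redundant_blocks):
        if spec.n_informative == 0:
            break
        src = int(rng.integers(spec.n_informative))
        source = values[src]
        s_sd = source.std() or 1.0
        for b in range(spec.block_size):
            noise = rng.normal(0.0, s_sd, size=n)
            values[pos + b] = rho * source + np.sqrt(1 - rho**2) * noise
        pos += spec.block_size

    dataset = ExpressionDataset(gene_ids, sample_ids, values, labels)
    truth = [gene_ids[i] for i in info_idx]
    return dataset, truth


def _censor_horizon(rates: np.ndarray, target: float) -> float:
    """Solve for the Uniform(0, u) horizon giving the expected censor fraction.

    For T ~ Exp(lam) and C ~ Uniform(0, u) independent,
    P(censored) = P(C < T) = (1 - exp(-lam u)) / (lam u); the population
    censoring probability averages this over the per-sample rates.
    """

    def censored_prob(u: float) -> float:
        lu = rates * u
        return float(np.mean((1.0 - np.exp(-lu)) / lu))

    # censored_prob decreases from 1 (u -> 0) to 0 (u -> inf)
    lo, hi = 1e-9, 1.0
    while censored_prob(hi) > target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - defensive
            break
    return float(brentq(lambda u: censored_prob(u) - target, lo, hi))


def generate_survival(
    dataset: ExpressionDataset, spec: SimulationSpec
) -> tuple[ExpressionDataset, SurvivalTable]:
    """Plant two latent tumor subtypes with differential hazards.

    Half the samples are assigned subtype A (baseline exponential hazard),
    half subtype B (hazard multiplied by ``hazard_ratio``; an odd sample
    count puts the extra sample in A); the first
    ``n_informative`` genes get a +/- effect_size mean shift by subtype, and
    event times are drawn from the subtype's exponential with independent
    uniform censoring calibrated so the expected censored fraction equals
    ``censor_fraction``.
    """
    if spec.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be > 0")
    rng = np.random.default_rng(spec.seed + 1)
    n = dataset.n_samples
    if n < 4:
        raise ValueError("need >= 4 samples for two subtypes")
    # equal arms; an odd sample count puts the extra sample in subtype A
    subtype = np.array(["A"] * (n - n // 2) + ["B"] * (n // 2))
    rng.shuffle(subtype)

    values = dataset.values.copy()
    n_shift = min(spec.n_informative, dataset.n_genes)
    shift = np.where(subtype == "B", 1.0, -1.0) * (spec.effect_size / 2.0)
    signs = np.where(np.arange(n_shift) % 2 == 0, 1.0, -1.0)
    values[:n_shift] += signs[:, None] * shift[None, :]
    shifted = ExpressionDataset(
        dataset.gene_ids, dataset.sample_ids, values, {s: g for s, g in zip(dataset.sample_ids, subtype)}
    )

    rates = np.where(subtype == "B", spec.baseline_hazard * spec.hazard_ratio, spec.baseline_hazard)
    times = rng.exponential(1.0 / rates)
    if spec.censor_fraction > 0:
        horizon = _censor_horizon(rates, spec.censor_fraction)
        censor = rng.uniform(0.0, horizon, size=n)
        event = (times <= censor).astype(int)
        obs = np.minimum(times, censor)
    else:
        event = np.ones(n, dtype=int)
        obs = times
    table = SurvivalTable(dataset.sample_ids, obs, event, tuple(subtype))
    return shifted, table


def generate_genesets(truth: Sequence[str], spec: SimulationSpec) -> GeneSetCollection:
    """Build a pathway collection enriched for the planted genes.

    ``enriched_fraction`` of the planted genes are concentrated into the
    first ("true") pathway; the remaining pathways are uniform draws from the
    non-planted universe, with each gene appearing in at most
    ``max_sets_per_gene`` sets.
    """
    rng = np.random.default_rng(spec.seed + 2)
    if spec.n_pathways == 0:
        return GeneSetCollection({})
    universe = [f"g{i:04d}" for i in range(spec.n_genes)]
    planted = list(truth)
    non_planted = [g for g in universe if g not in set(planted)]
    membership_count = {g: 0 for g in universe}

    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}

    n_enriched = int(round(spec.enriched_fraction * len(planted)))
    members: list[str] = []
    if n_enriched > 0:
        members = list(rng.choice(planted, size=n_enriched, replace=False))
    pad = spec.pathway_size - len(members)
    if pad > 0 and non_planted:
        members += list(rng.choice(non_planted, size=min(pad, len(non_planted)), replace=False))
    if members:
        sets["PW_true"] = tuple(members)
        descriptions["PW_true"] = "pathway concentrating the planted signature genes"
        for g in members:
            membership_count[g] += 1

    for p in range(1, spec.n_pathways):
        pool = [g for g in non_planted if membership_count[g] < spec.max_sets_per_gene]
        if spec.enriched_fraction == 0:
            # planted genes scatter uniformly over the whole universe
            pool = [g for g in universe if membership_count[g] < spec.max_sets_per_gene]
        size = min(spec.pathway_size, len(pool))
        if size == 0:
            break
        members = list(rng.choice(pool, size=size, replace=False))
        name = f"PW_{p:03d}"
        sets[name] = tuple(members)
        descriptions[name] = "background pathway"
        for g in members:
            membership_count[g] += 1
    return GeneSetCollection(sets, descriptions)
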