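"""End-to-end orchestration of the two analyses.

* **Progression pipeline** — fold-change prefilter, optional trend
  smoothing and ortholog integration, external k-fold selection with every
  configured method, per-method stability reports, cross-method frequency
  aggregation, pathway enrichment of the fold subsets, and AU-supported
  hierarchical clustering of the samples on the ensemble signature.
* **Survival pipeline** — DEG filtering between two subtype clusters,
  selection with the survival-stage method roster (GS1, GS2, F-TEST,
  RFE_SVM, MRMR), cross-method aggregation into a unique signature, and
  log-rank validation of the signature on an independent cohort.

Every stage derives its own sub-seed from the run seed, so a rerun with the
same config and seed reproduces byte-identical reports.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .cluster_boot import ClusterTree, bootstrap_support, hcluster, highlight_clusters
from .core_io import (
    ExpressionDataset,
    GeneSetCollection,
    HomologMap,
    PipelineConfig,
    SurvivalTable,
    derive_seed,
    get_logger,
    write_json_report,
)
from .enrichment import PathwaySignature, pathway_signature
from .evaluation import EvaluatorSpec, make_evaluator
from .metrics import GeneAnnotation
from .preprocessing import SmoothingSpec, fold_change_filter, map_orthologs, smooth_trend
from .search import GaSpec, RfeSpec, method_runner
from .stability import StabilityReport, cross_method_aggregate, run_stability
from .survival import t_test_deg, validate_signature

__all__ = [
    "RunManifest",
    "annotation_from_genesets",
    "run_progression_pipeline",
    "run_survival_pipeline",
]

SURVIVAL_METHODS = ("gs1", "gs2", "ftest", "rfe_svm", "mrmr")
DEFAULT_PROGRESSION_METHODS = ("ftest", "gs1", "gs2", "rfe", "mrmr")


@dataclass
class RunManifest:
    """Audit trail of a pipeline run: config snapshot, seed, timings, outputs."""

    config: dict
    seed: int
    version: str = __version__
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)


def annotation_from_genesets(collection: GeneSetCollection) -> GeneAnnotation:
    """Derive a functional annotation from a gene-set collection.

    Each set name becomes a term attached to its member genes, so genes
    sharing a pathway share a term — the knowledge base used by the
    GO-similarity redundancy modes when no dedicated annotation is supplied.
    """
    terms: dict[str, set[str]] = {}
    for name, members in collection.sets.items():
        for g in members:
            terms.setdefault(g, set()).add(name)
    return GeneAnnotation({g: frozenset(t) for g, t in terms.items()})


def _resolve_evaluator(evaluator_id: str, seed: int):
    """Map a short evaluator id to a bound evaluator callable."""
    if evaluator_id == "distance":
        spec = EvaluatorSpec(kind="distance_matrix", seed=seed)
    elif evaluator_id.startswith("wrapper_"):
        spec = EvaluatorSpec(kind="wrapper", classifier_id=evaluator_id[8:], seed=seed)
    elif evaluator_id == "cluster_dunn":
        spec = EvaluatorSpec(kind="cluster_external", index="dunn", seed=seed)
    elif evaluator_id == "cluster_fom":
        spec = EvaluatorSpec(kind="cluster_external", index="fom", seed=seed)
    else:
        raise ValueError(f"unknown evaluator id {evaluator_id!r}")
    return make_evaluator(spec)


def run_progression_pipeline(
    dataset: ExpressionDataset,
    config: PipelineConfig,
    genesets: GeneSetCollection | None = None,
    second_dataset: ExpressionDataset | None = None,
    homolog_map: HomologMap | None = None,
    sample_order: Sequence[str] | None = None,
    smooth: bool = False,
    methods: Sequence[str] | None = None,
    rfe_spec: RfeSpec | None = None,
    ga_spec: GaSpec | None = None,
    max_iter: int = 30,
    n_boot: int = 1000,
) -> dict:
    """Run the progression-signature analysis end to end.

    Returns a JSON-serializable report with per-method stability reports,
    the cross-method ensemble, the pathway signature over all fold subsets,
    and the AU-supported sample clustering on the ensemble signature.
    """
    log = get_logger("progression")
    t0 = time.perf_counter()
    seed = config.random_seed
    methods = tuple(methods or config.methods or DEFAULT_PROGRESSION_METHODS)
    log.info("progression pipeline: seed=%d methods=%s", seed, ",".join(methods))

    if second_dataset is not None:
        if homolog_map is None:
            raise ValueError("ortholog integration needs a homolog map")
        dataset = map_orthologs(dataset, second_dataset, homolog_map)
    filtered = fold_change_filter(dataset, config.fold_threshold, config.sample_fraction)
    log.info("fold-change filter: %d -> %d genes", dataset.n_genes, filtered.n_genes)
    if smooth:
        filtered = smooth_trend(filtered, SmoothingSpec(config.smoothing_window), sample_order)
    labels = filtered.label_vector()

    annotation = annotation_from_genesets(genesets) if genesets is not None else GeneAnnotation({})
    evaluator = _resolve_evaluator(config.evaluator, derive_seed(seed, "evaluator"))

    reports: dict[str, StabilityReport] = {}
    for method_id in methods:
        m_seed = derive_seed(seed, f"method:{method_id}")
        runner = method_runner(
            method_id,
            seed=m_seed,
            rfe_spec=rfe_spec,
            ga_spec=ga_spec,
            annotation=annotation,
            max_iter=max_iter,
        )
        reports[method_id] = run_stability(
            filtered, labels, runner, evaluator, config.n_folds, derive_seed(seed, f"cv:{method_id}")
        )
        log.info(
            "method %s: NAHD=%.3f ensemble=%d genes err=%.3f",
            method_id, reports[method_id].nahd,
            len(reports[method_id].ensemble_subset), reports[method_id].ensemble_error,
        )

    if len(reports) >= 2:
        ensemble = cross_method_aggregate(list(reports.values()), filtered, labels, evaluator)
    else:
        ensemble = next(iter(reports.values()))

    signature_genes = list(ensemble.ensemble_subset)
    pw_sig = None
    if genesets is not None:
        run_subsets = [s for r in reports.values() for s in r.fold_subsets]
        pw_sig = pathway_signature(
            run_subsets, genesets, list(filtered.gene_ids), config.alpha_enrich
        )

    tree = hcluster(filtered.subset_genes(signature_genes), "complete", "pearson")
    tree = bootstrap_support(
        filtered.subset_genes(signature_genes), tree, n_boot=n_boot,
        seed=derive_seed(seed, "bootstrap"),
    )
    highlighted = highlight_clusters(tree, config.au_highlight)

    report = {
        "methods": {m: r.to_dict() for m, r in reports.items()},
        "ensemble": ensemble.to_dict(),
        "pathway_signature": pw_sig.to_rows() if pw_sig is not None else None,
        "highlighted_clusters": [sorted(h) for h in highlighted],
        "cluster_nodes": [
            {"members": sorted(n.members), "bp": n.bp, "au": n.au}
            for n in tree.nodes
        ],
        "n_genes_after_filter": filtered.n_genes,
        "seed": seed,
    }
    log.info("progression pipeline done in %.1fs", time.perf_counter() - t0)
    return report


def run_survival_pipeline(
    train: ExpressionDataset,
    validation: ExpressionDataset,
    surv_table: SurvivalTable,
    config: PipelineConfig,
    methods: Sequence[str] = SURVIVAL_METHODS,
    n_clusters: int = 3,
    max_iter: int = 20,
) -> dict:
    """Run the survival-signature analysis end to end.

    ``train`` must carry two-class subtype labels (the A/B clusters); the
    aggregated signature is validated on ``validation`` + ``surv_table`` by
    clustering into ``n_clusters`` subtypes and testing survival separation.
    """
    log = get_logger("survival")
    seed = config.random_seed
    y = train.label_vector()
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError("survival training labels must define exactly 2 subtypes")
    group_a = [s for s in train.sample_ids if train.labels[s] == classes[0]]
    group_b = [s for s in train.sample_ids if train.labels[s] == classes[1]]
    degs = t_test_deg(train, group_a, group_b, config.alpha_deg)
    if not degs:
        raise ValueError(f"no DEG at alpha={config.alpha_deg}; nothing to select from")
    deg_ids = [g for g, _, _ in degs]
    log.info("DEG filter: %d genes at p<%g", len(deg_ids), config.alpha_deg)
    reduced = train.subset_genes(deg_ids)

    evaluator = _resolve_evaluator(config.evaluator, derive_seed(seed, "evaluator"))
    reports: dict[str, StabilityReport] = {}
    for method_id in methods:
        runner = method_runner(
            method_id, seed=derive_seed(seed, f"method:{method_id}"), max_iter=max_iter
        )
        reports[method_id] = run_stability(
            reduced, y, runner, evaluator, config.n_folds, derive_seed(seed, f"cv:{method_id}")
        )
    ensemble = cross_method_aggregate(list(reports.values()), reduced, y, evaluator)
    signature = list(ensemble.ensemble_subset)
    log.info("ensemble signature: %d genes, error %.3f", len(signature), ensemble.ensemble_error)

    validation_result = validate_signature(
        signature, validation, surv_table, n_clusters=n_clusters, alpha=0.05
    )
    return {
        "n_degs": len(deg_ids),
        "methods": {m: r.to_dict() for m, r in reports.items()},
        "signature": signature,
        "signature_frequencies": dict(sorted(ensemble.frequencies.items())),
        "ensemble_error": ensemble.ensemble_error,
        "validation": {
            "chi_square": validation_result["chi_square"],
            "df": validation_result["df"],
            "p_value": validation_result["p_value"],
            "significant": validation_result["significant"],
            "assignment": validation_result["assignment"],
        },
        "seed": seed,
    }
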