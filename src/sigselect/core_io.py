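"""Domain types and file readers/writers shared by every pipeline stage.

The universal currency is the :class:`ExpressionDataset`: a gene x sample
matrix of log2 expression ratios (M values, e.g. knockout vs wild type or
disease vs control) with optional per-sample class labels (disease stage or
tumor subtype).  Gene sets travel as GMT collections, cross-species gene
correspondences as two-column ortholog maps, and follow-up data as survival
tables.  All on-disk formats are plain text (TSV / GMT / JSON) so that runs
are diffable and auditable.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSetCollection",
    "HomologMap",
    "SurvivalTable",
    "PipelineConfig",
    "read_expression",
    "write_expression",
    "read_labels",
    "read_gmt",
    "write_gmt",
    "read_homolog_map",
    "read_survival",
    "write_survival",
    "get_logger",
    "derive_seed",
]

# ---------------------------------------------------------------------------
# Logging: every stage logs to stderr with its name and the seed in play, so
# a run transcript is enough to replay any stage in isolation.
# ---------------------------------------------------------------------------

_LOG_FORMAT = "%(asctime)s %(name)s %(levelname)s: %(message)s"


def get_logger(stage: str) -> logging.Logger:
    """Return a stderr logger namespaced under ``sigselect.<stage>``."""
    logger = logging.getLogger(f"sigselect.{stage}")
    root = logging.getLogger("sigselect")
    if not root.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(_LOG_FORMAT))
        root.addHandler(handler)
        root.setLevel(logging.INFO)
    return logger


def derive_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Derive a per-stage sub-seed deterministically from a master seed.

    Uses numpy's SeedSequence spawning keyed on a stable hash of the stage
    name, so the full pipeline is replayable from a single integer while
    stages remain statistically independent.  The result is always < 2**31.
    """
    key = np.frombuffer(stage.encode("utf-8"), dtype=np.uint8)
    ss = np.random.SeedSequence([int(master_seed), int(index), *key.tolist()])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionDataset:
    """Gene x sample matrix of log2 ratios with optional sample class labels.

    Parameters
    ----------
    gene_ids
        Unique gene identifiers, one per matrix row.
    sample_ids
        Unique sample identifiers, one per matrix column.
    values
        Array of shape ``(len(gene_ids), len(sample_ids))`` of finite M values.
    labels
        Optional mapping ``sample_id -> class label``; when present it must
        cover every sample and contain at least two distinct classes.
    """

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray
    labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids must be unique")
        if vals.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.sample_ids)})"
            )
        if not np.all(np.isfinite(vals)):
            g, s = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )
        if self.labels is not None:
            labels = {str(k): str(v) for k, v in self.labels.items()}
            object.__setattr__(self, "labels", labels)
            missing = [s for s in self.sample_ids if s not in labels]
            if missing:
                raise ValueError(f"samples without a label: {missing[:5]}")
            unknown = [s for s in labels if s not in set(self.sample_ids)]
            if unknown:
                raise ValueError(f"label for unknown sample(s): {unknown[:5]}")
            if len(set(labels.values())) < 2:
                raise ValueError("labels must contain at least 2 classes")

    # -- convenience accessors -------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def label_vector(self) -> np.ndarray:
        """Class labels in sample order (requires labels)."""
        if self.labels is None:
            raise ValueError("dataset has no labels")
        return np.array([self.labels[s] for s in self.sample_ids], dtype=object)

    def gene_index(self, gene_ids: Sequence[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([pos[g] for g in gene_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown gene id {exc.args[0]!r}") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(gene_ids)
        return ExpressionDataset(
            tuple(gene_ids), self.sample_ids, self.values[idx], self.labels
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        labels = None
        if self.labels is not None:
            labels = {s: self.labels[s] for s in sample_ids}
        return ExpressionDataset(self.gene_ids, tuple(sample_ids), self.values[:, idx], labels)

    def with_labels(self, labels: Mapping[str, str]) -> "ExpressionDataset":
        return ExpressionDataset(self.gene_ids, self.sample_ids, self.values, dict(labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=list(self.sample_ids))


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathway membership) with free-text descriptions."""

    sets: dict[str, tuple[str, ...]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if len(members) == 0:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


@dataclass(frozen=True)
class HomologMap:
    """Ortholog correspondences between two species' gene identifier spaces."""

    pairs: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(a), str(b)) for a, b in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate ortholog pairs")
        for a, b in pairs:
            if not a or not b:
                raise ValueError("empty gene id in ortholog pair")


@dataclass(frozen=True)
class SurvivalTable:
    """Per-sample follow-up time (days), event flag and optional group label."""

    sample_ids: tuple[str, ...]
    time: np.ndarray
    event: np.ndarray
    group: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in survival table")
        if t.shape != (len(self.sample_ids),) or e.shape != t.shape:
            raise ValueError("time/event length mismatch with sample ids")
        if np.any(t < 0):
            raise ValueError("negative follow-up time")
        if not np.all(np.isin(e, [0, 1])):
            raise ValueError("event flags must be 0 (censored) or 1 (death)")
        if self.group is not None:
            grp = tuple(str(g) for g in self.group)
            object.__setattr__(self, "group", grp)
            if len(grp) != len(self.sample_ids):
                raise ValueError("group length mismatch")

    def with_group(self, group: Sequence[str]) -> "SurvivalTable":
        return SurvivalTable(self.sample_ids, self.time, self.event, tuple(group))

    def subset(self, sample_ids: Sequence[str]) -> "SurvivalTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        grp = None if self.group is None else tuple(self.group[i] for i in idx)
        return SurvivalTable(tuple(sample_ids), self.time[idx], self.event[idx], grp)


@dataclass
class PipelineConfig:
    """Global constants of a pipeline run.

    Defaults mirror the study design the pipeline implements: external
    five-fold resampling around each selection method, a two-fold regulation
    prefilter in >= 20% of samples, enrichment at p < 0.05, DEG filtering at
    p < 0.001, AU highlight threshold 0.95 and a stage-wide smoothing window
    of four samples (one disease stage's worth of replicates).
    """

    random_seed: int = 0
    n_folds: int = 5
    fold_threshold: float = 2.0
    sample_fraction: float = 0.20
    alpha_enrich: float = 0.05
    alpha_deg: float = 0.001
    au_highlight: float = 0.95
    smoothing_window: int = 4
    methods: tuple[str, ...] = ()
    evaluator: str = "distance"

    def __post_init__(self) -> None:
        if not (0 < self.sample_fraction <= 1):
            raise ValueError("sample_fraction must be in (0, 1]")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for name in ("alpha_enrich", "alpha_deg", "au_highlight"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1)")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, labels_path: str | Path | None = None) -> ExpressionDataset:
    """Read a TSV expression matrix (gene rows, sample columns).

    The first column holds gene ids and the header row sample ids.  Duplicate
    gene rows are collapsed by the arithmetic mean of their values, mirroring
    the convention of averaging probes that map to the same gene.  A second
    TSV with columns ``sample_id``/``label`` attaches class labels.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if len(header) < 2:
        raise ValueError(f"{path}: malformed header (need gene column + >=1 sample)")
    sample_ids = header[1:]
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = df.index.astype(str)
    try:
        mat = df.to_numpy(dtype=float)
    except ValueError:
        # locate the offending cell for a descriptive error
        for g, row in zip(genes, df.itertuples(index=False)):
            for s, cell in zip(sample_ids, row):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} at gene {g!r}, sample {s!r}"
                    ) from None
        raise
    if not np.all(np.isfinite(mat)):
        g, s = np.argwhere(~np.isfinite(mat))[0]
        raise ValueError(
            f"{path}: non-finite value at gene {genes[g]!r}, sample {sample_ids[s]!r}"
        )
    # collapse duplicate gene rows by mean, preserving first-appearance order
    if genes.has_duplicates:
        frame = pd.DataFrame(mat, index=genes)
        order = list(dict.fromkeys(genes))
        frame = frame.groupby(level=0, sort=False).mean().loc[order]
        genes = frame.index
        mat = frame.to_numpy()
    labels = read_labels(labels_path, sample_ids) if labels_path is not None else None
    return ExpressionDataset(tuple(genes), tuple(sample_ids), mat, labels)


def read_labels(path: str | Path, sample_ids: Iterable[str]) -> dict[str, str]:
    """Read a two-column ``sample_id<TAB>label`` TSV (header optional)."""
    known = set(map(str, sample_ids))
    labels: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            sid, lab = parts
            if lineno == 1 and sid.lower() in {"sample", "sample_id"}:
                continue
            if sid not in known:
                raise ValueError(f"{path}:{lineno}: label for unknown sample {sid!r}")
            labels[sid] = lab
    return labels


def write_expression(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix as TSV with full float precision (round-trip safe)."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
        for g, row in zip(dataset.gene_ids, dataset.values):
            fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: per line set name, description, member ids."""
    sets: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=3 fields, got {len(parts)}")
            name, desc = parts[0], parts[1]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(m for m in parts[2:] if m))
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_homolog_map(path: str | Path) -> HomologMap:
    """Read a two-column ortholog map TSV (species A id, species B id)."""
    pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            pair = (parts[0], parts[1])
            if pair in seen:
                continue
            seen.add(pair)
            pairs.append(pair)
    return HomologMap(tuple(pairs))


def read_survival(path: str | Path) -> SurvivalTable:
    """Read a survival TSV: sample_id, time, event[, group]; header optional."""
    ids: list[str] = []
    times: list[float] = []
    events: list[int] = []
    groups: list[str] = []
    has_group = False
    with Path(path).open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) not in (3, 4):
                raise ValueError(f"{path}:{lineno}: expected 3-4 columns, got {len(parts)}")
            if lineno == 1 and parts[0].lower() in {"sample", "sample_id"}:
                continue
            ids.append(parts[0])
            times.append(float(parts[1]))
            events.append(int(parts[2]))
            if len(parts) == 4:
                has_group = True
                groups.append(parts[3])
    grp = tuple(groups) if has_group else None
    return SurvivalTable(tuple(ids), np.array(times), np.array(events), grp)


def write_survival(table: SurvivalTable, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        cols = ["sample_id", "time", "event"] + (["group"] if table.group else [])
        fh.write("\t".join(cols) + "\n")
        for i, sid in enumerate(table.sample_ids):
            row = [sid, repr(float(table.time[i])), str(int(table.event[i]))]
            if table.group:
                row.append(table.group[i])
            fh.write("\t".join(row) + "\n")


def write_json_report(obj, path: str | Path) -> None:
    """Serialize a report dict to stable, sorted JSON (byte-reproducible)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
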