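"""Core in-memory containers shared across pipeline stages.

Matrices are cells x genes throughout.  Cell metadata travels as a pandas
DataFrame (one row per cell) rather than as per-cell objects; tabular
results (DE tables, edge scores) are DataFrames with fixed column
contracts so they round-trip through TSV unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "GeneSignature",
    "Regulon",
    "GoldStandard",
    "DirectedNetwork",
    "validate_annotation",
    "ANNOTATION_COLUMNS",
]

#: required columns of a cell-annotation table
ANNOTATION_COLUMNS = ("cell_id", "condition", "total_counts", "mito_fraction")


def _check_unique(ids, what: str) -> list:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} ids are not unique")
    return ids


@dataclass
class CountMatrix:
    """UMI counts, cells x genes, non-negative integers."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes array")
        if np.any(self.values < 0):
            raise ValueError("counts contain negative entries")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.allclose(self.values, np.round(self.values)):
                raise ValueError("counts must be integers")
            self.values = self.values.astype(np.int64)
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.cell_ids)} cells x {len(self.gene_ids)} genes"
            )

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class NormalizedMatrix:
    """log1p of size-factor-scaled counts, with the per-cell size factors."""

    values: np.ndarray
    cell_ids: list
    gene_ids: list
    size_factors: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.size_factors = np.asarray(self.size_factors, dtype=float)
        self.cell_ids = _check_unique(self.cell_ids, "cell")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        if self.values.shape != (len(self.cell_ids), len(self.gene_ids)):
            raise ValueError("shape inconsistent with ids")
        if self.size_factors.shape != (len(self.cell_ids),):
            raise ValueError("one size factor per cell required")
        if np.any(self.size_factors <= 0):
            raise ValueError("size factors must be positive")
        if abs(self.size_factors.mean() - 1.0) > 1e-8:
            raise ValueError("size factors must average 1")
        if np.any(self.values < 0):
            raise ValueError("normalized values must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def gene_index(self, gene_id: str) -> int:
        try:
            return self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene {gene_id!r} not in matrix") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cell_ids, columns=self.gene_ids)


@dataclass
class GeneSignature:
    """A named gene set, e.g. a tolerogenic signature panel."""

    name: str
    genes: list
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = [str(g) for g in self.genes]
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicate genes")


@dataclass
class Regulon:
    """A transcription factor with its (inferred or curated) target genes."""

    tf: str
    targets: list

    def __post_init__(self) -> None:
        self.targets = [str(t) for t in self.targets]
        if not self.targets:
            raise ValueError(f"regulon {self.tf!r} has no targets")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError(f"regulon {self.tf!r} contains duplicate targets")
        if self.tf in self.targets:
            raise ValueError(f"regulon {self.tf!r} lists its own TF as target")


@dataclass
class GoldStandard:
    """The simulator's true directed TF->target edge set."""

    edges: set
    tf_list: list

    def __post_init__(self) -> None:
        self.edges = {(str(s), str(t)) for s, t in self.edges}
        self.tf_list = [str(t) for t in self.tf_list]
        tfs = set(self.tf_list)
        for s, t in self.edges:
            if s not in tfs:
                raise ValueError(f"edge source {s!r} not in tf_list")
            if s == t:
                raise ValueError(f"self-edge {s!r} in gold standard")

    @property
    def targets(self) -> set:
        return {t for _, t in self.edges}

    def children(self, tf: str) -> set:
        return {t for s, t in self.edges if s == tf}


@dataclass
class DirectedNetwork:
    """Thresholded TF->target network with optional hierarchy layers.

    ``edges`` has columns (source, target, weight); ``layers`` maps node ->
    hierarchy rank (TFs at 0) for export to graph formats.
    """

    edges: pd.DataFrame
    tf_list: list
    layers: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"source", "target", "weight"}
        if not required.issubset(self.edges.columns):
            raise ValueError(f"edge table must have columns {sorted(required)}")
        tfs = set(self.tf_list)
        if len(self.edges) and not set(self.edges["source"]).issubset(tfs):
            raise ValueError("every edge source must be a TF")
        pairs = list(zip(self.edges["source"], self.edges["target"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (source, target) edges")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def validate_annotation(ann: pd.DataFrame, cell_ids=None) -> pd.DataFrame:
    """Check a cell-annotation table and return it with a clean index."""
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation missing columns {missing}")
    ann = ann.copy()
    ann["cell_id"] = ann["cell_id"].astype(str)
    if ann["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in annotation")
    bad = ~ann["mito_fraction"].between(0.0, 1.0)
    if bad.any():
        raise ValueError("mito_fraction outside [0, 1]")
    if cell_ids is not None:
        want = [str(c) for c in cell_ids]
        have = set(ann["cell_id"])
        absent = [c for c in want if c not in have]
        if absent:
            raise ValueError(f"annotation missing cells: {absent[:5]}...")
        ann = ann.set_index("cell_id").loc[want].reset_index()
    return ann.reset_index(drop=True)
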