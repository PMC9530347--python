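"""Pipeline configuration.

All analysis thresholds live in a single :class:`PipelineConfig` so that a
run is fully described by one object (serialisable to/from YAML).  The
defaults are the study settings: 20% mitochondrial cut-off, genes kept when
detected in >=10 cells, top-2000 highly variable genes with mean in (0, 4)
and normalised dispersion >= 0.1, a 10-nearest-neighbour graph on 30
principal components, Leiden resolution 0.5, DEG calls at BH q < 0.01 and
|log2FC| > 1, regulon enrichment at z > 0.4, network edges kept at
confidence > 1, and a 5-TF inference panel.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig", "substream_seed"]


@dataclass
class PipelineConfig:
    """Thresholds and sizes for every pipeline stage."""

    mito_max: float = 0.20
    min_cells_per_gene: int = 10
    n_hvg: int = 2000
    hvg_min_mean: float = 0.0
    hvg_max_mean: float = 4.0
    hvg_min_disp: float = 0.1
    n_neighbors: int = 10
    n_pcs: int = 30
    leiden_resolution: float = 0.5
    deg_fdr: float = 0.01
    deg_logfc: float = 1.0
    regulon_z: float = 0.4
    edge_weight_min: float = 1.0
    n_top_tfs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.mito_max <= 1.0:
            raise ValueError(f"mito_max must be in (0, 1], got {self.mito_max}")
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be non-negative")
        if self.n_hvg < 1:
            raise ValueError("n_hvg must be positive")
        if self.hvg_min_mean >= self.hvg_max_mean:
            raise ValueError("hvg_min_mean must be below hvg_max_mean")
        if self.n_neighbors < 1:
            raise ValueError("n_neighbors must be positive")
        if self.n_pcs < 1:
            raise ValueError("n_pcs must be positive")
        if self.leiden_resolution <= 0:
            raise ValueError("leiden_resolution must be positive")
        if not 0.0 < self.deg_fdr < 1.0:
            raise ValueError("deg_fdr must be in (0, 1)")
        if self.deg_logfc < 0:
            raise ValueError("deg_logfc must be non-negative")
        if self.n_top_tfs < 1:
            raise ValueError("n_top_tfs must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def substream_seed(seed: int, stage: str) -> int:
    """Derive a stable per-stage RNG seed from one global seed.

    Hashing (seed, stage) keeps every stage reproducible regardless of the
    order stages are invoked in, and keeps the derived seed below 2**31.
    """
    digest = hashlib.blake2b(f"{seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)
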