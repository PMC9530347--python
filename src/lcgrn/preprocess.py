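"""Quality control, normalization, HVG selection and graph clustering.

QC removes stressed/dying cells by mitochondrial fraction and rarely
detected genes.  Normalization uses pooled size-factor deconvolution:
cells are arranged on a ring (library sizes interleaved so pools are
balanced), pool-level factors are estimated as median count ratios to an
average pseudo-cell, and per-cell factors are recovered from the pooled
linear system by least squares.  For very small data sets the estimator
falls back to plain library-size factors.  Clustering is Leiden community
detection on a 10-nearest-neighbour graph over the leading principal
components of the standardized HVG submatrix.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig, substream_seed
from .containers import CountMatrix, NormalizedMatrix, validate_annotation

logger = logging.getLogger(__name__)

__all__ = ["qc_filter", "normalize", "select_hvg", "cluster_cells",
           "mito_fraction_from_gene_names", "POOL_SIZES"]

#: deconvolution pool sizes (clipped to n-1 for small data sets)
POOL_SIZES = (21, 26, 31, 36, 41)

#: below this cell count, pooling is unstable; use library-size factors
MIN_CELLS_FOR_POOLING = 50


def mito_fraction_from_gene_names(counts: CountMatrix, prefix: str = "MT-") -> np.ndarray:
    """Fallback mito fraction for real data with human gene nomenclature."""
    is_mt = np.array([g.upper().startswith(prefix) for g in counts.gene_ids])
    total = counts.values.sum(axis=1)
    if not is_mt.any():
        logger.warning("no gene names start with %r; mito fraction set to 0", prefix)
        return np.zeros(counts.n_cells)
    return counts.values[:, is_mt].sum(axis=1) / np.maximum(total, 1)


def qc_filter(counts: CountMatrix, ann: pd.DataFrame, cfg: PipelineConfig):
    """Drop cells with mito fraction >= mito_max, then genes detected in
    fewer than min_cells_per_gene of the surviving cells."""
    ann = validate_annotation(ann, counts.cell_ids)
    keep_cells = (ann["mito_fraction"] < cfg.mito_max).to_numpy()
    if not keep_cells.any():
        raise ValueError("QC removed every cell (mitochondrial filter)")
    values = counts.values[keep_cells]
    detected = (values > 0).sum(axis=0)
    keep_genes = detected >= cfg.min_cells_per_gene
    if not keep_genes.any():
        raise ValueError("QC removed every gene (detection filter)")
    logger.info(
        "QC: removed %d/%d cells (mito >= %.2f), %d/%d genes (< %d cells)",
        (~keep_cells).sum(), counts.n_cells, cfg.mito_max,
        (~keep_genes).sum(), counts.n_genes, cfg.min_cells_per_gene,
    )
    filtered = CountMatrix(
        values=values[:, keep_genes],
        cell_ids=[c for c, k in zip(counts.cell_ids, keep_cells) if k],
        gene_ids=[g for g, k in zip(counts.gene_ids, keep_genes) if k],
    )
    ann_out = ann.loc[keep_cells].reset_index(drop=True)
    return filtered, ann_out


# ---------------------------------------------------------------------------
# normalization

def _library_size_factors(lib: np.ndarray) -> np.ndarray:
    return lib / lib.mean()


def _ring_order(lib: np.ndarray) -> np.ndarray:
    """Interleave cells sorted by library size so that pools taken along
    the ring mix small and large libraries."""
    order = np.argsort(lib, kind="stable")
    return np.concatenate([order[::2], order[1::2][::-1]])


def _deconvolution_factors(values: np.ndarray) -> np.ndarray:
    """Pooled deconvolution, solved on the library-size-adjusted scale.

    Cells are first scaled to equal library size; the pooled system then
    estimates each cell's residual (composition) factor theta around 1,
    and the final size factor is theta times the library-size factor.
    Working near 1 keeps the median-ratio pool estimates well behaved
    even for cells with outlying library sizes.
    """
    n = values.shape[0]
    lib = values.sum(axis=1).astype(float)
    lib_factors = _library_size_factors(lib)
    adjusted = values / lib_factors[:, None]
    ring = _ring_order(lib)
    reference = adjusted.mean(axis=0)
    usable = reference > 0
    ref = reference[usable]

    sizes = sorted({min(s, n - 1) for s in POOL_SIZES})
    rows, cols, data, b = [], [], [], []
    row = 0
    for size in sizes:
        for start in range(n):
            pool = ring[(start + np.arange(size)) % n]
            pooled = adjusted[pool][:, usable].sum(axis=0)
            b.append(np.median(pooled / ref))
            for j in pool:
                rows.append(row)
                cols.append(j)
                data.append(1.0)
            row += 1
    # low-weight anchors tie each theta to 1 (pure library-size scaling)
    anchor_weight = np.sqrt(0.1)
    for j in range(n):
        rows.append(row)
        cols.append(j)
        data.append(anchor_weight)
        b.append(anchor_weight)
        row += 1

    design = np.zeros((row, n))
    design[rows, cols] = data
    theta, *_ = np.linalg.lstsq(design, np.asarray(b), rcond=None)
    # a noisy median (few genes) can push single cells to non-positive
    # estimates; fall back to pure library-size scaling for those
    degenerate = theta < 0.05
    if degenerate.any():
        logger.warning("deconvolution: %d degenerate factors replaced by "
                       "library-size factors", int(degenerate.sum()))
        theta = np.where(degenerate, 1.0, theta)
    solution = theta * lib_factors
    return solution / solution.mean()


def normalize(counts: CountMatrix) -> NormalizedMatrix:
    """Size-factor normalization by pooled deconvolution; log1p output."""
    lib = counts.values.sum(axis=1)
    zero = [c for c, t in zip(counts.cell_ids, lib) if t == 0]
    if zero:
        raise ValueError(f"cells with zero total counts: {zero[:5]}")
    if counts.n_cells < MIN_CELLS_FOR_POOLING:
        logger.info("n=%d < %d cells: using library-size factors",
                    counts.n_cells, MIN_CELLS_FOR_POOLING)
        sf = _library_size_factors(lib.astype(float))
    else:
        sf = _deconvolution_factors(counts.values.astype(float))
    values = np.log1p(counts.values / sf[:, None])
    return NormalizedMatrix(values=values, cell_ids=list(counts.cell_ids),
                            gene_ids=list(counts.gene_ids), size_factors=sf)


# ---------------------------------------------------------------------------
# highly variable genes

N_DISPERSION_BINS = 20


def select_hvg(norm: NormalizedMatrix, cfg: PipelineConfig) -> list:
    """Mean/dispersion HVG selection.

    Works on the de-logged scale: per gene, mean and dispersion
    (variance/mean) of expm1(values); dispersions are z-scored within 20
    mean-bins; genes pass with mean strictly inside
    (hvg_min_mean, hvg_max_mean) and normalized dispersion >= hvg_min_disp;
    the top n_hvg by normalized dispersion are returned.
    """
    if norm.n_cells < 2:
        raise ValueError("HVG selection requires at least 2 cells")
    x = np.expm1(norm.values)
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), np.nan)

    finite = np.isfinite(disp)
    norm_disp = np.full(norm.n_genes, np.nan)
    if finite.any():
        # bins need several genes each to z-score within; small panels get
        # proportionally fewer bins (a single one below ~20 genes)
        n_bins = max(1, min(N_DISPERSION_BINS, int(finite.sum()) // 10))
        bins = pd.cut(mean[finite], bins=n_bins, labels=False,
                      duplicates="drop")
        d = disp[finite]
        z = np.full(d.shape, 0.0)
        for b in np.unique(bins):
            in_bin = bins == b
            if in_bin.sum() > 1:
                mu, sd = d[in_bin].mean(), d[in_bin].std(ddof=1)
                if sd > 0:
                    z[in_bin] = (d[in_bin] - mu) / sd
        norm_disp[finite] = z

    qualifies = (
        np.isfinite(norm_disp)
        & (mean > cfg.hvg_min_mean)
        & (mean < cfg.hvg_max_mean)
        & (norm_disp >= cfg.hvg_min_disp)
    )
    if not qualifies.any():
        raise ValueError("no gene passes the HVG criteria")
    idx = np.flatnonzero(qualifies)
    # descending dispersion, gene id as deterministic tie-break
    order = sorted(idx, key=lambda i: (-norm_disp[i], norm.gene_ids[i]))
    return [norm.gene_ids[i] for i in order[: cfg.n_hvg]]


# ---------------------------------------------------------------------------
# clustering

def cluster_cells(norm: NormalizedMatrix, cfg: PipelineConfig) -> list:
    """Leiden clustering on a kNN graph over the leading PCs of the
    standardized HVG submatrix; labels '0','1',... by decreasing size."""
    import igraph as ig
    import leidenalg

    if norm.n_cells < cfg.n_neighbors + 1:
        raise ValueError(
            f"need at least n_neighbors+1={cfg.n_neighbors + 1} cells, "
            f"got {norm.n_cells}"
        )
    hvg = select_hvg(norm, cfg)
    cols = [norm.gene_ids.index(g) for g in hvg]
    x = norm.values[:, cols]
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    n_comp = min(cfg.n_pcs, min(x.shape) - 1) or 1
    pcs = PCA(n_components=n_comp, svd_solver="full").fit_transform(x)

    nn = NearestNeighbors(n_neighbors=cfg.n_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = set()
    for i, row in enumerate(idx):
        for j in row[1:]:  # skip self
            edges.add((min(i, int(j)), max(i, int(j))))
    graph = ig.Graph(n=norm.n_cells, edges=sorted(edges), directed=False)
    part = leidenalg.find_partition(
        graph,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=cfg.leiden_resolution,
        seed=substream_seed(cfg.seed, "leiden"),
        n_iterations=-1,
    )
    membership = np.asarray(part.membership)
    sizes = pd.Series(membership).value_counts()
    relabel = {old: str(new) for new, old in enumerate(sizes.index)}
    return [relabel[m] for m in membership]
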