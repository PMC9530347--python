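"""Per-cell gene-signature scoring and between-group comparison.

Two scoring routes:

* ``zscore_signature_score`` — each signature gene is standardized across
  cells and a cell's score is the mean z-score over present genes (the
  "average expression of whole signatures" display statistic);
* ``gsva_score`` — a single-sample enrichment score in the GSVA style:
  a Gaussian-kernel cumulative density statistic per gene (bandwidth
  sd/4), per-cell gene ranking by that statistic, ranks symmetrized
  around the middle of the list, and a weighted Kolmogorov-Smirnov-like
  random walk whose signed extrema are summed into the enrichment score.

Score tables are DataFrames (cells x signatures) carrying the method name
in ``attrs['method']``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr
from statsmodels.stats.multitest import multipletests

from .containers import GeneSignature, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["zscore_signature_score", "gsva_score", "compare_signature_enrichment"]

#: Gaussian-kernel bandwidth as a fraction of the per-gene sd
GSVA_BANDWIDTH_FACTOR = 0.25
#: exponent on the symmetrized rank statistic in the random walk
GSVA_TAU = 1.0


def _present_genes(norm: NormalizedMatrix, sig: GeneSignature) -> list:
    present = [g for g in sig.genes if g in set(norm.gene_ids)]
    if len(present) < len(sig.genes):
        logger.warning("signature %r: %d/%d genes absent from the matrix",
                       sig.name, len(sig.genes) - len(present), len(sig.genes))
    if not present:
        raise ValueError(f"no gene of signature {sig.name!r} is in the matrix")
    return present


def zscore_signature_score(norm: NormalizedMatrix, sig: GeneSignature) -> pd.DataFrame:
    """Mean per-gene z-score over the signature's present genes."""
    if norm.n_cells < 2:
        raise ValueError("z-scoring requires at least 2 cells")
    present = _present_genes(norm, sig)
    cols = [norm.gene_index(g) for g in present]
    x = norm.values[:, cols]
    sd = x.std(axis=0, ddof=0)
    informative = sd > 0
    if not informative.any():
        raise ValueError(f"all genes of signature {sig.name!r} are constant")
    if not informative.all():
        logger.warning("signature %r: dropping %d constant genes",
                       sig.name, int((~informative).sum()))
    z = (x[:, informative] - x[:, informative].mean(axis=0)) / sd[informative]
    table = pd.DataFrame({sig.name: z.mean(axis=1)}, index=norm.cell_ids)
    table.attrs["method"] = "zscore"
    return table


# ---------------------------------------------------------------------------
# GSVA-style scoring

def _kernel_cdf_statistic(values: np.ndarray) -> np.ndarray:
    """Per-gene Gaussian-kernel CDF estimate evaluated at each cell.

    values: cells x genes; returns the same shape.  Bandwidth sd/4 per
    gene; constant genes get identical statistics in every cell.
    """
    n_cells, n_genes = values.shape
    out = np.empty_like(values, dtype=float)
    sd = values.std(axis=0, ddof=1) if n_cells > 1 else np.zeros(n_genes)
    for g in range(n_genes):
        h = GSVA_BANDWIDTH_FACTOR * sd[g]
        col = values[:, g]
        if h <= 0:
            out[:, g] = 0.5
            continue
        diff = (col[:, None] - col[None, :]) / h  # eval at i, kernel at k
        out[:, g] = ndtr(diff).mean(axis=1)
    return out


def gsva_score(norm: NormalizedMatrix, sigs) -> pd.DataFrame:
    """Single-sample enrichment scores for one or more signatures."""
    if isinstance(sigs, GeneSignature):
        sigs = [sigs]
    if norm.n_cells < 3:
        raise ValueError("GSVA-style scoring requires at least 3 cells")
    n_genes = norm.n_genes
    stat = _kernel_cdf_statistic(norm.values)

    # per cell: gene ranks by decreasing statistic, deterministic tie-break
    order = np.lexsort((np.arange(n_genes)[None, :].repeat(norm.n_cells, 0),
                        -stat), axis=1)
    ranks = np.empty_like(order)
    rows = np.arange(norm.n_cells)[:, None]
    ranks[rows, order] = np.arange(1, n_genes + 1)[None, :]
    sym = np.abs(n_genes / 2.0 - ranks)  # symmetrized around the middle

    tables = {}
    for sig in sigs:
        present = _present_genes(norm, sig)
        if len(present) >= n_genes:
            raise ValueError(
                f"signature {sig.name!r} covers every gene; complement is empty")
        in_set = np.zeros(n_genes, dtype=bool)
        for g in present:
            in_set[norm.gene_index(g)] = True

        scores = np.empty(norm.n_cells)
        n_out = n_genes - in_set.sum()
        for c in range(norm.n_cells):
            ordered = order[c]
            member = in_set[ordered]
            w = np.where(member, np.power(sym[c, ordered], GSVA_TAU), 0.0)
            denom = w.sum()
            inc = w / denom if denom > 0 else np.zeros_like(w)
            dec = np.where(member, 0.0, 1.0 / n_out)
            walk = np.cumsum(inc - dec)
            scores[c] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
        tables[sig.name] = scores

    table = pd.DataFrame(tables, index=norm.cell_ids)
    table.attrs["method"] = "gsva"
    return table


def compare_signature_enrichment(scores: pd.DataFrame, groups,
                                 group_a=None, group_b=None) -> pd.DataFrame:
    """Welch t-test per signature between two cell groups, BH across
    signatures; logFC is mean(B) - mean(A) of the (log-like) scores."""
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != len(scores):
        raise ValueError("one group label per cell required")
    levels = sorted(set(groups))
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError(f"expected two group levels, got {levels}")
        group_a, group_b = levels
    in_a, in_b = groups == str(group_a), groups == str(group_b)
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("both groups need at least 2 cells")

    rows = []
    for name in scores.columns:
        a = scores.loc[in_a, name].to_numpy()
        b = scores.loc[in_b, name].to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            _, p = stats.ttest_ind(b, a, equal_var=False)
        rows.append({"signature": name,
                     "logfc": float(b.mean() - a.mean()),
                     "p": 1.0 if np.isnan(p) else float(p)})
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
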