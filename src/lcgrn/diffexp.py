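"""Differential expression and consensus signature assembly.

DE between two groups of cells uses a per-gene Welch (unequal-variance)
t-test on normalized values with Benjamini-Hochberg correction across all
tested genes.  The fold change is computed on the de-logged scale,
log2((mean expm1 B + eps) / (mean expm1 A + eps)), and a gene is flagged
when q < deg_fdr and |log2FC| > deg_logfc.  Consensus signatures collect
genes co-upregulated in at least k of several input DEG lists (the logic
behind the 217-gene tolerogenic consensus panel).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .containers import GeneSignature, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = ["differential_expression", "assemble_consensus_signature",
           "signature_overlap", "DEG_COLUMNS"]

DEG_COLUMNS = ("gene", "logFC", "pval", "qval", "mean_a", "mean_b", "up_in")

_EPS = 1e-9


def differential_expression(norm: NormalizedMatrix, groups, cfg: PipelineConfig,
                            group_a=None, group_b=None) -> pd.DataFrame:
    """Per-gene Welch t-test between two cell groups.

    ``groups`` gives one label per cell; with more than two levels,
    ``group_a``/``group_b`` pick the contrast.  Returns a DataFrame with
    columns (gene, logFC, pval, qval, mean_a, mean_b, up_in) where logFC
    is log2 of condition B over condition A on the de-logged scale and
    ``up_in`` is 'A', 'B' or '' by the q/logFC thresholds.
    """
    groups = np.asarray([str(g) for g in groups])
    if len(groups) != norm.n_cells:
        raise ValueError("one group label per cell required")
    levels = sorted(set(groups))
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError(f"expected two group levels, got {levels}")
        group_a, group_b = levels
    in_a, in_b = groups == str(group_a), groups == str(group_b)
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("both groups need at least 2 cells")

    xa, xb = norm.values[in_a], norm.values[in_b]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(xb, xa, axis=0, equal_var=False)
    constant = np.isnan(p)
    if constant.any():
        logger.info("%d genes constant in both groups; p set to 1", constant.sum())
        p = np.where(constant, 1.0, p)

    mean_a = np.expm1(xa).mean(axis=0)
    mean_b = np.expm1(xb).mean(axis=0)
    logfc = np.log2((mean_b + _EPS) / (mean_a + _EPS))
    q = multipletests(p, method="fdr_bh")[1]

    sig = (q < cfg.deg_fdr) & (np.abs(logfc) > cfg.deg_logfc)
    up_in = np.where(sig & (logfc > 0), "B", np.where(sig & (logfc < 0), "A", ""))
    return pd.DataFrame({
        "gene": norm.gene_ids,
        "logFC": logfc,
        "pval": p,
        "qval": q,
        "mean_a": mean_a,
        "mean_b": mean_b,
        "up_in": up_in,
    })


def assemble_consensus_signature(deg_lists: dict, k: int, name: str) -> GeneSignature:
    """Genes appearing in >= k of the named input gene lists.

    ``deg_lists`` maps a list name to its gene ids.  Provenance records,
    per gene, which lists contributed it.
    """
    if len(deg_lists) < 2:
        raise ValueError("need at least 2 input lists")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(deg_lists):
        raise ValueError(f"k={k} exceeds the {len(deg_lists)} input lists")
    membership: dict = {}
    for list_name, genes in deg_lists.items():
        for g in set(map(str, genes)):
            membership.setdefault(g, []).append(list_name)
    consensus = sorted(g for g, lists in membership.items() if len(lists) >= k)
    if not consensus:
        raise ValueError(f"no gene appears in >= {k} lists; reduce k")
    provenance = "; ".join(
        f"{g}: {','.join(sorted(membership[g]))}" for g in consensus
    )
    return GeneSignature(name=name, genes=consensus, provenance=provenance)


def signature_overlap(sig: GeneSignature, expressed) -> tuple:
    """Intersect a signature with a dataset's expressed-gene universe.

    Returns (n_present, n_total, present_genes) — e.g. 30/64 of a
    tolerogenic panel expressed in a given data set.
    """
    universe = set(map(str, expressed))
    present = sorted(g for g in sig.genes if g in universe)
    return len(present), len(sig.genes), present
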