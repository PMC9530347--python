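"""Information-theoretic gene-regulatory-network inference (directional PIDC).

The method ranks gene pairs by the *proportional unique contribution*
(PUC): the share of a pair's mutual information that is unique rather
than redundant with third genes.  For a pair (X, Y) and every context
gene Z, partial information decomposition with the Williams-Beer I_min
redundancy splits I(X;Y) into a redundant part — the expected minimum
specific information of X and Z about each outcome of Y — and a unique
part.  Summing the unique/total ratio over all contexts, in both
directions of the pair, gives the PUC score

    u_XY = sum_Z unique_X(Y|Z)/I(X;Y) + sum_Z unique_Y(X|Z)/I(X;Y).

Raw PUC scores are not comparable between genes, so each gene's score
set is converted to a CDF (empirical by default, moment-matched gamma
optionally) and an edge's confidence is the sum of the two endpoint CDFs
evaluated at its score — a value in [0, 2].  The directional step then
keeps only pairs touching a transcription factor, orients them TF ->
target (both directions for TF-TF pairs), and applies a strict weight
threshold (> 1 by default).

All information quantities are maximum-likelihood plug-in estimates on
discretized expression (uniform-width bins, ceil(sqrt(n)) by default) and
are reported in bits (log base 2).  A key simplification used throughout:
I_min redundancy depends only on the *pairwise* joints p(x, y) and
p(z, y), never on the three-way joint.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .containers import DirectedNetwork, GeneSignature, NormalizedMatrix, Regulon

logger = logging.getLogger(__name__)

__all__ = [
    "DiscretizedGene",
    "discretize",
    "discretize_panel",
    "mutual_information",
    "redundancy_unique",
    "puc_matrix",
    "edge_confidence",
    "select_network_genes",
    "build_directed_network",
    "extract_regulons",
    "infer_network",
    "export_graphml",
    "export_dot",
]


# ---------------------------------------------------------------------------
# discretization

@dataclass
class DiscretizedGene:
    """Bin assignments of one gene's expression across cells."""

    gene_id: str
    assignments: np.ndarray
    bin_edges: np.ndarray
    n_bins: int

    def __post_init__(self) -> None:
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if self.assignments.min(initial=0) < 0 or \
                self.assignments.max(initial=0) >= self.n_bins:
            raise ValueError("assignments outside [0, n_bins)")
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly ascending")

    @property
    def n_cells(self) -> int:
        return len(self.assignments)


def _bayesian_blocks_edges(values: np.ndarray) -> np.ndarray:
    """Bayesian-blocks change points for point data (Scargle-style
    dynamic program over the events fitness, p0 = 0.05)."""
    x = np.sort(values)
    n = len(x)
    edges = np.concatenate([[x[0]], 0.5 * (x[1:] + x[:-1]), [x[-1]]])
    block_length = x[-1] - edges
    ncp_prior = 4.0 - np.log(73.53 * 0.05 * n ** -0.478)

    best = np.zeros(n)
    last = np.zeros(n, dtype=int)
    for r in range(n):
        widths = block_length[: r + 1] - block_length[r + 1]
        widths[widths <= 0] = np.inf
        counts = r + 1 - np.arange(r + 1)
        fitness = counts * (np.log(counts) - np.log(widths))
        fitness -= ncp_prior
        fitness[1:] += best[:r]
        last[r] = np.argmax(fitness)
        best[r] = fitness[last[r]]
    change_points = []
    idx = n
    while idx > 0:
        change_points.append(idx)
        idx = last[idx - 1]
    change_points.append(0)
    return edges[np.array(change_points[::-1])]


def discretize(values, method: str = "uniform", n_bins: int | None = None,
               gene_id: str = "") -> DiscretizedGene:
    """Bin one gene's expression vector.

    ``uniform``: equal-width bins over [min, max], right-open except the
    last, with n_bins = max(2, ceil(sqrt(n))) unless given.  A constant
    vector collapses to a single bin.  ``bayesian_blocks`` adapts the bin
    edges to the empirical density instead.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError("need a 1-D vector of at least 2 values")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return DiscretizedGene(gene_id, np.zeros(len(values), dtype=np.int64),
                               np.array([vmin, vmin + 1.0]), 1)
    if method == "uniform":
        k = n_bins if n_bins is not None else max(2, int(np.ceil(np.sqrt(len(values)))))
        if k < 1:
            raise ValueError("n_bins must be >= 1")
        edges = vmin + (vmax - vmin) * np.arange(k + 1) / k
        assign = np.minimum(((values - vmin) / (vmax - vmin) * k).astype(np.int64), k - 1)
        return DiscretizedGene(gene_id, assign, edges, k)
    if method == "bayesian_blocks":
        edges = _bayesian_blocks_edges(values)
        assign = np.clip(np.searchsorted(edges, values, side="right") - 1,
                         0, len(edges) - 2)
        return DiscretizedGene(gene_id, assign, edges, len(edges) - 1)
    raise ValueError(f"unknown discretization method {method!r}")


def discretize_panel(norm: NormalizedMatrix, genes=None, method: str = "uniform",
                     n_bins: int | None = None) -> list:
    genes = list(genes) if genes is not None else list(norm.gene_ids)
    return [discretize(norm.values[:, norm.gene_index(g)], method=method,
                       n_bins=n_bins, gene_id=g) for g in genes]


# ---------------------------------------------------------------------------
# plug-in information measures

def _joint(x: DiscretizedGene, y: DiscretizedGene) -> np.ndarray:
    if x.n_cells != y.n_cells:
        raise ValueError("genes discretized over different cell counts")
    flat = x.assignments * y.n_bins + y.assignments
    counts = np.bincount(flat, minlength=x.n_bins * y.n_bins)
    return counts.reshape(x.n_bins, y.n_bins) / x.n_cells


def mi_from_joint(pxy: np.ndarray) -> float:
    """Plug-in mutual information (bits) of a joint probability table."""
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = pxy * np.log2(pxy / (px * py))
    return float(max(np.nansum(terms), 0.0))


def specific_information(p_sy: np.ndarray) -> np.ndarray:
    """I_spec(S; Y=y) for each y: KL(p(s|y) || p(s)), in bits.

    p_sy is the joint table source x target; returns one value per target
    outcome (0 where p(y) = 0).
    """
    ps = p_sy.sum(axis=1, keepdims=True)
    py = p_sy.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = p_sy / py
        terms = cond * np.log2(cond / ps)
    return np.where(py[0] > 0, np.nansum(terms, axis=0), 0.0)


def mutual_information(x: DiscretizedGene, y: DiscretizedGene) -> float:
    """I(X;Y) in bits from the empirical contingency table."""
    return mi_from_joint(_joint(x, y))


def redundancy_from_joints(p_xy: np.ndarray, p_zy: np.ndarray) -> float:
    """Williams-Beer I_min of sources X, Z about target Y, in bits.

    Both joints are source x target tables.  Only the two source-target
    joints are needed: the redundancy is the expectation over y of the
    smaller specific information.
    """
    py = p_xy.sum(axis=0)
    if not np.allclose(py, p_zy.sum(axis=0), atol=1e-12):
        raise ValueError("joints disagree on the target marginal")
    ix = specific_information(p_xy)
    iz = specific_information(p_zy)
    return float(np.sum(py * np.minimum(ix, iz)))


def redundancy_unique(x: DiscretizedGene, z: DiscretizedGene,
                      y: DiscretizedGene) -> tuple:
    """(redundancy, unique_x) of sources X, Z about target Y, in bits."""
    p_xy, p_zy = _joint(x, y), _joint(z, y)
    red = redundancy_from_joints(p_xy, p_zy)
    unique_x = max(mi_from_joint(p_xy) - red, 0.0)
    return red, unique_x


# ---------------------------------------------------------------------------
# PUC and confidence

def puc_matrix(panel) -> pd.DataFrame:
    """Proportional unique contribution for every unordered gene pair.

    Returns a DataFrame (gene_a, gene_b, mi, puc, confidence=NaN) with
    gene_a < gene_b; confidence is filled by :func:`edge_confidence`.
    Pairs with zero mutual information score u = 0.
    """
    panel = list(panel)
    if len(panel) < 3:
        raise ValueError("PUC needs at least 3 genes (no context otherwise)")
    ids = [g.gene_id for g in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate gene ids in panel")
    order = np.argsort(ids)
    panel = [panel[i] for i in order]
    ids = [ids[i] for i in order]
    n = len(panel)

    # pairwise joints, MI, and specific-information vectors I_spec(S; T=t)
    joints = {}
    for i, j in itertools.combinations(range(n), 2):
        joints[(i, j)] = _joint(panel[i], panel[j])

    def joint(i, j):
        return joints[(i, j)] if i < j else joints[(j, i)].T

    mi = {}
    ispec = {}  # (source, target) -> vector over target bins
    py = {}
    for i in range(n):
        py[i] = np.bincount(panel[i].assignments, minlength=panel[i].n_bins) / panel[i].n_cells
    for i, j in itertools.permutations(range(n), 2):
        ispec[(i, j)] = specific_information(joint(i, j))
    for i, j in itertools.combinations(range(n), 2):
        mi[(i, j)] = mi_from_joint(joints[(i, j)])

    rows = []
    for i, j in itertools.combinations(range(n), 2):
        pair_mi = mi[(i, j)]
        if pair_mi <= 0.0:
            rows.append((ids[i], ids[j], 0.0, 0.0))
            continue
        u = 0.0
        for k in range(n):
            if k in (i, j):
                continue
            # unique of X=i about Y=j in context Z=k
            red_j = np.sum(py[j] * np.minimum(ispec[(i, j)], ispec[(k, j)]))
            u += max(pair_mi - red_j, 0.0) / pair_mi
            # unique of Y=j about X=i in context Z=k
            red_i = np.sum(py[i] * np.minimum(ispec[(j, i)], ispec[(k, i)]))
            u += max(pair_mi - red_i, 0.0) / pair_mi
        rows.append((ids[i], ids[j], pair_mi, u))
    out = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "puc"])
    out["confidence"] = np.nan
    return out


def _gene_cdfs(scores: pd.DataFrame, fit: str) -> dict:
    """Per-gene CDF over that gene's PUC scores."""
    by_gene: dict = {}
    for r in scores.itertuples():
        by_gene.setdefault(r.gene_a, []).append(r.puc)
        by_gene.setdefault(r.gene_b, []).append(r.puc)
    cdfs = {}
    for gene, vals in by_gene.items():
        vals = np.asarray(vals, dtype=float)
        if len(vals) < 2:
            raise ValueError(f"gene {gene!r} has fewer than 2 scored partners")
        use_fit = fit
        if fit == "gamma" and (vals.var() == 0 or vals.mean() == 0):
            warnings.warn(f"gene {gene}: zero-variance scores, "
                          "falling back to empirical CDF")
            use_fit = "empirical"
        if use_fit == "empirical":
            ranks = stats.rankdata(vals, method="average")
            lookup = {}
            for v, r in zip(vals, ranks):
                lookup[v] = r / len(vals)
            cdfs[gene] = lambda u, lk=lookup: lk[u]
        elif use_fit == "gamma":
            mean, var = vals.mean(), vals.var(ddof=1)
            shape = mean ** 2 / var
            scale = var / mean
            cdfs[gene] = lambda u, a=shape, s=scale: float(stats.gamma.cdf(u, a, scale=s))
        else:
            raise ValueError(f"unknown CDF fit {fit!r}")
    return cdfs


def edge_confidence(scores: pd.DataFrame, fit: str = "empirical") -> pd.DataFrame:
    """Fill edge confidences: c_gh = F_g(u_gh) + F_h(u_gh) in [0, 2].

    ``empirical`` uses each gene's within-gene score ranks (ties
    averaged); ``gamma`` fits a gamma distribution by moment matching.
    Output is sorted by descending confidence.
    """
    out = scores.copy()
    cdfs = _gene_cdfs(out, fit)
    conf = [cdfs[r.gene_a](r.puc) + cdfs[r.gene_b](r.puc) for r in out.itertuples()]
    out["confidence"] = np.clip(conf, 0.0, 2.0)
    return out.sort_values("confidence", ascending=False, kind="stable",
                           ignore_index=True)


# ---------------------------------------------------------------------------
# panel selection, orientation, regulons

def select_network_genes(norm: NormalizedMatrix, sig: GeneSignature,
                         candidate_tfs, deg: pd.DataFrame,
                         cfg: PipelineConfig) -> tuple:
    """(gene panel, TF panel) for inference: signature genes present in
    the matrix plus the n_top_tfs candidates with the largest |logFC|."""
    candidate_tfs = [str(t) for t in candidate_tfs]
    if not candidate_tfs:
        raise ValueError("candidate TF list is empty")
    deg_idx = deg.set_index("gene")
    missing = [t for t in candidate_tfs if t not in deg_idx.index]
    if missing:
        raise ValueError(f"DEG table does not cover candidate TFs: {missing}")
    universe = set(norm.gene_ids)
    panel = [g for g in sig.genes if g in universe]
    if len(panel) < 2:
        raise ValueError(
            f"only {len(panel)} signature genes present; need at least 2")
    if cfg.n_top_tfs > len(candidate_tfs):
        logger.warning("n_top_tfs=%d exceeds %d candidates; taking all",
                       cfg.n_top_tfs, len(candidate_tfs))
    ranked = sorted(candidate_tfs,
                    key=lambda t: (-abs(deg_idx.loc[t, "logFC"]), t))
    tf_panel = ranked[: cfg.n_top_tfs]
    return panel, tf_panel


def build_directed_network(scores: pd.DataFrame, tf_list,
                           cfg: PipelineConfig) -> DirectedNetwork:
    """Directional restriction: keep pairs touching a TF, orient TF ->
    target (two edges for TF-TF pairs), threshold strictly above
    edge_weight_min, and assign hierarchy layers for export."""
    if scores["confidence"].isna().any():
        raise ValueError("run edge_confidence before building the network")
    tfs = set(str(t) for t in tf_list)
    edges = []
    for r in scores.itertuples():
        a_tf, b_tf = r.gene_a in tfs, r.gene_b in tfs
        if not (a_tf or b_tf) or r.confidence <= cfg.edge_weight_min:
            continue
        if a_tf:
            edges.append((r.gene_a, r.gene_b, r.confidence))
        if b_tf:
            edges.append((r.gene_b, r.gene_a, r.confidence))
    table = pd.DataFrame(edges, columns=["source", "target", "weight"])
    table = table.sort_values(["weight", "source", "target"],
                              ascending=[False, True, True], ignore_index=True)
    if table.empty:
        warnings.warn("no edge survives the confidence threshold")

    # hierarchy layers: TFs at 0; targets grouped by their parent TF set
    layers = {t: 0 for t in sorted(tfs)}
    parent_sets: dict = {}
    for r in table.itertuples():
        if r.target not in tfs:
            parent_sets.setdefault(r.target, set()).add(r.source)
    groups = sorted({frozenset(v) for v in parent_sets.values()},
                    key=lambda s: tuple(sorted(s)))
    group_layer = {g: i + 1 for i, g in enumerate(groups)}
    for node, parents in parent_sets.items():
        layers[node] = group_layer[frozenset(parents)]
    return DirectedNetwork(edges=table, tf_list=sorted(tfs), layers=layers)


def extract_regulons(net: DirectedNetwork) -> list:
    """One regulon per TF with outgoing edges; targets by descending weight."""
    regulons = []
    for tf in net.tf_list:
        sub = net.edges[net.edges["source"] == tf]
        if sub.empty:
            continue
        sub = sub.sort_values(["weight", "target"], ascending=[False, True])
        regulons.append(Regulon(tf=tf, targets=list(sub["target"])))
    return regulons


def infer_network(norm: NormalizedMatrix, genes, tf_list, cfg: PipelineConfig,
                  method: str = "uniform", n_bins: int | None = None,
                  fit: str = "empirical"):
    """Convenience pipeline: discretize -> PUC -> confidence -> orient.

    Returns (scored edge table, DirectedNetwork)."""
    panel = discretize_panel(norm, genes=genes, method=method, n_bins=n_bins)
    scores = edge_confidence(puc_matrix(panel), fit=fit)
    return scores, build_directed_network(scores, tf_list, cfg)


# ---------------------------------------------------------------------------
# export

def _as_nx(net: DirectedNetwork):
    import networkx as nx

    g = nx.DiGraph()
    for node, layer in net.layers.items():
        g.add_node(node, layer=int(layer), is_tf=node in set(net.tf_list))
    for r in net.edges.itertuples():
        g.add_edge(r.source, r.target, weight=float(r.weight))
    return g


def export_graphml(net: DirectedNetwork, path: str) -> None:
    import networkx as nx

    nx.write_graphml(_as_nx(net), path)


def export_dot(net: DirectedNetwork, path: str) -> None:
    """Minimal DOT writer (rank-grouped by layer, yED/graphviz readable)."""
    lines = ["digraph grn {"]
    by_layer: dict = {}
    for node, layer in sorted(net.layers.items()):
        by_layer.setdefault(layer, []).append(node)
    for layer in sorted(by_layer):
        members = " ".join(f'"{n}";' for n in by_layer[layer])
        lines.append(f"  {{ rank=same; {members} }}")
    for r in net.edges.itertuples():
        lines.append(f'  "{r.source}" -> "{r.target}" [weight={r.weight:.4f}];')
    lines.append("}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
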