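"""Synthetic two-condition scRNA-seq benchmark with a known regulatory network.

The generator emulates the structure of a steady-state vs migrated
dendritic-cell experiment: a small panel of transcription factors (TFs)
drives target genes through a Hill-type activation function, one condition
("B", the migrated-like state) elevates the latent activity of a chosen TF
subset and up-shifts a planted immunoregulatory gene module, and observed
UMI counts are negative-binomial with logistic dropout.  Because the true
TF->target edge set, the planted differentially expressed genes and the
planted module are all known, every downstream stage (DE calling,
signature scoring, network inference, regulon enrichment) can be scored
against ground truth.

Generative model, per cell:

* each TF ``i`` has latent activity ``a_i ~ LogNormal(mu_i, sigma)``;
  ``mu_i`` is shifted up by ``activity_shift`` for active TFs in
  condition B;
* each TF also emits its own mRNA with rate ``tf_expression_scale * a_i``,
  so TF expression tracks activity (required for expression-based network
  inference to have any chance);
* each target's rate is ``baseline * prod_parents (1 + beta_e * hill(a))``
  with ``hill(a) = a^h / (a^h + 1)``; module genes are multiplied by
  ``module_fold`` in condition B;
* counts are NegativeBinomial(mean=rate, dispersion=alpha) — variance
  ``rate + alpha * rate^2`` — then zeroed by Bernoulli dropout with
  probability ``sigmoid(-slope * (log rate - midpoint))``;
* a pool of background genes is expressed at condition-independent
  baseline rates — the stable majority that size-factor normalization
  relies on in real transcriptomes;
* the mitochondrial fraction is a Beta-distributed nuisance with a small
  contaminated subpopulation above the QC cut-off, so the mito filter has
  something to remove.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .config import substream_seed
from .containers import CountMatrix, GeneSignature, GoldStandard

__all__ = [
    "SimulationSpec",
    "BenchmarkBundle",
    "RecoveryReport",
    "default_spec",
    "sample_grn",
    "simulate_counts",
    "make_benchmark",
    "network_recovery_metrics",
    "deg_recovery",
]


# ---------------------------------------------------------------------------
# specification

@dataclass
class SimulationSpec:
    """All knobs of the generative model; defaults give the packaged benchmark."""

    n_tf: int = 5
    n_target: int = 25
    n_background: int = 70
    edge_density: float = 0.2
    hill_coefficient: float = 3.0
    regulation_strength_range: tuple = (3.0, 6.0)
    baseline_rate_range: tuple = (0.5, 3.0)
    nb_dispersion: float = 0.3
    dropout_midpoint: float = 0.0
    dropout_slope: float = 1.0
    n_cells_per_condition: int = 600
    module_genes: tuple = ()
    module_fold: float = 4.0
    active_tfs_condition_b: tuple = ()
    seed: int = 0
    # latent-activity model
    activity_log_mean: float = -1.2
    activity_log_sd: float = 1.0
    activity_shift: float = 2.0
    tf_expression_scale: float = 20.0
    # mitochondrial nuisance
    mito_beta: tuple = (2.0, 40.0)
    mito_contaminated_beta: tuple = (12.0, 20.0)
    mito_contaminated_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.n_tf < 1:
            raise ValueError(f"n_tf must be >= 1, got {self.n_tf}")
        if self.n_target < 1:
            raise ValueError(f"n_target must be >= 1, got {self.n_target}")
        if self.n_background < 0:
            raise ValueError(f"n_background must be >= 0, got {self.n_background}")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError(f"edge_density must be in (0, 1], got {self.edge_density}")
        if self.hill_coefficient <= 0:
            raise ValueError("hill_coefficient must be positive")
        for name in ("regulation_strength_range", "baseline_rate_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi <= 0 or lo > hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.dropout_slope <= 0:
            raise ValueError("dropout_slope must be positive")
        if self.n_cells_per_condition < 1:
            raise ValueError("n_cells_per_condition must be >= 1")
        if self.module_fold < 1.0:
            raise ValueError(f"module_fold must be >= 1, got {self.module_fold}")
        self.module_genes = tuple(str(g) for g in self.module_genes)
        self.active_tfs_condition_b = tuple(str(t) for t in self.active_tfs_condition_b)
        universe = set(self.tf_ids) | set(self.target_ids)
        unknown = [g for g in self.module_genes if g not in universe]
        if unknown:
            raise ValueError(f"module_genes not in simulated universe: {unknown}")
        bad_tfs = [t for t in self.active_tfs_condition_b if t not in self.tf_ids]
        if bad_tfs:
            raise ValueError(f"active_tfs_condition_b not simulated TFs: {bad_tfs}")

    @property
    def tf_ids(self) -> list:
        return [f"TF{i + 1}" for i in range(self.n_tf)]

    @property
    def target_ids(self) -> list:
        return [f"G{i + 1:02d}" for i in range(self.n_target)]

    @property
    def background_ids(self) -> list:
        return [f"BG{i + 1:02d}" for i in range(self.n_background)]

    @property
    def gene_ids(self) -> list:
        return self.tf_ids + self.target_ids + self.background_ids

    @property
    def network_gene_ids(self) -> list:
        """Genes inside the regulatory network (TFs and targets)."""
        return self.tf_ids + self.target_ids


def default_spec(seed: int = 0) -> SimulationSpec:
    """The packaged benchmark: 5 TFs, 25 targets, 70 background genes,
    600 cells per condition, a 6-gene planted module at 4-fold, and 2 TFs
    activated in condition B."""
    return SimulationSpec(
        module_genes=tuple(f"G{i:02d}" for i in range(20, 26)),
        active_tfs_condition_b=("TF1", "TF2"),
        seed=seed,
    )


@dataclass
class RecoveryReport:
    """Scores of an inferred edge ranking or DEG call set against truth."""

    aupr: float
    auroc: float
    prevalence: float
    sensitivity: float
    empirical_fdp: float

    def __post_init__(self) -> None:
        for name in ("aupr", "auroc", "prevalence", "sensitivity", "empirical_fdp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} = {v} outside [0, 1]")


@dataclass
class BenchmarkBundle:
    """Everything a benchmark run needs: data, truth, and planted effects."""

    counts_a: CountMatrix
    counts_b: CountMatrix
    annotation_a: pd.DataFrame
    annotation_b: pd.DataFrame
    gold: GoldStandard
    planted_de: list
    planted_signature: GeneSignature
    spec: SimulationSpec

    def __post_init__(self) -> None:
        if self.counts_a.gene_ids != self.counts_b.gene_ids:
            raise ValueError("conditions must share one gene universe")
        missing = set(self.planted_signature.genes) - set(self.counts_a.gene_ids)
        if missing:
            raise ValueError(f"planted signature genes outside universe: {missing}")

    @property
    def gene_ids(self) -> list:
        return self.counts_a.gene_ids


# ---------------------------------------------------------------------------
# network sampling

def sample_grn(spec: SimulationSpec) -> GoldStandard:
    """Sample the true TF->target edge set.

    Each of the n_tf x n_target candidate edges is included independently
    with probability ``edge_density``; any target left parentless is
    assigned one uniformly chosen TF parent so every target is regulated.
    """
    rng = np.random.default_rng(substream_seed(spec.seed, "grn"))
    edges = set()
    for t in spec.target_ids:
        for tf in spec.tf_ids:
            if rng.random() < spec.edge_density:
                edges.add((tf, t))
    with_parent = {t for _, t in edges}
    for t in spec.target_ids:
        if t not in with_parent:
            edges.add((spec.tf_ids[rng.integers(spec.n_tf)], t))
    return GoldStandard(edges=edges, tf_list=list(spec.tf_ids))


def _hill(a: np.ndarray, h: float) -> np.ndarray:
    ah = np.power(a, h)
    return ah / (ah + 1.0)


def _shared_params(grn: GoldStandard, spec: SimulationSpec):
    """Edge strengths and gene baselines, shared by both conditions."""
    rng = np.random.default_rng(substream_seed(spec.seed, "params"))
    lo, hi = spec.regulation_strength_range
    strengths = {e: rng.uniform(lo, hi) for e in sorted(grn.edges)}
    blo, bhi = spec.baseline_rate_range
    baselines = {g: rng.uniform(blo, bhi)
                 for g in spec.target_ids + spec.background_ids}
    return strengths, baselines


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    """NB with mean ``mean`` and variance ``mean + alpha * mean^2``
    via the gamma-Poisson mixture."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, np.maximum(mean, 1e-12) * alpha)
    return rng.poisson(lam)


def simulate_counts(grn: GoldStandard, spec: SimulationSpec, condition: str):
    """Simulate one condition; returns (CountMatrix, annotation DataFrame).

    Deterministic given (spec.seed, condition); parameters shared between
    conditions (edge strengths, baselines) come from their own substream so
    A and B differ only through TF activation and the module fold.
    """
    if condition not in ("A", "B"):
        raise ValueError(f"unknown condition {condition!r}; expected 'A' or 'B'")
    if set(grn.tf_list) != set(spec.tf_ids):
        raise ValueError("gold standard TF list inconsistent with spec")

    n = spec.n_cells_per_condition
    rng = np.random.default_rng(substream_seed(spec.seed, f"counts:{condition}"))
    strengths, baselines = _shared_params(grn, spec)
    active = set(spec.active_tfs_condition_b) if condition == "B" else set()

    # latent TF activities
    activity = {}
    for tf in spec.tf_ids:
        mu = spec.activity_log_mean + (spec.activity_shift if tf in active else 0.0)
        activity[tf] = np.exp(rng.normal(mu, spec.activity_log_sd, size=n))

    # per-cell, per-gene expected rates
    rates = np.empty((n, spec.n_tf + spec.n_target + spec.n_background))
    for j, tf in enumerate(spec.tf_ids):
        rates[:, j] = spec.tf_expression_scale * activity[tf]
    parents = {t: [] for t in spec.target_ids}
    for s, t in grn.edges:
        parents[t].append(s)
    for j, g in enumerate(spec.target_ids):
        rate = np.full(n, baselines[g])
        for tf in sorted(parents[g]):
            beta = strengths[(tf, g)]
            rate = rate * (1.0 + beta * _hill(activity[tf], spec.hill_coefficient))
        if condition == "B" and g in spec.module_genes:
            rate = rate * spec.module_fold
        rates[:, spec.n_tf + j] = rate
    # condition-independent background genes (the stable majority real
    # normalization relies on)
    for j, g in enumerate(spec.background_ids):
        rates[:, spec.n_tf + spec.n_target + j] = baselines[g]
    # TF genes in the planted module are folded too (module may include TFs)
    for j, tf in enumerate(spec.tf_ids):
        if condition == "B" and tf in spec.module_genes:
            rates[:, j] *= spec.module_fold

    counts = _nb_sample(rng, rates, spec.nb_dispersion)
    # logistic dropout: low-rate genes lose more observations
    with np.errstate(divide="ignore"):
        lograte = np.log(np.maximum(rates, 1e-300))
    p_drop = 1.0 / (1.0 + np.exp(spec.dropout_slope * (lograte - spec.dropout_midpoint)))
    counts = np.where(rng.random(counts.shape) < p_drop, 0, counts)

    # mitochondrial nuisance with a contaminated subpopulation
    a0, b0 = spec.mito_beta
    mito = rng.beta(a0, b0, size=n)
    n_bad = int(round(spec.mito_contaminated_fraction * n))
    if n_bad:
        bad = rng.choice(n, size=n_bad, replace=False)
        a1, b1 = spec.mito_contaminated_beta
        mito[bad] = rng.beta(a1, b1, size=n_bad)

    cell_ids = [f"{condition}_{i:04d}" for i in range(n)]
    cm = CountMatrix(values=counts.astype(np.int64), cell_ids=cell_ids,
                     gene_ids=list(spec.gene_ids))
    ann = pd.DataFrame({
        "cell_id": cell_ids,
        "condition": condition,
        "total_counts": counts.sum(axis=1).astype(np.int64),
        "mito_fraction": mito,
    })
    return cm, ann


def make_benchmark(spec: SimulationSpec | None = None) -> BenchmarkBundle:
    """Sample a full benchmark: truth network, both conditions, planted effects.

    ``planted_de`` collects every gene whose generative rate differs between
    conditions: the planted module, the targets of TFs activated in
    condition B, and the mRNA of those TFs themselves (their expression
    tracks the elevated activity by construction).
    """
    spec = spec if spec is not None else default_spec()
    gold = sample_grn(spec)
    counts_a, ann_a = simulate_counts(gold, spec, "A")
    counts_b, ann_b = simulate_counts(gold, spec, "B")
    planted = set(spec.module_genes)
    for tf in spec.active_tfs_condition_b:
        planted.add(tf)
        planted |= gold.children(tf)
    sig = GeneSignature(name="planted_module", genes=sorted(spec.module_genes),
                        provenance="simulated immunoregulatory module")
    if not sig.genes:
        warnings.warn("module_genes is empty: planted signature has no genes")
    return BenchmarkBundle(
        counts_a=counts_a, counts_b=counts_b,
        annotation_a=ann_a, annotation_b=ann_b,
        gold=gold, planted_de=sorted(planted), planted_signature=sig, spec=spec,
    )


# ---------------------------------------------------------------------------
# scoring against truth

def _candidate_edges(gold: GoldStandard, universe: list, mode: str) -> list:
    if mode == "directed":
        return [(tf, g) for tf in gold.tf_list for g in universe if g != tf]
    pairs = set()
    for i, a in enumerate(universe):
        for b in universe[i + 1:]:
            pairs.add(frozenset((a, b)))
    return sorted(pairs, key=lambda p: tuple(sorted(p)))


def network_recovery_metrics(ranked_edges, gold: GoldStandard, mode: str = "directed",
                             universe=None) -> RecoveryReport:
    """Score a weighted edge ranking against the gold standard.

    ``ranked_edges`` is an iterable of ((source, target), weight) or a
    DataFrame with source/target/weight columns.  AUPR and AUROC sweep the
    weight threshold over all candidate edges, counting candidates absent
    from the ranking at weight -inf; ``sensitivity``/``empirical_fdp``
    treat every ranked edge as a call.
    """
    if mode not in ("directed", "undirected"):
        raise ValueError(f"mode must be directed|undirected, got {mode!r}")
    if not gold.edges:
        raise ValueError("gold standard has no edges")
    if isinstance(ranked_edges, pd.DataFrame):
        ranked_edges = [((r.source, r.target), r.weight) for r in ranked_edges.itertuples()]
    ranked_edges = [((str(a), str(b)), float(w)) for (a, b), w in ranked_edges]
    if any(not np.isfinite(w) for _, w in ranked_edges):
        raise ValueError("ranked edge weights must be finite")

    if universe is None:
        universe = set(gold.tf_list) | {g for e in gold.edges for g in e}
        for (a, b), _ in ranked_edges:
            universe |= {a, b}
    universe = sorted(str(g) for g in universe)

    def key(pair):
        return tuple(pair) if mode == "directed" else frozenset(pair)

    weights = {}
    for pair, w in ranked_edges:
        k = key(pair)
        if k in weights:
            raise ValueError(f"duplicate ranked edge {pair}")
        weights[k] = w

    candidates = _candidate_edges(gold, universe, mode)
    gold_keys = {key(e) for e in gold.edges}
    # unranked candidates sort below every ranked edge (all tied)
    floor = min(weights.values(), default=0.0) - 1.0
    y_true = np.array([1 if key(c) in gold_keys else 0 for c in candidates])
    y_score = np.array([weights.get(key(c), floor) for c in candidates])
    if y_true.sum() == 0:
        raise ValueError("no gold edge lies in the candidate universe")

    called = set(weights)
    tp = len(called & gold_keys)
    return RecoveryReport(
        aupr=float(average_precision_score(y_true, y_score)),
        auroc=float(roc_auc_score(y_true, y_score)),
        prevalence=float(y_true.mean()),
        sensitivity=tp / len(gold_keys),
        empirical_fdp=(len(called) - tp) / max(len(called), 1),
    )


def deg_recovery(called, planted, universe) -> RecoveryReport:
    """Score a DEG call set against the planted differential genes."""
    called, planted, universe = set(called), set(planted), set(universe)
    if not planted:
        raise ValueError("planted gene list is empty")
    if not called <= universe or not planted <= universe:
        raise ValueError("called and planted genes must lie in the universe")
    genes = sorted(universe)
    y_true = np.array([1 if g in planted else 0 for g in genes])
    y_score = np.array([1.0 if g in called else 0.0 for g in genes])
    tp = len(called & planted)
    if called:
        aupr = float(average_precision_score(y_true, y_score))
        auroc = float(roc_auc_score(y_true, y_score)) if 0 < y_true.sum() < len(genes) else 1.0
    else:
        aupr, auroc = y_true.mean(), 0.5
    return RecoveryReport(
        aupr=aupr,
        auroc=auroc,
        prevalence=float(y_true.mean()),
        sensitivity=tp / len(planted),
        empirical_fdp=len(called - planted) / max(len(called), 1),
    )
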