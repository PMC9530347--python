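"""Tests for discretization, plug-in information measures, PUC scoring,
edge confidence, and the directional network construction.

The oracle functions here re-derive every quantity with explicit Python
loops over outcome tuples — no numpy vectorization, no shared code with
the implementation under test.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from conftest import make_norm
from lcgrn import GeneSignature, PipelineConfig
from lcgrn.containers import DirectedNetwork
from lcgrn.pidc import (DiscretizedGene, build_directed_network, discretize,
                        discretize_panel, edge_confidence, export_dot,
                        export_graphml, extract_regulons, mutual_information,
                        puc_matrix, redundancy_unique, select_network_genes)


# ---------------------------------------------------------------------------
# loop oracles

def oracle_mi(xs, ys):
    n = len(xs)
    pxy, px, py = {}, {}, {}
    for x, y in zip(xs, ys):
        pxy[(x, y)] = pxy.get((x, y), 0) + 1 / n
        px[x] = px.get(x, 0) + 1 / n
        py[y] = py.get(y, 0) + 1 / n
    total = 0.0
    for (x, y), p in pxy.items():
        total += p * math.log2(p / (px[x] * py[y]))
    return max(total, 0.0)


def oracle_specific_info(ss, ys):
    """dict y -> I_spec(S; Y=y)."""
    n = len(ss)
    ps, py, psy = {}, {}, {}
    for s, y in zip(ss, ys):
        ps[s] = ps.get(s, 0) + 1 / n
        py[y] = py.get(y, 0) + 1 / n
        psy[(s, y)] = psy.get((s, y), 0) + 1 / n
    out = {}
    for y in py:
        acc = 0.0
        for s in ps:
            joint = psy.get((s, y), 0.0)
            if joint > 0:
                cond = joint / py[y]
                acc += cond * math.log2(cond / ps[s])
        out[y] = acc
    return out


def oracle_redundancy(xs, zs, ys):
    n = len(ys)
    py = {}
    for y in ys:
        py[y] = py.get(y, 0) + 1 / n
    ix = oracle_specific_info(xs, ys)
    iz = oracle_specific_info(zs, ys)
    return sum(py[y] * min(ix[y], iz[y]) for y in py)


def oracle_unique(xs, zs, ys):
    return max(oracle_mi(xs, ys) - oracle_redundancy(xs, zs, ys), 0.0)


def oracle_puc(assignments):
    """dict (i, j) -> u for every i < j over a list of assignment vectors."""
    n = len(assignments)
    out = {}
    for i, j in itertools.combinations(range(n), 2):
        mi = oracle_mi(assignments[i], assignments[j])
        if mi <= 0:
            out[(i, j)] = 0.0
            continue
        u = 0.0
        for k in range(n):
            if k in (i, j):
                continue
            u += oracle_unique(assignments[i], assignments[k], assignments[j]) / mi
            u += oracle_unique(assignments[j], assignments[k], assignments[i]) / mi
        out[(i, j)] = u
    return out


def oracle_confidence(ids, u_by_pair):
    """Empirical per-gene CDFs summed per edge, by explicit rank counting."""
    per_gene = {g: [] for g in ids}
    for (a, b), u in u_by_pair.items():
        per_gene[a].append(u)
        per_gene[b].append(u)

    def cdf(gene, u):
        vals = per_gene[gene]
        below = sum(1 for v in vals if v < u)
        ties = sum(1 for v in vals if v == u)
        return (below + (ties + 1) / 2) / len(vals)  # average tie rank

    return {(a, b): cdf(a, u) + cdf(b, u) for (a, b), u in u_by_pair.items()}


def dg(values, **kw):
    return discretize(np.asarray(values, float), **kw)


# ---------------------------------------------------------------------------

class TestDiscretize:
    def test_constant_vector_collapses_to_one_bin(self):
        out = dg([2.0] * 5, gene_id="g")
        assert out.n_bins == 1
        assert (out.assignments == 0).all()

    def test_sqrt_rule(self):
        out = dg(np.linspace(0, 1, 16))
        assert out.n_bins == 4

    def test_equal_width_edges(self):
        out = dg([0.0, 1.0, 2.0, 3.0], n_bins=2)
        np.testing.assert_array_equal(out.assignments, [0, 0, 1, 1])
        assert out.bin_edges[1] == pytest.approx(1.5)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            dg([0.0, np.nan, 1.0])

    def test_bayesian_blocks_separates_two_tight_modes(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([rng.normal(0, 0.01, 50),
                               rng.normal(10, 0.01, 50)])
        out = dg(vals, method="bayesian_blocks")
        assert out.n_bins >= 2
        # the two modes may share at most the sparse gap block
        left = set(out.assignments[vals < 5])
        right = set(out.assignments[vals > 5])
        shared = left & right
        in_shared = np.isin(out.assignments, sorted(shared)).mean()
        assert in_shared <= 0.05


class TestMutualInformation:
    def test_identical_binary_gives_one_bit(self):
        x = dg([0.0, 1.0] * 4, n_bins=2)
        assert mutual_information(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_gives_zero(self):
        x = dg([1.0] * 6)
        y = dg([0.0, 1.0, 0.0, 1.0, 0.0, 1.0], n_bins=2)
        assert mutual_information(x, y) == 0.0

    def test_printed_contingency_value(self):
        # joint counts ((2,1),(1,2)) over 6 cells ~= 0.0817 bits
        x = dg([0, 0, 0, 1, 1, 1.0], n_bins=2)
        y = dg([0, 0, 1, 0, 1, 1.0], n_bins=2)
        mi = mutual_information(x, y)
        expected = (2 / 3) * math.log2(4 / 3) + (1 / 3) * math.log2(2 / 3)
        assert mi == pytest.approx(expected, abs=1e-12)
        assert mi == pytest.approx(0.0817, abs=5e-5)

    def test_matches_loop_oracle_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            xs = rng.integers(0, 4, 40)
            ys = rng.integers(0, 3, 40)
            x = DiscretizedGene("x", xs, np.arange(5) - 0.5, 4)
            y = DiscretizedGene("y", ys, np.arange(4) - 0.5, 3)
            assert mutual_information(x, y) == pytest.approx(
                oracle_mi(list(xs), list(ys)), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="cell count"):
            mutual_information(dg([0.0, 1.0]), dg([0.0, 1.0, 2.0]))


class TestRedundancyUnique:
    def test_independent_context_gives_zero_redundancy(self):
        x = dg([0, 0, 1, 1, 0, 0, 1, 1.0], n_bins=2)
        y = dg([0, 0, 1, 1, 0, 0, 1, 1.0], n_bins=2)
        z = dg([5.0] * 8)  # constant, independent of everything
        red, unique = redundancy_unique(x, z, y)
        assert red == pytest.approx(0.0, abs=1e-12)
        assert unique == pytest.approx(mutual_information(x, y), abs=1e-12)

    def test_duplicate_source_absorbs_everything(self):
        rng = np.random.default_rng(2)
        xs = rng.integers(0, 3, 30)
        ys = (xs + rng.integers(0, 2, 30)) % 3
        x = DiscretizedGene("x", xs, np.arange(4) - 0.5, 3)
        y = DiscretizedGene("y", ys, np.arange(4) - 0.5, 3)
        red, unique = redundancy_unique(x, x, y)
        assert red == pytest.approx(mutual_information(x, y), abs=1e-12)
        assert unique == pytest.approx(0.0, abs=1e-12)

    def test_enumerated_triplet_matches_loop_oracle(self):
        xs = [0, 0, 1, 1, 0, 1, 0, 1]
        zs = [0, 1, 0, 1, 1, 1, 0, 0]
        ys = [0, 0, 0, 1, 1, 1, 1, 0]
        x = DiscretizedGene("x", np.array(xs), np.array([-.5, .5, 1.5]), 2)
        z = DiscretizedGene("z", np.array(zs), np.array([-.5, .5, 1.5]), 2)
        y = DiscretizedGene("y", np.array(ys), np.array([-.5, .5, 1.5]), 2)
        red, unique = redundancy_unique(x, z, y)
        assert red == pytest.approx(oracle_redundancy(xs, zs, ys), abs=1e-12)
        assert unique == pytest.approx(oracle_unique(xs, zs, ys), abs=1e-12)


class TestPucMatrix:
    def random_panel(self, rng, n_genes, n_cells=40):
        panel = []
        for i in range(n_genes):
            vals = rng.normal(size=n_cells) + rng.integers(0, 2) * rng.normal(size=n_cells)
            panel.append(discretize(vals, n_bins=3, gene_id=f"g{i}"))
        return panel

    def test_independent_context_gives_u_two(self):
        x = dg([0, 0, 1, 1, 0, 1, 1, 0.0], n_bins=2, gene_id="a")
        y = DiscretizedGene("b", x.assignments.copy(), x.bin_edges, 2)
        z = dg([3.0] * 8, gene_id="c")
        out = puc_matrix([x, y, z]).set_index(["gene_a", "gene_b"])
        assert out.loc[("a", "b"), "puc"] == pytest.approx(2.0, abs=1e-12)
        # pairs with the constant gene have zero MI -> u = 0 by convention
        assert out.loc[("a", "c"), "puc"] == 0.0
        assert out.loc[("b", "c"), "puc"] == 0.0

    def test_matches_exhaustive_oracle_on_random_panels(self):
        rng = np.random.default_rng(3)
        for n_genes in (4, 5):
            panel = self.random_panel(rng, n_genes)
            out = puc_matrix(panel).set_index(["gene_a", "gene_b"])
            expected = oracle_puc([list(g.assignments) for g in panel])
            for (i, j), u in expected.items():
                got = out.loc[(f"g{i}", f"g{j}"), "puc"]
                assert got == pytest.approx(u, abs=1e-10)

    def test_invariant_to_gene_order_and_cell_permutation(self):
        rng = np.random.default_rng(4)
        panel = self.random_panel(rng, 4)
        base = puc_matrix(panel)
        shuffled = puc_matrix(panel[::-1])
        pd.testing.assert_frame_equal(base, shuffled)
        perm = rng.permutation(panel[0].n_cells)
        permuted = [DiscretizedGene(g.gene_id, g.assignments[perm],
                                    g.bin_edges, g.n_bins) for g in panel]
        pd.testing.assert_frame_equal(base, puc_matrix(permuted))

    def test_fewer_than_three_genes_rejected(self):
        with pytest.raises(ValueError, match="3 genes"):
            puc_matrix([dg([0.0, 1.0], gene_id="a"),
                        dg([0.0, 1.0], gene_id="b")])


class TestEdgeConfidence:
    def scores_frame(self, u_by_pair):
        rows = [(a, b, 1.0, u) for (a, b), u in sorted(u_by_pair.items())]
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "puc"])
        df["confidence"] = np.nan
        return df

    def test_double_maximum_edge_scores_two(self):
        u = {("a", "b"): 5.0, ("a", "c"): 1.0, ("b", "c"): 0.5}
        out = edge_confidence(self.scores_frame(u)).set_index(["gene_a", "gene_b"])
        assert out.loc[("a", "b"), "confidence"] == pytest.approx(2.0)

    def test_all_equal_scores_give_equal_confidence(self):
        u = {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0}
        out = edge_confidence(self.scores_frame(u))
        assert out["confidence"].nunique() == 1

    def test_matches_rank_oracle_on_four_genes(self):
        rng = np.random.default_rng(5)
        ids = list("abcd")
        u = {(x, y): float(rng.random()) for x, y in itertools.combinations(ids, 2)}
        out = edge_confidence(self.scores_frame(u)).set_index(["gene_a", "gene_b"])
        expected = oracle_confidence(ids, u)
        for pair, c in expected.items():
            assert out.loc[pair, "confidence"] == pytest.approx(c, abs=1e-12)

    def test_gamma_zero_variance_falls_back_with_warning(self):
        u = {("a", "b"): 1.0, ("a", "c"): 1.0, ("b", "c"): 1.0}
        with pytest.warns(UserWarning, match="zero-variance"):
            out = edge_confidence(self.scores_frame(u), fit="gamma")
        assert out["confidence"].notna().all()


class TestSelectNetworkGenes:
    def deg_frame(self, logfcs):
        return pd.DataFrame({"gene": list(logfcs), "logFC": list(logfcs.values()),
                             "pval": 0.0, "qval": 0.0})

    def test_top_tfs_by_absolute_logfc(self, cfg):
        rng = np.random.default_rng(6)
        norm = make_norm(rng.random((5, 9)),
                         gene_ids=[f"t{i}" for i in range(7)] + ["s1", "s2"])
        logfcs = {f"t{i}": v for i, v in
                  enumerate([3.0, -2.5, 2.0, 1.5, -1.0, 0.5, 0.1])}
        logfcs.update({"s1": 0.0, "s2": 0.0})
        sig = GeneSignature("sig", ["s1", "s2"])
        panel, tfs = select_network_genes(norm, sig,
                                          [f"t{i}" for i in range(7)],
                                          self.deg_frame(logfcs), cfg)
        assert tfs == ["t0", "t1", "t2", "t3", "t4"]
        assert panel == ["s1", "s2"]

    def test_fewer_candidates_than_requested_returns_all(self, cfg):
        rng = np.random.default_rng(7)
        norm = make_norm(rng.random((4, 4)),
                         gene_ids=["t0", "t1", "s1", "s2"])
        deg = self.deg_frame({"t0": 1.0, "t1": 2.0, "s1": 0.0, "s2": 0.0})
        panel, tfs = select_network_genes(
            norm, GeneSignature("sig", ["s1", "s2"]), ["t0", "t1"], deg, cfg)
        assert tfs == ["t1", "t0"]

    def test_too_small_panel_rejected(self, cfg):
        norm = make_norm(np.random.default_rng(8).random((4, 2)),
                         gene_ids=["t0", "s1"])
        deg = self.deg_frame({"t0": 1.0, "s1": 0.0})
        with pytest.raises(ValueError, match="signature genes"):
            select_network_genes(norm, GeneSignature("sig", ["s1"]),
                                 ["t0"], deg, cfg)


class TestDirectedNetwork:
    def scores(self, rows):
        df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "mi", "puc",
                                         "confidence"])
        return df

    def test_orientation_and_strict_threshold(self, cfg):
        scores = self.scores([
            ("IRF4", "LGALS1", 1.0, 3.0, 1.8),   # TF -> target, kept
            ("IDO1", "IRF4", 1.0, 2.0, 0.9),     # at 0.9 <= 1: removed
            ("IDO1", "LGALS1", 1.0, 1.0, 1.7),   # no TF endpoint: dropped
        ])
        net = build_directed_network(scores, ["IRF4"], cfg)
        assert list(net.edges.itertuples(index=False)) == [
            ("IRF4", "LGALS1", 1.8)]

    def test_tf_tf_pair_emits_both_directions(self, cfg):
        scores = self.scores([("IRF4", "KLF6", 1.0, 2.0, 1.5)])
        net = build_directed_network(scores, ["IRF4", "KLF6"], cfg)
        got = {(r.source, r.target) for r in net.edges.itertuples()}
        assert got == {("IRF4", "KLF6"), ("KLF6", "IRF4")}

    def test_empty_result_warns_not_raises(self, cfg):
        scores = self.scores([("IRF4", "LGALS1", 1.0, 1.0, 0.2)])
        with pytest.warns(UserWarning, match="no edge"):
            net = build_directed_network(scores, ["IRF4"], cfg)
        assert net.n_edges == 0

    def test_layers_group_targets_by_parent_set(self, cfg):
        scores = self.scores([
            ("TF1", "a", 1.0, 2.0, 1.9), ("TF2", "a", 1.0, 2.0, 1.8),
            ("TF1", "b", 1.0, 2.0, 1.7), ("TF2", "b", 1.0, 2.0, 1.6),
            ("TF1", "c", 1.0, 2.0, 1.5),
        ])
        net = build_directed_network(scores, ["TF1", "TF2"], cfg)
        assert net.layers["TF1"] == net.layers["TF2"] == 0
        assert net.layers["a"] == net.layers["b"] != net.layers["c"]

    def test_extract_regulons_sorted_by_weight(self, cfg):
        scores = self.scores([
            ("TF1", "a", 1.0, 2.0, 1.2), ("TF1", "b", 1.0, 2.0, 1.9),
        ])
        net = build_directed_network(scores, ["TF1", "TF9"], cfg)
        regs = extract_regulons(net)
        assert len(regs) == 1  # TF9 has no out-edges
        assert regs[0].tf == "TF1" and regs[0].targets == ["b", "a"]

    def test_exports_write_files(self, cfg, tmp_path):
        scores = self.scores([("TF1", "a", 1.0, 2.0, 1.5)])
        net = build_directed_network(scores, ["TF1"], cfg)
        export_graphml(net, tmp_path / "n.graphml")
        export_dot(net, tmp_path / "n.dot")
        assert (tmp_path / "n.graphml").stat().st_size > 0
        assert "TF1" in (tmp_path / "n.dot").read_text()
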