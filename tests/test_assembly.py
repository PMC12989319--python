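import subprocess

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from microassembly import (
    CommunityTable,
    NullModelConfig,
    PROCESS_CLASSES,
    beta_mntd,
    beta_nti,
    build_pair_table,
    classify_pair,
    patristic_distances,
    raup_crick_bray,
    simulate_tree,
    summarize_processes,
)
from microassembly import io as mio

from conftest import brute_force_beta_mntd, random_community


def graph_patristic(tree: TreeNode, taxa) -> np.ndarray:
    """Independent patristic oracle: Dijkstra on the tree's edge graph."""
    g = nx.Graph()
    ids = {}

    def node_id(node):
        if id(node) not in ids:
            ids[id(node)] = node.name or f"n{len(ids)}"
        return ids[id(node)]

    for node in tree.traverse(include_self=False):
        g.add_edge(node_id(node.parent), node_id(node), weight=node.length)
    out = np.zeros((len(taxa), len(taxa)))
    for i, a in enumerate(taxa):
        lengths = nx.single_source_dijkstra_path_length(g, a)
        for j, b in enumerate(taxa):
            out[i, j] = lengths[b]
    return out


class TestPatristicDistances:
    def test_path_sums_on_small_tree(self):
        tree = TreeNode.read(["(A:1,(B:1,C:1):1);"])
        dm = patristic_distances(tree, ["A", "B", "C"])
        assert dm[("A", "B")] == pytest.approx(3.0)
        assert dm[("B", "C")] == pytest.approx(2.0)

    def test_star_tree_all_distances_two(self):
        tree = TreeNode.read(["(A:1,B:1,C:1,D:1);"])
        dm = patristic_distances(tree, list("ABCD"))
        off = dm.data[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 2.0)

    def test_matches_graph_shortest_path_oracle(self):
        tree = simulate_tree(8, seed=21)
        taxa = [t.name for t in tree.tips()]
        dm = patristic_distances(tree, taxa)
        assert np.max(np.abs(dm.data - graph_patristic(tree, taxa))) < 1e-10

    def test_unknown_taxon_named_in_error(self, random_tree):
        with pytest.raises(ValueError, match="nope"):
            patristic_distances(random_tree, ["nope"])


class TestBetaMNTD:
    def test_identical_communities_have_zero_turnover(self, random_tree):
        taxa = [t.name for t in random_tree.tips()]
        col = np.arange(1, len(taxa) + 1)
        table = CommunityTable(
            pd.DataFrame({"s1": col, "s2": col}, index=taxa)
        )
        dm = beta_mntd(table, patristic_distances(random_tree, taxa))
        assert dm[("s1", "s2")] == pytest.approx(0.0, abs=1e-12)

    def test_single_taxon_communities_give_patristic_distance(self, random_tree):
        taxa = [t.name for t in random_tree.tips()]
        counts = pd.DataFrame(0, index=taxa, columns=["s1", "s2"])
        counts.loc[taxa[0], "s1"] = 10
        counts.loc[taxa[3], "s2"] = 25
        pat = patristic_distances(random_tree, taxa)
        dm = beta_mntd(CommunityTable(counts), pat)
        assert dm[("s1", "s2")] == pytest.approx(pat[(taxa[0], taxa[3])])

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force_on_random_instances(self, weighted):
        rng = np.random.default_rng(31)
        for k in range(8):
            n_taxa = int(rng.integers(3, 9))
            n_samples = int(rng.integers(2, 7))
            tree = simulate_tree(n_taxa, seed=300 + k)
            taxa = [t.name for t in tree.tips()]
            table = random_community(rng, n_taxa, n_samples)
            table = CommunityTable(
                table.counts.set_axis(taxa, axis=0), table.is_normalized
            )
            pat = patristic_distances(tree, taxa)
            got = beta_mntd(table, pat, abundance_weighted=weighted)
            want = brute_force_beta_mntd(table, pat.data, abundance_weighted=weighted)
            assert np.max(np.abs(got.data - want)) < 1e-12

    def test_matches_picante_comdistnt(self, tmp_path):
        """picante::comdistnt (abundance-weighted) is the field's reference."""
        rng = np.random.default_rng(17)
        tree = simulate_tree(8, seed=3)
        taxa = [t.name for t in tree.tips()]
        table = random_community(rng, 8, 4, max_count=100)
        table = CommunityTable(table.counts.set_axis(taxa, axis=0))
        comm, nwk = tmp_path / "comm.tsv", tmp_path / "tree.nwk"
        table.counts.to_csv(comm, sep="\t")
        mio.write_tree(tree, nwk)
        script = (
            "suppressMessages({library(picante); library(ape)});"
            f"comm <- t(as.matrix(read.delim('{comm}', row.names=1)));"
            f"tree <- read.tree('{nwk}');"
            "tree$tip.label <- gsub(\"'\", '', tree$tip.label);"
            "r <- as.matrix(comdistnt(comm, cophenetic(tree),"
            " abundance.weighted=TRUE, exclude.conspecifics=FALSE));"
            "cat(sprintf('%.12f', r), sep='\\n')"
        )
        proc = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, check=True
        )
        ref = np.array([float(v) for v in proc.stdout.split()]).reshape(4, 4)
        got = beta_mntd(table, patristic_distances(tree, taxa))
        assert np.max(np.abs(got.data - ref)) < 1e-8


def clade_tree_table(n_per_sample=3, overlap=1):
    """Two communities inside one shallow clade of a many-clade tree."""
    tree = simulate_tree(100, seed=5, n_clades=20, clade_depth=0.2)
    taxa = [t.name for t in tree.tips()]
    k_taxa = taxa[0:n_per_sample]
    m_taxa = taxa[n_per_sample - overlap : 2 * n_per_sample - overlap]
    counts = pd.DataFrame(0, index=taxa, columns=["k", "m"])
    counts.loc[k_taxa, "k"] = 100
    counts.loc[m_taxa, "m"] = 100
    return tree, CommunityTable(counts)


class TestBetaNTI:
    def test_clade_confined_communities_signal_homogeneous_selection(self):
        tree, table = clade_tree_table()
        nti = beta_nti(table, tree, NullModelConfig(n_null=999, seed=3))
        assert nti.bnti.at["k", "m"] < -2

    def test_invariant_to_taxon_input_order(self):
        rng = np.random.default_rng(41)
        tree = simulate_tree(15, seed=9)
        taxa = [t.name for t in tree.tips()]
        table = random_community(rng, 15, 5)
        table = CommunityTable(table.counts.set_axis(taxa, axis=0))
        shuffled = CommunityTable(
            table.counts.sample(frac=1.0, random_state=1)
        )
        cfg = NullModelConfig(n_null=199, seed=11)
        a = beta_nti(table, tree, cfg)
        b = beta_nti(shuffled, tree, cfg)
        assert np.allclose(a.bnti.to_numpy(), b.bnti.to_numpy(), equal_nan=True)

    def test_degenerate_null_reported_missing_with_warning(self):
        tree = TreeNode.read(["(A:1,B:1);"])
        table = CommunityTable(
            pd.DataFrame({"s1": [5, 0], "s2": [7, 0]}, index=["A", "B"])
        )
        with pytest.warns(UserWarning, match="zero null variance"):
            nti = beta_nti(table, tree, NullModelConfig(n_null=99, seed=0))
        assert np.isnan(nti.bnti.at["s1", "s2"])

    def test_deterministic_given_seed(self):
        tree, table = clade_tree_table()
        cfg = NullModelConfig(n_null=199, seed=5)
        a = beta_nti(table, tree, cfg)
        b = beta_nti(table, tree, cfg)
        assert a.bnti.equals(b.bnti)


def rc_fixture_table(seed=0, n_bg=30, depth=600, r_u=16):
    """Background samples + a duplicated pair + a pool-disjoint pair."""
    rng = np.random.default_rng(seed)
    taxa = [f"BG{i:02d}" for i in range(n_bg)] + [
        f"U{i:02d}" for i in range(2 * r_u)
    ]
    base = rng.dirichlet(np.ones(n_bg))
    cols = {}
    for s in range(8):
        cols[f"B{s}"] = np.concatenate(
            [rng.multinomial(depth, base), np.zeros(2 * r_u, int)]
        )
    dup = np.concatenate([rng.multinomial(depth, base), np.zeros(2 * r_u, int)])
    cols["D1"], cols["D2"] = dup.copy(), dup.copy()
    u1 = np.zeros(n_bg + 2 * r_u, int)
    u1[n_bg : n_bg + r_u] = rng.multinomial(depth - r_u, np.ones(r_u) / r_u) + 1
    u2 = np.zeros(n_bg + 2 * r_u, int)
    u2[n_bg + r_u :] = rng.multinomial(depth - r_u, np.ones(r_u) / r_u) + 1
    cols["U1"], cols["U2"] = u1, u2
    return CommunityTable(pd.DataFrame(cols, index=taxa))


class TestRaupCrick:
    def test_duplicated_samples_sit_far_below_the_null(self):
        table = rc_fixture_table()
        rc = raup_crick_bray(
            table, NullModelConfig(n_null=999, seed=7), pairs=[("D1", "D2")]
        )
        assert rc.at["D1", "D2"] <= -0.9

    def test_pool_disjoint_samples_sit_far_above_the_null(self):
        table = rc_fixture_table()
        rc = raup_crick_bray(
            table, NullModelConfig(n_null=999, seed=7), pairs=[("U1", "U2")]
        )
        assert rc.at["U1", "U2"] >= 0.9

    def test_range_symmetry_and_determinism(self):
        rng = np.random.default_rng(51)
        table = random_community(rng, 15, 6, max_count=80)
        cfg = NullModelConfig(n_null=199, seed=13)
        a = raup_crick_bray(table, cfg)
        b = raup_crick_bray(table, cfg)
        off = a.to_numpy()[~np.eye(6, dtype=bool)]
        assert np.all(off >= -1) and np.all(off <= 1)
        assert np.allclose(a.to_numpy(), a.to_numpy().T)
        assert a.equals(b)

    def test_normalized_input_rejected(self):
        table = CommunityTable(
            pd.DataFrame({"a": [1.5, 2.0], "b": [2.0, 1.5]}, index=["x", "y"]),
            is_normalized=True,
        )
        with pytest.raises(ValueError, match="integer"):
            raup_crick_bray(table, NullModelConfig(n_null=99, seed=0))


class TestClassifyPair:
    @pytest.mark.parametrize(
        "bnti, rc, expected",
        [
            (2.5, None, "variable_selection"),
            (-2.5, None, "homogeneous_selection"),
            (-1.0, 0.97, "dispersal_limitation"),
            (0.0, 0.0, "undominated"),
            (1.9, -0.97, "homogenising_dispersal"),
            (-2.0, 0.0, "undominated"),   # thresholds are strict
            (2.0, 0.95, "undominated"),
            (0.0, -0.95, "undominated"),
        ],
    )
    def test_rule_table(self, bnti, rc, expected):
        assert classify_pair(bnti, rc) == expected

    def test_missing_rc_inside_stochastic_band_is_an_error(self):
        with pytest.raises(ValueError, match="RCbray required"):
            classify_pair(0.5, None)

    def test_non_finite_bnti_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            classify_pair(np.nan, 0.0)

    def test_rc_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            classify_pair(0.0, 1.5)


class TestSummaries:
    def make_pairs(self, processes, group="g"):
        return pd.DataFrame(
            {
                "sample_i": [f"a{i}" for i in range(len(processes))],
                "sample_j": [f"b{i}" for i in range(len(processes))],
                "group": group,
                "bmntd_obs": 0.0,
                "null_mean": 0.0,
                "null_sd": 1.0,
                "bnti": 0.0,
                "rc": 0.0,
                "process": processes,
            }
        )

    def test_counting_example(self):
        pairs = self.make_pairs(
            ["homogeneous_selection", "homogeneous_selection",
             "undominated", "dispersal_limitation"]
        )
        out = summarize_processes(pairs)
        row = out.iloc[0]
        assert row["homogeneous_selection"] == 0.5
        assert row["variable_selection"] == 0.0
        assert row["dispersal_limitation"] == 0.25
        assert row["undominated"] == 0.25
        assert row["homogenising_dispersal"] == 0.0
        assert row["n_pairs"] == 4

    def test_single_pair_group(self):
        out = summarize_processes(self.make_pairs(["undominated"]))
        fracs = out.iloc[0][list(PROCESS_CLASSES)].astype(float)
        assert fracs["undominated"] == 1.0 and fracs.sum() == 1.0

    def test_fractions_sum_to_one_for_random_labelings(self):
        rng = np.random.default_rng(61)
        processes = rng.choice(PROCESS_CLASSES, size=40)
        pairs = pd.concat(
            [self.make_pairs(list(processes[:20]), "g1"),
             self.make_pairs(list(processes[20:]), "g2")]
        )
        out = summarize_processes(pairs)
        for _, row in out.iterrows():
            assert sum(row[c] for c in PROCESS_CLASSES) == pytest.approx(1.0, abs=1e-12)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning, match="no pairs"):
            out = summarize_processes(pd.DataFrame(columns=["group", "process"]))
        assert out.empty


class TestPairTable:
    def test_within_group_pairs_classified_and_deterministic(self, tmp_path):
        tree, table = clade_tree_table()
        big = CommunityTable(
            pd.concat(
                [table.counts,
                 table.counts.rename(columns={"k": "k2", "m": "m2"})],
                axis=1,
            )
        )
        cfg = NullModelConfig(n_null=199, seed=3)
        nti = beta_nti(big, tree, cfg)
        groups = pd.Series({"k": "A", "m": "A", "k2": "B", "m2": "B"})
        pairs = [("k", "m"), ("k2", "m2")]
        rc = raup_crick_bray(big, cfg, pairs=pairs)
        out = build_pair_table(nti, rc, groups)
        assert len(out) == 2
        assert set(out["group"]) == {"A", "B"}
        assert set(out["process"]) <= set(PROCESS_CLASSES)
        p1 = mio.write_tidy_results({"pairs": out}, tmp_path / "r1")
        out2 = build_pair_table(nti, rc, groups)
        p2 = mio.write_tidy_results({"pairs": out2}, tmp_path / "r2")
        assert p1[0].read_bytes() == p2[0].read_bytes()
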