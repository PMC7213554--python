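import pytest

from conftest import brute_force_lineage_tally
from occutree.errors import (
    AlgebraError,
    AmbiguousTaxonError,
    ParameterError,
    StateError,
    UnknownTaxonError,
)
from occutree.fixtures import (
    T1_CLASS_COUNTS,
    FixtureSpec,
    make_backbone,
    make_landscape,
    tutorial_backbone,
)
from occutree.grid import GridSpec
from occutree.taxonomy import Occurrence, TaxonRank
from occutree.tree import Tree, build_tree, merge


def random_tree(seed, n=80, backbone=None):
    spec = FixtureSpec(seed=seed, n_occurrences=n,
                       grid=GridSpec(0.0, 0.0, 1.0, 1.0, 0.2))
    _, occs, bb = make_landscape(spec, backbone=backbone)
    if backbone is not None:
        bb = backbone
    # distinct id spaces per seed so different trees can overlap or not
    occs = [Occurrence(o.id + seed * 10_000, o.species_id, o.longitude, o.latitude)
            for o in occs]
    return Tree(occs, bb), bb


class TestBuildTree:
    def test_empty_tree(self, tutorial):
        _, backbone, _, _ = tutorial
        tree = build_tree([], backbone)
        assert tree.n_count == 0
        assert repr(tree) == "<LocalTree Of Life | No record available: - n.count: 0- >"

    def test_t1_printed_counts(self, t1_tree):
        assert t1_tree.n_count == 1062
        assert repr(t1_tree) == "<LocalTree Of Life | Root: LUCA - n.count: 1062- >"
        got = {n.taxon.name: n.n_count for n in t1_tree.classes}
        assert got == T1_CLASS_COUNTS
        assert t1_tree.to_Animalia.n_count == 742
        phyla = {n.taxon.name: n.n_count for n in t1_tree.phyla}
        assert phyla == {"Chordata": 740, "Arthropoda": 2, "Bryophyta": 99,
                         "Magnoliophyta": 175, "Mycetozoa": 46}

    def test_count_conservation_at_every_node(self, t1_tree):
        for node in t1_tree.root.walk():
            if node.children:
                assert node.n_count == sum(c.n_count for c in node.children)
            assert node.n_count == len(node.occurrence_ids)

    def test_sibling_occurrence_sets_disjoint(self, t1_tree):
        for node in t1_tree.root.walk():
            seen: set[int] = set()
            for child in node.children:
                ids = child.occurrence_ids
                assert not (seen & ids)
                seen |= ids
            if node.children:
                assert seen == node.occurrence_ids

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_counts_match_brute_force_tally(self, seed):
        tree, bb = random_tree(seed)
        tally = brute_force_lineage_tally(tree.occurrences, bb)
        for node in tree.root.walk():
            assert node.n_count == tally[node.taxon.id]
        # every tallied taxon appears in the tree exactly once
        assert {n.taxon.id for n in tree.root.walk()} == set(tally)

    def test_unresolvable_occurrence_rejected(self, tutorial):
        _, backbone, t1, _ = tutorial
        bogus = [Occurrence(10**6, 10**6, 0.5, 0.5)]
        tree = Tree(list(t1) + bogus, backbone)
        assert tree.n_count == 1062
        assert tree.rejected == 1

    def test_duplicate_ids_collapse(self, tutorial):
        _, backbone, t1, _ = tutorial
        tree = Tree(list(t1) + list(t1), backbone)
        assert tree.n_count == 1062


class TestMerge:
    def test_printed_t3_counts(self, t1_tree, t2_tree):
        t3 = t1_tree + t2_tree
        got = {n.taxon.name: n.n_count for n in t3.classes}
        assert got["Myxomycetes"] == 158
        assert got["Liliopsida"] == 44
        assert got["Magnoliopsida"] == 164
        assert got["Aves"] == 667          # present only in t1
        assert got["Bryopsida"] == 99      # present only in t1
        assert got["Protosteliomycetes"] == 2
        assert t3.n_count == 1062 + 151

    def test_identity_element(self, t1_tree):
        empty = Tree([], t1_tree.backbone)
        assert (t1_tree + empty) == t1_tree
        assert (empty + t1_tree) == t1_tree

    @pytest.mark.parametrize("seed", [3, 4])
    def test_merge_counts_equal_union_build(self, seed):
        bb = make_backbone((2, 2, 2, 2, 2, 2, 2))
        a, _ = random_tree(seed, backbone=bb)
        b, _ = random_tree(seed + 50, backbone=bb)
        merged = a + b
        union = {**{o.id: o for o in a.occurrences}, **{o.id: o for o in b.occurrences}}
        rebuilt = Tree(union.values(), bb)
        assert {(n.taxon.id, n.n_count) for n in merged.root.walk()} == {
            (n.taxon.id, n.n_count) for n in rebuilt.root.walk()
        }

    def test_algebra_laws(self):
        bb = make_backbone((2, 2, 2, 2, 2, 2, 2))
        a, _ = random_tree(10, backbone=bb)
        b, _ = random_tree(11, backbone=bb)
        c, _ = random_tree(12, backbone=bb)
        assert a + b == b + a
        assert (a + b) + c == a + (b + c)
        assert a + a == a

    def test_fold_sum_equals_single_shot(self):
        bb = make_backbone((2, 2, 2, 2, 2, 2, 2))
        trees = [random_tree(s, n=40, backbone=bb)[0] for s in range(20, 26)]
        folded = trees[0]
        for t in trees[1:]:
            folded = folded + t
        single = merge(*trees)
        assert folded == single
        assert {(n.taxon.id, n.n_count) for n in folded.root.walk()} == {
            (n.taxon.id, n.n_count) for n in single.root.walk()
        }

    def test_backbone_mismatch_raises(self, t1_tree):
        other_bb = tutorial_backbone()
        foreign = Tree([], other_bb)
        with pytest.raises(AlgebraError):
            t1_tree + foreign


class TestIntersect:
    def test_disjoint_cells_empty(self, t1_tree, t2_tree):
        result = t1_tree & t2_tree
        assert result.n_count == 0
        assert repr(result) == "<LocalTree Of Life | No record available: - n.count: 0- >"

    def test_idempotence(self, t1_tree):
        assert (t1_tree & t1_tree) == t1_tree

    def test_set_distribution(self):
        bb = make_backbone((2, 2, 2, 2, 2, 2, 2))
        a, _ = random_tree(30, backbone=bb)
        b, _ = random_tree(31, backbone=bb)
        assert (a & (a + b)) == a
        assert (a & b).occurrence_ids == a.occurrence_ids & b.occurrence_ids

    def test_overlapping_sets_counts_match_oracle(self):
        bb = make_backbone((2, 2, 2, 2, 2, 2, 2))
        a, _ = random_tree(33, backbone=bb)
        shared = a.occurrences[::2]
        extra, _ = random_tree(34, backbone=bb)
        b = Tree(shared + extra.occurrences, bb)
        inter = a & b
        expected = Tree(shared, bb)
        assert {(n.taxon.id, n.n_count) for n in inter.root.walk()} == {
            (n.taxon.id, n.n_count) for n in expected.root.walk()
        }


class TestPlant:
    def test_plant_at_root_is_identity(self, t1_tree):
        assert t1_tree.plant(t1_tree.root) == t1_tree

    @pytest.mark.parametrize("cls, expected", [("Mammalia", 70), ("Aves", 667)])
    def test_plant_class_keeps_its_count(self, t1_tree, cls, expected):
        planted = t1_tree.plant_at("Animalia", "Chordata", cls)
        assert planted.n_count == expected
        assert planted.root.taxon.name == "LUCA"
        # single surviving lineage spine down to the planted class
        node = planted.root
        while node.taxon.rank < TaxonRank.CLASS:
            assert len(node.children) == 1
            node = node.children[0]
        assert node.taxon.name == cls

    def test_plant_branches_then_merge_equals_common_ancestor_restriction(
        self, t1_tree
    ):
        chordata = t1_tree.plant_at("Animalia", "Chordata")
        branches = [t1_tree.plant_at("Animalia", "Chordata", c)
                    for c in ("Amphibia", "Aves", "Reptilia", "Mammalia")]
        assert merge(*branches) == chordata

    def test_missing_path_raises(self, t1_tree):
        with pytest.raises(UnknownTaxonError):
            t1_tree.plant_at("Animalia", "Nonexistia")


class TestAppearanceFrequency:
    @pytest.fixture()
    def reference(self, tutorial):
        _, backbone, t1, t2 = tutorial
        trees = [Tree(t1, backbone), Tree(t2, backbone),
                 Tree(t1[:100], backbone), Tree([], backbone)]
        return backbone, trees

    def test_af_bounds_and_extremes(self, reference):
        backbone, trees = reference
        target = merge(*trees)
        target.count_node_frequencies_on_list(trees)
        by_name = {n.taxon.name: n.af for n in target.root.walk()}
        assert by_name["LUCA"] == 1.0            # even the empty tree has a root
        assert by_name["Agaricomycetes"] == 0.25  # only in t2
        for node in target.root.walk():
            assert 0.0 <= node.af <= 1.0

    def test_af_matches_membership_oracle(self, reference):
        backbone, trees = reference
        target = merge(*trees)
        target.count_node_frequencies_on_list(trees)
        for node in target.root.walk():
            expected = sum(
                any(n.taxon.id == node.taxon.id for n in t.root.walk())
                for t in trees
            ) / len(trees)
            assert node.af == pytest.approx(expected)

    def test_parent_af_at_least_child_af(self, reference):
        backbone, trees = reference
        target = merge(*trees)
        target.count_node_frequencies_on_list(trees)
        for node in target.root.walk():
            for child in node.children:
                assert node.af >= child.af

    def test_empty_reference_rejected(self, t1_tree):
        with pytest.raises(ParameterError):
            t1_tree.count_node_frequencies_on_list([])


class TestRankLevels:
    def test_requires_af(self, t1_tree, tutorial):
        _, backbone, t1, _ = tutorial
        fresh = Tree(t1, backbone)
        with pytest.raises(StateError):
            fresh.rank_levels()

    def test_descending_af_with_fixture_values(self, tutorial):
        """A 0.30 / 0.29 / 0.16 frequency profile ranks in that order."""
        _, backbone, t1, _ = tutorial
        tree = Tree(t1, backbone)
        afs = {"Aves": 0.30, "Mammalia": 0.29, "Reptilia": 0.16}
        # reference list of 100 trees engineered to produce those frequencies
        by_class = {}
        for occ in t1:
            cls = backbone.lineage_of(occ.species_id)[TaxonRank.CLASS].name
            by_class.setdefault(cls, []).append(occ)
        refs = []
        for i in range(100):
            occs = []
            for cls, frac in afs.items():
                if i < round(frac * 100):
                    occs.append(by_class[cls][0])
            refs.append(Tree(occs, backbone))
        tree.count_node_frequencies_on_list(refs)
        tree.rank_levels()
        ranked = [(n.taxon.name, n.af) for n in tree.classes[:3]]
        assert ranked == [("Aves", 0.30), ("Mammalia", 0.29), ("Reptilia", 0.16)]

    def test_all_equal_af_is_alphabetical(self, tutorial):
        _, backbone, t1, _ = tutorial
        tree = Tree(t1, backbone)
        tree.count_node_frequencies_on_list([tree])  # every node af = 1.0
        tree.rank_levels()
        names = [n.taxon.name for n in tree.classes]
        assert names == sorted(names)

    def test_sorted_matches_comparison_oracle(self):
        bb = make_backbone((2, 2, 2, 2, 2, 2, 2))
        tree, _ = random_tree(40, n=120, backbone=bb)
        refs = [random_tree(41 + i, n=30, backbone=bb)[0] for i in range(7)]
        tree.count_node_frequencies_on_list(refs)
        tree.rank_levels()
        for rank in (TaxonRank.FAMILY, TaxonRank.SPECIES):
            nodes = tree.nodes_at(rank)
            expected = sorted(nodes, key=lambda n: (-n.af, n.taxon.name))
            assert [n.taxon.id for n in nodes] == [n.taxon.id for n in expected]


class TestAdjacency:
    def test_depth_zero_is_single_zero_matrix(self, t1_tree):
        mat, nodes = t1_tree.to_adjacency(0)
        assert mat.shape == (1, 1) and mat[0, 0] == 0
        assert nodes[0].taxon.rank == TaxonRank.ROOT

    def test_single_lineage_is_path_graph(self, chain_backbone):
        sp = chain_backbone.pick_node(TaxonRank.SPECIES, "s1.1.1.1.1.1.1")
        tree = Tree([Occurrence(0, sp.id, 0.1, 0.1)], chain_backbone)
        mat, nodes = tree.to_adjacency(7)
        assert mat.shape == (8, 8)
        assert mat.sum() == 2 * 7  # 7 undirected edges
        degrees = mat.sum(axis=1)
        assert sorted(degrees.tolist()) == [1, 1] + [2] * 6

    def test_row_sums_equal_degree_oracle(self):
        bb = make_backbone((2, 2, 2, 2, 2, 2, 2))
        tree, _ = random_tree(50, n=60, backbone=bb)
        for depth in (3, 5, 7):
            mat, nodes = tree.to_adjacency(depth)
            idset = {n.taxon.id for n in nodes}
            # independent edge count from parent links in the backbone
            for i, node in enumerate(nodes):
                parent = node.taxon.parent_id
                degree = int(parent in idset)
                degree += sum(
                    1 for other in nodes if other.taxon.parent_id == node.taxon.id
                )
                assert mat[i].sum() == degree

    def test_depth_out_of_range(self, t1_tree):
        with pytest.raises(ParameterError):
            t1_tree.to_adjacency(8)

    def test_networkx_export_counts(self, t1_tree):
        g = t1_tree.to_networkx(depth_level=3)
        n_taxa = sum(
            1 for n in t1_tree.root.walk() if n.taxon.rank <= TaxonRank.CLASS
        )
        assert g.number_of_nodes() == n_taxa
        assert g.number_of_edges() == n_taxa - 1  # a tree

    def test_graphml_round_trip(self, t1_tree, tmp_path):
        import networkx as nx

        path = tmp_path / "t1.graphml"
        t1_tree.write_graphml(path, depth_level=3)
        g = nx.read_graphml(path)
        ranks = {d["rank"] for _, d in g.nodes(data=True)}
        assert ranks == {"root", "kingdom", "phylum", "class"}


class TestNavigation:
    def test_to_accessor_with_sanitized_names(self, tutorial):
        _, backbone, t1, _ = tutorial
        tree = Tree(t1, backbone)
        mammalia = tree.to_Animalia.to_Chordata.to_Mammalia
        assert mammalia.n_count == 70
        # species names contain spaces; sanitized to underscores
        genus = mammalia.to_Mammalia_order.to_Mammalia_family.to_Mammalia_genus
        assert genus.taxon.rank == TaxonRank.GENUS

    def test_ambiguous_sanitized_names(self, chain_backbone):
        from occutree.tree import LocalTree

        from occutree.taxonomy import TaxonNode

        root = LocalTree(chain_backbone.root)
        # two distinct kingdom nodes whose names sanitize identically
        root._child_for(TaxonNode(998, "k.1", TaxonRank.KINGDOM, chain_backbone.root.id))
        root._child_for(TaxonNode(999, "k 1", TaxonRank.KINGDOM, chain_backbone.root.id))
        with pytest.raises(AmbiguousTaxonError):
            root.to_k_1
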