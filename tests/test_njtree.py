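"""Neighbor joining: additive recovery, determinism, bootstrap, monophyly."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcode_audit.distance import DistanceMatrix, pairwise_matrix
from barcode_audit.njtree import (
    bootstrap_support,
    nj_tree,
    read_newick,
    species_monophyly,
    write_newick,
)
from barcode_audit.simulate import mutate_sequence

from conftest import make_library


def make_dm(d, ids=None, species=None):
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    ids = tuple(ids or (f"t{i}" for i in range(n)))
    return DistanceMatrix(ids=ids, d=d, sites=np.zeros((n, n), np.int32),
                          species=tuple(species or ()))


def random_additive_matrix(rng, n):
    """Distances induced by a random binary tree with random edge lengths.

    Built independently of any NJ code: tips are joined in random order
    and tip-to-tip path lengths accumulated directly.
    """
    # each active cluster: (set of tip indices, distance-from-cluster-root per tip)
    clusters = [({i}, {i: 0.0}) for i in range(n)]
    D = np.zeros((n, n))
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (tips_a, da), (tips_b, db) = clusters[i], clusters[j]
        la, lb = rng.uniform(0.05, 1.0, size=2)
        for x in tips_a:
            for y in tips_b:
                D[x, y] = D[y, x] = da[x] + la + db[y] + lb
        merged = {x: v + la for x, v in da.items()}
        merged.update({y: v + lb for y, v in db.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((tips_a | tips_b, merged))
    return D


def tree_path_matrix(stree, ids):
    td = stree.tree.tip_tip_distances()
    out = np.zeros((len(ids), len(ids)))
    for a in range(len(ids)):
        for b in range(len(ids)):
            if a != b:
                out[a, b] = td[ids[a], ids[b]]
    return out


class TestAdditiveRecovery:
    def test_four_taxon_tree_recovered_exactly(self):
        # ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        d = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 7, 0],
            ],
            dtype=float,
        )
        dm = make_dm(d, ids=["A", "B", "C", "D"])
        st_ = nj_tree(dm)
        assert np.allclose(tree_path_matrix(st_, list(dm.ids)), d, atol=1e-9)
        # the (A,B) | (C,D) split must be present
        sides = {frozenset(t.name for t in n.tips()) for n in st_.tree.non_tips()}
        assert frozenset({"A", "B"}) in sides or frozenset({"C", "D"}) in sides

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        st_ = nj_tree(make_dm(d))
        lengths = {t.name: t.length for t in st_.tree.tips()}
        assert lengths == pytest.approx({"t0": 1.0, "t1": 2.0, "t2": 3.0})

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(4, 12))
    def test_random_additive_matrices_inverted_exactly(self, seed, n):
        rng = np.random.default_rng(seed)
        D = random_additive_matrix(rng, n)
        st_ = nj_tree(make_dm(D))
        assert np.allclose(tree_path_matrix(st_, list(make_dm(D).ids)), D, atol=1e-9)

    def test_agrees_with_independent_nj_implementation(self):
        import skbio

        rng = np.random.default_rng(3)
        D = random_additive_matrix(rng, 8)
        ids = [f"t{i}" for i in range(8)]
        ours = nj_tree(make_dm(D, ids=ids))
        ref = skbio.tree.nj(skbio.DistanceMatrix(D, ids))
        taxa = frozenset(ids)

        def splits(tree):
            out = set()
            for node in tree.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                if 2 <= len(side) <= len(taxa) - 2:
                    out.add(min(side, taxa - side, key=sorted))
            return out

        assert splits(ours.tree) == splits(ref)


class TestConventions:
    def test_deterministic_tie_break(self):
        # fully tied matrix: every iteration has equal Q values
        d = np.ones((4, 4)) - np.eye(4)
        s1 = nj_tree(make_dm(d)).newick()
        s2 = nj_tree(make_dm(d)).newick()
        assert s1 == s2

    def test_negative_branches_clamped_by_default(self):
        # non-additive matrix known to induce a negative NJ branch
        d = np.array(
            [[0, 1, 8, 9], [1, 0, 2, 3], [8, 2, 0, 1], [9, 3, 1, 0]], dtype=float
        )
        clamped = nj_tree(make_dm(d))
        free = nj_tree(make_dm(d), allow_negative=True)
        all_lengths = [n.length for n in clamped.tree.traverse() if n.length is not None]
        assert min(all_lengths) >= 0
        free_lengths = [n.length for n in free.tree.traverse() if n.length is not None]
        assert clamped.n_clamped_branches > 0
        assert min(free_lengths) < 0

    def test_incomplete_matrix_rejected(self):
        d = np.zeros((3, 3))
        d[0, 1] = d[1, 0] = np.nan
        with pytest.raises(ValueError, match="undefined"):
            nj_tree(make_dm(d))

    def test_newick_round_trip(self, tmp_path):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        st_ = nj_tree(make_dm(d))
        buf = io.StringIO()
        write_newick(st_, buf)
        back = read_newick(io.StringIO(buf.getvalue()))
        assert back.tip_names() == st_.tip_names()


def two_species_library(divergence_muts=120, n_each=5, length=600, seed=4):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list("ACGT"), size=length))
    b = mutate_sequence(a, divergence_muts, divergence_muts // 2, rng)
    entries = []
    for i in range(n_each):
        entries.append((f"a{i}", "Alpha one", mutate_sequence(a, int(rng.integers(0, 3)), 0, rng)))
        entries.append((f"b{i}", "Beta two", mutate_sequence(b, int(rng.integers(0, 3)), 0, rng)))
    return make_library(entries)


class TestBootstrap:
    def test_deep_species_split_has_high_support(self):
        lib = two_species_library()
        st_ = bootstrap_support(lib, replicates=100, seed=1)
        supports = [n.support for n in st_.tree.non_tips() if hasattr(n, "support")]
        assert max(supports) >= 95  # the species bipartition

    def test_single_replicate_supports_are_zero_or_hundred(self):
        lib = two_species_library(n_each=3)
        st_ = bootstrap_support(lib, replicates=1, seed=2)
        for n in st_.tree.non_tips():
            if hasattr(n, "support"):
                assert n.support in (0.0, 100.0)

    def test_same_seed_reproduces_supports(self):
        lib = two_species_library(n_each=4)
        s1 = bootstrap_support(lib, replicates=25, seed=7)
        s2 = bootstrap_support(lib, replicates=25, seed=7)
        assert s1.newick() == s2.newick()

    def test_supports_invariant_to_specimen_order(self):
        lib = two_species_library(n_each=4)
        reordered = make_library(
            [(r.specimen_id, r.species, r.sequence) for r in reversed(lib.records)]
        )
        s1 = bootstrap_support(lib, replicates=25, seed=7)
        s2 = bootstrap_support(reordered, replicates=25, seed=7)

        def support_map(st_):
            taxa = frozenset(st_.tip_names())
            ref = min(taxa)
            out = {}
            for n in st_.tree.non_tips():
                if hasattr(n, "support"):
                    side = frozenset(t.name for t in n.tips())
                    canon = side if ref not in side else taxa - side
                    out[canon] = n.support
            return out

        assert support_map(s1) == support_map(s2)


class TestMonophyly:
    def test_clean_split_is_monophyletic(self):
        lib = two_species_library(n_each=3)
        st_ = nj_tree(pairwise_matrix(lib))
        mono = species_monophyly(st_, lib)
        assert mono == {"Alpha one": True, "Beta two": True}

    def test_interleaved_species_are_not_monophyletic(self):
        # identical sequences within mixed pairs force an interleaved topology
        rng = np.random.default_rng(8)
        base = "".join(rng.choice(list("ACGT"), size=400))
        far = mutate_sequence(base, 60, 30, rng)
        lib = make_library(
            [
                ("a1", "Alpha one", base),
                ("b1", "Beta two", mutate_sequence(base, 1, 0, rng)),
                ("a2", "Alpha one", far),
                ("b2", "Beta two", mutate_sequence(far, 1, 0, rng)),
            ]
        )
        st_ = nj_tree(pairwise_matrix(lib))
        mono = species_monophyly(st_, lib)
        assert mono == {"Alpha one": False, "Beta two": False}

    def test_singletons_are_trivially_monophyletic(self):
        lib = two_species_library(n_each=2)
        extra = make_library(
            [(r.specimen_id, r.species, r.sequence) for r in lib.records]
            + [("c1", "Gamma three", mutate_sequence(lib.records[0].sequence, 80, 40, 3))]
        )
        st_ = nj_tree(pairwise_matrix(extra))
        assert species_monophyly(st_, extra)["Gamma three"] is True
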