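"""K2P distance engine: closed form, pairwise deletion, oracle parity."""

import io
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcode_audit.distance import (
    base_composition,
    compare_pair,
    k2p_distance,
    k2p_from_pq,
    pairwise_matrix,
    read_matrix_tsv,
    write_matrix_phylip,
    write_matrix_tsv,
)
from barcode_audit.simulate import mutate_sequence

from conftest import make_library

PURINES = {"A", "G"}


def oracle_counts(a: str, b: str):
    """Independent nested-loop transition/transversion counter."""
    L = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        L += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    return L, ts, tv


class TestClosedForm:
    def test_identical_sequences_have_zero_distance(self):
        seq = "ACGT" * 150
        d, cmp = k2p_distance(seq, seq)
        assert d == 0.0 and cmp.transitions == 0 and cmp.transversions == 0

    @pytest.mark.parametrize(
        "P,Q,expected",
        [
            # d = -0.5*ln((1-2P-Q)*sqrt(1-2Q)), evaluated independently
            (0.10, 0.05, 0.170181165140347),
            (0.0, 0.0, 0.0),
            (2 / 90, 0.0, 0.022731187038379),
        ],
    )
    def test_known_pq_values(self, P, Q, expected):
        assert k2p_from_pq(P, Q) == pytest.approx(expected, abs=1e-9)

    def test_closed_form_matches_direct_evaluation_to_1e9(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            P = rng.uniform(0, 0.35)
            Q = rng.uniform(0, min(0.45, 1 - 2 * P - 1e-3))
            expected = -0.5 * math.log((1 - 2 * P - Q) * math.sqrt(1 - 2 * Q))
            assert k2p_from_pq(P, Q) == pytest.approx(expected, abs=1e-9)

    def test_constructed_mutations_reproduce_target_pq(self):
        seq = mutate_sequence("A" * 600, 0, 0, 1)  # identity check below too
        assert seq == "A" * 600
        base = "ACGT" * 150
        mutant = mutate_sequence(base, 60, 30, seed_or_rng=3)
        d, cmp = k2p_distance(base, mutant)
        assert (cmp.transitions, cmp.transversions) == (60, 30)
        assert d == pytest.approx(0.170181165140347, abs=1e-9)

    def test_sites_with_n_are_pairwise_deleted(self):
        a = "A" * 100
        b = "N" * 10 + "G" * 2 + "A" * 88
        d, cmp = k2p_distance(a, b, min_overlap=50)
        assert cmp.comparable_sites == 90
        assert cmp.transitions == 2
        assert d == pytest.approx(-0.5 * math.log(1 - 4 / 90), abs=1e-9)

    def test_saturation_is_undefined_not_clamped(self):
        assert math.isnan(k2p_from_pq(0.5, 0.1))
        assert math.isnan(k2p_from_pq(0.1, 0.5))

    def test_low_overlap_is_undefined(self):
        a, b = "A" * 200, "N" * 150 + "A" * 50
        d, _ = k2p_distance(a, b, min_overlap=100)
        assert math.isnan(d)


class TestCountingOracle:
    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_counts_match_nested_loop_oracle_on_random_pairs(self, data):
        alphabet = "ACGTN-"
        n = 30
        a = "".join(data.draw(st.sampled_from(alphabet)) for _ in range(n))
        b = "".join(data.draw(st.sampled_from(alphabet)) for _ in range(n))
        L, ts, tv = oracle_counts(a, b)
        cmp = compare_pair(a, b)
        assert (cmp.comparable_sites, cmp.transitions, cmp.transversions) == (L, ts, tv)

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_complementing_both_sequences_preserves_distance(self, seed):
        rng = np.random.default_rng(seed)
        comp = str.maketrans("ACGT", "TGCA")
        base = "".join(rng.choice(list("ACGT"), size=300))
        mutant = mutate_sequence(base, int(rng.integers(0, 30)), int(rng.integers(0, 15)), rng)
        d1, c1 = k2p_distance(base, mutant)
        d2, c2 = k2p_distance(base.translate(comp), mutant.translate(comp))
        assert c1 == c2
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_k2p_dominates_p_distance(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), size=400))
        for _ in range(20):
            mutant = mutate_sequence(base, int(rng.integers(0, 40)), int(rng.integers(0, 20)), rng)
            d, cmp = k2p_distance(base, mutant)
            p = cmp.P + cmp.Q
            assert d >= p - 1e-12
            assert (d == pytest.approx(p)) == (p == 0)

    def test_extra_transition_strictly_increases_distance(self):
        L = 200
        for ts in range(0, 30):
            d1 = k2p_from_pq(ts / L, 5 / L)
            d2 = k2p_from_pq((ts + 1) / L, 5 / L)
            assert d2 > d1


class TestMatrix:
    def test_three_identical_sequences_give_zero_matrix(self):
        lib = make_library([(f"s{i}", "X y", "ACGT" * 50) for i in range(3)])
        dm = pairwise_matrix(lib)
        assert np.allclose(dm.d, 0.0)

    def test_matrix_agrees_with_per_pair_recount(self, small_sim, small_dm):
        lib = small_sim.library
        rng = np.random.default_rng(2)
        idx = rng.choice(len(lib), size=12, replace=False)
        for i in idx[:6]:
            for j in idx[6:]:
                a, b = lib.records[int(i)].sequence, lib.records[int(j)].sequence
                d, _ = k2p_distance(a, b)
                assert small_dm.d[int(i), int(j)] == pytest.approx(d, abs=1e-12)

    def test_removing_a_record_yields_principal_submatrix(self, toy_library):
        dm = pairwise_matrix(toy_library, min_overlap=10)
        keep = [i for i in dm.ids if i != "q3"]
        sub = dm.submatrix(keep)
        lib2 = toy_library.subset(keep)
        dm2 = pairwise_matrix(lib2, min_overlap=10)
        assert np.allclose(sub.d, dm2.d)

    def test_matrix_tsv_round_trip(self, toy_library, tmp_path):
        dm = pairwise_matrix(toy_library, min_overlap=10)
        path = tmp_path / "m.tsv"
        write_matrix_tsv(dm, path)
        back = read_matrix_tsv(path, toy_library)
        assert back.ids == dm.ids
        assert np.allclose(back.d, dm.d)
        assert back.species == dm.species

    def test_phylip_writer_emits_lower_triangle(self, toy_library, tmp_path):
        dm = pairwise_matrix(toy_library, min_overlap=10)
        path = tmp_path / "m.phy"
        write_matrix_phylip(dm, str(path))
        lines = path.read_text().splitlines()
        assert lines[0] == "4"
        assert len(lines[1].split("\t")) == 1  # first taxon, no cells
        assert len(lines[-1].split("\t")) == 4


class TestBaseComposition:
    def test_single_base_sequence(self):
        lib = make_library([("a", "X y", "AAAA")])
        assert base_composition(lib)["A"] == pytest.approx(1.0)

    def test_uniform_sequence(self):
        lib = make_library([("a", "X y", "ACGT")])
        assert all(v == pytest.approx(0.25) for v in base_composition(lib).values())

    def test_mean_is_unweighted_across_records(self):
        lib = make_library([("a", "X y", "AAAAAAAA"), ("b", "X y", "TT")])
        comp = base_composition(lib)
        assert comp["A"] == pytest.approx(0.5)
        assert comp["T"] == pytest.approx(0.5)

    def test_frequencies_sum_to_one(self, small_sim):
        comp = base_composition(small_sim.library)
        assert sum(comp.values()) == pytest.approx(1.0, abs=1e-9)


class TestAgainstApe:
    """Cross-check against an independent phylogenetics implementation
    (R ape's dist.dna, K80 model, pairwise deletion)."""

    def test_matrix_matches_ape_k80(self, tmp_path):
        rng = np.random.default_rng(9)
        base = "".join(rng.choice(list("ACGT"), size=300, p=[0.26, 0.19, 0.19, 0.36]))
        seqs = {"t0": base}
        for i in range(1, 8):
            seqs[f"t{i}"] = mutate_sequence(
                base, int(rng.integers(0, 40)), int(rng.integers(0, 20)), rng
            )
        fasta = tmp_path / "seqs.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        rscript = tmp_path / "k80.R"
        rscript.write_text(
            """
            suppressMessages(library(ape))
            args <- commandArgs(trailingOnly=TRUE)
            x <- read.dna(args[1], format="fasta")
            d <- dist.dna(x, model="K80", pairwise.deletion=TRUE)
            m <- as.matrix(d)
            write.table(format(m, digits=12), args[2], sep="\\t", quote=FALSE)
            """
        )
        out = tmp_path / "ape.tsv"
        subprocess.run(
            ["Rscript", str(rscript), str(fasta), str(out)],
            check=True,
            capture_output=True,
        )
        import pandas as pd

        ape = pd.read_csv(out, sep="\t", index_col=0).astype(float)
        lib = make_library([(k, "X y", v) for k, v in seqs.items()])
        dm = pairwise_matrix(lib)
        ours = dm.to_dataframe().loc[ape.index, ape.columns]
        assert np.allclose(ours.to_numpy(), ape.to_numpy(), atol=1e-9)
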