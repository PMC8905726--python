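"""Greedy clustering, center-star alignment, insert trimming, consensus."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steamerscan import cluster_consensus as cc
from steamerscan import simdata as sd
from steamerscan._seqs import global_identity, random_dna, revcomp


def _mutate(seq, n_subs, seed):
    rng = np.random.default_rng(seed)
    out = list(seq)
    for pos in rng.choice(len(seq), n_subs, replace=False):
        out[pos] = "ACGT".replace(seq[pos], "")[rng.integers(0, 3)]
    return "".join(out)


class TestClusterSequences:
    def test_single_sequence_is_singleton(self):
        cs = cc.cluster_sequences({"a": "ACGT" * 100})
        assert len(cs.clusters) == 1
        assert cs.clusters[0].centroid_id == "a"

    def test_near_identical_and_revcomp_cluster_together(self):
        rng = np.random.default_rng(1)
        a = random_dna(1_000, rng)
        b = _mutate(a, 10, 2)  # 99% identity
        c = revcomp(a)
        cs = cc.cluster_sequences({"A": a, "B": b, "C": c})
        assert len(cs.clusters) == 1
        assert cs.clusters[0].strands["C"] == "-"
        assert cs.clusters[0].strands["B"] == "+"

    def test_divergent_sequence_founds_new_cluster(self):
        rng = np.random.default_rng(3)
        a = random_dna(1_000, rng)
        b = _mutate(a, 300, 4)  # 70% identity < 0.8
        cs = cc.cluster_sequences({"A": a, "B": b})
        assert len(cs.clusters) == 2

    def test_empty_input(self):
        assert cc.cluster_sequences({}).clusters == []

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_partition_property(self, seed):
        rng = np.random.default_rng(seed)
        base = random_dna(400, rng)
        seqs = {}
        for i in range(8):
            if rng.random() < 0.5:
                seqs[f"s{i}"] = _mutate(base, int(rng.integers(0, 40)), i)
            else:
                seqs[f"s{i}"] = random_dna(int(rng.integers(200, 600)), rng)
        cs = cc.cluster_sequences(seqs)
        members = [m for cl in cs.clusters for m in cl.members]
        assert sorted(members) == sorted(seqs)

    def test_equal_length_inputs_order_insensitive(self):
        rng = np.random.default_rng(5)
        base = random_dna(500, rng)
        seqs = {f"s{i}": _mutate(base, 20, i) for i in range(4)}
        seqs["far"] = random_dna(500, rng)
        n1 = len(cc.cluster_sequences(seqs).clusters)
        n2 = len(cc.cluster_sequences(dict(reversed(list(seqs.items())))).clusters)
        assert n1 == n2


class TestAlignCluster:
    def test_identical_members_no_gaps(self):
        rng = np.random.default_rng(6)
        s = random_dna(300, rng)
        aln = cc.align_cluster([("a", s), ("b", s), ("c", s)])
        assert all(("-" not in row) for _, row in aln)

    def test_single_member_unchanged(self):
        aln = cc.align_cluster([("a", "ACGTACGT")])
        assert aln == [("a", "ACGTACGT")]

    def test_insertion_makes_gap_block_in_other_rows(self):
        rng = np.random.default_rng(7)
        base = random_dna(1_000, rng)
        ins = random_dna(300, rng)
        with_ins = base[:500] + ins + base[500:]
        aln = cc.align_cluster([("long", with_ins), ("a", base), ("b", base)])
        rows = dict(aln)
        # 300 columns gapped in every member lacking the insertion
        assert rows["a"].count("-") == 300
        assert rows["b"].count("-") == 300
        assert "-" * 300 in rows["a"]

    def test_ungapping_restores_members(self):
        rng = np.random.default_rng(8)
        base = random_dna(800, rng)
        members = [("m0", base)]
        for i in range(1, 5):
            s = _mutate(base, 30, i)
            if i == 2:
                s = s[:200] + random_dna(50, rng) + s[200:]
            if i == 3:
                s = s[:600] + s[650:]
            members.append((f"m{i}", s))
        aln = cc.align_cluster(members)
        width = len(aln[0][1])
        for (mid, row), (_, orig) in zip(aln, members):
            assert len(row) == width
            assert row.replace("-", "") == orig


class TestTrimNonconserved:
    def test_minority_insertion_column_trimmed(self):
        aln = [("a", "AC-G"), ("b", "AC-G"), ("c", "AC-G"), ("d", "AC-G"), ("e", "ACTG")]
        trimmed, cols = cc.trim_nonconserved(aln)
        assert cols == [2]
        assert dict(trimmed)["e"] == "ACG"

    def test_exactly_80pct_occupancy_retained(self):
        aln = [("a", "ACTG")] * 4 + [("e", "AC-G")]
        aln = [(f"r{i}", s) for i, (_, s) in enumerate(aln)]
        trimmed, cols = cc.trim_nonconserved(aln, occupancy_threshold=0.80)
        assert cols == []

    def test_identity_mode_uses_modal_residue(self):
        aln = [("a", "A"), ("b", "A"), ("c", "A"), ("d", "A"), ("e", "C")]
        _, cols_occ = cc.trim_nonconserved(aln, mode="occupancy")
        _, cols_id = cc.trim_nonconserved(aln, mode="identity")
        assert cols_occ == [] and cols_id == []
        aln2 = [("a", "A"), ("b", "A"), ("c", "C"), ("d", "C"), ("e", "G")]
        _, cols_id2 = cc.trim_nonconserved(aln2, mode="identity")
        assert cols_id2 == [0]

    def test_all_identical_alignment_untouched(self):
        aln = [(f"r{i}", "ACGTACGT") for i in range(5)]
        trimmed, cols = cc.trim_nonconserved(aln)
        assert cols == [] and trimmed == aln

    def test_bad_threshold_rejected(self):
        with pytest.raises(cc.ParameterError):
            cc.trim_nonconserved([("a", "ACGT")], occupancy_threshold=0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000), st.floats(0.2, 1.0))
    def test_matches_column_counting_oracle(self, seed, threshold):
        rng = np.random.default_rng(seed)
        nrows, ncols = int(rng.integers(2, 8)), int(rng.integers(1, 30))
        mat = rng.choice(list("ACGT-"), size=(nrows, ncols))
        aln = [(f"r{i}", "".join(mat[i])) for i in range(nrows)]
        for mode in ("occupancy", "identity"):
            _, cols = cc.trim_nonconserved(aln, threshold, mode)
            expected = []
            for j in range(ncols):
                col = [mat[i][j] for i in range(nrows)]
                residues = [c for c in col if c != "-"]
                if mode == "occupancy":
                    keep = len(residues) >= threshold * nrows
                else:
                    keep = bool(residues) and max(
                        residues.count(r) for r in set(residues)
                    ) >= threshold * nrows
                if not keep:
                    expected.append(j)
            assert cols == expected


class TestBuildConsensus:
    def test_identical_rows(self):
        rec = cc.build_consensus([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")])
        assert rec.consensus == "ACGT"
        assert rec.n_members == 3

    def test_majority_rule(self):
        rec = cc.build_consensus([("a", "A"), ("b", "A"), ("c", "G")])
        assert rec.consensus == "A"

    def test_tie_breaks_alphabetically_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING):
            rec = cc.build_consensus([("a", "A"), ("b", "A"), ("c", "G"), ("d", "G")])
        assert rec.consensus == "A"
        assert any("tied" in r.message for r in caplog.records)

    def test_empty_rejected(self):
        with pytest.raises(cc.ParameterError):
            cc.build_consensus([])


class TestIterate:
    def test_insert_free_input_is_fixed_point(self):
        rng = np.random.default_rng(9)
        base = random_dna(600, rng)
        seqs = {f"s{i}": _mutate(base, 10, i) for i in range(5)}
        cs1, cons1 = cc.iterate_cluster_consensus(seqs, rounds=1)
        cs2, cons2 = cc.iterate_cluster_consensus(seqs, rounds=2)
        assert len(cs1.clusters) == len(cs2.clusters) == 1
        assert cons1[0].consensus == cons2[0].consensus

    def test_two_round_consensus_removes_insertion(self, small_element):
        _, canonical, feat = small_element
        rng = np.random.default_rng(10)
        seqs = {}
        for i in range(8):
            copy, _, _ = sd.mutate_copy(
                canonical, feat, sd.MutationParams(substitution_rate=0.03, seed=100 + i)
            )
            if i == 0:
                copy = copy[:1500] + random_dna(500, rng) + copy[1500:]
            seqs[f"c{i}"] = copy
        cs, consensi = cc.iterate_cluster_consensus(seqs, rounds=2)
        assert len(cs.clusters) == 1
        cons = consensi[0].consensus
        assert global_identity(cons, canonical) >= 99.0
        assert abs(len(cons) - len(canonical)) <= 0.01 * len(canonical)

    def test_two_subfamilies_stay_apart(self):
        rng = np.random.default_rng(11)
        fam1 = random_dna(900, rng)
        fam2 = random_dna(900, rng)
        seqs = {}
        for i in range(4):
            seqs[f"a{i}"] = _mutate(fam1, 20, i)
            seqs[f"b{i}"] = _mutate(fam2, 20, 10 + i)
        cs, consensi = cc.iterate_cluster_consensus(seqs, rounds=2)
        assert len(cs.clusters) == 2
        assert len(consensi) == 2

    def test_invalid_rounds(self):
        with pytest.raises(cc.ParameterError):
            cc.iterate_cluster_consensus({"a": "ACGT"}, rounds=0)
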