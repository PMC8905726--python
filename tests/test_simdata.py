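"""Synthetic genome generator: canonical structure, mutation model, planting."""

import numpy as np
import pytest

from steamerscan import simdata as sd
from steamerscan._seqs import global_identity, revcomp


class TestCanonicalElement:
    def test_reference_dimensions(self, canonical_element):
        spec, seq, feat = canonical_element
        assert len(seq) == 4968 == 2 * 177 + 12 + 4602
        assert feat["ltr5"] == (0, 177)
        assert feat["ltr3"] == (4791, 4968)

    def test_structure_motifs_and_features(self, canonical_element):
        spec, seq, feat = canonical_element
        ltr5 = seq[slice(*feat["ltr5"])]
        ltr3 = seq[slice(*feat["ltr3"])]
        assert ltr5 == ltr3, "the two LTRs are identical in the canonical element"
        assert ltr5.startswith("TGTAACA") and ltr5.endswith("TTAAACA")
        assert seq[slice(*feat["pbs"])] == "TGGTGTCAGAAG"
        ppt = seq[slice(*feat["ppt"])]
        assert set(ppt) <= {"A", "G"}
        assert feat["ppt"][1] == feat["ltr3"][0], "PPT abuts the 3' LTR"

    def test_orf_is_stop_free_in_frame(self, canonical_element):
        from Bio.Seq import Seq

        spec, seq, feat = canonical_element
        orf = seq[slice(*feat["orf"])]
        assert orf.startswith("ATG")
        assert len(orf) % 3 == 0
        assert "*" not in str(Seq(orf).translate())
        assert len(orf) >= 0.9 * spec.orf_fraction * spec.internal_length

    def test_orf_fraction_zero_drops_orf_feature(self):
        spec = sd.ElementSpec(internal_length=500, orf_fraction=0.0, seed=1)
        _, feat = sd.make_canonical_element(spec)
        assert "orf" not in feat

    def test_deterministic_for_fixed_seed(self, steamer_spec):
        a, _ = sd.make_canonical_element(steamer_spec)
        b, _ = sd.make_canonical_element(steamer_spec)
        assert a == b

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"ltr_length": 79},
            {"ltr_length": 1201},
            {"pbs_motif": "TGGTGTCAGAA"},
            {"orf_fraction": 1.5},
            {"superfamily_label": "LINE"},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(sd.ParameterError):
            sd.make_canonical_element(sd.ElementSpec(**kwargs))

    def test_orf_protein_is_encoded(self):
        from Bio.Seq import Seq

        prot = "MKVLWAALLVTFLAGCQA"
        spec = sd.ElementSpec(internal_length=300, orf_protein=prot, seed=5)
        seq, feat = sd.make_canonical_element(spec)
        orf = seq[slice(*feat["orf"])]
        assert str(Seq(orf).translate()) == "M" + prot


class TestMutateCopy:
    def test_zero_params_is_identity(self, small_element):
        _, seq, feat = small_element
        out, log, feat2 = sd.mutate_copy(seq, feat, sd.MutationParams())
        assert out == seq
        assert log.n_substitutions == log.n_indels == 0
        assert feat2 == feat

    def test_substitution_rate_matches_observed_mismatches(self, canonical_element):
        _, seq, feat = canonical_element
        params = sd.MutationParams(substitution_rate=0.05, seed=11)
        out, log, _ = sd.mutate_copy(seq, feat, params)
        assert len(out) == len(seq)
        observed = sum(a != b for a, b in zip(seq, out)) / len(seq)
        assert abs(observed - 0.05) <= 0.01
        assert log.n_substitutions == sum(a != b for a, b in zip(seq, out))

    @pytest.mark.parametrize("n", [0, 1, 2, 3])
    def test_edit_log_frameshift_count_matches_request(self, small_element, n):
        _, seq, feat = small_element
        for seed in range(25):
            _, log, _ = sd.mutate_copy(
                seq, feat, sd.MutationParams(n_frameshifts=n, seed=seed)
            )
            assert log.n_frameshifts == n
            assert all(length % 3 != 0 for _, length, _ in log.frameshifts)
            s, e = feat["orf"]
            assert all(s <= pos < e for pos, _, _ in log.frameshifts)

    def test_revcomp_flag(self, small_element):
        _, seq, feat = small_element
        out, log, feat2 = sd.mutate_copy(seq, feat, sd.MutationParams(revcomp=True))
        assert out == revcomp(seq)
        assert log.revcomp
        s, e = feat2["ltr5"]
        assert out[s:e] == revcomp(seq[slice(*feat["ltr5"])])

    def test_truncation_drops_features(self, small_element):
        _, seq, feat = small_element
        out, log, feat2 = sd.mutate_copy(
            seq, feat, sd.MutationParams(truncate_3prime=len(seq) - 2500)
        )
        assert len(out) == 2500
        assert "ltr3" not in feat2

    def test_frameshift_without_orf_rejected(self):
        with pytest.raises(sd.ParameterError):
            sd.mutate_copy("ACGT" * 100, {}, sd.MutationParams(n_frameshifts=1))

    def test_identity_decreases_monotonically_with_rate(self, small_element):
        _, seq, feat = small_element
        idents = []
        for rate in (0.0, 0.05, 0.15, 0.30):
            vals = []
            for seed in range(3):
                out, _, _ = sd.mutate_copy(
                    seq, feat, sd.MutationParams(substitution_rate=rate, seed=seed)
                )
                vals.append(global_identity(out, seq))
            idents.append(np.mean(vals))
        assert all(a > b for a, b in zip(idents, idents[1:]))


class TestPlantGenome:
    def test_empty_plan(self):
        g, truth = sd.plant_genome(10_000, 0.5, [], seed=1)
        assert len(g) == 10_000 and truth == []

    def test_length_arithmetic(self, steamer_spec):
        g, truth = sd.plant_genome(
            100_000, 0.4, [sd.Insertion(steamer_spec, 30_000)], seed=2
        )
        assert len(g) == 104_968
        assert truth[0].end - truth[0].start == 4968

    def test_truth_coordinates_slice_planted_sequence(self, steamer_spec):
        canonical, feat = sd.make_canonical_element(steamer_spec)
        for seed in range(5):
            plan = [
                sd.Insertion(steamer_spec, 10_000,
                             sd.MutationParams(substitution_rate=0.03, seed=seed)),
                sd.Insertion(steamer_spec, 40_000,
                             sd.MutationParams(revcomp=True, seed=seed + 1)),
                sd.Insertion(steamer_spec, 70_000,
                             sd.MutationParams(truncate_5prime=1000, seed=seed + 2)),
            ]
            g, truth = sd.plant_genome(100_000, 0.4, plan, seed=seed)
            for t, ins in zip(truth, plan):
                copy, _, _ = sd.mutate_copy(canonical, feat, ins.mutation)
                assert g[t.start : t.end] == copy
                assert t.ltr5_start <= t.ltr5_end <= t.ltr3_start <= t.ltr3_end

    def test_ltr_spans_slice_ltr_sequence(self, steamer_spec):
        canonical, feat = sd.make_canonical_element(steamer_spec)
        g, truth = sd.plant_genome(
            50_000, 0.4,
            [sd.Insertion(steamer_spec, 20_000, sd.MutationParams(revcomp=True))],
            seed=3,
        )
        t = truth[0]
        ltr = canonical[slice(*feat["ltr5"])]
        assert g[t.ltr5_start : t.ltr5_end] == revcomp(ltr)
        assert t.strand == "-"

    def test_overlapping_insertions_rejected(self, steamer_spec):
        with pytest.raises(sd.PlanError, match="overlapping"):
            sd.plant_genome(
                100_000, 0.4,
                [sd.Insertion(steamer_spec, 10_000), sd.Insertion(steamer_spec, 12_000)],
                seed=1,
            )

    def test_deterministic(self, steamer_spec):
        plan = [sd.Insertion(steamer_spec, 10_000 + 6_000 * i,
                             sd.MutationParams(substitution_rate=0.02, seed=i))
                for i in range(5)]
        g1, t1 = sd.plant_genome(60_000, 0.4, plan, seed=9)
        g2, t2 = sd.plant_genome(60_000, 0.4, plan, seed=9)
        assert g1 == g2 and t1 == t2


class TestDomainPanel:
    def test_labels_lengths_and_determinism(self):
        p1 = sd.make_domain_panel(5, domain_length_aa=400, seed=4)
        p2 = sd.make_domain_panel(5, domain_length_aa=400, seed=4)
        assert p1 == p2
        assert len(p1) == 15
        assert all(len(seq) == 400 for _, _, _, seq in p1)
        labels = {lab for _, lab, _, _ in p1}
        assert labels == {"Gypsy", "Copia", "BEL/Pao"}
        gypsy_clades = {clade for _, lab, clade, _ in p1 if lab == "Gypsy"}
        assert "C-clade" in gypsy_clades

    def test_within_label_identity_exceeds_between(self):
        panel = sd.make_domain_panel(5, 200, divergence_within=0.1,
                                     divergence_between=0.5, seed=6)

        def ident(a, b):
            return sum(x == y for x, y in zip(a, b)) / len(a)

        within, between = [], []
        for i in range(len(panel)):
            for j in range(i + 1, len(panel)):
                pair = ident(panel[i][3], panel[j][3])
                (within if panel[i][1] == panel[j][1] else between).append(pair)
        assert np.mean(within) > np.mean(between)

    def test_closest_neighbor_shares_label(self):
        panel = sd.make_domain_panel(5, 200, divergence_within=0.1,
                                     divergence_between=0.5, seed=7)

        def ident(a, b):
            return sum(x == y for x, y in zip(a, b))

        for i, (_, lab, _, seq) in enumerate(panel):
            best = max(
                (j for j in range(len(panel)) if j != i),
                key=lambda j: ident(seq, panel[j][3]),
            )
            assert panel[best][1] == lab

    def test_small_panel_rejected(self):
        with pytest.raises(sd.ParameterError):
            sd.make_domain_panel(1)
        with pytest.raises(sd.ParameterError):
            sd.make_domain_panel(5, divergence_within=0.5, divergence_between=0.2)
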