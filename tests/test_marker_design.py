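"""HRM marker design: filtering, amplicons, Tm thermodynamics, panels."""

import numpy as np
import pytest

from mabckit.genome_map import GenomeMap, ChromosomeMap, brassica_rapa_map
from mabckit.marker_design import (
    AmpliconRejection,
    DEFAULT_PANEL_COUNTS,
    Marker,
    MarkerPanel,
    NNParameterTable,
    build_amplicon_pair,
    density_report,
    design_hrm_candidates,
    design_target_marker,
    filter_variants,
    predict_tm,
    revcomp,
    score_delta_tm,
    select_even_panel,
)
from mabckit.synthetic_data import TargetLocus, Variant, variant_context

from nn_oracle import tm_brute_force


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestFilterVariants:
    @pytest.mark.parametrize(
        "variant,kept",
        [
            (Variant("A01", 10, "ATTT", "A", "INDEL", 3, "hom"), True),
            (Variant("A01", 10, "ATT", "A", "INDEL", 2, "hom"), False),
            (Variant("A01", 10, "A" * 11, "A", "INDEL", 10, "het"), False),
            (Variant("A01", 10, "A", "C", "SNP", 0, "hom"), False),
        ],
    )
    def test_homozygous_long_indels_only(self, variant, kept):
        assert (filter_variants([variant]) == [variant]) is kept

    def test_threshold_configurable(self):
        v = Variant("A01", 10, "AT", "A", "INDEL", 1, "hom")
        assert filter_variants([v], min_indel_len=1) == [v]


class TestBuildAmpliconPair:
    @pytest.fixture
    def deletion(self):
        return Variant("A02", 5000, "ACCC", "A", "INDEL", 3, "hom")

    def test_products_conserve_indel_length(self, deletion):
        ctx, vi = variant_context(deletion, seed=1)
        pair = build_amplicon_pair(deletion, ctx, var_index=vi)
        assert len(pair.amp_rec) - len(pair.amp_don) == 3
        for amp in (pair.amp_rec, pair.amp_don):
            assert 130 <= len(amp) <= 260
            assert amp.startswith(pair.primer_fwd)
            assert amp.endswith(revcomp(pair.primer_rev))
        assert 18 <= len(pair.primer_fwd) <= 23
        assert 18 <= len(pair.primer_rev) <= 23
        assert pair.delta_tm >= 0

    def test_primers_outside_variant_make_identical_flanks(self, deletion):
        ctx, vi = variant_context(deletion, seed=1)
        pair = build_amplicon_pair(deletion, ctx, var_index=vi)
        assert pair.amp_don.startswith(pair.primer_fwd)
        assert pair.amp_don.endswith(revcomp(pair.primer_rev))

    def test_variant_too_close_to_edge_rejected(self, deletion):
        rng = np.random.default_rng(2)
        ctx = _rand_seq(rng, 12) + "ACCC" + _rand_seq(rng, 400)
        with pytest.raises(AmpliconRejection):
            build_amplicon_pair(deletion, ctx, var_index=12)

    def test_snp_input_is_an_error(self):
        snp = Variant("A02", 5000, "G", "C", "SNP", 0, "hom")
        with pytest.raises(ValueError, match="INDEL"):
            build_amplicon_pair(snp, "A" * 301, var_index=150)

    def test_short_context_is_an_error(self, deletion):
        with pytest.raises(ValueError, match="context"):
            build_amplicon_pair(deletion, "ACCC" + "A" * 50, var_index=0)


class TestPredictTm:
    def test_matches_brute_force_oracle_on_fixed_20mer(self):
        seq = "AGCTTGACCTGAAGTCCTAT"
        assert predict_tm(seq) == pytest.approx(tm_brute_force(seq), abs=1e-9)

    def test_matches_brute_force_oracle_on_1000_random_sequences(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            seq = _rand_seq(rng, int(rng.integers(15, 260)))
            assert predict_tm(seq) == pytest.approx(tm_brute_force(seq), abs=1e-9)

    def test_reverse_complement_symmetry_exact(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            seq = _rand_seq(rng, 60)
            assert predict_tm(seq) == predict_tm(revcomp(seq))

    def test_matches_independent_library_implementation(self):
        """Cross-check against Biopython's NN Tm at identical conditions."""
        from Bio.SeqUtils import MeltingTemp as mt

        rng = np.random.default_rng(5)
        for _ in range(200):
            seq = _rand_seq(rng, int(rng.integers(18, 120)))
            if seq == revcomp(seq):
                continue
            ref = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=1000, dnac1=125, dnac2=125,
                           saltcorr=0)
            assert predict_tm(seq) == pytest.approx(ref, abs=1e-8)

    def test_gc_substitution_raises_tm_in_at_run(self):
        base = "A" * 50
        assert predict_tm("A" * 24 + "G" + "A" * 25) > predict_tm(base)

    def test_gc_substitutions_raise_tm_almost_surely(self):
        rng = np.random.default_rng(6)
        diffs = []
        for _ in range(200):
            s = list(_rand_seq(rng, 100))
            idx = [i for i, c in enumerate(s) if c == "A"]
            if not idx:
                continue
            i = int(rng.choice(idx))
            t0 = predict_tm("".join(s))
            s[i] = "G"
            diffs.append(predict_tm("".join(s)) - t0)
        diffs = np.array(diffs)
        assert diffs.mean() > 0
        assert (diffs > 0).mean() > 0.95

    def test_input_validation(self):
        with pytest.raises(ValueError):
            predict_tm("A")
        with pytest.raises(ValueError):
            predict_tm("ACGTN")


class TestNNParameterTable:
    def test_bundled_table_complete_and_symmetric(self):
        t = NNParameterTable.unified()
        assert len(t.stacks) == 16
        for st, v in t.stacks.items():
            assert t.stacks[revcomp(st)] == v

    def test_asymmetric_table_rejected(self):
        t = NNParameterTable.unified()
        broken = dict(t.stacks)
        broken["AA"] = (-1.0, -1.0)  # revcomp TT keeps the old value
        with pytest.raises(ValueError):
            NNParameterTable(broken, t.init_at, t.init_gc, t.sym)


class TestScoreDeltaTm:
    def test_strict_threshold(self):
        v = Variant("A01", 10, "ATTT", "A", "INDEL", 3, "hom")

        def pair_with(dtm):
            from mabckit.marker_design import AmpliconPair

            return AmpliconPair(v, "A" * 18, "A" * 18, "A" * 130, "A" * 133,
                                80.0, 80.0 + dtm)

        assert score_delta_tm(pair_with(0.8)) == (True, pytest.approx(0.8))
        assert score_delta_tm(pair_with(0.5))[0] is False
        assert score_delta_tm(pair_with(0.0))[0] is False


def _uniform_candidates(gm, step_cm=0.5, delta=1.0):
    out = []
    for c in gm:
        n = int(c.gen_len / step_cm)
        for k in range(1, n):
            cm = k * step_cm
            bp = int(c.cm_to_bp(cm))
            v = Variant(c.name, bp, "ATTT", "A", "INDEL", 3, "hom")
            from mabckit.marker_design import AmpliconPair

            pair = AmpliconPair(v, "A" * 18, "A" * 18, "A" * 130, "A" * 133,
                                80.0, 80.0 + delta)
            out.append(Marker(f"c-{c.name}-{bp}", c.name, bp, cm, "HRM", pair))
    return out


@pytest.fixture(scope="module")
def gm():
    return brassica_rapa_map()


class TestSelectEvenPanel:
    def test_default_counts_give_131_markers(self, gm):
        panel = select_even_panel(_uniform_candidates(gm), gm)
        assert len(panel) == 131
        by = panel.by_chrom()
        assert {c: len(ms) for c, ms in by.items()} == DEFAULT_PANEL_COUNTS

    def test_even_spacing_bounds_max_gap(self, gm):
        panel = select_even_panel(_uniform_candidates(gm), gm)
        rep = density_report(panel, gm)
        for row in rep.itertuples(index=False):
            if row.chrom == "genome":
                continue
            width = row.gen_len / row.n_markers
            assert row.max_gap_cm <= 2 * width

    def test_single_candidate_per_bin_is_taken(self):
        gm = GenomeMap([ChromosomeMap("A01", 10_000_000, 100.0)])
        cands = _uniform_candidates(gm, step_cm=25.0)  # 3 candidates: 25, 50, 75
        panel = select_even_panel(cands, gm, {"A01": 3})
        assert sorted(m.pos_cm for m in panel) == [25.0, 50.0, 75.0]

    def test_empty_bin_steals_nearest_with_warning(self):
        gm = GenomeMap([ChromosomeMap("A01", 10_000_000, 100.0)])
        cands = [c for c in _uniform_candidates(gm, step_cm=5.0) if c.pos_cm < 50]
        with pytest.warns(UserWarning, match="no candidate in bin"):
            panel = select_even_panel(cands, gm, {"A01": 4})
        assert len(panel) == 4

    def test_insufficient_candidates_rejected(self):
        gm = GenomeMap([ChromosomeMap("A01", 10_000_000, 100.0)])
        with pytest.raises(ValueError, match="candidates"):
            select_even_panel(_uniform_candidates(gm, step_cm=40.0), gm, {"A01": 10})


class TestDensityReport:
    def test_chromosome_without_markers_rejected(self):
        gm = brassica_rapa_map()
        one = _uniform_candidates(gm)[:5]  # A01 only
        panel = MarkerPanel.from_markers(one)
        with pytest.raises(ValueError, match="no markers"):
            density_report(panel, gm)


class TestMarkerPanel:
    def test_unique_ids_enforced(self):
        m = Marker("x", "A01", 10, 0.1, "HRM")
        with pytest.raises(ValueError):
            MarkerPanel((m, m))

    def test_tsv_round_trip_positions(self, tmp_path):
        gm = brassica_rapa_map()
        panel = select_even_panel(_uniform_candidates(gm), gm)
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = MarkerPanel.from_tsv(path)
        assert [(m.id, m.chrom, m.pos_bp) for m in back] == [
            (m.id, m.chrom, m.pos_bp) for m in panel
        ]


class TestDesignChain:
    def test_all_retained_markers_satisfy_constraints(self, gmap, parents):
        _, _, variants = parents
        cands = design_hrm_candidates(variants, gmap, seed=9)
        assert len(cands) > 0
        for m in cands:
            p = m.amplicon
            assert 130 <= len(p.amp_rec) <= 260
            assert 130 <= len(p.amp_don) <= 260
            assert 18 <= len(p.primer_fwd) <= 23
            assert 18 <= len(p.primer_rev) <= 23
            assert p.delta_tm > 0.5
            assert p.variant.donor_zygosity == "hom"
            assert p.variant.indel_len >= 3


class TestTargetMarker:
    @pytest.fixture
    def kasp(self):
        locus = TargetLocus()
        rng = np.random.default_rng(10)
        ctx = _rand_seq(rng, 150) + "G" + _rand_seq(rng, 150)
        return design_target_marker(locus, ctx, 150)

    def test_allele_primers_end_on_the_snp(self, kasp):
        assert kasp.primer_dominant[-1] == "G"
        assert kasp.primer_recessive[-1] == "C"
        assert kasp.primer_dominant[:-1] == kasp.primer_recessive[:-1]
        assert 50 <= kasp.product_len <= 120

    @pytest.mark.parametrize(
        "signals,expected",
        [
            ({"FAM", "VIC"}, "Mm"),
            ({"FAM"}, "MM"),
            ({"VIC"}, "mm"),
            (set(), None),
        ],
    )
    def test_signal_decoding(self, kasp, signals, expected):
        assert kasp.genotype_call(signals) == expected

    def test_unknown_signal_rejected(self, kasp):
        with pytest.raises(ValueError):
            kasp.genotype_call({"ROX"})

    def test_context_must_carry_dominant_allele(self):
        locus = TargetLocus()
        with pytest.raises(ValueError):
            design_target_marker(locus, "A" * 301, 150)
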