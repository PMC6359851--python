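import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tfcoop.features import (DINUC_CLASSES, MONO_CLASSES, RATE_NAMES,
                             MotifModel, TrapParams, best_hit_score,
                             best_hit_scores, build_feature_matrix,
                             composition_matrix, composition_rates,
                             load_feature_matrix, parse_jaspar_pfm, pfm_to_pwm,
                             reverse_complement, save_feature_matrix,
                             trap_affinity, write_jaspar_pfm)
from tfcoop.synthetic import random_motif_library

from conftest import (brute_force_best_hit, brute_force_trap, random_motif,
                       random_sequence)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestJasparParsing:
    def test_bracketed_dialect(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M1 TFX\nA [1 0]\nC [0 1]\nG [0 0]\nT [0 0]\n")
        [m] = parse_jaspar_pfm(p)
        assert (m.motif_id, m.tf_name, m.width) == ("M1", "TFX", 2)
        assert np.array_equal(m.counts, [[1, 0, 0, 0], [0, 1, 0, 0]])

    def test_bare_matrix_dialect(self, tmp_path):
        p = tmp_path / "m.pfm"
        p.write_text(">M2\n3 1\n1 3\n0 0\n0 0\n")
        [m] = parse_jaspar_pfm(p)
        assert m.counts[0, 0] == 3 and m.counts[1, 1] == 3

    def test_multiple_records_order_preserved(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">A1 tf1\nA [1]\nC [1]\nG [1]\nT [1]\n"
                     ">B2 tf2\nA [2]\nC [2]\nG [2]\nT [2]\n")
        assert [m.motif_id for m in parse_jaspar_pfm(p)] == ["A1", "B2"]

    def test_wrong_row_count_names_motif(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M3 tf\nA [1]\nC [1]\nG [1]\n")
        with pytest.raises(ValueError, match="M3"):
            parse_jaspar_pfm(p)

    def test_unequal_row_width_names_motif(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(">M4 tf\nA [1 2]\nC [1]\nG [1 2]\nT [1 2]\n")
        with pytest.raises(ValueError, match="M4"):
            parse_jaspar_pfm(p)

    def test_round_trip(self, tmp_path, rng):
        motifs = random_motif_library(4, seed=3)
        write_jaspar_pfm(motifs, tmp_path / "lib.jaspar")
        again = parse_jaspar_pfm(tmp_path / "lib.jaspar")
        for a, b in zip(motifs, again):
            assert a.motif_id == b.motif_id
            assert np.allclose(a.counts, b.counts)


class TestPfmToPwm:
    def test_known_cell_value(self):
        # row (10,0,0,0), pseudocount 1, uniform: p_A = 10.25/11,
        # cell = log2((10.25/11)/0.25)
        pwm = pfm_to_pwm(np.array([[10, 0, 0, 0]]), pseudocount=1.0)
        assert pwm[0, 0] == pytest.approx(np.log2((10.25 / 11) / 0.25))
        assert pwm[0, 0] == pytest.approx(1.898, abs=1e-3)

    @pytest.mark.parametrize("pseudocount", [0.1, 0.8, 5.0])
    def test_uniform_row_scores_zero(self, pseudocount):
        pwm = pfm_to_pwm(np.array([[1, 1, 1, 1]]), pseudocount=pseudocount)
        assert np.allclose(pwm, 0.0)

    def test_background_proportional_counts_score_zero(self):
        bg = np.array([0.3, 0.2, 0.2, 0.3])
        pwm = pfm_to_pwm(np.array([[30, 20, 20, 30]]), 0.8, bg)
        assert np.allclose(pwm, 0.0)

    def test_zero_rowsum_rejected(self):
        with pytest.raises(ValueError, match="zero-sum"):
            pfm_to_pwm(np.array([[0, 0, 0, 0]]))


class TestBestHit:
    def test_single_position_enumeration(self):
        m = MotifModel("t", "m", np.array([[100, 0, 0, 0]], dtype=float))
        pwm = m.pwm()
        # the only A is at position 3 of CCAC
        assert best_hit_score("CCAC", m) == pytest.approx(pwm[0, 0])

    def test_reverse_strand_found(self, simple_motif):
        # consensus ACG planted only as reverse complement CGT
        fwd = best_hit_score("TTACGTT", simple_motif)
        rc_only = best_hit_score(reverse_complement("TTACGTT"), simple_motif)
        assert fwd == pytest.approx(rc_only)

    def test_sequence_shorter_than_motif_rejected(self, simple_motif):
        with pytest.raises(ValueError, match="shorter"):
            best_hit_score("AC", simple_motif)

    def test_all_n_falls_back_to_minimum_score(self, simple_motif):
        assert best_hit_score("NNNNN", simple_motif) == \
            pytest.approx(simple_motif.min_score())

    def test_matches_brute_force(self, rng):
        for _ in range(60):
            motif = random_motif(rng, int(rng.integers(1, 9)))
            seq = random_sequence(rng, int(rng.integers(motif.width, 50)))
            assert best_hit_score(seq, motif) == pytest.approx(
                brute_force_best_hit(seq, motif.pwm()), abs=1e-9)

    @given(seq=dna)
    @settings(max_examples=60, deadline=None)
    def test_strand_symmetry(self, seq):
        motif = MotifModel("TFX", "M1", np.array(
            [[97, 1, 1, 1], [1, 97, 1, 1], [1, 1, 97, 1]], dtype=float))
        if len(seq) < motif.width:
            return
        assert best_hit_score(seq, motif) == pytest.approx(
            best_hit_score(reverse_complement(seq), motif), abs=1e-9)


class TestTrap:
    def test_saturation_at_consensus_site(self, simple_motif):
        # with enormous R0 both strand sites of the best word saturate
        affinity = trap_affinity("ACG", simple_motif, TrapParams(r0=1e15))
        assert affinity == pytest.approx(2.0, abs=1e-4)

    def test_appending_consensus_never_decreases(self, rng, simple_motif):
        for _ in range(20):
            seq = random_sequence(rng, 30)
            a0 = trap_affinity(seq, simple_motif)
            a1 = trap_affinity(seq + simple_motif.consensus(), simple_motif)
            assert a1 >= a0

    def test_matches_direct_summation(self, rng):
        for _ in range(40):
            motif = random_motif(rng, int(rng.integers(2, 6)))
            seq = random_sequence(rng, int(rng.integers(motif.width, 40)))
            params = TrapParams()
            expected = brute_force_trap(seq, motif, params.lambda_trap,
                                        params.r0_for_width(motif.width))
            assert trap_affinity(seq, motif, params) == pytest.approx(
                expected, abs=1e-10)

    def test_bounded_by_site_count(self, rng):
        motif = random_motif(rng, 4)
        seq = random_sequence(rng, 30)
        assert trap_affinity(seq, motif) <= 2 * (30 - 4 + 1)

    def test_default_r0_follows_width_rule(self):
        assert TrapParams().r0_for_width(10) == pytest.approx(
            np.exp(0.584 * 10 - 5.66))


class TestComposition:
    def test_acgt_hand_count(self):
        r = composition_rates("ACGT")
        assert r["A|T"] == 0.5 and r["G|C"] == 0.5
        assert r["AC|GT"] == pytest.approx(0.5)   # AC at 1, GT at 3
        assert r["CG"] == pytest.approx(0.25)
        for name in set(DINUC_CLASSES) - {"AC|GT", "CG"}:
            assert r[name] == 0.0

    def test_aaaa_hand_count(self):
        r = composition_rates("AAAA")
        assert r["A|T"] == 1.0
        assert r["AA|TT"] == pytest.approx(0.75)
        assert sum(r[d] for d in DINUC_CLASSES) == pytest.approx(0.75)

    def test_exactly_twelve_classes(self):
        assert len(RATE_NAMES) == 12
        assert len(composition_rates("ACGTACGT")) == 12

    def test_rate_sums_without_n(self):
        r = composition_rates("ACGTTGCAAT")
        L = 10
        assert r["A|T"] + r["G|C"] == pytest.approx(1.0)
        assert sum(r[d] for d in DINUC_CLASSES) == pytest.approx((L - 1) / L)

    def test_n_excluded_from_counts_not_length(self):
        r = composition_rates("AANA")
        assert r["A|T"] == pytest.approx(3 / 4)
        assert r["AA|TT"] == pytest.approx(1 / 4)  # only the leading AA

    @given(seq=dna)
    @settings(max_examples=80, deadline=None)
    def test_reverse_complement_invariance(self, seq):
        assert composition_rates(seq) == pytest.approx(
            composition_rates(reverse_complement(seq)))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            composition_rates("")


class TestFeatureMatrix:
    def test_shape_and_column_order(self, rng):
        motifs = random_motif_library(5, width_range=(3, 5), seed=1)
        seqs = {f"s{i}": random_sequence(rng, 40) for i in range(3)}
        X = build_feature_matrix(seqs, motifs)
        assert X.shape == (3, 17)
        assert list(X.columns[:5]) == [m.motif_id for m in motifs]
        assert tuple(X.columns[5:]) == RATE_NAMES

    def test_full_library_column_count(self, rng):
        # the reference motif library holds 638 PWMs -> 650 predictors
        motifs = random_motif_library(638, width_range=(3, 4), seed=2)
        seqs = {"s": random_sequence(rng, 30)}
        X = build_feature_matrix(seqs, motifs)
        assert X.shape[1] == 650

    def test_duplicate_motif_ids_rejected(self, rng, simple_motif):
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_matrix({"s": "ACGTACGT"},
                                 [simple_motif, simple_motif])

    def test_trap_scorer_column_values(self, rng, simple_motif):
        X = build_feature_matrix({"s": "ACGACG"}, [simple_motif],
                                 scorer="trap")
        assert X.loc["s", "M1"] == pytest.approx(
            trap_affinity("ACGACG", simple_motif))

    def test_save_load_round_trip(self, tmp_path, rng, simple_motif):
        X = build_feature_matrix({"a": "ACGTACG", "b": "GGGACGT"},
                                 [simple_motif])
        save_feature_matrix(X, tmp_path / "X.tsv")
        again = load_feature_matrix(tmp_path / "X.tsv")
        assert list(again.columns) == list(X.columns)
        assert np.allclose(again.to_numpy(), X.to_numpy())
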