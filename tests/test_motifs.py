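"""PPM/PWM construction, exact p-values, scanning and the composite search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from zfrec._seq import revcomp
from zfrec import motifs as mz
from zfrec.simulate import GenomePlant, plant_genome, random_sequence


@pytest.fixture(scope="module")
def small_ppm():
    return mz.build_ppm(
        ["ACGTA", "ACGTT", "ACGAA", "CCGTA", "ACGTC", "ACTTA"], pseudocount=0.1
    )


@pytest.fixture(scope="module")
def small_pwm(small_ppm):
    return mz.ppm_to_pwm(small_ppm)


def exhaustive_pvalue(pwm: mz.Pwm, score: float) -> float:
    """Oracle: exact tail probability by enumerating all 4^w words."""
    total = 0.0
    for word in itertools.product("ACGT", repeat=pwm.width):
        w = "".join(word)
        if pwm.score(w) >= score:
            prob = 1.0
            for b in w:
                prob *= pwm.background["ACGT".index(b)]
            total += prob
    return total


class TestPpm:
    def test_single_sequence_one_hot(self):
        ppm = mz.build_ppm(["ACGT"], pseudocount=0.0)
        assert np.allclose(ppm.matrix, np.eye(4))

    def test_pseudocount_arithmetic(self):
        ppm = mz.build_ppm(["A"], pseudocount=1.0)
        assert np.allclose(ppm.matrix[0], [2 / 5, 1 / 5, 1 / 5, 1 / 5])

    def test_columns_sum_to_one(self, small_ppm):
        assert np.allclose(small_ppm.matrix.sum(axis=1), 1.0, atol=1e-9)

    def test_ragged_input_rejected(self):
        with pytest.raises(ValueError):
            mz.build_ppm(["ACGT", "ACG"])


class TestPwm:
    def test_uniform_ppm_gives_zero_pwm(self):
        ppm = mz.Ppm(matrix=np.full((3, 4), 0.25))
        pwm = mz.ppm_to_pwm(ppm)
        assert np.allclose(pwm.matrix, 0.0)

    def test_certain_base_scores_log2_4(self):
        ppm = mz.build_ppm(["A"] * 100, pseudocount=0.0001)
        pwm = mz.ppm_to_pwm(ppm)
        assert pwm.matrix[0, 0] == pytest.approx(2.0, abs=1e-2)

    def test_min_max_scores_are_column_extrema_sums(self, small_pwm):
        assert small_pwm.min_score == pytest.approx(small_pwm.matrix.min(axis=1).sum())
        assert small_pwm.max_score == pytest.approx(small_pwm.matrix.max(axis=1).sum())

    def test_max_score_is_consensus_score(self, small_ppm, small_pwm):
        assert small_pwm.score(small_ppm.consensus) == pytest.approx(small_pwm.max_score)

    def test_zero_probability_rejected(self):
        ppm = mz.build_ppm(["ACGT"], pseudocount=0.0)
        with pytest.raises(ValueError):
            mz.ppm_to_pwm(ppm)


class TestPvalue:
    def test_min_score_has_pvalue_one(self, small_pwm):
        assert mz.pwm_pvalue(small_pwm, small_pwm.min_score) == 1.0

    def test_width1_uniform_quarter(self):
        ppm = mz.build_ppm(["A"] * 50, pseudocount=0.1)
        pwm = mz.ppm_to_pwm(ppm)
        # unique maximum attained by exactly 1 of the 4 bases
        assert mz.pwm_pvalue(pwm, pwm.max_score) == pytest.approx(0.25)

    @pytest.mark.parametrize("width", [2, 4, 6, 8])
    def test_dp_equals_enumeration(self, width):
        rng = np.random.default_rng(width)
        sites = ["".join("ACGT"[i] for i in rng.integers(0, 4, width)) for _ in range(8)]
        pwm = mz.ppm_to_pwm(mz.build_ppm(sites, pseudocount=0.25))
        bin_width = 0.001
        tol = pwm.width * bin_width  # discretization error bound
        for q in (0.0, 0.3, 0.6, 0.9, 1.0):
            score = pwm.min_score + q * (pwm.max_score - pwm.min_score)
            dp = mz.pwm_pvalue(pwm, score, bin_width)
            lo = exhaustive_pvalue(pwm, score + tol)
            hi = exhaustive_pvalue(pwm, score - tol)
            assert lo - 1e-12 <= dp <= hi + 1e-12

    def test_monotone_non_increasing(self, small_pwm):
        grid = np.linspace(small_pwm.min_score, small_pwm.max_score, 50)
        ps = [mz.pwm_pvalue(small_pwm, s) for s in grid]
        assert all(a >= b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_nonuniform_background(self):
        bg = np.array([0.4, 0.1, 0.1, 0.4])
        rng = np.random.default_rng(9)
        sites = ["".join("ACGT"[i] for i in rng.integers(0, 4, 5)) for _ in range(6)]
        pwm = mz.ppm_to_pwm(mz.build_ppm(sites, pseudocount=0.2), bg)
        score = 0.5 * (pwm.min_score + pwm.max_score)
        tol = pwm.width * 0.001
        dp = mz.pwm_pvalue(pwm, score)
        lo = exhaustive_pvalue(pwm, score + tol)
        hi = exhaustive_pvalue(pwm, score - tol)
        assert lo - 1e-12 <= dp <= hi + 1e-12


class TestScan:
    def test_planted_consensus_found_forward(self, small_ppm, small_pwm):
        bg = random_sequence(400, np.random.default_rng(1))
        seq = bg[:200] + small_ppm.consensus + bg[200:]
        hits = mz.scan_sequence(small_pwm, seq, p_threshold=0.002)
        assert any(h.start == 200 and h.strand == "+" for h in hits)

    def test_planted_reverse_complement_found_on_minus(self, small_ppm, small_pwm):
        bg = random_sequence(400, np.random.default_rng(2))
        seq = bg[:150] + revcomp(small_ppm.consensus) + bg[150:]
        hits = mz.scan_sequence(small_pwm, seq, p_threshold=0.002)
        assert any(h.start == 150 and h.strand == "-" for h in hits)

    def test_threshold_monotonicity(self, small_pwm):
        seq = random_sequence(3000, np.random.default_rng(3))
        loose = {(h.start, h.strand) for h in mz.scan_sequence(small_pwm, seq, 0.05)}
        tight = {(h.start, h.strand) for h in mz.scan_sequence(small_pwm, seq, 0.005)}
        assert tight <= loose

    def test_non_acgt_windows_skipped(self, small_pwm):
        seq = "N" * 10 + "ACGTA" + "N" * 10
        hits = mz.scan_sequence(small_pwm, seq, p_threshold=1.0)
        assert all("N" not in seq[h.start : h.end] for h in hits)

    def test_strand_mirror_symmetry(self, small_pwm):
        seq = random_sequence(800, np.random.default_rng(4))
        fwd = mz.scan_sequence(small_pwm, seq, 0.01)
        rev = mz.scan_sequence(small_pwm, revcomp(seq), 0.01)
        w = small_pwm.width
        mirrored = {(len(seq) - h.end, {"+": "-", "-": "+"}[h.strand]) for h in rev}
        assert {(h.start, h.strand) for h in fwd} == mirrored

    def test_false_positive_rate_matches_binomial_expectation(self, small_pwm):
        # uniform random sequence: expected hit count per scanned window equals
        # the realized tail probability at the p<=threshold cutoff
        seq = random_sequence(100_000, np.random.default_rng(5))
        p_threshold = 1e-3
        hits = mz.scan_sequence(small_pwm, seq, p_threshold)
        sf, offset, _ = mz._score_distribution(small_pwm, 0.001)
        passing = sf[sf <= p_threshold]
        p_star = float(passing.max()) if passing.size else 0.0
        n_windows = 2 * (len(seq) - small_pwm.width + 1)
        expected = n_windows * p_star
        sd = np.sqrt(n_windows * p_star * (1 - p_star))
        assert abs(len(hits) - expected) <= 3 * sd


@pytest.fixture(scope="module")
def halves():
    rng = np.random.default_rng(6)
    left_sites = ["".join("ACGT"[i] for i in rng.integers(0, 4, 13)) for _ in range(6)]
    right_sites = ["".join("ACGT"[i] for i in rng.integers(0, 4, 13)) for _ in range(6)]
    return mz.build_ppm(left_sites, 0.1), mz.build_ppm(right_sites, 0.1)


class TestCompositeScan:
    def test_composite_width_is_34_for_13_8_13(self, halves):
        left, right = halves
        assert left.width + 8 + right.width == 34

    def test_planted_composite_recovered(self, halves):
        left, right = halves
        rng = np.random.default_rng(7)
        spacer = random_sequence(8, rng)
        composite = left.consensus + spacer + right.consensus
        bg = random_sequence(10_000, rng)
        seq = bg[:5000] + composite + bg[5000:]
        hits = mz.scan_lox_candidates(left, right, 8, seq, p_threshold=0.001)
        assert any(h.start == 5000 and h.strand == "+" for h in hits)

    def test_off_by_one_spacer_not_reported(self, halves):
        left, right = halves
        rng = np.random.default_rng(8)
        composite = left.consensus + random_sequence(7, rng) + right.consensus
        bg = random_sequence(5000, rng)
        seq = bg[:2500] + composite + bg[2500:]
        hits = mz.scan_lox_candidates(left, right, 8, seq, p_threshold=0.001)
        assert not any(h.start == 2500 for h in hits)

    def test_minus_strand_composite(self, halves):
        left, right = halves
        rng = np.random.default_rng(9)
        composite = left.consensus + random_sequence(8, rng) + right.consensus
        bg = random_sequence(4000, rng)
        seq = bg[:2000] + revcomp(composite) + bg[2000:]
        hits = mz.scan_lox_candidates(left, right, 8, seq, p_threshold=0.001)
        assert any(h.start == 2000 and h.strand == "-" for h in hits)


@pytest.fixture(scope="module")
def setup():
    lox = "ATAACTTCGTATAGCATACATTATACGAAGTTAT"
    left_ppm = mz.build_ppm([lox[:13]] * 4, 0.1)
    right_ppm = mz.build_ppm([lox[21:]] * 4, 0.1)
    zf_up = mz.build_ppm(["GCAATGAAT"] * 4, 0.1)
    zf_down = mz.build_ppm(["CAAGATTGG"] * 4, 0.1)
    return lox, left_ppm, right_ppm, zf_up, zf_down


class TestFlankConstrainedScan:
    def _scan(self, genome, setup, distance_range=(4, 6)):
        lox, left_ppm, right_ppm, zf_up, zf_down = setup
        lox_hits = mz.scan_lox_candidates(left_ppm, right_ppm, 8, genome, 0.001)
        return mz.flank_constrained_scan(
            lox_hits,
            mz.ppm_to_pwm(zf_up),
            mz.ppm_to_pwm(zf_down),
            genome,
            distance_range=distance_range,
        )

    def test_both_flanks_detected(self, setup):
        lox, *_ , = setup
        plant = GenomePlant(lox, "GCAATGAAT", "CAAGATTGG", upstream_gap=5, downstream_gap=4,
                            position=2000)
        genome, truth = plant_genome(6000, [plant], seed=11)
        hits = self._scan(genome, setup)
        assert len(hits) == 1
        h = hits[0]
        assert h.sides is mz.FlankSides.BOTH
        assert h.left_distance == 5 and h.right_distance == 4
        assert h.lox.start == truth.iloc[0].lox_start

    def test_upstream_only_gives_left_side(self, setup):
        lox, *_ = setup
        plant = GenomePlant(lox, upstream_motif="GCAATGAAT", downstream_motif=None,
                            upstream_gap=5, position=1500)
        genome, _ = plant_genome(4000, [plant], seed=12)
        hits = self._scan(genome, setup)
        assert len(hits) == 1 and hits[0].sides is mz.FlankSides.LEFT

    def test_gap_7_outside_range_not_reported(self, setup):
        lox, *_ = setup
        plant = GenomePlant(lox, "GCAATGAAT", "CAAGATTGG", upstream_gap=7, downstream_gap=7,
                            position=1500)
        genome, _ = plant_genome(4000, [plant], seed=13)
        assert self._scan(genome, setup) == []

    def test_wrong_strand_flank_not_reported(self, setup):
        lox, *_ = setup
        # upstream motif on the forward strand violates the strand convention
        plant = GenomePlant(lox, upstream_motif="GCAATGAAT", upstream_gap=5,
                            upstream_strand="+", position=1500)
        genome, _ = plant_genome(4000, [plant], seed=14)
        assert self._scan(genome, setup) == []

    def test_minus_strand_lox_with_flanks(self, setup):
        lox, left_ppm, right_ppm, zf_up, zf_down = setup
        rng = np.random.default_rng(15)
        block = (
            revcomp("GCAATGAAT") + "C" * 5 + lox + "A" * 4 + "CAAGATTGG"
        )
        bg = random_sequence(4000, rng)
        genome = bg[:1500] + revcomp(block) + bg[1500:]
        hits = self._scan(genome, setup)
        assert len(hits) == 1
        assert hits[0].lox.strand == "-"
        assert hits[0].sides is mz.FlankSides.BOTH

    def test_inverted_distance_range_rejected(self, setup):
        with pytest.raises(ValueError):
            self._scan("ACGT" * 100, setup, distance_range=(6, 4))


class TestCloneTally:
    def test_identical_clones_all_zero(self):
        table = mz.tally_clone_mutations(["MKRA"] * 10, "MKRA")
        assert table.mutated_counts.sum() == 0

    def test_single_substitution_frequency(self):
        clones = ["MKRA"] * 9 + ["MKRG"]
        table = mz.tally_clone_mutations(clones, "MKRA")
        assert table.frequencies[3] == pytest.approx(0.1)
        assert table.distinct_residues[3] == {"G"}

    def test_distinct_residue_count(self):
        clones = ["MKRG", "MKRV", "MKRA"]
        table = mz.tally_clone_mutations(clones, "MKRA")
        assert len(table.distinct_residues[3]) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            mz.tally_clone_mutations(["MKR"], "MKRA")


class TestMemeRoundTrip:
    def test_write_read_round_trip(self, small_ppm, tmp_path):
        path = tmp_path / "motifs.meme"
        mz.write_meme(path, {"zf_test": small_ppm})
        back = mz.read_meme(path)
        assert set(back) == {"zf_test"}
        assert np.allclose(back["zf_test"].matrix, small_ppm.matrix, atol=1e-5)
        assert back["zf_test"].n_sequences == small_ppm.n_sequences


class TestProperties:
    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15)
    def test_word_scores_within_bounds(self, seed):
        rng = np.random.default_rng(seed)
        sites = ["".join("ACGT"[i] for i in rng.integers(0, 4, 6)) for _ in range(5)]
        pwm = mz.ppm_to_pwm(mz.build_ppm(sites, 0.1))
        word = "".join("ACGT"[i] for i in rng.integers(0, 4, 6))
        s = pwm.score(word)
        assert pwm.min_score - 1e-9 <= s <= pwm.max_score + 1e-9
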