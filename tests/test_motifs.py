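import numpy as np
import pytest

from zicreg.core import GenomicInterval, PeakCall, ValidationError
from zicreg.motifs import (
    CalibratedThreshold,
    MotifHit,
    Pwm,
    background_hit_rate,
    calibrate_threshold,
    cooccurrence,
    decode,
    detection_rate,
    encode,
    sample_from_pwm,
    scan_peaks,
    score_best_match,
)

from oracles import brute_best_score, brute_cooccurrence


def random_pwm(rng, length=6):
    probs = rng.dirichlet(np.ones(4), size=length)
    return Pwm(probs, name="rand")


class TestPwm:
    def test_columns_must_sum_to_one(self):
        with pytest.raises(ValidationError):
            Pwm(np.full((5, 4), 0.3))

    def test_consensus_and_length(self):
        pwm = Pwm.from_consensus("ACGTAC", dominance=0.9)
        assert pwm.consensus == "ACGTAC"
        assert pwm.length == 6

    def test_probabilities_strictly_positive_after_pseudocount(self):
        probs = np.zeros((4, 4))
        probs[:, 0] = 1.0
        pwm = Pwm(probs)
        assert (pwm.probs > 0).all()


class TestScoring:
    def test_consensus_sequence_attains_maximum(self):
        pwm = Pwm.from_consensus("CCAGCA", dominance=0.97)
        max_score = float(np.log2(pwm.probs.max(axis=1) / 0.25).sum())
        assert score_best_match(pwm, "CCAGCA") == pytest.approx(max_score)

    def test_strand_symmetry(self, rng):
        pwm = random_pwm(rng, length=7)
        seq = decode(rng.integers(0, 4, size=50).astype(np.int8))
        rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert score_best_match(pwm, seq) == pytest.approx(score_best_match(pwm, rc))

    def test_too_short_sequence_is_error(self):
        pwm = Pwm.from_consensus("ACGTA")
        with pytest.raises(ValidationError):
            score_best_match(pwm, "ACG")

    def test_n_bases_score_as_background(self):
        pwm = Pwm.from_consensus("ACGT", dominance=0.9)
        assert score_best_match(pwm, "NNNN") == pytest.approx(0.0)

    def test_matches_exhaustive_enumeration_oracle(self, rng):
        """Vectorized best-match equals a pure-python offset/strand scan."""
        for _ in range(500):
            pwm = random_pwm(rng, length=int(rng.integers(4, 9)))
            seq = decode(
                np.where(
                    rng.random(40) < 0.05, -1, rng.integers(0, 4, size=40)
                ).astype(np.int8)
            )
            expected = brute_best_score(pwm.probs, pwm.background, seq)
            assert score_best_match(pwm, seq) == pytest.approx(expected)


class TestSampling:
    def test_degenerate_columns_give_identical_sequences(self):
        probs = np.zeros((5, 4))
        probs[:, 0] = 1.0
        pwm = Pwm(probs, pseudocount=0.0)
        samples = sample_from_pwm(pwm, 20, rng=1)
        assert (samples == 0).all()

    def test_per_position_frequencies_match_columns(self):
        pwm = Pwm(np.full((6, 4), 0.25))
        samples = sample_from_pwm(pwm, 10_000, rng=2)
        freqs = np.stack([(samples == b).mean(axis=0) for b in range(4)], axis=1)
        sigma = 3 * np.sqrt(0.25 * 0.75 / 10_000)
        assert np.abs(freqs - 0.25).max() < sigma

    def test_same_seed_reproduces_sample(self):
        pwm = Pwm.from_consensus("ACGTAC")
        a = sample_from_pwm(pwm, 100, rng=5)
        b = sample_from_pwm(pwm, 100, rng=5)
        np.testing.assert_array_equal(a, b)


class TestCalibration:
    def test_threshold_equals_direct_quantile(self):
        """Calibrated threshold equals the empirical 15th percentile of the
        same seeded sample's scores (type-1 / lower quantile)."""
        import zicreg
        from zicreg.motifs import _sample_scores

        pwm = zicreg.zic3_consensus_pwm()
        cal = calibrate_threshold(pwm, n=2000, target_rate=0.85, seed=3)
        scores = np.sort(
            _sample_scores(pwm, sample_from_pwm(pwm, 2000, np.random.default_rng(3)))
        )
        k = 2000 - int(np.ceil(0.85 * 2000))
        assert cal.threshold == pytest.approx(float(scores[k]))
        assert np.mean(scores >= cal.threshold) >= 0.85

    @pytest.mark.parametrize("target", [0.5, 0.85, 0.95])
    def test_out_of_sample_detection_near_target(self, target, rng):
        """Fresh cohorts are detected at the calibration target within
        3-sigma binomial error plus the tie mass at the threshold.

        PWM sampling yields a discrete score law; when the quantile falls
        inside a tie atom, "score >= threshold" captures the whole atom, so
        detection can exceed the target by at most that atom's mass."""
        import zicreg
        from zicreg.motifs import _sample_scores

        for pwm in (zicreg.zic3_consensus_pwm(), random_pwm(rng, 8)):
            n = 10_000
            cal = calibrate_threshold(pwm, n=n, target_rate=target, seed=11)
            out = detection_rate(pwm, cal.threshold, n, rng=12)
            scores = _sample_scores(
                pwm, sample_from_pwm(pwm, n, np.random.default_rng(11))
            )
            # near-ties split by float summation order belong to the atom
            atom = float(np.mean(np.abs(scores - cal.threshold) <= 1e-9))
            sigma3 = 3 * np.sqrt(target * (1 - target) / n)
            atom_sigma3 = 3 * np.sqrt(max(atom, 1e-4) * (1 - atom) / n)
            assert -(sigma3 + 2 / n) <= out - target <= atom + atom_sigma3 + sigma3

    def test_degenerate_pwm_detects_everything_with_warning(self, caplog):
        probs = np.zeros((5, 4))
        probs[:, 2] = 1.0
        pwm = Pwm(probs, pseudocount=0.0)
        with caplog.at_level("WARNING"):
            cal = calibrate_threshold(pwm, n=500, seed=0)
        assert cal.calibration_detection_rate == 1.0
        assert any("degenerate" in r.message for r in caplog.records)

    def test_invalid_target_rate(self):
        pwm = Pwm.from_consensus("ACGTA")
        with pytest.raises(ValidationError):
            calibrate_threshold(pwm, target_rate=1.0)


def _toy_genome_with_peaks(motif, positions, length=20_000):
    rng = np.random.default_rng(99)
    seq = list(decode(rng.integers(0, 4, size=length).astype(np.int8)))
    peaks = []
    for i, (summit, offset) in enumerate(positions):
        if offset is not None:
            start = summit + offset
            seq[start : start + len(motif)] = list(motif)
        peaks.append(
            PeakCall(
                f"p{i}",
                GenomicInterval("chr1", max(0, summit - 500), summit + 500),
                summit,
                1.0,
                "s",
            )
        )
    return {"chr1": "".join(seq)}, peaks


class TestScanPeaks:
    def setup_method(self):
        import zicreg

        self.pwm = zicreg.zic3_consensus_pwm()
        self.threshold = calibrate_threshold(self.pwm, n=2000, seed=1).threshold

    def test_planted_motifs_all_detected(self):
        genome, peaks = _toy_genome_with_peaks(
            self.pwm.consensus, [(2000, -100), (6000, 0), (10_000, 250)]
        )
        hits, frac = scan_peaks(self.pwm, self.threshold, peaks, genome)
        assert frac == 1.0
        offsets = {h.peak_id: [x.offset for x in hits if x.peak_id == h.peak_id] for h in hits}
        assert -100 in offsets["p0"] and 0 in offsets["p1"] and 250 in offsets["p2"]

    def test_offset_at_minus_400_is_included(self):
        """A motif starting exactly at summit - 400 lies inside the
        half-open scan window (inclusive lower bound)."""
        genome, peaks = _toy_genome_with_peaks(self.pwm.consensus, [(3000, -400)])
        hits, frac = scan_peaks(self.pwm, self.threshold, peaks, genome)
        assert any(h.offset == -400 for h in hits)

    def test_threshold_monotonicity(self):
        genome, peaks = _toy_genome_with_peaks(
            self.pwm.consensus, [(2000 + 1000 * i, -50 if i % 2 else None) for i in range(10)]
        )
        _, frac_low = scan_peaks(self.pwm, self.threshold - 2, peaks, genome)
        _, frac_high = scan_peaks(self.pwm, self.threshold + 2, peaks, genome)
        assert frac_high <= frac_low

    def test_half_window_monotonicity(self):
        genome, peaks = _toy_genome_with_peaks(self.pwm.consensus, [(3000, -390)])
        _, frac_narrow = scan_peaks(
            self.pwm, self.threshold, peaks, genome, half_window=100
        )
        _, frac_wide = scan_peaks(
            self.pwm, self.threshold, peaks, genome, half_window=400
        )
        assert frac_narrow <= frac_wide

    def test_window_truncated_at_chromosome_start(self):
        genome, peaks = _toy_genome_with_peaks(self.pwm.consensus, [(450, 100)])
        hits, frac = scan_peaks(self.pwm, self.threshold, peaks, genome)
        assert frac == 1.0


class TestCooccurrence:
    def test_same_offset_pairs_give_one(self):
        a = [MotifHit("p1", 10, "+", 5.0), MotifHit("p2", -20, "+", 5.0)]
        b = [MotifHit("p1", 10, "+", 4.0), MotifHit("p2", -20, "-", 4.0)]
        assert cooccurrence(a, b, adjacency=250) == 1.0

    def test_disjoint_peak_sets_give_zero(self):
        a = [MotifHit("p1", 0, "+", 5.0)]
        b = [MotifHit("p2", 0, "+", 4.0)]
        assert cooccurrence(a, b, adjacency=250) == 0.0

    def test_no_b_hits_is_error(self):
        with pytest.raises(ValidationError, match="B-bearing"):
            cooccurrence([MotifHit("p1", 0, "+", 1.0)], [], adjacency=100)

    def test_matches_pair_enumeration_oracle(self, rng):
        for _ in range(500):
            n_peaks = int(rng.integers(1, 8))
            ids = [f"p{i}" for i in range(n_peaks)]
            a = [
                MotifHit(ids[int(rng.integers(n_peaks))], int(rng.integers(-400, 400)), "+", 1.0)
                for _ in range(int(rng.integers(0, 10)))
            ]
            b = [
                MotifHit(ids[int(rng.integers(n_peaks))], int(rng.integers(-400, 400)), "+", 1.0)
                for _ in range(int(rng.integers(1, 10)))
            ]
            adj = int(rng.integers(0, 300))
            expected = brute_cooccurrence(
                [(h.peak_id, h.offset) for h in a],
                [(h.peak_id, h.offset) for h in b],
                adj,
            )
            assert cooccurrence(a, b, adjacency=adj) == pytest.approx(expected)
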