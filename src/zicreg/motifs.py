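"""Position weight matrices: scoring, simulation-calibrated thresholds,
summit-window scanning, and motif co-occurrence.

The match score is the standard log2 odds of the PWM against a background
base distribution, maximized over offsets and both strands.  The detection
threshold is not fixed a priori: it is calibrated by sampling sequences
from the PWM's own columns and taking the score quantile at which a target
fraction (default 85%) of that cohort is recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import ceil
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import PeakCall, ValidationError

log = logging.getLogger(__name__)

BASES = "ACGT"
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes; N and other letters become -1."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return "".join(BASES[c] if c >= 0 else "N" for c in codes)


class Pwm:
    """A column-stochastic position weight matrix over {A, C, G, T}.

    Input columns must each sum to 1 (tolerance 1e-9).  A pseudocount mass
    is mixed in (``p' = (p + c*bg) / (1 + c)``) so every probability is
    strictly positive and log-odds are finite.
    """

    def __init__(
        self,
        probs,
        name: str = "pwm",
        pseudocount: float = 1e-3,
        background: Optional[Sequence[float]] = None,
    ):
        probs = np.asarray(probs, dtype=np.float64)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValidationError("PWM must have shape (length, 4)")
        if probs.shape[0] < 4:
            raise ValidationError("PWM length must be >= 4")
        if np.any(probs < 0):
            raise ValidationError("PWM probabilities must be >= 0")
        sums = probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError("PWM columns must each sum to 1 (tol 1e-9)")
        if background is None:
            background = np.full(4, 0.25)
        background = np.asarray(background, dtype=np.float64)
        if abs(background.sum() - 1.0) > 1e-9 or np.any(background <= 0):
            raise ValidationError("background must be a positive distribution")
        self.name = name
        self.pseudocount = float(pseudocount)
        self.background = background
        self.raw_probs = probs
        self.probs = (probs + self.pseudocount * background) / (1 + self.pseudocount)
        with np.errstate(divide="ignore"):  # -inf allowed when pseudocount=0
            self.log_odds = np.log2(self.probs / background)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))

    def reverse_complement_log_odds(self) -> np.ndarray:
        return self.log_odds[::-1, ::-1]

    @classmethod
    def from_consensus(
        cls,
        consensus: str,
        dominance: float = 0.85,
        name: str = "consensus",
        **kwargs,
    ) -> "Pwm":
        """A PWM putting ``dominance`` mass on each consensus base."""
        probs = np.full((len(consensus), 4), (1 - dominance) / 3)
        codes = encode(consensus)
        if np.any(codes < 0):
            raise ValidationError("consensus must be over ACGT")
        probs[np.arange(len(consensus)), codes] = dominance
        return cls(probs, name=name, **kwargs)


def _offset_scores(log_odds: np.ndarray, codes: np.ndarray) -> np.ndarray:
    """Score of the motif at every offset of one strand; N bases score 0."""
    L = log_odds.shape[0]
    windows = sliding_window_view(codes, L)
    mask = windows >= 0
    idx = np.where(mask, windows, 0)
    per_pos = log_odds[np.arange(L)[None, :], idx]
    return np.where(mask, per_pos, 0.0).sum(axis=1)


def score_best_match(pwm: Pwm, sequence: str) -> float:
    """Best log-odds match score over all offsets and both strands."""
    codes = encode(sequence)
    if codes.size < pwm.length:
        raise ValidationError(
            f"sequence length {codes.size} < motif length {pwm.length}"
        )
    fwd = _offset_scores(pwm.log_odds, codes)
    rev = _offset_scores(pwm.reverse_complement_log_odds(), codes)
    return float(max(fwd.max(), rev.max()))


def scan_sequence(
    pwm: Pwm, threshold: float, sequence: str
) -> list[tuple[int, str, float]]:
    """All (position, strand, score) with score >= threshold, both strands.

    Positions index the motif's leftmost base on the forward strand.
    """
    codes = encode(sequence)
    if codes.size < pwm.length:
        return []
    hits = []
    for strand, lom in (
        ("+", pwm.log_odds),
        ("-", pwm.reverse_complement_log_odds()),
    ):
        scores = _offset_scores(lom, codes)
        for pos in np.flatnonzero(scores >= threshold):
            hits.append((int(pos), strand, float(scores[pos])))
    hits.sort()
    return hits


# ---------------------------------------------------------------------------
# Calibration

@dataclass(frozen=True)
class CalibratedThreshold:
    """A match threshold tuned so ~target_rate of PWM draws are detected."""

    pwm_name: str
    threshold: float
    target_rate: float
    n_samples: int
    seed: Optional[int]
    calibration_detection_rate: float


def sample_from_pwm(pwm: Pwm, n: int, rng) -> np.ndarray:
    """Sample n sequences (as an (n, L) code array), column-independently."""
    rng = np.random.default_rng(rng)
    cols = [
        rng.choice(4, size=n, p=pwm.probs[i] / pwm.probs[i].sum())
        for i in range(pwm.length)
    ]
    return np.stack(cols, axis=1).astype(np.int8)


def _sample_scores(pwm: Pwm, samples: np.ndarray) -> np.ndarray:
    """Best-match score of each motif-length sample (both strands)."""
    idx = np.arange(pwm.length)
    fwd = pwm.log_odds[idx, samples].sum(axis=1)
    rev = pwm.reverse_complement_log_odds()[idx, samples].sum(axis=1)
    return np.maximum(fwd, rev)


def calibrate_threshold(
    pwm: Pwm,
    n: int = 10000,
    target_rate: float = 0.85,
    seed: Optional[int] = None,
    rng=None,
) -> CalibratedThreshold:
    """Calibrate a match threshold by simulation.

    n sequences are sampled from the PWM columns; the threshold is the
    lower empirical (1 - target_rate) quantile of their best-match scores,
    so at least ``ceil(target_rate * n)`` of the calibration cohort scores
    at or above it.
    """
    if not 0 < target_rate < 1:
        raise ValidationError("target_rate must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    scores = np.sort(_sample_scores(pwm, sample_from_pwm(pwm, n, rng)))
    if scores[0] == scores[-1]:
        log.warning(
            "PWM %s is degenerate: all calibration scores equal %.4g; "
            "detection rate is 1.0",
            pwm.name,
            scores[0],
        )
        return CalibratedThreshold(pwm.name, float(scores[0]), target_rate, n, seed, 1.0)
    k = n - ceil(target_rate * n)
    threshold = float(scores[k])
    detection = float(np.mean(scores >= threshold))
    return CalibratedThreshold(pwm.name, threshold, target_rate, n, seed, detection)


def detection_rate(pwm: Pwm, threshold: float, n: int, rng) -> float:
    """Fraction of a fresh PWM-sampled cohort scoring >= threshold."""
    rng = np.random.default_rng(rng)
    return float(np.mean(_sample_scores(pwm, sample_from_pwm(pwm, n, rng)) >= threshold))


def background_hit_rate(
    pwm: Pwm,
    threshold: float,
    window_length: int = 800,
    n: int = 1000,
    rng=None,
) -> float:
    """Chance rate: fraction of random background windows with >= 1 hit."""
    rng = np.random.default_rng(rng)
    seqs = rng.choice(4, size=(n, window_length), p=pwm.background).astype(np.int8)
    rc = pwm.reverse_complement_log_odds()
    hits = 0
    for row in seqs:
        if _offset_scores(pwm.log_odds, row).max() >= threshold:
            hits += 1
        elif _offset_scores(rc, row).max() >= threshold:
            hits += 1
    return hits / n


# ---------------------------------------------------------------------------
# Peak scanning

@dataclass(frozen=True)
class MotifHit:
    """One above-threshold PWM match near a peak summit.

    ``offset`` is the motif's leftmost base minus the summit coordinate.
    """

    peak_id: str
    offset: int
    strand: str
    score: float


def scan_peaks(
    pwm: Pwm,
    threshold: float,
    peaks: Iterable[PeakCall],
    genome: dict[str, str],
    half_window: int = 400,
) -> tuple[list[MotifHit], float]:
    """Scan [summit - half_window, summit + half_window) around every peak.

    Returns all hits on both strands plus the fraction of peaks with at
    least one hit.  Windows running off a chromosome end are truncated.
    """
    peaks = list(peaks)
    if not peaks:
        raise ValidationError("no peaks to scan")
    hits: list[MotifHit] = []
    n_with_hit = 0
    for p in peaks:
        seq = genome[p.chrom]
        lo = p.summit - half_window
        hi = p.summit + half_window
        if lo < 0 or hi > len(seq):
            log.info("peak %s: scan window truncated to chromosome", p.peak_id)
            lo, hi = max(0, lo), min(len(seq), hi)
        found = scan_sequence(pwm, threshold, seq[lo:hi])
        if found:
            n_with_hit += 1
        hits.extend(
            MotifHit(p.peak_id, lo + pos - p.summit, strand, score)
            for pos, strand, score in found
        )
    return hits, n_with_hit / len(peaks)


def cooccurrence(
    hits_a: Iterable[MotifHit],
    hits_b: Iterable[MotifHit],
    adjacency: int = 250,
) -> float:
    """Fraction of B-bearing peaks with an A hit within ``adjacency`` bp.

    A peak counts if any of its (a, b) hit pairs satisfies
    |offset_a - offset_b| <= adjacency.  Raises if no peak bears a B hit.
    """
    by_peak_a: dict[str, list[int]] = {}
    for h in hits_a:
        by_peak_a.setdefault(h.peak_id, []).append(h.offset)
    by_peak_b: dict[str, list[int]] = {}
    for h in hits_b:
        by_peak_b.setdefault(h.peak_id, []).append(h.offset)
    if not by_peak_b:
        raise ValidationError("no B-bearing peaks: co-occurrence undefined")
    n_both = 0
    for pid, offs_b in by_peak_b.items():
        offs_a = by_peak_a.get(pid)
        if offs_a and any(
            abs(a - b) <= adjacency for a in offs_a for b in offs_b
        ):
            n_both += 1
    return n_both / len(by_peak_b)
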