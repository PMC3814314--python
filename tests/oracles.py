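"""Independent brute-force reference implementations used by the tests.

Each oracle recomputes a quantity with the most naive possible algorithm
(per-base loops, exhaustive enumeration) and stays independent of the
vectorized / interval-tree code paths it checks.
"""

from __future__ import annotations

import math


def brute_repeat_fraction(start, end, mask_intervals):
    """Per-base membership count over the peak interval."""
    covered = 0
    for b in range(start, end):
        if any(s <= b < e for s, e in mask_intervals):
            covered += 1
    return covered / (end - start)


def brute_best_score(probs, background, sequence):
    """Exhaustive offset/strand enumeration of the best log-odds match."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(probs)
    best = -math.inf
    for strand in ("+", "-"):
        seq = sequence if strand == "+" else "".join(
            comp.get(c, "N") for c in reversed(sequence)
        )
        for off in range(len(seq) - L + 1):
            score = 0.0
            for i in range(L):
                c = seq[off + i]
                if c in idx:
                    score += math.log2(probs[i][idx[c]] / background[idx[c]])
            best = max(best, score)
    return best


def brute_radius_association(peaks, genes, radius):
    """O(n*m) double loop: gene -> peaks with |summit - TSS| <= radius."""
    out = {g.gene_id: [] for g in genes}
    for g in genes:
        for p in peaks:
            if p.chrom == g.chrom and abs(p.summit - g.tss) <= radius:
                out[g.gene_id].append(p.peak_id)
    return {k: sorted(v) for k, v in out.items()}


def brute_domains(genes, chrom_sizes, basal_up=5000, basal_down=1000, extension=100000):
    """Per-gene scan over all other genes' basal boundaries."""

    def basal(g):
        t = g.tss
        if g.strand == "+":
            s, e = t - basal_up, t + basal_down
        else:
            s, e = t - basal_down + 1, t + basal_up + 1
        L = chrom_sizes[g.chrom]
        return max(0, s), min(L, e)

    out = {}
    for g in genes:
        bs, be = basal(g)
        L = chrom_sizes[g.chrom]
        left = 0
        right = L
        for o in genes:
            if o is g or o.chrom != g.chrom:
                continue
            obs, obe = basal(o)
            if obe <= bs:
                left = max(left, obe)
            if obs >= be:
                right = min(right, obs)
        es = max(bs - extension, left, 0)
        ee = min(be + extension, right, L)
        out[g.gene_id] = ((bs, be), (min(es, bs), max(ee, be)))
    return out


def brute_great_association(peaks, domains):
    """Double loop: peak -> genes whose extended domain holds the summit."""
    out = {}
    for p in peaks:
        hits = []
        for d in domains:
            if d.chrom == p.chrom and d.extended[0] <= p.summit < d.extended[1]:
                hits.append(d.gene_id)
        out[p.peak_id] = sorted(hits)
    return out


def brute_window_ok(values, window, min_identity):
    """Naive per-window means: ok[i] for windows [i, i + window)."""
    n = len(values)
    ok = []
    for i in range(n - window + 1):
        total = 0.0
        for j in range(i, i + window):
            total += values[j]
        ok.append(total >= min_identity * window - 1e-9)
    return ok


def brute_cnes(values, window, min_identity):
    """Maximal intervals where every sub-window passes, by naive run scan."""
    ok = brute_window_ok(values, window, min_identity)
    out = []
    i = 0
    n = len(ok)
    while i < n:
        if ok[i]:
            j = i
            while j + 1 < n and ok[j + 1]:
                j += 1
            out.append((i, j + window))
            i = j + 1
        else:
            i += 1
    return out


def brute_cooccurrence(hits_a, hits_b, adjacency):
    """Direct pair enumeration over (peak, offset) hit tuples."""
    peaks_b = {pid for pid, _ in hits_b}
    if not peaks_b:
        raise ValueError("no B-bearing peaks")
    n_both = 0
    for pid in peaks_b:
        offs_a = [o for q, o in hits_a if q == pid]
        offs_b = [o for q, o in hits_b if q == pid]
        if any(abs(a - b) <= adjacency for a in offs_a for b in offs_b):
            n_both += 1
    return n_both / len(peaks_b)
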