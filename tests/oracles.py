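"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives a pipeline quantity by the most literal possible
method — all-pairs scans, per-base loops, exhaustive enumeration — sharing
no code path with the package implementation it checks.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Dict, List, Sequence, Tuple

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def naive_scan(seq: str, motif: str) -> List[Tuple[int, str]]:
    """Position-by-position consensus matcher on both strands."""
    seq = seq.upper()
    m = len(motif)
    hits = []
    for o in range(len(seq) - m + 1):
        window = seq[o : o + m]
        if all(b in IUPAC[c] for b, c in zip(window, motif)):
            hits.append((o, "+"))
        if all(b in IUPAC[c] for b, c in zip(naive_revcomp(window), motif)):
            hits.append((o, "-"))
    return sorted(hits)


def naive_pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """From-scratch covariance / variance Pearson coefficient."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5


def naive_assign(peaks, genes, promoter_bp: int, intergenic_bp: int):
    """All-pairs peak-to-gene assignment under the promoter-first rules.

    Returns a set of (peak_id, gene_id, category, distance) tuples.
    """
    links = set()
    for p in peaks:
        same = [g for g in genes if g.chrom == p.chrom]
        prom = [(g, abs(p.summit - g.tss)) for g in same if abs(p.summit - g.tss) <= promoter_bp]
        if prom:
            for g, d in prom:
                links.add((p.peak_id, g.gene_id, "promoter", d))
            continue
        inside = [g for g in same if g.start <= p.summit < g.end]
        if inside:
            for g in inside:
                links.add((p.peak_id, g.gene_id, "intragenic", 0))
            continue
        left = [(g, p.summit - (g.end - 1)) for g in same if g.end - 1 < p.summit]
        right = [(g, g.start - p.summit) for g in same if g.start > p.summit]
        for side, cat in ((left, "intergenic_5prime"), (right, "intergenic_3prime")):
            if not side:
                continue
            dmin = min(d for _, d in side)
            if dmin <= intergenic_bp:
                for g, d in side:
                    if d == dmin:
                        links.add((p.peak_id, g.gene_id, cat, d))
    return links


def hypergeom_exact_upper(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by direct summation of hypergeometric point masses."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1)) / total


def hypergeom_by_enumeration(universe: Sequence[str], set_a: set, n_b: int, k: int) -> float:
    """P(|draw ∩ A| >= k) enumerated over every size-n_b subset of the universe."""
    hits = 0
    total = 0
    for draw in combinations(universe, n_b):
        total += 1
        if len(set_a & set(draw)) >= k:
            hits += 1
    return hits / total


def mean_coverage_by_base(track, chrom: str, a: int, b: int) -> float:
    """Per-base loop over a CoverageTrack (slow, for small windows only)."""
    rec = track.intervals(chrom)
    total = 0.0
    for pos in range(a, b):
        if rec is not None:
            starts, ends, values = rec
            for s, e, v in zip(starts, ends, values):
                if s <= pos < e:
                    total += v
                    break
    return total / (b - a)
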