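"""Peak-to-gene assignment and peak-location summaries.

Assignment is summit-anchored with a strict priority: a summit within the
promoter window of any TSS yields promoter links to every qualifying gene;
otherwise a summit inside any gene body yields intragenic links; otherwise
the summit is intergenic and is linked to the nearest gene on each side of
it along the chromosome, provided that gene's nearest boundary lies within
the intergenic window.  "5'" and "3'" intergenic neighbours are read in
chromosome coordinates (lower / higher position than the summit), not gene
strand.  Ties — two genes at the same distance — are all linked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np

from .config import PipelineConfig
from .genomic_io import GeneModel, Peak

__all__ = [
    "PeakGeneLink",
    "PROMOTER",
    "INTRAGENIC",
    "INTERGENIC_5P",
    "INTERGENIC_3P",
    "assign_peaks",
    "candidate_targets",
    "location_breakdown",
    "peak_category",
]

PROMOTER = "promoter"
INTRAGENIC = "intragenic"
INTERGENIC_5P = "intergenic_5prime"
INTERGENIC_3P = "intergenic_3prime"

_CATEGORY_PRIORITY = {PROMOTER: 0, INTRAGENIC: 1, INTERGENIC_5P: 2, INTERGENIC_3P: 2}


@dataclass(frozen=True)
class PeakGeneLink:
    peak_id: str
    gene_id: str
    category: str
    #: summit-to-TSS distance for promoter links, 0 for intragenic, and
    #: summit to the nearest gene boundary for intergenic links
    distance: int


class _ChromIndex:
    """Per-chromosome arrays for vectorised summit queries."""

    def __init__(self, genes: Sequence[GeneModel]):
        genes = sorted(genes, key=lambda g: (g.start, g.gene_id))
        self.genes = genes
        self.starts = np.array([g.start for g in genes], dtype=np.int64)
        self.ends = np.array([g.end for g in genes], dtype=np.int64)
        tss = np.array([g.tss for g in genes], dtype=np.int64)
        self.tss_order = np.argsort(tss, kind="stable")
        self.tss_sorted = tss[self.tss_order]

    def promoter_hits(self, summit: int, window: int) -> List[Tuple[GeneModel, int]]:
        lo = np.searchsorted(self.tss_sorted, summit - window, side="left")
        hi = np.searchsorted(self.tss_sorted, summit + window, side="right")
        return [
            (self.genes[self.tss_order[i]], abs(summit - int(self.tss_sorted[i])))
            for i in range(lo, hi)
        ]

    def containing(self, summit: int) -> List[GeneModel]:
        inside = (self.starts <= summit) & (self.ends > summit)
        return [g for g, ok in zip(self.genes, inside) if ok]

    def flanking(self, summit: int, window: int) -> List[Tuple[GeneModel, str, int]]:
        """Nearest gene(s) strictly left and strictly right of the summit."""
        out: List[Tuple[GeneModel, str, int]] = []
        left = self.ends - 1 < summit
        if left.any():
            d = summit - (self.ends[left] - 1)
            dmin = int(d.min())
            if dmin <= window:
                for g, di in zip(np.array(self.genes, dtype=object)[left], d):
                    if int(di) == dmin:
                        out.append((g, INTERGENIC_5P, dmin))
        right = self.starts > summit
        if right.any():
            d = self.starts[right] - summit
            dmin = int(d.min())
            if dmin <= window:
                for g, di in zip(np.array(self.genes, dtype=object)[right], d):
                    if int(di) == dmin:
                        out.append((g, INTERGENIC_3P, dmin))
        return out


def assign_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    cfg: PipelineConfig = PipelineConfig(),
) -> List[PeakGeneLink]:
    """Assign every peak summit to genes under the promoter-first rules.

    Peaks on chromosomes with no gene models produce no links and trigger a
    single warning naming the orphan chromosomes.  The output is sorted by
    (peak id, gene id) and is independent of input ordering.
    """
    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    index = {chrom: _ChromIndex(lst) for chrom, lst in by_chrom.items()}

    orphans = sorted({p.chrom for p in peaks} - set(index))
    if orphans:
        warnings.warn(f"peaks on chromosomes without genes: {orphans}", stacklevel=2)

    links: List[PeakGeneLink] = []
    for p in peaks:
        ix = index.get(p.chrom)
        if ix is None:
            continue
        hits = ix.promoter_hits(p.summit, cfg.promoter_window_bp)
        if hits:
            links.extend(PeakGeneLink(p.peak_id, g.gene_id, PROMOTER, d) for g, d in hits)
            continue
        inside = ix.containing(p.summit)
        if inside:
            links.extend(PeakGeneLink(p.peak_id, g.gene_id, INTRAGENIC, 0) for g in inside)
            continue
        for g, cat, d in ix.flanking(p.summit, cfg.intergenic_window_bp):
            links.append(PeakGeneLink(p.peak_id, g.gene_id, cat, d))
    return sorted(links, key=lambda l: (l.peak_id, l.gene_id, l.category))


def candidate_targets(links: Iterable[PeakGeneLink]) -> Set[str]:
    """Distinct gene ids across all links — the bound candidate target set."""
    return {l.gene_id for l in links}


def peak_category(links: Iterable[PeakGeneLink]) -> Dict[str, str]:
    """Each linked peak's single highest-priority location category.

    Intergenic 5'/3' collapse to ``intergenic`` for counting purposes.
    """
    best: Dict[str, Tuple[int, str]] = {}
    for l in links:
        cat = "intergenic" if l.category in (INTERGENIC_5P, INTERGENIC_3P) else l.category
        prio = _CATEGORY_PRIORITY[l.category]
        if l.peak_id not in best or prio < best[l.peak_id][0]:
            best[l.peak_id] = (prio, cat)
    return {pid: cat for pid, (_, cat) in best.items()}


def location_breakdown(
    links: Iterable[PeakGeneLink],
    partition_labels: Mapping[str, str],
) -> Dict[str, Dict[str, int]]:
    """Promoter / intragenic / intergenic / unlinked counts per partition.

    Every peak in ``partition_labels`` is counted exactly once, in its
    highest-priority category or as ``unlinked``; per-partition counts
    therefore sum to that partition's peak count.
    """
    category = peak_category(links)
    out: Dict[str, Dict[str, int]] = {}
    for pid, label in partition_labels.items():
        counts = out.setdefault(
            label, {"promoter": 0, "intragenic": 0, "intergenic": 0, "unlinked": 0}
        )
        counts[category.get(pid, "unlinked")] += 1
    return out
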