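"""Consensus motif scanning on peak cores and the binary annotation matrix.

Scanning is IUPAC-consensus matching (not position-weight scoring): a motif
written over the degenerate nucleotide alphabet matches a sequence window if
every window base is in the corresponding code's set.  Both strands are
scanned; an ambiguous base ``N`` in the *sequence* never matches any code.

The module also extracts the central core of each peak (excluding cores
dominated by repeat-masked sequence), counts extended-consensus occurrences
against the uniform 1-in-4 expectation, builds the binary peak-annotation
matrix (partition / promoter / motif presence) and clusters it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist
from scipy.stats import binomtest, fisher_exact

from .config import PipelineConfig
from .genomic_io import Peak

__all__ = [
    "IUPAC_CODES",
    "DEFAULT_MOTIFS",
    "NEW_COFACTOR_BOX",
    "revcomp",
    "instantiate_iupac",
    "scan_consensus",
    "extract_cores",
    "CoreExclusion",
    "extended_consensus_counts",
    "ExtendedCounts",
    "build_annotation_matrix",
    "ANNOTATION_COLUMNS",
    "cluster_annotation",
    "motif_promoter_association",
]

IUPAC_CODES: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: the consensus motifs the analysis scans by default: the regulator's own
#: core consensus, the GATA-family consensus, and the conserved 3' box of
#: the novel promoter-associated motif (with its 5' co-factor box below)
DEFAULT_MOTIFS: Dict[str, str] = {
    "runx": "TGYGGT",
    "gata": "WGATAA",
    "new": "TGTAGT",
}

#: conserved 5' box that co-occurs with the novel motif in promoter peaks
NEW_COFACTOR_BOX = "TGGGA"


def revcomp(seq: str) -> str:
    """Reverse complement; IUPAC degenerate letters are complemented too."""
    return seq.translate(_COMPLEMENT)[::-1]


def _validate_motif(motif: str) -> str:
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    bad = set(motif) - set(IUPAC_CODES)
    if bad:
        raise ValueError(f"invalid IUPAC letters in motif {motif!r}: {sorted(bad)}")
    return motif


def instantiate_iupac(motif: str, rng: np.random.Generator) -> str:
    """Draw one concrete ACGT instance of a degenerate consensus."""
    motif = _validate_motif(motif)
    return "".join(
        sorted(IUPAC_CODES[c])[int(rng.integers(len(IUPAC_CODES[c])))] for c in motif
    )


def scan_consensus(seq: str, motif: str) -> List[Tuple[int, str]]:
    """All matches of an IUPAC consensus on both strands of ``seq``.

    Returns sorted ``(offset, strand)`` pairs, where ``offset`` is the
    forward-strand position of the match window and a ``-`` strand hit
    means the reverse complement of that window matches the motif.
    Overlapping matches are all reported; ``N`` in the sequence matches
    nothing.
    """
    motif = _validate_motif(motif)
    seq = seq.upper()
    m = len(motif)
    n = len(seq)
    if n < m:
        return []
    # vectorized window matching over a byte view of the sequence
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    hits: List[Tuple[int, str]] = []
    for pattern, strand in ((motif, "+"), (revcomp(motif), "-")):
        ok = np.ones(n - m + 1, dtype=bool)
        for j, code in enumerate(pattern):
            allowed = np.frombuffer(
                "".join(sorted(IUPAC_CODES[code])).encode("ascii"), dtype=np.uint8
            )
            ok &= np.isin(windows[:, j], allowed)
        hits.extend((int(o), strand) for o in np.nonzero(ok)[0])
    return sorted(hits)


# ---------------------------------------------------------------------------
# peak cores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CoreExclusion:
    peak_id: str
    masked_fraction: float


def extract_cores(
    peaks: Sequence[Peak],
    sequences: Mapping[str, str],
    repeat_mask: Sequence[Tuple[str, int, int]] | None,
    cfg: PipelineConfig = PipelineConfig(),
) -> Tuple[Dict[str, str], List[CoreExclusion]]:
    """Centred ``core_bp`` substring of each peak, minus repeat-heavy cores.

    Each peak's sequence must span its full width.  The core is the middle
    ``cfg.core_bp`` bases (the whole sequence when shorter).  A core whose
    repeat-masked fraction exceeds ``cfg.repeat_fraction`` is excluded.
    Masked bases come from ``repeat_mask`` projected onto the peak; with no
    mask, lower-case or ``N`` letters count as masked.
    """
    merged: Dict[str, List[Tuple[int, int]]] = {}
    if repeat_mask is not None:
        for chrom, s, e in sorted(repeat_mask):
            ivals = merged.setdefault(chrom, [])
            if ivals and s <= ivals[-1][1]:
                ivals[-1] = (ivals[-1][0], max(ivals[-1][1], e))
            else:
                ivals.append((s, e))

    cores: Dict[str, str] = {}
    excluded: List[CoreExclusion] = []
    for p in peaks:
        seq = sequences.get(p.peak_id)
        if seq is None:
            raise ValueError(f"no sequence for peak {p.peak_id}")
        if len(seq) != len(p):
            raise ValueError(
                f"peak {p.peak_id}: sequence length {len(seq)} != width {len(p)}"
            )
        core_len = min(cfg.core_bp, len(p))
        off = (len(p) - core_len) // 2
        core = seq[off : off + core_len]
        core_start = p.start + off
        if repeat_mask is not None:
            masked = 0
            for s, e in merged.get(p.chrom, []):
                masked += max(0, min(e, core_start + core_len) - max(s, core_start))
        else:
            masked = sum(1 for c in core if c.islower() or c.upper() == "N")
        frac = masked / core_len
        if frac > cfg.repeat_fraction:
            excluded.append(CoreExclusion(p.peak_id, frac))
        else:
            cores[p.peak_id] = core.upper()
    return cores, excluded


# ---------------------------------------------------------------------------
# extended consensus counting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExtendedCounts:
    """Core-motif matches and how many carry the extension base 3' of them."""

    n_total: int
    n_extended: int
    n_expected: int
    n_eligible: int
    p_value: float


def extended_consensus_counts(
    cores: Mapping[str, str] | Iterable[str],
    core_motif: str,
    extension_base: str,
) -> ExtendedCounts:
    """Count extended-consensus occurrences against the 1/4 expectation.

    For every match of ``core_motif`` (both strands, all cores pooled), the
    base immediately 3' of the match *on the match's strand* is inspected;
    the match is "extended" when that base equals ``extension_base``.  The
    expected extended count is ``round(n_total / 4)`` under a uniform
    background, and a two-sided binomial test at p=1/4 is reported over the
    matches that have a 3' base at all (matches flush with a sequence edge
    count toward ``n_total`` only).
    """
    extension_base = extension_base.upper()
    if extension_base not in "ACGT" or len(extension_base) != 1:
        raise ValueError("extension base must be a single ACGT letter")
    seqs = list(cores.values()) if isinstance(cores, Mapping) else list(cores)
    m = len(_validate_motif(core_motif))
    n_total = n_extended = n_eligible = 0
    for seq in seqs:
        seq = seq.upper()
        for off, strand in scan_consensus(seq, core_motif):
            n_total += 1
            if strand == "+":
                nxt = seq[off + m] if off + m < len(seq) else None
            else:
                nxt = revcomp(seq[off - 1]) if off > 0 else None
            if nxt is None or nxt == "N":
                continue
            n_eligible += 1
            if nxt == extension_base:
                n_extended += 1
    # half-up rounding: the quarter expectation of an even count rounds away
    # from zero (1138 -> 285), unlike Python's banker's rounding
    n_expected = int(math.floor(n_total / 4 + 0.5)) if n_total else 0
    if n_eligible:
        p = float(binomtest(n_extended, n_eligible, 0.25).pvalue)
    else:
        p = 1.0
    return ExtendedCounts(n_total, n_extended, n_expected, n_eligible, p)


# ---------------------------------------------------------------------------
# annotation matrix and clustering
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = (
    "shared_partition",
    "promoter",
    "has_new_motif",
    "has_runx_motif",
    "has_gata_motif",
)


def build_annotation_matrix(
    peak_ids: Sequence[str],
    partition_labels: Mapping[str, str],
    promoter_peaks: Iterable[str],
    motif_hits: Mapping[str, Iterable[str]],
):
    """Binary peak x feature matrix for clustering and association tests.

    ``motif_hits`` maps motif name (``new``/``runx``/``gata``) to the peak
    ids with at least one core hit.
    """
    import pandas as pd

    promoters = set(promoter_peaks)
    hits = {name: set(ids) for name, ids in motif_hits.items()}
    rows = []
    for pid in peak_ids:
        rows.append(
            [
                1 if partition_labels.get(pid) == "2,3,4" else 0,
                1 if pid in promoters else 0,
                1 if pid in hits.get("new", ()) else 0,
                1 if pid in hits.get("runx", ()) else 0,
                1 if pid in hits.get("gata", ()) else 0,
            ]
        )
    return pd.DataFrame(
        rows, index=pd.Index(peak_ids, name="peak_id"), columns=list(ANNOTATION_COLUMNS)
    )


def cluster_annotation(matrix) -> Tuple[List[str], np.ndarray | None]:
    """Average-linkage clustering of binary rows under Jaccard distance.

    Rows are pre-sorted by peak id so the leaf order is a pure function of
    the matrix content.  Returns (ordered peak ids, linkage matrix); a
    single row yields a trivial order and no linkage.
    """
    matrix = matrix.sort_index()
    ids = list(matrix.index)
    if len(ids) < 2:
        return ids, None
    X = matrix.to_numpy(dtype=bool)
    dist = pdist(X, metric="jaccard")  # all-zero pairs have distance 0
    Z = average(dist)
    order = leaves_list(Z)
    return [ids[i] for i in order], Z


def motif_promoter_association(matrix) -> Tuple[np.ndarray, float]:
    """2x2 promoter x novel-motif contingency with Fisher's exact test."""
    prom = matrix["promoter"].to_numpy(dtype=bool)
    new = matrix["has_new_motif"].to_numpy(dtype=bool)
    table = np.array(
        [
            [int(np.sum(prom & new)), int(np.sum(prom & ~new))],
            [int(np.sum(~prom & new)), int(np.sum(~prom & ~new))],
        ]
    )
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)
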