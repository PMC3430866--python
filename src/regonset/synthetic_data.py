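"""Synthetic study generator with known planted truth.

Emulates the data a developmental ChIP-seq/expression study produces — gene
models on a small genome, four-population expression on two array platforms,
binding peaks with sequences and a repeat mask, and a knockout-vs-
heterozygote replicate table — while recording exactly which signals were
planted, so every downstream stage can be scored against ground truth.

The planted structure mirrors the regulatory scenario the pipeline is built
for: a regulator whose expression rises monotonically across four sorted
populations; target genes whose profiles copy (or mirror) the regulator's up
to log-normal noise; binding peaks either shared by the three regulator-
positive populations or specific to the last one; consensus motif instances
planted in peak cores on either strand; and knockout effects of a fixed
linear fold on the planted targets.

All randomness flows from ``SimConfig.seed`` through named substreams, so a
given config reproduces byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import ConfigError
from .genomic_io import (
    POPULATIONS,
    ExpressionMatrix,
    GeneModel,
    Peak,
    write_expression_tsv,
    write_fasta,
    write_genes_bed,
    write_intervals_bed,
    write_json,
    write_ko_tsv,
    write_peaks_bed,
)
from .motif_analysis import DEFAULT_MOTIFS, NEW_COFACTOR_BOX, instantiate_iupac, revcomp

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SimulationError",
    "SimOutput",
    "generate_gene_models",
    "generate_expression",
    "generate_peaks_and_sequences",
    "generate_ko_table",
    "simulate",
    "REGULATOR_PROFILE",
]


class SimulationError(ValueError):
    """The requested synthetic genome cannot be built."""


#: Linear regulator profile across populations 1-4: a geometric sweep from 10
#: to 1000, i.e. affine on the log2 scale and safely above the ``>100``
#: expression floor in the later populations.
REGULATOR_PROFILE = 10.0 * (100.0 ** (np.arange(4) / 3.0))

_GAP_SMALL = (2_000, 40_000)
_GAP_LARGE = (110_000, 160_000)
_GENE_LEN = (2_000, 15_000)
_EDGE_PAD = 1_000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    The defaults are the package's reference study conditions: 200 genes on
    two 5 Mb chromosomes, 100 peaks skewed strongly toward the late-only
    class, log2 expression noise of 0.25, and knockout effects of linear
    fold 1.5 on the planted targets with 2 biological x 2 technical
    replicates per genotype.
    """

    n_genes: int = 200
    chrom_lengths: Tuple[Tuple[str, int], ...] = (("chr1", 5_000_000), ("chr2", 5_000_000))
    n_peaks_shared: int = 20
    n_peaks_late: int = 80
    regulator_gene: str = "Runx1"
    fraction_positive: float = 0.15
    fraction_negative: float = 0.10
    expression_noise_sd: float = 0.25
    ko_fold: float = 1.5
    ko_noise_sd: float = 0.1
    n_bio_replicates: int = 2
    n_tech_replicates: int = 2
    seed: int = 0
    # peak geometry and motif planting
    frac_bound_targets: float = 0.6
    frac_promoter_bg: float = 0.2
    frac_intragenic_bg: float = 0.3
    frac_intergenic_near_bg: float = 0.3
    frac_repeat_peaks: float = 0.1
    motif_prob_runx: float = 0.7
    motif_prob_gata_late: float = 0.5
    motif_prob_gata_shared: float = 0.1
    motif_prob_new_promoter: float = 0.6
    motif_prob_new_other: float = 0.05

    def __post_init__(self) -> None:
        if isinstance(self.chrom_lengths, dict):  # tolerate mapping input
            object.__setattr__(self, "chrom_lengths", tuple(self.chrom_lengths.items()))
        if self.fraction_positive + self.fraction_negative > 1.0:
            raise ConfigError("fraction_positive + fraction_negative must be <= 1")
        if self.fraction_positive < 0 or self.fraction_negative < 0:
            raise ConfigError("planted fractions must be non-negative")
        if self.ko_fold <= 1.0:
            raise ConfigError("ko_fold is a linear ratio and must exceed 1")
        if self.expression_noise_sd < 0 or self.ko_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if self.n_bio_replicates < 1 or self.n_tech_replicates < 1:
            raise ConfigError("replicate counts must be >= 1")
        bg = self.frac_promoter_bg + self.frac_intragenic_bg + self.frac_intergenic_near_bg
        if bg > 1.0:
            raise ConfigError("background peak location fractions exceed 1")

    @property
    def chroms(self) -> Dict[str, int]:
        return dict(self.chrom_lengths)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["chrom_lengths"] = {c: int(l) for c, l in self.chrom_lengths}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "chrom_lengths" in d and isinstance(d["chrom_lengths"], Mapping):
            d["chrom_lengths"] = tuple(d["chrom_lengths"].items())
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth recorded while generating a synthetic study."""

    planted_positive_targets: List[str] = field(default_factory=list)
    planted_negative_targets: List[str] = field(default_factory=list)
    #: peak id -> list of (offset, motif name, planted instance, strand)
    planted_motif_positions: Dict[str, List[Tuple[int, str, str, str]]] = field(
        default_factory=dict
    )
    peak_class_truth: Dict[str, str] = field(default_factory=dict)
    #: gene id -> true het/null linear fold change
    ko_effect_genes: Dict[str, float] = field(default_factory=dict)
    bound_positive_targets: List[str] = field(default_factory=list)
    bound_negative_targets: List[str] = field(default_factory=list)
    repeat_peak_ids: List[str] = field(default_factory=list)

    def validate(self, genes: Sequence[GeneModel], sequences: Mapping[str, str] | None = None) -> None:
        pos, neg = set(self.planted_positive_targets), set(self.planted_negative_targets)
        if pos & neg:
            raise ValueError(f"planted target sets overlap: {sorted(pos & neg)[:5]}")
        known = {g.gene_id for g in genes}
        missing = (pos | neg | set(self.ko_effect_genes)) - known
        if missing:
            raise ValueError(f"truth references unknown genes: {sorted(missing)[:5]}")
        if sequences is not None:
            for pid, hits in self.planted_motif_positions.items():
                for off, _name, instance, _strand in hits:
                    if off < 0 or off + len(instance) > len(sequences[pid]):
                        raise ValueError(f"motif offset out of bounds in {pid}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["planted_motif_positions"] = {
            pid: [list(hit) for hit in hits]
            for pid, hits in self.planted_motif_positions.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticTruth":
        d = dict(d)
        d["planted_motif_positions"] = {
            pid: [(int(o), n, i, s) for o, n, i, s in hits]
            for pid, hits in d.get("planted_motif_positions", {}).items()
        }
        return cls(**d)


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


# ---------------------------------------------------------------------------
# gene models
# ---------------------------------------------------------------------------


def generate_gene_models(cfg: SimConfig) -> List[GeneModel]:
    """Place non-nested genes with varied inter-gene gaps.

    Genes are laid out left to right per chromosome with mostly short gaps
    plus a regular sprinkling of >110 kb deserts, so downstream tests can
    exercise both sub-50 kb intergenic assignment and unassignable peaks.
    The first placed gene is renamed to ``cfg.regulator_gene``.
    """
    if cfg.n_genes < 2:
        raise SimulationError("nothing to place: need at least 2 genes")
    chroms = cfg.chroms
    if not chroms:
        raise SimulationError("chrom_lengths is empty")
    rng = _rng(cfg, 1)

    total_len = sum(chroms.values())
    counts: Dict[str, int] = {}
    remaining = cfg.n_genes
    items = list(chroms.items())
    for i, (chrom, length) in enumerate(items):
        if i == len(items) - 1:
            counts[chrom] = remaining
        else:
            k = int(round(cfg.n_genes * length / total_len))
            counts[chrom] = min(k, remaining)
            remaining -= counts[chrom]

    genes: List[GeneModel] = []
    idx = 0
    for chrom, length in items:
        cursor = _EDGE_PAD
        for j in range(counts[chrom]):
            if j % 10 == 7:  # periodic gene desert
                gap = int(rng.integers(*_GAP_LARGE))
            else:
                gap = int(rng.integers(*_GAP_SMALL))
            glen = int(rng.integers(*_GENE_LEN))
            start = cursor + gap
            end = start + glen
            if end > length - _EDGE_PAD:
                raise SimulationError(
                    f"chromosome {chrom} too short to place gene {idx + 1} "
                    f"of {cfg.n_genes} (needs {end + _EDGE_PAD} bp, has {length})"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = cfg.regulator_gene if idx == 0 else f"g{idx:04d}"
            genes.append(GeneModel(gene_id, chrom, start, end, strand))
            cursor = end
            idx += 1
    return genes


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def generate_expression(
    genes: Sequence[GeneModel], cfg: SimConfig
) -> Tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Two-platform four-population expression with planted correlation.

    The regulator follows :data:`REGULATOR_PROFILE` exactly (strictly
    increasing).  Planted positive targets copy its log2 profile plus
    Gaussian noise; planted negatives get the reversed profile plus noise;
    every other gene is a flat baseline plus noise.  Both platforms share
    the planted truth but draw independent noise.
    """
    gene_ids = [g.gene_id for g in genes]
    if cfg.regulator_gene not in gene_ids:
        raise SimulationError(f"regulator {cfg.regulator_gene!r} not in gene models")
    rng = _rng(cfg, 2)

    others = [g for g in gene_ids if g != cfg.regulator_gene]
    n_pos = int(round(cfg.fraction_positive * cfg.n_genes))
    n_neg = int(round(cfg.fraction_negative * cfg.n_genes))
    if n_pos + n_neg > len(others):
        raise ConfigError("fraction_positive + fraction_negative too large")
    chosen = rng.choice(len(others), size=n_pos + n_neg, replace=False)
    pos = sorted(others[i] for i in chosen[:n_pos])
    neg = sorted(others[i] for i in chosen[n_pos:])

    log_reg = np.log2(REGULATOR_PROFILE)
    baseline = {g: float(rng.uniform(2.0, 10.0)) for g in others}

    def one_platform(label: str) -> ExpressionMatrix:
        rows = np.empty((len(gene_ids), 4))
        for i, g in enumerate(gene_ids):
            if g == cfg.regulator_gene:
                mean = log_reg
            elif g in set(pos):
                mean = log_reg
            elif g in set(neg):
                mean = log_reg[::-1]
            else:
                mean = np.full(4, baseline[g])
            noise = (
                rng.normal(0.0, cfg.expression_noise_sd, size=4)
                if g != cfg.regulator_gene
                else np.zeros(4)
            )
            rows[i] = 2.0 ** (mean + noise)
        df = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=POPULATIONS)
        return ExpressionMatrix(label, df)

    # membership sets built once; platform noise drawn sequentially from the
    # same stream keeps the whole call deterministic in cfg.seed
    truth = SyntheticTruth(planted_positive_targets=pos, planted_negative_targets=neg)
    mat_a = one_platform("A")
    mat_b = one_platform("B")
    return mat_a, mat_b, truth


# ---------------------------------------------------------------------------
# peaks, sequences, repeat mask
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def _plant(
    rng: np.random.Generator,
    seq: List[str],
    occupied: List[Tuple[int, int]],
    core_lo: int,
    core_hi: int,
    unit: str,
    boxes: List[Tuple[int, str, str]],
    records: List[Tuple[int, str, str, str]],
) -> bool:
    """Insert ``unit`` (or its reverse complement) at a free core offset.

    ``boxes`` lists (relative offset, motif name, instance) for each
    consensus box inside the unit; their absolute forward-strand offsets are
    appended to ``records``.
    """
    ulen = len(unit)
    if core_hi - core_lo < ulen:
        return False
    strand = "+" if rng.random() < 0.5 else "-"
    for _ in range(50):
        off = int(rng.integers(core_lo, core_hi - ulen + 1))
        if any(off < e and off + ulen > s for s, e in occupied):
            continue
        inserted = unit if strand == "+" else revcomp(unit)
        seq[off : off + ulen] = list(inserted)
        occupied.append((off, off + ulen))
        for rel, name, instance in boxes:
            if strand == "+":
                fwd = off + rel
            else:
                fwd = off + ulen - rel - len(instance)
            records.append((fwd, name, instance, strand))
        return True
    return False


def generate_peaks_and_sequences(
    genes: Sequence[GeneModel], cfg: SimConfig, truth: SyntheticTruth
) -> Tuple[List[Peak], Dict[str, str], List[Tuple[str, int, int]], SyntheticTruth]:
    """Peaks with heights/calls, their sequences, and a repeat mask.

    A configurable fraction of planted expression targets receive a peak in
    their promoter or gene body ("bound targets"); the remaining peak budget
    is spread over promoters, gene bodies, near (<50 kb) and far (>50 kb)
    intergenic space of non-target genes.  Peak classes: ``shared`` peaks
    are called in populations 2, 3 and 4 with tightly correlated heights;
    ``late_only`` peaks are called only in population 4 with a height at
    least five-fold above their population 2/3 signal.
    """
    rng = _rng(cfg, 3)
    chroms = cfg.chroms
    n_total = cfg.n_peaks_shared + cfg.n_peaks_late
    if n_total < 1:
        raise ConfigError("need at least one peak")

    by_chrom: Dict[str, List[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for lst in by_chrom.values():
        lst.sort(key=lambda g: g.start)

    def in_any_gene(chrom: str, pos: int) -> bool:
        return any(g.start <= pos < g.end for g in by_chrom.get(chrom, []))

    def near_any_tss(chrom: str, pos: int, pad: int = 600) -> bool:
        return any(abs(pos - g.tss) <= pad for g in by_chrom.get(chrom, []))

    gene_index = {g.gene_id: g for g in genes}
    pos_set = list(truth.planted_positive_targets)
    neg_set = list(truth.planted_negative_targets)
    n_bound_pos = int(round(cfg.frac_bound_targets * len(pos_set)))
    n_bound_neg = int(round(cfg.frac_bound_targets * len(neg_set)))
    bound_pos = sorted(
        pos_set[i] for i in rng.choice(len(pos_set), size=n_bound_pos, replace=False)
    ) if pos_set else []
    bound_neg = sorted(
        neg_set[i] for i in rng.choice(len(neg_set), size=n_bound_neg, replace=False)
    ) if neg_set else []
    target_genes = bound_pos + bound_neg
    if len(target_genes) > n_total:
        raise ConfigError("peak budget smaller than the number of bound targets")
    n_bg = n_total - len(target_genes)
    n_bg_prom = int(round(cfg.frac_promoter_bg * n_bg))
    n_bg_intra = int(round(cfg.frac_intragenic_bg * n_bg))
    n_bg_near = int(round(cfg.frac_intergenic_near_bg * n_bg))
    n_bg_far = max(n_bg - n_bg_prom - n_bg_intra - n_bg_near, 0)

    nontarget_ids = [
        g.gene_id
        for g in genes
        if g.gene_id not in set(truth.planted_positive_targets)
        and g.gene_id not in set(truth.planted_negative_targets)
        and g.gene_id != cfg.regulator_gene
    ]

    def promoter_summit(gene: GeneModel) -> Tuple[str, int]:
        return gene.chrom, gene.tss + int(rng.integers(-300, 301))

    def intragenic_summit(gene: GeneModel) -> Tuple[str, int]:
        if gene.strand == "+":
            lo, hi = gene.start + 700, gene.end - 50
        else:
            lo, hi = gene.start + 50, gene.end - 700
        return gene.chrom, int(rng.integers(lo, hi))

    placements: List[Tuple[str, int, str]] = []  # (chrom, summit, category)
    for gid in target_genes:
        gene = gene_index[gid]
        if rng.random() < 0.5:
            chrom, summit = promoter_summit(gene)
            placements.append((chrom, summit, "promoter"))
        else:
            chrom, summit = intragenic_summit(gene)
            placements.append((chrom, summit, "intragenic"))
    for _ in range(n_bg_prom):
        gene = gene_index[nontarget_ids[int(rng.integers(len(nontarget_ids)))]]
        chrom, summit = promoter_summit(gene)
        placements.append((chrom, summit, "promoter"))
    for _ in range(n_bg_intra):
        gene = gene_index[nontarget_ids[int(rng.integers(len(nontarget_ids)))]]
        chrom, summit = intragenic_summit(gene)
        placements.append((chrom, summit, "intragenic"))
    for _ in range(n_bg_near):
        for _try in range(200):
            gene = gene_index[nontarget_ids[int(rng.integers(len(nontarget_ids)))]]
            summit = gene.end - 1 + int(rng.integers(2_000, 45_001))
            if summit >= chroms[gene.chrom] - _EDGE_PAD:
                continue
            if in_any_gene(gene.chrom, summit) or near_any_tss(gene.chrom, summit):
                continue
            placements.append((gene.chrom, summit, "intergenic_near"))
            break
        else:
            raise SimulationError("could not place a near-intergenic peak")
    far_windows: List[Tuple[str, int, int]] = []
    margin = 50_000 + 600
    for chrom, lst in by_chrom.items():
        for left, right in zip(lst, lst[1:]):
            lo, hi = left.end - 1 + margin, right.start - margin
            if hi - lo > 1_000:
                far_windows.append((chrom, lo, hi))
    for _ in range(n_bg_far):
        if not far_windows:
            raise SimulationError("no inter-gene desert wide enough for far peaks")
        chrom, lo, hi = far_windows[int(rng.integers(len(far_windows)))]
        placements.append((chrom, int(rng.integers(lo, hi)), "intergenic_far"))

    # class labels: a random subset of peaks is shared, the rest late-only
    labels = np.array(["late_only"] * n_total, dtype=object)
    labels[rng.choice(n_total, size=cfg.n_peaks_shared, replace=False)] = "shared"

    drafts = []
    for (chrom, summit, category), label in zip(placements, labels):
        width = int(rng.integers(300, 501))
        offset = int(rng.integers(100, width - 100))
        start = max(summit - offset, 0)
        end = start + width
        if label == "shared":
            base = float(rng.lognormal(3.0, 0.5))
            heights = tuple(base * float(np.exp(rng.normal(0.0, 0.05))) for _ in range(3))
            called = (True, True, True)
        else:
            h4 = float(rng.lognormal(3.5, 0.4))
            heights = (
                h4 * float(rng.uniform(0.05, 0.18)),
                h4 * float(rng.uniform(0.05, 0.18)),
                h4,
            )
            called = (False, False, True)
        drafts.append((chrom, start, end, summit, heights, called, label, category))

    drafts.sort(key=lambda d: (d[0], d[1], d[3]))
    width_digits = max(3, len(str(n_total)))
    peaks: List[Peak] = []
    categories: Dict[str, str] = {}
    for i, (chrom, start, end, summit, heights, called, label, category) in enumerate(drafts):
        pid = f"peak{i + 1:0{width_digits}d}"
        peaks.append(Peak(pid, chrom, start, end, summit, heights, called))
        truth.peak_class_truth[pid] = label
        categories[pid] = category

    sequences: Dict[str, str] = {}
    truth.planted_motif_positions = {}
    runx = DEFAULT_MOTIFS["runx"]
    gata = DEFAULT_MOTIFS["gata"]
    new = DEFAULT_MOTIFS["new"]
    for p in peaks:
        w = len(p)
        seq = list(_random_seq(rng, w))
        core = min(200, w)
        core_lo = (w - core) // 2
        core_hi = core_lo + core
        occupied: List[Tuple[int, int]] = []
        records: List[Tuple[int, str, str, str]] = []
        if rng.random() < cfg.motif_prob_runx:
            inst = instantiate_iupac(runx, rng)
            _plant(rng, seq, occupied, core_lo, core_hi, inst, [(0, "runx", inst)], records)
        p_gata = (
            cfg.motif_prob_gata_shared
            if truth.peak_class_truth[p.peak_id] == "shared"
            else cfg.motif_prob_gata_late
        )
        if rng.random() < p_gata:
            inst = instantiate_iupac(gata, rng)
            _plant(rng, seq, occupied, core_lo, core_hi, inst, [(0, "gata", inst)], records)
        p_new = (
            cfg.motif_prob_new_promoter
            if categories[p.peak_id] == "promoter"
            else cfg.motif_prob_new_other
        )
        if rng.random() < p_new:
            spacer = _random_seq(rng, int(rng.integers(1, 5)))
            box_a = NEW_COFACTOR_BOX
            box_b = instantiate_iupac(new, rng)
            unit = box_a + spacer + box_b
            boxes = [(0, "new_cofactor", box_a), (len(box_a) + len(spacer), "new", box_b)]
            _plant(rng, seq, occupied, core_lo, core_hi, unit, boxes, records)
        sequences[p.peak_id] = "".join(seq)
        if records:
            truth.planted_motif_positions[p.peak_id] = sorted(records)

    # repeat mask: a fraction of background peaks get >60% masked, plus decoys
    n_repeat = int(round(cfg.frac_repeat_peaks * n_total))
    bg_ids = [p.peak_id for p in peaks if categories[p.peak_id] in ("intergenic_near", "intergenic_far")]
    n_repeat = min(n_repeat, len(bg_ids))
    repeat_ids = sorted(
        bg_ids[i] for i in rng.choice(len(bg_ids), size=n_repeat, replace=False)
    )
    mask: List[Tuple[str, int, int]] = []
    peak_by_id = {p.peak_id: p for p in peaks}
    for pid in repeat_ids:
        p = peak_by_id[pid]
        w = len(p)
        s = p.start + int(0.15 * w)
        mask.append((p.chrom, s, s + int(0.7 * w)))
    for _ in range(15):  # decoy repeats away from all peaks
        for _try in range(200):
            chrom = list(chroms)[int(rng.integers(len(chroms)))]
            s = int(rng.integers(_EDGE_PAD, chroms[chrom] - _EDGE_PAD - 300))
            if all(
                p.chrom != chrom or s + 300 <= p.start - 2_000 or s >= p.end + 2_000
                for p in peaks
            ):
                mask.append((chrom, s, s + 300))
                break
    mask.sort()

    truth.bound_positive_targets = bound_pos
    truth.bound_negative_targets = bound_neg
    truth.repeat_peak_ids = repeat_ids
    return peaks, sequences, mask, truth


# ---------------------------------------------------------------------------
# knockout table
# ---------------------------------------------------------------------------


def generate_ko_table(
    genes: Sequence[GeneModel], truth: SyntheticTruth, cfg: SimConfig
) -> pd.DataFrame:
    """Knockout-vs-heterozygote replicate expression table.

    Planted positive targets are ``ko_fold``-fold lower in the null
    genotype, planted negatives ``ko_fold``-fold higher; all other genes are
    unchanged up to log-normal replicate noise.  The regulator itself is set
    ``ko_fold``-fold down in the null (its locus is disrupted) but is not
    part of the planted effect truth.
    """
    if cfg.ko_fold <= 1.0:
        raise ConfigError("ko_fold must exceed 1")
    rng = _rng(cfg, 4)
    gene_ids = [g.gene_id for g in genes]
    pos = set(truth.planted_positive_targets)
    neg = set(truth.planted_negative_targets)
    shift = math.log2(cfg.ko_fold)

    cols = [
        f"{geno}_b{b + 1}_t{t + 1}"
        for geno in ("het", "null")
        for b in range(cfg.n_bio_replicates)
        for t in range(cfg.n_tech_replicates)
    ]
    rows = np.empty((len(gene_ids), len(cols)))
    for i, g in enumerate(gene_ids):
        base = float(rng.uniform(4.0, 10.0))
        if g in pos or g == cfg.regulator_gene:
            null_mean = base - shift
        elif g in neg:
            null_mean = base + shift
        else:
            null_mean = base
        vals = []
        for geno_mean in (base, null_mean):
            n = cfg.n_bio_replicates * cfg.n_tech_replicates
            vals.extend(2.0 ** (geno_mean + rng.normal(0.0, cfg.ko_noise_sd, size=n)))
        rows[i] = vals

    truth.ko_effect_genes = {
        **{g: cfg.ko_fold for g in sorted(pos)},
        **{g: 1.0 / cfg.ko_fold for g in sorted(neg)},
    }
    return pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"), columns=cols)


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


@dataclass
class SimOutput:
    """Everything one synthetic study produced, in memory and on disk."""

    config: SimConfig
    genes: List[GeneModel]
    expr_a: ExpressionMatrix
    expr_b: ExpressionMatrix
    peaks: List[Peak]
    sequences: Dict[str, str]
    repeat_mask: List[Tuple[str, int, int]]
    ko_table: pd.DataFrame
    truth: SyntheticTruth
    paths: Dict[str, Path] = field(default_factory=dict)


def simulate(cfg: SimConfig, outdir: str | Path | None = None) -> SimOutput:
    """Run the full generator; optionally write every emitted file."""
    genes = generate_gene_models(cfg)
    expr_a, expr_b, truth = generate_expression(genes, cfg)
    peaks, sequences, mask, truth = generate_peaks_and_sequences(genes, cfg, truth)
    ko = generate_ko_table(genes, truth, cfg)
    truth.validate(genes, sequences)

    out = SimOutput(cfg, genes, expr_a, expr_b, peaks, sequences, mask, ko, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.bed",
            "expr_a": outdir / "exprA.tsv",
            "expr_b": outdir / "exprB.tsv",
            "peaks": outdir / "peaks.bed",
            "peaks_fa": outdir / "peaks.fa",
            "repeats": outdir / "repeats.bed",
            "ko": outdir / "ko.tsv",
            "truth": outdir / "truth.json",
        }
        write_genes_bed(genes, paths["genes"])
        write_expression_tsv(expr_a, paths["expr_a"])
        write_expression_tsv(expr_b, paths["expr_b"])
        write_peaks_bed(peaks, paths["peaks"])
        write_fasta(sequences, paths["peaks_fa"])
        write_intervals_bed(mask, paths["repeats"])
        write_ko_tsv(ko, paths["ko"])
        write_json(truth.to_dict(), paths["truth"])
        out.paths = paths
    return out
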