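"""Knockout differential calling and evidence-set intersection.

The final stage combines three independent lines of evidence on a shared
gene namespace: correlation class from the timecourse (both platforms in
agreement), binding from peak-to-gene assignment, and differential
expression between regulator-null and heterozygote cells.  Genes positively
correlated, bound, and down in the null are the positively controlled
target set; negatively correlated, bound, and up in the null are the
negatively controlled set.  Overlap significance between gene sets is the
upper-tail hypergeometric probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .expression_dynamics import NEGATIVE, POSITIVE
from .genomic_io import parse_ko_column

__all__ = [
    "DifferentialRecord",
    "DOWN_IN_NULL",
    "UP_IN_NULL",
    "UNCHANGED",
    "ko_differential",
    "OverlapResult",
    "hypergeometric_overlap",
    "ControlledSets",
    "controlled_target_sets",
    "reference_cobinding",
    "bound_fraction_by_class",
]

DOWN_IN_NULL = "down_in_null"
UP_IN_NULL = "up_in_null"
UNCHANGED = "unchanged"


@dataclass(frozen=True)
class DifferentialRecord:
    gene_id: str
    log2fc: float  # het minus null on the log2 scale of bio-replicate means
    fold: float  # mean(het) / mean(null), linear
    p_value: float
    direction: str


def ko_differential(
    ko_table: pd.DataFrame, cfg: PipelineConfig = PipelineConfig()
) -> List[DifferentialRecord]:
    """Call differential genes between heterozygote and null genotypes.

    Technical replicates are averaged (linear scale) into biological
    replicates per genotype.  The fold is the ratio of genotype means of
    those biological-replicate values; the p-value is a two-sided Welch
    t-test on their log2 values.  A gene is ``down_in_null`` when fold >=
    ``cfg.ko_fold`` with p < ``cfg.ko_alpha``, ``up_in_null`` when fold <=
    1 / ``cfg.ko_fold`` with p < ``cfg.ko_alpha``, otherwise unchanged.
    """
    groups: Dict[Tuple[str, int], List[str]] = {}
    for col in ko_table.columns:
        geno, bio, _tech = parse_ko_column(col)
        groups.setdefault((geno, bio), []).append(col)
    bio_cols: Dict[str, List[List[str]]] = {"het": [], "null": []}
    for (geno, _bio), cols in sorted(groups.items()):
        bio_cols[geno].append(cols)
    if len(bio_cols["het"]) < 2 or len(bio_cols["null"]) < 2:
        raise ValueError("need >= 2 biological replicates per genotype")

    het = np.column_stack(
        [ko_table[cols].mean(axis=1).to_numpy() for cols in bio_cols["het"]]
    )
    null = np.column_stack(
        [ko_table[cols].mean(axis=1).to_numpy() for cols in bio_cols["null"]]
    )
    fold = het.mean(axis=1) / null.mean(axis=1)
    log_het, log_null = np.log2(het), np.log2(null)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # zero-variance genes (e.g. noiseless controls) are legitimate input;
        # their undefined t statistic maps to p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_res = stats.ttest_ind(log_het, log_null, axis=1, equal_var=False)
    p = np.nan_to_num(t_res.pvalue, nan=1.0)

    records: List[DifferentialRecord] = []
    for gene, f, lfc, pv in zip(
        ko_table.index, fold, log_het.mean(axis=1) - log_null.mean(axis=1), p
    ):
        if f >= cfg.ko_fold and pv < cfg.ko_alpha:
            direction = DOWN_IN_NULL
        elif f <= 1.0 / cfg.ko_fold and pv < cfg.ko_alpha:
            direction = UP_IN_NULL
        else:
            direction = UNCHANGED
        records.append(DifferentialRecord(str(gene), float(lfc), float(f), float(pv), direction))
    return records


@dataclass(frozen=True)
class OverlapResult:
    set_a_size: int
    set_b_size: int
    universe_size: int
    overlap: int
    p_hyper: float


def hypergeometric_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Upper-tail hypergeometric probability of the observed overlap.

    ``P(X >= k)`` where X counts successes when ``|B|`` genes are drawn
    without replacement from a universe containing ``|A|`` successes.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    outside = (a | b) - u
    if outside:
        raise ValueError(f"elements outside the universe: {sorted(outside)[:10]}")
    k = len(a & b)
    p = float(stats.hypergeom.sf(k - 1, len(u), len(a), len(b)))
    return OverlapResult(len(a), len(b), len(u), k, min(p, 1.0))


@dataclass
class ControlledSets:
    """Triple-intersection target sets plus all Venn region sizes."""

    positively_controlled: Set[str]
    negatively_controlled: Set[str]
    venn_positive: Dict[str, int] = field(default_factory=dict)
    venn_negative: Dict[str, int] = field(default_factory=dict)


def _venn_counts(a: Set[str], b: Set[str], c: Set[str]) -> Dict[str, int]:
    return {
        "set_a": len(a),
        "set_b": len(b),
        "set_c": len(c),
        "a_and_b": len(a & b),
        "a_and_c": len(a & c),
        "b_and_c": len(b & c),
        "a_and_b_and_c": len(a & b & c),
        "union": len(a | b | c),
    }


def controlled_target_sets(
    consensus_labels: Mapping[str, str],
    ko_records: Sequence[DifferentialRecord],
    bound_genes: Iterable[str],
) -> ControlledSets:
    """Intersect correlation class, knockout response and binding.

    Positively controlled = positive consensus AND down in the null AND
    bound; negatively controlled = negative consensus AND up in the null
    AND bound.  All pairwise and triple intersection sizes are reported for
    both Venn diagrams.
    """
    bound = set(bound_genes)
    pos_corr = {g for g, lab in consensus_labels.items() if lab == POSITIVE}
    neg_corr = {g for g, lab in consensus_labels.items() if lab == NEGATIVE}
    ko_down = {r.gene_id for r in ko_records if r.direction == DOWN_IN_NULL}
    ko_up = {r.gene_id for r in ko_records if r.direction == UP_IN_NULL}
    return ControlledSets(
        positively_controlled=pos_corr & ko_down & bound,
        negatively_controlled=neg_corr & ko_up & bound,
        venn_positive=_venn_counts(pos_corr, ko_down, bound),
        venn_negative=_venn_counts(neg_corr, ko_up, bound),
    )


def reference_cobinding(
    target_sets: Mapping[str, Iterable[str]],
    reference_bound_sets: Mapping[str, Iterable[str]],
) -> Dict[str, Dict[str, float]]:
    """Fraction of each target set bound by all / any reference factors."""
    refs = {name: set(v) for name, v in reference_bound_sets.items()}
    out: Dict[str, Dict[str, float]] = {}
    for name, members in target_sets.items():
        members = set(members)
        n = len(members)
        if refs:
            bound_all = {g for g in members if all(g in r for r in refs.values())}
            bound_any = {g for g in members if any(g in r for r in refs.values())}
        else:
            bound_all = bound_any = set()
        out[name] = {
            "n": n,
            "bound_all": len(bound_all),
            "bound_any": len(bound_any),
            "fraction_all": len(bound_all) / n if n else 0.0,
            "fraction_any": len(bound_any) / n if n else 0.0,
        }
    return out


def bound_fraction_by_class(
    consensus_labels: Mapping[str, str], bound_genes: Iterable[str]
) -> Dict[str, float | None]:
    """|bound ∩ class| / |class| for each correlation class.

    An empty class yields ``None`` (undefined), not zero.
    """
    bound = set(bound_genes)
    out: Dict[str, float | None] = {}
    for label in (POSITIVE, NEGATIVE, "unclassified"):
        members = {g for g, lab in consensus_labels.items() if lab == label}
        out[label] = len(members & bound) / len(members) if members else None
    return out
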