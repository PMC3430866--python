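"""End-to-end orchestration: one configuration, one reproducible run.

``run_all`` executes simulate (optional) -> dynamics -> peaks -> annotate ->
motifs -> integrate -> report in order, writes every stage's outputs under
one directory, and returns a manifest with the config snapshot, seed,
version and SHA-256 digests of all files.  A single seed drives every
stochastic stage through named substreams, so two runs with the same config
and seed produce identical reports.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .config import ConfigError, PipelineConfig
from .expression_dynamics import (
    SomResult,
    classify,
    correlate_with_regulator,
    filter_dynamic,
    platform_consensus,
    randomized_control,
    som_mosaic,
)
from .genomic_io import (
    ExpressionMatrix,
    GeneModel,
    Peak,
    read_expression_tsv,
    read_fasta,
    read_genes_bed,
    read_intervals_bed,
    read_ko_tsv,
    read_peaks_bed,
    write_json,
    write_peaks_bed,
)
from .motif_analysis import (
    DEFAULT_MOTIFS,
    build_annotation_matrix,
    cluster_annotation,
    extended_consensus_counts,
    extract_cores,
    motif_promoter_association,
    scan_consensus,
)
from .peak_annotation import assign_peaks, candidate_targets, location_breakdown, peak_category
from .peak_processing import filter_repeat_peaks, partition_peaks
from .synthetic_data import SimConfig, simulate
from .target_integration import (
    bound_fraction_by_class,
    controlled_target_sets,
    hypergeometric_overlap,
    ko_differential,
)

__all__ = ["RunManifest", "run_all", "load_config", "stage_seed"]

log = logging.getLogger("regonset")

_INPUT_KEYS = ("genes", "expr_a", "expr_b", "peaks", "peaks_fa", "repeats", "ko")


def stage_seed(seed: int, stage: int) -> int:
    """Independent, reproducible sub-seed for one pipeline stage."""
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    started: str
    finished: str = ""
    digests: Dict[str, str] = field(default_factory=dict)


def load_config(path_or_mapping) -> dict:
    if isinstance(path_or_mapping, Mapping):
        return dict(path_or_mapping)
    with open(path_or_mapping) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, Mapping):
        raise ConfigError("pipeline config must be a mapping")
    return dict(cfg)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# stage helpers (shared by run_all and the CLI subcommands)
# ---------------------------------------------------------------------------


@dataclass
class DynamicsResult:
    dynamic_a: set
    dynamic_b: set
    records_a: list
    records_b: list
    consensus: Dict[str, str]
    null_pcc: np.ndarray
    som: SomResult | None


def run_dynamics(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    regulator: str,
    cfg: PipelineConfig,
    n_permutations: int = 100,
    som_params: Mapping | None = None,
    seed: int = 0,
) -> DynamicsResult:
    dyn_a = filter_dynamic(expr_a, cfg)
    dyn_b = filter_dynamic(expr_b, cfg)
    rec_a = classify(correlate_with_regulator(expr_a, regulator, dyn_a, cfg), cfg)
    rec_b = classify(correlate_with_regulator(expr_b, regulator, dyn_b, cfg), cfg)
    consensus = platform_consensus(
        {r.gene_id: r.label for r in rec_a}, {r.gene_id: r.label for r in rec_b}
    )
    null = randomized_control(expr_a, regulator, n_permutations, stage_seed(seed, 20), dyn_a)
    som = None
    if som_params is not None:
        som = som_mosaic(
            expr_a,
            int(som_params.get("rows", 10)),
            int(som_params.get("cols", 10)),
            int(som_params.get("epochs", 50)),
            stage_seed(seed, 21),
            genes=dyn_a,
        )
    log.info(
        "dynamics: %d/%d dynamic (A/B), consensus positive=%d negative=%d",
        len(dyn_a),
        len(dyn_b),
        sum(v == "positive" for v in consensus.values()),
        sum(v == "negative" for v in consensus.values()),
    )
    return DynamicsResult(dyn_a, dyn_b, rec_a, rec_b, consensus, null, som)


def write_dynamics(res: DynamicsResult, outdir: Path) -> List[Path]:
    paths = []
    pa = {r.gene_id: r for r in res.records_a}
    pb = {r.gene_id: r for r in res.records_b}
    p = outdir / "classes.tsv"
    with open(p, "w") as fh:
        fh.write("gene_id\tpcc_a\tpcc_b\tlabel_a\tlabel_b\tconsensus\n")
        for g in sorted(res.consensus):
            ra, rb = pa.get(g), pb.get(g)
            fh.write(
                "\t".join(
                    [
                        g,
                        "NA" if ra is None or ra.pcc is None else "%.6f" % ra.pcc,
                        "NA" if rb is None or rb.pcc is None else "%.6f" % rb.pcc,
                        ra.label if ra else "absent",
                        rb.label if rb else "absent",
                        res.consensus[g],
                    ]
                )
                + "\n"
            )
    paths.append(p)
    p = outdir / "null_pcc.tsv"
    with open(p, "w") as fh:
        fh.write("pcc\n")
        for v in res.null_pcc:
            fh.write("%.6f\n" % v)
    paths.append(p)
    if res.som is not None:
        p = outdir / "som_assignment.tsv"
        with open(p, "w") as fh:
            fh.write("gene_id\trow\tcol\n")
            for g in sorted(res.som.assignment):
                r, c = res.som.assignment[g]
                fh.write(f"{g}\t{r}\t{c}\n")
        paths.append(p)
    return paths


def run_integration(
    consensus: Mapping[str, str],
    ko_table,
    bound: set,
    universe: set,
    cfg: PipelineConfig,
):
    ko = ko_differential(ko_table, cfg)
    sets = controlled_target_sets(consensus, ko, bound)
    pos_corr = {g for g, l in consensus.items() if l == "positive"} & universe
    neg_corr = {g for g, l in consensus.items() if l == "negative"} & universe
    overlaps = {
        "positive_vs_bound": hypergeometric_overlap(pos_corr, bound & universe, universe),
        "negative_vs_bound": hypergeometric_overlap(neg_corr, bound & universe, universe),
    }
    fractions = bound_fraction_by_class(
        {g: l for g, l in consensus.items() if g in universe}, bound & universe
    )
    log.info(
        "integrate: %d KO records, %d positively / %d negatively controlled",
        len(ko),
        len(sets.positively_controlled),
        len(sets.negatively_controlled),
    )
    return ko, sets, overlaps, fractions


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_all(config, outdir: str | Path | None = None, seed: int | None = None) -> RunManifest:
    """Execute every stage from one structured configuration.

    ``config`` is a mapping or a YAML file path; ``outdir`` and ``seed``
    override the config's values.  Missing input files abort before any
    stage runs.  Returns the run manifest (also written as manifest.json).
    """
    cfg_all = load_config(config)
    outdir = Path(outdir or cfg_all.get("outdir", "regonset_run"))
    seed = int(seed if seed is not None else cfg_all.get("seed", 0))
    thresholds = PipelineConfig.from_dict(cfg_all.get("thresholds", {}))
    dyn_cfg = dict(cfg_all.get("dynamics", {}))
    simulate_cfg = dict(cfg_all.get("simulate", {}))
    do_sim = bool(simulate_cfg.pop("enabled", True))

    manifest = RunManifest(
        config=cfg_all, seed=seed, version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    outdir.mkdir(parents=True, exist_ok=True)

    # preflight
    inputs = dict(cfg_all.get("inputs", {}))
    if not do_sim:
        missing = [k for k in _INPUT_KEYS if not inputs.get(k) or not Path(inputs[k]).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files before any stage ran: {missing}")

    report: Dict[str, object] = {"seed": seed, "thresholds": thresholds.to_dict()}
    written: List[Path] = []

    # --- simulate -----------------------------------------------------------
    if do_sim:
        sim_conf = SimConfig.from_dict({**simulate_cfg, "seed": stage_seed(seed, 10)})
        sim = simulate(sim_conf, outdir / "sim")
        inputs = {k: sim.paths[k] for k in _INPUT_KEYS}
        written.extend(sim.paths.values())
        regulator = sim_conf.regulator_gene
        log.info("simulate: %d genes, %d peaks", len(sim.genes), len(sim.peaks))
    else:
        regulator = cfg_all.get("regulator")
        if not regulator:
            raise ConfigError("config must name the regulator gene when not simulating")

    genes = read_genes_bed(inputs["genes"])
    expr_a = read_expression_tsv(inputs["expr_a"], "A")
    expr_b = read_expression_tsv(inputs["expr_b"], "B")
    peaks = read_peaks_bed(inputs["peaks"])
    sequences = read_fasta(inputs["peaks_fa"])
    mask = read_intervals_bed(inputs["repeats"])
    ko_table = read_ko_tsv(inputs["ko"])

    # --- dynamics -----------------------------------------------------------
    dyn = run_dynamics(
        expr_a,
        expr_b,
        regulator,
        thresholds,
        int(dyn_cfg.get("n_permutations", 100)),
        dyn_cfg.get("som", {}),
        seed,
    )
    written.extend(write_dynamics(dyn, outdir))
    if dyn.som is not None and dyn_cfg.get("mosaic", False):
        from .expression_dynamics import plot_mosaic

        plot_mosaic(dyn.som, outdir / "mosaic.png")
        written.append(outdir / "mosaic.png")
    report["dynamics"] = {
        "dynamic_a": len(dyn.dynamic_a),
        "dynamic_b": len(dyn.dynamic_b),
        "consensus_positive": sum(v == "positive" for v in dyn.consensus.values()),
        "consensus_negative": sum(v == "negative" for v in dyn.consensus.values()),
        "null_pcc_mean": float(np.mean(dyn.null_pcc)) if dyn.null_pcc.size else None,
    }

    # --- peaks --------------------------------------------------------------
    retained, excluded = filter_repeat_peaks(peaks, mask, thresholds)
    part_shared, part_late, overall_corr = partition_peaks(retained)
    labels = {pid: part_shared.label for pid in part_shared.peak_ids}
    labels.update({pid: part_late.label for pid in part_late.peak_ids})
    write_peaks_bed(retained, outdir / "retained.bed")
    with open(outdir / "partition.tsv", "w") as fh:
        fh.write("peak_id\tpartition\n")
        for pid in sorted(labels):
            fh.write(f"{pid}\t{labels[pid]}\n")
    written += [outdir / "retained.bed", outdir / "partition.tsv"]
    log.info("peaks: %d retained, %d repeat-excluded", len(retained), len(excluded))
    report["peaks"] = {
        "input": len(peaks),
        "retained": len(retained),
        "repeat_excluded": len(excluded),
        "shared": len(part_shared.peak_ids),
        "late_only": len(part_late.peak_ids),
        "height_correlations": {
            "shared": part_shared.height_correlations,
            "late_only": part_late.height_correlations,
            "overall": overall_corr,
        },
    }

    # --- annotate -----------------------------------------------------------
    links = assign_peaks(retained, genes, thresholds)
    targets = candidate_targets(links)
    breakdown = location_breakdown(links, labels)
    with open(outdir / "links.tsv", "w") as fh:
        fh.write("peak_id\tgene_id\tcategory\tdistance\n")
        for l in links:
            fh.write(f"{l.peak_id}\t{l.gene_id}\t{l.category}\t{l.distance}\n")
    (outdir / "targets.txt").write_text("".join(g + "\n" for g in sorted(targets)))
    write_json(breakdown, outdir / "breakdown.json")
    written += [outdir / "links.tsv", outdir / "targets.txt", outdir / "breakdown.json"]
    log.info("annotate: %d links, %d candidate targets", len(links), len(targets))
    report["annotation"] = {"links": len(links), "candidate_targets": len(targets),
                            "breakdown": breakdown}

    # --- motifs -------------------------------------------------------------
    cores, core_excluded = extract_cores(retained, sequences, mask, thresholds)
    hits = {
        name: sorted(pid for pid, seq in cores.items() if scan_consensus(seq, motif))
        for name, motif in DEFAULT_MOTIFS.items()
    }
    promoter_peaks = [pid for pid, cat in peak_category(links).items() if cat == "promoter"]
    matrix = build_annotation_matrix(
        sorted(cores), labels, promoter_peaks, hits
    )
    order, _ = cluster_annotation(matrix)
    ext = extended_consensus_counts(cores, "WGATA", "A")
    table, fisher_p = motif_promoter_association(matrix)
    with open(outdir / "hits.tsv", "w") as fh:
        fh.write("peak_id\tmotif\toffset\tstrand\n")
        for name, motif in DEFAULT_MOTIFS.items():
            for pid in sorted(cores):
                for off, strand in scan_consensus(cores[pid], motif):
                    fh.write(f"{pid}\t{name}\t{off}\t{strand}\n")
    matrix.to_csv(outdir / "annotation_matrix.tsv", sep="\t")
    (outdir / "cluster_order.txt").write_text("".join(pid + "\n" for pid in order))
    write_json(
        {
            "n_total": ext.n_total,
            "n_extended": ext.n_extended,
            "n_expected": ext.n_expected,
            "n_eligible": ext.n_eligible,
            "p_value": ext.p_value,
        },
        outdir / "extended_counts.json",
    )
    written += [
        outdir / "hits.tsv",
        outdir / "annotation_matrix.tsv",
        outdir / "cluster_order.txt",
        outdir / "extended_counts.json",
    ]
    log.info("motifs: %d cores (%d excluded), WGATA n=%d", len(cores), len(core_excluded), ext.n_total)
    report["motifs"] = {
        "cores": len(cores),
        "core_excluded": len(core_excluded),
        "hits": {name: len(v) for name, v in hits.items()},
        "extended_wgata": {"n_total": ext.n_total, "n_extended": ext.n_extended,
                           "n_expected": ext.n_expected},
        "promoter_association": {"table": table.tolist(), "p_value": fisher_p},
    }

    # --- integrate ----------------------------------------------------------
    universe = set(expr_a.genes) & set(expr_b.genes) & {g.gene_id for g in genes}
    ko, sets, overlaps, fractions = run_integration(
        dyn.consensus, ko_table, targets, universe, thresholds
    )
    write_json(
        {
            "positively_controlled": sorted(sets.positively_controlled),
            "negatively_controlled": sorted(sets.negatively_controlled),
            "venn_positive": sets.venn_positive,
            "venn_negative": sets.venn_negative,
        },
        outdir / "controlled_sets.json",
    )
    write_json({"positive": sets.venn_positive, "negative": sets.venn_negative},
               outdir / "venn.json")
    with open(outdir / "overlaps.tsv", "w") as fh:
        fh.write("comparison\tset_a\tset_b\tuniverse\toverlap\tp_hyper\n")
        for name, res in overlaps.items():
            fh.write(
                f"{name}\t{res.set_a_size}\t{res.set_b_size}\t{res.universe_size}\t"
                f"{res.overlap}\t{res.p_hyper:.6g}\n"
            )
    written += [outdir / "controlled_sets.json", outdir / "venn.json", outdir / "overlaps.tsv"]
    report["integration"] = {
        "ko_down": sum(r.direction == "down_in_null" for r in ko),
        "ko_up": sum(r.direction == "up_in_null" for r in ko),
        "positively_controlled": len(sets.positively_controlled),
        "negatively_controlled": len(sets.negatively_controlled),
        "venn_positive": sets.venn_positive,
        "venn_negative": sets.venn_negative,
        "overlap_p": {k: v.p_hyper for k, v in overlaps.items()},
        "bound_fraction_by_class": fractions,
    }

    # --- report + manifest --------------------------------------------------
    write_json(report, outdir / "report.json")
    written.append(outdir / "report.json")
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.digests = {
        str(p.relative_to(outdir)): _sha256(Path(p)) for p in sorted(set(map(Path, written)))
    }
    write_json(
        {
            "config": cfg_all,
            "seed": seed,
            "version": manifest.version,
            "started": manifest.started,
            "finished": manifest.finished,
            "digests": manifest.digests,
        },
        outdir / "manifest.json",
    )
    return manifest
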