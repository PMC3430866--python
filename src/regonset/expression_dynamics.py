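"""Dynamic-gene selection, regulator correlation and the SOM mosaic.

The timecourse analysis runs in four steps: (1) keep genes whose expression
is both dynamic (standard deviation of the four log2 values above a
threshold) and detectably expressed (linear value above a floor in at least
one population); (2) compute each dynamic gene's four-point Pearson
correlation with the regulator on the log2 scale; (3) classify genes as
positively / negatively correlated with inclusive cut-offs, requiring both
array platforms to agree; (4) summarise the dynamics as a self-organising-
map mosaic, with a column-permutation null confirming that the observed
correlation structure is not an artefact of the value distributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genomic_io import ExpressionMatrix, POPULATIONS

__all__ = [
    "CorrelationRecord",
    "filter_dynamic",
    "correlate_with_regulator",
    "classify",
    "platform_consensus",
    "randomized_control",
    "som_mosaic",
    "SomResult",
    "plot_mosaic",
]

POSITIVE = "positive"
NEGATIVE = "negative"
UNCLASSIFIED = "unclassified"


@dataclass
class CorrelationRecord:
    gene_id: str
    pcc: float | None  # None when the gene has zero variance
    label: str = UNCLASSIFIED


def _log2p1(values: np.ndarray) -> np.ndarray:
    return np.log2(values + 1.0)


def filter_dynamic(expr: ExpressionMatrix, cfg: PipelineConfig = PipelineConfig()) -> Set[str]:
    """Genes with log2 SD above threshold and a linear value above the floor.

    The variability criterion uses the sample (n-1) standard deviation of
    ``log2(value + 1)`` over the four populations; the expression floor is
    applied to the raw linear values.
    """
    X = expr.values.to_numpy(dtype=float)
    sd = np.std(_log2p1(X), axis=1, ddof=1)
    keep = (sd > cfg.sd_threshold) & (X.max(axis=1) > cfg.min_expression)
    return set(np.asarray(expr.genes)[keep])


def _pearson_rows(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row of X with y; NaN for zero variance."""
    Xc = X - X.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = Xc @ yc
    den = np.sqrt((Xc**2).sum(axis=1) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def correlate_with_regulator(
    expr: ExpressionMatrix,
    regulator_gene: str,
    dynamic_set: Iterable[str],
    cfg: PipelineConfig = PipelineConfig(),
) -> List[CorrelationRecord]:
    """Four-point Pearson correlation of each dynamic gene with the regulator.

    Correlations are computed on ``log2(value + 1)`` profiles.  Genes whose
    profile has zero variance get no coefficient and stay unclassified.
    """
    if regulator_gene not in expr.values.index:
        raise KeyError(f"regulator {regulator_gene!r} absent from platform {expr.platform}")
    genes = sorted(set(dynamic_set) & set(expr.genes))
    y = _log2p1(expr.profile(regulator_gene))
    if np.allclose(y, y[0]):
        raise ValueError(f"regulator {regulator_gene!r} has a flat profile")
    X = _log2p1(expr.values.loc[genes].to_numpy(dtype=float))
    r = _pearson_rows(X, y)
    records = []
    for g, ri in zip(genes, r):
        records.append(CorrelationRecord(g, None if np.isnan(ri) else float(ri)))
    return records


def classify(
    records: Sequence[CorrelationRecord], cfg: PipelineConfig = PipelineConfig()
) -> List[CorrelationRecord]:
    """Label records with inclusive cut-offs (>= pos_cut / <= neg_cut)."""
    out = []
    for rec in records:
        if rec.pcc is None:
            label = UNCLASSIFIED
        elif rec.pcc >= cfg.pos_cut:
            label = POSITIVE
        elif rec.pcc <= cfg.neg_cut:
            label = NEGATIVE
        else:
            label = UNCLASSIFIED
        out.append(CorrelationRecord(rec.gene_id, rec.pcc, label))
    return out


def platform_consensus(
    labels_a: Mapping[str, str], labels_b: Mapping[str, str]
) -> Dict[str, str]:
    """Per-gene consensus: a class only when both platforms agree on it.

    Genes absent from either platform, or labelled differently by the two,
    are unclassified.  The result covers the union of both gene sets.
    """
    out: Dict[str, str] = {}
    for g in set(labels_a) | set(labels_b):
        la, lb = labels_a.get(g), labels_b.get(g)
        if la == lb and la in (POSITIVE, NEGATIVE):
            out[g] = la
        else:
            out[g] = UNCLASSIFIED
    return out


def randomized_control(
    expr: ExpressionMatrix,
    regulator_gene: str,
    n_permutations: int,
    seed: int,
    genes: Iterable[str] | None = None,
) -> np.ndarray:
    """Null correlation distribution from within-gene column shuffles.

    Each permutation independently shuffles every gene's four values
    (preserving each gene's value multiset) and recomputes the correlation
    with the *unshuffled* regulator; all finite coefficients are pooled.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if regulator_gene not in expr.values.index:
        raise KeyError(f"regulator {regulator_gene!r} absent")
    rng = np.random.default_rng(seed)
    use = sorted(set(genes) & set(expr.genes)) if genes is not None else [
        g for g in expr.genes if g != regulator_gene
    ]
    X = _log2p1(expr.values.loc[use].to_numpy(dtype=float))
    y = _log2p1(expr.profile(regulator_gene))
    pooled = []
    for _ in range(n_permutations):
        r = _pearson_rows(rng.permuted(X, axis=1), y)
        pooled.append(r[np.isfinite(r)])
    return np.concatenate(pooled) if pooled else np.array([])


# ---------------------------------------------------------------------------
# self-organising map mosaic
# ---------------------------------------------------------------------------


@dataclass
class SomResult:
    """Gene-to-tile assignment and per-tile summaries of a trained SOM."""

    grid: Tuple[int, int]
    assignment: Dict[str, Tuple[int, int]]
    codebook: np.ndarray  # (rows, cols, 4) in standardized profile space
    tile_mean_profile: np.ndarray  # (rows, cols, 4) mean log2 profile, NaN if empty
    tile_counts: np.ndarray  # (rows, cols) genes per tile


def som_mosaic(
    expr: ExpressionMatrix,
    grid_rows: int = 10,
    grid_cols: int = 10,
    epochs: int = 50,
    seed: int = 0,
    genes: Iterable[str] | None = None,
) -> SomResult:
    """Batch self-organising map of standardized four-point profiles.

    Profiles are z-scored per gene (flat profiles map to the zero vector),
    the codebook is initialised from random genes, and each epoch assigns
    every gene to its best-matching tile then replaces each tile's code
    vector by the Gaussian-neighbourhood-weighted mean of the profiles.
    The neighbourhood radius decays geometrically from half the larger grid
    dimension to 0.5 over the epochs.  Deterministic for a fixed seed; ties
    in the best-matching-unit search resolve to the lowest tile index.
    """
    if grid_rows < 2 or grid_cols < 2:
        raise ValueError("SOM grid must be at least 2x2")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    use = sorted(set(genes) & set(expr.genes)) if genes is not None else list(expr.genes)
    if not use:
        raise ValueError("no genes to train on")
    n_tiles = grid_rows * grid_cols
    if len(use) < n_tiles:
        warnings.warn(
            f"fewer genes ({len(use)}) than tiles ({n_tiles}); training proceeds",
            stacklevel=2,
        )

    raw = _log2p1(expr.values.loc[use].to_numpy(dtype=float))
    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    X = np.where(sd > 0, (raw - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    rng = np.random.default_rng(seed)
    init_idx = rng.choice(len(use), size=n_tiles, replace=len(use) < n_tiles)
    W = X[init_idx] + rng.normal(0.0, 1e-3, size=(n_tiles, 4))

    coords = np.array([(r, c) for r in range(grid_rows) for c in range(grid_cols)], dtype=float)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    sigma0 = max(grid_rows, grid_cols) / 2.0
    sigma1 = 0.5

    bmu = np.zeros(len(use), dtype=int)
    for t in range(epochs):
        sigma = sigma0 * (sigma1 / sigma0) ** (t / max(epochs - 1, 1))
        d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
        bmu = np.argmin(d2, axis=1)
        H = np.exp(-grid_d2 / (2.0 * sigma**2))  # (tile, tile)
        weight = H[:, bmu]  # (tile, gene)
        denom = weight.sum(axis=1)
        numer = weight @ X
        nonzero = denom > 1e-12
        W[nonzero] = numer[nonzero] / denom[nonzero, None]

    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=2)
    bmu = np.argmin(d2, axis=1)

    assignment = {
        g: (int(coords[b, 0]), int(coords[b, 1])) for g, b in zip(use, bmu)
    }
    tile_counts = np.zeros((grid_rows, grid_cols), dtype=int)
    tile_mean = np.full((grid_rows, grid_cols, 4), np.nan)
    for tile in range(n_tiles):
        members = np.nonzero(bmu == tile)[0]
        r, c = int(coords[tile, 0]), int(coords[tile, 1])
        tile_counts[r, c] = len(members)
        if len(members):
            tile_mean[r, c] = raw[members].mean(axis=0)
    return SomResult(
        (grid_rows, grid_cols),
        assignment,
        W.reshape(grid_rows, grid_cols, 4),
        tile_mean,
        tile_counts,
    )


def plot_mosaic(result: SomResult, path) -> None:
    """Render the per-population tile-mean mosaic to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
    finite = result.tile_mean_profile[np.isfinite(result.tile_mean_profile)]
    vmin = float(finite.min()) if finite.size else 0.0
    vmax = float(finite.max()) if finite.size else 1.0
    for k, ax in enumerate(axes):
        im = ax.imshow(
            result.tile_mean_profile[:, :, k], cmap="RdYlBu_r", vmin=vmin, vmax=vmax
        )
        ax.set_title(POPULATIONS[k])
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, shrink=0.8, label="mean log2 expression")
    fig.savefig(path, dpi=120)
    plt.close(fig)
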