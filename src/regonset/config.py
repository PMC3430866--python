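"""Numeric thresholds shared by every analysis stage.

All thresholds the method depends on live in a single :class:`PipelineConfig`
so a run is fully described by one object: the dynamic-gene filter (standard
deviation of log2 intensities and a linear intensity floor), the correlation
cut-offs used to classify genes against the regulator, the promoter and
intergenic windows for peak-to-gene assignment, the motif-core geometry and
repeat-exclusion fraction, and the knockout differential-expression rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds for the full expression/binding integration analysis.

    Parameters
    ----------
    sd_threshold:
        Minimum sample standard deviation of the four log2 expression values
        for a gene to count as dynamically expressed.
    min_expression:
        Linear intensity a gene must exceed in at least one population.
    pos_cut, neg_cut:
        Pearson-correlation cut-offs (inclusive) for the positively and
        negatively correlated classes.
    promoter_window_bp:
        Half-width of the symmetric window around a TSS within which a peak
        summit is a promoter binding event.
    intergenic_window_bp:
        Maximum summit-to-gene distance for intergenic assignment.
    core_bp:
        Length of the central peak core used for motif scanning.
    repeat_fraction:
        A peak (or core) with more than this fraction of repeat-masked bases
        is excluded.
    ko_fold, ko_alpha:
        Fold-change and p-value thresholds of the knockout differential
        expression rule.
    heatmap_halfwindow_bp:
        Flank on either side of a summit in binding-density heatmaps.
    height_corr_threshold:
        Pearson correlation of peak heights above which two populations are
        considered to share a binding pattern.
    """

    sd_threshold: float = 1.0
    min_expression: float = 100.0
    pos_cut: float = 0.8
    neg_cut: float = -0.6
    promoter_window_bp: int = 500
    intergenic_window_bp: int = 50_000
    core_bp: int = 200
    repeat_fraction: float = 0.6
    ko_fold: float = 1.5
    ko_alpha: float = 0.05
    heatmap_halfwindow_bp: int = 5_000
    height_corr_threshold: float = 0.80

    def __post_init__(self) -> None:
        if not (self.neg_cut < 0.0 < self.pos_cut):
            raise ConfigError(
                f"require neg_cut < 0 < pos_cut, got {self.neg_cut}, {self.pos_cut}"
            )
        for name in (
            "sd_threshold",
            "min_expression",
            "promoter_window_bp",
            "intergenic_window_bp",
            "core_bp",
            "heatmap_halfwindow_bp",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not 0.0 < self.repeat_fraction < 1.0:
            raise ConfigError("repeat_fraction must lie in (0, 1)")
        if self.ko_fold <= 1.0:
            raise ConfigError("ko_fold is a linear ratio and must exceed 1")
        if not 0.0 < self.ko_alpha < 1.0:
            raise ConfigError("ko_alpha must lie in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        return cls(**dict(d))
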