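"""Analysis configuration.

All thresholds used across the pipeline live in one flat record so that a
single config file fully determines a run.  The defaults reproduce the
published analysis settings for the 50-day hESC myogenesis time course:
probes must be detected in at least 3 samples, show a log2 range of at
least 2 with a log2 level of at least 5 somewhere, differential calls
require a 4-fold change at p <= 0.05 and BH FDR <= 0.05, clusters must
reach homogeneity 0.85, motif over-representation requires Z >= 5 at a
0.60 conservation cutoff over +/-2000 bp promoters, and the cross-dataset
quadrants use a 4-fold cutoff.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml


@dataclass
class AnalysisConfig:
    """Thresholds and parameters shared by every pipeline stage.

    Parameters
    ----------
    detection_min_samples:
        A probe is kept only if flagged detected-above-background in at
        least this many samples.
    expr_floor:
        Minimum log2 expression a probe must reach in at least one sample.
    range_min:
        Minimum (max - min) log2 range across samples for the variation
        filter feeding clustering.
    fc_min:
        Minimum linear fold change for differential-expression calls.
    p_max, fdr_max:
        Two-sided t-test p-value and Benjamini-Hochberg FDR ceilings.
    homogeneity_min:
        Minimum mean member-vs-centroid Pearson correlation a cluster must
        reach.
    merge_r:
        Centroid Pearson correlation above which similarly patterned
        clusters are grouped.
    z_min:
        Motif over-representation Z-score significance threshold.
    conservation_min:
        Mean per-base conservation a motif hit window must reach when a
        conservation track is supplied.
    promoter_halfwidth:
        Bases taken on each side of the transcription start site.
    rel_score_min:
        Relative PWM score threshold in (0, 1] for calling a motif hit.
    quadrant_fold:
        Linear fold cutoff defining the cross-dataset scatter quadrants.
    coexpr_r:
        Pearson threshold for single-gene co-expression neighbour lists.
    min_cluster_size:
        Clusters smaller than this are dissolved into the unclustered pool.
    seed:
        Seed for any stochastic step.
    """

    detection_min_samples: int = 3
    expr_floor: float = 5.0
    range_min: float = 2.0
    fc_min: float = 4.0
    p_max: float = 0.05
    fdr_max: float = 0.05
    homogeneity_min: float = 0.85
    merge_r: float = 0.90
    z_min: float = 5.0
    conservation_min: float = 0.60
    promoter_halfwidth: int = 2000
    rel_score_min: float = 0.85
    quadrant_fold: float = 4.0
    coexpr_r: float = 0.8
    min_cluster_size: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.detection_min_samples < 0:
            raise ValueError("detection_min_samples must be >= 0")
        if self.fc_min <= 1:
            raise ValueError("fc_min must exceed 1 (linear fold)")
        if self.quadrant_fold <= 1:
            raise ValueError("quadrant_fold must exceed 1 (linear fold)")
        for name in ("p_max", "fdr_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        for name in ("homogeneity_min", "merge_r", "rel_score_min",
                     "conservation_min"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if not -1 < self.coexpr_r <= 1:
            raise ValueError("coexpr_r must lie in (-1, 1]")
        if self.promoter_halfwidth <= 0:
            raise ValueError("promoter_halfwidth must be positive")
        if self.z_min <= 0 or not math.isfinite(self.z_min):
            raise ValueError("z_min must be a positive finite number")

    @property
    def log2_fc_min(self) -> float:
        return math.log2(self.fc_min)

    @property
    def log2_quadrant_cut(self) -> float:
        return math.log2(self.quadrant_fold)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
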