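"""Pipeline configuration: fixed analysis constants and input paths.

The defaults encode the analysis conventions used throughout the package:
GISTIC-style calls at or above +2 count as high-level amplification, cells
are stratified at the within-sample expression quartiles (0.25 / 0.75),
differential expression requires |avg_log2FC| > 2 at BH-adjusted p < 0.05,
spatial high-expression regions are the top 25% of spots, permutation nulls
use 1,000 shuffles, and significance is declared at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import yaml

from .errors import ConfigurationError


@dataclass
class Thresholds:
    """Numeric constants shared by the analysis stages."""

    amp_call_cutoff: int = 2          # copy-number call >= cutoff => amplified
    quartile_low: float = 0.25        # bottom-quartile bound for "low" cells
    quartile_high: float = 0.75       # top-quartile bound for "high" cells
    lfc_threshold: float = 2.0        # |avg_log2FC| must exceed this to pass
    deg_alpha: float = 0.05           # BH-adjusted p cutoff for DE genes
    top_fraction: float = 0.25        # spatial high-expression region size
    permutations: int = 1000          # B, coordinate-shuffle null size
    alpha: float = 0.05               # global significance level

    def validate(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ConfigurationError(
                f"top_fraction must lie in (0, 1), got {self.top_fraction}"
            )
        if self.permutations < 1:
            raise ConfigurationError(
                f"permutations must be >= 1, got {self.permutations}"
            )
        if not 0 <= self.quartile_low < self.quartile_high <= 1:
            raise ConfigurationError(
                "quartile bounds must satisfy 0 <= low < high <= 1, got "
                f"({self.quartile_low}, {self.quartile_high})"
            )
        for name in ("deg_alpha", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1), got {v}")
        if self.lfc_threshold < 0:
            raise ConfigurationError("lfc_threshold must be nonnegative")


@dataclass
class PipelineConfig:
    """Paths, anchor gene, thresholds and seed for a pipeline run."""

    inputs: dict[str, str] = field(default_factory=dict)
    anchor_gene: str = "CCNE1"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    outdir: str = "results"

    def validate(self) -> None:
        self.thresholds.validate()
        if not self.anchor_gene:
            raise ConfigurationError("anchor_gene must be a nonempty label")

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML pipeline configuration.

    Unknown top-level keys are rejected so that typos fail loudly rather
    than silently falling back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping: {path}")
    known = {"inputs", "anchor_gene", "thresholds", "seed", "outdir"}
    extra = set(raw) - known
    if extra:
        raise ConfigurationError(f"unknown config keys: {sorted(extra)}")
    thr_raw = raw.pop("thresholds", {}) or {}
    thr_known = {f.name for f in Thresholds.__dataclass_fields__.values()}
    thr_extra = set(thr_raw) - thr_known
    if thr_extra:
        raise ConfigurationError(f"unknown threshold keys: {sorted(thr_extra)}")
    cfg = PipelineConfig(thresholds=Thresholds(**thr_raw), **raw)
    cfg.validate()
    return cfg


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
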