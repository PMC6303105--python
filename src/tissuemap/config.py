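"""Pipeline configuration: every tunable threshold in one validated object.

Defaults are the conventions of the deep-coverage full-length single-cell
workflow this package implements: cell QC at 20% mitochondrial reads /
500k alignments / 500 detected genes / 20% mRNA bases; the expression
gene filter log2(CPM) > 2 in >= 10 cells; the count gene filter >= 10
counts in >= 10 cells; k = 3 consensus clusters; top-70 tissue
signatures; t-SNE perplexity 13 with 5 initial dimensions; 5 unscaled
principal components for HCPC; bulk mean-count cutoff 1000; pseudocount 1.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .clustering import DISTANCES, TRANSFORMS
from .containers import ValidationError


@dataclass
class PipelineConfig:
    seed: int = 0
    # cell QC
    max_mito: float = 0.20
    min_alignments: int = 500_000
    min_genes: int = 500
    min_mrna: float = 0.20
    # gene filters
    min_log2_cpm: float = 2.0
    min_cells_expression: int = 10
    min_count: int = 10
    min_cells_count: int = 10
    biotype: str = "protein_coding"
    # clustering
    k: int = 3
    distances: tuple[str, ...] = DISTANCES
    transforms: tuple[str, ...] = TRANSFORMS
    dim_fraction_low: float = 0.04
    dim_fraction_high: float = 0.07
    min_auroc: float = 0.85
    max_p: float = 0.01
    # tissue classification
    top_n: int = 70
    perplexity: float = 13.0
    initial_dims: int = 5
    n_components: int = 5
    scale: bool = False
    # comparative
    min_bulk_mean: float = 1000.0
    # normalization
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        self.distances = tuple(self.distances)
        self.transforms = tuple(self.transforms)

    def validate(self) -> "PipelineConfig":
        if self.k < 2:
            raise ValidationError(f"k must be >= 2, got {self.k}")
        for name in ("max_mito", "min_mrna"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a fraction in [0, 1], got {v}")
        for name in ("min_alignments", "min_genes", "min_cells_expression",
                     "min_count", "min_cells_count", "top_n", "n_components"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.perplexity <= 0:
            raise ValidationError("perplexity must be positive")
        if self.initial_dims < 2:
            raise ValidationError("initial_dims must be >= 2")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if not 0 < self.dim_fraction_low <= self.dim_fraction_high < 1:
            raise ValidationError("dimension fractions must satisfy 0 < low <= high < 1")
        unknown = set(self.distances) - set(DISTANCES)
        if unknown or not self.distances:
            raise ValidationError(f"distances must be a non-empty subset of {DISTANCES}")
        unknown = set(self.transforms) - set(TRANSFORMS)
        if unknown or not self.transforms:
            raise ValidationError(f"transforms must be a non-empty subset of {TRANSFORMS}")
        if self.min_bulk_mean < 0:
            raise ValidationError("min_bulk_mean must be non-negative")
        return self

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["distances"] = list(self.distances)
        d["transforms"] = list(self.transforms)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)
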