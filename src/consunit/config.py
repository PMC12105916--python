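"""Run configuration: clustering, filtering and scoring parameters."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

__all__ = ["RunConfig", "DEFAULT_GVALUE_WEIGHTS"]

#: Equal weights over the four genetic metrics entering the composite
#: genetic value; member count available as a fifth variable, default off.
DEFAULT_GVALUE_WEIGHTS: dict[str, float] = {
    "allele_prop": 1.0,
    "heterozygosity": 1.0,
    "dist_between": 1.0,
    "dist_within": 1.0,
    "n_members": 0.0,
}


@dataclass
class RunConfig:
    """Parameters of a full unit-definition / scoring run.

    Distances and sizes are metres in the projected CRS; frequency and
    missingness thresholds are proportions in (0, 1).
    """

    eps_m: float = 100.0
    min_pts: int = 3
    perimeter_max_m: float = 700.0
    grid_sizes_m: list[float] = field(default_factory=lambda: [50.0, 100.0, 250.0, 500.0])
    maf_common: float = 0.05
    maf_rare_low: float = 0.01
    locus_missing_max: float = 0.30
    sample_missing_max: float = 0.30
    reproducibility_min: float = 0.96
    gvalue_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GVALUE_WEIGHTS)
    )
    buffer_m: float = 100.0
    hull_buffer_m: float = 10.0
    crs_code: str | None = None
    rng_seed: int = 0
    grid_binning: str = "round"  # or "floor"
    normalize_variables: bool = True
    between_mode: str = "mean_of_means"  # or "pooled"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("maf_common", "maf_rare_low", "locus_missing_max",
                     "sample_missing_max", "reproducibility_min"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.maf_rare_low > self.maf_common:
            raise ValueError("maf_rare_low must not exceed maf_common")
        for name in ("eps_m", "perimeter_max_m", "buffer_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.min_pts < 1:
            raise ValueError("min_pts must be >= 1")
        if any(s <= 0 for s in self.grid_sizes_m):
            raise ValueError("grid sizes must be > 0")
        w = self.gvalue_weights
        if any(x < 0 for x in w.values()):
            raise ValueError("gvalue weights must be >= 0")
        if not any(x > 0 for x in w.values()):
            raise ValueError("gvalue weights must not be all zero")
        if self.grid_binning not in ("round", "floor"):
            raise ValueError("grid_binning must be 'round' or 'floor'")
        if self.between_mode not in ("mean_of_means", "pooled"):
            raise ValueError("between_mode must be 'mean_of_means' or 'pooled'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
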