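"""Pipeline configuration: one flat document, serializable to YAML.

CLI flags override config values; every tunable the pipeline consumes is
explicit here so a run is fully described by (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PlatformPaths", "PipelineConfig"]


@dataclass
class PlatformPaths:
    """File locations for one expression dataset."""

    platform_id: str
    values: str
    groups: str
    probe_map: str | None = None


@dataclass
class PipelineConfig:
    # inputs
    network_path: str = ""
    expression: list[PlatformPaths] = field(default_factory=list)
    omim_path: str = ""
    proteomics_path: str = ""
    loci_path: str = ""
    gmt_path: str = ""
    abundance_path: str | None = None
    reference_network_path: str | None = None
    drug_targets_path: str | None = None
    # outputs
    out_dir: str = "katznet_out"
    # expression screen
    fdr_level: float = 0.10
    fold_low: float = 0.67
    fold_high: float = 1.5
    pooled_fdr: bool = False
    # propagation / calibration
    phi_grid_min: float = 1e-6
    phi_grid_max: float = 1e-2
    phi_grid_points: int = 30
    n_candidates: int = 100
    top_fraction: float = 0.10
    top_denominator: str = "all_genes"
    # subnetwork / topology
    weight_floor: float = 0.5
    prune_isolated: bool = True
    k_outer_max: int = 10
    k_medium_max: int = 35
    # enrichment
    alpha: float = 0.05
    enrich_query: str = "subnetwork"  # or "top"
    # misc
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.expression = [
            p if isinstance(p, PlatformPaths) else PlatformPaths(**p) for p in self.expression
        ]
        self.validate()

    def validate(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must lie in (0, 1)")
        if not 0 < self.fold_low < 1 < self.fold_high:
            raise ValueError("fold bounds must satisfy 0 < low < 1 < high")
        if not 0 < self.phi_grid_min < self.phi_grid_max:
            raise ValueError("phi grid bounds must satisfy 0 < min < max")
        if self.phi_grid_points < 1:
            raise ValueError("phi_grid_points must be >= 1")
        if not 0 < self.top_fraction <= 1:
            raise ValueError("top_fraction must lie in (0, 1]")
        if self.top_denominator not in ("all_genes", "positive_score"):
            raise ValueError("top_denominator must be 'all_genes' or 'positive_score'")
        if not 0 <= self.weight_floor <= 1:
            raise ValueError("weight_floor must lie in [0, 1]")
        if not 0 < self.k_outer_max < self.k_medium_max:
            raise ValueError("partition cutpoints must satisfy 0 < outer < medium")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.enrich_query not in ("subnetwork", "top"):
            raise ValueError("enrich_query must be 'subnetwork' or 'top'")
        if self.n_candidates < 1:
            raise ValueError("n_candidates must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def required_input_paths(self) -> dict[str, str]:
        paths = {
            "network_path": self.network_path,
            "omim_path": self.omim_path,
            "proteomics_path": self.proteomics_path,
            "loci_path": self.loci_path,
            "gmt_path": self.gmt_path,
        }
        for p in self.expression:
            paths[f"expression[{p.platform_id}].values"] = p.values
            paths[f"expression[{p.platform_id}].groups"] = p.groups
            if p.probe_map:
                paths[f"expression[{p.platform_id}].probe_map"] = p.probe_map
        return paths

    def preflight(self) -> None:
        """Validate that every required input exists before any stage runs."""
        if not self.expression:
            raise ValueError("config lists no expression datasets")
        missing = [
            f"{name}: {path!r}"
            for name, path in self.required_input_paths().items()
            if not path or not Path(path).exists()
        ]
        if missing:
            raise FileNotFoundError("missing pipeline inputs:\n  " + "\n  ".join(missing))
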