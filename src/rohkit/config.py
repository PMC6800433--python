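"""Pipeline configuration.

One dataclass holds every tunable the stages share, with defaults fixed
to the standard study values where one exists: recombination rate 1.1
cM/Mb, ROH length floor 2 Mb, mitochondrial clock 1.15%/Myr.  Configs
round-trip through YAML; command-line flags override file values.
"""

from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field

import yaml

from .dating import DEFAULT_BIN_EDGES_MB, DEFAULT_RATE_CM_PER_MB
from .heterozygosity import DEFAULT_WINDOW, MIN_CALLABLE_FRAC
from .ibd import DEFAULT_IDENTITY_THRESHOLD, DEFAULT_MIN_OVERLAP
from .mito import DEFAULT_CLOCK_RATE
from .roh_hmm import DEFAULT_MIN_LENGTH


@dataclass
class PipelineConfig:
    window_size: int = DEFAULT_WINDOW
    r_cm_per_mb: float = DEFAULT_RATE_CM_PER_MB
    min_roh_length: int = DEFAULT_MIN_LENGTH
    bin_edges_mb: tuple[float, ...] = DEFAULT_BIN_EDGES_MB
    min_callable_frac: float = MIN_CALLABLE_FRAC
    ancestry_eps: float = 0.01
    ancestry_tau: float = 2e-7
    clock_rate: float = DEFAULT_CLOCK_RATE
    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
    min_overlap: int = DEFAULT_MIN_OVERLAP
    seed: int = 0
    # simulation defaults (used by the `simulate` and `run` stages)
    scenario: str = "isolated_inbred"
    g: int = 3
    het_rate: float = 1e-3
    fixed_diff_rate: float = 1e-4
    scaffold_length: int = 25_000_000
    n_scaffolds: int = 4
    n_founders: int | None = None
    n_panel: int = 3

    def __post_init__(self) -> None:
        positive = {
            "window_size": self.window_size,
            "r_cm_per_mb": self.r_cm_per_mb,
            "min_roh_length": self.min_roh_length,
            "clock_rate": self.clock_rate,
            "scaffold_length": self.scaffold_length,
            "n_scaffolds": self.n_scaffolds,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")

    def scaffold_lengths(self) -> dict[str, int]:
        return {f"scaf{i+1}": self.scaffold_length for i in range(self.n_scaffolds)}

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["bin_edges_mb"] = [
            e if e != float("inf") else ".inf" for e in d["bin_edges_mb"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "bin_edges_mb" in d:
            d["bin_edges_mb"] = tuple(
                float("inf") if e in (".inf", "inf") else float(e)
                for e in d["bin_edges_mb"]
            )
        return cls(**d)
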