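"""Analysis configuration and seeded random-stream derivation.

One master seed governs the whole pipeline.  Every stochastic stage
derives its own independent generator keyed by a stage name, so adding
or reordering stages never perturbs the streams of the others.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field

import numpy as np


class ConfigError(ValueError):
    pass


def derive_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one named stage under a master seed."""
    key = zlib.crc32(stage.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


@dataclass
class AnalysisConfig:
    """Knobs shared across the pipeline.

    depth / iterations: rarefaction depth in reads and number of
    independent rarefactions averaged for alpha diversity (defaults 500
    and 10, the even-sampling convention for desk-scale 454 data).
    prevalence: core-membership threshold as a fraction of individuals.
    permutations: B for every permutation/Monte-Carlo test.
    draw: individuals drawn per null replicate of the core-length test.
    """

    depth: int = 500
    iterations: int = 10
    prevalence: float = 0.8
    permutations: int = 1000
    draw: int = 5
    alpha: float = 0.05
    seed: int = 0
    min_samples: int = 2
    singleton_min_reads: int = 4
    exclude_phylum: str = "Cyanobacteria"
    exceptions: tuple = ("Melainabacteria", "YS2", "4C0d-2")
    below_depth: str = "drop"  # or "error"
    min_indval: float = 0.6

    def __post_init__(self):
        if not (0 < self.prevalence <= 1):
            raise ConfigError(f"prevalence must be in (0, 1], got {self.prevalence}")
        if self.depth < 1:
            raise ConfigError(f"depth must be >= 1, got {self.depth}")
        if self.permutations < 1:
            raise ConfigError(f"permutations must be >= 1, got {self.permutations}")
        if self.iterations < 1:
            raise ConfigError(f"iterations must be >= 1, got {self.iterations}")
        if self.draw < 2:
            raise ConfigError(f"draw must be >= 2, got {self.draw}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.below_depth not in ("drop", "error"):
            raise ConfigError("below_depth must be 'drop' or 'error'")
        self.exceptions = tuple(self.exceptions)

    def rng(self, stage: str) -> np.random.Generator:
        return derive_rng(self.seed, stage)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)
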