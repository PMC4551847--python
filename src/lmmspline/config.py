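"""Run configuration, seed fan-out and report writing.

One master seed deterministically fans out to per-stage seeds via
``numpy.random.SeedSequence`` so that the composite pipeline is
byte-for-byte reproducible.  Every run writes its resolved configuration
(YAML) next to its outputs.  TSV is the canonical inter-stage format;
floats are written with a fixed repr-stable format.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"

STAGES = ("filter", "model", "de", "cluster", "simulate", "benchmark")


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run."""

    matrix: str | None = None
    samples: str | None = None
    outdir: str = "lmmspline_out"
    stages: list[str] = field(default_factory=lambda: ["filter", "model",
                                                       "de"])
    seed: int = 0
    # filtering
    per_group: bool = True
    max_missing: float = 0.5
    # modelling
    alpha: float = 0.05
    basis: str = "linear"
    derivative: bool = False
    grid: list[float] | None = None
    # differential expression
    effects: list[str] = field(default_factory=lambda: ["time"])
    random_structure: str = "auto"
    spline_df: str = "random"
    fdr: float = 0.05
    filter_first: bool = False
    # clustering
    algorithms: list[str] = field(default_factory=lambda: [
        "hierarchical", "kmeans", "pam", "som", "model_based"])
    kmin: int = 2
    kmax: int = 9
    metric: str = "euclidean"
    annotations: str | None = None

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage child seed below 2^31."""
        idx = STAGES.index(stage)
        child = np.random.SeedSequence([int(self.seed), idx])
        return int(child.generate_state(1, np.uint32)[0] % (2 ** 31))

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self),
                                             sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied (flags beat file)."""
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)


def write_tsv(frame: pd.DataFrame, path, index: bool = True) -> None:
    """Write a TSV with a fixed float format for reproducible bytes."""
    frame.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index=index)
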