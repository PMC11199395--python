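"""Run configuration shared by the CLI subcommands.

Defaults mirror the pipeline's standard settings: 100 nodes per tract,
outlier exclusion at 3 SD (Mahalanobis) / 5 SD (length) over 5 rounds, the
24 standard tract names, 4 DKI-derived metrics, half-float zip-compressed
TRX output, and 5-fold family-grouped nested CV repeated 100 times.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

from .core import METRIC_NAMES, TRACT_NAMES


@dataclass
class RunConfig:
    # profile extraction
    n_nodes: int = 100
    distance_threshold: float = 3.0
    length_threshold: float = 5.0
    n_rounds: int = 5
    metrics: list[str] = field(default_factory=lambda: list(METRIC_NAMES))
    tracts: list[str] = field(default_factory=lambda: list(TRACT_NAMES))
    weighting: str = "inverse_distance"

    # TRX output
    trx_dtype: str = "float16"
    trx_compress: bool = True
    zip_level: int = 6

    # heritability
    heritability_convention: str = "squared_difference"
    n_boot: int = 1000

    # prediction
    model: str = "lasso"
    alpha_mix: float = 0.95
    n_lambda: int = 100
    lambda_min_ratio: float = 1e-4
    cv_k: int = 5
    n_repeats: int = 100

    # simulation (desk-scale synthetic subject / cohort)
    n_streamlines: int = 100
    radial_sd: float = 2.0
    outlier_fraction: float = 0.05
    outlier_offset: float = 12.0
    n_mz_pairs: int = 138
    n_dz_pairs: int = 75

    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as f:
                f.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls.from_dict(json.load(f))

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
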