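"""Pipeline configuration: every decision threshold in one place."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path


@dataclass
class PipelineConfig:
    """Thresholds and paths for a full pipeline run.

    Thresholds are on the internal fraction scale (``dpsi_threshold=0.10``
    is the 10% dPSI cutoff; ``ratio_floor=0.01`` the 1% denominator floor).
    """

    dpsi_threshold: float = 0.10
    prob_threshold: float = 0.95
    min_donors: int = 2
    ratio_floor: float = 0.01
    ratio_threshold: float = 2.0
    fold_drop_threshold: float = 2.0
    flank: int = 250
    donor_exclusion: int = 7
    acceptor_exclusion: int = 30
    e_value_cutoff: float = 0.05
    enrichment_ratio_cutoff: float = 2.0
    k_min: int = 5
    k_max: int = 8
    log2fc_threshold: float = 1.5
    prior_strength: float = 0.5
    n_draws: int = 2000
    temporal_input_set: str = "union"  # or "sig_48h"
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "out"

    def validate(self) -> None:
        if not (0 < self.dpsi_threshold < 1):
            raise ValueError("dpsi_threshold must be in (0, 1)")
        if not (0 < self.prob_threshold < 1):
            raise ValueError("prob_threshold must be in (0, 1)")
        if self.min_donors < 1:
            raise ValueError("min_donors must be >= 1")
        if self.ratio_floor <= 0 or self.ratio_threshold <= 0:
            raise ValueError("ratio parameters must be positive")
        if self.fold_drop_threshold <= 1:
            raise ValueError("fold_drop_threshold must exceed 1")
        if self.flank <= max(self.donor_exclusion, self.acceptor_exclusion):
            raise ValueError("flank must exceed both exclusion widths")
        if not (0 < self.e_value_cutoff <= 1):
            raise ValueError("e_value_cutoff must be in (0, 1]")
        if not (4 <= self.k_min <= self.k_max <= 12):
            raise ValueError("require 4 <= k_min <= k_max <= 12")
        if self.temporal_input_set not in ("union", "sig_48h"):
            raise ValueError("temporal_input_set must be 'union' or 'sig_48h'")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg
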