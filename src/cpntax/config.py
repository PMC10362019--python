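"""Run configuration: every tunable constant of the pipeline in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """Resolved pipeline settings; serializes to/from a single YAML file.

    The confidence constants carry the conventional defaults for this kind
    of workflow: 0.8 for rank assignment, 0.9 for cross-validation scoring,
    0.6 at phylum rank for off-target filtering, and a 55% nearest-neighbor
    identity floor for true marker-gene sequences.
    """

    word_size: int = 8
    trials: int = 100
    subsample_divisor: int = 8
    assignment_cutoff: float = 0.8
    loo_cutoff: float = 0.9
    phylum_filter_cutoff: float = 0.6
    identity_threshold: float = 55.0
    sw_match: float = 5.0
    sw_mismatch: float = -4.0
    sw_gap_open: float = 20.0
    sw_gap_extend: float = 10.0
    seed: int = 0
    threads: int = 1

    def __post_init__(self) -> None:
        if self.word_size < 1 or self.trials < 1 or self.subsample_divisor < 1:
            raise ValueError("word_size, trials and subsample_divisor must be >= 1")
        for name in ("assignment_cutoff", "loo_cutoff", "phylum_filter_cutoff"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.identity_threshold <= 100:
            raise ValueError("identity_threshold must be in [0, 100]")
        if self.threads < 1:
            raise ValueError("threads must be >= 1")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def summary_line(self) -> str:
        return " ".join(f"{k}={v}" for k, v in sorted(asdict(self).items()))
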