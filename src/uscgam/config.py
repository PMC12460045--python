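"""Run configuration: the pipeline's user-facing thresholds and switches.

Defaults are the pipeline's published operating point: 50 bp minimum read
length; gene-hit identity 50 % and coverage 80 %; marker-hit bitscore 40 and
coverage 80 %; reference dereplication at 60 % identity.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class RunConfig:
    """All tunable thresholds of a pipeline run.

    Round-trips losslessly through YAML (``dump``/``load``).
    """

    min_length: int = 50
    filter_identity: float = 50.0
    filter_coverage: float = 80.0
    uscg_min_bitscore: float = 40.0
    uscg_min_coverage: float = 80.0
    derep_identity: float = 0.60
    zero_policy: str = "na"
    aa_to_bp: int = 3
    keep_intermediates: bool = False
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError(f"min_length must be >= 1, got {self.min_length}")
        if self.zero_policy not in ("na", "error", "pseudocount"):
            raise ValueError(f"unknown zero_policy {self.zero_policy!r}")
        if not (0.0 < self.derep_identity <= 1.0):
            raise ValueError(f"derep_identity must be in (0, 1], got {self.derep_identity}")

    def dump(self, path: str | Path | None = None) -> str:
        """Serialise to YAML; write to ``path`` when given."""
        text = yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ValueError(f"{path}: not a mapping")
        return cls(**data)
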