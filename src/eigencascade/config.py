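"""Pipeline configuration: one serializable object holding every threshold."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their defaults.

    Normalization follows the two conventions used for reference and query
    data (log2(RPM+1) and ln(RPM+1)); structure learning defaults to the
    Fisher z-test at alpha 0.01 with conditioning sets up to size 3.
    """

    normalization: str = "rpm_log2"          # rpm_log2 | rpm_ln | none
    mito_prefix: str = "MT-"
    mito_ceiling: float = 0.10
    alpha: float = 0.01
    max_cond: int = 3
    test_kind: str = "fisher_z"              # fisher_z | chi_square
    min_class_cells: int = 30
    msa_floor: float = 0.6
    loading_floor: float = 0.5
    communality_floor: float = 0.5
    top_n: int = 1000
    n_perm: int = 100
    percentile: float = 95.0
    k_min: int = 2
    k_max: int = 15
    n_init: int = 10
    reg_l1: float = 0.1
    reg_l2: float = 0.1
    n_folds: int = 5
    labeling_vertices: str = "markers"       # markers | all | file
    seed: int = 0

    def __post_init__(self) -> None:
        if self.normalization not in ("rpm_log2", "rpm_ln", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.test_kind not in ("fisher_z", "chi_square"):
            raise ValueError(f"unknown test kind {self.test_kind!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 <= self.mito_ceiling <= 1.0:
            raise ValueError("mito_ceiling must lie in [0, 1]")
        if self.max_cond < 0 or self.n_perm < 1 or self.n_init < 1:
            raise ValueError("max_cond, n_perm and n_init must be positive")
        if not 0.0 < self.percentile <= 100.0:
            raise ValueError("percentile must lie in (0, 100]")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)
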