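"""Pipeline configuration.

One flat dataclass carries every tunable threshold of the workflow, with the
defaults used throughout: genome-wide instrument selection at p < 1e-5,
clumping at r^2 < 0.001 within a 10,000 kb window, weak-instrument screen at
F >= 10, and nominal alpha = 0.05 for every significance gate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import InvalidParameterError


@dataclass
class PipelineConfig:
    # instrument selection
    p_threshold: float = 1e-5
    r2_threshold: float = 0.001
    window_kb: float = 10_000.0
    f_min: float = 10.0
    #: use the literal reading beta/se^2 of the instrument-strength screen
    #: instead of the conventional (beta/se)^2
    f_literal: bool = False
    # significance gates
    alpha: float = 0.05
    #: apply Benjamini-Hochberg across a screen instead of nominal alpha
    bh_correction: bool = False
    #: third-method confirmation in candidate selection requires p < alpha
    #: (False: directional consistency with IVW suffices)
    confirm_requires_pval: bool = True
    # estimator settings
    ivw_variant: str = "multiplicative_random"
    n_boot: int = 1000
    mode_phi: float = 1.0
    mode_grid: int = 512
    second_order_wald: bool = False
    # BWMR
    bwmr_tol: float = 1e-6
    bwmr_max_iter: int = 5000
    # MR-PRESSO
    n_sim_presso: int = 1000
    presso_outlier_alpha: float = 0.05
    # mediation
    delta_order: str = "first"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold <= 1:
            raise InvalidParameterError("p_threshold must be in (0, 1]")
        if not 0 <= self.r2_threshold <= 1:
            raise InvalidParameterError("r2_threshold must be in [0, 1]")
        if self.window_kb < 0 or self.f_min < 0:
            raise InvalidParameterError("window_kb and f_min must be non-negative")
        if self.ivw_variant not in ("fixed", "multiplicative_random"):
            raise InvalidParameterError(f"unknown IVW variant: {self.ivw_variant!r}")
        if self.delta_order not in ("first", "second"):
            raise InvalidParameterError(f"unknown delta order: {self.delta_order!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)
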