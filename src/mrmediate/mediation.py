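"""Two-step MR mediation with product-method decomposition.

The total effect c of an exposure on an outcome is decomposed into an
indirect component through a mediator, estimated by the product method
a*b (a: exposure->mediator, b: mediator->outcome, each from its own
univariable two-sample MR leg), and the residual direct effect
c' = c - a*b.  The proportion mediated is a*b/c.  Uncertainty in the
product uses the delta method: first order

    se(a*b) = sqrt(a^2 se_b^2 + b^2 se_a^2),

with the second-order refinement adding se_a^2 se_b^2 under the root.
The proportion's CI uses the delta method on the ratio a*b/c treating the
three estimates as independent, which the two-sample design supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .errors import InvalidParameterError
from .estimators import Z95, MREstimate, ivw
from .gwas import SummaryStats, harmonize, select_instruments
from .ld import LDMatrix


def product_effect(a: float, b: float) -> float:
    """Indirect (mediated) effect by the product method: a*b."""
    if not (np.isfinite(a) and np.isfinite(b)):
        raise InvalidParameterError("a and b must be finite")
    return float(a * b)


def delta_se_product(a: float, se_a: float, b: float, se_b: float,
                     order: str = "first") -> float:
    """Delta-method standard error of the product a*b."""
    if se_a < 0 or se_b < 0:
        raise InvalidParameterError("standard errors must be non-negative")
    var = a**2 * se_b**2 + b**2 * se_a**2
    if order == "second":
        var = var + se_a**2 * se_b**2
    elif order != "first":
        raise InvalidParameterError(f"unknown delta order {order!r}")
    return float(np.sqrt(var))


@dataclass
class MediationEstimate:
    """Product-method decomposition of a total effect.

    ``direct + indirect == total`` holds exactly; ``proportion`` is on the
    raw scale (multiply by 100 for percent) and is flagged undefined when
    c = 0 and inconsistent when indirect and total effects have opposite
    signs (proportion not interpretable as a share).
    """

    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: float
    se_a: float
    b: float
    se_b: float
    c: float
    se_c: float
    indirect: float = field(init=False)
    se_indirect: float = field(init=False)
    direct: float = field(init=False)
    proportion: float | None = field(init=False)
    ci_indirect: tuple[float, float] = field(init=False)
    ci_proportion: tuple[float, float] | None = field(init=False)
    delta_order: str = "first"
    proportion_defined: bool = field(init=False, default=True)
    consistent: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        self.indirect = product_effect(self.a, self.b)
        self.se_indirect = delta_se_product(self.a, self.se_a, self.b,
                                            self.se_b, order=self.delta_order)
        self.direct = self.c - self.indirect
        self.ci_indirect = (self.indirect - Z95 * self.se_indirect,
                            self.indirect + Z95 * self.se_indirect)
        if self.c == 0:
            self.proportion = None
            self.ci_proportion = None
            self.proportion_defined = False
            self.consistent = False
            return
        self.proportion = self.indirect / self.c
        # delta method on (a*b)/c assuming independent legs
        var_prop = ((self.b / self.c) ** 2 * self.se_a**2
                    + (self.a / self.c) ** 2 * self.se_b**2
                    + (self.indirect / self.c**2) ** 2 * self.se_c**2)
        half = Z95 * float(np.sqrt(var_prop))
        self.ci_proportion = (self.proportion - half, self.proportion + half)
        self.consistent = (self.indirect == 0) or (
            np.sign(self.indirect) == np.sign(self.c)
        )

    @property
    def proportion_pct(self) -> float | None:
        return None if self.proportion is None else 100.0 * self.proportion

    def to_row(self) -> dict:
        """One tidy table row mirroring a mediation-summary table."""
        return {
            "exposure": self.exposure_id, "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "a": self.a, "se_a": self.se_a, "b": self.b, "se_b": self.se_b,
            "c": self.c, "se_c": self.se_c,
            "indirect": self.indirect, "se_indirect": self.se_indirect,
            "direct": self.direct,
            "proportion_pct": self.proportion_pct,
            "ci_indirect_low": self.ci_indirect[0],
            "ci_indirect_high": self.ci_indirect[1],
            "ci_proportion_pct_low": (
                None if self.ci_proportion is None
                else 100 * self.ci_proportion[0]),
            "ci_proportion_pct_high": (
                None if self.ci_proportion is None
                else 100 * self.ci_proportion[1]),
            "consistent_mediation": self.consistent,
        }


def decompose(a_est: MREstimate, b_est: MREstimate, c_est: MREstimate,
              exposure_id: str = "exposure", mediator_id: str = "mediator",
              outcome_id: str = "outcome",
              delta_order: str = "first") -> MediationEstimate:
    """Decompose a total effect from the three per-leg MR estimates."""
    return MediationEstimate(
        exposure_id=exposure_id, mediator_id=mediator_id,
        outcome_id=outcome_id,
        a=a_est.beta, se_a=a_est.se, b=b_est.beta, se_b=b_est.se,
        c=c_est.beta, se_c=c_est.se, delta_order=delta_order,
    )


def mediation_pipeline(
    exposure: SummaryStats,
    mediator: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    config: PipelineConfig | None = None,
) -> MediationEstimate:
    """Full two-step mediation on three summary-statistic sets.

    Runs select -> harmonize -> IVW for each leg (exposure->mediator for a,
    mediator->outcome for b, exposure->outcome for c) and decomposes.
    Instrument selection is per selecting trait, so the two steps use
    disjoint instrument sets whenever exposure and mediator instruments do
    not overlap.
    """
    cfg = config or PipelineConfig()

    def leg(exp_stats, out_stats, name):
        try:
            inst = select_instruments(
                exp_stats, ld=ld, p_threshold=cfg.p_threshold,
                r2_threshold=cfg.r2_threshold, window_kb=cfg.window_kb,
                f_min=cfg.f_min, f_literal=cfg.f_literal,
            )
            pair = harmonize(inst, out_stats)
            return ivw(pair, variant=cfg.ivw_variant)
        except Exception as exc:
            raise type(exc)(f"mediation leg {name!r}: {exc}") from exc

    a_est = leg(exposure, mediator, "exposure->mediator")
    b_est = leg(mediator, outcome, "mediator->outcome")
    c_est = leg(exposure, outcome, "exposure->outcome")
    est = decompose(a_est, b_est, c_est,
                    exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
                    outcome_id=outcome.trait_id, delta_order=cfg.delta_order)
    return est


def mediation_table(estimates: list[MediationEstimate]) -> pd.DataFrame:
    """Tidy table of decompositions, one row per triplet."""
    return pd.DataFrame([e.to_row() for e in estimates])
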