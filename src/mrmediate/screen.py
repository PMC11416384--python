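"""Batch screening: forward MR over many exposures, reverse-MR exclusion,
sensitivity gating, and mediation-candidate selection.

The screening rules operationalize the study workflow: an exposure-outcome
association is *significant* when IVW and BWMR are both nominally
significant with concordant signs, unless a diagnostic gate (Cochran's Q,
Egger intercept, or MR-PRESSO global test below alpha) excludes it.
Mediation candidates additionally require the exposure->outcome leg to be
supported by at least three methods (IVW, BWMR and one of Egger / weighted
median / modes), no reverse-direction signal, and sign-consistent
mediation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig
from .diagnostics import SensitivityReport, sensitivity_report
from .errors import MrMediateError
from .estimators import MREstimate, fit_all, ivw
from .gwas import SummaryStats, harmonize, select_instruments
from .ld import LDMatrix

logger = logging.getLogger(__name__)

VERDICTS = ("significant", "not_significant", "excluded_pleiotropy",
            "excluded_heterogeneity", "excluded_reverse", "skipped")

#: methods that can serve as the confirming third method
CONFIRMING_METHODS = ("egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclass
class ScreenDecision:
    """Outcome of screening one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    estimates: dict[str, MREstimate] = field(default_factory=dict)
    sensitivity: SensitivityReport | None = None
    reverse_significant: bool = False
    verdict: str = "skipped"
    reason: str = ""
    n_methods_concordant: int = 0

    def to_row(self) -> dict:
        row = {"exposure": self.exposure_id, "outcome": self.outcome_id,
               "verdict": self.verdict, "reason": self.reason,
               "reverse_significant": self.reverse_significant,
               "n_methods_concordant": self.n_methods_concordant}
        for name, est in self.estimates.items():
            row[f"beta_{name}"] = est.beta
            row[f"pval_{name}"] = est.pval
        if self.sensitivity is not None:
            row["q_pval"] = self.sensitivity.q_pval
            row["egger_intercept_pval"] = self.sensitivity.egger_intercept_pval
            row["presso_global_pval"] = self.sensitivity.presso_global_pval
        return row


def _concordant(est: MREstimate, ref: MREstimate, alpha: float,
                require_pval: bool = True) -> bool:
    same_sign = np.sign(est.beta) == np.sign(ref.beta)
    return same_sign and (est.pval < alpha or not require_pval)


def count_concordant(estimates: dict[str, MREstimate], alpha: float = 0.05
                     ) -> int:
    """Number of methods nominally significant and sign-concordant with IVW."""
    ivw_est = estimates["ivw"]
    n = int(ivw_est.pval < alpha)
    for name, est in estimates.items():
        if name in ("ivw", "ivw_fe"):
            continue
        if _concordant(est, ivw_est, alpha):
            n += 1
    return n


def classify_significance(
    estimates: dict[str, MREstimate],
    sensitivity: SensitivityReport | None,
    alpha: float = 0.05,
) -> str:
    """Verdict for one pair under the default decision rule.

    Significant iff IVW and BWMR are both below alpha with the same sign;
    diagnostic gates take precedence and exclude the pair outright.
    """
    if "ivw" not in estimates or "bwmr" not in estimates:
        raise MrMediateError("classification requires IVW and BWMR estimates")
    if sensitivity is not None:
        if sensitivity.pleiotropic:
            return "excluded_pleiotropy"
        if sensitivity.heterogeneous:
            return "excluded_heterogeneity"
    ivw_est, bw_est = estimates["ivw"], estimates["bwmr"]
    ok = (ivw_est.pval < alpha and bw_est.pval < alpha
          and np.sign(ivw_est.beta) == np.sign(bw_est.beta))
    return "significant" if ok else "not_significant"


def screen_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> ScreenDecision:
    """Select, harmonize, estimate, diagnose and classify one pair."""
    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    decision = ScreenDecision(exposure.trait_id, outcome.trait_id)
    try:
        inst = select_instruments(
            exposure, ld=ld, p_threshold=cfg.p_threshold,
            r2_threshold=cfg.r2_threshold, window_kb=cfg.window_kb,
            f_min=cfg.f_min, f_literal=cfg.f_literal,
        )
        pair = harmonize(inst, outcome)
        decision.estimates = fit_all(pair, config=cfg, seed=seed)
        decision.sensitivity = sensitivity_report(
            pair, n_sim=cfg.n_sim_presso, seed=seed, alpha=cfg.alpha,
        )
        decision.n_methods_concordant = count_concordant(
            decision.estimates, alpha=cfg.alpha)
        decision.verdict = classify_significance(
            decision.estimates, decision.sensitivity, alpha=cfg.alpha)
    except MrMediateError as exc:
        decision.verdict = "skipped"
        decision.reason = str(exc)
        logger.info("skipped %s -> %s: %s",
                    exposure.trait_id, outcome.trait_id, exc)
    return decision


def run_forward_screen(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    ld: LDMatrix | None = None,
    config: PipelineConfig | None = None,
    seed: int | None = None,
) -> list[ScreenDecision]:
    """Screen every exposure against one outcome; never aborts the batch."""
    if not exposures:
        raise MrMediateError("forward screen needs at least one exposure")
    cfg = config or PipelineConfig()
    decisions = [screen_pair(e, outcome, ld=ld, config=cfg, seed=seed)
                 for e in exposures]
    if cfg.bh_correction:
        _apply_bh(decisions, cfg.alpha)
    return decisions


def _apply_bh(decisions: list[ScreenDecision], alpha: float) -> None:
    """Optional Benjamini-Hochberg across the batch on the IVW p-values."""
    idx = [i for i, d in enumerate(decisions) if "ivw" in d.estimates]
    if not idx:
        return
    pvals = [decisions[i].estimates["ivw"].pval for i in idx]
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    for keep, i in zip(reject, idx):
        d = decisions[i]
        if d.verdict == "significant" and not keep:
            d.verdict = "not_significant"
            d.reason = "fails Benjamini-Hochberg correction"


def run_reverse_screen(
    outcome: SummaryStats,
    exposures: list[SummaryStats],
    ld: LDMatrix | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, bool]:
    """Reverse MR: instrument the outcome, test each original exposure.

    Returns ``exposure_id -> reverse_significant`` (reverse IVW p < alpha).
    Traits the reverse leg cannot be run for (no instruments, empty
    harmonization) are flagged False and logged.
    """
    cfg = config or PipelineConfig()
    flags: dict[str, bool] = {}
    try:
        inst = select_instruments(
            outcome, ld=ld, p_threshold=cfg.p_threshold,
            r2_threshold=cfg.r2_threshold, window_kb=cfg.window_kb,
            f_min=cfg.f_min, f_literal=cfg.f_literal,
        )
    except MrMediateError as exc:
        logger.info("reverse screen: no outcome instruments (%s)", exc)
        return {e.trait_id: False for e in exposures}
    for exp_stats in exposures:
        try:
            pair = harmonize(inst, exp_stats)
            est = ivw(pair, variant=cfg.ivw_variant)
            flags[exp_stats.trait_id] = bool(est.pval < cfg.alpha)
        except MrMediateError as exc:
            logger.info("reverse leg %s -> %s skipped: %s",
                        outcome.trait_id, exp_stats.trait_id, exc)
            flags[exp_stats.trait_id] = False
    return flags


@dataclass
class CandidateTriplet:
    """One evaluated (exposure, mediator, outcome) mediation candidate."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    accepted: bool
    reason: str


def _passes_two_method(decision: ScreenDecision, alpha: float) -> bool:
    if decision.verdict != "significant":
        return False
    est = decision.estimates
    return (est["ivw"].pval < alpha and est["bwmr"].pval < alpha
            and np.sign(est["ivw"].beta) == np.sign(est["bwmr"].beta))


def select_mediation_candidates(
    gm_outcome: list[ScreenDecision],
    gm_cell: list[ScreenDecision],
    cell_outcome: list[ScreenDecision],
    reverse_flags: dict[str, bool] | None = None,
    config: PipelineConfig | None = None,
) -> list[CandidateTriplet]:
    """Evaluate every (exposure, mediator) pairing against the outcome.

    A triplet is a candidate iff the exposure->outcome association passes
    the three-method rule (IVW + BWMR + at least one confirming method,
    sign-concordant; confirmation needs p < alpha unless
    ``confirm_requires_pval`` is off), is not reverse-flagged and is
    diagnostics-clean; both mediation legs pass IVW+BWMR concordance and
    are diagnostics-clean; and the indirect effect's sign matches the total
    effect's.
    """
    cfg = config or PipelineConfig()
    alpha = cfg.alpha
    reverse_flags = reverse_flags or {}
    cell_by_id = {d.exposure_id: d for d in cell_outcome}
    results: list[CandidateTriplet] = []

    for gm_out in gm_outcome:
        gm = gm_out.exposure_id
        outcome_id = gm_out.outcome_id
        gm_cells = [d for d in gm_cell if d.exposure_id == gm]
        for gc in gm_cells:
            cell = gc.outcome_id
            co = cell_by_id.get(cell)

            def reject(reason: str) -> CandidateTriplet:
                return CandidateTriplet(gm, cell, outcome_id, False, reason)

            if gm_out.verdict == "skipped":
                results.append(reject("exposure->outcome skipped"))
                continue
            if gm_out.verdict in ("excluded_pleiotropy",
                                  "excluded_heterogeneity"):
                results.append(reject(gm_out.verdict))
                continue
            if reverse_flags.get(gm, False) or gm_out.reverse_significant:
                results.append(reject("excluded_reverse"))
                continue
            if gm_out.verdict != "significant":
                results.append(reject("exposure->outcome not significant"))
                continue
            est = gm_out.estimates
            confirming = [m for m in CONFIRMING_METHODS if m in est
                          and _concordant(est[m], est["ivw"], alpha,
                                          require_pval=cfg.confirm_requires_pval)]
            if not confirming:
                results.append(
                    reject("no third method confirms exposure->outcome"))
                continue
            if co is None:
                results.append(reject("mediator->outcome leg missing"))
                continue
            if not _passes_two_method(gc, alpha):
                results.append(reject("exposure->mediator not significant"))
                continue
            if not _passes_two_method(co, alpha):
                results.append(reject("mediator->outcome not significant"))
                continue
            a = gc.estimates["ivw"].beta
            b = co.estimates["ivw"].beta
            c = est["ivw"].beta
            if np.sign(a * b) != np.sign(c):
                results.append(reject("inconsistent mediation sign"))
                continue
            results.append(CandidateTriplet(gm, cell, outcome_id, True,
                                            "candidate"))
    return results


def decisions_table(decisions: list[ScreenDecision]) -> pd.DataFrame:
    return pd.DataFrame([d.to_row() for d in decisions])


def candidates_table(cands: list[CandidateTriplet]) -> pd.DataFrame:
    return pd.DataFrame([{
        "exposure": c.exposure_id, "mediator": c.mediator_id,
        "outcome": c.outcome_id, "accepted": c.accepted, "reason": c.reason,
    } for c in cands])
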