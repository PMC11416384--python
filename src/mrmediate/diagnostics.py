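"""Heterogeneity and pleiotropy diagnostics for one harmonized pair.

Every reported association is gated on these checks: Cochran's Q over the
per-SNP Wald ratios (heterogeneity), the MR-Egger intercept (directional
pleiotropy), MR-PRESSO (simulation-based global pleiotropy, per-SNP
outliers, and distortion of the estimate by those outliers), and
leave-one-out re-estimation (single-SNP influence).  All diagnostics are
pure functions of the pair plus seeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, MREgger, ivw, wald_ratio
from .gwas import HarmonizedPair


def cochran_q(pair: HarmonizedPair, beta_ivw: float | None = None
              ) -> tuple[float, int, float]:
    """Cochran's Q over Wald ratios: Q = sum w_j (ratio_j - beta)^2.

    ``beta_ivw`` defaults to the fixed-effect IVW estimate.  The p-value is
    from chi-square with J-1 degrees of freedom.
    """
    if pair.n_snp < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 SNPs")
    ratio, ratio_se = wald_ratio(pair.gamma_hat, pair.sigma_x,
                                 pair.Gamma_hat, pair.sigma_y)
    w = 1.0 / ratio_se**2
    if beta_ivw is None:
        beta_ivw = float(np.sum(w * ratio) / np.sum(w))
    q = float(np.sum(w * (ratio - beta_ivw) ** 2))
    df = pair.n_snp - 1
    return q, df, float(sps.chi2.sf(q, df))


def q_contributions(pair: HarmonizedPair, beta_ivw: float | None = None
                    ) -> np.ndarray:
    """Per-SNP terms w_j (ratio_j - beta)^2 summing to Q."""
    ratio, ratio_se = wald_ratio(pair.gamma_hat, pair.sigma_x,
                                 pair.Gamma_hat, pair.sigma_y)
    w = 1.0 / ratio_se**2
    if beta_ivw is None:
        beta_ivw = float(np.sum(w * ratio) / np.sum(w))
    return w * (ratio - beta_ivw) ** 2


def leave_one_out(pair: HarmonizedPair,
                  variant: str = "multiplicative_random") -> pd.DataFrame:
    """IVW estimate excluding each SNP in turn; one row per excluded SNP."""
    if pair.n_snp < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 SNPs")
    rows = []
    mask = np.ones(pair.n_snp, dtype=bool)
    for j in range(pair.n_snp):
        mask[j] = False
        est = ivw(pair.drop(mask), variant=variant)
        mask[j] = True
        rows.append({"excluded_rsid": pair.rsids[j], "beta": est.beta,
                     "se": est.se, "pval": est.pval})
    return pd.DataFrame(rows)


def egger_intercept_test(pair: HarmonizedPair) -> tuple[float, float, float]:
    """The MR-Egger intercept and its test, exposed as a pleiotropy gate."""
    fit = MREgger().fit(pair)
    return fit.intercept_, fit.intercept_se_, fit.intercept_pval_


def _loo_origin_slopes(gamma: np.ndarray, Gamma: np.ndarray,
                       w: np.ndarray) -> np.ndarray:
    """Leave-one-out WLS-through-origin slopes of Gamma on gamma, weights w."""
    sxy = np.sum(w * gamma * Gamma)
    sxx = np.sum(w * gamma**2)
    return (sxy - w * gamma * Gamma) / (sxx - w * gamma**2)


@dataclass
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss: float
    global_pval: float
    outlier_ids: list[str]
    outlier_pvals: pd.DataFrame
    distortion_pval: float | None
    corrected: MREstimate | None
    n_sim: int


def mr_presso(pair: HarmonizedPair, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> PressoResult:
    """Pleiotropy residual sum and outlier test.

    The observed statistic is the weighted residual sum of squares
    RSS = sum_j w_j (Gamma_j - beta_{-j} gamma_j)^2 with leave-one-out
    through-origin slopes beta_{-j} and w_j = 1/sigma_yj^2.  The null
    distribution comes from ``n_sim`` parametric datasets drawn at the
    leave-one-out fits; the global p-value uses the plus-one estimator
    (smallest reportable value 1/(n_sim+1)).  Per-SNP outlier p-values are
    the empirical tail proportions of each SNP's simulated contribution,
    Bonferroni-adjusted over J; when outliers exist, the outlier-corrected
    IVW estimate and a distortion test (observed shift of the estimate vs
    the shift from removing random same-size SNP subsets) are returned.
    """
    J = pair.n_snp
    if J < 4:
        raise InsufficientInstrumentsError("MR-PRESSO needs >= 4 SNPs")
    if n_sim < 100:
        raise InsufficientInstrumentsError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    gamma, sx = pair.gamma_hat, pair.sigma_x
    Gamma, sy = pair.Gamma_hat, pair.sigma_y
    w = 1.0 / sy**2

    beta_loo = _loo_origin_slopes(gamma, Gamma, w)
    obs_contrib = w * (Gamma - beta_loo * gamma) ** 2
    rss_obs = float(np.sum(obs_contrib))

    # parametric null at the leave-one-out fits
    g_sim = rng.normal(gamma, sx, size=(n_sim, J))
    G_sim = rng.normal(beta_loo * gamma, sy, size=(n_sim, J))
    w_row = w[None, :]
    sxy = np.sum(w_row * g_sim * G_sim, axis=1, keepdims=True)
    sxx = np.sum(w_row * g_sim**2, axis=1, keepdims=True)
    beta_loo_sim = (sxy - w_row * g_sim * G_sim) / (sxx - w_row * g_sim**2)
    sim_contrib = w_row * (G_sim - beta_loo_sim * g_sim) ** 2
    rss_sim = sim_contrib.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_raw = np.mean(sim_contrib >= obs_contrib[None, :], axis=0)
    p_adj = np.minimum(1.0, p_raw * J)
    out_mask = p_adj < outlier_alpha
    outlier_ids = [str(r) for r in pair.rsids[out_mask]]
    outlier_pvals = pd.DataFrame({
        "rsid": pair.rsids, "pval_raw": p_raw, "pval_bonferroni": p_adj,
        "outlier": out_mask,
    })

    distortion_pval = None
    corrected = None
    if out_mask.any() and (~out_mask).sum() >= 2:
        corrected = ivw(pair.drop(~out_mask))
        beta_all = ivw(pair).beta
        d_obs = _distortion(beta_all, corrected.beta)
        n_out = int(out_mask.sum())
        d_null = np.empty(n_sim)
        for i in range(n_sim):
            drop = rng.choice(J, size=n_out, replace=False)
            keep = np.ones(J, dtype=bool)
            keep[drop] = False
            b = float(np.sum(w[keep] * gamma[keep] * Gamma[keep])
                      / np.sum(w[keep] * gamma[keep] ** 2))
            d_null[i] = _distortion(beta_all, b)
        distortion_pval = float(
            (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1)
        )

    return PressoResult(
        global_rss=rss_obs, global_pval=global_pval, outlier_ids=outlier_ids,
        outlier_pvals=outlier_pvals, distortion_pval=distortion_pval,
        corrected=corrected, n_sim=n_sim,
    )


def _distortion(beta_all: float, beta_sub: float) -> float:
    if beta_sub == 0:
        return 0.0
    return (beta_all - beta_sub) / abs(beta_sub)


@dataclass
class SensitivityReport:
    """All heterogeneity/pleiotropy gates for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_se: float | None
    egger_intercept_pval: float | None
    presso_global_pval: float | None
    presso_outlier_ids: list[str]
    presso_distortion_pval: float | None
    loo_table: pd.DataFrame = field(repr=False)
    alpha: float = 0.05

    @property
    def heterogeneous(self) -> bool:
        return self.q_pval < self.alpha

    @property
    def pleiotropic(self) -> bool:
        egger = (self.egger_intercept_pval is not None
                 and self.egger_intercept_pval < self.alpha)
        presso = (self.presso_global_pval is not None
                  and self.presso_global_pval < self.alpha)
        return egger or presso

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "exposure_id", "outcome_id", "q_stat", "q_df", "q_pval",
            "egger_intercept", "egger_intercept_se", "egger_intercept_pval",
            "presso_global_pval", "presso_outlier_ids",
            "presso_distortion_pval", "alpha",
        )}
        d["heterogeneous"] = self.heterogeneous
        d["pleiotropic"] = self.pleiotropic
        return d

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def sensitivity_report(pair: HarmonizedPair, n_sim: int = 1000, seed: int = 0,
                       alpha: float = 0.05, run_presso: bool = True
                       ) -> SensitivityReport:
    """Run every diagnostic on one pair and assemble the report.

    Diagnostics that need more SNPs than the pair has are recorded as None
    rather than failing the batch.
    """
    q_stat, q_df, q_pval = cochran_q(pair)
    if pair.n_snp >= 3:
        intercept, intercept_se, intercept_p = egger_intercept_test(pair)
        loo = leave_one_out(pair)
    else:
        intercept = intercept_se = intercept_p = None
        loo = pd.DataFrame(columns=["excluded_rsid", "beta", "se", "pval"])
    presso_p = None
    outliers: list[str] = []
    distortion = None
    if run_presso and pair.n_snp >= 4:
        res = mr_presso(pair, n_sim=n_sim, seed=seed)
        presso_p = res.global_pval
        outliers = res.outlier_ids
        distortion = res.distortion_pval
    return SensitivityReport(
        exposure_id=pair.exposure_id, outcome_id=pair.outcome_id,
        q_stat=q_stat, q_df=q_df, q_pval=q_pval,
        egger_intercept=intercept, egger_intercept_se=intercept_se,
        egger_intercept_pval=intercept_p, presso_global_pval=presso_p,
        presso_outlier_ids=outliers, presso_distortion_pval=distortion,
        loo_table=loo, alpha=alpha,
    )
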