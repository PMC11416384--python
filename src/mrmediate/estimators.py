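"""Point estimators of the causal effect from harmonized summary statistics.

Every estimator is a scikit-learn-style class: construct with
hyperparameters, call ``fit`` on a :class:`~mrmediate.gwas.HarmonizedPair`
(or on arrays), and read the fitted attributes ``beta_``, ``se_``,
``pval_``, ``n_snp_`` and the packaged :class:`MREstimate` in
``estimate_``.  ``get_params``/``set_params`` come from
``sklearn.base.BaseEstimator``, so the classes compose with sklearn
model-selection utilities.  The module-level functions ``ivw``,
``mr_egger``, ``weighted_median``, ``mode_estimators`` are thin wrappers.

Implemented methods
-------------------
- Wald ratio per SNP: Gamma_hat / gamma_hat with first-order (optionally
  second-order) delta standard error.
- IVW: inverse-variance-weighted mean of the Wald ratios, equivalent to WLS
  of Gamma_hat on gamma_hat through the origin with weights 1/sigma_y^2;
  fixed-effect or multiplicative random-effects standard errors.
- MR-Egger: weighted regression with a free intercept estimating average
  directional pleiotropy; instruments are pre-oriented to non-negative
  gamma_hat so the intercept is interpretable.
- Weighted median: consistent when valid instruments carry a majority of
  the weight; parametric-bootstrap standard error.
- Simple/weighted mode: kernel-density mode of the ratio distribution with
  a modified-Silverman bandwidth; parametric-bootstrap standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .errors import InsufficientInstrumentsError, InvalidParameterError, UndefinedRatioError
from .gwas import HarmonizedPair

#: two-sided 95% Gaussian critical value
Z95 = 1.959964

METHODS = ("wald_ratio", "ivw_fe", "ivw_mre", "egger", "weighted_median",
           "simple_mode", "weighted_mode", "bwmr")

_MIN_SNPS = {"wald_ratio": 1, "ivw_fe": 2, "ivw_mre": 2, "weighted_median": 2,
             "egger": 3, "simple_mode": 3, "weighted_mode": 3, "bwmr": 3}


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snp: int
    or_value: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise InvalidParameterError(f"unknown method {self.method!r}")
        if not self.se > 0:
            raise InvalidParameterError("se must be positive")
        if self.n_snp < _MIN_SNPS[self.method]:
            raise InsufficientInstrumentsError(
                f"{self.method} needs >= {_MIN_SNPS[self.method]} SNPs"
            )
        self.pval = float(min(max(self.pval, np.finfo(float).tiny), 1.0))
        self.or_value, self.ci_low, self.ci_high = to_odds_ratio(self.beta, self.se)


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Odds ratio exp(beta) with 95% CI exp(beta -/+ 1.959964 se)."""
    if not se > 0:
        raise InvalidParameterError("se must be positive")
    return (float(np.exp(beta)),
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)))


def wald_ratio(gamma_hat, sigma_x, Gamma_hat, sigma_y, second_order: bool = False):
    """Per-SNP causal estimate Gamma/gamma with delta-method standard error.

    First order: se = sigma_y/|gamma|.  Second order adds the exposure
    uncertainty term Gamma^2 sigma_x^2 / gamma^4 under the square root.
    """
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    sigma_x = np.asarray(sigma_x, dtype=float)
    Gamma_hat = np.asarray(Gamma_hat, dtype=float)
    sigma_y = np.asarray(sigma_y, dtype=float)
    if np.any(gamma_hat == 0):
        raise UndefinedRatioError("Wald ratio undefined for gamma_hat = 0")
    est = Gamma_hat / gamma_hat
    var = sigma_y**2 / gamma_hat**2
    if second_order:
        var = var + Gamma_hat**2 * sigma_x**2 / gamma_hat**4
    se = np.sqrt(var)
    if est.ndim == 0:
        return float(est), float(se)
    return est, se


def _pair_arrays(X, y=None, sigma_x=None, sigma_y=None):
    """Accept a HarmonizedPair, or arrays (X=gamma_hat, y=Gamma_hat)."""
    if isinstance(X, HarmonizedPair):
        return X.gamma_hat, X.sigma_x, X.Gamma_hat, X.sigma_y
    gamma = np.asarray(X, dtype=float).reshape(-1)
    if y is None or sigma_y is None:
        raise InvalidParameterError(
            "array input requires y (Gamma_hat) and sigma_y; sigma_x optional"
        )
    Gamma = np.asarray(y, dtype=float).reshape(-1)
    sy = np.asarray(sigma_y, dtype=float).reshape(-1)
    sx = (np.zeros_like(gamma) if sigma_x is None
          else np.asarray(sigma_x, dtype=float).reshape(-1))
    if not len(gamma) == len(Gamma) == len(sy) == len(sx):
        raise InvalidParameterError("input arrays must have equal length")
    return gamma, sx, Gamma, sy


def _two_sided_norm_p(z: float) -> float:
    return float(2.0 * sps.norm.sf(abs(z)))


class _BaseMR(BaseEstimator):
    """Shared fit plumbing: input coercion and MREstimate packaging."""

    _method: str = ""

    def fit(self, X, y=None, *, sigma_x=None, sigma_y=None):
        gamma, sx, Gamma, sy = _pair_arrays(X, y, sigma_x, sigma_y)
        if len(gamma) < _MIN_SNPS[self._method]:
            raise InsufficientInstrumentsError(
                f"{self._method} needs >= {_MIN_SNPS[self._method]} SNPs, "
                f"got {len(gamma)}"
            )
        self.n_snp_ = len(gamma)
        self._fit(gamma, sx, Gamma, sy)
        self.estimate_ = MREstimate(
            method=self._method, beta=self.beta_, se=self.se_,
            pval=self.pval_, n_snp=self.n_snp_, extra=self._extra(),
        )
        return self

    def _fit(self, gamma, sx, Gamma, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    def _extra(self) -> dict:
        return {}

    def predict(self, X):
        """Predicted SNP-outcome effect for SNP-exposure effects ``X``."""
        gamma = X.gamma_hat if isinstance(X, HarmonizedPair) else np.asarray(X, float)
        return getattr(self, "intercept_", 0.0) + self.beta_ * gamma


class IVW(_BaseMR):
    """Inverse-variance-weighted meta-analysis of per-SNP Wald ratios.

    ``variant="fixed"`` uses the fixed-effect standard error
    (sum of weights)^(-1/2); ``"multiplicative_random"`` scales it by
    sqrt(max(1, Q/(J-1))).  Algebraically identical to weighted least
    squares of Gamma_hat on gamma_hat through the origin with weights
    1/sigma_y^2.
    """

    def __init__(self, variant: str = "multiplicative_random"):
        self.variant = variant

    @property
    def _method(self):
        return "ivw_mre" if self.variant == "multiplicative_random" else "ivw_fe"

    def _fit(self, gamma, sx, Gamma, sy):
        if self.variant not in ("fixed", "multiplicative_random"):
            raise InvalidParameterError(f"unknown IVW variant {self.variant!r}")
        ratio, ratio_se = wald_ratio(gamma, sx, Gamma, sy)
        w = 1.0 / ratio_se**2
        beta = float(np.sum(w * ratio) / np.sum(w))
        se_fixed = float(1.0 / np.sqrt(np.sum(w)))
        q = float(np.sum(w * (ratio - beta) ** 2))
        self.q_ = q
        self.q_df_ = len(gamma) - 1
        self.se_fixed_ = se_fixed
        phi = max(1.0, q / self.q_df_) if self.q_df_ > 0 else 1.0
        se = se_fixed * np.sqrt(phi) if self.variant == "multiplicative_random" else se_fixed
        self.beta_ = beta
        self.se_ = float(se)
        self.pval_ = _two_sided_norm_p(beta / se)

    def _extra(self):
        return {"variant": self.variant, "q": self.q_, "q_df": self.q_df_,
                "se_fixed": self.se_fixed_}


class MREgger(_BaseMR):
    """Weighted regression of Gamma_hat on gamma_hat with a free intercept.

    Instruments are oriented so gamma_hat >= 0 before fitting (pairs with
    negative gamma_hat have both signs flipped), which makes the intercept
    an estimate of average directional pleiotropy.  Standard errors carry a
    multiplicative overdispersion factor floored at 1; p-values use the t
    distribution with J-2 degrees of freedom.
    """

    _method = "egger"

    def _fit(self, gamma, sx, Gamma, sy):
        flip = np.sign(gamma)
        flip[flip == 0] = 1.0
        x = gamma * flip
        yv = Gamma * flip
        if np.allclose(x, x[0]):
            raise InvalidParameterError("zero variance in gamma_hat")
        w = 1.0 / sy**2
        res = sm.WLS(yv, sm.add_constant(x), weights=w).fit()
        dof = len(x) - 2
        sigma2 = float(res.scale)  # RSS/(J-2) on the weighted scale
        scale_adj = np.sqrt(max(1.0, sigma2) / sigma2)
        inter_se, slope_se = res.bse * scale_adj
        self.beta_ = float(res.params[1])
        self.se_ = float(slope_se)
        self.pval_ = float(2 * sps.t.sf(abs(self.beta_ / self.se_), dof))
        self.intercept_ = float(res.params[0])
        self.intercept_se_ = float(inter_se)
        self.intercept_pval_ = float(
            2 * sps.t.sf(abs(self.intercept_ / self.intercept_se_), dof)
        )

    def _extra(self):
        return {"intercept": self.intercept_, "intercept_se": self.intercept_se_,
                "intercept_pval": self.intercept_pval_}


def _weighted_median_interp(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: cumulative weight midpoints vs 1/2."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


class WeightedMedian(_BaseMR):
    """Weighted median of the Wald ratios with parametric-bootstrap SE.

    Consistent when instruments carrying at least half the inverse-variance
    weight are valid.  The bootstrap resamples gamma_hat and Gamma_hat from
    their Gaussian sampling distributions (``n_boot`` draws, seeded).
    """

    _method = "weighted_median"

    def __init__(self, n_boot: int = 1000, seed: int = 0):
        self.n_boot = n_boot
        self.seed = seed

    def _fit(self, gamma, sx, Gamma, sy):
        ratio, ratio_se = wald_ratio(gamma, sx, Gamma, sy)
        w = 1.0 / ratio_se**2
        self.beta_ = _weighted_median_interp(ratio, w)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            g = rng.normal(gamma, sx) if np.any(sx > 0) else gamma
            G = rng.normal(Gamma, sy)
            g = np.where(g == 0, np.finfo(float).tiny, g)
            rb = G / g
            wb = g**2 / sy**2
            boots[i] = _weighted_median_interp(rb, wb)
        self.se_ = float(boots.std(ddof=1))
        if self.se_ == 0:
            self.se_ = np.finfo(float).tiny
        self.pval_ = _two_sided_norm_p(self.beta_ / self.se_)


def _mode_bandwidth(ratios: np.ndarray, phi: float) -> float:
    """Modified Silverman rule: 0.9 min(sd, MAD/0.6745) n^(-1/5), times phi."""
    sd = ratios.std(ddof=1) if len(ratios) > 1 else 0.0
    mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6745
    spread = min(x for x in (sd, mad) if x > 0) if max(sd, mad) > 0 else 0.0
    return phi * 0.9 * spread * len(ratios) ** (-1 / 5)


def _kde_mode(ratios: np.ndarray, weights: np.ndarray, phi: float,
              n_grid: int) -> float:
    h = _mode_bandwidth(ratios, phi)
    if h == 0:  # all ratios identical
        return float(ratios[0])
    grid = np.linspace(ratios.min() - 3 * h, ratios.max() + 3 * h, n_grid)
    dens = np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2) @ weights
    return float(grid[np.argmax(dens)])


class ModeEstimator(_BaseMR):
    """Kernel-density mode of the Wald-ratio distribution.

    ``weighted=False`` is the simple mode (equal weights); ``weighted=True``
    weights the density by inverse-variance weights.  Consistent when the
    largest cluster of SNPs shares the true causal ratio (ZEMPA).  SE by
    parametric bootstrap.
    """

    def __init__(self, weighted: bool = False, phi: float = 1.0,
                 n_boot: int = 1000, seed: int = 0, n_grid: int = 512):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.seed = seed
        self.n_grid = n_grid

    @property
    def _method(self):
        return "weighted_mode" if self.weighted else "simple_mode"

    def _weights(self, ratio_se: np.ndarray) -> np.ndarray:
        if self.weighted:
            w = 1.0 / ratio_se**2
        else:
            w = np.ones_like(ratio_se)
        return w / w.sum()

    def _fit(self, gamma, sx, Gamma, sy):
        ratio, ratio_se = wald_ratio(gamma, sx, Gamma, sy)
        self.beta_ = _kde_mode(ratio, self._weights(ratio_se), self.phi, self.n_grid)
        rng = np.random.default_rng(self.seed)
        boots = np.empty(self.n_boot)
        for i in range(self.n_boot):
            g = rng.normal(gamma, sx) if np.any(sx > 0) else gamma
            G = rng.normal(Gamma, sy)
            g = np.where(g == 0, np.finfo(float).tiny, g)
            rb, rsb = G / g, sy / np.abs(g)
            boots[i] = _kde_mode(rb, self._weights(rsb), self.phi, self.n_grid)
        self.se_ = float(boots.std(ddof=1))
        if self.se_ == 0:
            self.se_ = np.finfo(float).tiny
        self.pval_ = _two_sided_norm_p(self.beta_ / self.se_)


# ---------------------------------------------------------------------------
# functional wrappers

def ivw(pair, variant: str = "multiplicative_random") -> MREstimate:
    return IVW(variant=variant).fit(pair).estimate_


def mr_egger(pair) -> MREstimate:
    return MREgger().fit(pair).estimate_


def weighted_median(pair, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    return WeightedMedian(n_boot=n_boot, seed=seed).fit(pair).estimate_


def mode_estimators(pair, bandwidth_factor_phi: float = 1.0,
                    n_boot: int = 1000, seed: int = 0) -> tuple[MREstimate, MREstimate]:
    simple = ModeEstimator(weighted=False, phi=bandwidth_factor_phi,
                           n_boot=n_boot, seed=seed).fit(pair).estimate_
    weighted = ModeEstimator(weighted=True, phi=bandwidth_factor_phi,
                             n_boot=n_boot, seed=seed).fit(pair).estimate_
    return simple, weighted


def fit_all(pair, config=None, seed: int | None = None) -> dict[str, MREstimate]:
    """Run the full estimator suite on one harmonized pair.

    Returns a dict keyed by short method name: ivw (headline variant from
    config), ivw_fe, egger, weighted_median, simple_mode, weighted_mode,
    bwmr.
    """
    from .bwmr import BWMR
    from .config import PipelineConfig

    cfg = config or PipelineConfig()
    seed = cfg.seed if seed is None else seed
    out: dict[str, MREstimate] = {}
    out["ivw"] = ivw(pair, variant=cfg.ivw_variant)
    out["ivw_fe"] = ivw(pair, variant="fixed")
    if pair.n_snp >= 3:
        out["egger"] = mr_egger(pair)
    out["weighted_median"] = weighted_median(pair, n_boot=cfg.n_boot, seed=seed)
    if pair.n_snp >= 3:
        simple, wmode = mode_estimators(pair, bandwidth_factor_phi=cfg.mode_phi,
                                        n_boot=cfg.n_boot, seed=seed)
        out["simple_mode"] = simple
        out["weighted_mode"] = wmode
        out["bwmr"] = BWMR(tol=cfg.bwmr_tol, max_iter=cfg.bwmr_max_iter,
                           seed=seed).fit(pair).estimate_
    return out


def estimates_table(estimates: dict[str, MREstimate], exposure_id: str,
                    outcome_id: str) -> pd.DataFrame:
    """Tidy per-method table: the machine-readable analogue of a forest plot."""
    rows = []
    for est in estimates.values():
        rows.append({
            "exposure": exposure_id, "outcome": outcome_id,
            "method": est.method, "nsnp": est.n_snp, "beta": est.beta,
            "se": est.se, "pval": est.pval, "or": est.or_value,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
        })
    return pd.DataFrame(rows)
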