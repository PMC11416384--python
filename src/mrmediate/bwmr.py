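"""Bayesian weighted Mendelian randomization.

Hierarchical model over J instruments:

    gamma_hat_j ~ Normal(gamma_j, sigma_xj^2)        (exposure estimate)
    Gamma_hat_j ~ Normal(beta * gamma_j + alpha_j, sigma_yj^2)
    gamma_j     ~ Normal(0, sigma0^2)                (true instrument effects)
    alpha_j     ~ Normal(0, tau^2)                   (horizontal pleiotropy)

Unlike IVW, the model propagates weak-instrument uncertainty (sigma_x
enters the likelihood rather than being ignored) and absorbs balanced
pleiotropy into tau^2.  Robustness to outlying pleiotropic SNPs comes from
per-SNP weights updated from standardized residuals t_j:

    w_j = exp(-max(0, t_j^2 - 1) / 2)

so SNPs whose residuals behave like N(0,1) keep weight ~1 and gross
outliers are smoothly down-weighted.  Fitting alternates posterior updates
of the latent gamma_j and of (beta, tau^2, sigma0^2) with weight updates,
starting from the IVW fixed-effect estimate, until |delta beta| < tol.
The standard error comes from the curvature of the weighted likelihood at
the optimum; the p-value is two-sided Gaussian.

The scheme is deterministic: ``seed`` is accepted for interface parity but
no Monte-Carlo integration step is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator

from .errors import InsufficientInstrumentsError
from .estimators import MREstimate, _pair_arrays, _two_sided_norm_p


@dataclass
class BwmrFit:
    """Converged (or last-iterate) state of a BWMR fit."""

    beta: float
    se: float
    pval: float
    tau: float
    sigma0: float
    weights: np.ndarray
    n_iter: int
    converged: bool
    estimate: MREstimate

    def __post_init__(self) -> None:
        assert self.tau >= 0
        assert np.all((self.weights > 0) & (self.weights <= 1))


def robust_weight(t: np.ndarray) -> np.ndarray:
    """Down-weighting of standardized residuals: exp(-max(0, t^2-1)/2)."""
    t = np.asarray(t, dtype=float)
    return np.exp(-np.maximum(0.0, t**2 - 1.0) / 2.0)


def _variance_inflation() -> float:
    """M-estimation variance correction for the redescending weight.

    The estimating equation uses psi(t) = w(t) t, so the asymptotic
    variance relative to the weighted curvature is
    E[w] E[psi^2] / E[psi']^2 under t ~ N(0, 1).  Exact value computed by
    quadrature once at import.
    """
    from scipy.integrate import quad

    phi = sps.norm.pdf
    e_w = quad(lambda t: robust_weight(t) * phi(t), -np.inf, np.inf)[0]
    e_psi2 = quad(lambda t: (robust_weight(t) * t) ** 2 * phi(t),
                  -np.inf, np.inf)[0]

    def dpsi(t):
        # d/dt [w(t) t]: 1 inside |t|<=1, w(t)(1-t^2) outside
        return np.where(np.abs(t) <= 1.0, 1.0, robust_weight(t) * (1 - t**2))

    e_dpsi = quad(lambda t: dpsi(t) * phi(t), -np.inf, np.inf)[0]
    return e_w * e_psi2 / e_dpsi**2


_SE_INFLATION: float = _variance_inflation()


class BWMR(BaseEstimator):
    """Bayesian weighted MR estimator (scikit-learn style).

    Parameters
    ----------
    tol : convergence tolerance on successive beta values.
    max_iter : iteration cap; non-convergence is flagged, not raised.
    fix_tau : optionally pin the pleiotropy SD (e.g. 0) instead of
        estimating it.
    seed : unused by the deterministic fit; kept for interface parity.
    """

    def __init__(self, tol: float = 1e-6, max_iter: int = 5000,
                 fix_tau: float | None = None, seed: int | None = None):
        self.tol = tol
        self.max_iter = max_iter
        self.fix_tau = fix_tau
        self.seed = seed

    def fit(self, X, y=None, *, sigma_x=None, sigma_y=None):
        gamma, sx, Gamma, sy = _pair_arrays(X, y, sigma_x, sigma_y)
        J = len(gamma)
        if J < 3:
            raise InsufficientInstrumentsError(f"bwmr needs >= 3 SNPs, got {J}")
        sx2 = np.maximum(sx, 1e-12) ** 2
        sy2 = sy**2

        # deterministic initialization at the IVW fixed-effect estimate
        w_ivw = gamma**2 / sy2
        beta = float(np.sum(w_ivw * (Gamma / gamma)) / np.sum(w_ivw))
        tau2 = 0.0 if self.fix_tau is None else float(self.fix_tau) ** 2
        sigma02 = max(float(np.mean(gamma**2 - sx2)), 1e-12)
        w = np.ones(J)

        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            v_y = sy2 + tau2
            # posterior of latent gamma_j given current (beta, variances, w);
            # robustness weights act on the outcome equation only — the
            # exposure estimate is not under suspicion of pleiotropy
            prec = 1.0 / sx2 + w * beta**2 / v_y + 1.0 / sigma02
            m = (gamma / sx2 + w * beta * Gamma / v_y) / prec
            V = 1.0 / prec
            # beta update: weighted expected-likelihood maximizer
            denom = np.sum(w * (m**2 + V) / v_y)
            beta_new = float(np.sum(w * m * Gamma / v_y) / denom)
            # variance updates (method of moments on weighted residuals)
            sigma02 = max(float(np.mean(m**2 + V)), 1e-12)
            resid = Gamma - beta_new * m
            if self.fix_tau is None:
                tau2 = max(0.0, float(
                    np.sum(w * (resid**2 + beta_new**2 * V - sy2)) / np.sum(w)
                ))
            # robust weight update from standardized residuals; floor keeps
            # weights in (0, 1] when exp() underflows for gross outliers
            t = resid / np.sqrt(sy2 + tau2 + beta_new**2 * V)
            w = np.maximum(robust_weight(t), np.finfo(float).tiny)
            if abs(beta_new - beta) < self.tol:
                beta = beta_new
                converged = True
                break
            beta = beta_new

        v_y = sy2 + tau2
        prec = 1.0 / sx2 + w * beta**2 / v_y + 1.0 / sigma02
        m = (gamma / sx2 + w * beta * Gamma / v_y) / prec
        V = 1.0 / prec
        se = float(np.sqrt(_SE_INFLATION / np.sum(w * (m**2 + V) / v_y)))
        self.beta_ = beta
        self.se_ = se
        self.pval_ = _two_sided_norm_p(beta / se)
        self.tau_ = float(np.sqrt(tau2))
        self.sigma0_ = float(np.sqrt(sigma02))
        self.weights_ = w
        self.n_iter_ = it
        self.converged_ = converged
        self.n_snp_ = J
        self.estimate_ = MREstimate(
            method="bwmr", beta=beta, se=se, pval=self.pval_, n_snp=J,
            extra={"tau": self.tau_, "n_iter": it, "converged": converged},
        )
        self.fit_ = BwmrFit(
            beta=beta, se=se, pval=self.pval_, tau=self.tau_,
            sigma0=self.sigma0_, weights=w, n_iter=it, converged=converged,
            estimate=self.estimate_,
        )
        return self

    def predict(self, X):
        gamma = X.gamma_hat if hasattr(X, "gamma_hat") else np.asarray(X, float)
        return self.beta_ * gamma


def fit_bwmr(pair, tol: float = 1e-6, max_iter: int = 5000,
             seed: int | None = None, fix_tau: float | None = None) -> BwmrFit:
    """Functional wrapper returning the :class:`BwmrFit` summary."""
    return BWMR(tol=tol, max_iter=max_iter, seed=seed, fix_tau=fix_tau).fit(pair).fit_
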