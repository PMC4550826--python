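"""Multi-SNP causal estimators for two-sample summary-data MR.

Two estimators of the causal log-odds of outcome per 1 kb of telomere
length:

* :class:`IVWEstimator` — the inverse-variance weighted average of per-SNP
  Wald ratios,

  .. math::

     \\hat\\beta = \\frac{\\sum_k x_k y_k \\sigma_{yk}^{-2}}
                        {\\sum_k x_k^2 \\sigma_{yk}^{-2}},
     \\qquad
     \\mathrm{SE}(\\hat\\beta) = \\Big(\\sum_k x_k^2
                        \\sigma_{yk}^{-2}\\Big)^{-1/2},

  algebraically a weighted least-squares regression of outcome effects on
  exposure effects through the origin with weights :math:`\\sigma_{yk}^{-2}`.

* :class:`LikelihoodMrEstimator` — a maximum-likelihood fit in which each
  SNP's observed ``(x_k, y_k)`` pair is bivariate normal around
  ``(xi_k, beta * xi_k)`` with known SEs and within-SNP correlation ``rho``
  (0 in the two-sample setting), the per-SNP instrument effects ``xi_k``
  treated as nuisance parameters.  ``xi_k`` has a closed-form profile given
  ``beta``, so the fit reduces to a 1-D quasi-Newton optimisation warm-
  started at the IVW solution.

Both follow the scikit-learn estimator contract: hyperparameters in
``__init__``, data in ``fit(X, y, ...)``, fitted attributes with trailing
underscores, and ``predict`` returning fitted outcome effects ``beta * x``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConvergenceError, DomainError, EmptyInstrumentError
from .summary_io import InstrumentSet, two_sided_p

logger = logging.getLogger("telomr")

#: z quantile used for all 95% intervals
Z95 = 1.959964


def _as_1d(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2 and x.shape[1] == 1:
        x = x[:, 0]
    if x.ndim != 1:
        raise DomainError("X must be a 1-D array of per-SNP exposure effects "
                          "or a single-column matrix")
    return x


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MrEstimate:
    """A multi-SNP causal estimate on the log-odds-per-kb scale."""

    method: str
    beta: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_snps: int
    snp_ids: tuple[str, ...]
    analysis: str = "all"

    def to_row(self) -> dict:
        """Tidy row matching the published table layout (OR, 95% CI, P)."""
        return {
            "method": self.method,
            "analysis": self.analysis,
            "beta": self.beta,
            "se": self.se,
            "or": round(self.or_point, 2),
            "ci_low": round(self.ci_low, 2),
            "ci_high": round(self.ci_high, 2),
            "p_value": self.p_value,
            "n_snps": self.n_snps,
            "snp_ids": ",".join(self.snp_ids),
        }


@dataclass(frozen=True)
class LikelihoodFit(MrEstimate):
    """Likelihood-method estimate plus fit diagnostics."""

    xi: tuple[float, ...] = ()
    rho: float = 0.0
    loglik: float = float("nan")
    converged: bool = False
    ci_method: str = "profile"
    beta_ci_low: float = float("nan")
    beta_ci_high: float = float("nan")


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float, float]:
    """(OR, 95% CI low, high, two-sided P) for a log-odds estimate."""
    if not se > 0:
        raise DomainError("se must be > 0")
    or_point = float(np.exp(beta))
    return (or_point,
            float(np.exp(beta - Z95 * se)),
            float(np.exp(beta + Z95 * se)),
            two_sided_p(beta, se))


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------

class IVWEstimator(BaseEstimator, RegressorMixin):
    """Inverse-variance weighted two-sample MR estimator.

    Parameters
    ----------
    None — the estimator is fully determined by the data.

    Attributes
    ----------
    beta_ : float
        Causal log-odds of outcome per unit of exposure.
    se_ : float
        Standard error of ``beta_`` (fixed-effect, first-order weights).
    p_value_ : float
        Two-sided normal P-value for ``beta_ = 0``.
    n_snps_ : int
        Number of instruments used.
    """

    def fit(self, X, y, y_se=None):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if y_se is None:
            raise DomainError("y_se (outcome standard errors) is required")
        s = np.asarray(y_se, dtype=float)
        if x.size == 0:
            raise EmptyInstrumentError("no instruments supplied")
        if not (x.shape == y.shape == s.shape):
            raise DomainError("X, y and y_se must have equal length")
        if np.any(s <= 0):
            raise DomainError("all outcome SEs must be > 0")
        w = s ** -2.0
        denom = float(np.sum(x * x * w))
        self.beta_ = float(np.sum(x * y * w) / denom)
        self.se_ = float(denom ** -0.5)
        self.p_value_ = two_sided_p(self.beta_, self.se_)
        self.n_snps_ = int(x.size)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "beta_")
        return self.beta_ * _as_1d(X)


# ---------------------------------------------------------------------------
# likelihood method
# ---------------------------------------------------------------------------

class LikelihoodMrEstimator(BaseEstimator, RegressorMixin):
    """Bivariate-normal maximum-likelihood two-sample MR estimator.

    Parameters
    ----------
    rho : float, default 0.0
        Within-SNP correlation between the exposure and outcome estimate
        errors.  Zero for non-overlapping (two-sample) GWAS; exposed for
        sensitivity analysis.
    ci_method : {"profile", "wald"}, default "profile"
        Profile-likelihood interval (cutoff 3.841 on the deviance) or a
        Wald interval from the observed information.
    n_restarts : int, default 3
        Jittered restarts tried after the IVW warm start if the first
        optimisation fails to converge.
    random_state : int, default 0
        Seed for the restart jitter.

    Attributes
    ----------
    beta_, se_, p_value_, n_snps_ : as for :class:`IVWEstimator`.
    xi_ : ndarray
        Fitted per-SNP instrument effects (profile MLEs at ``beta_``).
    loglik_ : float
        Maximised log-likelihood.
    converged_ : bool
        True when the gradient and step tolerances were met.
    beta_ci_low_, beta_ci_high_ : float
        95% interval for ``beta_`` on the log-odds scale, per ``ci_method``.
    """

    _GRAD_TOL = 1e-8
    _STEP_TOL = 1e-10

    def __init__(self, rho: float = 0.0, ci_method: str = "profile",
                 n_restarts: int = 3, random_state: int = 0):
        self.rho = rho
        self.ci_method = ci_method
        self.n_restarts = n_restarts
        self.random_state = random_state

    # profile machinery ----------------------------------------------------

    def _profile_xi(self, beta, x, y, sx, sy):
        """Closed-form maximiser of the likelihood over xi at fixed beta."""
        r = self.rho
        num = x / sx**2 + beta * y / sy**2 - r * (beta * x + y) / (sx * sy)
        den = 1.0 / sx**2 + beta**2 / sy**2 - 2.0 * r * beta / (sx * sy)
        return num / den

    def _loglik(self, beta, x, y, sx, sy, xi=None):
        r = self.rho
        if xi is None:
            xi = self._profile_xi(beta, x, y, sx, sy)
        a = (x - xi) / sx
        b = (y - beta * xi) / sy
        q = (a * a - 2.0 * r * a * b + b * b) / (1.0 - r * r)
        const = -np.log(2.0 * np.pi * sx * sy * np.sqrt(1.0 - r * r))
        return float(np.sum(const - 0.5 * q))

    def fit(self, X, y, x_se=None, y_se=None):
        x = _as_1d(X)
        y = np.asarray(y, dtype=float)
        if x_se is None or y_se is None:
            raise DomainError("x_se and y_se are required")
        sx = np.asarray(x_se, dtype=float)
        sy = np.asarray(y_se, dtype=float)
        if x.size < 2:
            raise EmptyInstrumentError(
                "likelihood method needs at least 2 instruments")
        if not -1.0 < self.rho < 1.0:
            raise DomainError("rho must lie in (-1, 1)")
        if np.any(sx <= 0) or np.any(sy <= 0):
            raise DomainError("all SEs must be > 0")

        pl = lambda b: self._loglik(b, x, y, sx, sy)
        nll = lambda b: -pl(b[0])

        ivw = IVWEstimator().fit(x, y, y_se=sy)
        rng = np.random.default_rng(self.random_state)
        starts = [ivw.beta_] + [
            ivw.beta_ + rng.normal(scale=max(3 * ivw.se_, 1e-3))
            for _ in range(self.n_restarts)]

        best, diagnostics = None, []
        for b0 in starts:
            res = optimize.minimize(nll, np.array([b0]), method="BFGS",
                                    options={"gtol": self._GRAD_TOL,
                                             "xrtol": self._STEP_TOL})
            grad_ok = np.linalg.norm(res.jac) < 1e-5  # scipy's gtol is loose
            diagnostics.append({"start": b0, "beta": float(res.x[0]),
                                "nll": float(res.fun),
                                "grad_norm": float(np.linalg.norm(res.jac)),
                                "success": bool(res.success)})
            if (res.success or grad_ok) and (best is None or res.fun < best.fun):
                best = res
            if best is not None and res is best:
                break  # warm start converged; no need for restarts
        if best is None:
            raise ConvergenceError(
                "likelihood optimisation failed to converge after "
                f"{len(starts)} starts", {"attempts": diagnostics})

        beta = float(best.x[0])
        self.beta_ = beta
        self.loglik_ = pl(beta)
        self.converged_ = True
        self.xi_ = self._profile_xi(beta, x, y, sx, sy)
        self.n_snps_ = int(x.size)
        self.n_features_in_ = 1

        # Wald SE from the curvature of the profile log-likelihood, whose
        # observed information at the MLE equals the beta block of the full
        # information's inverse.
        h = max(1e-5, 1e-4 * abs(beta))
        d2 = (pl(beta + h) - 2.0 * self.loglik_ + pl(beta - h)) / h**2
        if d2 >= 0:
            raise ConvergenceError("non-concave profile likelihood at optimum",
                                   {"beta": beta, "d2": d2})
        self.se_ = float((-d2) ** -0.5)
        self.p_value_ = two_sided_p(beta, self.se_)

        if self.ci_method == "profile":
            self.beta_ci_low_, self.beta_ci_high_ = self._profile_ci(pl, beta)
        elif self.ci_method == "wald":
            self.beta_ci_low_ = beta - Z95 * self.se_
            self.beta_ci_high_ = beta + Z95 * self.se_
        else:
            raise DomainError(f"unknown ci_method {self.ci_method!r}")
        return self

    def _profile_ci(self, pl, beta):
        """Invert 2*(loglik_max - pl(b)) = 3.841 on each side of the MLE."""
        cutoff = self.loglik_ - stats.chi2.ppf(0.95, 1) / 2.0
        f = lambda b: pl(b) - cutoff

        def solve(direction):
            step = max(self.se_, 1e-6)
            b = beta + direction * step
            for _ in range(60):
                if f(b) < 0:
                    return optimize.brentq(f, min(beta, b), max(beta, b),
                                           xtol=1e-10)
                b += direction * step
                step *= 1.6
            raise ConvergenceError("profile CI bound not bracketed",
                                   {"direction": direction, "beta": beta})

        return solve(-1.0), solve(+1.0)

    def predict(self, X):
        check_is_fitted(self, "beta_")
        return self.beta_ * _as_1d(X)


# ---------------------------------------------------------------------------
# instrument-set wrappers
# ---------------------------------------------------------------------------

def ivw_estimate(instruments: InstrumentSet, analysis: str = "all") -> MrEstimate:
    """IVW causal estimate for a harmonized instrument set."""
    if len(instruments) == 0:
        raise EmptyInstrumentError("empty instrument set")
    est = IVWEstimator().fit(instruments.x, instruments.y,
                             y_se=instruments.sigma_y)
    or_point, lo, hi, p = to_odds_ratio(est.beta_, est.se_)
    return MrEstimate(method="ivw", beta=est.beta_, se=est.se_,
                      or_point=or_point, ci_low=lo, ci_high=hi, p_value=p,
                      n_snps=est.n_snps_,
                      snp_ids=tuple(instruments.snp_ids), analysis=analysis)


def likelihood_estimate(instruments: InstrumentSet, rho: float = 0.0,
                        ci_method: str = "profile",
                        analysis: str = "all") -> LikelihoodFit:
    """Likelihood-method causal estimate for a harmonized instrument set."""
    est = LikelihoodMrEstimator(rho=rho, ci_method=ci_method).fit(
        instruments.x, instruments.y,
        x_se=instruments.sigma_x, y_se=instruments.sigma_y)
    or_point, _, _, _ = to_odds_ratio(est.beta_, est.se_)
    return LikelihoodFit(
        method="likelihood", beta=est.beta_, se=est.se_, or_point=or_point,
        ci_low=float(np.exp(est.beta_ci_low_)),
        ci_high=float(np.exp(est.beta_ci_high_)),
        p_value=est.p_value_, n_snps=est.n_snps_,
        snp_ids=tuple(instruments.snp_ids), analysis=analysis,
        xi=tuple(est.xi_), rho=rho, loglik=est.loglik_,
        converged=est.converged_, ci_method=ci_method,
        beta_ci_low=est.beta_ci_low_, beta_ci_high=est.beta_ci_high_)


def per_snp_odds_ratios(instruments: InstrumentSet) -> pd.DataFrame:
    """Forest-plot table of per-SNP ORs for the long-TL allele.

    Rows are ordered by increasing magnitude of the SNP's TL association,
    the convention used for published forest plots.
    """
    rows = []
    for v in sorted(instruments, key=lambda v: v.x):
        or_point, lo, hi, p = to_odds_ratio(v.y, v.sigma_y)
        rows.append({"snp_id": v.snp_id, "beta_kb": v.x, "or": or_point,
                     "ci_low": lo, "ci_high": hi, "p_value": p,
                     "flipped": v.flipped})
    return pd.DataFrame(rows, columns=["snp_id", "beta_kb", "or", "ci_low",
                                       "ci_high", "p_value", "flipped"])
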