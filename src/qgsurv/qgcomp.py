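"""Quantile g-computation with a Cox proportional-hazards underlying model.

Each mixture exposure is quantized to quartile scores 0-3 and entered as a
numeric term; the mixture index effect psi is the sum of the exposure
coefficients and measures the log hazard ratio for a simultaneous
one-quantile increase in every mixture component.  Component weights are
the coefficients' shares of their direction's total: when all coefficients
share a sign the weights sum to 1; with mixed signs the positive-direction
weights sum to 1 and the negative-direction weights sum to 1 (total 2).

This is the linear, no-interaction specification: psi and the weights come
directly from the underlying fit's coefficients, and var(psi) = 1' Sigma 1
over the exposure block of the coefficient covariance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import Cohort, design_matrix, empirical_cuts
from .cox import CoxTimeVarying

__all__ = ["QGCompCox", "fit_qgcomp"]


class QGCompCox(BaseEstimator):
    """Quantile g-computation estimator for survival outcomes.

    Parameters
    ----------
    mixture : list of str
        Names of the exposure columns forming the mixture (each is quantized
        internally to quartile scores unless already integer-coded).
    n_quantiles : int
        Number of exposure categories (default 4, i.e. quartiles 0-3).
    ties, tol, max_iter :
        Passed to the underlying :class:`~qgsurv.cox.CoxTimeVarying`.

    Attributes
    ----------
    psi_ : float
        Mixture log hazard ratio per simultaneous one-quantile increment.
    psi_se_ : float
    component_betas_ : pandas Series
        Per-exposure coefficients from the underlying Cox fit.
    weights_ : pandas Series
        Per-exposure weight (share of its direction's effect, positive).
    directions_ : pandas Series of {+1, -1}
    covariance_components_ : ndarray
        Exposure block of the coefficient covariance.
    cox_ : CoxTimeVarying
        The underlying fitted model (exposure scores first, then covariates).
    """

    def __init__(self, mixture=("pm25", "o3"), n_quantiles: int = 4,
                 ties: str = "efron", tol: float = 1e-8, max_iter: int = 50):
        self.mixture = mixture
        self.n_quantiles = n_quantiles
        self.ties = ties
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X: pd.DataFrame, y):
        """Fit on a design frame whose mixture columns hold raw exposures.

        Non-mixture columns of ``X`` are passed to the Cox model untouched
        (they should already be numeric / dummy coded).  ``y`` carries
        ``start, stop, event``.
        """
        mixture = list(self.mixture)
        if len(mixture) < 1:
            raise ValueError("mixture must name at least one exposure")
        Xw = X.copy()
        self.quantile_specs_ = {}
        probs = 100.0 * np.arange(1, self.n_quantiles) / self.n_quantiles
        for name in mixture:
            vals = Xw[name].to_numpy(dtype=float)
            cuts = np.percentile(vals, probs)
            if np.any(np.diff(cuts) <= 0):
                from .cohort import DegenerateQuantileError

                raise DegenerateQuantileError(f"{name}: degenerate quantile cuts")
            Xw[name] = np.searchsorted(cuts, vals, side="left").astype(float)
            self.quantile_specs_[name] = cuts
        # exposures first so the covariance block is the leading k x k
        order = mixture + [c for c in Xw.columns if c not in mixture]
        self.cox_ = CoxTimeVarying(ties=self.ties, tol=self.tol, max_iter=self.max_iter).fit(
            Xw[order], y
        )
        k = len(mixture)
        beta = self.cox_.coef_[:k]
        cov = self.cox_.covariance_[:k, :k]
        self.component_betas_ = pd.Series(beta, index=mixture)
        self.covariance_components_ = cov
        self.psi_ = float(beta.sum())
        self.psi_var_ = float(np.ones(k) @ cov @ np.ones(k))
        self.psi_se_ = float(np.sqrt(self.psi_var_))

        pos, neg = beta[beta >= 0], beta[beta < 0]
        w = np.empty(k)
        for i, b in enumerate(beta):
            denom = pos.sum() if b >= 0 else neg.sum()
            w[i] = b / denom if denom != 0 else np.nan
        self.weights_ = pd.Series(w, index=mixture)
        self.directions_ = pd.Series(np.where(beta >= 0, 1, -1), index=mixture)
        return self

    @property
    def joint_hr_(self) -> float:
        return float(np.exp(self.psi_))

    def joint_hr_ci(self, alpha: float = 0.05) -> tuple[float, float]:
        from scipy.stats import norm

        z = norm.ppf(1 - alpha / 2)
        return (
            float(np.exp(self.psi_ - z * self.psi_se_)),
            float(np.exp(self.psi_ + z * self.psi_se_)),
        )


def fit_qgcomp(
    cohort: Cohort,
    exposures=("pm25", "o3"),
    covariates=(),
    ties: str = "efron",
    tol: float = 1e-8,
    max_iter: int = 50,
) -> QGCompCox:
    """Quantize each mixture exposure to quartiles, fit the joint Cox model,
    and summarize psi, the joint HR, and component weights."""
    exposures = list(exposures)
    for e in exposures:
        # fail early with the cohort-level degenerate-quantile diagnostics
        empirical_cuts(cohort.data[e], e)
    Xcov = design_matrix(cohort, list(covariates))
    Xexp = cohort.data[exposures].astype(float)
    X = pd.concat([Xexp, Xcov], axis=1)
    y = cohort.data[["start", "stop", "event"]]
    return QGCompCox(
        mixture=exposures, ties=ties, tol=tol, max_iter=max_iter
    ).fit(X, y)
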