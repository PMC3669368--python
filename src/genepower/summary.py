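"""Regression of estimated power on design parameters.

The headline quantity is the *cancellation ratio*: from a main-effects OLS of
power on the simulation parameters, the power gained per additional causal
SNP divided by the power lost per additional non-causal SNP -- i.e. how many
non-causal SNPs it takes to cancel one causal SNP's contribution.  Ratios
are computed from the unrounded coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ParameterError

__all__ = [
    "RegressionSummary",
    "DEFAULT_PARAMETERS",
    "LD_PARAMETERS",
    "fit_power_regression",
    "cancellation_ratio",
    "average_noncausal_loss",
    "summarize_power_table",
]

DEFAULT_PARAMETERS = ("rr", "n_causal", "n_noncausal", "maf_causal",
                      "maf_noncausal", "n_total")
LD_PARAMETERS = DEFAULT_PARAMETERS + ("ld_level", "n_blocks")


@dataclass
class RegressionSummary:
    """Main-effects OLS fit of power for one gene-based test."""

    method: str
    coefficients: dict  # parameter -> (estimate, standard error)
    r_squared: float
    n_settings: int

    @property
    def loss_per_noncausal(self) -> float:
        """Absolute power lost per additional non-causal SNP (negated slope)."""
        return -self.coefficients["n_noncausal"][0]

    @property
    def gain_per_causal(self) -> float:
        return self.coefficients["n_causal"][0]

    @property
    def cancellation_ratio(self) -> float | None:
        return cancellation_ratio(self)


def fit_power_regression(power_table: pd.DataFrame, method: str,
                         parameters=DEFAULT_PARAMETERS,
                         logit_power: bool = False) -> RegressionSummary:
    """OLS of power on numerically coded design parameters, main effects only.

    ``logit_power`` fits logit-transformed power (clipped away from 0/1)
    instead; coefficients are then on the log-odds scale and the
    cancellation ratio loses its per-SNP interpretation, so it is off by
    default.
    """
    rows = power_table[power_table["method"] == method]
    if rows.empty:
        raise ParameterError(f"no rows for method {method!r} in the power table")
    X = rows.loc[:, list(parameters)].astype(float)
    constant = [c for c in parameters if X[c].nunique() < 2]
    if constant:
        raise ParameterError(
            f"parameters with fewer than 2 distinct values: {constant}")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ParameterError(
            f"design matrix is rank deficient; collinear columns among {list(parameters)}")
    y = rows["power"].astype(float)
    if logit_power:
        clipped = y.clip(1e-4, 1 - 1e-4)
        y = np.log(clipped / (1 - clipped))
    fit = sm.OLS(y, design).fit()
    coefficients = {
        name: (float(fit.params[name]), float(fit.bse[name]))
        for name in parameters
    }
    r_squared = 0.0 if np.isclose(y.var(), 0.0) else float(fit.rsquared)
    return RegressionSummary(method=method, coefficients=coefficients,
                             r_squared=r_squared, n_settings=len(rows))


def cancellation_ratio(summary: RegressionSummary) -> float | None:
    """gain_per_causal / loss_per_noncausal; None when the loss is not
    positive (small grids can flip the sign by Monte Carlo noise)."""
    loss = summary.loss_per_noncausal
    if loss <= 0:
        return None
    return summary.gain_per_causal / loss


def average_noncausal_loss(summaries) -> float:
    """Mean per-non-causal-SNP power loss across method summaries."""
    summaries = list(summaries)
    if not summaries:
        raise ParameterError("need at least one regression summary")
    return float(np.mean([s.loss_per_noncausal for s in summaries]))


def summarize_power_table(power_table: pd.DataFrame,
                          parameters=DEFAULT_PARAMETERS) -> pd.DataFrame:
    """Per-method table of loss, gain, cancellation ratio, and fit r^2."""
    rows = []
    for method in power_table["method"].unique():
        s = fit_power_regression(power_table, method, parameters)
        rows.append({
            "method": method,
            "loss_per_noncausal": s.loss_per_noncausal,
            "loss_se": s.coefficients["n_noncausal"][1],
            "gain_per_causal": s.gain_per_causal,
            "gain_se": s.coefficients["n_causal"][1],
            "cancellation_ratio": s.cancellation_ratio,
            "r_squared": s.r_squared,
            "n_settings": s.n_settings,
        })
    return pd.DataFrame(rows)
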