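"""BIC and sum-of-squared-residual comparison of intensity models.

Each candidate model supplies one predicted feedback intensity per
(participant, condition, location) cell; the comparison is against the
measured (or synthetic) per-cell mean intensities.  The likelihood is
independent Gaussian residuals with the residual standard deviation profiled
out, so log L depends on the data only through the SSR.

Sign convention: ``delta_bic`` is BIC(reference) - BIC(model), so *positive*
values favour the model over the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

KEY = ["participant", "condition", "location_cm"]


def bic(log_lik: float, k_params: int, n_points: int) -> float:
    """Bayesian information criterion, k*ln(n) - 2*logL (lower is better)."""
    if n_points < 1:
        raise ValueError("need at least one data point")
    return k_params * np.log(n_points) - 2.0 * log_lik


def ssr(predictions: pd.Series, observations: pd.Series) -> float:
    """Sum of squared residuals over aligned keys; raises on key mismatch."""
    if not predictions.index.equals(observations.index):
        pred_aligned, obs_aligned = predictions.align(observations, join="inner")
        if len(pred_aligned) != len(predictions) or len(obs_aligned) != len(
            observations
        ):
            raise ValueError("prediction and observation keys do not match")
        predictions, observations = pred_aligned, obs_aligned
    resid = observations.to_numpy(dtype=float) - predictions.to_numpy(dtype=float)
    return float(resid @ resid)


def profiled_gaussian_loglik(ssr_value: float, n_points: int) -> float:
    """Gaussian log-likelihood with sigma^2 = SSR/n profiled out."""
    sigma2 = max(ssr_value, 1e-300) / n_points
    return -0.5 * n_points * (np.log(2 * np.pi * sigma2) + 1.0)


@dataclass(frozen=True)
class ModelFitResult:
    """One model's predictions scored against the data."""

    label: str
    n_points: int
    k_params: int
    ssr: float
    log_lik: float
    bic: float
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_points <= self.k_params:
            raise ValueError("need more data points than parameters")
        if self.ssr < 0:
            raise ValueError("SSR cannot be negative")


def score_model(
    label: str,
    predictions: pd.Series,
    observations: pd.Series,
    k_params: int,
    fit_scale: bool = False,
) -> ModelFitResult:
    """Score one model's per-cell predictions against observed intensities.

    With ``fit_scale`` a single least-squares gain is applied to the
    predictions before scoring (and counted as a parameter): the comparison
    is then about the *pattern* of intensities across conditions and
    locations, not their absolute magnitude.
    """
    if fit_scale:
        p = predictions.to_numpy(dtype=float)
        o = observations.to_numpy(dtype=float)
        denom = float(p @ p)
        c = float(p @ o) / denom if denom > 0 else 0.0
        predictions = predictions * c
        k_params = k_params + 1
    else:
        c = 1.0
    s = ssr(predictions, observations)
    n = len(observations)
    ll = profiled_gaussian_loglik(s, n)
    return ModelFitResult(
        label=label,
        n_points=n,
        k_params=k_params,
        ssr=s,
        log_lik=ll,
        bic=bic(ll, k_params, n),
        scale=c,
    )


def compare_models(
    results: list[ModelFitResult],
    observations: pd.Series,
    reference: str = "classical",
) -> pd.DataFrame:
    """Delta-BIC (positive favours the model over the reference), SSR and R^2.

    All results must score the same data points.  R^2 is 1 - SSR/TSS with
    TSS about the grand mean of the observations.
    """
    labels = [r.label for r in results]
    if reference not in labels:
        raise ValueError(f"reference {reference!r} not among models {labels}")
    ns = {r.n_points for r in results}
    if len(ns) != 1 or ns.pop() != len(observations):
        raise ValueError("models were scored on different data points")
    obs = observations.to_numpy(dtype=float)
    tss = float(((obs - obs.mean()) ** 2).sum())
    ref_bic = next(r.bic for r in results if r.label == reference)
    rows = [
        {
            "model": r.label,
            "k_params": r.k_params,
            "ssr": r.ssr,
            "log_lik": r.log_lik,
            "bic": r.bic,
            "delta_bic": ref_bic - r.bic,
            "r_squared": 1.0 - r.ssr / tss if tss > 0 else np.nan,
        }
        for r in results
    ]
    return pd.DataFrame(rows).set_index("model")
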