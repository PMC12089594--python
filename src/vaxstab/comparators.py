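"""Baseline models for the simulation benchmark.

Two comparators:

* a collection of per-(batch, type) ordinary least-squares fits with a common
  intercept and temperature-specific slopes, carrying exact t-based
  prediction intervals;
* a single linear mixed-effects model with fixed effects for time,
  temperature (categorical), their interaction and container, plus random
  intercept and time slope per batch, fitted by maximum likelihood.

Mixed-model intervals are plug-in normal intervals (conditional prediction
variance + residual variance, no degrees-of-freedom correction); the slight
undercoverage this implies is deliberate and documented.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .core_io import Container, StabilityDataset
from .hier_model import PredictionInterval, PredictionTarget

__all__ = [
    "StratumFit",
    "LinearFitSet",
    "MixedFit",
    "fit_perbatch_linear",
    "predict_linear",
    "fit_mixed_model",
    "predict_mixed",
]


@dataclass(frozen=True)
class StratumFit:
    """OLS fit for one (batch, type): common intercept, slope per temperature."""

    coef: np.ndarray            # (1 + K,) intercept then slopes in temp order
    xtx_inv: np.ndarray         # (1 + K, 1 + K)
    sigma2_hat: float
    df_resid: int
    temperatures: tuple[float, ...]

    def design_row(self, temperature: float, time_months: float) -> np.ndarray:
        row = np.zeros(1 + len(self.temperatures))
        row[0] = 1.0
        row[1 + self.temperatures.index(float(temperature))] = time_months
        return row


@dataclass
class LinearFitSet:
    """Per-(batch, type) OLS fits; strata below the parameter count are
    recorded as unfittable and excluded from prediction."""

    fits: dict[tuple[str, str], StratumFit] = field(default_factory=dict)
    unfittable: list[tuple[str, str]] = field(default_factory=list)
    temperatures: tuple[float, ...] = ()


def fit_perbatch_linear(ds: StabilityDataset) -> LinearFitSet:
    """Fit each (batch, type) stratum separately by OLS.

    Predictions from one stratum are exactly invariant to every other batch
    in the training set (no pooling).
    """
    frame = ds.to_frame()
    temps = tuple(sorted(frame["temperature_C"].astype(float).unique()))
    result = LinearFitSet(temperatures=temps)
    p = 1 + len(temps)
    for (batch, mol_type), sub in frame.groupby(["batch_id", "molecular_type"], sort=False):
        sub_temps = tuple(sorted(sub["temperature_C"].astype(float).unique()))
        X = np.zeros((len(sub), 1 + len(sub_temps)))
        X[:, 0] = 1.0
        t_arr = sub["time_months"].to_numpy(float)
        for i, temp in enumerate(sub_temps):
            mask = sub["temperature_C"].to_numpy(float) == temp
            X[mask, 1 + i] = t_arr[mask]
        y = sub["potency"].to_numpy(float)
        rank = np.linalg.matrix_rank(X)
        if len(sub) <= X.shape[1] or rank < X.shape[1]:
            result.unfittable.append((batch, mol_type))
            continue
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        df = len(sub) - X.shape[1]
        result.fits[(batch, mol_type)] = StratumFit(
            coef=coef,
            xtx_inv=np.linalg.inv(X.T @ X),
            sigma2_hat=float(resid @ resid / df),
            df_resid=df,
            temperatures=sub_temps,
        )
    return result


def predict_linear(
    fits: LinearFitSet, target: PredictionTarget, alpha: float = 0.05
) -> PredictionInterval:
    """Standard t prediction interval for a new observation at the target."""
    key = (target.batch_id, target.molecular_type)
    if key not in fits.fits:
        raise KeyError(f"stratum {key} was not fitted (unfittable or unseen)")
    fit = fits.fits[key]
    if float(target.temperature_C) not in fit.temperatures:
        raise KeyError(f"temperature {target.temperature_C} unseen in stratum {key}")
    xv = fit.design_row(target.temperature_C, target.time_months)
    center = float(xv @ fit.coef)
    se = np.sqrt(fit.sigma2_hat * (1.0 + xv @ fit.xtx_inv @ xv))
    q = stats.t.ppf(1.0 - alpha / 2.0, df=fit.df_resid)
    return PredictionInterval(
        target=target, alpha=alpha, lower=center - q * se, center=center,
        upper=center + q * se, kind="predictive",
    )


@dataclass
class MixedFit:
    """ML mixed-effects fit: time * C(temperature) + container fixed effects,
    random intercept + time slope per batch."""

    fe_params: pd.Series
    cov_fe: pd.DataFrame
    cov_re: np.ndarray          # (2, 2) random intercept/slope covariance
    sigma2_hat: float
    random_effects: Mapping[str, np.ndarray]  # batch -> (intercept, slope)
    temperatures: tuple[float, ...]
    containers: tuple[str, ...]
    converged: bool
    degenerate: bool

    def design_row(self, target: PredictionTarget) -> np.ndarray:
        names = list(self.fe_params.index)
        row = np.zeros(len(names))
        t = float(target.time_months)
        temp = float(target.temperature_C)
        for i, name in enumerate(names):
            if name == "Intercept":
                row[i] = 1.0
            elif name == "time_months":
                row[i] = t
            elif name.startswith("C(temperature_C)[T.") and "time_months" not in name:
                level = float(name.split("[T.")[1].rstrip("]"))
                row[i] = 1.0 if temp == level else 0.0
            elif name.startswith("time_months:C(temperature_C)[T."):
                level = float(name.split("[T.")[1].rstrip("]"))
                row[i] = t if temp == level else 0.0
            elif name.startswith("container[T."):
                level = name.split("[T.")[1].rstrip("]")
                row[i] = 1.0 if target.container.value == level else 0.0
            else:  # pragma: no cover - formula drift guard
                raise KeyError(f"unrecognized fixed-effect term {name!r}")
        return row


def fit_mixed_model(ds: StabilityDataset) -> MixedFit:
    """Maximum-likelihood mixed model over the whole dataset.

    Singular/unconverged fits are not raised; they are flagged on the result.
    """
    frame = ds.to_frame()
    if frame["batch_id"].nunique() < 2:
        raise ValueError("mixed model needs >= 2 batches")
    formula = "potency ~ time_months * C(temperature_C)"
    if frame["container"].nunique() > 1:
        formula += " + container"
    model = smf.mixedlm(
        formula, data=frame, groups=frame["batch_id"], re_formula="~time_months"
    )
    degenerate = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        try:
            fit = model.fit(reml=False, method="lbfgs")
        except np.linalg.LinAlgError:
            fit = model.fit(reml=False, method="powell")
    # statsmodels stores cov_re already on the response scale
    cov_re = np.asarray(fit.cov_re)
    if not np.all(np.isfinite(cov_re)) or np.linalg.eigvalsh(cov_re).min() < -1e-8:
        degenerate = True
    re = {
        str(batch): np.asarray(effects, float)
        for batch, effects in fit.random_effects.items()
    }
    k_fe = len(fit.fe_params)
    return MixedFit(
        fe_params=fit.fe_params,
        cov_fe=fit.cov_params().iloc[:k_fe, :k_fe],
        cov_re=cov_re,
        sigma2_hat=float(fit.scale),
        random_effects=re,
        temperatures=tuple(sorted(frame["temperature_C"].astype(float).unique())),
        containers=tuple(sorted(frame["container"].unique())),
        converged=bool(getattr(fit, "converged", True)),
        degenerate=degenerate,
    )


def predict_mixed(
    fit: MixedFit,
    target: PredictionTarget,
    alpha: float = 0.05,
    new_batch: bool = False,
) -> PredictionInterval:
    """Plug-in normal prediction interval for a new observation.

    Seen batches use their predicted (BLUP-style) effects; ``new_batch``
    targets use the population level with the estimated between-batch
    variance added.
    """
    xv = fit.design_row(target)
    center = float(xv @ fit.fe_params.to_numpy())
    zv = np.array([1.0, float(target.time_months)])
    var = float(xv @ fit.cov_fe.to_numpy() @ xv) + fit.sigma2_hat
    if new_batch:
        var += float(zv @ fit.cov_re @ zv)
    else:
        if target.batch_id not in fit.random_effects:
            raise KeyError(
                f"batch {target.batch_id!r} unseen by the mixed model; "
                "pass new_batch=True for population-level prediction"
            )
        center += float(zv @ fit.random_effects[target.batch_id])
    q = stats.norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(var)
    return PredictionInterval(
        target=target, alpha=alpha, lower=center - q * se, center=center,
        upper=center + q * se, kind="predictive",
    )
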