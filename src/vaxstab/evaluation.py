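"""Coverage/MSE metrics, time-split validation and the simulation benchmark.

The benchmark works per scenario (setting x training batch count x training
window): replicate
cohorts are simulated, a subset of batches is sampled and truncated to the
training window at all temperatures, each model is fitted, and 95 %-nominal
coverage plus MSE are recorded on the sampled batches' 5 degC observations
beyond the window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from . import comparators, hier_model
from .core_io import Container, StabilityDataset, split_by_time
from .hier_model import (
    McmcConfig,
    ModelSpec,
    PredictionInterval,
    PredictionTarget,
    PriorConfig,
)
from .synthetic_data import (
    CohortDesign,
    GeneratorConfig,
    default_cohort_design,
    sample_true_parameters,
    simulate_dataset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageReport",
    "ScenarioSpec",
    "TimeSplitReport",
    "MODEL_NAMES",
    "empirical_coverage",
    "prediction_mse_by_type",
    "run_time_split_validation",
    "full_study_scenarios",
    "run_simulation_study",
    "interval_width_curve",
    "prior_sensitivity_scan",
]

MODEL_NAMES = ("hierarchical", "linear", "mixed")

SETTING_TOTALS = {"full": 30, "syringe_only": 17, "vial_only": 13}
ALLOWED_WINDOWS = (4, 6, 9, 12)

#: Cheap MCMC settings used inside replicated studies (overridable).
BENCH_MCMC = McmcConfig(n_iterations=1500, burn_in=500, thin=1, n_chains=1)


@dataclass(frozen=True)
class CoverageReport:
    model_name: str
    alpha: float
    n_points: int
    n_covered: int
    stratum: str = ""

    def __post_init__(self) -> None:
        if self.n_covered > self.n_points:
            raise ValueError("n_covered cannot exceed n_points")

    @property
    def empirical_coverage(self) -> float:
        return self.n_covered / self.n_points if self.n_points else float("nan")


@dataclass(frozen=True)
class ScenarioSpec:
    setting: Literal["full", "syringe_only", "vial_only"] = "full"
    n_batches_train: int = 5
    train_window_months: int = 6
    n_replicates: int = 50
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in SETTING_TOTALS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.n_batches_train > SETTING_TOTALS[self.setting]:
            raise ValueError(
                f"n_batches_train={self.n_batches_train} exceeds the "
                f"{self.setting} total of {SETTING_TOTALS[self.setting]}"
            )
        if self.train_window_months not in ALLOWED_WINDOWS:
            raise ValueError(
                f"train_window_months must be one of {ALLOWED_WINDOWS}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")

    def design(self) -> CohortDesign:
        base = default_cohort_design()
        if self.setting == "full":
            return base
        if self.setting == "syringe_only":
            return replace(base, n_batches=17, container_split={"syringe": 17})
        return replace(base, n_batches=13, container_split={"vial": 13})


def empirical_coverage(
    intervals: Sequence[PredictionInterval],
    observations,
    model_name: str = "",
    stratum: str = "",
) -> CoverageReport:
    """Fraction of observations inside their matched (closed) interval.

    Intervals and observations are paired positionally and must agree on
    coordinates; a mismatch raises ``ValueError``.
    """
    observations = list(observations)
    if len(intervals) != len(observations):
        raise ValueError(
            f"{len(intervals)} intervals cannot be paired with "
            f"{len(observations)} observations"
        )
    n_covered = 0
    alphas = set()
    for interval, rec in zip(intervals, observations):
        t = interval.target
        if (
            t.batch_id != rec.batch_id
            or t.molecular_type != rec.molecular_type
            or t.temperature_C != rec.temperature_C
            or t.time_months != rec.time_months
        ):
            raise ValueError(
                f"interval target {t} does not match observation "
                f"({rec.batch_id}, {rec.molecular_type}, {rec.temperature_C}, "
                f"{rec.time_months})"
            )
        alphas.add(interval.alpha)
        if interval.covers(rec.potency):
            n_covered += 1
    if len(alphas) > 1:
        raise ValueError(f"mixed alpha levels in interval set: {sorted(alphas)}")
    return CoverageReport(
        model_name=model_name,
        alpha=alphas.pop() if alphas else float("nan"),
        n_points=len(observations),
        n_covered=n_covered,
        stratum=stratum,
    )


def prediction_mse_by_type(
    predictions: Sequence[float], observations
) -> dict[str, float]:
    """Mean squared error grouped by molecular type plus pooled ``overall``."""
    observations = list(observations)
    if len(predictions) != len(observations):
        raise ValueError("predictions and observations must be paired 1:1")
    if not observations:
        return {"overall": float("nan")}
    errors = np.array(
        [p - r.potency for p, r in zip(predictions, observations)], float
    )
    types = np.array([r.molecular_type for r in observations])
    out: dict[str, float] = {"overall": float(np.mean(errors**2))}
    for label in dict.fromkeys(types):
        out[str(label)] = float(np.mean(errors[types == label] ** 2))
    return out


# ---------------------------------------------------------------------------
# Model adapters
# ---------------------------------------------------------------------------


class _FittedModel:
    """Uniform interface: intervals + point predictions on observed records."""

    name: str

    def intervals(self, records, alpha: float, seed: int) -> list[PredictionInterval]:
        raise NotImplementedError

    def predictable(self, records) -> list[bool]:
        return [True] * len(list(records))


class _FittedHierarchical(_FittedModel):
    name = "hierarchical"

    def __init__(self, draws):
        self.draws = draws

    def intervals(self, records, alpha, seed):
        return hier_model.predictive_intervals_for_records(
            self.draws, records, alpha=alpha, kind="predictive", seed=seed
        )


class _FittedLinear(_FittedModel):
    name = "linear"

    def __init__(self, fits: comparators.LinearFitSet):
        self.fits = fits

    def predictable(self, records):
        return [
            (r.batch_id, r.molecular_type) in self.fits.fits for r in records
        ]

    def intervals(self, records, alpha, seed):
        return [
            comparators.predict_linear(
                self.fits, _target_of(r), alpha=alpha
            )
            for r in records
        ]


class _FittedMixed(_FittedModel):
    name = "mixed"

    def __init__(self, fit: comparators.MixedFit):
        self.fit = fit

    def intervals(self, records, alpha, seed):
        return [
            comparators.predict_mixed(self.fit, _target_of(r), alpha=alpha)
            for r in records
        ]


def _target_of(record) -> PredictionTarget:
    return PredictionTarget(
        batch_id=record.batch_id,
        molecular_type=record.molecular_type,
        container=record.container,
        temperature_C=record.temperature_C,
        time_months=record.time_months,
    )


def _fit_model(
    name: str,
    train: StabilityDataset,
    mcmc: McmcConfig,
    priors: PriorConfig,
    spec: ModelSpec,
) -> _FittedModel:
    if name == "hierarchical":
        return _FittedHierarchical(hier_model.fit_gibbs(train, spec, priors, mcmc))
    if name == "linear":
        return _FittedLinear(comparators.fit_perbatch_linear(train))
    if name == "mixed":
        return _FittedMixed(comparators.fit_mixed_model(train))
    raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")


# ---------------------------------------------------------------------------
# Time-split validation
# ---------------------------------------------------------------------------


@dataclass
class TimeSplitReport:
    coverage: pd.DataFrame  # model, alpha, n_points, n_covered, empirical_coverage
    mse: pd.DataFrame       # model, molecular_type, mse
    n_train: int
    n_test: int


def run_time_split_validation(
    ds: StabilityDataset,
    cutoff: float = 6.0,
    models: Sequence[str] = MODEL_NAMES,
    alphas: Sequence[float] = (0.01, 0.05, 0.1),
    holdout_temperature: float | None = None,
    mcmc: McmcConfig | None = None,
    priors: PriorConfig | None = None,
    seed: int = 0,
) -> TimeSplitReport:
    """Train on time <= cutoff (all temperatures), evaluate beyond it."""
    train, test = split_by_time(ds, cutoff, holdout_temperature=holdout_temperature)
    if len(test) == 0:
        raise ValueError(f"cutoff {cutoff} leaves no test data")
    mcmc = mcmc or McmcConfig(seed=seed)
    priors = priors or PriorConfig()
    spec = ModelSpec()

    cov_rows, mse_rows = [], []
    for name in models:
        try:
            fitted = _fit_model(name, train, mcmc, priors, spec)
            ok = fitted.predictable(test.records)
            usable = [r for r, keep in zip(test.records, ok) if keep]
            for alpha in alphas:
                ivs = fitted.intervals(usable, alpha, seed)
                rep = empirical_coverage(ivs, usable, model_name=name)
                cov_rows.append(
                    {
                        "model": name, "alpha": alpha, "n_points": rep.n_points,
                        "n_covered": rep.n_covered,
                        "empirical_coverage": rep.empirical_coverage,
                    }
                )
            centers = [iv.center for iv in fitted.intervals(usable, 0.05, seed)]
            for label, value in prediction_mse_by_type(centers, usable).items():
                mse_rows.append({"model": name, "molecular_type": label, "mse": value})
        except Exception as exc:  # propagate with model annotation
            raise RuntimeError(f"model {name!r} failed in time-split: {exc}") from exc
    return TimeSplitReport(
        coverage=pd.DataFrame(cov_rows),
        mse=pd.DataFrame(mse_rows),
        n_train=len(train),
        n_test=len(test),
    )


# ---------------------------------------------------------------------------
# Simulation study
# ---------------------------------------------------------------------------


def full_study_scenarios(
    n_replicates: int = 50, base_seed: int = 0
) -> list[ScenarioSpec]:
    """The benchmark grid: full setting 5 batch sizes x 4 windows, plus
    syringe-only and vial-only at sizes {5, 10} x 4 windows."""
    scenarios = [
        ScenarioSpec("full", nb, w, n_replicates, base_seed)
        for nb in (5, 10, 15, 20, 30)
        for w in ALLOWED_WINDOWS
    ]
    for setting in ("syringe_only", "vial_only"):
        scenarios += [
            ScenarioSpec(setting, nb, w, n_replicates, base_seed)
            for nb in (5, 10)
            for w in ALLOWED_WINDOWS
        ]
    return scenarios


def run_simulation_study(
    scenarios: Iterable[ScenarioSpec],
    generator: GeneratorConfig | None = None,
    models: Sequence[str] = MODEL_NAMES,
    mcmc: McmcConfig | None = None,
    priors: PriorConfig | None = None,
    alpha: float = 0.05,
    holdout_temperature: float = 5.0,
) -> pd.DataFrame:
    """Run the benchmark; one result row per (scenario, replicate, model).

    Per replicate: a cohort is simulated with seed ``base_seed + replicate``,
    ``n_batches_train`` batches are sampled without replacement (separate
    seed stream from the measurement noise), their data are truncated to the
    training window at all temperatures, each model is fitted, and coverage
    at the 95 % nominal level plus MSE (overall and per type) are recorded on
    the sampled batches' 5 degC observations beyond the window.
    Deterministic given ``base_seed``.
    """
    generator = generator or GeneratorConfig()
    mcmc = mcmc or BENCH_MCMC
    priors = priors or PriorConfig()
    spec = ModelSpec()
    rows = []
    for scen in scenarios:
        design = scen.design()
        for rep in range(scen.n_replicates):
            seed = scen.base_seed + rep
            params = sample_true_parameters(
                generator, seed=seed, type_labels=design.type_labels,
                temperatures=design.temperature_set,
            )
            cohort = simulate_dataset(params, design, seed=seed)
            batch_rng = np.random.default_rng([scen.base_seed, rep, 314159])
            sampled = sorted(
                batch_rng.choice(
                    design.batch_ids(), size=scen.n_batches_train, replace=False
                )
            )
            in_sample = cohort.subset([r.batch_id in sampled for r in cohort.records])
            train, test = split_by_time(
                in_sample, scen.train_window_months,
                holdout_temperature=holdout_temperature,
            )
            rep_mcmc = replace(mcmc, seed=seed)
            for name in models:
                try:
                    fitted = _fit_model(name, train, rep_mcmc, priors, spec)
                    ok = fitted.predictable(test.records)
                    usable = [r for r, keep in zip(test.records, ok) if keep]
                    ivs = fitted.intervals(usable, alpha, seed)
                    cov = empirical_coverage(ivs, usable, model_name=name)
                    mse = prediction_mse_by_type([iv.center for iv in ivs], usable)
                except Exception as exc:
                    logger.warning(
                        "model %s failed on %s rep %d: %s", name, scen, rep, exc
                    )
                    continue
                row = {
                    "setting": scen.setting,
                    "n_batches_train": scen.n_batches_train,
                    "train_window_months": scen.train_window_months,
                    "replicate": rep,
                    "seed": seed,
                    "model": name,
                    "sampled_batches": "|".join(sampled),
                    "n_test": cov.n_points,
                    "coverage": cov.empirical_coverage,
                    "mse_overall": mse.get("overall", float("nan")),
                }
                for label in design.type_labels:
                    row[f"mse_{label}"] = mse.get(label, float("nan"))
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Data-requirement and prior-sensitivity scans
# ---------------------------------------------------------------------------


def interval_width_curve(
    generator: GeneratorConfig | None = None,
    data_sizes: Sequence[int] = (5, 10, 20, 30),
    target: PredictionTarget | None = None,
    alpha: float = 0.05,
    n_replicates: int = 3,
    width_threshold: float | None = None,
    mcmc: McmcConfig | None = None,
    base_seed: int = 0,
) -> tuple[pd.DataFrame, int | None]:
    """Mean predictive-interval width at the target versus training size.

    ``data_sizes`` counts training batches. Returns the width table and the
    smallest size whose mean width is <= ``width_threshold`` (``None`` when
    the threshold is never reached; the smallest size when no threshold is
    given and it is wider than every width — i.e. trivially met).
    """
    if list(data_sizes) != sorted(data_sizes):
        raise ValueError("data_sizes must be increasing")
    generator = generator or GeneratorConfig()
    mcmc = mcmc or BENCH_MCMC
    target = target or PredictionTarget(
        batch_id=hier_model.NEW_BATCH, molecular_type="A",
        container=Container.VIAL, temperature_C=5.0, time_months=36.0,
    )
    rows = []
    for size in data_sizes:
        design = replace(
            default_cohort_design(), n_batches=size, container_split={"vial": size}
        )
        widths = []
        for rep in range(n_replicates):
            seed = base_seed + rep
            params = sample_true_parameters(generator, seed=seed)
            cohort = simulate_dataset(params, design, seed=seed)
            draws = hier_model.fit_gibbs(cohort, mcmc=replace(mcmc, seed=seed))
            iv = hier_model.predictive_interval(
                draws, target, alpha=alpha, kind="predictive", seed=seed
            )
            widths.append(iv.width)
        rows.append({"n_batches": size, "mean_width": float(np.mean(widths))})
    table = pd.DataFrame(rows)
    smallest: int | None = None
    if width_threshold is not None:
        hits = table[table["mean_width"] <= width_threshold]
        smallest = int(hits["n_batches"].iloc[0]) if len(hits) else None
    return table, smallest


def prior_sensitivity_scan(
    ds: StabilityDataset,
    prior_grid: Sequence[PriorConfig],
    quantity: Callable[[hier_model.PosteriorDraws], float],
    mcmc: McmcConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit per prior configuration (shared seed) and tabulate a scalar
    quantity of interest (e.g. the 36-month lower bound). Failed cells are
    recorded with their error and the scan continues."""
    if not prior_grid:
        raise ValueError("prior_grid must be non-empty")
    mcmc = mcmc or McmcConfig(seed=seed)
    rows = []
    for priors in prior_grid:
        row = {
            "mean_prior_variance": priors.mean_prior_variance,
            "variance_prior_shape": priors.variance_prior_shape,
            "variance_prior_rate": priors.variance_prior_rate,
            "interval_inflation": priors.interval_inflation,
        }
        try:
            draws = hier_model.fit_gibbs(ds, priors=priors, mcmc=mcmc)
            row["quantity"] = float(quantity(draws))
            row["error"] = ""
        except Exception as exc:
            row["quantity"] = float("nan")
            row["error"] = str(exc)
        rows.append(row)
    table = pd.DataFrame(rows)
    finite = table["quantity"].dropna()
    table.attrs["quantity_range"] = (
        (float(finite.min()), float(finite.max())) if len(finite) else (None, None)
    )
    return table
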