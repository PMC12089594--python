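"""Synthetic stability-cohort generator.

Generates long-format potency datasets with the statistical structure the
hierarchical analysis assumes: a grand intercept near 100 % of label claim,
molecular-type and batch offsets, temperature-indexed degradation slopes with
type- and batch-level spread, an additive container offset, an optional
saturating taper of the time trend, and dominant iid assay noise that is
independent of batch and molecular type.

The default design is a 30-batch cohort (17 syringe, 13 vial) with 9
molecular types stored at 5/25/37 degC; its training grid yields exactly
30 x 9 x 8 = 2160 measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core_io import Container, StabilityDataset, StabilityRecord

__all__ = [
    "CohortDesign",
    "TrueParameters",
    "GeneratorConfig",
    "VarianceDecomposition",
    "default_cohort_design",
    "default_generator_config",
    "arrhenius_slope_means",
    "sample_true_parameters",
    "simulate_dataset",
    "residual_variance_fraction",
    "DEFAULT_SPEC_LIMIT",
]

GAS_CONSTANT_KJ = 8.314462618e-3  # kJ/(mol*K)

#: Default lower specification limit for normalized potency (percent of label).
#: Chosen so the default synthetic product, like the real one it emulates,
#: supports a >= 36-month shelf life at 5 degC despite 4 % assay noise.
DEFAULT_SPEC_LIMIT = 80.0

DEFAULT_TYPE_LABELS = tuple("ABCDEFGHI")
DEFAULT_FULL_GRID: dict[float, tuple[float, ...]] = {
    5.0: (0, 3, 6, 9, 12, 18, 24, 30, 36),
    25.0: (0, 1, 2, 3, 6),
    37.0: (0, 1, 2, 3),
}
# 8 points per batch x type so the default training design has 30*9*8 = 2160 rows.
DEFAULT_TRAINING_GRID: dict[float, tuple[float, ...]] = {
    5.0: (0, 3, 6),
    25.0: (1, 3, 6),
    37.0: (1, 3),
}


@dataclass(frozen=True)
class CohortDesign:
    """Study layout: batches, containers, types, temperatures, time grids."""

    n_batches: int = 30
    container_split: Mapping[str, int] = field(
        default_factory=lambda: {"syringe": 17, "vial": 13}
    )
    type_labels: tuple[str, ...] = DEFAULT_TYPE_LABELS
    temperature_set: tuple[float, ...] = (5.0, 25.0, 37.0)
    full_grid: Mapping[float, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_FULL_GRID)
    )
    training_grid: Mapping[float, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRAINING_GRID)
    )

    def __post_init__(self) -> None:
        if sum(self.container_split.values()) != self.n_batches:
            raise ValueError(
                f"container_split {dict(self.container_split)} does not sum to "
                f"n_batches={self.n_batches}"
            )
        for temp in self.training_grid:
            if temp not in self.full_grid:
                raise ValueError(f"training grid temperature {temp} not in full grid")

    @property
    def n_types(self) -> int:
        return len(self.type_labels)

    def batch_ids(self) -> tuple[str, ...]:
        return tuple(f"B{i + 1:02d}" for i in range(self.n_batches))

    def container_of(self) -> dict[str, Container]:
        """Deterministic batch -> container assignment (syringe block first)."""
        out: dict[str, Container] = {}
        ids = iter(self.batch_ids())
        for name, count in self.container_split.items():
            for _ in range(count):
                out[next(ids)] = Container(name)
        return out

    def n_training_records(self) -> int:
        per_stratum = sum(len(ts) for ts in self.training_grid.values())
        return self.n_batches * self.n_types * per_stratum


def default_cohort_design() -> CohortDesign:
    """The packaged default cohort design (30 batches: 17 syringe + 13 vial)."""
    return CohortDesign()


@dataclass(frozen=True)
class GeneratorConfig:
    """Hyperparameters of the generative hierarchy.

    ``slope_mean_by_temp`` gives the global mean degradation rate per
    temperature (percent/month, <= 0 and non-increasing in temperature).
    Alternatively pass ``arrhenius=(A, Ea_kJ_mol)`` to derive them from a
    single activation energy.
    """

    grand_intercept: float = 100.0
    type_intercept_sd: float = 0.4  # tau_a
    batch_intercept_sd: float = 0.4  # sigma_alpha
    container_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"vial": 0.0, "syringe": 0.5}
    )
    slope_mean_by_temp: Mapping[float, float] = field(
        default_factory=lambda: {5.0: -0.05, 25.0: -0.8, 37.0: -2.5}
    )
    arrhenius: tuple[float, float] | None = None
    type_slope_sd: float = 0.06  # tau_beta
    batch_slope_sd: float = 0.06  # sigma_beta
    residual_sd: float = 4.0  # sigma (assay noise)
    taper_rate: float = 0.0  # kappa, per month; 0 = exactly linear

    def __post_init__(self) -> None:
        for name in ("type_intercept_sd", "batch_intercept_sd", "type_slope_sd",
                     "batch_slope_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.taper_rate < 0:
            raise ValueError("taper_rate must be >= 0")
        if self.container_offsets.get("vial", 0.0) != 0.0:
            raise ValueError("vial is the reference container; its offset must be 0")

    def resolved_slope_means(self, temperatures: Sequence[float]) -> dict[float, float]:
        if self.arrhenius is not None:
            means = arrhenius_slope_means(self.arrhenius[0], self.arrhenius[1], temperatures)
        else:
            means = {float(t): float(self.slope_mean_by_temp[t]) for t in temperatures}
        ordered = [means[t] for t in sorted(means)]
        if any(m > 0 for m in ordered) or any(
            later > earlier for earlier, later in zip(ordered, ordered[1:])
        ):
            raise ValueError(
                "slope means must be <= 0 and non-increasing with temperature, "
                f"got {means}"
            )
        return means


def default_generator_config() -> GeneratorConfig:
    return GeneratorConfig()


def arrhenius_slope_means(
    pre_exponential: float, activation_energy_kj: float, temperatures: Sequence[float]
) -> dict[float, float]:
    """Slope means M_T = -A * exp(-Ea / (R * T_K)) with T_K = T_C + 273.15."""
    return {
        float(t): -pre_exponential
        * math.exp(-activation_energy_kj / (GAS_CONSTANT_KJ * (float(t) + 273.15)))
        for t in temperatures
    }


@dataclass(frozen=True)
class TrueParameters:
    """Realized generative parameters for one synthetic cohort family.

    Type-level effects (intercept offsets and per-temperature slope means)
    are realized here; batch-level effects and assay noise are drawn per
    cohort inside :func:`simulate_dataset`.
    """

    grand_intercept: float
    type_intercepts: Mapping[str, float]
    batch_intercept_sd: float
    container_offset: Mapping[str, float]
    slope_mean_by_temp: Mapping[float, float]
    type_slope_means: Mapping[tuple[str, float], float]
    type_slope_sd: float
    batch_slope_sd: float
    residual_sd: float
    taper_rate: float

    def mean_slope(self, mol_type: str, temperature: float) -> float:
        return self.type_slope_means[(mol_type, float(temperature))]


def sample_true_parameters(
    config: GeneratorConfig,
    seed: int,
    *,
    type_labels: Sequence[str] = DEFAULT_TYPE_LABELS,
    temperatures: Sequence[float] = (5.0, 25.0, 37.0),
) -> TrueParameters:
    """Draw type-level intercepts and slope means from their normal layers.

    Deterministic given ``seed``; all realized values are recorded on the
    returned :class:`TrueParameters`.
    """
    rng = np.random.default_rng(seed)
    slope_means = config.resolved_slope_means(temperatures)
    type_intercepts = {
        lab: float(rng.normal(0.0, config.type_intercept_sd)) for lab in type_labels
    }
    type_slope_means = {}
    for temp in temperatures:
        temp = float(temp)
        for lab in type_labels:
            type_slope_means[(lab, temp)] = float(
                rng.normal(slope_means[temp], config.type_slope_sd)
            )
    return TrueParameters(
        grand_intercept=config.grand_intercept,
        type_intercepts=type_intercepts,
        batch_intercept_sd=config.batch_intercept_sd,
        container_offset=dict(config.container_offsets),
        slope_mean_by_temp=slope_means,
        type_slope_means=type_slope_means,
        type_slope_sd=config.type_slope_sd,
        batch_slope_sd=config.batch_slope_sd,
        residual_sd=config.residual_sd,
        taper_rate=config.taper_rate,
    )


def time_transform(t: np.ndarray | float, taper_rate: float) -> np.ndarray | float:
    """g(t) = t for kappa = 0, else (1 - exp(-kappa t)) / kappa (saturating)."""
    if taper_rate == 0.0:
        return t
    return (1.0 - np.exp(-taper_rate * np.asarray(t, float))) / taper_rate


def true_mean_potency(
    params: TrueParameters,
    mol_type: str,
    container: Container | str,
    temperature: float,
    time_months: float | np.ndarray,
) -> np.ndarray | float:
    """Population mean profile (no batch effects, no noise)."""
    container = Container(container)
    intercept = (
        params.grand_intercept
        + params.type_intercepts[mol_type]
        + params.container_offset[container.value]
    )
    g = time_transform(time_months, params.taper_rate)
    return intercept + params.mean_slope(mol_type, temperature) * g


def simulate_dataset(
    params: TrueParameters,
    design: CohortDesign,
    seed: int,
    use_training_grid: bool = False,
    spec_limit: float | None = DEFAULT_SPEC_LIMIT,
) -> StabilityDataset:
    """Simulate one cohort.

    potency = intercept(batch, type, container) + slope(batch, type, T) * g(t)
    + iid N(0, sigma^2) noise, with g the optional saturating-taper transform.
    Batch intercepts are drawn around the type intercepts and batch slopes
    around the type slope means. Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    grid = design.training_grid if use_training_grid else design.full_grid
    containers = design.container_of()
    batch_ids = design.batch_ids()
    labels = design.type_labels

    missing = [lab for lab in labels if lab not in params.type_intercepts]
    if missing:
        raise ValueError(f"TrueParameters lacks type intercepts for {missing}")

    # Draw all batch-level effects first, in a fixed order, so that the noise
    # stream is identical across grid choices for the same seed.
    batch_intercept = {
        (b, lab): float(rng.normal(0.0, params.batch_intercept_sd))
        for b in batch_ids
        for lab in labels
    }
    batch_slope = {
        (b, lab, float(temp)): float(
            rng.normal(params.mean_slope(lab, temp), params.batch_slope_sd)
        )
        for b in batch_ids
        for lab in labels
        for temp in design.temperature_set
    }

    records: list[StabilityRecord] = []
    for b in batch_ids:
        cont = containers[b]
        for lab in labels:
            intercept = (
                params.grand_intercept
                + params.type_intercepts[lab]
                + batch_intercept[(b, lab)]
                + params.container_offset[cont.value]
            )
            for temp in design.temperature_set:
                times = grid.get(float(temp), ())
                if not len(times):
                    continue
                slope = batch_slope[(b, lab, float(temp))]
                g = time_transform(np.asarray(times, float), params.taper_rate)
                noise = rng.normal(0.0, params.residual_sd, size=len(times))
                potencies = intercept + slope * g + noise
                for t, y in zip(times, potencies):
                    records.append(
                        StabilityRecord(
                            batch_id=b,
                            molecular_type=lab,
                            container=cont,
                            temperature_C=float(temp),
                            time_months=float(t),
                            potency=float(y),
                        )
                    )
    return StabilityDataset(
        records,
        type_labels=labels,
        temperature_set=tuple(float(t) for t in design.temperature_set),
        spec_limit=spec_limit,
    )


@dataclass(frozen=True)
class VarianceDecomposition:
    """Residual-variance share plus per-batch homogeneity diagnostics."""

    fraction: float
    ss_resid: float
    ss_total: float
    per_batch_variance: Mapping[str, float]
    homogeneity_ratio: float  # max/min per-batch residual variance


def residual_variance_fraction(
    ds: StabilityDataset,
    fit: Callable[[StabilityRecord], float] | Sequence[float],
) -> VarianceDecomposition:
    """Fraction of detrended variability attributable to random assay noise.

    ``fit`` supplies the full mean structure (batch/type/container aware),
    either as a per-record callable or an array aligned with ``ds.records``.
    SS_total is taken about the grand detrended structure: a pooled
    per-temperature linear trend fit to all records, ignoring batch and type.
    The returned fraction SS_resid / SS_total is the share of the
    batch/type-free variability that the full structure also cannot explain,
    i.e. random noise. Per-batch residual variances and their max/min ratio
    check that the noise is batch-independent.

    Computed on detrended potency values (not rate-of-drop values).
    """
    n = len(ds.records)
    if n < 2:
        raise ValueError("residual_variance_fraction undefined for < 2 records")
    y = np.array([r.potency for r in ds.records], float)
    if callable(fit):
        yhat = np.array([fit(r) for r in ds.records], float)
    else:
        yhat = np.asarray(fit, float)
        if yhat.shape != y.shape:
            raise ValueError("fit array length does not match record count")

    # Grand detrended structure: pooled OLS potency ~ time per temperature.
    temps = np.array([r.temperature_C for r in ds.records], float)
    times = np.array([r.time_months for r in ds.records], float)
    grand = np.empty_like(y)
    for temp in np.unique(temps):
        mask = temps == temp
        t_sub, y_sub = times[mask], y[mask]
        if len(np.unique(t_sub)) >= 2:
            coeffs = np.polynomial.polynomial.polyfit(t_sub, y_sub, 1)
            grand[mask] = coeffs[0] + coeffs[1] * t_sub
        else:
            grand[mask] = y_sub.mean()

    resid = y - yhat
    ss_resid = float(np.sum(resid**2))
    ss_total = float(np.sum((y - grand) ** 2))
    fraction = ss_resid / ss_total if ss_total > 0 else 0.0

    per_batch: dict[str, float] = {}
    batch_arr = np.array([r.batch_id for r in ds.records])
    for b in np.unique(batch_arr):
        sub = resid[batch_arr == b]
        if len(sub) >= 2:
            per_batch[str(b)] = float(np.var(sub, ddof=1))
    if per_batch:
        values = np.array(list(per_batch.values()))
        ratio = float(values.max() / values.min()) if values.min() > 0 else float("inf")
    else:
        ratio = float("nan")
    return VarianceDecomposition(
        fraction=float(fraction),
        ss_resid=ss_resid,
        ss_total=ss_total,
        per_batch_variance=per_batch,
        homogeneity_ratio=ratio,
    )
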