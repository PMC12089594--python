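"""Hierarchical Bayesian stability model.

The likelihood is normal with a linear time trend and a shared residual
variance::

    y_i = alpha[batch_i, type_i] + gamma * 1{syringe_i}
          + beta[batch_i, type_i, temp_i] * t_i + eps_i,   eps_i ~ N(0, sigma^2)

with a hierarchically centred parameter tree:

* intercepts: alpha[b, t] ~ N(a[t], sigma_alpha^2),
  a[t] ~ N(mu, tau_a^2), mu ~ N(0, V0);
* slopes (one family per temperature): beta[b, t, T] ~ N(m[t, T], sigma_beta^2),
  m[t, T] ~ N(M[T], tau_beta^2), M[T] ~ N(0, V0);
* container: additive fixed offset gamma for syringe, vial = 0 reference
  (gamma is pinned to 0 when the data contain a single container);
* every variance component and sigma^2 carries an inverse-gamma prior.

All full conditionals are conjugate (normal-normal for locations,
inverse-gamma for variances), so the model is estimated by a pure Gibbs
sampler. An optional Arrhenius-constrained variant ties the per-temperature
slope means to a single activation energy via a Metropolis-within-Gibbs step,
enabling extrapolation to unseen temperatures.

The supplementary equations of the source study are not public; this
hierarchy is the reconstruction documented in the project README.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import Container, StabilityDataset
from .synthetic_data import GAS_CONSTANT_KJ

__all__ = [
    "ModelSpec",
    "PriorConfig",
    "McmcConfig",
    "PosteriorDraws",
    "PredictionTarget",
    "PredictionInterval",
    "NEW_BATCH",
    "fit_gibbs",
    "closed_form_posterior_oracle",
    "ConjugatePosterior",
    "predictive_interval",
    "estimate_shelf_life",
    "posterior_summary",
    "save_draws",
    "load_draws",
]

#: Sentinel batch id requesting fresh batch-level effects from the hierarchy.
NEW_BATCH = "new-batch"


@dataclass(frozen=True)
class ModelSpec:
    """Structural switches of the hierarchy (defaults follow the docstring)."""

    arrhenius_slopes: bool = False
    #: Metropolis proposal SDs for (log pre-exponential, activation energy kJ/mol).
    arrhenius_proposal_sd: tuple[float, float] = (0.05, 1.0)


@dataclass(frozen=True)
class PriorConfig:
    """Non-informative defaults: N(0, 1e6) locations, IG(0.001, 0.001) scales."""

    mean_prior_variance: float = 1e6
    variance_prior_shape: float = 0.001
    variance_prior_rate: float = 0.001
    interval_inflation: float = 1.0

    def __post_init__(self) -> None:
        for name in ("mean_prior_variance", "variance_prior_shape",
                     "variance_prior_rate", "interval_inflation"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class McmcConfig:
    n_iterations: int = 4000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    n_chains: int = 2

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_kept(self) -> int:
        return self.n_chains * ((self.n_iterations - self.burn_in) // self.thin)


@dataclass
class PosteriorDraws:
    """Post-burn-in, thinned Gibbs draws of every model parameter."""

    batch_ids: tuple[str, ...]
    type_labels: tuple[str, ...]
    temperatures: tuple[float, ...]
    batch_container: Mapping[str, Container]
    mu: np.ndarray            # (D,)
    a: np.ndarray             # (D, T)
    alpha: np.ndarray         # (D, B, T)
    gamma: np.ndarray         # (D,)
    M: np.ndarray             # (D, K)
    m: np.ndarray             # (D, T, K)
    beta: np.ndarray          # (D, B, T, K)
    tau_a2: np.ndarray        # (D,)
    sigma_alpha2: np.ndarray  # (D,)
    tau_beta2: np.ndarray     # (D,)
    sigma_beta2: np.ndarray   # (D,)
    sigma2: np.ndarray        # (D,)
    chain: np.ndarray         # (D,)
    interval_inflation: float = 1.0
    log_A: np.ndarray | None = None  # (D,) when Arrhenius-constrained
    Ea: np.ndarray | None = None     # (D,) kJ/mol

    @property
    def n_draws(self) -> int:
        return len(self.mu)

    def batch_index(self, batch_id: str) -> int:
        return self.batch_ids.index(batch_id)

    def type_index(self, label: str) -> int:
        return self.type_labels.index(label)

    def temp_index(self, temperature: float) -> int:
        return self.temperatures.index(float(temperature))

    def fitted_values(self, records) -> np.ndarray:
        """Posterior-mean predictions of the mean structure at observed
        coordinates (batch intercept + container offset + batch slope x t)."""
        alpha_mean = self.alpha.mean(axis=0)
        beta_mean = self.beta.mean(axis=0)
        gamma_mean = float(self.gamma.mean())
        out = np.empty(len(records))
        for n, r in enumerate(records):
            i = self.batch_index(r.batch_id)
            j = self.type_index(r.molecular_type)
            k = self.temp_index(r.temperature_C)
            value = alpha_mean[i, j] + beta_mean[i, j, k] * r.time_months
            if r.container is Container.SYRINGE:
                value += gamma_mean
            out[n] = value
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long audit table: one row per draw x scalar parameter."""
        rows: dict[str, np.ndarray] = {}
        rows["mu"] = self.mu
        rows["gamma_syringe"] = self.gamma
        for j, lab in enumerate(self.type_labels):
            rows[f"a[{lab}]"] = self.a[:, j]
        for k, temp in enumerate(self.temperatures):
            rows[f"M[{temp:g}C]"] = self.M[:, k]
        for j, lab in enumerate(self.type_labels):
            for k, temp in enumerate(self.temperatures):
                rows[f"m[{lab},{temp:g}C]"] = self.m[:, j, k]
        for i, b in enumerate(self.batch_ids):
            for j, lab in enumerate(self.type_labels):
                rows[f"alpha[{b},{lab}]"] = self.alpha[:, i, j]
                for k, temp in enumerate(self.temperatures):
                    rows[f"beta[{b},{lab},{temp:g}C]"] = self.beta[:, i, j, k]
        rows["tau_a2"] = self.tau_a2
        rows["sigma_alpha2"] = self.sigma_alpha2
        rows["tau_beta2"] = self.tau_beta2
        rows["sigma_beta2"] = self.sigma_beta2
        rows["sigma2"] = self.sigma2
        if self.log_A is not None:
            rows["log_A"] = self.log_A
            rows["Ea_kJ_mol"] = self.Ea
        frame = pd.DataFrame(rows)
        frame.insert(0, "chain", self.chain)
        frame.insert(1, "draw", np.arange(self.n_draws))
        return frame.melt(
            id_vars=["chain", "draw"], var_name="parameter", value_name="value"
        )


@dataclass(frozen=True)
class PredictionTarget:
    """Coordinates of a prediction; ``batch_id=NEW_BATCH`` requests fresh
    batch-level effects drawn from the fitted hierarchy."""

    batch_id: str
    molecular_type: str
    container: Container | str
    temperature_C: float
    time_months: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "container", Container(self.container))


@dataclass(frozen=True)
class PredictionInterval:
    target: PredictionTarget
    alpha: float
    lower: float
    center: float
    upper: float
    kind: Literal["predictive", "mean_profile"]

    def __post_init__(self) -> None:
        if not self.lower <= self.center <= self.upper:
            raise ValueError("interval must satisfy lower <= center <= upper")

    def covers(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _index_dataset(ds: StabilityDataset):
    frame = ds.to_frame()
    y = frame["potency"].to_numpy(float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite potency in training data")
    batch_ids = tuple(dict.fromkeys(frame["batch_id"]))
    type_labels = tuple(ds.type_labels) or tuple(dict.fromkeys(frame["molecular_type"]))
    temps = tuple(sorted({float(t) for t in frame["temperature_C"]}))
    b_idx = frame["batch_id"].map({b: i for i, b in enumerate(batch_ids)}).to_numpy()
    t_idx = frame["molecular_type"].map(
        {t: i for i, t in enumerate(type_labels)}
    ).to_numpy()
    k_idx = frame["temperature_C"].astype(float).map(
        {t: i for i, t in enumerate(temps)}
    ).to_numpy()
    syr = (frame["container"] == Container.SYRINGE.value).to_numpy(float)
    x = frame["time_months"].to_numpy(float)
    batch_container = {b: ds.container_of(b) for b in batch_ids}
    return batch_ids, type_labels, temps, b_idx, t_idx, k_idx, syr, x, y, batch_container


def _check_strata(type_labels, temps, t_idx, k_idx, x) -> None:
    for j, lab in enumerate(type_labels):
        for k, temp in enumerate(temps):
            mask = (t_idx == j) & (k_idx == k)
            if mask.any() and len(np.unique(x[mask])) < 2:
                raise ValueError(
                    f"rank-deficient stratum (type={lab}, temperature={temp:g}C): "
                    "needs >= 2 distinct time points"
                )


def _sample_inv_gamma(rng: np.random.Generator, shape: float, rate: float) -> float:
    return float(rate / rng.gamma(shape))


def _arrhenius_means(log_A: float, Ea: float, temps_K: np.ndarray) -> np.ndarray:
    return -np.exp(log_A - Ea / (GAS_CONSTANT_KJ * temps_K))


def fit_gibbs(
    ds: StabilityDataset,
    spec: ModelSpec | None = None,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorDraws:
    """Fit the hierarchy by cycling conjugate full-conditional updates.

    Deterministic given ``mcmc.seed``; chains use independent spawned
    substreams. Raises ``ValueError`` for rank-deficient (type, temperature)
    strata or non-finite potency.
    """
    spec = spec or ModelSpec()
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    if len(ds) == 0:
        raise ValueError("cannot fit an empty dataset")

    (batch_ids, type_labels, temps, b_idx, t_idx, k_idx, syr, x, y,
     batch_container) = _index_dataset(ds)
    _check_strata(type_labels, temps, t_idx, k_idx, x)

    B, T, K, N = len(batch_ids), len(type_labels), len(temps), len(y)
    idx_bt = b_idx * T + t_idx
    idx_btk = idx_bt * K + k_idx
    n_bt = np.bincount(idx_bt, minlength=B * T).reshape(B, T)
    sx2_btk = np.bincount(idx_btk, weights=x * x, minlength=B * T * K).reshape(B, T, K)
    n_syr = syr.sum()
    two_containers = 0 < n_syr < N

    V0 = priors.mean_prior_variance
    a0, b0 = priors.variance_prior_shape, priors.variance_prior_rate
    temps_K = np.array(temps) + 273.15

    # Rough data-driven initialization; burn-in does the rest.
    mu0 = float(np.mean(y[x == x.min()])) if np.any(x == x.min()) else float(np.mean(y))
    slope0 = np.zeros(K)
    for k in range(K):
        mask = k_idx == k
        if len(np.unique(x[mask])) >= 2:
            slope0[k] = np.polynomial.polynomial.polyfit(x[mask], y[mask], 1)[1]

    keep_per_chain = (mcmc.n_iterations - mcmc.burn_in) // mcmc.thin
    D = mcmc.n_chains * keep_per_chain
    out = {
        "mu": np.empty(D), "a": np.empty((D, T)), "alpha": np.empty((D, B, T)),
        "gamma": np.empty(D), "M": np.empty((D, K)), "m": np.empty((D, T, K)),
        "beta": np.empty((D, B, T, K)), "tau_a2": np.empty(D),
        "sigma_alpha2": np.empty(D), "tau_beta2": np.empty(D),
        "sigma_beta2": np.empty(D), "sigma2": np.empty(D), "chain": np.empty(D, int),
    }
    log_A_out = np.empty(D) if spec.arrhenius_slopes else None
    Ea_out = np.empty(D) if spec.arrhenius_slopes else None

    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.n_chains)
    pos = 0
    for chain, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        mu = mu0
        a = np.full(T, mu0)
        alpha = np.full((B, T), mu0)
        gamma = 0.0
        M = slope0.copy()
        m = np.tile(slope0, (T, 1))
        beta = np.tile(slope0, (B, T, 1))
        tau_a2 = sigma_alpha2 = tau_beta2 = sigma_beta2 = 1.0
        sigma2 = max(float(np.var(y)), 1e-6)
        log_A, Ea = 0.0, 80.0
        if spec.arrhenius_slopes:
            # crude init from the pooled slopes where negative
            neg = slope0 < 0
            if neg.sum() >= 2:
                coef = np.polynomial.polynomial.polyfit(
                    1.0 / temps_K[neg], np.log(-slope0[neg]), 1
                )
                log_A, Ea = float(coef[0]), float(-coef[1] * GAS_CONSTANT_KJ)
            M = _arrhenius_means(log_A, Ea, temps_K)

        for it in range(mcmc.n_iterations):
            beta_obs = beta.reshape(-1)[idx_btk]
            # -- batch intercepts alpha[b,t]
            r = y - gamma * syr - beta_obs * x
            s_bt = np.bincount(idx_bt, weights=r, minlength=B * T).reshape(B, T)
            prec = 1.0 / sigma_alpha2 + n_bt / sigma2
            mean = (a[None, :] / sigma_alpha2 + s_bt / sigma2) / prec
            alpha = rng.normal(mean, np.sqrt(1.0 / prec))
            alpha_obs = alpha.reshape(-1)[idx_bt]
            # -- container offset (syringe), vial reference
            if two_containers:
                r = y - alpha_obs - beta_obs * x
                prec_g = 1.0 / V0 + n_syr / sigma2
                mean_g = ((r * syr).sum() / sigma2) / prec_g
                gamma = rng.normal(mean_g, math.sqrt(1.0 / prec_g))
            # -- batch slopes beta[b,t,k]
            r2 = y - alpha_obs - gamma * syr
            sxr = np.bincount(
                idx_btk, weights=x * r2, minlength=B * T * K
            ).reshape(B, T, K)
            prec = 1.0 / sigma_beta2 + sx2_btk / sigma2
            mean = (m[None, :, :] / sigma_beta2 + sxr / sigma2) / prec
            beta = rng.normal(mean, np.sqrt(1.0 / prec))
            # -- type intercepts and grand mean
            prec_a = 1.0 / tau_a2 + B / sigma_alpha2
            mean_a = (mu / tau_a2 + alpha.sum(axis=0) / sigma_alpha2) / prec_a
            a = rng.normal(mean_a, math.sqrt(1.0 / prec_a))
            prec_mu = 1.0 / V0 + T / tau_a2
            mu = rng.normal((a.sum() / tau_a2) / prec_mu, math.sqrt(1.0 / prec_mu))
            # -- type slope means and global slope means
            prec_m = 1.0 / tau_beta2 + B / sigma_beta2
            mean_m = (M[None, :] / tau_beta2 + beta.sum(axis=0) / sigma_beta2) / prec_m
            m = rng.normal(mean_m, math.sqrt(1.0 / prec_m))
            if spec.arrhenius_slopes:
                log_A, Ea, M = _arrhenius_step(
                    rng, log_A, Ea, m, tau_beta2, temps_K, spec.arrhenius_proposal_sd
                )
            else:
                prec_M = 1.0 / V0 + T / tau_beta2
                M = rng.normal(
                    (m.sum(axis=0) / tau_beta2) / prec_M, math.sqrt(1.0 / prec_M)
                )
            # -- translation moves: shift whole hierarchy levels jointly.
            # With small between-level variances the layers move in lockstep
            # and plain Gibbs mixes by a slow random walk; these are exact
            # Gibbs updates in level-translated coordinates and restore
            # mixing of the level means (intercept chain and slope chains).
            alpha_obs = alpha.reshape(-1)[idx_bt]
            beta_obs = beta.reshape(-1)[idx_btk]
            r = y - alpha_obs - gamma * syr - beta_obs * x
            prec_s = N / sigma2 + 1.0 / V0
            delta = rng.normal(
                (r.sum() / sigma2 - mu / V0) / prec_s, math.sqrt(1.0 / prec_s)
            )
            mu += delta
            a += delta
            alpha += delta
            r -= delta
            # per-type intercept shifts (a_t with its batch intercepts)
            n_t = np.bincount(t_idx, minlength=T)
            s_t = np.bincount(t_idx, weights=r, minlength=T)
            prec_t = n_t / sigma2 + 1.0 / tau_a2
            delta_t = rng.normal(
                (s_t / sigma2 - (a - mu) / tau_a2) / prec_t, np.sqrt(1.0 / prec_t)
            )
            a += delta_t
            alpha += delta_t[None, :]
            r -= delta_t[t_idx]
            # per-temperature slope shifts (M_k with its m and beta)
            if not spec.arrhenius_slopes:  # would break the M = f(A, Ea) tie
                sxx_k = np.bincount(k_idx, weights=x * x, minlength=K)
                sxr_k = np.bincount(k_idx, weights=x * r, minlength=K)
                prec_k = sxx_k / sigma2 + 1.0 / V0
                delta_k = rng.normal(
                    (sxr_k / sigma2 - M / V0) / prec_k, np.sqrt(1.0 / prec_k)
                )
                M += delta_k
                m += delta_k[None, :]
                beta += delta_k[None, None, :]
                r -= delta_k[k_idx] * x
            # per-(type, temperature) slope shifts (m with its betas)
            idx_tk = t_idx * K + k_idx
            sxx_tk = np.bincount(idx_tk, weights=x * x, minlength=T * K).reshape(T, K)
            sxr_tk = np.bincount(idx_tk, weights=x * r, minlength=T * K).reshape(T, K)
            prec_tk = sxx_tk / sigma2 + 1.0 / tau_beta2
            delta_tk = rng.normal(
                (sxr_tk / sigma2 - (m - M[None, :]) / tau_beta2) / prec_tk,
                np.sqrt(1.0 / prec_tk),
            )
            m += delta_tk
            beta += delta_tk[None, :, :]
            r -= delta_tk.reshape(-1)[idx_tk] * x
            # -- variance components
            tau_a2 = _sample_inv_gamma(rng, a0 + T / 2, b0 + 0.5 * np.sum((a - mu) ** 2))
            sigma_alpha2 = _sample_inv_gamma(
                rng, a0 + B * T / 2, b0 + 0.5 * np.sum((alpha - a[None, :]) ** 2)
            )
            tau_beta2 = _sample_inv_gamma(
                rng, a0 + T * K / 2, b0 + 0.5 * np.sum((m - M[None, :]) ** 2)
            )
            sigma_beta2 = _sample_inv_gamma(
                rng, a0 + B * T * K / 2, b0 + 0.5 * np.sum((beta - m[None, :, :]) ** 2)
            )
            # r has been kept current through the translation moves
            sigma2 = _sample_inv_gamma(rng, a0 + N / 2, b0 + 0.5 * np.sum(r**2))

            if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
                out["mu"][pos] = mu
                out["a"][pos] = a
                out["alpha"][pos] = alpha
                out["gamma"][pos] = gamma
                out["M"][pos] = M
                out["m"][pos] = m
                out["beta"][pos] = beta
                out["tau_a2"][pos] = tau_a2
                out["sigma_alpha2"][pos] = sigma_alpha2
                out["tau_beta2"][pos] = tau_beta2
                out["sigma_beta2"][pos] = sigma_beta2
                out["sigma2"][pos] = sigma2
                out["chain"][pos] = chain
                if spec.arrhenius_slopes:
                    log_A_out[pos] = log_A
                    Ea_out[pos] = Ea
                pos += 1

    return PosteriorDraws(
        batch_ids=batch_ids,
        type_labels=type_labels,
        temperatures=temps,
        batch_container=batch_container,
        interval_inflation=priors.interval_inflation,
        log_A=log_A_out,
        Ea=Ea_out,
        **out,
    )


def _arrhenius_step(rng, log_A, Ea, m, tau_beta2, temps_K, proposal_sd):
    """Metropolis update of (log_A, Ea) given type slope means m ~ N(M(T), tau)."""

    def logpost(la: float, ea: float) -> float:
        if ea <= 0:
            return -np.inf
        M = _arrhenius_means(la, ea, temps_K)
        return -0.5 * np.sum((m - M[None, :]) ** 2) / tau_beta2

    current = logpost(log_A, Ea)
    for _ in range(5):  # a few inner proposals per sweep helps mixing
        la_p = log_A + rng.normal(0.0, proposal_sd[0])
        ea_p = Ea + rng.normal(0.0, proposal_sd[1])
        cand = logpost(la_p, ea_p)
        if math.log(rng.uniform()) < cand - current:
            log_A, Ea, current = la_p, ea_p, cand
    return log_A, Ea, _arrhenius_means(log_A, Ea, temps_K)


# ---------------------------------------------------------------------------
# Closed-form conjugate oracle (single-group linear model; used in tests)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConjugatePosterior:
    """Exact normal-inverse-gamma posterior for y = b0 + b1 x + eps."""

    coef_mean: np.ndarray           # (2,)
    precision: np.ndarray           # (2, 2)  Lambda_n (sigma^2-scaled)
    shape: float                    # a_n
    rate: float                     # b_n

    @property
    def sigma2_mean(self) -> float:
        if self.shape <= 1:
            raise ValueError("sigma^2 posterior mean undefined for shape <= 1")
        return self.rate / (self.shape - 1)

    @property
    def coef_cov(self) -> np.ndarray:
        """Marginal covariance of the coefficients (multivariate-t)."""
        if self.shape <= 1:
            raise ValueError("coefficient covariance undefined for shape <= 1")
        return self.rate / (self.shape - 1) * np.linalg.inv(self.precision)

    def predictive_interval(self, x_star: float, alpha: float) -> tuple[float, float, float]:
        """Central (1 - alpha) Student-t predictive interval at x_star."""
        xv = np.array([1.0, x_star])
        center = float(xv @ self.coef_mean)
        scale = math.sqrt(
            self.rate / self.shape * (1.0 + xv @ np.linalg.solve(self.precision, xv))
        )
        q = stats.t.ppf(1.0 - alpha / 2.0, df=2.0 * self.shape)
        return center - q * scale, center, center + q * scale


def closed_form_posterior_oracle(
    x: Sequence[float],
    y: Sequence[float],
    priors: PriorConfig | None = None,
    prior_mean: Sequence[float] = (0.0, 0.0),
) -> ConjugatePosterior:
    """Analytic conjugate posterior for a single-group line (test oracle).

    Uses the variance-scaled normal-inverse-gamma family with prior
    ``b | sigma^2 ~ N(prior_mean, sigma^2 * V0 I)`` and
    ``sigma^2 ~ IG(shape, rate)``; in the vague-prior limit this coincides
    with the sampler's independent-prior model and with OLS.
    """
    priors = priors or PriorConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(np.unique(x)) < 2:
        raise np.linalg.LinAlgError("collinear design: need >= 2 distinct x values")
    X = np.column_stack([np.ones_like(x), x])
    m0 = np.asarray(prior_mean, float)
    L0 = np.eye(2) / priors.mean_prior_variance
    Ln = L0 + X.T @ X
    mn = np.linalg.solve(Ln, L0 @ m0 + X.T @ y)
    an = priors.variance_prior_shape + len(y) / 2.0
    bn = priors.variance_prior_rate + 0.5 * float(
        y @ y + m0 @ L0 @ m0 - mn @ Ln @ mn
    )
    return ConjugatePosterior(coef_mean=mn, precision=Ln, shape=an, rate=bn)


# ---------------------------------------------------------------------------
# Prediction, shelf life, summaries
# ---------------------------------------------------------------------------


def _profile_draws(
    draws: PosteriorDraws,
    target: PredictionTarget,
    rng: np.random.Generator,
    times: np.ndarray | None = None,
) -> np.ndarray:
    """Per-draw mean-trend values at the target; shape (D,) or (D, len(times))."""
    j = draws.type_index(target.molecular_type)
    temp = float(target.temperature_C)
    if temp in draws.temperatures:
        k = draws.temp_index(temp)
        slope_mean = draws.m[:, j, k]
    elif draws.log_A is not None:
        slope_mean = _arrhenius_means(
            draws.log_A, draws.Ea, np.array([temp + 273.15])
        ).ravel() + rng.normal(0.0, np.sqrt(draws.tau_beta2))
    else:
        raise ValueError(
            f"temperature {temp:g}C unseen in training and no Arrhenius "
            "extension was fitted (extrapolation error)"
        )

    if target.batch_id == NEW_BATCH:
        intercept = draws.a[:, j] + rng.normal(0.0, np.sqrt(draws.sigma_alpha2))
        slope = slope_mean + rng.normal(0.0, np.sqrt(draws.sigma_beta2))
    else:
        i = draws.batch_index(target.batch_id)
        intercept = draws.alpha[:, i, j]
        if temp in draws.temperatures:
            slope = draws.beta[:, i, draws.type_index(target.molecular_type),
                               draws.temp_index(temp)]
        else:
            slope = slope_mean + rng.normal(0.0, np.sqrt(draws.sigma_beta2))
    if target.container is Container.SYRINGE:
        intercept = intercept + draws.gamma

    t = np.asarray(target.time_months if times is None else times, float)
    if t.ndim == 0:
        return intercept + slope * float(t)
    return intercept[:, None] + slope[:, None] * t[None, :]


def _interval_from_values(values, target, alpha, kind, inflation) -> PredictionInterval:
    lower, upper = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0])
    center = float(np.mean(values))
    if inflation != 1.0:
        lower = center - inflation * (center - lower)
        upper = center + inflation * (upper - center)
    return PredictionInterval(
        target=target, alpha=alpha, lower=float(lower), center=center,
        upper=float(upper), kind=kind,
    )


def predictive_interval(
    draws: PosteriorDraws,
    target: PredictionTarget,
    alpha: float = 0.05,
    kind: Literal["predictive", "mean_profile"] = "predictive",
    seed: int = 0,
) -> PredictionInterval:
    """Central (1 - alpha) interval at the target coordinates.

    ``predictive`` simulates new observations (mean trend + assay noise, with
    fresh batch effects for ``NEW_BATCH`` targets); ``mean_profile`` uses the
    mean trend only. The fit-time ``interval_inflation`` scales the spread
    about the center.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    rng = np.random.default_rng(seed)
    values = _profile_draws(draws, target, rng)
    if kind == "predictive":
        values = values + rng.normal(0.0, np.sqrt(draws.sigma2))
    elif kind != "mean_profile":
        raise ValueError(f"unknown interval kind {kind!r}")
    return _interval_from_values(values, target, alpha, kind, draws.interval_inflation)


def predictive_intervals_for_records(
    draws: PosteriorDraws,
    records,
    alpha: float = 0.05,
    kind: Literal["predictive", "mean_profile"] = "predictive",
    seed: int = 0,
) -> list[PredictionInterval]:
    """Vectorized-per-target intervals for many observed coordinates."""
    rng = np.random.default_rng(seed)
    out = []
    for r in records:
        target = PredictionTarget(
            batch_id=r.batch_id, molecular_type=r.molecular_type,
            container=r.container, temperature_C=r.temperature_C,
            time_months=r.time_months,
        )
        values = _profile_draws(draws, target, rng)
        if kind == "predictive":
            values = values + rng.normal(0.0, np.sqrt(draws.sigma2))
        out.append(
            _interval_from_values(values, target, alpha, kind, draws.interval_inflation)
        )
    return out


def estimate_shelf_life(
    draws: PosteriorDraws,
    molecular_type: str,
    container: Container | str = Container.VIAL,
    spec_limit: float = 90.0,
    temperature_C: float = 5.0,
    horizon: int = 48,
    level: float = 0.95,
    grid_step: int = 1,
    kind: Literal["mean_profile", "predictive"] = "mean_profile",
    seed: int = 0,
) -> int:
    """Largest month on the grid at which the one-sided lower ``level`` bound
    of a new batch's stability profile stays at or above ``spec_limit``.

    Returns ``horizon`` when the bound never crosses the limit, 0 when it is
    already below at t = 0. The one-sided lower 95 % bound is the 5th
    percentile of the relevant posterior distribution; grid ties resolve
    downward (conservative).
    """
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    rng = np.random.default_rng(seed)
    times = np.arange(0, horizon + 1, grid_step, dtype=float)
    target = PredictionTarget(
        batch_id=NEW_BATCH, molecular_type=molecular_type, container=container,
        temperature_C=temperature_C, time_months=0.0,
    )
    values = _profile_draws(draws, target, rng, times=times)
    if kind == "predictive":
        values = values + rng.normal(0.0, np.sqrt(draws.sigma2))[:, None]
    centers = values.mean(axis=0)
    lowers = np.quantile(values, 1.0 - level, axis=0)
    if draws.interval_inflation != 1.0:
        lowers = centers - draws.interval_inflation * (centers - lowers)
    below = lowers < spec_limit
    if below[0]:
        return 0
    if not below.any():
        return int(times[-1])
    first_cross = int(np.argmax(below))
    return int(times[first_cross - 1])


def save_draws(draws: PosteriorDraws, csv_path, meta_path) -> None:
    """Persist draws as a wide CSV (one row per draw) + JSON dimension sidecar."""
    import json

    wide: dict[str, np.ndarray] = {"chain": draws.chain}
    wide["mu"] = draws.mu
    wide["gamma_syringe"] = draws.gamma
    for j, lab in enumerate(draws.type_labels):
        wide[f"a[{lab}]"] = draws.a[:, j]
    for k, temp in enumerate(draws.temperatures):
        wide[f"M[{temp:g}]"] = draws.M[:, k]
    for j, lab in enumerate(draws.type_labels):
        for k, temp in enumerate(draws.temperatures):
            wide[f"m[{lab}|{temp:g}]"] = draws.m[:, j, k]
    for i, b in enumerate(draws.batch_ids):
        for j, lab in enumerate(draws.type_labels):
            wide[f"alpha[{b}|{lab}]"] = draws.alpha[:, i, j]
            for k, temp in enumerate(draws.temperatures):
                wide[f"beta[{b}|{lab}|{temp:g}]"] = draws.beta[:, i, j, k]
    for name in ("tau_a2", "sigma_alpha2", "tau_beta2", "sigma_beta2", "sigma2"):
        wide[name] = getattr(draws, name)
    if draws.log_A is not None:
        wide["log_A"] = draws.log_A
        wide["Ea"] = draws.Ea
    pd.DataFrame(wide).to_csv(csv_path, index=False)
    meta = {
        "batch_ids": list(draws.batch_ids),
        "type_labels": list(draws.type_labels),
        "temperatures": list(draws.temperatures),
        "batch_container": {b: c.value for b, c in draws.batch_container.items()},
        "interval_inflation": draws.interval_inflation,
        "arrhenius": draws.log_A is not None,
    }
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def load_draws(csv_path, meta_path) -> PosteriorDraws:
    """Inverse of :func:`save_draws`."""
    import json

    with open(meta_path, encoding="utf-8") as fh:
        meta = json.load(fh)
    frame = pd.read_csv(csv_path)
    batch_ids = tuple(meta["batch_ids"])
    type_labels = tuple(meta["type_labels"])
    temps = tuple(float(t) for t in meta["temperatures"])
    D = len(frame)
    B, T, K = len(batch_ids), len(type_labels), len(temps)
    a = np.column_stack([frame[f"a[{lab}]"] for lab in type_labels])
    M = np.column_stack([frame[f"M[{t:g}]"] for t in temps])
    m = np.empty((D, T, K))
    for j, lab in enumerate(type_labels):
        for k, t in enumerate(temps):
            m[:, j, k] = frame[f"m[{lab}|{t:g}]"]
    alpha = np.empty((D, B, T))
    beta = np.empty((D, B, T, K))
    for i, b in enumerate(batch_ids):
        for j, lab in enumerate(type_labels):
            alpha[:, i, j] = frame[f"alpha[{b}|{lab}]"]
            for k, t in enumerate(temps):
                beta[:, i, j, k] = frame[f"beta[{b}|{lab}|{t:g}]"]
    return PosteriorDraws(
        batch_ids=batch_ids,
        type_labels=type_labels,
        temperatures=temps,
        batch_container={
            b: Container(c) for b, c in meta["batch_container"].items()
        },
        mu=frame["mu"].to_numpy(),
        a=a,
        alpha=alpha,
        gamma=frame["gamma_syringe"].to_numpy(),
        M=M,
        m=m,
        beta=beta,
        tau_a2=frame["tau_a2"].to_numpy(),
        sigma_alpha2=frame["sigma_alpha2"].to_numpy(),
        tau_beta2=frame["tau_beta2"].to_numpy(),
        sigma_beta2=frame["sigma_beta2"].to_numpy(),
        sigma2=frame["sigma2"].to_numpy(),
        chain=frame["chain"].to_numpy(int),
        interval_inflation=float(meta["interval_inflation"]),
        log_A=frame["log_A"].to_numpy() if meta.get("arrhenius") else None,
        Ea=frame["Ea"].to_numpy() if meta.get("arrhenius") else None,
    )


def posterior_summary(draws: PosteriorDraws, credible_level: float = 0.95) -> pd.DataFrame:
    """Per-parameter mean, SD and central credible interval (one row each)."""
    if draws.n_draws == 0:
        raise ValueError("empty posterior draws")
    lo_q = (1.0 - credible_level) / 2.0
    long = draws.to_frame()
    grouped = long.groupby("parameter", sort=False)["value"]
    summary = grouped.agg(
        mean="mean",
        sd=lambda v: v.std(ddof=1),
        lower=lambda v: v.quantile(lo_q),
        upper=lambda v: v.quantile(1.0 - lo_q),
    ).reset_index()
    summary.insert(1, "credible_level", credible_level)
    return summary
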