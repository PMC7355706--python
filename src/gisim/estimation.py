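"""Least-squares estimation of transit/dissolution/precipitation parameters.

Fits any subset of the kinetic coefficients to per-compartment
concentration–time observations by bounded local least squares from multiple
seeded starts. Rate-like parameters are searched in log10 space and the
particle-transfer fraction in logit space, so that coefficients spanning many
decades are fit without scaling pathologies; the reported estimate is the
best of all starts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .physchem import DrugProperties
from .transit import (
    COMPARTMENTS,
    ConditionConfig,
    TransitParameters,
    concentration_series,
    simulate_gis,
)

__all__ = [
    "IdentifiabilityError",
    "FitProblem",
    "FitResult",
    "fit_transit_parameters",
    "goodness_of_fit",
    "DEFAULT_BOUNDS",
    "DEFAULT_FREE_PARAMETERS",
]


class IdentifiabilityError(ValueError):
    """Observations cannot determine the requested free parameters."""


DEFAULT_FREE_PARAMETERS = ("z_s", "z_d", "z_j", "frac", "k_pre_d", "k_pre_j")

#: Natural-scale box bounds. z-factors on the tabulated (unscaled) mL/µg/min
#: scale; precipitation rates in min⁻¹.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "z_s": (1e-13, 1e-8),
    "z_d": (1e-13, 1e-8),
    "z_j": (1e-13, 1e-8),
    "frac": (0.01, 0.99),
    "k_pre_d": (1e-6, 10.0),
    "k_pre_j": (1e-6, 10.0),
}

_RATE_PARAMS = frozenset({"z_s", "z_d", "z_j", "k_pre_d", "k_pre_j"})


@dataclass(frozen=True)
class FitProblem:
    """Observed data plus everything needed to simulate candidates."""

    observed: pd.DataFrame
    condition: ConditionConfig
    drug: DrugProperties
    free_parameters: tuple[str, ...] = DEFAULT_FREE_PARAMETERS
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    initial_guess: TransitParameters | None = None
    loss: str = "sse"

    def __post_init__(self) -> None:
        if self.loss not in ("sse", "weighted_sse"):
            raise ValueError(f"unknown loss {self.loss!r}")
        unknown = set(self.free_parameters) - set(DEFAULT_FREE_PARAMETERS)
        if unknown:
            raise ValueError(f"unknown free parameter(s): {sorted(unknown)}")

    def resolved_bounds(self) -> dict[str, tuple[float, float]]:
        out = dict(DEFAULT_BOUNDS)
        out.update(self.bounds)
        for name, (lo, hi) in out.items():
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lo < hi")
        return out


@dataclass(frozen=True)
class FitResult:
    """Best-of-starts estimate with residuals and convergence diagnostics."""

    estimate: TransitParameters
    loss_value: float
    residuals: dict[str, np.ndarray]
    observed: dict[str, tuple[np.ndarray, np.ndarray]]
    predicted: dict[str, np.ndarray]
    diagnostics: dict


def _to_internal(name: str, value: float) -> float:
    if name == "frac":
        v = min(max(value, 1e-9), 1 - 1e-9)
        return math.log(v / (1.0 - v))
    return math.log10(value)


def _from_internal(name: str, value: float) -> float:
    if name == "frac":
        return 1.0 / (1.0 + math.exp(-value))
    return 10.0**value


def _observations_by_compartment(observed: pd.DataFrame, duration: float):
    obs = {}
    for comp, grp in observed.groupby("compartment"):
        if comp not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {comp!r} in observations")
        grp = grp.sort_values("time_min")
        t = grp["time_min"].to_numpy(dtype=float)
        if t.size and (t[0] < 0 or t[-1] > duration):
            raise ValueError("observation times must lie within the condition duration")
        obs[comp] = (
            t,
            grp["mean_conc_ug_per_ml"].to_numpy(dtype=float),
            grp["sd"].to_numpy(dtype=float) if "sd" in grp else np.zeros_like(t),
        )
    return obs


def fit_transit_parameters(
    problem: FitProblem,
    seed: int,
    n_starts: int = 8,
    sim_rtol: float = 1e-6,
    sim_atol: float = 1e-8,
    max_nfev: int | None = None,
    xtol: float = 1e-12,
    ftol: float = 1e-14,
    gtol: float = 1e-14,
    diff_step: float = 1e-4,
) -> FitResult:
    """Fit the free kinetic parameters to the observed concentration tables.

    Deterministic for a given seed: extra starts beyond the initial guess are
    drawn from a seeded scrambled-Sobol sequence inside the (transformed)
    bounds, each refined by trust-region-reflective least squares; the
    lowest-loss solution wins.
    """
    if problem.observed.empty:
        raise IdentifiabilityError("empty observation set")
    free = list(problem.free_parameters)
    obs = _observations_by_compartment(problem.observed, problem.condition.duration)
    n_obs = sum(len(t) for t, _, _ in obs.values())
    if n_obs < len(free):
        raise IdentifiabilityError(
            f"{n_obs} observations cannot determine {len(free)} free parameters"
        )

    bounds = problem.resolved_bounds()
    base = problem.initial_guess
    if base is None:
        base = TransitParameters(
            **{
                name: (
                    math.sqrt(bounds[name][0] * bounds[name][1])
                    if name in _RATE_PARAMS
                    else 0.5
                )
                for name in DEFAULT_FREE_PARAMETERS
            }
        )

    lo = np.array([_to_internal(p, bounds[p][0]) for p in free])
    hi = np.array([_to_internal(p, bounds[p][1]) for p in free])

    # simulation grid: union of observation times, anchored at t = 0
    all_times = np.unique(np.concatenate([[0.0], *[t for t, _, _ in obs.values()]]))

    # weights: 1/SD with a floor of 5% of each compartment's maximum mean,
    # preventing zero-SD points from dominating the weighted loss
    weights = {}
    for comp, (t, mean, sd) in obs.items():
        if problem.loss == "weighted_sse":
            floor = 0.05 * max(mean.max(), 1e-12)
            weights[comp] = 1.0 / np.maximum(sd, floor)
        else:
            weights[comp] = np.ones_like(t)

    idx = {comp: np.searchsorted(all_times, t) for comp, (t, _, _) in obs.items()}

    def make_params(x: np.ndarray) -> TransitParameters:
        return replace(base, **{p: _from_internal(p, v) for p, v in zip(free, x)})

    def residual_vec(x: np.ndarray) -> np.ndarray:
        params = make_params(x)
        try:
            traj = simulate_gis(
                problem.drug,
                problem.condition,
                params,
                output_grid=all_times,
                rtol=sim_rtol,
                atol=sim_atol,
            )
        except RuntimeError as err:
            raise RuntimeError(f"simulator failed during fitting at {params}: {err}") from err
        parts = []
        for comp, (t, mean, _) in obs.items():
            model = concentration_series(traj, comp)[idx[comp]]
            parts.append((model - mean) * weights[comp])
        return np.concatenate(parts)

    x0 = np.clip(np.array([_to_internal(p, getattr(base, p)) for p in free]), lo, hi)
    starts = [x0]
    if n_starts > 1:
        sampler = qmc.Sobol(d=len(free), scramble=True, rng=np.random.default_rng(seed))
        n_draw = 1 << (n_starts - 2).bit_length() if n_starts > 2 else 1
        unit = sampler.random(n_draw)[: n_starts - 1]
        starts.extend(lo + unit * (hi - lo))

    best = None
    nfev_total = 0
    for i, start in enumerate(starts):
        try:
            res = least_squares(
                residual_vec,
                start,
                bounds=(lo, hi),
                method="trf",
                # finite-difference steps must stay well above the ODE solver
                # noise floor or the Jacobian drowns in integration error
                diff_step=diff_step,
                max_nfev=max_nfev,
                xtol=xtol,
                ftol=ftol,
                gtol=gtol,
            )
        except RuntimeError:
            continue
        nfev_total += res.nfev
        if best is None or res.cost < best[0].cost:
            best = (res, i)
    if best is None:
        raise RuntimeError("all optimization starts failed")

    res, best_start = best
    estimate = make_params(res.x)
    traj = simulate_gis(
        problem.drug,
        problem.condition,
        estimate,
        output_grid=all_times,
        rtol=sim_rtol,
        atol=sim_atol,
    )
    residuals = {}
    predicted = {}
    observed_out = {}
    loss_value = 0.0
    for comp, (t, mean, _) in obs.items():
        model = concentration_series(traj, comp)[idx[comp]]
        r = (model - mean) * weights[comp]
        residuals[comp] = r
        predicted[comp] = model
        observed_out[comp] = (t, mean)
        loss_value += float(np.sum(r**2))

    return FitResult(
        estimate=estimate,
        loss_value=loss_value,
        residuals=residuals,
        observed=observed_out,
        predicted=predicted,
        diagnostics={
            "n_starts": len(starts),
            "best_start": best_start,
            "nfev_total": nfev_total,
            "terminated_on": int(res.status),
            "optimizer_success": bool(res.success),
        },
    )


def goodness_of_fit(result: FitResult) -> dict[str, dict[str, float]]:
    """Per-compartment RMSE (unweighted) and R² against the observed mean."""
    out = {}
    for comp, (t, mean) in result.observed.items():
        model = result.predicted[comp]
        resid = model - mean
        rmse = float(np.sqrt(np.mean(resid**2)))
        ss_tot = float(np.sum((mean - mean.mean()) ** 2))
        ss_res = float(np.sum(resid**2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else float("-inf"))
        out[comp] = {"rmse": rmse, "r2": r2}
    return out
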