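"""Mass-transport simulator for a three-chamber gastrointestinal simulator.

Couples first-order gastric emptying, constant gastric/duodenal secretions,
z-factor dissolution with pH-dependent solubility, and first-order
precipitation of the supersaturated excess, across stomach, duodenum
(constant volume) and jejunum (accumulating, no outflow).

State bookkeeping distinguishes, in each chamber, solid, dissolved and
precipitated drug; solids leaving the stomach split into a transferred
fraction (``frac``) and an inert retained residue (``1 - frac``),
representing the part of the dosage form that never disintegrates finely
enough to be carried by the transfer pump.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .physchem import DrugProperties, degree_of_supersaturation, solubility_at_ph

__all__ = [
    "PiecewiseProfile",
    "ConditionConfig",
    "TransitParameters",
    "CompartmentSeries",
    "GISTrajectory",
    "gastric_emptying_rate",
    "dissolution_flux",
    "precipitation_flux",
    "simulate_gis",
    "concentration_series",
    "ds_series",
    "DEFAULT_Z_UNIT_SCALE",
    "COMPARTMENTS",
]

COMPARTMENTS = ("stomach", "duodenum", "jejunum")

#: Uniform multiplier applied to the tabulated z-factors (mL/µg/min).
#: The published dissolution coefficients are ~1e-11 mL/µg/min, which on the
#: µg/mL concentration scale of this system would give dissolution half-lives
#: of years; the multiplier (together with the default intrinsic-solubility
#: preset) is calibrated once against the published condition-1 simulated
#: exposure, preserving the published relative ordering of the z-factors.
DEFAULT_Z_UNIT_SCALE = 2.0e5

#: Volume (mL) below which a chamber concentration is defined as zero.
VOLUME_EPS = 0.1


@dataclass(frozen=True)
class PiecewiseProfile:
    """Piecewise-linear time profile, e.g. pH as a function of time (min)."""

    times: tuple[float, ...]
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.values) or not self.times:
            raise ValueError("times and values must be equal-length, non-empty")
        if any(t1 <= t0 for t0, t1 in zip(self.times, self.times[1:])):
            raise ValueError("profile times must be strictly increasing")

    @classmethod
    def constant(cls, value: float, duration: float = 60.0) -> "PiecewiseProfile":
        return cls(times=(0.0, float(duration)), values=(float(value), float(value)))

    @classmethod
    def from_points(cls, points) -> "PiecewiseProfile":
        pts = sorted((float(t), float(v)) for t, v in points)
        return cls(times=tuple(t for t, _ in pts), values=tuple(v for _, v in pts))

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.values))


@dataclass(frozen=True)
class ConditionConfig:
    """Physiological scenario of one dissolution run.

    Volumes in mL, secretion rates in mL/min, times in min. The duodenal
    chamber is held at constant volume by matching its outflow to its inflow;
    the jejunal chamber starts empty and only accumulates.
    """

    label: str
    t_half_gastric: float
    gastric_ph_profile: PiecewiseProfile
    duodenal_ph_profile: PiecewiseProfile
    jejunal_ph_profile: PiecewiseProfile
    gastric_initial_volume: float = 300.0
    gastric_residual_floor: float = 5.0
    duodenal_volume: float = 50.0
    jejunal_initial_volume: float = 0.0
    k_sec_s: float = 1.0
    k_sec_d: float = 1.0
    duration: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "gastric_initial_volume",
            "gastric_residual_floor",
            "jejunal_initial_volume",
            "k_sec_s",
            "k_sec_d",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.duodenal_volume <= 0:
            raise ValueError("duodenal_volume must be positive")
        if self.t_half_gastric <= 0:
            raise ValueError("t_half_gastric must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("gastric_ph_profile", "duodenal_ph_profile", "jejunal_ph_profile"):
            prof = getattr(self, name)
            if prof.times[0] > 0 or prof.times[-1] < self.duration:
                raise ValueError(f"{name} must cover [0, {self.duration}] min")


@dataclass(frozen=True)
class TransitParameters:
    """Kinetic coefficients of the mass-transport model.

    z_* are dissolution coefficients (mL/µg/min, tabulated scale) per chamber;
    ``frac`` is the fraction of emptied solid particles actually transferred
    downstream; k_pre_* are first-order precipitation rate constants (min⁻¹)
    acting on the supersaturated excess. ``z_unit_scale`` multiplies every
    z-factor uniformly (see :data:`DEFAULT_Z_UNIT_SCALE`).
    """

    z_s: float
    z_d: float
    z_j: float
    frac: float
    k_pre_d: float
    k_pre_j: float
    z_unit_scale: float = DEFAULT_Z_UNIT_SCALE

    def __post_init__(self) -> None:
        for name in ("z_s", "z_d", "z_j", "k_pre_d", "k_pre_j", "z_unit_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.frac <= 1.0:
            raise ValueError("frac must lie in [0, 1]")

    @property
    def z_s_eff(self) -> float:
        return self.z_s * self.z_unit_scale

    @property
    def z_d_eff(self) -> float:
        return self.z_d * self.z_unit_scale

    @property
    def z_j_eff(self) -> float:
        return self.z_j * self.z_unit_scale

    def with_values(self, **kwargs) -> "TransitParameters":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CompartmentSeries:
    """Time series of one chamber's state along the output grid."""

    volume: np.ndarray
    x_solid: np.ndarray
    x_dissolved: np.ndarray
    x_precipitated: np.ndarray
    ph: np.ndarray
    solubility: np.ndarray

    @property
    def concentration(self) -> np.ndarray:
        c = np.zeros_like(self.volume)
        ok = self.volume > VOLUME_EPS
        c[ok] = self.x_dissolved[ok] / self.volume[ok]
        return c


@dataclass(frozen=True)
class GISTrajectory:
    """Simulated state of the three-chamber system on an output time grid."""

    times: np.ndarray
    stomach: CompartmentSeries
    duodenum: CompartmentSeries
    jejunum: CompartmentSeries
    retained_residue: np.ndarray
    emptied_dissolved: np.ndarray
    emptied_solid: np.ndarray
    transferred_dissolved: np.ndarray
    transferred_solid: np.ndarray
    dose_ug: float
    condition: ConditionConfig = field(repr=False)
    parameters: TransitParameters = field(repr=False)

    def compartment(self, label: str) -> CompartmentSeries:
        if label not in COMPARTMENTS:
            raise KeyError(f"unknown compartment {label!r}; expected one of {COMPARTMENTS}")
        return getattr(self, label)

    def total_drug(self) -> np.ndarray:
        """Total drug across all pools (should equal the dose at all times)."""
        tot = self.retained_residue.copy()
        for comp in COMPARTMENTS:
            s = self.compartment(comp)
            tot = tot + s.x_solid + s.x_dissolved + s.x_precipitated
        return tot

    def total_volume(self) -> np.ndarray:
        return self.stomach.volume + self.duodenum.volume + self.jejunum.volume

    def to_frame(self):
        """Tidy table: one row per (time, compartment)."""
        import pandas as pd

        rows = []
        for comp in COMPARTMENTS:
            s = self.compartment(comp)
            conc = s.concentration
            with np.errstate(divide="ignore", invalid="ignore"):
                ds = np.where(s.solubility > 0, conc / s.solubility, np.nan)
            rows.append(
                pd.DataFrame(
                    {
                        "time_min": self.times,
                        "compartment": comp,
                        "volume_ml": s.volume,
                        "dissolved_ug": s.x_dissolved,
                        "solid_ug": s.x_solid,
                        "precipitated_ug": s.x_precipitated,
                        "conc_ug_per_ml": conc,
                        "ds": ds,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def extend_condition(condition: ConditionConfig, duration: float) -> ConditionConfig:
    """Extend a scenario to a longer horizon, holding each pH at its final value.

    Used to drive the disposition model past the in vitro sampling window:
    the transfer pumps and secretions are assumed to keep running and each
    chamber's pH to stay at its last recorded value.
    """
    if duration <= condition.duration:
        return condition

    def ext(prof: PiecewiseProfile) -> PiecewiseProfile:
        if prof.times[-1] >= duration:
            return prof
        return PiecewiseProfile(
            times=prof.times + (float(duration),),
            values=prof.values + (prof.values[-1],),
        )

    return replace(
        condition,
        duration=float(duration),
        gastric_ph_profile=ext(condition.gastric_ph_profile),
        duodenal_ph_profile=ext(condition.duodenal_ph_profile),
        jejunal_ph_profile=ext(condition.jejunal_ph_profile),
    )


def gastric_emptying_rate(t_half: float) -> float:
    """First-order gastric emptying rate constant k = ln(2)/t_half (min⁻¹)."""
    if t_half <= 0:
        raise ValueError(f"t_half must be positive, got {t_half}")
    return math.log(2.0) / t_half


def dissolution_flux(z: float, x_solid: float, solubility: float, concentration: float) -> float:
    """z-factor dissolution rate (µg/min): z · X_solid · (Cs − C)+.

    The driving force is the distance to saturation; no dissolution occurs at
    or above saturation, or without solid.
    """
    if min(z, x_solid, solubility, concentration) < 0:
        raise ValueError("dissolution_flux inputs must be non-negative")
    return z * x_solid * max(0.0, solubility - concentration)


def precipitation_flux(k_pre: float, x_dissolved: float, solubility: float, volume: float) -> float:
    """First-order precipitation rate (µg/min) on the supersaturated excess.

    k_pre · (X_dissolved − Cs·V)+ : nothing precipitates at or below
    saturation.
    """
    if volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    if min(k_pre, x_dissolved, solubility) < 0:
        raise ValueError("precipitation_flux inputs must be non-negative")
    return k_pre * max(0.0, x_dissolved - solubility * volume)


# state vector layout for the ODE system
_IV_S, _IV_J = 0, 1
_IXS_S, _IXD_S = 2, 3
_IXS_D, _IXD_D, _IXP_D = 4, 5, 6
_IXS_J, _IXD_J, _IXP_J = 7, 8, 9
_IRES = 10
_IE_DISS, _IE_SOL, _IT_DISS, _IT_SOL = 11, 12, 13, 14
_NSTATE = 15


def simulate_gis(
    drug: DrugProperties,
    condition: ConditionConfig,
    params: TransitParameters,
    output_grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> GISTrajectory:
    """Integrate the three-chamber mass-transport ODE system.

    Parameters
    ----------
    drug, condition, params
        Compound, scenario and kinetic coefficients.
    output_grid
        Output times (min) within [0, condition.duration]; defaults to a
        1-min grid over the whole duration.
    rtol, atol
        Solver tolerances (atol in µg / mL units of the state).

    Returns
    -------
    GISTrajectory
        Per-chamber volumes, solid/dissolved/precipitated amounts, pH and
        solubility series, plus cumulative transfer ledgers.
    """
    if output_grid is None:
        output_grid = np.arange(0.0, condition.duration + 0.5, 1.0)
    grid = np.asarray(output_grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("output_grid must be a non-empty 1-D time series")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("output_grid must be strictly increasing")
    if grid[0] < 0 or grid[-1] > condition.duration:
        raise ValueError("output_grid must lie within [0, duration]")

    k_ge = gastric_emptying_rate(condition.t_half_gastric)
    floor = condition.gastric_residual_floor
    k_sec_s, k_sec_d = condition.k_sec_s, condition.k_sec_d
    v_d = condition.duodenal_volume
    frac = params.frac
    z_s, z_d, z_j = params.z_s_eff, params.z_d_eff, params.z_j_eff
    k_pre_d, k_pre_j = params.k_pre_d, params.k_pre_j

    gp, dp, jp = (
        condition.gastric_ph_profile,
        condition.duodenal_ph_profile,
        condition.jejunal_ph_profile,
    )

    def sol_at(profile: PiecewiseProfile, t: float) -> float:
        return solubility_at_ph(drug, profile.at(t))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        v_s = y[_IV_S]
        v_j = y[_IV_J]
        xs_s, xd_s = max(y[_IXS_S], 0.0), max(y[_IXD_S], 0.0)
        xs_d, xd_d = max(y[_IXS_D], 0.0), max(y[_IXD_D], 0.0)
        xs_j, xd_j = max(y[_IXS_J], 0.0), max(y[_IXD_J], 0.0)

        # gastric outflow: first-order emptying until the residual floor,
        # then outflow matches secretion (volume pinned)
        if v_s > floor:
            q_s = k_ge * v_s
            r_s = k_ge  # specific emptying rate Q_s / V_s
        else:
            q_s = k_sec_s
            r_s = q_s / max(v_s, VOLUME_EPS)

        s_s = sol_at(gp, t)
        s_d = sol_at(dp, t)
        s_j = sol_at(jp, t)

        c_s = xd_s / v_s if v_s > VOLUME_EPS else 0.0
        c_d = xd_d / v_d
        c_j = xd_j / v_j if v_j > VOLUME_EPS else 0.0

        diss_s = z_s * xs_s * max(0.0, s_s - c_s)
        diss_d = z_d * xs_d * max(0.0, s_d - c_d)
        diss_j = z_j * xs_j * max(0.0, s_j - c_j)
        prec_d = k_pre_d * max(0.0, xd_d - s_d * v_d)
        prec_j = k_pre_j * max(0.0, xd_j - s_j * v_j) if v_j > VOLUME_EPS else 0.0

        q_dj = q_s + k_sec_d
        r_d = q_dj / v_d

        dy = np.empty(_NSTATE)
        dy[_IV_S] = k_sec_s - q_s
        dy[_IV_J] = q_dj
        dy[_IXS_S] = -diss_s - r_s * xs_s
        dy[_IXD_S] = diss_s - r_s * xd_s
        dy[_IXS_D] = frac * r_s * xs_s - diss_d - r_d * xs_d
        dy[_IXD_D] = r_s * xd_s + diss_d - prec_d - r_d * xd_d
        dy[_IXP_D] = prec_d
        dy[_IXS_J] = r_d * xs_d - diss_j
        dy[_IXD_J] = r_d * xd_d + diss_j - prec_j
        dy[_IXP_J] = prec_j
        dy[_IRES] = (1.0 - frac) * r_s * xs_s
        dy[_IE_DISS] = r_s * xd_s
        dy[_IE_SOL] = frac * r_s * xs_s
        dy[_IT_DISS] = r_d * xd_d
        dy[_IT_SOL] = r_d * xs_d
        return dy

    y0 = np.zeros(_NSTATE)
    y0[_IV_S] = condition.gastric_initial_volume
    y0[_IV_J] = condition.jejunal_initial_volume
    y0[_IXS_S] = drug.dose_ug

    sol = solve_ivp(
        rhs,
        (float(grid[0]), float(grid[-1])),
        y0,
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"transit ODE integration failed for condition {condition.label!r}: {sol.message}"
        )

    y = np.clip(sol.y, 0.0, None)  # amounts are non-negative up to solver noise

    ph_s = np.array([gp.at(t) for t in grid])
    ph_d = np.array([dp.at(t) for t in grid])
    ph_j = np.array([jp.at(t) for t in grid])
    sol_s = np.array([solubility_at_ph(drug, p) for p in ph_s])
    sol_d = np.array([solubility_at_ph(drug, p) for p in ph_d])
    sol_j = np.array([solubility_at_ph(drug, p) for p in ph_j])

    stomach = CompartmentSeries(
        volume=y[_IV_S],
        x_solid=y[_IXS_S],
        x_dissolved=y[_IXD_S],
        x_precipitated=np.zeros_like(grid),
        ph=ph_s,
        solubility=sol_s,
    )
    duodenum = CompartmentSeries(
        volume=np.full_like(grid, v_d),
        x_solid=y[_IXS_D],
        x_dissolved=y[_IXD_D],
        x_precipitated=y[_IXP_D],
        ph=ph_d,
        solubility=sol_d,
    )
    jejunum = CompartmentSeries(
        volume=y[_IV_J],
        x_solid=y[_IXS_J],
        x_dissolved=y[_IXD_J],
        x_precipitated=y[_IXP_J],
        ph=ph_j,
        solubility=sol_j,
    )
    return GISTrajectory(
        times=grid,
        stomach=stomach,
        duodenum=duodenum,
        jejunum=jejunum,
        retained_residue=y[_IRES],
        emptied_dissolved=y[_IE_DISS],
        emptied_solid=y[_IE_SOL],
        transferred_dissolved=y[_IT_DISS],
        transferred_solid=y[_IT_SOL],
        dose_ug=drug.dose_ug,
        condition=condition,
        parameters=params,
    )


def concentration_series(traj: GISTrajectory, compartment: str) -> np.ndarray:
    """Dissolved concentration C(t) = X_dissolved/V (µg/mL); 0 where V ≤ ε."""
    return traj.compartment(compartment).concentration


def ds_series(traj: GISTrajectory, compartment: str) -> np.ndarray:
    """Degree of supersaturation over time in one chamber."""
    series = traj.compartment(compartment)
    conc = series.concentration
    if np.any(series.solubility <= 0):
        raise ValueError(f"non-positive solubility in {compartment}; DS undefined")
    return np.array(
        [degree_of_supersaturation(c, s) for c, s in zip(conc, series.solubility)]
    )
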