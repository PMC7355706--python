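"""Two-compartment open pharmacokinetic model driven by luminal dissolved drug.

The dissolved intestinal amount simulated in vitro forces first-order
absorption into a central compartment with elimination (K10) and exchange
with a peripheral compartment (K12/K21); plasma concentration is the central
amount over the apparent distribution volume V/F. Coupling is open-loop: the
luminal series is an exogenous input not depleted by absorption, because the
in vitro system has no absorptive sink.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "PKParameters",
    "PlasmaProfile",
    "ExposureMetrics",
    "BioequivalenceReport",
    "simulate_plasma",
    "exposure_metrics",
    "pool_pk_parameters",
    "bioequivalence_compare",
    "scenario_fold_change",
    "load_pk_studies",
    "pk_parameters_from_frame",
]

MIN_PER_H = 60.0


@dataclass(frozen=True)
class PKParameters:
    """Two-compartment disposition constants.

    Rate constants in h⁻¹ (ka absorption, k10 elimination, k12/k21
    central↔peripheral exchange); v_over_f is the apparent volume of
    distribution in litres.
    """

    ka: float
    k10: float
    k12: float
    k21: float
    v_over_f: float

    def __post_init__(self) -> None:
        for name in ("ka", "k10", "k12", "k21"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.v_over_f <= 0:
            raise ValueError("v_over_f must be positive")

    @property
    def clearance_l_per_h(self) -> float:
        """Apparent clearance CL/F = K10 · V/F (L/h)."""
        return self.k10 * self.v_over_f


@dataclass(frozen=True)
class PlasmaProfile:
    """Simulated plasma concentration-time curve (times in min, C in µg/mL)."""

    times: np.ndarray
    concentration: np.ndarray
    central_amount: np.ndarray
    peripheral_amount: np.ndarray
    v_over_f_ml: float


@dataclass(frozen=True)
class ExposureMetrics:
    """Non-compartmental exposure summary over a stated AUC window."""

    cmax: float
    tmax: float
    auc: float
    auc_window: tuple[float, float]


@dataclass(frozen=True)
class BioequivalenceReport:
    """Percent difference per metric against a reference, pass flag at 20%."""

    pct_diff_cmax: float
    pct_diff_auc: float
    threshold_pct: float
    bioequivalent: bool


def simulate_plasma(
    luminal_times: np.ndarray,
    luminal_amounts: np.ndarray,
    pk: PKParameters,
    horizon: float = 360.0,
    extrapolation_decay_per_min: float = 0.0,
    output_grid: np.ndarray | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> PlasmaProfile:
    """Integrate the forced two-compartment system on a minute grid.

    dXc/dt = ka'·A(t) − (k10'+k12')·Xc + k21'·Xp
    dXp/dt = k12'·Xc − k21'·Xp

    with primed constants converted h⁻¹ → min⁻¹. A(t) is the dissolved
    intestinal amount (µg): linear interpolation of the supplied series
    within its span; beyond the span it is held at its last value with
    first-order decay at ``extrapolation_decay_per_min`` (the intestinal
    precipitation rate, since no new drug enters once the stomach is empty).
    """
    t_lum = np.asarray(luminal_times, dtype=float)
    a_lum = np.asarray(luminal_amounts, dtype=float)
    if t_lum.ndim != 1 or t_lum.shape != a_lum.shape or t_lum.size < 2:
        raise ValueError("luminal series must be 1-D, equal length, with >= 2 points")
    if np.any(np.diff(t_lum) <= 0):
        raise ValueError("luminal times must be strictly increasing")
    if t_lum[0] > 0:
        raise ValueError("luminal series must start at t = 0")
    if np.any(a_lum < 0):
        raise ValueError("luminal amounts must be non-negative")
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if extrapolation_decay_per_min < 0:
        raise ValueError("extrapolation_decay_per_min must be non-negative")

    ka = pk.ka / MIN_PER_H
    k10 = pk.k10 / MIN_PER_H
    k12 = pk.k12 / MIN_PER_H
    k21 = pk.k21 / MIN_PER_H

    t_end = float(t_lum[-1])
    a_end = float(a_lum[-1])

    def a_of_t(t: float) -> float:
        if t <= t_end:
            return float(np.interp(t, t_lum, a_lum))
        return a_end * np.exp(-extrapolation_decay_per_min * (t - t_end))

    def rhs(t: float, y: np.ndarray) -> list[float]:
        xc, xp = y
        return [
            ka * a_of_t(t) - (k10 + k12) * xc + k21 * xp,
            k12 * xc - k21 * xp,
        ]

    if output_grid is None:
        output_grid = np.arange(0.0, horizon + 0.5, 1.0)
    grid = np.asarray(output_grid, dtype=float)

    sol = solve_ivp(
        rhs,
        (float(grid[0]), float(grid[-1])),
        [0.0, 0.0],
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"plasma ODE integration failed: {sol.message}")

    xc = np.clip(sol.y[0], 0.0, None)
    xp = np.clip(sol.y[1], 0.0, None)
    v_ml = pk.v_over_f * 1000.0
    return PlasmaProfile(
        times=grid,
        concentration=xc / v_ml,
        central_amount=xc,
        peripheral_amount=xp,
        v_over_f_ml=v_ml,
    )


def exposure_metrics(
    profile: PlasmaProfile, t_start: float = 5.0, t_end: float = 360.0
) -> ExposureMetrics:
    """Cmax/Tmax over the full profile; trapezoidal AUC over [t_start, t_end].

    Window endpoints are interpolated onto the grid when they fall between
    grid points.
    """
    if t_start >= t_end:
        raise ValueError("t_start must be < t_end")
    t = profile.times
    c = profile.concentration
    if t_start < t[0] or t_end > t[-1]:
        raise ValueError("AUC window must lie within the simulated grid")

    i_max = int(np.argmax(c))
    cmax = float(c[i_max])
    tmax = float(t[i_max])

    inside = (t > t_start) & (t < t_end)
    tw = np.concatenate(([t_start], t[inside], [t_end]))
    cw = np.concatenate(
        ([np.interp(t_start, t, c)], c[inside], [np.interp(t_end, t, c)])
    )
    auc = float(np.trapezoid(cw, tw))
    return ExposureMetrics(cmax=cmax, tmax=tmax, auc=auc, auc_window=(t_start, t_end))


def pool_pk_parameters(studies: list[PKParameters]) -> PKParameters:
    """Arithmetic mean of each disposition constant across studies."""
    if not studies:
        raise ValueError("cannot pool an empty list of PK parameter sets")
    n = len(studies)
    return PKParameters(
        ka=sum(s.ka for s in studies) / n,
        k10=sum(s.k10 for s in studies) / n,
        k12=sum(s.k12 for s in studies) / n,
        k21=sum(s.k21 for s in studies) / n,
        v_over_f=sum(s.v_over_f for s in studies) / n,
    )


def bioequivalence_compare(
    test: ExposureMetrics, reference: ExposureMetrics, threshold_pct: float = 20.0
) -> BioequivalenceReport:
    """Percent difference per metric, 100·|test − ref|/ref; pass iff all below threshold."""
    if reference.cmax <= 0 or reference.auc <= 0:
        raise ValueError("reference metrics must be positive")
    d_cmax = 100.0 * abs(test.cmax - reference.cmax) / reference.cmax
    d_auc = 100.0 * abs(test.auc - reference.auc) / reference.auc
    return BioequivalenceReport(
        pct_diff_cmax=d_cmax,
        pct_diff_auc=d_auc,
        threshold_pct=threshold_pct,
        bioequivalent=bool(d_cmax < threshold_pct and d_auc < threshold_pct),
    )


def scenario_fold_change(metric_a: ExposureMetrics, metric_b: ExposureMetrics) -> dict:
    """Per-metric ratios a/b for Cmax and AUC (e.g. cola vs water scenario)."""
    if metric_b.cmax <= 0 or metric_b.auc <= 0:
        raise ValueError("denominator metrics must be positive")
    return {
        "cmax_fold": metric_a.cmax / metric_b.cmax,
        "auc_fold": metric_a.auc / metric_b.auc,
    }


PK_TABLE_COLUMNS = ["study_id", "ka_per_h", "k10_per_h", "k12_per_h", "k21_per_h", "v_over_f_L"]


def load_pk_studies(path=None) -> pd.DataFrame:
    """Load a PK study table (defaults to the packaged 12-study compilation)."""
    if path is None:
        ref = resources.files("gisim.data") / "pk_studies.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    missing = [c for c in PK_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PK study table missing required columns: {missing}")
    return df


def pk_parameters_from_frame(df: pd.DataFrame) -> list[PKParameters]:
    """One PKParameters per study row of a PK table."""
    return [
        PKParameters(
            ka=row.ka_per_h,
            k10=row.k10_per_h,
            k12=row.k12_per_h,
            k21=row.k21_per_h,
            v_over_f=row.v_over_f_L,
        )
        for row in df.itertuples()
    ]
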