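"""Physicochemical primitives for weakly basic drugs.

pH-dependent solubility (Henderson–Hasselbalch for a monobasic weak base),
degree of supersaturation, and buffer capacity computed from strong-acid/base
titration records, with the monoprotic Van Slyke equation as an analytic
cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "DrugProperties",
    "TitrationRecord",
    "BufferCapacityResult",
    "solubility_at_ph",
    "degree_of_supersaturation",
    "buffer_capacity",
    "van_slyke_buffer_capacity",
]


@dataclass(frozen=True)
class DrugProperties:
    """Dose and solubility model of a weakly basic compound.

    Parameters
    ----------
    name : str
        Compound / product label.
    dose_ug : float
        Administered dose in µg.
    pka_basic : float
        Basic pKa of the ionizable centre.
    intrinsic_solubility : float
        Solubility of the neutral species, µg/mL. Sets the high-pH plateau
        of the Henderson–Hasselbalch curve.
    logp : float, optional
        Octanol–water partition coefficient (informational).
    mw : float, optional
        Molecular weight, g/mol (informational).
    solubility_overrides : dict, optional
        Map of pH -> solubility (µg/mL). When present, solubility is linearly
        interpolated between override points instead of using the
        Henderson–Hasselbalch form (measured solubility takes precedence
        over the ideal curve).
    """

    name: str
    dose_ug: float
    pka_basic: float
    intrinsic_solubility: float
    logp: float | None = None
    mw: float | None = None
    solubility_overrides: dict[float, float] | None = field(default=None)

    def __post_init__(self) -> None:
        if self.dose_ug <= 0:
            raise ValueError(f"dose_ug must be positive, got {self.dose_ug}")
        if self.intrinsic_solubility <= 0:
            raise ValueError(
                f"intrinsic_solubility must be positive, got {self.intrinsic_solubility}"
            )
        if not 0 < self.pka_basic < 14:
            raise ValueError(f"pka_basic must lie in (0, 14), got {self.pka_basic}")
        if self.solubility_overrides is not None:
            if not self.solubility_overrides:
                raise ValueError("solubility_overrides must be non-empty when given")
            for ph, s in self.solubility_overrides.items():
                if not 0 <= ph <= 14:
                    raise ValueError(f"override pH {ph} outside [0, 14]")
                if s <= 0:
                    raise ValueError(f"override solubility at pH {ph} must be positive")


@dataclass(frozen=True)
class TitrationRecord:
    """One strong-acid or strong-base titration of a buffered medium.

    `titrant_sign` is +1 for base (NaOH), -1 for acid (HCl); the sign does not
    enter the buffer-capacity magnitude, which uses |ΔpH|.
    """

    initial_volume_l: float
    titrant_concentration_m: float
    titrant_volume_added_l: float
    titrant_sign: int
    ph_before: float
    ph_after: float

    def __post_init__(self) -> None:
        if self.initial_volume_l <= 0:
            raise ValueError("initial_volume_l must be positive")
        if self.titrant_concentration_m <= 0:
            raise ValueError("titrant_concentration_m must be positive")
        if self.titrant_volume_added_l < 0:
            raise ValueError("titrant_volume_added_l must be non-negative")
        if self.titrant_sign not in (+1, -1):
            raise ValueError("titrant_sign must be +1 (base) or -1 (acid)")


@dataclass(frozen=True)
class BufferCapacityResult:
    """Buffer capacity β = Δn / |ΔpH| with its ingredients."""

    beta: float
    delta_ph: float
    equivalents_per_liter: float


def solubility_at_ph(drug: DrugProperties, ph: float) -> float:
    """Solubility (µg/mL) of a monobasic weak base at a given pH.

    Without overrides this is the Henderson–Hasselbalch total solubility
    S(pH) = S0 · (1 + 10^(pKa − pH)): the neutral species contributes S0 and
    the protonated species multiplies it by the ionized/neutral ratio. With
    overrides, linear interpolation between the override points is used
    (clamped at the extremes).
    """
    if not 0 <= ph <= 14:
        raise ValueError(f"pH must lie in [0, 14], got {ph}")
    if drug.solubility_overrides:
        pts = sorted(drug.solubility_overrides.items())
        phs = [p for p, _ in pts]
        vals = [s for _, s in pts]
        if ph <= phs[0]:
            return vals[0]
        if ph >= phs[-1]:
            return vals[-1]
        # linear interpolation between bracketing override points
        for (p0, s0), (p1, s1) in zip(pts, pts[1:]):
            if p0 <= ph <= p1:
                w = (ph - p0) / (p1 - p0)
                return s0 + w * (s1 - s0)
    return drug.intrinsic_solubility * (1.0 + 10.0 ** (drug.pka_basic - ph))


def degree_of_supersaturation(c: float, ceq: float) -> float:
    """Degree of supersaturation DS = C / Ceq.

    C is the dissolved concentration at a time point and Ceq the thermodynamic
    solubility at the same time point; DS > 1 flags supersaturation.
    """
    if ceq <= 0:
        raise ValueError(f"ceq must be positive, got {ceq}")
    if c < 0:
        raise ValueError(f"c must be non-negative, got {c}")
    return c / ceq


def buffer_capacity(record: TitrationRecord) -> BufferCapacityResult:
    """Buffer capacity from a titration: β = Δn / |ΔpH| (mol/L/ΔpH).

    Δn is the equivalents of strong acid or base added per litre of medium.
    Acid and base titrations both yield a positive β.
    """
    delta_ph = record.ph_after - record.ph_before
    if delta_ph == 0:
        raise ValueError("degenerate titration: ΔpH is zero")
    eq_per_l = (
        record.titrant_concentration_m * record.titrant_volume_added_l / record.initial_volume_l
    )
    return BufferCapacityResult(
        beta=eq_per_l / abs(delta_ph),
        delta_ph=delta_ph,
        equivalents_per_liter=eq_per_l,
    )


def van_slyke_buffer_capacity(buffer_concentration: float, pka: float, ph: float) -> float:
    """Monoprotic Van Slyke buffer capacity β = ln(10)·C·Ka·[H+]/(Ka+[H+])².

    Excludes the water autoprotolysis terms; maximal (ln(10)·C/4) at pH = pKa.
    Serves as the analytic cross-check for titration-derived β values.
    """
    if buffer_concentration < 0:
        raise ValueError("buffer_concentration must be non-negative")
    ka = 10.0 ** (-pka)
    h = 10.0 ** (-ph)
    return math.log(10.0) * buffer_concentration * ka * h / (ka + h) ** 2
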