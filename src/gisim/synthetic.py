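"""Synthetic study-condition generators.

Produces everything the analysis pipeline consumes without external data:
the four shipped condition presets, noisy triplicate concentration tables
drawn around a simulated truth, and titration record sets with a known
buffer capacity. Noise is multiplicative Gaussian (analytical error scales
with concentration), clipped at zero, reported as mean ± SD per time point,
mirroring triplicate in vitro sampling.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .io import load_condition
from .physchem import DrugProperties, TitrationRecord
from .transit import (
    COMPARTMENTS,
    ConditionConfig,
    GISTrajectory,
    TransitParameters,
    concentration_series,
    simulate_gis,
)

__all__ = [
    "NoiseModel",
    "default_sampling_times",
    "generate_gis_dataset",
    "condition_preset",
    "generate_titration_dataset",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-level measurement noise: proportional Gaussian with given CV."""

    kind: str = "proportional_gaussian"
    cv: float = 0.05
    replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind != "proportional_gaussian":
            raise ValueError(f"unknown noise model kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def default_sampling_times() -> np.ndarray:
    """Plausible in vitro sampling schedule: every 2.5 min to 20 min, then every 10 min to 60 min."""
    return np.concatenate([np.arange(0.0, 20.0 + 1e-9, 2.5), np.array([30.0, 40.0, 50.0, 60.0])])


def generate_gis_dataset(
    drug: DrugProperties,
    condition: ConditionConfig,
    params: TransitParameters,
    sampling_times: np.ndarray | None = None,
    noise: NoiseModel | None = None,
) -> tuple[pd.DataFrame, GISTrajectory]:
    """Simulate a condition and report noisy per-compartment mean ± SD tables.

    Returns the tidy observation table (time_min, compartment,
    mean_conc_ug_per_ml, sd, n) alongside the noise-free ground-truth
    trajectory it was drawn from. Bit-reproducible for a fixed seed.
    """
    if sampling_times is None:
        sampling_times = default_sampling_times()
    if noise is None:
        noise = NoiseModel()
    grid = np.asarray(sampling_times, dtype=float)
    if grid[0] > 0:
        grid = np.concatenate([[0.0], grid])

    truth = simulate_gis(drug, condition, params, output_grid=grid)
    rng = np.random.default_rng(noise.seed)

    rows = []
    for comp in COMPARTMENTS:
        conc = concentration_series(truth, comp)
        for t, c in zip(grid, conc):
            if noise.cv > 0:
                reps = c * (1.0 + noise.cv * rng.standard_normal(noise.replicates))
                reps = np.clip(reps, 0.0, None)
                sd = float(np.std(reps, ddof=1)) if noise.replicates > 1 else 0.0
            else:
                reps = np.full(noise.replicates, c)
                sd = 0.0
            rows.append(
                {
                    "time_min": t,
                    "compartment": comp,
                    "mean_conc_ug_per_ml": float(np.mean(reps)),
                    "sd": sd,
                    "n": noise.replicates,
                }
            )
    return pd.DataFrame(rows), truth


def condition_preset(n: int) -> tuple[ConditionConfig, TransitParameters]:
    """Shipped scenario presets 1–4 with their tabulated kinetic coefficients.

    1: water, fast emptying (t1/2 15 min); 2: water, slow (30 min);
    3: cola, fast; 4: cola, slow.
    """
    if n not in (1, 2, 3, 4):
        raise KeyError(f"unknown condition preset {n!r}; expected 1..4")
    ref = resources.files("gisim.data") / "conditions" / f"condition{n}.yaml"
    with resources.as_file(ref) as p:
        cond, params = load_condition(p)
    assert params is not None
    return cond, params


def generate_titration_dataset(
    true_beta: float,
    initial_volume: float,
    titrant_concentration: float,
    steps: int,
    seed: int = 0,
    noise_cv: float = 0.0,
    delta_ph: float = 1.0,
) -> list[TitrationRecord]:
    """Titration records constructed so β = Δn/|ΔpH| recovers ``true_beta``.

    Each record is one unit-ΔpH titration (alternating base/acid direction);
    ``noise_cv`` perturbs the recorded titrant volume multiplicatively, so the
    per-record β estimator stays unbiased under noise.
    """
    if true_beta < 0 or initial_volume <= 0 or titrant_concentration <= 0 or delta_ph <= 0:
        raise ValueError("titration generator inputs must be positive")
    if steps < 0:
        raise ValueError("steps must be non-negative")
    rng = np.random.default_rng(seed)
    v_added_true = true_beta * delta_ph * initial_volume / titrant_concentration
    records = []
    ph0 = 2.0
    for i in range(steps):
        sign = +1 if i % 2 == 0 else -1
        v = v_added_true
        if noise_cv > 0:
            v = max(0.0, v * (1.0 + noise_cv * rng.standard_normal()))
        records.append(
            TitrationRecord(
                initial_volume_l=initial_volume,
                titrant_concentration_m=titrant_concentration,
                titrant_volume_added_l=v,
                titrant_sign=sign,
                ph_before=ph0,
                ph_after=ph0 + sign * delta_ph,
            )
        )
    return records
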