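"""Readers and writers for the package's delimited-text and YAML formats.

All tabular I/O is comma-separated UTF-8 with dot decimals; configs are YAML;
reports are JSON. Schema validation reports offending columns/rows by name
and line number.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .physchem import DrugProperties, TitrationRecord
from .transit import COMPARTMENTS, ConditionConfig, PiecewiseProfile, TransitParameters

__all__ = [
    "SchemaError",
    "OBSERVATION_COLUMNS",
    "TITRATION_COLUMNS",
    "read_observations",
    "write_observations",
    "read_titrations",
    "write_titrations",
    "load_drug",
    "dump_drug",
    "load_condition",
    "dump_condition",
    "drug_preset",
    "write_trajectory",
    "write_json_report",
]

OBSERVATION_COLUMNS = ["time_min", "compartment", "mean_conc_ug_per_ml", "sd", "n"]
TITRATION_COLUMNS = ["v0_L", "c_titrant_M", "v_added_L", "sign", "ph_before", "ph_after"]


class SchemaError(ValueError):
    """A delimited table or config file violates its schema."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required column(s): {missing}")


def _require_numeric(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[parsed.isna() & df[col].notna()]
        if len(bad):
            # +2: header line and 1-based file numbering
            lines = [int(i) + 2 for i in bad[:5]]
            raise SchemaError(f"{what}: non-numeric value(s) in column {col!r} at line(s) {lines}")
        df[col] = parsed
    return df


def read_observations(path) -> pd.DataFrame:
    """Read a tidy concentration observation table.

    Columns: time_min, compartment, mean_conc_ug_per_ml, sd, n.
    """
    df = pd.read_csv(path)
    _require_columns(df, OBSERVATION_COLUMNS, f"observation table {path}")
    df = _require_numeric(df, ["time_min", "mean_conc_ug_per_ml", "sd", "n"], f"observation table {path}")
    unknown = set(df["compartment"].unique()) - set(COMPARTMENTS)
    if unknown:
        raise SchemaError(f"observation table {path}: unknown compartment label(s) {sorted(unknown)}")
    return df[OBSERVATION_COLUMNS]


def write_observations(df: pd.DataFrame, path) -> None:
    _require_columns(df, OBSERVATION_COLUMNS, "observation table")
    df[OBSERVATION_COLUMNS].to_csv(path, index=False)


def read_titrations(path) -> list[TitrationRecord]:
    """Read titration records (columns v0_L, c_titrant_M, v_added_L, sign, ph_before, ph_after)."""
    df = pd.read_csv(path)
    _require_columns(df, TITRATION_COLUMNS, f"titration table {path}")
    df = _require_numeric(df, TITRATION_COLUMNS, f"titration table {path}")
    return [
        TitrationRecord(
            initial_volume_l=row.v0_L,
            titrant_concentration_m=row.c_titrant_M,
            titrant_volume_added_l=row.v_added_L,
            titrant_sign=int(row.sign),
            ph_before=row.ph_before,
            ph_after=row.ph_after,
        )
        for row in df.itertuples()
    ]


def write_titrations(records: list[TitrationRecord], path) -> None:
    pd.DataFrame(
        {
            "v0_L": [r.initial_volume_l for r in records],
            "c_titrant_M": [r.titrant_concentration_m for r in records],
            "v_added_L": [r.titrant_volume_added_l for r in records],
            "sign": [r.titrant_sign for r in records],
            "ph_before": [r.ph_before for r in records],
            "ph_after": [r.ph_after for r in records],
        }
    ).to_csv(path, index=False)


def _drug_from_mapping(doc: dict, source: str) -> DrugProperties:
    required = {"name", "dose_mg", "pka", "s0_ug_per_ml"}
    missing = required - doc.keys()
    if missing:
        raise SchemaError(f"drug config {source} missing key(s): {sorted(missing)}")
    overrides = None
    if doc.get("overrides"):
        overrides = {float(o["ph"]): float(o["s_ug_per_ml"]) for o in doc["overrides"]}
    return DrugProperties(
        name=str(doc["name"]),
        dose_ug=float(doc["dose_mg"]) * 1000.0,
        pka_basic=float(doc["pka"]),
        intrinsic_solubility=float(doc["s0_ug_per_ml"]),
        logp=float(doc["logp"]) if "logp" in doc else None,
        mw=float(doc["mw"]) if "mw" in doc else None,
        solubility_overrides=overrides,
    )


def load_drug(path) -> DrugProperties:
    """Load a drug property set from YAML (keys name, dose_mg, pka, s0_ug_per_ml, overrides)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"drug config {path} is not a mapping")
    return _drug_from_mapping(doc, str(path))


def dump_drug(drug: DrugProperties, path) -> None:
    doc = {
        "name": drug.name,
        "dose_mg": drug.dose_ug / 1000.0,
        "pka": drug.pka_basic,
        "s0_ug_per_ml": drug.intrinsic_solubility,
    }
    if drug.logp is not None:
        doc["logp"] = drug.logp
    if drug.mw is not None:
        doc["mw"] = drug.mw
    if drug.solubility_overrides:
        doc["overrides"] = [
            {"ph": ph, "s_ug_per_ml": s} for ph, s in sorted(drug.solubility_overrides.items())
        ]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def drug_preset(name: str = "loratadine") -> DrugProperties:
    """Load a packaged drug preset (``loratadine`` or ``loratadine_admet``)."""
    ref = resources.files("gisim.data") / "drugs" / f"{name}.yaml"
    if not ref.is_file():
        raise KeyError(f"no packaged drug preset named {name!r}")
    with resources.as_file(ref) as p:
        return load_drug(p)


def _condition_from_mapping(doc: dict, source: str) -> tuple[ConditionConfig, TransitParameters | None]:
    required = {
        "label",
        "t_half_gastric",
        "gastric_ph_profile",
        "duodenal_ph_profile",
        "jejunal_ph_profile",
    }
    missing = required - doc.keys()
    if missing:
        raise SchemaError(f"condition config {source} missing key(s): {sorted(missing)}")
    cond = ConditionConfig(
        label=str(doc["label"]),
        t_half_gastric=float(doc["t_half_gastric"]),
        gastric_ph_profile=PiecewiseProfile.from_points(doc["gastric_ph_profile"]),
        duodenal_ph_profile=PiecewiseProfile.from_points(doc["duodenal_ph_profile"]),
        jejunal_ph_profile=PiecewiseProfile.from_points(doc["jejunal_ph_profile"]),
        gastric_initial_volume=float(doc.get("gastric_initial_volume", 300.0)),
        gastric_residual_floor=float(doc.get("gastric_residual_floor", 5.0)),
        duodenal_volume=float(doc.get("duodenal_volume", 50.0)),
        jejunal_initial_volume=float(doc.get("jejunal_initial_volume", 0.0)),
        k_sec_s=float(doc.get("k_sec_s", 1.0)),
        k_sec_d=float(doc.get("k_sec_d", 1.0)),
        duration=float(doc.get("duration", 60.0)),
    )
    params = None
    if "transit_parameters" in doc:
        tp = doc["transit_parameters"]
        params = TransitParameters(
            z_s=float(tp["z_s"]),
            z_d=float(tp["z_d"]),
            z_j=float(tp["z_j"]),
            frac=float(tp["frac"]),
            k_pre_d=float(tp["k_pre_d"]),
            k_pre_j=float(tp["k_pre_j"]),
            **({"z_unit_scale": float(tp["z_unit_scale"])} if "z_unit_scale" in tp else {}),
        )
    return cond, params


def load_condition(path) -> tuple[ConditionConfig, TransitParameters | None]:
    """Load a condition config (and optional transit parameters) from YAML."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise SchemaError(f"condition config {path} is not a mapping")
    return _condition_from_mapping(doc, str(path))


def dump_condition(
    condition: ConditionConfig, path, params: TransitParameters | None = None
) -> None:
    doc = {
        "label": condition.label,
        "t_half_gastric": condition.t_half_gastric,
        "gastric_initial_volume": condition.gastric_initial_volume,
        "gastric_residual_floor": condition.gastric_residual_floor,
        "duodenal_volume": condition.duodenal_volume,
        "jejunal_initial_volume": condition.jejunal_initial_volume,
        "k_sec_s": condition.k_sec_s,
        "k_sec_d": condition.k_sec_d,
        "duration": condition.duration,
        "gastric_ph_profile": [
            [t, v] for t, v in zip(condition.gastric_ph_profile.times, condition.gastric_ph_profile.values)
        ],
        "duodenal_ph_profile": [
            [t, v] for t, v in zip(condition.duodenal_ph_profile.times, condition.duodenal_ph_profile.values)
        ],
        "jejunal_ph_profile": [
            [t, v] for t, v in zip(condition.jejunal_ph_profile.times, condition.jejunal_ph_profile.values)
        ],
    }
    if params is not None:
        doc["transit_parameters"] = {
            "z_s": params.z_s,
            "z_d": params.z_d,
            "z_j": params.z_j,
            "frac": params.frac,
            "k_pre_d": params.k_pre_d,
            "k_pre_j": params.k_pre_j,
            "z_unit_scale": params.z_unit_scale,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def write_trajectory(traj, path) -> None:
    """Export a trajectory as the tidy delimited format."""
    traj.to_frame().to_csv(path, index=False)


def write_json_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=False) + "\n")
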