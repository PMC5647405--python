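"""Plain-text (CSV + YAML) persistence for every pipeline artifact.

A model lives in one directory: ``groups.csv`` (basic inputs), ``diet.csv``
(square matrix, prey rows × predator columns), ``thermal.csv`` (tolerance
envelopes, optional explicit sigmas), optional ``vulnerability.csv`` (square
matrix) and ``model.yaml`` (assimilation, maturation rates).  Forcings,
observations, pedigrees and scenarios each have a documented one-file schema.
Parse failures raise :class:`InputError` naming the file and, where known,
the line or column at fault.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .dynamics import vulnerability_matrix
from .fitting import ObservedSeries, TimeSeriesSet
from .foodweb import FoodWebModel, Group
from .thermal import ThermalNiche, build_niche
from .uncertainty import Pedigree, PedigreeEntry
from .scenarios import ScenarioSpec

__all__ = [
    "InputError",
    "ModelBundle",
    "read_model_dir",
    "write_model_dir",
    "read_temperature_csv",
    "read_f_csv",
    "read_pp_csv",
    "read_observed_csv",
    "write_observed_csv",
    "read_pedigree_csv",
    "read_scenario_yaml",
]

GROUP_COLUMNS = [
    "name", "is_producer", "is_detritus", "biomass", "pb", "qb", "ee",
    "catch", "stanza_partner",
]
THERMAL_COLUMNS = ["name", "t_min", "p10", "p90", "t_max"]


class InputError(ValueError):
    """A user-input file failed to parse or validate."""

    def __init__(self, path: str, message: str):
        self.path = str(path)
        super().__init__(f"{path}: {message}")


def _read_csv(path, **kwargs) -> pd.DataFrame:
    if not os.path.exists(path):
        raise InputError(path, "file not found")
    try:
        return pd.read_csv(path, **kwargs)
    except pd.errors.ParserError as exc:
        # pandas parser messages include the offending line and column counts
        raise InputError(path, f"malformed CSV: {exc}") from exc
    except pd.errors.EmptyDataError as exc:
        raise InputError(path, "file is empty") from exc


def _require_columns(path, frame: pd.DataFrame, columns) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise InputError(path, f"missing column(s) {missing}")


def _parse_bool(path, value, line: int, column: str) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float)) and not pd.isna(value):
        return bool(int(value))
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", "", "nan"):
        return False
    raise InputError(
        path, f"line {line}, column {column!r}: cannot parse boolean {value!r}"
    )


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() == "":
        return None
    return float(value)


@dataclass
class ModelBundle:
    """A model directory in memory: web, niches, vulnerabilities, config."""

    model: FoodWebModel
    niches: Optional[dict[str, ThermalNiche]] = None
    vulnerability: Optional[np.ndarray] = None
    config: dict = field(default_factory=dict)


def _read_groups(path) -> list[Group]:
    frame = _read_csv(path)
    _require_columns(path, frame, GROUP_COLUMNS)
    groups = []
    for i, row in frame.iterrows():
        line = i + 2  # header is line 1
        try:
            partner = row["stanza_partner"]
            if pd.isna(partner) or str(partner).strip() == "":
                partner = None
            else:
                partner = str(partner)
            groups.append(
                Group(
                    name=str(row["name"]),
                    is_producer=_parse_bool(path, row["is_producer"], line, "is_producer"),
                    is_detritus=_parse_bool(path, row["is_detritus"], line, "is_detritus"),
                    biomass=_opt_float(row["biomass"]),
                    pb=float(row["pb"]) if not pd.isna(row["pb"]) else 0.0,
                    qb=float(row["qb"]) if not pd.isna(row["qb"]) else 0.0,
                    ee=_opt_float(row["ee"]),
                    catch=float(row["catch"]) if not pd.isna(row["catch"]) else 0.0,
                    stanza_partner=partner,
                )
            )
        except (ValueError, TypeError) as exc:
            if isinstance(exc, InputError):
                raise
            raise InputError(path, f"line {line}: {exc}") from exc
    return groups


def _read_matrix(path, names: list[str]) -> np.ndarray:
    frame = _read_csv(path, index_col=0)
    cols = [str(c) for c in frame.columns]
    rows = [str(r) for r in frame.index]
    for label, found in (("column", cols), ("row", rows)):
        unknown = [n for n in found if n not in names]
        if unknown:
            raise InputError(path, f"unknown group name(s) in {label}s: {unknown}")
        missing = [n for n in names if n not in found]
        if missing:
            raise InputError(path, f"missing {label}(s) for group(s): {missing}")
    return frame.loc[names, names].to_numpy(dtype=float)


def _read_thermal(path, names: list[str]) -> dict[str, ThermalNiche]:
    frame = _read_csv(path)
    _require_columns(path, frame, THERMAL_COLUMNS)
    has_sigmas = "sigma_lower" in frame.columns and "sigma_upper" in frame.columns
    niches = {}
    for i, row in frame.iterrows():
        line = i + 2
        name = str(row["name"])
        if name not in names:
            raise InputError(path, f"line {line}: unknown group {name!r}")
        try:
            if has_sigmas and not pd.isna(row["sigma_lower"]):
                niches[name] = ThermalNiche(
                    t_opt=0.5 * (float(row["p10"]) + float(row["p90"])),
                    sigma_lower=float(row["sigma_lower"]),
                    sigma_upper=float(row["sigma_upper"]),
                    t_min=_opt_float(row["t_min"]),
                    t_max=_opt_float(row["t_max"]),
                    p10=float(row["p10"]),
                    p90=float(row["p90"]),
                )
            else:
                niches[name] = build_niche(
                    t_min=float(row["t_min"]),
                    p10=float(row["p10"]),
                    p90=float(row["p90"]),
                    t_max=float(row["t_max"]),
                )
        except ValueError as exc:
            raise InputError(path, f"line {line}: {exc}") from exc
    return niches


def read_model_dir(path: str) -> ModelBundle:
    """Load a model directory (groups, diet, thermal, vulnerability, config)."""
    if not os.path.isdir(path):
        raise InputError(path, "model directory not found")
    groups = _read_groups(os.path.join(path, "groups.csv"))
    names = [g.name for g in groups]
    diet = _read_matrix(os.path.join(path, "diet.csv"), names)

    config: dict = {}
    yaml_path = os.path.join(path, "model.yaml")
    if os.path.exists(yaml_path):
        with open(yaml_path) as fh:
            try:
                config = yaml.safe_load(fh) or {}
            except yaml.YAMLError as exc:
                raise InputError(yaml_path, f"malformed YAML: {exc}") from exc

    try:
        model = FoodWebModel(
            groups=groups,
            diet=diet,
            assimilation=float(config.get("assimilation", 0.8)),
            maturation_rate=dict(config.get("maturation_rate", {}) or {}),
        )
    except ValueError as exc:
        raise InputError(path, f"inconsistent model: {exc}") from exc

    niches = None
    thermal_path = os.path.join(path, "thermal.csv")
    if os.path.exists(thermal_path):
        niches = _read_thermal(thermal_path, names)

    v = None
    v_path = os.path.join(path, "vulnerability.csv")
    if os.path.exists(v_path):
        v = _read_matrix(v_path, names)

    return ModelBundle(model=model, niches=niches, vulnerability=v, config=config)


def write_model_dir(bundle: ModelBundle, path: str) -> None:
    """Write a model bundle to a directory in the documented schema."""
    os.makedirs(path, exist_ok=True)
    model = bundle.model
    names = model.names
    rows = []
    for g in model.groups:
        rows.append(
            (g.name, int(g.is_producer), int(g.is_detritus), g.biomass, g.pb,
             g.qb, g.ee, g.catch, g.stanza_partner or "")
        )
    pd.DataFrame(rows, columns=GROUP_COLUMNS).to_csv(
        os.path.join(path, "groups.csv"), index=False
    )
    pd.DataFrame(model.diet, index=names, columns=names).to_csv(
        os.path.join(path, "diet.csv")
    )
    if bundle.niches:
        trows = []
        for name, niche in bundle.niches.items():
            trows.append(
                (name, niche.t_min, niche.p10, niche.p90, niche.t_max,
                 niche.sigma_lower, niche.sigma_upper)
            )
        pd.DataFrame(
            trows, columns=THERMAL_COLUMNS + ["sigma_lower", "sigma_upper"]
        ).to_csv(os.path.join(path, "thermal.csv"), index=False)
    if bundle.vulnerability is not None:
        pd.DataFrame(bundle.vulnerability, index=names, columns=names).to_csv(
            os.path.join(path, "vulnerability.csv")
        )
    config = dict(bundle.config)
    config.setdefault("assimilation", model.assimilation)
    config.setdefault("maturation_rate", dict(model.maturation_rate))
    with open(os.path.join(path, "model.yaml"), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def read_temperature_csv(path: str) -> pd.Series:
    """``forcing_temperature.csv``: columns year,value (°C)."""
    frame = _read_csv(path)
    _require_columns(path, frame, ["year", "value"])
    return pd.Series(
        frame["value"].to_numpy(dtype=float),
        index=frame["year"].astype(int).to_numpy(),
        name="temperature",
    )


def read_pp_csv(path: str) -> pd.Series:
    """``forcing_ppanomaly.csv``: columns year,value (multiplier)."""
    frame = _read_csv(path)
    _require_columns(path, frame, ["year", "value"])
    vals = frame["value"].to_numpy(dtype=float)
    if np.any(vals <= 0):
        raise InputError(path, "production multipliers must be positive")
    return pd.Series(vals, index=frame["year"].astype(int).to_numpy(), name="pp")


def read_f_csv(path: str) -> pd.DataFrame:
    """``forcing_f.csv``: wide table, year column then one column per group."""
    frame = _read_csv(path)
    _require_columns(path, frame, ["year"])
    frame = frame.set_index(frame["year"].astype(int)).drop(columns=["year"])
    if (frame.to_numpy(dtype=float) < 0).any():
        raise InputError(path, "fishing mortalities must be >= 0")
    return frame.astype(float)


def read_observed_csv(path: str) -> TimeSeriesSet:
    """``observed.csv``: columns group,kind,year,value,weight."""
    frame = _read_csv(path)
    _require_columns(path, frame, ["group", "kind", "year", "value", "weight"])
    series = []
    for (group, kind), sub in frame.groupby(["group", "kind"], sort=False):
        weights = sub["weight"].unique()
        if len(weights) > 1:
            raise InputError(
                path, f"series ({group}, {kind}) has inconsistent weights {weights}"
            )
        values = pd.Series(
            sub["value"].to_numpy(dtype=float),
            index=sub["year"].astype(int).to_numpy(),
        ).sort_index()
        try:
            series.append(
                ObservedSeries(str(group), str(kind), values, float(weights[0]))
            )
        except ValueError as exc:
            raise InputError(path, str(exc)) from exc
    return TimeSeriesSet(series)


def write_observed_csv(observed: TimeSeriesSet, path: str) -> None:
    observed.to_frame().to_csv(path, index=False)


def read_pedigree_csv(path: str) -> Pedigree:
    """``pedigree.csv``: columns group,cv_b,cv_pb,cv_qb,cv_ee."""
    frame = _read_csv(path)
    _require_columns(path, frame, ["group", "cv_b", "cv_pb", "cv_qb", "cv_ee"])
    entries = {}
    for i, row in frame.iterrows():
        try:
            entry = PedigreeEntry(
                group=str(row["group"]),
                cv_b=float(row["cv_b"]),
                cv_pb=float(row["cv_pb"]),
                cv_qb=float(row["cv_qb"]),
                cv_ee=float(row["cv_ee"]),
            )
        except ValueError as exc:
            raise InputError(path, f"line {i + 2}: {exc}") from exc
        entries[entry.group] = entry
    return Pedigree(entries=entries)


def read_scenario_yaml(path: str) -> tuple[ScenarioSpec, dict]:
    """``scenario.yaml``: name, f (group → F), temperature_mode, rcp_label,
    start_year, end_year, optional series file paths and seed.

    Returns the scenario spec plus the residual options (file paths, seed).
    """
    if not os.path.exists(path):
        raise InputError(path, "file not found")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise InputError(path, f"malformed YAML: {exc}") from exc
    for key in ("name", "f", "start_year", "end_year"):
        if key not in raw:
            raise InputError(path, f"missing key {key!r}")
    try:
        spec = ScenarioSpec(
            name=str(raw["name"]),
            f_by_group={str(k): float(v) for k, v in (raw["f"] or {}).items()},
            temperature_mode=str(raw.get("temperature_mode", "constant_last_year")),
            rcp_label=raw.get("rcp_label"),
            start_year=int(raw["start_year"]),
            end_year=int(raw["end_year"]),
        )
    except ValueError as exc:
        raise InputError(path, str(exc)) from exc
    extras = {
        k: v for k, v in raw.items()
        if k not in ("name", "f", "temperature_mode", "rcp_label",
                     "start_year", "end_year")
    }
    return spec, extras


def default_vulnerability(model: FoodWebModel) -> np.ndarray:
    """Neutral vulnerability matrix for models shipped without one."""
    return vulnerability_matrix(model)
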