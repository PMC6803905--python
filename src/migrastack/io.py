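"""Scenario configuration I/O (YAML canonical, JSON equivalent) and result
serialisation.

Config files accept convenience units on any scalar written as a string
(``"0.3 mm"``, ``"100 d"``, ``"40 degC"``); bare numbers are SI (m, s, K,
Pa, kg·m⁻³).  Files are always written back in SI.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import re
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import (
    Assembly,
    AttachFluid,
    EquilibrateWithin,
    Fluid,
    KeepProfiles,
    KineticsResult,
    Layer,
    RemoveLayers,
    Scenario,
    Step,
)

__all__ = [
    "read_scenario",
    "write_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "write_kinetics",
    "read_kinetics",
    "parse_quantity",
]

# multiplicative unit table; temperatures handled separately (offset)
_UNITS = {
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "nm": 1e-9, "cm": 1e-2,
    "s": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0,
    "d": 86400.0, "day": 86400.0, "days": 86400.0,
    "Pa": 1.0, "kPa": 1e3, "MPa": 1e6, "atm": 101325.0, "bar": 1e5,
    "K": 1.0,
    "kg/m3": 1.0, "g/L": 1.0, "mg/L": 1e-3,
    "m2/s": 1.0, "m^2/s": 1.0,
    "": 1.0,
}

_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([^\s]*)\s*$")


def parse_quantity(value: Any) -> float:
    """Convert a config scalar to SI: numbers pass through, strings may
    carry a unit suffix (``"0.3 mm"`` → 3e-4)."""
    if isinstance(value, (int, float)):
        return float(value)
    if not isinstance(value, str):
        raise TypeError(f"cannot parse quantity from {value!r}")
    m = _QUANTITY_RE.match(value)
    if not m:
        raise ValueError(f"malformed quantity {value!r}")
    num, unit = m.groups()
    x = float(num)
    if unit in ("degC", "°C", "C"):
        return x + 273.15
    if unit not in _UNITS:
        raise ValueError(f"unknown unit {unit!r} in {value!r}")
    return x * _UNITS[unit]


# ---------------------------------------------------------------------------
# scenario <-> dict


def _layer_to_dict(lay: Layer) -> dict:
    c0 = lay.initial_concentration
    return {
        "material": lay.material,
        "thickness": float(lay.thickness),
        "henry_k": float(lay.henry_k),
        "diffusivity": float(lay.diffusivity),
        "initial_concentration": float(c0) if np.ndim(c0) == 0 else [float(v) for v in np.asarray(c0)],
        "density": float(lay.density),
    }


def _layer_from_dict(d: dict, index: int) -> Layer:
    for key in ("material", "thickness", "henry_k", "diffusivity"):
        if key not in d:
            raise ValueError(f"layer {index}: missing field {key!r}")
    c0 = d.get("initial_concentration", 0.0)
    c0 = np.asarray([parse_quantity(v) for v in c0]) if isinstance(c0, list) else parse_quantity(c0)
    return Layer(
        material=str(d["material"]),
        thickness=parse_quantity(d["thickness"]),
        henry_k=parse_quantity(d["henry_k"]),
        diffusivity=parse_quantity(d["diffusivity"]),
        initial_concentration=c0,
        density=parse_quantity(d.get("density", 1000.0)),
    )


def _fluid_to_dict(fl: Fluid) -> dict:
    out = {
        "equiv_thickness": float(fl.equiv_thickness),
        "henry_k": float(fl.henry_k),
        "initial_concentration": float(fl.initial_concentration),
        "density": float(fl.density),
    }
    if fl.biot is not None:
        out["biot"] = float(fl.biot)
    else:
        out["h"] = float(fl.h)
    return out


def _fluid_from_dict(d: dict) -> Fluid:
    return Fluid(
        equiv_thickness=parse_quantity(d["equiv_thickness"]),
        henry_k=parse_quantity(d["henry_k"]),
        biot=parse_quantity(d["biot"]) if "biot" in d else None,
        h=parse_quantity(d["h"]) if "h" in d else None,
        initial_concentration=parse_quantity(d.get("initial_concentration", 0.0)),
        density=parse_quantity(d.get("density", 1000.0)),
    )


def _assembly_to_dict(asm: Assembly) -> dict:
    out: dict[str, Any] = {
        "boundary_near": asm.boundary_near,
        "boundary_far": asm.boundary_far,
        "layers": [_layer_to_dict(lay) for lay in asm.layers],
    }
    if asm.fluid is not None:
        out["fluid"] = _fluid_to_dict(asm.fluid)
    return out


def _assembly_from_dict(d: dict) -> Assembly:
    layers = [_layer_from_dict(ld, i + 1) for i, ld in enumerate(d.get("layers", []))]
    if not layers:
        raise ValueError("assembly: no layers given")
    fluid = _fluid_from_dict(d["fluid"]) if "fluid" in d else None
    return Assembly(
        layers=tuple(layers),
        fluid=fluid,
        boundary_near=d.get("boundary_near", "fluid" if fluid is not None else "impervious"),
        boundary_far=d.get("boundary_far", "impervious"),
    )


def _transform_to_dict(tr) -> dict:
    if isinstance(tr, KeepProfiles):
        return {"keep_profiles": True}
    if isinstance(tr, EquilibrateWithin):
        return {"equilibrate_within": list(tr.indices)}
    if isinstance(tr, RemoveLayers):
        return {"remove_layers": list(tr.indices)}
    if isinstance(tr, AttachFluid):
        return {"attach_fluid": _fluid_to_dict(tr.fluid)}
    raise TypeError(f"unknown transform {tr!r}")


def _transform_from_dict(d: dict):
    if "keep_profiles" in d:
        return KeepProfiles()
    if "equilibrate_within" in d:
        return EquilibrateWithin(tuple(d["equilibrate_within"]))
    if "remove_layers" in d:
        return RemoveLayers(tuple(d["remove_layers"]))
    if "attach_fluid" in d:
        return AttachFluid(_fluid_from_dict(d["attach_fluid"]))
    raise ValueError(f"unknown transform spec {d!r}")


def _step_to_dict(st: Step) -> dict:
    out: dict[str, Any] = {"duration": float(st.duration)}
    if st.transforms:
        out["transforms"] = [_transform_to_dict(t) for t in st.transforms]
    if st.overrides:
        out["overrides"] = {
            int(k): {kk: float(vv) for kk, vv in v.items()} for k, v in st.overrides.items()
        }
    if st.label:
        out["label"] = st.label
    if st.temperature is not None:
        out["temperature"] = float(st.temperature)
    return out


def _step_from_dict(d: dict, index: int) -> Step:
    if "duration" not in d:
        raise ValueError(f"step {index}: missing duration")
    overrides = {
        int(k): {kk: parse_quantity(vv) for kk, vv in v.items()}
        for k, v in d.get("overrides", {}).items()
    }
    return Step(
        duration=parse_quantity(d["duration"]),
        transforms=tuple(_transform_from_dict(t) for t in d.get("transforms", [])),
        overrides=overrides,
        label=str(d.get("label", "")),
        temperature=parse_quantity(d["temperature"]) if "temperature" in d else None,
    )


def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "name": scenario.name,
        "assembly": _assembly_to_dict(scenario.assembly),
        "steps": [_step_to_dict(s) for s in scenario.steps],
    }


def scenario_from_dict(d: dict) -> Scenario:
    if "assembly" not in d:
        raise ValueError("scenario: missing 'assembly' section")
    if "steps" not in d or not d["steps"]:
        raise ValueError("scenario: missing 'steps' section")
    return Scenario(
        name=str(d.get("name", "scenario")),
        assembly=_assembly_from_dict(d["assembly"]),
        steps=tuple(_step_from_dict(s, i + 1) for i, s in enumerate(d["steps"])),
    )


def read_scenario(path: str | Path) -> Scenario:
    """Load a scenario from a YAML (or JSON) file; all quantities are
    SI-normalised on the way in."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return scenario_from_dict(data)


def write_scenario(scenario: Scenario, path: str | Path) -> None:
    path = Path(path)
    data = scenario_to_dict(scenario)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# kinetics tables


def scenario_hash(scenario: Scenario) -> str:
    payload = json.dumps(scenario_to_dict(scenario), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_kinetics(
    result: KineticsResult,
    path: str | Path,
    *,
    scenario_id: str = "",
    time_unit: str = "d",
    seed: int | None = None,
    tolerances: str = "",
) -> None:
    """Write a kinetics table as CSV with a provenance header (scenario
    identifier, solver tolerances, seed)."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_s": result.times}
    if time_unit:
        cols[f"time_{time_unit}"] = result.times / _UNITS[time_unit]
    labels = result.layer_labels or tuple(f"layer{j}" for j in range(1, result.layer_amounts.shape[0] + 1))
    for j, lab in enumerate(labels):
        cols[f"m_{j + 1}_{lab}"] = result.layer_amounts[j]
    if result.fluid_amount is not None:
        cols["m_fluid"] = result.fluid_amount
        if result.fluid_concentration is not None:
            cols["C_fluid_kg_m3"] = result.fluid_concentration
    df = pd.DataFrame(cols)
    buf = _io.StringIO()
    buf.write(f"# scenario: {scenario_id}\n")
    buf.write(f"# base_kg_m2: {result.base:.12g}\n")
    if tolerances:
        buf.write(f"# tolerances: {tolerances}\n")
    if seed is not None:
        buf.write(f"# seed: {seed}\n")
    df.to_csv(buf, index=False, float_format="%.15g")
    path.write_text(buf.getvalue())


def read_kinetics(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a kinetics CSV written by :func:`write_kinetics`; returns the
    table and the header metadata."""
    path = Path(path)
    meta: dict[str, str] = {}
    lines = path.read_text().splitlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        key, _, val = line.lstrip("# ").partition(":")
        meta[key.strip()] = val.strip()
    df = pd.read_csv(_io.StringIO("\n".join(lines[n_header:])))
    return df, meta


def read_kinetics_observations(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read observed (time, fraction-released) pairs from a two-column
    delimited text file with a header row; times in the unit declared in
    the header (``time_s``, ``time_d``, ...)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError("kinetics file must have a time column and a fraction column")
    tcol = df.columns[0]
    unit = tcol.rsplit("_", 1)[-1] if "_" in tcol else "s"
    factor = _UNITS.get(unit, 1.0)
    return df[tcol].to_numpy(float) * factor, df[df.columns[1]].to_numpy(float)
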