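"""Built-in scenarios: the two dimensionless case studies (S1, S2) and the
single-use-bag loading/migration configurations for ε-caprolactam, BHT and
the ten surrogate solutes.

The physical fixtures describe a bag (trilayer laminate, contact-first:
contact layer / EVOH barrier / outer layer) stored inside a PE/PA6/PE
overpackaging, separated by an optional air gap.  During the loading step
the migrant travels from the overpackaging across the gap into the bag;
during the migration step the overpackaging and gap are discarded and the
bag releases into a liquid simulant (ethanol).

Henry coefficients are stored in the activity form ``p = k·C`` with
``k = (k/RT)·RT`` for the condensed layers and ``k = RT`` for air, the
convention under which the tabulated ``k_j/RT`` columns equal 1 for air.
For migration steps only partition ratios with the fluid are known, so the
fluid is the reference phase (``k_F = 1``) and each layer carries
``k_j = K_F/j``; the dynamics only depend on these ratios.
"""

from __future__ import annotations

import numpy as np

from .core import (
    Assembly,
    AttachFluid,
    Fluid,
    Layer,
    RemoveLayers,
    Scenario,
    Step,
    build_assembly,
)
from .engine import distribute_equilibrium_initial
from .thermo import air_henry

__all__ = ["fixture", "FIXTURE_NAMES", "SURROGATES", "MIGRATION_PARAMS", "LOADING_TABLES"]

DAY = 86400.0

# ---------------------------------------------------------------------------
# surrogate solutes: molar mass (g/mol), p_sat at 25 °C (Pa) and the
# equilibrated wall concentrations in bags T1/T2 (mg/kg)

SURROGATES: dict[str, dict] = {
    "acetic_acid": {"molar_mass": 60.05, "p_sat": 2.14e3, "c_T1": 754.0, "c_T2": 540.0},
    "hexanol": {"molar_mass": 102.17, "p_sat": 105.0, "c_T1": 533.0, "c_T2": 213.0},
    "caprolactam": {"molar_mass": 113.16, "p_sat": 0.483, "c_T1": 854.0, "c_T2": 630.0},
    "decane": {"molar_mass": 142.29, "p_sat": 211.0, "c_T1": 2227.0, "c_T2": 1189.0},
    "prodox146": {"molar_mass": 206.33, "p_sat": 0.356, "c_T1": 1258.0, "c_T2": 324.0},
    "BHT": {"molar_mass": 220.35, "p_sat": 0.236, "c_T1": 1159.0, "c_T2": 299.0},
    "hexadecane": {"molar_mass": 286.8, "p_sat": 0.929, "c_T1": 4299.0, "c_T2": 2989.0},
    "irganox1076": {"molar_mass": 530.87, "p_sat": 4.51e-11, "c_T1": 2562.0, "c_T2": 666.0},
    "irgafos168": {"molar_mass": 646.92, "p_sat": 6.32e-12, "c_T1": 1907.0, "c_T2": 172.0},
    "irganox1010": {"molar_mass": 1177.65, "p_sat": 9.84e-29, "c_T1": 635.0, "c_T2": 48.0},
}

# migration-step inputs per solute: partition coefficients with ethanol
# (K_F/contact, K_F/EVOH) and diffusivities (m²/s) in the contact material
# and in EVOH, for each bag type
MIGRATION_PARAMS: dict[str, dict[str, tuple[float, float, float, float]]] = {
    #            T1: (K_F/EVA, K_F/EVOH, D_EVA, D_EVOH)   T2: (K_F/PE, K_F/EVOH, D_PE, D_EVOH)
    "acetic_acid": {"T1": (0.16, 0.23, 147e-14, 6.97e-14), "T2": (0.09, 0.23, 209e-14, 6.97e-14)},
    "BHT": {"T1": (0.57, 0.97, 2.52e-14, 0.18e-14), "T2": (1.12, 0.97, 5.39e-14, 0.18e-14)},
    "caprolactam": {"T1": (0.25, 0.31, 3.71e-14, 0.27e-14), "T2": (0.14, 0.31, 8.2e-14, 0.27e-14)},
    "decane": {"T1": (0.30, 0.57, 97.5e-14, 3.90e-14), "T2": (0.28, 0.57, 117e-14, 3.90e-14)},
    "hexadecane": {"T1": (0.20, 0.26, 10.1e-14, 0.44e-14), "T2": (0.07, 0.26, 13.3e-14, 0.44e-14)},
    "hexanol": {"T1": (0.35, 0.59, 187e-14, 4.07e-14), "T2": (0.82, 0.59, 122e-14, 4.07e-14)},
    "irgafos168": {"T1": (0.20, 0.38, 4.11e-14, 0.06e-14), "T2": (0.52, 0.38, 5.78e-14, 0.06e-14)},
    "irganox1010": {"T1": (0.45, 0.94, 1.21e-14, 0.24e-14), "T2": (0.50, 0.94, 2.13e-14, 0.24e-14)},
    "irganox1076": {"T1": (0.29, 0.57, 7.70e-14, 0.22e-14), "T2": (0.60, 0.57, 6.73e-14, 0.22e-14)},
    "prodox146": {"T1": (0.55, 1.37, 3.12e-14, 0.23e-14), "T2": (0.97, 1.37, 6.9e-14, 0.23e-14)},
}

# ---------------------------------------------------------------------------
# loading-step tables at 40 °C: per layer (material, k/RT, D, C0) for the
# stack bag(1..3) | air(4) | overpackaging(5..7), contact-first

T_LOADING = 313.15  # K

# bag laminates (total thickness, relative thicknesses contact-first)
BAG_GEOMETRY = {
    "T1": {"materials": ("EVA", "EVOH", "EVA"), "total": 0.3e-3, "ratios": (53.0, 1.0, 6.0)},
    "T2": {"materials": ("PE", "EVOH", "PE"), "total": 0.4e-3, "ratios": (10.2, 1.0, 4.8)},
}
# overpackaging laminate, gap-side first (j = 5, 6, 7)
OVERPACK_GEOMETRY = {"materials": ("PE", "PA6", "PE"), "total": 0.08e-3, "ratios": (2.3, 1.0, 1.3)}

LOADING_TABLES: dict[str, dict] = {
    # (k/RT, D) per material, plus initial concentrations in the overpack (kg/m³)
    "caprolactam": {
        "T1": {"EVA": (1.83e-7, 7.94e-14), "EVOH": (3.83e-7, 0.34e-14)},
        "T2": {"PE": (2.47e-7, 10.8e-14), "EVOH": (3.83e-7, 0.34e-14)},
        "overpack": {"PE": (2.47e-7, 10.8e-14), "PA6": (3.96e-8, 1.92e-16)},
        "air_D": {"T1": 8.12e-6, "T2": 8.12e-6},
        "C0_overpack": (0.58, 3.62, 0.58),
    },
    "BHT": {
        "T1": {"EVA": (2.37e-6, 3.52e-14), "EVOH": (2.90e-6, 0.24e-14)},
        "T2": {"PE": (1.63e-6, 9.97e-14), "EVOH": (2.90e-6, 0.33e-14)},
        "overpack": {"PE": (1.63e-6, 9.97e-14), "PA6": (3.20e-6, 4.50e-17)},
        # the tabulated air diffusivities differ between bags; both kept verbatim
        "air_D": {"T1": 5.29e-6, "T2": 8.12e-6},
        "C0_overpack": (4.0, 2.1, 4.0),
    },
}

# bag capacity (m³) and wall area (m²) for the migration-study bags
BAG_FLUID = {
    "T1": {"volume": 150e-6, "area": 2 * 0.155 * 0.09},
    "T2": {"volume": 100e-6, "area": 2 * 0.13 * 0.11},
}


def _bag_layers(bag: str, table: dict) -> list[Layer]:
    geo = BAG_GEOMETRY[bag]
    total, ratios = geo["total"], np.asarray(geo["ratios"])
    rt = air_henry(T_LOADING)
    layers = []
    for mat, frac in zip(geo["materials"], ratios / ratios.sum()):
        k_rt, d = table[bag][mat]
        layers.append(Layer(material=mat, thickness=total * frac, henry_k=k_rt * rt, diffusivity=d))
    return layers


def _overpack_layers(table: dict) -> list[Layer]:
    geo = OVERPACK_GEOMETRY
    total, ratios = geo["total"], np.asarray(geo["ratios"])
    rt = air_henry(T_LOADING)
    layers = []
    for mat, frac, c0 in zip(geo["materials"], ratios / ratios.sum(), table["C0_overpack"]):
        k_rt, d = table["overpack"][mat]
        layers.append(
            Layer(material=mat, thickness=total * frac, henry_k=k_rt * rt, diffusivity=d,
                  initial_concentration=c0)
        )
    return layers


def loading_assembly(bag: str, solute: str, air_gap_mm: float = 0.0) -> Assembly:
    """Bag + (optional) air gap + overpackaging stack, sealed on both
    sides (impervious/symmetric), parameters from the 40 °C loading
    tables.  ``air_gap_mm`` spans the studied 0–50 mm range; 0 means
    permanent perfect contact (the air layer is omitted)."""
    if not 0.0 <= air_gap_mm <= 50.0:
        raise ValueError("air gap thickness must be within 0-50 mm")
    table = LOADING_TABLES[solute]
    layers = _bag_layers(bag, table)
    if air_gap_mm > 0:
        layers.append(
            Layer(
                material="air",
                thickness=air_gap_mm * 1e-3,
                henry_k=air_henry(T_LOADING),
                diffusivity=table["air_D"][bag],
            )
        )
    layers.extend(_overpack_layers(table))
    return build_assembly(layers, boundary_far="impervious")


def migration_fluid(bag: str, biot: float = 1000.0) -> Fluid:
    """Ethanol compartment of the migration step; its equivalent thickness
    is the filled volume divided by the wetted wall area."""
    geo = BAG_FLUID[bag]
    return Fluid(equiv_thickness=geo["volume"] / geo["area"], henry_k=1.0, biot=biot)


def migration_assembly(bag: str, solute: str, biot: float = 1000.0) -> Assembly:
    """Bag trilayer in contact with ethanol at 25 °C; the fluid is the
    reference phase (k_F = 1) and layers carry k_j = K_F/j; the total
    spiked amount is distributed at uniform activity across the wall."""
    k_contact, k_evoh, d_contact, d_evoh = MIGRATION_PARAMS[solute][bag]
    geo = BAG_GEOMETRY[bag]
    total, ratios = geo["total"], np.asarray(geo["ratios"])
    mats = geo["materials"]
    ks = (k_contact, k_evoh, k_contact)
    ds = (d_contact, d_evoh, d_contact)
    layers = [
        Layer(material=m, thickness=total * f, henry_k=k, diffusivity=d)
        for m, f, k, d in zip(mats, ratios / ratios.sum(), ks, ds)
    ]
    asm = build_assembly(layers, fluid=migration_fluid(bag, biot))
    c_avg_mg_kg = SURROGATES[solute][f"c_{bag}"]
    density = 1000.0  # kg/m³, laminate density for mg/kg → kg/m³ (user input)
    total_amount = c_avg_mg_kg * 1e-6 * density * total  # kg/m²
    return distribute_equilibrium_initial(total_amount, asm, subset=(1, 2, 3))


def _migration_step(bag: str, solute: str, duration: float, biot: float) -> Step:
    """Step that discards gap+overpack, attaches ethanol and switches the
    layer parameters to the 25 °C migration values (fluid-referenced k)."""
    k_contact, k_evoh, d_contact, d_evoh = MIGRATION_PARAMS[solute][bag]
    overrides = {
        1: {"henry_k": k_contact, "diffusivity": d_contact},
        2: {"henry_k": k_evoh, "diffusivity": d_evoh},
        3: {"henry_k": k_contact, "diffusivity": d_contact},
    }
    return Step(
        duration=duration,
        transforms=(RemoveLayers((4, 5, 6, 7)), AttachFluid(migration_fluid(bag, biot))),
        overrides=overrides,
        label="migration",
        temperature=298.15,
    )


# ---------------------------------------------------------------------------
# dimensionless case studies (reference layer B: l = 1, k = 1, D = 1, so
# durations are Fourier numbers and concentrations are dimensionless)


def _case_study(name: str, solute: str, fo_step1: float, fo_step2: float) -> Scenario:
    # substance "sB" starts in B (contact layer), "sA" in A (far layer);
    # k and D ratios per layer follow the case-study tables
    if solute not in ("sA", "sB"):
        raise ValueError("case-study solute must be 'sA' or 'sB'")
    k_ratio = {"sB": {"A": 2.0, "air": 1e8, "F": 2.0}, "sA": {"A": 0.5, "air": 1e4, "F": 0.5}}[solute]
    b = Layer(material="B", thickness=1.0, henry_k=1.0, diffusivity=1.0,
              initial_concentration=1.0 if solute == "sB" else 0.0)
    a = Layer(material="A", thickness=0.5, henry_k=k_ratio["A"], diffusivity=0.5,
              initial_concentration=1.0 if solute == "sA" else 0.0)
    fluid = Fluid(equiv_thickness=10.0, henry_k=k_ratio["F"], biot=1000.0)
    if name == "S1":
        assembly = build_assembly([b, a])
        steps = (
            Step(duration=fo_step1, label="storage"),
            Step(duration=fo_step2, transforms=(AttachFluid(fluid),), label="contact"),
        )
    else:  # S2: A-air-B during storage, A and air discarded before contact
        air = Layer(material="air", thickness=1.0, henry_k=k_ratio["air"], diffusivity=1e8)
        assembly = build_assembly([b, air, a])
        steps = (
            Step(duration=fo_step1, label="storage"),
            Step(
                duration=fo_step2,
                transforms=(RemoveLayers((2, 3)), AttachFluid(fluid)),
                label="contact",
            ),
        )
    return Scenario(name=f"{name}_{solute}", assembly=assembly, steps=steps)


# ---------------------------------------------------------------------------
# public factory


def fixture(
    name: str,
    *,
    solute: str = "sA",
    air_gap_mm: float = 0.0,
    loading_days: float = 100.0,
    migration_days: float = 120.0,
    with_migration: bool = False,
    fo_step1: float = 100.0,
    fo_step2: float = 50.0,
    biot: float = 1000.0,
) -> Scenario:
    """Return a fully parameterised built-in scenario.

    Names: ``"S1"``/``"S2"`` (dimensionless case studies; choose the
    substance with ``solute="sA"|"sB"``), ``"T1_caprolactam"``,
    ``"T2_caprolactam"``, ``"T1_BHT"``, ``"T2_BHT"`` (loading at 40 °C,
    optionally followed by a migration step when ``with_migration=True``),
    and ``"T1_migration_<solute>"`` / ``"T2_migration_<solute>"`` for the
    ethanol desorption study of any surrogate (see :data:`SURROGATES`).
    """
    if name in ("S1", "S2"):
        return _case_study(name, solute, fo_step1, fo_step2)
    if name.startswith(("T1_migration_", "T2_migration_")):
        bag = name[:2]
        sol = name[len("Tx_migration_"):]
        if sol not in SURROGATES:
            raise KeyError(f"unknown solute {sol!r}")
        assembly = migration_assembly(bag, sol, biot)
        return Scenario(
            name=name,
            assembly=assembly,
            steps=(Step(duration=migration_days * DAY, label="migration", temperature=298.15),),
        )
    if name in ("T1_caprolactam", "T2_caprolactam", "T1_BHT", "T2_BHT"):
        bag, sol = name.split("_", 1)
        assembly = loading_assembly(bag, sol, air_gap_mm)
        steps = [Step(duration=loading_days * DAY, label="loading", temperature=T_LOADING)]
        if with_migration:
            if air_gap_mm == 0:
                # without a gap there is no layer 4..7 split: the overpack
                # occupies indices 4..6
                k_c, k_e, d_c, d_e = MIGRATION_PARAMS[sol][bag]
                steps.append(
                    Step(
                        duration=migration_days * DAY,
                        transforms=(RemoveLayers((4, 5, 6)), AttachFluid(migration_fluid(bag, biot))),
                        overrides={
                            1: {"henry_k": k_c, "diffusivity": d_c},
                            2: {"henry_k": k_e, "diffusivity": d_e},
                            3: {"henry_k": k_c, "diffusivity": d_c},
                        },
                        label="migration",
                        temperature=298.15,
                    )
                )
            else:
                steps.append(_migration_step(bag, sol, migration_days * DAY, biot))
        return Scenario(name=name, assembly=assembly, steps=tuple(steps))
    raise KeyError(f"unknown fixture {name!r}")


FIXTURE_NAMES = (
    ("S1", "S2", "T1_caprolactam", "T2_caprolactam", "T1_BHT", "T2_BHT")
    + tuple(f"T1_migration_{s}" for s in SURROGATES)
    + tuple(f"T2_migration_{s}" for s in SURROGATES)
)
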