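"""Sorption thermodynamics, analytic equilibria and transport-parameter
estimation.

The sorption model is the linearised Flory–Huggins (Henry) isotherm: in
layer *j* the migrant exerts the partial pressure ``p = k_j · C_j`` with

    k_j = p_sat · V̄ · exp(1 + χ_j)          (polymer layer)
    k_j = R·T                                (air layer, ideal gas)

where ``p_sat`` is the saturation pressure of the solute at temperature T,
``V̄`` its molar volume and ``χ_j`` the Flory–Huggins interaction
parameter with the layer material.  At equilibrium the activity ``k_j·C_j``
is uniform, so every partition coefficient is a concentration ratio at
equal activity: ``K_{a/b} = C_a/C_b = k_b/k_a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import Assembly, Layer, R_GAS

__all__ = [
    "henry_coefficient",
    "air_henry",
    "polymer_partition",
    "EquilibriumResult",
    "equilibrium_distribution",
    "effective_henry",
    "missing_henry",
    "fuller_gas_diffusivity",
    "diffusion_volume",
    "resistance_ratios",
    "apparent_partition",
    "FULLER_INCREMENTS",
    "AIR_MOLAR_MASS",
    "AIR_DIFFUSION_VOLUME",
]


def henry_coefficient(chi: float, p_sat: float, molar_volume: float) -> float:
    """Henry coefficient ``k = p_sat · V̄ · exp(1 + χ)`` (Pa·m³·mol⁻¹)."""
    if p_sat < 0:
        raise ValueError("p_sat must be >= 0")
    if not molar_volume > 0:
        raise ValueError("molar_volume must be > 0")
    return p_sat * molar_volume * math.exp(1.0 + chi)


def air_henry(temperature: float) -> float:
    """Henry coefficient of any solute in air, ``k = R·T`` (ideal gas)."""
    if not temperature > 0:
        raise ValueError("temperature must be > 0 K")
    return R_GAS * temperature


def polymer_partition(chi_target: float, chi_source: float) -> float:
    """Partition coefficient ``K_{target/source} = C_target/C_source`` at
    equal activity between two polymers hosting the same solute:
    ``ln K = χ_source − χ_target``.

    Example: with χ_LDPE = 0.76 and χ_PA6 = −1.19 the ratio
    ``polymer_partition(chi_target=χ_PA6, chi_source=χ_LDPE)`` gives
    K_PA6/LDPE ≈ 7.03 (ε-caprolactam at 20 °C).
    """
    if not (np.isfinite(chi_target) and np.isfinite(chi_source)):
        raise ValueError("chi values must be finite")
    return math.exp(chi_source - chi_target)


@dataclass
class EquilibriumResult:
    """Uniform-activity split of a closed stack (fluid included).

    ``fractions`` are amounts relative to the total (fluid first entry if
    present is ``fluid_fraction``); ``concentrations`` in kg·m⁻³;
    ``activity`` is the common value of ``k_j·C_j``.
    """

    fractions: np.ndarray  # per layer, j = 1..m
    concentrations: np.ndarray
    fluid_fraction: float | None
    fluid_concentration: float | None
    activity: float


def equilibrium_distribution(assembly: Assembly, total_amount: float | None = None) -> EquilibriumResult:
    """Analytic equilibrium of a closed assembly.

    At uniform activity ``a`` each layer holds ``C_j = a/k_j`` and the
    amount per area ``l_j·a/k_j``; the fluid contributes ``l_0·a/k_0``.
    The per-layer capacities ``l_j/k_j`` therefore set the split, which
    reproduces the classical two- and three-layer closed forms (residual
    and transferred amounts) for any m.

    ``total_amount`` (kg·m⁻²) defaults to the assembly's initial amount;
    it fixes the absolute concentrations, not the fractions.
    """
    caps = assembly.thicknesses / assembly.henry_coefficients()
    cap_fluid = 0.0
    if assembly.fluid is not None:
        cap_fluid = assembly.fluid.equiv_thickness / assembly.fluid.henry_k
    cap_total = float(np.sum(caps) + cap_fluid)
    if total_amount is None:
        total_amount = assembly.initial_amount()
    activity = total_amount / cap_total
    fractions = caps / cap_total
    concentrations = activity / assembly.henry_coefficients()
    fluid_fraction = None
    fluid_concentration = None
    if assembly.fluid is not None:
        fluid_fraction = cap_fluid / cap_total
        fluid_concentration = activity / assembly.fluid.henry_k
    return EquilibriumResult(
        fractions=fractions,
        concentrations=concentrations,
        fluid_fraction=fluid_fraction,
        fluid_concentration=fluid_concentration,
        activity=activity,
    )


def effective_henry(volume_fractions: Sequence[float], henry_ks: Sequence[float]) -> float:
    """Effective Henry coefficient of a composite:
    ``1/k_eff = Σ φ_j / k_j`` (harmonic, volume-fraction weighted)."""
    phi = np.asarray(volume_fractions, dtype=float)
    k = np.asarray(henry_ks, dtype=float)
    if np.any(phi < 0):
        raise ValueError("volume fractions must be >= 0")
    if not math.isclose(float(phi.sum()), 1.0, rel_tol=1e-9, abs_tol=1e-12):
        raise ValueError("volume fractions must sum to 1")
    if np.any(k == 0):
        raise ValueError("henry coefficients must be nonzero")
    return float(1.0 / np.sum(phi / k))


def missing_henry(
    k_eff: float, volume_fractions: Sequence[float], henry_ks: Sequence[float | None]
) -> float:
    """Solve ``1/k_eff = Σ φ_j/k_j`` for the single unknown ``k_j``
    (marked ``None``); errors if zero or more than one entry is unknown."""
    phi = np.asarray(volume_fractions, dtype=float)
    unknown = [i for i, k in enumerate(henry_ks) if k is None]
    if len(unknown) != 1:
        raise ValueError("exactly one henry coefficient must be unknown")
    i = unknown[0]
    rest = sum(p / k for j, (p, k) in enumerate(zip(phi, henry_ks)) if j != i)
    residual = 1.0 / k_eff - rest
    if residual <= 0:
        raise ValueError("inconsistent inputs: residual capacity is not positive")
    return float(phi[i] / residual)


# ---------------------------------------------------------------------------
# Fuller–Schettler–Giddings gas diffusivity

#: Atomic diffusion-volume increments (Fuller, Schettler and Giddings);
#: ``ring`` is the correction per aromatic or heterocyclic ring.
FULLER_INCREMENTS = {
    "C": 15.9,
    "H": 2.31,
    "O": 6.11,
    "N": 4.54,
    "S": 22.9,
    "F": 14.7,
    "Cl": 21.0,
    "Br": 21.9,
    "I": 29.8,
    "ring": -18.3,
}

AIR_MOLAR_MASS = 28.96  # g·mol⁻¹
AIR_DIFFUSION_VOLUME = 19.7


def diffusion_volume(atoms: dict, rings: int = 0) -> float:
    """Sum the Fuller atomic increments for a molecular formula given as
    ``{"C": 6, "H": 11, ...}`` with an optional ring correction."""
    sv = sum(FULLER_INCREMENTS[sym] * n for sym, n in atoms.items())
    sv += rings * FULLER_INCREMENTS["ring"]
    if sv <= 0:
        raise ValueError("diffusion volume must be > 0")
    return sv


def fuller_gas_diffusivity(
    molar_mass: float,
    sigma_v: float,
    temperature: float,
    pressure: float = 101325.0,
) -> float:
    """Binary gas diffusivity of a solute in air (m²·s⁻¹).

    Fuller–Schettler–Giddings correlation,
    ``D ∝ T^1.75 · sqrt(1/M_A + 1/M_air) / (P · (Σv_A^⅓ + Σv_air^⅓)²)``,
    with the classical prefactor 1.0·10⁻³ for D in cm²·s⁻¹, T in K, P in
    atm and M in g·mol⁻¹.
    """
    if not temperature > 0:
        raise ValueError("temperature must be > 0")
    if not pressure > 0:
        raise ValueError("pressure must be > 0")
    if not sigma_v > 0:
        raise ValueError("sigma_v must be > 0")
    p_atm = pressure / 101325.0
    d_cm2 = (
        1.0e-3
        * temperature**1.75
        * math.sqrt(1.0 / molar_mass + 1.0 / AIR_MOLAR_MASS)
        / (p_atm * (sigma_v ** (1.0 / 3.0) + AIR_DIFFUSION_VOLUME ** (1.0 / 3.0)) ** 2)
    )
    return d_cm2 * 1e-4


# ---------------------------------------------------------------------------
# resistances and apparent partitioning


def resistance_ratios(
    assembly: Assembly,
    *,
    reference_thickness: float = 1e-4,
    reference_henry_k: float | None = None,
    reference_diffusivity: float | None = None,
    rounded: bool = False,
) -> np.ndarray:
    """Per-layer mass-transfer resistance ``l_j·k_j/D_j`` relative to a
    reference air layer (default 0.1 mm thick).

    The reference Henry coefficient and diffusivity default to those of the
    first air layer found in the assembly; a high ratio marks a functional
    barrier.  ``rounded=True`` returns nearest integers, the convention of
    printed resistance tables.
    """
    if reference_henry_k is None or reference_diffusivity is None:
        air = next((lay for lay in assembly.layers if lay.is_air), None)
        if air is None:
            raise ValueError(
                "no air layer in the assembly: pass reference_henry_k and reference_diffusivity"
            )
        if reference_henry_k is None:
            reference_henry_k = air.henry_k
        if reference_diffusivity is None:
            reference_diffusivity = air.diffusivity
    r_ref = reference_thickness * reference_henry_k / reference_diffusivity
    r = np.array([lay.thickness * lay.henry_k / lay.diffusivity for lay in assembly.layers])
    out = r / r_ref
    if rounded:
        return np.rint(out).astype(int)
    return out


def apparent_partition(assembly: Assembly) -> float:
    """Apparent partition coefficient ``K_F/P`` between the fluid and the
    whole material at equilibrium: fluid concentration over the
    thickness-averaged material concentration, i.e. ``k_eff/k_0``."""
    if assembly.fluid is None:
        raise ValueError("apparent partition requires a fluid compartment")
    eq = equilibrium_distribution(assembly)
    mean_material = float(
        np.sum(assembly.thicknesses * eq.concentrations) / assembly.total_thickness
    )
    if mean_material == 0:
        raise ValueError("material holds no migrant at equilibrium")
    return eq.fluid_concentration / mean_material


def layer_from_solute(
    solute, material: str, thickness: float, temperature: float, **kwargs
) -> Layer:
    """Build a :class:`Layer` resolving k and D from the solute's
    per-material parameters (χ or k, plus D); air resolves to ``k = RT``."""
    if material.lower() in ("air", "gas"):
        params = solute.materials.get(material, None)
        d = params.diffusivity if params is not None and params.diffusivity else None
        if d is None:
            raise ValueError("air layer needs a diffusivity (e.g. from Fuller's law)")
        return Layer(material=material, thickness=thickness, henry_k=air_henry(temperature), diffusivity=d, **kwargs)
    try:
        params = solute.materials[material]
    except KeyError:
        raise ValueError(f"solute {solute.name!r} has no parameters for material {material!r}")
    if params.diffusivity is None:
        raise ValueError(f"material {material!r}: missing diffusivity")
    if params.henry_k is not None:
        k = params.henry_k
    elif params.chi is not None:
        k = henry_coefficient(params.chi, solute.p_sat, solute.molar_volume)
    else:
        raise ValueError(f"material {material!r}: missing sorption parameter (chi or henry_k)")
    return Layer(material=material, thickness=thickness, henry_k=k, diffusivity=params.diffusivity, **kwargs)
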