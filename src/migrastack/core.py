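"""Domain types shared by every module of :mod:`migrastack`.

The system is a one-dimensional stack of ``m`` layers (polymer films or air
gaps) optionally terminated on the contact side by a well-mixed fluid
compartment.  Conventions used throughout the package:

* layer index 1 is the contact side, index ``m`` the far side; the fluid
  compartment, when present, carries index 0;
* concentrations are mass concentrations in kg·m⁻³;
* sorption is linear (Henry regime): the partial pressure of the migrant in
  layer *j* is ``p = k_j · C_j``; for an air layer the ideal-gas law gives
  ``k = R·T``.  Only ratios of Henry coefficients matter for the dynamics,
  so any consistent scale may be used within one step;
* a dimensionless time (Fourier number) ``Fo = D₁·t/l₁²`` refers to the
  contact layer unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "R_GAS",
    "Solute",
    "MaterialParams",
    "Layer",
    "Fluid",
    "Assembly",
    "Step",
    "Scenario",
    "SimulationState",
    "KineticsResult",
    "build_assembly",
    "KeepProfiles",
    "EquilibrateWithin",
    "RemoveLayers",
    "AttachFluid",
]

#: Ideal-gas constant, J·mol⁻¹·K⁻¹ (``k = R·T`` for air layers).
R_GAS = 8.314

AIR_MATERIALS = frozenset({"air", "gas"})


@dataclass(frozen=True)
class MaterialParams:
    """Per-material sorption/transport parameters of one solute.

    Either ``chi`` (Flory–Huggins interaction parameter, dimensionless) or
    ``henry_k`` (Pa·m³·mol⁻¹) must be given for a sorption description;
    ``diffusivity`` is in m²·s⁻¹.
    """

    chi: float | None = None
    henry_k: float | None = None
    diffusivity: float | None = None


@dataclass(frozen=True)
class Solute:
    """Physical constants of a migrant.

    Parameters
    ----------
    name:
        Identifier (e.g. ``"caprolactam"``).
    molar_mass:
        g·mol⁻¹.
    p_sat:
        Saturation (vapour) pressure in Pa at the stated temperature.
    molar_volume:
        Molar volume in m³·mol⁻¹.
    materials:
        Mapping material name → :class:`MaterialParams`.
    """

    name: str
    molar_mass: float = float("nan")
    p_sat: float = float("nan")
    molar_volume: float = float("nan")
    materials: Mapping[str, MaterialParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.p_sat) and self.p_sat < 0:
            raise ValueError("p_sat must be >= 0")
        if np.isfinite(self.molar_volume) and self.molar_volume <= 0:
            raise ValueError("molar_volume must be > 0")


@dataclass(frozen=True)
class Layer:
    """One slab of the stack.

    ``henry_k`` follows the activity convention ``p = k·C`` (air: ``k = RT``);
    ``initial_concentration`` is either a uniform value or a cell-average
    profile (kg·m⁻³).  ``density`` only matters for mg·kg⁻¹ conversions.
    """

    material: str
    thickness: float
    henry_k: float
    diffusivity: float
    initial_concentration: float | np.ndarray = 0.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not self.thickness > 0:
            raise ValueError(f"layer {self.material!r}: thickness must be > 0")
        if not self.diffusivity > 0:
            raise ValueError(f"layer {self.material!r}: diffusivity must be > 0")
        if not self.henry_k > 0:
            raise ValueError(f"layer {self.material!r}: henry_k must be > 0")
        if np.min(np.asarray(self.initial_concentration)) < 0:
            raise ValueError(f"layer {self.material!r}: initial concentration must be >= 0")
        if not self.density > 0:
            raise ValueError(f"layer {self.material!r}: density must be > 0")

    @property
    def is_air(self) -> bool:
        return self.material.lower() in AIR_MATERIALS

    @property
    def mean_initial_concentration(self) -> float:
        return float(np.mean(np.asarray(self.initial_concentration, dtype=float)))


@dataclass(frozen=True)
class Fluid:
    """Well-mixed fluid compartment (index 0) coupled through a Robin
    boundary condition.

    ``equiv_thickness`` is the fluid volume per unit contact area (m).
    Exactly one of ``biot`` (mass Biot number ``Bi = h·l₁/D₁``) or ``h``
    (surface mass-transfer coefficient, m·s⁻¹) must be supplied; the other
    is derived once the contact layer is known.
    """

    equiv_thickness: float
    henry_k: float
    biot: float | None = None
    h: float | None = None
    initial_concentration: float = 0.0
    density: float = 1000.0

    def __post_init__(self) -> None:
        if not self.equiv_thickness > 0:
            raise ValueError("fluid: equiv_thickness must be > 0")
        if not self.henry_k > 0:
            raise ValueError("fluid: henry_k must be > 0")
        if (self.biot is None) == (self.h is None):
            raise ValueError("fluid: exactly one of {biot, h} must be given")
        given = self.biot if self.biot is not None else self.h
        if not given > 0:
            raise ValueError("fluid: Bi (or h) must be > 0")
        if self.initial_concentration < 0:
            raise ValueError("fluid: initial concentration must be >= 0")

    def transfer_coefficient(self, contact_layer: Layer) -> float:
        """Surface mass-transfer coefficient h (m·s⁻¹) on the fluid side."""
        if self.h is not None:
            return self.h
        return self.biot * contact_layer.diffusivity / contact_layer.thickness

    def biot_number(self, contact_layer: Layer) -> float:
        if self.biot is not None:
            return self.biot
        return self.h * contact_layer.thickness / contact_layer.diffusivity


@dataclass(frozen=True)
class Assembly:
    """Ordered stack of layers, contact side first, plus boundary flags.

    ``boundary_near`` is the condition on the contact side (x = 0):
    ``"fluid"`` (Robin coupling to the fluid compartment), ``"impervious"``
    or ``"periodic"``.  ``boundary_far`` applies at ``x = L_m`` and is
    ``"impervious"`` (symmetric stack) or ``"periodic"`` (set-off, reel
    storage: the far face contacts the near face of the next repeat).
    """

    layers: tuple[Layer, ...]
    fluid: Fluid | None = None
    boundary_near: str = "impervious"
    boundary_far: str = "impervious"

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        if len(self.layers) == 0:
            raise ValueError("assembly must contain at least one layer")
        if self.boundary_far not in ("impervious", "periodic"):
            raise ValueError(f"unknown boundary_far {self.boundary_far!r}")
        if self.boundary_near not in ("fluid", "impervious", "periodic"):
            raise ValueError(f"unknown boundary_near {self.boundary_near!r}")
        if (self.boundary_near == "periodic") != (self.boundary_far == "periodic"):
            raise ValueError("periodic condition must be set on both ends")
        if self.boundary_near == "fluid" and self.fluid is None:
            raise ValueError("boundary_near='fluid' requires a fluid compartment")
        if self.fluid is not None and self.boundary_near != "fluid":
            raise ValueError("a fluid compartment requires boundary_near='fluid'")

    @property
    def m(self) -> int:
        """Number of layers."""
        return len(self.layers)

    @property
    def thicknesses(self) -> np.ndarray:
        return np.array([lay.thickness for lay in self.layers])

    @property
    def cumulated_thickness(self) -> np.ndarray:
        """``L_j = Σ_{k<=j} l_k`` for j = 1…m."""
        return np.cumsum(self.thicknesses)

    @property
    def total_thickness(self) -> float:
        return float(np.sum(self.thicknesses))

    def henry_coefficients(self) -> np.ndarray:
        return np.array([lay.henry_k for lay in self.layers])

    def diffusivities(self) -> np.ndarray:
        return np.array([lay.diffusivity for lay in self.layers])

    def initial_amount(self) -> float:
        """Initial amount per unit area (kg·m⁻²), fluid included."""
        total = sum(lay.thickness * lay.mean_initial_concentration for lay in self.layers)
        if self.fluid is not None:
            total += self.fluid.equiv_thickness * self.fluid.initial_concentration
        return float(total)

    def replace_layer(self, index: int, **changes) -> "Assembly":
        """Return a copy with layer ``index`` (1-based) modified."""
        layers = list(self.layers)
        layers[index - 1] = replace(layers[index - 1], **changes)
        return replace(self, layers=tuple(layers))


def build_assembly(
    layers: Sequence[Layer],
    fluid: Fluid | None = None,
    *,
    boundary_near: str | None = None,
    boundary_far: str = "impervious",
) -> Assembly:
    """Assemble a validated stack; contact side first (j = 1 … m).

    ``boundary_near`` defaults to ``"fluid"`` when a fluid compartment is
    given and ``"impervious"`` otherwise.
    """
    if boundary_near is None:
        boundary_near = "fluid" if fluid is not None else "impervious"
    return Assembly(
        layers=tuple(layers),
        fluid=fluid,
        boundary_near=boundary_near,
        boundary_far=boundary_far,
    )


# ---------------------------------------------------------------------------
# scenario steps


@dataclass(frozen=True)
class KeepProfiles:
    """Carry the concentration profiles unchanged into the next step."""


@dataclass(frozen=True)
class EquilibrateWithin:
    """Redistribute the amount held by ``indices`` (1-based; 0 = fluid) to
    uniform activity within that subset before the step starts."""

    indices: tuple[int, ...]

    def __init__(self, indices: Sequence[int]):
        object.__setattr__(self, "indices", tuple(int(i) for i in indices))


@dataclass(frozen=True)
class RemoveLayers:
    """Discard layers (1-based indices); their content is logged, the
    remaining layers are renumbered contact-first."""

    indices: tuple[int, ...]

    def __init__(self, indices: Sequence[int]):
        object.__setattr__(self, "indices", tuple(int(i) for i in indices))


@dataclass(frozen=True)
class AttachFluid:
    """Bring the contact face in contact with a well-mixed fluid."""

    fluid: Fluid


Transform = KeepProfiles | EquilibrateWithin | RemoveLayers | AttachFluid


@dataclass(frozen=True)
class Step:
    """One storage/contact period of a scenario.

    ``transforms`` are applied, in order, to the state inherited from the
    previous step; ``overrides`` maps a 1-based layer index (after the
    transforms) to replacement ``henry_k``/``diffusivity`` values, which is
    how per-step temperatures enter (k and D are per-step inputs).
    """

    duration: float
    transforms: tuple[Transform, ...] = ()
    overrides: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    label: str = ""
    temperature: float | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValueError("step duration must be > 0")
        object.__setattr__(self, "transforms", tuple(self.transforms))


@dataclass(frozen=True)
class Scenario:
    """An initial assembly followed by an ordered list of steps."""

    name: str
    assembly: Assembly
    steps: tuple[Step, ...]
    solute: Solute | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))
        if len(self.steps) == 0:
            raise ValueError("scenario must contain at least one step")


# ---------------------------------------------------------------------------
# state and results


@dataclass
class SimulationState:
    """Cell-average concentrations on the per-layer grids at one instant.

    ``concentrations[j]`` is the array for layer j+1 (contact-first);
    ``edges[j]`` the corresponding cell-edge coordinates (m), covering
    ``[L_{j-1}, L_j]`` without gaps.
    """

    time: float
    edges: list[np.ndarray]
    concentrations: list[np.ndarray]
    fluid_concentration: float | None = None

    def layer_amounts(self) -> np.ndarray:
        """Per-layer amounts per unit area (kg·m⁻²)."""
        return np.array(
            [float(np.sum(np.diff(e) * c)) for e, c in zip(self.edges, self.concentrations)]
        )

    def validate(self, tol: float = 0.0) -> None:
        for j, c in enumerate(self.concentrations):
            if np.min(c) < -tol:
                raise ValueError(f"negative concentration in layer {j + 1}: {np.min(c):g}")
        for j, (e, c) in enumerate(zip(self.edges, self.concentrations)):
            if len(e) != len(c) + 1:
                raise ValueError(f"layer {j + 1}: edges/cells mismatch")


@dataclass
class KineticsResult:
    """Time series of per-layer amounts, normalised per the macroscopic
    mass balance: every amount is divided by ``base``, the total initial
    amount in the scenario (kg·m⁻²), so that a closed system sums to 1.
    """

    times: np.ndarray
    layer_amounts: np.ndarray  # shape (m, n_times), normalised
    fluid_amount: np.ndarray | None  # shape (n_times,), normalised
    base: float
    layer_labels: tuple[str, ...] = ()
    fluid_concentration: np.ndarray | None = None  # kg·m⁻³

    def total(self) -> np.ndarray:
        """Normalised total amount tracked at each time."""
        tot = self.layer_amounts.sum(axis=0)
        if self.fluid_amount is not None:
            tot = tot + self.fluid_amount
        return tot

    def fraction_in(self, indices: Sequence[int]) -> np.ndarray:
        """Normalised amount in a subset of layers (1-based; 0 = fluid)."""
        out = np.zeros_like(self.times, dtype=float)
        for i in indices:
            if i == 0:
                if self.fluid_amount is None:
                    raise ValueError("no fluid compartment in this result")
                out += self.fluid_amount
            else:
                out += self.layer_amounts[i - 1]
        return out
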