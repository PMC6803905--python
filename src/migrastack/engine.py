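"""Scenario engine: chain multi-step storage/contact scenarios.

Each step starts from the previous step's final concentration profile
after an assembly transformation (keep profiles, equilibrate a subset,
remove layers, attach a fluid).  Amounts removed together with a layer are
logged, never silently dropped, and the normalisation base (total initial
amount of the scenario) is preserved across steps so the kinetics of all
steps share one scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import (
    Assembly,
    AttachFluid,
    EquilibrateWithin,
    KeepProfiles,
    KineticsResult,
    RemoveLayers,
    Scenario,
    SimulationState,
    Step,
)
from .solver import GridSpec, StepResult, solve_step

__all__ = [
    "ScenarioResult",
    "run_scenario",
    "apply_transforms",
    "distribute_equilibrium_initial",
]


@dataclass
class ScenarioResult:
    """Per-step trajectories plus the mass bookkeeping of removals."""

    scenario: Scenario
    step_results: list[StepResult]
    assemblies: list[Assembly]
    removed: list[float]  # normalised amount removed before each step
    base: float

    @property
    def final_state(self) -> SimulationState:
        return self.step_results[-1].final_state

    @property
    def kinetics(self) -> list[KineticsResult]:
        return [r.kinetics for r in self.step_results]


def _state_amounts(assembly: Assembly, state: SimulationState) -> float:
    total = float(np.sum(state.layer_amounts()))
    if assembly.fluid is not None and state.fluid_concentration is not None:
        total += assembly.fluid.equiv_thickness * state.fluid_concentration
    return total


def _initial_state(assembly: Assembly, grid: GridSpec) -> SimulationState:
    nodes = grid.nodes_for(assembly)
    edges, conc = [], []
    x0 = 0.0
    for lay, nj in zip(assembly.layers, nodes):
        e = x0 + lay.thickness / nj * np.arange(nj + 1)
        c0 = np.asarray(lay.initial_concentration, dtype=float)
        conc.append(np.full(nj, float(c0)) if c0.ndim == 0 else c0.astype(float).copy())
        edges.append(e)
        x0 += lay.thickness
    fluid_c = assembly.fluid.initial_concentration if assembly.fluid is not None else None
    return SimulationState(time=0.0, edges=edges, concentrations=conc, fluid_concentration=fluid_c)


def apply_transforms(
    assembly: Assembly, state: SimulationState, step: Step
) -> tuple[Assembly, SimulationState, float]:
    """Apply one step's transforms and parameter overrides.

    Returns the transformed assembly, the mapped state and the amount
    (kg·m⁻²) removed from the system by ``RemoveLayers`` transforms.
    """
    removed = 0.0
    for tr in step.transforms:
        if isinstance(tr, KeepProfiles):
            continue
        elif isinstance(tr, EquilibrateWithin):
            assembly, state = _equilibrate_within(assembly, state, tr.indices)
        elif isinstance(tr, RemoveLayers):
            assembly, state, gone = _remove_layers(assembly, state, tr.indices)
            removed += gone
        elif isinstance(tr, AttachFluid):
            if assembly.fluid is not None:
                raise ValueError("assembly already has a fluid compartment")
            assembly = replace(assembly, fluid=tr.fluid, boundary_near="fluid")
            state = replace(state, fluid_concentration=tr.fluid.initial_concentration)
        else:
            raise TypeError(f"unknown transform {tr!r}")
    for idx, changes in step.overrides.items():
        idx = int(idx)
        if idx == 0:
            if assembly.fluid is None:
                raise ValueError("override for the fluid but no fluid compartment")
            assembly = replace(assembly, fluid=replace(assembly.fluid, **changes))
        else:
            if not 1 <= idx <= assembly.m:
                raise ValueError(f"override for layer {idx}: no such layer")
            assembly = assembly.replace_layer(idx, **changes)
    return assembly, state, removed


def _remove_layers(
    assembly: Assembly, state: SimulationState, indices: tuple[int, ...]
) -> tuple[Assembly, SimulationState, float]:
    bad = [i for i in indices if not 1 <= i <= assembly.m]
    if bad:
        raise ValueError(f"cannot remove layers {bad}: out of range (m={assembly.m})")
    drop = set(indices)
    if len(drop) == assembly.m:
        raise ValueError("cannot remove every layer")
    amounts = state.layer_amounts()
    removed = float(sum(amounts[i - 1] for i in drop))
    keep = [i for i in range(1, assembly.m + 1) if i not in drop]
    layers = tuple(assembly.layers[i - 1] for i in keep)
    new_assembly = replace(assembly, layers=layers)
    # re-anchor the grid so it covers [0, L'] contact-first without gaps
    new_edges, new_conc = [], []
    x0 = 0.0
    for i in keep:
        e = state.edges[i - 1]
        new_edges.append(x0 + (e - e[0]))
        new_conc.append(state.concentrations[i - 1].copy())
        x0 += e[-1] - e[0]
    new_state = SimulationState(
        time=state.time,
        edges=new_edges,
        concentrations=new_conc,
        fluid_concentration=state.fluid_concentration,
    )
    return new_assembly, new_state, removed


def _equilibrate_within(
    assembly: Assembly, state: SimulationState, indices: tuple[int, ...]
) -> tuple[Assembly, SimulationState]:
    if len(indices) == 0:
        raise ValueError("equilibrate_within: empty subset")
    layer_idx = [i for i in indices if i != 0]
    with_fluid = 0 in indices
    if with_fluid and assembly.fluid is None:
        raise ValueError("equilibrate_within includes the fluid but none is attached")
    for i in layer_idx:
        if not 1 <= i <= assembly.m:
            raise ValueError(f"equilibrate_within: no layer {i}")
    amounts = state.layer_amounts()
    total = float(sum(amounts[i - 1] for i in layer_idx))
    cap = sum(
        assembly.layers[i - 1].thickness / assembly.layers[i - 1].henry_k for i in layer_idx
    )
    if with_fluid:
        total += assembly.fluid.equiv_thickness * (state.fluid_concentration or 0.0)
        cap += assembly.fluid.equiv_thickness / assembly.fluid.henry_k
    if cap <= 0:
        raise ValueError("equilibrate_within: zero-capacity subset")
    activity = total / cap
    conc = [c.copy() for c in state.concentrations]
    for i in layer_idx:
        conc[i - 1][:] = activity / assembly.layers[i - 1].henry_k
    fluid_c = state.fluid_concentration
    if with_fluid:
        fluid_c = activity / assembly.fluid.henry_k
    return assembly, SimulationState(
        time=state.time,
        edges=[e.copy() for e in state.edges],
        concentrations=conc,
        fluid_concentration=fluid_c,
    )


def run_scenario(scenario: Scenario, grid: GridSpec | None = None) -> ScenarioResult:
    """Run every step of a scenario, carrying profiles (and the
    normalisation base) from step to step."""
    grid = grid or GridSpec()
    assembly = scenario.assembly
    state = _initial_state(assembly, grid)
    base = assembly.initial_amount()
    if base == 0.0:
        base = 1.0
    step_results: list[StepResult] = []
    assemblies: list[Assembly] = []
    removed_log: list[float] = []
    for step in scenario.steps:
        assembly, state, removed = apply_transforms(assembly, state, step)
        removed_log.append(removed / base)
        state = replace(state, time=0.0)  # each step runs in its own clock
        res = solve_step(assembly, step.duration, grid=grid, state=state, base=base)
        step_results.append(res)
        assemblies.append(assembly)
        state = res.final_state
    return ScenarioResult(
        scenario=scenario,
        step_results=step_results,
        assemblies=assemblies,
        removed=removed_log,
        base=base,
    )


def distribute_equilibrium_initial(
    total_amount: float, assembly: Assembly, subset: tuple[int, ...] | None = None
) -> Assembly:
    """Return a copy of ``assembly`` whose initial concentrations place
    ``total_amount`` (kg·m⁻²) at uniform activity within ``subset``
    (1-based layer indices; default all layers) and zero elsewhere.

    This encodes the standard loading assumption that a migrant endogenous
    to a multilayer part is distributed between its layers according to
    their relative chemical affinity (capacity ``l_j/k_j``).
    """
    if subset is None:
        subset = tuple(range(1, assembly.m + 1))
    if len(subset) == 0:
        raise ValueError("subset must be non-empty")
    for i in subset:
        if not 1 <= i <= assembly.m:
            raise ValueError(f"no layer {i} in the assembly")
    cap = sum(assembly.layers[i - 1].thickness / assembly.layers[i - 1].henry_k for i in subset)
    if cap <= 0:
        raise ValueError("zero-capacity subset")
    activity = total_amount / cap
    out = assembly
    for i in range(1, assembly.m + 1):
        c = activity / assembly.layers[i - 1].henry_k if i in subset else 0.0
        out = out.replace_layer(i, initial_concentration=c)
    return out
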