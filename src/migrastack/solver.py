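"""Transient finite-volume solver for one-dimensional diffusion with
partitioning discontinuities at layer interfaces.

Formulation
-----------
The solver works on the activity ``a = k·C`` rather than on the
concentration.  Within a layer, Fick's law ``F = −D ∂C/∂x`` becomes
``F = −(D/k) ∂a/∂x``; across an interface, local thermodynamic equilibrium
(continuity of activity) plus flux continuity are encoded by a series
half-cell conductance

    G = 1 / [ (Δx_j/2)·k_j/D_j + (Δx_{j+1}/2)·k_{j+1}/D_{j+1} ]

applied to the activity difference of the adjacent cell averages, so that
the steady state satisfies ``C_j/C_{j+1} = k_{j+1}/k_j`` at every interface
by construction.  The well-mixed fluid compartment (capacity ``l₀/k₀``) is
coupled through the Robin condition, adding the film resistance ``k₀/h``
in series with the first half cell; the far boundary is zero-flux
(impervious/symmetric) or wraps around to the contact face (periodic,
set-off configuration).

With cell capacities ``c_i = Δx_i/k_i`` the semi-discrete system is
``diag(c) · da/dt = L·a`` with L a symmetric weighted graph Laplacian, so
the scheme conserves mass exactly in space; time integration uses BDF
(adaptive implicit multistep) with the constant sparse Jacobian, which
handles the up-to-10⁸ diffusivity contrast between air and glassy
polymers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.integrate import solve_ivp

from .core import Assembly, KineticsResult, SimulationState

__all__ = [
    "GridSpec",
    "StepResult",
    "solve_step",
    "superpose",
    "mass_balance",
    "short_time_rate",
    "time_to_fraction",
]


@dataclass(frozen=True)
class GridSpec:
    """Discretisation and solver controls.

    ``nodes_per_layer`` is either one integer applied to every layer or a
    sequence of per-layer counts (min 3 enforced).  Output times follow a
    geometric schedule spanning ``output_decades`` decades up to the step
    duration.  ``negative_tol`` is the largest tolerated undershoot of the
    normalised concentration before the run is declared failed (clipping
    is never applied).
    """

    nodes_per_layer: int | tuple[int, ...] = 20
    n_output: int = 61
    output_decades: float = 6.0
    rtol: float = 1e-8
    atol_factor: float = 1e-13
    negative_tol: float = 1e-9
    max_step: float = np.inf

    def nodes_for(self, assembly: Assembly) -> np.ndarray:
        if np.isscalar(self.nodes_per_layer):
            n = np.full(assembly.m, int(self.nodes_per_layer))
        else:
            n = np.asarray(self.nodes_per_layer, dtype=int)
            if len(n) != assembly.m:
                raise ValueError("nodes_per_layer length must match the number of layers")
        if np.any(n < 3):
            raise ValueError("at least 3 nodes per layer are required")
        return n

    def output_times(self, duration: float) -> np.ndarray:
        t = np.geomspace(duration * 10.0 ** (-self.output_decades), duration, self.n_output)
        t[-1] = duration
        return np.concatenate(([0.0], t))


@dataclass
class StepResult:
    """Trajectory of one solve: states at the output times plus the
    normalised kinetics."""

    kinetics: KineticsResult
    states: list[SimulationState]

    @property
    def final_state(self) -> SimulationState:
        return self.states[-1]


class _System:
    """Assembled FV operator for one assembly on one grid."""

    def __init__(self, assembly: Assembly, nodes: np.ndarray):
        self.assembly = assembly
        self.nodes = nodes
        self.has_fluid = assembly.fluid is not None
        self.n_cells = int(nodes.sum())
        self.n = self.n_cells + (1 if self.has_fluid else 0)
        # cell geometry, contact-first; fluid unknown is appended last
        widths, ks, ds = [], [], []
        self.slices: list[slice] = []
        self.edges: list[np.ndarray] = []
        start = 0
        x0 = 0.0
        for lay, nj in zip(assembly.layers, nodes):
            dx = lay.thickness / nj
            widths.append(np.full(nj, dx))
            ks.append(np.full(nj, lay.henry_k))
            ds.append(np.full(nj, lay.diffusivity))
            self.slices.append(slice(start, start + nj))
            self.edges.append(x0 + dx * np.arange(nj + 1))
            start += nj
            x0 += lay.thickness
        self.widths = np.concatenate(widths)
        self.k = np.concatenate(ks)
        self.d = np.concatenate(ds)
        # capacities: mass in cell i = c_i * a_i
        cap = self.widths / self.k
        if self.has_fluid:
            cap = np.concatenate([cap, [assembly.fluid.equiv_thickness / assembly.fluid.henry_k]])
        self.capacity = cap
        self.laplacian = self._build_laplacian()
        self.operator = sparse.csc_matrix(
            sparse.diags(1.0 / self.capacity) @ self.laplacian
        )

    def _half_resistance(self, i: int) -> float:
        return 0.5 * self.widths[i] * self.k[i] / self.d[i]

    def _build_laplacian(self) -> sparse.csc_matrix:
        rows, cols, vals = [], [], []

        def link(i: int, j: int, g: float) -> None:
            rows.extend([i, j, i, j])
            cols.extend([j, i, i, j])
            vals.extend([g, g, -g, -g])

        for i in range(self.n_cells - 1):
            g = 1.0 / (self._half_resistance(i) + self._half_resistance(i + 1))
            link(i, i + 1, g)
        asm = self.assembly
        if self.has_fluid:
            h = asm.fluid.transfer_coefficient(asm.layers[0])
            g = 1.0 / (asm.fluid.henry_k / h + self._half_resistance(0))
            link(self.n_cells, 0, g)
        if asm.boundary_far == "periodic":
            g = 1.0 / (self._half_resistance(0) + self._half_resistance(self.n_cells - 1))
            link(0, self.n_cells - 1, g)
        return sparse.csc_matrix(
            sparse.coo_matrix((vals, (rows, cols)), shape=(self.n, self.n))
        )

    # -- state mapping ------------------------------------------------------

    def initial_activity(self, state: SimulationState | None) -> np.ndarray:
        a = np.empty(self.n)
        if state is None:
            for sl, lay in zip(self.slices, self.assembly.layers):
                a[sl] = lay.henry_k * np.asarray(lay.initial_concentration, dtype=float)
            if self.has_fluid:
                a[-1] = self.assembly.fluid.henry_k * self.assembly.fluid.initial_concentration
        else:
            if len(state.concentrations) != self.assembly.m:
                raise ValueError("state is incompatible with the assembly (layer count)")
            for sl, lay, c in zip(self.slices, self.assembly.layers, state.concentrations):
                c = np.asarray(c, dtype=float)
                nj = sl.stop - sl.start
                if c.ndim == 0:
                    a[sl] = lay.henry_k * float(c)
                elif len(c) == nj:
                    a[sl] = lay.henry_k * c
                else:
                    # conservative remap onto this grid
                    a[sl] = lay.henry_k * _remap_cell_average(c, nj)
            if self.has_fluid:
                c0 = state.fluid_concentration
                c0 = 0.0 if c0 is None else c0
                a[-1] = self.assembly.fluid.henry_k * c0
        return a

    def state_at(self, t: float, a: np.ndarray) -> SimulationState:
        conc = [a[sl] / lay.henry_k for sl, lay in zip(self.slices, self.assembly.layers)]
        fluid_c = float(a[-1] / self.assembly.fluid.henry_k) if self.has_fluid else None
        return SimulationState(
            time=t,
            edges=[e.copy() for e in self.edges],
            concentrations=conc,
            fluid_concentration=fluid_c,
        )

    def layer_amounts(self, a: np.ndarray) -> np.ndarray:
        cap_a = self.capacity[: self.n_cells] * a[: self.n_cells]
        return np.array([float(cap_a[sl].sum()) for sl in self.slices])

    def fluid_amount(self, a: np.ndarray) -> float | None:
        if not self.has_fluid:
            return None
        return float(self.capacity[-1] * a[-1])


def _remap_cell_average(values: np.ndarray, n_new: int) -> np.ndarray:
    """Conservative remap of a cell-average profile onto ``n_new`` equal
    cells of the same interval (piecewise-constant reconstruction)."""
    n_old = len(values)
    edges_old = np.linspace(0.0, 1.0, n_old + 1)
    cum = np.concatenate(([0.0], np.cumsum(values * np.diff(edges_old))))
    edges_new = np.linspace(0.0, 1.0, n_new + 1)
    cum_new = np.interp(edges_new, edges_old, cum)
    return np.diff(cum_new) / np.diff(edges_new)


def solve_step(
    assembly: Assembly,
    duration: float,
    *,
    grid: GridSpec | None = None,
    state: SimulationState | None = None,
    t_eval: np.ndarray | None = None,
    base: float | None = None,
) -> StepResult:
    """Integrate one contact/storage period.

    Parameters
    ----------
    assembly:
        Stack to simulate (with its boundary conditions and optional fluid).
    duration:
        Step duration in seconds (dimensionless setups simply use Fo).
    grid:
        Discretisation controls; defaults to :class:`GridSpec()`.
    state:
        Profile inherited from a previous step; ``None`` starts from the
        layers' declared initial concentrations.
    t_eval:
        Output times (s), strictly increasing, within ``[0, duration]``;
        defaults to the grid's geometric schedule.
    base:
        Normalisation base (kg·m⁻²) for the kinetics; defaults to the total
        amount present at the start of this step.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    grid = grid or GridSpec()
    sys_ = _System(assembly, grid.nodes_for(assembly))
    a0 = sys_.initial_activity(state)
    t0 = 0.0 if state is None else state.time
    if t_eval is None:
        times = t0 + grid.output_times(duration)
    else:
        times = np.asarray(t_eval, dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError("output times must be strictly increasing")
        if times[0] > t0:
            times = np.concatenate(([t0], times))
    a_scale = float(np.max(np.abs(a0)))
    if a_scale == 0.0:
        # null input: nothing moves
        a_traj = np.zeros((sys_.n, len(times)))
    else:
        op = sys_.operator
        sol = solve_ivp(
            lambda t, y: op @ y,
            (t0, t0 + duration),
            a0,
            method="BDF",
            t_eval=times,
            jac=op,
            rtol=grid.rtol,
            atol=grid.atol_factor * a_scale,
            max_step=grid.max_step,
        )
        if not sol.success:
            raise RuntimeError(f"stiff integration failed: {sol.message}")
        a_traj = sol.y
        undershoot = float(a_traj.min()) / a_scale
        if undershoot < -grid.negative_tol:
            raise RuntimeError(
                f"negative concentration beyond tolerance: min(u) = {undershoot:.3e}"
            )
    if base is None:
        base = float(np.sum(sys_.capacity * a0))
    norm = base if base != 0.0 else 1.0
    amounts = np.stack([sys_.layer_amounts(a_traj[:, i]) for i in range(len(times))], axis=1)
    fluid_amt = None
    fluid_conc = None
    if sys_.has_fluid:
        fluid_amt = sys_.capacity[-1] * a_traj[-1, :] / norm
        fluid_conc = a_traj[-1, :] / assembly.fluid.henry_k
    kin = KineticsResult(
        times=times,
        layer_amounts=amounts / norm,
        fluid_amount=fluid_amt,
        base=base,
        layer_labels=tuple(lay.material for lay in assembly.layers),
        fluid_concentration=fluid_conc,
    )
    states = [sys_.state_at(t, a_traj[:, i]) for i, t in enumerate(times)]
    return StepResult(kinetics=kin, states=states)


def superpose(*results: KineticsResult) -> KineticsResult:
    """Sum the kinetics of independent sources simulated in the same
    assembly (superposition holds because the transport problem is linear
    in concentration).  Geometry and output times must match exactly."""
    if len(results) < 1:
        raise ValueError("need at least one result")
    first = results[0]
    for r in results[1:]:
        if r.layer_amounts.shape != first.layer_amounts.shape:
            raise ValueError("mismatched geometry between results")
        if not np.array_equal(r.times, first.times):
            raise ValueError("mismatched time grids between results")
        if (r.fluid_amount is None) != (first.fluid_amount is None):
            raise ValueError("mismatched fluid compartments between results")
    base = sum(r.base for r in results)
    norm = base if base != 0.0 else 1.0
    layer_amounts = sum(r.layer_amounts * (r.base if r.base != 0.0 else 1.0) for r in results) / norm
    fluid_amount = None
    fluid_conc = None
    if first.fluid_amount is not None:
        fluid_amount = sum(r.fluid_amount * (r.base if r.base != 0.0 else 1.0) for r in results) / norm
        fluid_conc = sum(r.fluid_concentration for r in results)
    return KineticsResult(
        times=first.times.copy(),
        layer_amounts=layer_amounts,
        fluid_amount=fluid_amount,
        base=base,
        layer_labels=first.layer_labels,
        fluid_concentration=fluid_conc,
    )


def mass_balance(kinetics: KineticsResult, expected: float | None = None) -> float:
    """Largest absolute deviation of the tracked normalised total from
    ``expected`` (default: its initial value).  Closed systems should stay
    below ~1e-6."""
    tot = kinetics.total()
    if expected is None:
        expected = tot[0]
    return float(np.max(np.abs(tot - expected)))


def short_time_rate(
    source_thickness: float,
    source_henry_k: float,
    air_thickness: float,
    air_diffusivity: float,
    air_henry_k: float,
) -> float:
    """Initial fractional depletion rate of a source layer feeding an air
    gap under the quasi-steady gas-film approximation (s⁻¹):

        (1 − C(t)/C(0)) ≈ (h_air/l_source) · (k_source/RT) · t

    with ``h_air = D_air/l_air`` the gas-gap conductance.  This is a fast
    screening estimate for short contacts, valid while the receiving side
    stays dilute; it is proportional to the solute volatility through
    ``k_source = p_sat·V̄·exp(1+χ)``.
    """
    if air_thickness <= 0:
        raise ValueError("air gap thickness must be > 0")
    h_air = air_diffusivity / air_thickness
    return h_air * source_henry_k / (air_henry_k * source_thickness)


def time_to_fraction(
    times: np.ndarray, amounts: np.ndarray, target: float, fraction: float = 0.95
) -> float:
    """First time a (monotone) uptake curve reaches ``fraction`` of the
    ``target`` (typically the analytic equilibrium amount); log-time
    interpolation between output samples.  Returns ``inf`` if never
    reached within the trajectory."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    threshold = fraction * target
    above = amounts >= threshold
    if not above.any():
        return math.inf
    i = int(np.argmax(above))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = amounts[i - 1], amounts[i]
    if y1 == y0:
        return float(t1)
    if t0 <= 0:
        return float(t0 + (threshold - y0) * (t1 - t0) / (y1 - y0))
    w = (threshold - y0) / (y1 - y0)
    return float(math.exp(math.log(t0) + w * (math.log(t1) - math.log(t0))))
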