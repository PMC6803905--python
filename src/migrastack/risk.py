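"""Probabilistic cross-contamination: random contact times, exceedance
probabilities and percentile kinetics.

Storage (loading) times between an overpackaging and a bag are rarely
known; they are modelled as a random variable ``t₁ = t̄₁ · t₁*`` with
``t₁*`` a unit-scale Weibull variate.  Because the loading map
``Ω: t₁ ↦ transferred amount`` is monotone, the distribution of the
loaded amount is the push-forward of the contact-time distribution, so

    Pr(m(t₁) ≥ m) = 1 − F_{t₁}(Ω⁻¹(m))

and the q-th percentile of the loaded amount is ``Ω(quantile(q))`` — no
Monte-Carlo is needed (sampling is retained as a cross-check oracle).
The percentile-kinetics procedure re-simulates the loading step exactly up
to ``t₁(q)`` and uses the resulting concentration profile as the initial
condition of the migration step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.stats import weibull_min

from .core import KineticsResult, Scenario
from .engine import run_scenario
from .solver import GridSpec, solve_step

__all__ = [
    "ContactTimeDistribution",
    "LoadingMap",
    "build_loading_map",
    "exceedance_probability",
    "sample_contact_times",
    "percentile_kinetics",
]


@dataclass(frozen=True)
class ContactTimeDistribution:
    """Weibull contact-time model: ``t₁ = scale · (−ln(1−q))^(1/shape)``.

    ``shape = inf`` is the degenerate (point-mass) limit, useful to reduce
    the probabilistic pipeline to the deterministic scenario.
    """

    scale: float
    shape: float = 3.0

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if not self.shape > 0:
            raise ValueError("shape must be > 0")

    @property
    def is_point_mass(self) -> bool:
        return math.isinf(self.shape)

    def quantile(self, q: float | np.ndarray) -> float | np.ndarray:
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile level must be in (0, 1)")
        if self.is_point_mass:
            out = np.full_like(q, self.scale)
        else:
            out = self.scale * (-np.log1p(-q)) ** (1.0 / self.shape)
        return float(out) if out.ndim == 0 else out

    def cdf(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.is_point_mass:
            out = (t >= self.scale).astype(float)
        else:
            out = weibull_min.cdf(t, c=self.shape, scale=self.scale)
        return float(out) if out.ndim == 0 else out

    def pdf(self, t: float | np.ndarray) -> float | np.ndarray:
        if self.is_point_mass:
            raise ValueError("point-mass distribution has no density")
        return weibull_min.pdf(t, c=self.shape, scale=self.scale)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-transform draws (reproducible given the generator)."""
        if not n > 0:
            raise ValueError("n must be > 0")
        u = rng.uniform(size=n)
        if self.is_point_mass:
            return np.full(n, self.scale)
        return self.scale * (-np.log1p(-u)) ** (1.0 / self.shape)


def sample_contact_times(
    distribution: ContactTimeDistribution, n: int, seed: int
) -> np.ndarray:
    """Reproducible contact-time draws via inverse transform."""
    return distribution.sample(n, np.random.default_rng(seed))


@dataclass
class LoadingMap:
    """Tabulated monotone map Ω: contact time → normalised loaded amount,
    with Ω(0) = 0, plus its monotone (PCHIP) interpolant and inverse."""

    times: np.ndarray
    amounts: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        m = np.asarray(self.amounts, dtype=float)
        if t[0] != 0.0:
            t = np.concatenate(([0.0], t))
            m = np.concatenate(([0.0], m))
        if np.any(np.diff(t) <= 0):
            raise ValueError("loading-map times must be strictly increasing")
        if np.any(np.diff(m) < -1e-8 * max(m.max(), 1e-300)):
            raise ValueError("loading map must be non-decreasing")
        m = np.maximum.accumulate(m)  # flatten round-off wiggles only
        self.times, self.amounts = t, m
        self._omega = PchipInterpolator(t, m, extrapolate=False)

    @property
    def max_amount(self) -> float:
        return float(self.amounts[-1])

    def omega(self, t: float | np.ndarray) -> float | np.ndarray:
        t = np.clip(np.asarray(t, dtype=float), 0.0, self.times[-1])
        out = self._omega(t)
        return float(out) if out.ndim == 0 else out

    def inverse(self, m: float) -> float:
        """Smallest t with Ω(t) = m (monotone root bracketing on the
        interpolant)."""
        if m <= 0.0:
            return 0.0
        if m > self.max_amount:
            return math.inf
        i = int(np.searchsorted(self.amounts, m))
        lo, hi = self.times[max(i - 1, 0)], self.times[min(i, len(self.times) - 1)]
        if hi <= lo:
            return float(lo)
        from scipy.optimize import brentq

        f = lambda t: self._omega(t) - m
        if f(lo) >= 0:
            return float(lo)
        return float(brentq(f, lo, hi, xtol=1e-12 * max(hi, 1.0)))


def build_loading_map(
    scenario: Scenario,
    receiving_layers: tuple[int, ...],
    t_grid: np.ndarray | None = None,
    *,
    t_scale: float | None = None,
    grid: GridSpec | None = None,
) -> LoadingMap:
    """Tabulate Ω from the scenario's loading (first) step.

    ``receiving_layers`` are the 1-based indices of the receiving part
    (e.g. the bag wall).  ``t_grid`` defaults to a geometric grid spanning
    [1e−3, 1e2]·``t_scale`` (``t_scale`` defaults to the step duration)."""
    if t_grid is None:
        ref = t_scale if t_scale is not None else scenario.steps[0].duration
        t_grid = np.geomspace(1e-3 * ref, 1e2 * ref, 49)
    t_grid = np.asarray(t_grid, dtype=float)
    step = scenario.steps[0]
    res = solve_step(
        scenario.assembly,
        float(t_grid[-1]),
        grid=grid,
        t_eval=t_grid,
        base=scenario.assembly.initial_amount(),
    )
    kin = res.kinetics
    loaded = kin.fraction_in(receiving_layers)
    return LoadingMap(times=kin.times, amounts=loaded)


def exceedance_probability(
    m: float, loading_map: LoadingMap, distribution: ContactTimeDistribution
) -> float:
    """``Pr(loaded amount ≥ m) = 1 − F_{t₁}(Ω⁻¹(m))`` by monotone
    change of variables on the loading map."""
    if m < 0:
        raise ValueError("m must be >= 0")
    if m <= 0.0:
        return 1.0
    t = loading_map.inverse(m)
    if math.isinf(t):
        return 0.0
    return float(1.0 - distribution.cdf(t))


def percentile_kinetics(
    scenario: Scenario,
    distribution: ContactTimeDistribution,
    percentile: float,
    grid: GridSpec | None = None,
) -> KineticsResult:
    """Migration kinetics at a given percentile of the contact-time
    distribution.

    The loading (first) step is re-run with its duration set to the exact
    contact-time quantile ``t₁(q)``; the resulting profile seeds the
    remaining steps.  Returns the kinetics of the final (migration) step.
    """
    if not 0.0 < percentile < 1.0:
        raise ValueError("percentile must be in (0, 1)")
    if len(scenario.steps) < 2:
        raise ValueError("scenario must contain a loading step followed by a migration step")
    t1 = distribution.quantile(percentile)
    steps = (replace(scenario.steps[0], duration=float(t1)),) + scenario.steps[1:]
    result = run_scenario(replace(scenario, steps=steps), grid=grid)
    return result.step_results[-1].kinetics
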