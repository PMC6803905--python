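import numpy as np
import pytest

import migrastack as ms


@pytest.fixture
def unit_slab():
    """Single dimensionless layer loaded uniformly at C=1."""
    return ms.Layer(material="P", thickness=1.0, henry_k=1.0, diffusivity=1.0,
                    initial_concentration=1.0)


@pytest.fixture
def desorption_assembly(unit_slab):
    """Plane-sheet desorption setup: impervious back, near-infinite stirred
    fluid with K=1 and Bi=1000."""
    fluid = ms.Fluid(equiv_thickness=1e6, henry_k=1.0, biot=1000.0)
    return ms.build_assembly([unit_slab], fluid=fluid)


def crank_release(fo: float, terms: int = 400) -> float:
    """Fraction released from a plane sheet with the surface activity
    clamped at zero and an impervious back (classical series solution)."""
    n = np.arange(terms)
    lam = ((2 * n + 1) * np.pi / 2) ** 2
    return float(1.0 - np.sum(8.0 / ((2 * n + 1) ** 2 * np.pi**2) * np.exp(-lam * fo)))


@pytest.fixture
def crank():
    return crank_release
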