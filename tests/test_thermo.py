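"""Sorption thermodynamics: Henry coefficients, partition ratios, analytic
equilibria, Fuller diffusivities and resistance tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import migrastack as ms
from migrastack.core import Layer
from migrastack.thermo import AIR_DIFFUSION_VOLUME

positive = st.floats(min_value=1e-3, max_value=1e3)


class TestHenry:
    def test_chi_minus_one_cancels_exponent(self):
        assert ms.henry_coefficient(-1.0, 7.0, 0.3) == pytest.approx(7.0 * 0.3)

    def test_air_is_rt(self):
        assert ms.air_henry(313.15) == pytest.approx(8.314 * 313.15)
        assert ms.air_henry(313.15) == pytest.approx(2603.5, abs=0.1)

    def test_caprolactam_value(self):
        # p_sat and molar volume of the PA6 monomer at 25 °C
        k = ms.henry_coefficient(-0.19, 0.483, 1.06e-4)
        assert k == pytest.approx(0.483 * 1.06e-4 * math.exp(0.81))

    def test_preconditions(self):
        with pytest.raises(ValueError):
            ms.henry_coefficient(0.0, -1.0, 1.0)
        with pytest.raises(ValueError):
            ms.henry_coefficient(0.0, 1.0, 0.0)


class TestPolymerPartition:
    def test_equal_chi_gives_unity(self):
        assert ms.polymer_partition(0.3, 0.3) == pytest.approx(1.0)

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_symmetry(self, a, b):
        assert ms.polymer_partition(a, b) * ms.polymer_partition(b, a) == pytest.approx(1.0)


class TestEquilibrium:
    def test_symmetric_split(self):
        lay = Layer(material="P", thickness=1.0, henry_k=1.0, diffusivity=1.0,
                    initial_concentration=1.0)
        asm = ms.build_assembly([lay, lay])
        eq = ms.equilibrium_distribution(asm)
        np.testing.assert_allclose(eq.fractions, [0.5, 0.5])

    def test_activity_uniform_and_fractions_sum_to_one(self):
        asm = ms.fixture("T1_caprolactam", air_gap_mm=5.0).assembly
        eq = ms.equilibrium_distribution(asm)
        acts = eq.concentrations * asm.henry_coefficients()
        assert np.ptp(acts) / acts.mean() < 1e-12
        assert eq.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    @given(
        l=st.tuples(positive, positive, positive),
        k=st.tuples(positive, positive, positive),
        l0=positive,
        k0=positive,
        m1=positive,
        m2=positive,
        m3=positive,
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_two_and_three_layer_closed_forms(self, l, k, l0, k0, m1, m2, m3):
        """The uniform-activity split reproduces the classical residual and
        transferred-amount formulas for bilayer and trilayer stacks with and
        without a fluid, on random parameter draws."""
        l1, l2, l3 = l
        k1, k2, k3 = k
        total2 = m1 + m2

        def layers(specs):
            return [
                Layer(material=f"L{i}", thickness=li, henry_k=ki, diffusivity=1.0,
                      initial_concentration=mi / li)
                for i, (li, ki, mi) in enumerate(specs)
            ]

        # bilayer, closed: residual in layer 2 and complement in layer 1
        asm = ms.build_assembly(layers([(l1, k1, m1), (l2, k2, m2)]))
        eq = ms.equilibrium_distribution(asm)
        m2_res = total2 / (1 + l1 * k2 / (l2 * k1))
        m1_res = total2 / (1 + l2 * k1 / (l1 * k2))
        assert eq.fractions[1] * total2 == pytest.approx(m2_res, rel=1e-10)
        assert eq.fractions[0] * total2 == pytest.approx(m1_res, rel=1e-10)

        # bilayer + fluid: transferred amount to the fluid
        fl = ms.Fluid(equiv_thickness=l0, henry_k=k0, biot=1.0)
        asm_f = ms.build_assembly(layers([(l1, k1, m1), (l2, k2, m2)]), fluid=fl)
        eq_f = ms.equilibrium_distribution(asm_f)
        m0 = total2 / (1 + l1 * k0 / (l0 * k1) + l2 * k0 / (l0 * k2))
        m2_f = total2 / (1 + l1 * k2 / (l2 * k1) + l0 * k2 / (l2 * k0))
        assert eq_f.fluid_fraction * total2 == pytest.approx(m0, rel=1e-10)
        assert eq_f.fractions[1] * total2 == pytest.approx(m2_f, rel=1e-10)

        # trilayer, closed: residual in the far layer
        total3 = m1 + m2 + m3
        asm3 = ms.build_assembly(layers([(l1, k1, m1), (l2, k2, m2), (l3, k3, m3)]))
        eq3 = ms.equilibrium_distribution(asm3)
        m3_res = total3 / (1 + l1 * k3 / (l3 * k1) + l2 * k3 / (l3 * k2))
        m1_res3 = total3 / (1 + l3 * k1 / (l1 * k3) + l2 * k1 / (l1 * k2))
        assert eq3.fractions[2] * total3 == pytest.approx(m3_res, rel=1e-10)
        assert eq3.fractions[0] * total3 == pytest.approx(m1_res3, rel=1e-10)

    def test_missing_fluid_fraction_none_without_fluid(self):
        lay = Layer(material="P", thickness=1.0, henry_k=2.0, diffusivity=1.0)
        eq = ms.equilibrium_distribution(ms.build_assembly([lay]))
        assert eq.fluid_fraction is None


class TestEffectiveHenry:
    def test_uniform_k_is_identity(self):
        assert ms.effective_henry([0.2, 0.8], [3.0, 3.0]) == pytest.approx(3.0)

    def test_harmonic_mean(self):
        assert ms.effective_henry([0.5, 0.5], [1.0, 3.0]) == pytest.approx(1.5)

    @given(phi1=st.floats(0.05, 0.95), k1=positive, k2=positive)
    @settings(max_examples=50, deadline=None)
    def test_inverse_round_trip(self, phi1, k1, k2):
        phi = [phi1, 1.0 - phi1]
        keff = ms.effective_henry(phi, [k1, k2])
        assert ms.missing_henry(keff, phi, [k1, None]) == pytest.approx(k2, rel=1e-9)

    def test_inverse_rejects_multiple_unknowns(self):
        with pytest.raises(ValueError):
            ms.missing_henry(1.0, [0.5, 0.5], [None, None])


class TestFuller:
    def test_pressure_and_temperature_scaling(self):
        d1 = ms.fuller_gas_diffusivity(100.0, 50.0, 313.0, 101325.0)
        assert ms.fuller_gas_diffusivity(100.0, 50.0, 313.0, 2 * 101325.0) == pytest.approx(d1 / 2)
        assert ms.fuller_gas_diffusivity(100.0, 50.0, 626.0, 101325.0) == pytest.approx(
            d1 * 2**1.75
        )

    def test_caprolactam_in_air(self):
        # azepan-2-one C6H11NO with one heterocyclic ring; tabulated
        # reference 8.12e-6 m²/s at 40 °C, 15% tolerance for increment sets
        sv = ms.diffusion_volume({"C": 6, "H": 11, "N": 1, "O": 1}, rings=1)
        d = ms.fuller_gas_diffusivity(113.16, sv, 313.15)
        assert d == pytest.approx(8.12e-6, rel=0.15)

    def test_air_constants(self):
        assert AIR_DIFFUSION_VOLUME == 19.7


class TestResistances:
    def test_reference_layer_against_itself(self):
        air = Layer(material="air", thickness=1e-4, henry_k=ms.air_henry(313.15),
                    diffusivity=8.12e-6)
        asm = ms.build_assembly([air])
        assert ms.resistance_ratios(asm)[0] == pytest.approx(1.0)

    def test_t1_table(self):
        asm = ms.fixture("T1_caprolactam", air_gap_mm=0.1).assembly
        r = ms.resistance_ratios(asm, rounded=True)
        # PA6 (index 5) excluded: printed value is not reproducible from the
        # exact thickness ratios
        np.testing.assert_array_equal(r[[0, 1, 2, 3, 4, 6]], [50, 46, 6, 1, 7, 4])

    def test_t2_table(self):
        asm = ms.fixture("T2_caprolactam", air_gap_mm=0.1).assembly
        r = ms.resistance_ratios(asm, rounded=True)
        np.testing.assert_array_equal(r[[0, 1, 2, 3, 4, 6]], [47, 229, 22, 1, 7, 4])

    def test_requires_reference_when_no_air(self):
        lay = Layer(material="P", thickness=1.0, henry_k=1.0, diffusivity=1.0)
        with pytest.raises(ValueError):
            ms.resistance_ratios(ms.build_assembly([lay]))


class TestApparentPartition:
    def test_single_layer_equal_k_is_unity(self):
        lay = Layer(material="P", thickness=1.0, henry_k=2.0, diffusivity=1.0,
                    initial_concentration=1.0)
        fl = ms.Fluid(equiv_thickness=5.0, henry_k=2.0, biot=1.0)
        asm = ms.build_assembly([lay], fluid=fl)
        assert ms.apparent_partition(asm) == pytest.approx(1.0)

    def test_consistent_with_effective_henry(self):
        # K_F/P,app must equal k_eff/k_0 for any stack
        lays = [
            Layer(material="A", thickness=0.3, henry_k=2.0, diffusivity=1.0,
                  initial_concentration=1.0),
            Layer(material="B", thickness=0.7, henry_k=0.5, diffusivity=1.0),
        ]
        fl = ms.Fluid(equiv_thickness=2.0, henry_k=1.3, biot=1.0)
        asm = ms.build_assembly(lays, fluid=fl)
        keff = ms.effective_henry([0.3, 0.7], [2.0, 0.5])
        assert ms.apparent_partition(asm) == pytest.approx(keff / 1.3, rel=1e-12)
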