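"""Descriptor arithmetic: SET mapping, dipolar correction, aggregation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from iset.descriptor import (
    AtomElectronicState,
    DipolarContext,
    SetMap,
    atom_contribution,
    compute_descriptor,
    dipolar_function,
    effective_sets,
    local_dipole,
    set_from_charge,
    total_iset,
)
from iset.molgraph import CarbonCategory, MoleculeGraph, parse_structure
from iset.synthetic import SynthSpec, sidecar_from_states, synth_molecule

from conftest import brute_iset

# Published 4-decimal reference values for the 3-hexanone walkthrough:
# (atom index in SMILES order, element, contribution)
HEXANONE_CONTRIBUTIONS = {
    1: 0.9891,   # C1 methyl
    2: 0.5860,   # C2 methylene next to the carbonyl
    3: 0.6799,   # carbonyl carbon
    4: 1.5416,   # carbonyl oxygen
    5: 0.5444,   # C4 methylene
    6: 0.8986,   # C5 methylene
    7: 0.9535,   # C6 methyl
}


class TestLocalDipole:
    @pytest.mark.parametrize(
        "d, qc, qx, expected",
        [
            (1.2342, 0.224, -0.288, 0.6319),  # 3-hexanone carbonyl
            (2.0, 0.1, -0.1, 0.4),
            (1.5, 0.2, 0.2, 0.0),
        ],
    )
    def test_values(self, d, qc, qx, expected):
        assert local_dipole(d, qc, qx) == pytest.approx(expected, abs=5e-5)

    def test_nonpositive_bond_length_rejected(self):
        with pytest.raises(ValueError):
            local_dipole(0.0, 0.2, -0.3)


class TestDipolarFunction:
    @pytest.mark.parametrize(
        "mu, mu_f, expected",
        [
            (2.6790, 0.63191, 1.7193),
            (0.0, 0.5, 1.0),
            (9.0, 1.0, 2.0),       # 1 + log10(10)
            (0.09, 0.01, 2.0),
        ],
    )
    def test_values(self, mu, mu_f, expected):
        assert dipolar_function(mu, mu_f) == pytest.approx(expected, abs=5e-5)

    def test_zero_mu_f_with_polar_molecule_is_singular(self):
        with pytest.raises(ZeroDivisionError, match="polar-group"):
            dipolar_function(2.0, 0.0)

    @given(
        mu1=st.floats(0.01, 10.0), mu2=st.floats(0.01, 10.0),
        mu_f=st.floats(0.05, 2.0),
    )
    def test_monotone_in_mu(self, mu1, mu2, mu_f):
        lo, hi = sorted((mu1, mu2))
        assert dipolar_function(lo, mu_f) <= dipolar_function(hi, mu_f)
        assert dipolar_function(hi, mu_f) >= 1.0


class TestSetMap:
    def test_override_wins(self):
        m = SetMap(linear={"CH3": (0.5, 1.0)}, overrides={1: 0.9892})
        assert set_from_charge(-0.2, CarbonCategory.CH3, m, index=1) == 0.9892

    @pytest.mark.parametrize(
        "q, slope, intercept, expected",
        [(0.0, 2.0, 0.7, 0.7), (0.1, -1.0, 1.0, 0.9)],
    )
    def test_linear_mode(self, q, slope, intercept, expected):
        m = SetMap(linear={"CH2": (slope, intercept)})
        got = set_from_charge(q, CarbonCategory.CH2, m, index=2)
        assert got == pytest.approx(expected)

    def test_missing_category_and_domain_errors(self):
        m = SetMap(linear={"CH3": (1.0, 1.0)}, charge_domain=(-0.5, 0.5))
        with pytest.raises(KeyError):
            set_from_charge(0.0, CarbonCategory.CH2, m)
        with pytest.raises(ValueError, match="domain"):
            set_from_charge(0.9, CarbonCategory.CH3, m)
        with pytest.raises(ValueError, match="nonpositive"):
            set_from_charge(-2.0, CarbonCategory.CH3,
                            SetMap(linear={"CH3": (1.0, 1.0)}, charge_domain=(-3, 3)))


class TestEffectiveSets:
    def test_scaled_subset_only(self, hexanone_graph):
        states = [
            AtomElectronicState(i, hexanone_graph.element(i), set_value=1.0)
            for i in hexanone_graph.atom_indices
        ]
        ctx = DipolarContext(mu=2.679, d=1.2342, q_c=0.224, q_x=-0.288)
        out = effective_sets(hexanone_graph, states, ctx)
        by_index = {s.index: s.effective_set for s in out}
        assert by_index[3] == pytest.approx(ctx.a_mu)
        assert by_index[4] == pytest.approx(ctx.a_mu)
        assert all(by_index[i] == 1.0 for i in (1, 2, 5, 6, 7))

    def test_no_context_keeps_raw_values(self, hexanone_graph):
        states = [
            AtomElectronicState(i, hexanone_graph.element(i), set_value=0.9)
            for i in hexanone_graph.atom_indices
        ]
        out = effective_sets(hexanone_graph, states, None)
        assert all(s.effective_set == s.set_value for s in out)

    def test_unknown_scaled_index_rejected(self, hexanone_graph):
        states = [
            AtomElectronicState(i, hexanone_graph.element(i), set_value=1.0)
            for i in hexanone_graph.atom_indices
        ]
        with pytest.raises(KeyError):
            effective_sets(hexanone_graph, states, None, scaled={99})


class TestAggregation:
    def test_hexanone_walkthrough(self, hexanone_graph, hexanone_breakdown):
        bd = hexanone_breakdown
        assert bd.mu_f == pytest.approx(0.6319, abs=5e-5)
        assert bd.a_mu == pytest.approx(1.7193, abs=5e-5)
        for i, expected in HEXANONE_CONTRIBUTIONS.items():
            assert bd.per_atom[i] == pytest.approx(expected, abs=5e-5), i
        assert bd.rounded_total == pytest.approx(6.1931, abs=1e-9)
        assert bd.total == pytest.approx(6.1931, abs=2e-4)

    def test_oxygen_contribution_from_effective_values(self, hexanone_graph):
        # oxygen: own scaled SET plus log10 of the carbonyl carbon's
        eff = {i: 1.0 for i in hexanone_graph.atom_indices}
        eff[4] = 1.9507
        eff[3] = 0.3899
        got = atom_contribution(4, hexanone_graph, eff)
        assert round(got, 4) == pytest.approx(1.5416, abs=1e-4)

    def test_isolated_atom_contribution_is_its_set(self):
        g = MoleculeGraph(elements=("C",), bonds=frozenset())
        assert atom_contribution(1, g, {1: 0.77}) == 0.77
        assert total_iset(g, {1: 0.77}).total == 0.77

    def test_unit_sets_sum_to_atom_count(self):
        g = parse_structure("CCCCC")
        eff = {i: 1.0 for i in g.atom_indices}
        assert total_iset(g, eff).total == pytest.approx(5.0)

    def test_total_equals_sum_of_contributions(self, hexanone_breakdown):
        assert hexanone_breakdown.total == pytest.approx(
            sum(hexanone_breakdown.per_atom.values()), abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_edge_based_oracle_on_random_graphs(self, seed):
        g, states, ctx = synth_molecule(
            SynthSpec(n_atoms=3 + seed % 6, topology="branched",
                      heteroatom_position=None, seed=seed)
        )
        eff = {s.index: s.set_value for s in states}
        got = total_iset(g, eff).total
        assert got == pytest.approx(brute_iset(g.elements, g.bonds, eff), abs=1e-10)

    @pytest.mark.parametrize("seed", range(6))
    def test_total_invariant_under_relabeling(self, seed):
        g, states, _ = synth_molecule(
            SynthSpec(n_atoms=8, topology="branched", seed=seed)
        )
        eff = {s.index: s.set_value for s in states}
        rng = np.random.default_rng(seed)
        perm = {i: int(p) + 1 for i, p in
                zip(g.atom_indices, rng.permutation(g.n_atoms))}
        elements = [""] * g.n_atoms
        for i in g.atom_indices:
            elements[perm[i] - 1] = g.element(i)
        g2 = MoleculeGraph(
            elements=tuple(elements),
            bonds=frozenset(frozenset(perm[i] for i in p) for p in g.bonds),
        )
        eff2 = {perm[i]: v for i, v in eff.items()}
        bd1, bd2 = total_iset(g, eff), total_iset(g2, eff2)
        assert bd1.total == pytest.approx(bd2.total, abs=1e-10)
        for i in g.atom_indices:
            assert bd1.per_atom[i] == pytest.approx(bd2.per_atom[perm[i]], abs=1e-10)


class TestComputeDescriptor:
    def test_alkane_with_unit_sets(self):
        g = parse_structure("CCCC")
        sidecar = {
            "dipole_debye": 0.0,
            "atoms": [{"index": i, "element": "C", "set_value": 1.0}
                      for i in g.atom_indices],
        }
        assert compute_descriptor(g, sidecar).total == pytest.approx(4.0)

    def test_ethanol_matches_hand_computed_sum(self):
        # CCO with SET values (0.98, 0.95, 1.10), mu = 1.7 D, O-C pair
        g = parse_structure("CCO")
        sidecar = {
            "dipole_debye": 1.7,
            "polar_group": {"c_index": 2, "x_index": 3,
                            "bond_length_angstrom": 1.41},
            "atoms": [
                {"index": 1, "element": "C", "set_value": 0.98},
                {"index": 2, "element": "C", "net_charge_e": 0.05,
                 "set_value": 0.95},
                {"index": 3, "element": "O", "net_charge_e": -0.33,
                 "set_value": 1.10},
            ],
        }
        mu_f = 1.41 * abs(0.05 - (-0.33))
        a_mu = 1 + math.log10(1 + 1.7 / mu_f)
        s1, s2, s3 = 0.98, a_mu * 0.95, a_mu * 1.10
        expected = (
            (s1 + math.log10(s2))
            + (s2 + math.log10(s1) + math.log10(s3))
            + (s3 + math.log10(s2))
        )
        bd = compute_descriptor(g, sidecar)
        assert bd.total == pytest.approx(expected, abs=1e-12)
        assert bd.a_mu == pytest.approx(a_mu)

    def test_atom_count_mismatch_rejected(self):
        g = parse_structure("CC")
        sidecar = {"atoms": [{"index": 1, "element": "C", "set_value": 1.0}]}
        with pytest.raises(ValueError, match="mismatch"):
            compute_descriptor(g, sidecar)

    def test_element_mismatch_rejected(self):
        g = parse_structure("CO")
        sidecar = {
            "dipole_debye": 0.0,
            "atoms": [{"index": 1, "element": "C", "set_value": 1.0},
                      {"index": 2, "element": "N", "set_value": 1.0}],
        }
        with pytest.raises(ValueError, match="mismatch"):
            compute_descriptor(g, sidecar)

    def test_zero_dipole_heteromolecule_skips_scaling(self):
        g, states, ctx = synth_molecule(
            SynthSpec(n_atoms=5, heteroatom_position=3, seed=11)
        )
        sidecar = sidecar_from_states(states, ctx)
        sidecar["dipole_debye"] = 0.0
        bd = compute_descriptor(g, sidecar)
        eff = {s.index: s.set_value for s in states}
        assert bd.a_mu == 1.0
        assert bd.total == pytest.approx(total_iset(g, eff).total, abs=1e-12)
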