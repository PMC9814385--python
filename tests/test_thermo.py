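"""Unit tests for the thermodynamic combination layer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rxngen import thermo as th
from rxngen.errors import ConfigurationError, LookupMissingError
from rxngen.reaction import ReactionEquation, Species, parse_reaction_string
from rxngen.synthetic import DEFAULT_LIBRARY, PLANTED_THERMO, generate_thermo_table


@pytest.fixture(scope="module")
def table():
    return th.PropertyTable.from_frame(generate_thermo_table(seed=42))


class TestSpeciesGibbs:
    def test_entropy_free(self):
        t = th.SpeciesThermo("C", 1.0, 0.0, 0.0)
        assert th.gibbs_of_species(t, 500.0) == 1.0

    def test_sign_modes(self):
        t = th.SpeciesThermo("C", 0.0, 0.5 / 298.15, 0.0)
        assert th.gibbs_of_species(t, 298.15, "standard") == pytest.approx(-0.5)
        assert th.gibbs_of_species(t, 298.15, "paper") == pytest.approx(0.5)

    def test_nonpositive_temperature(self):
        t = th.SpeciesThermo("C", 0.0, 0.0, 0.0)
        with pytest.raises(ConfigurationError):
            th.gibbs_of_species(t, 0.0)

    def test_random_against_one_liner(self, rng):
        for _ in range(200):
            h, s = rng.normal(), rng.uniform(0, 0.01)
            T = rng.uniform(1, 1000)
            t = th.SpeciesThermo("C", h, s, 0.0)
            assert th.gibbs_of_species(t, T) == pytest.approx(h - T * s, abs=1e-12)


class TestReactionAggregates:
    def test_identity_reaction_zero(self, table):
        eq = parse_reaction_string("O >> O")
        assert th.reaction_gibbs(eq, table) == 0.0
        assert th.reaction_entropy_diff(eq, table) == 0.0
        assert th.reaction_dipole_diff(eq, table) == 0.0

    def test_coefficient_homogeneity(self, table):
        eq = parse_reaction_string("2[H][H] + O=O >> 2O")
        doubled = parse_reaction_string("4[H][H] + 2O=O >> 4O")
        assert th.reaction_gibbs(doubled, table) == pytest.approx(
            2 * th.reaction_gibbs(eq, table), abs=1e-12
        )
        assert th.reaction_entropy_diff(doubled, table) == pytest.approx(
            2 * th.reaction_entropy_diff(eq, table), abs=1e-12
        )
        assert th.reaction_dipole_diff(doubled, table) == pytest.approx(
            2 * th.reaction_dipole_diff(eq, table), abs=1e-12
        )

    def test_antisymmetry_under_side_swap(self, table):
        eq = parse_reaction_string("2[H][H] + O=O >> 2O")
        rev = eq.swapped()
        assert th.reaction_gibbs(rev, table) == pytest.approx(
            -th.reaction_gibbs(eq, table), abs=1e-12
        )
        assert th.reaction_entropy_diff(rev, table) == pytest.approx(
            -th.reaction_entropy_diff(eq, table), abs=1e-12
        )
        assert th.reaction_dipole_diff(rev, table) == pytest.approx(
            -th.reaction_dipole_diff(eq, table), abs=1e-12
        )

    def test_planted_hydrogen_combustion_hand_computed(self, table):
        """2 H2 + O2 >> 2 H2O with the planted exact values."""
        eq = parse_reaction_string("2[H][H] + O=O >> 2O")
        h2 = PLANTED_THERMO["[H][H]"]
        o2 = PLANTED_THERMO["O=O"]
        h2o = PLANTED_THERMO["O"]
        T = th.STANDARD_TEMPERATURE
        dH = 2 * h2o[0] - (2 * h2[0] + o2[0])
        dS = 2 * h2o[1] - (2 * h2[1] + o2[1])
        dmu = 2 * h2o[2] - (2 * h2[2] + o2[2])
        assert th.reaction_gibbs(eq, table) == pytest.approx(dH - T * dS, abs=1e-12)
        assert th.reaction_entropy_diff(eq, table) == pytest.approx(dS, abs=1e-12)
        assert th.reaction_dipole_diff(eq, table) == pytest.approx(dmu, abs=1e-12)

    def test_missing_species_named(self, table):
        eq = parse_reaction_string("FC(F)(F)F >> FC(F)(F)F")
        with pytest.raises(LookupMissingError, match="FC"):
            th.reaction_gibbs(eq, table)

    def test_random_equation_brute_force_oracle(self, rng, table):
        species = list(table.rows)
        for _ in range(50):
            pick = lambda: [(int(rng.integers(1, 5)), Species(s))
                            for s in rng.choice(species, size=rng.integers(1, 4), replace=False)]
            eq = ReactionEquation(tuple(pick()), tuple(pick()))
            T = 298.15
            expected = sum(
                c * (table.rows[s.canonical_smiles].enthalpy_H
                     - T * table.rows[s.canonical_smiles].entropy_S)
                for c, s in eq.products
            ) - sum(
                c * (table.rows[s.canonical_smiles].enthalpy_H
                     - T * table.rows[s.canonical_smiles].entropy_S)
                for c, s in eq.reactants
            )
            assert th.reaction_gibbs(eq, table) == pytest.approx(expected, abs=1e-12)


class TestDipole:
    def test_single_charge_at_origin(self):
        atoms = [th.AtomCharge("H", 1.0, (0.0, 0.0, 0.0))]
        vec, mag = th.dipole_moment(atoms, origin=(0.0, 0.0, 0.0))
        assert np.allclose(vec, 0.0) and mag == 0.0

    def test_two_charge_dumbbell(self):
        atoms = [
            th.AtomCharge("H", +1.0, (1.0, 0.0, 0.0)),
            th.AtomCharge("H", -1.0, (-1.0, 0.0, 0.0)),
        ]
        vec, mag = th.dipole_moment(atoms)
        assert np.allclose(vec, [2.0, 0.0, 0.0])
        assert mag == pytest.approx(2.0)

    def test_random_sets_against_naive_sum(self, rng):
        for _ in range(20):
            atoms = [
                th.AtomCharge("C", float(rng.normal()), tuple(rng.normal(size=3)))
                for _ in range(50)
            ]
            origin = tuple(rng.normal(size=3))
            vec, mag = th.dipole_moment(atoms, origin=origin)
            naive = np.zeros(3)
            for a in atoms:
                naive += a.partial_charge_q * (np.array(a.position_r) - np.array(origin))
            assert np.allclose(vec, naive, atol=1e-12)
            assert mag == pytest.approx(np.linalg.norm(naive), abs=1e-12)

    def test_translation_invariance_iff_neutral(self, rng):
        neutral = [
            th.AtomCharge("O", +0.4, (0.3, 0.1, -0.2)),
            th.AtomCharge("H", -0.4, (1.0, 0.5, 0.7)),
        ]
        charged = neutral + [th.AtomCharge("H", 0.25, (0.0, 0.0, 0.0))]
        v1, _ = th.dipole_moment(neutral, origin=(0, 0, 0))
        v2, _ = th.dipole_moment(neutral, origin=(5, -3, 2))
        assert np.allclose(v1, v2, atol=1e-12)
        w1, _ = th.dipole_moment(charged, origin=(0, 0, 0))
        w2, _ = th.dipole_moment(charged, origin=(5, -3, 2))
        assert not np.allclose(w1, w2)

    def test_empty_atom_list(self):
        with pytest.raises(ConfigurationError):
            th.dipole_moment([])


class TestStabilityFilter:
    def test_boundary_semantics(self):
        kept, removed = th.stability_filter([5.0, 5.0001, 0.0, -5.0, -5.0001])
        assert kept == [5.0, 0.0, -5.0]
        assert removed == [5.0001, -5.0001]

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.uniform(-10, 10, size=1000).tolist()
        kept, removed = th.stability_filter(values, bound=5.0)
        assert len(kept) == sum(1 for v in values if abs(v) <= 5.0)
        assert len(kept) + len(removed) == len(values)


class TestPropertyTable:
    def test_missing_unit_columns_rejected(self):
        import pandas as pd

        with pytest.raises(ConfigurationError, match="unit"):
            th.PropertyTable.from_frame(pd.DataFrame({"canonical_smiles": ["C"], "H": [1.0]}))

    def test_csv_round_trip(self, table, tmp_path):
        path = tmp_path / "props.csv"
        table.write_csv(path)
        again = th.PropertyTable.read_csv(path)
        assert set(again.rows) == set(table.rows)
        for key in table.rows:
            assert again.rows[key].enthalpy_H == pytest.approx(table.rows[key].enthalpy_H)

    def test_lookup_by_any_dialect(self, table):
        assert table.lookup(Species("[H][O][H]")).canonical_smiles == "O"

    def test_evaluate_reactions_frame(self, table):
        eqs = [parse_reaction_string("2[H][H] + O=O >> 2O"), parse_reaction_string("O >> O")]
        frame = th.evaluate_reactions(eqs, table)
        assert list(frame.columns) == [
            "equation", "delta_G_eV", "delta_S_eV_per_K", "delta_mu_debye", "kept",
        ]
        assert frame.loc[1, "delta_G_eV"] == 0.0
        assert bool(frame.loc[1, "kept"]) is True
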