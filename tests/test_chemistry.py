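"""Mass bookkeeping: residue formulas, condensation, reduction, moiety labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import mass as pyteomics_mass

import lpptether.chemistry as chem
from lpptether.chemistry import (
    ElementalComposition,
    LabelState,
    MuropeptideSpec,
    assemble_composition,
    fragment_series,
    heavy_shift,
    isotopologue_mass,
    monoisotopic_mass,
    parse_formula,
    residue_library,
    round_half_up,
    theoretical_table,
    tri_kr_spec,
)

WATER_MASS = 18.0105646859
H2_MASS = 2.0156500638

# Published 2-dp mass grid of the Tri->KR MS2 ladder: rows are the fragment
# series (parental down to free Arg), columns the four isotopologues in the
# order (light,light), (light stem, heavy lpp), (heavy stem, light lpp),
# (heavy,heavy).
PRINTED_GRID = np.array(
    [
        [1154.57, 1172.59, 1194.66, 1212.69],
        [951.49, 969.51, 982.56, 1000.58],
        [674.37, 692.39, 693.41, 711.43],
        [603.33, 621.36, 618.37, 636.39],
        [474.29, 492.31, 483.31, 501.33],
        [302.21, 320.23, 302.21, 320.23],
        [174.11, 184.12, 174.11, 184.12],
    ]
)

RESIDUE_NAMES = list(residue_library())


class TestCompositions:
    def test_formula_parser_round_trip(self):
        comp = ElementalComposition.from_formula("C8H15NO6")
        assert comp.counts == {"C": 8, "H": 15, "N": 1, "O": 6}
        assert parse_formula(comp.formula()) == comp.counts

    @pytest.mark.parametrize("bad", ["", "8C", "Cx?", "C-2"])
    def test_formula_parser_rejects_garbage(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    def test_arithmetic(self):
        a = ElementalComposition.from_formula("C2H4O")
        b = ElementalComposition.from_formula("H2O")
        assert (a + b).counts == {"C": 2, "H": 6, "O": 2}
        assert (a - b).counts == {"C": 2, "H": 2}
        assert (2 * b).counts == {"H": 4, "O": 2}
        with pytest.raises(ValueError):
            b - a  # would go negative

    def test_empty_composition_has_zero_mass(self):
        assert monoisotopic_mass(ElementalComposition()) == 0.0

    def test_unsupported_element(self):
        with pytest.raises(chem.UnsupportedElementError):
            monoisotopic_mass(ElementalComposition({"Se": 1}))

    def test_water_mass(self):
        assert monoisotopic_mass(chem.WATER) == pytest.approx(WATER_MASS, abs=1e-6)


class TestResidueLibrary:
    @pytest.mark.parametrize("name", RESIDUE_NAMES)
    def test_masses_agree_with_pyteomics(self, library, name):
        """Independent oracle: pyteomics' own atomic-mass tables."""
        ours = library[name].mass
        theirs = pyteomics_mass.calculate_mass(formula=library[name].composition.formula())
        assert ours == pytest.approx(theirs, abs=5e-4)

    def test_arg_printed_mass(self, library):
        assert round_half_up(library["Arg"].mass) == 174.11

    def test_lys_arg_dipeptide_printed_mass(self, library):
        mass = library["Lys"].mass + library["Arg"].mass - WATER_MASS
        assert round_half_up(mass) == 302.21

    def test_unknown_residue(self, library):
        spec = MuropeptideSpec(residues=("Xyz",), n_bonds=0)
        with pytest.raises(chem.MissingResidueError):
            assemble_composition(spec, library)

    def test_extension_cannot_shadow(self):
        with pytest.raises(ValueError):
            residue_library(extra={"Arg": "C6H14N4O2"})


class TestAssembly:
    def test_single_residue_identity(self, library):
        spec = MuropeptideSpec(residues=("DAP",), n_bonds=0)
        assert assemble_composition(spec, library) == library["DAP"].composition

    def test_lys_arg_composition(self, library):
        spec = MuropeptideSpec(residues=("Lys", "Arg"), n_bonds=1)
        comp = assemble_composition(spec, library)
        assert comp.counts == {"C": 12, "H": 26, "N": 6, "O": 3}
        assert round_half_up(monoisotopic_mass(comp)) == 302.21

    def test_full_tri_kr_mass(self):
        assert round_half_up(monoisotopic_mass(assemble_composition(tri_kr_spec()))) == 1154.57

    def test_reduction_adds_exactly_h2(self, library):
        spec = tri_kr_spec()
        unreduced = MuropeptideSpec(spec.residues, spec.n_bonds, False, spec.moieties)
        delta = assemble_composition(spec, library) - assemble_composition(unreduced, library)
        assert delta.counts == {"H": 2}
        assert monoisotopic_mass(delta) == pytest.approx(H2_MASS, abs=1e-4)

    @given(
        residues=st.lists(st.sampled_from(RESIDUE_NAMES), min_size=1, max_size=8),
        reduced=st.booleans(),
    )
    @settings(max_examples=60, deadline=None)
    def test_condensation_bookkeeping(self, residues, reduced):
        """n-residue assembly = sum of free masses - (n-1) waters (+H2 if reduced),
        checked against a brute-force element summation."""
        library = residue_library()
        spec = MuropeptideSpec(tuple(residues), len(residues) - 1, reduced)
        mass = monoisotopic_mass(assemble_composition(spec, library))
        expected = (
            sum(library[r].mass for r in residues)
            - (len(residues) - 1) * WATER_MASS
            + (H2_MASS if reduced else 0.0)
        )
        assert mass == pytest.approx(expected, abs=1e-6)
        # brute-force element counts, bypassing ElementalComposition arithmetic
        counts: dict[str, int] = {}
        for r in residues:
            for e, n in library[r].composition.counts.items():
                counts[e] = counts.get(e, 0) + n
        counts["H"] = counts.get("H", 0) - 2 * (len(residues) - 1) + (2 if reduced else 0)
        counts["O"] = counts.get("O", 0) - (len(residues) - 1)
        brute = sum(n * chem.MONOISOTOPIC_MASS[e] for e, n in counts.items())
        assert mass == pytest.approx(brute, abs=1e-9)


class TestHeavyShift:
    def test_dap_shift(self, library):
        assert round_half_up(heavy_shift(library["DAP"].composition)) == 9.02

    def test_lys_arg_shift(self, library):
        spec = MuropeptideSpec(residues=("Lys", "Arg"), n_bonds=1)
        comp = assemble_composition(spec, library)
        assert round_half_up(heavy_shift(comp)) == 18.02
        assert round_half_up(monoisotopic_mass(comp) + heavy_shift(comp)) == 320.23

    def test_no_carbon_no_nitrogen(self):
        assert heavy_shift(ElementalComposition.from_formula("H2O")) == 0.0

    def test_label_must_cover_moieties(self):
        with pytest.raises(ValueError):
            isotopologue_mass(tri_kr_spec(), LabelState({"stem": "light"}))


class TestFragmentLadder:
    def test_series_structure(self):
        series = fragment_series(tri_kr_spec())
        assert len(series) == 7
        assert series[-1].residues == ("Arg",)
        assert series[-2].residues == ("Lys", "Arg")
        assert [f.reduced for f in series] == [True, True, False, False, False, False, False]

    def test_light_mass_ladder(self, library):
        expected = (1154.57, 951.49, 674.37, 603.33, 474.29, 302.21, 174.11)
        for frag, want in zip(fragment_series(tri_kr_spec()), expected):
            mass = monoisotopic_mass(assemble_composition(frag, library))
            assert round_half_up(mass) == want

    def test_consecutive_losses(self, library):
        """Each step of the ladder loses exactly (free residue mass - water),
        except the MurNAc step which also loses the reduction H2."""
        series = fragment_series(tri_kr_spec())
        masses = [monoisotopic_mass(assemble_composition(f, library)) for f in series]
        for i in range(len(series) - 1):
            lost = series[i].residues[0]
            expected = library[lost].mass - WATER_MASS
            if lost == "MurNAc":
                expected += H2_MASS
            assert masses[i] - masses[i + 1] == pytest.approx(expected, abs=1e-6)

    def test_requires_single_assembly(self):
        with pytest.raises(ValueError):
            fragment_series(MuropeptideSpec(("Lys", "Arg"), n_bonds=0))


class TestTheoreticalTable:
    def test_shape_and_order(self, table):
        assert table.shape == (7, 4)
        assert list(table.columns) == ["new_new", "new_old", "old_new", "old_old"]

    def test_matches_printed_grid(self, table):
        rounded = table.apply(np.vectorize(round_half_up))
        np.testing.assert_allclose(rounded.to_numpy(), PRINTED_GRID, atol=1e-9)

    def test_moiety_shift_additivity(self, table):
        """Hybrid masses are additive: col2 + col3 = col1 + col4 per row, and
        the all-heavy/all-light difference is the whole fragment's shift."""
        arr = table.to_numpy()
        np.testing.assert_allclose(
            arr[:, 1] + arr[:, 2], arr[:, 0] + arr[:, 3], atol=0.02
        )
        for frag, row in zip(fragment_series(tri_kr_spec()), arr):
            whole = assemble_composition(frag)
            assert row[3] - row[0] == pytest.approx(heavy_shift(whole), abs=1e-9)

    def test_kr_fragments_insensitive_to_stem_label(self, table):
        for row in ("->Lys-Arg", "->Arg"):
            assert table.loc[row, "new_new"] == table.loc[row, "old_new"]
            assert table.loc[row, "new_old"] == table.loc[row, "old_old"]
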