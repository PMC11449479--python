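"""Elemental-composition and monoisotopic-mass engine for isotope-labeled muropeptides.

Muropeptides are the disaccharide-peptide fragments released by muramidase
digestion of peptidoglycan (PG).  The diagnostic species for PG-tethered Braun
lipoprotein (Lpp) is the Tri->KR muropeptide: the disaccharide-tripeptide
GlcNAc-MurNAc(reduced)-L-Ala-D-iGlu-DAP cross-linked, through the DAP side
chain, to the Lys-Arg dipeptide remnant that trypsin digestion leaves behind
from the Lpp C-terminus.

Metabolic labeling with [13C]glucose and [15N]ammonium chloride produces
*moiety-wise* isotopologues: the stem (disaccharide-tripeptide) moiety and the
Lpp (Lys-Arg) moiety of one molecule may independently be light (synthesized
after the switch to light medium, "new") or heavy (pre-existing, "old").  This
module computes neutral monoisotopic masses for any such branched, reduced,
moiety-labeled assembly, the MS2 fragment-ion ladder of the Tri->KR parental,
and the full 7-fragment x 4-isotopologue theoretical mass grid used for peak
assignment.

Conventions
-----------
* All masses are neutral monoisotopic masses in Da (not protonated m/z).
  Charge handling is a display transform: m/z = (M + k*1.007276)/k.
* Full isotopic enrichment is assumed: every C of a heavy moiety is 13C and
  every N is 15N.
* Each condensation bond (peptide, isopeptide, glycosidic, lactyl-amide) loses
  exactly one water; borohydride reduction of MurNAc to muramitol adds H2.
* Reported/tabulated values are rounded half-up to 2 decimals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ElementalComposition",
    "ResidueDef",
    "MuropeptideSpec",
    "LabelState",
    "MONOISOTOPIC_MASS",
    "HEAVY_ISOTOPE_MASS",
    "DELTA_C13",
    "DELTA_N15",
    "PROTON_MASS",
    "WATER",
    "ISOTOPOLOGUES",
    "TABLE_LABEL_STATES",
    "QUANT_ORDER",
    "residue_library",
    "load_residue_library",
    "parse_formula",
    "assemble_composition",
    "monoisotopic_mass",
    "heavy_shift",
    "moiety_composition",
    "isotopologue_mass",
    "fragment_series",
    "theoretical_table",
    "tri_kr_spec",
    "round_half_up",
    "describe",
]

# --------------------------------------------------------------------------
# Isotope constants (monoisotopic atomic masses, Da)
# --------------------------------------------------------------------------

#: Mass of the light (most abundant) isotope per element.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
}

#: Mass of the heavy isotope incorporated under full 13C/15N labeling.
HEAVY_ISOTOPE_MASS: dict[str, float] = {
    "C": 13.0033548378,
    "N": 15.0001088984,
}

#: Mass shift per 12C -> 13C substitution.
DELTA_C13: float = HEAVY_ISOTOPE_MASS["C"] - MONOISOTOPIC_MASS["C"]
#: Mass shift per 14N -> 15N substitution.
DELTA_N15: float = HEAVY_ISOTOPE_MASS["N"] - MONOISOTOPIC_MASS["N"]

#: Proton mass for the (display-only) m/z transform.
PROTON_MASS: float = 1.007276


class MissingResidueError(KeyError):
    """A residue name was looked up that is not in the residue library."""


class UnsupportedElementError(KeyError):
    """A composition contains an element with no tabulated isotope mass."""


# --------------------------------------------------------------------------
# Elemental compositions
# --------------------------------------------------------------------------

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a molecular formula string such as ``"C8H15NO6"``.

    Element symbols are one capital letter optionally followed by a lowercase
    letter; a missing count means 1.  Repeated symbols accumulate.
    """
    counts: dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        pos = match.end()
        symbol, digits = match.groups()
        counts[symbol] = counts.get(symbol, 0) + (int(digits) if digits else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


@dataclass(frozen=True)
class ElementalComposition:
    """Integer atom counts per element; the unit of all mass arithmetic.

    Compositions add and subtract element-wise; subtraction raises if any
    count would go negative (an inconsistent assembly).  Scalar multiplication
    repeats a composition.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean = {e: int(n) for e, n in self.counts.items() if n != 0}
        if any(n < 0 for n in clean.values()):
            raise ValueError(f"negative element count in {clean}")
        object.__setattr__(self, "counts", clean)

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        return cls(parse_formula(formula))

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for e, n in other.counts.items():
            merged[e] = merged.get(e, 0) + n
        return ElementalComposition(merged)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        merged = dict(self.counts)
        for e, n in other.counts.items():
            merged[e] = merged.get(e, 0) - n
            if merged[e] < 0:
                raise ValueError(
                    f"inconsistent composition: subtracting {other.formula()} "
                    f"from {self.formula()} leaves negative {e}"
                )
        return ElementalComposition(merged)

    def __mul__(self, k: int) -> "ElementalComposition":
        if k < 0:
            raise ValueError("cannot repeat a composition a negative number of times")
        return ElementalComposition({e: n * k for e, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def formula(self) -> str:
        """Hill-ish formula string (C, H first, then alphabetical)."""
        order = sorted(self.counts, key=lambda e: (e != "C", e != "H", e))
        return "".join(f"{e}{self.counts[e] if self.counts[e] != 1 else ''}" for e in order)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)


WATER = ElementalComposition.from_formula("H2O")
_H2 = ElementalComposition.from_formula("H2")


def monoisotopic_mass(comp: ElementalComposition) -> float:
    """Neutral monoisotopic mass (Da) using light-isotope atomic masses."""
    total = 0.0
    for element, n in comp.counts.items():
        try:
            total += n * MONOISOTOPIC_MASS[element]
        except KeyError:
            raise UnsupportedElementError(element) from None
    return total


def heavy_shift(comp: ElementalComposition) -> float:
    """Mass increase (Da) of a composition under full 13C/15N enrichment."""
    return comp["C"] * DELTA_C13 + comp["N"] * DELTA_N15


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, as printed mass tables are rounded."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


# --------------------------------------------------------------------------
# Residue library
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ResidueDef:
    """A muropeptide building block with its free-molecule composition."""

    name: str
    composition: ElementalComposition

    @property
    def mass(self) -> float:
        return self.composition.mass


#: Free-molecule formulas of the residues occurring in the Tri->KR muropeptide.
_BUILTIN_RESIDUES: dict[str, str] = {
    "GlcNAc": "C8H15NO6",   # N-acetyl-glucosamine
    "MurNAc": "C11H19NO8",  # N-acetyl-muramic acid
    "Ala": "C3H7NO2",       # L- or D-alanine
    "iGlu": "C5H9NO4",      # D-isoglutamate
    "DAP": "C7H14N2O4",     # meso-diaminopimelate
    "Lys": "C6H14N2O2",     # L-lysine (Lpp position 58)
    "Arg": "C6H14N4O2",     # L-arginine (Lpp C-terminus)
}


def residue_library(extra: Mapping[str, str] | None = None) -> dict[str, ResidueDef]:
    """Return the residue library (name -> :class:`ResidueDef`).

    Parameters
    ----------
    extra
        Optional additional entries, name -> formula string; these may not
        shadow built-in names.
    """
    lib = {
        name: ResidueDef(name, ElementalComposition.from_formula(f))
        for name, f in _BUILTIN_RESIDUES.items()
    }
    if extra:
        for name, formula in extra.items():
            if name in lib:
                raise ValueError(f"residue {name!r} already defined")
            lib[name] = ResidueDef(name, ElementalComposition.from_formula(formula))
    return lib


def load_residue_library(path) -> dict[str, ResidueDef]:
    """Load a residue library from a YAML/JSON mapping of name -> formula."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("residue library file must be a mapping name -> formula")
    return {
        str(name): ResidueDef(str(name), ElementalComposition.from_formula(str(f)))
        for name, f in raw.items()
    }


def _lookup(name: str, library: Mapping[str, ResidueDef]) -> ResidueDef:
    try:
        return library[name]
    except KeyError:
        raise MissingResidueError(name) from None


# --------------------------------------------------------------------------
# Muropeptide specifications and label states
# --------------------------------------------------------------------------

#: Moiety tags of the Tri->KR muropeptide.
STEM = "stem"
LPP = "lpp"

LIGHT = "light"
HEAVY = "heavy"


@dataclass(frozen=True)
class MuropeptideSpec:
    """A branched residue assembly with condensation-bond bookkeeping.

    Parameters
    ----------
    residues
        Residue names in ladder order (glycan end first; the Lpp remnant
        residues last).  Branch points need no explicit encoding: mass
        bookkeeping depends only on the residue multiset and the bond count.
    n_bonds
        Number of condensation bonds.  A single covalently fused assembly of
        n residues has n-1 bonds.
    reduced
        Whether MurNAc has been reduced to muramitol (+H2).
    moieties
        Moiety tag per residue (same length as ``residues``), partitioning
        the molecule into independently labelable units.
    """

    residues: tuple[str, ...]
    n_bonds: int
    reduced: bool = False
    moieties: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError("a muropeptide needs at least one residue")
        if not self.moieties:
            object.__setattr__(self, "moieties", (STEM,) * len(self.residues))
        if len(self.moieties) != len(self.residues):
            raise ValueError("moieties must assign exactly one tag per residue")
        if not 0 <= self.n_bonds <= len(self.residues) - 1:
            raise ValueError(
                f"{self.n_bonds} condensation bonds is impossible for "
                f"{len(self.residues)} residues"
            )

    @property
    def moiety_tags(self) -> tuple[str, ...]:
        """Distinct moiety tags in order of first appearance."""
        seen: list[str] = []
        for tag in self.moieties:
            if tag not in seen:
                seen.append(tag)
        return tuple(seen)


@dataclass(frozen=True)
class LabelState:
    """Per-moiety heavy/light assignment defining one isotopologue."""

    labels: Mapping[str, str]

    def __post_init__(self) -> None:
        for tag, value in self.labels.items():
            if value not in (LIGHT, HEAVY):
                raise ValueError(f"label for moiety {tag!r} must be 'light' or 'heavy'")
        object.__setattr__(self, "labels", dict(self.labels))

    def __getitem__(self, tag: str) -> str:
        return self.labels[tag]

    def heavy_moieties(self) -> tuple[str, ...]:
        return tuple(t for t, v in self.labels.items() if v == HEAVY)

    def matches(self, spec: MuropeptideSpec) -> bool:
        return set(self.labels) == set(spec.moiety_tags)


# The four Tri->KR isotopologue categories.  Pulse-chase direction: heavy =
# pre-existing ("old"), light = newly synthesized ("new").  Category names
# read stem->lpp: "old_new" = old (heavy) stem, new (light) Lpp.
ISOTOPOLOGUES: tuple[str, ...] = ("new_new", "new_old", "old_new", "old_old")

#: Label states in theoretical-table column order.
TABLE_LABEL_STATES: dict[str, LabelState] = {
    "new_new": LabelState({STEM: LIGHT, LPP: LIGHT}),
    "new_old": LabelState({STEM: LIGHT, LPP: HEAVY}),
    "old_new": LabelState({STEM: HEAVY, LPP: LIGHT}),
    "old_old": LabelState({STEM: HEAVY, LPP: HEAVY}),
}

#: Column order of quantification tables (short keys nn, oo, on, no).
QUANT_ORDER: tuple[str, ...] = ("new_new", "old_old", "old_new", "new_old")
QUANT_KEYS: dict[str, str] = {
    "new_new": "nn",
    "old_old": "oo",
    "old_new": "on",
    "new_old": "no",
}


def tri_kr_spec() -> MuropeptideSpec:
    """The parental Tri->KR muropeptide: reduced disaccharide-tripeptide
    cross-linked to the Lys-Arg remnant of Lpp (7 residues, 6 bonds)."""
    return MuropeptideSpec(
        residues=("GlcNAc", "MurNAc", "Ala", "iGlu", "DAP", "Lys", "Arg"),
        n_bonds=6,
        reduced=True,
        moieties=(STEM, STEM, STEM, STEM, STEM, LPP, LPP),
    )


# --------------------------------------------------------------------------
# Assembly and isotopologue masses
# --------------------------------------------------------------------------


def assemble_composition(
    spec: MuropeptideSpec,
    library: Mapping[str, ResidueDef] | None = None,
) -> ElementalComposition:
    """Composition of the assembled (light) molecule.

    Sum of free-residue compositions, minus one water per condensation bond,
    plus H2 if MurNAc is reduced to muramitol.
    """
    library = library if library is not None else residue_library()
    total = ElementalComposition()
    for name in spec.residues:
        total = total + _lookup(name, library).composition
    total = total - spec.n_bonds * WATER
    if spec.reduced:
        total = total + _H2
    return total


def moiety_composition(
    spec: MuropeptideSpec,
    tag: str,
    library: Mapping[str, ResidueDef] | None = None,
) -> ElementalComposition:
    """Summed free-residue composition of one moiety.

    Condensation waters are deliberately not apportioned to moieties: water
    contains no C or N, so the heavy shift of a moiety depends only on its
    residues' C and N counts.
    """
    library = library if library is not None else residue_library()
    total = ElementalComposition()
    for name, t in zip(spec.residues, spec.moieties):
        if t == tag:
            total = total + _lookup(name, library).composition
    return total


def isotopologue_mass(
    spec: MuropeptideSpec,
    labels: LabelState,
    library: Mapping[str, ResidueDef] | None = None,
) -> float:
    """Neutral monoisotopic mass of one isotopologue.

    The light assembled mass plus, for each heavy moiety, the full 13C/15N
    shift of that moiety's residue C and N atoms.
    """
    if not labels.matches(spec):
        raise ValueError(
            f"label state covers moieties {sorted(labels.labels)} but the spec "
            f"has moieties {sorted(spec.moiety_tags)}"
        )
    library = library if library is not None else residue_library()
    mass = monoisotopic_mass(assemble_composition(spec, library))
    for tag in labels.heavy_moieties():
        mass += heavy_shift(moiety_composition(spec, tag, library))
    return mass


# --------------------------------------------------------------------------
# MS2 fragment ladder and theoretical table
# --------------------------------------------------------------------------


def fragment_series(spec: MuropeptideSpec) -> list[MuropeptideSpec]:
    """The MS2 fragment ladder: successive loss of residues from the glycan end.

    For the Tri->KR parental this yields the seven species observed on
    collision-induced dissociation: parental, -GlcNAc, -MurNAc(red), -Ala,
    -iGlu, -DAP (leaving Lys-Arg), -Lys (leaving Arg).  Each fragment is a
    standard condensation product (hydrolytic cleavage bookkeeping) and
    inherits its moiety partition from the parent.
    """
    if spec.n_bonds != len(spec.residues) - 1:
        raise ValueError(
            "fragment_series requires a single fused assembly "
            "(n_bonds == n_residues - 1)"
        )
    series = []
    for k in range(len(spec.residues)):
        residues = spec.residues[k:]
        series.append(
            MuropeptideSpec(
                residues=residues,
                n_bonds=len(residues) - 1,
                reduced=spec.reduced and "MurNAc" in residues,
                moieties=spec.moieties[k:],
            )
        )
    return series


def describe(spec: MuropeptideSpec) -> str:
    """Human-readable structure string, marking reduction and the cross-link."""
    parts = []
    for i, (name, tag) in enumerate(zip(spec.residues, spec.moieties)):
        shown = f"{name}(r)" if name == "MurNAc" and spec.reduced else name
        if tag == LPP and (i == 0 or spec.moieties[i - 1] != LPP):
            parts.append("->" + shown)
        elif i == 0:
            parts.append(shown)
        else:
            parts.append("-" + shown)
    return "".join(parts)


def theoretical_table(
    spec: MuropeptideSpec | None = None,
    library: Mapping[str, ResidueDef] | None = None,
    rounded: bool = False,
) -> pd.DataFrame:
    """Fragment-ladder x isotopologue grid of neutral monoisotopic masses.

    Rows are the fragment series of ``spec`` (default: Tri->KR parental);
    columns are the four label states in the order new_new, new_old, old_new,
    old_old, i.e. (light,light), (light stem, heavy lpp), (heavy stem, light
    lpp), (heavy,heavy).  Fragments lacking a moiety (e.g. the Lys-Arg and Arg
    fragments have no stem residues) simply receive a zero shift for it.
    """
    spec = spec if spec is not None else tri_kr_spec()
    library = library if library is not None else residue_library()
    fragments = fragment_series(spec)
    data = np.empty((len(fragments), len(ISOTOPOLOGUES)))
    for i, frag in enumerate(fragments):
        for j, iso in enumerate(ISOTOPOLOGUES):
            labels = LabelState(
                {t: TABLE_LABEL_STATES[iso][t] for t in frag.moiety_tags}
            )
            data[i, j] = isotopologue_mass(frag, labels, library)
    if rounded:
        data = np.vectorize(round_half_up)(data)
    return pd.DataFrame(
        data, index=[describe(f) for f in fragments], columns=list(ISOTOPOLOGUES)
    )
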