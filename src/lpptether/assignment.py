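"""Peak assignment, isotopologue classification, and relative-abundance quantification.

Inputs are deisotoped neutral-mass peak lists (MS1 precursor peaks and MS2
fragment peaks) as tidy tables with columns ``mz, intensity, level, time_min,
replicate, precursor_mz``.  MS1 peaks are matched against the four parental
isotopologue masses; MS2 peaks against the full 7-fragment x 4-isotopologue
grid.  Quantification is the relative abundance of each isotopologue: the
ratio (%) between its intensity and the sum of the intensities of all four,
computed per replicate and never pooled across replicates before the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chemistry import (
    ISOTOPOLOGUES,
    QUANT_KEYS,
    QUANT_ORDER,
    TABLE_LABEL_STATES,
    LabelState,
    theoretical_table,
)

__all__ = [
    "Peak",
    "Classification",
    "DiagnosticResult",
    "DEFAULT_MS1_TOL_PPM",
    "DEFAULT_MS2_TOL_DA",
    "match_peaks",
    "classify_isotopologue",
    "diagnostic_fragments",
    "relative_abundance",
    "quantify",
    "aggregate_moieties",
    "read_peaklist",
    "PEAKLIST_COLUMNS",
]

#: Default MS1 matching tolerance (relative).
DEFAULT_MS1_TOL_PPM = 20.0
#: Default MS2 matching tolerance (absolute, Da).
DEFAULT_MS2_TOL_DA = 0.02

PEAKLIST_COLUMNS = ["mz", "intensity", "level", "time_min", "replicate", "precursor_mz"]

QUANT_COLUMNS = ["time_min", "replicate"] + [QUANT_KEYS[iso] for iso in QUANT_ORDER]


@dataclass(frozen=True)
class Peak:
    """One deisotoped peak (neutral-mass convention)."""

    mz: float
    intensity: float
    level: str = "MS1"
    time_min: float = 0.0
    replicate: str = "r1"
    precursor_mz: float | None = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak mz must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


def _peaks_frame(peaks) -> pd.DataFrame:
    if isinstance(peaks, pd.DataFrame):
        df = peaks.copy()
    else:
        df = pd.DataFrame([vars(p) if isinstance(p, Peak) else p for p in peaks])
    for col in PEAKLIST_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col == "precursor_mz" else (
                "MS1" if col == "level" else 0 if col == "time_min" else
                "r1" if col == "replicate" else np.nan
            )
    return df


def read_peaklist(path) -> pd.DataFrame:
    """Read a peak-list CSV (columns mz, intensity, level, time_min, replicate,
    precursor_mz; precursor_mz empty for MS1 rows)."""
    df = pd.read_csv(path)
    missing = {"mz", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"peak list is missing columns {sorted(missing)}")
    return _peaks_frame(df)


def _flatten_theoretical(theoretical: pd.DataFrame) -> pd.DataFrame:
    """Long form of the fragment x isotopologue grid."""
    if theoretical.size == 0:
        raise ValueError("theoretical mass table is empty")
    long = theoretical.reset_index(names="fragment").melt(
        id_vars="fragment", var_name="isotopologue", value_name="mass"
    )
    frag_index = {name: i for i, name in enumerate(theoretical.index)}
    long["fragment_index"] = long["fragment"].map(frag_index)
    return long


def _nearest_candidate(mz: float, candidates: pd.DataFrame, tol_da: float):
    """Nearest theoretical mass within ``tol_da``; ties go to the lower mass.

    Returns (row or None, ambiguous).  Ambiguous is set when two or more
    candidates fall within the tolerance window (including exact ties).
    """
    err = (candidates["mass"] - mz).to_numpy()
    within = np.abs(err) <= tol_da
    n_within = int(within.sum())
    if n_within == 0:
        return None, False
    sub = candidates.loc[within].copy()
    sub["abs_err"] = np.abs(sub["mass"] - mz)
    # nearest first; exact tie in |error| resolved to the lower theoretical mass
    sub = sub.sort_values(["abs_err", "mass"], kind="mergesort")
    return sub.iloc[0], n_within > 1


def match_peaks(
    peaks,
    theoretical: pd.DataFrame | None = None,
    tol_ppm: float = DEFAULT_MS1_TOL_PPM,
    ms2_tol_da: float = DEFAULT_MS2_TOL_DA,
) -> pd.DataFrame:
    """Assign peaks to theoretical isotopologue/fragment masses.

    MS1 peaks are matched against the parental quartet (first row of the
    grid) within ``tol_ppm``; MS2 peaks against the whole grid within
    ``ms2_tol_da``.  Each peak gets the nearest candidate within tolerance,
    else stays unassigned.  Deterministic and permutation-invariant: the
    result depends only on each peak's own fields.

    Returns the peak table with added columns ``matched, fragment,
    fragment_index, isotopologue, mass_error_da, mass_error_ppm, ambiguous``.
    """
    if tol_ppm <= 0 or ms2_tol_da <= 0:
        raise ValueError("matching tolerances must be positive")
    theoretical = theoretical if theoretical is not None else theoretical_table()
    long = _flatten_theoretical(theoretical)
    parental = long[long["fragment_index"] == 0]

    df = _peaks_frame(peaks)
    out = {
        "matched": [], "fragment": [], "fragment_index": [], "isotopologue": [],
        "mass_error_da": [], "mass_error_ppm": [], "ambiguous": [],
    }
    for row in df.itertuples(index=False):
        if str(row.level).upper() == "MS2":
            cands, tol_da = long, ms2_tol_da
        else:
            cands, tol_da = parental, row.mz * tol_ppm * 1e-6
        best, ambiguous = _nearest_candidate(row.mz, cands, tol_da)
        if best is None:
            out["matched"].append(False)
            for key in ("fragment", "fragment_index", "isotopologue"):
                out[key].append(None)
            out["mass_error_da"].append(np.nan)
            out["mass_error_ppm"].append(np.nan)
            out["ambiguous"].append(False)
        else:
            err = row.mz - best["mass"]
            out["matched"].append(True)
            out["fragment"].append(best["fragment"])
            out["fragment_index"].append(int(best["fragment_index"]))
            out["isotopologue"].append(best["isotopologue"])
            out["mass_error_da"].append(err)
            out["mass_error_ppm"].append(err / best["mass"] * 1e6)
            out["ambiguous"].append(ambiguous)
    for key, values in out.items():
        df[key] = values
    return df


@dataclass(frozen=True)
class Classification:
    """Result of classifying a parental mass into an isotopologue."""

    isotopologue: str
    label_state: LabelState
    mass_error_da: float
    ambiguous: bool


def classify_isotopologue(
    parental_mass: float,
    quartet: Mapping[str, float] | pd.Series | None = None,
    tol_da: float = DEFAULT_MS2_TOL_DA,
) -> Classification:
    """Classify an observed parental mass into one of the four isotopologues.

    ``quartet`` maps isotopologue name -> theoretical parental mass (default:
    first row of the Tri->KR theoretical table).  The nearest mass within
    ``tol_da`` wins; an exact tie is resolved to the lower theoretical mass
    and flagged ambiguous.  Raises if no candidate is within tolerance.
    """
    if quartet is None:
        quartet = theoretical_table().iloc[0]
    items = pd.DataFrame(
        {"isotopologue": list(quartet.keys()) if isinstance(quartet, Mapping) else quartet.index,
         "mass": list(quartet.values()) if isinstance(quartet, Mapping) else quartet.to_numpy()}
    )
    best, ambiguous = _nearest_candidate(parental_mass, items, tol_da)
    if best is None:
        raise ValueError(
            f"no isotopologue within {tol_da} Da of parental mass {parental_mass}"
        )
    iso = best["isotopologue"]
    return Classification(
        isotopologue=iso,
        label_state=TABLE_LABEL_STATES[iso],
        mass_error_da=parental_mass - best["mass"],
        ambiguous=ambiguous,
    )


@dataclass(frozen=True)
class DiagnosticResult:
    """Label-state confirmation from MS2 diagnostic fragments.

    ``candidates`` holds the isotopologues consistent with every matched
    fragment; ``conflict`` is set when the fragment evidence is contradictory
    (no isotopologue explains all fragments).  ``label_state`` is filled only
    when the evidence pins down a single isotopologue.
    """

    candidates: frozenset[str]
    conflict: bool
    label_state: LabelState | None
    n_fragments_used: int
    messages: tuple[str, ...] = ()

    @property
    def isotopologue(self) -> str | None:
        return next(iter(self.candidates)) if len(self.candidates) == 1 else None


def diagnostic_fragments(
    fragment_masses: Iterable[float],
    theoretical: pd.DataFrame | None = None,
    tol_da: float = DEFAULT_MS2_TOL_DA,
) -> DiagnosticResult:
    """Read the label state of a precursor off its MS2 fragment masses.

    The Lpp-moiety label is carried by the Lys-Arg fragment (302.21 light vs
    320.23 heavy) and the stem label by the DAP->Lys-Arg increment (+9.02 for
    heavy DAP).  Implemented generally: each fragment mass constrains the set
    of isotopologues whose ladder contains a matching mass; the sets are
    intersected.  Contradictory evidence yields ``conflict=True``, never a
    silent override.
    """
    theoretical = theoretical if theoretical is not None else theoretical_table()
    candidates = set(ISOTOPOLOGUES)
    used = 0
    messages: list[str] = []
    for mz in fragment_masses:
        consistent = {
            iso
            for iso in ISOTOPOLOGUES
            if np.any(np.abs(theoretical[iso].to_numpy() - mz) <= tol_da)
        }
        if not consistent:
            messages.append(f"fragment {mz:.4f} matches no theoretical mass; ignored")
            continue
        used += 1
        candidates &= consistent
        if not candidates:
            return DiagnosticResult(
                candidates=frozenset(),
                conflict=True,
                label_state=None,
                n_fragments_used=used,
                messages=tuple(messages + [f"fragment {mz:.4f} contradicts earlier evidence"]),
            )
    label = TABLE_LABEL_STATES[next(iter(candidates))] if len(candidates) == 1 else None
    return DiagnosticResult(
        candidates=frozenset(candidates),
        conflict=False,
        label_state=label,
        n_fragments_used=used,
        messages=tuple(messages),
    )


def relative_abundance(intensities: Sequence[float]) -> np.ndarray:
    """Relative abundances (%) of the four isotopologues.

    Input and output order is (new_new, old_old, old_new, new_old), i.e. the
    quant-table columns nn, oo, on, no.  Each value is 100 * I_i / sum(I);
    the four always sum to 100.
    """
    arr = np.asarray(intensities, dtype=float)
    if arr.shape != (4,):
        raise ValueError("expected exactly four intensities (nn, oo, on, no)")
    if np.any(arr < 0) or not np.all(np.isfinite(arr)):
        raise ValueError("intensities must be finite and non-negative")
    total = arr.sum()
    if total <= 0:
        raise ValueError("relative abundance undefined for all-zero intensities")
    return 100.0 * arr / total


def quantify(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-sample isotopologue relative abundances from matched MS1 peaks.

    Sums intensity per isotopologue within each (time_min, replicate) sample
    (parental assignments only), then converts to relative abundance.
    Replicates are never pooled before the ratio.  Returns a tidy table with
    columns ``time_min, replicate, nn, oo, on, no`` (percent).
    """
    ms1 = assignments[
        assignments["matched"]
        & (assignments["level"].astype(str).str.upper() == "MS1")
        & (assignments["fragment_index"] == 0)
    ]
    rows = []
    for (t, rep), group in ms1.groupby(["time_min", "replicate"], sort=True):
        sums = group.groupby("isotopologue")["intensity"].sum()
        intensities = [float(sums.get(iso, 0.0)) for iso in QUANT_ORDER]
        rel = relative_abundance(intensities)
        rows.append([t, rep, *rel])
    return pd.DataFrame(rows, columns=QUANT_COLUMNS)


def aggregate_moieties(quant: pd.DataFrame | Sequence[float]) -> pd.DataFrame:
    """Moiety-wise aggregation of isotopologue relative abundances.

    old_lpp = oo + no (isotopologues containing pre-existing Lpp),
    new_lpp = nn + on, old_stem = oo + on, new_stem = nn + no.  Each old/new
    pair sums to 100 for any valid quant row.

    Accepts a quant table (returns it with the four aggregate columns added)
    or a single (nn, oo, on, no) vector (returns a one-row table).
    """
    if not isinstance(quant, pd.DataFrame):
        rel = np.asarray(quant, dtype=float)
        if rel.shape != (4,):
            raise ValueError("expected four relative abundances (nn, oo, on, no)")
        quant = pd.DataFrame([rel], columns=["nn", "oo", "on", "no"])
    else:
        quant = quant.copy()
    quant["old_lpp"] = quant["oo"] + quant["no"]
    quant["new_lpp"] = quant["nn"] + quant["on"]
    quant["old_stem"] = quant["oo"] + quant["on"]
    quant["new_stem"] = quant["nn"] + quant["no"]
    return quant
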