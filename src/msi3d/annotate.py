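"""Molecular-formula parsing, monoisotopic adduct m/z computation, and peak
annotation against a bundled lipid candidate table.

The candidate table covers the lipid classes relevant to spinal-cord-injury
lesions in positive-ion MALDI: medium/long-chain acylcarnitines (lesion
margin), lysophosphatidylcholines (lesion core), an arachidonoyl PC, and the
heme b fragment of hemoglobin (hemorrhage marker). Adduct species are recorded
explicitly per candidate because TOF data at ~0.1 Da accuracy cannot decide
them; lysoPCs only reconcile with the observed masses as sodiated species and
PC(16:0/20:4) as the potassiated one.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import InputError

__all__ = [
    "MONOISOTOPIC_MASS",
    "ELECTRON_MASS",
    "ADDUCTS",
    "LipidCandidate",
    "Assignment",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "load_candidates",
    "match_peaks",
]

#: Masses of the most abundant isotope of each supported element (Da, CODATA/
#: AME-2020 values). Extend here if new formulas need more elements.
MONOISOTOPIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Li": 7.0160034366,
    "Cl": 34.96885268,
    "Fe": 55.9349375,
}

ELECTRON_MASS = 0.000548579909  # Da

#: Supported positive-mode adducts: neutral species gained (None for a radical
#: cation, which only loses the electron).
ADDUCTS: dict[str, str | None] = {
    "[M+H]+": "H",
    "[M+Na]+": "Na",
    "[M+K]+": "K",
    "[M+Li]+": "Li",
    "[M]+.": None,
}
# unicode alias for the radical-cation label
_ADDUCT_ALIASES = {"[M]+•": "[M]+."}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> dict[str, int]:
    """Parse a Hill-notation molecular formula into element counts.

    >>> parse_formula("C23H45NO4")
    {'C': 23, 'H': 45, 'N': 1, 'O': 4}
    """
    if not isinstance(text, str) or not text.strip():
        raise InputError("empty molecular formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise InputError(f"cannot parse formula {text!r} at position {pos}")
        elem, num = m.group(1), m.group(2)
        if elem not in MONOISOTOPIC_MASS:
            raise InputError(f"unknown element symbol {elem!r} in {text!r}")
        counts[elem] = counts.get(elem, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(text):
        raise InputError(f"cannot parse formula {text!r} at position {pos}")
    return counts


def monoisotopic_mass(counts: dict[str, int]) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a neutral formula in Da."""
    total = 0.0
    for elem, n in counts.items():
        if elem not in MONOISOTOPIC_MASS:
            raise InputError(f"unknown element symbol {elem!r}")
        if n < 0:
            raise InputError(f"negative count for element {elem!r}")
        total += MONOISOTOPIC_MASS[elem] * n
    return total


def adduct_mz(formula: str | dict[str, int], adduct: str) -> float:
    """Theoretical m/z of a singly charged positive adduct ion.

    ``[M+X]+`` ions gain the neutral X and lose one electron; the radical
    cation ``[M]+.`` only loses the electron.
    """
    adduct = _ADDUCT_ALIASES.get(adduct, adduct)
    if adduct not in ADDUCTS:
        raise InputError(f"unsupported adduct {adduct!r}; known: {sorted(ADDUCTS)}")
    counts = parse_formula(formula) if isinstance(formula, str) else formula
    mass = monoisotopic_mass(counts)
    gained = ADDUCTS[adduct]
    if gained is not None:
        mass += MONOISOTOPIC_MASS[gained]
    return mass - ELECTRON_MASS


@dataclass(frozen=True)
class LipidCandidate:
    name: str
    formula: str
    adduct: str
    theoretical_mz: float = field(default=0.0)

    @staticmethod
    def from_formula(name: str, formula: str, adduct: str) -> "LipidCandidate":
        return LipidCandidate(name, formula, adduct, adduct_mz(formula, adduct))


@dataclass(frozen=True)
class Assignment:
    peak_mz: float
    candidate: LipidCandidate
    error_da: float
    error_ppm: float
    ambiguous: bool = False


def load_candidates(path=None) -> list[LipidCandidate]:
    """Load the candidate table (bundled CSV by default).

    The CSV columns are ``name, formula, adduct``; theoretical m/z is always
    recomputed from the formula, never read from disk.
    """
    if path is None:
        with resources.files("msi3d.data").joinpath("lipid_candidates.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"name", "formula", "adduct"}
    if not required.issubset(table.columns):
        raise InputError(f"candidate table must have columns {sorted(required)}")
    return [
        LipidCandidate.from_formula(r["name"], r["formula"], r["adduct"])
        for _, r in table.iterrows()
    ]


def match_peaks(
    peak_centers,
    candidates: list[LipidCandidate],
    tolerance_da: float = 0.3,
) -> list[Assignment]:
    """Assign detected peak centers to the nearest candidate within tolerance.

    When two or more candidates fall within the tolerance of one peak, every
    hit is reported with ``ambiguous=True`` so downstream users can see the
    conflict instead of silently trusting the nearest mass.
    """
    if tolerance_da <= 0:
        raise InputError("tolerance_da must be positive")
    assignments: list[Assignment] = []
    for mz in peak_centers:
        hits = [c for c in candidates if abs(c.theoretical_mz - mz) <= tolerance_da]
        if not hits:
            continue
        hits.sort(key=lambda c: abs(c.theoretical_mz - mz))
        ambiguous = len(hits) > 1
        for c in hits if ambiguous else hits[:1]:
            err = mz - c.theoretical_mz
            assignments.append(
                Assignment(
                    peak_mz=float(mz),
                    candidate=c,
                    error_da=err,
                    error_ppm=1e6 * err / c.theoretical_mz,
                    ambiguous=ambiguous,
                )
            )
    return assignments


def assignments_to_frame(assignments: list[Assignment]) -> pd.DataFrame:
    """Tabulate assignments for CSV export."""
    return pd.DataFrame(
        {
            "peak_mz": [a.peak_mz for a in assignments],
            "name": [a.candidate.name for a in assignments],
            "formula": [a.candidate.formula for a in assignments],
            "adduct": [a.candidate.adduct for a in assignments],
            "theoretical_mz": [a.candidate.theoretical_mz for a in assignments],
            "error_da": [a.error_da for a in assignments],
            "error_ppm": [a.error_ppm for a in assignments],
            "ambiguous": [a.ambiguous for a in assignments],
        }
    )
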