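"""Elemental-formula arithmetic, adduct rules, and the lipid reference database.

Monoisotopic masses are derived from IUPAC atomic masses at run time; the
reference CSV stores elemental formulas only, never masses.  Adduct m/z use
the charged-species convention: the mass of the attached ion includes the
electron ledger ([M+H]+ adds a proton, 1.007276 Da; [M+Cl]- adds a chloride
anion, 34.969401 Da).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "POSITIVE_ADDUCTS",
    "NEGATIVE_ADDUCTS",
    "AdductRule",
    "ElementalFormula",
    "FormulaError",
    "LipidDB",
    "LipidRecord",
    "adduct_mz",
    "lipid_formula",
    "load_reference_db",
    "monoisotopic_mass",
    "default_db_path",
]

ELECTRON_MASS = 0.000548579909

#: Monoisotopic atomic masses (Da) for the element table supported here.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "P": 30.97376163,
    "S": 31.97207100,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "Cl": 34.96885268,
}


class FormulaError(ValueError):
    """Raised when an elemental formula cannot be parsed or evaluated."""


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, e.g. C42H82NO8P for PC(34:1).

    The grammar is a flat sequence of element symbols with optional integer
    counts; no parentheses, charges or isotope labels.
    """

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for elem, n in self.counts.items():
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {elem!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for element {elem}")
            if n:
                clean[elem] = n
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
            elem, digits = match.groups()
            if elem not in MONOISOTOPIC_MASS:
                raise FormulaError(f"unknown element symbol: {elem!r} in {text!r}")
            counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(text):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        return cls(counts)

    def __str__(self) -> str:
        # Hill-like serialization: C, H first, then remaining symbols A-Z.
        order = ["C", "H"] + sorted(k for k in self.counts if k not in ("C", "H"))
        parts = []
        for elem in order:
            n = self.counts.get(elem, 0)
            if n:
                parts.append(elem if n == 1 else f"{elem}{n}")
        return "".join(parts)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for elem, n in other.counts.items():
            merged[elem] = merged.get(elem, 0) + n
        return ElementalFormula(merged)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def __bool__(self) -> bool:
        return bool(self.counts)


def monoisotopic_mass(formula: ElementalFormula | str) -> float:
    """Monoisotopic mass (Da) of a neutral formula; the empty formula is 0."""
    if isinstance(formula, str):
        formula = ElementalFormula.parse(formula)
    return float(sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts.items()))


@dataclass(frozen=True)
class AdductRule:
    """A singly charged ionization rule: observed m/z = neutral mass + delta."""

    label: str
    polarity: int  # +1 or -1
    mass_delta: float

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")


_PROTON = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

POSITIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M+H]+", +1, _PROTON),
    AdductRule("[M+Na]+", +1, MONOISOTOPIC_MASS["Na"] - ELECTRON_MASS),
    AdductRule("[M+K]+", +1, MONOISOTOPIC_MASS["K"] - ELECTRON_MASS),
)

NEGATIVE_ADDUCTS: tuple[AdductRule, ...] = (
    AdductRule("[M-H]-", -1, -_PROTON),
    AdductRule("[M+Cl]-", -1, MONOISOTOPIC_MASS["Cl"] + ELECTRON_MASS),
)

ADDUCTS_BY_LABEL: dict[str, AdductRule] = {
    r.label: r for r in POSITIVE_ADDUCTS + NEGATIVE_ADDUCTS
}


def adduct_mz(neutral_mass: float, rule: AdductRule) -> float:
    """m/z of a singly charged adduct of a neutral molecule."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + rule.mass_delta


# ---------------------------------------------------------------------------
# Compositional formula rules for the lipid classes handled here.  c = total
# acyl carbons, d = total double bonds (for sphingolipids the sphingoid base
# contributes to both).  These reproduce the textbook sum formulas, e.g.
# PC(34:1) -> C42H82NO8P and SM(d34:1) -> C39H79N2O6P.
# ---------------------------------------------------------------------------

_CLASS_RULES: dict[str, tuple[int, int, dict[str, int]]] = {
    # class: (carbon offset, hydrogen offset at d=0, fixed heteroatoms)
    "PC": (8, 16, {"N": 1, "O": 8, "P": 1}),
    "PE": (5, 10, {"N": 1, "O": 8, "P": 1}),
    "PS": (6, 10, {"N": 1, "O": 10, "P": 1}),
    "PI": (9, 15, {"O": 13, "P": 1}),
    "LPC": (8, 18, {"N": 1, "O": 7, "P": 1}),
    "LPE": (5, 12, {"N": 1, "O": 7, "P": 1}),
    "LPS": (6, 12, {"N": 1, "O": 9, "P": 1}),
    "LPI": (9, 17, {"O": 12, "P": 1}),
    "SM": (5, 13, {"N": 2, "O": 6, "P": 1}),
    "Cer": (0, 1, {"N": 1, "O": 3}),
    "CE": (27, 44, {"O": 2}),
    "CAR": (7, 13, {"N": 1, "O": 4}),
    "FA": (0, 0, {"O": 2}),
}


def lipid_formula(lipid_class: str, carbons: int, double_bonds: int) -> ElementalFormula:
    """Sum elemental formula for a diacyl/standard species of a lipid class.

    ``carbons``/``double_bonds`` count the acyl (plus sphingoid, for SM and
    Cer) contribution, matching the shorthand ``PC(34:1)`` or ``SM(d42:2)``.
    """
    try:
        c_off, h_off, hetero = _CLASS_RULES[lipid_class]
    except KeyError:
        raise FormulaError(f"no compositional rule for lipid class {lipid_class!r}")
    counts = {"C": carbons + c_off, "H": 2 * carbons - 2 * double_bonds + h_off}
    counts.update(hetero)
    return ElementalFormula(counts)


@dataclass(frozen=True)
class LipidRecord:
    name: str
    lipid_class: str
    formula: ElementalFormula
    tier: str  # "generic" (public database) or "tissue_specific"

    def __post_init__(self) -> None:
        if not self.formula:
            raise ValueError(f"lipid {self.name!r} has an empty formula")
        if self.tier not in ("generic", "tissue_specific"):
            raise ValueError(f"unknown tier {self.tier!r} for {self.name!r}")

    @property
    def neutral_mass(self) -> float:
        return self.formula.mass


@dataclass
class LipidDB:
    """Lipid records with a sorted index of theoretical adducted m/z.

    The index is built per polarity; each record is reachable through every
    polarity-compatible adduct.
    """

    records: list[LipidRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._build_index()

    def _build_index(self) -> None:
        self._index: dict[int, tuple[np.ndarray, list[tuple[int, AdductRule]]]] = {}
        for polarity, rules in ((+1, POSITIVE_ADDUCTS), (-1, NEGATIVE_ADDUCTS)):
            entries = []
            for i, rec in enumerate(self.records):
                for rule in rules:
                    entries.append((adduct_mz(rec.neutral_mass, rule), i, rule))
            entries.sort(key=lambda t: t[0])
            mzs = np.array([e[0] for e in entries], dtype=float)
            payload = [(e[1], e[2]) for e in entries]
            self._index[polarity] = (mzs, payload)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, name: str) -> LipidRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    def query(
        self, mz: float, polarity: int, rel_tolerance: float
    ) -> list[tuple[LipidRecord, AdductRule, float]]:
        """All (record, adduct, theoretical m/z) with |mz-theo|/theo <= tol."""
        mzs, payload = self._index[polarity]
        if mzs.size == 0:
            return []
        # tolerance is relative to the theoretical mass
        lo = np.searchsorted(mzs, mz / (1 + rel_tolerance), side="left")
        hi = np.searchsorted(mzs, mz / (1 - rel_tolerance), side="right")
        out = []
        for k in range(lo, hi):
            rec_idx, rule = payload[k]
            theo = float(mzs[k])
            if abs(mz - theo) / theo <= rel_tolerance:
                out.append((self.records[rec_idx], rule, theo))
        return out


def load_reference_db(path: str | Path) -> LipidDB:
    """Read a ``name,class,formula,tier`` CSV into a :class:`LipidDB`.

    Malformed formulas raise with the offending row number; duplicate
    (name, tier) pairs warn and keep the first occurrence.
    """
    df = pd.read_csv(path, comment="#")
    required = {"name", "class", "formula", "tier"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"reference CSV is missing columns: {sorted(missing)}")
    records: list[LipidRecord] = []
    seen: set[tuple[str, str]] = set()
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        key = (row["name"], row["tier"])
        if key in seen:
            warnings.warn(
                f"duplicate record {key} at row {row_no}; keeping the first",
                stacklevel=2,
            )
            continue
        try:
            formula = ElementalFormula.parse(str(row["formula"]))
        except FormulaError as exc:
            raise FormulaError(f"row {row_no}: {exc}") from exc
        records.append(
            LipidRecord(str(row["name"]), str(row["class"]), formula, str(row["tier"]))
        )
        seen.add(key)
    return LipidDB(records)


def default_db_path() -> Path:
    """Path of the bundled bovine follicle lipid reference CSV."""
    return Path(__file__).with_name("data") / "lipid_db.csv"


def load_default_db() -> LipidDB:
    return load_reference_db(default_db_path())
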