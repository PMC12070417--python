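"""Exact-mass chemistry primitives for CHNOS molecular formulas.

Everything downstream — internal calibration, constrained formula
assignment, molecular indices — reduces to arithmetic on neutral
:class:`MolecularFormula` objects and a single table of element constants.
The element model is deliberately restricted to C, H, N, O and S:
phosphorus ionizes poorly in negative-mode ESI of natural organic matter
and is excluded from the assignment constraint box, so it is excluded from
the formula model entirely.

Index conventions (all computed from stoichiometry alone):

* DBE (double-bond equivalents, rings plus pi bonds):
  ``DBE = 1 + C - H/2 + N/2`` (O and S contribute zero).
* NOSC (nominal oxidation state of carbon, LaRowe & Van Cappellen form):
  ``NOSC = 4 - (4C + H - 3N - 2O - 2S) / C``; -4 for methane, 0 for
  carbohydrates, +4 for CO2.
* AI (aromaticity index, Koch & Dittmar form):
  ``AI = (1 + C - O - S - H/2) / (C - O - S - N)``, clamped to 0 when the
  numerator is negative or the denominator is non-positive.  The modified
  variant (AImod) counts only half the oxygen in both numerator and
  denominator.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from importlib import resources
from types import MappingProxyType
from typing import Mapping


class InvalidFormulaError(ValueError):
    """Raised for formulas that violate an operation's preconditions."""


class NotIonizableError(ValueError):
    """Raised when a formula cannot form the requested ion."""


# --------------------------------------------------------------------------
# Element constants
# --------------------------------------------------------------------------

#: Hill-order element symbols of the model (C, H, then alphabetical).
ELEMENTS = ("C", "H", "N", "O", "S")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class ElementMassTable:
    """Immutable per-element monoisotopic masses and atomic weights (Da).

    Loaded from the plain-text constants file shipped with the package;
    ``electron`` is the electron rest mass used in ion m/z arithmetic.
    """

    monoisotopic: Mapping[str, float]
    atomic_weight: Mapping[str, float]
    electron: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "monoisotopic", MappingProxyType(dict(self.monoisotopic)))
        object.__setattr__(self, "atomic_weight", MappingProxyType(dict(self.atomic_weight)))
        if self.monoisotopic.get("C") != 12.0:
            raise ValueError("carbon-12 monoisotopic mass must be exactly 12.0 Da")
        for el in ELEMENTS:
            if el not in self.monoisotopic or el not in self.atomic_weight:
                raise ValueError(f"constants file is missing element {el!r}")


@functools.lru_cache(maxsize=1)
def default_mass_table() -> ElementMassTable:
    """Load the packaged element constants (cached singleton)."""
    mono: dict[str, float] = {}
    weight: dict[str, float] = {}
    text = (resources.files("fticrdom") / "data" / "elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("element\t"):
            continue
        symbol, m, w = line.split("\t")
        mono[symbol] = float(m)
        weight[symbol] = float(w)
    electron = mono.pop("e-")
    weight.pop("e-", None)
    return ElementMassTable(monoisotopic=mono, atomic_weight=weight, electron=electron)


# --------------------------------------------------------------------------
# Molecular formulas
# --------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class MolecularFormula:
    """Integer element counts of a neutral CHNOS molecule."""

    c: int = 0
    h: int = 0
    n: int = 0
    o: int = 0
    s: int = 0

    def __post_init__(self) -> None:
        for el in ELEMENTS:
            count = getattr(self, el.lower())
            if not isinstance(count, int) or count < 0:
                raise InvalidFormulaError(f"{el} count must be a non-negative integer, got {count!r}")

    @property
    def n_atoms(self) -> int:
        return self.c + self.h + self.n + self.o + self.s

    @property
    def heteroatoms(self) -> int:
        """Nitrogen plus sulfur count, used by assignment tie-breaking."""
        return self.n + self.s

    def hill(self) -> str:
        """Canonical Hill-order string, e.g. ``C6H12O6`` or ``CH4``."""
        parts = []
        for el in ELEMENTS:
            count = getattr(self, el.lower())
            if count == 1:
                parts.append(el)
            elif count > 1:
                parts.append(f"{el}{count}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        return MolecularFormula(
            c=self.c + other.c, h=self.h + other.h, n=self.n + other.n,
            o=self.o + other.o, s=self.s + other.s,
        )

    @classmethod
    def from_hill(cls, text: str) -> "MolecularFormula":
        """Parse a Hill-order CHNOS string; inverse of :meth:`hill`."""
        counts = dict.fromkeys(ELEMENTS, 0)
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text):
            if match.start() != pos or not match.group(0):
                break
            symbol, digits = match.group(1), match.group(2)
            if symbol not in counts:
                raise InvalidFormulaError(f"unknown element {symbol!r} in {text!r}")
            counts[symbol] += int(digits) if digits else 1
            pos = match.end()
        if pos != len(text) or pos == 0:
            raise InvalidFormulaError(f"cannot parse formula string {text!r}")
        return cls(**{el.lower(): v for el, v in counts.items()})


def monoisotopic_mass(formula: MolecularFormula, table: ElementMassTable | None = None) -> float:
    """Neutral monoisotopic mass in Da (sum of count x isotope mass)."""
    if formula.n_atoms == 0:
        raise InvalidFormulaError("empty formula has no mass")
    table = table or default_mass_table()
    m = table.monoisotopic
    return (formula.c * m["C"] + formula.h * m["H"] + formula.n * m["N"]
            + formula.o * m["O"] + formula.s * m["S"])


def ion_mz(
    formula: MolecularFormula,
    table: ElementMassTable | None = None,
    include_electron: bool = True,
) -> float:
    """[M-H]- m/z of a neutral formula (singly charged, even-electron).

    The deprotonated ion loses a hydrogen atom and gains an electron; the
    electron mass matters at sub-ppm accuracy but can be dropped with
    ``include_electron=False`` for comparison with tools that omit it.
    """
    if formula.h < 1:
        raise NotIonizableError(f"{formula.hill() or formula!r} has no proton to lose")
    table = table or default_mass_table()
    mz = monoisotopic_mass(formula, table) - table.monoisotopic["H"]
    if include_electron:
        mz += table.electron
    return mz


# --------------------------------------------------------------------------
# Molecular indices
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class IndexSet:
    """Per-formula molecular indices (all dimensionless)."""

    dbe: float
    dbe_per_c: float
    ai: float
    nosc: float
    h_c: float
    o_c: float
    n_c: float


def dbe(formula: MolecularFormula) -> float:
    """Double-bond equivalents of the neutral formula."""
    return 1.0 + formula.c - formula.h / 2.0 + formula.n / 2.0


def compute_indices(formula: MolecularFormula, ai_modified: bool = False) -> IndexSet:
    """DBE, AI, NOSC and molar ratios of a formula with at least one carbon.

    ``ai_modified=True`` selects AImod, which discounts half the oxygen as
    non-aromatic (carboxyl-like) in both numerator and denominator.
    """
    c, h, n, o, s = formula.c, formula.h, formula.n, formula.o, formula.s
    if c < 1:
        raise InvalidFormulaError("per-carbon indices require at least one carbon")
    d = dbe(formula)
    nosc = 4.0 - (4.0 * c + h - 3.0 * n - 2.0 * o - 2.0 * s) / c
    o_eff = 0.5 * o if ai_modified else float(o)
    ai_num = 1.0 + c - o_eff - s - 0.5 * h
    ai_den = c - o_eff - s - n
    ai = ai_num / ai_den if (ai_num > 0 and ai_den > 0) else 0.0
    return IndexSet(
        dbe=d, dbe_per_c=d / c, ai=ai, nosc=nosc,
        h_c=h / c, o_c=o / c, n_c=n / c,
    )
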