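"""Elemental-composition arithmetic and adduct-aware ion m/z computation.

This module is the numeric substrate for every mass in the package.  A
:class:`ChemicalFormula` is an immutable signed multiset of element counts:
counts may be negative so that neutral-loss arithmetic (e.g. ``M - H2O``)
stays closed under addition and subtraction.  Heavy isotopes (``[13C]``,
``[2H]``/``D``, ``[15N]``) are distinct pseudo-elements in the mass table,
so isotope-labeled formulas reuse the same integer arithmetic as unlabeled
ones.

Monoisotopic masses are pinned to the IUPAC 2021 atomic mass evaluation and
shipped as a versioned CSV (``data/elements.csv``).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "ELECTRON_MASS",
    "PROTON_MASS",
    "ChemicalFormula",
    "Adduct",
    "element_mass",
    "parse_formula",
    "combine_formulas",
    "monoisotopic_mass",
    "ion_mz",
    "load_adducts",
    "get_adduct",
]

#: Electron rest mass in Da (CODATA).  Included in ion m/z by default; see
#: :func:`ion_mz` for the toggle.
ELECTRON_MASS = 0.000548579909


def _load_element_table() -> dict[str, float]:
    text = resources.files("lipidbench.data").joinpath("elements.csv").read_text()
    table: dict[str, float] = {}
    for row in csv.DictReader(
        line for line in text.splitlines() if line and not line.startswith("#")
    ):
        table[row["symbol"]] = float(row["mass"])
    return table


ELEMENT_MASSES: dict[str, float] = _load_element_table()

#: Proton mass = H minus one electron.
PROTON_MASS = ELEMENT_MASSES["H"] - ELECTRON_MASS

# Synonyms accepted on input; canonical symbol used everywhere internally.
_SYMBOL_ALIASES = {"D": "[2H]", "T": "[3H]"}

_TOKEN_RE = re.compile(r"(\[\d+[A-Z][a-z]?\]|[A-Z][a-z]?)(\d*)")


def element_mass(symbol: str) -> float:
    """Monoisotopic mass of one element (or isotope pseudo-element)."""
    try:
        return ELEMENT_MASSES[symbol]
    except KeyError:
        raise KeyError(f"unknown element symbol: {symbol!r}") from None


@dataclass(frozen=True)
class ChemicalFormula:
    """Signed elemental composition with monoisotopic-mass semantics.

    Equality is count-map equality; zero counts are normalized away on
    construction.  Supports ``+``, ``-`` and scalar ``*``.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        cleaned = {}
        for sym, n in self.counts.items():
            sym = _SYMBOL_ALIASES.get(sym, sym)
            if sym not in ELEMENT_MASSES:
                raise KeyError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int):
                raise TypeError(f"count for {sym} must be an integer, got {n!r}")
            if n != 0:
                cleaned[sym] = cleaned.get(sym, 0) + n
        object.__setattr__(self, "counts", dict(cleaned))

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        merged = dict(self.counts)
        for sym, n in other.counts.items():
            merged[sym] = merged.get(sym, 0) + n
        return ChemicalFormula(merged)

    def __sub__(self, other: "ChemicalFormula") -> "ChemicalFormula":
        return self + (other * -1)

    def __mul__(self, k: int) -> "ChemicalFormula":
        if not isinstance(k, int):
            raise TypeError("formula can only be scaled by an integer")
        return ChemicalFormula({sym: n * k for sym, n in self.counts.items()})

    __rmul__ = __mul__

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(_SYMBOL_ALIASES.get(sym, sym), 0)

    # -- properties ----------------------------------------------------
    @property
    def mass(self) -> float:
        """Monoisotopic mass in Da (signed; empty formula is 0)."""
        return sum(n * ELEMENT_MASSES[sym] for sym, n in self.counts.items())

    def is_physical(self) -> bool:
        """True when every element count is non-negative."""
        return all(n >= 0 for n in self.counts.values())

    def substitute(self, light: str, heavy: str, n: int) -> "ChemicalFormula":
        """Replace ``n`` atoms of ``light`` with the isotope ``heavy``.

        Raises ``ValueError`` if fewer than ``n`` light atoms are available,
        reporting the available count.
        """
        avail = self[light]
        if n < 0:
            raise ValueError("substitution count must be non-negative")
        if n > avail:
            raise ValueError(
                f"cannot substitute {n} x {light} -> {heavy}: only {avail} "
                f"{light} atoms available"
            )
        return self + ChemicalFormula({light: -n, heavy: n})

    # -- formatting ----------------------------------------------------
    def hill(self) -> str:
        """Hill-convention string: C, H first, remaining symbols sorted.

        Negative counts are collected into a single trailing ``-`` block so
        that loss formulas round-trip through :func:`parse_formula`.
        """

        def block(items: dict[str, int]) -> str:
            def key(sym: str) -> tuple:
                base = sym.strip("[]0123456789") or sym
                rank = {"C": 0, "H": 1}.get(base, 2)
                return (rank, base, sym)

            out = []
            for sym in sorted(items, key=key):
                n = items[sym]
                out.append(sym if n == 1 else f"{sym}{n}")
            return "".join(out)

        pos = {s: n for s, n in self.counts.items() if n > 0}
        neg = {s: -n for s, n in self.counts.items() if n < 0}
        text = block(pos)
        if neg:
            text += "-" + block(neg)
        return text

    def __str__(self) -> str:
        return self.hill()

    def __repr__(self) -> str:
        return f"ChemicalFormula({self.hill()!r})"


def parse_formula(text: str) -> ChemicalFormula:
    """Parse a Hill-style formula string into a :class:`ChemicalFormula`.

    Grammar: a sequence of element tokens (``C``, ``H2``, ``[13C]6`` ...);
    an optional single ``-`` introduces a loss block whose counts are
    negated.  The empty string parses to the empty formula.

    >>> parse_formula("H2O").counts
    {'H': 2, 'O': 1}
    """
    text = text.strip()
    counts: dict[str, int] = {}
    sign = 1
    pos = 0
    if text.startswith("-"):
        sign = -1
        pos = 1
    first_block = True
    while pos < len(text):
        ch = text[pos]
        if ch == "-":
            if not first_block and sign == -1:
                raise ValueError(f"multiple '-' blocks in formula {text!r}")
            sign = -1
            pos += 1
            continue
        m = _TOKEN_RE.match(text, pos)
        if not m or m.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        sym = _SYMBOL_ALIASES.get(sym, sym)
        if sym not in ELEMENT_MASSES:
            raise KeyError(f"unknown element symbol: {sym!r} in {text!r}")
        n = int(digits) if digits else 1
        counts[sym] = counts.get(sym, 0) + sign * n
        pos = m.end()
        if sign == -1:
            first_block = False
    return ChemicalFormula(counts)


def combine_formulas(
    terms: Iterable[tuple[ChemicalFormula, int]]
) -> ChemicalFormula:
    """Signed integer linear combination of formulas.

    Commutative and associative by construction; the empty combination is
    the empty formula.
    """
    total = ChemicalFormula()
    for f, coeff in terms:
        total = total + f * coeff
    return total


def monoisotopic_mass(f: ChemicalFormula, strict: bool = False) -> float:
    """Monoisotopic mass in Da.  With ``strict=True`` a net-negative element
    count is rejected (no physical neutral has one)."""
    if strict and not f.is_physical():
        raise ValueError(f"formula {f} has negative element counts")
    return f.mass


@dataclass(frozen=True)
class Adduct:
    """An ionizing modification: atoms gained/lost plus a net charge.

    The charge sign determines polarity.  ``delta`` may be empty (pure
    electron gain/loss ions).
    """

    name: str
    delta: ChemicalFormula
    charge: int

    def __post_init__(self) -> None:
        if self.charge == 0:
            raise ValueError("adduct charge must be non-zero")

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"


def ion_mz(
    neutral: ChemicalFormula,
    adduct: Adduct,
    include_electron: bool = True,
) -> float:
    """m/z of the ion formed from ``neutral`` by ``adduct``.

    m/z = (M + M_delta - z * m_e) / |z|.  The electron-mass correction is
    applied by default; ``include_electron=False`` reproduces tools that
    omit it (the difference is ~0.5 mDa per charge).
    """
    m = neutral.mass + adduct.delta.mass
    if include_electron:
        m -= adduct.charge * ELECTRON_MASS
    mz = m / abs(adduct.charge)
    if mz <= 0:
        raise ValueError(
            f"non-physical ion: neutral {neutral} with adduct {adduct.name} "
            f"gives m/z {mz:.4f}"
        )
    return mz


def load_adducts(path=None) -> dict[str, Adduct]:
    """Load the adduct table (packaged default or user CSV).

    Columns: ``name,delta_formula,charge``; lines starting ``#`` ignored.
    """
    if path is None:
        text = resources.files("lipidbench.data").joinpath("adducts.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, Adduct] = {}
    for row in csv.DictReader(
        line for line in text.splitlines() if line and not line.startswith("#")
    ):
        name = row["name"].strip()
        if name in table:
            raise ValueError(f"duplicate adduct name: {name}")
        table[name] = Adduct(
            name=name,
            delta=parse_formula(row["delta_formula"].strip()),
            charge=int(row["charge"]),
        )
    return table


_DEFAULT_ADDUCTS: dict[str, Adduct] | None = None


def get_adduct(name: str) -> Adduct:
    """Look up a shipped adduct by name (e.g. ``"[M+H]1+"``)."""
    global _DEFAULT_ADDUCTS
    if _DEFAULT_ADDUCTS is None:
        _DEFAULT_ADDUCTS = load_adducts()
    try:
        return _DEFAULT_ADDUCTS[name]
    except KeyError:
        known = ", ".join(sorted(_DEFAULT_ADDUCTS))
        raise KeyError(f"unknown adduct {name!r}; shipped adducts: {known}") from None
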