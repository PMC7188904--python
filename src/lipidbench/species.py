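"""Concrete lipid species: shorthand names, canonical ordering, enumeration.

A molecular species is a lipid class plus an ordered list of chain instances
(fatty acyls and, for sphingolipids, a long-chain base).  Shorthand names
follow the updated community nomenclature: ``PC 16:0/18:1`` (sn-positions
known), ``PE 16:0_18:1`` (unknown, chains canonically sorted), ``Cer
18:1;2/16:0`` (LCB first, ``;n`` = hydroxyl count), ``PC O-16:0/18:1``
(plasmanyl) and ``PC P-16:0/18:1`` (plasmenyl).  A trailing ``(d<n>)``
denotes a whole-molecule deuterium label.

To avoid redundant assay rows, chains in ``_``-joined names are sorted
numerically by carbon count, then double bonds, then hydroxyls, so that
``PC 14:0_12:0`` and ``PC 12:0_14:0`` collapse to one species.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

from .chem import ChemicalFormula
from .kb import FattyAcylSpec, KnowledgeBase, LipidClassDef

__all__ = [
    "FattyAcylInstance",
    "IsotopeLabel",
    "LipidSpecies",
    "canonicalize_acyls",
    "enumerate_species",
    "parse_lipid_name",
    "parse_acyl_constraint",
    "assemble_neutral",
    "block_formulas",
    "CLASS_SYNONYMS",
]

#: LIPID MAPS and legacy class tokens accepted on input (translation is a
#: finite synonym table over class tokens only).
CLASS_SYNONYMS = {
    "TAG": "TG",
    "DAG": "DG",
    "MAG": "MG",
    "CE": "ChE",
    "GlcCer": "HexCer",
    "GalCer": "HexCer",
    "LysoPC": "LPC",
    "LysoPE": "LPE",
}

_BOND_PREFIX = {"O-": "ether", "P-": "vinyl"}
_PREFIX_FOR_BOND = {"ether": "O-", "vinyl": "P-"}


@dataclass(frozen=True, order=True)
class FattyAcylInstance:
    """One concrete chain: carbons, double bonds, hydroxyls, linkage."""

    carbons: int
    double_bonds: int = 0
    hydroxyls: int = 0
    bond_type: str = "acyl"

    def __post_init__(self) -> None:
        if self.carbons < 2:
            raise ValueError("chain needs at least 2 carbons")
        if self.double_bonds < 0 or self.double_bonds > (self.carbons - 1) // 2:
            raise ValueError(
                f"{self.carbons}:{self.double_bonds} exceeds the double-bond "
                f"capacity of a {self.carbons}-carbon chain"
            )
        if self.hydroxyls < 0:
            raise ValueError("hydroxyl count must be non-negative")

    # -- formulas ------------------------------------------------------
    def residue_formula(self) -> ChemicalFormula:
        """Composition contributed to the assembled neutral molecule.

        Ester/amide water loss is accounted in the class scaffold, so the
        acyl residue is RCO–O (C_c H_{2c-2db-1} O_{1+OH}); ether and
        vinyl-ether chains bind through the backbone oxygen and add none.
        """
        c, db, oh = self.carbons, self.double_bonds, self.hydroxyls
        if self.bond_type == "acyl":
            return ChemicalFormula({"C": c, "H": 2 * c - 2 * db - 1, "O": 1 + oh})
        if self.bond_type == "ether":
            return ChemicalFormula({"C": c, "H": 2 * c + 1 - 2 * db, "O": oh})
        if self.bond_type == "vinyl":
            return ChemicalFormula({"C": c, "H": 2 * c - 1 - 2 * db, "O": oh})
        if self.bond_type == "lcb":
            return ChemicalFormula({"C": c, "H": 2 * c + 3 - 2 * db, "N": 1, "O": oh})
        raise ValueError(f"unknown bond type {self.bond_type!r}")

    def free_formula(self) -> ChemicalFormula:
        """Composition of the free building block (fatty acid / alcohol /
        sphingoid base) used as the FAi/LCB token in fragment rules."""
        c, db, oh = self.carbons, self.double_bonds, self.hydroxyls
        if self.bond_type == "acyl":
            return ChemicalFormula({"C": c, "H": 2 * c - 2 * db, "O": 2 + oh})
        if self.bond_type == "ether":
            return ChemicalFormula({"C": c, "H": 2 * c + 2 - 2 * db, "O": 1 + oh})
        if self.bond_type == "vinyl":
            return ChemicalFormula({"C": c, "H": 2 * c - 2 * db, "O": 1 + oh})
        if self.bond_type == "lcb":
            return self.residue_formula()
        raise ValueError(f"unknown bond type {self.bond_type!r}")

    # -- naming --------------------------------------------------------
    def shorthand(self) -> str:
        text = _PREFIX_FOR_BOND.get(self.bond_type, "")
        text += f"{self.carbons}:{self.double_bonds}"
        if self.hydroxyls:
            text += f";{self.hydroxyls}"
        return text


@dataclass(frozen=True)
class IsotopeLabel:
    """Stable-isotope label on a building block.

    ``target`` is ``"M"`` (whole molecule), ``"HG"``, ``"FA1"``..``"FA4"``
    or ``"LCB"``; ``substitutions`` maps light element → number of atoms
    replaced by the heavy isotope (C→13C, H→2H, N→15N).
    """

    target: str = "M"
    substitutions: tuple[tuple[str, int], ...] = ()

    _HEAVY = {"C": "[13C]", "H": "[2H]", "N": "[15N]"}

    def __post_init__(self) -> None:
        for light, n in self.substitutions:
            if light not in self._HEAVY:
                raise ValueError(f"no heavy isotope configured for {light!r}")
            if n < 0:
                raise ValueError("substitution count must be non-negative")

    def __bool__(self) -> bool:
        return any(n > 0 for _, n in self.substitutions)

    def apply(self, formula: ChemicalFormula) -> ChemicalFormula:
        for light, n in self.substitutions:
            formula = formula.substitute(light, self._HEAVY[light], n)
        return formula

    @property
    def mass_shift(self) -> float:
        from .chem import element_mass

        return sum(
            n * (element_mass(self._HEAVY[light]) - element_mass(light))
            for light, n in self.substitutions
        )

    def suffix(self) -> str:
        if not self:
            return ""
        subs = dict(self.substitutions)
        if self.target == "M" and set(k for k, v in subs.items() if v) == {"H"}:
            return f"(d{subs['H']})"
        parts = []
        for light, n in self.substitutions:
            if n:
                parts.append(f"{self._HEAVY[light]}{n}")
        where = "" if self.target == "M" else f"@{self.target}"
        return "(" + ",".join(parts) + where + ")"


def canonicalize_acyls(
    acyls: list[FattyAcylInstance] | tuple[FattyAcylInstance, ...]
) -> tuple[FattyAcylInstance, ...]:
    """Stable ascending sort by (carbons, double bonds, hydroxyls).

    Ether/vinyl chains sort before plain acyls (they occupy sn-1 by
    convention); the LCB, when present, is a distinct slot and is not
    passed through here.  Idempotent.
    """
    if not acyls:
        raise ValueError("need at least one chain")
    rank = {"ether": 0, "vinyl": 0, "acyl": 1}
    return tuple(
        sorted(
            acyls,
            key=lambda a: (
                rank.get(a.bond_type, 2),
                a.carbons,
                a.double_bonds,
                a.hydroxyls,
            ),
        )
    )


@dataclass(frozen=True)
class LipidSpecies:
    """A concrete lipid: class + ordered chains (+ optional isotope label).

    ``acyls`` holds the LCB first for sphingolipid classes, then the fatty
    acyl slots in canonical order (unless ``sn_known``).  ``species_level``
    marks sum-composition names like ``PC 34:1`` whose per-chain make-up is
    unresolved.
    """

    class_name: str
    acyls: tuple[FattyAcylInstance, ...]
    sn_known: bool = False
    label: IsotopeLabel = field(default_factory=IsotopeLabel)
    species_level: bool = False

    @property
    def lcb(self) -> FattyAcylInstance | None:
        return self.acyls[0] if self.acyls and self.acyls[0].bond_type == "lcb" else None

    @property
    def fatty_acyls(self) -> tuple[FattyAcylInstance, ...]:
        return self.acyls[1:] if self.lcb else self.acyls

    def display_name(self) -> str:
        sep = "/" if self.sn_known else "_"
        chains = sep.join(a.shorthand() for a in self.acyls)
        return f"{self.class_name} {chains}{self.label.suffix()}"

    def with_label(self, label: IsotopeLabel) -> "LipidSpecies":
        return replace(self, label=label)


def _canonical(species: LipidSpecies) -> LipidSpecies:
    if species.sn_known or species.species_level:
        return species
    lcb = species.lcb
    fas = canonicalize_acyls(species.fatty_acyls) if species.fatty_acyls else ()
    acyls = ((lcb,) + fas) if lcb else fas
    return replace(species, acyls=acyls)


# ----------------------------------------------------------------------
# assembly

def assemble_neutral(species: LipidSpecies, cdef: LipidClassDef) -> ChemicalFormula:
    """Neutral molecular formula: scaffold + chain residues, label applied."""
    blocks = block_formulas(species, cdef)
    return blocks["PRECURSOR"]


def block_formulas(
    species: LipidSpecies, cdef: LipidClassDef
) -> dict[str, ChemicalFormula]:
    """Free building-block formulas for fragment-rule tokens.

    Returns PRECURSOR (assembled neutral), HG, FA1..FAn and LCB as
    applicable.  The isotope label is applied to its target block, so a
    label on FA1 shifts only blocks whose expression references FA1 (and
    the precursor, which contains every block).
    """
    if species.species_level:
        k = cdef.n_acyl_slots
        tot = species.acyls[0]
        c, db, oh = tot.carbons, tot.double_bonds, tot.hydroxyls
        residue_sum = ChemicalFormula({"C": c, "H": 2 * c - 2 * db - k, "O": k + oh})
        neutral = cdef.scaffold + residue_sum
        if species.label and species.label.target == "M":
            neutral = species.label.apply(neutral)
        return {"PRECURSOR": neutral, "HG": cdef.head_group}

    lcb = species.lcb
    fas = species.fatty_acyls
    if len(fas) != cdef.n_acyl_slots or bool(lcb) != cdef.has_lcb:
        raise ValueError(
            f"{species.display_name()}: expected {cdef.n_acyl_slots} fatty "
            f"acyl(s){' + LCB' if cdef.has_lcb else ''} for class "
            f"{cdef.class_name}, got {len(fas)}{' + LCB' if lcb else ''}"
        )
    for fa in fas:
        if fa.bond_type not in cdef.fa_spec.bond_types:
            raise ValueError(
                f"class {cdef.class_name} does not admit {fa.bond_type} chains"
            )

    label = species.label
    blocks: dict[str, ChemicalFormula] = {}
    hg = cdef.head_group
    if label and label.target == "HG":
        hg = label.apply(hg)
    blocks["HG"] = hg

    residues: list[ChemicalFormula] = []
    if lcb:
        free = lcb.free_formula()
        res = lcb.residue_formula()
        if label and label.target == "LCB":
            free, res = label.apply(free), label.apply(res)
        blocks["LCB"] = free
        residues.append(res)
    for i, fa in enumerate(fas, start=1):
        free = fa.free_formula()
        res = fa.residue_formula()
        if label and label.target == f"FA{i}":
            free, res = label.apply(free), label.apply(res)
        blocks[f"FA{i}"] = free
        residues.append(res)

    neutral = cdef.scaffold
    for res in residues:
        neutral = neutral + res
    if label and label.target == "HG":
        # head-group atoms sit in the scaffold; shift the assembled neutral
        # by the label mass via direct substitution
        neutral = label.apply(neutral)
    if label and label.target == "M":
        neutral = label.apply(neutral)
    if not neutral.is_physical():
        raise ValueError(
            f"{species.display_name()}: assembled formula {neutral} has "
            f"negative element counts"
        )
    blocks["PRECURSOR"] = neutral
    return blocks


# ----------------------------------------------------------------------
# enumeration

def _variants(spec: FattyAcylSpec, bond_type: str = "acyl") -> list[FattyAcylInstance]:
    out = []
    for c in range(spec.carbons[0], spec.carbons[1] + 1):
        for db in range(spec.double_bonds[0], spec.double_bonds[1] + 1):
            if db > (c - 1) // 2:
                continue
            for oh in range(spec.hydroxyls[0], spec.hydroxyls[1] + 1):
                out.append(FattyAcylInstance(c, db, oh, bond_type))
    return out


def enumerate_species(
    cdef: LipidClassDef,
    fa_specs: list[FattyAcylSpec] | None = None,
    lcb_spec: FattyAcylSpec | None = None,
    even_chain: bool = False,
) -> list[LipidSpecies]:
    """Expand constraint envelopes into the canonical, duplicate-free
    species set for one class.

    When all fatty-acyl slots share one spec (pass a single-element list or
    ``None`` for the class default), equivalent slots are treated as an
    unordered multiset — ``PC 12:0_14:0`` appears once.  Per-slot distinct
    specs fall back to a cartesian product followed by canonical dedup.
    ``even_chain`` restricts to even carbon counts (biological convention).
    """
    n = cdef.n_acyl_slots
    if fa_specs is None:
        fa_specs = [cdef.fa_spec] * n
    elif len(fa_specs) == 1 and n > 1:
        fa_specs = list(fa_specs) * n
    if len(fa_specs) != n:
        raise ValueError(f"class {cdef.class_name} has {n} acyl slots, got "
                         f"{len(fa_specs)} specs")
    for spec in fa_specs:
        if not (
            spec.carbons[0] >= cdef.fa_spec.carbons[0]
            and spec.carbons[1] <= cdef.fa_spec.carbons[1]
        ):
            raise ValueError(
                f"requested carbons {spec.carbons} outside class envelope "
                f"{cdef.fa_spec.carbons}"
            )

    def keep(v: FattyAcylInstance) -> bool:
        return not even_chain or v.carbons % 2 == 0

    per_slot = [[v for v in _variants(s) if keep(v)] for s in fa_specs]

    lcb_variants: list[FattyAcylInstance | None] = [None]
    if cdef.has_lcb:
        spec = lcb_spec or cdef.lcb_spec
        lcb_variants = [v for v in _variants(spec, "lcb") if keep(v)]  # type: ignore[arg-type]

    species: list[LipidSpecies] = []
    seen: set[tuple] = set()
    equivalent = n > 1 and all(s == fa_specs[0] for s in fa_specs)
    if equivalent:
        combos = list(itertools.combinations_with_replacement(sorted(per_slot[0]), n))
    elif per_slot:
        combos = list(itertools.product(*per_slot))
    else:
        combos = [()]

    for lcb in lcb_variants:
        for combo in combos:
            acyls = canonicalize_acyls(list(combo)) if combo else ()
            full = ((lcb,) + acyls) if lcb else acyls
            key = (lcb, acyls)
            if key in seen:
                continue
            seen.add(key)
            species.append(LipidSpecies(cdef.class_name, full, sn_known=False))
    species.sort(key=lambda s: s.display_name())
    return species


def parse_acyl_constraint(text: str) -> FattyAcylSpec:
    """Parse a CLI constraint like ``"C:12-18,db:0-2,oh:0"``."""
    carbons, db, oh = (2, 26), (0, 6), (0, 0)
    bond_types: tuple[str, ...] = ("acyl",)
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        key, _, val = part.partition(":")
        lo, _, hi = val.partition("-")
        rng = (int(lo), int(hi) if hi else int(lo))
        key = key.lower()
        if key == "c":
            carbons = rng
        elif key == "db":
            db = rng
        elif key == "oh":
            oh = rng
        elif key == "bond":
            bond_types = tuple(val.split("|"))
        else:
            raise ValueError(f"unknown constraint key {key!r} in {text!r}")
    return FattyAcylSpec(carbons, db, oh, bond_types)


# ----------------------------------------------------------------------
# shorthand name parsing

_CHAIN_RE = re.compile(r"^(O-|P-)?(\d+):(\d+)(?:;(\d+))?$")
_LABEL_RE = re.compile(r"\(d(\d+)\)$")


def _parse_chain(tok: str, pos: int, bond_type: str = "acyl") -> FattyAcylInstance:
    m = _CHAIN_RE.match(tok)
    if not m:
        raise ValueError(f"malformed chain token {tok!r} at position {pos}")
    prefix, c, db, oh = m.groups()
    bt = _BOND_PREFIX.get(prefix, bond_type) if prefix else bond_type
    return FattyAcylInstance(int(c), int(db), int(oh or 0), bt)


def parse_lipid_name(text: str, kb: KnowledgeBase) -> LipidSpecies:
    """Parse a shorthand lipid name into a :class:`LipidSpecies`.

    Accepts the updated shorthand dialect plus LIPID MAPS class-token
    synonyms (``TAG`` → ``TG`` etc.).  ``format(parse(x))`` reproduces the
    canonical form of ``x``; ``_``-joined chains are canonicalized.  Sum
    composition names (``PC 34:1``) parse to a species-level record.
    """
    text = text.strip()
    label = IsotopeLabel()
    m = _LABEL_RE.search(text)
    if m:
        label = IsotopeLabel("M", (("H", int(m.group(1))),))
        text = text[: m.start()].strip()

    cls_tok, _, chain_text = text.partition(" ")
    cls_name = CLASS_SYNONYMS.get(cls_tok, cls_tok)
    cdef = kb.get_class(cls_name)  # raises listing known classes
    if not chain_text:
        raise ValueError(f"lipid name {text!r} has no chain part")

    sn_known = "/" in chain_text
    if "/" in chain_text and "_" in chain_text:
        raise ValueError(f"mixed '/' and '_' separators in {text!r}")
    tokens = re.split(r"[/_]", chain_text)
    chains = []
    pos = len(cls_tok) + 1
    for i, tok in enumerate(tokens):
        bt = "lcb" if (cdef.has_lcb and i == 0) else "acyl"
        chains.append(_parse_chain(tok.strip(), pos, bt))
        pos += len(tok) + 1

    n_expected = cdef.n_acyl_slots + (1 if cdef.has_lcb else 0)
    if len(chains) == 1 and n_expected > 1 and chains[0].bond_type == "acyl":
        sp = LipidSpecies(cls_name, tuple(chains), sn_known=False,
                          label=label, species_level=True)
        return sp
    if len(chains) != n_expected:
        raise ValueError(
            f"class {cls_name} expects {n_expected} chains, got {len(chains)} "
            f"in {text!r}"
        )
    sp = LipidSpecies(cls_name, tuple(chains), sn_known=sn_known, label=label)
    return _canonical(sp)


def expand_species_name(species: LipidSpecies, cdef: LipidClassDef) -> list[LipidSpecies]:
    """Expand a sum-composition species into all molecular species with the
    same totals inside the class envelope."""
    if not species.species_level:
        return [species]
    tot = species.acyls[0]
    n = cdef.n_acyl_slots
    out = []
    seen = set()
    spec = cdef.fa_spec
    for carbons in itertools.product(
        range(spec.carbons[0], spec.carbons[1] + 1), repeat=n
    ):
        if sum(carbons) != tot.carbons:
            continue
        for dbs in itertools.product(
            range(spec.double_bonds[0], spec.double_bonds[1] + 1), repeat=n
        ):
            if sum(dbs) != tot.double_bonds:
                continue
            try:
                acyls = canonicalize_acyls(
                    [FattyAcylInstance(c, d) for c, d in zip(carbons, dbs)]
                )
            except ValueError:
                continue
            if acyls in seen:
                continue
            seen.add(acyls)
            out.append(replace(species, acyls=acyls, species_level=False))
    out.sort(key=lambda s: s.display_name())
    return out
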