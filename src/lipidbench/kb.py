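"""Declarative lipid knowledge base: classes, building blocks, fragment rules.

The store has two levels.  The *precursor level* (``classes.csv``) describes
how each lipid class is assembled from building blocks: a scaffold formula,
the number of fatty-acyl slots, whether a long-chain base (LCB) is present,
the allowed adducts per polarity and the acyl constraint envelope.  The
*fragment level* (``fragments.csv``) holds named calculation rules — signed
linear expressions over building-block tokens plus literal formulas — that
generate fragment compositions for any concrete species of the class.

Both files are plain CSV so that new classes and fragments can be added by
editing text, mirroring a community-extension workflow; every row carries a
provenance citation.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .chem import ChemicalFormula, parse_formula

__all__ = [
    "FattyAcylSpec",
    "LipidClassDef",
    "FragmentRule",
    "KnowledgeBase",
    "load_knowledge_base",
    "resolve_fragment_rule",
    "BLOCK_TOKENS",
]

#: Tokens a fragment-rule expression may reference, besides literal formulas.
BLOCK_TOKENS = ("PRECURSOR", "HG", "FA1", "FA2", "FA3", "FA4", "LCB")

BOND_TYPES = ("acyl", "ether", "vinyl", "lcb")

CATEGORIES = ("GL", "PL", "SP", "ST", "LM")


def _parse_range(text: str, default: tuple[int, int]) -> tuple[int, int]:
    text = (text or "").strip()
    if not text:
        return default
    if "-" in text:
        lo, hi = text.split("-")
        return int(lo), int(hi)
    v = int(text)
    return v, v


@dataclass(frozen=True)
class FattyAcylSpec:
    """Constraint envelope for one chain slot.

    ``carbons``/``double_bonds``/``hydroxyls`` are inclusive integer ranges;
    ``bond_types`` the admissible linkages (ester acyl, plasmanyl ether,
    plasmenyl vinyl-ether, or LCB).
    """

    carbons: tuple[int, int]
    double_bonds: tuple[int, int]
    hydroxyls: tuple[int, int]
    bond_types: tuple[str, ...] = ("acyl",)

    def __post_init__(self) -> None:
        if self.carbons[0] < 2:
            raise ValueError("chains need at least 2 carbons")
        for bt in self.bond_types:
            if bt not in BOND_TYPES:
                raise ValueError(f"unknown bond type {bt!r}")

    def admits(self, carbons: int, double_bonds: int, hydroxyls: int) -> bool:
        return (
            self.carbons[0] <= carbons <= self.carbons[1]
            and self.double_bonds[0] <= double_bonds <= self.double_bonds[1]
            and self.hydroxyls[0] <= hydroxyls <= self.hydroxyls[1]
            and double_bonds <= (carbons - 1) // 2
        )


@dataclass(frozen=True)
class LipidClassDef:
    """One lipid class at the precursor level."""

    category: str
    class_name: str
    n_acyl_slots: int
    has_lcb: bool
    scaffold: ChemicalFormula
    head_group: ChemicalFormula
    adducts_pos: tuple[str, ...]
    adducts_neg: tuple[str, ...]
    fa_spec: FattyAcylSpec
    lcb_spec: FattyAcylSpec | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0 <= self.n_acyl_slots <= 4:
            raise ValueError("acyl slot count must be in 0..4")
        if not (self.adducts_pos or self.adducts_neg):
            raise ValueError(f"class {self.class_name}: at least one adduct required")
        if self.has_lcb and self.lcb_spec is None:
            raise ValueError(f"class {self.class_name}: LCB slot without LCB spec")

    @property
    def slots(self) -> tuple[str, ...]:
        """Token names of the chain slots this backbone provides."""
        toks = tuple(f"FA{i + 1}" for i in range(self.n_acyl_slots))
        return (("LCB",) + toks) if self.has_lcb else toks

    def allowed_adducts(self, polarity: str) -> tuple[str, ...]:
        return self.adducts_pos if polarity == "+" else self.adducts_neg


@dataclass(frozen=True)
class FragmentRule:
    """A named fragment as a signed linear expression over block tokens.

    ``terms`` maps token → integer coefficient; ``constant`` is the literal
    formula part.  The resolved composition is that of the *charged*
    fragment, so m/z follows as (mass − charge·m_e)/|charge|.
    """

    class_name: str
    fragment_name: str
    polarity: str
    charge: int
    terms: tuple[tuple[str, int], ...]
    constant: ChemicalFormula
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in "+-":
            raise ValueError("polarity must be '+' or '-'")
        if self.charge == 0 or (self.charge > 0) != (self.polarity == "+"):
            raise ValueError(
                f"rule {self.fragment_name!r}: charge {self.charge} inconsistent "
                f"with polarity {self.polarity!r}"
            )

    @property
    def referenced_blocks(self) -> tuple[str, ...]:
        return tuple(tok for tok, _ in self.terms)

    def expression_text(self) -> str:
        parts = [f"{tok} {c:+d}" for tok, c in self.terms]
        if self.constant:
            parts.append(f"{self.constant.hill()} +1")
        return ", ".join(parts)


def parse_rule_expression(text: str) -> tuple[tuple[tuple[str, int], ...], ChemicalFormula]:
    """Parse ``"PRECURSOR +1, H +1, FA1 -1"`` into (token terms, constant)."""
    terms: list[tuple[str, int]] = []
    constant = ChemicalFormula()
    for raw in text.split(","):
        raw = raw.strip()
        if not raw:
            continue
        fields = raw.rsplit(None, 1)
        if len(fields) != 2:
            raise ValueError(f"malformed expression term {raw!r}")
        tok, coeff_text = fields
        try:
            coeff = int(coeff_text)
        except ValueError:
            raise ValueError(f"malformed coefficient in term {raw!r}") from None
        if tok in BLOCK_TOKENS:
            terms.append((tok, coeff))
        else:
            constant = constant + parse_formula(tok) * coeff
    return tuple(terms), constant


@dataclass
class KnowledgeBase:
    """Validated collection of class definitions and fragment rules."""

    classes: dict[str, LipidClassDef] = field(default_factory=dict)
    rules: list[FragmentRule] = field(default_factory=list)

    def get_class(self, name: str) -> LipidClassDef:
        try:
            return self.classes[name]
        except KeyError:
            known = ", ".join(sorted(self.classes))
            raise KeyError(f"unknown lipid class {name!r}; known: {known}") from None

    def rules_for(self, class_name: str, polarity: str | None = None) -> list[FragmentRule]:
        return [
            r
            for r in self.rules
            if r.class_name == class_name
            and (polarity is None or r.polarity == polarity)
        ]

    def summary(self) -> str:
        return f"{len(self.classes)} classes, {len(self.rules)} fragment rules"

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        """Debug/round-trip export of the loaded KB."""
        payload = {
            "classes": [
                {
                    "category": c.category,
                    "class_name": c.class_name,
                    "n_acyl_slots": c.n_acyl_slots,
                    "has_lcb": c.has_lcb,
                    "scaffold": c.scaffold.hill(),
                    "head_group": c.head_group.hill(),
                    "adducts_pos": list(c.adducts_pos),
                    "adducts_neg": list(c.adducts_neg),
                    "fa_spec": {
                        "carbons": c.fa_spec.carbons,
                        "double_bonds": c.fa_spec.double_bonds,
                        "hydroxyls": c.fa_spec.hydroxyls,
                        "bond_types": list(c.fa_spec.bond_types),
                    },
                    "lcb_spec": None
                    if c.lcb_spec is None
                    else {
                        "carbons": c.lcb_spec.carbons,
                        "double_bonds": c.lcb_spec.double_bonds,
                        "hydroxyls": c.lcb_spec.hydroxyls,
                    },
                    "provenance": c.provenance,
                }
                for c in self.classes.values()
            ],
            "rules": [
                {
                    "class_name": r.class_name,
                    "fragment_name": r.fragment_name,
                    "polarity": r.polarity,
                    "charge": r.charge,
                    "expression": r.expression_text(),
                    "provenance": r.provenance,
                }
                for r in self.rules
            ],
        }
        return json.dumps(payload, indent=2)


def _read_csv(path_or_text) -> list[dict]:
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        text = path_or_text
    else:
        text = Path(path_or_text).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    return list(csv.DictReader(io.StringIO("\n".join(lines))))


def _class_from_row(row: dict) -> LipidClassDef:
    fa_spec = FattyAcylSpec(
        carbons=_parse_range(row.get("fa_carbons", ""), (2, 26)),
        double_bonds=_parse_range(row.get("fa_double_bonds", ""), (0, 6)),
        hydroxyls=_parse_range(row.get("fa_hydroxyls", ""), (0, 1)),
        bond_types=tuple((row.get("fa_bond_types") or "acyl").split(";")),
    )
    has_lcb = row.get("has_lcb", "0").strip() in ("1", "true", "yes")
    lcb_spec = None
    if has_lcb:
        lcb_spec = FattyAcylSpec(
            carbons=_parse_range(row.get("lcb_carbons", ""), (14, 22)),
            double_bonds=_parse_range(row.get("lcb_double_bonds", ""), (0, 2)),
            hydroxyls=_parse_range(row.get("lcb_hydroxyls", ""), (1, 3)),
            bond_types=("lcb",),
        )

    def adduct_list(key: str) -> tuple[str, ...]:
        raw = (row.get(key) or "").strip()
        return tuple(a for a in raw.split(";") if a) if raw else ()

    return LipidClassDef(
        category=row["category"].strip(),
        class_name=row["class_name"].strip(),
        n_acyl_slots=int(row["n_acyl_slots"]),
        has_lcb=has_lcb,
        scaffold=parse_formula(row["scaffold_formula"].strip()),
        head_group=parse_formula((row.get("head_group_formula") or "").strip()),
        adducts_pos=adduct_list("adducts_pos"),
        adducts_neg=adduct_list("adducts_neg"),
        fa_spec=fa_spec,
        lcb_spec=lcb_spec,
        provenance=(row.get("provenance") or "").strip(),
    )


def load_knowledge_base(path: str | Path | None = None) -> KnowledgeBase:
    """Load and validate a knowledge base.

    ``path`` is a directory containing ``classes.csv`` and ``fragments.csv``;
    ``None`` loads the packaged default KB.  Validation rejects duplicate
    class names, duplicate fragment names per (class, polarity), and rules
    referencing chain slots the class backbone does not provide.
    """
    if path is None:
        pkg = resources.files("lipidbench.data").joinpath("kb")
        classes_text = pkg.joinpath("classes.csv").read_text()
        fragments_text = pkg.joinpath("fragments.csv").read_text()
    else:
        path = Path(path)
        classes_text = (path / "classes.csv").read_text()
        fragments_text = (path / "fragments.csv").read_text()

    kb = KnowledgeBase()
    for row in _read_csv(classes_text):
        cdef = _class_from_row(row)
        if cdef.class_name in kb.classes:
            raise ValueError(f"duplicate lipid class {cdef.class_name!r}")
        kb.classes[cdef.class_name] = cdef

    seen: set[tuple[str, str, str]] = set()
    for row in _read_csv(fragments_text):
        terms, constant = parse_rule_expression(row["expression"])
        rule = FragmentRule(
            class_name=row["class_name"].strip(),
            fragment_name=row["fragment_name"].strip(),
            polarity=row["polarity"].strip(),
            charge=int(row["charge"]),
            terms=terms,
            constant=constant,
            provenance=(row.get("provenance") or "").strip(),
        )
        if rule.class_name not in kb.classes:
            raise ValueError(
                f"fragment {rule.fragment_name!r} references unknown class "
                f"{rule.class_name!r}"
            )
        key = (rule.class_name, rule.polarity, rule.fragment_name)
        if key in seen:
            raise ValueError(
                f"duplicate fragment name {rule.fragment_name!r} for "
                f"({rule.class_name}, {rule.polarity})"
            )
        seen.add(key)
        cdef = kb.classes[rule.class_name]
        valid_tokens = ("PRECURSOR", "HG") + cdef.slots
        for tok in rule.referenced_blocks:
            if tok not in valid_tokens:
                raise ValueError(
                    f"rule {rule.fragment_name!r} of class {rule.class_name} "
                    f"references slot {tok!r} absent from its backbone "
                    f"(available: {', '.join(valid_tokens)})"
                )
        kb.rules.append(rule)
    return kb


def resolve_fragment_rule(
    rule: FragmentRule, blocks: dict[str, ChemicalFormula]
) -> tuple[ChemicalFormula, int]:
    """Evaluate a rule against concrete building-block formulas.

    ``blocks`` maps token → free building-block formula (``PRECURSOR`` is the
    assembled neutral species; ``FAi``/``LCB`` the free fatty acid / base).
    Returns the charged fragment's composition and its charge.  A resolved
    formula with any negative element count is rejected, naming the rule.
    """
    formula = ChemicalFormula(dict(rule.constant.counts))
    for tok, coeff in rule.terms:
        if tok not in blocks:
            raise KeyError(
                f"rule {rule.fragment_name!r} needs block {tok!r} which the "
                f"species does not provide"
            )
        formula = formula + blocks[tok] * coeff
    if not formula.is_physical():
        raise ValueError(
            f"rule {rule.fragment_name!r} resolves to non-physical composition "
            f"{formula} for the given species"
        )
    return formula, rule.charge
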