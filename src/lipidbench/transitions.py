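"""Assemble precursor/fragment ions and export transition lists & libraries.

The transition layer turns selected species into precursor–product ion pairs
(with isotope labels applied block-wise), and the export layer writes them
as CSV transition lists — a Skyline small-molecule importable dialect and a
vendor-agnostic "plain" dialect — or as spectral libraries (msp text, and a
minimal BiblioSpec-style SQLite ``.blib``).
"""

from __future__ import annotations

import csv
import sqlite3
import struct
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

from .chem import ChemicalFormula, ELECTRON_MASS, Adduct, get_adduct, ion_mz
from .kb import KnowledgeBase, resolve_fragment_rule
from .species import IsotopeLabel, LipidSpecies, block_formulas

__all__ = [
    "IonRecord",
    "Transition",
    "build_precursor_ion",
    "build_fragment_ions",
    "apply_isotope_label",
    "build_transitions",
    "export_transition_list",
    "read_transition_list",
    "write_msp",
    "read_msp",
    "write_blib",
]


@dataclass(frozen=True)
class IonRecord:
    """A named ion: composition of the charged species plus m/z."""

    name: str
    formula: ChemicalFormula
    mz: float
    charge: int

    @property
    def polarity(self) -> str:
        return "+" if self.charge > 0 else "-"


@dataclass(frozen=True)
class Transition:
    """One precursor → product row of a targeted assay."""

    molecule_list: str
    precursor_name: str
    precursor_formula: str
    precursor_adduct: str
    precursor_mz: float
    precursor_charge: int
    product_name: str
    product_formula: str
    product_mz: float
    product_charge: int
    explicit_ce: float | None = None
    relative_intensity: float | None = None

    def __post_init__(self) -> None:
        if (self.precursor_charge > 0) != (self.product_charge > 0):
            raise ValueError(
                f"transition {self.precursor_name} -> {self.product_name}: "
                f"precursor and product polarities differ"
            )
        # sanity bound: a product heavier than its (singly charged) precursor
        # indicates a charge-state bookkeeping error
        if abs(self.product_charge) >= abs(self.precursor_charge) and (
            self.product_mz > self.precursor_mz + 1.0
        ):
            raise ValueError(
                f"transition {self.precursor_name} -> {self.product_name}: "
                f"product m/z {self.product_mz:.4f} exceeds precursor "
                f"{self.precursor_mz:.4f} + 1.0"
            )


def fragment_mz(formula: ChemicalFormula, charge: int) -> float:
    """m/z of a charged fragment whose composition already includes all atoms."""
    return (formula.mass - charge * ELECTRON_MASS) / abs(charge)


def build_precursor_ion(
    species: LipidSpecies, adduct: Adduct | str, kb: KnowledgeBase
) -> IonRecord:
    """Assemble the precursor ion of ``species`` under ``adduct``.

    The adduct must be enabled for the species' class in the KB (polarity
    taken from the adduct charge sign).
    """
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    cdef = kb.get_class(species.class_name)
    allowed = cdef.allowed_adducts(adduct.polarity)
    if adduct.name not in allowed:
        raise ValueError(
            f"adduct {adduct.name} not enabled for class {cdef.class_name} "
            f"(allowed: {', '.join(allowed) or 'none'})"
        )
    neutral = block_formulas(species, cdef)["PRECURSOR"]
    mz = ion_mz(neutral, adduct)
    name = f"{species.display_name()} {adduct.name}"
    return IonRecord(name, neutral + adduct.delta, mz, adduct.charge)


def build_fragment_ions(
    species: LipidSpecies, polarity: str, kb: KnowledgeBase
) -> list[IonRecord]:
    """Resolve every applicable fragment rule of the species' class.

    Rules referencing chain slots are evaluated with the species' actual
    building blocks, so an isotope label on FA1 shifts only fragments whose
    expression includes FA1.  Classes without rules for the requested
    polarity yield an empty list with a warning (many classes carry a single
    informative fragment in positive mode only).
    """
    cdef = kb.get_class(species.class_name)
    rules = kb.rules_for(cdef.class_name, polarity)
    if not rules:
        warnings.warn(
            f"class {cdef.class_name} has no fragment rules for polarity "
            f"{polarity!r}",
            stacklevel=2,
        )
        return []
    blocks = block_formulas(species, cdef)
    out = []
    for rule in rules:
        formula, charge = resolve_fragment_rule(rule, blocks)
        out.append(IonRecord(rule.fragment_name, formula, fragment_mz(formula, charge), charge))
    return out


def apply_isotope_label(species: LipidSpecies, label: IsotopeLabel, kb: KnowledgeBase) -> LipidSpecies:
    """Return the labeled species, checking substitution feasibility.

    The label target must have enough light atoms; otherwise the rejection
    names the available count.  The labeled species' neutral mass exceeds
    the unlabeled one by exactly the summed isotope mass differences.
    """
    labeled = species.with_label(label)
    block_formulas(labeled, kb.get_class(species.class_name))  # feasibility
    return labeled


def build_transitions(
    species_list: list[LipidSpecies],
    adduct_names: list[str],
    kb: KnowledgeBase,
    molecule_list: str = "lipidbench",
    explicit_ce: float | None = None,
) -> list[Transition]:
    """Cross species with adducts; one transition per resolved fragment.

    Adducts not enabled for a class are skipped silently (so one adduct
    panel can serve a mixed-class assay); classes without fragment rules in
    an adduct's polarity contribute no rows.
    """
    rows: list[Transition] = []
    for sp in species_list:
        cdef = kb.get_class(sp.class_name)
        for aname in adduct_names:
            adduct = get_adduct(aname)
            if aname not in cdef.allowed_adducts(adduct.polarity):
                continue
            prec = build_precursor_ion(sp, adduct, kb)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                frags = build_fragment_ions(sp, adduct.polarity, kb)
            for frag in frags:
                rows.append(
                    Transition(
                        molecule_list=molecule_list,
                        precursor_name=sp.display_name(),
                        precursor_formula=prec.formula.hill(),
                        precursor_adduct=aname,
                        precursor_mz=prec.mz,
                        precursor_charge=prec.charge,
                        product_name=frag.name,
                        product_formula=frag.formula.hill(),
                        product_mz=frag.mz,
                        product_charge=frag.charge,
                        explicit_ce=explicit_ce,
                    )
                )
    rows.sort(key=lambda t: (t.precursor_name, t.product_mz))
    return rows


# ----------------------------------------------------------------------
# transition list CSV

_SKYLINE_HEADER = [
    "Molecule List Name",
    "Precursor Name",
    "Precursor Formula",
    "Precursor Adduct",
    "Precursor m/z",
    "Precursor Charge",
    "Product Name",
    "Product Formula",
    "Product m/z",
    "Product Charge",
    "Explicit Collision Energy",
    "Library Intensity",
]

_PLAIN_HEADER = ["name", "precursor_mz", "product_name", "product_mz", "charge", "ce"]


def export_transition_list(
    transitions: list[Transition], path: str | Path, dialect: str = "skyline"
) -> Path:
    """Write transitions as CSV (``skyline`` or ``plain`` dialect).

    Rows are sorted by precursor name then product m/z for bit-stable
    output.  Mixed-polarity lists are legal (both-polarity assays are a
    feature) but flagged with a warning; nothing is dropped.
    """
    if not transitions:
        raise ValueError("refusing to export an empty transition list")
    pols = {t.precursor_charge > 0 for t in transitions}
    if len(pols) > 1:
        warnings.warn("transition list mixes polarities", stacklevel=2)
    rows = sorted(transitions, key=lambda t: (t.precursor_name, t.product_mz))
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        if dialect == "skyline":
            w.writerow(_SKYLINE_HEADER)
            for t in rows:
                w.writerow(
                    [
                        t.molecule_list,
                        t.precursor_name,
                        t.precursor_formula,
                        t.precursor_adduct,
                        f"{t.precursor_mz:.6f}",
                        t.precursor_charge,
                        t.product_name,
                        t.product_formula,
                        f"{t.product_mz:.6f}",
                        t.product_charge,
                        "" if t.explicit_ce is None else f"{t.explicit_ce:g}",
                        ""
                        if t.relative_intensity is None
                        else f"{t.relative_intensity:.6f}",
                    ]
                )
        elif dialect == "plain":
            w.writerow(_PLAIN_HEADER)
            for t in rows:
                w.writerow(
                    [
                        t.precursor_name,
                        f"{t.precursor_mz:.6f}",
                        t.product_name,
                        f"{t.product_mz:.6f}",
                        t.precursor_charge,
                        "" if t.explicit_ce is None else f"{t.explicit_ce:g}",
                    ]
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r} (skyline or plain)")
    return path


def read_transition_list(path: str | Path) -> list[Transition]:
    """Re-import a ``skyline``-dialect transition CSV written by
    :func:`export_transition_list`."""
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                Transition(
                    molecule_list=row["Molecule List Name"],
                    precursor_name=row["Precursor Name"],
                    precursor_formula=row["Precursor Formula"],
                    precursor_adduct=row["Precursor Adduct"],
                    precursor_mz=float(row["Precursor m/z"]),
                    precursor_charge=int(row["Precursor Charge"]),
                    product_name=row["Product Name"],
                    product_formula=row["Product Formula"],
                    product_mz=float(row["Product m/z"]),
                    product_charge=int(row["Product Charge"]),
                    explicit_ce=float(row["Explicit Collision Energy"])
                    if row.get("Explicit Collision Energy")
                    else None,
                    relative_intensity=float(row["Library Intensity"])
                    if row.get("Library Intensity")
                    else None,
                )
            )
    return out


# ----------------------------------------------------------------------
# spectral libraries

def write_msp(
    spectra: list[dict], path: str | Path
) -> Path:
    """Write an msp text spectral library.

    Each spectrum dict: ``name``, ``precursor_mz``, ``precursor_charge``,
    ``ce`` (optional) and ``peaks`` = list of (mz, relative_intensity,
    annotation).
    """
    path = Path(path)
    with path.open("w") as fh:
        for sp in spectra:
            fh.write(f"Name: {sp['name']}\n")
            fh.write(f"PrecursorMZ: {sp['precursor_mz']:.6f}\n")
            fh.write(f"Charge: {sp['precursor_charge']}\n")
            if sp.get("ce") is not None:
                fh.write(f"Comment: CE={sp['ce']:g}\n")
            fh.write(f"Num Peaks: {len(sp['peaks'])}\n")
            for mz, inten, ann in sp["peaks"]:
                fh.write(f"{mz:.6f} {inten:.6f} \"{ann}\"\n")
            fh.write("\n")
    return path


def read_msp(path: str | Path) -> list[dict]:
    """Parse an msp library written by :func:`write_msp`."""
    spectra: list[dict] = []
    current: dict | None = None
    n_expected = 0
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            current = None
            continue
        if line.startswith("Name:"):
            current = {"name": line[5:].strip(), "peaks": [], "ce": None}
            spectra.append(current)
        elif current is None:
            raise ValueError(f"peak data before Name: line: {line!r}")
        elif line.startswith("PrecursorMZ:"):
            current["precursor_mz"] = float(line.split(":")[1])
        elif line.startswith("Charge:"):
            current["precursor_charge"] = int(line.split(":")[1])
        elif line.startswith("Comment:"):
            for tok in line.split(":", 1)[1].split():
                if tok.startswith("CE="):
                    current["ce"] = float(tok[3:])
        elif line.startswith("Num Peaks:"):
            n_expected = int(line.split(":")[1])
        else:
            mz_s, inten_s, ann = line.split(None, 2)
            current["peaks"].append((float(mz_s), float(inten_s), ann.strip('"')))
    return spectra


def write_blib(spectra: list[dict], path: str | Path) -> Path:
    """Write a minimal BiblioSpec-style SQLite library (schema subset).

    Stores RefSpectra plus zlib-compressed little-endian peak arrays
    (float64 m/z, float32 intensity), enough for round-tripping in tools
    that read the core tables.  Not a byte-identical BiblioSpec build.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    con = sqlite3.connect(path)
    cur = con.cursor()
    cur.execute(
        "CREATE TABLE RefSpectra (id INTEGER PRIMARY KEY, peptideSeq TEXT, "
        "precursorMZ REAL, precursorCharge INTEGER, numPeaks INTEGER)"
    )
    cur.execute(
        "CREATE TABLE RefSpectraPeaks (RefSpectraID INTEGER, "
        "peakMZ BLOB, peakIntensity BLOB)"
    )
    for i, sp in enumerate(spectra, start=1):
        peaks = sp["peaks"]
        cur.execute(
            "INSERT INTO RefSpectra VALUES (?,?,?,?,?)",
            (i, sp["name"], sp["precursor_mz"], sp["precursor_charge"], len(peaks)),
        )
        mz_blob = zlib.compress(struct.pack(f"<{len(peaks)}d", *[p[0] for p in peaks]))
        in_blob = zlib.compress(struct.pack(f"<{len(peaks)}f", *[p[1] for p in peaks]))
        cur.execute("INSERT INTO RefSpectraPeaks VALUES (?,?,?)", (i, mz_blob, in_blob))
    con.commit()
    con.close()
    return path
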