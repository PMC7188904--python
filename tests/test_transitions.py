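"""Precursor/fragment assembly, isotope labels and list/library export."""

import warnings

import pytest

from lipidbench.chem import ELECTRON_MASS, element_mass, parse_formula
from lipidbench.kb import FattyAcylSpec
from lipidbench.species import IsotopeLabel, enumerate_species, parse_lipid_name
from lipidbench.transitions import (
    Transition,
    apply_isotope_label,
    build_fragment_ions,
    build_precursor_ion,
    build_transitions,
    export_transition_list,
    fragment_mz,
    read_msp,
    read_transition_list,
    write_blib,
    write_msp,
)

C13_SHIFT = element_mass("[13C]") - element_mass("C")  # 1.003355
D_SHIFT = element_mass("[2H]") - element_mass("H")


def test_pc_precursor_mz(kb):
    sp = parse_lipid_name("PC 16:0/18:1", kb)
    prec = build_precursor_ion(sp, "[M+H]1+", kb)
    assert prec.mz == pytest.approx(760.5851, abs=2e-4)
    assert prec.charge == 1


def test_adduct_polarity_symmetry(kb):
    sp = parse_lipid_name("PE 16:0_18:1", kb)
    pos = build_precursor_ion(sp, "[M+H]1+", kb)
    neg = build_precursor_ion(sp, "[M-H]1-", kb)
    assert pos.mz - neg.mz == pytest.approx(
        2 * (element_mass("H") - ELECTRON_MASS), abs=1e-9
    )


def test_disallowed_adduct_rejected(kb):
    sp = parse_lipid_name("TG 16:0_16:0_18:1", kb)
    with pytest.raises(ValueError, match="not enabled"):
        build_precursor_ion(sp, "[M-H]1-", kb)


def test_fragment_ions_positive_pc(kb):
    sp = parse_lipid_name("PC 16:0/18:1", kb)
    frags = build_fragment_ions(sp, "+", kb)
    by_name = {f.name: f for f in frags}
    assert any(abs(f.mz - 184.0733) < 2e-4 for f in frags)
    assert all(f.charge > 0 for f in frags)
    assert "NL183 [M+H-HG]" in by_name


def test_no_rules_polarity_warns_empty(kb):
    sp = parse_lipid_name("ChE 18:1", kb)
    with pytest.warns(UserWarning, match="no fragment rules"):
        assert build_fragment_ions(sp, "-", kb) == []


def test_label_shifts_only_referencing_fragments(kb):
    sp = parse_lipid_name("PC 16:0/18:1", kb)
    label = IsotopeLabel("FA1", (("C", 16),))
    labeled = apply_isotope_label(sp, label, kb)

    prec = build_precursor_ion(sp, "[M+H]1+", kb)
    prec_l = build_precursor_ion(labeled, "[M+H]1+", kb)
    assert prec_l.mz - prec.mz == pytest.approx(16 * C13_SHIFT, abs=1e-4)

    plain = {f.name: f.mz for f in build_fragment_ions(sp, "+", kb)}
    lab = {f.name: f.mz for f in build_fragment_ions(labeled, "+", kb)}
    # head-group fragment is FA1-independent, NL183 contains FA1
    assert lab["HG 184 (phosphocholine)"] == plain["HG 184 (phosphocholine)"]
    assert lab["NL183 [M+H-HG]"] - plain["NL183 [M+H-HG]"] == pytest.approx(
        16 * C13_SHIFT, abs=1e-4
    )


def test_d7_and_13c3_label_shifts(kb):
    sp = parse_lipid_name("PC 15:0_18:1", kb)
    d7 = apply_isotope_label(sp, IsotopeLabel("M", (("H", 7),)), kb)
    cdef = kb.get_class("PC")
    from lipidbench.species import assemble_neutral

    shift = assemble_neutral(d7, cdef).mass - assemble_neutral(sp, cdef).mass
    assert shift == pytest.approx(7 * D_SHIFT, abs=1e-4)

    tg = parse_lipid_name("TG 16:0_16:0_18:1", kb)
    c3 = apply_isotope_label(tg, IsotopeLabel("M", (("C", 3),)), kb)
    tg_def = kb.get_class("TG")
    shift = assemble_neutral(c3, tg_def).mass - assemble_neutral(tg, tg_def).mass
    assert shift == pytest.approx(3 * C13_SHIFT, abs=1e-4)


def test_empty_label_is_identity(kb):
    sp = parse_lipid_name("PC 16:0/18:1", kb)
    assert apply_isotope_label(sp, IsotopeLabel(), kb) == sp


def test_infeasible_label_names_available_atoms(kb):
    sp = parse_lipid_name("LPC 16:0", kb)
    with pytest.raises(ValueError, match="available"):
        apply_isotope_label(sp, IsotopeLabel("FA1", (("H", 40),)), kb)


def test_label_neutrality_across_shipped_rules(kb):
    """Labeled-minus-unlabeled fragment mass equals the label mass confined
    to the blocks each rule references (swept over the shipped KB)."""
    label_shift = 2 * C13_SHIFT
    for cls in ("PC", "PE", "TG", "Cer", "SM"):
        cdef = kb.get_class(cls)
        name = {
            "PC": "PC 16:0/18:1",
            "PE": "PE 16:0/18:1",
            "TG": "TG 16:0/16:0/18:1",
            "Cer": "Cer 18:1;2/16:0",
            "SM": "SM 18:1;2/16:0",
        }[cls]
        sp = parse_lipid_name(name, kb)
        labeled = apply_isotope_label(sp, IsotopeLabel("FA1", (("C", 2),)), kb)
        for pol in "+-":
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                plain = {f.name: f.mz for f in build_fragment_ions(sp, pol, kb)}
                lab = {f.name: f.mz for f in build_fragment_ions(labeled, pol, kb)}
            for rule in kb.rules_for(cls, pol):
                # net coefficient of blocks containing the labeled FA1
                # (the precursor holds FA1; subtracting FA1 removes the label)
                net = sum(c for tok, c in rule.terms if tok in ("FA1", "PRECURSOR"))
                got = lab[rule.fragment_name] - plain[rule.fragment_name]
                assert got == pytest.approx(net * label_shift, abs=1e-6), rule.fragment_name


def test_build_transitions_cardinality_and_order(kb):
    species = [
        parse_lipid_name("PC 16:0/18:1", kb),
        parse_lipid_name("PC 16:0/16:0", kb),
        parse_lipid_name("PE 16:0_18:1", kb),
    ]
    rows = build_transitions(species, ["[M+H]1+"], kb)
    # PC has 2 positive rules, PE 1
    assert len(rows) == 2 + 2 + 1
    assert rows == sorted(rows, key=lambda t: (t.precursor_name, t.product_mz))


def test_exported_mz_matches_formula_recomputation(kb, tmp_path):
    species = [parse_lipid_name("PC 16:0/18:1", kb), parse_lipid_name("Cer 18:1;2/16:0", kb)]
    rows = build_transitions(species, ["[M+H]1+"], kb)
    path = export_transition_list(rows, tmp_path / "t.csv")
    back = read_transition_list(path)
    assert len(back) == len(rows)
    for t in back:
        recomputed = fragment_mz(parse_formula(t.product_formula), t.product_charge)
        assert abs(recomputed - t.product_mz) < 1e-5


def test_export_round_trip_and_empty_rejection(kb, tmp_path):
    rows = build_transitions([parse_lipid_name("PC 16:0/18:1", kb)], ["[M+H]1+"], kb)
    path = export_transition_list(rows, tmp_path / "t.csv")
    back = read_transition_list(path)
    for a, b in zip(rows, back):
        assert a.product_name == b.product_name
        assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-6)
    with pytest.raises(ValueError):
        export_transition_list([], tmp_path / "empty.csv")


def test_mixed_polarity_flagged_not_dropped(kb, tmp_path):
    species = [parse_lipid_name("PE 16:0_18:1", kb)]
    rows = build_transitions(species, ["[M+H]1+", "[M-H]1-"], kb)
    assert {t.precursor_charge > 0 for t in rows} == {True, False}
    with pytest.warns(UserWarning, match="mixes polarities"):
        export_transition_list(rows, tmp_path / "m.csv")
    assert len(read_transition_list(tmp_path / "m.csv")) == len(rows)


def test_transition_polarity_validation():
    with pytest.raises(ValueError, match="polarities differ"):
        Transition("l", "p", "", "[M+H]1+", 700.0, 1, "f", "", 300.0, -1)
    with pytest.raises(ValueError, match="exceeds precursor"):
        Transition("l", "p", "", "[M+H]1+", 300.0, 1, "f", "", 500.0, 1)


def test_msp_round_trip(tmp_path):
    spectra = [
        {
            "name": "PC 16:0/18:1 [M+H]1+",
            "precursor_mz": 760.5851,
            "precursor_charge": 1,
            "ce": 30.0,
            "peaks": [(184.0733, 1.0, "HG"), (577.5190, 0.25, "NL183")],
        }
    ]
    path = write_msp(spectra, tmp_path / "lib.msp")
    back = read_msp(path)
    assert len(back) == 1
    sp = back[0]
    assert sp["name"] == spectra[0]["name"]
    assert sp["ce"] == 30.0
    assert sp["peaks"][0][0] == pytest.approx(184.0733)
    assert sp["peaks"][1][2] == "NL183"


def test_blib_schema_subset(tmp_path):
    import sqlite3
    import struct
    import zlib

    spectra = [
        {
            "name": "x",
            "precursor_mz": 500.0,
            "precursor_charge": 1,
            "peaks": [(100.0, 1.0, "a"), (200.0, 0.5, "b")],
        }
    ]
    path = write_blib(spectra, tmp_path / "lib.blib")
    con = sqlite3.connect(path)
    n, mz_blob = con.execute(
        "SELECT numPeaks, peakMZ FROM RefSpectra JOIN RefSpectraPeaks "
        "ON id = RefSpectraID"
    ).fetchone()
    con.close()
    mzs = struct.unpack(f"<{n}d", zlib.decompress(mz_blob))
    assert mzs == (100.0, 200.0)


def test_whole_kb_envelope_mass_consistency(kb):
    """Every transition m/z across a KB-wide envelope matches independent
    element-table summation within 1e-4 Th (including a labeled species)."""
    species = []
    for cls in kb.classes:
        cdef = kb.get_class(cls)
        spec = FattyAcylSpec((16, 16), (0, 1), (0, 0))
        lcb = FattyAcylSpec((18, 18), (1, 1), (2, 2), ("lcb",)) if cdef.has_lcb else None
        species.extend(enumerate_species(cdef, [spec] * max(cdef.n_acyl_slots, 1) if cdef.n_acyl_slots else None, lcb_spec=lcb))
    labeled = apply_isotope_label(
        parse_lipid_name("PC 16:0/16:1", kb), IsotopeLabel("M", (("H", 9),)), kb
    )
    species.append(labeled)
    adducts = ["[M+H]1+", "[M+NH4]1+", "[M-H]1-", "[M+HCOO]1-", "[M-2H]2-", "[M-CH3]1-"]
    rows = build_transitions(species, adducts, kb)
    assert len(rows) > 50
    from lipidbench.chem import ELEMENT_MASSES

    for t in rows:
        # independent oracle: plain per-element summation from the table
        def table_mass(formula_text):
            return sum(
                n * ELEMENT_MASSES[sym]
                for sym, n in parse_formula(formula_text).counts.items()
            )

        prec = (table_mass(t.precursor_formula) - t.precursor_charge * ELECTRON_MASS) / abs(
            t.precursor_charge
        )
        prod = (table_mass(t.product_formula) - t.product_charge * ELECTRON_MASS) / abs(
            t.product_charge
        )
        assert abs(prec - t.precursor_mz) < 1e-4
        assert abs(prod - t.product_mz) < 1e-4
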