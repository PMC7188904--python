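"""Transition extraction: centroided MS/MS spectra → per-fragment CE profiles.

Given a stream of centroided MS2 scans (each annotated with its precursor
m/z and collision energy) and a transition list, every scan matching a
target precursor within the ppm window contributes one observation per
target fragment: the nearest centroid within the window, with intensities
normalized to the summed intensity of all matched fragments in that scan
(scan-relative intensity).  Fragments with no centroid in the window are
recorded as 0.  Scans matching no fragment contribute no rows.

The default window is 5 ppm (appropriate for Orbitrap-class resolution);
a 10 ppm fallback is available for noisier platforms or sparse data.
"""

from __future__ import annotations

import base64
import struct
import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from lxml import etree

from .ce import CEProfile
from .transitions import Transition

__all__ = [
    "FeatureRow",
    "TargetIon",
    "read_mzml_scans",
    "extract_ce_profiles",
    "targets_from_transitions",
    "feature_table",
]


@dataclass(frozen=True)
class FeatureRow:
    """One extracted fragment observation in one scan."""

    lipid: str
    fragment: str
    collision_energy: float
    scan_id: str
    mz_observed: float  # NaN when the fragment was not matched
    ppm_error: float  # NaN when the fragment was not matched
    scan_relative_intensity: float


@dataclass(frozen=True)
class TargetIon:
    """A precursor with its named fragment m/z targets."""

    lipid: str
    precursor_mz: float
    fragments: tuple[tuple[str, float], ...]


def targets_from_transitions(transitions: Iterable[Transition]) -> list[TargetIon]:
    """Group a transition list into per-precursor extraction targets."""
    grouped: dict[tuple[str, float], list[tuple[str, float]]] = {}
    for t in transitions:
        grouped.setdefault((t.precursor_name, t.precursor_mz), []).append(
            (t.product_name, t.product_mz)
        )
    return [
        TargetIon(lipid=name, precursor_mz=mz, fragments=tuple(frs))
        for (name, mz), frs in grouped.items()
    ]


def _looks_profile_mode(mz: np.ndarray, max_dense: int = 5) -> bool:
    """Heuristic: many points closer than 0.01 Th indicates profile data."""
    if len(mz) < max_dense + 1:
        return False
    diffs = np.diff(np.sort(mz))
    return int(np.sum(diffs < 0.01)) > max_dense


_NS = "{http://psi.hupo.org/ms/mzml}"

# PSI-MS accessions used by the reader
_ACC_MS_LEVEL = "MS:1000511"
_ACC_SELECTED_MZ = "MS:1000744"
_ACC_CE = "MS:1000045"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INTENSITY_ARRAY = "MS:1000515"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"


def _cv(elem, accession: str) -> str | None:
    for cv in elem.iter(f"{_NS}cvParam"):
        if cv.get("accession") == accession:
            return cv.get("value", "")
    return None


def _decode_binary_array(bda) -> np.ndarray:
    accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
    node = bda.find(f"{_NS}binary")
    raw = base64.b64decode((node.text or "").strip())
    if _ACC_ZLIB in accs:
        raw = zlib.decompress(raw)
    fmt, width = ("f", 4) if _ACC_F32 in accs else ("d", 8)
    n = len(raw) // width
    return np.array(struct.unpack(f"<{n}{fmt}", raw[: n * width]))


def read_mzml_scans(path: str | Path) -> Iterator[dict]:
    """Yield centroided MS2 scans from an mzML file (streaming parse).

    Each scan dict carries ``scan_id``, ``precursor_mz``,
    ``collision_energy``, ``mz`` and ``intensity`` arrays.  Binary arrays
    may be 32- or 64-bit floats, plain or zlib-compressed.  Scans lacking
    precursor or collision-energy annotation are skipped with a warning.
    """
    for _, spec in etree.iterparse(str(path), tag=f"{_NS}spectrum"):
        try:
            level = _cv(spec, _ACC_MS_LEVEL)
            if level is not None and int(level) != 2:
                continue
            prec = spec.find(
                f"{_NS}precursorList/{_NS}precursor"
            )
            prec_mz = ce = None
            if prec is not None:
                sel = prec.find(f"{_NS}selectedIonList/{_NS}selectedIon")
                if sel is not None:
                    v = _cv(sel, _ACC_SELECTED_MZ)
                    prec_mz = float(v) if v else None
                act = prec.find(f"{_NS}activation")
                if act is not None:
                    v = _cv(act, _ACC_CE)
                    ce = float(v) if v else None
            if prec_mz is None or ce is None:
                warnings.warn(
                    f"scan {spec.get('id')!r} lacks precursor/CE annotation; "
                    f"skipped",
                    stacklevel=2,
                )
                continue
            mz = intensity = None
            for bda in spec.iter(f"{_NS}binaryDataArray"):
                accs = {cv.get("accession") for cv in bda.iter(f"{_NS}cvParam")}
                if _ACC_MZ_ARRAY in accs:
                    mz = _decode_binary_array(bda)
                elif _ACC_INTENSITY_ARRAY in accs:
                    intensity = _decode_binary_array(bda)
            if mz is None or intensity is None:
                warnings.warn(
                    f"scan {spec.get('id')!r} lacks m/z or intensity array; "
                    f"skipped",
                    stacklevel=2,
                )
                continue
            yield {
                "scan_id": str(spec.get("id", "")),
                "precursor_mz": prec_mz,
                "collision_energy": ce,
                "mz": mz,
                "intensity": intensity,
            }
        finally:
            spec.clear(keep_tail=True)


def _match_fragment(
    mz: np.ndarray, intensity: np.ndarray, target_mz: float, ppm_window: float
) -> tuple[float, float, float] | None:
    """Nearest centroid within the ppm window; ties go to higher intensity.

    Returns (observed m/z, ppm error, raw intensity) or None.
    """
    if len(mz) == 0:
        return None
    ppm = (mz - target_mz) / target_mz * 1e6
    inside = np.abs(ppm) <= ppm_window
    if not np.any(inside):
        return None
    idx = np.flatnonzero(inside)
    # sort by (|ppm|, -intensity): nearest wins, equal distance -> taller peak
    order = sorted(idx, key=lambda i: (abs(ppm[i]), -intensity[i]))
    best = order[0]
    return float(mz[best]), float(ppm[best]), float(intensity[best])


def extract_ce_profiles(
    scans: Iterable[dict] | str | Path,
    targets: list[TargetIon],
    ppm_window: float = 5.0,
) -> tuple[list[FeatureRow], dict[tuple[str, str], CEProfile]]:
    """Extract per-fragment CE profiles from centroided scans.

    ``scans`` may be an mzML path or an iterable of scan dicts (as yielded
    by :func:`read_mzml_scans`).  The precursor match also uses
    ``ppm_window``.  Returns the flat feature rows plus profiles grouped
    per (lipid, fragment).  Profile-mode spectra are rejected; inputs with
    no matching scans produce empty output with a warning.
    """
    if isinstance(scans, (str, Path)):
        scans = read_mzml_scans(scans)

    rows: list[FeatureRow] = []
    obs: dict[tuple[str, str], list[tuple[float, float]]] = {}
    n_scans = 0
    for scan in scans:
        n_scans += 1
        mz, intensity = scan["mz"], scan["intensity"]
        if _looks_profile_mode(mz):
            raise ValueError(
                f"scan {scan['scan_id']!r} looks like profile-mode data "
                f"(dense m/z spacing); centroid the input first"
            )
        # nearest precursor target within the window
        best_target = None
        best_ppm = ppm_window
        for tgt in targets:
            ppm = abs(scan["precursor_mz"] - tgt.precursor_mz) / tgt.precursor_mz * 1e6
            if ppm <= best_ppm:
                best_target, best_ppm = tgt, ppm
        if best_target is None:
            continue

        matches: list[tuple[str, tuple[float, float, float] | None]] = [
            (name, _match_fragment(mz, intensity, frag_mz, ppm_window))
            for name, frag_mz in best_target.fragments
        ]
        total = sum(m[2] for _, m in matches if m is not None)
        if total <= 0:
            continue  # scans with zero matched fragments contribute no rows
        for name, m in matches:
            if m is None:
                row = FeatureRow(
                    lipid=best_target.lipid,
                    fragment=name,
                    collision_energy=scan["collision_energy"],
                    scan_id=scan["scan_id"],
                    mz_observed=float("nan"),
                    ppm_error=float("nan"),
                    scan_relative_intensity=0.0,
                )
            else:
                row = FeatureRow(
                    lipid=best_target.lipid,
                    fragment=name,
                    collision_energy=scan["collision_energy"],
                    scan_id=scan["scan_id"],
                    mz_observed=m[0],
                    ppm_error=m[1],
                    scan_relative_intensity=m[2] / total,
                )
            rows.append(row)
            obs.setdefault((best_target.lipid, name), []).append(
                (row.collision_energy, row.scan_relative_intensity)
            )

    if not rows:
        warnings.warn(
            f"no scans matched any of the {len(targets)} targets "
            f"({n_scans} scans inspected)",
            stacklevel=2,
        )
    profiles = {
        key: CEProfile(lipid=key[0], fragment=key[1], observations=o)
        for key, o in obs.items()
    }
    return rows, profiles


def feature_table(rows: list[FeatureRow]) -> pd.DataFrame:
    """Feature rows as a DataFrame (TSV-ready)."""
    return pd.DataFrame(
        {
            "lipid": [r.lipid for r in rows],
            "fragment": [r.fragment for r in rows],
            "collision_energy": [r.collision_energy for r in rows],
            "scan_id": [r.scan_id for r in rows],
            "mz_observed": [r.mz_observed for r in rows],
            "ppm_error": [r.ppm_error for r in rows],
            "scan_relative_intensity": [r.scan_relative_intensity for r in rows],
        }
    )
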