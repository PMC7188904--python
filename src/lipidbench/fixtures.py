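"""Seeded synthetic data generators.

Everything downstream of raw instrument data is testable without downloads:
this module simulates (a) fragment CE profiles with known ground-truth
parameters, emulating repeated direct-infusion MS/MS acquisitions across a
CE ramp (~16 repetitions per NCE step on an HCD Orbitrap-type platform);
(b) centroided MS/MS spectra written as minimal valid mzML, so the real
reader path is exercised; and (c) lipid-ion sets with planted
precursor-mass collisions and controlled fragment overlaps, whose expected
unambiguity curve is computable in closed form.

The generators emulate scan-relative intensities with additive Gaussian
noise; they do not simulate chromatography, isotope envelopes or detector
saturation.
"""

from __future__ import annotations

import base64
import struct
from dataclasses import dataclass, field
from pathlib import Path
from xml.sax.saxutils import escape

import numpy as np

from .ambiguity import LipidIon
from .ce import CEModelParams, CEProfile, ce_response

__all__ = [
    "SimulationConfig",
    "simulate_ce_profile",
    "draw_true_params",
    "simulate_lipidome",
    "write_mzml",
    "simulate_spectra_mzml",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Reproducible simulation settings; identical config ⇒ identical data."""

    seed: int = 0
    ce_min: float = 10.0
    ce_max: float = 60.0
    ce_step: float = 1.0
    reps_per_ce: int = 16
    noise_sd: float = 0.02
    n_ions: int = 50
    mass_range: tuple[float, float] = (400.0, 900.0)
    planted_collisions: int = 0
    fragments_per_ion: int = 3

    def ce_grid(self) -> np.ndarray:
        n = int(round((self.ce_max - self.ce_min) / self.ce_step)) + 1
        return np.linspace(self.ce_min, self.ce_max, n)


# ----------------------------------------------------------------------
# CE profiles

def simulate_ce_profile(
    params: CEModelParams,
    cfg: SimulationConfig,
    lipid: str = "synthetic",
    fragment: str = "frag",
) -> CEProfile:
    """Sample ``reps_per_ce`` noisy observations of the response at each CE.

    Observations are ``g(x) + N(0, noise_sd)`` clipped to [0, 1]; with
    ``noise_sd = 0`` they equal the model response exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    obs: list[tuple[float, float]] = []
    for ce in cfg.ce_grid():
        truth = float(ce_response(ce, params))
        for _ in range(cfg.reps_per_ce):
            y = truth + (rng.normal(0.0, cfg.noise_sd) if cfg.noise_sd > 0 else 0.0)
            obs.append((float(ce), float(min(max(y, 0.0), 1.0))))
    return CEProfile(lipid=lipid, fragment=fragment, observations=obs)


def draw_true_params(
    rng: np.random.Generator,
    ce_window: tuple[float, float] = (18.0, 45.0),
    peak_height: tuple[float, float] = (0.15, 0.9),
) -> CEModelParams:
    """Draw a realistic ground-truth parameter set for recovery studies.

    The draws emulate HCD-type dissociation profiles: a steep onset just
    above the ramp start (shift delta in [-9.5, -4] for a 10-60 NCE ramp,
    placing the kernel's support origin 0.5-6 NCE above the lowest sampled
    CE) and pronounced right skew (sigma in [0.4, 0.7]).  Candidates are
    rejection-sampled until the response peaks inside ``ce_window`` with
    height inside ``peak_height``.  Profiles whose support origin lies far
    below the sampled window are nearly Gaussian over the ramp and leave
    the shift ill-determined, so they are not representative draws.
    """
    while True:
        mu = rng.uniform(2.4, 4.1)
        sigma = rng.uniform(0.4, 0.7)
        s = rng.uniform(2.0, 10.0)
        delta = rng.uniform(-9.5, -4.0)
        p = CEModelParams(mu, sigma, s, delta)
        mode = p.mode
        if not ce_window[0] <= mode <= ce_window[1]:
            continue
        height = float(ce_response(mode, p))
        if peak_height[0] <= height <= peak_height[1]:
            return p


# ----------------------------------------------------------------------
# lipidome ion sets with planted ambiguity structure

def simulate_lipidome(
    cfg: SimulationConfig, tol_da: float = 0.5
) -> tuple[list[LipidIon], list[LipidIon], list[LipidIon]]:
    """Generate disjoint background/target/decoy ion sets.

    Exactly ``cfg.planted_collisions`` precursor pairs lie within
    ``tol_da`` of each other (offset tol/2) with mutually dissimilar
    fragment lists; all remaining precursors and all fragments are spaced
    > 4x the tolerance apart.  With k planted pairs among N ions the
    expected unambiguity curve is closed form: P(0) = 1 - 2k/N, P(n>=1) = 1.

    Set sizes split the ``n_ions`` total roughly 70/15/15 across
    background/targets/decoys (the unit of the analysis is the combined
    set).
    """
    n = cfg.n_ions
    k = cfg.planted_collisions
    if n < 2 * k:
        raise ValueError(f"cannot plant {k} collision pairs among {n} ions")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mass_range
    spacing_needed = (n + 1) * 4 * tol_da
    if spacing_needed > hi - lo:
        raise ValueError(
            f"infeasible planting density: {n} ions at >4x{tol_da} Da spacing "
            f"need {spacing_needed:.0f} Da, range provides {hi - lo:.0f}"
        )

    # well-separated precursor anchor masses
    slots = np.linspace(lo, hi, n)
    jitter = rng.uniform(-tol_da, tol_da, size=n)
    precursors = slots + jitter
    assert np.all(np.diff(precursors) > 2 * tol_da)

    # global pool of mutually dissimilar fragment masses
    n_frag = n * cfg.fragments_per_ion
    frag_pool = np.linspace(50.0, lo - 50.0, n_frag) + rng.uniform(
        -tol_da, tol_da, size=n_frag
    )
    rng.shuffle(frag_pool)

    ions: list[LipidIon] = []
    fp = 0
    for i in range(n):
        frags = sorted(float(m) for m in frag_pool[fp : fp + cfg.fragments_per_ion])
        fp += cfg.fragments_per_ion
        ions.append(
            LipidIon(
                name=f"SYN {i:03d}",
                polarity="+",
                precursor_mz=float(precursors[i]),
                fragment_mzs=tuple(frags),
            )
        )

    # plant k colliding pairs: pull the partner's precursor within tolerance
    pair_idx = rng.choice(n, size=2 * k, replace=False)
    for a, b in zip(pair_idx[:k], pair_idx[k:]):
        ions[b] = LipidIon(
            name=ions[b].name,
            polarity=ions[b].polarity,
            precursor_mz=ions[a].precursor_mz + tol_da / 2.0,
            fragment_mzs=ions[b].fragment_mzs,
        )

    order = rng.permutation(n)
    shuffled = [ions[i] for i in order]
    n_bg = max(int(round(0.7 * n)), 1)
    n_tg = max((n - n_bg) // 2, 0)
    background = shuffled[:n_bg]
    targets = shuffled[n_bg : n_bg + n_tg]
    decoys = shuffled[n_bg + n_tg :]
    return background, targets, decoys


# ----------------------------------------------------------------------
# minimal centroided mzML

_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="PSI-MS" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription>
    <fileContent>
      <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
      <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    </fileContent>
  </fileDescription>
  <run id="{run_id}">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64_floats(values, fmt: str) -> str:
    raw = struct.pack(f"<{len(values)}{fmt}", *[float(v) for v in values])
    return base64.b64encode(raw).decode("ascii")


def write_mzml(scans: list[dict], path: str | Path, run_id: str = "synthetic") -> Path:
    """Write centroided MS2 scans as minimal valid mzML.

    Each scan dict: ``scan_id``, ``precursor_mz``, ``collision_energy``,
    ``mz`` (array) and ``intensity`` (array).  Arrays are stored as
    uncompressed little-endian 64-bit floats.
    """
    path = Path(path)
    parts = [_MZML_HEADER.format(run_id=escape(run_id), count=len(scans))]
    for idx, scan in enumerate(scans):
        mz = list(scan["mz"])
        inten = list(scan["intensity"])
        assert len(mz) == len(inten)
        sid = escape(str(scan.get("scan_id", f"scan={idx + 1}")))
        parts.append(
            f"""      <spectrum index="{idx}" id="{sid}" defaultArrayLength="{len(mz)}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="2"/>
        <cvParam cvRef="MS" accession="MS:1000580" name="MSn spectrum" value=""/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <precursorList count="1">
          <precursor>
            <selectedIonList count="1">
              <selectedIon>
                <cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{scan['precursor_mz']:.6f}" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
              </selectedIon>
            </selectedIonList>
            <activation>
              <cvParam cvRef="MS" accession="MS:1000422" name="beam-type collision-induced dissociation" value=""/>
              <cvParam cvRef="MS" accession="MS:1000045" name="collision energy" value="{scan['collision_energy']:g}" unitCvRef="UO" unitAccession="UO:0000266" unitName="electronvolt"/>
            </activation>
          </precursor>
        </precursorList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(_b64_floats(mz, 'd'))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{_b64_floats(mz, 'd')}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(_b64_floats(inten, 'd'))}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{_b64_floats(inten, 'd')}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
"""
        )
    parts.append(_MZML_FOOTER)
    path.write_text("".join(parts))
    return path


def simulate_spectra_mzml(
    targets: list[dict],
    cfg: SimulationConfig,
    path: str | Path,
    mz_jitter_ppm: float = 1.0,
    intensity_scale: float = 1e4,
) -> Path:
    """Synthesize a CE-ramp acquisition for target precursors.

    ``targets``: list of dicts with ``name``, ``precursor_mz`` and
    ``fragments`` = list of (fragment_mz, CEModelParams).  For each
    precursor and CE step, ``reps_per_ce`` centroided MS2 scans are
    generated whose fragment peak intensities follow the planted response
    curves (times ``intensity_scale``) with relative Gaussian noise
    ``noise_sd`` and m/z jitter of ``mz_jitter_ppm``.
    """
    rng = np.random.default_rng(cfg.seed)
    scans = []
    idx = 0
    for tgt in targets:
        for ce in cfg.ce_grid():
            for _ in range(cfg.reps_per_ce):
                mzs, intens = [], []
                for frag_mz, params in tgt["fragments"]:
                    y = float(ce_response(ce, params))
                    y = max(y * (1.0 + rng.normal(0.0, cfg.noise_sd)), 0.0)
                    if y <= 0:
                        continue
                    jitter = rng.normal(0.0, mz_jitter_ppm * 1e-6 * frag_mz)
                    mzs.append(frag_mz + jitter)
                    intens.append(y * intensity_scale)
                if not mzs:
                    continue
                order = np.argsort(mzs)
                idx += 1
                scans.append(
                    {
                        "scan_id": f"scan={idx}",
                        "precursor_mz": tgt["precursor_mz"],
                        "collision_energy": float(ce),
                        "mz": [mzs[i] for i in order],
                        "intensity": [intens[i] for i in order],
                    }
                )
    return write_mzml(scans, path)
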