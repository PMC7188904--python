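"""False-match probability and target-decoy accuracy for lipid ion sets.

Within one polarity, a lipid ion is *unambiguous with respect to n
fragments* when either (i) no other ion in the set has a tolerance-similar
precursor mass, or (ii) every ion with a similar precursor shares fewer
than n tolerance-similar fragments with it.  Fragment sharing is the size
of a maximum one-to-one matching between the two sorted fragment mass
lists, computed by a global-alignment dynamic program adapted to numeric
values (match = 1 when masses are similar, gaps are free, dissimilar
masses cannot align).

Tolerances are absolute (±Da, low-resolution instruments) or relative
(±ppm, high-resolution).  The cumulative unambiguity distribution over n
is the fraction of ions identifiable with at most n fragments; the
target-decoy accuracy is (TP + TN) / (TP + FN + FP + TN).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "MassTolerance",
    "LipidIon",
    "ConfusionCounts",
    "masses_similar",
    "fragment_overlap",
    "min_fragments_for_unambiguity",
    "unambiguity_distribution",
    "combined_unambiguity_distribution",
    "target_decoy_accuracy",
    "AMBIGUOUS",
    "read_ion_tsv",
    "write_ion_tsv",
]

#: Sentinel returned when no fragment count within max_n disambiguates.
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class MassTolerance:
    """±Da (``absolute_da``) or ±ppm (``ppm``) mass-match tolerance."""

    mode: str
    value: float

    def __post_init__(self) -> None:
        if self.mode not in ("absolute_da", "ppm"):
            raise ValueError(f"unknown tolerance mode {self.mode!r}")
        if self.value <= 0:
            raise ValueError("tolerance must be positive")

    @classmethod
    def parse(cls, text: str) -> "MassTolerance":
        """Parse ``"0.5da"`` or ``"2.5ppm"``."""
        text = text.strip().lower()
        if text.endswith("ppm"):
            return cls("ppm", float(text[:-3]))
        if text.endswith("da"):
            return cls("absolute_da", float(text[:-2]))
        raise ValueError(f"cannot parse tolerance {text!r} (use e.g. 0.5da, 2.5ppm)")


def masses_similar(a: float, b: float, tol: MassTolerance) -> bool:
    """True when |a − b| is within the tolerance (symmetric in a, b).

    ppm tolerances are taken relative to the smaller mass so the predicate
    stays symmetric.
    """
    diff = abs(a - b)
    if tol.mode == "absolute_da":
        return diff <= tol.value
    return diff / min(a, b) * 1e6 <= tol.value


@dataclass(frozen=True)
class LipidIon:
    """A named ion: polarity, precursor m/z and sorted fragment m/z list."""

    name: str
    polarity: str
    precursor_mz: float
    fragment_mzs: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.polarity not in "+-":
            raise ValueError(f"polarity must be '+' or '-', got {self.polarity!r}")
        frags = tuple(sorted(self.fragment_mzs))
        object.__setattr__(self, "fragment_mzs", frags)


def fragment_overlap(
    a: tuple[float, ...] | list[float],
    b: tuple[float, ...] | list[float],
    tol: MassTolerance,
) -> int:
    """Maximum number of one-to-one similar-mass pairs between two sorted
    lists (global numeric alignment: match 1, gap 0, no mismatch)."""
    n, m = len(a), len(b)
    if n == 0 or m == 0:
        return 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        for j in range(1, m + 1):
            best = max(prev[j], cur[j - 1])
            if masses_similar(a[i - 1], b[j - 1], tol):
                best = max(best, prev[j - 1] + 1)
            cur[j] = best
        prev = cur
    return prev[m]


def min_fragments_for_unambiguity(
    ion: LipidIon,
    others: list[LipidIon],
    tol: MassTolerance,
    max_n: int = 5,
) -> int | str:
    """Smallest fragment count n that identifies ``ion`` uniquely.

    Returns 0 when no same-polarity ion in ``others`` has a similar
    precursor mass; otherwise the smallest n ≤ min(max_n, available
    fragments) such that every precursor-similar ion shares fewer than n
    fragments; :data:`AMBIGUOUS` when no such n exists.
    """
    rivals = [
        o
        for o in others
        if o is not ion
        and o.polarity == ion.polarity
        and masses_similar(ion.precursor_mz, o.precursor_mz, tol)
    ]
    if not rivals:
        return 0
    cap = min(max_n, len(ion.fragment_mzs))
    worst = max(
        fragment_overlap(ion.fragment_mzs, r.fragment_mzs, tol) for r in rivals
    )
    # need n > worst overlap, and the ion must own n fragments itself
    n = worst + 1
    return n if n <= cap else AMBIGUOUS


def unambiguity_distribution(
    ions: list[LipidIon], tol: MassTolerance, max_n: int = 5
) -> list[float]:
    """Cumulative fraction of ions unambiguous with 0, 1, ..., max_n
    fragments (same-polarity comparisons within ``ions``)."""
    if not ions:
        raise ValueError("empty ion set")
    levels = []
    for ion in ions:
        levels.append(min_fragments_for_unambiguity(ion, ions, tol, max_n))
    out = []
    for n in range(max_n + 1):
        ok = sum(1 for lv in levels if lv != AMBIGUOUS and lv <= n)
        out.append(ok / len(ions))
    return out


def combined_unambiguity_distribution(
    ions: list[LipidIon], tol: MassTolerance, max_n: int = 5
) -> list[float]:
    """Per-lipid cumulative unambiguity taking both polarities into account.

    Ions are grouped by name; a lipid counts as unambiguous at level n when
    any of its ions (either polarity) is.  Comparisons still run within
    polarity only.
    """
    if not ions:
        raise ValueError("empty ion set")
    best: dict[str, float] = {}
    for ion in ions:
        lv = min_fragments_for_unambiguity(ion, ions, tol, max_n)
        lv_num = float("inf") if lv == AMBIGUOUS else float(lv)
        best[ion.name] = min(best.get(ion.name, float("inf")), lv_num)
    n_lipids = len(best)
    return [
        sum(1 for lv in best.values() if lv <= n) / n_lipids
        for n in range(max_n + 1)
    ]


@dataclass(frozen=True)
class ConfusionCounts:
    """Target-decoy outcome: identified/unidentified targets and decoys."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def target_decoy_accuracy(c: ConfusionCounts) -> float:
    """Accuracy in percent: 100 · (TP + TN) / (TP + FN + FP + TN)."""
    total = c.tp + c.tn + c.fp + c.fn
    if total == 0:
        raise ValueError("accuracy undefined for all-zero counts")
    return 100.0 * (c.tp + c.tn) / total


# ----------------------------------------------------------------------
# ion set TSV I/O

def write_ion_tsv(ions: list[LipidIon], path: str | Path) -> Path:
    """TSV columns: name, polarity, precursor_mz, fragment_mzs (';'-joined)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["name", "polarity", "precursor_mz", "fragment_mzs"])
        for ion in ions:
            w.writerow(
                [
                    ion.name,
                    ion.polarity,
                    f"{ion.precursor_mz:.6f}",
                    ";".join(f"{m:.6f}" for m in ion.fragment_mzs),
                ]
            )
    return path


def read_ion_tsv(path: str | Path) -> list[LipidIon]:
    out = []
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            frags = tuple(
                float(tok) for tok in row["fragment_mzs"].split(";") if tok
            )
            out.append(
                LipidIon(
                    name=row["name"],
                    polarity=row["polarity"],
                    precursor_mz=float(row["precursor_mz"]),
                    fragment_mzs=frags,
                )
            )
    return out
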