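"""False-match framework: mass similarity, overlap alignment, unambiguity."""

import itertools

import numpy as np
import pytest

from lipidbench.ambiguity import (
    AMBIGUOUS,
    ConfusionCounts,
    LipidIon,
    MassTolerance,
    fragment_overlap,
    masses_similar,
    min_fragments_for_unambiguity,
    read_ion_tsv,
    target_decoy_accuracy,
    unambiguity_distribution,
    write_ion_tsv,
)

DA05 = MassTolerance("absolute_da", 0.5)
PPM25 = MassTolerance("ppm", 2.5)


@pytest.mark.parametrize(
    "a,b,tol,expected",
    [
        (500.000, 500.400, DA05, True),
        (500.000, 500.600, DA05, False),
        (400.0000, 400.0009, PPM25, True),  # 2.5 ppm of 400 = 0.001 Da
        (400.0000, 400.0011, PPM25, False),
    ],
)
def test_masses_similar(a, b, tol, expected):
    assert masses_similar(a, b, tol) is expected
    assert masses_similar(b, a, tol) is expected  # symmetric


def test_tolerance_parsing_and_validation():
    assert MassTolerance.parse("0.5da") == DA05
    assert MassTolerance.parse("2.5PPM") == PPM25
    with pytest.raises(ValueError):
        MassTolerance.parse("5mmu")
    with pytest.raises(ValueError):
        MassTolerance("absolute_da", -1.0)


def _overlap_brute_force(a, b, tol):
    """Exhaustive maximum one-to-one matching over all injective mappings."""
    best = 0
    idx_b = range(len(b))
    for r in range(min(len(a), len(b)), 0, -1):
        for a_sub in itertools.combinations(range(len(a)), r):
            for b_perm in itertools.permutations(idx_b, r):
                if all(
                    masses_similar(a[i], b[j], tol)
                    for i, j in zip(a_sub, b_perm)
                ):
                    return r
    return best


def test_overlap_identical_and_disjoint():
    xs = [100.0, 200.0, 300.0]
    assert fragment_overlap(xs, xs, DA05) == 3
    assert fragment_overlap(xs, [150.0, 250.0], DA05) == 0
    assert fragment_overlap([], xs, DA05) == 0


def test_overlap_equals_exhaustive_matching_on_random_lists():
    """DP alignment equals brute-force maximum matching: 200 seeded trials,
    lists up to 8 elements."""
    rng = np.random.default_rng(1234)
    for _ in range(200):
        na, nb = rng.integers(0, 9), rng.integers(0, 9)
        # cluster masses so similar pairs are common
        a = sorted(rng.choice(np.arange(100, 110, 0.3), size=na))
        b = sorted(rng.choice(np.arange(100, 110, 0.3), size=nb))
        tol = MassTolerance("absolute_da", float(rng.choice([0.2, 0.5, 1.0])))
        assert fragment_overlap(a, b, tol) == _overlap_brute_force(a, b, tol)


def _min_frags_oracle(ion, others, tol, max_n):
    """Direct evaluation of the unambiguity definition."""
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
    for n in range(1, cap + 1):
        if all(
            _overlap_brute_force(list(ion.fragment_mzs), list(r.fragment_mzs), tol) < n
            for r in rivals
        ):
            return n
    return AMBIGUOUS


def test_min_fragments_simple_cases():
    a = LipidIon("a", "+", 700.0, (100.0, 200.0))
    b = LipidIon("b", "+", 700.1, (300.0, 400.0))
    c = LipidIon("c", "+", 900.0, (100.0, 200.0))
    # unique precursor -> 0
    assert min_fragments_for_unambiguity(c, [a, b, c], DA05) == 0
    # precursor-similar neighbor sharing no fragments -> 1
    assert min_fragments_for_unambiguity(a, [a, b, c], DA05) == 1
    # identical twin -> ambiguous at any n
    twin = LipidIon("t", "+", 700.0, (100.0, 200.0))
    assert min_fragments_for_unambiguity(a, [a, twin], DA05, max_n=2) == AMBIGUOUS
    # opposite polarity never rivals
    neg = LipidIon("n", "-", 700.0, (100.0, 200.0))
    assert min_fragments_for_unambiguity(a, [a, neg], DA05) == 0


def _random_lipidome(rng, n_ions):
    ions = []
    for i in range(n_ions):
        nf = int(rng.integers(1, 5))
        ions.append(
            LipidIon(
                name=f"ion{i}",
                polarity=str(rng.choice(["+", "-"])),
                precursor_mz=float(rng.uniform(600, 610)),
                fragment_mzs=tuple(
                    float(m) for m in rng.choice(np.arange(100, 120, 0.4), size=nf)
                ),
            )
        )
    return ions


def test_min_fragments_matches_oracle_on_simulated_lipidomes():
    """Definition-direct oracle equivalence on 100 dense simulated lipidomes
    (<= 50 ions, crowded mass range to force collisions)."""
    rng = np.random.default_rng(77)
    for _ in range(100):
        ions = _random_lipidome(rng, int(rng.integers(5, 51)))
        tol = MassTolerance("absolute_da", 0.5)
        for ion in ions:
            got = min_fragments_for_unambiguity(ion, ions, tol, max_n=4)
            assert got == _min_frags_oracle(ion, ions, tol, max_n=4)


def test_distribution_trivial_cases():
    far = [
        LipidIon(f"i{k}", "+", 500.0 + 10 * k, (100.0 + k,)) for k in range(5)
    ]
    assert unambiguity_distribution(far, DA05, max_n=3) == [1.0] * 4
    # two ions, same precursor, same single fragment: ambiguous at max_n=1
    twins = [
        LipidIon("a", "+", 700.0, (100.0,)),
        LipidIon("b", "+", 700.1, (100.2,)),
    ]
    dist = unambiguity_distribution(twins, DA05, max_n=1)
    assert dist == [0.0, 0.0]
    with pytest.raises(ValueError):
        unambiguity_distribution([], DA05)


def test_distribution_monotone_in_n_and_tolerance():
    rng = np.random.default_rng(5)
    ions = _random_lipidome(rng, 40)
    loose = unambiguity_distribution(ions, MassTolerance("absolute_da", 0.5), 5)
    tight = unambiguity_distribution(ions, MassTolerance("absolute_da", 0.05), 5)
    assert all(b >= a - 1e-12 for a, b in zip(loose, loose[1:]))  # monotone in n
    assert all(t >= l - 1e-12 for l, t in zip(loose, tight))  # tightening helps


@pytest.mark.parametrize(
    "counts,expected",
    [
        (ConfusionCounts(21, 20, 1, 0), 97.61904761904762),
        (ConfusionCounts(1, 1, 0, 0), 100.0),
        (ConfusionCounts(0, 0, 1, 1), 0.0),
    ],
)
def test_target_decoy_accuracy(counts, expected):
    assert target_decoy_accuracy(counts) == pytest.approx(expected)


def test_accuracy_rejects_empty_counts():
    with pytest.raises(ValueError):
        target_decoy_accuracy(ConfusionCounts(0, 0, 0, 0))
    with pytest.raises(ValueError):
        ConfusionCounts(-1, 0, 0, 0)


def test_ion_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(9)
    ions = _random_lipidome(rng, 10)
    path = write_ion_tsv(ions, tmp_path / "ions.tsv")
    back = read_ion_tsv(path)
    assert len(back) == len(ions)
    for a, b in zip(ions, back):
        assert a.name == b.name and a.polarity == b.polarity
        assert a.precursor_mz == pytest.approx(b.precursor_mz, abs=1e-6)
        assert np.allclose(a.fragment_mzs, b.fragment_mzs, atol=1e-6)
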