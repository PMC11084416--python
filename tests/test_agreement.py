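"""Percent agreement and Cohen's kappa (weighted and unweighted)."""

import math

import numpy as np
import pytest
from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

from aldress.agreement import (
    KappaInterpretation,
    KappaResult,
    Weighting,
    cohen_kappa,
    interpret_kappa,
    kappa_from_table,
    percent_agreement,
)


def brute_force_kappa(table: np.ndarray, weighting: str):
    """Direct elementwise sums for p_o, p_e and the asymptotic variance."""
    t = np.asarray(table, float)
    n = t.sum()
    k = t.shape[0]
    if weighting == "unweighted":
        w = [[1.0 if i == j else 0.0 for j in range(k)] for i in range(k)]
    else:
        w = [
            [
                1.0 - (abs(i - j) / (k - 1)) ** (1 if weighting == "linear" else 2)
                for j in range(k)
            ]
            for i in range(k)
        ]
    p = t / n
    row = [sum(p[i][j] for j in range(k)) for i in range(k)]
    col = [sum(p[i][j] for i in range(k)) for j in range(k)]
    po = sum(w[i][j] * p[i][j] for i in range(k) for j in range(k))
    pe = sum(w[i][j] * row[i] * col[j] for i in range(k) for j in range(k))
    kappa = (po - pe) / (1 - pe)
    wi = [sum(col[j] * w[i][j] for j in range(k)) for i in range(k)]
    wj = [sum(row[i] * w[i][j] for i in range(k)) for j in range(k)]
    s = sum(
        p[i][j] * (w[i][j] * (1 - pe) - (wi[i] + wj[j]) * (1 - po)) ** 2
        for i in range(k)
        for j in range(k)
    )
    var = (s - (po * pe - 2 * pe + po) ** 2) / (n * (1 - pe) ** 4)
    return kappa, math.sqrt(var)


# ---------------------------------------------------------------------------
# Percent agreement
# ---------------------------------------------------------------------------


def test_identical_vectors_agree_fully():
    assert percent_agreement([1, 2, 3], [1, 2, 3]) == 1.0


@pytest.mark.parametrize("matches,expected", [(32, 0.8649), (33, 0.8919)])
def test_published_matching_rates(matches, expected):
    a = list(range(37))
    b = list(range(matches)) + [99] * (37 - matches)
    assert round(percent_agreement(a, b), 4) == expected


def test_percent_agreement_rejects_bad_input():
    with pytest.raises(ValueError):
        percent_agreement([], [])
    with pytest.raises(ValueError):
        percent_agreement([1], [1, 2])


# ---------------------------------------------------------------------------
# Kappa
# ---------------------------------------------------------------------------


def test_perfect_agreement_gives_kappa_one():
    r = cohen_kappa(["a", "b", "a", "c"], ["a", "b", "a", "c"])
    assert r.kappa == pytest.approx(1.0)


def test_chance_level_table_gives_kappa_zero():
    # cells proportional to the product of the margins
    table = np.outer([30, 10], [20, 20]) / 40.0
    r = kappa_from_table(table)
    assert r.kappa == pytest.approx(0.0, abs=1e-12)


def test_binary_ratings_weighted_equals_unweighted():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a = list(rng.integers(0, 2, 30))
        b = list(rng.integers(0, 2, 30))
        if len(set(a)) < 2 and len(set(b)) < 2:
            continue
        ku = cohen_kappa(a, b, Weighting.unweighted)
        for w in (Weighting.linear, Weighting.quadratic):
            kw = cohen_kappa(a, b, w)
            assert kw.kappa == pytest.approx(ku.kappa, abs=1e-12)
            assert kw.ase == pytest.approx(ku.ase, abs=1e-12)


def test_constant_identical_ratings_are_an_explicit_error():
    with pytest.raises(ValueError, match="undefined"):
        cohen_kappa([1, 1, 1], [1, 1, 1])


def test_kappa_matches_brute_force_oracle_on_random_tables():
    rng = np.random.default_rng(17)
    for _ in range(60):
        table = rng.integers(0, 8, (3, 3)).astype(float)
        if np.count_nonzero(table) < 2:  # avoid the degenerate p_e = 1 case
            table[0, 0] += 2
            table[1, 1] += 2
        for w in ("unweighted", "linear", "quadratic"):
            ok, oa = brute_force_kappa(table, w)
            r = kappa_from_table(table, Weighting(w))
            assert abs(r.kappa - ok) < 1e-10
            assert abs(r.ase - oa) < 1e-10


def test_kappa_matches_statsmodels():
    rng = np.random.default_rng(23)
    for _ in range(20):
        table = rng.integers(1, 10, (4, 4)).astype(float)
        for ours, theirs in ((Weighting.unweighted, None), (Weighting.linear, "linear"), (Weighting.quadratic, "quadratic")):
            r = kappa_from_table(table, ours)
            s = sm_kappa(table, wt=theirs)
            assert r.kappa == pytest.approx(float(s.kappa), abs=1e-10)
            assert r.ase == pytest.approx(float(s.std_kappa), abs=1e-10)


def test_kappa_is_invariant_under_subject_permutation():
    rng = np.random.default_rng(3)
    a = list(rng.integers(0, 3, 40))
    b = list(rng.integers(0, 3, 40))
    perm = rng.permutation(40)
    r1 = cohen_kappa(a, b, Weighting.quadratic, categories=[0, 1, 2])
    r2 = cohen_kappa(
        [a[i] for i in perm], [b[i] for i in perm], Weighting.quadratic, categories=[0, 1, 2]
    )
    assert r1.kappa == pytest.approx(r2.kappa)
    assert r1.ase == pytest.approx(r2.ase)


def test_unweighted_kappa_survives_category_relabeling_but_weighted_does_not():
    a = [0, 2, 0, 2, 1, 0, 2, 1, 0, 2, 0, 1]
    b = [2, 0, 0, 2, 1, 2, 0, 1, 0, 2, 2, 1]
    swap = {0: 2, 1: 1, 2: 0}
    a2 = [swap[x] for x in a]
    b2 = [swap[x] for x in b]
    u1 = cohen_kappa(a, b, categories=[0, 1, 2])
    u2 = cohen_kappa(a2, b2, categories=[0, 1, 2])
    assert u1.kappa == pytest.approx(u2.kappa)
    # an order-breaking relabeling changes the quadratic-weighted value
    scramble = {0: 1, 1: 0, 2: 2}
    a3 = [scramble[x] for x in a]
    b3 = [scramble[x] for x in b]
    q1 = cohen_kappa(a, b, Weighting.quadratic, categories=[0, 1, 2])
    q3 = cohen_kappa(a3, b3, Weighting.quadratic, categories=[0, 1, 2])
    assert abs(q1.kappa - q3.kappa) > 1e-6


def test_result_invariants_z_and_ci_derive_from_the_ase():
    rng = np.random.default_rng(31)
    for _ in range(20):
        table = rng.integers(1, 9, (3, 3)).astype(float)
        r = kappa_from_table(table)
        assert r.z == pytest.approx(r.kappa / r.ase)
        assert r.ci_low == pytest.approx(r.kappa - 1.959963984540054 * r.ase)
        assert r.ci_high == pytest.approx(r.kappa + 1.959963984540054 * r.ase)
        assert -1.0 <= r.kappa <= 1.0


# ---------------------------------------------------------------------------
# Interpretation bands
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kappa,band",
    [
        (0.5761, KappaInterpretation.moderate),
        (0.88, KappaInterpretation.near_perfect),
        (0.05, KappaInterpretation.none),
        (0.15, KappaInterpretation.slight),
        (0.30, KappaInterpretation.fair),
        (0.70, KappaInterpretation.substantial),
        (-0.4, KappaInterpretation.none),
    ],
)
def test_landis_koch_bands(kappa, band):
    assert interpret_kappa(kappa) is band


def test_interpret_rejects_out_of_range_values():
    with pytest.raises(ValueError):
        interpret_kappa(1.5)
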