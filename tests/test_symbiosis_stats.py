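"""Factorial ANOVA and Tukey letters against brute-force oracles."""

import itertools

import numpy as np
import pytest
from scipy.stats import studentized_range

import symflux as sf


# --- independent residual-projection oracle -------------------------------

def _rss(y, X):
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _dummies(levels):
    labels = sorted(set(levels))
    return np.column_stack([[1.0 if l == lab else 0.0 for l in levels] for lab in labels])


def type2_oracle(y, a, b):
    """Type II F-ratios by explicit residual projection (lstsq on dummy bases)."""
    y = np.asarray(y, dtype=float)
    one = np.ones((len(y), 1))
    A, B = _dummies(a), _dummies(b)
    AB = np.column_stack(
        [A[:, i] * B[:, j] for i in range(A.shape[1]) for j in range(B.shape[1])]
    )
    full = np.column_stack([one, A, B, AB])
    rss_full = _rss(y, full)
    df_resid = len(y) - np.linalg.matrix_rank(full)
    mse = rss_full / df_resid
    df_a, df_b = A.shape[1] - 1, B.shape[1] - 1
    ss_a = _rss(y, np.column_stack([one, B])) - _rss(y, np.column_stack([one, A, B]))
    ss_b = _rss(y, np.column_stack([one, A])) - _rss(y, np.column_stack([one, A, B]))
    ss_ab = _rss(y, np.column_stack([one, A, B])) - rss_full
    return {
        "species": (ss_a / df_a) / mse,
        "co2": (ss_b / df_b) / mse,
        "species_x_co2": (ss_ab / (df_a * df_b)) / mse,
    }, df_resid


def _balanced_species_fixture():
    """Balanced 2x2, n=3: cell means 10,10,20,20 and residuals (+1,-1,0) per
    cell, so SSE=8 on 8 df (MSE=1) and species SS=300."""
    y, a, b = [], [], []
    for sp, co2, mean in [("s1", "l", 10), ("s1", "h", 10), ("s2", "l", 20), ("s2", "h", 20)]:
        for dev in (1.0, -1.0, 0.0):
            y.append(mean + dev)
            a.append(sp)
            b.append(co2)
    return np.array(y), a, b


def test_hand_computed_balanced_fixture():
    y, a, b = _balanced_species_fixture()
    report = sf.two_way_anova(y, a, b)
    assert report.terms["species"].F == pytest.approx(300.0, rel=1e-9)
    assert report.terms["co2"].F == pytest.approx(0.0, abs=1e-9)
    assert report.terms["species_x_co2"].F == pytest.approx(0.0, abs=1e-9)
    assert report.residual_df == 8
    oracle, df = type2_oracle(y, a, b)
    assert df == 8
    for term, f in oracle.items():
        assert report.terms[term].F == pytest.approx(f, rel=1e-9, abs=1e-9)


@pytest.mark.parametrize("drop", [0, 3])
def test_matches_projection_oracle_on_random_data(rng, drop):
    """Type II F-ratios agree with the lstsq oracle, balanced and unbalanced."""
    for _ in range(5):
        a = ["s1"] * 10 + ["s2"] * 10
        b = (["l"] * 5 + ["h"] * 5) * 2
        y = rng.normal(size=20) + np.where(np.array(a) == "s1", 0.0, rng.normal())
        if drop:
            keep = rng.permutation(20)[drop:]
            y, a, b = y[keep], [a[i] for i in keep], [b[i] for i in keep]
        report = sf.two_way_anova(y, a, b)
        oracle, df = type2_oracle(y, a, b)
        assert report.residual_df == df
        for term, f in oracle.items():
            assert report.terms[term].F == pytest.approx(f, rel=1e-9)


def test_type_two_equals_sequential_on_balanced(rng):
    """On balanced data Type II SS coincide with Type I for either ordering,
    so the F-ratios cannot depend on factor order."""
    y = rng.normal(size=16)
    a = ["s1"] * 8 + ["s2"] * 8
    b = (["l"] * 4 + ["h"] * 4) * 2
    fwd = sf.two_way_anova(y, a, b)
    swapped = sf.two_way_anova(y, b, a)
    assert fwd.terms["species"].F == pytest.approx(swapped.terms["co2"].F, rel=1e-9)
    assert fwd.terms["co2"].F == pytest.approx(swapped.terms["species"].F, rel=1e-9)
    assert fwd.terms["species_x_co2"].F == pytest.approx(
        swapped.terms["species_x_co2"].F, rel=1e-9
    )


def test_f_invariant_under_affine_response_transform(rng):
    y = rng.normal(size=20)
    a = ["s1"] * 10 + ["s2"] * 10
    b = (["l"] * 5 + ["h"] * 5) * 2
    base = sf.two_way_anova(y, a, b)
    shifted = sf.two_way_anova(3.7 * y + 11.0, a, b)
    for term in base.terms:
        assert shifted.terms[term].F == pytest.approx(base.terms[term].F, rel=1e-9)
        assert shifted.terms[term].p == pytest.approx(base.terms[term].p, rel=1e-9)


def test_degenerate_constant_response():
    y = np.full(12, 5.0)
    a = ["s1"] * 6 + ["s2"] * 6
    b = (["l"] * 3 + ["h"] * 3) * 2
    report = sf.two_way_anova(y, a, b)
    assert report.degenerate
    for term in report.terms.values():
        assert term.F == 0.0 and term.p == 1.0


def test_single_level_factor_dropped_with_warning(rng):
    y = rng.normal(size=8)
    with pytest.warns(UserWarning, match="dropped"):
        report = sf.two_way_anova(y, ["s1"] * 8, (["l"] * 2 + ["h"] * 2) * 2)
    assert set(report.terms) == {"co2"}


# --- Tukey letters ---------------------------------------------------------

def brute_force_differs(means, n, mse, df, alpha):
    """Pairwise studentized-range p-values, independent of the letter code."""
    out = {}
    k = len(means)
    for g1, g2 in itertools.combinations(means, 2):
        q = abs(means[g1] - means[g2]) / np.sqrt(mse / 2 * (1 / n[g1] + 1 / n[g2]))
        out[frozenset((g1, g2))] = studentized_range.sf(q, k, df) < alpha
    return out


def _assert_letters_encode(decisions, letters):
    for pair, differ in decisions.items():
        g1, g2 = tuple(pair)
        assert letters.share_letter(g1, g2) == (not differ), (g1, g2)


def test_two_groups_forced_apart():
    letters = sf.tukey_letters({"g1": 0.0, "g2": 100.0}, {"g1": 5, "g2": 5}, 1.0, 8)
    assert letters.letters["g1"] == "a" and letters.letters["g2"] == "b"


def test_identical_means_share_one_letter():
    letters = sf.tukey_letters({"g1": 5.0, "g2": 5.0, "g3": 5.0}, {"g1": 4, "g2": 4, "g3": 4}, 1.0, 9)
    assert set(letters.letters.values()) == {"a"}


def test_four_group_fixture_partition():
    means = {"g1": 0.0, "g2": 0.1, "g3": 5.0, "g4": 5.1}
    n = {g: 5 for g in means}
    letters = sf.tukey_letters(means, n, 1.0, 16, alpha=0.05)
    assert letters.letters == {"g1": "a", "g2": "a", "g3": "b", "g4": "b"}
    _assert_letters_encode(brute_force_differs(means, n, 1.0, 16, 0.05), letters)


def test_letters_match_brute_force_on_random_instances(rng):
    for _ in range(20):
        k = int(rng.integers(3, 6))
        means = {f"g{i}": float(rng.normal(scale=2.0)) for i in range(k)}
        n = {g: int(rng.integers(3, 8)) for g in means}
        mse = float(rng.uniform(0.2, 3.0))
        df = int(sum(n.values()) - k)
        letters = sf.tukey_letters(means, n, mse, df)
        _assert_letters_encode(brute_force_differs(means, n, mse, df, 0.05), letters)


def test_letters_order_invariant():
    means = {"g1": 0.0, "g2": 0.1, "g3": 5.0, "g4": 5.1}
    n = {g: 5 for g in means}
    fwd = sf.tukey_letters(means, n, 1.0, 16)
    rev = sf.tukey_letters(dict(reversed(means.items())), n, 1.0, 16)
    assert fwd.letters == rev.letters


def test_zero_mse_degenerate():
    letters = sf.tukey_letters({"g1": 1.0, "g2": 1.0, "g3": 2.0}, {"g1": 3, "g2": 3, "g3": 3}, 0.0, 6)
    assert letters.degenerate
    assert letters.share_letter("g1", "g2")
    assert not letters.share_letter("g1", "g3")


def test_anova_table_shape(small_noisy):
    _, _, campaign, _ = small_noisy
    table, reports, letters = sf.analyze_campaign(campaign)
    assert len(table) == 6
    assert set(reports) == set(letters)
    for rep in reports.values():
        assert set(rep.terms) == {"species", "co2", "species_x_co2"}
        for term in rep.terms.values():
            assert term.F >= 0 and 0 <= term.p <= 1
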