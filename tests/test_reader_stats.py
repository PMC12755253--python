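"""Rank tests, Holm correction and Likert preference analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mambasr.reader_stats import (AllTiesError, dunn_holm,
                                  exact_binomial_two_sided, holm_adjust,
                                  kruskal_wallis, likert_winner,
                                  preference_analysis, preference_rate,
                                  validate_likert_table)


def test_kruskal_wallis_hand_fixture():
    h, p = kruskal_wallis([[1, 2], [3, 4]])
    assert h == pytest.approx(2.4)  # 12/20 * (9/2 + 49/2) - 15


def test_kruskal_wallis_identical_groups():
    h, p = kruskal_wallis([[1, 2, 3], [1, 2, 3]])
    assert h == pytest.approx(0.0, abs=1e-12)
    h, p = kruskal_wallis([[5, 5], [5, 5]])  # all values tied
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_matches_scipy_on_random_instances(rng):
    for trial in range(50):
        k = int(rng.integers(2, 5))
        groups = [rng.integers(0, 8, size=rng.integers(3, 12)).astype(float)
                  for _ in range(k)]
        if all(np.all(g == groups[0][0]) for g in groups):
            continue
        h, p = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert h == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


def test_holm_step_down_example():
    np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.03]), [0.03, 0.04, 0.04])
    np.testing.assert_allclose(holm_adjust([0.2]), [0.2])  # single pair: unchanged


def test_holm_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    for trial in range(50):
        p = rng.random(int(rng.integers(1, 9)))
        ref = multipletests(p, method="holm")[1]
        np.testing.assert_allclose(holm_adjust(p), ref, atol=1e-12)


def test_dunn_hand_fixture():
    """Three groups of two without ties: z statistics are closed-form."""
    table = dunn_holm([[1, 2], [3, 4], [5, 6]], ["a", "b", "c"])
    se = np.sqrt(3.5)  # n(n+1)/12 * (1/2 + 1/2) with n = 6, no ties
    expected_z = {("a", "b"): -2.0 / se, ("a", "c"): -4.0 / se, ("b", "c"): -2.0 / se}
    for _, row in table.iterrows():
        z = expected_z[(row.method_a, row.method_b)]
        assert row.z == pytest.approx(z, abs=1e-10)
        assert row.p_raw == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)
    # Holm on the three raw p-values, checked independently
    from statsmodels.stats.multitest import multipletests

    np.testing.assert_allclose(table["p_holm"],
                               multipletests(table["p_raw"], method="holm")[1],
                               atol=1e-12)


def test_dunn_holm_monotone_and_bounded(rng):
    for trial in range(20):
        groups = [rng.normal(size=rng.integers(4, 10)) for _ in range(4)]
        table = dunn_holm(groups)
        assert (table.p_holm >= table.p_raw - 1e-15).all()
        assert (table.p_holm <= 1.0).all()
        ordered = table.sort_values("p_raw")["p_holm"].to_numpy()
        assert np.all(np.diff(ordered) >= -1e-15)


def test_likert_winner_branches():
    assert likert_winner(5, 3) == "a"
    assert likert_winner(2, 4) == "b"
    assert likert_winner(3, 3) == "tie"
    with pytest.raises(ValueError):
        likert_winner(0, 3)


def test_preference_rate_printed_values():
    assert round(preference_rate(28, 5), 3) == 0.848
    assert round(preference_rate(22, 4), 3) == 0.846
    assert preference_rate(7, 7) == 0.5
    with pytest.raises(AllTiesError):
        preference_rate(0, 0)


def test_exact_binomial_printed_values():
    assert exact_binomial_two_sided(28, 33) == pytest.approx(6.6e-5, rel=0.05)
    assert exact_binomial_two_sided(22, 26) == pytest.approx(5.3e-4, rel=0.05)
    assert exact_binomial_two_sided(3, 3) == pytest.approx(0.25)
    with pytest.raises(ValueError):
        exact_binomial_two_sided(5, 3)


def test_exact_binomial_symmetry_and_bounds(rng):
    for _ in range(30):
        n = int(rng.integers(1, 60))
        k = int(rng.integers(0, n + 1))
        p = exact_binomial_two_sided(k, n)
        assert 0.0 < p <= 1.0
        assert p == exact_binomial_two_sided(n - k, n)
    ref = stats.binomtest(28, 33, 0.5).pvalue
    assert exact_binomial_two_sided(28, 33) == pytest.approx(ref, rel=1e-10)


def _table(rows):
    return pd.DataFrame(rows, columns=["dataset", "reader", "case", "method", "score"])


def test_preference_analysis_enumerated_example():
    rows = []
    for i, (sa, sb) in enumerate([(5, 3), (4, 4), (2, 1)]):
        rows.append(("d", "r1", f"c{i}", "A", sa))
        rows.append(("d", "r1", f"c{i}", "B", sb))
    result = preference_analysis(_table(rows))
    pair = result["pairs"].iloc[0]
    assert (pair.wins_a, pair.wins_b, pair.ties) == (2, 0, 1)
    assert pair.preference_rate == 1.0
    mat = result["matrix"]
    assert mat.loc["A", "A"] == 0.5 and mat.loc["B", "B"] == 0.5
    assert mat.loc["A", "B"] == 1.0 and mat.loc["B", "A"] == 0.0


def test_preference_analysis_single_method():
    rows = [("d", "r1", f"c{i}", "only", s) for i, s in enumerate([3, 4, 5])]
    result = preference_analysis(_table(rows))
    assert result["pairs"].empty
    assert result["descriptives"].iloc[0]["median"] == 4.0


def test_preference_analysis_invariants(rng):
    rows = []
    for reader in range(3):
        for case in range(10):
            for m in ("A", "B", "C"):
                rows.append(("d", f"r{reader}", f"c{case}", m,
                             int(rng.integers(1, 6))))
    result = preference_analysis(_table(rows))
    for _, row in result["pairs"].iterrows():
        assert row.wins_a + row.wins_b + row.ties == row.shared_instances == 30
        if not np.isnan(row.preference_rate):
            # antisymmetry through the matrix
            mat = result["matrix"]
            assert mat.loc[row.method_a, row.method_b] + \
                mat.loc[row.method_b, row.method_a] == pytest.approx(1.0)


def test_likert_table_validation():
    with pytest.raises(ValueError):
        validate_likert_table(_table([("d", "r", "c", "A", 6)]))
    with pytest.raises(ValueError):
        validate_likert_table(_table([("d", "r", "c", "A", 3),
                                      ("d", "r", "c", "A", 4)]))
    with pytest.raises(ValueError):
        validate_likert_table(pd.DataFrame({"method": ["A"], "score": [3]}))
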