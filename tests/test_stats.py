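import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from qsarspace.stats import (FriedmanResult, chi2_sf, friedman,
                             posthoc_groups, rank_table)


def perf_frame(values, datasets=None, treatments=None):
    values = np.asarray(values, dtype=float)
    datasets = datasets or [f"d{i}" for i in range(values.shape[0])]
    treatments = treatments or [f"t{j}" for j in range(values.shape[1])]
    return pd.DataFrame(values, index=datasets, columns=treatments)


def brute_force_friedman(perf: pd.DataFrame) -> float:
    """Independent re-implementation: rank by hand, tie-correct via scipy."""
    return float(sps.friedmanchisquare(*[perf.iloc[:, j] for j in
                                         range(perf.shape[1])]).statistic)


class TestRankTable:
    def test_rank_one_is_best_pve(self):
        table = rank_table(perf_frame([[0.9, 0.1, 0.5]]))
        assert list(table.ranks.iloc[0]) == [1.0, 3.0, 2.0]

    def test_ties_receive_averaged_ranks(self):
        table = rank_table(perf_frame([[0.5, 0.5, 0.1]]))
        assert list(table.ranks.iloc[0]) == [1.5, 1.5, 3.0]

    def test_rank_sums_total(self):
        rng = np.random.default_rng(0)
        perf = perf_frame(rng.random((5, 4)))
        table = rank_table(perf)
        n, k = 5, 4
        assert table.ranks.to_numpy().sum() == pytest.approx(n * k * (k + 1) / 2)

    def test_missing_cells_rejected(self):
        perf = perf_frame([[0.5, np.nan], [0.2, 0.3]])
        with pytest.raises(ValueError, match="missing"):
            rank_table(perf)


class TestChi2Sf:
    def test_worked_examples(self):
        assert chi2_sf(38.44, 17) == pytest.approx(2.2e-3, rel=0.05)
        assert chi2_sf(15.2, 5) == pytest.approx(9.5e-3, rel=0.05)
        assert chi2_sf(0.0, 3) == 1.0

    def test_matches_regularized_incomplete_gamma(self):
        from scipy.special import gammaincc
        for x, df in [(3.2, 2), (21.1, 5), (38.44, 17)]:
            assert chi2_sf(x, df) == pytest.approx(gammaincc(df / 2, x / 2),
                                                   rel=1e-6)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            chi2_sf(1.0, 0)


class TestFriedman:
    def test_unanimous_ranking_k3_n5(self):
        # every dataset ranks t0 > t1 > t2; rank sums (5, 10, 15) -> 10.0
        perf = perf_frame([[0.9, 0.5, 0.1]] * 5)
        result = friedman(perf)
        assert result.statistic == pytest.approx(10.0)
        assert result.df == 2
        assert list(result.rank_sums) == [5.0, 10.0, 15.0]

    def test_all_equal_performance_is_null(self):
        result = friedman(perf_frame([[0.5] * 4] * 3))
        assert result.statistic == 0.0
        assert result.p_value == 1.0

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            perf = perf_frame(rng.random((5, 4)))
            assert friedman(perf).statistic == pytest.approx(
                brute_force_friedman(perf), abs=1e-9)

    def test_tie_correction_matches_scipy(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            vals = rng.integers(0, 3, (6, 5)) / 4.0  # heavy ties
            perf = perf_frame(vals)
            assert friedman(perf).statistic == pytest.approx(
                brute_force_friedman(perf), abs=1e-9)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        perf = perf_frame(rng.random((4, 5)))
        transformed = perf_frame(np.exp(3 * perf.to_numpy()))
        assert friedman(perf).statistic == pytest.approx(
            friedman(transformed).statistic)

    def test_too_small_table_rejected(self):
        with pytest.raises(ValueError):
            friedman(perf_frame([[0.5, 0.6]]))


def oracle_lsd(table, alpha):
    """Conover least-significant difference recomputed from the rank table."""
    R = table.ranks.to_numpy()
    n, k = R.shape
    A = (R ** 2).sum()
    C = n * k * (k + 1) ** 2 / 4.0
    Rj = R.sum(axis=0)
    T1 = (k - 1) * ((Rj - n * (k + 1) / 2) ** 2).sum() / (A - C)
    dfe = (n - 1) * (k - 1)
    return sps.t.ppf(1 - alpha / 2, dfe) * np.sqrt(
        2 * n * (A - C) * max(0.0, 1 - T1 / (n * (k - 1))) / dfe)


def brute_force_letters(table, result, alpha):
    """Oracle: all-pairs significance from an independent LSD, letters by graph."""
    lsd = oracle_lsd(table, alpha)
    names = list(result.rank_sums.sort_values().index)
    nonsig = {(a, b): abs(result.rank_sums[a] - result.rank_sums[b]) <= lsd
              for a, b in itertools.combinations(names, 2)}
    return names, nonsig


class TestPosthocGroups:
    def test_identical_rank_sums_share_a_letter(self):
        perf = perf_frame([[0.9, 0.9, 0.1], [0.8, 0.8, 0.2],
                           [0.7, 0.7, 0.3], [0.6, 0.6, 0.1]])
        result = friedman(perf)
        groups = posthoc_groups(result, rank_table(perf))
        assert set(groups["t0"]) & set(groups["t1"])

    def test_extreme_separation_gets_disjoint_letters(self):
        rng = np.random.default_rng(4)
        base = np.tile([0.95, 0.75, 0.5, 0.25, 0.05], (12, 1))
        perf = perf_frame(base + rng.normal(0, 0.01, base.shape))
        table = rank_table(perf)
        result = friedman(table)
        groups = posthoc_groups(result, table)
        assert not set(groups["t0"]) & set(groups["t4"])

    def test_letter_relation_matches_pairwise_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            perf = perf_frame(rng.random((5, 6)))
            table = rank_table(perf)
            result = friedman(table)
            groups = posthoc_groups(result, table, alpha=0.05)
            names, nonsig = brute_force_letters(table, result, 0.05)
            for a, b in itertools.combinations(names, 2):
                share = bool(set(groups[a]) & set(groups[b]))
                assert share == nonsig[(a, b)], (groups, result.rank_sums)

    def test_every_treatment_holds_a_letter(self):
        rng = np.random.default_rng(6)
        perf = perf_frame(rng.random((4, 8)))
        table = rank_table(perf)
        groups = posthoc_groups(friedman(table), table)
        assert all(groups[t] for t in perf.columns)

    def test_single_treatment_rejected(self):
        result = FriedmanResult(statistic=0, df=1, p_value=1,
                                rank_sums=pd.Series([1.0], index=["t0"]))
        perf = perf_frame([[0.5], [0.6]])
        with pytest.raises(ValueError):
            posthoc_groups(result, rank_table(perf))


def test_null_type_one_error_rate_is_calibrated():
    """Under i.i.d. performances the Friedman test rejects ~5% at alpha=.05."""
    rng = np.random.default_rng(7)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        perf = perf_frame(rng.random((5, 6)))
        if friedman(perf).p_value < 0.05:
            rejections += 1
    assert 0.03 <= rejections / n_sim <= 0.07
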