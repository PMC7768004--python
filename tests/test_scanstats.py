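"""Mann-Whitney scan tests: enumeration oracles, run bookkeeping, trend."""

import itertools

import numpy as np
import pandas as pd
import pytest

from trusteeg.containers import DISTRUST, TRUST
from trusteeg.erp import D_ALL, T_ALL
from trusteeg.errors import DataError
from trusteeg.scanstats import (
    GRID_MS,
    _flags_to_runs,
    mann_whitney,
    scan_bin_means,
    scan_case_pair,
    trust_rate_test,
    trust_trend_test,
)
from trusteeg.synthdata import ChoiceModel, ExperimentSpec, simulate_decisions


def exact_mw_pvalue(a, b):
    """Oracle: two-sided p by enumerating all rank assignments."""
    a, b = list(a), list(b)
    pooled = a + b
    n1 = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}

    def u_of(sample):
        r = sum(ranks[v] for v in sample)
        return r - n1 * (n1 + 1) / 2

    u_obs = u_of(a)
    n1n2 = n1 * len(b)
    dev = abs(u_obs - n1n2 / 2)
    count = total = 0
    for combo in itertools.combinations(pooled, n1):
        u = sum(ranks[v] for v in combo) - n1 * (n1 + 1) / 2
        total += 1
        count += abs(u - n1n2 / 2) >= dev - 1e-12
    return count / total


class TestMannWhitney:
    def test_separated_samples_exact(self):
        """a=[1,2,3] vs b=[4,5,6]: U=0, exact two-sided p = 2/20 = 0.1."""
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(0.1)
        assert res.p_value == pytest.approx(exact_mw_pvalue([1, 2, 3], [4, 5, 6]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=4)
        b = rng.normal(size=4)
        res = mann_whitney(a, b)
        assert res.method == "mann-whitney-exact"
        assert res.p_value == pytest.approx(exact_mw_pvalue(a, b))

    def test_identical_samples_symmetric_null(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value > 0.9

    def test_swap_antisymmetry(self, rng):
        a = rng.normal(size=30)
        b = rng.normal(loc=0.5, size=25)
        r1 = mann_whitney(a, b)
        r2 = mann_whitney(b, a)
        assert r1.statistic + r2.statistic == pytest.approx(30 * 25)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_large_samples_use_tie_corrected_normal(self, rng):
        a = rng.integers(0, 5, size=50).astype(float)  # heavy ties
        b = rng.integers(0, 5, size=50).astype(float)
        res = mann_whitney(a, b)
        assert res.method == "mann-whitney-asymptotic"
        assert 0.0 <= res.p_value <= 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(DataError):
            mann_whitney([], [1.0])


class TestRunExtraction:
    def test_flag_pattern_bookkeeping(self):
        """[F,T,T,T,F,T] on a grid starting at 0 -> runs (10,40) and (50,60)."""
        flags = np.array([False, True, True, True, False, True])
        starts = np.arange(6) * GRID_MS
        p = np.array([0.5, 0.001, 0.002, 0.003, 0.7, 0.004])
        runs = _flags_to_runs(flags, starts, p)
        assert [(r.start_ms, r.end_ms) for r in runs] == [(10.0, 40.0), (50.0, 60.0)]
        assert runs[0].n_bins == 3 and runs[1].n_bins == 1
        assert runs[0].p_summary == pytest.approx(0.003)

    def test_runs_cover_exactly_flagged_bins(self, rng):
        """Reconstructing the flag vector from runs is lossless."""
        flags = rng.random(40) < 0.3
        starts = np.arange(40) * GRID_MS
        p = np.where(flags, 0.001, 0.5)
        runs = _flags_to_runs(flags, starts, p)
        rebuilt = np.zeros(40, dtype=bool)
        for r in runs:
            i = int(r.start_ms // GRID_MS)
            rebuilt[i : i + r.n_bins] = True
        assert np.array_equal(rebuilt, flags)
        # maximality: runs are separated by at least one unflagged bin
        ends = [r.end_ms for r in runs]
        nexts = [r.start_ms for r in runs[1:]]
        assert all(s > e for e, s in zip(ends, nexts))

    def test_no_significant_bins_empty_runs(self, rng):
        table = pd.DataFrame(
            {
                "participant": 0,
                "trial": np.arange(40),
                "scl": 50,
                "decision": [TRUST] * 20 + [DISTRUST] * 20,
                "bin_0": rng.normal(size=40),
                "bin_10": rng.normal(size=40),
            }
        )
        res = scan_bin_means(table, T_ALL, D_ALL, alpha=1e-6)
        assert res.runs == []


class TestScanRecovery:
    def test_longest_run_overlaps_injected_window(self, lead64, cog64, effect_cohort):
        """The longest T-vs-D run overlaps the injected 372-796 ms window
        with Jaccard >= 0.5."""
        _, _, epochs = effect_cohort
        res = scan_case_pair(epochs, T_ALL, D_ALL, cog64, span_ms=(250.0, 800.0))
        run = res.longest_run
        assert run is not None
        lo, hi = 372.0, 796.0
        inter = max(0.0, min(run.end_ms, hi) - max(run.start_ms, lo))
        union = max(run.end_ms, hi) - min(run.start_ms, lo)
        assert inter / union >= 0.5

    def test_empty_case_names_the_case(self, lead64, cog64, effect_cohort):
        _, _, epochs = effect_cohort
        only_trust = epochs.subset(epochs.labels.decision == TRUST)
        with pytest.raises(DataError, match="D"):
            scan_case_pair(only_trust, T_ALL, D_ALL, cog64)


class TestTrustRate:
    def test_equal_proportions_chi2_zero(self):
        dec = pd.DataFrame(
            {
                "participant": 0,
                "trial": range(60),
                "scl": [50] * 20 + [70] * 20 + [90] * 20,
                "decision": ([TRUST] * 10 + [DISTRUST] * 10) * 3,
            }
        )
        res = trust_rate_test(dec)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_built_table_matches_cellwise_formula(self):
        """Counts [[30,42,54],[30,18,6]] vs the brute-force chi2 sum."""
        rows = []
        trust_counts = {50: 30, 70: 42, 90: 54}
        distrust_counts = {50: 30, 70: 18, 90: 6}
        for scl in (50, 70, 90):
            rows += [{"scl": scl, "decision": TRUST}] * trust_counts[scl]
            rows += [{"scl": scl, "decision": DISTRUST}] * distrust_counts[scl]
        dec = pd.DataFrame(rows)
        res = trust_rate_test(dec)
        table = np.array([[30, 42, 54], [30, 18, 6]], dtype=float)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert res.statistic == pytest.approx(chi2)
        assert res.extra["trust_rate"] == {50: 0.5, 70: 0.7, 90: 0.9}

    def test_generator_defaults_reject_independence(self):
        for seed in (0, 1, 2):
            spec = ExperimentSpec(n_participants=20, seed=seed)
            dec = simulate_decisions(spec, ChoiceModel())
            res = trust_rate_test(dec)
            assert res.p_value < 0.05
            rates = res.extra["trust_rate"]
            assert rates[50] < rates[70] < rates[90]

    def test_single_level_rejected(self):
        dec = pd.DataFrame(
            {"scl": [50] * 10, "decision": [TRUST, DISTRUST] * 5}
        )
        with pytest.raises(DataError):
            trust_rate_test(dec)

    def test_trend_statistic_positive_under_increasing_rates(self):
        spec = ExperimentSpec(n_participants=30, seed=4)
        dec = simulate_decisions(spec, ChoiceModel())
        res = trust_trend_test(dec)
        assert res.statistic > 0
        assert res.p_value < 0.01
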