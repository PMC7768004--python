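"""Nonparametric hypothesis tests and the sliding 10 ms interval scan.

Two families of tests drive the analysis:

* the trust-rate test -- a chi-squared test of independence on the 2 x 3
  decision-by-SCL count table (does the share of trusting decisions move
  with source credibility?), plus a one-sided Cochran-Armitage trend test;
* the interval scan -- for a pair of experimental cases, the per-trial
  cognitive-ERP mean in every 10 ms bin forms two samples compared with a
  two-sided Mann-Whitney U test; maximal runs of consecutive significant
  bins are reported, the longest being the "longest joint interval" of a
  contrast.

No multiple-testing correction is applied by default (each run probes one
hypothesis at different latencies); a Benjamini-Hochberg option exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet
from .erp import CaseLabel, CognitiveSet, select_case
from .errors import ConfigError, DataError

GRID_MS = 10.0

#: Default scan span [ms]: reported differences start around 250 ms and the
#: analysis window ends at 800 ms post-stimulus.
DEFAULT_SCAN_SPAN = (250.0, 800.0)
DEFAULT_ALPHA = 0.01


@dataclass
class TestResult:
    """Outcome of a two-sample or contingency test."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    method: str = ""
    extra: dict = field(default_factory=dict)


@dataclass
class Run:
    """A maximal run of consecutive significant 10 ms bins."""

    start_ms: float
    end_ms: float
    n_bins: int
    p_summary: float  # max per-bin p inside the run (conservative)


@dataclass
class ScanResult:
    """Per-bin p-values and significant runs for one case pair."""

    case_pair: tuple[str, str]
    bin_starts_ms: np.ndarray
    p_values: np.ndarray
    alpha: float
    runs: list[Run]

    @property
    def longest_run(self) -> Run | None:
        if not self.runs:
            return None
        return max(self.runs, key=lambda r: (r.n_bins, -r.start_ms))

    def runs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_a": self.case_pair[0],
                "case_b": self.case_pair[1],
                "start_ms": [r.start_ms for r in self.runs],
                "end_ms": [r.end_ms for r in self.runs],
                "n_bins": [r.n_bins for r in self.runs],
                "p_summary": [r.p_summary for r in self.runs],
            }
        )

    def pvalues_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "case_a": self.case_pair[0],
                "case_b": self.case_pair[1],
                "bin_start_ms": self.bin_starts_ms,
                "bin_end_ms": self.bin_starts_ms + GRID_MS,
                "p_value": self.p_values,
            }
        )


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact null enumeration when the pooled sample is small (n1+n2 <= 12)
    and tie-free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise DataError("Mann-Whitney requires nonempty samples")
    pooled = np.concatenate([a, b])
    no_ties = len(np.unique(pooled)) == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=a.size,
        n2=b.size,
        method=f"mann-whitney-{method}",
    )


def cognitive_bin_means(
    epochs: EpochSet,
    cog: CognitiveSet,
    span_ms: tuple[float, float] = DEFAULT_SCAN_SPAN,
) -> pd.DataFrame:
    """Per-trial cognitive-ERP mean in every 10 ms bin of the span.

    Returns the trial label table extended with one column per bin, named
    ``bin_<start_ms>``.  These per-trial values are the scan's samples.
    """
    t1, t2 = span_ms
    if abs(t1 / GRID_MS - round(t1 / GRID_MS)) > 1e-9 or abs(
        t2 / GRID_MS - round(t2 / GRID_MS)
    ) > 1e-9:
        raise ConfigError("scan span must be aligned to the 10 ms grid")
    times = epochs.times_ms
    if t1 < times[0] - 1e-9 or t2 > times[-1] + 1000.0 / epochs.sfreq + 1e-9:
        raise ConfigError(f"scan span [{t1}, {t2}) outside the epoch")
    idx = np.asarray(cog.channel_indices, dtype=int)
    cog_tc = epochs.data[:, idx, :].mean(axis=1)  # trials x samples
    out = epochs.labels.copy()
    starts = np.arange(t1, t2 - 1e-9, GRID_MS)
    for s in starts:
        inside = (times >= s - 1e-9) & (times < s + GRID_MS - 1e-9)
        out[f"bin_{int(round(s))}"] = cog_tc[:, inside].mean(axis=1)
    return out


def _flags_to_runs(flags: np.ndarray, starts: np.ndarray, p: np.ndarray) -> list[Run]:
    """Maximal runs of consecutive True flags on the bin grid."""
    runs: list[Run] = []
    i = 0
    n = len(flags)
    while i < n:
        if flags[i]:
            j = i
            while j + 1 < n and flags[j + 1]:
                j += 1
            runs.append(
                Run(
                    start_ms=float(starts[i]),
                    end_ms=float(starts[j] + GRID_MS),
                    n_bins=j - i + 1,
                    p_summary=float(p[i : j + 1].max()),
                )
            )
            i = j + 1
        else:
            i += 1
    return runs


def scan_bin_means(
    bin_table: pd.DataFrame,
    case1: CaseLabel,
    case2: CaseLabel,
    alpha: float = DEFAULT_ALPHA,
    correction: str | None = None,
) -> ScanResult:
    """Interval scan on a precomputed per-trial bin-mean table."""
    bin_cols = [c for c in bin_table.columns if c.startswith("bin_")]
    if not bin_cols:
        raise DataError("bin-mean table has no bin columns")
    m1 = case1.mask(bin_table)
    m2 = case2.mask(bin_table)
    for case, m in ((case1, m1), (case2, m2)):
        if not m.any():
            raise DataError(f"case {case} selects no trials")
    starts = np.array([float(c[4:]) for c in bin_cols])
    order = np.argsort(starts)
    starts = starts[order]
    bin_cols = [bin_cols[i] for i in order]
    p = np.empty(len(bin_cols))
    for k, col in enumerate(bin_cols):
        p[k] = mann_whitney(
            bin_table.loc[m1, col].to_numpy(), bin_table.loc[m2, col].to_numpy()
        ).p_value
    if correction == "bh":
        flags = _bh_reject(p, alpha)
    elif correction is None:
        flags = p <= alpha
    else:
        raise ConfigError(f"unknown correction {correction!r}")
    return ScanResult(
        case_pair=(str(case1), str(case2)),
        bin_starts_ms=starts,
        p_values=p,
        alpha=alpha,
        runs=_flags_to_runs(flags, starts, p),
    )


def scan_case_pair(
    epochs: EpochSet,
    case1: CaseLabel,
    case2: CaseLabel,
    cog: CognitiveSet,
    alpha: float = DEFAULT_ALPHA,
    span_ms: tuple[float, float] = DEFAULT_SCAN_SPAN,
    correction: str | None = None,
) -> ScanResult:
    """Mann-Whitney interval scan between two experimental cases."""
    for case in (case1, case2):
        if select_case(epochs, case).n_trials == 0:
            raise DataError(f"case {case} selects no trials")
    table = cognitive_bin_means(epochs, cog, span_ms)
    return scan_bin_means(table, case1, case2, alpha=alpha, correction=correction)


def _bh_reject(p: np.ndarray, alpha: float) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags."""
    m = len(p)
    order = np.argsort(p)
    thresh = alpha * (np.arange(1, m + 1)) / m
    passed = p[order] <= thresh
    flags = np.zeros(m, dtype=bool)
    if passed.any():
        k = np.max(np.flatnonzero(passed))
        flags[order[: k + 1]] = True
    return flags


def trust_rate_test(decisions: pd.DataFrame) -> TestResult:
    """Chi-squared independence test on the decision x SCL count table.

    Requires all SCL levels present; also reports the per-level trust
    proportion in ``extra['trust_rate']``.
    """
    levels = sorted(decisions["scl"].unique())
    if len(levels) < 2:
        raise DataError("trust-rate test needs at least two SCL levels")
    counts = (
        decisions.assign(trusting=decisions["decision"] == "trust")
        .groupby("scl")["trusting"]
        .agg(["sum", "count"])
    )
    table = np.array(
        [
            counts["sum"].to_numpy(float),
            (counts["count"] - counts["sum"]).to_numpy(float),
        ]
    )
    if np.any(table.sum(axis=0) == 0):
        raise DataError("an SCL level has no decisions")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    rates = {int(s): float(r) for s, r in (counts["sum"] / counts["count"]).items()}
    return TestResult(
        statistic=float(chi2),
        p_value=float(p),
        n1=int(table[0].sum()),
        n2=int(table[1].sum()),
        method="chi2-independence",
        extra={"trust_rate": rates},
    )


def trust_trend_test(decisions: pd.DataFrame) -> TestResult:
    """One-sided Cochran-Armitage trend test (trust rate increasing in SCL)."""
    grouped = (
        decisions.assign(trusting=decisions["decision"] == "trust")
        .groupby("scl")["trusting"]
        .agg(["sum", "count"])
        .sort_index()
    )
    x = grouped.index.to_numpy(float)
    t = grouped["sum"].to_numpy(float)
    n = grouped["count"].to_numpy(float)
    big_n = n.sum()
    p_bar = t.sum() / big_n
    observed = (x * t).sum()
    expected = p_bar * (x * n).sum()
    var = p_bar * (1 - p_bar) * ((n * x**2).sum() - (n * x).sum() ** 2 / big_n)
    if var <= 0:
        raise DataError("degenerate trend test (all decisions identical)")
    z = (observed - expected) / np.sqrt(var)
    return TestResult(
        statistic=float(z),
        p_value=float(stats.norm.sf(z)),
        n1=int(t.sum()),
        n2=int(big_n - t.sum()),
        method="cochran-armitage-increasing",
    )
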