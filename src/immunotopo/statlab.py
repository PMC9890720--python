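"""The association and survival statistics battery.

Cross-tabulations of dichotomized densities / phenotypes against molecular
status are tested with Pearson's chi-square (no continuity correction, the
convention that matches classical statistics-suite output) or Fisher's exact
test (hypergeometric for 2x2; Freeman-Halton enumeration for r x c).
Group-wise density comparisons use Mann-Whitney U, Kruskal-Wallis and Dunn's
post hoc test on pooled midranks; correlations use Spearman's rho. Overall
survival is analysed with the Kaplan-Meier product-limit estimator, the
log-rank test, and the restricted mean survival time (the "mean OS" that
standard statistics suites print) with its standard error.

Standard tests are delegated to scipy / lifelines; Dunn's test and the
Freeman-Halton extension are implemented here (no installed package provides
them) and are cross-checked against independent oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable",
    "TestResult",
    "SurvCurve",
    "DegenerateTableError",
    "pearson_chi_square",
    "fisher_exact",
    "spearman",
    "mann_whitney",
    "kruskal_wallis",
    "dunn_posthoc",
    "km_estimate",
    "logrank",
    "restricted_mean",
]


class DegenerateTableError(ValueError):
    """Raised for tables with a zero row/column margin (test undefined)."""


@dataclass(frozen=True)
class ContingencyTable:
    """r x c table of non-negative integer counts with optional labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        c = c.astype(np.int64)
        if c.sum() == 0:
            raise DegenerateTableError("empty table")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    effect: float | None = None  # odds ratio for 2x2, rank-biserial-free otherwise
    n: int | None = None
    groups: tuple[str, str] | None = None
    warnings: tuple[str, ...] = ()


def _as_table(table) -> ContingencyTable:
    return table if isinstance(table, ContingencyTable) else ContingencyTable(np.asarray(table))


def _check_margins(counts: np.ndarray) -> None:
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise DegenerateTableError("zero row or column margin")


def pearson_chi_square(table) -> TestResult:
    """Pearson chi-square without continuity correction.

    Expected counts below 5 are reported as a warning, not an error: the
    test is still applied (small expected counts merely weaken the
    chi-square approximation).
    """
    t = _as_table(table)
    _check_margins(t.counts)
    res = stats.chi2_contingency(t.counts, correction=False)
    warn = ()
    if (res.expected_freq < 5).any():
        n_small = int((res.expected_freq < 5).sum())
        warn = (f"{n_small} cell(s) with expected count < 5",)
    effect = None
    if t.counts.shape == (2, 2):
        a, b, c, d = t.counts.ravel().astype(float)
        effect = (a * d) / (b * c) if b * c > 0 else np.inf
    return TestResult(
        method="pearson_chi_square",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=float(res.dof),
        effect=effect,
        n=t.n,
        warnings=warn,
    )


def _log_table_prob(counts: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - sum(lgamma(v + 1) for v in counts.ravel())


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row_idx, remaining_cols, out):
        if row_idx == r - 1:
            yield out + [list(remaining_cols)]
            return
        target = row_sums[row_idx]

        def fill(col_idx, left, row):
            if col_idx == c - 1:
                if left <= remaining_cols[col_idx]:
                    yield row + [left]
                return
            for v in range(min(left, remaining_cols[col_idx]) + 1):
                yield from fill(col_idx + 1, left - v, row + [v])

        for row in fill(0, target, []):
            new_rem = tuple(rc - v for rc, v in zip(remaining_cols, row))
            yield from rec(row_idx + 1, new_rem, out + [row])

    yield from rec(0, tuple(col_sums), [])


def fisher_exact(table, max_tables: int = 2_000_000) -> TestResult:
    """Fisher's exact test: 2x2 hypergeometric, r x c by Freeman-Halton.

    Two-sided p is the sum of probabilities of all tables with the observed
    margins that are no more probable than the observed one. ``max_tables``
    guards the enumeration; larger tables should use chi-square instead.
    """
    t = _as_table(table)
    _check_margins(t.counts)
    counts = t.counts
    if counts.shape == (2, 2):
        stat, p = stats.fisher_exact(counts, alternative="two-sided")
        return TestResult(method="fisher_exact", statistic=float(stat),
                          p_value=float(p), effect=float(stat), n=t.n)

    row_sums = counts.sum(axis=1)
    col_sums = counts.sum(axis=0)
    n_bound = float(np.prod([float(rs + 1) for rs in row_sums[:-1]])) ** (len(col_sums) - 1)
    if n_bound > max_tables:
        raise ValueError(
            f"table too large for exact enumeration (bound {n_bound:.0f} tables); "
            "use pearson_chi_square"
        )
    log_margin = (
        sum(lgamma(v + 1) for v in row_sums)
        + sum(lgamma(v + 1) for v in col_sums)
        - lgamma(counts.sum() + 1)
    )
    log_p_obs = _log_table_prob(counts, log_margin)
    total = 0.0
    tol = 1e-7  # absorbs float noise in "no more probable than observed"
    for tab in _enumerate_tables(row_sums.tolist(), col_sums.tolist()):
        lp = _log_table_prob(np.asarray(tab), log_margin)
        if lp <= log_p_obs + tol:
            total += np.exp(lp)
    return TestResult(method="freeman_halton", statistic=float(np.exp(log_p_obs)),
                      p_value=float(min(total, 1.0)), n=t.n)


def spearman(x, y) -> TestResult:
    """Spearman rank correlation with midranks and t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = stats.spearmanr(x, y)
    return TestResult(method="spearman", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=len(x))


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact null distribution for small tie-free samples (where it equals full
    permutation enumeration), tie-corrected normal approximation otherwise.
    """
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return TestResult(method="mann_whitney", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=len(x) + len(y))


def kruskal_wallis(groups) -> TestResult:
    """Kruskal-Wallis H with tie correction and chi-square approximation."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    res = stats.kruskal(*groups)
    return TestResult(method="kruskal_wallis", statistic=float(res.statistic),
                      p_value=float(res.pvalue), df=float(len(groups) - 1),
                      n=sum(len(g) for g in groups))


def dunn_posthoc(groups: dict, adjustment: str = "holm") -> list[TestResult]:
    """Dunn's pairwise post hoc test on pooled midranks after Kruskal-Wallis.

    z_ij = (mean_rank_i - mean_rank_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)). Adjustment: "holm"
    (default) or "none"; both the adjusted and raw p are reported (raw p in
    ``statistic``-adjacent field via separate results when adjustment none).
    """
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(len(a) == 0 for a in arrays):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    mean_ranks, sizes = [], []
    offset = 0
    for a in arrays:
        mean_ranks.append(float(ranks[offset:offset + len(a)].mean()))
        sizes.append(len(a))
        offset += len(a)

    pairs, zs, ps = [], [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            pairs.append((names[i], names[j]))
            zs.append(float(z))
            ps.append(float(2.0 * stats.norm.sf(abs(z))))
    if adjustment == "holm":
        adj = multipletests(ps, method="holm")[1]
    elif adjustment == "none":
        adj = np.asarray(ps)
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return [
        TestResult(method=f"dunn[{adjustment}]", statistic=z, p_value=float(p_adj),
                   groups=pair, n=sizes[names.index(pair[0])] + sizes[names.index(pair[1])],
                   warnings=(f"raw_p={p_raw:.6g}",))
        for pair, z, p_adj, p_raw in zip(pairs, zs, adj, ps)
    ]


# ---------------------------------------------------------------------------
# survival


@dataclass(frozen=True)
class SurvCurve:
    """Kaplan-Meier step function with its event table."""

    times: np.ndarray       # event/censor times in ascending order (t > 0)
    survival: np.ndarray    # S(t) just after each time
    at_risk: np.ndarray     # n at risk just before each time
    events: np.ndarray      # deaths at each time
    label: str = ""

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events, label: str = "") -> SurvCurve:
    """Product-limit survival estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if np.any(times < 0):
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    t = table.index.to_numpy(dtype=float)
    keep = t > 0
    sf = kmf.survival_function_.iloc[:, 0]
    surv = np.array([float(sf.loc[ti]) for ti in t[keep]])
    return SurvCurve(
        times=t[keep],
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=float)[keep],
        events=table["observed"].to_numpy(dtype=float)[keep],
        label=label,
    )


def logrank(times, events, group) -> TestResult:
    """Log-rank test across groups (chi-square, k-1 df)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if not events.any():
        raise ValueError("log-rank undefined: no events observed")
    res = multivariate_logrank_test(times, group, events)
    return TestResult(method="logrank", statistic=float(res.test_statistic),
                      p_value=float(res.p_value), df=float(len(labels) - 1),
                      n=len(times))


def restricted_mean(curve: SurvCurve, tau: float | None = None) -> tuple[float, float]:
    """Restricted mean survival time (area under KM up to tau) and its SE.

    With ``tau`` None the largest observed time is used — this is the
    "mean survival" printed by standard statistics suites. The SE follows
    the classical variance formula
    ``sum_i A_i^2 d_i / (n_i (n_i - d_i))`` where ``A_i`` is the area under
    the curve from t_i to tau.
    """
    if tau is None:
        tau = float(curve.times[-1]) if len(curve.times) else 0.0
    if tau <= 0:
        return 0.0, 0.0
    # step integration of S(t) from 0 to tau
    ts = np.concatenate(([0.0], curve.times))
    ss = np.concatenate(([1.0], curve.survival))
    rmst = 0.0
    for i in range(len(ts)):
        t0 = ts[i]
        t1 = ts[i + 1] if i + 1 < len(ts) else np.inf
        if t0 >= tau:
            break
        rmst += ss[i] * (min(t1, tau) - t0)

    var = 0.0
    for i, (ti, di, ni) in enumerate(zip(curve.times, curve.events, curve.at_risk)):
        if di == 0 or ti >= tau or ni <= di:
            continue
        # area under the curve from ti to tau
        area = 0.0
        for j in range(i, len(curve.times)):
            t0 = curve.times[j]
            t1 = curve.times[j + 1] if j + 1 < len(curve.times) else np.inf
            if t0 >= tau:
                break
            area += curve.survival[j] * (min(t1, tau) - t0)
        var += area**2 * di / (ni * (ni - di))
    return float(rmst), float(np.sqrt(var))
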