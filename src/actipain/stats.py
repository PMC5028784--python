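"""Univariate inference: classical tests plus bootstrap CIs and permutation p.

Every comparison reports the classical ("original") p-value alongside a
95 % percentile bootstrap confidence interval (default 10,000 stratified
resamples) and a permutation p-value (default 10,000 label permutations,
add-one estimator; exhaustive enumeration when the number of distinct
group assignments is small).  Resampling is reproducible through explicit
seeds and can be disabled by passing ``n_boot=0`` / ``n_perm=0``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "two_sample_t",
    "two_sample_t_from_stats",
    "wilcoxon_rank_sum",
    "fisher_exact_2x2",
    "chi_square_trend",
    "spearman",
    "bootstrap_statistic",
    "permutation_pvalue",
    "mean_difference",
    "median_difference",
]

EXHAUSTIVE_LIMIT = 20_000


@dataclass
class TestResult:
    """A statistic with its resampling annotations."""

    statistic: float
    p_original: float
    ci_low: float | None = None
    ci_high: float | None = None
    p_permuted: float | None = None
    n_resamples: int = 0
    n_permutations: int = 0
    seed: int | None = None
    method: str = ""
    estimate: float | None = None  # quantity the CI refers to

    def __post_init__(self) -> None:
        # p = 0 never occurs: permutation uses the add-one estimator and
        # classical p-values are floored at the smallest positive float
        if self.p_original is not None and self.p_original <= 0:
            self.p_original = np.nextafter(0.0, 1.0)

    def format_p(self, floor: float = 1e-4) -> str:
        p = self.p_original
        return f"<{floor:g}" if p < floor else f"{p:.2f}"


def mean_difference(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.mean(x) - np.mean(y))


def median_difference(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.median(x) - np.median(y))


def _resample_annotations(
    x: np.ndarray,
    y: np.ndarray,
    estimate_fn: Callable,
    n_boot: int,
    n_perm: int,
    seed: int | None,
) -> dict:
    out: dict = {"seed": seed}
    ss = np.random.SeedSequence(seed)
    s_boot, s_perm = ss.spawn(2)
    if n_boot:
        est, (lo, hi), _ = bootstrap_statistic(
            (x, y), estimate_fn, n_boot=n_boot, seed=s_boot
        )
        out.update(estimate=est, ci_low=lo, ci_high=hi, n_resamples=n_boot)
    if n_perm:
        out["p_permuted"] = permutation_pvalue(
            x, y, estimate_fn, n_perm=n_perm, seed=s_perm
        )
        out["n_permutations"] = n_perm
    return out


def two_sample_t(
    x: Sequence[float],
    y: Sequence[float],
    equal_var: bool = True,
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Unpaired two-sided t-test (pooled variance by default; Welch optional)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero variance in both groups: t-test undefined")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    res = TestResult(
        statistic=float(t),
        p_original=float(p),
        method="t-test (pooled)" if equal_var else "t-test (Welch)",
    )
    for k, v in _resample_annotations(x, y, mean_difference, n_boot, n_perm, seed).items():
        setattr(res, k, v)
    return res


def two_sample_t_from_stats(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Pooled t-test from published summary statistics (no resampling possible)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    t, p = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return TestResult(statistic=float(t), p_original=float(p), method="t-test (summary)")


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Exact enumeration for small samples without ties, tie-corrected normal
    approximation otherwise.  The bootstrap CI refers to the difference in
    medians.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("empty group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= 20 and not has_ties) else "asymptotic"
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    res = TestResult(
        statistic=float(u),
        p_original=float(min(p, 1.0)),
        method=f"wilcoxon rank-sum ({method})",
    )
    for k, v in _resample_annotations(
        x, y, median_difference, n_boot, n_perm, seed
    ).items():
        setattr(res, k, v)
    return res


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> TestResult:
    """Fisher's exact test; two-sided p sums hypergeometric probabilities
    of tables no more probable than the observed one."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError(f"Fisher's exact test needs a 2x2 table, got {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return TestResult(statistic=float(odds), p_original=float(p), method="fisher exact")


def chi_square_trend(
    table: Sequence[Sequence[int]], scores: Sequence[float] | None = None
) -> TestResult:
    """Cochran-Armitage chi-square test for trend on a 2 x k ordered table.

    ``table`` rows are the two groups, columns the ordered categories
    (a k x 2 table is transposed automatically).  Default scores 0..k-1.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    if t.shape[0] != 2 and t.shape[1] == 2:
        t = t.T
    if t.shape[0] != 2 or t.shape[1] < 3:
        raise ValueError(
            f"trend test needs 2 groups x >=3 ordered categories, got {t.shape}"
        )
    if np.any(t < 0) or np.any(np.isnan(t)):
        raise ValueError("counts must be non-negative and complete")
    k = t.shape[1]
    s = np.arange(k, dtype=float) if scores is None else np.asarray(scores, dtype=float)
    if len(s) != k:
        raise ValueError("scores must match the number of categories")
    n = t.sum(axis=0)
    N = n.sum()
    r1 = t[0].sum()
    obs = float((s * t[0]).sum())
    mean_s = float((s * n).sum() / N)
    var_s = float((s**2 * n).sum() / N - mean_s**2)
    expected = r1 * mean_s
    variance = r1 * (N - r1) * var_s / (N - 1)
    if variance == 0:
        raise ValueError("degenerate table: zero score variance")
    z = (obs - expected) / np.sqrt(variance)
    chi2 = z * z
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(statistic=float(chi2), p_original=p, method="chi-square trend")


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    n_boot: int = 10_000,
    seed: int | None = None,
) -> TestResult:
    """Average-rank Spearman correlation with a bootstrap CI over pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("spearman needs paired data with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("zero variance: correlation undefined")
    r, p = sps.spearmanr(x, y)
    res = TestResult(
        statistic=float(r), p_original=float(p), method="spearman", estimate=float(r)
    )
    if n_boot:
        rng = np.random.default_rng(seed)
        n = len(x)
        vals = np.empty(n_boot)
        skipped = 0
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            xb, yb = x[idx], y[idx]
            if np.all(xb == xb[0]) or np.all(yb == yb[0]):
                skipped += 1
                vals[b] = np.nan
                continue
            vals[b] = sps.spearmanr(xb, yb)[0]
        ok = vals[~np.isnan(vals)]
        res.ci_low, res.ci_high = (
            float(np.percentile(ok, 2.5)),
            float(np.percentile(ok, 97.5)),
        )
        res.n_resamples = n_boot
        res.seed = seed
    return res


def bootstrap_statistic(
    data: Sequence,
    stat_fn: Callable,
    n_boot: int = 10_000,
    seed=None,
) -> tuple[float, tuple[float, float], int]:
    """Percentile bootstrap of ``stat_fn``.

    ``data`` is either one array (plain bootstrap) or a tuple of group
    arrays resampled independently (stratified bootstrap);  ``stat_fn``
    receives the resampled array(s) as positional arguments.  Returns
    ``(point estimate, (ci_low, ci_high), n_skipped)`` where resamples on
    which the statistic is undefined (raises or returns NaN) are skipped
    and counted.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    groups = (
        tuple(np.asarray(g, dtype=float) for g in data)
        if isinstance(data, tuple)
        else (np.asarray(data, dtype=float),)
    )
    rng = np.random.default_rng(seed)
    estimate = float(stat_fn(*groups))
    vals = np.empty(n_boot)
    skipped = 0
    for b in range(n_boot):
        resampled = tuple(g[rng.integers(0, len(g), len(g))] for g in groups)
        try:
            v = float(stat_fn(*resampled))
        except (ValueError, ZeroDivisionError, FloatingPointError):
            v = float("nan")
        if np.isnan(v):
            skipped += 1
        vals[b] = v
    ok = vals[~np.isnan(vals)]
    if ok.size == 0:
        raise ValueError("statistic undefined on every bootstrap resample")
    ci = (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5)))
    return estimate, ci, skipped


def permutation_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    stat_fn: Callable = mean_difference,
    n_perm: int = 10_000,
    seed=None,
) -> float:
    """Two-sided permutation p-value for a two-group statistic.

    Exhaustive over all distinct group assignments when there are at most
    20,000 of them; otherwise Monte Carlo with the add-one estimator
    ``(1 + #{|stat*| >= |stat|}) / (n_perm + 1)``, which avoids p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("permutation test needs two non-empty groups")
    pooled = np.concatenate([x, y])
    n, n1 = len(pooled), len(x)
    observed = abs(float(stat_fn(x, y)))
    tol = 1e-12 * max(1.0, observed)
    # built-in statistics evaluate over whole batches of rearrangements
    batch_fn = {id(mean_difference): "mean", id(median_difference): "median"}.get(
        id(stat_fn)
    )
    total = comb(n, n1)
    if total <= EXHAUSTIVE_LIMIT:
        sel = np.zeros((total, n), dtype=bool)
        for r, combo in enumerate(itertools.combinations(range(n), n1)):
            sel[r, list(combo)] = True
        if batch_fn is not None:
            A = pooled[np.nonzero(sel)[1].reshape(total, n1)]
            B = pooled[np.nonzero(~sel)[1].reshape(total, n - n1)]
            red = np.mean if batch_fn == "mean" else np.median
            stats_abs = np.abs(red(A, axis=1) - red(B, axis=1))
        else:
            stats_abs = np.array(
                [abs(float(stat_fn(pooled[s], pooled[~s]))) for s in sel]
            )
        return int(np.sum(stats_abs >= observed - tol)) / total
    rng = np.random.default_rng(seed)
    if batch_fn is not None:
        red = np.mean if batch_fn == "mean" else np.median
        hits = 0
        for start in range(0, n_perm, 2000):
            m = min(2000, n_perm - start)
            order = np.argsort(rng.random((m, n)), axis=1)
            P = pooled[order]
            s = np.abs(red(P[:, :n1], axis=1) - red(P[:, n1:], axis=1))
            hits += int(np.sum(s >= observed - tol))
        return (1 + hits) / (n_perm + 1)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = abs(float(stat_fn(pooled[perm[:n1]], pooled[perm[n1:]])))
        if s >= observed - tol:
            hits += 1
    return (1 + hits) / (n_perm + 1)
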