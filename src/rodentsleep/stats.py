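"""Two-sample and repeated-measures statistics for strain comparisons.

Small-cohort (n = 7-8 per strain) comparisons use the exact Mann-Whitney U
test (two-tailed, full null enumeration) paired with the AUC effect size
(the probability that a random group-B value exceeds a random group-A
value; ties half-credited) and a bootstrap percentile CI. Circadian time
courses use a two-way mixed-design (repeated-measures) ANOVA with Sidak
post-hoc tests per time point.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ComparisonResult:
    U: float
    p: float
    auc: float
    ci: tuple[float, float]
    n_a: int
    n_b: int
    method: str = "exact"


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_null_counts(n_a: int, n_b: int) -> np.ndarray:
    """Counts of each U value (0..n_a*n_b) under the tie-free null.

    Partition-counting recursion: c[m][u] after adding the m-th group-A
    observation satisfies c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1),
    implemented as iterated polynomial (Gaussian binomial) products.
    """
    # c(u; m, n) = c(u - n; m - 1, n) + c(u; m, n - 1): partitions of u into
    # at most m parts, each part <= n (the Gaussian-binomial coefficients).
    # Iterate n from 0..n_b, updating the full (m, u) table in place.
    table = [[0] * (n_a * n_b + 1) for _ in range(n_a + 1)]
    for m in range(n_a + 1):
        table[m][0] = 1  # n = 0: only the empty partition
    for n in range(1, n_b + 1):
        for m in range(1, n_a + 1):
            row, prev = table[m], table[m - 1]  # row holds level n-1; prev already at n
            for u in range(n, m * n + 1):
                row[u] += prev[u - n]
    return np.array(table[n_a], dtype=object)


def exact_u_tail(U: float, n_a: int, n_b: int) -> float:
    """Exact two-tailed p for Mann-Whitney U under the tie-free null.

    p = 2 x P(U' <= U), capped at 1, from full enumeration of the
    C(n_a+n_b, n_a) equally likely group labelings via the restricted-
    partition recursion.
    """
    if not (0 <= U <= n_a * n_b):
        raise ValueError(f"U={U} outside [0, {n_a * n_b}]")
    if abs(U - round(U)) > 1e-9:
        raise ValueError(
            "non-integer U implies ties; use the permutation path of mannwhitney()"
        )
    counts = _u_null_counts(n_a, n_b)
    total = math.comb(n_a + n_b, n_a)
    lower = sum(counts[: int(round(U)) + 1])
    return min(1.0, 2.0 * lower / total)


def _u_statistics(a: np.ndarray, b: np.ndarray) -> tuple[float, float, bool]:
    """(U_a, U_b, has_ties) with mid-rank tie handling."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = ranks[: a.size].sum()
    u_a = r_a - a.size * (a.size + 1) / 2.0
    u_b = a.size * b.size - u_a
    has_ties = np.unique(pooled).size < pooled.size
    return float(u_a), float(u_b), bool(has_ties)


def mannwhitney(
    a,
    b,
    method: str = "auto",
    seed: int | None = 0,
    max_enumeration: int = 200_000,
    mc_reps: int = 100_000,
) -> ComparisonResult:
    """Two-tailed Mann-Whitney U test; U reported as min(U_a, U_b).

    ``method``: 'exact' (tie-free enumeration), 'permutation', 'approx'
    (normal with tie correction) or 'auto' (exact when n_a+n_b <= 20 and no
    ties, permutation with ties at small n, normal otherwise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u_a, u_b, has_ties = _u_statistics(a, b)
    u = min(u_a, u_b)
    n_a, n_b = a.size, b.size
    if method == "auto":
        if n_a + n_b <= 20:
            method = "permutation" if has_ties else "exact"
        else:
            method = "approx"
    if method == "exact":
        if has_ties:
            method = "permutation"
        else:
            p = exact_u_tail(u, n_a, n_b)
    if method == "permutation":
        p = _permutation_p(a, b, u, seed=seed, max_enumeration=max_enumeration, reps=mc_reps)
    elif method == "approx":
        mu = n_a * n_b / 2.0
        pooled = np.concatenate([a, b])
        _, tie_counts = np.unique(pooled, return_counts=True)
        n = n_a + n_b
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma = math.sqrt(n_a * n_b / 12.0 * (n + 1 - tie_term))
        if sigma == 0:
            p = 1.0
        else:
            z = (u - mu + 0.5) / sigma  # continuity-corrected, lower tail
            p = min(1.0, 2.0 * sps.norm.cdf(z))
    auc = auc_effect(a, b)
    return ComparisonResult(U=u, p=float(p), auc=auc, ci=(np.nan, np.nan),
                            n_a=n_a, n_b=n_b, method=method)


def _permutation_p(a, b, u_obs, seed, max_enumeration, reps):
    """P(min-U <= observed) over group relabelings (exhaustive or Monte Carlo)."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    n_total = math.comb(n, n_a)
    if n_total <= max_enumeration:
        count = 0
        idx_all = frozenset(range(n))
        for comb in itertools.combinations(range(n), n_a):
            pa = pooled[list(comb)]
            pb = pooled[list(idx_all - set(comb))]
            ua, ub, _ = _u_statistics(pa, pb)
            if min(ua, ub) <= u_obs + 1e-9:
                count += 1
        return count / n_total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        perm = rng.permutation(pooled)
        ua, ub, _ = _u_statistics(perm[:n_a], perm[n_a:])
        if min(ua, ub) <= u_obs + 1e-9:
            count += 1
    return (count + 1) / (reps + 1)


# ---------------------------------------------------------------------------
# AUC effect size
# ---------------------------------------------------------------------------

def auc_effect(a, b) -> float:
    """AUC = P(B > A) + 0.5 P(B = A) by exhaustive pair counting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = b[None, :] - a[:, None]
    wins = (diff > 0).sum() + 0.5 * (diff == 0).sum()
    return float(wins / (a.size * b.size))


def auc_from_u(U: float, n_a: int, n_b: int, b_larger: bool) -> float:
    """Reconstruct the AUC effect size from a reported U statistic.

    U is min(U_a, U_b), so the orientation is recovered from which group's
    median is larger: AUC = 1 - U/(n_a n_b) when group B tends larger,
    U/(n_a n_b) otherwise.
    """
    frac = U / (n_a * n_b)
    return 1.0 - frac if b_larger else frac


def bootstrap_auc_ci(a, b, reps: int = 10_000, level: float = 0.95,
                     seed: int | None = None) -> tuple[float, float]:
    """Percentile bootstrap CI of the AUC (groups resampled independently)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("bootstrap needs n >= 2 per group")
    if reps < 100:
        warnings.warn(f"only {reps} bootstrap replicates; CI will be unstable", stacklevel=2)
    rng = np.random.default_rng(seed)
    ia = rng.integers(0, a.size, size=(reps, a.size))
    ib = rng.integers(0, b.size, size=(reps, b.size))
    # vectorized pair counting per replicate
    aa = a[ia][:, :, None]  # (reps, n_a, 1)
    bb = b[ib][:, None, :]  # (reps, 1, n_b)
    diff = bb - aa
    aucs = ((diff > 0).sum(axis=(1, 2)) + 0.5 * (diff == 0).sum(axis=(1, 2))) / (
        a.size * b.size
    )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(aucs, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def compare_groups(a, b, reps: int = 10_000, seed: int | None = 0) -> ComparisonResult:
    """Full two-sample comparison: exact/permutation U test, AUC, bootstrap CI."""
    res = mannwhitney(a, b, seed=seed)
    res.ci = bootstrap_auc_ci(a, b, reps=reps, seed=seed)
    return res


# ---------------------------------------------------------------------------
# Two-way mixed (repeated measures) ANOVA with Sidak post-hoc
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_strain: float
    p_strain: float
    df_strain: tuple[int, int]
    f_time: float
    p_time: float
    df_time: tuple[int, int]
    f_interaction: float
    p_interaction: float
    df_interaction: tuple[int, int]
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def sidak_adjust(p: float | np.ndarray, m: int) -> float | np.ndarray:
    """Sidak family-wise adjustment p_adj = 1 - (1 - p)^m."""
    return 1.0 - (1.0 - np.asarray(p, dtype=float)) ** m


def rm_anova_sidak(group_a: np.ndarray, group_b: np.ndarray,
                   time_labels=None) -> AnovaResult:
    """Two-way mixed ANOVA: between = strain (group), within = time (RM).

    ``group_a``/``group_b`` are (subjects x time) matrices with no missing
    cells and the same number of time points. Post-hoc: per-time-point
    pooled-variance t tests, Sidak-adjusted with m = number of time points.
    """
    A = np.asarray(group_a, dtype=float)
    B = np.asarray(group_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[1] != B.shape[1]:
        raise ValueError("groups must be (subjects x time) with equal time points")
    if not (np.isfinite(A).all() and np.isfinite(B).all()):
        raise ValueError("missing cells not supported")
    k = A.shape[1]
    n_a, n_b = A.shape[0], B.shape[0]
    N = n_a + n_b
    X = np.vstack([A, B])
    grand = X.mean()
    subj_means = X.mean(axis=1)
    group_of = np.array([0] * n_a + [1] * n_b)
    group_means = np.array([A.mean(), B.mean()])
    time_means = X.mean(axis=0)
    cell = np.stack([A.mean(axis=0), B.mean(axis=0)])  # (2, k)

    ss_total = ((X - grand) ** 2).sum()
    ss_bs = k * ((subj_means - grand) ** 2).sum()
    ss_group = k * (n_a * (group_means[0] - grand) ** 2 + n_b * (group_means[1] - grand) ** 2)
    ss_subjwg = ss_bs - ss_group
    ss_time = N * ((time_means - grand) ** 2).sum()
    ns = np.array([n_a, n_b])[:, None]
    ss_int = (ns * (cell - group_means[:, None] - time_means[None, :] + grand) ** 2).sum()
    ss_err = ss_total - ss_bs - ss_time - ss_int

    df_g, df_swg = 1, N - 2
    df_t, df_i, df_e = k - 1, k - 1, (N - 2) * (k - 1)

    def _f_ratio(ss_eff, df_eff, ss_err_, df_err_):
        # zero-variance degenerate designs: no effect -> F = 0 (p = 1);
        # effect with exactly zero error -> F = inf (p = 0)
        if ss_err_ <= 0:
            return (0.0, 1.0) if ss_eff <= 0 else (float("inf"), 0.0)
        f = (ss_eff / df_eff) / (ss_err_ / df_err_)
        return float(f), float(sps.f.sf(f, df_eff, df_err_))

    f_g, p_g = _f_ratio(ss_group, df_g, ss_subjwg, df_swg)
    f_t, p_t = _f_ratio(ss_time, df_t, ss_err, df_e)
    f_i, p_i = _f_ratio(ss_int, df_i, ss_err, df_e)

    labels = list(time_labels) if time_labels is not None else list(range(k))
    rows = []
    for j in range(k):
        t, p = sps.ttest_ind(A[:, j], B[:, j], equal_var=True)
        if not np.isfinite(p):  # zero-variance cells
            t = 0.0
            p = 1.0 if A[:, j].mean() == B[:, j].mean() else 0.0
        rows.append((labels[j], float(t), float(p), float(sidak_adjust(p, k))))
    posthoc = pd.DataFrame(rows, columns=["time", "t", "p", "p_sidak"])
    return AnovaResult(
        f_strain=float(f_g), p_strain=p_g, df_strain=(df_g, df_swg),
        f_time=float(f_t), p_time=p_t, df_time=(df_t, df_e),
        f_interaction=float(f_i), p_interaction=p_i, df_interaction=(df_i, df_e),
        posthoc=posthoc,
    )


# ---------------------------------------------------------------------------
# QQ normality data
# ---------------------------------------------------------------------------

def qq_points(sample) -> np.ndarray:
    """(theoretical, observed) normal QQ pairs at plotting positions (i-0.5)/n."""
    x = np.sort(np.asarray(sample, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("QQ plot needs n >= 3")
    theo = sps.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return np.column_stack([theo, x])


# ---------------------------------------------------------------------------
# report table
# ---------------------------------------------------------------------------

def comparison_table(metrics: dict[str, tuple[np.ndarray, np.ndarray]],
                     reps: int = 10_000, seed: int | None = 0) -> pd.DataFrame:
    """Mann-Whitney/AUC report, one row per metric (A vs B group samples)."""
    rows = []
    for name, (a, b) in metrics.items():
        res = compare_groups(a, b, reps=reps, seed=seed)
        rows.append(
            (
                name,
                float(np.median(a)),
                float(np.median(b)),
                res.p,
                res.U,
                res.auc,
                res.ci[0],
                res.ci[1],
                res.n_a,
                res.n_b,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "metric", "median_a", "median_b", "p", "U", "AUC",
            "CI_lo", "CI_hi", "n_a", "n_b",
        ],
    )
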