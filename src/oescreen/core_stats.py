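"""Statistical primitives shared by every pipeline stage.

Each operation is small, deterministic and exactly testable: Fisher tests
enumerate tables with exact rational arithmetic, the permutation correlation
test enumerates all permutations exhaustively at small n, and the BH
adjustment is the plain step-up procedure. Conventions that the literature
leaves open (two-sided Fisher rule, permutation-p smoothing, quartile
interpolation) are explicit keyword arguments with documented defaults.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DegenerateInputError",
    "CollinearityError",
    "CapacityError",
    "ContingencyTable",
    "TestResult",
    "PermutationResult",
    "spearman_rho",
    "permutation_corr_test",
    "bh_adjust",
    "welch_t",
    "t_from_summary",
    "fisher_exact_2x2",
    "fisher_exact_rxc",
    "hypergeom_upper_tail",
    "ols_residualize",
    "zscore_vector",
    "iqr_outlier_mask",
    "pearson_corr_matrix",
]

# Enumeration tests use exact rationals up to this total count, log-gamma beyond.
_EXACT_ENUMERATION_LIMIT = 200

# Tolerance when comparing floating-point permutation statistics for "as or
# more extreme"; guards against spurious strict inequalities from rounding.
_TIE_EPS = 1e-12


class DegenerateInputError(ValueError):
    """A vector is constant (or otherwise carries no usable variation)."""


class CollinearityError(ValueError):
    """The regression design matrix is rank deficient."""


class CapacityError(ValueError):
    """Exact enumeration was requested beyond the feasible table size."""


@dataclass(frozen=True)
class ContingencyTable:
    """Small r x c count table for exact categorical tests.

    Only 2 x 2 and 2 x 3 shapes are exercised by the pipeline (group vs a
    binary or three-level demographic category).
    """

    counts: np.ndarray

    def __init__(self, counts) -> None:
        arr = np.asarray(counts, dtype=np.int64)
        if arr.ndim != 2:
            raise ValueError("contingency table must be 2-dimensional")
        if (arr < 0).any():
            raise ValueError("contingency table entries must be non-negative")
        if arr.sum() == 0:
            raise ValueError("contingency table is entirely zero")
        object.__setattr__(self, "counts", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    sided: Literal["one", "two"]
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class PermutationResult:
    rho: float
    p_value: float
    n_permutations: int
    seed: int | None
    sided: Literal["one", "two"]
    exhaustive: bool

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside (0, 1]")
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| {self.rho} exceeds 1")


def _as_1d(v, name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if not np.isfinite(arr).all():
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _check_pair(x, y) -> tuple[np.ndarray, np.ndarray]:
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if xa.size != ya.size:
        raise ValueError(f"length mismatch: {xa.size} vs {ya.size}")
    if xa.size < 3:
        raise ValueError("need at least 3 paired observations")
    for name, arr in (("x", xa), ("y", ya)):
        if np.unique(arr).size < 2:
            raise DegenerateInputError(f"{name} is constant")
    return xa, ya


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson correlation of average ranks.

    Ties receive average ranks, so the statistic is exact under ties (no
    large-sample approximation is used anywhere downstream either).
    """
    xa, ya = _check_pair(x, y)
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


def _rank_unit(v: np.ndarray) -> np.ndarray:
    """Centered, unit-norm average ranks; dot product of two such = Spearman rho."""
    r = stats.rankdata(v)
    r -= r.mean()
    n = np.linalg.norm(r)
    if n == 0.0:
        raise DegenerateInputError("constant vector has no rank variation")
    return r / n


def permutation_corr_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10_000,
    seed: int | None = 0,
    sided: Literal["one", "two"] = "two",
    mode: Literal["auto", "exhaustive", "monte-carlo"] = "auto",
) -> PermutationResult:
    """Permutation test of the Spearman correlation between x and y.

    Permutes y, recomputing rho each draw. Monte-Carlo p-values use add-one
    smoothing, p = (1 + #extreme) / (n_perm + 1), so p >= 1/(n_perm+1) and a
    zero p-value is impossible. For n <= 7 (mode="auto") all n! permutations
    are enumerated instead and p is the exact proportion of permutations at
    least as extreme as the observed statistic.

    One-sided tests measure the upper tail of rho (use -x for the lower tail).
    """
    xa, ya = _check_pair(x, y)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    n = xa.size
    rx = _rank_unit(xa)
    ry = _rank_unit(ya)
    rho_obs = float(rx @ ry)

    if mode == "exhaustive" or (mode == "auto" and n <= 7):
        perms = np.array(list(itertools.permutations(range(n))))
        perms_rho = ry[perms] @ rx
        n_total = perms.shape[0]
        if sided == "two":
            extreme = int(np.sum(np.abs(perms_rho) >= abs(rho_obs) - _TIE_EPS))
        else:
            extreme = int(np.sum(perms_rho >= rho_obs - _TIE_EPS))
        return PermutationResult(
            rho=rho_obs, p_value=extreme / n_total, n_permutations=n_total,
            seed=seed, sided=sided, exhaustive=True,
        )

    rng = np.random.default_rng(seed)
    extreme = 0
    chunk = 200_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((m, n)), axis=1)
        rho_perm = ry[idx] @ rx
        if sided == "two":
            extreme += int(np.sum(np.abs(rho_perm) >= abs(rho_obs) - _TIE_EPS))
        else:
            extreme += int(np.sum(rho_perm >= rho_obs - _TIE_EPS))
        done += m
    return PermutationResult(
        rho=rho_obs, p_value=(1 + extreme) / (n_perm + 1), n_permutations=n_perm,
        seed=seed, sided=sided, exhaustive=False,
    )


def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (FDR control)."""
    arr = _as_1d(p, "p")
    if arr.size == 0:
        return arr.copy()
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values outside [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's unequal-variance two-sample t-test (two-sided)."""
    aa, ba = _as_1d(a, "a"), _as_1d(b, "b")
    if aa.size < 2 or ba.size < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = aa.var(ddof=1), ba.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if aa.mean() == ba.mean():
            return TestResult(0.0, float(aa.size + ba.size - 2), 1.0, "two", "welch_t")
        raise DegenerateInputError("both groups have zero variance and unequal means")
    res = stats.ttest_ind(aa, ba, equal_var=False)
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue),
                      "two", "welch_t")


def t_from_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    pooled: bool = False,
) -> TestResult:
    """Two-sample t-test from the six summary numbers (mean, sd, n per group).

    Welch by default; ``pooled=True`` gives the classical equal-variance test.
    This is how printed cohort tables (mean +/- s.d. rows) are re-tested.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    res = stats.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                     equal_var=pooled)
    if pooled:
        df = float(n_a + n_b - 2)
        method = "pooled_t"
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
        method = "welch_t"
    return TestResult(float(res.statistic), df, float(res.pvalue), "two", method)


def _table_counts(t) -> np.ndarray:
    if isinstance(t, ContingencyTable):
        return t.counts
    return ContingencyTable(t).counts


def fisher_exact_2x2(
    t, rule: Literal["prob", "double"] = "prob"
) -> TestResult:
    """Two-sided Fisher exact test for a 2x2 table, exact rational arithmetic.

    Default two-sided rule sums hypergeometric point probabilities of every
    table (same margins) whose probability does not exceed the observed
    table's; ``rule="double"`` doubles the smaller one-sided tail instead
    (capped at 1).
    """
    c = _table_counts(t)
    if c.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got {c.shape}")
    a = int(c[0, 0])
    r1, r2 = int(c[0].sum()), int(c[1].sum())
    c1 = int(c[:, 0].sum())
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    probs = {k: Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
             for k in range(lo, hi + 1)}
    p_obs = probs[a]
    if rule == "prob":
        p = sum(q for q in probs.values() if q <= p_obs)
    elif rule == "double":
        lower = sum(q for k, q in probs.items() if k <= a)
        upper = sum(q for k, q in probs.items() if k >= a)
        p = min(Fraction(1), 2 * min(lower, upper))
    else:
        raise ValueError(f"unknown two-sided rule {rule!r}")
    return TestResult(float(p_obs), float("nan"), float(min(p, Fraction(1))),
                      "two", f"fisher_exact_2x2[{rule}]")


def fisher_exact_rxc(t) -> TestResult:
    """Freeman-Halton exact test for a 2 x c table (c = 2 or 3).

    Enumerates every table with the observed margins and sums the exact
    multivariate hypergeometric probabilities of tables no more probable
    than the observed one.
    """
    c = _table_counts(t)
    if c.shape[0] != 2 or c.shape[1] not in (2, 3):
        raise ValueError(f"expected a 2x2 or 2x3 table, got {c.shape}")
    c = c[:, c.sum(axis=0) > 0]            # unobserved levels carry no information
    if c.shape[1] < 2:
        return TestResult(1.0, float("nan"), 1.0, "two", "fisher_exact_rxc")
    if c.shape[1] == 2:
        return fisher_exact_2x2(c)
    n = int(c.sum())
    if n > _EXACT_ENUMERATION_LIMIT:
        raise CapacityError(f"table total {n} exceeds enumeration limit "
                            f"{_EXACT_ENUMERATION_LIMIT}")
    r1 = int(c[0].sum())
    cols = [int(v) for v in c.sum(axis=0)]
    denom = math.comb(n, r1)

    def prob(row: tuple[int, int, int]) -> Fraction:
        return Fraction(
            math.comb(cols[0], row[0]) * math.comb(cols[1], row[1])
            * math.comb(cols[2], row[2]), denom)

    p_obs = prob(tuple(int(v) for v in c[0]))
    p = Fraction(0)
    for a in range(min(r1, cols[0]) + 1):
        for b in range(min(r1 - a, cols[1]) + 1):
            cc = r1 - a - b
            if cc > cols[2]:
                continue
            q = prob((a, b, cc))
            if q <= p_obs:
                p += q
    return TestResult(float(p_obs), float("nan"), float(min(p, Fraction(1))),
                      "two", "fisher_exact_rxc")


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Exact rational summation for N <= 200, scipy's log-gamma survival
    function beyond.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    lo, hi = max(0, n + K - N), min(n, K)
    if not (lo <= k <= hi):
        raise ValueError(f"k={k} outside support [{lo}, {hi}]")
    if N <= _EXACT_ENUMERATION_LIMIT:
        denom = math.comb(N, n)
        p = sum(Fraction(math.comb(K, j) * math.comb(N - K, n - j), denom)
                for j in range(k, hi + 1))
        return float(p)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ols_residualize(y: Sequence[float], covariates) -> np.ndarray:
    """Residuals of y after OLS on the covariate columns plus an intercept.

    Residuals are orthogonal to each covariate column and sum to ~0; this is
    the "actual minus expected score" adjustment used before Z-scoring.
    """
    ya = _as_1d(y, "y")
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != ya.size:
        raise ValueError("covariate rows must match len(y)")
    # constant covariate columns duplicate the intercept: keep the intercept
    varying = [j for j in range(X.shape[1]) if np.unique(X[:, j]).size > 1]
    X = X[:, varying]
    design = np.column_stack([np.ones(ya.size), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise CollinearityError("design matrix (with intercept) is rank deficient")
    beta, *_ = np.linalg.lstsq(design, ya, rcond=None)
    return ya - design @ beta


def zscore_vector(v: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (n-1 denominator)."""
    arr = _as_1d(v, "v")
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("zero standard deviation")
    return (arr - arr.mean()) / sd


def iqr_outlier_mask(
    v: Sequence[float],
    k: float = 1.5,
    quartile_method: str = "linear",
) -> np.ndarray:
    """Tukey fence outlier flags: v < Q1 - k*IQR or v > Q3 + k*IQR.

    Quartiles use numpy's interpolation conventions; the default "linear"
    (interpolation between order statistics) is the documented convention for
    the qPCR outlier rule.
    """
    arr = _as_1d(v, "v")
    if arr.size < 4:
        raise ValueError("need at least 4 values to define quartile fences")
    q1, q3 = np.percentile(arr, [25, 75], method=quartile_method)
    iqr = q3 - q1
    return (arr < q1 - k * iqr) | (arr > q3 + k * iqr)


def pearson_corr_matrix(X) -> np.ndarray:
    """All-to-all Pearson correlation of the rows of X (variables x samples)."""
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 samples (columns)")
    sd = arr.std(axis=1)
    if (sd == 0).any():
        bad = np.flatnonzero(sd == 0)
        raise DegenerateInputError(
            f"constant rows have undefined correlations: indices {bad.tolist()}")
    r = np.corrcoef(arr)
    np.fill_diagonal(r, 1.0)
    return np.clip(r, -1.0, 1.0)
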