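"""Mann-Whitney U and Kendall tau-b, built from first principles.

Both statistics are rank-based and therefore invariant under strictly
monotone transforms of their inputs.

Mann-Whitney U uses the convention U = #{(x, y) pairs with x > y} plus half
the tied pairs, i.e. the statistic of the first sample.  The p-value is
exact (distribution of U over all C(n1+n2, n1) rank labelings, computed by
the standard recursion) when there are no ties and n1*n2 <= 400; with ties
a full enumeration over labelings is used when feasible; otherwise the
normal approximation with tie and continuity corrections.

Kendall tau-b is (C - D) / sqrt((n0 - t_x)(n0 - t_y)) with the usual tie
terms.  Its p-value defaults to the normal approximation on the
tie-corrected variance of S = C - D; an exact full-permutation option is
available for n <= 8.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import norm, rankdata

from .errors import DegenerateInputError, ValidationError

_EXACT_MAX_PRODUCT = 400  # exact Mann-Whitney when n1*n2 at or below this
_EXACT_MAX_COMB = 20000  # full enumeration budget when ties are present
_EXACT_KENDALL_MAX_N = 8


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n1: int
    n2: int
    sidedness: str  # "one" | "two"
    method: str  # "exact" | "normal-approx"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #pairs x > y + 0.5 * ties, via midranks of the pooled sample."""
    n1 = x.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)  # midranks
    r1 = ranks[:n1].sum()
    return float(r1 - n1 * (n1 + 1) / 2.0)


@lru_cache(maxsize=32)
def _u_null_counts(n1: int, n2: int) -> np.ndarray:
    """Number of rank labelings with each U value, 0..n1*n2 (no ties)."""
    # f(a, b, u) = f(a-1, b, u-b) + f(a, b-1, u)
    u_max = n1 * n2
    table = np.zeros((n1 + 1, n2 + 1, u_max + 1))
    table[0, :, 0] = 1.0
    table[:, 0, 0] = 1.0
    for a in range(1, n1 + 1):
        for b in range(1, n2 + 1):
            table[a, b, b:] += table[a - 1, b, : u_max + 1 - b]
            table[a, b] += table[a, b - 1]
    return table[n1, n2]


def _exact_p_no_ties(u: float, n1: int, n2: int, sidedness: str, direction: str) -> float:
    counts = _u_null_counts(n1, n2)
    total = counts.sum()
    k = int(round(u))
    p_ge = counts[k:].sum() / total
    p_le = counts[: k + 1].sum() / total
    if sidedness == "one":
        return p_ge if direction == "greater" else p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def _exact_p_enumerate(
    x: np.ndarray, y: np.ndarray, u_obs: float, sidedness: str, direction: str
) -> float:
    """Exact p by enumerating all labelings of the pooled sample (handles ties)."""
    pooled = np.concatenate([x, y])
    n, n1 = pooled.size, x.size
    ge = le = total = 0
    for idx in itertools.combinations(range(n), n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(idx)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        total += 1
        if u >= u_obs - 1e-12:
            ge += 1
        if u <= u_obs + 1e-12:
            le += 1
    p_ge, p_le = ge / total, le / total
    if sidedness == "one":
        return p_ge if direction == "greater" else p_le
    return min(1.0, 2.0 * min(p_ge, p_le))


def _approx_p_u(
    u: float, x: np.ndarray, y: np.ndarray, sidedness: str, direction: str
) -> float:
    n1, n2 = x.size, y.size
    n = n1 + n2
    mu = n1 * n2 / 2.0
    pooled = np.concatenate([x, y])
    _, t = np.unique(pooled, return_counts=True)
    tie_term = (t**3 - t).sum() / (n * (n - 1.0)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if var <= 0:
        raise DegenerateInputError("all observations tied; U variance is 0")
    sd = math.sqrt(var)
    if sidedness == "one":
        if direction == "greater":
            return float(norm.sf((u - mu - 0.5) / sd))
        return float(norm.cdf((u - mu + 0.5) / sd))
    z = (abs(u - mu) - 0.5) / sd
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def mann_whitney_u(
    x,
    y,
    sidedness: str = "two",
    direction: str = "greater",
    method: str = "auto",
) -> StatResult:
    """Mann-Whitney U test of two independent samples.

    Parameters
    ----------
    sidedness : "one" or "two".
    direction : for one-sided tests, "greater" tests the alternative that x
        tends to exceed y; "less" the reverse.
    method : "auto", "exact" or "normal-approx".
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValidationError("both samples must be non-empty")
    if sidedness not in ("one", "two"):
        raise ValidationError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    if direction not in ("greater", "less"):
        raise ValidationError(f"direction must be 'greater' or 'less', got {direction!r}")
    n1, n2 = x.size, y.size
    u = _u_statistic(x, y)
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2

    if method == "auto":
        if not has_ties and n1 * n2 <= _EXACT_MAX_PRODUCT:
            method = "exact"
        elif has_ties and math.comb(n1 + n2, n1) <= _EXACT_MAX_COMB:
            method = "exact"
        else:
            method = "normal-approx"
    if method == "exact":
        if has_ties:
            if math.comb(n1 + n2, n1) > _EXACT_MAX_COMB:
                raise ValidationError(
                    "exact method with ties requires enumerating "
                    f"C({n1 + n2},{n1}) labelings; too many"
                )
            p = _exact_p_enumerate(x, y, u, sidedness, direction)
        else:
            p = _exact_p_no_ties(u, n1, n2, sidedness, direction)
    elif method == "normal-approx":
        p = _approx_p_u(u, x, y, sidedness, direction)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return StatResult(u, p, n1, n2, sidedness, method)


# ---------------------------------------------------------------------------
# Kendall tau-b


def _concordance(x: np.ndarray, y: np.ndarray) -> float:
    """S = C - D over all unordered index pairs."""
    sx = np.sign(x[:, None] - x[None, :])
    sy = np.sign(y[:, None] - y[None, :])
    return float((sx * sy)[np.triu_indices(x.size, k=1)].sum())


def _tie_counts(v: np.ndarray) -> np.ndarray:
    _, counts = np.unique(v, return_counts=True)
    return counts[counts > 1].astype(float)


def _tau_b(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = x.size
    n0 = n * (n - 1) / 2.0
    tx = _tie_counts(x)
    ty = _tie_counts(y)
    t1 = (tx * (tx - 1) / 2.0).sum()
    t2 = (ty * (ty - 1) / 2.0).sum()
    denom = math.sqrt((n0 - t1) * (n0 - t2))
    if denom == 0.0:
        raise DegenerateInputError("a variable is entirely tied; tau-b undefined")
    s = _concordance(x, y)
    return s / denom, s


def _var_s(x: np.ndarray, y: np.ndarray) -> float:
    """Tie-corrected null variance of S = C - D."""
    n = float(x.size)
    tx = _tie_counts(x)
    ty = _tie_counts(y)
    v0 = n * (n - 1) * (2 * n + 5)
    vt = (tx * (tx - 1) * (2 * tx + 5)).sum()
    vu = (ty * (ty - 1) * (2 * ty + 5)).sum()
    var = (v0 - vt - vu) / 18.0
    if n > 2:
        var += (
            (tx * (tx - 1) * (tx - 2)).sum()
            * (ty * (ty - 1) * (ty - 2)).sum()
            / (9.0 * n * (n - 1) * (n - 2))
        )
    var += (tx * (tx - 1)).sum() * (ty * (ty - 1)).sum() / (2.0 * n * (n - 1))
    return var


def kendall_tau_b(
    x,
    y,
    sidedness: str = "two",
    method: str = "normal-approx",
) -> StatResult:
    """Kendall rank correlation tau-b with tie correction in both margins.

    ``method="exact"`` enumerates all permutations of y (n <= 8 only) and
    reports the permutation p-value of |tau| (or of tau for one-sided).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValidationError(f"length mismatch: {x.size} vs {y.size}")
    n = x.size
    if n < 3:
        raise ValidationError("need at least 3 paired observations")
    if sidedness not in ("one", "two"):
        raise ValidationError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    tau, s = _tau_b(x, y)

    if method == "exact":
        if n > _EXACT_KENDALL_MAX_N:
            raise ValidationError(
                f"exact permutation p-value limited to n <= {_EXACT_KENDALL_MAX_N}"
            )
        ge = gt_abs = total = 0
        for perm in itertools.permutations(range(n)):
            sp = _concordance(x, y[list(perm)])
            total += 1
            if sp >= s - 1e-12:
                ge += 1
            if abs(sp) >= abs(s) - 1e-12:
                gt_abs += 1
        p = (ge / total) if sidedness == "one" else (gt_abs / total)
    elif method == "normal-approx":
        var = _var_s(x, y)
        if var <= 0:
            raise DegenerateInputError("null variance of S is 0")
        z = s / math.sqrt(var)
        p = float(norm.sf(z)) if sidedness == "one" else float(2.0 * norm.sf(abs(z)))
        p = min(1.0, p)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return StatResult(tau, p, n, 0, sidedness, method)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional output correction)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
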