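"""Rank statistics, exact contingency tests, Holm correction, bootstrap CIs.

Every procedure here is implemented from first principles (average ranks,
tie corrections, exact enumeration, step-down adjustment, percentile
bootstrap); only the reference distributions (t, chi-squared, normal) come
from :mod:`scipy.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _dist


@dataclass
class StatResult:
    """Outcome of a single hypothesis test or correlation.

    ``n`` is the sample size, or a tuple of per-group sizes for two- and
    k-sample tests.  ``p_adjusted`` is filled in by :func:`holm_adjust`
    (or by the pipeline) and carries the family label used.
    """

    name: str
    statistic: float
    p_raw: float
    n: object
    df: float | None = None
    p_adjusted: float | None = None
    family: str | None = None
    extra: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def average_ranks(x) -> np.ndarray:
    """Ranks 1..n with ties replaced by the mean rank of the tie group."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-d array")
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        # mean of ranks i+1 .. j+1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _tie_term(x) -> float:
    """Sum of t^3 - t over tie groups of x."""
    _, counts = np.unique(np.asarray(x, dtype=float), return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0.0:
        raise ValueError("zero variance: correlation undefined")
    return float(a @ b) / denom


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def spearman(x, y, name: str = "spearman") -> StatResult:
    """Two-tailed Spearman rank correlation.

    Average ranks for ties; rho is the Pearson correlation of the ranks and
    the p-value comes from t = rho*sqrt((n-2)/(1-rho^2)) on n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rho = _pearson(average_ranks(x), average_ranks(y))
    n = len(x)
    df = n - 2
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * float(_dist.t.sf(abs(t), df))
    return StatResult(name, rho, min(p, 1.0), n, df=df)


def partial_spearman(x, y, controls=None, name: str = "partial_spearman") -> StatResult:
    """Partial Spearman correlation of x and y given control variables.

    All variables are rank-transformed (average ranks); the partial
    correlation is read off the inverse of the Pearson correlation matrix of
    the ranks: rho_xy.z = -Omega_xy / sqrt(Omega_xx * Omega_yy).  Two-tailed
    p from a t distribution on n - 2 - k df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if controls is None or (hasattr(controls, "__len__") and len(controls) == 0):
        res = spearman(x, y, name=name)
        return res
    Z = np.atleast_2d(np.asarray(controls, dtype=float))
    if Z.shape[0] == len(x) and Z.shape[1] != len(x):
        Z = Z.T  # accept n x k as well as k x n
    k = Z.shape[0]
    n = len(x)
    if n <= k + 2:
        raise ValueError("need n > k + 2")
    cols = [average_ranks(x), average_ranks(y)] + [average_ranks(z) for z in Z]
    R = np.corrcoef(np.vstack(cols))
    try:
        omega = np.linalg.inv(R)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise ValueError("singular rank-correlation matrix") from exc
    rho = float(-omega[0, 1] / math.sqrt(omega[0, 0] * omega[1, 1]))
    df = n - 2 - k
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * float(_dist.t.sf(abs(t), df))
    return StatResult(name, rho, min(p, 1.0), n, df=df, extra={"k_controls": k})


# ---------------------------------------------------------------------------
# k-sample and two-sample location tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups, name: str = "kruskal_wallis") -> StatResult:
    """Kruskal-Wallis H with tie correction; p from chi2 on g-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    N = len(pooled)
    if N < 3:
        raise ValueError("need total N >= 3")
    if np.all(pooled == pooled[0]):
        raise ValueError("all values identical: H undefined")
    ranks = average_ranks(pooled)
    H = 0.0
    i = 0
    sizes = []
    for g in groups:
        r = ranks[i : i + len(g)]
        H += r.sum() ** 2 / len(g)
        sizes.append(len(g))
        i += len(g)
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    correction = 1.0 - _tie_term(pooled) / (N**3 - N)
    H /= correction
    df = len(groups) - 1
    p = float(_dist.chi2.sf(H, df))
    return StatResult(name, H, p, tuple(sizes), df=df)


def _mwu_exact_counts(m: int, n: int) -> np.ndarray:
    """counts[u] = number of arrangements with U statistic u (no ties)."""
    # recurrence N_{m,n}(u) = N_{m-1,n}(u-n) + N_{m,n-1}(u)
    prev = [np.zeros(m * n + 1) for _ in range(n + 1)]
    for j in range(n + 1):
        prev[j][0] = 1.0  # m = 0
    for i in range(1, m + 1):
        cur = [np.zeros(m * n + 1) for _ in range(n + 1)]
        cur[0][0] = 1.0
        for j in range(1, n + 1):
            cur[j] = cur[j - 1].copy()
            cur[j][j:] += prev[j][: m * n + 1 - j]
        prev = cur
    return prev[n]


def mann_whitney_u(a, b, mode: str = "auto", name: str = "mwu") -> StatResult:
    """Two-tailed Mann-Whitney U test.

    ``mode``: "exact" enumerates the null distribution of U (valid without
    ties), "approx" uses the tie-corrected normal approximation with
    continuity correction, "auto" picks exact when m*n <= 400 and no ties.
    The reported statistic is min(U_a, U_b).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    m, n = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = average_ranks(pooled)
    ra = ranks[:m].sum()
    ua = ra - m * (m + 1) / 2.0
    ub = m * n - ua
    u = min(ua, ub)
    ties = _tie_term(pooled) > 0
    if mode == "auto":
        mode = "exact" if (m * n <= 400 and not ties) else "approx"
    if mode == "exact":
        if ties:
            raise ValueError("exact mode requires untied data")
        counts = _mwu_exact_counts(m, n)
        total = counts.sum()
        p = 2.0 * counts[: int(round(u)) + 1].sum() / total
        p = min(p, 1.0)
        return StatResult(name, u, p, (m, n), extra={"mode": "exact"})
    N = m + n
    mu = m * n / 2.0
    var = m * n / 12.0 * ((N + 1) - _tie_term(pooled) / (N * (N - 1)))
    if var <= 0:
        return StatResult(name, u, 1.0, (m, n), extra={"mode": "approx"})
    # continuity correction toward the mean
    z = (u - mu + 0.5) / math.sqrt(var) if u < mu else (u - mu - 0.5) / math.sqrt(var)
    if abs(u - mu) <= 0.5:
        z = 0.0
    p = 2.0 * float(_dist.norm.sf(abs(z)))
    return StatResult(name, u, min(p, 1.0), (m, n), extra={"mode": "approx", "z": z})


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("contingency table must be 2-d")
    if np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("counts must be non-negative integers")
    return t


def expected_counts(table) -> np.ndarray:
    t = _as_table(table)
    rs = t.sum(axis=1, keepdims=True)
    cs = t.sum(axis=0, keepdims=True)
    N = t.sum()
    if np.any(rs == 0) or np.any(cs == 0):
        raise ValueError("zero row/column margin")
    return rs * cs / N


def pearson_chi2(table, name: str = "chi2") -> StatResult:
    """Pearson chi-squared test of independence, no Yates correction."""
    t = _as_table(table)
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    E = expected_counts(t)
    stat = float(np.sum((t - E) ** 2 / E))
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(_dist.chi2.sf(stat, df))
    return StatResult(name, stat, p, int(t.sum()), df=df)


def _log_table_prob(t: np.ndarray, lg_margins: float, lgN: float) -> float:
    return lg_margins - lgN - sum(math.lgamma(v + 1.0) for v in t.flat)


def fisher_exact(table, name: str = "fisher") -> StatResult:
    """Two-sided Fisher exact test for 2xC (or Cx2) tables.

    For 2x2 this is the classic hypergeometric test; for wider tables it is
    the Freeman-Halton extension: all tables with the observed margins are
    enumerated and those no more probable than the observed one (probability
    mass method) contribute to p.
    """
    t = _as_table(table)
    if t.shape[0] != 2:
        if t.shape[1] == 2:
            t = t.T
        else:
            raise ValueError("need a 2xC or Cx2 table")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin: table infeasible for the exact test")
    N = t.sum()
    lg_margins = sum(math.lgamma(v + 1.0) for v in rows) + sum(
        math.lgamma(v + 1.0) for v in cols
    )
    lgN = math.lgamma(N + 1.0)
    lp_obs = _log_table_prob(t, lg_margins, lgN)
    c = t.shape[1]
    r0 = int(rows[0])

    total = 0.0
    p_sum = 0.0

    def rec(col: int, remaining: int, cells: list):
        nonlocal total, p_sum
        if col == c - 1:
            if remaining > cols[col]:
                return
            full = cells + [remaining]
            top = np.array(full, dtype=float)
            bottom = cols - top
            if np.any(bottom < 0):
                return
            lp = _log_table_prob(
                np.vstack([top, bottom]), lg_margins, lgN
            )
            pr = math.exp(lp)
            total += pr
            if lp <= lp_obs + 1e-9:
                p_sum += pr
            return
        for v in range(0, min(int(cols[col]), remaining) + 1):
            rec(col + 1, remaining - v, cells + [v])

    rec(0, r0, [])
    # `total` should be 1 up to rounding; normalise to be safe
    p = min(p_sum / total, 1.0)
    stat = math.exp(lp_obs)
    return StatResult(name, stat, p, int(N), extra={"method": "freeman-halton" if c > 2 else "hypergeometric"})


def choose_test(table) -> str:
    """'fisher' if any expected cell count is below 5, else 'chi2'."""
    E = expected_counts(table)
    return "fisher" if np.any(E < 5.0) else "chi2"


def composition_test(table, name: str = "composition") -> StatResult:
    """Run the test selected by :func:`choose_test` on the table."""
    if choose_test(table) == "fisher":
        return fisher_exact(table, name=name)
    return pearson_chi2(table, name=name)


# ---------------------------------------------------------------------------
# multiplicity and resampling
# ---------------------------------------------------------------------------

def holm_adjust(p_values, m: int | None = None) -> list:
    """Holm step-down adjustment, returned in input order.

    ``m`` is the family size and may exceed ``len(p_values)`` when the
    family includes tests not passed here (e.g. recalculations of the same
    quantity with alternative variable definitions).
    """
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m must be >= number of p-values")
    if any(not (0.0 <= v <= 1.0) for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    order = sorted(range(len(p)), key=lambda i: p[i])
    adjusted = [0.0] * len(p)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adjusted[i] = min(1.0, running)
    return adjusted


def bootstrap_median_ci(sample, B: int = 100_000, level: float = 0.95,
                        seed: int = 0) -> tuple:
    """Percentile bootstrap CI for the median, nearest-rank endpoints.

    Draws ``B`` resamples with replacement using a counter-based Philox
    generator so results are bit-reproducible across platforms.
    """
    x = np.asarray(sample, dtype=float)
    if len(x) == 0:
        raise ValueError("empty sample")
    if B < 1:
        raise ValueError("need B >= 1")
    rng = np.random.Generator(np.random.Philox(seed))
    meds = np.empty(B)
    chunk = max(1, min(B, int(2e7) // max(len(x), 1)))
    i = 0
    while i < B:
        j = min(B, i + chunk)
        idx = rng.integers(0, len(x), size=(j - i, len(x)))
        meds[i:j] = np.median(x[idx], axis=1)
        i = j
    meds.sort()
    alpha = 1.0 - level
    lo_rank = max(1, math.ceil(alpha / 2.0 * B))
    hi_rank = max(1, math.ceil((1.0 - alpha / 2.0) * B))
    return float(meds[lo_rank - 1]), float(meds[hi_rank - 1])
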