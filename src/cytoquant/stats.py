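"""Two-sample tests applied to pipeline outputs.

Both tests return raw (uncorrected) two-tailed p-values: the pipeline makes
single planned comparisons between two groups (orientation spreads, adhesion
densities, track metrics), so no multiplicity correction is applied here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.stats import distributions

EXACT_RANKSUM_MAX_N = 12  # exact null enumeration up to this combined n


@dataclass
class TestResult:
    statistic: float
    p_two_tailed: float
    n_x: int
    n_y: int
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_two_tailed <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _welch_arrays(x: np.ndarray, y: np.ndarray):
    """Welch t, Welch-Satterthwaite df, two-tailed p along the last axis.

    Broadcasts over leading axes, so a (n_sims, n) matrix evaluates all
    simulations in one call.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.shape[-1], y.shape[-1]
    if nx < 2 or ny < 2:
        raise ValueError("Welch's t-test needs >= 2 observations per sample")
    vx = x.var(axis=-1, ddof=1)
    vy = y.var(axis=-1, ddof=1)
    if np.any((vx == 0) & (vy == 0)):
        raise ValueError("both samples have zero variance")
    se2 = vx / nx + vy / ny
    t = (x.mean(axis=-1) - y.mean(axis=-1)) / np.sqrt(se2)
    df = se2 ** 2 / (vx ** 2 / (nx ** 2 * (nx - 1)) + vy ** 2 / (ny ** 2 * (ny - 1)))
    p = 2.0 * distributions.t.sf(np.abs(t), df)
    return t, df, p


def welch_t_two_tailed(x, y) -> TestResult:
    """Two-tailed Welch's t-test (unequal variances).

    t = (mean(x) - mean(y)) / sqrt(s2x/nx + s2y/ny) with Welch-Satterthwaite
    degrees of freedom; the p-value is from Student's t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1:
        raise ValueError("welch_t_two_tailed expects 1-D samples")
    t, df, p = _welch_arrays(x, y)
    return TestResult(float(t), float(min(p, 1.0)), x.size, y.size,
                      "welch_t_two_tailed", df=float(df))


def welch_rejection_rate(x_mat, y_mat, alpha: float = 0.05) -> float:
    """Fraction of row-wise Welch tests rejecting at level ``alpha``.

    ``x_mat`` and ``y_mat`` are (n_sims, n) matrices of simulated samples;
    used for null-calibration studies.
    """
    _, _, p = _welch_arrays(np.asarray(x_mat), np.asarray(y_mat))
    return float(np.mean(p < alpha))


# ---------------------------------------------------------------------------
# rank-sum
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size, dtype=float)
    ranks[order] = np.arange(1, pooled.size + 1, dtype=float)
    # average ranks over ties
    vals, inv = np.unique(pooled, return_inverse=True)
    for i in range(vals.size):
        sel = inv == i
        if sel.sum() > 1:
            ranks[sel] = ranks[sel].mean()
    return ranks


def _exact_two_tailed_p(ranks: np.ndarray, nx: int, u_obs: float) -> float:
    """Two-tailed p by enumeration of all C(n, nx) group assignments.

    p = P(U <= u_low) + P(U >= nx*ny - u_low) with u_low = min(u, nx*ny - u),
    evaluated on the permutation null that respects the observed ties.
    """
    n = ranks.size
    ny = n - nx
    m = nx * ny
    u_low = min(u_obs, m - u_obs)
    offset = nx * (nx + 1) / 2.0
    tol = 1e-9
    hits = 0
    total = 0
    for combo in combinations(range(n), nx):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if u <= u_low + tol or u >= m - u_low - tol:
            hits += 1
    return min(1.0, hits / total)


def rank_sum_two_tailed(x, y) -> TestResult:
    """Two-tailed Mann-Whitney / Wilcoxon rank-sum test with midrank ties.

    The U statistic for sample x is rank-sum(x) - nx(nx+1)/2.  For combined
    sample sizes up to ``EXACT_RANKSUM_MAX_N`` the null is enumerated exactly
    over all group assignments (tie-aware); larger samples use the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test requires non-empty samples")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    if nx + ny <= EXACT_RANKSUM_MAX_N:
        p = _exact_two_tailed_p(ranks, nx, u)
        method = "rank_sum_exact"
    else:
        n = nx + ny
        mu = nx * ny / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts ** 3 - counts) / (n * (n - 1))
        var = nx * ny / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            raise ValueError("degenerate rank-sum variance (all values tied)")
        # continuity correction toward the mean
        z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
        p = min(1.0, 2.0 * distributions.norm.sf(abs(z)))
        method = "rank_sum_normal_approx"

    return TestResult(u, p, nx, ny, method)
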