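"""Statistical primitives shared across the pipeline.

Pearson correlation with a per-pair permutation null, the two-group one-way
ANOVA used for stage-wise treatment comparisons, the exact hypergeometric
upper tail used for set enrichment, and Benjamini-Hochberg adjustment.

Randomness policy: every permutation stream is derived from a user seed plus
a stable hash of the pair of feature labels involved, so p-values do not
depend on the order in which pairs are evaluated.
"""

from __future__ import annotations

import zlib

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ZeroVarianceError",
    "pearson",
    "permutation_pvalue",
    "permutation_pvalues_bulk",
    "one_way_anova",
    "hypergeometric_upper_tail",
    "bh_adjust",
    "pair_rng",
]

# float-compare slack when counting permutation ties as exceedances
_TIE_EPS = 1e-12


class ZeroVarianceError(ValueError):
    """A correlation was requested for a zero-variance vector."""


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name} contains non-finite values")
    return v


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors.

    Requires n >= 3 and non-zero variance in both vectors; raises
    :class:`ZeroVarianceError` otherwise (callers skip such pairs).
    """
    xv = _as_vector(x, "x")
    yv = _as_vector(y, "y")
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ZeroVarianceError("zero-variance vector in correlation")
    r = float(np.corrcoef(xv, yv)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def pair_rng(seed: int, key_a: str, key_b: str = "") -> np.random.Generator:
    """Deterministic RNG for an unordered pair of feature labels.

    The stream depends on (seed, {key_a, key_b}) only, never on evaluation
    order, so networks are reproducible under parallel or reordered scans.
    """
    a, b = sorted((str(key_a), str(key_b)))
    h = zlib.crc32(f"{a}\x1f{b}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))


def _standardize(v: np.ndarray) -> np.ndarray:
    c = v - v.mean()
    return c / np.sqrt(np.sum(c * c))


def permutation_pvalue(x, y, B: int = 2000, seed: int = 0,
                       key_a: str = "x", key_b: str = "y") -> float:
    """Two-sided permutation p-value for the Pearson correlation of x and y.

    One vector's sample labels are permuted ``B`` times; the p-value is the
    +1-corrected exceedance rate (#{|r_b| >= |r_obs|} + 1) / (B + 1), so the
    smallest attainable value is 1/(B+1) (e.g. 1/2001 at B=2000, which is what
    makes a P < 0.001 gate satisfiable). Ties count as exceedances.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    r_obs = pearson(x, y)
    xs = _standardize(np.asarray(x, dtype=float).ravel())
    ys = _standardize(np.asarray(y, dtype=float).ravel())
    n = xs.size
    rng = pair_rng(seed, key_a, key_b)
    # permuting a centered unit-norm vector preserves centering and norm,
    # so each permuted correlation is a plain dot product
    idx = rng.permuted(np.tile(np.arange(n), (B, 1)), axis=1)
    r_perm = ys[idx] @ xs
    exceed = int(np.sum(np.abs(r_perm) >= abs(r_obs) - _TIE_EPS))
    return (exceed + 1) / (B + 1)


def permutation_pvalues_bulk(x, Y: np.ndarray, B: int, seed: int,
                             x_id: str, y_ids: list[str],
                             chunk: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Observed correlations and permutation p-values of one vector vs many.

    ``Y`` is an (m, n) matrix of candidate partners (rows aligned with
    ``y_ids``). Each row gets its own permutation stream keyed by
    (seed, x_id, y_id), exactly as if :func:`permutation_pvalue` had been
    called pairwise; rows with zero variance yield r = nan, p = 1.
    """
    xv = _as_vector(x, "x")
    Y = np.asarray(Y, dtype=float)
    m, n = Y.shape
    if n != xv.size:
        raise ValueError("Y columns must match len(x)")
    if len(y_ids) != m:
        raise ValueError("y_ids must match Y rows")
    xs = _standardize(xv)
    r_out = np.full(m, np.nan)
    p_out = np.ones(m)
    base = np.tile(np.arange(n), (B, 1))
    for start in range(0, m, chunk):
        for i in range(start, min(start + chunk, m)):
            row = Y[i]
            if np.ptp(row) == 0:
                continue
            ys = _standardize(row)
            r_obs = float(np.clip(ys @ xs, -1.0, 1.0))
            rng = pair_rng(seed, x_id, y_ids[i])
            idx = rng.permuted(base, axis=1)
            r_perm = ys[idx] @ xs
            exceed = int(np.sum(np.abs(r_perm) >= abs(r_obs) - _TIE_EPS))
            r_out[i] = r_obs
            p_out[i] = (exceed + 1) / (B + 1)
    return r_out, p_out


def one_way_anova(group_a, group_b) -> tuple[float, float]:
    """Two-group one-way fixed-effects ANOVA.

    Returns (F, p) with df = (1, n_a + n_b - 2). For two groups F equals the
    square of the pooled-variance t statistic. Degenerate case of zero pooled
    within-group variance: identical group means give (0, 1); unequal means
    give (inf, 0), which callers flag as degenerate-significant.
    """
    a = _as_vector(group_a, "group_a")
    b = _as_vector(group_b, "group_b")
    if a.size < 2 or b.size < 2 or a.size + b.size < 4:
        raise ValueError("each group needs >= 2 values and >= 4 in total")
    na, nb = a.size, b.size
    grand = (a.sum() + b.sum()) / (na + nb)
    ssb = na * (a.mean() - grand) ** 2 + nb * (b.mean() - grand) ** 2
    ssw = float(np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2))
    df2 = na + nb - 2
    if ssw == 0.0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float("inf"), 0.0
    f = float(ssb / (ssw / df2))
    p = float(sps.f.sf(f, 1, df2))
    return f, p


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    This is the enrichment tail shared by motif and GO-slim testing: the
    chance of seeing at least k annotated genes in a set of n drawn without
    replacement from N genes of which K are annotated.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer")
    if K > N or n > N:
        raise ValueError("K and n must not exceed N")
    if k > min(K, n):
        raise ValueError("k must not exceed min(K, n)")
    return float(sps.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
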