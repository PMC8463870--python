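"""Resampling statistics for per-image EV counts and populations.

The two-sample KS test is conservative on discrete (tied) counts, so its
p-value is computed from a bootstrap null: both sample sizes are redrawn with
replacement from the pooled sample and the D-statistic null distribution is
built from n_b replicates. Density equality is tested by label permutation of
the integrated squared difference between common-bandwidth kernel density
estimates. Independence between images from the same well is tested with the
sample distance covariance against a bootstrap null that breaks the pairing.
All Monte-Carlo p-values use the add-one estimator p = (1 + #{T* >= T}) /
(n_resamples + 1), so p is never exactly zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import N_CHANNELS

log = logging.getLogger(__name__)

_CHUNK = 500  # bootstrap replicates processed per vectorized block


@dataclass(frozen=True)
class TestResult:
    """One named statistic with its (resampling) p-value."""

    statistic_name: str
    statistic_value: float
    p_value: float
    n_resamples: int = 0  # 0 for non-resampling (asymptotic) tests
    seed: Optional[int] = None
    sample_sizes: tuple[int, ...] = ()
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError("p_value must lie in (0, 1]")


def _as_array(x: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be nonempty")
    return arr


@dataclass(frozen=True)
class FrequencySummary:
    frequencies: pd.Series  # index: value (or bin left edge), values sum to 1
    median: float
    zero_fraction: float
    n: int


def frequency_distribution(
    values: Sequence[float], binning: Optional[Sequence[float]] = None
) -> FrequencySummary:
    """Relative frequency distribution of per-image counts.

    With ``binning=None`` frequencies are tabulated on the observed values;
    otherwise ``binning`` gives histogram bin edges. Also reports the median
    and the fraction of zero-count images.
    """
    arr = _as_array(values, "values")
    if binning is None:
        freq = pd.Series(arr).value_counts(normalize=True).sort_index()
    else:
        hist, edges = np.histogram(arr, bins=np.asarray(binning, dtype=float))
        freq = pd.Series(hist / arr.size, index=edges[:-1])
    return FrequencySummary(
        frequencies=freq,
        median=float(np.median(arr)),
        zero_fraction=float(np.mean(arr == 0)),
        n=arr.size,
    )


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov with bootstrap null
# ---------------------------------------------------------------------------

def ks_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sample D = sup |ECDF_x - ECDF_y| on the pooled support (tie-safe)."""
    xa = np.sort(_as_array(x, "x"))
    ya = np.sort(_as_array(y, "y"))
    support = np.unique(np.concatenate([xa, ya]))
    fx = np.searchsorted(xa, support, side="right") / xa.size
    fy = np.searchsorted(ya, support, side="right") / ya.size
    return float(np.max(np.abs(fx - fy)))


def _ks_replicates(pool: np.ndarray, nx: int, ny: int, n_b: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Vectorized bootstrap D* replicates from the pooled sample."""
    support = np.unique(pool)
    out = np.empty(n_b)
    done = 0
    while done < n_b:
        m = min(_CHUNK, n_b - done)
        samp = pool[rng.integers(0, pool.size, size=(m, nx + ny))]
        fx = (samp[:, :nx, None] <= support[None, None, :]).mean(axis=1)
        fy = (samp[:, nx:, None] <= support[None, None, :]).mean(axis=1)
        out[done : done + m] = np.abs(fx - fy).max(axis=1)
        done += m
    return out


def ks_bootstrap_pvalue(
    x: Sequence[float],
    y: Sequence[float],
    n_b: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> TestResult:
    """Two-sided KS test with a bootstrap null for discrete (tied) data.

    n_b replicates redraw |x| and |y| values with replacement from the pooled
    sample; p = (1 + #{D* >= D_obs}) / (n_b + 1).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if n_b < 1:
        raise ValueError("n_b must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    d_obs = ks_statistic(xa, ya)
    pool = np.concatenate([xa, ya])
    d_star = _ks_replicates(pool, xa.size, ya.size, n_b, rng)
    p = (1.0 + np.count_nonzero(d_star >= d_obs - 1e-12)) / (n_b + 1.0)
    return TestResult("D_KS", d_obs, p, n_b, seed, (xa.size, ya.size))


# ---------------------------------------------------------------------------
# Permutation test of density equality
# ---------------------------------------------------------------------------

def silverman_bandwidth(pooled: np.ndarray) -> float:
    """Silverman rule-of-thumb bandwidth on the pooled sample."""
    n = pooled.size
    sd = float(np.std(pooled, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(pooled, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    return 0.9 * spread * n ** (-0.2)


def permutation_density_test(
    x: Sequence[float],
    y: Sequence[float],
    n_perm: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    grid_size: int = 256,
) -> TestResult:
    """Equality-of-distribution test on kernel density estimates.

    T = integrated squared difference between Gaussian-KDE estimates of x and
    y on a common grid, with one common Silverman bandwidth computed on the
    pooled sample; the null is built by permuting sample labels.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    nx, ny = xa.size, ya.size
    pooled = np.concatenate([xa, ya])
    h = silverman_bandwidth(pooled)
    if h <= 0:
        log.warning("degenerate pooled sample (zero spread); density test returns p = 1")
        return TestResult("T_density", 0.0, 1.0, n_perm, seed, (nx, ny),
                          extra={"degenerate": True})

    grid = np.linspace(pooled.min() - 3 * h, pooled.max() + 3 * h, grid_size)
    # kernel matrix: K[i, g] = phi_h(grid_g - pooled_i)
    kmat = np.exp(-0.5 * ((grid[None, :] - pooled[:, None]) / h) ** 2) / (
        h * np.sqrt(2 * np.pi)
    )

    labels = np.zeros(nx + ny)
    labels[:nx] = 1.0

    def t_stat(lbl_rows: np.ndarray) -> np.ndarray:
        w = np.where(lbl_rows > 0, 1.0 / nx, -1.0 / ny)
        diff = w @ kmat
        return np.trapezoid(diff**2, grid, axis=-1)

    t_obs = float(t_stat(labels[None, :])[0])
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        perm = np.argsort(rng.random((m, nx + ny)), axis=1)
        t_star = t_stat(labels[perm])
        exceed += int(np.count_nonzero(t_star >= t_obs - 1e-15))
        done += m
    p = (1.0 + exceed) / (n_perm + 1.0)
    return TestResult("T_density", t_obs, p, n_perm, seed, (nx, ny))


# ---------------------------------------------------------------------------
# Distance covariance independence test
# ---------------------------------------------------------------------------

def _center(dmat: np.ndarray) -> np.ndarray:
    return dmat - dmat.mean(0) - dmat.mean(1)[:, None] + dmat.mean()


def distance_covariance(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample distance covariance test statistic n * V_n^2(x, y).

    V_n^2 = (1/n^2) sum_ij A_ij B_ij with A, B the double-centered pairwise
    distance matrices. Scaled by n (the conventional test-statistic scale);
    nonnegative, and exactly zero when either argument is constant.
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    if xa.size < 2:
        raise ValueError("need n >= 2")
    a = _center(np.abs(xa[:, None] - xa[None, :]))
    b = _center(np.abs(ya[:, None] - ya[None, :]))
    v2 = float((a * b).mean())
    return xa.size * max(v2, 0.0)


def dcov_bootstrap_test(
    x: Sequence[float],
    y: Sequence[float],
    n_b: int = 10000,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    method: str = "bootstrap",
) -> TestResult:
    """Independence test on n * V_n^2 with a resampled null.

    ``method='bootstrap'`` (default) breaks the pairing by resampling y with
    replacement; ``method='permutation'`` permutes y instead (sensitivity
    option). p = (1 + #{stat* >= stat_obs}) / (n_b + 1).
    """
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise ValueError("x and y must have equal length")
    n = xa.size
    if n < 4:
        raise ValueError("need n >= 4")
    if method not in ("bootstrap", "permutation"):
        raise ValueError("method must be 'bootstrap' or 'permutation'")
    rng = rng if rng is not None else np.random.default_rng(seed)

    a = _center(np.abs(xa[:, None] - xa[None, :]))
    dy = np.abs(ya[:, None] - ya[None, :])
    stat_obs = n * max(float((a * _center(dy)).mean()), 0.0)

    exceed = 0
    for _ in range(n_b):
        if method == "bootstrap":
            k = rng.integers(0, n, size=n)
        else:
            k = rng.permutation(n)
        b_star = _center(dy[np.ix_(k, k)])
        stat = n * max(float((a * b_star).mean()), 0.0)
        if stat >= stat_obs - 1e-15:
            exceed += 1
    p = (1.0 + exceed) / (n_b + 1.0)
    return TestResult("D_Cov", stat_obs, p, n_b, seed, (n, n),
                      extra={"method": method})


# ---------------------------------------------------------------------------
# Pearson channel correlations, chi-square composition test, median ratio
# ---------------------------------------------------------------------------

def pearson_matrix(
    intensity_table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlation of per-EV channel intensities.

    Expects the complete-row table from :func:`evtirf.classify.intensity_table`
    (columns ``intensity_ch0..3``). Returns (r, p) as 4x4 DataFrames with unit
    diagonal; entries involving a zero-variance channel are NaN and reported
    as missing.
    """
    cols = [f"intensity_ch{i}" for i in range(N_CHANNELS)]
    data = intensity_table[cols].to_numpy(dtype=float)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 EVs with paired intensities")
    r = np.eye(N_CHANNELS)
    p = np.full((N_CHANNELS, N_CHANNELS), np.nan)
    np.fill_diagonal(p, 1.0)
    for i in range(N_CHANNELS):
        for j in range(i + 1, N_CHANNELS):
            xi, yj = data[:, i], data[:, j]
            if np.std(xi) == 0 or np.std(yj) == 0:
                r[i, j] = r[j, i] = np.nan
                log.warning("zero-variance channel in Pearson matrix (pair %d,%d)", i, j)
                continue
            res = sps.pearsonr(xi, yj)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return rdf, pdf


def chisq_population_test(
    counts_a: Sequence[float],
    counts_b: Sequence[float],
    min_expected: float = 5.0,
) -> TestResult:
    """Two-sample chi-square homogeneity test over the phenotype classes.

    Classes whose expected count under homogeneity falls below ``min_expected``
    are pooled (smallest combined totals first) into one residual class; the
    test needs at least 2 classes after pooling. No continuity correction.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must share the class schema")
    if a.sum() <= 0 or b.sum() <= 0:
        raise ValueError("both samples must have positive totals")

    order = np.argsort(a + b, kind="stable")  # ascending combined totals
    keep = list(order[::-1])  # descending

    def min_exp(av: np.ndarray, bv: np.ndarray) -> float:
        tbl = np.vstack([av, bv])
        exp = np.outer(tbl.sum(1), tbl.sum(0)) / tbl.sum()
        return float(exp.min())

    def build(k: int) -> tuple[np.ndarray, np.ndarray]:
        kept = keep[:k]
        rest = keep[k:]
        av = np.concatenate([a[kept], [a[rest].sum()]]) if rest else a[kept]
        bv = np.concatenate([b[kept], [b[rest].sum()]]) if rest else b[kept]
        return av, bv

    k = len(keep)
    av, bv = build(k)
    while min_exp(av, bv) < min_expected and k > 1:
        k -= 1
        av, bv = build(k)
    if len(av) < 2:
        raise ValueError("fewer than 2 classes remain after pooling")
    if min_exp(av, bv) < min_expected:
        warnings.warn("expected counts below threshold even after maximal pooling")

    table = np.vstack([av, bv])
    if np.allclose(a / a.sum(), b / b.sum()):
        # identical compositions: chi2 = 0 exactly, avoid float fuzz
        chi2, pval, dof = 0.0, 1.0, table.shape[1] - 1
    else:
        chi2, pval, dof, _ = sps.chi2_contingency(table, correction=False)
    return TestResult(
        "chi2", float(chi2), float(max(pval, np.finfo(float).tiny)), 0, None,
        (int(a.sum()), int(b.sum())), extra={"dof": int(dof), "classes_kept": len(av)},
    )


@dataclass(frozen=True)
class MedianFold:
    value: float
    finite: bool
    median_x: float
    median_y: float


def median_fold(x: Sequence[float], y: Sequence[float]) -> MedianFold:
    """Ratio median(x) / median(y); flagged infinite when median(y) = 0."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    mx, my = float(np.median(xa)), float(np.median(ya))
    if my == 0:
        return MedianFold(float("inf"), False, mx, my)
    return MedianFold(mx / my, True, mx, my)


def population_ks_tests(
    counts_a: pd.DataFrame,
    counts_b: pd.DataFrame,
    class_labels: Sequence[str],
    n_b: int = 10000,
    seed: Optional[int] = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Bootstrap-KS comparison of per-image counts for every phenotype class.

    One row per class with D, the bootstrap p-value and both medians; raw
    p-values are reported (``bh_adjust=True`` adds a Benjamini-Hochberg
    column). Count tables must carry one column per class label.
    """
    root = np.random.default_rng(seed)
    rows = []
    for lbl in class_labels:
        x = counts_a[lbl].to_numpy(dtype=float)
        y = counts_b[lbl].to_numpy(dtype=float)
        res = ks_bootstrap_pvalue(x, y, n_b=n_b, rng=root)
        rows.append(dict(label=lbl, D_KS=res.statistic_value, p_value=res.p_value,
                         median_a=float(np.median(x)), median_b=float(np.median(y)),
                         n_resamples=n_b))
    out = pd.DataFrame(rows)
    if bh_adjust:
        out["p_bh"] = benjamini_hochberg(out["p_value"].to_numpy())
    return out


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (optional column for population-wise tests)."""
    p = np.asarray(pvals, dtype=float)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj
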