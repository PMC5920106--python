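"""Inferential machinery: cluster permutation, RM-ANOVA, bootstrap correlations.

Cluster-corrected permutation test for paired time courses
----------------------------------------------------------
For each time sample a paired t statistic compares the two conditions.
Samples whose |t| exceeds the two-tailed critical value at alpha with
n-1 degrees of freedom are "significant"; maximal runs of contiguous
significant samples of the same sign form clusters, whose statistic is run
LENGTH in samples. The null distribution is built by independently flipping
each subject's condition assignment (sign of the paired difference) and
recording the maximal run length per permutation; the observed labeling is
included in the null, so p-values are strictly positive. A cluster's p is
the fraction of the null at or above its size, and it is called significant
when its size strictly exceeds the null's 95th percentile. When the number
of subjects is small enough that all 2^n sign patterns fit in the requested
permutation count, the test enumerates them exactly.

The remaining operations are the classical paired t test, the 2x2
within-subject ANOVA (whose 1-df F statistics equal squared paired t's on
the corresponding contrasts), and Spearman correlations with subject-level
nonparametric bootstrap confidence intervals, including a bootstrap test for
the difference of two correlations sharing subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, DataError, DegenerateDataError


# --- cluster permutation --------------------------------------------------


@dataclass
class Cluster:
    start_ms: float
    end_ms: float
    start_idx: int
    size: int  # samples
    sign: int  # +1 / -1
    p: float
    significant: bool


@dataclass
class ClusterTestResult:
    times_ms: np.ndarray
    t_obs: np.ndarray
    t_crit: float
    clusters: list[Cluster]
    null_q95: float
    null_sizes: np.ndarray
    n_perm: int
    exact: bool
    alpha: float

    @property
    def any_significant(self) -> bool:
        return any(c.significant for c in self.clusters)

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "t_crit": self.t_crit,
            "n_perm": self.n_perm,
            "exact": self.exact,
            "null_q95": float(self.null_q95),
            "clusters": [
                {"start_ms": c.start_ms, "end_ms": c.end_ms, "size": c.size,
                 "sign": c.sign, "p": c.p, "significant": c.significant}
                for c in self.clusters
            ],
        }


def _runs(mask: np.ndarray):
    """(start, length) of maximal True runs in a 1-D boolean mask."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts, ends - starts))


def _max_run_lengths(above: np.ndarray) -> np.ndarray:
    """Per-row maximal run of True in a (P, T) boolean matrix."""
    P, T = above.shape
    best = np.zeros(P, dtype=np.int64)
    cur = np.zeros(P, dtype=np.int64)
    for t in range(T):
        cur = (cur + 1) * above[:, t]
        np.maximum(best, cur, out=best)
    return best


def cluster_permutation_paired(a: np.ndarray, b: np.ndarray, times_ms: np.ndarray,
                               n_perm: int = 10_000, alpha: float = 0.05,
                               seed: int | None = None,
                               method: str = "auto") -> ClusterTestResult:
    """Cluster-corrected paired comparison of two per-subject time courses.

    ``a`` and ``b`` are (n_subjects, n_times) arrays aligned on subjects and
    time. ``method`` is "auto" (exact enumeration when 2^n <= n_perm, else
    Monte-Carlo), "exact", or "montecarlo".
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    times_ms = np.asarray(times_ms, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != len(times_ms):
        raise ConfigError("a and b must be (n_subjects, n_times) aligned with times")
    n, T = a.shape
    if n < 2:
        raise ConfigError("need at least 2 subjects")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very small; p-values will be coarse",
                      stacklevel=2)
    d = a - b
    sum_d2 = np.sum(d * d, axis=0)

    def t_from_mean(mean):  # sign flips leave sum of squares unchanged
        var = (sum_d2 - n * mean**2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        return np.nan_to_num(t, nan=0.0, posinf=np.inf, neginf=-np.inf)

    t_obs = t_from_mean(d.mean(axis=0))
    t_crit = float(sps.t.ppf(1 - alpha / 2, df=n - 1))

    exact = method == "exact" or (method == "auto" and 2**n <= n_perm)
    if exact:
        bits = np.arange(2**n, dtype=np.int64)
        signs = 1 - 2.0 * ((bits[:, None] >> np.arange(n)[None, :]) & 1)
        total = 2**n
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
        signs[0] = 1.0  # observed labeling included in the null
        total = n_perm

    null_sizes = np.zeros(total, dtype=np.int64)
    chunk = max(1, int(5e6 // max(T, 1)))
    for start in range(0, total, chunk):
        S = signs[start:start + chunk]
        t_perm = t_from_mean(S @ d / n)
        pos = _max_run_lengths(t_perm > t_crit)
        neg = _max_run_lengths(t_perm < -t_crit)
        null_sizes[start:start + len(S)] = np.maximum(pos, neg)

    null_q95 = float(np.quantile(null_sizes, 0.95))
    dt = times_ms[1] - times_ms[0] if T > 1 else 0.0
    clusters: list[Cluster] = []
    for sign, mask in ((1, t_obs > t_crit), (-1, t_obs < -t_crit)):
        for start, length in _runs(mask):
            p = float(np.mean(null_sizes >= length))
            clusters.append(Cluster(
                start_ms=float(times_ms[start]),
                end_ms=float(times_ms[start + length - 1] + dt),
                start_idx=int(start), size=int(length), sign=sign, p=p,
                significant=bool(length > null_q95),
            ))
    clusters.sort(key=lambda c: c.start_idx)
    return ClusterTestResult(times_ms=times_ms, t_obs=t_obs, t_crit=t_crit,
                             clusters=clusters, null_q95=null_q95,
                             null_sizes=null_sizes, n_perm=total, exact=exact,
                             alpha=alpha)


# --- paired t and RM-ANOVA ------------------------------------------------


@dataclass
class PairedTResult:
    t: float
    df: int
    p: float
    mean_diff: float
    ci_low: float
    ci_high: float


def paired_t(a, b) -> PairedTResult:
    """Classical paired t test with two-tailed p and 95% CI of the mean diff."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ConfigError("paired_t expects two aligned 1-D arrays")
    n = len(a)
    if n < 2:
        raise ConfigError("need at least 2 pairs")
    d = a - b
    if np.ptp(d) == 0:
        # constant difference: the t statistic degenerates. A uniformly zero
        # difference carries no information; a constant non-zero shift is the
        # limit t -> +/-inf with a point confidence interval at the shift.
        if d[0] == 0:
            raise DegenerateDataError("paired differences are identically zero")
        c = float(d[0])
        return PairedTResult(t=float(np.sign(c) * np.inf), df=n - 1, p=0.0,
                             mean_diff=c, ci_low=c, ci_high=c)
    res = sps.ttest_rel(a, b)
    ci = res.confidence_interval(0.95)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue),
                         mean_diff=float(d.mean()), ci_low=float(ci.low),
                         ci_high=float(ci.high))


def rm_anova_2x2(values: np.ndarray) -> pd.DataFrame:
    """Two-factor within-subject ANOVA for a (n_subjects, 2, 2) design.

    Classical sum-of-squares decomposition with each effect tested against
    its own effect-by-subject interaction. For 2-level factors each F equals
    the square of the paired t on the corresponding contrast.
    """
    y = np.asarray(values, float)
    if y.ndim != 3 or y.shape[1:] != (2, 2):
        raise ConfigError("values must be (n_subjects, 2, 2)")
    if np.isnan(y).any():
        raise DataError("missing cells are not supported (no imputation)")
    n = y.shape[0]
    if n < 2:
        raise ConfigError("need at least 2 subjects")
    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * 2 * np.sum((m_a - grand) ** 2)
    ss_b = n * 2 * np.sum((m_b - grand) ** 2)
    ss_ab = n * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = 2 * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = 2 * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    resid = (y - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = np.sum(resid**2)

    rows = []
    tiny = 1e-12 * max(np.sum((y - grand) ** 2), 1e-300)  # roundoff floor
    for name, ss_eff, ss_err in (("A", ss_a, ss_as), ("B", ss_b, ss_bs),
                                 ("A:B", ss_ab, ss_abs)):
        df1, df2 = 1, n - 1
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ms_err <= tiny:
            F = 0.0 if ms_eff <= tiny else np.inf
        else:
            F = ms_eff / ms_err
        p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        rows.append((name, ss_eff, ss_err, df1, df2, F, p))
    return pd.DataFrame(rows, columns=["effect", "ss_effect", "ss_error",
                                       "df1", "df2", "F", "p"])


# --- bootstrap correlations ----------------------------------------------


@dataclass
class SpearmanBootstrapResult:
    rho: float
    p: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_dropped: int  # degenerate (constant) resamples excluded
    boot_rhos: np.ndarray = field(repr=False)


def _rank_rows(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, axis=-1)


def _pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=-1, keepdims=True)
    yc = y - y.mean(axis=-1, keepdims=True)
    num = np.sum(xc * yc, axis=-1)
    den = np.sqrt(np.sum(xc**2, axis=-1) * np.sum(yc**2, axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def _check_corr_inputs(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("expected two aligned 1-D arrays")
    if len(x) < 4:
        raise ConfigError("need at least 4 subjects")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for a constant input")
    return x, y


def spearman_bootstrap(x, y, n_boot: int = 20_000,
                       seed: int | None = None) -> SpearmanBootstrapResult:
    """Spearman rho with two-tailed p and a percentile bootstrap 95% CI.

    Mid-ranks for ties; p from the t approximation; the CI resamples
    subjects with replacement. Resamples in which either variable collapses
    to a constant have undefined rho and are dropped (counted in
    ``n_dropped``).
    """
    x, y = _check_corr_inputs(x, y)
    n = len(x)
    rho, p = sps.spearmanr(x, y)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb = x[idx], y[idx]
    rhos = _pearson_rows(_rank_rows(xb), _rank_rows(yb))
    valid = np.isfinite(rhos)
    kept = rhos[valid]
    if len(kept) == 0:
        raise DegenerateDataError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(kept, [2.5, 97.5])
    return SpearmanBootstrapResult(rho=float(rho), p=float(p), ci_low=float(lo),
                                   ci_high=float(hi), n_boot=n_boot,
                                   n_dropped=int(n_boot - len(kept)),
                                   boot_rhos=kept)


@dataclass
class CorrelationDifferenceResult:
    delta_rho: float
    p: float
    ci_low: float
    ci_high: float
    n_boot: int
    n_dropped: int
    boot_deltas: np.ndarray = field(repr=False)


def correlation_difference(x, y_left, y_right, n_boot: int = 20_000,
                           seed: int | None = None) -> CorrelationDifferenceResult:
    """Bootstrap test of rho(x, y_left) - rho(x, y_right) on shared subjects.

    Each bootstrap draw resamples subjects once, jointly for all three
    vectors, and records the difference of Spearman coefficients. Two-tailed
    p = 2 * min(P(delta <= 0), P(delta >= 0)), capped at 1.
    """
    x, y_left = _check_corr_inputs(x, y_left)
    _, y_right = _check_corr_inputs(x, y_right)
    n = len(x)
    obs = sps.spearmanr(x, y_left)[0] - sps.spearmanr(x, y_right)[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xr = _rank_rows(x[idx])
    dl = _pearson_rows(xr, _rank_rows(y_left[idx]))
    dr = _pearson_rows(xr, _rank_rows(y_right[idx]))
    deltas = dl - dr
    valid = np.isfinite(deltas)
    kept = deltas[valid]
    if len(kept) == 0:
        raise DegenerateDataError("all bootstrap resamples degenerate")
    lo, hi = np.percentile(kept, [2.5, 97.5])
    p = 2.0 * min(np.mean(kept <= 0), np.mean(kept >= 0))
    return CorrelationDifferenceResult(delta_rho=float(obs), p=float(min(p, 1.0)),
                                       ci_low=float(lo), ci_high=float(hi),
                                       n_boot=n_boot,
                                       n_dropped=int(n_boot - len(kept)),
                                       boot_deltas=kept)
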