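"""Between-system agreement statistics.

Implements the paired statistics used to compare two (or three) measurement
systems that observed the same walking bout: event-time pairing, difference
statistics, Pearson correlation, two-way single-measure intraclass
correlations (McGraw-Wong consistency ICC(C,1) and absolute-agreement
ICC(A,1)), one-way repeated-measures ANOVA with Bonferroni post-hoc t-tests,
normalized cross-correlation at lag zero between cycle profiles, mean
absolute error of angle curves, and binning of per-stride records by
anterior-posterior walkway position (Start / Middle / End at +-0.50 m around
the walkway center).

The ICCs are computed from the two-way mean squares (subjects MS_R, raters
MS_C, error MS_E) with k raters:

    ICC(C,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E)
    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

Significance of either coefficient against zero uses F = MS_R / MS_E with
(n-1, (n-1)(k-1)) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

WALKWAY_BIN_BOUND_M = 0.50  # Start / Middle / End split around the center


# ---------------------------------------------------------------------------
# Event pairing and difference statistics
# ---------------------------------------------------------------------------


@dataclass
class MatchedEvents:
    a: np.ndarray
    b: np.ndarray
    unmatched_a: np.ndarray
    unmatched_b: np.ndarray

    @property
    def n(self) -> int:
        return len(self.a)


def match_events(
    events_a, events_b, tolerance_s: float
) -> MatchedEvents:
    """Greedy nearest-neighbor pairing of two event-time lists.

    Candidate pairs within ``tolerance_s`` are accepted in order of
    increasing absolute time difference, each event used at most once.  On
    small, well-separated lists this equals the exhaustive minimal-cost
    assignment.
    """
    a = np.sort(np.asarray(events_a, dtype=float))
    b = np.sort(np.asarray(events_b, dtype=float))
    pairs = [
        (abs(ta - tb), i, j)
        for i, ta in enumerate(a)
        for j, tb in enumerate(b)
        if abs(ta - tb) <= tolerance_s
    ]
    pairs.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((i, j))
    matched.sort()
    ia = [i for i, _ in matched]
    ib = [j for _, j in matched]
    return MatchedEvents(
        a=a[ia],
        b=b[ib],
        unmatched_a=a[[i for i in range(len(a)) if i not in used_a]],
        unmatched_b=b[[j for j in range(len(b)) if j not in used_b]],
    )


def difference_stats(a, b) -> dict[str, float]:
    """Mean +- SD of (a - b), of |a - b|, and the raw min/max of (a - b)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("difference_stats requires paired arrays of equal length")
    d = a - b
    ddof = 1 if len(d) > 1 else 0
    return {
        "n": int(len(d)),
        "mean": float(np.mean(d)) if len(d) else np.nan,
        "sd": float(np.std(d, ddof=ddof)) if len(d) else np.nan,
        "abs_mean": float(np.mean(np.abs(d))) if len(d) else np.nan,
        "abs_sd": float(np.std(np.abs(d), ddof=ddof)) if len(d) else np.nan,
        "min": float(np.min(d)) if len(d) else np.nan,
        "max": float(np.max(d)) if len(d) else np.nan,
    }


# ---------------------------------------------------------------------------
# Correlation and intraclass correlation
# ---------------------------------------------------------------------------


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson correlation and two-sided p-value; (nan, nan) when either
    vector has zero variance (r undefined)."""
    import warnings

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return (np.nan, np.nan)
    with warnings.catch_warnings():
        # near-constant inputs are reported as flagged-missing, not warned
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        warnings.simplefilter("ignore", getattr(stats, "NearConstantInputWarning", stats.ConstantInputWarning))
        res = stats.pearsonr(x, y)
    return (float(res.statistic), float(res.pvalue))


def _two_way_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) ANOVA mean squares (MS_R, MS_C, MS_E)."""
    n, k = data.shape
    grand = data.mean()
    ss_rows = k * float(np.sum((data.mean(axis=1) - grand) ** 2))
    ss_cols = n * float(np.sum((data.mean(axis=0) - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


@dataclass
class ICCResult:
    value: float
    F: float
    df1: float
    df2: float
    p: float


def _icc(x, y, form: str) -> ICCResult:
    data = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = data.shape
    if n < 3:
        raise ValueError("ICC requires at least 3 paired observations")
    ms_r, ms_c, ms_e = _two_way_mean_squares(data)
    denom = ms_r + (k - 1) * ms_e
    if form == "A1":
        denom = denom + (k / n) * (ms_c - ms_e)
    scale = float(np.var(data))
    if denom == 0 or (ms_r <= 1e-12 * max(scale, 1e-30) and ms_e <= 1e-12 * max(scale, 1e-30)) or scale == 0:
        value = np.nan  # no subject variance: the coefficient is undefined
    else:
        value = (ms_r - ms_e) / denom
    if ms_e == 0:
        F, p = (np.inf, 0.0) if ms_r > 0 else (0.0, 1.0)
    else:
        F = ms_r / ms_e
        p = float(stats.f.sf(F, n - 1, (n - 1) * (k - 1)))
    return ICCResult(value=float(value), F=float(F), df1=n - 1, df2=(n - 1) * (k - 1), p=p)


def icc_c1(x, y) -> ICCResult:
    """Two-way single-measure consistency ICC(C,1)."""
    return _icc(x, y, "C1")


def icc_a1(x, y) -> ICCResult:
    """Two-way single-measure absolute-agreement ICC(A,1)."""
    return _icc(x, y, "A1")


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA with Bonferroni post-hoc tests
# ---------------------------------------------------------------------------


@dataclass
class RMAnovaResult:
    F: float
    df1: float
    df2: float
    p: float
    posthoc_p: dict[tuple[int, int], float]


def rm_anova_bonferroni(matrix) -> RMAnovaResult:
    """One-way repeated-measures ANOVA across systems (columns) with paired
    Bonferroni-corrected post-hoc t-tests.

    ``matrix`` is participants x systems.  Post-hoc p-values are paired
    t-test p-values multiplied by the number of pairwise comparisons and
    capped at 1.  No sphericity correction is applied.
    """
    data = np.asarray(matrix, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("matrix must be (participants >= 2) x (systems >= 2)")
    n, k = data.shape
    grand = data.mean()
    ss_cond = n * float(np.sum((data.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((data.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = ss_tot - ss_cond - ss_subj
    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    if ss_cond <= 1e-300:
        F, p = 0.0, 1.0
    elif ss_err <= 0:
        F, p = np.inf, 0.0
    else:
        F = (ss_cond / df1) / (ss_err / df2)
        p = float(stats.f.sf(F, df1, df2))
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    posthoc: dict[tuple[int, int], float] = {}
    for i, j in pairs:
        d = data[:, i] - data[:, j]
        if np.std(d, ddof=1) == 0:
            raw = 1.0 if np.mean(d) == 0 else 0.0
        else:
            raw = float(stats.ttest_rel(data[:, i], data[:, j]).pvalue)
        posthoc[(i, j)] = min(1.0, raw * len(pairs))
    return RMAnovaResult(F=float(F), df1=df1, df2=df2, p=p, posthoc_p=posthoc)


# ---------------------------------------------------------------------------
# Cycle-profile comparisons
# ---------------------------------------------------------------------------


def xcorr_lag0(profile_a, profile_b) -> float:
    """Normalized (Pearson-type) cross-correlation of two equal-length cycle
    profiles at time lag zero."""
    a = np.asarray(profile_a, dtype=float)
    b = np.asarray(profile_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt(np.sum(a**2) * np.sum(b**2))
    if denom == 0:
        return np.nan
    return float(np.sum(a * b) / denom)


def mae_curves(cycles_a, cycles_b) -> float:
    """Mean absolute error over all cycle samples (and strides, if 2D)."""
    a = np.asarray(cycles_a, dtype=float)
    b = np.asarray(cycles_b, dtype=float)
    return float(np.nanmean(np.abs(a - b)))


def bin_by_walkway(
    positions,
    values,
    *,
    bound_m: float = WALKWAY_BIN_BOUND_M,
    center: float | None = None,
) -> dict[str, dict[str, float]]:
    """Group per-stride records into Start / Middle / End walkway bins.

    ``positions`` are mean anterior-posterior trunk positions per gait cycle;
    the walkway midpoint (defaulting to the midrange of the positions) is the
    origin.  Start spans positions < -bound, Middle [-bound, +bound], End
    > +bound.  Returns the per-bin count and mean of ``values`` (e.g. per-
    stride MAE).
    """
    positions = np.asarray(positions, dtype=float)
    values = np.asarray(values, dtype=float)
    if positions.shape != values.shape:
        raise ValueError("positions and values must be paired")
    if center is None:
        center = (np.nanmin(positions) + np.nanmax(positions)) / 2.0
    rel = positions - center
    bins = {
        "Start": rel < -bound_m,
        "Middle": (rel >= -bound_m) & (rel <= bound_m),
        "End": rel > bound_m,
    }
    out = {}
    for name, mask in bins.items():
        vals = values[mask & np.isfinite(values)]
        out[name] = {
            "n": int(mask.sum()),
            "mae": float(np.mean(vals)) if len(vals) else np.nan,
        }
    return out


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------


def paired_parameter_stats(a, b) -> dict:
    """Bundle of difference statistics, Pearson r and both ICCs for one
    parameter observed by two systems."""
    out = {"difference": difference_stats(a, b)}
    r, p = pearson_r(a, b)
    out["pearson_r"] = r
    out["pearson_p"] = p
    if len(np.asarray(a)) >= 3:
        c1 = icc_c1(a, b)
        a1 = icc_a1(a, b)
        out["icc_c1"] = c1.value
        out["icc_c1_p"] = c1.p
        out["icc_a1"] = a1.value
        out["icc_a1_p"] = a1.p
    else:
        out["icc_c1"] = out["icc_a1"] = np.nan
        out["icc_c1_p"] = out["icc_a1_p"] = np.nan
    return out


__all__ = [
    "WALKWAY_BIN_BOUND_M",
    "MatchedEvents",
    "match_events",
    "difference_stats",
    "pearson_r",
    "ICCResult",
    "icc_c1",
    "icc_a1",
    "RMAnovaResult",
    "rm_anova_bonferroni",
    "xcorr_lag0",
    "mae_curves",
    "bin_by_walkway",
    "paired_parameter_stats",
]
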