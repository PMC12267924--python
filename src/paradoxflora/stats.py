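"""Model II regression and the naturalized-vs-threatened AOO comparisons.

Major axis (MA) regression is the appropriate line-fitting method when both
variables carry comparable error, as log10 AOO estimates of naturalized and
threatened native range both do. The MA slope is the direction of the
leading eigenvector of the sample covariance matrix, equivalently the
minimizer of summed squared perpendicular distances. The slope's
confidence interval comes from inverting the F test of an hypothesized
axis direction (Jolicoeur–Mosimann / Anderson): with eigenvalues
lambda1 >= lambda2 of the covariance matrix and

    H = 4 F_{alpha}(1, n-2) lambda1 lambda2 / ((n-2) (lambda1-lambda2)^2)

the (1-alpha) interval for the axis angle is theta_hat +/- asin(sqrt(H))/2
(the whole circle when H >= 1). A percentile bootstrap alternative is
available behind a flag.

The companion comparisons mirror a range-balance analysis: a paired
Wilcoxon signed-rank test on untransformed km^2, a Bland–Altman agreement
summary on log10 values, the partial-compensation/net-increase split, and
the histogram summary of % native AOO threatened.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import round_half_up
from .errors import InputError

__all__ = [
    "MAFit", "ma_regression", "PairedTestResult", "paired_wilcoxon",
    "CompensationResult", "classify_compensation", "bland_altman",
    "pct_threatened_histogram",
]


@dataclass(frozen=True)
class MAFit:
    slope: float
    intercept: float
    slope_ci_low: float
    slope_ci_high: float
    n: int
    r: float
    ci_level: float = 0.95
    method: str = "analytic"


def _ma_slope(sxx: float, syy: float, sxy: float) -> float:
    if sxy == 0.0:
        raise InputError("degenerate fit: zero covariance between x and y")
    return (syy - sxx + math.hypot(syy - sxx, 2.0 * sxy)) / (2.0 * sxy)


def ma_regression(x: Sequence[float], y: Sequence[float], ci_level: float = 0.95,
                  bootstrap: bool = False, n_bootstrap: int = 2000,
                  seed: int = 0) -> MAFit:
    """Major axis regression of y on x.

    Inputs are finite vectors (log10 km^2 in the range analysis; zero-AOO
    species must be excluded upstream). Requires n >= 3 and a non-degenerate
    covariance (sxy != 0, or sxx != syy).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise InputError("x and y must have the same length")
    n = len(x)
    if n < 3:
        raise InputError(f"major axis regression needs n >= 3, got {n}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("non-finite values in x or y")
    sxx = float(np.var(x, ddof=1))
    syy = float(np.var(y, ddof=1))
    sxy = float(np.cov(x, y, ddof=1)[0, 1])
    if sxy == 0.0 and sxx == syy:
        raise InputError("degenerate fit: isotropic scatter has no major axis")
    slope = _ma_slope(sxx, syy, sxy) if sxy != 0.0 else (
        0.0 if sxx > syy else math.inf)
    intercept = float(np.mean(y) - slope * np.mean(x)) if np.isfinite(slope) else math.nan
    denom = math.sqrt(sxx * syy)
    r = sxy / denom if denom > 0 else 0.0

    if bootstrap:
        rng = np.random.default_rng(seed)
        slopes = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            bx, by = x[idx], y[idx]
            bxx, byy = np.var(bx, ddof=1), np.var(by, ddof=1)
            bxy = np.cov(bx, by, ddof=1)[0, 1]
            if bxy != 0.0:
                slopes.append(_ma_slope(bxx, byy, bxy))
        lo, hi = np.percentile(slopes, [100 * (1 - ci_level) / 2,
                                        100 * (1 + ci_level) / 2])
        return MAFit(slope, intercept, float(lo), float(hi), n, r, ci_level,
                     method="bootstrap")

    # analytic CI by F-test inversion on the axis angle
    tr, det = sxx + syy, sxx * syy - sxy * sxy
    disc = math.sqrt(max(tr * tr - 4.0 * det, 0.0))
    l1, l2 = (tr + disc) / 2.0, (tr - disc) / 2.0
    fcrit = sps.f.ppf(ci_level, 1, n - 2)
    if l1 == l2:
        lo, hi = -math.inf, math.inf
    else:
        H = 4.0 * fcrit * l1 * l2 / ((n - 2) * (l1 - l2) ** 2)
        if H >= 1.0:
            lo, hi = -math.inf, math.inf
        else:
            theta = math.atan(slope) if np.isfinite(slope) else math.pi / 2
            d = 0.5 * math.asin(math.sqrt(H))
            lo_a, hi_a = theta - d, theta + d
            lo = math.tan(lo_a) if abs(lo_a) < math.pi / 2 else -math.inf
            hi = math.tan(hi_a) if abs(hi_a) < math.pi / 2 else math.inf
    return MAFit(slope, intercept, float(lo), float(hi), n, r, ci_level)


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_value: float
    n_pairs: int
    median_a: float
    median_b: float


def paired_wilcoxon(a: Sequence[float], b: Sequence[float],
                    zero_method: str = "wilcox") -> PairedTestResult:
    """Two-sided paired Wilcoxon signed-rank test on a - b.

    Zero differences are dropped under the classic policy (``wilcox``);
    ``pratt`` keeps them in the ranking. The exact null distribution is
    used for n_pairs <= 25 without ties, the tie-corrected normal
    approximation otherwise. Medians are reported on the untransformed
    scale of the inputs.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) == 0:
        raise InputError("paired test needs equal-length non-empty vectors")
    d = a - b
    nz = d[d != 0]
    if len(nz) == 0:
        if zero_method == "wilcox":
            raise InputError("all paired differences are zero: no information")
        return PairedTestResult(statistic=0.0, p_value=1.0, n_pairs=len(d),
                                median_a=float(np.median(a)),
                                median_b=float(np.median(b)))
    n_pairs = len(nz) if zero_method == "wilcox" else len(d)
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    if zero_method == "wilcox" and len(nz) <= 25 and not has_ties:
        method = "exact"
    else:
        method = "approx"
    res = sps.wilcoxon(a, b, zero_method=zero_method, alternative="two-sided",
                       correction=False, method=method)
    return PairedTestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                            n_pairs=n_pairs, median_a=float(np.median(a)),
                            median_b=float(np.median(b)))


@dataclass(frozen=True)
class CompensationResult:
    accepted_name: str
    aoo_naturalized: float
    aoo_threatened: float
    difference: float  # naturalized - threatened
    klass: str         # partial_compensation | net_increase | tie


def classify_compensation(partitions) -> tuple[list[CompensationResult], float, float]:
    """Split paradox species by the sign of naturalized - threatened AOO.

    ``partitions`` is an iterable of objects/rows with aoo_naturalized and
    aoo_native_threatened (an OccupancyPartition, or a DataFrame with
    aooNaturalized/aooNativeThreatened columns). Exact ties form their own
    class and are excluded from the two percentages, which therefore sum
    to 100 over non-tie species.
    """
    if isinstance(partitions, pd.DataFrame):
        rows = [(r.acceptedName, r.aooNaturalized, r.aooNativeThreatened)
                for r in partitions.itertuples()]
    else:
        rows = [(p.accepted_name, p.aoo_naturalized, p.aoo_native_threatened)
                for p in partitions]
    results = []
    for name, nat, thr in rows:
        diff = nat - thr
        klass = ("tie" if diff == 0 else
                 "partial_compensation" if diff < 0 else "net_increase")
        results.append(CompensationResult(name, float(nat), float(thr),
                                          float(diff), klass))
    n_partial = sum(r.klass == "partial_compensation" for r in results)
    n_net = sum(r.klass == "net_increase" for r in results)
    n_nontie = n_partial + n_net
    if n_nontie == 0:
        return results, 0.0, 0.0
    return (results, 100.0 * n_partial / n_nontie, 100.0 * n_net / n_nontie)


def bland_altman(a: Sequence[float], b: Sequence[float]) -> dict:
    """Bland–Altman agreement summary of a - b (typically log10 AOO).

    Returns the mean difference, the mean +/- 1.96 sd limits of agreement
    and the per-item means/differences table used for the plot.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or len(a) < 2:
        raise InputError("Bland–Altman needs >= 2 paired finite values")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InputError("non-finite values supplied")
    diff = a - b
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    limits = (mean_diff - 1.96 * sd, mean_diff + 1.96 * sd)
    table = pd.DataFrame({"mean": (a + b) / 2.0, "difference": diff})
    return {"mean_difference": mean_diff, "sd": sd, "limits": limits,
            "table": table}


def pct_threatened_histogram(pct_values: Sequence[float], bin_width: float = 5.0
                             ) -> dict:
    """Histogram summary of % native AOO threatened.

    Bins are [0,5), [5,10), ..., [95,100] (the last bin closed). Species
    without a defined percentage must be excluded upstream.
    """
    v = np.asarray([p for p in pct_values if p is not None and np.isfinite(p)], float)
    if len(v) == 0:
        raise InputError("no defined percentages supplied")
    if ((v < 0) | (v > 100)).any():
        raise InputError("percentages must lie in [0, 100]")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(v, bins=edges)  # numpy closes the last bin
    return {
        "mean": float(v.mean()), "median": float(np.median(v)), "n": len(v),
        "mean_reported": round_half_up(float(v.mean())),
        "median_reported": round_half_up(float(np.median(v))),
        "bin_edges": edges.tolist(), "bin_counts": counts.tolist(),
    }
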