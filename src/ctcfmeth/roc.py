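"""Single-marker ROC statistics.

A marker here is one methylation variable measured in a tumor (positive)
and a normal (negative) class.  The module provides:

* orientation — hypermethylated markers score tumor-like when *high*,
  hypomethylated markers when *low*; ``auto`` picks the orientation with
  AUC >= 0.5;
* the empirical AUC (Mann-Whitney with ties credited 1/2), its DeLong
  standard error and a two-sided z-test against AUC = 0.5 (Hanley-McNeil
  variance available as an alternative);
* sensitivity at a fixed specificity level: the decision threshold is the
  cutpoint maximising sensitivity subject to empirical specificity >= level,
  with a percentile confidence interval from a stratified bootstrap in which
  the threshold is re-derived inside every replicate.

All routines work on oriented scores internally (higher = more tumor-like)
and translate thresholds back to the methylation scale for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DataError

__all__ = [
    "orient_marker", "auc", "sensitivity_at_specificity",
    "analyze_marker", "AucResult", "SensSpecResult", "RocResult",
    "MarkerRocAnalyzer",
]


def _clean(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def _oriented(values: np.ndarray, direction: str) -> np.ndarray:
    if direction == "hypo":
        return -values
    return values


def _auc_midrank(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUC with ties counted 1/2, via midranks."""
    m, n = len(pos), len(neg)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    return (ranks[:m].sum() - m * (m + 1) / 2) / (m * n)


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (midrank formulation)."""
    m, n = len(pos), len(neg)
    all_v = np.concatenate([pos, neg])
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    tz = stats.rankdata(all_v)
    a = _auc_midrank(pos, neg)
    v10 = (tz[:m] - tx) / n          # placement of each positive among negatives
    v01 = 1.0 - (tz[m:] - ty) / m    # placement of each negative among positives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    del a
    return s10 / m + s01 / n


def _hanley_mcneil_variance(a: float, m: int, n: int) -> float:
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    return (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)


def orient_marker(values_pos, values_neg, declared_direction: str = "auto") -> str:
    """Resolve a marker's orientation to ``hyper`` or ``hypo``.

    ``hyper``: larger values are more tumor-like; ``hypo``: smaller values
    are.  With ``auto``, the orientation whose AUC is >= 0.5 is chosen; an
    exact tie (AUC = 0.5) resolves to ``hyper``.
    """
    if declared_direction in ("hyper", "hypo"):
        return declared_direction
    if declared_direction != "auto":
        raise ValueError(f"unknown direction {declared_direction!r}")
    pos, neg = _clean(values_pos), _clean(values_neg)
    if len(pos) == 0 or len(neg) == 0:
        raise DataError("a class is empty after removing missing values")
    return "hyper" if _auc_midrank(pos, neg) >= 0.5 else "hypo"


@dataclass(frozen=True)
class AucResult:
    auc: float
    se: float
    p_value: float
    n_pos: int
    n_neg: int


def auc(values_pos, values_neg, direction: str = "hyper",
        p_method: str = "delong") -> AucResult:
    """Empirical AUC on oriented values, with standard error and p-value.

    AUC is the Mann-Whitney U statistic over n_pos * n_neg pairs with ties
    credited 1/2.  The p-value is a two-sided z-test of AUC = 0.5 using the
    DeLong variance (default) or the Hanley-McNeil approximation.
    """
    pos = _oriented(_clean(values_pos), direction)
    neg = _oriented(_clean(values_neg), direction)
    if len(pos) < 2 or len(neg) < 2:
        raise DataError("need at least 2 non-missing values per class")
    a = _auc_midrank(pos, neg)
    if np.unique(np.concatenate([pos, neg])).size == 1:
        warnings.warn("all values tied; AUC is uninformative", stacklevel=2)
        return AucResult(0.5, 0.0, 1.0, len(pos), len(neg))
    if p_method == "delong":
        var = _delong_variance(pos, neg)
    elif p_method == "hanley-mcneil":
        var = _hanley_mcneil_variance(a, len(pos), len(neg))
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    se = float(np.sqrt(max(var, 0.0)))
    if se == 0.0:
        p = 1.0 if a == 0.5 else 0.0
    else:
        z = (a - 0.5) / se
        p = float(2 * stats.norm.sf(abs(z)))
    return AucResult(float(a), se, p, len(pos), len(neg))


def _best_threshold(pos: np.ndarray, neg: np.ndarray,
                    spec_level: float) -> tuple[float, float, float]:
    """Maximise sensitivity subject to specificity >= level on oriented scores.

    Candidate cutpoints are the midpoints between adjacent distinct pooled
    values plus guards below/above the range; a sample is called positive
    when its score >= cutpoint.  Among feasible cutpoints the one with
    maximal sensitivity is chosen, ties resolved toward higher specificity.
    Returns (threshold, sensitivity, specificity).
    """
    vals = np.unique(np.concatenate([pos, neg]))
    if vals.size == 1:
        thr = np.array([vals[0] - 1.0, vals[0] + 1.0])
    else:
        thr = np.concatenate(
            [[vals[0] - 1.0], (vals[:-1] + vals[1:]) / 2.0, [vals[-1] + 1.0]]
        )
    neg_sorted = np.sort(neg)
    pos_sorted = np.sort(pos)
    spec = np.searchsorted(neg_sorted, thr, side="left") / len(neg)
    sens = (len(pos) - np.searchsorted(pos_sorted, thr, side="left")) / len(pos)
    feasible = spec >= spec_level - 1e-12
    # the +inf guard always satisfies any level, so feasible is never empty
    cand = np.flatnonzero(feasible)
    order = np.lexsort((spec[cand], sens[cand]))
    best = cand[order[-1]]
    return float(thr[best]), float(sens[best]), float(spec[best])


@dataclass(frozen=True)
class SensSpecResult:
    spec_level: float
    point: float
    ci_lo: float
    ci_hi: float
    threshold: float          # on the methylation scale
    achieved_specificity: float
    n_boot: int


def sensitivity_at_specificity(
    values_pos, values_neg, direction: str = "hyper",
    spec_level: float = 0.95, n_boot: int = 1000, ci: float = 0.95,
    seed=None,
) -> SensSpecResult:
    """Sensitivity at a fixed specificity level with a bootstrap CI.

    The point estimate comes from the full data; the confidence interval is
    the (alpha/2, 1-alpha/2) percentile of sensitivities across ``n_boot``
    stratified bootstrap replicates (positives and negatives resampled
    independently, the threshold re-derived within each replicate).  The
    returned threshold is expressed on the original methylation scale; for
    a hypo marker the positivity rule is "value <= threshold".
    """
    if not 0 < spec_level < 1:
        raise ValueError("spec_level must lie in (0, 1)")
    pos = _oriented(_clean(values_pos), direction)
    neg = _oriented(_clean(values_neg), direction)
    if len(pos) == 0:
        raise DataError("positive class empty after removing missing values")
    if len(neg) < 5:
        raise DataError(
            f"need >= 5 negatives to anchor a {spec_level:.0%} specificity "
            f"threshold, got {len(neg)}"
        )
    thr, sens, spec = _best_threshold(pos, neg, spec_level)

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty(n_boot)
        for b in range(n_boot):
            p = pos[rng.integers(0, len(pos), size=len(pos))]
            n = neg[rng.integers(0, len(neg), size=len(neg))]
            _, boot[b], _ = _best_threshold(p, n, spec_level)
        alpha = 1.0 - ci
        lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    else:  # point estimate only (e.g. panel threshold derivation)
        lo = hi = np.nan

    thr_meth = -thr if direction == "hypo" else thr
    return SensSpecResult(
        spec_level=spec_level, point=float(sens),
        ci_lo=float(lo), ci_hi=float(hi),
        threshold=float(thr_meth), achieved_specificity=float(spec),
        n_boot=n_boot,
    )


@dataclass
class RocResult:
    """Complete single-marker report: orientation, AUC and sensitivities."""

    marker_id: str
    direction: str
    auc: float
    auc_se: float
    p_value: float
    n_pos: int
    n_neg: int
    sens_at_spec: dict[float, SensSpecResult] = field(default_factory=dict)

    def format_sensitivity(self, level: float) -> str:
        """Percent-scale ``point [lo,hi]`` string, e.g. ``97.37 [82.46,100.0]``."""
        r = self.sens_at_spec[level]
        return (f"{100 * r.point:.2f} "
                f"[{100 * r.ci_lo:.2f},{100 * r.ci_hi:.2f}]")


def analyze_marker(
    marker_id: str, values_pos, values_neg, declared_direction: str = "auto",
    spec_levels=(0.95,), n_boot: int = 1000, ci: float = 0.95,
    seed: int | None = None, p_method: str = "delong",
) -> RocResult:
    """Orient a marker, compute its AUC and sensitivity at each level."""
    direction = orient_marker(values_pos, values_neg, declared_direction)
    a = auc(values_pos, values_neg, direction, p_method=p_method)
    result = RocResult(marker_id=marker_id, direction=direction, auc=a.auc,
                       auc_se=a.se, p_value=a.p_value, n_pos=a.n_pos, n_neg=a.n_neg)
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    elif seed is not None:
        ss = np.random.SeedSequence(seed)
    else:
        ss = np.random.SeedSequence()
    children = ss.spawn(len(tuple(spec_levels)))
    for level, child in zip(spec_levels, children):
        result.sens_at_spec[level] = sensitivity_at_specificity(
            values_pos, values_neg, direction, spec_level=level,
            n_boot=n_boot, ci=ci, seed=child,
        )
    return result


class MarkerRocAnalyzer(BaseEstimator):
    """Fit-style wrapper computing :class:`RocResult` for every matrix column.

    Parameters
    ----------
    spec_levels : tuple of float
        Specificity levels at which sensitivity is reported.
    n_boot : int
        Bootstrap replicates for the sensitivity confidence intervals.
    ci : float
        Confidence level of the percentile interval.
    directions : mapping or None
        Optional marker -> {hyper, hypo} declarations; unlisted markers are
        oriented automatically.
    seed : int or None
        Seed for the bootstrap stream (one child stream per marker).
    p_method : str
        ``delong`` (default) or ``hanley-mcneil`` AUC variance.

    Attributes
    ----------
    results_ : dict marker_id -> RocResult
    table_ : pandas.DataFrame, one row per marker with percent-scale
        sensitivity columns mirroring a published marker table.
    """

    def __init__(self, spec_levels=(0.95,), n_boot: int = 1000, ci: float = 0.95,
                 directions=None, seed: int | None = None, p_method: str = "delong"):
        self.spec_levels = spec_levels
        self.n_boot = n_boot
        self.ci = ci
        self.directions = directions
        self.seed = seed
        self.p_method = p_method

    def fit(self, X: pd.DataFrame, y):
        """Analyse each column of ``X`` against binary labels ``y``.

        ``y`` may be 0/1 or "normal"/"tumor" labels aligned with ``X`` rows.
        """
        X = pd.DataFrame(X)
        y = np.asarray(y)
        if y.dtype.kind in "OUS":
            pos_mask = y == "tumor"
        else:
            pos_mask = y.astype(bool)
        ss = np.random.SeedSequence(self.seed) if self.seed is not None \
            else np.random.SeedSequence()
        children = ss.spawn(X.shape[1])
        directions = dict(self.directions or {})
        self.results_ = {}
        for col, child in zip(X.columns, children):
            declared = directions.get(col, "auto")
            self.results_[col] = analyze_marker(
                col, X.loc[pos_mask, col], X.loc[~pos_mask, col],
                declared_direction=declared, spec_levels=self.spec_levels,
                n_boot=self.n_boot, ci=self.ci, seed=child,
                p_method=self.p_method,
            )
        self.table_ = results_table(self.results_.values(), self.spec_levels)
        return self


def results_table(results, spec_levels=(0.95,)) -> pd.DataFrame:
    """Flatten RocResults into a report frame (percent-scale sensitivities)."""
    rows = []
    for r in results:
        row = {"marker": r.marker_id, "direction": r.direction,
               "auc": r.auc, "auc_se": r.auc_se, "p": r.p_value,
               "n_pos": r.n_pos, "n_neg": r.n_neg}
        for level in spec_levels:
            s = r.sens_at_spec[level]
            pct = int(round(100 * level))
            row[f"sens_at_{pct}"] = 100 * s.point
            row[f"sens_at_{pct}_lo"] = 100 * s.ci_lo
            row[f"sens_at_{pct}_hi"] = 100 * s.ci_hi
            row[f"threshold_at_{pct}"] = s.threshold
        rows.append(row)
    return pd.DataFrame(rows)
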