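"""m-of-k marker-panel evaluation.

A panel combines k single markers by voting: each marker has a positivity
threshold (by default its own cutpoint at 95% specificity, derived on the
same negative class), a sample is tumor-positive when at least ``m`` of the
k markers are individually positive.  Hypomethylated markers count a sample
positive when its value is *at or below* the threshold.

Missing marker values count as not positive — conservative toward
specificity — and a sample missing all k markers has no defined call and is
excluded from every denominator.  The m = 1..k sweep reports stage-stratified
sensitivity, pooled total sensitivity and specificity together with the
underlying counts, so every proportion is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DataError
from .io import MethylationMatrix, SampleMeta
from .roc import orient_marker, sensitivity_at_specificity

logger = logging.getLogger(__name__)

STAGE_COLUMNS = ("adenoma", "I", "II", "III")


@dataclass(frozen=True)
class MarkerThreshold:
    threshold: float
    direction: str  # hyper: value >= threshold is positive; hypo: value <= threshold

    def is_positive(self, values) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        with np.errstate(invalid="ignore"):
            pos = v <= self.threshold if self.direction == "hypo" else v >= self.threshold
        return np.where(np.isnan(v), False, pos)


@dataclass
class PanelSpec:
    """A concrete voting panel: markers, per-marker cutpoints, vote count."""

    marker_ids: list[str]
    thresholds: dict[str, MarkerThreshold]
    vote_m: int = 2

    def __post_init__(self):
        k = len(self.marker_ids)
        if not 1 <= self.vote_m <= k:
            raise DataError(f"vote_m must lie in [1, {k}], got {self.vote_m}")
        missing = set(self.marker_ids) - set(self.thresholds)
        if missing:
            raise DataError(f"no threshold for markers: {sorted(missing)}")


@dataclass
class PanelResult:
    """Stage-stratified sweep over vote thresholds m = 1..k.

    ``table`` has one row per m with percent-scale sensitivity per stage,
    pooled total sensitivity and specificity; ``counts`` keeps the raw
    numerators/denominators behind every proportion.
    """

    table: pd.DataFrame
    counts: pd.DataFrame
    spec: PanelSpec
    excluded_samples: list[str] = field(default_factory=list)


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, MethylationMatrix) else pd.DataFrame(matrix)


def derive_thresholds(
    matrix, meta: SampleMeta, markers, spec_level: float = 0.95,
    directions: dict[str, str] | None = None, vote_m: int = 2,
) -> PanelSpec:
    """Per-marker positivity cutpoints at the given specificity level.

    Each marker's threshold is the sensitivity-at-specificity cutpoint from
    the ROC machinery (no bootstrap needed here), derived on the oriented
    values of the full negative class.
    """
    df = _as_frame(matrix)
    markers = list(markers)
    cls = meta.classes_for(df.index)
    pos_mask = (cls == "tumor").to_numpy()
    neg_mask = (cls == "normal").to_numpy()
    directions = dict(directions or {})
    thresholds = {}
    for mk in markers:
        if mk not in df.columns:
            raise DataError(f"marker {mk!r} absent from matrix")
        vp, vn = df.loc[pos_mask, mk], df.loc[neg_mask, mk]
        d = orient_marker(vp, vn, directions.get(mk, "auto"))
        r = sensitivity_at_specificity(vp, vn, d, spec_level=spec_level, n_boot=0)
        thresholds[mk] = MarkerThreshold(threshold=r.threshold, direction=d)
    return PanelSpec(marker_ids=markers, thresholds=thresholds, vote_m=vote_m)


def call_panel(matrix, spec: PanelSpec, meta: SampleMeta | None = None) -> pd.DataFrame:
    """Per-sample positive-marker counts and the binary panel call.

    Returns a frame indexed by sample with columns n_positive, n_observed
    and call (pandas nullable boolean; <NA> when all k markers are missing).
    """
    df = _as_frame(matrix)
    missing_cols = set(spec.marker_ids) - set(df.columns)
    if missing_cols:
        raise DataError(f"panel markers absent from matrix: {sorted(missing_cols)}")
    sub = df[spec.marker_ids]
    positive = np.column_stack(
        [spec.thresholds[mk].is_positive(sub[mk]) for mk in spec.marker_ids]
    )
    observed = sub.notna().to_numpy()
    n_positive = positive.sum(axis=1)
    n_observed = observed.sum(axis=1)
    call = pd.array(n_positive >= spec.vote_m, dtype="boolean")
    call[n_observed == 0] = pd.NA
    n_dropped = int((n_observed == 0).sum())
    if n_dropped:
        logger.warning("%d samples missing all %d panel markers; call undefined",
                       n_dropped, len(spec.marker_ids))
    partial = (n_observed < len(spec.marker_ids)) & (n_observed > 0)
    if partial.any():
        logger.info("%d samples with partially missing panel markers "
                    "(missing counts as not positive)", int(partial.sum()))
    return pd.DataFrame(
        {"n_positive": n_positive, "n_observed": n_observed, "call": call},
        index=sub.index,
    )


def _stratum_rate(calls: pd.Series, want_positive: bool) -> tuple[float, int, int]:
    defined = calls.dropna()
    denom = len(defined)
    if denom == 0:
        return np.nan, 0, 0
    num = int(defined.sum()) if want_positive else int((~defined.astype(bool)).sum())
    return 100.0 * num / denom, num, denom


def sweep_panel(matrix, meta: SampleMeta, spec: PanelSpec) -> PanelResult:
    """Evaluate the panel for every vote threshold m = 1..k.

    Sensitivity per tumor stage is the proportion of that stage's tumors
    called positive; total sensitivity pools all tumors (count-weighted, not
    a mean of stages); specificity is the proportion of normals called
    negative.  Strata with no defined calls report NaN, not zero.
    """
    df = _as_frame(matrix)
    cls = meta.classes_for(df.index)
    stage = meta.stages_for(df.index)
    k = len(spec.marker_ids)

    base = call_panel(matrix, spec, meta)
    excluded = list(base.index[base["call"].isna()])

    rows, count_rows = [], []
    for m in range(1, k + 1):
        call = pd.array(base["n_positive"].to_numpy() >= m, dtype="boolean")
        call[base["n_observed"].to_numpy() == 0] = pd.NA
        call = pd.Series(call, index=base.index)
        row: dict[str, float | int] = {"m": m}
        crow: dict[str, float | int] = {"m": m}
        for st in STAGE_COLUMNS:
            mask = (cls == "tumor") & (stage == st)
            rate, num, den = _stratum_rate(call[mask.to_numpy()], True)
            row[f"sens_{st}"] = rate
            crow[f"n_pos_{st}"], crow[f"n_{st}"] = num, den
        rate, num, den = _stratum_rate(call[(cls == "tumor").to_numpy()], True)
        row["sens_total"] = rate
        crow["n_pos_total"], crow["n_total"] = num, den
        rate, num, den = _stratum_rate(call[(cls == "normal").to_numpy()], False)
        row["specificity"] = rate
        crow["n_neg_normal"], crow["n_normal"] = num, den
        rows.append(row)
        count_rows.append(crow)

    return PanelResult(
        table=pd.DataFrame(rows).set_index("m"),
        counts=pd.DataFrame(count_rows).set_index("m"),
        spec=spec,
        excluded_samples=excluded,
    )


class MarkerPanelClassifier(BaseEstimator, ClassifierMixin):
    """scikit-learn interface to the m-of-k voting panel.

    ``fit(X, y)`` derives per-marker thresholds at ``spec_level`` on the
    negative class of ``y`` (0/1 or normal/tumor labels); ``predict`` votes.
    Samples with every marker missing predict 0 (the functional interface
    :func:`call_panel` exposes the undefined-call distinction instead).
    """

    def __init__(self, markers=None, vote_m: int = 2, spec_level: float = 0.95,
                 directions=None):
        self.markers = markers
        self.vote_m = vote_m
        self.spec_level = spec_level
        self.directions = directions

    def fit(self, X, y):
        df = _as_frame(X)
        y = np.asarray(y)
        pos = (y == "tumor") if y.dtype.kind in "OUS" else y.astype(bool)
        markers = list(self.markers) if self.markers is not None else list(df.columns)
        directions = dict(self.directions or {})
        thresholds = {}
        for mk in markers:
            vp, vn = df.loc[pos, mk], df.loc[~pos, mk]
            d = orient_marker(vp, vn, directions.get(mk, "auto"))
            r = sensitivity_at_specificity(vp, vn, d, spec_level=self.spec_level,
                                           n_boot=0)
            thresholds[mk] = MarkerThreshold(threshold=r.threshold, direction=d)
        self.panel_spec_ = PanelSpec(marker_ids=markers, thresholds=thresholds,
                                     vote_m=self.vote_m)
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "panel_spec_")
        df = _as_frame(X)
        spec = self.panel_spec_
        return np.column_stack(
            [spec.thresholds[mk].is_positive(df[mk]) for mk in spec.marker_ids]
        ).sum(axis=1)

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= self.vote_m).astype(int)
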