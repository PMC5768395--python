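"""Reliability filters applied before any statistics.

Mass-spectrometry methylation quantitation leaves holes: a CpG unit that
yields data for fewer than 30% of samples is unreliable, as is a sample
missing more than 30% of its data points.  Both are discarded, never
imputed.  Boundaries follow the stated rules strictly: a unit observed in
*exactly* 30% of samples survives ("less than"), a sample missing *exactly*
30% survives ("more than").

The unit filter is applied first; the sample filter is then computed on the
surviving units.  Each filter is a scikit-learn style transformer; the
module-level functions wrap them for one-shot use.
"""

from __future__ import annotations

import logging

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DataError, EmptyResultError
from .io import MethylationMatrix

logger = logging.getLogger(__name__)


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, MethylationMatrix):
        return matrix.data
    return pd.DataFrame(matrix)


class UnitCompletenessFilter(BaseEstimator, TransformerMixin):
    """Drop CpG units observed in fewer than ``min_fraction`` of samples.

    Attributes
    ----------
    keep_units_ : list of retained unit ids (input order preserved)
    discarded_units_ : list of dropped unit ids
    observed_fraction_ : pandas.Series, fraction of samples observed per unit
    """

    def __init__(self, min_fraction: float = 0.30):
        self.min_fraction = min_fraction

    def fit(self, X, y=None):
        df = _as_frame(X)
        if df.empty:
            raise DataError("empty matrix")
        frac = df.notna().mean(axis=0)
        keep = frac >= self.min_fraction   # strict "less than" is discarded
        self.observed_fraction_ = frac
        self.keep_units_ = list(df.columns[keep])
        self.discarded_units_ = list(df.columns[~keep])
        if not self.keep_units_:
            raise EmptyResultError(
                f"all {df.shape[1]} units observed in < {self.min_fraction:.0%} "
                "of samples"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "keep_units_")
        df = _as_frame(X)[self.keep_units_]
        return MethylationMatrix(df) if isinstance(X, MethylationMatrix) else df


class SampleCompletenessFilter(BaseEstimator, TransformerMixin):
    """Drop samples missing more than ``max_missing`` of their data points.

    Because the missing fraction depends on which units are present, fit
    this *after* the unit filter on the reduced matrix.
    """

    def __init__(self, max_missing: float = 0.30):
        self.max_missing = max_missing

    def fit(self, X, y=None):
        df = _as_frame(X)
        if df.empty:
            raise DataError("empty matrix")
        frac = df.isna().mean(axis=1)
        keep = frac <= self.max_missing    # strict "more than" is discarded
        self.missing_fraction_ = frac
        self.keep_samples_ = list(df.index[keep])
        self.discarded_samples_ = list(df.index[~keep])
        if not self.keep_samples_:
            raise EmptyResultError(
                f"all {df.shape[0]} samples miss > {self.max_missing:.0%} "
                "of their data points"
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "keep_samples_")
        df = _as_frame(X).loc[self.keep_samples_]
        return MethylationMatrix(df) if isinstance(X, MethylationMatrix) else df


def filter_units(
    matrix: MethylationMatrix, min_fraction: float = 0.30
) -> tuple[MethylationMatrix, list[str]]:
    """Remove unreliable CpG units; returns (filtered matrix, discarded ids)."""
    f = UnitCompletenessFilter(min_fraction=min_fraction).fit(matrix)
    if f.discarded_units_:
        logger.info("discarded %d/%d units observed in < %.0f%% of samples",
                    len(f.discarded_units_), matrix.shape[1], 100 * min_fraction)
    return f.transform(matrix), f.discarded_units_


def filter_samples(
    matrix: MethylationMatrix, max_missing: float = 0.30
) -> tuple[MethylationMatrix, list[str]]:
    """Remove unreliable samples; returns (filtered matrix, discarded ids)."""
    f = SampleCompletenessFilter(max_missing=max_missing).fit(matrix)
    if f.discarded_samples_:
        logger.info("discarded %d/%d samples missing > %.0f%% of data points",
                    len(f.discarded_samples_), matrix.shape[0], 100 * max_missing)
    return f.transform(matrix), f.discarded_samples_


def apply_qc(
    matrix: MethylationMatrix,
    min_unit_fraction: float = 0.30,
    max_sample_missing: float = 0.30,
) -> tuple[MethylationMatrix, dict[str, list[str]]]:
    """Unit filter, then sample filter on the surviving units.

    Returns the filtered matrix and a discard log
    ``{"units": [...], "samples": [...]}``.
    """
    m1, bad_units = filter_units(matrix, min_unit_fraction)
    m2, bad_samples = filter_samples(m1, max_sample_missing)
    return m2, {"units": bad_units, "samples": bad_samples}
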