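"""Semiquantitative MS-HRM triage of candidate sites.

Methylation-sensitive high-resolution melting compares a sample's PCR-product
melting profile with profiles of standards mixed at known methylated-DNA
ratios (here 0, 1, 10 and 100%).  The assay is summarised by a scalar
melt-shift statistic that increases monotonically with methylation; each
sample is binned into the interval between the two standards that bracket
it — [0-1%), [1-10%) or [10-100%].  Bins are left-closed/right-open except
the last, and observations outside the standard range clamp to the outer
bins.

Tumor specificity of a site is then called from matched normal-tumor pairs:
each pair votes by the sign of (tumor bin - normal bin); a site passes when
one direction carries at least ``min_fraction`` (default 0.60) of the
informative pairs.  Tied pairs stay in the denominator — a pair whose tumor
and normal fall in the same bin is evidence *against* tumor specificity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError
from .io import SampleMeta

logger = logging.getLogger(__name__)

BIN_LABELS = ("[0-1%)", "[1-10%)", "[10-100%]")


@dataclass(frozen=True)
class StandardCurve:
    """Dilution standards: methylated-DNA ratios and their melt statistics."""

    ratios: Sequence[float] = (0.0, 0.01, 0.10, 1.00)
    statistics: Sequence[float] = (0.0, 1.0, 2.0, 3.0)

    def __post_init__(self):
        r = np.asarray(self.ratios, dtype=float)
        s = np.asarray(self.statistics, dtype=float)
        if len(r) != len(s) or len(r) < 2:
            raise CalibrationError("standards need matching ratios and statistics")
        if not np.all(np.diff(r) > 0):
            raise CalibrationError("standard ratios must be strictly increasing")
        if not np.all(np.diff(s) > 0):
            raise CalibrationError(
                "melt statistics must be strictly monotone in the methylation "
                "ratio; the standard curve is not usable for interval binning"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"ratio": self.ratios, "melt_statistic": self.statistics})


def assign_bin(melt_statistic: float, curve: StandardCurve) -> int:
    """Interval bin of one observation against the standard curve.

    Bin ``i`` covers statistics in [s_i, s_{i+1}); values below the 0%
    standard clamp to the first bin, values at or above the top standard to
    the last.  With the canonical 0/1/10/100% standards the bins read
    [0-1%), [1-10%) and [10-100%].
    """
    s = np.asarray(curve.statistics, dtype=float)
    idx = int(np.searchsorted(s, melt_statistic, side="right")) - 1
    return int(np.clip(idx, 0, len(s) - 2))


def assign_bins(observations: pd.DataFrame, curve: StandardCurve) -> pd.DataFrame:
    """Vectorised binning of an observations table (adds a ``bin`` column)."""
    s = np.asarray(curve.statistics, dtype=float)
    stat = observations["melt_statistic"].to_numpy(dtype=float)
    if not np.all(np.isfinite(stat)):
        raise DataError("non-finite melt statistics")
    bins = np.clip(np.searchsorted(s, stat, side="right") - 1, 0, len(s) - 2)
    out = observations.copy()
    out["bin"] = bins.astype(int)
    out["bin_label"] = [BIN_LABELS[b] if len(s) == 4 else str(b) for b in bins]
    return out


def call_site_specificity(
    calls: pd.DataFrame, meta: SampleMeta, min_fraction: float = 0.60
) -> pd.DataFrame:
    """Tumor-specificity triage per site from matched-pair bin calls.

    ``calls`` needs columns sample_id, site_id, bin.  For each site, every
    matched pair with both members called votes by ``sign(tumor bin -
    normal bin)``.  The site passes when the majority direction covers at
    least ``min_fraction`` of informative pairs (ties included in the
    denominator).  Sites without any informative pair are skipped with a
    warning.

    Returns one row per site: n_pairs, n_gt (T>N), n_lt (T<N), n_tied,
    fraction_specific, direction (hyper/hypo/None), passed.
    """
    pairs = meta.pairs()
    if pairs.empty:
        raise DataError("metadata contains no complete matched pairs")
    by_sample = calls.set_index(["site_id", "sample_id"])["bin"]

    rows = []
    for site in calls["site_id"].unique():
        site_bins = by_sample.loc[site] if site in by_sample.index.levels[0] else None
        n_gt = n_lt = n_tied = 0
        for _, pair in pairs.iterrows():
            try:
                tb = site_bins.loc[pair["tumor_id"]]
                nb = site_bins.loc[pair["normal_id"]]
            except (KeyError, AttributeError):
                continue
            d = int(tb) - int(nb)
            if d > 0:
                n_gt += 1
            elif d < 0:
                n_lt += 1
            else:
                n_tied += 1
        n_pairs = n_gt + n_lt + n_tied
        if n_pairs == 0:
            logger.warning("site %s has no informative matched pairs; skipped", site)
            continue
        majority = max(n_gt, n_lt)
        fraction = majority / n_pairs
        passed = fraction >= min_fraction and majority > 0
        if n_gt > n_lt:
            direction = "hyper"
        elif n_lt > n_gt:
            direction = "hypo"
        else:
            direction = None
        if direction is None:
            passed = False
        rows.append((site, n_pairs, n_gt, n_lt, n_tied, fraction,
                     direction, bool(passed)))
    return pd.DataFrame(
        rows,
        columns=["site_id", "n_pairs", "n_gt", "n_lt", "n_tied",
                 "fraction_specific", "direction", "passed"],
    )


def screen_sites(
    observations: pd.DataFrame, curve: StandardCurve, meta: SampleMeta,
    min_fraction: float = 0.60,
) -> pd.DataFrame:
    """Bin observations against the standards and triage every site."""
    calls = assign_bins(observations, curve)
    return call_site_specificity(calls, meta, min_fraction=min_fraction)
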