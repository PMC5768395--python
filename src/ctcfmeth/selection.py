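"""Representative-unit selection, marker ranking and candidate discovery.

Three stages of the screening funnel live here:

* each CTCF-binding site is represented by its CpG unit with the highest
  oriented AUC for tumor vs normal (ties broken lexicographically by unit
  id so the choice is reproducible);
* markers are ranked by AUC for top-k shortlisting, with sensitivity at 95%
  specificity and then the marker id as tie-breaks — a total order;
* the cell-line discovery screen: keep sites whose CTCF occupancy is
  specific to immortal lines, then keep those where methylation in
  unoccupied lines exceeds methylation in occupied lines (one-sided
  Mann-Whitney, exact p-values at the tiny per-site n).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import DataError
from .io import MethylationMatrix, SampleMeta, SiteAnnotation
from .roc import _auc_midrank, _clean
from .simulate import OccupancyStudy

logger = logging.getLogger(__name__)


def _unit_auc(values: pd.Series, is_tumor: np.ndarray, direction: str) -> float:
    """Oriented AUC of one unit; NaN when a class has no data."""
    pos = _clean(values.to_numpy()[is_tumor])
    neg = _clean(values.to_numpy()[~is_tumor])
    if len(pos) == 0 or len(neg) == 0:
        return np.nan
    a = _auc_midrank(pos, neg)
    if direction == "hypo":
        return 1.0 - a
    if direction == "hyper":
        return a
    return max(a, 1.0 - a)  # auto: orientation-free discriminative power


class RepresentativeUnitReducer(BaseEstimator, TransformerMixin):
    """Reduce a unit-level matrix to one representative column per site.

    Fitting computes, for every annotated site, the oriented tumor-vs-normal
    AUC of each surviving CpG unit and keeps the argmax (ties -> smallest
    unit id).  ``transform`` returns the site-level matrix whose columns are
    the chosen units, renamed to their site ids.

    Attributes
    ----------
    representative_units_ : dict site_id -> unit_id
    unit_aucs_ : pandas.DataFrame (site_id, unit_id, auc)
    dropped_sites_ : sites with no surviving unit
    """

    def __init__(self, annotation: SiteAnnotation):
        self.annotation = annotation

    def fit(self, X, y):
        df = X.data if isinstance(X, MethylationMatrix) else pd.DataFrame(X)
        y = np.asarray(y)
        is_tumor = (y == "tumor") if y.dtype.kind in "OUS" else y.astype(bool)
        if is_tumor.all() or not is_tumor.any():
            raise DataError("need both tumor and normal samples")
        self.representative_units_ = {}
        self.dropped_sites_ = []
        rows = []
        for site in self.annotation.site_ids:
            direction = self.annotation.direction_of(site)
            units = [u for u in self.annotation.units_for(site) if u in df.columns]
            scored = []
            for u in sorted(units):
                a = _unit_auc(df[u], is_tumor, direction)
                rows.append((site, u, a))
                if np.isfinite(a):
                    scored.append((a, u))
            if not scored:
                self.dropped_sites_.append(site)
                logger.warning("site %s has no surviving CpG unit; dropped", site)
                continue
            best_auc = max(a for a, _ in scored)
            best_unit = min(u for a, u in scored if a == best_auc)
            self.representative_units_[site] = best_unit
        self.unit_aucs_ = pd.DataFrame(rows, columns=["site_id", "unit_id", "auc"])
        return self

    def transform(self, X) -> pd.DataFrame:
        check_is_fitted(self, "representative_units_")
        df = X.data if isinstance(X, MethylationMatrix) else pd.DataFrame(X)
        out = pd.DataFrame(
            {site: df[unit] for site, unit in self.representative_units_.items()}
        )
        return out


def select_representative_unit(
    matrix: MethylationMatrix, annotation: SiteAnnotation, meta: SampleMeta
) -> dict[str, str]:
    """Map each site to its highest-AUC CpG unit (QC-filtered matrix in)."""
    y = meta.classes_for(matrix.sample_ids).to_numpy()
    reducer = RepresentativeUnitReducer(annotation).fit(matrix, y)
    return dict(reducer.representative_units_)


def site_level_matrix(
    matrix: MethylationMatrix, annotation: SiteAnnotation, meta: SampleMeta
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Site-level frame (columns = site ids) plus the site -> unit map."""
    y = meta.classes_for(matrix.sample_ids).to_numpy()
    reducer = RepresentativeUnitReducer(annotation).fit(matrix, y)
    return reducer.transform(matrix), dict(reducer.representative_units_)


def rank_markers(roc_results, k: int | None = None) -> list[str]:
    """Rank markers by AUC descending; return the top ``k`` ids.

    Accepts an iterable of :class:`~ctcfmeth.roc.RocResult` or the flattened
    results table.  Ties resolve by sensitivity at 95% specificity (when
    present), then marker id — the order is total and reproducible.
    """
    if isinstance(roc_results, pd.DataFrame):
        records = []
        for _, row in roc_results.iterrows():
            sens = row.get("sens_at_95", 0.0)
            records.append((row["marker"], float(row["auc"]),
                            float(sens) if pd.notna(sens) else 0.0))
    else:
        records = []
        for r in roc_results:
            sens = r.sens_at_spec.get(0.95)
            records.append((r.marker_id, r.auc, sens.point if sens else 0.0))
    ordered = sorted(records, key=lambda t: (-t[1], -t[2], t[0]))
    ids = [m for m, _, _ in ordered]
    if k is not None:
        if k > len(ids):
            raise DataError(f"requested top {k} of only {len(ids)} markers")
        ids = ids[:k]
    return ids


def discover_candidates(
    occupancy: OccupancyStudy | pd.DataFrame,
    alpha: float = 0.05,
    method: str = "mannwhitney",
    fdr: bool = False,
    min_lines: int = 4,
) -> tuple[list[str], pd.DataFrame]:
    """Two-step candidate screen on the cell-line panel.

    Step 1 keeps sites occupied *only* in immortal cell lines (and in at
    least one); step 2 keeps sites where methylation in unoccupied lines
    significantly exceeds methylation in occupied lines — the negative
    occupancy-methylation association expected of a methylation-sensitive
    CTCF site.  ``method`` is ``mannwhitney`` (one-sided, exact) or
    ``spearman`` (one-sided negative correlation).  ``fdr`` applies
    Benjamini-Hochberg across step-2 tests before thresholding at ``alpha``.

    Returns (selected site ids, per-site detail frame).
    """
    table = occupancy.table if isinstance(occupancy, OccupancyStudy) else occupancy
    rows = []
    for site, grp in table.groupby("site_id", sort=True):
        occ_cls = grp.loc[grp["occupied"] == 1, "class"]
        step1 = len(occ_cls) > 0 and (occ_cls == "immortal").all()
        p = np.nan
        skipped = False
        if step1:
            occ_m = grp.loc[grp["occupied"] == 1, "methylation"].to_numpy()
            unocc_m = grp.loc[grp["occupied"] == 0, "methylation"].to_numpy()
            if len(grp) < min_lines or len(occ_m) == 0 or len(unocc_m) == 0:
                logger.warning(
                    "site %s lacks occupied/unoccupied coverage across >= %d "
                    "lines; skipped", site, min_lines)
                skipped = True
            elif method == "mannwhitney":
                p = stats.mannwhitneyu(
                    unocc_m, occ_m, alternative="greater", method="exact"
                ).pvalue
            elif method == "spearman":
                rho, p_two = stats.spearmanr(grp["methylation"], grp["occupied"])
                p = p_two / 2 if rho < 0 else 1.0 - p_two / 2
            else:
                raise ValueError(f"unknown method {method!r}")
        rows.append((site, bool(step1), skipped, p))
    detail = pd.DataFrame(
        rows, columns=["site_id", "immortal_specific", "skipped", "p_value"]
    )
    tested = detail["immortal_specific"] & ~detail["skipped"] & detail["p_value"].notna()
    pvals = detail.loc[tested, "p_value"].to_numpy()
    if fdr and len(pvals):
        detail.loc[tested, "p_adjusted"] = stats.false_discovery_control(pvals)
        crit = detail.get("p_adjusted")
    else:
        crit = detail["p_value"]
    detail["selected"] = tested & (crit <= alpha)
    selected = detail.loc[detail["selected"], "site_id"].tolist()
    return selected, detail
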