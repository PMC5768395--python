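"""Tabular input/output and the validated in-memory containers.

Three tables drive the pipeline:

* a methylation matrix — samples in rows, CpG units in columns, values are
  methylation proportions in [0, 1], empty cells (or ``NA``) are missing;
* sample metadata — class (normal/tumor), tumor stage, optional matched-pair id;
* site annotation — BED-style coordinates of each CTCF-binding site plus a
  map from CpG units to their parent site.

All readers validate on load and raise :class:`~ctcfmeth.errors.FormatError`
subclasses with the offending row/column named.  Coordinates follow the BED
convention (0-based, half-open).  ``read(write(x))`` round-trips exactly.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError, RangeError

logger = logging.getLogger(__name__)

CLASSES = ("normal", "tumor")
STAGES = ("adenoma", "I", "II", "III", "none")
DIRECTIONS = ("hyper", "hypo", "auto")

_NA_STRINGS = {"", "NA", "na", "NaN", "nan"}


def _sep_for(path: str | Path, delimiter: str | None) -> str:
    """Pick a field separator: explicit flag wins, then file extension."""
    if delimiter is not None:
        return delimiter
    return "," if str(path).lower().endswith(".csv") else "\t"


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


class MethylationMatrix:
    """Samples x CpG-unit methylation proportions with missing values.

    Wraps a float :class:`pandas.DataFrame` (rows = samples, columns = CpG
    units, ``NaN`` = missing) and enforces the container invariants: unique
    sample and unit ids, every non-missing value in [0, 1].
    """

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data).astype(float)
        if data.index.has_duplicates:
            dupes = data.index[data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if data.columns.has_duplicates:
            dupes = data.columns[data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate unit ids: {dupes}")
        bad = (data < 0) | (data > 1)
        if bad.any().any():
            row, col = next(zip(*np.nonzero(bad.to_numpy())))
            raise RangeError(
                f"methylation value {data.iat[row, col]!r} outside [0, 1] "
                f"at sample {data.index[row]!r}, unit {data.columns[col]!r}"
            )
        data.index = data.index.astype(str).rename("sample_id")
        data.columns = data.columns.astype(str)
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset(self, samples=None, units=None) -> "MethylationMatrix":
        data = self.data
        if samples is not None:
            data = data.loc[list(samples)]
        if units is not None:
            data = data[list(units)]
        return MethylationMatrix(data)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        n, p = self.data.shape
        miss = float(self.data.isna().to_numpy().mean()) if n and p else 0.0
        return f"<MethylationMatrix {n} samples x {p} units, {miss:.1%} missing>"


class SampleMeta:
    """Per-sample class / stage / matched-pair labels.

    Invariants: normal samples carry stage ``none``; a pair id joins at most
    one normal and one tumor sample.  A tumor without a stage is accepted
    with a logged warning (stage-stratified outputs then skip it).
    """

    def __init__(self, data: pd.DataFrame):
        data = pd.DataFrame(data).copy()
        required = {"sample_id", "class"}
        missing = required - set(data.columns)
        if missing:
            raise FormatError(f"metadata missing required columns: {sorted(missing)}")
        if "stage" not in data.columns:
            data["stage"] = "none"
        if "pair_id" not in data.columns:
            data["pair_id"] = pd.NA
        data["sample_id"] = data["sample_id"].astype(str)
        if data["sample_id"].duplicated().any():
            dupes = data.loc[data["sample_id"].duplicated(), "sample_id"].tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dupes}")
        data["stage"] = data["stage"].fillna("none").replace("", "none").astype(str)
        data["pair_id"] = data["pair_id"].replace("", pd.NA).astype("string")

        bad_class = set(data["class"]) - set(CLASSES)
        if bad_class:
            raise FormatError(f"unknown class labels: {sorted(bad_class)}")
        bad_stage = set(data["stage"]) - set(STAGES)
        if bad_stage:
            raise FormatError(f"unknown stage labels: {sorted(bad_stage)}")

        staged_normal = data[(data["class"] == "normal") & (data["stage"] != "none")]
        if len(staged_normal):
            raise ConsistencyError(
                f"normal samples with a tumor stage: {staged_normal['sample_id'].tolist()}"
            )
        unstaged_tumor = data[(data["class"] == "tumor") & (data["stage"] == "none")]
        if len(unstaged_tumor):
            logger.warning(
                "%d tumor samples without a stage (accepted; excluded from "
                "stage-stratified tables)", len(unstaged_tumor)
            )
        for pid, grp in data.dropna(subset=["pair_id"]).groupby("pair_id"):
            counts = grp["class"].value_counts()
            if counts.get("normal", 0) > 1 or counts.get("tumor", 0) > 1:
                raise ConsistencyError(
                    f"pair id {pid!r} joins more than one sample per class"
                )
        self.data = data.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    def classes_for(self, sample_ids) -> pd.Series:
        """Class label (normal/tumor) per requested sample, in order."""
        s = self.data.set_index("sample_id")["class"]
        return s.reindex(list(sample_ids))

    def stages_for(self, sample_ids) -> pd.Series:
        s = self.data.set_index("sample_id")["stage"]
        return s.reindex(list(sample_ids))

    @property
    def normal_ids(self) -> list[str]:
        d = self.data
        return d.loc[d["class"] == "normal", "sample_id"].tolist()

    @property
    def tumor_ids(self) -> list[str]:
        d = self.data
        return d.loc[d["class"] == "tumor", "sample_id"].tolist()

    def pairs(self) -> pd.DataFrame:
        """Complete matched pairs as a frame (pair_id, normal_id, tumor_id)."""
        d = self.data.dropna(subset=["pair_id"])
        rows = []
        for pid, grp in d.groupby("pair_id"):
            by_class = grp.set_index("class")["sample_id"]
            if "normal" in by_class.index and "tumor" in by_class.index:
                rows.append((pid, by_class["normal"], by_class["tumor"]))
        return pd.DataFrame(rows, columns=["pair_id", "normal_id", "tumor_id"])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        c = self.data["class"].value_counts()
        return f"<SampleMeta {c.get('normal', 0)} normal / {c.get('tumor', 0)} tumor>"


class SiteAnnotation:
    """CTCF-binding-site coordinates and the CpG-unit -> site map.

    ``sites`` is indexed by site id with columns chrom/start/end/direction
    (BED 0-based half-open; direction in hyper/hypo/auto).  ``unit_map``
    maps each CpG unit id to exactly one site id.
    """

    def __init__(self, sites: pd.DataFrame, unit_map: Mapping[str, str] | pd.Series):
        sites = pd.DataFrame(sites).copy()
        required = {"site_id", "chrom", "start", "end"}
        missing = required - set(sites.columns)
        if sites.index.name == "site_id" and "site_id" in missing:
            sites = sites.reset_index()
            missing = required - set(sites.columns)
        if missing:
            raise FormatError(f"annotation missing columns: {sorted(missing)}")
        if "direction" not in sites.columns:
            sites["direction"] = "auto"
        sites["site_id"] = sites["site_id"].astype(str)
        if sites["site_id"].duplicated().any():
            raise FormatError("duplicate site ids in annotation")
        sites[["start", "end"]] = sites[["start", "end"]].astype(int)
        bad = sites[sites["start"] >= sites["end"]]
        if len(bad):
            raise FormatError(
                f"start >= end for sites: {bad['site_id'].tolist()} "
                "(coordinates are 0-based half-open)"
            )
        bad_dir = set(sites["direction"]) - set(DIRECTIONS)
        if bad_dir:
            raise FormatError(f"unknown direction labels: {sorted(bad_dir)}")

        unit_map = pd.Series(dict(unit_map) if not isinstance(unit_map, pd.Series) else unit_map)
        unit_map.index = unit_map.index.astype(str)
        unit_map = unit_map.astype(str)
        if unit_map.index.has_duplicates:
            raise FormatError("a CpG unit maps to more than one site")
        unknown = set(unit_map) - set(sites["site_id"])
        if unknown:
            raise FormatError(f"unit map references unknown sites: {sorted(unknown)}")
        self.sites = sites.set_index("site_id")
        self.unit_map = unit_map.rename_axis("unit_id").rename("site_id")

    @property
    def site_ids(self) -> list[str]:
        return list(self.sites.index)

    def units_for(self, site_id: str) -> list[str]:
        return self.unit_map.index[self.unit_map == site_id].tolist()

    def direction_of(self, site_id: str) -> str:
        return str(self.sites.at[site_id, "direction"])

    def site_of(self, unit_id: str) -> str:
        return str(self.unit_map[unit_id])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _parse_cell(raw: str, sample: str, unit: str) -> float:
    text = raw.strip()
    if text in _NA_STRINGS:
        return np.nan
    if text.endswith("%"):
        raise RangeError(
            f"percent-formatted value {raw!r} at sample {sample!r}, unit {unit!r}: "
            "the matrix stores proportions in [0, 1]"
        )
    try:
        value = float(text)
    except ValueError as exc:
        raise FormatError(
            f"non-numeric cell {raw!r} at sample {sample!r}, unit {unit!r}"
        ) from exc
    if not 0.0 <= value <= 1.0:
        raise RangeError(
            f"methylation value {value} outside [0, 1] at sample {sample!r}, "
            f"unit {unit!r}"
        )
    return value


def read_matrix(path: str | Path, delimiter: str | None = None) -> MethylationMatrix:
    """Read a methylation matrix (header = unit ids, first column = sample ids)."""
    sep = _sep_for(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, index_col=0)
    parsed = pd.DataFrame(
        [
            [_parse_cell(raw.iat[i, j], raw.index[i], raw.columns[j])
             for j in range(raw.shape[1])]
            for i in range(raw.shape[0])
        ],
        index=raw.index,
        columns=raw.columns,
    )
    return MethylationMatrix(parsed)


def write_matrix(matrix: MethylationMatrix, path: str | Path,
                 delimiter: str | None = None) -> None:
    sep = _sep_for(path, delimiter)
    matrix.data.to_csv(path, sep=sep, na_rep="", float_format="%.17g")


def read_meta(path: str | Path, delimiter: str | None = None) -> SampleMeta:
    sep = _sep_for(path, delimiter)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.replace(sorted(_NA_STRINGS), pd.NA)
    return SampleMeta(raw)


def write_meta(meta: SampleMeta, path: str | Path, delimiter: str | None = None) -> None:
    sep = _sep_for(path, delimiter)
    meta.data.to_csv(path, sep=sep, index=False, na_rep="")


def read_annotation(sites_path: str | Path, unit_map_path: str | Path,
                    delimiter: str | None = None) -> SiteAnnotation:
    """Read site annotation from a BED-derived TSV plus a unit-map TSV.

    The sites table needs columns chrom/start/end/site_id (direction
    optional); the unit map needs unit_id/site_id.
    """
    sep = _sep_for(sites_path, delimiter)
    sites = pd.read_csv(sites_path, sep=sep, dtype=str, keep_default_na=False)
    umap = pd.read_csv(unit_map_path, sep=_sep_for(unit_map_path, delimiter),
                       dtype=str, keep_default_na=False)
    for col in ("unit_id", "site_id"):
        if col not in umap.columns:
            raise FormatError(f"unit map missing column {col!r}")
    return SiteAnnotation(sites, umap.set_index("unit_id")["site_id"])


def write_annotation(annotation: SiteAnnotation, sites_path: str | Path,
                     unit_map_path: str | Path, delimiter: str | None = None) -> None:
    sep = _sep_for(sites_path, delimiter)
    cols = ["chrom", "start", "end", "direction"]
    annotation.sites.reset_index()[["site_id"] + cols].to_csv(
        sites_path, sep=sep, index=False)
    annotation.unit_map.reset_index().to_csv(
        unit_map_path, sep=_sep_for(unit_map_path, delimiter), index=False)


def read_hrm_observations(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read HRM observations (sample_id, site_id, melt_statistic)."""
    sep = _sep_for(path, delimiter)
    df = pd.read_csv(path, sep=sep)
    required = {"sample_id", "site_id", "melt_statistic"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"HRM table missing columns: {sorted(missing)}")
    df["melt_statistic"] = df["melt_statistic"].astype(float)
    if not np.isfinite(df["melt_statistic"]).all():
        raise FormatError("non-finite melt statistics in HRM table")
    return df
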