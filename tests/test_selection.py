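"""Representative-unit choice, marker ranking, cell-line discovery screen."""

import numpy as np
import pandas as pd
import pytest

from ctcfmeth import (MethylationMatrix, SiteAnnotation, discover_candidates,
                      rank_markers, select_representative_unit,
                      simulate_celllines)
from ctcfmeth.errors import DataError
from ctcfmeth.selection import RepresentativeUnitReducer, site_level_matrix
from conftest import make_meta


def _annotation(units_by_site):
    sites = pd.DataFrame({
        "site_id": list(units_by_site),
        "chrom": "chr1",
        "start": [100 * i for i in range(len(units_by_site))],
        "end": [100 * i + 30 for i in range(len(units_by_site))],
        "direction": "auto",
    })
    umap = {u: s for s, units in units_by_site.items() for u in units}
    return SiteAnnotation(sites, umap)


def _graded_matrix():
    """One site, three units with separation strong > medium > weak."""
    rng = np.random.default_rng(0)
    n = 30
    normal = {"sA.u1": rng.beta(3, 6, n), "sA.u2": rng.beta(1, 20, n),
              "sA.u3": rng.beta(4, 5, n)}
    tumor = {"sA.u1": rng.beta(6, 3, n), "sA.u2": rng.beta(20, 1, n),
             "sA.u3": rng.beta(5, 4, n)}
    df = pd.DataFrame({k: np.concatenate([normal[k], tumor[k]])
                       for k in normal},
                      index=[f"N{i}" for i in range(n)] + [f"T{i}" for i in range(n)])
    return MethylationMatrix(df), make_meta(n, n)


def test_highest_auc_unit_selected():
    m, meta = _graded_matrix()
    ann = _annotation({"sA": ["sA.u1", "sA.u2", "sA.u3"]})
    chosen = select_representative_unit(m, ann, meta)
    assert chosen == {"sA": "sA.u2"}


def test_single_unit_site_is_identity():
    m, meta = _graded_matrix()
    ann = _annotation({"sA": ["sA.u3"]})
    assert select_representative_unit(m, ann, meta) == {"sA": "sA.u3"}


def test_selection_invariant_to_column_order():
    m, meta = _graded_matrix()
    ann = _annotation({"sA": ["sA.u1", "sA.u2", "sA.u3"]})
    shuffled = MethylationMatrix(m.data[["sA.u3", "sA.u1", "sA.u2"]])
    assert select_representative_unit(shuffled, ann, meta) == \
        select_representative_unit(m, ann, meta)


def test_tie_breaks_lexicographic():
    df = pd.DataFrame({
        "s.u2": [0.9, 0.8, 0.1, 0.2],
        "s.u1": [0.9, 0.8, 0.1, 0.2],   # identical values, identical AUC
    }, index=["T0", "T1", "N0", "N1"])
    ann = _annotation({"s": ["s.u1", "s.u2"]})
    meta = make_meta(2, 2)
    assert select_representative_unit(MethylationMatrix(df), ann, meta) == \
        {"s": "s.u1"}


def test_site_with_no_surviving_units_dropped(caplog):
    import logging
    m, meta = _graded_matrix()
    ann = _annotation({"sA": ["sA.u1"], "ghost": ["ghost.u1"]})
    with caplog.at_level(logging.WARNING, logger="ctcfmeth.selection"):
        sm, units = site_level_matrix(m, ann, meta)
    assert list(sm.columns) == ["sA"]
    assert any("ghost" in r.message for r in caplog.records)


def test_transform_renames_units_to_sites():
    m, meta = _graded_matrix()
    ann = _annotation({"sA": ["sA.u1", "sA.u2", "sA.u3"]})
    y = meta.classes_for(m.sample_ids).to_numpy()
    red = RepresentativeUnitReducer(ann).fit(m, y)
    out = red.transform(m)
    pd.testing.assert_series_equal(out["sA"], m.data["sA.u2"], check_names=False)


# -- ranking -----------------------------------------------------------------


def _roc_table(rows):
    return pd.DataFrame(rows, columns=["marker", "auc", "sens_at_95"])


def test_rank_markers_by_auc_then_sensitivity_then_id():
    t = _roc_table([("b", 0.90, 70.0), ("a", 0.95, 50.0),
                    ("d", 0.90, 80.0), ("c", 0.90, 80.0)])
    assert rank_markers(t) == ["a", "c", "d", "b"]  # tie: sens desc, then id
    assert rank_markers(t, k=2) == ["a", "c"]
    with pytest.raises(DataError):
        rank_markers(t, k=10)


def test_rank_is_total_order_across_runs():
    t = _roc_table([("m2", 0.9, 60.0), ("m1", 0.9, 60.0)])
    assert rank_markers(t) == rank_markers(t.iloc[::-1]) == ["m1", "m2"]


# -- discovery ---------------------------------------------------------------


def test_planted_candidates_recovered_and_prefilter_applied():
    occ = simulate_celllines(30, n_true_candidates=4, seed=2,
                             nonspecific_fraction=0.3)
    selected, detail = discover_candidates(occ, alpha=0.05)
    assert set(occ.true_candidates) <= set(selected)
    # sites occupied in a normal line never reach step 2
    d = detail.set_index("site_id")
    t = occ.table
    occupied_in_normal = t[(t["occupied"] == 1) & (t["class"] == "normal")][
        "site_id"].unique()
    assert len(occupied_in_normal) > 0
    assert not d.loc[occupied_in_normal, "immortal_specific"].any()
    assert not d.loc[occupied_in_normal, "selected"].any()


def test_site_below_line_minimum_skipped(caplog):
    import logging
    table = pd.DataFrame({
        "site_id": ["tiny"] * 3,
        "cell_line": ["IM1", "IM2", "NL1"],
        "class": ["immortal", "immortal", "normal"],
        "occupied": [1, 0, 0],
        "methylation": [0.1, 0.8, 0.9],
    })
    with caplog.at_level(logging.WARNING, logger="ctcfmeth.selection"):
        selected, detail = discover_candidates(table, min_lines=4)
    assert selected == []
    assert detail.iloc[0]["skipped"]


def test_spearman_alternative_selects_planted():
    occ = simulate_celllines(12, n_true_candidates=3, seed=8)
    selected, _ = discover_candidates(occ, alpha=0.05, method="spearman")
    assert set(occ.true_candidates) <= set(selected)
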