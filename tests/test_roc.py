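"""ROC statistics against independent oracles.

The AUC is checked against exhaustive concordant-pair counting, the DeLong
standard error against values computed independently with the R package
pROC (frozen below), and sensitivity-at-specificity against an exhaustive
scan over all midpoint thresholds.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcfmeth import auc, orient_marker, sensitivity_at_specificity
from ctcfmeth.errors import DataError
from ctcfmeth.roc import MarkerRocAnalyzer, analyze_marker

# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def pair_counting_auc(pos, neg):
    """Exhaustive concordant-pair count: (wins + ties/2) / (m*n)."""
    wins = sum(1.0 for p in pos for n in neg if p > n)
    ties = sum(1.0 for p in pos for n in neg if p == n)
    return (wins + ties / 2) / (len(pos) * len(neg))


def exhaustive_sens_at_spec(pos, neg, level):
    """Scan every midpoint threshold; best sensitivity with spec >= level."""
    pos, neg = np.asarray(pos, float), np.asarray(neg, float)
    vals = np.unique(np.concatenate([pos, neg]))
    cands = np.concatenate([[vals[0] - 1], (vals[:-1] + vals[1:]) / 2,
                            [vals[-1] + 1]])
    best = -1.0
    for t in cands:
        spec = np.mean(neg < t)
        if spec >= level:
            best = max(best, float(np.mean(pos >= t)))
    return best


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------


def test_auc_perfect_separation():
    r = auc([0.9, 0.8], [0.1, 0.2])
    assert r.auc == 1.0 and r.p_value < 0.05


def test_auc_all_tied_is_half_with_warning():
    with pytest.warns(UserWarning, match="tied"):
        r = auc([0.5, 0.5], [0.5, 0.5])
    assert r.auc == 0.5 and r.p_value == 1.0


def test_auc_matches_pair_counting_with_ties():
    rng = np.random.default_rng(0)
    for _ in range(50):
        m, n = rng.integers(2, 13, size=2)
        # quantised values force ties within and across classes
        pos = np.round(rng.random(m), 1)
        neg = np.round(rng.random(n), 1)
        assert auc(pos, neg).auc == pair_counting_auc(pos, neg)


def test_delong_se_matches_pROC_frozen_values():
    # frozen from R pROC var(roc, method="delong") on these exact vectors
    pos = [0.81, 0.62, 0.47, 0.90, 0.55, 0.73, 0.66, 0.38]
    neg = [0.12, 0.33, 0.51, 0.24, 0.45, 0.09, 0.58, 0.27, 0.41, 0.19]
    r = auc(pos, neg)
    assert r.auc == pytest.approx(0.9125, abs=1e-12)
    assert r.se == pytest.approx(0.0664057394, abs=1e-9)
    assert r.p_value == pytest.approx(5.2376913e-10, rel=1e-5)
    # with ties
    r2 = auc([0.5, 0.7, 0.7, 0.9, 0.3], [0.5, 0.2, 0.7, 0.4, 0.3, 0.1])
    assert r2.auc == pytest.approx(0.8, abs=1e-12)
    assert r2.se == pytest.approx(0.1396424004, abs=1e-9)


def test_hanley_mcneil_variance_available():
    pos = [0.8, 0.35, 0.9, 0.6]
    neg = [0.2, 0.3, 0.4, 0.5, 0.1]
    r = auc(pos, neg, p_method="hanley-mcneil")
    assert 0 < r.se < 1 and 0 <= r.p_value <= 1


def test_orient_marker():
    assert orient_marker([0.9, 0.8], [0.1, 0.2]) == "hyper"
    assert orient_marker([0.1, 0.2], [0.9, 0.8]) == "hypo"
    assert orient_marker([0.5, 0.5], [0.5, 0.5]) == "hyper"  # tie-break
    assert orient_marker([0.1], [0.9], declared_direction="hyper") == "hyper"
    with pytest.raises(DataError):
        orient_marker([], [0.5])


def test_orientation_invariance():
    """Negating a hypo marker and flipping its direction changes nothing."""
    rng = np.random.default_rng(3)
    pos, neg = rng.beta(2, 8, 30), rng.beta(6, 3, 30)  # hypo marker
    r_hypo = auc(pos, neg, "hypo")
    r_flip = auc(-pos, -neg, "hyper")
    assert r_hypo.auc == r_flip.auc and r_hypo.p_value == r_flip.p_value
    s_hypo = sensitivity_at_specificity(pos, neg, "hypo", 0.90, n_boot=200, seed=1)
    s_flip = sensitivity_at_specificity(-pos, -neg, "hyper", 0.90, n_boot=200, seed=1)
    assert s_hypo.point == s_flip.point
    assert (s_hypo.ci_lo, s_hypo.ci_hi) == (s_flip.ci_lo, s_flip.ci_hi)


# ---------------------------------------------------------------------------
# sensitivity at fixed specificity
# ---------------------------------------------------------------------------


def test_sens_perfect_separation_degenerate_ci():
    r = sensitivity_at_specificity(
        [0.9, 0.8, 0.85, 0.95, 0.7], [0.1, 0.2, 0.15, 0.05, 0.3],
        spec_level=0.95, n_boot=200, seed=0)
    assert r.point == 1.0 and (r.ci_lo, r.ci_hi) == (1.0, 1.0)


def test_sens_point_matches_exhaustive_scan():
    pos = [0.62, 0.55, 0.71, 0.40, 0.66]
    neg = [0.30, 0.45, 0.58, 0.25, 0.51]
    for level in (0.6, 0.8, 0.95):
        r = sensitivity_at_specificity(pos, neg, spec_level=level, n_boot=0)
        assert r.point == exhaustive_sens_at_spec(pos, neg, level)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_sens_oracle_and_level_monotonicity_property(seed):
    rng = np.random.default_rng(seed)
    pos = np.round(rng.random(rng.integers(3, 11)), 2)
    neg = np.round(rng.random(rng.integers(5, 11)), 2)
    r90 = sensitivity_at_specificity(pos, neg, spec_level=0.90, n_boot=0)
    r95 = sensitivity_at_specificity(pos, neg, spec_level=0.95, n_boot=0)
    assert r90.point == exhaustive_sens_at_spec(pos, neg, 0.90)
    assert r95.point == exhaustive_sens_at_spec(pos, neg, 0.95)
    assert r95.point <= r90.point  # tighter specificity cannot gain sensitivity
    assert r90.achieved_specificity >= 0.90
    assert r95.achieved_specificity >= 0.95


def test_bootstrap_reproducible_under_seed():
    rng = np.random.default_rng(5)
    pos, neg = rng.beta(5, 3, 40), rng.beta(2, 10, 40)
    a = sensitivity_at_specificity(pos, neg, n_boot=300, seed=11)
    b = sensitivity_at_specificity(pos, neg, n_boot=300, seed=11)
    assert (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)
    assert a.ci_lo <= a.point <= a.ci_hi


def test_too_few_negatives_rejected():
    with pytest.raises(DataError, match="negatives"):
        sensitivity_at_specificity([0.9, 0.8], [0.1, 0.2], n_boot=0)


def test_analyzer_table_and_report_format():
    rng = np.random.default_rng(9)
    import pandas as pd
    X = pd.DataFrame({
        "mk_hyper": np.concatenate([rng.beta(6, 3, 25), rng.beta(2, 12, 25)]),
        "mk_hypo": np.concatenate([rng.beta(2, 12, 25), rng.beta(6, 3, 25)]),
    }, index=[f"s{i}" for i in range(50)])
    y = np.array([1] * 25 + [0] * 25)
    an = MarkerRocAnalyzer(spec_levels=(0.90, 0.95), n_boot=100, seed=2).fit(X, y)
    t = an.table_
    assert set(t["direction"]) == {"hyper", "hypo"}
    assert ((t["auc"] >= 0.5) & (t["auc"] <= 1.0)).all()
    assert (t["sens_at_95"] <= t["sens_at_90"]).all()
    # report string in percent "point [lo,hi]" form
    s = an.results_["mk_hyper"].format_sensitivity(0.95)
    assert "[" in s and "," in s and float(s.split()[0]) <= 100.0


def test_analyzer_honours_declared_directions():
    rng = np.random.default_rng(4)
    import pandas as pd
    X = pd.DataFrame({"m": np.concatenate([rng.beta(2, 12, 20), rng.beta(6, 3, 20)])})
    y = np.array([1] * 20 + [0] * 20)
    an = MarkerRocAnalyzer(n_boot=0, directions={"m": "hypo"}).fit(X, y)
    assert an.results_["m"].direction == "hypo"
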