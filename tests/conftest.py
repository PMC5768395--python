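import numpy as np
import pandas as pd
import pytest

from ctcfmeth import SampleMeta, SimConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact simulated study shared by read-only tests."""
    return simulate_study(SimConfig(
        n_normal=30,
        n_tumor_by_stage={"adenoma": 12, "I": 8, "II": 12, "III": 8},
        n_sites=8, n_hyper=4, n_hypo=2,
        units_per_site=(2, 3),
        missing_rate=0.05,
        seed=11,
    ))


def make_meta(n_normal: int, n_tumor: int, stages=None) -> SampleMeta:
    """Metadata with n_normal normals and n_tumor tumors (stage II default)."""
    rows = [(f"N{i}", "normal", "none", None) for i in range(n_normal)]
    stages = stages or ["II"] * n_tumor
    rows += [(f"T{i}", "tumor", stages[i], None) for i in range(n_tumor)]
    return SampleMeta(pd.DataFrame(
        rows, columns=["sample_id", "class", "stage", "pair_id"]))


def separated_matrix(n_normal=20, n_tumor=20, n_sites=6, seed=0,
                     contaminated=0):
    """Well-separated two-class site-level frame for clustering tests.

    ``contaminated`` tumors are drawn from the normal distribution — the
    planted misassignments a clustering should reproduce.
    """
    rng = np.random.default_rng(seed)
    cols = [f"S{j}" for j in range(n_sites)]
    normal = rng.beta(1.5, 28.0, size=(n_normal, n_sites))
    tumor = rng.beta(10.0, 4.0, size=(n_tumor, n_sites))
    if contaminated:
        tumor[:contaminated] = rng.beta(1.5, 28.0, size=(contaminated, n_sites))
    values = np.vstack([normal, tumor])
    idx = [f"N{i}" for i in range(n_normal)] + [f"T{i}" for i in range(n_tumor)]
    df = pd.DataFrame(values, index=idx, columns=cols)
    meta = make_meta(n_normal, n_tumor)
    return df, meta
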