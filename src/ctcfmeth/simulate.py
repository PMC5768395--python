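"""Synthetic methylation studies with known ground truth.

The real tissue data behind this kind of biomarker screen are rarely
deposited, so every downstream stage is exercised against simulated studies
whose discriminative structure is known analytically.

Model
-----
Each CTCF-binding site ``k`` carries two Beta distributions over methylation
proportion — one for normal tissue, one for tumor tissue.  A site is

* *hyper*: tumor distribution shifted above normal,
* *hypo*: tumor shifted below normal,
* *null*: the two distributions identical.

Per sample a site-level value ``x`` is drawn from the class distribution.
Each CpG unit ``u`` of the site reports a perturbed copy on the logit scale::

    value = expit( lam_u * (logit(x) - z0) + z0 + delta_u + eps )

where ``z0`` anchors the normal-class mean, ``delta_u ~ N(0, jitter)`` is a
fixed per-unit level offset, ``eps ~ N(0, noise)`` is per-measurement noise,
and ``lam_u`` (default 1) attenuates the class signal so that one unit of a
site can be planted as the strongest — exercising representative-unit
selection.  Entries are masked missing completely at random.

The ground truth records, per site, the *analytic* AUC ``P(tumor more
tumor-like than normal)`` obtained by numerical integration of the two Beta
densities; for hypo sites the orientation is flipped so the truth AUC is
always >= 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, stats
from scipy.special import expit, logit

from .errors import ConfigError
from .io import MethylationMatrix, SampleMeta, SiteAnnotation

STAGE_ORDER = ("adenoma", "I", "II", "III")

_LOGIT_EPS = 1e-9


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def _default_stage_counts() -> dict[str, int]:
    # cohort layout of the emulated study: 84 normals vs 295 tumors
    return {"adenoma": 108, "I": 39, "II": 101, "III": 47}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated methylation study.

    Defaults emulate the reference cohort: 84 normal vs 295 tumor samples
    (adenoma 108, stage I 39, II 101, III 47), 23 informative sites of which
    16 are hypermethylated and 7 hypomethylated in tumors, 2-5 CpG units per
    site, 5% missing data, and 84 matched normal-tumor pairs.  Per-site Beta
    parameters default to a calibration whose analytic AUCs span roughly
    0.85-0.99.
    """

    n_normal: int = 84
    n_tumor_by_stage: Mapping[str, int] = field(default_factory=_default_stage_counts)
    n_sites: int = 23
    units_per_site: tuple[int, int] = (2, 5)
    n_hyper: int = 16
    n_hypo: int = 7
    beta_params_normal: Sequence[tuple[float, float]] | None = None
    beta_params_tumor: Sequence[tuple[float, float]] | None = None
    missing_rate: float = 0.05
    pairing_fraction: float = 84 / 295
    unit_jitter_sd: float = 0.2
    unit_noise_sd: float = 0.15
    unit_attenuation: Mapping[int, Sequence[float]] | None = None
    stage_shift: Mapping[str, float] | None = None
    seed: int = 0

    @property
    def n_tumor(self) -> int:
        return int(sum(self.n_tumor_by_stage.values()))

    def validate(self) -> None:
        if self.n_normal <= 0 or self.n_tumor <= 0:
            raise ConfigError("sample counts must be positive")
        if any(n < 0 for n in self.n_tumor_by_stage.values()):
            raise ConfigError("per-stage tumor counts must be non-negative")
        if self.n_sites <= 0:
            raise ConfigError("n_sites must be positive")
        if self.n_hyper + self.n_hypo > self.n_sites:
            raise ConfigError("n_hyper + n_hypo exceeds n_sites")
        if not 0 <= self.missing_rate < 1:
            raise ConfigError("missing_rate must lie in [0, 1)")
        if not 0 <= self.pairing_fraction <= 1:
            raise ConfigError("pairing_fraction must lie in [0, 1]")
        lo, hi = self.units_per_site
        if lo < 1 or hi < lo:
            raise ConfigError("units_per_site must be a (min, max) range with min >= 1")
        if self.unit_jitter_sd < 0 or self.unit_noise_sd < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        for params in (self.beta_params_normal, self.beta_params_tumor):
            if params is not None:
                if len(params) != self.n_sites:
                    raise ConfigError("per-site Beta parameters must cover every site")
                if any(a <= 0 or b <= 0 for a, b in params):
                    raise ConfigError("Beta shape parameters must be positive")


def default_beta_params(
    n_sites: int, n_hyper: int, n_hypo: int
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Per-site Beta shape pairs for (normal, tumor) classes.

    Hyper sites keep normal tissue at low methylation (mean 0.08,
    concentration 20) and ramp the tumor mean from 0.28 to 0.55 at
    concentration 5; hypo sites mirror this with normal tissue ramping from
    0.32 to 0.60 and tumors at mean 0.12.  Null sites share one
    distribution.  The resulting analytic AUCs span ~0.85-0.99, the range a
    strong single-locus methylation marker shows.
    """
    normal: list[tuple[float, float]] = []
    tumor: list[tuple[float, float]] = []
    hyper_means = np.linspace(0.28, 0.55, n_hyper) if n_hyper else []
    hypo_means = np.linspace(0.32, 0.60, n_hypo) if n_hypo else []
    for m in hyper_means:
        normal.append((0.08 * 20, 0.92 * 20))
        tumor.append((float(m) * 5, (1 - float(m)) * 5))
    for m in hypo_means:
        normal.append((float(m) * 8, (1 - float(m)) * 8))
        tumor.append((0.12 * 6, 0.88 * 6))
    for _ in range(n_sites - n_hyper - n_hypo):
        normal.append((2.0, 18.0))
        tumor.append((2.0, 18.0))
    return normal, tumor


def hrm_separable_beta_params(
    n_sites: int, n_hyper: int, n_hypo: int
) -> tuple[list[tuple[float, float]], list[tuple[float, float]]]:
    """Beta calibration keeping the two classes in different dilution bins.

    The melting-assay standards quantise methylation into [0-1%), [1-10%)
    and [10-100%] intervals, so a site is cleanly triaged only when normal
    and tumor tissue fall on opposite sides of a standard.  Here hyper sites
    put normal tissue at mean ~0.03 (below the 10% standard with
    probability ~0.96) and tumors at mean 0.5; hypo sites mirror this.
    Null sites straddle the 10% standard (mean 0.1), which is exactly the
    regime where pairs tie.  Use for studies feeding the melting-curve
    triage; the default calibration instead spreads effect sizes for the
    quantitative stages.
    """
    normal: list[tuple[float, float]] = []
    tumor: list[tuple[float, float]] = []
    for _ in range(n_hyper):
        normal.append((1.0, 30.0))
        tumor.append((2.5, 2.5))
    for _ in range(n_hypo):
        normal.append((2.5, 2.5))
        tumor.append((1.0, 30.0))
    for _ in range(n_sites - n_hyper - n_hypo):
        normal.append((2.0, 18.0))
        tumor.append((2.0, 18.0))
    return normal, tumor


def analytic_auc(params_pos: tuple[float, float],
                 params_neg: tuple[float, float]) -> float:
    """P(X_pos > X_neg) for independent Beta variates, by quadrature.

    Ties have probability zero for continuous distributions, so this is the
    population AUC of the marker.  Computed as the integral of
    ``pdf_pos(x) * cdf_neg(x)`` over [0, 1].
    """
    a1, b1 = params_pos
    a0, b0 = params_neg
    if (a1, b1) == (a0, b0):
        return 0.5
    val, _ = integrate.quad(
        lambda x: stats.beta.pdf(x, a1, b1) * stats.beta.cdf(x, a0, b0),
        0.0, 1.0, limit=200,
    )
    return float(min(max(val, 0.0), 1.0))


# ---------------------------------------------------------------------------
# study simulation
# ---------------------------------------------------------------------------


@dataclass
class StudyTruth:
    """Ground truth of a simulated study.

    ``sites`` has one row per site (direction, Beta parameters, oriented
    analytic AUC); ``units`` one row per CpG unit (jitter, attenuation);
    ``site_values`` holds the latent per-sample site-level methylation draws
    before unit perturbation and masking.
    """

    sites: pd.DataFrame
    units: pd.DataFrame
    site_values: pd.DataFrame


@dataclass
class SimulatedStudy:
    matrix: MethylationMatrix
    meta: SampleMeta
    annotation: SiteAnnotation
    truth: StudyTruth
    config: SimConfig


def _make_meta(config: SimConfig, rng: np.random.Generator) -> SampleMeta:
    rows = []
    for i in range(config.n_normal):
        rows.append((f"N{i + 1:03d}", "normal", "none", None))
    t = 0
    for stage in STAGE_ORDER:
        for _ in range(int(config.n_tumor_by_stage.get(stage, 0))):
            t += 1
            rows.append((f"T{t:03d}", "tumor", stage, None))
    meta = pd.DataFrame(rows, columns=["sample_id", "class", "stage", "pair_id"])

    n_pairs = min(config.n_normal,
                  int(round(config.pairing_fraction * config.n_tumor)))
    tumor_idx = meta.index[meta["class"] == "tumor"].to_numpy()
    normal_idx = meta.index[meta["class"] == "normal"].to_numpy()
    chosen_t = rng.choice(tumor_idx, size=n_pairs, replace=False)
    for p, (ni, ti) in enumerate(zip(normal_idx[:n_pairs], chosen_t), start=1):
        meta.loc[[ni, ti], "pair_id"] = f"P{p:03d}"
    return SampleMeta(meta)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Draw a complete simulated study (matrix, metadata, annotation, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    bp_normal, bp_tumor = config.beta_params_normal, config.beta_params_tumor
    if bp_normal is None or bp_tumor is None:
        dn, dt = default_beta_params(config.n_sites, config.n_hyper, config.n_hypo)
        bp_normal = bp_normal if bp_normal is not None else dn
        bp_tumor = bp_tumor if bp_tumor is not None else dt

    directions = (["hyper"] * config.n_hyper + ["hypo"] * config.n_hypo
                  + ["null"] * (config.n_sites - config.n_hyper - config.n_hypo))
    site_ids = [f"CTCF_{i + 1:02d}" for i in range(config.n_sites)]

    meta = _make_meta(config, rng)
    sample_ids = meta.sample_ids
    is_tumor = (meta.classes_for(sample_ids) == "tumor").to_numpy()
    stages = meta.stages_for(sample_ids).to_numpy()
    n_samples = len(sample_ids)

    lo, hi = config.units_per_site
    units_per_site = rng.integers(lo, hi + 1, size=config.n_sites)

    site_rows, unit_rows = [], []
    unit_cols: dict[str, np.ndarray] = {}
    site_vals: dict[str, np.ndarray] = {}
    unit_map: dict[str, str] = {}

    for k, site in enumerate(site_ids):
        a0, b0 = bp_normal[k]
        a1, b1 = bp_tumor[k]
        direction = directions[k]

        x = np.where(is_tumor, rng.beta(a1, b1, size=n_samples),
                     rng.beta(a0, b0, size=n_samples))
        z = logit(np.clip(x, _LOGIT_EPS, 1 - _LOGIT_EPS))
        if config.stage_shift:
            for stage, shift in config.stage_shift.items():
                z = np.where(is_tumor & (stages == stage), z + shift, z)
        z0 = logit(np.clip(a0 / (a0 + b0), _LOGIT_EPS, 1 - _LOGIT_EPS))

        n_units = int(units_per_site[k])
        atten = np.ones(n_units)
        if config.unit_attenuation and k in config.unit_attenuation:
            given = np.asarray(config.unit_attenuation[k], dtype=float)
            atten[: len(given)] = given[:n_units]
        jitter = rng.normal(0.0, config.unit_jitter_sd, size=n_units)

        for j in range(n_units):
            uid = f"{site}.u{j + 1}"
            eps = rng.normal(0.0, config.unit_noise_sd, size=n_samples) \
                if config.unit_noise_sd > 0 else 0.0
            vals = expit(atten[j] * (z - z0) + z0 + jitter[j] + eps)
            unit_cols[uid] = vals
            unit_map[uid] = site
            unit_rows.append((uid, site, atten[j], jitter[j]))

        auc_raw = analytic_auc((a1, b1), (a0, b0))
        oriented = 1.0 - auc_raw if direction == "hypo" else auc_raw
        site_vals[site] = x
        site_rows.append((site, direction, a0, b0, a1, b1, oriented))

    values = pd.DataFrame(unit_cols, index=pd.Index(sample_ids, name="sample_id"))
    if config.missing_rate > 0:
        mask = rng.random(values.shape) < config.missing_rate
        values = values.mask(mask)
    matrix = MethylationMatrix(values)

    sites = pd.DataFrame({
        "site_id": site_ids,
        "chrom": "chr1",
        "start": [10_000 * (k + 1) for k in range(config.n_sites)],
        "end": [10_000 * (k + 1) + 30 for k in range(config.n_sites)],
        "direction": [d if d in ("hyper", "hypo") else "auto" for d in directions],
    })
    annotation = SiteAnnotation(sites, unit_map)

    truth = StudyTruth(
        sites=pd.DataFrame(
            site_rows,
            columns=["site_id", "direction", "alpha_normal", "beta_normal",
                     "alpha_tumor", "beta_tumor", "analytic_auc"],
        ).set_index("site_id"),
        units=pd.DataFrame(
            unit_rows, columns=["unit_id", "site_id", "attenuation", "jitter"]
        ).set_index("unit_id"),
        site_values=pd.DataFrame(site_vals, index=pd.Index(sample_ids, name="sample_id")),
    )
    return SimulatedStudy(matrix=matrix, meta=meta, annotation=annotation,
                          truth=truth, config=config)


# ---------------------------------------------------------------------------
# HRM observations
# ---------------------------------------------------------------------------

HRM_STANDARD_RATIOS = (0.0, 0.01, 0.10, 1.00)


def melt_statistic(methylation) -> np.ndarray | float:
    """Map a methylation proportion to the simulated melt-shift scalar.

    ``log10(1 + 99 m)`` — strictly increasing, 0 at fully unmethylated and
    2 at fully methylated, with the compressed high end a melting-profile
    shift shows.  Any strictly monotone map works for interval binning; the
    log form keeps the 1% standard well separated from 0%.
    """
    return np.log10(1.0 + 99.0 * np.asarray(methylation, dtype=float))


def simulate_hrm_observations(
    study: SimulatedStudy, noise_sd: float = 0.0, seed: int = 0
) -> tuple[pd.DataFrame, "StandardCurve"]:
    """Melt-shift observations per sample x site, plus the dilution standards.

    The statistic is the monotone map of the sample's latent site-level
    methylation plus Gaussian noise; standards at methylated-DNA ratios
    0/1/10/100% are emitted noiselessly.
    """
    from .hrm import StandardCurve  # local import to avoid a cycle

    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    sv = study.truth.site_values
    stat = melt_statistic(sv.to_numpy())
    if noise_sd > 0:
        stat = stat + rng.normal(0.0, noise_sd, size=stat.shape)
    obs = pd.DataFrame(stat, index=sv.index, columns=sv.columns) \
        .stack().rename("melt_statistic").reset_index() \
        .rename(columns={"level_1": "site_id"})
    curve = StandardCurve(
        ratios=HRM_STANDARD_RATIOS,
        statistics=tuple(float(melt_statistic(r)) for r in HRM_STANDARD_RATIOS),
    )
    return obs, curve


# ---------------------------------------------------------------------------
# cell-line occupancy/methylation tables for candidate discovery
# ---------------------------------------------------------------------------


@dataclass
class OccupancyStudy:
    """Per-site x cell-line occupancy and methylation table with truth."""

    table: pd.DataFrame  # site_id, cell_line, class, occupied, methylation
    true_candidates: list[str]


def simulate_celllines(
    n_sites: int,
    n_immortal: int = 6,
    n_normal_lines: int = 7,
    n_true_candidates: int = 0,
    seed: int = 0,
    nonspecific_fraction: float = 0.0,
) -> OccupancyStudy:
    """Simulate the cell-line panel feeding candidate discovery.

    True-candidate sites are occupied in every immortal line and in no
    normal line, with methylation low where occupied and high where not.
    Null sites keep an immortal-specific occupancy pattern (so they reach
    the association test) but methylation independent of occupancy;
    ``nonspecific_fraction`` of null sites are additionally occupied in a
    normal line and must fall to the specificity prefilter.
    """
    if n_true_candidates > n_sites:
        raise ConfigError("n_true_candidates exceeds n_sites")
    if not 0 <= nonspecific_fraction <= 1:
        raise ConfigError("nonspecific_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    lines = [(f"IM{i + 1}", "immortal") for i in range(n_immortal)] + \
            [(f"NL{i + 1}", "normal") for i in range(n_normal_lines)]
    n_null = n_sites - n_true_candidates
    n_nonspec = int(round(nonspecific_fraction * n_null))

    rows = []
    true_ids = []
    for k in range(n_sites):
        site = f"site_{k + 1:04d}"
        is_true = k < n_true_candidates
        nonspecific = (not is_true) and (k - n_true_candidates < n_nonspec)
        if is_true:
            true_ids.append(site)
            occ_immortal = np.ones(n_immortal, dtype=int)
        else:
            # 3-6 occupied immortal lines: keeps both groups large enough
            # that the exact rank-sum test can attain its nominal level
            n_occ = int(rng.integers(min(3, n_immortal), n_immortal + 1))
            occ_immortal = np.zeros(n_immortal, dtype=int)
            occ_immortal[rng.choice(n_immortal, size=n_occ, replace=False)] = 1
        occ_normal = np.zeros(n_normal_lines, dtype=int)
        if nonspecific:
            occ_normal[rng.integers(n_normal_lines)] = 1
        occupancy = np.concatenate([occ_immortal, occ_normal])
        if is_true:
            meth = np.where(occupancy == 1,
                            rng.beta(1.5, 15.0, size=len(lines)),
                            rng.beta(15.0, 1.5, size=len(lines)))
        else:
            meth = rng.beta(2.0, 2.0, size=len(lines))
        for (line, cls), occ, m in zip(lines, occupancy, meth):
            rows.append((site, line, cls, int(occ), float(m)))

    table = pd.DataFrame(
        rows, columns=["site_id", "cell_line", "class", "occupied", "methylation"]
    )
    return OccupancyStudy(table=table, true_candidates=true_ids)


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of ``config`` with a different seed (convenience for replicates)."""
    return replace(config, seed=seed)
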