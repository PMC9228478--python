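"""Synthetic twin cohorts with known variance structure.

Generates MZ/DZ twin families and a samples x metabolites panel whose latent
(pre-noise) values follow the classical twin decomposition

    y = beta_sex * sex + beta_age * age + a + c + d + e

where the within-pair correlations of the components are corr(a) = 1 (MZ) /
0.5 (DZ), corr(d) = 1 / 0.25, corr(c) = 1 and corr(e) = 0, and the component
variances are the per-metabolite fractions (A, C, D, E) of a unit latent
variance.  On top of the latent scale the generator layers every nuisance a
real urinary panel carries: a monotone lognormal raw scale, multiplicative
creatinine dilution, left-censoring at a limit of detection, item
missingness (completely at random), and pooled-QC replicate injections with
a controllable coefficient of variation.  Everything that is masked is also
recorded in a :class:`GroundTruth` so downstream stages can be tested
against the truth.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PLATFORMS = ("amine", "organic_acid", "steroid")

#: Default panel sizes: the post-QC panel of the motivating study
#: (56 amines, 20 organic acids, 10 steroid hormones).
DEFAULT_PANEL = {"amine": 56, "organic_acid": 20, "steroid": 10}


@dataclass
class SimulationSpec:
    """Ground-truth description of one synthetic twin cohort.

    Defaults reproduce the discovery-cohort conditions of the motivating
    study: 531 complete MZ pairs plus 6 MZ singletons and 114 complete DZ
    pairs plus 4 DZ singletons (1300 children), ages 5.7-12.9 years,
    48.2% girls.
    """

    n_mz_pairs: int = 531
    n_dz_pairs: int = 114
    n_mz_singletons: int = 6
    n_dz_singletons: int = 4
    n_metabolites: dict = field(default_factory=lambda: dict(DEFAULT_PANEL))
    #: (n_metabolites_total, 4) array of (A, C, D, E) fractions, or None to
    #: draw a panel-like mixture of ADE- and ACE-regime metabolites.
    var_fracs: np.ndarray | None = None
    beta_sex: float | np.ndarray = 0.1
    beta_age: float | np.ndarray = 0.05
    age_range: tuple = (5.7, 12.9)
    prop_female: float = 0.482
    creatinine_lognormal: tuple = (0.0, 0.5)
    raw_scale: float = 0.5
    lod_quantile: float = 0.0
    missing_rate: float = 0.0
    qc_cv_percent: float | np.ndarray = 8.0
    qc_interval: int = 10
    #: Probability that a DZ pair is opposite-sex is implied by independent
    #: per-twin sex draws; set same_sex_dz=True to force same-sex DZ pairs.
    same_sex_dz: bool = False
    seed: int = 0

    @property
    def n_metabolites_total(self) -> int:
        return int(sum(self.n_metabolites.values()))

    @property
    def n_children(self) -> int:
        return (
            2 * (self.n_mz_pairs + self.n_dz_pairs)
            + self.n_mz_singletons
            + self.n_dz_singletons
        )

    def validate(self) -> None:
        if self.var_fracs is not None:
            vf = np.asarray(self.var_fracs, dtype=float)
            if vf.shape != (self.n_metabolites_total, 4):
                raise ValueError(
                    f"var_fracs must have shape ({self.n_metabolites_total}, 4)"
                )
            if not np.allclose(vf.sum(axis=1), 1.0, atol=1e-8):
                raise ValueError("each (A, C, D, E) tuple must sum to 1")
            if np.any(vf[:, 1] * vf[:, 2] > 0):
                raise ValueError(
                    "C and D cannot both be nonzero for the same metabolite: "
                    "the ACDE model is not identified in the classical twin design"
                )
            if np.any(vf < -1e-12):
                raise ValueError("variance fractions must be nonnegative")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.lod_quantile < 1:
            raise ValueError("lod_quantile must be in [0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knew before masking."""

    var_fracs: pd.DataFrame        # metabolite x (A, C, D, E)
    beta_sex: pd.Series
    beta_age: pd.Series
    latent: pd.DataFrame           # samples x metabolites, pre-noise
    raw: pd.DataFrame              # samples x metabolites, pre-masking
    lod: pd.Series                 # per metabolite (NaN when no censoring)
    censored_mask: pd.DataFrame
    missing_mask: pd.DataFrame


@dataclass
class MetaboliteMatrix:
    """Samples x metabolites relative response ratios plus metadata.

    ``values`` holds NaN where an entry is missing or still censored;
    ``censored`` flags the entries that fell below the limit of detection
    (distinct from item missingness); ``meta`` carries one row per
    metabolite with columns ``platform`` and ``lod`` (NaN when unknown).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    censored: pd.DataFrame | None = None

    def __post_init__(self):
        if self.censored is None:
            self.censored = pd.DataFrame(
                False, index=self.values.index, columns=self.values.columns
            )
        unknown = set(self.meta["platform"]) - set(PLATFORMS)
        if unknown:
            raise ValueError(f"unknown platform label(s): {sorted(unknown)}")
        if not self.meta.index.equals(self.values.columns):
            raise ValueError("meta must be indexed by the value columns")
        with np.errstate(invalid="ignore"):
            if (self.values.to_numpy() < 0).any():
                raise ValueError("observed relative response ratios must be >= 0")

    def copy(self) -> "MetaboliteMatrix":
        return MetaboliteMatrix(
            self.values.copy(), self.meta.copy(), self.censored.copy()
        )

    @property
    def missing_rate(self) -> pd.Series:
        """Item missingness per metabolite (censored entries are not missing)."""
        na = self.values.isna() & ~self.censored
        return na.mean(axis=0)


def default_var_fracs(n_metabolites: int, rng: np.random.Generator) -> np.ndarray:
    """Draw a panel-like mixture of variance structures.

    80% of metabolites fall in the ADE regime (r_MZ > 2 r_DZ) and 20% in the
    ACE regime, echoing the 69/17 split observed on the real panel.  Twin
    correlations are drawn so all four components stay nonnegative:
    ADE needs r_MZ/4 <= r_DZ <= r_MZ/2, ACE needs r_DZ >= r_MZ/2.
    """
    out = np.zeros((n_metabolites, 4))
    is_ade = rng.random(n_metabolites) < 0.8
    r_mz = rng.uniform(0.4, 0.75, n_metabolites)
    for j in range(n_metabolites):
        if is_ade[j]:
            r_dz = rng.uniform(r_mz[j] / 4, r_mz[j] / 2 * 0.95)
            a = 4 * r_dz - r_mz[j]
            d = 2 * r_mz[j] - 4 * r_dz
            out[j] = (a, 0.0, d, 1 - r_mz[j])
        else:
            r_dz = rng.uniform(r_mz[j] / 2 * 1.05, r_mz[j] * 0.75)
            a = 2 * (r_mz[j] - r_dz)
            c = 2 * r_dz - r_mz[j]
            out[j] = (a, c, 0.0, 1 - r_mz[j])
    return out


def _metabolite_ids(n_metabolites: dict) -> tuple[list, list]:
    prefix = {"amine": "am", "organic_acid": "oa", "steroid": "st"}
    ids, platforms = [], []
    for plat in PLATFORMS:
        for j in range(n_metabolites.get(plat, 0)):
            ids.append(f"{prefix[plat]}{j + 1:03d}")
            platforms.append(plat)
    return ids, platforms


def _simulate_families(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    fam = 0

    def add_family(zygosity: str, n_twins: int):
        nonlocal fam
        fam += 1
        age = rng.uniform(*spec.age_range)
        if zygosity == "MZ" or spec.same_sex_dz:
            sexes = [rng.random() < spec.prop_female] * n_twins
        else:
            sexes = [rng.random() < spec.prop_female for _ in range(n_twins)]
        for order in range(1, n_twins + 1):
            rows.append(
                dict(
                    child_id=f"c{fam:04d}_{order}",
                    family_id=f"f{fam:04d}",
                    cohort="discovery",
                    zygosity=zygosity,
                    birth_order=order,
                    sex="female" if sexes[order - 1] else "male",
                    age=round(age, 2),
                )
            )

    for _ in range(spec.n_mz_pairs):
        add_family("MZ", 2)
    for _ in range(spec.n_mz_singletons):
        add_family("MZ", 1)
    for _ in range(spec.n_dz_pairs):
        add_family("DZ", 2)
    for _ in range(spec.n_dz_singletons):
        add_family("DZ", 1)

    cohort = pd.DataFrame(rows)
    mu, sigma = spec.creatinine_lognormal
    cohort["creatinine"] = rng.lognormal(mu, sigma, len(cohort))
    cohort["first_morning"] = True
    cohort["freeze_delay"] = np.round(rng.uniform(0.0, 1.5, len(cohort)), 2)
    cohort["urine_sufficient"] = True
    cohort["second_multiple"] = False
    cohort["duplicate_of_other_cohort"] = False
    return cohort


def _latent_components(
    spec: SimulationSpec, cohort: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Latent a+c+d+e for every child x metabolite, with twin correlations."""
    vf = spec.var_fracs
    if vf is None:
        vf = default_var_fracs(spec.n_metabolites_total, rng)
    vf = np.asarray(vf, dtype=float)
    n, m = len(cohort), spec.n_metabolites_total

    fam_codes, fam_index = pd.factorize(cohort["family_id"])
    n_fam = len(fam_index)
    is_mz = (
        cohort.drop_duplicates("family_id").set_index("family_id")["zygosity"]
        .reindex(fam_index)
        .eq("MZ")
        .to_numpy()
    )
    # within-pair correlation of each component, per family
    r_a = np.where(is_mz, 1.0, 0.5)[fam_codes]
    r_d = np.where(is_mz, 1.0, 0.25)[fam_codes]

    def correlated(r):
        # x_i = sqrt(r) * shared + sqrt(1-r) * own  ->  corr(x_1, x_2) = r
        shared = rng.standard_normal((n_fam, m))[fam_codes]
        own = rng.standard_normal((n, m))
        return np.sqrt(r)[:, None] * shared + np.sqrt(1 - r)[:, None] * own

    a = correlated(r_a)
    d = correlated(r_d)
    c = rng.standard_normal((n_fam, m))[fam_codes]
    e = rng.standard_normal((n, m))
    sd = np.sqrt(vf)  # columns A, C, D, E
    latent = a * sd[:, 0] + c * sd[:, 1] + d * sd[:, 2] + e * sd[:, 3]
    return latent, vf


def simulate_cohort(
    spec: SimulationSpec,
) -> tuple[pd.DataFrame, MetaboliteMatrix, pd.DataFrame, GroundTruth]:
    """Generate one cohort: roster, metabolite panel, QC injections, truth.

    Returns ``(cohort, matrix, qc, truth)`` where ``qc`` is an
    injections x metabolites table of pooled-QC replicate measurements.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    cohort = _simulate_families(spec, rng)
    ids, platforms = _metabolite_ids(spec.n_metabolites)
    latent, vf = _latent_components(spec, cohort, rng)

    sex = cohort["sex"].eq("female").to_numpy(dtype=float)
    age = cohort["age"].to_numpy()
    beta_sex = np.broadcast_to(
        np.asarray(spec.beta_sex, dtype=float), (spec.n_metabolites_total,)
    )
    beta_age = np.broadcast_to(
        np.asarray(spec.beta_age, dtype=float), (spec.n_metabolites_total,)
    )
    latent = latent + sex[:, None] * beta_sex + age[:, None] * beta_age

    # monotone raw scale, then multiplicative urine-dilution (creatinine)
    raw = np.exp(spec.raw_scale * latent) * cohort["creatinine"].to_numpy()[:, None]

    sample_ids = cohort["child_id"].to_numpy()
    raw_df = pd.DataFrame(raw, index=sample_ids, columns=ids)
    latent_df = pd.DataFrame(latent, index=sample_ids, columns=ids)

    # left-censoring at the per-metabolite LOD quantile
    if spec.lod_quantile > 0:
        lod = raw_df.quantile(spec.lod_quantile)
        censored = raw_df.lt(lod, axis=1)
    else:
        lod = pd.Series(np.nan, index=ids)
        censored = pd.DataFrame(False, index=sample_ids, columns=ids)

    missing = pd.DataFrame(
        rng.random(raw_df.shape) < spec.missing_rate, index=sample_ids, columns=ids
    )
    values = raw_df.mask(censored | missing)

    meta = pd.DataFrame({"platform": platforms, "lod": lod}, index=pd.Index(ids, name="metabolite"))
    matrix = MetaboliteMatrix(values, meta, censored & ~missing)

    # pooled-QC replicate injections around the pooled mean with stated CV
    n_inj = max(2, math.ceil(len(cohort) / spec.qc_interval))
    cv = np.broadcast_to(
        np.asarray(spec.qc_cv_percent, dtype=float), (spec.n_metabolites_total,)
    )
    pooled = raw_df.mean(axis=0).to_numpy()
    qc_vals = np.abs(
        rng.normal(pooled, (cv / 100.0) * pooled, size=(n_inj, spec.n_metabolites_total))
    )
    qc = pd.DataFrame(
        qc_vals, index=[f"qc{k + 1:03d}" for k in range(n_inj)], columns=ids
    )

    truth = GroundTruth(
        var_fracs=pd.DataFrame(vf, index=ids, columns=["A", "C", "D", "E"]),
        beta_sex=pd.Series(beta_sex, index=ids),
        beta_age=pd.Series(beta_age, index=ids),
        latent=latent_df,
        raw=raw_df,
        lod=lod,
        censored_mask=censored & ~missing,
        missing_mask=missing,
    )
    return cohort, matrix, qc, truth


# ---------------------------------------------------------------------------
# Deterministic worked-example fixtures
# ---------------------------------------------------------------------------

#: Exclusion-flag counts of the discovery collection round.
DISCOVERY_FLAG_COUNTS = {
    "insufficient_urine": 2,
    "not_first_morning": 13,
    "late_freeze": 25,
    "second_multiple": 22,
}
#: Replication round: 1 cross-cohort duplicate, 3 not first-morning,
#: 3 frozen later than 2 h; 179 clean.
REPLICATION_FLAG_COUNTS = {
    "cross_cohort_duplicate": 1,
    "not_first_morning": 3,
    "late_freeze": 3,
}


def make_paper_fixture_roster() -> pd.DataFrame:
    """Deterministic rosters mirroring the published collection rounds.

    Discovery: 1362 children of whom 2 had insufficient urine, 13 were not
    first-morning samples, 25 were frozen later than 2 h after collection,
    and 22 were the second multiple pair in their family; the remaining 1300
    are clean (531 MZ pairs + 6 MZ singletons + 114 DZ pairs + 4 DZ
    singletons).  Replication: 186 children, 179 clean.  Returned as one
    table with a ``cohort`` column.
    """
    rng = np.random.default_rng(20220522)  # fixed: fixture is deterministic

    spec = SimulationSpec(seed=20220522)
    clean = _simulate_families(spec, rng)  # 1300 clean discovery children

    rows = []
    fam = 2000
    def flagged_child(cohort_label, **flags):
        nonlocal fam
        fam += 1
        base = dict(
            child_id=f"x{fam:04d}_1",
            family_id=f"x{fam:04d}",
            cohort=cohort_label,
            zygosity="MZ" if fam % 2 else "DZ",
            birth_order=1,
            sex="female" if fam % 2 else "male",
            age=round(float(rng.uniform(5.7, 12.9)), 2),
            creatinine=round(float(rng.lognormal(0, 0.5)), 3),
            first_morning=True,
            freeze_delay=0.5,
            urine_sufficient=True,
            second_multiple=False,
            duplicate_of_other_cohort=False,
        )
        base.update(flags)
        rows.append(base)

    for _ in range(DISCOVERY_FLAG_COUNTS["insufficient_urine"]):
        flagged_child("discovery", urine_sufficient=False)
    for _ in range(DISCOVERY_FLAG_COUNTS["not_first_morning"]):
        flagged_child("discovery", first_morning=False)
    for _ in range(DISCOVERY_FLAG_COUNTS["late_freeze"]):
        flagged_child("discovery", freeze_delay=3.0)
    for _ in range(DISCOVERY_FLAG_COUNTS["second_multiple"]):
        flagged_child("discovery", second_multiple=True)

    # replication cohort: unrelated children (zygosity not assessed)
    rep_rows = []
    for k in range(179):
        rep_rows.append(
            dict(
                child_id=f"r{k + 1:04d}_1",
                family_id=f"r{k + 1:04d}",
                cohort="replication",
                zygosity="NA",
                birth_order=1,
                sex="female" if rng.random() < 0.251 else "male",
                age=round(float(rng.uniform(6.3, 13.4)), 2),
                creatinine=round(float(rng.lognormal(0, 0.5)), 3),
                first_morning=True,
                freeze_delay=0.5,
                urine_sufficient=True,
                second_multiple=False,
                duplicate_of_other_cohort=False,
            )
        )
    for _ in range(REPLICATION_FLAG_COUNTS["cross_cohort_duplicate"]):
        flagged_child("replication", duplicate_of_other_cohort=True)
    for _ in range(REPLICATION_FLAG_COUNTS["not_first_morning"]):
        flagged_child("replication", first_morning=False)
    for _ in range(REPLICATION_FLAG_COUNTS["late_freeze"]):
        flagged_child("replication", freeze_delay=2.5)

    roster = pd.concat(
        [clean, pd.DataFrame(rows), pd.DataFrame(rep_rows)], ignore_index=True
    )
    return roster


def make_paper_fixture_panel(
    n_samples: int = 120, seed: int = 20220522
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Metabolite panel + QC fixture reproducing the published QC attrition.

    66 amines, 21 organic acids and 13 steroids, of which exactly 4 amines
    exceed 10% item missingness and, among the rest, 6 amines, 1 organic
    acid and 3 steroids have pooled-QC RSD >= 15%; the surviving panel is
    56 + 20 + 10 = 86 metabolites.
    """
    rng = np.random.default_rng(seed)
    counts = {"amine": 66, "organic_acid": 21, "steroid": 13}
    ids, platforms = _metabolite_ids(counts)
    values = pd.DataFrame(
        rng.lognormal(0.0, 0.4, size=(n_samples, len(ids))),
        index=[f"s{k + 1:04d}" for k in range(n_samples)],
        columns=ids,
    )
    high_missing = [f"am{j:03d}" for j in range(1, 5)]          # 4 amines
    high_rsd = (
        [f"am{j:03d}" for j in range(5, 11)]                    # 6 amines
        + ["oa001"]                                             # 1 organic acid
        + [f"st{j:03d}" for j in range(1, 4)]                   # 3 steroids
    )
    n_miss = int(round(0.2 * n_samples))
    for mid in high_missing:
        drop = rng.choice(n_samples, size=n_miss, replace=False)
        values.iloc[drop, values.columns.get_loc(mid)] = np.nan

    meta = pd.DataFrame(
        {"platform": platforms, "lod": np.nan}, index=pd.Index(ids, name="metabolite")
    )
    matrix = MetaboliteMatrix(values, meta)

    n_inj = 12
    pooled = np.nanmean(values.to_numpy(), axis=0)
    cv = np.where(np.isin(ids, high_rsd), 25.0, 5.0)
    qc = np.abs(rng.normal(pooled, (cv / 100.0) * pooled, size=(n_inj, len(ids))))
    # guarantee the intended side of the 15% threshold regardless of draw
    from .preprocess import compute_rsdqc  # local import to avoid cycle

    qc_df = pd.DataFrame(qc, index=[f"qc{k + 1:03d}" for k in range(n_inj)], columns=ids)
    rsd = compute_rsdqc(qc_df)
    for mid in ids:
        if mid in high_rsd and rsd[mid] < 15:
            qc_df[mid] *= rng.normal(1.0, 0.3, n_inj) ** 2
        elif mid not in high_rsd and rsd[mid] >= 15:
            qc_df[mid] = pooled[ids.index(mid)] * (
                1 + 0.02 * rng.standard_normal(n_inj)
            )
    return matrix, qc_df


def exact_moment_pairs(
    n: int, v: float, cov: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n pairs whose ML sample moments are exactly (0, v, cov).

    The draws are empirically whitened (mean zero, identity covariance with
    the 1/n convention) and recolored, so a constrained ML fit of the
    common-variance bivariate normal recovers (v, cov) exactly — the
    construction behind closed-form equivalence checks.
    """
    z = rng.standard_normal((n, 2))
    z = z - z.mean(axis=0)
    S = z.T @ z / n
    z = z @ np.linalg.inv(np.linalg.cholesky(S)).T
    L = np.linalg.cholesky(np.array([[v, cov], [cov, v]]))
    return z @ L.T


def simulate_paired(
    n_mz: int,
    n_dz: int,
    var_fracs=(0.5, 0.1, 0.0, 0.4),
    beta_sex: float = 0.0,
    beta_age: float = 0.0,
    age_range: tuple = (5.7, 12.9),
    prop_female: float = 0.482,
    n_mz_singletons: int = 0,
    n_dz_singletons: int = 0,
    rng: np.random.Generator | int = 0,
):
    """Directly simulate one metabolite's family-arranged values.

    Bypasses the roster/panel machinery for replicate-based calibration
    studies: draws complete MZ/DZ pairs (plus optional singletons) from the
    bivariate normal implied by the (A, C, D, E) fractions and returns a
    :class:`twinmetab.twin.PairedData`.
    """
    from .twin import PairedData  # simulate does not otherwise depend on twin

    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    A, C, D, E = var_fracs
    if C * D > 0:
        raise ValueError("C and D cannot both be nonzero (ACDE not identified)")
    r = {"MZ": A + C + D, "DZ": 0.5 * A + C + 0.25 * D}

    def draws(n, zyg):
        L = np.linalg.cholesky([[1.0, r[zyg]], [r[zyg], 1.0]])
        y = rng.standard_normal((n, 2)) @ L.T
        if zyg == "MZ":
            sex = np.repeat(
                (rng.random(n) < prop_female).astype(float)[:, None], 2, axis=1
            )
        else:
            sex = (rng.random((n, 2)) < prop_female).astype(float)
        age = rng.uniform(*age_range, n)
        y = y + beta_sex * sex + beta_age * age[:, None]
        return y, sex, age

    mz_y, mz_sex, mz_age = draws(n_mz, "MZ")
    dz_y, dz_sex, dz_age = draws(n_dz, "DZ")
    n_s = n_mz_singletons + n_dz_singletons
    s_sex = (rng.random(n_s) < prop_female).astype(float)
    s_age = rng.uniform(*age_range, n_s)
    s_y = rng.standard_normal(n_s) + beta_sex * s_sex + beta_age * s_age
    s_is_mz = np.repeat([True, False], [n_mz_singletons, n_dz_singletons])
    return PairedData(
        mz_y, mz_sex, mz_age, dz_y, dz_sex, dz_age, s_y, s_sex, s_age, s_is_mz
    )


#: Published per-band counts of MZ correlations (amine, organic acid, steroid).
RELIABILITY_BAND_COUNTS = {
    "excellent": {"amine": 1, "organic_acid": 0, "steroid": 4},
    "good": {"amine": 8, "organic_acid": 3, "steroid": 0},
    "moderate": {"amine": 43, "organic_acid": 13, "steroid": 6},
    "indeterminate": {"amine": 4, "organic_acid": 4, "steroid": 0},
}


def make_paper_fixture_correlations(seed: int = 20220522) -> pd.DataFrame:
    """86 MZ correlations drawn inside the published reliability bands.

    Per-platform band counts follow the published tallies (5 excellent,
    11 good, 62 moderate, 8 indeterminate).  Returns columns
    ``metabolite``, ``platform``, ``r_mz``.
    """
    rng = np.random.default_rng(seed)
    band_range = {
        "excellent": (0.75, 0.81),
        "good": (0.60, 0.74),
        "moderate": (0.40, 0.59),
        "indeterminate": (0.10, 0.39),
    }
    rows = []
    k = 0
    for band, per_plat in RELIABILITY_BAND_COUNTS.items():
        lo, hi = band_range[band]
        for plat, n in per_plat.items():
            for _ in range(n):
                k += 1
                rows.append(
                    dict(
                        metabolite=f"m{k:03d}",
                        platform=plat,
                        r_mz=round(float(rng.uniform(lo, hi)), 3),
                    )
                )
    return pd.DataFrame(rows)
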