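"""Classical twin design by raw-data (full-information) maximum likelihood.

Each family contributes the multivariate-normal log-density of its observed
sub-vector: complete pairs a bivariate density with equal means and
variances across birth order and zygosity, incomplete pairs (singletons)
the univariate marginal.  The saturated model estimates a common variance
and one covariance per zygosity; likelihood-ratio tests against reduced
mean models select the sex/age covariates.  Variance components are then
estimated under the expected twin covariances

    ADE:  cov_MZ = A + D,      cov_DZ = A/2 + D/4
    ACE:  cov_MZ = A + C,      cov_DZ = A/2 + C

with the ADE model chosen iff r_MZ > 2 r_DZ (ties to ACE).  Components are
parameterized as unconstrained reals, so negative estimates are allowed;
only total-variance positivity and a proper implied correlation are
enforced during the search.  Confidence intervals for standardized shares
are profile-likelihood intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import chi2

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_BIG = 1e12

COVARIATE_SETS = (("sex", "age"), ("sex",), ("age",), ())


# ---------------------------------------------------------------------------
# data layout
# ---------------------------------------------------------------------------

@dataclass
class PairedData:
    """One metabolite's values arranged one row per family.

    ``pairs_*`` arrays cover complete pairs split by zygosity; ``single_*``
    cover families contributing one observed value (co-twin absent or
    missing).  Twin order follows birth order; the model's equality
    constraints make the order irrelevant.
    """

    mz_y: np.ndarray          # (n_mz, 2)
    mz_sex: np.ndarray        # (n_mz, 2) 1 = female
    mz_age: np.ndarray        # (n_mz,)
    dz_y: np.ndarray
    dz_sex: np.ndarray
    dz_age: np.ndarray
    single_y: np.ndarray      # (n_single,)
    single_sex: np.ndarray
    single_age: np.ndarray
    single_is_mz: np.ndarray  # bool
    family_ids: dict = field(default_factory=dict)

    @property
    def n_complete(self) -> dict:
        return {"MZ": len(self.mz_y), "DZ": len(self.dz_y)}

    @property
    def n_obs(self) -> int:
        return 2 * (len(self.mz_y) + len(self.dz_y)) + len(self.single_y)

    def all_y(self) -> np.ndarray:
        return np.concatenate(
            [self.mz_y.ravel(), self.dz_y.ravel(), self.single_y]
        )


def pair_data(values: pd.Series, cohort: pd.DataFrame) -> PairedData:
    """Arrange one metabolite's processed values by family.

    ``values`` is indexed by child_id; ``cohort`` must be restricted to
    twins with known zygosity and at most two children per family (second
    multiples already excluded).
    """
    info = cohort.set_index("child_id")
    info = info[info["zygosity"].isin(["MZ", "DZ"])]
    sizes = info.groupby("family_id").size()
    if (sizes > 2).any():
        bad = sizes[sizes > 2].index.tolist()[:5]
        raise ValueError(f">2 twins in family(ies) {bad}; exclude second multiples")
    if info.duplicated(["family_id", "birth_order"]).any():
        raise ValueError("duplicate birth order within a family")

    df = info[["family_id", "birth_order", "age", "zygosity"]].copy()
    df["y"] = values.reindex(df.index).to_numpy(dtype=float)
    df["sexf"] = info["sex"].eq("female").astype(float)

    y = df.pivot(index="family_id", columns="birth_order", values="y").reindex(
        columns=[1, 2]
    )
    sx = df.pivot(index="family_id", columns="birth_order", values="sexf").reindex(
        columns=[1, 2]
    )
    fam = df.drop_duplicates("family_id").set_index("family_id").loc[y.index]
    age = fam["age"].to_numpy(dtype=float)
    is_mz = fam["zygosity"].eq("MZ").to_numpy()

    yv = y.to_numpy(dtype=float)
    sv = sx.to_numpy(dtype=float)
    o1, o2 = ~np.isnan(yv[:, 0]), ~np.isnan(yv[:, 1])
    complete = o1 & o2
    single = o1 ^ o2

    def split(zyg_mask):
        sel = complete & zyg_mask
        return yv[sel], sv[sel], age[sel]

    mz_y, mz_sex, mz_age = split(is_mz)
    dz_y, dz_sex, dz_age = split(~is_mz)
    side = np.where(o1[single], 0, 1)
    rows = np.flatnonzero(single)
    return PairedData(
        mz_y, mz_sex, mz_age, dz_y, dz_sex, dz_age,
        yv[rows, side], sv[rows, side], age[rows], is_mz[rows],
    )


def pair_all(processed: pd.DataFrame, cohort: pd.DataFrame) -> dict:
    """PairedData for every metabolite column of ``processed``."""
    return {mid: pair_data(processed[mid], cohort) for mid in processed.columns}


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------

def _pair_negll(y, mu, v, cov):
    """Sum of -log bivariate normal densities with common variance v."""
    rho = cov / v
    e = y - mu
    quad = (e[:, 0] ** 2 + e[:, 1] ** 2 - 2 * rho * e[:, 0] * e[:, 1]) / (
        v * (1 - rho**2)
    )
    return np.sum(_LOG2PI + 0.5 * (np.log(v * v * (1 - rho**2)) + quad))


def _single_negll(y, mu, v):
    e = y - mu
    return np.sum(0.5 * (_LOG2PI + np.log(v) + e**2 / v))


def _means(paired: PairedData, mu, b_sex, b_age):
    mz = mu + b_sex * paired.mz_sex + b_age * paired.mz_age[:, None]
    dz = mu + b_sex * paired.dz_sex + b_age * paired.dz_age[:, None]
    sg = mu + b_sex * paired.single_sex + b_age * paired.single_age
    return mz, dz, sg


def _negll(paired: PairedData, mu, b_sex, b_age, v, cov_mz, cov_dz):
    if not np.isfinite(v) or v <= 1e-12:
        return _BIG
    if max(abs(cov_mz), abs(cov_dz)) >= 0.999 * v:
        # infeasible 2x2 covariance; smooth penalty keeps the search inside
        excess = max(abs(cov_mz), abs(cov_dz)) / v - 0.999
        return _BIG * (1.0 + excess)
    m_mz, m_dz, m_sg = _means(paired, mu, b_sex, b_age)
    total = 0.0
    if len(paired.mz_y):
        total += _pair_negll(paired.mz_y, m_mz, v, cov_mz)
    if len(paired.dz_y):
        total += _pair_negll(paired.dz_y, m_dz, v, cov_dz)
    if len(paired.single_y):
        total += _single_negll(paired.single_y, m_sg, v)
    return total


def saturated_negll(paired: PairedData, mu, b_sex, b_age, v, cov_mz, cov_dz):
    """Raw-data negative log-likelihood at explicit parameter values."""
    return _negll(paired, mu, b_sex, b_age, v, cov_mz, cov_dz)


# ---------------------------------------------------------------------------
# saturated model
# ---------------------------------------------------------------------------

@dataclass
class SaturatedFit:
    mu: float
    beta_sex: float
    beta_age: float
    sigma2: float
    cov_mz: float
    cov_dz: float
    r_mz: float
    r_dz: float
    loglik: float
    covariate_set: tuple
    n_complete: dict
    n_obs: int
    converged: bool


def _moment_start(paired: PairedData):
    y = paired.all_y()
    mu0, v0 = float(np.mean(y)), float(np.var(y))
    def cov0(pairs):
        if len(pairs) < 2:
            return 0.0
        c = float(np.cov(pairs[:, 0], pairs[:, 1])[0, 1])
        return float(np.clip(c, -0.95 * v0, 0.95 * v0))
    return mu0, v0, cov0(paired.mz_y), cov0(paired.dz_y)


def _optimize(fun, x0, jitter_scale, rng_seed=0, n_restarts=3):
    best = None
    rng = np.random.default_rng(rng_seed)
    x_start = np.asarray(x0, dtype=float)
    for attempt in range(n_restarts + 1):
        res = optimize.minimize(fun, x_start, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
        res_nm = optimize.minimize(
            fun, best.x, method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000},
        )
        if res_nm.fun < best.fun:
            best = res_nm
        if best.fun < _BIG / 2 and (res.success or res_nm.success):
            break
        x_start = np.asarray(x0) + jitter_scale * rng.standard_normal(len(x0))
    return best


def fit_saturated(
    paired: PairedData, covariate_set: tuple = ("sex", "age")
) -> SaturatedFit:
    """FIML saturated fit: mean model + common variance + per-zygosity covariance."""
    for z, n in paired.n_complete.items():
        if n < 5:
            raise ValueError(
                f"only {n} complete {z} pairs; covariance not estimable (need >= 5)"
            )
    covariate_set = tuple(c for c in ("sex", "age") if c in covariate_set)
    use_sex, use_age = "sex" in covariate_set, "age" in covariate_set

    mu0, v0, cmz0, cdz0 = _moment_start(paired)

    def unpack(x):
        i = 0
        mu = x[i]; i += 1
        b_sex = x[i] if use_sex else 0.0
        i += use_sex
        b_age = x[i] if use_age else 0.0
        i += use_age
        v = np.exp(x[i]); i += 1
        cov_mz = v * np.tanh(x[i]); i += 1
        cov_dz = v * np.tanh(x[i])
        return mu, b_sex, b_age, v, cov_mz, cov_dz

    def fun(x):
        return _negll(paired, *unpack(x))

    x0 = [mu0]
    if use_sex:
        x0.append(0.0)
    if use_age:
        x0.append(0.0)
    x0 += [np.log(v0), np.arctanh(np.clip(cmz0 / v0, -0.9, 0.9)),
           np.arctanh(np.clip(cdz0 / v0, -0.9, 0.9))]

    best = _optimize(fun, x0, jitter_scale=0.3)
    if best.fun >= _BIG / 2:
        raise RuntimeError(f"saturated fit did not converge: {best.message}")
    mu, b_sex, b_age, v, cov_mz, cov_dz = unpack(best.x)
    return SaturatedFit(
        mu=float(mu),
        beta_sex=float(b_sex),
        beta_age=float(b_age),
        sigma2=float(v),
        cov_mz=float(cov_mz),
        cov_dz=float(cov_dz),
        r_mz=float(cov_mz / v),
        r_dz=float(cov_dz / v),
        loglik=-float(best.fun),
        covariate_set=covariate_set,
        n_complete=paired.n_complete,
        n_obs=paired.n_obs,
        converged=True,
    )


def select_covariates(
    paired: PairedData, alpha: float = 0.05, criterion: str = "lrt"
) -> tuple[tuple, pd.DataFrame]:
    """Likelihood-ratio covariate selection against the full mean model.

    Fits the saturated model under all four covariate sets and compares the
    full {sex, age} model with each reduced model.  A covariate is retained
    iff its removal is rejected at ``alpha`` (or, with ``criterion='aic'``,
    iff removal increases AIC).
    """
    fits = {cs: fit_saturated(paired, cs) for cs in COVARIATE_SETS}
    full = fits[("sex", "age")]
    rows = []
    for cs in COVARIATE_SETS[1:]:
        reduced = fits[cs]
        df = 2 - len(cs)
        stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
        p = float(chi2.sf(stat, df))
        rows.append(
            dict(
                removed="+".join(sorted(set(("sex", "age")) - set(cs))),
                df=df,
                lrt_stat=stat,
                p_value=p,
                loglik_full=full.loglik,
                loglik_reduced=reduced.loglik,
            )
        )
    table = pd.DataFrame(rows)
    if criterion == "aic":
        keep_age = 2 * (full.loglik - fits[("sex",)].loglik) > 2
        keep_sex = 2 * (full.loglik - fits[("age",)].loglik) > 2
    else:
        keep_age = table.loc[table["removed"] == "age", "p_value"].iloc[0] < alpha
        keep_sex = table.loc[table["removed"] == "sex", "p_value"].iloc[0] < alpha
    chosen = tuple(
        c for c, keep in (("sex", keep_sex), ("age", keep_age)) if keep
    )
    return chosen, table


def choose_model(r_mz: float, r_dz: float) -> str:
    """ADE iff r_MZ > 2 r_DZ, else ACE (ties to ACE)."""
    return "ADE" if r_mz > 2.0 * r_dz else "ACE"


# ---------------------------------------------------------------------------
# variance-component models
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponentsFit:
    model: str                # "ADE" or "ACE"
    A: float
    DorC: float               # D under ADE, C under ACE
    E: float
    V: float
    a2: float
    dc2: float                # d2 under ADE, c2 under ACE
    e2: float
    h2: float                 # broad-sense (ADE) or narrow-sense (ACE)
    h2_type: str              # "broad" or "narrow"
    loglik: float
    covariate_set: tuple
    mu: float
    beta_sex: float
    beta_age: float
    converged: bool


def _component_covs(model: str, A: float, X: float):
    if model == "ADE":
        return A + X, 0.5 * A + 0.25 * X
    if model == "ACE":
        return A + X, 0.5 * A + X
    raise ValueError(f"model must be 'ADE' or 'ACE', got {model!r}")


def closed_form_components(model: str, v: float, cov_mz: float, cov_dz: float):
    """Exact 3-moment solution (the models are just identified).

    ADE: A = 4 cov_DZ - cov_MZ, D = 2 cov_MZ - 4 cov_DZ, E = V - cov_MZ.
    ACE: A = 2 (cov_MZ - cov_DZ), C = 2 cov_DZ - cov_MZ, E = V - cov_MZ.
    """
    if model == "ADE":
        A = 4 * cov_dz - cov_mz
        X = 2 * cov_mz - 4 * cov_dz
    else:
        A = 2 * (cov_mz - cov_dz)
        X = 2 * cov_dz - cov_mz
    return A, X, v - cov_mz


def fit_ace_ade(
    paired: PairedData, model: str, covariate_set: tuple = ()
) -> VarianceComponentsFit:
    """FIML variance-component fit with unconstrained (possibly negative) components."""
    use_sex, use_age = "sex" in covariate_set, "age" in covariate_set

    sat = fit_saturated(paired, covariate_set)
    A0, X0, E0 = closed_form_components(
        model, sat.sigma2, sat.cov_mz, sat.cov_dz
    )

    def unpack(x):
        i = 0
        mu = x[i]; i += 1
        b_sex = x[i] if use_sex else 0.0
        i += use_sex
        b_age = x[i] if use_age else 0.0
        i += use_age
        A, X, E = x[i], x[i + 1], x[i + 2]
        return mu, b_sex, b_age, A, X, E

    def fun(x):
        mu, b_sex, b_age, A, X, E = unpack(x)
        cov_mz, cov_dz = _component_covs(model, A, X)
        return _negll(paired, mu, b_sex, b_age, A + X + E, cov_mz, cov_dz)

    x0 = [sat.mu]
    if use_sex:
        x0.append(sat.beta_sex)
    if use_age:
        x0.append(sat.beta_age)
    x0 += [A0, X0, max(E0, 0.05 * sat.sigma2)]

    best = _optimize(fun, x0, jitter_scale=0.1 * sat.sigma2)
    if best.fun >= _BIG / 2:
        raise RuntimeError(f"{model} fit did not converge: {best.message}")
    mu, b_sex, b_age, A, X, E = unpack(best.x)
    V = A + X + E
    return VarianceComponentsFit(
        model=model,
        A=float(A),
        DorC=float(X),
        E=float(E),
        V=float(V),
        a2=float(A / V),
        dc2=float(X / V),
        e2=float(E / V),
        h2=float((A + X) / V) if model == "ADE" else float(A / V),
        h2_type="broad" if model == "ADE" else "narrow",
        loglik=-float(best.fun),
        covariate_set=tuple(covariate_set),
        mu=float(mu),
        beta_sex=float(b_sex),
        beta_age=float(b_age),
        converged=True,
    )


# ---------------------------------------------------------------------------
# profile-likelihood confidence intervals
# ---------------------------------------------------------------------------

def _profile_negll(paired, model, covariate_set, component, s, warm, fit):
    """Minimized negll with the standardized ``component`` share fixed at s."""
    use_sex, use_age = "sex" in covariate_set, "age" in covariate_set

    def build(mu, b_sex, b_age, logv, t, w):
        V = np.exp(logv)
        if component == "a2":
            A, X = s * V, t * V
        elif component in ("d2", "c2"):
            A, X = t * V, s * V
        elif component == "e2":
            # E fixed at s V; t is the A share
            A, X = t * V, (1 - s - t) * V
        elif component == "h2":
            if model == "ADE":          # A + D = s V, split by w
                A, X = w * V, (s - w) * V
            else:                        # narrow-sense: A = s V
                A, X = s * V, t * V
        else:
            raise ValueError(f"unknown component {component!r}")
        if component in ("a2", "d2", "c2") or (component == "h2" and model == "ACE"):
            E = (1 - s - t) * V
        elif component == "e2":
            E = s * V
        else:                            # h2 under ADE
            E = (1 - s) * V
        cov_mz, cov_dz = _component_covs(model, A, X)
        return _negll(paired, mu, b_sex, b_age, A + X + E, cov_mz, cov_dz)

    def fun(x):
        i = 0
        mu = x[i]; i += 1
        b_sex = x[i] if use_sex else 0.0
        i += use_sex
        b_age = x[i] if use_age else 0.0
        i += use_age
        logv = x[i]; i += 1
        t = w = 0.0
        if component == "h2" and model == "ADE":
            w = x[i]
        else:
            t = x[i]
        return build(mu, b_sex, b_age, logv, t, w)

    res = optimize.minimize(
        fun, warm, method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    return float(res.fun), res.x


def profile_ci(
    paired: PairedData,
    fit: VarianceComponentsFit,
    component: str = "h2",
    level: float = 0.95,
    window: tuple = (-1.0, 2.0),
) -> tuple[float, float]:
    """Profile-likelihood interval for a standardized component share.

    ``component``: 'a2', 'd2', 'c2', 'e2' or 'h2'.  Bounds are where twice
    the profile log-likelihood drop equals the chi-square(1) quantile.  A
    bound pushed outside ``window`` is reported open-ended (+-inf) with a
    warning.
    """
    model, covariate_set = fit.model, fit.covariate_set
    share = {
        "a2": fit.a2, "d2": fit.dc2, "c2": fit.dc2, "e2": fit.e2, "h2": fit.h2
    }[component]
    crit = chi2.ppf(level, 1)
    ll_max = fit.loglik

    # warm start at the MLE
    warm = [fit.mu]
    if "sex" in covariate_set:
        warm.append(fit.beta_sex)
    if "age" in covariate_set:
        warm.append(fit.beta_age)
    warm.append(np.log(max(fit.V, 1e-8)))
    if component == "h2" and model == "ADE":
        warm.append(fit.a2)          # w = A share
    elif component == "e2":
        warm.append(fit.a2)          # t = A share
    elif component in ("d2", "c2"):
        warm.append(fit.a2)
    else:
        warm.append(fit.dc2)
    warm = np.asarray(warm, dtype=float)

    cache = {}
    state = {"warm": warm}

    def deficit(s):
        if s not in cache:
            nll, x = _profile_negll(
                paired, model, covariate_set, component, s, state["warm"], fit
            )
            state["warm"] = x  # nearby s values share the nuisance optimum
            cache[s] = 2.0 * (ll_max + nll) - crit
        return cache[s]

    def find_bound(direction):
        step = 0.02
        prev = share
        state["warm"] = warm
        for k in range(1, 200):
            s = share + direction * step * k
            if s <= window[0] or s >= window[1]:
                log.warning(
                    "profile bound for %s beyond search window; open-ended",
                    component,
                )
                return direction * np.inf
            if deficit(s) > 0:
                return optimize.brentq(deficit, min(prev, s), max(prev, s),
                                       xtol=1e-5)
            prev = s
        return direction * np.inf

    lo = find_bound(-1.0)
    hi = find_bound(+1.0)
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def run_twin_pipeline(
    processed: pd.DataFrame,
    cohort: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    alpha: float = 0.05,
    ci_level: float = 0.95,
    compute_ci: bool = True,
) -> pd.DataFrame:
    """Covariate selection, saturated fit, model choice and variance
    decomposition for every metabolite; per-metabolite failures are logged
    and skipped."""
    rows = []
    for mid in processed.columns:
        try:
            paired = pair_data(processed[mid], cohort)
            if paired.n_obs == 0:
                raise ValueError("no observed values")
            chosen, _ = select_covariates(paired, alpha=alpha)
            sat = fit_saturated(paired, chosen)
            model = choose_model(sat.r_mz, sat.r_dz)
            vc = fit_ace_ade(paired, model, chosen)
            ci = (np.nan, np.nan)
            if compute_ci:
                ci = profile_ci(paired, vc, "h2", level=ci_level)
        except (ValueError, RuntimeError) as err:
            log.warning("metabolite %s skipped: %s", mid, err)
            continue
        if meta is not None and mid in meta.index:
            platform = meta.at[mid, "platform"]
        else:
            # simulator ids carry their platform as a prefix
            platform = {"am": "amine", "oa": "organic_acid", "st": "steroid"}.get(
                str(mid)[:2], "unknown"
            )
        rows.append(
            dict(
                metabolite=mid,
                platform=platform,
                covariate_set="+".join(chosen) if chosen else "none",
                r_mz=sat.r_mz,
                r_dz=sat.r_dz,
                model=model,
                A=vc.A,
                D_or_C=vc.DorC,
                E=vc.E,
                V=vc.V,
                h2=vc.h2,
                h2_type=vc.h2_type,
                ci_low=ci[0],
                ci_high=ci[1],
                loglik_sat=sat.loglik,
                loglik_model=vc.loglik,
            )
        )
    return pd.DataFrame(rows)
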