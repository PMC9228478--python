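"""Sex/age association scans with family clustering and BH-FDR.

Eight analyses are run per cohort: the joint sex + age model with age
continuous or dichotomized at 10 years, age-only models within each sex
stratum (again continuous and dichotomized), and sex-only models within the
younger (< 10 y) and older (>= 10 y) strata.  Each analysis is corrected
for multiple testing separately by Benjamini-Hochberg step-up at q <= 0.05,
using an analysis-specific metabolite count m that may exceed the number of
tests actually run (as when a replication panel lacks some metabolites).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lmm import fit_random_intercept_lmm

log = logging.getLogger(__name__)

AGE_CUTOFF = 10.0

#: analysis label -> (fixed-effect terms, stratum column, stratum value)
ANALYSES = {
    "sex_age_continuous": (("sex", "age"), None, None),
    "sex_age_dichotomized": (("sex", "age_dichotomized"), None, None),
    "age_in_males": (("age",), "sex", "male"),
    "age_in_females": (("age",), "sex", "female"),
    "age_dichotomized_in_males": (("age_dichotomized",), "sex", "male"),
    "age_dichotomized_in_females": (("age_dichotomized",), "sex", "female"),
    "sex_in_younger": (("sex",), "age_group", "younger"),
    "sex_in_older": (("sex",), "age_group", "older"),
}

#: Default per-analysis metabolite counts for FDR correction.  The
#: discovery panel has 86 metabolites in every analysis; the replication
#: panel retained fewer metabolites per analysis.
DEFAULT_FDR_M = {
    "discovery": {name: 86 for name in ANALYSES},
    "replication": {
        "sex_age_continuous": 79,
        "sex_age_dichotomized": 76,
        "age_in_males": 73,
        "age_in_females": 67,
        "age_dichotomized_in_males": 63,
        "age_dichotomized_in_females": 51,
        "sex_in_younger": 11,
        "sex_in_older": 13,
    },
}


def dichotomize_age(age, cutoff: float = AGE_CUTOFF) -> np.ndarray:
    """0 for age < cutoff, 1 for age >= cutoff (boundary goes to the older group)."""
    return (np.asarray(age, dtype=float) >= cutoff).astype(int)


def bh_fdr(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m`` is the number of hypotheses the correction is run over; it may
    exceed ``len(p_values)`` when some hypotheses were untestable.  q(i) =
    min_{j >= i} p(j) * m / j over the sorted p-values, clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError("m must be at least the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty_like(p)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _design(sub: pd.DataFrame, terms: tuple) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for t in terms:
        if t == "sex":
            cols.append(sub["sex"].eq("female").to_numpy(dtype=float))
        elif t == "age":
            cols.append(sub["age"].to_numpy(dtype=float))
        elif t == "age_dichotomized":
            cols.append(dichotomize_age(sub["age"]).astype(float))
        else:
            raise ValueError(f"unknown term {t!r}")
        names.append(t)
    return np.column_stack(cols), names


def run_association_scan(
    processed: pd.DataFrame,
    cohort: pd.DataFrame,
    analysis: str,
    fdr_m: int | None = None,
    q_threshold: float = 0.05,
    min_families: int = 10,
) -> pd.DataFrame:
    """One analysis over every metabolite; BH-FDR within the analysis.

    ``processed`` is the samples x metabolites table on the INT scale,
    indexed by child_id.  Returns a tidy table with one row per metabolite
    and tested term: beta, se, p, q, significant, n_used.
    """
    if analysis not in ANALYSES:
        raise ValueError(f"unknown analysis {analysis!r}")
    terms, strat_col, strat_val = ANALYSES[analysis]

    info = cohort.set_index("child_id").loc[processed.index].copy()
    info["age_group"] = np.where(
        dichotomize_age(info["age"]) == 1, "older", "younger"
    )
    if strat_col is not None:
        keep = info[strat_col] == strat_val
        info = info[keep]
    if info["family_id"].nunique() < min_families:
        raise ValueError(
            f"analysis {analysis!r}: stratum has fewer than {min_families} families"
        )
    data = processed.loc[info.index]

    rows = []
    for mid in data.columns:
        y = data[mid].to_numpy(dtype=float)
        obs = ~np.isnan(y)
        sub = info[obs]
        try:
            X, names = _design(sub, terms)
            fit = fit_random_intercept_lmm(
                y[obs], X, sub["family_id"].to_numpy(), names=names
            )
        except (ValueError, np.linalg.LinAlgError) as err:
            log.warning("metabolite %s skipped in %s: %s", mid, analysis, err)
            continue
        if not fit.converged:
            log.warning("metabolite %s: LMM did not converge; excluded from FDR", mid)
            continue
        for k, term in enumerate(names):
            if term == "intercept":
                continue
            rows.append(
                dict(
                    metabolite=mid,
                    term=term,
                    beta=fit.beta[k],
                    se=fit.se[k],
                    p_value=fit.p_values[k],
                    analysis=analysis,
                    n_used=fit.n_obs,
                )
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["q_value"] = np.nan
    for term, idx in out.groupby("term").groups.items():
        m = fdr_m if fdr_m is not None else len(idx)
        out.loc[idx, "q_value"] = bh_fdr(out.loc[idx, "p_value"].to_numpy(), m=m)
    out["significant"] = out["q_value"] <= q_threshold
    return out


def run_all_analyses(
    processed: pd.DataFrame,
    cohort: pd.DataFrame,
    cohort_label: str = "discovery",
    fdr_m: dict | None = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """All eight analyses with their per-analysis FDR counts."""
    if fdr_m is None:
        fdr_m = DEFAULT_FDR_M.get(cohort_label, {})
    tables = []
    for name in ANALYSES:
        try:
            tab = run_association_scan(
                processed,
                cohort,
                name,
                fdr_m=fdr_m.get(name),
                q_threshold=q_threshold,
            )
        except ValueError as err:
            log.warning("analysis %s skipped: %s", name, err)
            continue
        tables.append(tab)
    return pd.concat(tables, ignore_index=True)


@dataclass
class ConcordanceSummary:
    beta_correlation: dict
    sign_agreement: dict
    replicated: dict  # term -> set of metabolite ids


def replication_concordance(
    discovery: pd.DataFrame, replication: pd.DataFrame
) -> ConcordanceSummary:
    """Cross-cohort agreement of association results.

    A discovery hit replicates iff the metabolite is significant
    (q <= 0.05) in both cohorts with the same beta sign.  Also reports the
    Pearson correlation of betas and the sign-agreement fraction over the
    shared metabolite set, per term.
    """
    merged = discovery.merge(
        replication, on=["metabolite", "term"], suffixes=("_disc", "_rep")
    )
    if merged.empty:
        raise ValueError("no shared (metabolite, term) pairs between cohorts")
    corr, agree, replicated = {}, {}, {}
    for term, sub in merged.groupby("term"):
        corr[term] = float(np.corrcoef(sub["beta_disc"], sub["beta_rep"])[0, 1])
        agree[term] = float(
            (np.sign(sub["beta_disc"]) == np.sign(sub["beta_rep"])).mean()
        )
        hits = sub[
            sub["significant_disc"]
            & sub["significant_rep"]
            & (np.sign(sub["beta_disc"]) == np.sign(sub["beta_rep"]))
        ]
        replicated[term] = set(hits["metabolite"])
    return ConcordanceSummary(corr, agree, replicated)
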