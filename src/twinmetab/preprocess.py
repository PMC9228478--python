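"""Sample exclusions and metabolite-level QC / normalization.

The preprocessing contract, applied in this order:

1. sample exclusions (insufficient urine, not first-morning, freeze delay
   > 2 h, second multiple pair in the family, cross-cohort duplicate);
2. metabolite filters (item missingness > 10%, pooled-QC RSD >= 15%);
3. imputation of left-censored entries at half the limit of detection (or
   half the lowest observed level when the limit is unknown);
4. division by the sample's creatinine concentration (urine dilution);
5. rank-based inverse normal transformation per metabolite within cohort.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import ndtri
from scipy.stats import rankdata

from .simulate import MetaboliteMatrix

log = logging.getLogger(__name__)

#: Sample-exclusion reasons, in the order they are applied.
def _flag_false(s):
    return (~s.astype("boolean").fillna(True)).to_numpy(dtype=bool)


def _flag_true(s):
    return s.astype("boolean").fillna(False).to_numpy(dtype=bool)


EXCLUSION_ORDER = [
    ("insufficient_urine", "urine_sufficient", _flag_false),
    ("not_first_morning", "first_morning", _flag_false),
    ("late_freeze", "freeze_delay", lambda s: (s.fillna(0.0) > 2.0).to_numpy()),
    ("second_multiple", "second_multiple", _flag_true),
    ("cross_cohort_duplicate", "duplicate_of_other_cohort", _flag_true),
]


def apply_sample_exclusions(
    cohort: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop flagged samples; report the first matching reason per child.

    Missing flags count as passing and are logged as a warning.  Returns
    the retained cohort and a report with one row per input child
    (``child_id``, ``retained``, ``reason``).
    """
    reason = pd.Series(pd.NA, index=cohort.index, dtype="object")
    for name, col, rule in EXCLUSION_ORDER:
        if col not in cohort.columns:
            log.warning("flag column %r absent; rule %r treated as pass", col, name)
            continue
        if cohort[col].isna().any():
            log.warning(
                "%d missing values in flag %r treated as pass",
                int(cohort[col].isna().sum()),
                col,
            )
        hit = rule(cohort[col]) & reason.isna()
        reason[hit] = name
    retained = cohort[reason.isna()].copy()
    report = pd.DataFrame(
        {
            "child_id": cohort["child_id"].to_numpy(),
            "retained": reason.isna().to_numpy(),
            "reason": reason.to_numpy(),
        }
    )
    return retained, report


def compute_rsdqc(qc: pd.DataFrame) -> pd.Series:
    """Percent relative standard deviation of pooled-QC injections.

    100 * sample-sd / mean per metabolite (columns of ``qc``).  A zero mean
    leaves the RSD undefined (NaN), which downstream filtering treats as a
    failure.
    """
    if len(qc) < 2:
        raise ValueError("RSDqc needs at least 2 QC injections")
    mean = qc.mean(axis=0)
    sd = qc.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = 100.0 * sd / mean
    rsd[mean == 0] = np.nan
    return rsd


def filter_metabolites(
    matrix: MetaboliteMatrix,
    rsd: pd.Series,
    missing_threshold: float = 0.10,
    rsd_threshold: float = 15.0,
) -> tuple[MetaboliteMatrix, pd.DataFrame]:
    """Drop metabolites by item missingness, then by QC reproducibility.

    Missingness uses a strict ``> missing_threshold``; the RSD rule is
    inclusive (``>= rsd_threshold``); undefined RSD fails.  Returns the
    filtered matrix and a per-metabolite report
    (``metabolite``, ``platform``, ``retained``, ``reason``).
    """
    missing = matrix.missing_rate
    reason = pd.Series(pd.NA, index=matrix.values.columns, dtype="object")
    reason[missing > missing_threshold] = "high_missingness"
    rsd = rsd.reindex(matrix.values.columns)
    bad_rsd = (rsd.isna() | (rsd >= rsd_threshold)) & reason.isna()
    reason[bad_rsd] = "high_rsdqc"
    keep = reason.isna()
    report = pd.DataFrame(
        {
            "metabolite": matrix.values.columns,
            "platform": matrix.meta["platform"].to_numpy(),
            "retained": keep.to_numpy(),
            "reason": reason.to_numpy(),
        }
    )
    kept = keep[keep].index
    out = MetaboliteMatrix(
        matrix.values[kept].copy(),
        matrix.meta.loc[kept].copy(),
        matrix.censored[kept].copy(),
    )
    return out, report


def impute_below_lod(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Replace left-censored entries with half the detection limit.

    When the limit is unknown for a metabolite, half the lowest observed
    level is used instead.  A metabolite with every entry censored and no
    known limit has no defined minimum and raises.
    """
    out = matrix.copy()
    for mid in out.values.columns:
        cmask = out.censored[mid]
        if not cmask.any():
            continue
        lod = out.meta.at[mid, "lod"]
        if pd.isna(lod):
            observed = out.values[mid].dropna()
            if observed.empty:
                raise ValueError(
                    f"metabolite {mid!r}: all entries censored and no LOD known"
                )
            lod = observed.min()
        out.values.loc[cmask, mid] = lod / 2.0
    out.censored = pd.DataFrame(
        False, index=out.values.index, columns=out.values.columns
    )
    return out


def normalize_creatinine(
    matrix: MetaboliteMatrix, cohort: pd.DataFrame
) -> MetaboliteMatrix:
    """Divide every sample's responses by its creatinine concentration."""
    creat = cohort.set_index("child_id")["creatinine"].reindex(matrix.values.index)
    if creat.isna().any():
        missing = creat[creat.isna()].index.tolist()[:5]
        raise ValueError(f"no creatinine value for sample(s) {missing}")
    if (creat <= 0).any():
        bad = creat[creat <= 0].index.tolist()[:5]
        raise ValueError(f"nonpositive creatinine for sample(s) {bad}")
    out = matrix.copy()
    out.values = out.values.div(creat, axis=0)
    return out


def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform (Blom offset by default).

    Non-missing values are ranked (average ranks for ties) and mapped
    through the standard-normal quantile of ``(rank - offset) /
    (n - 2*offset + 1)``; missing entries stay missing.  A constant vector
    maps to all zeros (logged as degenerate).
    """
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    obs = ~np.isnan(x)
    n = int(obs.sum())
    if n < 2:
        raise ValueError("inverse normal transform needs >= 2 non-missing values")
    xo = x[obs]
    if np.all(xo == xo[0]):
        log.warning("constant vector: inverse normal transform is degenerate (all 0)")
    ranks = rankdata(xo, method="average")
    out[obs] = ndtri((ranks - offset) / (n - 2 * offset + 1))
    return out


def preprocess_pipeline(
    cohort: pd.DataFrame,
    matrix: MetaboliteMatrix,
    qc: pd.DataFrame,
    missing_threshold: float = 0.10,
    rsd_threshold: float = 15.0,
    int_offset: float = 3.0 / 8.0,
) -> dict:
    """Full preprocessing: exclusions -> filters -> LOD -> creatinine -> INT.

    The inverse normal transform is computed per metabolite within each
    cohort (discovery and replication handled separately).  Returns a dict
    with keys ``cohort`` (retained children), ``processed`` (samples x
    metabolites, INT scale), ``sample_report``, ``metabolite_report``,
    ``rsdqc``.
    """
    kept_cohort, sample_report = apply_sample_exclusions(cohort)
    rsd = compute_rsdqc(qc)

    sub = MetaboliteMatrix(
        matrix.values.loc[matrix.values.index.isin(kept_cohort["child_id"])].copy(),
        matrix.meta.copy(),
        matrix.censored.loc[
            matrix.censored.index.isin(kept_cohort["child_id"])
        ].copy(),
    )
    filtered, metabolite_report = filter_metabolites(
        sub, rsd, missing_threshold, rsd_threshold
    )
    imputed = impute_below_lod(filtered)
    normalized = normalize_creatinine(imputed, kept_cohort)

    processed = normalized.values.copy()
    groups = kept_cohort.set_index("child_id")["cohort"].reindex(processed.index)
    for _, idx in groups.groupby(groups).groups.items():
        block = processed.loc[idx]
        processed.loc[idx] = np.column_stack(
            [
                inverse_normal_transform(block[mid].to_numpy(), offset=int_offset)
                for mid in block.columns
            ]
        )
    return {
        "cohort": kept_cohort,
        "processed": processed,
        "meta": normalized.meta,
        "sample_report": sample_report,
        "metabolite_report": metabolite_report,
        "rsdqc": rsd,
    }
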