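"""Reliability banding of MZ correlations and per-platform summaries.

The MZ twin correlation is a lower bound on test-retest reliability: MZ
co-twins are biologically matched duplicates, so a high within-pair
correlation certifies the assay, while a low one does not by itself imply
poor reliability.  Correlations are banded as excellent (>= 0.75), good
[0.60, 0.75), moderate [0.40, 0.60) and indeterminate (< 0.40).  The band
edges are half-open real intervals so every correlation receives a band.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BANDS = ("excellent", "good", "moderate", "indeterminate")


def classify_reliability(r_mz: float) -> str:
    """Band an MZ correlation; r outside [-1, 1] is rejected."""
    if not -1.0 <= r_mz <= 1.0:
        raise ValueError(f"correlation {r_mz} outside [-1, 1]")
    if r_mz >= 0.75:
        return "excellent"
    if r_mz >= 0.60:
        return "good"
    if r_mz >= 0.40:
        return "moderate"
    return "indeterminate"


def classify_reliability_table(results: pd.DataFrame) -> pd.DataFrame:
    """Add a ``band`` column from ``r_mz``."""
    out = results.copy()
    out["band"] = [classify_reliability(r) for r in out["r_mz"]]
    return out


def platform_summary(results: pd.DataFrame) -> pd.DataFrame:
    """Means and min-max ranges per platform (and model class where present).

    ``results`` is the twin-pipeline output (columns ``platform``, ``r_mz``,
    ``r_dz`` and optionally ``model``, ``h2``).  Heritability is summarized
    within model class, mirroring the convention of reporting broad-sense
    h2 for ADE metabolites and narrow-sense h2 for ACE metabolites.
    """
    if results.empty:
        raise ValueError("no results to summarize")
    results = results.assign(platform=results["platform"].fillna("unknown"))
    rows = []
    has_model = "model" in results.columns

    def stats(sub, col):
        x = sub[col].dropna()
        if x.empty:
            return {}
        return {
            f"{col}_mean": float(x.mean()),
            f"{col}_min": float(x.min()),
            f"{col}_max": float(x.max()),
        }

    for plat, sub in results.groupby("platform"):
        row = {"platform": plat, "n_metabolites": len(sub)}
        for col in ("r_mz", "r_dz"):
            if col in sub.columns:
                row.update(stats(sub, col))
        if has_model:
            for model, msub in sub.groupby("model"):
                row[f"n_{model.lower()}"] = len(msub)
                if "h2" in msub.columns:
                    for k, val in stats(msub, "h2").items():
                        row[f"{model.lower()}_{k}"] = val
        if "r_mz" in sub.columns:
            bands = pd.Series(
                [classify_reliability(r) for r in sub["r_mz"]]
            ).value_counts()
            for band in BANDS:
                row[f"n_{band}"] = int(bands.get(band, 0))
        rows.append(row)
    return pd.DataFrame(rows)


def moderate_or_better_fraction(results: pd.DataFrame) -> float:
    """Fraction of metabolites banded moderate, good or excellent."""
    bands = np.array([classify_reliability(r) for r in results["r_mz"]])
    return float(np.isin(bands, ("excellent", "good", "moderate")).mean())
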