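"""Tab-delimited interchange tables and run configuration.

All stage outputs are UTF-8 TSV with a header row and ``NA`` as the
missing-value token, re-readable by :func:`read_table`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

log = logging.getLogger(__name__)

NA_TOKEN = "NA"

#: column name -> pandas dtype ("float", "int", "bool", "str")
COHORT_SCHEMA = {
    "child_id": "str",
    "family_id": "str",
    "cohort": "str",
    "zygosity": "str",
    "birth_order": "int",
    "sex": "str",
    "age": "float",
    "creatinine": "float",
}


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=index)


def read_table(path, schema: dict | None = None, index_col=None) -> pd.DataFrame:
    """Typed TSV reader; unknown extra columns warn, missing ones error."""
    df = pd.read_csv(
        path, sep="\t", na_values=[NA_TOKEN], keep_default_na=False,
        index_col=index_col,
    )
    if schema:
        missing = set(schema) - set(df.columns)
        if missing:
            raise ValueError(
                f"{path}: missing mandatory column(s) {sorted(missing)}"
            )
        extra = set(df.columns) - set(schema)
        if extra:
            log.warning("%s: ignoring unknown column(s) %s", path, sorted(extra))
        casts = {"float": float, "int": "int64", "str": "string", "bool": bool}
        for col, kind in schema.items():
            df[col] = df[col].astype(casts[kind])
    return df


@dataclass
class RunConfig:
    """Thresholds and labels driving a full pipeline run.

    Defaults are the published analysis settings: >10% missingness and
    >=15% RSDqc metabolite filters, q <= 0.05 FDR, alpha = 0.05 for the
    covariate LRTs, 95% confidence level.
    """

    missing_threshold: float = 0.10
    rsd_threshold: float = 15.0
    fdr_q: float = 0.05
    lrt_alpha: float = 0.05
    ci_level: float = 0.95
    int_offset: float = 3.0 / 8.0
    fdr_m: dict | None = None
    seed: int = 0
    compute_ci: bool = True

    def __post_init__(self):
        if not 0 <= self.missing_threshold <= 1:
            raise ValueError("missing_threshold must be in [0, 1]")
        if self.rsd_threshold < 0:
            raise ValueError("rsd_threshold must be >= 0")
        for name in ("fdr_q", "lrt_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            log.warning("config: ignoring unknown key(s) %s", sorted(unknown))
        return cls(**{k: v for k, v in data.items() if k in known})

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_provenance(out_dir, config: RunConfig, extra: dict | None = None) -> Path:
    """Machine-readable provenance record: config hash, seed, versions."""
    import numpy, scipy, statsmodels  # versions recorded, not imported for use

    record = {
        "config": dataclasses.asdict(config),
        "config_sha256": config.digest(),
        "seed": config.seed,
        "versions": {
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
        },
    }
    if extra:
        record.update(extra)
    path = Path(out_dir) / "provenance.json"
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
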