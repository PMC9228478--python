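"""End-to-end orchestration: simulate -> preprocess -> associate -> twinfit -> report."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import pandas as pd

from . import association, preprocess, simulate, summarize, twin
from .io import RunConfig, write_provenance, write_table

log = logging.getLogger(__name__)


def run_all(
    config: RunConfig,
    out_dir,
    sim_spec: simulate.SimulationSpec | None = None,
    cohort: pd.DataFrame | None = None,
    matrix: simulate.MetaboliteMatrix | None = None,
    qc: pd.DataFrame | None = None,
) -> dict:
    """Run every stage and write all interchange tables under ``out_dir``.

    Either a simulation spec (inputs are generated) or a concrete
    (cohort, matrix, qc) triple must be supplied.  Any stage failure halts
    the run with an error naming the stage.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = {}

    if sim_spec is not None:
        sim_spec = dataclasses.replace(sim_spec, seed=config.seed)
        try:
            cohort, matrix, qc, truth = simulate.simulate_cohort(sim_spec)
        except Exception as err:
            raise RuntimeError(f"stage 'simulate' failed: {err}") from err
        write_table(cohort, out_dir / "cohort.tsv")
        write_table(matrix.values, out_dir / "metabolites.tsv", index=True)
        write_table(qc, out_dir / "qc.tsv", index=True)
        write_table(truth.var_fracs, out_dir / "truth.tsv", index=True)
        results["truth"] = truth
    if cohort is None or matrix is None or qc is None:
        raise ValueError("need either sim_spec or (cohort, matrix, qc)")

    try:
        pre = preprocess.preprocess_pipeline(
            cohort, matrix, qc,
            missing_threshold=config.missing_threshold,
            rsd_threshold=config.rsd_threshold,
            int_offset=config.int_offset,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'preprocess' failed: {err}") from err
    write_table(pre["processed"], out_dir / "processed.tsv", index=True)
    write_table(pre["sample_report"], out_dir / "exclusions.tsv")
    write_table(pre["metabolite_report"], out_dir / "metabolite_exclusions.tsv")
    results["preprocess"] = pre

    try:
        assoc = association.run_all_analyses(
            pre["processed"], pre["cohort"],
            fdr_m=config.fdr_m, q_threshold=config.fdr_q,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'associate' failed: {err}") from err
    write_table(assoc, out_dir / "associations.tsv")
    results["associations"] = assoc

    try:
        twin_results = twin.run_twin_pipeline(
            pre["processed"], pre["cohort"], meta=pre["meta"],
            alpha=config.lrt_alpha, ci_level=config.ci_level,
            compute_ci=config.compute_ci,
        )
    except Exception as err:
        raise RuntimeError(f"stage 'twinfit' failed: {err}") from err
    write_table(twin_results, out_dir / "twin_results.tsv")
    results["twin"] = twin_results

    try:
        banded = summarize.classify_reliability_table(twin_results)
        summary = summarize.platform_summary(twin_results)
    except Exception as err:
        raise RuntimeError(f"stage 'report' failed: {err}") from err
    write_table(banded[["metabolite", "platform", "r_mz", "band"]],
                out_dir / "reliability.tsv")
    write_table(summary, out_dir / "platform_summary.tsv")
    results["summary"] = summary

    write_provenance(out_dir, config)
    return results
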