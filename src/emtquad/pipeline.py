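"""End-to-end pipeline: config in, report directory out.

A pipeline config is a YAML/JSON mapping with either a ``simulate`` block
(:class:`~emtquad.config.SimConfig` fields) or an ``inputs`` block with
file paths (``expression``, ``clinical``, optional ``drugs``,
``dependency``, ``qpcr``), plus an optional ``analysis`` block::

    analysis:
      feature: ZNF71_KRAB   # feature stratified by the cutoff
      cutoff: 1.5           # TPM threshold (high iff TPM >= cutoff)
      score_mode: mean_log  # EMT aggregate scoring mode
      dependency_threshold: -0.5

The run is a pure function of the config: reruns produce byte-identical
artifacts (the log records seed, package versions and parameters, never
wall-clock time).
"""

from __future__ import annotations

import json
from pathlib import Path

import lifelines
import numpy as np
import pandas as pd
import scipy

from . import __version__, chemo, dependency, emt, survival
from .config import SimConfig, load_config
from .dataio import (
    align_samples,
    read_clinical_table,
    read_dependency_table,
    read_drug_table,
    read_expression_table,
    read_qpcr_plate,
    write_clinical_table,
    write_dependency_table,
    write_drug_table,
)
from .datagen import simulate_cell_lines, simulate_cohort, simulate_qpcr
from .errors import ConfigurationError

_FLOAT_FMT = "%.6g"


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default)
                    + "\n", encoding="utf-8")


def run_pipeline(config_path: str | Path, out_dir: str | Path) -> Path:
    """Run the full analysis described by a config file.

    Writes emt_calls.tsv, survival_report.json and run.log always;
    drug_response.tsv + diff_expr.tsv, dependency_calls.tsv and
    qpcr_foldchanges.tsv when the corresponding inputs exist.  Returns the
    output directory path.
    """
    cfg = load_config(config_path)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    analysis = dict(cfg.get("analysis") or {})
    feature = analysis.get("feature", "ZNF71_KRAB")
    cutoff = float(analysis.get("cutoff", 1.5))
    score_mode = analysis.get("score_mode", "mean_log")
    dep_threshold = float(analysis.get("dependency_threshold",
                                       dependency.DEFAULT_THRESHOLD))

    log_lines = [f"emtquad {__version__}",
                 f"numpy {np.__version__}, scipy {scipy.__version__}, "
                 f"pandas {pd.__version__}, lifelines {lifelines.__version__}",
                 f"config: {json.dumps(cfg, sort_keys=True, default=_json_default)}"]

    drug_table = dep_table = plate = None
    cell_expr = None
    if "simulate" in cfg:
        sim = SimConfig.from_dict(cfg["simulate"] or {})
        log_lines.append(f"simulate: seed={sim.seed} n_tumors={sim.n_tumors} "
                         f"n_cell_lines={sim.n_cell_lines}")
        expr, clinical, truth = simulate_cohort(sim)
        cell_expr, drug_table, dep_table, panel_truth = simulate_cell_lines(sim)
        plate = simulate_qpcr(sim)
        expr.write_tsv(out / "expression.tsv")
        write_clinical_table(clinical, out / "clinical.tsv")
        cell_expr.write_tsv(out / "cell_line_expression.tsv")
        write_drug_table(drug_table, out / "drugs.csv")
        write_dependency_table(dep_table, out / "dependency.tsv")
        plate.write_csv(out / "qpcr.csv")
        _write_json({"cohort": truth.to_dict(), "panel": panel_truth.to_dict()},
                    out / "truth.json")
    elif "inputs" in cfg:
        inputs = cfg["inputs"] or {}
        for required in ("expression", "clinical"):
            if required not in inputs:
                raise ConfigurationError(
                    f"config needs either a 'simulate' block or "
                    f"'inputs.{required}'"
                )
        expr = read_expression_table(inputs["expression"])
        clinical = read_clinical_table(inputs["clinical"])
        if "drugs" in inputs:
            drug_table = read_drug_table(inputs["drugs"])
            if "cell_line_expression" in inputs:
                cell_expr = read_expression_table(inputs["cell_line_expression"])
        if "dependency" in inputs:
            dep_table = read_dependency_table(inputs["dependency"])
        if "qpcr" in inputs:
            plate = read_qpcr_plate(inputs["qpcr"])
    else:
        raise ConfigurationError(
            "config needs either a 'simulate' block or an 'inputs' block"
        )

    expr, clinical, n_dropped = align_samples(expr, clinical)
    log_lines.append(f"sample join: {expr.n_samples} kept, {n_dropped} dropped")

    # EMT classification + per-phenotype survival
    calls = emt.classify_emt_quadrants(expr, score_mode=score_mode)
    calls_out = calls.copy()
    calls_out.insert(0, "sample_id", calls_out.index)
    calls_out.to_csv(out / "emt_calls.tsv", sep="\t", index=False,
                     float_format=_FLOAT_FMT)

    labels, high_frac = survival.stratify_by_cutoff(expr.feature(feature), cutoff)
    overall = survival.compare_two_groups(clinical["time"], clinical["event"],
                                          labels.to_numpy())
    by_ph = survival.per_phenotype_survival(expr, clinical, calls, feature, cutoff)
    ph_stat, ph_df, ph_p = survival.logrank_test(
        clinical["time"], clinical["event"], calls["phenotype"].to_numpy())
    report = {
        "feature": feature,
        "cutoff": cutoff,
        "high_fraction": high_frac,
        "overall": overall.to_dict(),
        "phenotype_logrank": {"statistic": ph_stat, "df": ph_df, "p": ph_p},
        "by_phenotype": {r.label: r.to_dict() for r in by_ph},
    }
    stage = clinical.set_index("sample_id")["stage"] if "stage" in clinical else None
    if stage is not None and stage.nunique() >= 2:
        chi = emt.phenotype_association_test(calls, stage)
        report["stage_association"] = {"statistic": chi.statistic, "df": chi.df,
                                       "p": chi.p}
    chi_krab = emt.phenotype_association_test(
        calls, labels.rename("krab_group"))
    report["krab_association"] = {"statistic": chi_krab.statistic,
                                  "df": chi_krab.df, "p": chi_krab.p}
    _write_json(report, out / "survival_report.json")

    # Drug response
    if drug_table is not None:
        categorized = chemo.categorize_panel(drug_table)
        write_drug_table(categorized, out / "drug_response.tsv")
        if cell_expr is not None:
            diff_rows = []
            for drug, idx in categorized.groupby("drug").groups.items():
                cat = categorized.loc[idx].set_index("cell_line")["category_ic50"]
                n_res = int((cat == "resistant").sum())
                n_sen = int((cat == "sensitive").sum())
                if n_res < 2 or n_sen < 2:
                    continue
                de = chemo.diff_expr_by_response(cell_expr, cat)
                de.insert(0, "drug", drug)
                diff_rows.append(de.reset_index())
            if diff_rows:
                pd.concat(diff_rows, ignore_index=True).to_csv(
                    out / "diff_expr.tsv", sep="\t", index=False,
                    float_format=_FLOAT_FMT)

    # Dependency
    if dep_table is not None:
        norm = dependency.normalize_panel(dep_table)
        calls_dep, summary = dependency.call_dependency(
            norm["normalized_effect"], threshold=dep_threshold)
        norm["call"] = calls_dep.to_numpy()
        write_dependency_table(norm, out / "dependency_calls.tsv")
        query = norm[norm["control_label"] == "query"]
        _q_calls, q_summary = dependency.call_dependency(
            query["normalized_effect"], threshold=dep_threshold)
        _write_json({"all": summary, "query_genes": q_summary},
                    out / "dependency_summary.json")

    # qPCR
    if plate is not None:
        fc = chemo.ddct_fold_change(plate)
        fc.insert(0, "sample_id", fc.index)
        fc.to_csv(out / "qpcr_foldchanges.tsv", sep="\t", index=False,
                  float_format=_FLOAT_FMT)

    (out / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return out
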