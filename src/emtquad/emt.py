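"""Rank-quadrant EMT classification and phenotype-level comparisons.

Each sample receives an aggregate mesenchymal score (mean log2(TPM+1) over
3 mesenchymal markers) and an aggregate epithelial score (mean over 11
epithelial markers).  Median splits of the two scores define four
phenotypes::

    mes > median,  epi > median   ->  HighOverlap  (hybrid, high both)
    mes > median,  epi <= median  ->  Mesenchymal
    mes <= median, epi > median   ->  Epithelial
    mes <= median, epi <= median  ->  LowOverlap

"top" means strictly above the cohort median, so a cohort of identical
samples is all LowOverlap.  The classification is rank-based: any strictly
increasing transform of the scores leaves it unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import stats
from .config import EPI_MARKERS, MES_MARKERS
from .dataio import ExpressionMatrix
from .errors import DegenerateInputError, InsufficientCohortError

PHENOTYPES = ("Epithelial", "Mesenchymal", "HighOverlap", "LowOverlap")


@dataclass(frozen=True)
class MarkerPanel:
    """Mesenchymal and epithelial marker gene lists (disjoint, non-empty)."""

    mesenchymal: tuple[str, ...] = field(default=MES_MARKERS)
    epithelial: tuple[str, ...] = field(default=EPI_MARKERS)

    def __post_init__(self) -> None:
        if not self.mesenchymal or not self.epithelial:
            raise ValueError("both marker lists must be non-empty")
        overlap = set(self.mesenchymal) & set(self.epithelial)
        if overlap:
            raise ValueError(f"marker lists overlap: {sorted(overlap)}")

    @classmethod
    def from_dict(cls, d: dict) -> "MarkerPanel":
        return cls(mesenchymal=tuple(d["mesenchymal"]),
                   epithelial=tuple(d["epithelial"]))


def aggregate_marker_score(expr: ExpressionMatrix, markers) -> pd.Series:
    """Per-sample mean of log2(TPM+1) over the given marker genes."""
    markers = list(markers)
    if not markers:
        raise InsufficientCohortError("need at least one marker gene")
    expr.require_features(markers)
    return expr.log2p1(markers).mean(axis=1)


def classify_emt_quadrants(expr: ExpressionMatrix, panel: MarkerPanel | None = None,
                           score_mode: str = "mean_log") -> pd.DataFrame:
    """Classify every sample into one of the four EMT quadrant phenotypes.

    Parameters
    ----------
    score_mode
        ``"mean_log"`` (default): aggregate = per-sample mean of marker
        log2(TPM+1) values, then median-split the aggregates ("rank of the
        average").  ``"mean_rank"``: aggregate = per-sample mean of each
        marker's within-cohort rank ("average of the ranks").

    Returns
    -------
    DataFrame indexed by sample id, in input order, with columns
    mes_score, epi_score, mes_top, epi_top, phenotype.
    """
    if panel is None:
        panel = MarkerPanel()
    if expr.n_samples < 4:
        raise InsufficientCohortError(
            f"need >= 4 samples to median-split, got {expr.n_samples}"
        )
    if score_mode == "mean_log":
        mes = aggregate_marker_score(expr, panel.mesenchymal)
        epi = aggregate_marker_score(expr, panel.epithelial)
    elif score_mode == "mean_rank":
        log = expr.log2p1()
        mes = pd.Series(
            rankdata(log[list(panel.mesenchymal)], axis=0).mean(axis=1),
            index=log.index)
        epi = pd.Series(
            rankdata(log[list(panel.epithelial)], axis=0).mean(axis=1),
            index=log.index)
    else:
        raise ValueError(f"unknown score_mode {score_mode!r}")

    mes_top = mes > mes.median()
    epi_top = epi > epi.median()
    phenotype = np.where(mes_top & epi_top, "HighOverlap",
                np.where(mes_top & ~epi_top, "Mesenchymal",
                np.where(~mes_top & epi_top, "Epithelial", "LowOverlap")))
    return pd.DataFrame({
        "mes_score": mes, "epi_score": epi,
        "mes_top": mes_top, "epi_top": epi_top,
        "phenotype": phenotype,
    }, index=mes.index)


def split_by_median_gene(expr: ExpressionMatrix, feature_id: str) -> pd.Series:
    """Median split on one gene: 'top' iff strictly above the cohort median."""
    if expr.n_samples < 2:
        raise InsufficientCohortError("need >= 2 samples to median-split")
    vals = np.log2(expr.feature(feature_id) + 1.0)
    return pd.Series(np.where(vals > vals.median(), "top", "bottom"),
                     index=vals.index, name=f"{feature_id}_median_group")


def phenotype_association_test(calls: pd.DataFrame, labels: pd.Series) -> stats.TestResult:
    """Chi-square test of independence between phenotype and a second label.

    ``labels`` is aligned to ``calls`` on the sample index.  Expected counts
    and a low-expected-count warning flag ride along in ``extra``.
    """
    labels = labels.reindex(calls.index)
    if labels.isna().any():
        raise InsufficientCohortError("labels missing for some classified samples")
    if labels.nunique() < 2:
        raise DegenerateInputError("labels have a single level; association undefined")
    table = pd.crosstab(calls["phenotype"], labels)
    res = stats.chi_square(table.to_numpy())
    res.extra["table"] = table
    return res


def compare_across_phenotypes(values: pd.Series, calls: pd.DataFrame):
    """One-way ANOVA plus all pairwise Tukey HSD comparisons across phenotypes.

    Phenotype groups with fewer than 2 samples are dropped (with a warning
    from the stats kernel).  Returns ``(anova_result, tukey_results)``.
    """
    values = values.reindex(calls.index)
    groups, labels = [], []
    for ph in PHENOTYPES:
        g = values[calls["phenotype"] == ph].dropna().to_numpy()
        if len(g):
            groups.append(g)
            labels.append(ph)
    anova = stats.anova_oneway(groups)
    kept = [(g, l) for g, l in zip(groups, labels) if len(g) >= 2]
    tukey = stats.tukey_hsd([g for g, _ in kept], labels=[l for _, l in kept])
    return anova, tukey
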