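"""Synthetic cohorts, cell-line panels, and qPCR plates.

The generators reproduce the statistical structure the downstream analyses
assume, so the whole pipeline is exercisable without any external data:

* isoform expression — bivariate Gaussian log2(TPM+1) for the KRAB and
  KRAB-less isoforms with configurable correlation; the KRAB location is
  placed so the expected fraction of tumors above the TPM cutoff equals
  ``high_fraction``, and each tumor's side of the cutoff is planted
  explicitly (Bernoulli label, then a truncated normal on that side — the
  mixture marginal is exactly the untruncated normal);
* EMT markers — two correlated latent epithelial/mesenchymal axes drive
  the 14 marker genes through per-marker loadings plus residual noise;
  TPM = 2^x − 1 truncated at 0, so log2(TPM+1) analyses downstream see
  exactly Gaussian values;
* survival — exponential event times whose log-hazard is
  ``true_log_hr × 1[high-KRAB]`` (optionally restricted to one latent
  phenotype), with uniform administrative censoring;
* drug response — per-drug Gaussian log-IC50/EC50; hidden
  resistant/sensitive labels are derived from the generating distribution's
  own mean ± 0.5·SD thresholds, and resistant lines receive a planted
  log2 expression shift in designated genes;
* gene effects — Gaussian raw scores per control class (essential,
  non-essential, query), ready for two-point control anchoring;
* qPCR — triplicate Ct values from planted per-sample ΔCt with Gaussian
  technical noise.

Ground truth (latent phenotypes, planted high/low labels, hidden response
categories) is returned as an explicit sidecar object that analysis code
never reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .config import EPI_MARKERS, MES_MARKERS, QpcrParams, SimConfig
from .dataio import ExpressionMatrix, QpcrPlate
from .errors import ConfigurationError


@dataclass(frozen=True)
class CohortTruth:
    """Ground truth planted in a simulated tumor cohort (sidecar only)."""

    phenotype: pd.Series       # latent EMT quadrant per sample
    high_krab: pd.Series       # planted above-cutoff indicator per sample
    true_log_hr: float

    def to_dict(self) -> dict:
        return {
            "phenotype": self.phenotype.to_dict(),
            "high_krab": {k: bool(v) for k, v in self.high_krab.items()},
            "true_log_hr": self.true_log_hr,
        }


@dataclass(frozen=True)
class PanelTruth:
    """Ground truth planted in a simulated cell-line panel (sidecar only)."""

    response: pd.DataFrame     # cell line × drug hidden category
    shifts: dict               # drug -> (shift, shift_genes)

    def to_dict(self) -> dict:
        return {
            "response": {c: self.response[c].to_dict() for c in self.response.columns},
            "shifts": {d: {"shift": s, "genes": list(g)}
                       for d, (s, g) in self.shifts.items()},
        }


def _sample_ids(prefix: str, n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def _quadrant_labels(epi_axis: np.ndarray, mes_axis: np.ndarray) -> np.ndarray:
    """Median-split quadrant of the latent axes (same tie rule as the classifier)."""
    epi_top = epi_axis > np.median(epi_axis)
    mes_top = mes_axis > np.median(mes_axis)
    out = np.where(mes_top & epi_top, "HighOverlap",
          np.where(mes_top & ~epi_top, "Mesenchymal",
          np.where(~mes_top & epi_top, "Epithelial", "LowOverlap")))
    return out


def _isoform_logexpr(cfg: SimConfig, n: int, rng: np.random.Generator):
    """Planted high/low labels and correlated isoform log2(TPM+1) values."""
    c = np.log2(cfg.tpm_cutoff + 1.0)
    mu, sd, rho = cfg.krab_mu, cfg.logsd, cfg.iso_corr_rho
    high = rng.random(n) < cfg.high_fraction
    x_krab = np.empty(n)
    a_hi, a_lo = (c - mu) / sd, -np.inf
    n_hi = int(high.sum())
    if n_hi:
        x_krab[high] = truncnorm.rvs(a_hi, np.inf, loc=mu, scale=sd,
                                     size=n_hi, random_state=rng)
    if n - n_hi:
        x_krab[~high] = truncnorm.rvs(a_lo, a_hi, loc=mu, scale=sd,
                                      size=n - n_hi, random_state=rng)
    eps = rng.standard_normal(n)
    x_krabless = (cfg.krabless_mu + rho * (x_krab - mu)
                  + sd * np.sqrt(1.0 - rho**2) * eps)
    return high, x_krab, x_krabless


def _tpm(logexpr: np.ndarray) -> np.ndarray:
    return np.maximum(np.exp2(logexpr) - 1.0, 0.0)


def _marker_block(cfg: SimConfig, n: int, rng: np.random.Generator):
    """Latent EMT axes and the 14 marker TPM columns they drive."""
    corr = cfg.emt_axis_corr
    z = rng.standard_normal((n, 2))
    epi_axis = z[:, 0]
    mes_axis = corr * z[:, 0] + np.sqrt(1.0 - corr**2) * z[:, 1]
    cols = {}
    for markers, axis in ((EPI_MARKERS, epi_axis), (MES_MARKERS, mes_axis)):
        for m in markers:
            x = (cfg.marker_baseline + cfg.marker_loading * axis
                 + cfg.noise_sd * rng.standard_normal(n))
            cols[m] = _tpm(x)
    return epi_axis, mes_axis, cols


def _expression_frame(cfg: SimConfig, ids: list[str], rng: np.random.Generator):
    high, x_krab, x_krabless = _isoform_logexpr(cfg, len(ids), rng)
    epi_axis, mes_axis, marker_cols = _marker_block(cfg, len(ids), rng)
    tpm_krab = _tpm(x_krab)
    tpm_krabless = _tpm(x_krabless)
    cols = {
        "ZNF71_overall": tpm_krab + tpm_krabless,
        "ZNF71_KRAB": tpm_krab,
        "ZNF71_KRABless": tpm_krabless,
        **marker_cols,
    }
    df = pd.DataFrame(cols, index=pd.Index(ids, name="sample_id"))
    return df, high, epi_axis, mes_axis


def simulate_cohort(config: SimConfig):
    """Simulate a tumor cohort.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame, CohortTruth)
        Expression (isoforms + 14 EMT markers), clinical table
        (sample_id, time, event, stage, histology, stromal_score), and the
        planted ground truth.
    """
    rng = np.random.default_rng(config.seed)
    ids = _sample_ids("T", config.n_tumors)
    df, high, epi_axis, mes_axis = _expression_frame(config, ids, rng)

    phenotype = _quadrant_labels(epi_axis, mes_axis)
    exposed = high.copy()
    if config.hr_phenotype is not None:
        exposed &= phenotype == config.hr_phenotype
    hazard = config.baseline_hazard * np.exp(config.true_log_hr * exposed)
    t_event = rng.exponential(1.0 / hazard)
    t_censor = rng.uniform(0.0, config.censor_max, size=config.n_tumors)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)

    stage = rng.choice(["I", "II", "III", "IV"], size=config.n_tumors,
                       p=[0.40, 0.25, 0.25, 0.10])
    histology = rng.choice(["adenocarcinoma", "squamous"], size=config.n_tumors,
                           p=[0.6, 0.4])
    # stromal infiltration tracks the mesenchymal axis (ESTIMATE-like scale)
    stromal = 800.0 * (config.stromal_corr * mes_axis
                       + np.sqrt(1 - config.stromal_corr**2)
                       * rng.standard_normal(config.n_tumors))

    clinical = pd.DataFrame({
        "sample_id": ids,
        "time": time,
        "event": event,
        "stage": stage,
        "histology": histology,
        "stromal_score": stromal,
    })
    truth = CohortTruth(
        phenotype=pd.Series(phenotype, index=ids, name="phenotype"),
        high_krab=pd.Series(high, index=ids, name="high_krab"),
        true_log_hr=config.true_log_hr,
    )
    return ExpressionMatrix(df), clinical, truth


def simulate_cell_lines(config: SimConfig):
    """Simulate a cell-line panel.

    Returns
    -------
    (ExpressionMatrix, pandas.DataFrame, pandas.DataFrame, PanelTruth)
        Expression matrix (isoforms, markers, optional background genes),
        drug-response table (cell_line, drug, ic50, ec50 on the log scale),
        long-format dependency table (cell_line, gene, raw_effect,
        control_label), and the hidden response labels.
    """
    if not config.drug_params:
        raise ConfigurationError("invalid config field 'drug_params': no drugs given")
    rng = np.random.default_rng(config.seed)
    n = config.n_cell_lines
    ids = _sample_ids("CL", n)
    df, _high, _epi, _mes = _expression_frame(config, ids, rng)

    if config.n_background_genes:
        bg = config.marker_baseline + rng.standard_normal((n, config.n_background_genes))
        bg_names = [f"BG{i + 1:05d}" for i in range(config.n_background_genes)]
        df = pd.concat([df, pd.DataFrame(_tpm(bg), index=df.index, columns=bg_names)],
                       axis=1)

    log2p1 = np.log2(df + 1.0)

    drug_rows = []
    hidden = {}
    shifts = {}
    for dp in config.drug_params:
        ic50 = rng.normal(dp.log_ic50_mean, dp.log_ic50_sd, size=n)
        ec50 = rng.normal(dp.log_ec50_mean, dp.log_ec50_sd, size=n)
        # hidden labels from the generating distribution's own thresholds
        hi = dp.log_ic50_mean + 0.5 * dp.log_ic50_sd
        lo = dp.log_ic50_mean - 0.5 * dp.log_ic50_sd
        cat = np.where(ic50 > hi, "resistant",
              np.where(ic50 < lo, "sensitive", "partial"))
        hidden[dp.name] = cat
        shifts[dp.name] = (dp.resistant_shift, dp.shift_genes)
        if dp.resistant_shift != 0.0:
            missing = [g for g in dp.shift_genes if g not in log2p1.columns]
            if missing:
                raise ConfigurationError(
                    f"invalid config field 'drug_params': shift_genes {missing} "
                    f"absent from the simulated expression matrix"
                )
            mask = cat == "resistant"
            for g in dp.shift_genes:
                log2p1.loc[mask, g] += dp.resistant_shift
        drug_rows.append(pd.DataFrame({
            "cell_line": ids, "drug": dp.name, "ic50": ic50, "ec50": ec50,
        }))
    drug_table = pd.concat(drug_rows, ignore_index=True)
    df = pd.DataFrame(_tpm(log2p1.to_numpy()), index=df.index, columns=df.columns)

    dep = config.dep_params
    gene_blocks = [
        ([f"ESS{i + 1:04d}" for i in range(dep.n_essential)],
         "essential", dep.essential_mean, dep.essential_sd),
        ([f"NE{i + 1:04d}" for i in range(dep.n_nonessential)],
         "non_essential", dep.nonessential_mean, dep.nonessential_sd),
        (list(dep.query_genes), "query", dep.query_mean, dep.query_sd),
    ]
    dep_rows = []
    for cl in ids:
        for genes, label, mean, sd in gene_blocks:
            raw = rng.normal(mean, sd, size=len(genes))
            dep_rows.append(pd.DataFrame({
                "cell_line": cl, "gene": genes, "raw_effect": raw,
                "control_label": label,
            }))
    dep_table = pd.concat(dep_rows, ignore_index=True)

    truth = PanelTruth(
        response=pd.DataFrame(hidden, index=pd.Index(ids, name="cell_line")),
        shifts=shifts,
    )
    return ExpressionMatrix(df), drug_table, dep_table, truth


def simulate_qpcr(config: SimConfig) -> QpcrPlate:
    """Simulate a triplicate qPCR plate (first sample = reference)."""
    rng = np.random.default_rng(config.seed)
    qp: QpcrParams = config.qpcr_params
    ids = _sample_ids("Q", qp.n_samples)
    if qp.delta_cts is not None:
        delta = np.asarray(qp.delta_cts, dtype=float)
    else:
        delta = rng.normal(qp.delta_ct_mean, qp.delta_ct_sd, size=qp.n_samples)
    rows = []
    rep_cols = [f"rep{i + 1}" for i in range(qp.n_replicates)]
    for i, sid in enumerate(ids):
        for target, true_ct in ((qp.target, qp.hk_ct_mean + delta[i]),
                                (qp.housekeeping, qp.hk_ct_mean)):
            reps = true_ct + qp.technical_sd * rng.standard_normal(qp.n_replicates)
            rows.append({"sample_id": sid, "target": target,
                         **dict(zip(rep_cols, reps))})
    data = pd.DataFrame(rows)
    return QpcrPlate(data, reference_sample_id=ids[0], housekeeping=qp.housekeeping)
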