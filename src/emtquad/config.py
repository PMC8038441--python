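"""Simulation configuration.

:class:`SimConfig` collects every knob of the synthetic-data generators in
:mod:`emtquad.datagen`: cohort and panel sizes, the log-normal isoform
expression model, the latent EMT axes that drive the 14 marker genes, the
planted survival effect, per-drug response distributions, dependency-screen
control distributions, and the qPCR plate layout.  All generator defaults
encode the structure of the study cohorts being emulated (197 tumors, 117
cell lines, 17% of tumors above the 1.5 TPM cutoff, ~60% observed events).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml
from scipy.stats import norm

from .errors import ConfigurationError

#: Mesenchymal marker genes of the quadrant classifier.
MES_MARKERS: tuple[str, ...] = ("ZEB1", "VIM", "FN1")

#: Epithelial marker genes of the quadrant classifier.
EPI_MARKERS: tuple[str, ...] = (
    "CDH1", "EPCAM", "ESRP1", "ESRP2", "DDR1", "CTNNB1",
    "CD24", "CLDN7", "KRT8", "KRT19", "RAB25",
)

#: Isoform / gene-level feature ids emitted by every generator.
ISOFORM_FEATURES: tuple[str, ...] = ("ZNF71_overall", "ZNF71_KRAB", "ZNF71_KRABless")

#: Chemotherapy drugs simulated by default.
DEFAULT_DRUGS: tuple[str, ...] = (
    "carboplatin", "cisplatin", "paclitaxel", "docetaxel", "gemcitabine",
    "vinorelbine", "etoposide", "gefitinib", "erlotinib",
)


def _require(cond: bool, field_name: str, msg: str) -> None:
    if not cond:
        raise ConfigurationError(f"invalid config field '{field_name}': {msg}")


@dataclass(frozen=True)
class DrugParams:
    """Per-drug log-IC50/log-EC50 distribution and planted expression shift.

    ``resistant_shift`` is added, on the log2(TPM+1) scale, to the
    expression of ``shift_genes`` in cell lines whose hidden response label
    for this drug is resistant.  A shift of 0 yields a null panel.
    """

    name: str
    log_ic50_mean: float = 0.0
    log_ic50_sd: float = 1.0
    log_ec50_mean: float = 0.0
    log_ec50_sd: float = 1.0
    resistant_shift: float = 0.0
    shift_genes: tuple[str, ...] = ("ZNF71_overall", "ZNF71_KRAB")

    def validate(self) -> None:
        _require(bool(self.name), "drug_params.name", "drug name must be non-empty")
        for f in ("log_ic50_sd", "log_ec50_sd"):
            _require(getattr(self, f) >= 0, f"drug_params.{f}", "SD must be >= 0")


@dataclass(frozen=True)
class DepParams:
    """Control-set and query-gene distributions for the dependency screen."""

    essential_mean: float = -1.2
    essential_sd: float = 0.2
    nonessential_mean: float = 0.05
    nonessential_sd: float = 0.15
    query_mean: float = 0.0
    query_sd: float = 0.15
    n_essential: int = 50
    n_nonessential: int = 200
    query_genes: tuple[str, ...] = ("ZNF71",)

    def validate(self) -> None:
        for f in ("essential_sd", "nonessential_sd", "query_sd"):
            _require(getattr(self, f) >= 0, f"dep_params.{f}", "SD must be >= 0")
        _require(self.n_essential >= 1, "dep_params.n_essential", "need >= 1 control")
        _require(self.n_nonessential >= 1, "dep_params.n_nonessential", "need >= 1 control")


@dataclass(frozen=True)
class QpcrParams:
    """Layout and noise model of the simulated triplicate qPCR plate.

    The first sample on the plate is the reference sample.  True per-sample
    ``delta_cts`` (Ct_target − Ct_housekeeping) may be given explicitly;
    otherwise they are drawn N(delta_ct_mean, delta_ct_sd).  Replicate Ct
    values add independent N(0, technical_sd) noise.
    """

    n_samples: int = 9
    target: str = "ZNF71_KRAB"
    housekeeping: str = "UBC"
    hk_ct_mean: float = 20.0
    delta_ct_mean: float = 5.0
    delta_ct_sd: float = 1.0
    technical_sd: float = 0.15
    n_replicates: int = 3
    delta_cts: tuple[float, ...] | None = None

    def validate(self) -> None:
        _require(self.n_samples >= 2, "qpcr_params.n_samples", "need >= 2 samples")
        _require(self.technical_sd >= 0, "qpcr_params.technical_sd", "SD must be >= 0")
        _require(self.delta_ct_sd >= 0, "qpcr_params.delta_ct_sd", "SD must be >= 0")
        _require(self.n_replicates >= 1, "qpcr_params.n_replicates", "need >= 1 replicate")
        if self.delta_cts is not None:
            _require(len(self.delta_cts) == self.n_samples, "qpcr_params.delta_cts",
                     f"expected {self.n_samples} values, got {len(self.delta_cts)}")


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the synthetic cohort / panel / plate generators.

    Parameters
    ----------
    seed
        Seed of the generator; identical configs produce identical outputs.
    n_tumors, n_cell_lines
        Cohort and panel sizes (defaults mirror the emulated study cohorts).
    iso_corr_rho
        Correlation between log KRAB and log KRAB-less isoform expression.
    krab_logmean
        Location of log2(KRAB TPM + 1).  ``None`` (default) derives the
        location from ``high_fraction`` so that the expected fraction of
        samples with KRAB TPM >= ``tpm_cutoff`` equals ``high_fraction``.
    krabless_logmean
        Location of log2(KRAB-less TPM + 1); ``None`` = krab_logmean − 0.35
        (the KRAB isoform dominates in the emulated tumors; the gap keeps
        the zero-TPM floor rare so log-scale analyses stay Gaussian).
    logsd
        Scale of both isoform log-expressions.
    emt_axis_corr
        Correlation between the latent epithelial and mesenchymal axes.
    marker_loading, marker_baseline, noise_sd
        Each marker's log2 expression = baseline + loading·axis + N(0, noise_sd).
    true_log_hr
        Planted log hazard ratio of the high-KRAB group (default log 1.686).
    baseline_hazard
        Event rate per time unit of the low-KRAB group.
    censor_max
        Upper bound of the uniform administrative censoring time.
    high_fraction
        Probability a tumor is planted above the TPM cutoff (default 0.17).
    tpm_cutoff
        TPM cutoff of the high/low split (default 1.5).
    hr_phenotype
        When set to one of the four phenotype names, the planted hazard
        effect applies only to high-KRAB samples of that latent phenotype.
    n_background_genes
        Extra unshifted genes added to the cell-line expression matrix.
    stromal_corr
        Correlation of the simulated stromal score with the mesenchymal axis.
    """

    seed: int = 0
    n_tumors: int = 197
    n_cell_lines: int = 117
    iso_corr_rho: float = 0.6
    krab_logmean: float | None = None
    krabless_logmean: float | None = None
    logsd: float = 0.35
    emt_axis_corr: float = -0.3
    marker_loading: float = 1.5
    marker_baseline: float = 3.0
    noise_sd: float = 0.5
    true_log_hr: float = math.log(1.686)
    baseline_hazard: float = 0.037
    censor_max: float = 60.0
    high_fraction: float = 0.17
    tpm_cutoff: float = 1.5
    hr_phenotype: str | None = None
    n_background_genes: int = 0
    stromal_corr: float = 0.7
    drug_params: tuple[DrugParams, ...] = field(
        default_factory=lambda: tuple(
            DrugParams(name=d,
                       resistant_shift=1.0 if d in ("docetaxel", "paclitaxel") else 0.0)
            for d in DEFAULT_DRUGS
        )
    )
    dep_params: DepParams = field(default_factory=DepParams)
    qpcr_params: QpcrParams = field(default_factory=QpcrParams)

    def __post_init__(self) -> None:
        _require(isinstance(self.seed, int), "seed", "must be an integer")
        _require(self.n_tumors >= 4, "n_tumors", "need >= 4 samples")
        _require(self.n_cell_lines >= 4, "n_cell_lines", "need >= 4 cell lines")
        for f in ("iso_corr_rho", "emt_axis_corr", "stromal_corr"):
            _require(-1.0 <= getattr(self, f) <= 1.0, f, "correlation must be in [-1, 1]")
        for f in ("logsd", "noise_sd"):
            _require(getattr(self, f) >= 0, f, "SD must be >= 0")
        _require(self.logsd > 0, "logsd", "must be > 0")
        _require(self.baseline_hazard > 0, "baseline_hazard", "must be > 0")
        _require(self.censor_max > 0, "censor_max", "must be > 0")
        _require(0.0 < self.high_fraction < 1.0, "high_fraction", "must be in (0, 1)")
        _require(self.n_background_genes >= 0, "n_background_genes", "must be >= 0")
        if self.hr_phenotype is not None:
            valid = ("Epithelial", "Mesenchymal", "HighOverlap", "LowOverlap")
            _require(self.hr_phenotype in valid, "hr_phenotype",
                     f"must be one of {valid}")
        for dp in self.drug_params:
            dp.validate()
        self.dep_params.validate()
        self.qpcr_params.validate()

    # -- derived expression locations -------------------------------------

    @property
    def krab_mu(self) -> float:
        """Location of log2(KRAB TPM + 1), derived from high_fraction if unset."""
        if self.krab_logmean is not None:
            return self.krab_logmean
        c = math.log2(self.tpm_cutoff + 1.0)
        return c - self.logsd * float(norm.ppf(1.0 - self.high_fraction))

    @property
    def krabless_mu(self) -> float:
        if self.krabless_logmean is not None:
            return self.krabless_logmean
        return self.krab_mu - 0.35

    # -- (de)serialisation -------------------------------------------------

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(
                f"invalid config field(s): {sorted(unknown)}; known fields: {sorted(known)}"
            )
        if "drug_params" in d:
            try:
                d["drug_params"] = tuple(
                    DrugParams(**{**dp, "shift_genes": tuple(dp.get("shift_genes",
                               DrugParams.__dataclass_fields__["shift_genes"].default))})
                    for dp in d["drug_params"]
                )
            except TypeError as e:
                raise ConfigurationError(f"invalid config field 'drug_params': {e}") from e
        for key, klass in (("dep_params", DepParams), ("qpcr_params", QpcrParams)):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                for tup_field in ("query_genes", "delta_cts"):
                    if tup_field in sub and sub[tup_field] is not None:
                        sub[tup_field] = tuple(sub[tup_field])
                try:
                    d[key] = klass(**sub)
                except TypeError as e:
                    raise ConfigurationError(f"invalid config field '{key}': {e}") from e
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigurationError(f"invalid config: {e}") from e


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON pipeline configuration file into a dict.

    Both formats are accepted regardless of extension (JSON is a YAML
    subset).  The top-level document must be a mapping.
    """
    text = Path(path).read_text(encoding="utf-8")
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError:
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as e:
            raise ConfigurationError(f"unparseable config file {path}: {e}") from e
    if not isinstance(doc, dict):
        raise ConfigurationError(f"config file {path} must contain a mapping")
    return doc
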