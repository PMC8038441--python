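"""Drug-response categorization, differential expression, and 2^-ddCt.

Cell lines are called resistant / sensitive / partial per drug from the
panel's own IC50 (or EC50) distribution: resistant strictly above
mean + 0.5·SD, sensitive strictly below mean − 0.5·SD, partial in between
(sample SD, n−1).  The rule is affine-invariant, so it does not matter
whether the values arrive on the log scale.  Resistant and sensitive
groups are then compared per gene with a two-sided t-test on log2(TPM+1);
partial responders sit out.  qPCR fold changes use the comparative
threshold (2^-ddCt) method against a designated reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats
from .dataio import ExpressionMatrix, QpcrPlate
from .errors import FormatError, InsufficientCohortError


def categorize_response(values) -> pd.Series:
    """Ternary response category from IC50/EC50 values.

    resistant iff v > mean + 0.5·SD; sensitive iff v < mean − 0.5·SD;
    otherwise partial.  Missing values are excluded from mean/SD and left
    uncategorized (NaN).  Needs >= 3 non-missing values.
    """
    ser = pd.Series(values, dtype=float)
    obs = ser.dropna()
    if len(obs) < 3:
        raise InsufficientCohortError(
            f"categorize_response needs >= 3 non-missing values, got {len(obs)}"
        )
    mean, sd = obs.mean(), obs.std(ddof=1)
    hi, lo = mean + 0.5 * sd, mean - 0.5 * sd
    cat = pd.Series(
        np.select([ser > hi, ser < lo], ["resistant", "sensitive"], default="partial"),
        index=ser.index, dtype=object)
    cat[ser.isna()] = np.nan
    return cat


def categorize_panel(drug_table: pd.DataFrame, metrics=("ic50", "ec50")) -> pd.DataFrame:
    """Add category_<metric> columns to a (cell_line, drug, ic50, ec50) table."""
    out = drug_table.copy()
    for metric in metrics:
        if metric not in out.columns:
            continue
        out[f"category_{metric}"] = pd.Series(np.nan, index=out.index, dtype=object)
        for drug, idx in out.groupby("drug").groups.items():
            vals = out.loc[idx, metric]
            if vals.notna().sum() >= 3:
                out.loc[idx, f"category_{metric}"] = categorize_response(vals)
    return out


def diff_expr_by_response(expr: ExpressionMatrix, categories,
                          pooled: bool = True) -> pd.DataFrame:
    """Resistant-vs-sensitive differential expression on log2(TPM+1).

    ``categories`` maps cell-line ids to resistant/sensitive/partial;
    partial lines are excluded.  Returns a per-feature DataFrame with
    mean_resistant, mean_sensitive, diff, t, p (uncorrected, two-sided;
    pooled-variance by default, Welch with ``pooled=False``).
    """
    cat = pd.Series(categories).reindex(expr.sample_ids)
    res_ids = cat.index[cat == "resistant"]
    sen_ids = cat.index[cat == "sensitive"]
    if len(res_ids) < 2 or len(sen_ids) < 2:
        raise InsufficientCohortError(
            f"need >= 2 resistant and >= 2 sensitive lines, got "
            f"{len(res_ids)} and {len(sen_ids)}"
        )
    log = expr.log2p1()
    x = log.loc[res_ids].to_numpy()
    y = log.loc[sen_ids].to_numpy()
    t, p = sps.ttest_ind(x, y, axis=0, equal_var=pooled)
    mr, ms = x.mean(axis=0), y.mean(axis=0)
    # zero-variance features with equal means: define t=0, p=1
    flat = ~np.isfinite(t)
    t = np.where(flat & (mr == ms), 0.0, t)
    p = np.where(flat & (mr == ms), 1.0, p)
    return pd.DataFrame({
        "mean_resistant": mr,
        "mean_sensitive": ms,
        "diff": mr - ms,
        "t": t,
        "p": np.clip(p, np.nextafter(0.0, 1.0), 1.0),
    }, index=log.columns.rename("feature"))


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (optional; off by default)."""
    return sps.false_discovery_control(np.asarray(p, dtype=float), method="bh")


@dataclass(frozen=True)
class FoldChange:
    sample_id: str
    delta_ct: float
    delta_delta_ct: float
    fold_change: float


def ddct_fold_change(plate: QpcrPlate, target: str | None = None) -> pd.DataFrame:
    """Relative expression per sample by the comparative threshold method.

    Replicate Ct values are averaged; dCt = Ct_target − Ct_housekeeping;
    ddCt = dCt_sample − dCt_reference; fold = 2^−ddCt.  The reference
    sample's fold change is exactly 1.
    """
    data = plate.data
    if target is None:
        others = [t for t in data["target"].unique() if t != plate.housekeeping]
        if len(others) != 1:
            raise FormatError(
                f"plate holds several non-housekeeping targets {others}; pass one"
            )
        target = others[0]
    reps = plate.rep_columns
    mean_ct = (data.assign(ct=data[reps].mean(axis=1))
                   .pivot_table(index="sample_id", columns="target", values="ct"))
    for needed in (target, plate.housekeeping):
        if needed not in mean_ct.columns or mean_ct[needed].isna().any():
            missing = (mean_ct.index[mean_ct[needed].isna()].tolist()
                       if needed in mean_ct.columns else "all samples")
            raise FormatError(f"missing Ct for target '{needed}' in samples {missing}")
    delta = mean_ct[target] - mean_ct[plate.housekeeping]
    ref = str(plate.reference_sample_id)
    if ref not in delta.index:
        raise FormatError(f"reference sample '{ref}' missing from plate")
    ddct = delta - delta.loc[ref]
    out = pd.DataFrame({
        "delta_ct": delta,
        "delta_delta_ct": ddct,
        "fold_change": np.exp2(-ddct),
    })
    return out.reindex(pd.unique(data["sample_id"]))
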