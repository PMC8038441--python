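"""Table containers and file formats.

All tabular formats are plain text: TSV for expression matrices, clinical
tables and dependency panels (tab is unambiguous inside gene ids), CSV for
drug-response panels and qPCR plates.  UTF-8, '.' decimal, mandatory
header; floats are written with 6 significant digits, so write/read
round-trips are exact to that precision.

Containers are thin wrappers over :class:`pandas.DataFrame` that enforce
the invariants every downstream analysis assumes (unique ids, finite
non-negative TPM, binary event flags, positive times).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, MissingFeatureError

_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Sample × feature TPM table.

    ``values`` is a DataFrame whose index holds unique sample ids and whose
    columns hold unique feature (gene or isoform) ids; every entry is a
    finite TPM value >= 0.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.values
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
            raise FormatError(f"non-numeric expression column(s): {list(bad)}")
        bad = ~np.isfinite(arr) | (arr < 0)
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise FormatError(
                f"negative or non-finite TPM at sample '{df.index[i]}', "
                f"feature '{df.columns[j]}': {arr[i, j]!r}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values.index)

    def feature(self, feature_id: str) -> pd.Series:
        """TPM of one feature across samples; raises if the id is absent."""
        if feature_id not in self.values.columns:
            raise MissingFeatureError(
                f"feature '{feature_id}' not in matrix; available e.g. "
                f"{list(self.values.columns[:5])}"
            )
        return self.values[feature_id]

    def require_features(self, ids) -> None:
        missing = [f for f in ids if f not in self.values.columns]
        if missing:
            raise MissingFeatureError(f"missing feature id(s): {missing}")

    def log2p1(self, features=None) -> pd.DataFrame:
        """log2(TPM + 1), the scale on which all expression tests operate."""
        df = self.values if features is None else self.values[list(features)]
        return np.log2(df + 1.0)

    def write_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id",
                           float_format=_FLOAT_FMT)


def read_expression_table(path: str | Path) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column sample ids, header = features)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as e:
        raise FormatError(f"cannot parse expression table {path}: {e}") from e
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[col].notna()]
            if len(bad_rows):
                raise FormatError(
                    f"non-numeric cell in {path} at sample '{bad_rows[0]}', "
                    f"feature '{col}': {df.loc[bad_rows[0], col]!r}"
                )
            df[col] = coerced
    if df.isna().to_numpy().any():
        i, j = map(int, np.argwhere(df.isna().to_numpy())[0])
        raise FormatError(
            f"missing value in {path} at sample '{df.index[i]}', feature '{df.columns[j]}'"
        )
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

REQUIRED_CLINICAL = ("sample_id", "time", "event")


def validate_clinical(df: pd.DataFrame, source: str = "clinical table") -> pd.DataFrame:
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise FormatError(f"{source}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"{source}: duplicate sample ids {dups}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    for col, check, what in (
        ("time", lambda s: (s > 0) & np.isfinite(s), "a positive finite time"),
        ("event", lambda s: s.isin([0, 1]), "a binary 0/1 event flag"),
    ):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~check(vals) | vals.isna()
        if bad.any():
            row = df.loc[bad, "sample_id"].iloc[0]
            raise FormatError(
                f"{source}: column '{col}' of sample '{row}' is "
                f"{df.loc[bad, col].iloc[0]!r}, expected {what}"
            )
        df[col] = vals
    df["event"] = df["event"].astype(int)
    return df


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a clinical TSV (sample_id, time, event, extras)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as e:
        raise FormatError(f"cannot parse clinical table {path}: {e}") from e
    return validate_clinical(df, source=str(path))


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Drug-response panel
# ---------------------------------------------------------------------------

def read_drug_table(path: str | Path) -> pd.DataFrame:
    """Read a drug-response CSV (cell_line, drug, ic50, ec50; blank = missing)."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as e:
        raise FormatError(f"cannot parse drug table {path}: {e}") from e
    missing = [c for c in ("cell_line", "drug") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    if not any(c in df.columns for c in ("ic50", "ec50")):
        raise FormatError(f"{path}: need at least one of 'ic50', 'ec50'")
    for col in ("ic50", "ec50"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    df["cell_line"] = df["cell_line"].astype(str)
    return df


def write_drug_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Dependency panel
# ---------------------------------------------------------------------------

DEP_COLUMNS = ("cell_line", "gene", "raw_effect", "control_label")
CONTROL_LABELS = ("essential", "non_essential", "query")


def read_dependency_table(path: str | Path) -> pd.DataFrame:
    """Read a gene-effect TSV (cell_line, gene, raw_effect, control_label)."""
    try:
        df = pd.read_csv(path, sep="\t")
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as e:
        raise FormatError(f"cannot parse dependency table {path}: {e}") from e
    missing = [c for c in DEP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    bad = ~df["control_label"].isin(CONTROL_LABELS)
    if bad.any():
        raise FormatError(
            f"{path}: unknown control_label {df.loc[bad, 'control_label'].iloc[0]!r}; "
            f"expected one of {CONTROL_LABELS}"
        )
    df["raw_effect"] = pd.to_numeric(df["raw_effect"], errors="raise")
    return df


def write_dependency_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# qPCR plate
# ---------------------------------------------------------------------------

@dataclass
class QpcrPlate:
    """Triplicate Ct values per (sample, target) plus plate metadata.

    ``data`` columns: sample_id, target, rep1..repK.  ``housekeeping`` names
    the target whose rows normalise the others; ``reference_sample_id``
    names the calibrator sample of the 2^-ddCt method.
    """

    data: pd.DataFrame
    reference_sample_id: str
    housekeeping: str

    def __post_init__(self) -> None:
        cols = set(self.data.columns)
        if not {"sample_id", "target"} <= cols:
            raise FormatError("qPCR plate needs 'sample_id' and 'target' columns")
        if not self.rep_columns:
            raise FormatError("qPCR plate needs at least one 'rep*' column")
        samples = set(self.data["sample_id"].astype(str))
        if str(self.reference_sample_id) not in samples:
            raise FormatError(
                f"reference sample '{self.reference_sample_id}' absent from plate"
            )
        hk = self.data[self.data["target"] == self.housekeeping]
        missing = samples - set(hk["sample_id"].astype(str))
        if missing:
            raise FormatError(
                f"sample(s) without housekeeping target '{self.housekeeping}': "
                f"{sorted(missing)}"
            )

    @property
    def rep_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("rep")]

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#reference={self.reference_sample_id}\n")
            fh.write(f"#housekeeping={self.housekeeping}\n")
            self.data.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_qpcr_plate(path: str | Path) -> QpcrPlate:
    """Read a qPCR CSV with '#reference=' and '#housekeeping=' header lines."""
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, val = line[1:].strip().partition("=")
            meta[key] = val
            body_start = i + 1
        else:
            break
    for key in ("reference", "housekeeping"):
        if key not in meta:
            raise FormatError(f"{path}: missing '#{key}=<id>' header line")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    df["sample_id"] = df["sample_id"].astype(str)
    return QpcrPlate(df, reference_sample_id=meta["reference"],
                     housekeeping=meta["housekeeping"])


# ---------------------------------------------------------------------------
# Sample alignment
# ---------------------------------------------------------------------------

def align_samples(expr: ExpressionMatrix, clinical: pd.DataFrame,
                  min_overlap: int = 4):
    """Intersect expression and clinical sample ids, preserving expression order.

    Returns ``(expr_subset, clinical_subset, n_dropped)``.  Raises
    :class:`FormatError` if the intersection holds fewer than ``min_overlap``
    samples.
    """
    clin_ids = set(clinical["sample_id"])
    keep = [s for s in expr.sample_ids if s in clin_ids]
    n_dropped = (len(expr.sample_ids) - len(keep)) + (len(clin_ids) - len(keep))
    if len(keep) < min_overlap:
        raise FormatError(
            f"expression/clinical overlap has only {len(keep)} samples (< {min_overlap})"
        )
    sub_expr = ExpressionMatrix(expr.values.loc[keep])
    sub_clin = clinical.set_index("sample_id").loc[keep].reset_index()
    return sub_expr, sub_clin, n_dropped
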