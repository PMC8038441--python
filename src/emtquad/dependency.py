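"""Gene-effect normalization and dependency calls.

Knockout/knockdown screens report a per-(cell line, gene) growth effect.
Scores are made comparable across cell lines by a two-point affine map
anchored on control gene sets: after normalization the median effect of
the non-essential controls is exactly 0 and the median effect of the
essential controls is exactly −1, per cell line.  A gene is called a
dependency in a cell line when its normalized score is <= −0.5.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

DEFAULT_THRESHOLD = -0.5


def normalize_gene_effects(raw: pd.Series, essential_ids, noness_ids) -> pd.Series:
    """Anchor raw gene effects on the control medians of one cell line.

    f(x) = (x − m_ne) / (m_ne − m_e) with m_ne, m_e the medians of the
    non-essential and essential control sets; by construction
    f(m_ne) = 0 and f(m_e) = −1.  Monotone and invariant to affine
    pre-transforms of the raw scores.
    """
    raw = pd.Series(raw, dtype=float)
    essential_ids = [g for g in essential_ids]
    noness_ids = [g for g in noness_ids]
    if not essential_ids or not noness_ids:
        raise DegenerateInputError("both control sets must be non-empty")
    missing = [g for g in essential_ids + noness_ids if g not in raw.index]
    if missing:
        raise DegenerateInputError(f"control gene(s) absent from scores: {missing}")
    m_e = float(raw.loc[essential_ids].median())
    m_ne = float(raw.loc[noness_ids].median())
    if m_ne == m_e:
        raise DegenerateInputError(
            f"control medians coincide ({m_ne}); normalization degenerate"
        )
    return (raw - m_ne) / (m_ne - m_e)


def normalize_panel(dep_table: pd.DataFrame) -> pd.DataFrame:
    """Apply the two-point normalization per cell line on a long-format panel.

    Expects columns cell_line, gene, raw_effect, control_label; returns a
    copy with a normalized_effect column added.
    """
    out = dep_table.copy()
    out["normalized_effect"] = np.nan
    for _cl, idx in out.groupby("cell_line").groups.items():
        sub = out.loc[idx]
        raw = pd.Series(sub["raw_effect"].to_numpy(), index=sub["gene"].to_numpy())
        ess = sub.loc[sub["control_label"] == "essential", "gene"]
        ne = sub.loc[sub["control_label"] == "non_essential", "gene"]
        norm = normalize_gene_effects(raw, ess, ne)
        out.loc[idx, "normalized_effect"] = norm.to_numpy()
    return out


def call_dependency(normalized, threshold: float = DEFAULT_THRESHOLD):
    """Binary dependency calls from normalized scores.

    dependent iff score <= threshold.  Returns ``(calls, summary)`` where
    ``summary`` reports the dependent fraction and an overall verdict:
    "no significant effect" when no cell line crosses the threshold.
    """
    ser = pd.Series(normalized, dtype=float)
    calls = pd.Series(np.where(ser <= threshold, "dependent", "not_dependent"),
                      index=ser.index, dtype=object)
    frac = float((calls == "dependent").mean()) if len(calls) else 0.0
    summary = {
        "n_cell_lines": int(len(calls)),
        "n_dependent": int((calls == "dependent").sum()),
        "dependent_fraction": frac,
        "threshold": float(threshold),
        "verdict": "no significant effect" if frac == 0.0 else "dependency detected",
    }
    return calls, summary
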