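"""Build the QSAR analysis table from a labeled descriptor matrix.

Descriptors arrive precomputed (one numeric column per descriptor, one row
per drug, plus name / SMILES / label / curation flags).  Preparation applies
the curation rules: flagged rows (mixtures, large peptides, biologics,
inorganic or organometallic compounds, unresolved names) and duplicate drug
rows are removed; descriptor columns with any missing value, zero variance,
or perfect pairwise collinearity (r^2 = 1) are dropped.

A small RDKit-based utility computes 2D stand-ins (topological polar surface
area, Lipinski acceptor count) for a subset of descriptors from SMILES; the
stand-ins are not equivalent to force-field-optimized 3D descriptors and are
only order-of-magnitude comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .synthetic import EXCLUSION_REASONS

#: Columns that are metadata, never descriptors.
META_COLUMNS = ("drug_name", "smiles", "label")


@dataclass
class PruningReport:
    """What column pruning removed and why."""

    dropped_missing: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)
    dropped_collinear: list[tuple[str, str]] = field(default_factory=list)  # (kept, dropped)

    def to_dict(self) -> dict:
        return {
            "dropped_missing": self.dropped_missing,
            "dropped_constant": self.dropped_constant,
            "dropped_collinear": [list(p) for p in self.dropped_collinear],
        }


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """Numeric descriptor columns (everything but metadata and flags)."""
    return [c for c in matrix.columns
            if c not in META_COLUMNS and not c.startswith("excl_")
            and pd.api.types.is_numeric_dtype(matrix[c])]


def apply_row_exclusions(matrix: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Remove flagged and duplicate drug rows; return (matrix, removal log).

    Exclusion is flag-driven: each ``excl_<reason>`` boolean column marks
    rows curated out for that reason.  Duplicate drug names keep the first
    occurrence.
    """
    log: dict[str, int] = {}
    out = matrix
    for reason in EXCLUSION_REASONS:
        col = f"excl_{reason}"
        if col in out.columns:
            flagged = out[col].fillna(False).astype(bool)
            log[reason] = int(flagged.sum())
            out = out[~flagged]
    if "drug_name" in out.columns:
        before = len(out)
        out = out.drop_duplicates("drug_name", keep="first")
        log["duplicate"] = before - len(out)
    return out.reset_index(drop=True), log


def prune_columns(matrix: pd.DataFrame,
                  r2_tolerance: float = 1e-12) -> tuple[pd.DataFrame, PruningReport]:
    """Drop descriptor columns with missing values or perfect collinearity.

    Order of rules: (1) any column containing a missing value is dropped;
    (2) constant columns are dropped (correlation undefined); (3) for each
    unordered pair with pairwise Pearson r^2 >= 1 - ``r2_tolerance``, the
    later column in input order is dropped and the earlier kept.  Surviving
    columns keep their values untouched, so the operation is idempotent.
    """
    report = PruningReport()
    features = feature_columns(matrix)

    survivors = []
    for col in features:
        if matrix[col].isna().any():
            report.dropped_missing.append(col)
        elif matrix[col].nunique() <= 1:
            report.dropped_constant.append(col)
        else:
            survivors.append(col)

    if survivors:
        values = matrix[survivors].to_numpy(dtype=float)
        corr = np.corrcoef(values, rowvar=False)
        r2 = corr ** 2
        kept: list[int] = []
        for j in range(len(survivors)):
            partner = next((i for i in kept if r2[i, j] >= 1.0 - r2_tolerance),
                           None)
            if partner is None:
                kept.append(j)
            else:
                report.dropped_collinear.append(
                    (survivors[partner], survivors[j]))
        survivors = [survivors[j] for j in kept]

    dropped = (set(report.dropped_missing) | set(report.dropped_constant)
               | {d for _, d in report.dropped_collinear})
    columns = [c for c in matrix.columns if c not in dropped]
    return matrix[columns].copy(), report


def prepare_qsar_table(matrix: pd.DataFrame,
                       r2_tolerance: float = 1e-12
                       ) -> tuple[pd.DataFrame, dict, PruningReport]:
    """Full preparation: row exclusions then column pruning."""
    rows, row_log = apply_row_exclusions(matrix)
    pruned, report = prune_columns(rows, r2_tolerance)
    return pruned, row_log, report


def compute_open_descriptors(smiles_list) -> pd.DataFrame:
    """2D descriptor stand-ins from SMILES via RDKit.

    Returns a frame with ``tpsa`` (topological polar surface area, A^2) and
    ``lipinski_acceptors`` (the Lipinski rule-of-five acceptor count, i.e.
    the number of N and O atoms), plus a ``parsed`` flag;
    unparseable SMILES are flagged and left as NaN.  These 2D values are
    stand-ins for 3D polar-surface-area / acceptor-count descriptors and are
    not numerically equivalent to them.
    """
    from rdkit import Chem, RDLogger
    from rdkit.Chem import Descriptors, Lipinski

    RDLogger.DisableLog("rdApp.error")
    rows = []
    for smi in smiles_list:
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        if mol is None:
            rows.append((smi, np.nan, np.nan, False))
        else:
            rows.append((smi, Descriptors.TPSA(mol),
                         float(Lipinski.NOCount(mol)), True))
    return pd.DataFrame(rows, columns=["smiles", "tpsa",
                                       "lipinski_acceptors", "parsed"])


def class_summary(matrix: pd.DataFrame, descriptor: str) -> dict:
    """Per-class mean/sd and a two-sided rank-sum test for one descriptor.

    Uses the Wilcoxon rank-sum (Mann-Whitney) test.  A constant descriptor
    makes the test degenerate; the result is flagged rather than raised.
    """
    from scipy import stats

    if descriptor not in matrix.columns:
        raise DataError(f"descriptor {descriptor!r} not in matrix")
    groups = {lab: matrix.loc[matrix["label"] == lab, descriptor].dropna()
              for lab in ("positive", "negative")}
    if any(len(g) == 0 for g in groups.values()):
        raise DataError("both classes must be non-empty")
    pos, neg = groups["positive"], groups["negative"]
    degenerate = (pos.nunique() <= 1 and neg.nunique() <= 1
                  and pos.iloc[0] == neg.iloc[0])
    if degenerate:
        p_value = float("nan")
    else:
        p_value = float(stats.mannwhitneyu(pos, neg,
                                           alternative="two-sided").pvalue)
    return {
        "descriptor": descriptor,
        "positive_mean": float(pos.mean()), "positive_sd": float(pos.std(ddof=1)),
        "negative_mean": float(neg.mean()), "negative_sd": float(neg.std(ddof=1)),
        "rank_sum_p": p_value,
        "degenerate": bool(degenerate),
        "n_positive": int(len(pos)), "n_negative": int(len(neg)),
    }
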