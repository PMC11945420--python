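"""Per-drug disproportionality statistics and positive/negative labeling.

For each drug the analysis table is collapsed to the 2x2 contingency table

    a: target-event reports of the drug     b: other reports of the drug
    c: target-event reports of other drugs  d: other reports of other drugs

from which the reporting odds ratio (ROR, with the Haldane-Anscombe +0.5
correction to every cell), a two-sided Fisher exact p-value and the phi
coefficient are computed.  A drug is labeled positive when ROR > 1,
p < 0.05 and it has at least 100 reports in total (a + b); negative when
ROR < 1 under the same p and report-count gates; otherwise unclassified.
The same statistics drive the volcano plot (x = ln ROR, y = -log10 p).

The +0.5 correction applies to the ROR only; the exact test and phi use the
raw integer counts (an exact test requires integers, and the correction
exists to stabilize the odds-ratio estimate, not the test).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, SchemaError
from .synthetic import TARGET_EVENT_TERM

#: -log10(p) is clipped here so underflowing p-values stay plottable.
NEG_LOG10_CLIP = 300.0

#: Below this table total, the Fisher p-value is computed by exact integer
#: enumeration (exact tie handling); above it, scipy's implementation of the
#: same minimum-likelihood rule is used.
_EXACT_ENUMERATION_LIMIT = 500


class ContingencyTable(NamedTuple):
    a: int  # target-event reports of the drug
    b: int  # other-event reports of the drug
    c: int  # target-event reports of all other drugs
    d: int  # other reports of all other drugs

    @property
    def total_reports(self) -> int:
        """The drug's total report count (a + b), the labeling gate."""
        return self.a + self.b


@dataclass(frozen=True)
class LabelCriteria:
    """Thresholds for calling a drug positive or negative for the event."""

    ror_positive_threshold: float = 1.0
    ror_negative_threshold: float = 1.0
    alpha: float = 0.05
    min_total_reports: int = 100

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise DataError("alpha must be in (0, 1)")
        if self.min_total_reports < 0:
            raise DataError("min_total_reports must be >= 0")


def build_contingency(analysis_table: pd.DataFrame, drug_name: str,
                      target_term: str = TARGET_EVENT_TERM) -> ContingencyTable:
    """Count the 2x2 table for one drug against all others."""
    if analysis_table.empty:
        return ContingencyTable(0, 0, 0, 0)
    if "is_target_event" in analysis_table.columns:
        target = analysis_table["is_target_event"].to_numpy(dtype=bool)
    elif "pt" in analysis_table.columns:
        target = (analysis_table["pt"].astype("string").str.strip()
                  .str.casefold() == target_term.strip().casefold()).to_numpy()
    else:
        raise SchemaError("analysis table needs 'is_target_event' or 'pt'")
    is_drug = (analysis_table["drug_name"] == drug_name).to_numpy()
    a = int((is_drug & target).sum())
    b = int((is_drug & ~target).sum())
    c = int((~is_drug & target).sum())
    d = int((~is_drug & ~target).sum())
    return ContingencyTable(a, b, c, d)


def compute_ror(ct: ContingencyTable,
                correction: float = 0.5) -> tuple[float, float]:
    """Reporting odds ratio with a +``correction``-per-cell adjustment.

    Returns ``(ror, ln_ror)``.  With correction > 0 the estimate is finite
    and positive for every nonnegative integer table.
    """
    a, b, c, d = ct
    if min(a, b, c, d) < 0:
        raise DataError("contingency counts must be >= 0")
    k = correction
    denom = (b + k) * (c + k)
    if denom == 0:
        raise ZeroDivisionError(
            "ROR undefined: zero cell in b or c with no correction")
    ror = ((a + k) * (d + k)) / denom
    return ror, math.log(ror)


def fisher_exact_two_sided(ct: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value by the point-probability rule.

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed that of the observed table.
    Small tables are enumerated in exact integer arithmetic so ties are
    handled without floating-point ambiguity; large tables use scipy's
    implementation of the same rule.
    """
    a, b, c, d = ct
    for x in ct:
        if x < 0 or int(x) != x:
            raise DataError("Fisher's exact test needs nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    n = a + b + c + d
    if n == 0:
        return 1.0
    if n > _EXACT_ENUMERATION_LIMIT:
        return float(stats.fisher_exact([[a, b], [c, d]],
                                        alternative="two-sided")[1])
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    # Integer weights proportional to the hypergeometric pmf.
    weights = [math.comb(r1, k) * math.comb(n - r1, c1 - k)
               for k in range(lo, hi + 1)]
    observed = weights[a - lo]
    p = sum(w for w in weights if w <= observed) / sum(weights)
    return float(min(p, 1.0))


def phi_coefficient(ct: ContingencyTable) -> float:
    """Phi association coefficient on the raw counts; NaN if a margin is 0."""
    a, b, c, d = ct
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        return float("nan")
    return (a * d - b * c) / math.sqrt(margins)


def classify_drug(ror: float, fisher_p: float, total_reports: int,
                  criteria: LabelCriteria = LabelCriteria()) -> str:
    """Label a drug positive / negative / unclassified (strict inequalities)."""
    if total_reports < criteria.min_total_reports or not fisher_p < criteria.alpha:
        return "unclassified"
    if ror > criteria.ror_positive_threshold:
        return "positive"
    if ror < criteria.ror_negative_threshold:
        return "negative"
    return "unclassified"


def contingency_by_drug(analysis_table: pd.DataFrame,
                        target_term: str = TARGET_EVENT_TERM) -> pd.DataFrame:
    """Vectorized 2x2 counts for every drug in the analysis table."""
    if "is_target_event" in analysis_table.columns:
        target = analysis_table["is_target_event"].astype(bool)
    else:
        target = (analysis_table["pt"].astype("string").str.strip()
                  .str.casefold() == target_term.strip().casefold())
    counts = (pd.DataFrame({"drug_name": analysis_table["drug_name"],
                            "target": target})
              .groupby(["drug_name", "target"]).size().unstack(fill_value=0)
              .reindex(columns=[True, False], fill_value=0))
    out = pd.DataFrame({"drug_name": counts.index,
                        "a": counts[True].to_numpy(),
                        "b": counts[False].to_numpy()})
    total_target = int(out["a"].sum())
    total_other = int(out["b"].sum())
    out["c"] = total_target - out["a"]
    out["d"] = total_other - out["b"]
    return out.reset_index(drop=True)


def compute_signals(analysis_table: pd.DataFrame,
                    criteria: LabelCriteria = LabelCriteria(),
                    target_term: str = TARGET_EVENT_TERM) -> pd.DataFrame:
    """Per-drug signal table: counts, ROR, Fisher p, phi, label."""
    if analysis_table.empty:
        raise DataError("analysis table is empty")
    table = contingency_by_drug(analysis_table, target_term)
    rors, ps, phis = [], [], []
    for row in table.itertuples(index=False):
        ct = ContingencyTable(row.a, row.b, row.c, row.d)
        rors.append(compute_ror(ct)[0])
        ps.append(fisher_exact_two_sided(ct))
        phis.append(phi_coefficient(ct))
    table["ror"] = rors
    table["ln_ror"] = np.log(table["ror"])
    table["fisher_p"] = ps
    with np.errstate(divide="ignore"):
        table["neg_log10_p"] = np.minimum(-np.log10(table["fisher_p"]),
                                          NEG_LOG10_CLIP)
    table["phi"] = phis
    table["total_reports"] = table["a"] + table["b"]
    table["label"] = [
        classify_drug(r, p, t, criteria)
        for r, p, t in zip(table["ror"], table["fisher_p"],
                           table["total_reports"])
    ]
    return table


def volcano_coordinates(signals: pd.DataFrame,
                        min_total_reports: int = 100) -> pd.DataFrame:
    """Volcano-plot coordinates for drugs passing the report-count gate.

    x = ln ROR, y = -log10 Fisher p (clipped), point size/color = total
    report count.
    """
    kept = signals[signals["total_reports"] >= min_total_reports]
    return pd.DataFrame({
        "drug_name": kept["drug_name"],
        "x": kept["ln_ror"],
        "y": kept["neg_log10_p"],
        "total_reports": kept["total_reports"],
        "label": kept["label"],
    }).reset_index(drop=True)


def plot_volcano(coords: pd.DataFrame, path, alpha: float = 0.05) -> None:
    """Render the volcano plot to ``path`` (deterministic given the data)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    order = coords.sort_values("drug_name")
    sc = ax.scatter(order["x"], order["y"], c=order["total_reports"],
                    cmap="coolwarm", s=18, edgecolors="none")
    ax.axhline(-math.log10(alpha), linestyle=":", color="grey")
    ax.axvline(0.0, linestyle=":", color="grey")
    ax.set_xlabel("ln(ROR)")
    ax.set_ylabel("-log10(p)")
    fig.colorbar(sc, ax=ax, label="total reports")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
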