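"""The F-index: a single functional score per ABCA4 variant.

The F-index multiplies two WT-normalized quantities::

    E = relative expression of the variant               (fraction of WT)
    S = (stimulated - basal) activity of the variant
        / (stimulated - basal) activity of WT            (fraction of WT window)
    F = E * S

F near 1 means WT-like expression and substrate-stimulated ATPase activity;
F near 0 means the variant lacks expression and/or stimulation.  S (and hence
F) may be slightly negative when a dead variant's stimulated reading falls
below its basal reading.

Two computation modes are provided because replicate-averaged F-indexes do
not in general equal the F of the replicate-averaged E and S (a mean of
products is not a product of means):

``from_means``
    F computed from the per-variant summary means, with a first-order
    (delta-method) SD propagated from the three summary SDs.
``per_replicate``
    F computed within each experiment and then averaged, with the sample SD
    across experiments.  The two modes agree exactly on noiseless replicates.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import pandas as pd

from .errors import NoCommonExperimentsError, ZeroStimulationWindowError, ZeroWildTypeSignalError


class Severity(str, enum.Enum):
    """Functional-severity category assigned from the F-index."""

    SEVERE = "severe"
    MODERATE = "moderate"
    INDETERMINATE = "indeterminate"
    NORMAL_MILD = "normal_mild"

    @property
    def label(self) -> str:
        return {
            Severity.SEVERE: "Severe",
            Severity.MODERATE: "Moderate",
            Severity.INDETERMINATE: "Indeterminate",
            Severity.NORMAL_MILD: "Normal/mild",
        }[self]


@dataclass(frozen=True)
class SeverityBands:
    """Severity thresholds on F.

    Defaults: F < 0.15 severe; 0.15 <= F <= 0.50 moderate; F >= 0.70
    normal/mild.  The open interval (0.50, 0.70) is never named by the
    convention this score follows, so it is reported explicitly as
    ``indeterminate`` rather than silently snapped to a neighbour.
    """

    severe_max: float = 0.15
    moderate_max: float = 0.50
    normal_min: float = 0.70

    def __post_init__(self) -> None:
        if not (self.severe_max <= self.moderate_max <= self.normal_min):
            raise ValueError("severity thresholds must satisfy severe_max <= moderate_max <= normal_min")


DEFAULT_BANDS = SeverityBands()


@dataclass(frozen=True)
class FIndexResult:
    variant_id: str
    E: float
    S: float
    F: float
    F_sd: float
    severity: Severity
    method: str  # "from_means" | "per_replicate"


def _field(summary, name: str) -> float:
    """Read a field from an AssaySummary, a pandas row or a mapping."""
    if hasattr(summary, name):
        return float(getattr(summary, name))
    return float(summary[name])


def compute_E(summary_variant, summary_wt) -> float:
    """Relative expression of the variant as a fraction of WT.

    For summaries already on the %-of-WT scale (WT mean 100 by construction)
    this is simply ``mean/100``.
    """
    wt_mean = _field(summary_wt, "rel_expression_mean")
    if not wt_mean > 0:
        raise ZeroWildTypeSignalError(f"WT expression mean must be positive, got {wt_mean}")
    return _field(summary_variant, "rel_expression_mean") / wt_mean


def compute_S(summary_variant, summary_wt) -> float:
    """Relative substrate-stimulated activity: variant window over WT window."""
    wt_window = _field(summary_wt, "rel_stimulated_mean") - _field(summary_wt, "rel_basal_mean")
    if wt_window == 0:
        raise ZeroStimulationWindowError("WT stimulated minus basal activity is zero")
    window = _field(summary_variant, "rel_stimulated_mean") - _field(summary_variant, "rel_basal_mean")
    return window / wt_window


def compute_findex(E: float, S: float) -> float:
    """F = E * S (unrounded; round to 2 decimals only for tabular output)."""
    return E * S


def categorize_severity(F: float, bands: SeverityBands = DEFAULT_BANDS) -> Severity:
    if F < bands.severe_max:
        return Severity.SEVERE
    if F <= bands.moderate_max:
        return Severity.MODERATE
    if F < bands.normal_min:
        return Severity.INDETERMINATE
    return Severity.NORMAL_MILD


def propagate_f_sd(summary_variant, summary_wt) -> float:
    """First-order (delta-method) SD of the from-means F.

    Treats the variant's three summary means and the WT stimulated mean as
    independent with the reported SDs; the WT expression and basal means are
    100 by construction (their batch variation cancels in the per-experiment
    normalization) and carry no SD.
    """
    E = compute_E(summary_variant, summary_wt)
    S = compute_S(summary_variant, summary_wt)
    wt_expr = _field(summary_wt, "rel_expression_mean")
    wt_window = _field(summary_wt, "rel_stimulated_mean") - _field(summary_wt, "rel_basal_mean")
    se = _field(summary_variant, "rel_expression_sd")
    sb = _field(summary_variant, "rel_basal_sd")
    st = _field(summary_variant, "rel_stimulated_sd")
    sw = _field(summary_wt, "rel_stimulated_sd")
    var = (
        (S * se / wt_expr) ** 2
        + (E * st / wt_window) ** 2
        + (E * sb / wt_window) ** 2
        + (E * S * sw / wt_window) ** 2
    )
    return math.sqrt(var)


def findex_from_summaries(
    summary: pd.DataFrame, wt_id: str = "WT", bands: SeverityBands = DEFAULT_BANDS
) -> pd.DataFrame:
    """F-index for every variant in a summary table, from the summary means."""
    wt_rows = summary[summary["variant_id"] == wt_id]
    if wt_rows.empty:
        raise ZeroWildTypeSignalError(f"summary table contains no wild-type row ({wt_id!r})")
    wt = wt_rows.iloc[0]
    rows = []
    for _, row in summary.iterrows():
        E = compute_E(row, wt)
        S = compute_S(row, wt)
        F = compute_findex(E, S)
        rows.append(
            {
                "variant_id": row["variant_id"],
                "E": E,
                "S": S,
                "F": F,
                "F_sd": propagate_f_sd(row, wt),
                "severity": categorize_severity(F, bands).value,
                "method": "from_means",
            }
        )
    return pd.DataFrame(rows)


def findex_per_replicate(
    expression_rel: pd.DataFrame,
    atpase_rel: pd.DataFrame,
    wt_id: str = "WT",
    bands: SeverityBands = DEFAULT_BANDS,
) -> pd.DataFrame:
    """F computed within each experiment, then averaged across experiments.

    Requires the per-experiment relative tables produced by
    :func:`abca4func.assay.normalize_expression` and
    :func:`abca4func.assay.relative_atpase`.  For each variant, only
    experiments providing both its expression and its ATPase measurements
    (and the WT window) contribute.
    """
    wt_stim = (
        atpase_rel[atpase_rel["variant_id"] == wt_id]
        .set_index("experiment_id")["rel_stimulated"]
    )
    merged = expression_rel.merge(atpase_rel, on=["variant_id", "experiment_id"])
    merged = merged[merged["experiment_id"].isin(wt_stim.index)]
    wt_window = wt_stim.reindex(merged["experiment_id"]).to_numpy() - 100.0
    if (wt_window == 0).any():
        bad = sorted(merged.loc[wt_window == 0, "experiment_id"].unique())
        raise ZeroStimulationWindowError(f"WT stimulation window is zero in experiments {bad}")
    E = merged["rel_expression"].to_numpy() / 100.0
    S = (merged["rel_stimulated"].to_numpy() - merged["rel_basal"].to_numpy()) / wt_window
    merged = merged.assign(_F=E * S)

    rows = []
    for vid in expression_rel["variant_id"].unique():
        grp = merged[merged["variant_id"] == vid]
        if grp.empty:
            raise NoCommonExperimentsError(
                f"variant {vid!r} shares no experiments with both assays and WT"
            )
        f_vals = grp["_F"].to_numpy()
        F = float(f_vals.mean())
        F_sd = float(f_vals.std(ddof=1)) if f_vals.size > 1 else 0.0
        e_mean = float(grp["rel_expression"].mean()) / 100.0
        s_mean = float(((grp["rel_stimulated"] - grp["rel_basal"]) /
                        (wt_stim.reindex(grp["experiment_id"]).to_numpy() - 100.0)).mean())
        rows.append(
            {
                "variant_id": vid,
                "E": e_mean,
                "S": s_mean,
                "F": F,
                "F_sd": F_sd,
                "severity": categorize_severity(F, bands).value,
                "method": "per_replicate",
            }
        )
    return pd.DataFrame(rows)


def findex_table(
    summary: pd.DataFrame,
    findex: pd.DataFrame,
    localization: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assemble the study-style functional-data table (published layout).

    Columns: variant, relative expression +/- SD, intracellular localization
    (pass-through annotation), relative basal and stimulated activity +/- SD,
    F-index (2 dp) and predicted severity.
    """
    localization = localization or {}

    def fmt(mean: float, sd: float) -> str:
        if pd.isna(mean):
            return "."
        if sd == 0:
            return f"{mean:.0f}"
        return f"{mean:.0f} ± {sd:.0f}"

    merged = summary.merge(findex, on="variant_id")
    out = pd.DataFrame(
        {
            "variant_id": merged["variant_id"],
            "rel_expression": [fmt(m, s) for m, s in zip(merged["rel_expression_mean"], merged["rel_expression_sd"])],
            "localization": [localization.get(v, ".") for v in merged["variant_id"]],
            "rel_basal": [fmt(m, s) for m, s in zip(merged["rel_basal_mean"], merged["rel_basal_sd"])],
            "rel_stimulated": [fmt(m, s) for m, s in zip(merged["rel_stimulated_mean"], merged["rel_stimulated_sd"])],
            "F_index": [f"{f:.2f}" for f in merged["F"]],
            "predicted_severity": [Severity(s).label for s in merged["severity"]],
        }
    )
    return out
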