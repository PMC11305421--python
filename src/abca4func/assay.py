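"""Replicate-level assay normalization and summary statistics.

Raw inputs are per-experiment measurements for a set of ABCA4 constructs
expressed in HEK293T cells:

* Western-blot densitometry — band intensity of the tagged ABCA4 protein plus
  the intensity of a loading-control protein (Ezrin) for the same lane;
* ADP-Glo ATPase luminescence — a basal reading (no substrate), a reading
  stimulated with all-trans retinal (which forms the N-Ret-PE substrate in
  the assay buffer), and a 0-hour background reading for the same sample.

Everything is normalized *within* an experiment to that experiment's
wild-type (WT) measurements, so blot/plate batches are exchangeable:

* relative expression  = 100 * (band/loading)_variant / (band/loading)_WT
* relative basal       = 100 * (basal - background)_variant / (basal - background)_WT
* relative stimulated  = 100 * (stim  - background)_variant / (basal - background)_WT

Summaries are arithmetic means with sample (n-1) standard deviations across
independent experiments.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingWildTypeError, ZeroWildTypeSignalError

EXPRESSION_COLUMNS = ["variant_id", "experiment_id", "band_intensity", "loading_control_intensity"]
ATPASE_COLUMNS = ["variant_id", "experiment_id", "lum_basal", "lum_stimulated", "lum_background"]

#: Optional per-sample protein-amount scale factor for ATPase luminescence
#: (Coomassie-estimated amount); activities are divided by it. Defaults to 1.
AMOUNT_SCALE_COLUMN = "amount_scale"

MISSING_TOKEN = "."


@dataclass(frozen=True)
class ExpressionReplicate:
    """One Western-blot lane: band plus loading-control densitometry."""

    variant_id: str
    experiment_id: str
    band_intensity: float
    loading_control_intensity: float

    def __post_init__(self) -> None:
        if not self.loading_control_intensity > 0:
            raise ValueError("loading_control_intensity must be positive")
        if self.band_intensity < 0:
            raise ValueError("band_intensity must be nonnegative")


@dataclass(frozen=True)
class AtpaseReplicate:
    """One ADP-Glo sample: basal, stimulated and 0-hour background readings."""

    variant_id: str
    experiment_id: str
    lum_basal: float
    lum_stimulated: float
    lum_background: float
    amount_scale: float = 1.0


@dataclass(frozen=True)
class AssaySummary:
    """Per-variant summary on the %-of-WT scale (Table-style columns)."""

    variant_id: str
    rel_expression_mean: float
    rel_expression_sd: float
    rel_basal_mean: float
    rel_basal_sd: float
    rel_stimulated_mean: float
    rel_stimulated_sd: float
    n_replicates: int


def read_expression_table(path: str | Path) -> pd.DataFrame:
    """Read an expression replicate TSV (UTF-8, '.' for missing)."""
    df = pd.read_csv(path, sep="\t", na_values=MISSING_TOKEN, comment="#", dtype={"variant_id": str, "experiment_id": str})
    _require_columns(df, EXPRESSION_COLUMNS, "expression table")
    if (df["loading_control_intensity"] <= 0).any():
        raise ValueError("loading_control_intensity must be positive in every row")
    if (df["band_intensity"] < 0).any():
        raise ValueError("band_intensity must be nonnegative")
    return df


def read_atpase_table(path: str | Path) -> pd.DataFrame:
    """Read an ATPase replicate TSV; the amount_scale column is optional."""
    df = pd.read_csv(path, sep="\t", na_values=MISSING_TOKEN, comment="#", dtype={"variant_id": str, "experiment_id": str})
    _require_columns(df, ATPASE_COLUMNS, "atpase table")
    if AMOUNT_SCALE_COLUMN not in df.columns:
        df[AMOUNT_SCALE_COLUMN] = 1.0
    df[AMOUNT_SCALE_COLUMN] = df[AMOUNT_SCALE_COLUMN].fillna(1.0)
    return df


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required columns: {missing}")


def normalize_expression(
    replicates: pd.DataFrame, wt_id: str = "WT", *, on_missing_wt: str = "raise"
) -> pd.DataFrame:
    """Per-experiment relative expression as % of that experiment's WT.

    Parameters
    ----------
    replicates
        DataFrame with :data:`EXPRESSION_COLUMNS`.
    wt_id
        variant_id of the wild-type reference lane.
    on_missing_wt
        ``"raise"`` (default) raises :class:`MissingWildTypeError` naming the
        offending experiments; ``"drop"`` rejects those experiments' rows with
        a warning and continues.

    Returns a DataFrame with columns ``variant_id, experiment_id,
    rel_expression``. The WT rows come out exactly 100.
    """
    _require_columns(replicates, EXPRESSION_COLUMNS, "expression table")
    df = replicates.copy()
    wt = df[df["variant_id"] == wt_id].set_index("experiment_id")
    experiments = df["experiment_id"].unique()
    missing = sorted(set(experiments) - set(wt.index))
    if missing:
        if on_missing_wt == "drop":
            warnings.warn(f"dropping experiments without WT reference: {missing}", stacklevel=2)
            df = df[~df["experiment_id"].isin(missing)]
        else:
            raise MissingWildTypeError(
                f"experiments {missing} contain no wild-type ({wt_id!r}) lane"
            )
    if (wt["band_intensity"] <= 0).any():
        bad = sorted(wt.index[wt["band_intensity"] <= 0])
        raise ZeroWildTypeSignalError(f"zero WT band intensity in experiments {bad}")
    wt_ratio = wt["band_intensity"] / wt["loading_control_intensity"]
    ratio = df["band_intensity"].to_numpy() / df["loading_control_intensity"].to_numpy()
    rel = 100.0 * ratio / wt_ratio.reindex(df["experiment_id"]).to_numpy()
    out = df[["variant_id", "experiment_id"]].copy()
    out["rel_expression"] = rel
    # the WT lane is its own reference: force the identity exactly
    out.loc[out["variant_id"] == wt_id, "rel_expression"] = 100.0
    return out.reset_index(drop=True)


def relative_atpase(replicates: pd.DataFrame, wt_id: str = "WT") -> pd.DataFrame:
    """Background-corrected ATPase activities as % of WT basal, per experiment.

    Activities are ``(luminescence - background) / amount_scale``.  Negative
    background-corrected activities are retained as-is and flagged in the
    ``negative_activity`` column (clamping would bias S upward; genuinely
    inactive variants can yield a slightly negative F-index).
    """
    _require_columns(replicates, ATPASE_COLUMNS, "atpase table")
    df = replicates.copy()
    if AMOUNT_SCALE_COLUMN not in df.columns:
        df[AMOUNT_SCALE_COLUMN] = 1.0
    scale = df[AMOUNT_SCALE_COLUMN].fillna(1.0).to_numpy()
    act_basal = (df["lum_basal"].to_numpy() - df["lum_background"].to_numpy()) / scale
    act_stim = (df["lum_stimulated"].to_numpy() - df["lum_background"].to_numpy()) / scale

    df = df.assign(_act_basal=act_basal, _act_stim=act_stim)
    wt = df[df["variant_id"] == wt_id].set_index("experiment_id")
    experiments = df["experiment_id"].unique()
    missing = sorted(set(experiments) - set(wt.index))
    if missing:
        raise MissingWildTypeError(
            f"experiments {missing} contain no wild-type ({wt_id!r}) ATPase sample"
        )
    if (wt["_act_basal"] <= 0).any():
        bad = sorted(wt.index[wt["_act_basal"] <= 0])
        raise ZeroWildTypeSignalError(
            f"WT background-corrected basal activity is <= 0 in experiments {bad}"
        )
    denom = wt["_act_basal"].reindex(df["experiment_id"]).to_numpy()
    out = df[["variant_id", "experiment_id"]].copy()
    out["rel_basal"] = 100.0 * df["_act_basal"].to_numpy() / denom
    out["rel_stimulated"] = 100.0 * df["_act_stim"].to_numpy() / denom
    out["negative_activity"] = (df["_act_basal"].to_numpy() < 0) | (df["_act_stim"].to_numpy() < 0)
    out.loc[out["variant_id"] == wt_id, "rel_basal"] = 100.0
    return out.reset_index(drop=True)


def summarize_values(values) -> tuple[float, float, int, bool]:
    """Mean, sample SD (n-1), replicate count and a low-n flag.

    With a single value the SD is undefined and reported as 0.0, flagged.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    n = arr.size
    if n == 0:
        return (float("nan"), float("nan"), 0, True)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    return (mean, sd, n, n < 3)


def summarize(expression_rel: pd.DataFrame, atpase_rel: pd.DataFrame) -> pd.DataFrame:
    """Combine per-experiment relative values into per-variant summaries.

    Emits one row per variant with the :class:`AssaySummary` fields plus a
    ``low_n`` flag; a warning is issued for variants with fewer than three
    experiments for any assay.
    """

    def _agg(df: pd.DataFrame, col: str, prefix: str) -> pd.DataFrame:
        rows = []
        for vid, grp in df.groupby("variant_id", sort=False):
            mean, sd, n, low = summarize_values(grp[col])
            rows.append({"variant_id": vid, f"{prefix}_mean": mean, f"{prefix}_sd": sd,
                         f"{prefix}_n": n, f"{prefix}_low_n": low})
        return pd.DataFrame(rows)

    e = _agg(expression_rel, "rel_expression", "rel_expression")
    b = _agg(atpase_rel, "rel_basal", "rel_basal")
    s = _agg(atpase_rel, "rel_stimulated", "rel_stimulated")
    out = e.merge(b, on="variant_id", how="outer").merge(s, on="variant_id", how="outer")
    out["n_replicates"] = out[["rel_expression_n", "rel_basal_n", "rel_stimulated_n"]].min(axis=1).astype("Int64")
    out["low_n"] = out[["rel_expression_low_n", "rel_basal_low_n", "rel_stimulated_low_n"]].any(axis=1)
    low = out.loc[out["low_n"], "variant_id"].tolist()
    if low:
        warnings.warn(f"fewer than 3 independent experiments for: {low}", stacklevel=2)
    cols = ["variant_id", "rel_expression_mean", "rel_expression_sd", "rel_basal_mean",
            "rel_basal_sd", "rel_stimulated_mean", "rel_stimulated_sd", "n_replicates", "low_n"]
    return out[cols]


def write_summary_table(summary: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a summary TSV mirroring the assay columns of the published summary layout."""
    from .io import write_tsv

    write_tsv(summary, path, header_lines=header_lines)
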