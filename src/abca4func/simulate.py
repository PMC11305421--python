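"""Synthetic assay generator: replicate tables with controlled truth.

The generator emulates the measurement process the pipeline assumes:

* per experiment, a wild-type Western lane (band, loading control) and a
  wild-type ATPase sample (basal, stimulated, 0-hour background);
* per variant, a lane whose WT-normalized expression is ``true_E`` and an
  ATPase sample whose WT-normalized basal activity is ``true_basal`` and
  whose stimulation score is ``true_S`` — before noise.

Noise is multiplicative lognormal, which suits strictly positive intensity
data and matches reporting of spreads as a percentage of the mean.
``cv_expression`` and ``cv_luminescence`` are the coefficients of variation
of the variant's *relative* (WT-normalized) expression and activity: the
dominant experimental noise (loading, transfection, protein amount per
purification) is shared between the readings of one sample, so each
normalized quantity carries a single lognormal factor.  In particular the
basal and stimulated readings of a sample share their amount factor, and
the WT stimulated activity is its basal activity times
``wt_fold_stimulation`` within each experiment.  Backgrounds are drawn per
sample, added to every luminescence reading and recorded, so the pipeline's
background subtraction is exercised (and exact).

At zero cv the pipeline inverts the generator exactly:
``F = true_E * true_S`` for every variant.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import assay, findex
from .errors import SimulationSpecError


@dataclass(frozen=True)
class VariantSpec:
    """True state of one simulated variant."""

    variant_id: str
    true_E: float
    true_S: float
    true_basal: float = 1.0  # basal activity as a fraction of WT basal
    consequence: str | None = None
    revel: float | None = None
    spliceai: float | None = None
    gnomad_af: float | None = None
    gnomad_homozygotes: int | None = None
    passthrough_codes: str = ""


@dataclass(frozen=True)
class SimulationSpec:
    variants: tuple[VariantSpec, ...]
    n_replicates: int = 3
    cv_expression: float = 0.10
    cv_luminescence: float = 0.10
    wt_basal_lum: float = 1000.0
    wt_fold_stimulation: float = 1.71  # WT stimulated/basal activity ratio
    background_mean: float = 50.0
    seed: int = 0
    wt_id: str = "WT"
    wt_band: float = 100.0
    wt_loading: float = 10.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise SimulationSpecError("n_replicates must be >= 1")
        if self.cv_expression < 0 or self.cv_luminescence < 0:
            raise SimulationSpecError("coefficients of variation must be >= 0")
        if self.wt_basal_lum <= 0:
            raise SimulationSpecError("wt_basal_lum must be positive")
        if not self.variants:
            raise SimulationSpecError("at least one variant is required")


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-sigma**2 / 2, sigma=sigma, size=size)


def simulate_assays(spec: SimulationSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (expression, atpase) replicate tables for a spec.

    Deterministic given ``spec.seed``: the same spec yields byte-identical
    tables.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_replicates
    experiments = [f"E{i + 1}" for i in range(n)]

    expr_rows = []
    atp_rows = []

    # wild-type lanes/samples: their own draws define each experiment's scale
    wt_band = spec.wt_band * _lognormal_factors(rng, spec.cv_expression, n)
    wt_loading = spec.wt_loading * _lognormal_factors(rng, spec.cv_expression, n)
    wt_basal_act = spec.wt_basal_lum * _lognormal_factors(rng, spec.cv_luminescence, n)
    wt_stim_act = wt_basal_act * spec.wt_fold_stimulation
    wt_bg = spec.background_mean * _lognormal_factors(rng, spec.cv_luminescence, n)
    for i, exp in enumerate(experiments):
        expr_rows.append({"variant_id": spec.wt_id, "experiment_id": exp,
                          "band_intensity": wt_band[i], "loading_control_intensity": wt_loading[i]})
        atp_rows.append({"variant_id": spec.wt_id, "experiment_id": exp,
                         "lum_basal": wt_bg[i] + wt_basal_act[i],
                         "lum_stimulated": wt_bg[i] + wt_stim_act[i],
                         "lum_background": wt_bg[i]})

    window = spec.wt_fold_stimulation - 1.0
    for v in spec.variants:
        loading = spec.wt_loading * _lognormal_factors(rng, spec.cv_expression, n)
        rel_expr_noise = _lognormal_factors(rng, spec.cv_expression, n)
        # band chosen so the WT-normalized expression is true_E * noise exactly
        band = v.true_E * (wt_band / wt_loading) * loading * rel_expr_noise
        amount = _lognormal_factors(rng, spec.cv_luminescence, n)  # shared by basal+stim
        basal_act = v.true_basal * wt_basal_act * amount
        stim_act = (v.true_basal + v.true_S * window) * wt_basal_act * amount
        bg = spec.background_mean * _lognormal_factors(rng, spec.cv_luminescence, n)
        for i, exp in enumerate(experiments):
            expr_rows.append({"variant_id": v.variant_id, "experiment_id": exp,
                              "band_intensity": band[i], "loading_control_intensity": loading[i]})
            atp_rows.append({"variant_id": v.variant_id, "experiment_id": exp,
                             "lum_basal": bg[i] + basal_act[i],
                             "lum_stimulated": bg[i] + stim_act[i],
                             "lum_background": bg[i]})
    return pd.DataFrame(expr_rows), pd.DataFrame(atp_rows)


def simulated_annotation_frame(spec: SimulationSpec) -> pd.DataFrame:
    """An annotation-table skeleton from the variant specs' evidence fields."""
    rows = []
    for v in spec.variants:
        rows.append({"variant_id": v.variant_id, "cdna": v.variant_id,
                     "protein": None, "revel": v.revel, "spliceai_max_delta": v.spliceai,
                     "aux_splice_novel_site": False, "gnomad_af": v.gnomad_af,
                     "gnomad_homozygotes": v.gnomad_homozygotes,
                     "clinvar_same_residue": None, "reported_in_patient": False,
                     "hypomorphic_flag": False, "localization": None,
                     "passthrough_codes": v.passthrough_codes or None})
    return pd.DataFrame(rows)


def run_pipeline(
    expression: pd.DataFrame,
    atpase: pd.DataFrame,
    wt_id: str = "WT",
    bands: findex.SeverityBands = findex.DEFAULT_BANDS,
    method: str = "per_replicate",
) -> pd.DataFrame:
    """Replicates -> per-experiment normalization -> F-index table."""
    expr_rel = assay.normalize_expression(expression, wt_id)
    atp_rel = assay.relative_atpase(atpase, wt_id)
    if method == "per_replicate":
        return findex.findex_per_replicate(expr_rel, atp_rel, wt_id, bands)
    summary = assay.summarize(expr_rel, atp_rel)
    return findex.findex_from_summaries(summary, wt_id, bands)


def recovery_experiment(
    spec: SimulationSpec,
    n_sims: int,
    tolerance: float = 0.15,
    bands: findex.SeverityBands = findex.DEFAULT_BANDS,
) -> pd.DataFrame:
    """Monte-Carlo recovery report for the full generator->pipeline loop.

    Runs ``n_sims`` independent simulated studies (each with
    ``spec.n_replicates`` experiments), estimates every variant's F per
    replicate, and reports per variant the fraction of simulations whose
    estimate lies within ``tolerance`` of the true F plus the confusion
    counts between the true and estimated severity categories.
    Deterministic given ``spec.seed``.
    """
    if n_sims < 1:
        raise SimulationSpecError("n_sims must be >= 1")
    # All simulations share one generator pass: experiments are independent
    # under per-experiment normalization, so n_sims * n_replicates experiments
    # generated at once are exactly n_sims independent studies.
    big = replace(spec, n_replicates=spec.n_replicates * n_sims)
    expression, atpase = simulate_assays(big)
    expr_rel = assay.normalize_expression(expression, spec.wt_id)
    atp_rel = assay.relative_atpase(atpase, spec.wt_id)
    wt_stim = (
        atp_rel[atp_rel["variant_id"] == spec.wt_id].set_index("experiment_id")["rel_stimulated"]
    )
    merged = expr_rel.merge(atp_rel, on=["variant_id", "experiment_id"])
    wt_window = wt_stim.reindex(merged["experiment_id"]).to_numpy() - 100.0
    F = (merged["rel_expression"].to_numpy() / 100.0) * (
        (merged["rel_stimulated"].to_numpy() - merged["rel_basal"].to_numpy()) / wt_window
    )
    merged = merged.assign(_F=F)
    merged["_sim"] = (
        merged["experiment_id"].str.slice(1).astype(int).sub(1) // spec.n_replicates
    )

    rows = []
    truth = {v.variant_id: (v.true_E * v.true_S) for v in spec.variants}
    for vid, true_f in truth.items():
        grp = merged[merged["variant_id"] == vid]
        f_hat = grp.groupby("_sim")["_F"].mean()
        recovered = float(np.mean(np.abs(f_hat - true_f) <= tolerance))
        true_sev = findex.categorize_severity(true_f, bands)
        est_sev = [findex.categorize_severity(f, bands) for f in f_hat]
        confusion = {f"n_est_{s.value}": sum(1 for e in est_sev if e is s) for s in findex.Severity}
        rows.append({"variant_id": vid, "true_F": true_f, "n_sims": int(f_hat.size),
                     "mean_F_hat": float(f_hat.mean()), "recovered_fraction": recovered,
                     "true_severity": true_sev.value, **confusion})
    return pd.DataFrame(rows)


def load_simulation_spec(path: str | Path, seed: int | None = None) -> SimulationSpec:
    """Load a SimulationSpec from a YAML file; ``seed`` overrides the file."""
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "variants" not in raw:
        raise SimulationSpecError("simulation spec must be a mapping with a 'variants' list")
    known_variant = {f.name for f in VariantSpec.__dataclass_fields__.values()}
    variants = []
    for entry in raw["variants"]:
        unknown = set(entry) - known_variant
        if unknown:
            raise SimulationSpecError(f"unknown variant keys: {sorted(unknown)}")
        variants.append(VariantSpec(**entry))
    known_top = {f.name for f in SimulationSpec.__dataclass_fields__.values()}
    top = {k: v for k, v in raw.items() if k != "variants"}
    unknown = set(top) - known_top
    if unknown:
        raise SimulationSpecError(f"unknown simulation keys: {sorted(unknown)}")
    if seed is not None:
        top["seed"] = seed
    return SimulationSpec(variants=tuple(variants), **top)
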