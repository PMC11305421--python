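"""Packaged study fixtures: the ten characterized ABCA4 missense VUS.

Three in-study tables are shipped as data:

* the functional summary (relative expression, basal and stimulated ATPase
  activity, F-index and predicted severity) for the ten variants plus WT;
* the per-variant annotation/evidence table (REVEL, SpliceAI, population
  data, ClinVar same-residue references, pass-through ACMG codes) together
  with the expected published subscores and classifications for all 23
  variants carried by the ten patients;
* the patient genotype table (alleles, parental origin where known,
  phenotype stage, age at presentation, disease duration).

No raw measurements were deposited for the study, so the replicate-level
assay tables here are SYNTHETIC reconstructions: three per-variant
experiment triples solved numerically so that the per-experiment
normalization pipeline reproduces every published summary (mean ± SD, to
the printed rounding) and the published F-index column (to 2 decimals) when
F is computed per replicate and averaged.  They are faithful to the printed
statistics, not to the unpublished raw data.

The gnomAD frequencies/homozygote counts and ClinVar same-residue records
are likewise synthetic stand-ins chosen to reproduce the published PM2 and
PM5 assignments; the study prints the resulting codes, not these inputs.
"""
from __future__ import annotations

import pandas as pd

from .annotation import VariantAnnotation, annotation_from_row

WT_ID = "WT"

#: printed functional summary: cdna -> (protein, expr_mean, expr_sd, localization,
#: basal_mean, basal_sd, stim_mean, stim_sd, F_printed, severity_label)
TABLE_FUNCTIONAL = {
    "WT":        (None, 100, 0, "Vesicles", 100, 0, 171, 14, 1.00, "Normal/mild"),
    "c.317A>T":  ("p.(Tyr106Phe)", 111, 10, "Vesicles", 95, 10, 153, 14, 0.94, "Normal/mild"),
    "c.514G>A":  ("p.(Gly172Ser)", 113, 6, "Vesicles", 100, 4, 183, 13, 1.35, "Normal/mild"),
    "c.614G>T":  ("p.(Cys205Phe)", 50, 11, "ER/Vesicles", 41, 10, 42, 1, 0.00, "Severe"),
    "c.1244A>C": ("p.(Asn415Thr)", 72, 11, "Vesicles", 58, 9, 56, 10, -0.02, "Severe"),
    "c.1928T>G": ("p.(Val643Gly)", 121, 12, "Vesicles", 83, 6, 115, 15, 0.48, "Moderate"),
    "c.2396C>T": ("p.(Pro799Leu)", 43, 5, "ER/small vesicles", 70, 13, 99, 16, 0.17, "Moderate"),
    "c.2819C>G": ("p.(Pro940Arg)", 100, 18, "Vesicles", 100, 7, 170, 20, 1.01, "Normal/mild"),
    "c.3491A>G": ("p.(Lys1164Arg)", 115, 23, "Vesicles", 93, 4, 155, 30, 0.90, "Normal/mild"),
    "c.4297G>A": ("p.(Val1433Ile)", 86, 12, "Vesicles", 76, 17, 112, 28, 0.41, "Moderate"),
    "c.6148G>C": ("p.(Val2050Leu)", 107, 13, "Vesicles", 98, 10, 157, 3, 0.92, "Normal/mild"),
}

#: study variants with functional data (the ten bold VUS), in table order
STUDY_VARIANTS = [v for v in TABLE_FUNCTIONAL if v != WT_ID]

#: WT relative stimulated activity per synthetic experiment (mean 171, SD 14)
_WT_STIM = {"E1": 157.0, "E2": 171.0, "E3": 185.0}

#: synthetic per-experiment relative values (E1..E3): expression, basal, stimulated.
#: Solved so summaries reproduce the printed means/SDs and the per-replicate
#: mean F equals the printed F-index (2 dp).
_REPLICATES = {
    "c.317A>T":  {"expr": [99.76, 120.11, 112.10], "basal": [94.30, 85.76, 105.87], "stim": [168.82, 141.63, 149.14]},
    "c.514G>A":  {"expr": [105.43, 115.40, 117.01], "basal": [103.59, 95.76, 101.69], "stim": [197.15, 171.36, 180.93]},
    "c.614G>T":  {"expr": [53.02, 37.07, 58.82], "basal": [42.95, 30.53, 50.54], "stim": [43.32, 41.28, 41.94]},
    "c.1244A>C": {"expr": [62.24, 68.58, 84.05], "basal": [62.29, 47.98, 64.87], "stim": [67.28, 47.74, 53.52]},
    "c.1928T>G": {"expr": [131.21, 123.66, 106.96], "basal": [89.99, 81.71, 78.48], "stim": [101.51, 111.33, 130.83]},
    "c.2396C>T": {"expr": [37.17, 47.27, 45.22], "basal": [81.52, 73.79, 56.03], "stim": [115.52, 83.43, 98.14]},
    "c.2819C>G": {"expr": [85.19, 120.17, 93.63], "basal": [99.33, 93.76, 107.84], "stim": [192.52, 153.78, 164.26]},
    "c.3491A>G": {"expr": [131.09, 123.69, 88.86], "basal": [97.53, 93.35, 89.47], "stim": [120.42, 164.79, 178.44]},
    "c.4297G>A": {"expr": [72.07, 96.26, 88.61], "basal": [86.30, 86.23, 56.60], "stim": [140.11, 84.07, 112.12]},
    "c.6148G>C": {"expr": [95.13, 121.14, 103.70], "basal": [97.23, 88.80, 108.90], "stim": [160.58, 154.71, 156.28]},
}

_EXPERIMENTS = ["E1", "E2", "E3"]
_WT_BAND, _WT_LOADING = 100.0, 10.0
_BACKGROUND = 50.0
_LUM_PER_REL = 10.0  # 1 % of WT basal activity == 10 luminescence units


def expression_replicates() -> pd.DataFrame:
    """Synthetic Western-blot replicate table regenerating the summary column."""
    rows = []
    for exp in _EXPERIMENTS:
        rows.append({"variant_id": WT_ID, "experiment_id": exp,
                     "band_intensity": _WT_BAND, "loading_control_intensity": _WT_LOADING})
    for vid, triples in _REPLICATES.items():
        for exp, value in zip(_EXPERIMENTS, triples["expr"]):
            # loading equal to the WT lane, band scaled so the per-experiment
            # relative expression equals the solved value exactly
            rows.append({"variant_id": vid, "experiment_id": exp,
                         "band_intensity": value, "loading_control_intensity": _WT_LOADING})
    return pd.DataFrame(rows)


def atpase_replicates() -> pd.DataFrame:
    """Synthetic ADP-Glo replicate table (luminescence with 0-hour background)."""
    rows = []
    for exp in _EXPERIMENTS:
        rows.append({"variant_id": WT_ID, "experiment_id": exp,
                     "lum_basal": _BACKGROUND + 100.0 * _LUM_PER_REL,
                     "lum_stimulated": _BACKGROUND + _WT_STIM[exp] * _LUM_PER_REL,
                     "lum_background": _BACKGROUND})
    for vid, triples in _REPLICATES.items():
        for exp, basal, stim in zip(_EXPERIMENTS, triples["basal"], triples["stim"]):
            rows.append({"variant_id": vid, "experiment_id": exp,
                         "lum_basal": _BACKGROUND + basal * _LUM_PER_REL,
                         "lum_stimulated": _BACKGROUND + stim * _LUM_PER_REL,
                         "lum_background": _BACKGROUND})
    return pd.DataFrame(rows)


def functional_summary() -> pd.DataFrame:
    """The printed functional summary table (means ± SDs, F-index, severity)."""
    rows = []
    for vid, (protein, em, es, loc, bm, bs, sm, ss, f, sev) in TABLE_FUNCTIONAL.items():
        rows.append({"variant_id": vid, "protein": protein,
                     "rel_expression_mean": float(em), "rel_expression_sd": float(es),
                     "localization": loc,
                     "rel_basal_mean": float(bm), "rel_basal_sd": float(bs),
                     "rel_stimulated_mean": float(sm), "rel_stimulated_sd": float(ss),
                     "F_printed": float(f), "severity_printed": sev})
    return pd.DataFrame(rows)


def localization_map() -> dict[str, str]:
    return {vid: row[3] for vid, row in TABLE_FUNCTIONAL.items()}


def _cv(protein_change: str, classification: str, revel: float) -> str:
    import json

    return json.dumps([{"protein_change": protein_change, "classification": classification,
                        "reported_in_abca4rd_patient": True, "revel": revel}])


#: classification-table fixture: one dict per printed variant row.
#: ``subscores``/``classification`` are the published expected outputs;
#: everything else is rule-engine input.  gnomAD/ClinVar values are synthetic
#: stand-ins (see module docstring).
TABLE_CLASSIFICATION: list[dict] = [
    dict(patient="P1, P2", variant_id="c.317A>T", cdna="c.317A>T", protein="p.(Tyr106Phe)",
         revel=0.261, spliceai=0.01, gnomad_af=1e-05, gnomad_hom=0, study=True,
         passthrough="", subscores="BS3_sup, BP4, PM2_sup", classification="Likely benign"),
    dict(patient="P1, P2", variant_id="c.868C>T", cdna="c.868C>T", protein="p.(Arg290Trp)",
         revel=0.525, spliceai=0.06, gnomad_af=5e-05, gnomad_hom=0, study=False,
         clinvar=_cv("p.(Arg290Gln)", "P", 0.50),
         passthrough="PM3:very_strong", subscores="PM3_very strong, PM5, PM2_sup",
         classification="Pathogenic"),
    dict(patient="P1, P2", variant_id="c.2875A>G", cdna="c.2875A>G", protein="p.(Thr959Ala)",
         revel=0.962, spliceai=0.00, gnomad_af=2e-05, gnomad_hom=0, study=False,
         clinvar=_cv("p.(Thr959Ile)", "P", 0.88),
         passthrough="PM3", subscores="PM3, PM5, PM2_sup, PP3",
         classification="Likely pathogenic"),
    dict(patient="P3", variant_id="c.514G>A", cdna="c.514G>A", protein="p.(Gly172Ser)",
         revel=0.496, spliceai=0.03, gnomad_af=3e-04, gnomad_hom=0, study=True,
         passthrough="PM3:strong;BP2;BP5", subscores="PM3_strong, PM2_sup, BS3_sup, BP2, BP5",
         classification="VUS"),
    dict(patient="P3", variant_id="c.6148G>C", cdna="c.6148G>C", protein="p.(Val2050Leu)",
         revel=0.795, spliceai=0.01, gnomad_af=0.018, gnomad_hom=20, study=True,
         passthrough="BP2;BP5", subscores="BS3_sup, BP2, BP5, PP3",
         classification="Likely benign"),
    dict(patient="P4", variant_id="c.614G>T", cdna="c.614G>T", protein="p.(Cys205Phe)",
         revel=0.967, spliceai=0.00, gnomad_af=0.0, gnomad_hom=0, study=True,
         clinvar=_cv("p.(Cys205Tyr)", "P", 0.90),
         passthrough="PM3;PP5", subscores="PS3, PM2_sup, PM3, PM5, PP3, PP5",
         classification="Pathogenic"),
    dict(patient="P4", variant_id="c.5882G>A", cdna="c.5882G>A", protein="p.(Gly1961Glu)",
         revel=0.76, spliceai=0.01, gnomad_af=0.004, gnomad_hom=40, study=False,
         clinvar=_cv("p.(Gly1961Arg)", "P", 0.82),
         passthrough="PM3:very_strong;PP5", subscores="PM3_very strong, PM5, PP3, PP5",
         classification="Pathogenic"),
    dict(patient="P4", variant_id="c.3523-9C>G", cdna="c.3523-9C>G", protein=None,
         revel=None, spliceai=0.02, gnomad_af=1e-04, gnomad_hom=0, study=False,
         passthrough="BP2", subscores="PM2_sup, BP2, BP4", classification="Likely benign"),
    dict(patient="P5", variant_id="c.1244A>C", cdna="c.1244A>C", protein="p.(Asn415Thr)",
         revel=0.817, spliceai=0.00, gnomad_af=1e-05, gnomad_hom=0, study=True,
         passthrough="PM3:sup", subscores="PS3, PM2_sup, PM3_sup, PP3",
         classification="Likely pathogenic"),
    dict(patient="P5", variant_id="c.5461-10T>C", cdna="c.5461-10T>C", protein="p.Thr1821Aspfs*6",
         revel=None, spliceai=0.07, gnomad_af=2e-04, gnomad_hom=0, study=False,
         passthrough="PM3:very_strong;PS3;PP5", subscores="PM3_very strong, PS3, PM2_sup, PP5",
         classification="Pathogenic"),
    dict(patient="P5", variant_id="c.5603A>T", cdna="c.5603A>T", protein="p.(Asn1868Ile)",
         revel=0.402, spliceai=0.00, gnomad_af=0.04, gnomad_hom=400, study=False,
         hypomorphic=True, passthrough="", subscores="Hypomorphic", classification="NA"),
    dict(patient="P6", variant_id="c.1928T>G", cdna="c.1928T>G", protein="p.(Val643Gly)",
         revel=0.944, spliceai=0.01, gnomad_af=0.0025, gnomad_hom=4, study=True,
         passthrough="", subscores="PS3, PP3", classification="VUS"),
    dict(patient="P6", variant_id="c.6449G>A", cdna="c.6449G>A", protein="p.(Cys2150Tyr)",
         revel=0.923, spliceai=0.02, gnomad_af=3e-05, gnomad_hom=0, study=False,
         passthrough="PM3:very_strong;PP5", subscores="PM3_very strong, PM2_sup, PP3, PP5",
         classification="Pathogenic"),
    dict(patient="P7", variant_id="c.2396C>T", cdna="c.2396C>T", protein="p.(Pro799Leu)",
         revel=0.542, spliceai=0.01, gnomad_af=6e-05, gnomad_hom=0, study=True,
         passthrough="PM3:sup", subscores="PS3, PM2_sup, PM3_sup",
         classification="Likely pathogenic"),
    dict(patient="P7", variant_id="c.4734del", cdna="c.4734del", protein="p.(Leu1580*)",
         revel=None, spliceai=0.01, gnomad_af=1e-05, gnomad_hom=0, study=False,
         passthrough="PVS1;PM3", subscores="PVS1, PM3, PM2_sup", classification="Pathogenic"),
    dict(patient="P8", variant_id="c.2819C>G", cdna="c.2819C>G", protein="p.(Pro940Arg)",
         revel=0.273, spliceai=0.00, gnomad_af=2e-05, gnomad_hom=0, study=True,
         passthrough="BP2", subscores="PM2_sup, BS3_sup, BP4, BP2",
         classification="Likely benign"),
    dict(patient="P8", variant_id="c.3364G>A", cdna="c.3364G>A", protein="p.(Glu1122Lys)",
         revel=0.939, spliceai=0.02, gnomad_af=4e-05, gnomad_hom=0, study=False,
         passthrough="PM3:very_strong;PP5", subscores="PM3_very strong, PM2_sup, PP3, PP5",
         classification="Pathogenic"),
    dict(patient="P8", variant_id="c.161-23T>G", cdna="c.161-23T>G", protein="p.(Cys54=, Cys54Serfs*14)",
         revel=None, spliceai=0.02, gnomad_af=1e-04, gnomad_hom=0, study=False,
         passthrough="PM3:strong;PS3:mod", subscores="PM3_strong, PS3_mod, PM2_sup",
         classification="Likely pathogenic"),
    dict(patient="P9", variant_id="c.3491A>G", cdna="c.3491A>G", protein="p.(Lys1164Arg)",
         revel=0.199, spliceai=0.01, gnomad_af=5e-05, gnomad_hom=0, study=True,
         passthrough="", subscores="PM2_sup, BS3_sup, BP4", classification="Likely benign"),
    dict(patient="P9", variant_id="c.769-784C>T", cdna="c.769-784C>T", protein="p.(Leu257=, Leu257Aspfs*3)",
         revel=None, spliceai=0.08, gnomad_af=2e-04, gnomad_hom=0, study=False,
         passthrough="PS3:sup;PM3:strong;BP2", subscores="PM2_sup, PS3_sup, PM3_strong, BP2",
         classification="VUS"),
    dict(patient="P9", variant_id="c.4540-2077C>T", cdna="c.4540-2077C>T", protein=None,
         revel=None, spliceai=0.00, gnomad_af=1e-04, gnomad_hom=0, study=False,
         aux_splice=True, passthrough="", subscores="PM2_sup", classification="VUS"),
    dict(patient="P10", variant_id="c.4297G>A", cdna="c.4297G>A", protein="p.(Val1433Ile)",
         revel=0.605, spliceai=0.10, gnomad_af=0.0015, gnomad_hom=2, study=True,
         passthrough="", subscores="PS3", classification="VUS"),
    dict(patient="P10", variant_id="c.3607+771G>A", cdna="c.3607+771G>A", protein=None,
         revel=None, spliceai=0.00, gnomad_af=3e-04, gnomad_hom=0, study=False,
         passthrough="", subscores="PM2_sup, BP4", classification="VUS"),
]


def annotation_frame() -> pd.DataFrame:
    """The classification inputs as an annotation TSV-shaped DataFrame."""
    rows = []
    for entry in TABLE_CLASSIFICATION:
        rows.append(
            {
                "variant_id": entry["variant_id"],
                "cdna": entry["cdna"],
                "protein": entry["protein"],
                "revel": entry["revel"],
                "spliceai_max_delta": entry["spliceai"],
                "aux_splice_novel_site": entry.get("aux_splice", False),
                "gnomad_af": entry["gnomad_af"],
                "gnomad_homozygotes": entry["gnomad_hom"],
                "clinvar_same_residue": entry.get("clinvar"),
                "reported_in_patient": True,
                "hypomorphic_flag": entry.get("hypomorphic", False),
                "localization": localization_map().get(entry["variant_id"]),
                "passthrough_codes": entry["passthrough"] or None,
            }
        )
    return pd.DataFrame(rows)


def annotations() -> list[VariantAnnotation]:
    return [annotation_from_row(row) for _, row in annotation_frame().iterrows()]


def expected_classifications() -> pd.DataFrame:
    """Published subscores and verdicts, for comparison against recomputation."""
    return pd.DataFrame(
        [
            {"variant_id": e["variant_id"], "patient": e["patient"], "study": e["study"],
             "revel": e["revel"], "spliceai": e["spliceai"],
             "subscores_printed": e["subscores"], "classification_printed": e["classification"]}
            for e in TABLE_CLASSIFICATION
        ]
    )


#: patient genotypes: (patient, [(variant_id, origin), ...], stage, age at
#: presentation, disease duration).  Stage/duration are omitted where the
#: study excluded them (phenotype not attributable to ABCA4).
TABLE_GENOTYPES: list[tuple[str, list[tuple[str, str | None]], str | None, int, int | None]] = [
    ("P1", [("c.317A>T", None), ("c.868C>T", None), ("c.2875A>G", None)], "I", 16, 14),
    ("P2", [("c.317A>T", None), ("c.868C>T", None), ("c.2875A>G", None)], "I", 16, 14),
    ("P3", [("c.514G>A", "maternal"), ("c.6148G>C", "paternal")], None, 31, None),
    ("P4", [("c.614G>T", None), ("c.5882G>A", None), ("c.3523-9C>G", None)], "I", 36, 25),
    ("P5", [("c.1244A>C", None), ("c.5461-10T>C", None), ("c.5603A>T", None)], "IIIC", 6, 43),
    ("P6", [("c.1928T>G", None), ("c.6449G>A", None)], "II", 60, 2),
    ("P7", [("c.2396C>T", None), ("c.4734del", None)], "IIIA", 46, 5),
    ("P8", [("c.2819C>G", "maternal"), ("c.3364G>A", "maternal"), ("c.161-23T>G", "paternal")], "IIIB", 10, 38),
    ("P9", [("c.3491A>G", "maternal"), ("c.769-784C>T", "maternal"), ("c.4540-2077C>T", "paternal")], "IIIB", 19, 38),
    ("P10", [("c.4297G>A", None), ("c.3607+771G>A", None)], None, 60, None),
]


def genotype_frame() -> pd.DataFrame:
    rows = []
    for patient, alleles, stage, age, duration in TABLE_GENOTYPES:
        for idx, (vid, origin) in enumerate(alleles, start=1):
            rows.append({"patient_id": patient, "allele_index": idx, "variant_id": vid,
                         "origin": origin, "stage": stage, "age_at_presentation": age,
                         "disease_duration": duration})
    return pd.DataFrame(rows)


def printed_findex_frame() -> pd.DataFrame:
    """variant_id + published F for the functional-evidence input."""
    df = functional_summary()[["variant_id", "F_printed"]].rename(columns={"F_printed": "F"})
    return df


def make_fixture_tables(out_dir=None) -> dict[str, pd.DataFrame]:
    """All packaged fixtures as DataFrames; optionally written as TSVs."""
    tables = {
        "expression_replicates": expression_replicates(),
        "atpase_replicates": atpase_replicates(),
        "functional_summary": functional_summary(),
        "annotations": annotation_frame(),
        "expected_classifications": expected_classifications(),
        "genotypes": genotype_frame(),
    }
    if out_dir is not None:
        from pathlib import Path

        from .io import write_tsv

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            write_tsv(df, out / f"{name}.tsv")
    return tables
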