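"""Variant annotations: the evidence rules' input record.

A :class:`VariantAnnotation` bundles the parsed nomenclature with the
predictor scores (REVEL, SpliceAI max delta), population data (gnomAD allele
frequency and homozygote count), same-residue ClinVar references for PM5,
and any externally derived pass-through evidence codes.  Annotations arrive
as a TSV with one row per variant; the ClinVar references are a nested JSON
column and pass-through codes are semicolon-separated ``CODE:strength``
tokens.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .evidence import EvidenceCode, parse_code_list
from .hgvs import Consequence, VariantDescription, describe_variant
from .io import read_tsv, write_tsv

ANNOTATION_COLUMNS = [
    "variant_id", "cdna", "protein", "revel", "spliceai_max_delta",
    "aux_splice_novel_site", "gnomad_af", "gnomad_homozygotes",
    "clinvar_same_residue", "reported_in_patient", "hypomorphic_flag",
    "localization", "passthrough_codes",
]


@dataclass(frozen=True)
class ClinVarSameResidue:
    """A previously classified change at the same amino-acid residue."""

    protein_change: str
    classification: str  # "P" | "LP" | "other"
    reported_in_abca4rd_patient: bool = False
    revel: float | None = None


@dataclass(frozen=True)
class VariantAnnotation:
    variant_id: str
    description: VariantDescription
    revel: float | None = None
    spliceai_max_delta: float | None = None
    aux_splice_novel_site: bool = False
    gnomad_af: float | None = None
    gnomad_homozygotes: int | None = None
    clinvar_same_residue: tuple[ClinVarSameResidue, ...] = ()
    reported_in_patient: bool = False
    hypomorphic_flag: bool = False
    localization: str | None = None  # pass-through categorical: vesicles/er/mixed
    passthrough_codes: tuple[EvidenceCode, ...] = ()

    def __post_init__(self) -> None:
        for name in ("revel", "spliceai_max_delta", "gnomad_af"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.gnomad_homozygotes is not None and self.gnomad_homozygotes < 0:
            raise ValueError("gnomad_homozygotes must be a nonnegative integer")

    @property
    def consequence(self) -> Consequence:
        return self.description.consequence


def _opt_float(value) -> float | None:
    return None if pd.isna(value) else float(value)


def _opt_int(value) -> int | None:
    return None if pd.isna(value) else int(value)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    return bool(value) and not pd.isna(value)


def annotation_from_row(row: pd.Series, splice_region_window: int = 20) -> VariantAnnotation:
    clinvar_raw = row.get("clinvar_same_residue")
    clinvar: tuple[ClinVarSameResidue, ...] = ()
    if isinstance(clinvar_raw, str) and clinvar_raw.strip() not in ("", "."):
        clinvar = tuple(ClinVarSameResidue(**entry) for entry in json.loads(clinvar_raw))
    protein = row.get("protein")
    if pd.isna(protein) or protein in ("", "."):
        protein = None
    passthrough = row.get("passthrough_codes")
    codes = parse_code_list(passthrough) if isinstance(passthrough, str) else []
    localization = row.get("localization")
    if pd.isna(localization) or localization in ("", "."):
        localization = None
    return VariantAnnotation(
        variant_id=str(row["variant_id"]),
        description=describe_variant(str(row["cdna"]), protein, splice_region_window=splice_region_window),
        revel=_opt_float(row.get("revel")),
        spliceai_max_delta=_opt_float(row.get("spliceai_max_delta")),
        aux_splice_novel_site=_as_bool(row.get("aux_splice_novel_site", False)),
        gnomad_af=_opt_float(row.get("gnomad_af")),
        gnomad_homozygotes=_opt_int(row.get("gnomad_homozygotes")),
        clinvar_same_residue=clinvar,
        reported_in_patient=_as_bool(row.get("reported_in_patient", False)),
        hypomorphic_flag=_as_bool(row.get("hypomorphic_flag", False)),
        localization=localization,
        passthrough_codes=tuple(codes),
    )


def read_annotation_table(path: str | Path, splice_region_window: int = 20) -> list[VariantAnnotation]:
    df = read_tsv(path, dtype={"variant_id": str, "cdna": str, "protein": str,
                               "clinvar_same_residue": str, "passthrough_codes": str,
                               "localization": str})
    missing = [c for c in ("variant_id", "cdna") if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table is missing required columns: {missing}")
    return [annotation_from_row(row, splice_region_window) for _, row in df.iterrows()]


def annotations_to_frame(annotations: list[VariantAnnotation]) -> pd.DataFrame:
    """Serialize annotations back to the tabular schema (round-trippable)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "variant_id": a.variant_id,
                "cdna": str(a.description.cdna),
                "protein": str(a.description.protein) if a.description.protein else None,
                "revel": a.revel,
                "spliceai_max_delta": a.spliceai_max_delta,
                "aux_splice_novel_site": a.aux_splice_novel_site,
                "gnomad_af": a.gnomad_af,
                "gnomad_homozygotes": a.gnomad_homozygotes,
                "clinvar_same_residue": json.dumps([c.__dict__ for c in a.clinvar_same_residue])
                if a.clinvar_same_residue else None,
                "reported_in_patient": a.reported_in_patient,
                "hypomorphic_flag": a.hypomorphic_flag,
                "localization": a.localization,
                "passthrough_codes": ";".join(
                    f"{c.code}:{c.strength.value}" for c in a.passthrough_codes
                ) or None,
            }
        )
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def write_annotation_table(annotations: list[VariantAnnotation], path: str | Path) -> None:
    write_tsv(annotations_to_frame(annotations), path)


def read_vcf(path: str | Path, hgvs_cdna_tag: str = "HGVSC", hgvs_protein_tag: str = "HGVSP") -> pd.DataFrame:
    """Minimal convenience reader: SNVs with HGVS INFO tags from a VCF.

    Returns a DataFrame with ``variant_id`` (the cDNA change), ``cdna`` and
    ``protein`` columns suitable as the skeleton of an annotation table;
    all evidence fields still have to be filled in.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            cdna = info.get(hgvs_cdna_tag)
            if cdna is None:
                continue
            if isinstance(cdna, tuple):
                cdna = cdna[0]
            protein = info.get(hgvs_protein_tag)
            if isinstance(protein, tuple):
                protein = protein[0]
            rows.append({"variant_id": str(cdna), "cdna": str(cdna),
                         "protein": str(protein) if protein else None,
                         "chrom": rec.chrom, "pos": rec.pos,
                         "ref": rec.ref, "alt": rec.alts[0] if rec.alts else None})
    return pd.DataFrame(rows)
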