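"""A deliberately small HGVS parser for ABCA4 variant nomenclature.

Covers exactly the cDNA and protein notations that occur in ABCA4 clinical
reports of the kind this package processes: exonic substitutions
(``c.614G>T``), intron-offset substitutions (``c.5461-10T>C``,
``c.3607+771G>A``), single-position or range deletions/duplications
(``c.4734del``), and protein changes in 3-letter code including stops
(``p.(Leu1580*)``), frameshifts (``p.Thr1821Aspfs*6``), synonymous changes
(``p.(Cys54=)``) and dual-effect records (``p.(Cys54=, Cys54Serfs*14)``,
as reported for splice-altering variants).

Anything outside this subset raises :class:`~abca4func.errors.HgvsParseError`
carrying the offending token — misparsed nomenclature must never silently
feed the evidence rules.  Coordinates are 1-based cDNA positions; intron
offsets carry their sign.
"""
from __future__ import annotations

import enum
import re
from dataclasses import dataclass

from .errors import HgvsParseError

DEFAULT_TRANSCRIPT = "NM_000350.3"

AA3 = {
    "Ala", "Arg", "Asn", "Asp", "Cys", "Gln", "Glu", "Gly", "His", "Ile",
    "Leu", "Lys", "Met", "Phe", "Pro", "Ser", "Thr", "Trp", "Tyr", "Val",
}


class CdnaKind(str, enum.Enum):
    SUBSTITUTION = "substitution"
    DELETION = "deletion"
    DUPLICATION = "duplication"
    OTHER = "other"


class ProteinKind(str, enum.Enum):
    MISSENSE = "missense"
    TER = "ter"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    INTRONIC = "intronic"
    SPLICE_REGION = "splice_region"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SYNONYMOUS = "synonymous"
    OTHER = "other"


@dataclass(frozen=True)
class CdnaChange:
    position: int
    intron_offset: int = 0
    ref: str = ""
    alt: str = ""
    kind: CdnaKind = CdnaKind.SUBSTITUTION
    end_position: int | None = None  # for ranges like c.100_102del

    def __str__(self) -> str:
        off = "" if self.intron_offset == 0 else f"{self.intron_offset:+d}"
        span = f"{self.position}{off}"
        if self.end_position is not None:
            span += f"_{self.end_position}"
        if self.kind is CdnaKind.SUBSTITUTION:
            return f"c.{span}{self.ref}>{self.alt}"
        if self.kind is CdnaKind.DELETION:
            return f"c.{span}del"
        if self.kind is CdnaKind.DUPLICATION:
            return f"c.{span}dup"
        return f"c.{span}"


@dataclass(frozen=True)
class ProteinEffect:
    residue_index: int
    ref_aa: str
    alt_aa: str | None  # None for synonymous / bare Ter
    kind: ProteinKind
    fs_ter: int | None = None  # stop offset of a frameshift, e.g. fs*14

    def __str__(self) -> str:
        if self.kind is ProteinKind.SYNONYMOUS:
            return f"{self.ref_aa}{self.residue_index}="
        if self.kind is ProteinKind.FRAMESHIFT:
            tail = f"fs*{self.fs_ter}" if self.fs_ter is not None else "fs"
            return f"{self.ref_aa}{self.residue_index}{self.alt_aa or ''}{tail}"
        if self.kind is ProteinKind.TER:
            return f"{self.ref_aa}{self.residue_index}*"
        return f"{self.ref_aa}{self.residue_index}{self.alt_aa}"


@dataclass(frozen=True)
class ProteinChange:
    """One or more effects of a variant on the protein.

    Splice-altering variants are sometimes reported with a dual effect
    (e.g. a synonymous change on the unspliced reading plus a frameshift on
    the mis-spliced transcript); the first listed effect is primary.
    """

    effects: tuple[ProteinEffect, ...]
    predicted: bool = True  # printed with parentheses: p.(...)

    @property
    def primary(self) -> ProteinEffect:
        return self.effects[0]

    def __str__(self) -> str:
        inner = ", ".join(str(e) for e in self.effects)
        return f"p.({inner})" if self.predicted else f"p.{inner}"


_CDNA_RE = re.compile(
    r"^c\.(?P<pos>\d+)(?P<off>[+-]\d+)?"
    r"(?:_(?P<end>\d+)(?:[+-]\d+)?)?"
    r"(?:(?P<ref>[ACGT]+)>(?P<alt>[ACGT]+)|(?P<op>del|dup))$"
)


def parse_cdna(text: str) -> CdnaChange:
    """Parse a cDNA change string (must start with ``c.``)."""
    token = text.strip()
    m = _CDNA_RE.match(token)
    if not m:
        raise HgvsParseError(token)
    pos = int(m.group("pos"))
    off = int(m.group("off")) if m.group("off") else 0
    end = int(m.group("end")) if m.group("end") else None
    if m.group("op") == "del":
        return CdnaChange(pos, off, kind=CdnaKind.DELETION, end_position=end)
    if m.group("op") == "dup":
        return CdnaChange(pos, off, kind=CdnaKind.DUPLICATION, end_position=end)
    if end is not None:
        raise HgvsParseError(token, f"range substitution is not supported: {token!r}")
    return CdnaChange(pos, off, ref=m.group("ref"), alt=m.group("alt"))


_EFFECT_RE = re.compile(
    r"^(?P<ref>[A-Z][a-z]{2})(?P<pos>\d+)"
    r"(?:(?P<syn>=)|(?P<alt>[A-Z][a-z]{2}|\*|Ter)?(?P<fs>fs(?:\*(?P<fster>\d+))?)?)$"
)


def _parse_effect(token: str) -> ProteinEffect:
    m = _EFFECT_RE.match(token)
    if not m:
        raise HgvsParseError(token)
    ref = m.group("ref")
    if ref not in AA3:
        raise HgvsParseError(token, f"unknown amino-acid code {ref!r} in {token!r}")
    pos = int(m.group("pos"))
    if m.group("syn"):
        return ProteinEffect(pos, ref, None, ProteinKind.SYNONYMOUS)
    alt = m.group("alt")
    if m.group("fs"):
        if alt in ("*", "Ter"):
            raise HgvsParseError(token)
        if alt is not None and alt not in AA3:
            raise HgvsParseError(token, f"unknown amino-acid code {alt!r} in {token!r}")
        fster = int(m.group("fster")) if m.group("fster") else None
        return ProteinEffect(pos, ref, alt, ProteinKind.FRAMESHIFT, fs_ter=fster)
    if alt in ("*", "Ter"):
        return ProteinEffect(pos, ref, None, ProteinKind.TER)
    if alt is None:
        raise HgvsParseError(token)
    if alt not in AA3:
        raise HgvsParseError(token, f"unknown amino-acid code {alt!r} in {token!r}")
    return ProteinEffect(pos, ref, alt, ProteinKind.MISSENSE)


def parse_protein(text: str) -> ProteinChange:
    """Parse a protein change of the form ``p.(...)`` or ``p....``."""
    token = text.strip()
    if not token.startswith("p."):
        raise HgvsParseError(token)
    inner = token[2:]
    predicted = inner.startswith("(") and inner.endswith(")")
    if predicted:
        inner = inner[1:-1]
    if not inner:
        raise HgvsParseError(token)
    effects = tuple(_parse_effect(part.strip()) for part in inner.split(","))
    return ProteinChange(effects, predicted=predicted)


@dataclass(frozen=True)
class VariantDescription:
    transcript: str
    cdna: CdnaChange
    protein: ProteinChange | None
    consequence: Consequence


def infer_consequence(
    cdna: CdnaChange, protein: ProteinChange | None, splice_region_window: int = 20
) -> Consequence:
    """Deterministic consequence call from the parsed description.

    An intron offset dominates: |offset| within the splice-region window is
    ``splice_region``, otherwise deep ``intronic``.  For exonic changes the
    primary protein effect decides.
    """
    if cdna.intron_offset != 0:
        if abs(cdna.intron_offset) <= splice_region_window:
            return Consequence.SPLICE_REGION
        return Consequence.INTRONIC
    if protein is None:
        return Consequence.OTHER
    primary = protein.primary
    return {
        ProteinKind.TER: Consequence.NONSENSE,
        ProteinKind.FRAMESHIFT: Consequence.FRAMESHIFT,
        ProteinKind.SYNONYMOUS: Consequence.SYNONYMOUS,
        ProteinKind.MISSENSE: Consequence.MISSENSE,
    }[primary.kind]


def describe_variant(
    cdna_text: str,
    protein_text: str | None = None,
    transcript: str = DEFAULT_TRANSCRIPT,
    splice_region_window: int = 20,
) -> VariantDescription:
    cdna = parse_cdna(cdna_text)
    protein = parse_protein(protein_text) if protein_text else None
    return VariantDescription(
        transcript=transcript,
        cdna=cdna,
        protein=protein,
        consequence=infer_consequence(cdna, protein, splice_region_window),
    )
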