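"""Assignment of ACMG-AMP evidence codes for ABCA4 variants.

Four codes are computed here; everything else arrives as pass-through input
because the surrounding frameworks own them (PVS1 decision tree, ClinGen PM3
points table, PP5/BP2/BP5 literature curation, RNA-assay PS3 for splice
variants):

* PS3 / BS3 from the functional F-index: F < 0.5 gives PS3 (strong, the
  assay shows a damaging effect); F >= 0.9 gives BS3 at supporting strength.
  The BS3 boundary is inclusive so that a variant scoring exactly 0.90
  receives benign functional evidence, reconciling the ">0.9" phrasing with
  its worked application.
* PP3 / BP4 computational evidence: for missense variants from REVEL
  (>= 0.7 deleterious-supporting, <= 0.4 benign-supporting); for intronic
  variants BP4 requires SpliceAI < 0.2 AND no auxiliary-tool prediction of a
  novel exonic/deep-intronic splice site of any strength.  No PP3 route is
  defined for intronic variants.
* PM2 at supporting strength: rare/absent in gnomAD, with at most 3
  homozygotes and an allele frequency at or below a configurable ceiling.
* PM5 (different pathogenic missense change at the same residue): requires
  the variant to have been reported in an ABCA4-RD patient, a same-residue
  ClinVar P/LP reference, and REVEL(new) >= REVEL(ref) OR both >= 0.7.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Optional

from .errors import EvidenceConflictError
from .findex import FIndexResult
from .hgvs import Consequence

if TYPE_CHECKING:  # pragma: no cover
    from .annotation import VariantAnnotation

log = logging.getLogger(__name__)


class Direction(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Strength(str, enum.Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"

    @property
    def rank(self) -> int:
        return _STRENGTH_RANK[self]


_STRENGTH_RANK = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 3,
    Strength.VERY_STRONG: 4,
    Strength.STAND_ALONE: 5,
}

#: Canonical (unmodified) strength of each supported code.
DEFAULT_STRENGTH = {
    "PVS1": Strength.VERY_STRONG,
    "PS3": Strength.STRONG,
    "PM2": Strength.MODERATE,
    "PM3": Strength.MODERATE,
    "PM5": Strength.MODERATE,
    "PP3": Strength.SUPPORTING,
    "PP5": Strength.SUPPORTING,
    "BA1": Strength.STAND_ALONE,
    "BS1": Strength.STRONG,
    "BS3": Strength.STRONG,
    "BP2": Strength.SUPPORTING,
    "BP4": Strength.SUPPORTING,
    "BP5": Strength.SUPPORTING,
}

_STRENGTH_SUFFIX = {
    "sup": Strength.SUPPORTING,
    "supporting": Strength.SUPPORTING,
    "mod": Strength.MODERATE,
    "moderate": Strength.MODERATE,
    "strong": Strength.STRONG,
    "very strong": Strength.VERY_STRONG,
    "very_strong": Strength.VERY_STRONG,
    "vs": Strength.VERY_STRONG,
    "stand_alone": Strength.STAND_ALONE,
}


def code_direction(code: str) -> Direction:
    if code.startswith("P"):
        return Direction.PATHOGENIC
    if code.startswith("B"):
        return Direction.BENIGN
    raise ValueError(f"unknown ACMG code family: {code!r}")


@dataclass(frozen=True)
class EvidenceCode:
    """An ACMG-AMP code applied at a (possibly modified) strength."""

    code: str
    strength: Strength
    source: str = "computed"  # "computed" | "passthrough"
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.code not in DEFAULT_STRENGTH:
            raise ValueError(f"unsupported ACMG code {self.code!r}")

    @property
    def direction(self) -> Direction:
        return code_direction(self.code)

    @property
    def is_modified(self) -> bool:
        return self.strength is not DEFAULT_STRENGTH[self.code]

    def token(self) -> str:
        """Canonical printed form, e.g. ``PM3_very strong`` or ``BS3_sup``."""
        if not self.is_modified:
            return self.code
        suffix = {
            Strength.SUPPORTING: "sup",
            Strength.MODERATE: "mod",
            Strength.STRONG: "strong",
            Strength.VERY_STRONG: "very strong",
            Strength.STAND_ALONE: "stand_alone",
        }[self.strength]
        return f"{self.code}_{suffix}"


def make_code(code: str, strength: Strength | None = None, source: str = "computed", rationale: str = "") -> EvidenceCode:
    if code not in DEFAULT_STRENGTH:
        raise ValueError(f"unsupported ACMG code {code!r}")
    return EvidenceCode(code, strength or DEFAULT_STRENGTH[code], source, rationale)


def parse_code_token(token: str, source: str = "passthrough") -> EvidenceCode:
    """Parse ``PM3_very strong`` / ``PM3:very_strong`` / ``PM2_sup`` tokens."""
    text = token.strip()
    for sep in (":", "_"):
        if sep in text:
            code, _, suffix = text.partition(sep)
            code, suffix = code.strip(), suffix.strip().lower()
            if suffix in _STRENGTH_SUFFIX:
                return make_code(code, _STRENGTH_SUFFIX[suffix], source=source)
            raise ValueError(f"unknown strength modifier {suffix!r} in {token!r}")
    return make_code(text, source=source)


def parse_code_list(text: str, sep: str = ";", source: str = "passthrough") -> list[EvidenceCode]:
    """Parse a delimiter-separated list of code tokens (also accepts ', ')."""
    if not text or text.strip() in (".", ""):
        return []
    if sep not in text and "," in text:
        sep = ","
    return [parse_code_token(tok, source=source) for tok in text.split(sep) if tok.strip()]


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds for the computed evidence codes (all configurable)."""

    ps3_fmax: float = 0.5        # PS3 iff F < ps3_fmax (strict)
    bs3_fmin: float = 0.9        # BS3_sup iff F >= bs3_fmin (inclusive)
    revel_pp3: float = 0.7       # PP3 iff REVEL >= revel_pp3 (missense)
    revel_bp4: float = 0.4       # BP4 iff REVEL <= revel_bp4 (missense)
    spliceai_bp4: float = 0.2    # BP4 iff SpliceAI < spliceai_bp4 (intronic)
    pm2_max_homozygotes: int = 3
    pm2_max_af: float = 0.001    # artifact knob; only the homozygote cap is canonical
    splice_region_window: int = 20

    def __post_init__(self) -> None:
        if not self.revel_bp4 < self.revel_pp3:
            raise ValueError("revel_bp4 must be below revel_pp3")
        for name in ("revel_pp3", "revel_bp4", "spliceai_bp4"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")


DEFAULT_RULES = RuleConfig()

_INTRONIC = (Consequence.INTRONIC, Consequence.SPLICE_REGION)


def assign_functional(findex: FIndexResult | float | None, cfg: RuleConfig = DEFAULT_RULES) -> Optional[EvidenceCode]:
    """PS3 (strong) for F below the damaging cutoff; BS3_sup for WT-like F."""
    if findex is None:
        return None
    F = findex.F if isinstance(findex, FIndexResult) else float(findex)
    if F < cfg.ps3_fmax:
        return make_code("PS3", rationale=f"F-index {F:.2f} < {cfg.ps3_fmax}")
    if F >= cfg.bs3_fmin:
        return make_code("BS3", Strength.SUPPORTING, rationale=f"F-index {F:.2f} >= {cfg.bs3_fmin}")
    return None


def assign_computational(annotation: "VariantAnnotation", cfg: RuleConfig = DEFAULT_RULES) -> Optional[EvidenceCode]:
    """PP3/BP4 from REVEL (missense) or SpliceAI plus auxiliary tools (intronic)."""
    cons = annotation.consequence
    if cons is Consequence.MISSENSE:
        if annotation.revel is None:
            log.warning("%s: missense without REVEL score; no PP3/BP4", annotation.variant_id)
            return None
        if annotation.revel >= cfg.revel_pp3:
            return make_code("PP3", rationale=f"REVEL {annotation.revel} >= {cfg.revel_pp3}")
        if annotation.revel <= cfg.revel_bp4:
            return make_code("BP4", rationale=f"REVEL {annotation.revel} <= {cfg.revel_bp4}")
        return None
    if cons in _INTRONIC:
        if annotation.spliceai_max_delta is None:
            log.warning("%s: intronic without SpliceAI score; no BP4", annotation.variant_id)
            return None
        if annotation.spliceai_max_delta < cfg.spliceai_bp4 and not annotation.aux_splice_novel_site:
            return make_code(
                "BP4",
                rationale=f"SpliceAI {annotation.spliceai_max_delta} < {cfg.spliceai_bp4}, no novel-site prediction",
            )
        if annotation.spliceai_max_delta >= cfg.spliceai_bp4:
            # no PP3 route is defined for intronic variants
            log.info("%s: SpliceAI %.2f above BP4 cutoff; no intronic PP3 route defined",
                     annotation.variant_id, annotation.spliceai_max_delta)
        return None
    return None


def assign_pm2(annotation: "VariantAnnotation", cfg: RuleConfig = DEFAULT_RULES) -> Optional[EvidenceCode]:
    """PM2 at supporting strength for variants absent/rare in gnomAD.

    Missing population fields count as absence from the population data.
    """
    af_ok = annotation.gnomad_af is None or annotation.gnomad_af <= cfg.pm2_max_af
    hom_ok = (
        annotation.gnomad_homozygotes is None
        or annotation.gnomad_homozygotes <= cfg.pm2_max_homozygotes
    )
    if af_ok and hom_ok:
        return make_code("PM2", Strength.SUPPORTING, rationale="absent or rare in gnomAD")
    return None


def assign_pm5(annotation: "VariantAnnotation") -> Optional[EvidenceCode]:
    """PM5 from a different P/LP change at the same residue (REVEL-gated)."""
    if not annotation.reported_in_patient:
        return None
    for ref in annotation.clinvar_same_residue:
        if ref.classification not in ("P", "LP"):
            continue
        if annotation.revel is None or ref.revel is None:
            continue
        if annotation.revel >= ref.revel or (annotation.revel >= 0.7 and ref.revel >= 0.7):
            return make_code(
                "PM5",
                rationale=f"same-residue {ref.protein_change} ({ref.classification}, REVEL {ref.revel})",
            )
    return None


@dataclass(frozen=True)
class EvidenceBundle:
    """Deduplicated evidence for one variant, plus bookkeeping.

    ``override`` is ``"hypomorphic"`` for partially functional alleles the
    five-tier system does not apply to; the combiner then reports NA.
    """

    variant_id: str
    codes: tuple[EvidenceCode, ...]
    suppressed: tuple[EvidenceCode, ...] = ()
    override: str | None = None
    notes: tuple[str, ...] = ()


def _dedup_keep_stronger(codes: Iterable[EvidenceCode]) -> list[EvidenceCode]:
    by_code: dict[str, EvidenceCode] = {}
    for c in codes:
        prev = by_code.get(c.code)
        if prev is None:
            by_code[c.code] = c
            continue
        if prev.source == "passthrough" and c.source == "passthrough" and prev.strength is not c.strength:
            raise EvidenceConflictError(
                f"conflicting pass-through strengths for {c.code}: "
                f"{prev.strength.value} vs {c.strength.value}"
            )
        if c.strength.rank > prev.strength.rank:
            by_code[c.code] = c
    return list(by_code.values())


def collect_evidence(
    annotation: "VariantAnnotation",
    findex: FIndexResult | float | None = None,
    cfg: RuleConfig = DEFAULT_RULES,
) -> EvidenceBundle:
    """Union of computed and pass-through codes with the gene-specific collection rules.

    * duplicates collapse to the stronger strength (conflicting duplicate
      pass-through strengths raise);
    * for intronic/splice-region variants, a functional PS3/BS3 suppresses
      computational PP3/BP4 (the in-silico splice prediction is redundant
      once an RNA/functional assay has spoken);
    * a hypomorphic flag short-circuits to an override with empty evidence.
    """
    if annotation.hypomorphic_flag:
        return EvidenceBundle(
            annotation.variant_id, (), override="hypomorphic",
            notes=("hypomorphic allele: five-tier classification not attempted",),
        )
    computed = [
        assign_functional(findex, cfg),
        assign_computational(annotation, cfg),
        assign_pm2(annotation, cfg),
        assign_pm5(annotation),
    ]
    codes = [c for c in computed if c is not None] + list(annotation.passthrough_codes)
    codes = _dedup_keep_stronger(codes)

    suppressed: list[EvidenceCode] = []
    notes: list[str] = []
    if annotation.consequence in _INTRONIC and any(c.code in ("PS3", "BS3") for c in codes):
        keep = []
        for c in codes:
            if c.code in ("PP3", "BP4") and c.source == "computed":
                suppressed.append(c)
                notes.append(f"{c.code} suppressed: PS3/BS3 present for intronic variant")
            else:
                keep.append(c)
        codes = keep

    for c in codes:
        log.info("%s: %s (%s) %s", annotation.variant_id, c.token(), c.source, c.rationale)
    return EvidenceBundle(annotation.variant_id, tuple(codes), tuple(suppressed), None, tuple(notes))


def sort_codes(codes: Iterable[EvidenceCode]) -> list[EvidenceCode]:
    """Canonical order: pathogenic by strength descending, then benign."""
    return sorted(
        codes,
        key=lambda c: (c.direction is Direction.BENIGN, -c.strength.rank, c.code),
    )


def format_codes(codes: Iterable[EvidenceCode]) -> str:
    return ", ".join(c.token() for c in sort_codes(codes))
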