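"""Combination of ACMG-AMP evidence codes into a five-tier verdict.

The combination procedure has three stages:

1. **Rarity-only conflict drop.**  When PM2 at supporting strength is the
   only pathogenic-direction code and benign-direction evidence exists, PM2
   is ignored (rarity alone should not hold a verdict hostage against
   functional/computational benign evidence).  The dropped code is recorded.
2. **Point scoring for conflicting evidence.**  If both directions are still
   represented, codes are scored (supporting 1, moderate 2, strong 4, very
   strong 8; benign codes negative; a stand-alone benign code is verdict
   Benign outright) and mapped to bands: >= 10 pathogenic, 6..9 likely
   pathogenic, 0..5 VUS, -6..-1 likely benign, <= -7 benign.
3. **Categorical tables otherwise.**  Unidirectional evidence goes through
   the classical combining tables; a stronger code may stand in for a weaker
   requirement, and a code counts at its modified strength.

Two satisfiable tiers resolve to the stronger one.  The procedure is a
verified reconstruction: all printed evidence rows of the study it follows
reproduce their printed verdicts, and the categorical tables are checked
against a brute-force assignment oracle in the test suite.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .evidence import Direction, EvidenceBundle, EvidenceCode, Strength

SA, VS, ST, MO, SU = (
    Strength.STAND_ALONE,
    Strength.VERY_STRONG,
    Strength.STRONG,
    Strength.MODERATE,
    Strength.SUPPORTING,
)


class Verdict(str, enum.Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    VUS = "vus"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"
    HYPOMORPHIC_NA = "hypomorphic_na"

    @property
    def label(self) -> str:
        return {
            Verdict.PATHOGENIC: "Pathogenic",
            Verdict.LIKELY_PATHOGENIC: "Likely pathogenic",
            Verdict.VUS: "VUS",
            Verdict.LIKELY_BENIGN: "Likely benign",
            Verdict.BENIGN: "Benign",
            Verdict.HYPOMORPHIC_NA: "NA",
        }[self]


@dataclass(frozen=True)
class Classification:
    variant_id: str
    verdict: Verdict
    route: str  # "categorical" | "points_conflict" | "override"
    points: int | None = None
    matched_rule: str = ""
    dropped_codes: tuple[EvidenceCode, ...] = ()


#: Point values for the conflict route.
POINTS: Mapping[Strength, int] = {SU: 1, MO: 2, ST: 4, VS: 8}

#: Point bands: (minimum points inclusive, verdict), scanned top-down.
POINT_BANDS: Sequence[tuple[int, Verdict]] = (
    (10, Verdict.PATHOGENIC),
    (6, Verdict.LIKELY_PATHOGENIC),
    (0, Verdict.VUS),
    (-6, Verdict.LIKELY_BENIGN),
)

# Categorical rules as minimal slot multisets; a code satisfies a slot when
# its strength rank is >= the slot's.  Named for audit trails.
PATHOGENIC_RULES: Sequence[tuple[str, tuple[Strength, ...]]] = (
    ("P: 1 very strong + 1 strong", (VS, ST)),
    ("P: 1 very strong + 2 moderate", (VS, MO, MO)),
    ("P: 1 very strong + 1 moderate + 1 supporting", (VS, MO, SU)),
    ("P: 1 very strong + 2 supporting", (VS, SU, SU)),
    ("P: 2 strong", (ST, ST)),
    ("P: 1 strong + 3 moderate", (ST, MO, MO, MO)),
    ("P: 1 strong + 2 moderate + 2 supporting", (ST, MO, MO, SU, SU)),
    ("P: 1 strong + 1 moderate + 4 supporting", (ST, MO, SU, SU, SU, SU)),
)
LIKELY_PATHOGENIC_RULES: Sequence[tuple[str, tuple[Strength, ...]]] = (
    ("LP: 1 very strong + 1 moderate", (VS, MO)),
    ("LP: 1 strong + 1 moderate", (ST, MO)),
    ("LP: 1 strong + 2 supporting", (ST, SU, SU)),
    ("LP: 3 moderate", (MO, MO, MO)),
    ("LP: 2 moderate + 2 supporting", (MO, MO, SU, SU)),
    ("LP: 1 moderate + 4 supporting", (MO, SU, SU, SU, SU)),
)
BENIGN_RULES: Sequence[tuple[str, tuple[Strength, ...]]] = (
    ("B: 1 stand-alone", (SA,)),
    ("B: 2 strong", (ST, ST)),
)
LIKELY_BENIGN_RULES: Sequence[tuple[str, tuple[Strength, ...]]] = (
    ("LB: 1 strong + 1 supporting", (ST, SU)),
    ("LB: 2 supporting", (SU, SU)),
)


def _satisfies(strengths: Sequence[Strength], slots: tuple[Strength, ...]) -> bool:
    """Sorted-domination matching: strongest codes fill strongest slots.

    With a totally ordered strength scale, an injective assignment of codes
    to slots (code >= slot) exists iff, after sorting both descending, the
    i-th code dominates the i-th slot (Hall's condition collapses to prefix
    domination).
    """
    if len(strengths) < len(slots):
        return False
    ranked = sorted((s.rank for s in strengths), reverse=True)
    needed = sorted((s.rank for s in slots), reverse=True)
    return all(r >= n for r, n in zip(ranked, needed))


def _first_match(
    strengths: Sequence[Strength], rules: Sequence[tuple[str, tuple[Strength, ...]]]
) -> str | None:
    for name, slots in rules:
        if _satisfies(strengths, slots):
            return name
    return None


def score_points(codes: Iterable[EvidenceCode]) -> int:
    """Signed point total (pathogenic positive, benign negative)."""
    total = 0
    for c in codes:
        pts = POINTS[c.strength]
        total += pts if c.direction is Direction.PATHOGENIC else -pts
    return total


def combine(evidence: Iterable[EvidenceCode] | EvidenceBundle, variant_id: str = "") -> Classification:
    """Combine a deduplicated evidence list into a five-tier verdict."""
    if isinstance(evidence, EvidenceBundle):
        if evidence.override == "hypomorphic":
            return Classification(
                evidence.variant_id, Verdict.HYPOMORPHIC_NA, "override",
                matched_rule="hypomorphic allele",
            )
        variant_id = variant_id or evidence.variant_id
        codes = list(evidence.codes)
    else:
        codes = list(evidence)

    if not codes:
        return Classification(variant_id, Verdict.VUS, "categorical", matched_rule="no evidence")

    # Step 1: drop PM2_sup when it is the only pathogenic code amid benign evidence.
    pathogenic = [c for c in codes if c.direction is Direction.PATHOGENIC]
    benign = [c for c in codes if c.direction is Direction.BENIGN]
    dropped: tuple[EvidenceCode, ...] = ()
    if (
        benign
        and len(pathogenic) == 1
        and pathogenic[0].code == "PM2"
        and pathogenic[0].strength is SU
    ):
        dropped = (pathogenic[0],)
        codes = benign
        pathogenic = []

    # Step 2: conflicting directions are scored with points.
    if pathogenic and benign:
        if any(c.direction is Direction.BENIGN and c.strength is SA for c in codes):
            return Classification(
                variant_id, Verdict.BENIGN, "points_conflict",
                points=None, matched_rule="stand-alone benign", dropped_codes=dropped,
            )
        points = score_points(codes)
        verdict = Verdict.BENIGN
        rule = "points <= -7"
        for minimum, v in POINT_BANDS:
            if points >= minimum:
                verdict, rule = v, f"points {points} in band >= {minimum}"
                break
        return Classification(variant_id, verdict, "points_conflict", points, rule, dropped)

    # Step 3: unidirectional evidence goes through the categorical tables.
    if pathogenic:
        strengths = [c.strength for c in pathogenic]
        rule = _first_match(strengths, PATHOGENIC_RULES)
        if rule:
            return Classification(variant_id, Verdict.PATHOGENIC, "categorical", None, rule, dropped)
        rule = _first_match(strengths, LIKELY_PATHOGENIC_RULES)
        if rule:
            return Classification(variant_id, Verdict.LIKELY_PATHOGENIC, "categorical", None, rule, dropped)
        return Classification(variant_id, Verdict.VUS, "categorical", None,
                              "pathogenic evidence below likely-pathogenic rules", dropped)
    strengths = [c.strength for c in benign]
    rule = _first_match(strengths, BENIGN_RULES)
    if rule:
        return Classification(variant_id, Verdict.BENIGN, "categorical", None, rule, dropped)
    rule = _first_match(strengths, LIKELY_BENIGN_RULES)
    if rule:
        return Classification(variant_id, Verdict.LIKELY_BENIGN, "categorical", None, rule, dropped)
    return Classification(variant_id, Verdict.VUS, "categorical", None,
                          "benign evidence below likely-benign rules", dropped)


def classify_batch(bundles: Iterable[EvidenceBundle]) -> list[Classification]:
    """Order-preserving classification of many variants.

    Per-row errors propagate as a VUS classification with the error recorded
    in ``matched_rule`` rather than aborting the batch.
    """
    out = []
    for bundle in bundles:
        try:
            out.append(combine(bundle))
        except Exception as exc:  # noqa: BLE001 - row isolation is the contract
            out.append(
                Classification(bundle.variant_id, Verdict.VUS, "categorical",
                               matched_rule=f"error: {exc}")
            )
    return out
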