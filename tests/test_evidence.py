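"""ACMG evidence assignment: thresholds, PM5 logic, collection rules."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abca4func import fixtures
from abca4func.annotation import VariantAnnotation, ClinVarSameResidue
from abca4func.errors import EvidenceConflictError
from abca4func.evidence import (
    RuleConfig,
    Strength,
    assign_computational,
    assign_functional,
    assign_pm2,
    assign_pm5,
    collect_evidence,
    make_code,
    parse_code_list,
    parse_code_token,
)
from abca4func.hgvs import describe_variant

CFG = RuleConfig()


def missense_annotation(revel=None, **kwargs):
    return VariantAnnotation(
        variant_id=kwargs.pop("variant_id", "v"),
        description=describe_variant("c.614G>T", "p.(Cys205Phe)"),
        revel=revel,
        **kwargs,
    )


def intronic_annotation(spliceai=None, offset_text="c.5461-10T>C", **kwargs):
    return VariantAnnotation(
        variant_id=kwargs.pop("variant_id", "v"),
        description=describe_variant(offset_text),
        spliceai_max_delta=spliceai,
        **kwargs,
    )


class TestFunctionalEvidence:
    @pytest.mark.parametrize(
        "F,code,strength",
        [
            (0.17, "PS3", Strength.STRONG),
            (0.48, "PS3", Strength.STRONG),
            (0.499999, "PS3", Strength.STRONG),
            (0.90, "BS3", Strength.SUPPORTING),  # inclusive boundary
            (1.35, "BS3", Strength.SUPPORTING),
        ],
    )
    def test_cutoffs(self, F, code, strength):
        out = assign_functional(F, CFG)
        assert out is not None and (out.code, out.strength) == (code, strength)

    @pytest.mark.parametrize("F", [0.5, 0.60, 0.89])
    def test_intermediate_F_yields_no_code(self, F):
        assert assign_functional(F, CFG) is None

    def test_no_findex_no_code(self):
        assert assign_functional(None, CFG) is None

    @given(F=st.floats(min_value=-1, max_value=2))
    @settings(derandomize=True, max_examples=100)
    def test_never_both_ps3_and_bs3(self, F):
        out = assign_functional(F, CFG)
        assert out is None or out.code in ("PS3", "BS3")


class TestComputationalEvidence:
    @pytest.mark.parametrize(
        "revel,expected",
        [(0.967, "PP3"), (0.76, "PP3"), (0.7, "PP3"), (0.261, "BP4"), (0.4, "BP4"), (0.496, None), (0.542, None)],
    )
    def test_missense_revel_thresholds(self, revel, expected):
        out = assign_computational(missense_annotation(revel), CFG)
        assert (out.code if out else None) == expected

    def test_missing_revel_yields_none(self):
        assert assign_computational(missense_annotation(None), CFG) is None

    def test_intronic_bp4_requires_low_spliceai_and_no_aux_prediction(self):
        out = assign_computational(intronic_annotation(0.07), CFG)
        assert out is not None and out.code == "BP4"
        # an auxiliary-tool novel-site prediction of any strength blocks BP4
        assert assign_computational(intronic_annotation(0.0, aux_splice_novel_site=True), CFG) is None
        # no PP3 route is defined for intronic variants
        assert assign_computational(intronic_annotation(0.95), CFG) is None

    @given(revel=st.one_of(st.none(), st.floats(min_value=0, max_value=1)))
    @settings(derandomize=True, max_examples=100)
    def test_missense_never_both_pp3_and_bp4(self, revel):
        out = assign_computational(missense_annotation(revel), CFG)
        assert out is None or out.code in ("PP3", "BP4")


class TestPm2:
    def test_absent_variant_gets_supporting_pm2(self):
        out = assign_pm2(missense_annotation(gnomad_af=0.0, gnomad_homozygotes=0), CFG)
        assert out is not None and (out.code, out.strength) == ("PM2", Strength.SUPPORTING)

    def test_missing_population_fields_count_as_absent(self):
        assert assign_pm2(missense_annotation(), CFG) is not None

    def test_homozygote_cap_is_three(self):
        assert assign_pm2(missense_annotation(gnomad_homozygotes=3), CFG) is not None
        assert assign_pm2(missense_annotation(gnomad_homozygotes=4), CFG) is None

    def test_common_variant_excluded_by_af_ceiling(self):
        assert assign_pm2(missense_annotation(gnomad_af=0.0025), CFG) is None


class TestPm5:
    def ref(self, classification="P", revel=0.90):
        return ClinVarSameResidue("p.(Cys205Tyr)", classification, True, revel)

    def test_pm5_for_higher_revel_than_reference(self):
        ann = missense_annotation(0.967, reported_in_patient=True,
                                  clinvar_same_residue=(self.ref(),))
        out = assign_pm5(ann)
        assert out is not None and out.code == "PM5" and out.strength is Strength.MODERATE

    def test_empty_reference_list_gives_none(self):
        assert assign_pm5(missense_annotation(0.99, reported_in_patient=True)) is None

    def test_both_above_0p7_branch(self):
        # own 0.80 < reference 0.95, but both >= 0.7 satisfies the OR clause
        ann = missense_annotation(0.80, reported_in_patient=True,
                                  clinvar_same_residue=(self.ref(revel=0.95),))
        assert assign_pm5(ann) is not None

    def test_requires_patient_report_and_plp_reference(self):
        ann = missense_annotation(0.99, reported_in_patient=False,
                                  clinvar_same_residue=(self.ref(),))
        assert assign_pm5(ann) is None
        ann = missense_annotation(0.99, reported_in_patient=True,
                                  clinvar_same_residue=(self.ref(classification="other"),))
        assert assign_pm5(ann) is None

    def test_lower_revel_without_both_branch_gives_none(self):
        ann = missense_annotation(0.60, reported_in_patient=True,
                                  clinvar_same_residue=(self.ref(revel=0.65),))
        assert assign_pm5(ann) is None


class TestCollectEvidence:
    def test_intronic_ps3_suppresses_bp4(self):
        ann = intronic_annotation(
            0.07, gnomad_af=2e-4, gnomad_homozygotes=0,
            passthrough_codes=tuple(parse_code_list("PM3:very_strong;PS3;PP5")),
        )
        bundle = collect_evidence(ann, None, CFG)
        tokens = sorted(c.token() for c in bundle.codes)
        assert tokens == ["PM2_sup", "PM3_very strong", "PP5", "PS3"]
        assert [c.code for c in bundle.suppressed] == ["BP4"]

    def test_missense_keeps_ps3_and_pp3_together(self):
        ann = missense_annotation(0.967, gnomad_af=0.0, gnomad_homozygotes=0)
        bundle = collect_evidence(ann, 0.00, CFG)
        codes = {c.code for c in bundle.codes}
        assert {"PS3", "PP3", "PM2"} <= codes

    def test_hypomorphic_short_circuits(self):
        ann = missense_annotation(0.402, hypomorphic_flag=True)
        bundle = collect_evidence(ann, None, CFG)
        assert bundle.override == "hypomorphic" and bundle.codes == ()

    def test_duplicates_collapse_to_stronger(self):
        ann = missense_annotation(
            None, gnomad_af=0.5,
            passthrough_codes=(make_code("PS3", Strength.SUPPORTING, source="passthrough"),),
        )
        bundle = collect_evidence(ann, 0.1, CFG)  # computed PS3 at strong
        ps3 = [c for c in bundle.codes if c.code == "PS3"]
        assert len(ps3) == 1 and ps3[0].strength is Strength.STRONG

    def test_conflicting_passthrough_duplicates_raise(self):
        ann = missense_annotation(
            None, gnomad_af=0.5,
            passthrough_codes=(
                make_code("PM3", Strength.STRONG, source="passthrough"),
                make_code("PM3", Strength.SUPPORTING, source="passthrough"),
            ),
        )
        with pytest.raises(EvidenceConflictError, match="PM3"):
            collect_evidence(ann, None, CFG)

    def test_published_subscore_multisets_reproduced_for_every_row(self):
        f_map = dict(zip(fixtures.printed_findex_frame()["variant_id"],
                         fixtures.printed_findex_frame()["F"]))
        for entry, ann in zip(fixtures.TABLE_CLASSIFICATION, fixtures.annotations()):
            bundle = collect_evidence(ann, f_map.get(ann.variant_id), CFG)
            if entry["subscores"] == "Hypomorphic":
                assert bundle.override == "hypomorphic"
                continue
            got = sorted(c.token() for c in bundle.codes)
            want = sorted(c.token() for c in parse_code_list(entry["subscores"]))
            assert got == want, ann.variant_id


class TestCodeTokens:
    @pytest.mark.parametrize(
        "token,code,strength",
        [
            ("PM3_very strong", "PM3", Strength.VERY_STRONG),
            ("PM3:very_strong", "PM3", Strength.VERY_STRONG),
            ("BS3_sup", "BS3", Strength.SUPPORTING),
            ("PS3_mod", "PS3", Strength.MODERATE),
            ("PVS1", "PVS1", Strength.VERY_STRONG),
            ("BP4", "BP4", Strength.SUPPORTING),
        ],
    )
    def test_parse_and_canonical_form(self, token, code, strength):
        parsed = parse_code_token(token)
        assert (parsed.code, parsed.strength) == (code, strength)
        assert parse_code_token(parsed.token()) == parsed or parsed.token() == token

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            parse_code_token("PQ9")
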