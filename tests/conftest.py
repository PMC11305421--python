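import pytest

from abca4func import assay, findex, fixtures


@pytest.fixture(scope="session")
def expr_rel():
    return assay.normalize_expression(fixtures.expression_replicates(), fixtures.WT_ID)


@pytest.fixture(scope="session")
def atp_rel():
    return assay.relative_atpase(fixtures.atpase_replicates(), fixtures.WT_ID)


@pytest.fixture(scope="session")
def study_summary(expr_rel, atp_rel):
    return assay.summarize(expr_rel, atp_rel)


@pytest.fixture(scope="session")
def study_findex(expr_rel, atp_rel):
    return findex.findex_per_replicate(expr_rel, atp_rel, fixtures.WT_ID)


@pytest.fixture(scope="session")
def published_summary():
    return fixtures.functional_summary().set_index("variant_id")
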