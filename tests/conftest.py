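import pytest

import semannot as sa


@pytest.fixture(scope="session")
def toy_domain():
    return sa.toy_kitchen_domain()


@pytest.fixture(scope="session")
def brownie_domain():
    return sa.gen_toy_domain("brownie")


@pytest.fixture(scope="session")
def extract_tier():
    return sa.load_s09_extract()


@pytest.fixture(scope="session")
def extract_result(brownie_domain, extract_tier):
    """The S09 extract converted, validated, and its trajectory."""
    plan = sa.tier_to_plan(extract_tier, brownie_domain)
    report, trajectory = sa.validate_plan(brownie_domain, plan)
    return plan, report, trajectory


def make_tier(pairs, run_id="run", annotator_id="A", start=0):
    """Gap-free tier from (duration_ms, label) pairs."""
    segments, t = [], start
    for duration, label in pairs:
        segments.append(sa.Segment(t, t + duration, label))
        t += duration
    return sa.AnnotationTier(run_id=run_id, annotator_id=annotator_id, segments=segments)


@pytest.fixture
def tier_factory():
    return make_tier
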