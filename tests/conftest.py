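import pytest

from archevo import folate_fixture, parse_profile, read_newick


@pytest.fixture(scope="session")
def folate():
    return folate_fixture()


@pytest.fixture(scope="session")
def case_profiles():
    """The distinct genome profiles observed at the case-study tips."""
    return [
        parse_profile(t)
        for t in [".", "B-K-P", "B-B-K-P", "B-B;K-P", "B;K-P", "K-P"]
    ]


@pytest.fixture(scope="session")
def folate_infer():
    """Unconstrained Sankoff run on the case study (computed once per session)."""
    from archevo import run_case_study

    return run_case_study("infer")


@pytest.fixture
def three_tip_tree():
    return read_newick("((A,B)AB,C)root;")
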