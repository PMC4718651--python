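import pytest

from socialcascade.scenarios import LikelihoodSpec, load_scenarios


@pytest.fixture(scope="session")
def spec23():
    """The 2/3-reliability, equal-prior likelihood used in both designs."""
    return LikelihoodSpec(p_signal_given_match=2.0 / 3.0, prior_A=0.5)


@pytest.fixture(scope="session")
def study1():
    return load_scenarios("study1")


@pytest.fixture(scope="session")
def study2():
    return load_scenarios("study2")
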