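import numpy as np
import pytest

from steamerscan import clade_classifier as clc
from steamerscan import simdata as sd


@pytest.fixture(scope="session")
def steamer_spec() -> sd.ElementSpec:
    """Reference-like element: 177 bp LTRs, 12 bp PBS, 4602 bp internal."""
    return sd.default_steamer_spec()


@pytest.fixture(scope="session")
def canonical_element(steamer_spec):
    seq, features = sd.make_canonical_element(steamer_spec)
    return steamer_spec, seq, features


@pytest.fixture(scope="session")
def small_element():
    """A shorter element (3 kb internal) that keeps alignment-heavy tests fast."""
    spec = sd.ElementSpec(internal_length=3000, seed=42)
    seq, features = sd.make_canonical_element(spec)
    return spec, seq, features


@pytest.fixture(scope="session")
def domain_panel() -> list[clc.PanelEntry]:
    return clc.panel_from_tuples(sd.make_domain_panel(5, seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
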