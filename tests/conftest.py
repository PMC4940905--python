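import pytest

from comodiff import diff, load_builtin_vocabulary
from comodiff.fixtures import MUTATION_NAMES, make_version_pair

SEEDS = (1, 2, 3, 4, 5)


@pytest.fixture(scope="session")
def voc():
    return load_builtin_vocabulary()


@pytest.fixture(scope="session")
def fixture_pairs():
    """All scripted mutation fixtures: (mutation, seed) -> (doc_a, doc_b, expectation)."""
    return {(m, s): make_version_pair(m, seed=s)
            for m in MUTATION_NAMES for s in SEEDS}


@pytest.fixture(scope="session")
def fixture_deltas(fixture_pairs):
    """Deltas for every fixture pair, computed once per session."""
    return {key: diff(a, b, dialect="sbml")
            for key, (a, b, _) in fixture_pairs.items()}


MINIMAL_SBML_A = """\
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="m">
    <listOfParameters>
      <parameter id="Km1" value="23.24" units="molesperlitre"/>
    </listOfParameters>
  </model>
</sbml>
"""


@pytest.fixture
def km1_docs():
    """The minimal worked-example pair: parameter Km1 changes 23.24 -> 23.42."""
    return MINIMAL_SBML_A, MINIMAL_SBML_A.replace("23.24", "23.42")
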