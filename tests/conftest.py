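import io

import pytest
from hypothesis import HealthCheck, settings

from microgambi import parse_taxa_list

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[
        HealthCheck.too_slow,
        # the shared reference fixtures are read-only
        HealthCheck.function_scoped_fixture,
    ],
)
settings.load_profile("ci")


TINY_REF_TSV = "\n".join(
    [
        "n\ttaxon\tncbi\tworms\tEG\tlinks\tliterature\tcomments",
        "1\tDesulfobacter\tNCBI:1\t\tI\t\t\t",
        "2\tSensibacter calmus\t\t\tI\t\t\t",
        "3\tQuietus profundus\t\t\tI\t\t\t",
        "4\tVibrio\t\t\tIII\tdoi:10.1/x\tsome paper\topportunist",
        "5\tToleribacter durus\t\t\tIII\t\t\t",
        "6\tMysterium incertum\t\t\tnot assigned\t\t\t",
    ]
) + "\n"


@pytest.fixture
def tiny_ref():
    """Six-taxon reference: 3 EGI, 2 EGIII, 1 not assigned."""
    return parse_taxa_list(io.StringIO(TINY_REF_TSV))


@pytest.fixture
def tiny_ref_tsv():
    return TINY_REF_TSV


COUNTS_TSV = "\n".join(
    [
        "taxon\tST1\tST2\tST3",
        "Desulfobacter\t60\t0\t0",
        "Vibrio\t40\t0\t0",
        "Ignotus novus\t0\t0\t25",
        "Mysterium incertum\t0\t10\t0",
    ]
) + "\n"


@pytest.fixture
def counts_tsv():
    """ST1: 60 EGI / 40 EGIII; ST2: only not-assigned; ST3: only not-in-list."""
    return COUNTS_TSV
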