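import logging
import sys
from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

sys.path.insert(0, str(Path(__file__).parent))

from regmotif import RegulatoryNetwork, fixture_melanoma_circuits

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

logging.getLogger("regmotif").setLevel(logging.ERROR)


@pytest.fixture
def ffl_fixture():
    """The three-edge coherent FFL: miR-155 -| SOX10 -> MITF, miR-155 -| MITF."""
    net = RegulatoryNetwork(name="ffl_fixture")
    net.add_node("miR-155", "MIRNA", {"melanoma"})
    net.add_node("SOX10", "TF", {"melanoma"})
    net.add_node("MITF", "TF", {"melanoma"})
    net.add_edge("miR-155", "SOX10", -1, "post_transcriptional", {"melanoma"})
    net.add_edge("miR-155", "MITF", -1, "post_transcriptional", {"melanoma"})
    net.add_edge("SOX10", "MITF", 1, "transcriptional", {"melanoma"})
    return net


@pytest.fixture
def fbl_fixture():
    """The three-edge positive FBL: ATF2 -| SOX10 -> miR-204 -| ATF2."""
    net = RegulatoryNetwork(name="fbl_fixture")
    net.add_node("SOX10", "TF", {"melanoma"})
    net.add_node("ATF2", "TF", {"melanoma"})
    net.add_node("miR-204", "MIRNA", {"melanoma"})
    net.add_edge("ATF2", "SOX10", -1, "transcriptional", {"melanoma"})
    net.add_edge("SOX10", "miR-204", 1, "transcriptional", {"melanoma"})
    net.add_edge("miR-204", "ATF2", -1, "post_transcriptional", {"melanoma"})
    return net


@pytest.fixture
def melanoma_net():
    return fixture_melanoma_circuits()
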