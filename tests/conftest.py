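import pytest
from hypothesis import settings

from sabpipe import datasets
from sabpipe.panels import BeadPanel, BeadSpec, Control, parse_bead

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ls_panel():
    return datasets.load_ls_class1_panel()


@pytest.fixture(scope="session")
def lc_panel():
    return datasets.load_lc_class1_panel()


@pytest.fixture(scope="session")
def antigen_map():
    return datasets.load_antigen_map()


@pytest.fixture(scope="session")
def demo_freqs():
    return datasets.load_demo_frequency_table()


def make_toy_panel(vendor, labels, lot="toy"):
    """Small panel from allele labels, with the mandatory NC bead."""
    beads = [
        parse_bead(lab, bead_id=f"{vendor}-{i:02d}")
        for i, lab in enumerate(labels, start=1)
    ]
    beads.append(BeadSpec(bead_id=f"{vendor}-NC", control=Control.NEGATIVE))
    return BeadPanel(vendor=vendor, lot=lot, beads=beads)


@pytest.fixture
def toy_panel():
    return make_toy_panel("LS", ["A*01:01", "A*02:01", "B*07:02", "Cw*07:02"])
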