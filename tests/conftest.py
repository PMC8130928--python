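import pytest

from bovidzooms.panel import load_panel
from bovidzooms.spectra import Peak, PeakList
from bovidzooms.synthetic import build_reference_chains


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def reference_chains(panel):
    return build_reference_chains(panel)


@pytest.fixture
def clean_peaklist(panel):
    """Factory: ideal high-S/N peak list for a panel taxon."""

    def make(taxon: str, predicate=None) -> PeakList:
        masses = panel.clean_peaklist(taxon)
        if predicate is not None:
            masses = [m for m in masses if predicate(m)]
        return PeakList([Peak(mz=m, intensity=100.0, sn=50.0) for m in masses])

    return make
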