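import pytest

from tyland import annotation as ann
from tyland import simulate as sim
from tyland.datasets import load_regions


@pytest.fixture(scope="session")
def refs():
    """Shared Ty1/Ty2 reference set (canonical ancestor + evolved subfamilies)."""
    return sim.make_reference_set()


@pytest.fixture(scope="session")
def library():
    """Ty library matching the synthetic reference lengths."""
    return ann.TyLibrary(
        {
            "Ty1": ann.TyFamily("Ty1", 334, 5250),
            "Ty2": ann.TyFamily("Ty2", 332, 5296),
        }
    )


@pytest.fixture(scope="session")
def regions():
    return load_regions()
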