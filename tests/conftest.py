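import numpy as np
import pytest

from hemescan.config import RunConfig
from hemescan.fixtures import CANONICAL_SPECS, make_toy_heme_protein
from hemescan.template_library import build_library


@pytest.fixture(scope="session")
def canonical():
    """The canonical fixture set: list of (structure, ground_truth)."""
    return [make_toy_heme_protein(spec) for spec in CANONICAL_SPECS]


@pytest.fixture(scope="session")
def default_config():
    return RunConfig()


@pytest.fixture(scope="session")
def canonical_libraries(canonical, default_config):
    """One single-structure template library per canonical fixture."""
    libs = []
    for s, _ in canonical:
        lib, _ = build_library([s], default_config.heme_codes, default_config.library)
        libs.append(lib)
    return libs


@pytest.fixture()
def toy(canonical):
    """The first canonical fixture (His/Tyr/Leu site)."""
    return canonical[0]


def assert_structures_close(a, b, tol=1e-3):
    """Residue identities equal and every coordinate within tol (A)."""
    assert [r.rid for r in a.residues] == [r.rid for r in b.residues]
    assert [r.name for r in a.residues] == [r.name for r in b.residues]
    for ra, rb in zip(a.residues, b.residues):
        assert [x.name for x in ra.atoms] == [x.name for x in rb.atoms]
        ca = np.array([x.coord for x in ra.atoms])
        cb = np.array([x.coord for x in rb.atoms])
        assert np.abs(ca - cb).max() <= tol
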