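import pytest

from symlattice import fixtures, symmetry
from symlattice.config import PipelineConfig
from symlattice.sse import assign_sse


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def monomer2():
    """Two-domain pseudo-protein with assigned secondary structure."""
    model = fixtures.make_monomer(2, 44, seed=1)
    return assign_sse(model)


@pytest.fixture(scope="session")
def p4_fixture():
    return fixtures.make_lattice_pair("p4", seed=7)


@pytest.fixture(scope="session")
def p4_complexes(p4_fixture, cfg):
    sc_a = symmetry.detect(p4_fixture.complex_A, "layer", cfg)
    sc_b = symmetry.detect(p4_fixture.complexes_B[0], "layer", cfg)
    assert not isinstance(sc_a, symmetry.AxisRejection)
    assert not isinstance(sc_b, symmetry.AxisRejection)
    return sc_a, sc_b


@pytest.fixture(scope="session")
def p4_input_dir(tmp_path_factory, p4_fixture):
    d = tmp_path_factory.mktemp("p4set")
    p4_fixture.write(d)
    return d
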