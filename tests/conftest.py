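import pytest

from dipolescan.synthgen import make_toy_enzyme, toy_ncs_spec


@pytest.fixture(scope="session")
def toy_fixture():
    """Default toy-enzyme fixture (seed 42), shared read-only across tests."""
    return make_toy_enzyme(toy_ncs_spec(seed=42))


@pytest.fixture(scope="session")
def toy_files(tmp_path_factory):
    """The same fixture written to disk (PQR + QM JSON + ground-truth JSON)."""
    outdir = tmp_path_factory.mktemp("toy42")
    return make_toy_enzyme(toy_ncs_spec(seed=42), outdir=outdir)


@pytest.fixture
def catalytic_exclusions():
    return {("A", 60, "TYR"), ("A", 107, "TYR"), ("A", 109, "GLU"),
            ("A", 121, "LYS"), ("A", 140, "ASP")}
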