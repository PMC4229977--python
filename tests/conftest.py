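import pytest

from sitemotif.fixtures import FixtureSpec, synth_structure
from sitemotif.maker import ResidueSpec, build_motif
from sitemotif.structure import read_pdb


def motif_from_result(result, **kwargs):
    """Build a motif from the planted residues of a synthetic structure."""
    structure = read_pdb(result.pdb_text)
    specs = [
        ResidueSpec(r["res_name"], r["seq_id"], r["chain"])
        for r in result.manifest["planted_residues"]
    ]
    kwargs.setdefault("motif_id", f"motif_{result.manifest['struct_id']}")
    return build_motif(structure, specs, **kwargs), structure


@pytest.fixture(scope="session")
def triad_result():
    """One clean serine-protease-like fixture: planted triad + 40 decoys."""
    return synth_structure(FixtureSpec(seed=7))


@pytest.fixture(scope="session")
def triad_structure(triad_result):
    return read_pdb(triad_result.pdb_text)


@pytest.fixture(scope="session")
def triad_motif(triad_result):
    motif, _ = motif_from_result(triad_result, ec_number="3.4.21.4")
    return motif
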