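import pytest

from mybscan.simulate import FixtureSpec, generate_family


@pytest.fixture(scope="session")
def family():
    """Small labeled synthetic family shared by read-only tests."""
    return generate_family(FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def family_isoforms():
    """Family with explicit isoform groups (4 genes x 3 isoforms)."""
    return generate_family(FixtureSpec(seed=3, n_genes=4, isoforms_per_gene=3))


@pytest.fixture()
def family_dir(tmp_path, family):
    """The same family written out in the file formats the pipeline consumes."""
    return family.write(tmp_path / "fixture")
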