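import pytest

from bgckit import FixtureSpec, make_assembly_lines, make_reference_families, make_toy_genbank


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=42)


@pytest.fixture(scope="session")
def toy_genbank(tmp_path_factory, fixture_spec):
    """(path, manifest) for the planted-truth toy record."""
    path = tmp_path_factory.mktemp("toy") / "toy.gbk"
    manifest = make_toy_genbank(fixture_spec, path)
    return path, manifest


@pytest.fixture(scope="session")
def assembly_fixture(fixture_spec):
    """(query, refs, truth) assembly-line collection."""
    return make_assembly_lines(fixture_spec)


@pytest.fixture(scope="session")
def family_fixture():
    """(refs, queries, true_labels) with a small query count for unit tests."""
    return make_reference_families(FixtureSpec(seed=42, n_queries=9))
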