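import dataclasses

import pytest

from promispred import fixtures as fx


@pytest.fixture(scope="session")
def bundle_spec():
    return fx.bundle_spec(seed=0)


@pytest.fixture(scope="session")
def bundle_proteome(bundle_spec):
    return fx.generate_proteome(bundle_spec)


@pytest.fixture(scope="session")
def toy_gem(bundle_spec):
    return fx.generate_toy_gem(bundle_spec)


@pytest.fixture(scope="session")
def small_bundle_spec():
    """Bundle layout shrunk to 20 genes/organism for fast end-to-end runs."""
    return dataclasses.replace(fx.bundle_spec(seed=0), n_genes_per_organism=20)


@pytest.fixture(scope="session")
def small_bundle(small_bundle_spec, tmp_path_factory):
    """Small bundle fixture written to disk once per session."""
    outdir = tmp_path_factory.mktemp("bundle")
    prot = fx.generate_proteome(small_bundle_spec)
    gem = fx.generate_toy_gem(small_bundle_spec)
    paths = prot.write(outdir)
    paths.update(gem.write(outdir))
    return prot, gem, paths
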