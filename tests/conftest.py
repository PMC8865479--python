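from types import SimpleNamespace

import pytest

from viromine import homology_triage as ht
from viromine import synthetic_data as sd


@pytest.fixture(scope="session")
def community():
    """One small simulated community shared across the suite."""
    cfg = sd.default_config(seed=3, reads_per_library=400)
    genomes = sd.generate_genomes(cfg)
    dbs = sd.build_databases(genomes, seed=3)
    libraries, manifest = sd.simulate_reads(genomes, cfg)
    return SimpleNamespace(cfg=cfg, genomes=genomes, dbs=dbs, libraries=libraries, manifest=manifest)


@pytest.fixture(scope="session")
def viral_searcher(community):
    return ht.ProteinSearcher(community.dbs["viral_db"])


@pytest.fixture(scope="session")
def nvnr_searcher(community):
    return ht.ProteinSearcher(community.dbs["nvnr_db"])
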