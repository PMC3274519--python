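import numpy as np
import pytest

import mitopop as mp
from mitopop import coalsim as cs


@pytest.fixture
def tiny_alignment():
    """Four samples, two populations, two groups, L=8."""
    aln = mp.Alignment(
        ["a1", "a2", "b1", "b2"],
        ["AAAAAAAA", "AAAAAAAA", "AAAAAAGT", "AAAAAAGT"],
    )
    pm = mp.PopulationMap(
        {"a1": "p1", "a2": "p1", "b1": "p2", "b2": "p2"},
        {"p1": "g1", "p2": "g2"},
    )
    return aln, pm


@pytest.fixture
def fasta_files(tmp_path, tiny_alignment):
    aln, pm = tiny_alignment
    fasta = tmp_path / "aln.fasta"
    popmap = tmp_path / "popmap.tsv"
    cs.write_fasta(aln, fasta)
    cs.write_popmap(pm, popmap)
    return fasta, popmap


@pytest.fixture(scope="session")
def constant_sample():
    """One finite-sites sample from a constant-size coalescent (n=30)."""
    model = cs.DemographyModel(kind="constant", theta0=5.0)
    cfg = cs.SimConfig(n=30, L=600, ts_tv_kappa=5.33)
    return cs.simulate_alignment(model, cfg, np.random.default_rng(202)), model, cfg


@pytest.fixture(scope="session")
def study_dataset():
    """The packaged synthetic study-like dataset (deterministic, seed 0)."""
    return cs.make_study_like_dataset(seed=0)
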