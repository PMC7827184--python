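import numpy as np
import pytest

from seqddg.model import ModelConfig
from seqddg.seqdata import Mutation, MutationDataset, MutationRecord, ProteinSequence
from seqddg.synth import SynthConfig, synth_dataset


@pytest.fixture(scope="session")
def tiny_model_config():
    """A small, fast, deterministic boosting configuration for unit tests."""
    return ModelConfig(n_estimators=30, max_depth=3, learning_rate=0.3, seed=0)


@pytest.fixture(scope="session")
def small_ground_truth():
    """A small synthetic benchmark shared across tests (pure in config+seed)."""
    cfg = SynthConfig(n_proteins=4, n_mutations=25, noise_sd=0.4, seed=42)
    return synth_dataset(cfg)


@pytest.fixture
def toy_dataset():
    """Five proteins, one mutation each, mutually non-homologous sequences."""
    rng = np.random.default_rng(5)
    from seqddg.pssm import ALPHABET

    seqs, recs = {}, []
    for k in range(5):
        pid = f"P{k}"
        residues = "".join(ALPHABET[i] for i in rng.integers(0, 20, size=40))
        seqs[pid] = ProteinSequence(pid, residues)
        wt = residues[9]
        mut = "A" if wt != "A" else "G"
        recs.append(MutationRecord(pid, Mutation(wt, 10, mut), target=float(k)))
    return MutationDataset(recs, seqs)
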