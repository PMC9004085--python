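import numpy as np
import pytest

from hgdti import SynthConfig, generate, generate_sequences, load_heterograph
from hgdti.features import build_node_content, read_fasta_file, read_smiles_file
from hgdti.graph import DEFAULT_LAYOUT, write_matrix


@pytest.fixture(scope="session")
def default_fixture_dir(tmp_path_factory):
    """The default planted-structure benchmark with sequence fixtures."""
    out = tmp_path_factory.mktemp("synth_default")
    cfg = SynthConfig()
    generate(cfg, out)
    generate_sequences(cfg, out)
    return out


@pytest.fixture(scope="session")
def default_graph(default_fixture_dir):
    return load_heterograph(default_fixture_dir)


@pytest.fixture(scope="session")
def default_content(default_fixture_dir, default_graph):
    smiles = read_smiles_file(str(default_fixture_dir / "smiles.tsv"))
    fasta = read_fasta_file(str(default_fixture_dir / "proteins.fasta"))
    return build_node_content(default_graph, dim=128, seed=5,
                              smiles=smiles, fasta=fasta)


@pytest.fixture(scope="session")
def tiny_dir(tmp_path_factory):
    """A small, dense graph for fast model tests."""
    out = tmp_path_factory.mktemp("synth_tiny")
    generate(SynthConfig(n_drug=8, n_protein=10, n_disease=4, n_se=3,
                         density=0.25, seed=3), out)
    return out


@pytest.fixture(scope="session")
def tiny_graph(tiny_dir):
    return load_heterograph(tiny_dir)


def write_dtinet_dir(path, mats):
    """Write a DTINet-layout directory from a relation -> matrix dict."""
    path.mkdir(parents=True, exist_ok=True)
    for rel, name in DEFAULT_LAYOUT.items():
        write_matrix(path / name, np.asarray(mats[rel], dtype=float))
    return path


def manual_mats(n_drug=3, n_protein=2, n_disease=2, n_se=2):
    """All-zero matrix set of the given sizes (edit entries per test)."""
    return {
        "drug-interaction-protein": np.zeros((n_drug, n_protein)),
        "drug-interaction-drug": np.zeros((n_drug, n_drug)),
        "protein-interaction-protein": np.zeros((n_protein, n_protein)),
        "drug-similarity-drug": np.eye(n_drug),
        "protein-similarity-protein": np.eye(n_protein),
        "drug-association-disease": np.zeros((n_drug, n_disease)),
        "protein-association-disease": np.zeros((n_protein, n_disease)),
        "drug-association-side_effect": np.zeros((n_drug, n_se)),
    }
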