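import numpy as np
import pytest

import graphcell as gc


@pytest.fixture(scope="session")
def tiny_spec():
    """Small corpus spec shared by fast unit tests."""
    return gc.SyntheticSpec(n_cells=80, n_genes=60, seed=7)


@pytest.fixture(scope="session")
def tiny_kb(tiny_spec):
    return gc.simulate_knowledge_base(tiny_spec, seed=7, n_ref=400)


@pytest.fixture(scope="session")
def tiny_corpus(tiny_spec, tiny_kb):
    adata, truth = gc.simulate_corpus(tiny_spec, seed=7)
    profiles = gc.normalize_dataset(gc.profiles_from_anndata(adata, tiny_kb.vocab))
    return adata, truth, profiles


@pytest.fixture(scope="session")
def tiny_config(tiny_kb):
    return gc.ModelConfig(vocab_size=len(tiny_kb.vocab), hidden_dim=32,
                          n_gnn_layers=2, n_transformer_layers=2, n_heads=4,
                          n_bins=10, d_text=tiny_kb.d_text, dropout=0.0,
                          n_cell_types=3, two_step_mode="3class",
                          use_pert_flag=True)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return gc.CellGraphModel(tiny_config, seed=0)


@pytest.fixture(scope="session")
def tiny_tcfg():
    return gc.TrainConfig(epochs=2, batch_size=16, lr=1e-3, warmup_steps=5,
                          n_hvg=60, n_nodes=20, n_bins=10, seed=0)


@pytest.fixture(scope="session")
def tiny_batch(tiny_corpus, tiny_kb, tiny_tcfg):
    """One collated, masked graph batch of 8 cells."""
    from graphcell.training import build_masked_batch, _hvg_panel

    _, _, profiles = tiny_corpus
    hvg = _hvg_panel(profiles, tiny_tcfg)
    rng = np.random.default_rng(3)
    return build_masked_batch(profiles[:8], hvg, tiny_kb, tiny_tcfg, rng)
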