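"""Shared fixtures: desk-scale corpus, trained models, closed-loop harnesses.

Everything is generated programmatically with fixed seeds; the heavier
artifacts (trained VAE, trained surrogate ensembles) are session-scoped so
the whole suite trains each of them once.
"""

import numpy as np
import pytest

from uimd import ensemble, oracle, synthetic, vae

CORPUS_SEED = 7
CORPUS_N = 200
HARNESS_D = 16
HARNESS_PAIRS = 2000


@pytest.fixture(scope="session")
def corpus():
    """200-molecule random corpus with descriptor labels and conformers."""
    spec = synthetic.FixtureSpec(n_molecules=CORPUS_N, max_tokens=16, seed=CORPUS_SEED)
    records, vocab = synthetic.generate_selfies_corpus(spec)
    orc = oracle.DescriptorOracle()
    kept, P, names, units, n_unstable = synthetic.build_labelled_dataset(records, orc)
    return {
        "spec": spec, "records": records, "vocab": vocab, "oracle": orc,
        "kept": kept, "properties": P, "names": names, "units": units,
        "n_unstable": n_unstable,
        "max_atoms": max(r.graph.n_atoms for r in kept if r.graph is not None),
    }


@pytest.fixture(scope="session")
def trained_vae(corpus):
    """SGP-VAE trained with the standard recipe (50 epochs, batch 32)."""
    m = vae.SgpVae(corpus["vocab"], corpus["max_atoms"], corpus["names"],
                   corpus["units"], latent_dim=32, hidden=512, seed=0)
    history = m.train(corpus["kept"], corpus["properties"], epochs=50,
                      batch_size=32, lr=3e-3, seed=0)
    m.train_history = history
    return m


@pytest.fixture(scope="session")
def harness_runs():
    """Five seeded closed-loop harnesses with ensembles trained at the
    standard recipe (300 epochs, batch 32, q = 0.3)."""
    runs = []
    for seed in range(5):
        h = synthetic.closed_loop_harness(d=HARNESS_D, n_pairs=HARNESS_PAIRS, seed=seed)
        m = ensemble.build_ensemble(ensemble.EnsembleConfig(seed=seed), HARNESS_D, 3)
        m.train(h.dataset)
        runs.append((h, m))
    return runs


@pytest.fixture(scope="session")
def lossy_runs():
    """Three seeded lossy-autoencoder harnesses, each with one ensemble
    trained on legacy pairs and one on reacquired pairs."""
    runs = []
    for seed in range(3):
        h = synthetic.lossy_autoencoder_harness(d=HARNESS_D, n_pairs=1000,
                                                distortion=0.5, seed=seed)
        models = {}
        for name, ds in (("legacy", h.legacy_dataset),
                         ("reacquired", h.reacquired_dataset)):
            m = ensemble.build_ensemble(ensemble.EnsembleConfig(seed=seed),
                                        HARNESS_D, 3)
            m.train(ds)
            models[name] = m
        runs.append((h, models))
    return runs


@pytest.fixture(scope="session")
def molecular_surrogate(trained_vae, corpus):
    """Small molecular closed loop: reacquired pairs through the trained VAE
    and descriptor oracle, plus an ensemble trained on them."""
    from uimd import reacquisition
    latents = reacquisition.sample_prior_latents(300, trained_vae.latent_dim, seed=5)
    decoder, embedder = reacquisition.make_molecular_pipeline(
        trained_vae, corpus["oracle"], embed_seed=0)
    dataset = reacquisition.reacquire(latents, decoder, embedder,
                                      corpus["oracle"], seed=5)
    m = ensemble.build_ensemble(ensemble.EnsembleConfig(seed=5),
                                trained_vae.latent_dim, len(dataset.property_names))
    m.train(dataset)
    return {"dataset": dataset, "ensemble": m, "vae": trained_vae}
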