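"""SGP-VAE: loss components, sampling, decoding, training behavior."""

import numpy as np
import pytest
from rdkit import Chem

from uimd import grammar, vae
from uimd.vae import LatentDistribution, SgpVae, kl_gaussian, sample_latent


class TestKl:
    def test_standard_normal_against_itself_is_zero(self):
        assert kl_gaussian(np.zeros(4), np.zeros(4)) == 0.0

    def test_hand_computed_value(self):
        # ½(μ² + σ² − 1 − log σ²) with μ=1, σ²=1 → 0.5
        assert np.isclose(kl_gaussian(np.array([1.0]), np.array([0.0])), 0.5)

    def test_matches_monte_carlo_estimate(self):
        """Closed form vs MC estimate of E_q[log q − log p] at 2·10⁵ draws."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            d = 3
            mu = rng.normal(0, 1, d)
            logvar = rng.normal(0, 0.5, d)
            std = np.exp(0.5 * logvar)
            z = mu + std * rng.standard_normal((200_000, d))
            logq = -0.5 * (((z - mu) / std) ** 2 + np.log(2 * np.pi) + logvar).sum(1)
            logp = -0.5 * (z ** 2 + np.log(2 * np.pi)).sum(1)
            mc = np.mean(logq - logp)
            cf = kl_gaussian(mu, logvar)
            assert abs(cf - mc) / max(cf, 1e-9) < 0.05


class TestSampleLatent:
    def test_degenerate_variance_returns_the_mean(self):
        dist = LatentDistribution(np.array([1.0, -2.0]), np.array([-80.0, -80.0]))
        assert np.allclose(sample_latent(dist, seed=0), dist.mean)

    def test_fixed_seed_reproducible(self):
        dist = LatentDistribution(np.zeros(4), np.zeros(4))
        assert np.array_equal(sample_latent(dist, 7), sample_latent(dist, 7))

    def test_sample_mean_matches_mu_within_monte_carlo_bounds(self):
        mu = np.array([0.5, -1.5])
        dist = LatentDistribution(np.tile(mu, (100_000, 1)),
                                  np.zeros((100_000, 2)))
        draws = sample_latent(dist, seed=1)
        assert np.abs(draws.mean(axis=0) - mu).max() < 3.0 / np.sqrt(100_000)


class TestLossTerms:
    def test_perfect_reconstruction_gives_zero_components(self):
        B, L, V, A, E, k = 2, 3, 4, 2, 2, 2
        rng = np.random.default_rng(0)
        tok = np.eye(V)[rng.integers(0, V, (B, L))]
        types = np.eye(E)[rng.integers(0, E, (B, A))]
        coords = rng.standard_normal((B, A, 3))
        props = rng.standard_normal((B, k))
        comps = vae.loss_terms(
            logits=1e4 * tok, type_scores=types, coord_pred=coords,
            prop_pred=props, mu=np.zeros((B, 5)), logvar=np.zeros((B, 5)),
            tok_onehot=tok, type_onehot=types, coords=coords,
            atom_mask=np.ones((B, A)), graph_present=np.ones(B),
            prop_targets=props)
        for name in ("prop_l1", "graph_l2", "kl", "total"):
            assert abs(float(comps[name])) < 1e-6, name
        assert float(comps["selfies_ce"]) < 1e-6

    def test_absent_graph_zeroes_the_graph_term(self):
        B, L, V, A, E = 1, 2, 3, 2, 2
        tok = np.eye(V)[np.zeros((B, L), dtype=int)]
        comps = vae.loss_terms(
            logits=np.zeros((B, L, V)), type_scores=np.ones((B, A, E)),
            coord_pred=np.ones((B, A, 3)), prop_pred=np.zeros((B, 1)),
            mu=np.zeros((B, 2)), logvar=np.zeros((B, 2)), tok_onehot=tok,
            type_onehot=np.zeros((B, A, E)), coords=np.zeros((B, A, 3)),
            atom_mask=np.ones((B, A)), graph_present=np.zeros(B),
            prop_targets=np.zeros((B, 1)))
        assert float(comps["graph_l2"]) == 0.0

    def test_nan_component_is_reported_by_name(self, corpus, trained_vae):
        bad = np.full((1, len(trained_vae.property_names)), np.nan)
        with pytest.raises(vae.VaeDivergenceError, match="prop_l1"):
            trained_vae.loss_components(corpus["kept"][:1], bad)


class TestEncodeDecode:
    def test_encode_is_deterministic(self, trained_vae, corpus):
        r = corpus["kept"][0]
        a, b = trained_vae.encode(r), trained_vae.encode(r)
        assert np.array_equal(a.mean, b.mean)
        assert np.array_equal(a.log_variance, b.log_variance)

    def test_posterior_finite_for_all_corpus_molecules(self, trained_vae, corpus):
        dist = trained_vae.encode(corpus["kept"])
        assert np.isfinite(dist.mean).all() and np.isfinite(dist.log_variance).all()

    def test_encoding_tolerates_absent_graph(self, trained_vae, corpus):
        r = corpus["kept"][0].with_graph(None)
        dist = trained_vae.encode(r)
        assert np.isfinite(dist.mean).all()

    def test_decode_deterministic_and_dimension_checked(self, trained_vae):
        z = np.random.default_rng(0).standard_normal(trained_vae.latent_dim)
        assert trained_vae.greedy_selfies(z) == trained_vae.greedy_selfies(z)
        with pytest.raises(ValueError):
            trained_vae.decode(np.zeros(trained_vae.latent_dim + 1))

    def test_prior_samples_decode_to_valid_molecules(self, trained_vae):
        rng = np.random.default_rng(11)
        for _ in range(200):
            s = trained_vae.greedy_selfies(rng.standard_normal(trained_vae.latent_dim))
            mol = grammar.decode(s)
            assert mol is not None
            assert Chem.MolFromSmiles(Chem.MolToSmiles(mol)) is not None


class TestTraining:
    def _small(self, corpus, seed=0, weights=None, epochs=6, n=80):
        m = SgpVae(corpus["vocab"], corpus["max_atoms"], corpus["names"],
                   corpus["units"], latent_dim=16, hidden=128, seed=seed)
        hist = m.train(corpus["kept"][:n], corpus["properties"][:n],
                       epochs=epochs, batch_size=32, lr=3e-3, seed=seed,
                       weights=weights)
        return m, hist

    def test_history_and_loss_decrease(self, corpus):
        _, hist = self._small(corpus)
        assert len(hist) == 6
        assert set(hist[0]) >= {"prop_l1", "graph_l2", "selfies_ce", "kl", "total"}
        assert hist[-1]["total"] < hist[0]["total"]

    def test_same_seed_identical_final_loss(self, corpus):
        _, h1 = self._small(corpus, seed=3)
        _, h2 = self._small(corpus, seed=3)
        assert h1[-1]["total"] == h2[-1]["total"]

    def test_property_head_beats_untrained_on_held_out(self, corpus, trained_vae):
        held = corpus["kept"][150:]
        P = corpus["properties"][150:]
        fresh = SgpVae(corpus["vocab"], corpus["max_atoms"], corpus["names"],
                       corpus["units"], latent_dim=32, hidden=512, seed=0)
        fresh.prop_mean, fresh.prop_std = trained_vae.prop_mean, trained_vae.prop_std

        def mae(model):
            errs = []
            for r, p in zip(held, P):
                z = model.encode(r).mean
                pred = model.predict_properties(z).values
                errs.append(np.abs((pred - p) / model.prop_std))
            return np.mean(errs)

        assert mae(trained_vae) < mae(fresh)

    def test_reconstruction_beats_untrained(self, corpus, trained_vae):
        fresh = SgpVae(corpus["vocab"], corpus["max_atoms"], corpus["names"],
                       corpus["units"], latent_dim=32, hidden=512, seed=0)

        def token_accuracy(model):
            ok = total = 0
            for r in corpus["kept"][:100]:
                out = model.decode(model.encode(r).mean)
                ids = np.argmax(out.selfies_logits, axis=1)
                ok += int((ids == r.tokens).sum())
                total += len(r.tokens)
            return ok / total

        assert token_accuracy(trained_vae) > token_accuracy(fresh)

    def test_latent_space_is_property_organized(self, trained_vae, corpus):
        """After training, latent distance correlates with property distance:
        property-similar molecule pairs sit closer than random pairs."""
        Z = trained_vae.encode(corpus["kept"]).mean
        P = trained_vae.standardize(corpus["properties"])
        rng = np.random.default_rng(0)
        i = rng.integers(0, len(Z), 4000)
        j = rng.integers(0, len(Z), 4000)
        keep = i != j
        dz = np.linalg.norm(Z[i[keep]] - Z[j[keep]], axis=1)
        dp = np.linalg.norm(P[i[keep]] - P[j[keep]], axis=1)
        similar = dp < np.median(dp)
        assert dz[similar].mean() < dz[~similar].mean()

    def test_property_head_ablation_degrades_latent_organization(self, corpus):
        """With the property term weighted to zero, the correlation between
        latent distance and property distance weakens (3 seeds)."""
        def corr(weights, seed):
            m, _ = self._small(corpus, seed=seed, weights=weights, epochs=10, n=120)
            Z = m.encode(corpus["kept"][:120]).mean
            P = m.standardize(corpus["properties"][:120])
            rng = np.random.default_rng(0)
            i = rng.integers(0, len(Z), 3000)
            j = rng.integers(0, len(Z), 3000)
            keep = i != j
            dz = np.linalg.norm(Z[i[keep]] - Z[j[keep]], axis=1)
            dp = np.linalg.norm(P[i[keep]] - P[j[keep]], axis=1)
            return np.corrcoef(dz, dp)[0, 1]

        full = np.mean([corr(None, s) for s in range(3)])
        ablated = np.mean([corr({"prop_l1": 0.0}, s) for s in range(3)])
        assert full > ablated


class TestPersistence:
    def test_checkpoint_round_trip(self, trained_vae, tmp_path):
        trained_vae.save(tmp_path / "ckpt")
        loaded = SgpVae.load(tmp_path / "ckpt")
        z = np.random.default_rng(2).standard_normal(trained_vae.latent_dim)
        assert loaded.greedy_selfies(z) == trained_vae.greedy_selfies(z)
        out_a = trained_vae.decode(z)
        out_b = loaded.decode(z)
        assert np.array_equal(out_a.property_pred, out_b.property_pred)
        assert loaded.config_hash() == trained_vae.config_hash()
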