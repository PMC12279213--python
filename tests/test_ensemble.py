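"""Ensemble surrogate: construction, gated training, mean and uncertainty."""

import numpy as np
import pytest
from scipy import stats

from uimd import ensemble as ens
from uimd.ensemble import EnsembleConfig, EnsembleSurrogate, build_ensemble
from uimd.oracle import AnalyticOracle
from uimd.reacquisition import LatentPropertyDataset, sample_prior_latents


def _toy_dataset(n=200, d=4, k=2, seed=0):
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((k, d))
    Z = rng.standard_normal((n, d))
    return LatentPropertyDataset(Z, Z @ A.T, tuple(f"p{i}" for i in range(k)),
                                 ("a.u.",) * k)


def _constant_member(model, j, value):
    """Overwrite member j so it outputs `value` on every input."""
    params = model.members[j].params
    for layer in params:
        layer["W"] = np.zeros_like(layer["W"])
        layer["b"] = np.zeros_like(layer["b"])
    params[-1]["b"] = np.full_like(params[-1]["b"], value)
    from uimd import nn
    model.members[j] = nn.FlatModel(params)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"n_members": 1},
        {"update_probability": 0.0},
        {"update_probability": 1.5},
        {"hidden_layers": (0,)},
        {"activations": ("swoosh",)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EnsembleConfig(**kwargs)

    def test_members_get_distinct_cycled_activations(self):
        m = build_ensemble(EnsembleConfig(n_members=5), 4, 2)
        assert m.activations == ["relu", "tanh", "gelu", "silu", "elu"]
        m7 = build_ensemble(EnsembleConfig(n_members=7), 4, 2)
        assert m7.activations[5] == "relu"

    def test_members_initialized_differently(self):
        m = build_ensemble(EnsembleConfig(seed=0), 4, 2)
        z = np.ones(4)
        preds = [m.member_forward(j, z[None]) for j in range(5)]
        assert len({float(p[0, 0]) for p in preds}) == 5


class TestPredict:
    def test_hand_computed_mean_and_variance(self):
        m = build_ensemble(EnsembleConfig(n_members=2, activations=("relu", "tanh")),
                           3, 1)
        _constant_member(m, 0, 1.0)
        _constant_member(m, 1, 3.0)
        pred = m.predict(np.zeros(3))
        assert pred.mean[0] == 2.0
        assert pred.uncertainty[0] == 1.0  # (1+9)/2 − 4
        assert pred.uncertainty_total == 1.0

    def test_mean_is_permutation_invariant(self):
        m = build_ensemble(EnsembleConfig(seed=1), 4, 2)
        z = np.random.default_rng(0).standard_normal(4)
        base = m.predict(z).mean.copy()
        m.members.reverse()
        m.activations.reverse()
        assert np.allclose(m.predict(z).mean, base)

    def test_per_member_matches_solo_forward(self):
        m = build_ensemble(EnsembleConfig(seed=2), 4, 2)
        z = np.random.default_rng(1).standard_normal(4)
        pred = m.predict(z)
        for j in range(5):
            assert np.array_equal(pred.per_member[j], m.member_forward(j, z[None])[0])

    def test_dimension_mismatch_is_an_error(self):
        m = build_ensemble(EnsembleConfig(), 4, 2)
        with pytest.raises(ValueError):
            m.predict(np.zeros(5))


class TestUncertainty:
    def test_identical_members_give_exactly_zero(self):
        m = build_ensemble(EnsembleConfig(seed=3), 4, 2)
        for j in range(1, 5):
            m.members[j].theta = m.members[0].theta.copy()
            m.activations[j] = m.activations[0]
        u, total = m.epistemic_uncertainty(np.random.default_rng(0).standard_normal(4))
        assert (u == 0.0).all() and total == 0.0

    def test_one_pass_formula_matches_two_pass_variance(self):
        """U must equal the population variance of member predictions to
        1e-10 over many random ensembles and inputs, and never be negative."""
        rng = np.random.default_rng(5)
        for trial in range(10):
            m = build_ensemble(EnsembleConfig(seed=trial), 6, 3)
            Z = rng.standard_normal((30, 6))
            pred = m.predict(Z)
            two_pass = np.var(pred.per_member, axis=0, ddof=0)
            assert np.abs(pred.uncertainty - two_pass).max() < 1e-10
            assert (pred.uncertainty >= 0).all()

    def test_uncertainty_locates_data_sparsity(self):
        """Trained on two latent clusters, U is lower at the cluster centers
        than far outside them (the premise of trust-region optimization)."""
        ratios = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            centers = np.array([[-2.0] * 4, [2.0] * 4])
            Z = np.vstack([c + 0.5 * rng.standard_normal((200, 4)) for c in centers])
            P = np.tanh(Z[:, :2])
            ds = LatentPropertyDataset(Z, P, ("p0", "p1"), ("a.u.",) * 2)
            m = build_ensemble(EnsembleConfig(seed=seed, epochs=80), 4, 2)
            m.train(ds)
            probes_far = 0.5 * rng.standard_normal((50, 4)) + \
                rng.choice([-1, 1], (50, 1)) * 7.0  # ≥ 5 cluster-σ beyond
            probes_near = np.vstack([centers + 0.05 * rng.standard_normal((2, 4))
                                     for _ in range(25)])
            u_near = m.predict(probes_near).uncertainty_total.mean()
            u_far = m.predict(probes_far).uncertainty_total.mean()
            ratios.append(u_far / max(u_near, 1e-12))
        assert np.mean(ratios) > 1.0

    def test_more_members_stabilize_the_mean(self):
        """Across training seeds, the variance of Φ_avg at a fixed probe
        shrinks when the ensemble grows from 2 to 10 members."""
        ds = _toy_dataset(n=150, seed=0)
        probe = np.full(4, 0.5)

        def mean_var(n_members):
            vals = []
            for seed in range(6):
                m = build_ensemble(EnsembleConfig(n_members=n_members, seed=seed,
                                                  epochs=40), 4, 2)
                m.train(ds)
                vals.append(m.predict(probe).mean)
            return np.var(vals, axis=0).mean()

        assert mean_var(10) < mean_var(2)


class TestGatedTraining:
    def test_q_one_updates_every_iteration(self):
        ds = _toy_dataset(n=64)
        m = build_ensemble(EnsembleConfig(update_probability=1.0, epochs=5), 4, 2)
        m.train(ds)
        assert np.allclose(m.realized_update_fractions(), 1.0)

    def test_realized_update_fraction_near_q(self, harness_runs):
        """Each member's realized update fraction over the full schedule sits
        inside a 99.9% binomial band around q = 0.3."""
        h, m = harness_runs[0]
        n_batches = -(-len(h.dataset) // m.config.batch_size)
        draws_per_member = len(m.history) * n_batches
        band = 3.3 * np.sqrt(0.3 * 0.7 / draws_per_member)
        assert np.abs(m.realized_update_fractions() - 0.3).max() < band

    def test_expected_update_epochs_simulation(self):
        counts = ens.simulate_gated_update_epochs(300, 0.3, 2000, seed=0)
        assert abs(counts.mean() - 90.0) < 3 * np.sqrt(300 * 0.3 * 0.7 / 2000)


class TestPersistence:
    def test_checkpoint_round_trip(self, tmp_path):
        ds = _toy_dataset()
        m = build_ensemble(EnsembleConfig(seed=4, epochs=10), 4, 2)
        m.train(ds)
        m.save(tmp_path / "ens")
        loaded = EnsembleSurrogate.load(tmp_path / "ens")
        z = np.random.default_rng(2).standard_normal(4)
        assert np.array_equal(loaded.predict(z).mean, m.predict(z).mean)
        assert np.array_equal(loaded.prop_std, m.prop_std)
        assert loaded.config == m.config
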