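"""Latent design: gradient optimization, k-try budget, grids, penalties."""

import numpy as np
import pytest

from uimd import design
from uimd.design import (DesignRequest, design_molecule, design_property_matrix,
                         mass_penalty, optimize_latent, optimize_latent_batch,
                         target_grid)
from uimd.ensemble import EnsembleConfig, build_ensemble
from uimd.oracle import AnalyticOracle


def _linear_ensemble(A, duplicate=2):
    """Ensemble whose members are the exact linear map z ↦ A·z (U ≡ 0)."""
    k, d = A.shape
    m = build_ensemble(EnsembleConfig(n_members=duplicate, hidden_layers=(),
                                      activations=("relu", "tanh")), d, k)
    from uimd import nn
    for j in range(duplicate):
        m.members[j] = nn.FlatModel([{"W": A.T.copy(), "b": np.zeros(k)}])
    return m


class TestTargetGrid:
    def test_evenly_spaced_inclusive(self):
        assert target_grid(0, 4, 5).tolist() == [0, 1, 2, 3, 4]

    @pytest.mark.parametrize("low,high,n", [(0, 4, 1), (4, 0, 5), (2, 2, 3)])
    def test_invalid_ranges_rejected(self, low, high, n):
        with pytest.raises(ValueError):
            target_grid(low, high, n)

    def test_reference_protocol_ranges(self):
        lo, hi = design.SINGLE_OBJECTIVE_RANGES["homo"]
        grid = target_grid(lo, hi, 2000)
        assert grid[0] == -10.0 and grid[-1] == 0.0 and len(grid) == 2000
        assert design.MULTI_OBJECTIVE_RANGES["homo"] == (-8.0, -3.0)
        assert design.MULTI_OBJECTIVE_RANGES["lumo"] == (-3.0, 2.0)


class TestOptimizeLatent:
    def test_zero_steps_returns_the_initialization(self):
        A = np.random.default_rng(0).standard_normal((2, 4))
        m = _linear_ensemble(A)
        req = DesignRequest({"p1": 0.5, "p2": -0.2}, k=1, steps=0, seed=7)
        res = optimize_latent(req, m)
        z0 = np.random.default_rng(7).standard_normal((1, 4))[0]
        assert np.array_equal(res.latent, z0)
        assert len(res.objective_trace) == 1

    def test_best_iterate_objective_monotone_in_steps(self, harness_runs):
        h, m = harness_runs[0]
        targets = m.standardize(h.in_range_targets[:1])
        rng = np.random.default_rng(0)
        Z0 = rng.standard_normal((1, m.latent_dim))
        objs = []
        for steps in (10, 50, 200):
            _, best, _ = optimize_latent_batch(Z0, targets, m, steps=steps,
                                               learning_rate=0.05)
            objs.append(best[0])
        assert objs[0] >= objs[1] >= objs[2]

    def test_matches_least_squares_on_linear_surrogate(self):
        """λ=0 descent on an exact linear surrogate reaches the achievable
        target as precisely as the normal-equations solution."""
        rng = np.random.default_rng(1)
        A = rng.standard_normal((2, 6))
        m = _linear_ensemble(A)
        p = A @ rng.standard_normal(6)  # achievable target
        Z0 = rng.standard_normal((1, 6))
        Zb, best, _ = optimize_latent_batch(Z0, p[None, :], m, steps=800,
                                            learning_rate=0.1,
                                            uncertainty_weight=0.0)
        z_ls, *_ = np.linalg.lstsq(A, p, rcond=None)
        assert np.abs(A @ Zb[0] - p).sum() < 1e-3
        assert np.abs(A @ z_ls - p).sum() < 1e-9  # oracle solution is exact


class TestDesignMolecule:
    def test_k1_reduces_to_a_single_try(self):
        A = np.random.default_rng(0).standard_normal((2, 4))
        m = _linear_ensemble(A)
        req = DesignRequest({"p1": 0.3, "p2": 0.1}, k=1, steps=50, seed=3)
        single = optimize_latent(req, m)
        budgeted = design_molecule(req, m)
        assert np.array_equal(single.latent, budgeted.latent)

    def test_retained_error_is_the_candidate_minimum(self, harness_runs):
        h, m = harness_runs[0]
        t = {f"p{i + 1}": float(v) for i, v in enumerate(h.in_range_targets[0])}
        req = DesignRequest(t, k=5, steps=100, seed=1)
        res = design_molecule(req, m)
        scores = [c["surrogate_error_total"] for c in res.candidates]
        assert res.surrogate_error_total == min(scores)

    def test_oracle_selection_beats_every_single_try(self, harness_runs):
        """With the forward process available, the retained try's oracle
        error is the minimum over the budget."""
        h, m = harness_runs[0]
        out = design_property_matrix(m, h.in_range_targets[:5], k=8, steps=150,
                                     learning_rate=0.05, seed=2,
                                     oracle=h.oracle, select_by="oracle")
        P_all = h.oracle.predict(out.all_latents.reshape(-1, m.latent_dim))
        err_all = np.abs(m.standardize(P_all) -
                         np.repeat(m.standardize(h.in_range_targets[:5]), 8, axis=0)
                         ).sum(1).reshape(5, 8)
        assert np.allclose(out.oracle_error_std, err_all.min(axis=1))

    def test_unknown_target_property_rejected(self, harness_runs):
        _, m = harness_runs[0]
        with pytest.raises(ValueError):
            design_molecule(DesignRequest({"bogus": 1.0}, k=1, steps=1), m,
                            property_names=["p1", "p2", "p3"])


class TestUncertaintyTerm:
    def test_large_weight_keeps_designs_near_training_latents(self, harness_runs):
        """With λ large, optimized latents stay closer to the training set
        than with λ=0 when chasing out-of-range targets (3 seeds)."""
        gaps = {0.0: [], 10.0: []}
        for h, m in harness_runs[:3]:
            T = m.standardize(h.out_of_range_targets[:10])
            Z0 = np.random.default_rng(0).standard_normal((10, m.latent_dim))
            for lam in gaps:
                Zb, _, _ = optimize_latent_batch(Z0.copy(), T, m, steps=200,
                                                 learning_rate=0.05,
                                                 uncertainty_weight=lam)
                d2 = ((Zb[:, None, :] - h.dataset.latents[None, :500, :]) ** 2
                      ).sum(-1)
                gaps[lam].append(np.sqrt(d2.min(axis=1)).mean())
        assert np.mean(gaps[10.0]) < np.mean(gaps[0.0])


class TestMassPenalty:
    def test_monotone_in_molecular_mass(self):
        pen = mass_penalty(decoder=None)
        methane = pen(None, "[C]")
        decane = pen(None, "[C]" * 10)
        assert methane < decane

    def test_zero_weight_leaves_the_design_unchanged(self, molecular_surrogate):
        m = molecular_surrogate["ensemble"]
        dec = molecular_surrogate["vae"].greedy_selfies
        pen = mass_penalty(dec)
        t = {"mol_weight": 80.0}
        names = list(molecular_surrogate["dataset"].property_names)
        base = design_molecule(DesignRequest(t, k=3, steps=60, seed=4), m, dec,
                               property_names=names)
        with_zero = design_molecule(
            DesignRequest(t, k=3, steps=60, seed=4,
                          extra_penalties=(("mass", pen, 0.0),)), m, dec,
            property_names=names)
        assert np.array_equal(base.latent, with_zero.latent)

    def test_heavy_weight_prefers_lighter_molecules(self, molecular_surrogate):
        from rdkit.Chem import Descriptors

        from uimd import grammar
        m = molecular_surrogate["ensemble"]
        dec = molecular_surrogate["vae"].greedy_selfies
        pen = mass_penalty(dec)
        names = list(molecular_surrogate["dataset"].property_names)
        masses = {0.0: [], 5.0: []}
        for seed in range(3):
            for w in masses:
                res = design_molecule(
                    DesignRequest({"mol_weight": 90.0}, k=6, steps=60, seed=seed,
                                  extra_penalties=(("mass", pen, w),)),
                    m, dec, property_names=names)
                mol = grammar.decode(res.selfies)
                masses[w].append(Descriptors.MolWt(mol))
        assert np.mean(masses[5.0]) <= np.mean(masses[0.0])
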