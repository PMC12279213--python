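"""Deep-ensemble surrogate: latent → properties with epistemic uncertainty.

The surrogate is an ensemble of n MLPs with identical layer layout but a
different activation function per member.  Diversity is further encouraged by
stochastic gated training: at each mini-batch iteration every member
independently takes a gradient step with probability q (default 0.3), so over
300 epochs each member sees the equivalent of ~90 independent epochs.

Prediction is the arithmetic member mean Φ_avg(z); epistemic uncertainty is
the population variance of member predictions,

    U(z) = (1/n) Σ_j Φ_j(z)² − Φ_avg(z)²,

computed per property in standardized property space and aggregated by
summation.  High U marks regions of latent space the training pairs do not
cover — exactly where the surrogate should not be trusted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from . import nn
from .reacquisition import LatentPropertyDataset

DEFAULT_ACTIVATIONS = ("relu", "tanh", "gelu", "silu", "elu")


@dataclass(frozen=True)
class EnsembleConfig:
    n_members: int = 5
    hidden_layers: tuple[int, ...] = (64, 64)
    activations: tuple[str, ...] = DEFAULT_ACTIVATIONS
    update_probability: float = 0.3
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_members < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if not 0.0 < self.update_probability <= 1.0:
            raise ValueError("update probability must be in (0, 1]")
        if any(w <= 0 for w in self.hidden_layers):
            raise ValueError("hidden widths must be positive")
        for a in self.activations:
            if a not in nn.ACTIVATIONS:
                raise ValueError(f"unknown activation {a!r}")


@dataclass(frozen=True)
class SurrogatePrediction:
    mean: np.ndarray              # Φ_avg(z), (k,) or (B, k)
    per_member: np.ndarray        # (n_members, k) or (n_members, B, k)
    uncertainty: np.ndarray       # per-property U, same trailing shape as mean
    uncertainty_total: np.ndarray  # scalar or (B,)


class EnsembleSurrogate:
    """Container for member parameter pytrees plus the dataset's scaling."""

    def __init__(self, config: EnsembleConfig, latent_dim: int, property_dim: int):
        self.config = config
        self.latent_dim = int(latent_dim)
        self.property_dim = int(property_dim)
        sizes = [latent_dim, *config.hidden_layers, property_dim]
        self.members = []
        for j in range(config.n_members):
            rng = np.random.default_rng(np.random.SeedSequence([config.seed, j]))
            self.members.append(nn.FlatModel(nn.init_mlp(sizes, rng)))
        self.activations = [config.activations[j % len(config.activations)]
                            for j in range(config.n_members)]
        self.prop_mean = np.zeros(property_dim)
        self.prop_std = np.ones(property_dim)
        self.history: list[dict] = []

    # ---------------- prediction ----------------

    def member_forward(self, j: int, Z, theta=None):
        params = self.members[j].unflatten(theta if theta is not None else self.members[j].theta)
        return nn.mlp_forward(params, Z, activation=self.activations[j])

    def _check_dim(self, Z):
        if Z.shape[-1] != self.latent_dim:
            raise ValueError(f"latent dimension {Z.shape[-1]} != {self.latent_dim}")

    def predict(self, z: np.ndarray) -> SurrogatePrediction:
        """Mean, per-member and uncertainty for one latent or a batch.

        Outputs are in *standardized* property space; use
        :meth:`unstandardize` for natural units.
        """
        z = np.asarray(z, dtype=float)
        single = z.ndim == 1
        Z = np.atleast_2d(z)
        self._check_dim(Z)
        per = np.stack([self.member_forward(j, Z) for j in range(self.config.n_members)])
        mean = per.mean(axis=0)
        u = np.mean(per ** 2, axis=0) - mean ** 2
        assert (u > -1e-8).all(), "pre-clip uncertainty below floating-point floor"
        u = np.maximum(u, 0.0)
        total = u.sum(axis=-1)
        if single:
            return SurrogatePrediction(mean[0], per[:, 0, :], u[0], total[0])
        return SurrogatePrediction(mean, per, u, total)

    def epistemic_uncertainty(self, z: np.ndarray):
        """Per-property U(z) and its sum over properties."""
        pred = self.predict(z)
        return pred.uncertainty, pred.uncertainty_total

    def objective_terms(self, Z, targets_std, prop_indices=None):
        """Differentiable |Φ_avg − p| and U terms (autograd path for design)."""
        per = [self.member_forward(j, Z) for j in range(self.config.n_members)]
        stacked = anp.stack(per)
        mean = anp.mean(stacked, axis=0)
        u = anp.mean(stacked ** 2, axis=0) - mean ** 2
        if prop_indices is not None:
            mean = mean[:, prop_indices]
            u = u[:, prop_indices]
        err = anp.sum(anp.abs(mean - targets_std), axis=-1)
        return err, anp.sum(u, axis=-1)

    def standardize(self, P):
        return (np.asarray(P, dtype=float) - self.prop_mean) / self.prop_std

    def unstandardize(self, P):
        return np.asarray(P, dtype=float) * self.prop_std + self.prop_mean

    # ---------------- training ----------------

    def _member_loss(self, theta, j, Z, P_std):
        pred = self.member_forward(j, Z, theta=theta)
        return anp.mean(anp.sum(anp.abs(pred - P_std), axis=1))

    def train(self, dataset: LatentPropertyDataset, epochs: int | None = None,
              seed: int | None = None) -> list[dict]:
        """Stochastic gated training on L1 loss in standardized space.

        At each iteration each member independently performs an AdamW step
        with probability q.  The history records, per epoch, each member's
        realized update count and current loss.
        """
        cfg = self.config
        epochs = cfg.epochs if epochs is None else epochs
        seed = cfg.seed if seed is None else seed
        self.prop_mean, self.prop_std = dataset.prop_mean, dataset.prop_std
        Z = dataset.latents
        P_std = dataset.standardized_properties()
        n = len(dataset)
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        gate_rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
        n_batches = max(1, (n + cfg.batch_size - 1) // cfg.batch_size)
        total_steps = epochs * n_batches
        opts = [nn.AdamW(m.theta.size, lr=cfg.learning_rate,
                         weight_decay=cfg.weight_decay) for m in self.members]
        loss_grad = value_and_grad(self._member_loss)
        self.history = []
        step = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            updates = np.zeros(cfg.n_members, dtype=int)
            for bi in range(n_batches):
                idx = order[bi * cfg.batch_size:(bi + 1) * cfg.batch_size]
                if idx.size == 0:
                    continue
                lr_t = nn.cosine_lr(cfg.learning_rate, step, total_steps)
                gates = gate_rng.random(cfg.n_members) < cfg.update_probability
                for j in range(cfg.n_members):
                    if not gates[j]:
                        continue
                    val, g = loss_grad(self.members[j].theta, j, Z[idx], P_std[idx])
                    if not np.isfinite(val):
                        raise RuntimeError(f"non-finite loss in ensemble member {j}")
                    self.members[j].theta = opts[j].step(self.members[j].theta, g, lr=lr_t)
                    updates[j] += 1
                step += 1
            self.history.append({
                "epoch": epoch,
                "updates": updates.tolist(),
                "update_fraction": (updates / n_batches).tolist(),
            })
        return self.history

    def realized_update_fractions(self) -> np.ndarray:
        """Per-member fraction of iterations in which a step was taken."""
        if not self.history:
            raise RuntimeError("ensemble has not been trained")
        ups = np.array([h["update_fraction"] for h in self.history])
        return ups.mean(axis=0)

    # ---------------- persistence ----------------

    def save(self, path, extra: dict | None = None) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        arrays = {f"member_{j}": m.theta for j, m in enumerate(self.members)}
        np.savez(path / "members.npz", prop_mean=self.prop_mean,
                 prop_std=self.prop_std, **arrays)
        meta = {
            "config": {
                "n_members": self.config.n_members,
                "hidden_layers": list(self.config.hidden_layers),
                "activations": list(self.config.activations),
                "update_probability": self.config.update_probability,
                "epochs": self.config.epochs, "batch_size": self.config.batch_size,
                "learning_rate": self.config.learning_rate,
                "weight_decay": self.config.weight_decay, "seed": self.config.seed,
            },
            "latent_dim": self.latent_dim, "property_dim": self.property_dim,
        } | (extra or {})
        (path / "ensemble.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "EnsembleSurrogate":
        path = Path(path)
        meta = json.loads((path / "ensemble.json").read_text())
        c = meta["config"]
        config = EnsembleConfig(c["n_members"], tuple(c["hidden_layers"]),
                                tuple(c["activations"]), c["update_probability"],
                                c["epochs"], c["batch_size"], c["learning_rate"],
                                c["weight_decay"], c["seed"])
        model = cls(config, meta["latent_dim"], meta["property_dim"])
        data = np.load(path / "members.npz")
        for j in range(config.n_members):
            model.members[j].theta = data[f"member_{j}"]
        model.prop_mean = data["prop_mean"]
        model.prop_std = data["prop_std"]
        return model


def simulate_gated_update_epochs(epochs: int = 300, q: float = 0.3,
                                 n_replicates: int = 10000, seed: int = 0) -> np.ndarray:
    """Monte-Carlo simulation of the gated training schedule.

    Each replicate draws Bernoulli(q) per epoch, exactly as the trainer gates
    member updates; returns the realized update-epoch count per replicate.
    For q = 0.3 over 300 epochs the expectation is 90 update-epochs — the
    equivalent of independently training each member for 90 epochs.
    """
    rng = np.random.default_rng(seed)
    return (rng.random((n_replicates, epochs)) < q).sum(axis=1)


def build_ensemble(config: EnsembleConfig, latent_dim: int,
                   property_dim: int) -> EnsembleSurrogate:
    return EnsembleSurrogate(config, latent_dim, property_dim)


def train_ensemble(model: EnsembleSurrogate, dataset: LatentPropertyDataset,
                   **kwargs) -> list[dict]:
    return model.train(dataset, **kwargs)
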