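"""The string-graph-property VAE (SGP-VAE).

One latent vector per molecule is trained to carry three views at once: the
decoder reconstructs the token sequence (cross-entropy) and the padded 3D
heavy-atom graph (masked squared error, non-equivariant: coordinates are
regressed directly in the input frame), and a property head predicts the
molecule's properties from the sampled latent (L1 on standardized values).
Together with the KL term against the standard-normal prior the loss is the
unweighted sum

    L = |p - p̂| + ||x_graph - x̂_graph||² + CE(x_str, x̂_str) + KL(z ‖ N(0,1)).

The property and graph terms organize the latent space so that nearby latents
tend to decode to molecules with similar properties — the precondition for a
smooth latent-to-property surrogate.  Because the token grammar is robust,
greedy decoding of *any* latent yields a valid molecule.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad

from . import nn
from .oracle import PropertyVector
from .representation import ELEMENTS, MoleculeGraph, MoleculeRecord, SelfiesVocabulary

DEFAULT_LOSS_WEIGHTS = {"prop_l1": 1.0, "graph_l2": 1.0, "selfies_ce": 1.0, "kl": 1.0}


class VaeDivergenceError(RuntimeError):
    def __init__(self, component: str):
        super().__init__(f"non-finite VAE loss component: {component}")
        self.component = component


@dataclass(frozen=True)
class LatentDistribution:
    mean: np.ndarray
    log_variance: np.ndarray

    def __post_init__(self):
        assert np.isfinite(self.mean).all() and np.isfinite(self.log_variance).all()


@dataclass(frozen=True)
class VaeOutput:
    selfies_logits: np.ndarray      # (L, V) or (B, L, V)
    graph_types: np.ndarray         # (A, E) scores
    graph_coords: np.ndarray        # (A, 3)
    property_pred: np.ndarray       # standardized property vector
    posterior: LatentDistribution | None = None


def sample_latent(dist: LatentDistribution, seed: int) -> np.ndarray:
    """Reparameterized draw z = μ + exp(½ logσ²)·ε with seeded ε ~ N(0,1)."""
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(dist.mean.shape)
    return dist.mean + np.exp(0.5 * dist.log_variance) * eps


def kl_gaussian(mu, logvar):
    """Closed-form KL(N(μ, diag σ²) ‖ N(0, I)), summed over dimensions.

    ½ Σ (μ² + σ² − 1 − log σ²); batched input averages over the batch axis.
    """
    terms = 0.5 * (mu ** 2 + anp.exp(logvar) - 1.0 - logvar)
    if terms.ndim == 1:
        return anp.sum(terms)
    return anp.mean(anp.sum(terms, axis=1))


def loss_terms(logits, type_scores, coord_pred, prop_pred, mu, logvar,
               tok_onehot, type_onehot, coords, atom_mask, graph_present,
               prop_targets, weights=None):
    """The four loss components, each averaged over the batch.

    All arrays are batched; works both under autograd tracing and on plain
    numpy inputs.  Graph terms are masked to real atoms and zeroed for
    molecules whose embedding failed (``graph_present`` flag).
    """
    w = dict(DEFAULT_LOSS_WEIGHTS, **(weights or {}))
    B = logits.shape[0]
    prop_l1 = anp.mean(anp.sum(anp.abs(prop_pred - prop_targets), axis=1))
    logp = nn.log_softmax(logits, axis=2)
    ce = -anp.mean(anp.sum(tok_onehot * logp, axis=(1, 2)))
    m = atom_mask[:, :, None]
    g = graph_present[:, None, None]
    sq = anp.sum(((type_scores - type_onehot) ** 2) * m * g, axis=(1, 2)) \
        + anp.sum(((coord_pred - coords) ** 2) * m * g, axis=(1, 2))
    graph_l2 = anp.mean(sq)
    kl = kl_gaussian(mu, logvar)
    comps = {"prop_l1": prop_l1, "graph_l2": graph_l2, "selfies_ce": ce, "kl": kl}
    comps["total"] = sum(w[k] * comps[k] for k in DEFAULT_LOSS_WEIGHTS)
    return comps


class SgpVae:
    """Multi-view VAE over token sequences, 3D graphs and properties.

    Parameters
    ----------
    vocab : token table (defines sequence length and logits width)
    max_atoms : padded heavy-atom count of the graph view
    property_names/units : labels carried through the whole pipeline
    latent_dim : latent dimensionality d (default 64)
    hidden : width of the encoder/decoder hidden layer
    """

    def __init__(self, vocab: SelfiesVocabulary, max_atoms: int,
                 property_names, property_units, elements=ELEMENTS,
                 latent_dim: int = 64, hidden: int = 256, seed: int = 0):
        self.vocab = vocab
        self.max_atoms = int(max_atoms)
        self.elements = tuple(elements)
        self.property_names = tuple(property_names)
        self.property_units = tuple(property_units)
        self.latent_dim = int(latent_dim)
        self.hidden = int(hidden)
        self.seed = int(seed)
        self.prop_mean = np.zeros(len(self.property_names))
        self.prop_std = np.ones(len(self.property_names))

        L, V, A, E, k = (vocab.max_length, vocab.size, self.max_atoms,
                         len(self.elements), len(self.property_names))
        self._in_dim = L * V + A * (E + 3) + 1
        rng = np.random.default_rng(seed)
        params = {
            "enc": nn.init_mlp([self._in_dim, hidden], rng),
            "mu": nn.init_mlp([hidden, latent_dim], rng),
            "logvar": nn.init_mlp([hidden, latent_dim], rng),
            "dec": nn.init_mlp([latent_dim, hidden], rng),
            "head_selfies": nn.init_mlp([hidden, L * V], rng),
            "head_types": nn.init_mlp([hidden, A * E], rng),
            "head_coords": nn.init_mlp([hidden, A * 3], rng),
            "prop": nn.init_mlp([latent_dim, 64, k], rng),
        }
        self.model = nn.FlatModel(params)

    # ---------------- featurization ----------------

    def featurize(self, records: list[MoleculeRecord]) -> dict[str, np.ndarray]:
        L, V = self.vocab.max_length, self.vocab.size
        B = len(records)
        tokens = np.zeros((B, L), dtype=np.int64)
        type_onehot = np.zeros((B, self.max_atoms, len(self.elements)))
        coords = np.zeros((B, self.max_atoms, 3))
        mask = np.zeros((B, self.max_atoms))
        present = np.zeros(B)
        for i, rec in enumerate(records):
            t = rec.tokens if rec.tokens is not None else self.vocab.tokenize(rec.selfies)
            tokens[i] = t
            if rec.graph is not None and rec.graph.n_atoms <= self.max_atoms:
                oh, xyz, m = rec.graph.to_padded(self.max_atoms, self.elements)
                type_onehot[i], coords[i], mask[i] = oh, xyz, m
                present[i] = 1.0
        tok_onehot = np.eye(V)[tokens]  # (B, L, V)
        return {"tokens": tokens, "tok_onehot": tok_onehot, "type_onehot": type_onehot,
                "coords": coords, "mask": mask, "present": present}

    def _encoder_input(self, feats):
        B = feats["tok_onehot"].shape[0]
        m = feats["mask"][:, :, None] * feats["present"][:, None, None]
        return anp.concatenate([
            feats["tok_onehot"].reshape(B, -1),
            (feats["type_onehot"] * m).reshape(B, -1),
            (feats["coords"] * m).reshape(B, -1),
            feats["present"][:, None],
        ], axis=1)

    # ---------------- forward passes ----------------

    def _encode(self, params, feats):
        h = anp.tanh(nn.mlp_forward(params["enc"], self._encoder_input(feats)))
        mu = nn.mlp_forward(params["mu"], h)
        logvar = anp.clip(nn.mlp_forward(params["logvar"], h), -10.0, 10.0)
        return mu, logvar

    def encode(self, records_or_record) -> LatentDistribution:
        """Posterior for one record or a list; deterministic given parameters.

        Records without a graph are encoded from the token view alone (zeroed
        graph features plus an absence flag).
        """
        records = records_or_record if isinstance(records_or_record, list) else [records_or_record]
        mu, logvar = self._encode(self.model.params, self.featurize(records))
        if not isinstance(records_or_record, list):
            return LatentDistribution(mu[0], logvar[0])
        return LatentDistribution(mu, logvar)

    def _decode(self, params, Z):
        L, V, A, E = (self.vocab.max_length, self.vocab.size, self.max_atoms,
                      len(self.elements))
        h = anp.tanh(nn.mlp_forward(params["dec"], Z))
        logits = nn.mlp_forward(params["head_selfies"], h).reshape(-1, L, V)
        types = nn.mlp_forward(params["head_types"], h).reshape(-1, A, E)
        coords = nn.mlp_forward(params["head_coords"], h).reshape(-1, A, 3)
        props = nn.mlp_forward(params["prop"], Z, activation="silu")
        return logits, types, coords, props

    def decode(self, z: np.ndarray) -> VaeOutput:
        z = np.asarray(z, dtype=float)
        if z.shape[-1] != self.latent_dim:
            raise ValueError(f"latent dimension {z.shape[-1]} != {self.latent_dim}")
        single = z.ndim == 1
        logits, types, coords, props = self._decode(self.model.params, np.atleast_2d(z))
        if single:
            return VaeOutput(logits[0], types[0], coords[0], props[0])
        return VaeOutput(logits, types, coords, props)

    def greedy_selfies(self, z: np.ndarray) -> str:
        """Greedy per-position argmax decode, truncated at the first special
        token.  A latent whose every position decodes to a special token falls
        back to the single-carbon string, so decoding is total."""
        from . import grammar
        out = self.decode(np.asarray(z, dtype=float).reshape(-1))
        ids = np.argmax(out.selfies_logits, axis=1)
        s = self.vocab.detokenize(ids)
        if not s or grammar.decode(s) is None:
            return "[C]"
        return s

    def predict_properties(self, z: np.ndarray, natural_units: bool = True) -> PropertyVector:
        out = self.decode(np.asarray(z, dtype=float).reshape(-1))
        vals = out.property_pred * self.prop_std + self.prop_mean if natural_units \
            else out.property_pred
        return PropertyVector(self.property_names, vals, self.property_units)

    # ---------------- training ----------------

    def standardize(self, P: np.ndarray) -> np.ndarray:
        return (np.asarray(P, dtype=float) - self.prop_mean) / self.prop_std

    def unstandardize(self, P: np.ndarray) -> np.ndarray:
        return np.asarray(P, dtype=float) * self.prop_std + self.prop_mean

    def _loss(self, theta, feats, prop_std_targets, eps, weights):
        params = self.model.unflatten(theta)
        mu, logvar = self._encode(params, feats)
        Z = mu + anp.exp(0.5 * logvar) * eps
        logits, types, coords, props = self._decode(params, Z)
        comps = loss_terms(logits, types, coords, props, mu, logvar,
                           feats["tok_onehot"], feats["type_onehot"], feats["coords"],
                           feats["mask"], feats["present"], prop_std_targets, weights)
        return comps["total"]

    def loss_components(self, records, properties, seed: int = 0, weights=None) -> dict:
        """Loss components on a batch (reporting path, no gradients)."""
        feats = self.featurize(records)
        P = self.standardize(np.asarray(properties, dtype=float))
        rng = np.random.default_rng(seed)
        mu, logvar = self._encode(self.model.params, feats)
        Z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
        logits, types, coords, props = self._decode(self.model.params, Z)
        comps = loss_terms(logits, types, coords, props, mu, logvar,
                           feats["tok_onehot"], feats["type_onehot"], feats["coords"],
                           feats["mask"], feats["present"], P, weights)
        out = {k: float(v) for k, v in comps.items()}
        for k, v in out.items():
            if not np.isfinite(v):
                raise VaeDivergenceError(k)
        return out

    def train(self, records: list[MoleculeRecord], properties: np.ndarray,
              epochs: int = 50, batch_size: int = 32, lr: float = 1e-3,
              weight_decay: float = 1e-4, seed: int = 0, weights=None,
              standardize: bool = True) -> list[dict]:
        """Train with AdamW and a cosine-annealed learning rate.

        Returns the per-epoch history of the four loss components (epoch
        averages).  Raises :class:`VaeDivergenceError` on non-finite loss.
        """
        if not records:
            raise ValueError("empty training set")
        P = np.asarray(properties, dtype=float)
        if standardize:
            self.prop_mean, self.prop_std = nn.standardize_stats(P)
        P_std = self.standardize(P)
        feats_all = self.featurize(records)
        n = len(records)
        rng = np.random.default_rng(seed)
        opt = nn.AdamW(self.model.theta.size, lr=lr, weight_decay=weight_decay)
        n_batches = max(1, (n + batch_size - 1) // batch_size)
        total_steps = epochs * n_batches
        loss_grad = value_and_grad(self._loss)
        history = []
        step = 0
        for epoch in range(epochs):
            order = rng.permutation(n)
            sums = {k: 0.0 for k in ("prop_l1", "graph_l2", "selfies_ce", "kl", "total")}
            for bi in range(n_batches):
                idx = order[bi * batch_size:(bi + 1) * batch_size]
                if idx.size == 0:
                    continue
                feats = {k: v[idx] for k, v in feats_all.items()}
                eps = rng.standard_normal((idx.size, self.latent_dim))
                lr_t = nn.cosine_lr(lr, step, total_steps)
                val, g = loss_grad(self.model.theta, feats, P_std[idx], eps, weights)
                if not np.isfinite(val):
                    raise VaeDivergenceError("total")
                self.model.theta = opt.step(self.model.theta, g, lr=lr_t)
                step += 1
                comps = self.loss_components([records[i] for i in idx], P[idx],
                                             seed=seed + step, weights=weights)
                for k in sums:
                    sums[k] += comps[k]
            history.append({k: v / n_batches for k, v in sums.items()} | {"epoch": epoch})
        return history

    # ---------------- persistence ----------------

    def config_dict(self) -> dict:
        return {
            "tokens": list(self.vocab.tokens), "max_length": self.vocab.max_length,
            "max_atoms": self.max_atoms, "elements": list(self.elements),
            "property_names": list(self.property_names),
            "property_units": list(self.property_units),
            "latent_dim": self.latent_dim, "hidden": self.hidden, "seed": self.seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez(path / "params.npz", theta=self.model.theta,
                 prop_mean=self.prop_mean, prop_std=self.prop_std)
        meta = self.config_dict() | {"config_hash": self.config_hash()}
        (path / "config.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "SgpVae":
        path = Path(path)
        meta = json.loads((path / "config.json").read_text())
        vocab = SelfiesVocabulary(tuple(meta["tokens"]), meta["max_length"])
        model = cls(vocab, meta["max_atoms"], meta["property_names"],
                    meta["property_units"], tuple(meta["elements"]),
                    meta["latent_dim"], meta["hidden"], meta["seed"])
        data = np.load(path / "params.npz")
        model.model.theta = data["theta"]
        model.prop_mean = data["prop_mean"]
        model.prop_std = data["prop_std"]
        return model
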