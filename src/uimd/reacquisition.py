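"""Latent-property pair reacquisition for surrogate training.

The usual way to train a latent-to-property surrogate is to encode the
training molecules and pair each posterior mean with the molecule's known
property.  Those pairs are biased two ways: molecules the autoencoder cannot
reconstruct contribute latents whose decoded molecule (and hence property) is
wrong, and the latents only cover the encoded dataset, not the latent space
the design optimizer will roam.  Reacquisition fixes both by sampling latents
from the prior z ~ N(0,1), decoding each one, embedding the decoded molecule
and labelling it with the forward process:

    D_new = {(z_i, f(h(Ψ_dec(z_i))))},   z_i ~ N(0,1)

Pairs whose forward evaluation does not converge are dropped and counted.
The legacy encoded pairing is kept as the ablation baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .oracle import OracleResult, PropertyVector


@dataclass
class LatentPropertyDataset:
    """Aligned (latent, property) pairs plus provenance and scaling statistics.

    Properties are stored in natural units; ``prop_mean``/``prop_std`` are
    computed on the dataset itself so that the surrogate and the optimizer
    share one standardization.
    """

    latents: np.ndarray          # (N, d)
    properties: np.ndarray       # (N, k) natural units
    property_names: tuple[str, ...]
    property_units: tuple[str, ...]
    provenance: list[dict] = field(default_factory=list)
    n_unstable: int = 0
    source: str = "reacquired"

    def __post_init__(self):
        self.latents = np.asarray(self.latents, dtype=float)
        self.properties = np.asarray(self.properties, dtype=float)
        assert self.latents.shape[0] == self.properties.shape[0]
        self.prop_mean, self.prop_std = nn.standardize_stats(self.properties) \
            if len(self.properties) else (np.zeros(len(self.property_names)),
                                          np.ones(len(self.property_names)))

    def __len__(self) -> int:
        return self.latents.shape[0]

    @property
    def latent_dim(self) -> int:
        return self.latents.shape[1]

    def standardized_properties(self) -> np.ndarray:
        return (self.properties - self.prop_mean) / self.prop_std

    def save(self, path, manifest_extra: dict | None = None) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.save(path / "latents.npy", self.latents)
        df = pd.DataFrame(self.properties, columns=list(self.property_names))
        df.to_csv(path / "properties.csv", index=False)
        with open(path / "provenance.jsonl", "w") as fh:
            for rec in self.provenance:
                fh.write(json.dumps(rec) + "\n")
        manifest = {
            "n_pairs": len(self), "latent_dim": self.latent_dim,
            "property_names": list(self.property_names),
            "property_units": list(self.property_units),
            "n_unstable": self.n_unstable, "source": self.source,
        } | (manifest_extra or {})
        (path / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, path) -> "LatentPropertyDataset":
        path = Path(path)
        manifest = json.loads((path / "manifest.json").read_text())
        latents = np.load(path / "latents.npy")
        props = pd.read_csv(path / "properties.csv").to_numpy(dtype=float)
        provenance = []
        prov_path = path / "provenance.jsonl"
        if prov_path.exists():
            provenance = [json.loads(line) for line in prov_path.read_text().splitlines()]
        return cls(latents, props, tuple(manifest["property_names"]),
                   tuple(manifest["property_units"]), provenance,
                   manifest["n_unstable"], manifest["source"])


def sample_prior_latents(N: int, d: int, seed: int = 0) -> np.ndarray:
    """N i.i.d. standard-normal latent vectors of dimension d."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return np.random.default_rng(seed).standard_normal((N, d))


def reacquire(latents: np.ndarray, decoder=None, embedder=None, oracle=None,
              seed: int = 0) -> LatentPropertyDataset:
    """Label prior-sampled latents by decode → embed → forward process.

    ``decoder`` maps a latent to a grammar string (None = the latent *is* the
    molecule, for analytic closed loops), ``embedder`` maps a string to an
    embedding outcome (None = skip embedding; the oracle may embed itself),
    and ``oracle`` returns an :class:`OracleResult`.  Unstable outcomes are
    excluded and counted; every stored pair is recomputable by re-running the
    same composition on its latent.
    """
    if oracle is None:
        raise ValueError("an oracle is required")
    latents = np.atleast_2d(np.asarray(latents, dtype=float))
    kept_z, kept_p, provenance = [], [], []
    n_unstable = 0
    names = units = None
    for i, z in enumerate(latents):
        selfies = None
        if decoder is not None:
            selfies = decoder(z)
            target = selfies
            if embedder is not None:
                emb = embedder(selfies)
                if not emb.ok:
                    n_unstable += 1
                    provenance.append({"index": i, "selfies": selfies,
                                       "status": "unstable", "reason": emb.reason,
                                       "seed": seed})
                    continue
                from .representation import make_record
                target = make_record(selfies, graph=emb.graph)
        else:
            target = z
        res: OracleResult = oracle(target)
        if not res.ok:
            n_unstable += 1
            provenance.append({"index": i, "selfies": selfies, "status": "unstable",
                               "reason": res.reason, "seed": seed})
            continue
        names, units = res.properties.names, res.properties.units
        kept_z.append(z)
        kept_p.append(res.properties.values)
        provenance.append({"index": i, "selfies": selfies, "status": "ok", "seed": seed})
    if names is None:
        raise RuntimeError("every latent was unstable; nothing to train on")
    return LatentPropertyDataset(np.array(kept_z), np.array(kept_p), names, units,
                                 provenance, n_unstable, source="reacquired")


def legacy_encode_dataset(records, properties: np.ndarray, encoder,
                          property_names, property_units) -> LatentPropertyDataset:
    """Ablation baseline: pair each training molecule's encoded posterior mean
    with its ground-truth property (no relabelling through the decoder)."""
    dist = encoder.encode(list(records))
    P = np.asarray(properties, dtype=float)
    provenance = [{"index": i, "selfies": getattr(r, "selfies", None),
                   "status": "ok", "legacy": True}
                  for i, r in enumerate(records)]
    return LatentPropertyDataset(dist.mean, P, tuple(property_names),
                                 tuple(property_units), provenance, 0, source="legacy")


def make_molecular_pipeline(vae, oracle, embed_seed: int = 0):
    """(decoder, embedder) pair running greedy decode + seeded conformer
    embedding, for use with :func:`reacquire`."""
    from .representation import embed_conformer

    def decoder(z):
        return vae.greedy_selfies(z)

    def embedder(selfies):
        return embed_conformer(selfies, seed=embed_seed)

    return decoder, embedder
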