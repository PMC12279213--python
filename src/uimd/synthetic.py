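"""Deterministic desk-scale inputs: random valid molecule corpora, labelled
datasets and analytic closed-loop harnesses.

The corpus generator exploits the grammar's robustness guarantee — uniformly
random symbol sequences decode to valid molecules — to produce a seeded,
deduplicated set of small C/N/O/F molecules standing in for a quantum-
chemistry training corpus.  The closed-loop harness replaces the molecular
pipeline with a linear ground truth p = A·z + b whose training latents are
confined to a bounded region, so surrogate fit, uncertainty extrapolation
and design recovery can all be checked against linear-algebra oracles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from . import grammar, representation
from .oracle import AnalyticOracle
from .reacquisition import LatentPropertyDataset
from .representation import MoleculeRecord, SelfiesVocabulary, build_vocabulary, make_record

logger = logging.getLogger(__name__)

#: curated symbol set for fixture corpora: single/double/triple-bonded C and N,
#: single/double O, F, plus branch and ring symbols
DEFAULT_ALPHABET = (
    "[C]", "[=C]", "[#C]", "[N]", "[=N]", "[O]", "[=O]", "[F]",
    "[Branch1]", "[Ring1]", "[=Ring1]",
)


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 200
    max_tokens: int = 16
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    seed: int = 7
    oracle_name: str = "descriptors"
    embed: bool = True
    min_tokens: int = 3

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not self.alphabet:
            raise ValueError("alphabet must be non-empty")
        unknown = set(self.alphabet) - set(grammar.ALPHABET)
        if unknown:
            raise ValueError(f"invalid grammar symbols: {sorted(unknown)}")


def generate_selfies_corpus(spec: FixtureSpec,
                            vocab_max_length: int | None = None
                            ) -> tuple[list[MoleculeRecord], SelfiesVocabulary]:
    """Seeded random corpus, deduplicated by canonical structure.

    Sequence lengths are uniform on [min_tokens, max_tokens].  Strings that
    derive zero atoms are resampled; if the requested count of distinct
    structures is unreachable within the retry cap the corpus is returned
    short, with a warning.  When ``spec.embed`` is set each molecule also
    gets a seeded conformer (embedding failures leave the graph absent).
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(spec.alphabet)
    seen: dict[str, str] = {}
    attempts, cap = 0, 60 * spec.n_molecules
    while len(seen) < spec.n_molecules and attempts < cap:
        attempts += 1
        L = int(rng.integers(spec.min_tokens, spec.max_tokens + 1))
        s = "".join(rng.choice(alphabet, L))
        smiles = grammar.to_smiles(s)
        if smiles is None or smiles in seen:
            continue
        seen[smiles] = s
    if len(seen) < spec.n_molecules:
        logger.warning("corpus generation: only %d/%d distinct molecules after %d attempts",
                       len(seen), spec.n_molecules, attempts)
    strings = list(seen.values())
    vocab = build_vocabulary(strings, vocab_max_length or spec.max_tokens)
    records = []
    for i, s in enumerate(strings):
        graph = None
        if spec.embed:
            emb = representation.embed_conformer(s, seed=spec.seed + i)
            graph = emb.graph if emb.ok else None
        records.append(make_record(s, vocab, graph))
    return records, vocab


def build_labelled_dataset(records: list[MoleculeRecord], oracle):
    """Label a corpus with an oracle; unstable molecules are dropped.

    Returns (kept_records, properties array, names, units, n_unstable) with
    properties in natural units.
    """
    kept, values = [], []
    names = units = None
    n_unstable = 0
    for rec in records:
        res = oracle(rec)
        if not res.ok:
            n_unstable += 1
            continue
        names, units = res.properties.names, res.properties.units
        kept.append(rec)
        values.append(res.properties.values)
    if not kept:
        raise RuntimeError("every molecule in the corpus was unstable")
    return kept, np.array(values), names, units, n_unstable


@dataclass
class ClosedLoopHarness:
    """Analytic ground truth with a bounded training region.

    Training latents are truncated-normal inside the box |z_j| <= radius;
    the oracle p = A·z + b is defined everywhere.  In-range targets are
    property vectors of points inside the box; out-of-range targets push one
    or more properties beyond the box-achievable extreme
    max_{|z|<=r} a_j·z = r·||a_j||_1, so no in-region latent can reach them.
    """

    A: np.ndarray
    b: np.ndarray
    radius: float
    dataset: LatentPropertyDataset
    in_range_targets: np.ndarray    # (m, k)
    out_of_range_targets: np.ndarray
    oracle: AnalyticOracle = field(repr=False)

    def min_error_in_region(self, p: np.ndarray) -> float:
        """min_{|z|_inf <= radius} ||A z + b - p||_2 by bounded least squares."""
        res = lsq_linear(self.A, np.asarray(p, dtype=float) - self.b,
                         bounds=(-self.radius, self.radius))
        return float(np.linalg.norm(self.A @ res.x + self.b - p))


def closed_loop_harness(d: int = 16, n_pairs: int = 2000, k: int = 3,
                        radius: float = 1.0, n_targets: int = 20,
                        out_scale: tuple[float, float] = (1.05, 1.4),
                        seed: int = 0) -> ClosedLoopHarness:
    """Build the analytic closed-loop test bed.

    - A: (k, d) with rows scaled to unit L2 norm (seeded Gaussian), b = 0.
    - training latents: N(0,1) truncated per-coordinate to [-radius, radius].
    - in-range targets: images of fresh latents sampled well inside the box
      (0.9·radius), so each is achievable in-region to numerical precision.
    - out-of-range targets: per-property magnitudes scaled uniformly in
      ``out_scale`` times the achievable extreme r·||a_j||_1, with random
      signs — just beyond the boundary of the reachable property set.
    """
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((k, d))
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    b = np.zeros(k)
    oracle = AnalyticOracle(A, b)

    Z = rng.standard_normal((4 * n_pairs, d))
    Z = Z[(np.abs(Z) <= radius).all(axis=1)]
    while Z.shape[0] < n_pairs:  # top up per-coordinate truncated normals
        extra = rng.standard_normal((4 * n_pairs, d))
        Z = np.vstack([Z, extra[(np.abs(extra) <= radius).all(axis=1)]])
    Z = Z[:n_pairs]
    P = oracle.predict(Z)
    provenance = [{"index": i, "status": "ok", "analytic": True} for i in range(n_pairs)]
    dataset = LatentPropertyDataset(Z, P, oracle.names, oracle.units,
                                    provenance, 0, source="reacquired")

    Zt = rng.uniform(-0.9 * radius, 0.9 * radius, size=(n_targets, d))
    in_range = oracle.predict(Zt)

    extreme = radius * np.abs(A).sum(axis=1)  # max achievable |p_j| in the box
    scales = rng.uniform(out_scale[0], out_scale[1], size=(n_targets, k))
    signs = rng.choice([-1.0, 1.0], size=(n_targets, k))
    out_range = signs * scales * extreme

    return ClosedLoopHarness(A, b, radius, dataset, in_range, out_range, oracle)


@dataclass
class LossyAutoencoderHarness:
    """Closed-loop ablation bed for reacquired vs legacy surrogate pairs.

    The "molecule" is a d-vector; the decoder is the identity but the encoder
    is deliberately lossy, e(m) = R·m + c with R a distorted linear map, so
    encoded dataset latents live in coordinates inconsistent with what the
    decoder (and hence the forward process f(dec(z)) = A·z + b) assumes.
    Legacy pairs (e(m_i), f(m_i)) teach the surrogate a systematically wrong
    latent-to-property map; reacquired pairs (z_i, f(z_i)) are consistent.
    """

    oracle: AnalyticOracle
    legacy_dataset: LatentPropertyDataset
    reacquired_dataset: LatentPropertyDataset
    targets: np.ndarray  # (m, k) achievable property vectors

    def oracle_design_error(self, Z: np.ndarray, targets: np.ndarray) -> np.ndarray:
        P = self.oracle.predict(Z)
        return np.abs(P - targets).sum(axis=1)


def lossy_autoencoder_harness(d: int = 16, n_pairs: int = 1000, k: int = 3,
                              distortion: float = 0.5, n_targets: int = 20,
                              seed: int = 0) -> LossyAutoencoderHarness:
    """Build the reacquisition-ablation harness.

    ``distortion`` scales the off-identity part of the encoder map
    R = I + distortion·G (G standard Gaussian) and its offset c; at 0 the
    autoencoder is perfect and legacy == reacquired up to sampling.
    """
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((k, d))
    A /= np.linalg.norm(A, axis=1, keepdims=True)
    oracle = AnalyticOracle(A)

    M = rng.standard_normal((n_pairs, d))          # dataset "molecules"
    R = np.eye(d) + distortion * rng.standard_normal((d, d)) / np.sqrt(d)
    c = distortion * rng.standard_normal(d)
    legacy_latents = M @ R.T + c
    P_gt = oracle.predict(M)
    legacy = LatentPropertyDataset(legacy_latents, P_gt, oracle.names, oracle.units,
                                   [{"index": i, "status": "ok", "legacy": True}
                                    for i in range(n_pairs)], 0, source="legacy")

    Z = rng.standard_normal((n_pairs, d))          # prior samples, relabelled
    reacq = LatentPropertyDataset(Z, oracle.predict(Z), oracle.names, oracle.units,
                                  [{"index": i, "status": "ok"} for i in range(n_pairs)],
                                  0, source="reacquired")

    targets = oracle.predict(rng.standard_normal((n_targets, d)) * 0.8)
    return LossyAutoencoderHarness(oracle, legacy, reacq, targets)


def write_fixture_files(records: list[MoleculeRecord], properties: np.ndarray,
                        names, outdir, spec: FixtureSpec) -> None:
    """Persist a corpus as .selfies + labels CSV + manifest (plain text)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "corpus.selfies").write_text(
        "\n".join(r.selfies for r in records) + "\n")
    df = pd.DataFrame({"molecule": [r.selfies for r in records]})
    for j, name in enumerate(names):
        df[name] = properties[:, j]
    df.to_csv(outdir / "labels.csv", index=False)
    manifest = {"n_molecules": len(records), "max_tokens": spec.max_tokens,
                "alphabet": list(spec.alphabet), "seed": spec.seed,
                "oracle_name": spec.oracle_name}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
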