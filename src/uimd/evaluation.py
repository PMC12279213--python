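"""Evaluation metrics and studies for generated designs.

Covers the forward-process (NFP) error of designs against their targets,
novelty/uniqueness of the generated set, the NFP-surrogate *misalignment*
(the absolute gap between the error the surrogate claims and the error the
forward process measures — the trustworthiness metric), and the
representation-perturbation study that contrasts how robustly each molecular
view (3D coordinates, atom types, grammar string, latent) absorbs minimal
noise.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import representation
from .design import DesignResult
from .oracle import OracleResult
from .representation import MoleculeRecord, PerturbResult, perturb


@dataclass(frozen=True)
class EvaluationReport:
    nfp_mae: dict[str, float]
    novelty_pct: float
    uniqueness_pct: float
    misalignment: dict[str, float]
    n_designs: int
    n_unstable: int

    def __post_init__(self):
        assert 0.0 <= self.novelty_pct <= 100.0 and 0.0 <= self.uniqueness_pct <= 100.0
        assert all(v >= 0 for v in self.misalignment.values())

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def _oracle_errors(results: list[DesignResult], oracle, targets_of) -> tuple[dict, int]:
    """Per-property absolute oracle errors for stable designs + unstable count."""
    per_prop: dict[str, list[float]] = {}
    n_unstable = 0
    for res in results:
        target = res.selfies if res.selfies is not None else res.latent
        ores: OracleResult = oracle(target)
        if not ores.ok:
            n_unstable += 1
            continue
        for name, tval in targets_of(res).items():
            oval = ores.properties.values[list(ores.properties.names).index(name)]
            per_prop.setdefault(name, []).append(abs(oval - tval))
    return per_prop, n_unstable


def nfp_error(results: list[DesignResult], oracle, targets_of=None) -> dict[str, float]:
    """Per-property MAE between forward-process values and targets, natural
    units; unstable designs are excluded (raise if none survive).

    ``targets_of`` maps a result to its target dict; defaults to a ``targets``
    attribute stored on each result by the caller.
    """
    targets_of = targets_of or (lambda res: getattr(res, "targets"))
    per_prop, n_unstable = _oracle_errors(results, oracle, targets_of)
    if not per_prop:
        raise RuntimeError("no stable designs to evaluate")
    return {k: float(np.mean(v)) for k, v in per_prop.items()}


def novelty(results: list[DesignResult], reference_ids: set[str]) -> float:
    """Percentage of designs whose canonical id is absent from the reference set."""
    ids = [representation.canonical_id(r.selfies) for r in results]
    if not ids:
        return 0.0
    return 100.0 * sum(i not in reference_ids for i in ids) / len(ids)


def uniqueness(results: list[DesignResult]) -> float:
    """Percentage of distinct canonical ids among the designs."""
    ids = [representation.canonical_id(r.selfies) for r in results]
    if not ids:
        return 0.0
    return 100.0 * len(set(ids)) / len(ids)


def misalignment(nfp_mae: dict[str, float], surrogate_mae: dict[str, float]) -> dict[str, float]:
    """|MAE_nfp − MAE_surrogate| per property (natural units)."""
    return {k: abs(nfp_mae[k] - surrogate_mae[k]) for k in nfp_mae if k in surrogate_mae}


def surrogate_mae(results: list[DesignResult]) -> dict[str, float]:
    per_prop: dict[str, list[float]] = {}
    for res in results:
        for k, v in res.surrogate_error.items():
            per_prop.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in per_prop.items()}


def results_to_frame(results: list[DesignResult], targets_of=None) -> pd.DataFrame:
    """Persistable per-design table; every report metric is recomputable from it."""
    rows = []
    for res in results:
        row = {"selfies": res.selfies,
               "canonical_id": representation.canonical_id(res.selfies)
               if res.selfies else None,
               "uncertainty": res.uncertainty}
        if targets_of is not None:
            for k, v in targets_of(res).items():
                row[f"target_{k}"] = v
        for k, v in res.surrogate_error.items():
            row[f"surrogate_error_{k}"] = v
        if res.oracle_error:
            for k, v in res.oracle_error.items():
                row[f"oracle_error_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


PERTURBATION_MODES = ("graph_coord", "graph_atom_type", "selfies", "latent")


def perturbation_study(records: list[MoleculeRecord], oracle, sigma: float = 0.1,
                       seed: int = 0, vae=None, vocab=None,
                       modes=PERTURBATION_MODES) -> pd.DataFrame:
    """Minimal-noise robustness of the four design representations.

    For every molecule and mode, apply one minimal perturbation — N(0, sigma)
    noise on one atom coordinate or one latent component, or a single random
    atom-type / grammar-symbol substitution — then re-run the forward
    process.  A perturbed design is *stable* when it can be interpreted,
    embedded and scored; the property MAE between original and perturbed is
    computed over molecules where both are stable.
    """
    unknown = set(modes) - set(PERTURBATION_MODES)
    if unknown:
        raise ValueError(f"unknown perturbation modes: {sorted(unknown)}")
    if "latent" in modes and vae is None:
        raise ValueError("latent mode requires a trained VAE")
    rng = np.random.default_rng(seed)

    originals = []
    for rec in records:
        res = oracle(rec)
        if rec.graph is not None and res.ok:
            originals.append((rec, res.properties))
    if not originals:
        raise RuntimeError("no stable molecules with graphs to perturb")
    names = originals[0][1].names

    rows = []
    for mode in modes:
        n_stable = 0
        diffs: list[np.ndarray] = []
        for i, (rec, p0) in enumerate(originals):
            pseed = int(rng.integers(2**31))
            pres = _perturb_one(rec, mode, sigma, pseed, vae, vocab)
            if not pres.ok:
                continue
            ores = oracle(pres.record)
            if not ores.ok:
                continue
            n_stable += 1
            diffs.append(np.abs(ores.properties.values - p0.values))
        row = {"mode": mode, "n": len(originals),
               "stable_pct": 100.0 * n_stable / len(originals)}
        mae = np.mean(diffs, axis=0) if diffs else np.full(len(names), np.nan)
        for name, v in zip(names, mae):
            row[f"mae_{name}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)


def _perturb_one(rec, mode, sigma, seed, vae, vocab) -> PerturbResult:
    if mode == "graph_coord":
        return perturb(rec, "coord_noise", sigma, seed, vocab)
    if mode == "graph_atom_type":
        return perturb(rec, "atom_type_swap", sigma, seed, vocab)
    if mode == "selfies":
        return perturb(rec, "selfies_swap", sigma, seed, vocab)
    # latent: encode posterior mean, add N(0, sigma) noise to one randomly
    # chosen component, greedy-decode back to a molecule
    rng = np.random.default_rng(seed)
    dist = vae.encode(rec)
    z = np.array(dist.mean)
    j = int(rng.integers(z.size))
    z[j] += rng.normal(0.0, sigma) if sigma > 0 else 0.0
    selfies = vae.greedy_selfies(z)
    try:
        return PerturbResult(True, representation.make_record(selfies, None, None))
    except ValueError:
        return PerturbResult(False, reason="no_atoms")


def markdown_table(df: pd.DataFrame, floatfmt: str = "{:.3f}") -> str:
    """Small human-readable markdown rendering of a metric table."""
    cols = list(df.columns)
    lines = ["| " + " | ".join(cols) + " |",
             "|" + "|".join("---" for _ in cols) + "|"]
    for _, row in df.iterrows():
        cells = [floatfmt.format(v) if isinstance(v, float) else str(v) for v in row]
        lines.append("| " + " | ".join(cells) + " |")
    return "\n".join(lines)
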