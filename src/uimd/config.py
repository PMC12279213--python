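"""Run configuration, seed fan-out and pipeline orchestration.

One YAML document configures the whole pipeline; unknown keys are rejected at
load time.  A single global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, STAGE_IDS[stage]])`` so every stage is
independently reproducible from one knob.  Each stage persists its artifact
under the run directory and is skipped on re-run when the artifact already
exists, and a manifest records the resolved config, stage seeds and artifact
hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

logger = logging.getLogger(__name__)

STAGE_IDS = {"fixtures": 1, "vae": 2, "reacquisition": 3, "ensemble": 4,
             "design": 5, "evaluation": 6}


def stage_seed(global_seed: int, stage: str) -> int:
    """Derived per-stage seed (< 2^31), stable across runs and platforms."""
    ss = np.random.SeedSequence([int(global_seed), STAGE_IDS[stage]])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class DataConfig:
    n_molecules: int = 200
    max_tokens: int = 16
    max_length: int = 32
    corpus_path: str | None = None   # optional .smi/.selfies file
    labels_path: str | None = None   # optional CSV molecule,property_1..k


@dataclass
class VaeConfig:
    epochs: int = 50
    batch_size: int = 32
    latent_dim: int = 64
    hidden: int = 256
    learning_rate: float = 1e-3


@dataclass
class ReacquisitionConfig:
    n_pairs: int = 10000
    embed_seed: int = 0


@dataclass
class EnsembleSection:
    n_members: int = 5
    hidden_layers: list[int] = field(default_factory=lambda: [64, 64])
    update_probability: float = 0.3
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 1e-3


@dataclass
class DesignConfig:
    k: int = 10
    steps: int = 500
    learning_rate: float = 0.1
    uncertainty_weight: float = 1.0
    n_targets: int = 20
    target_property: str = "mol_weight"
    target_low: float = 40.0
    target_high: float = 160.0


@dataclass
class EvaluationConfig:
    perturbation_sigma: float = 0.1
    reference_ids_path: str | None = None


@dataclass
class RunConfig:
    seed: int = 0
    oracle: str = "descriptors"
    data: DataConfig = field(default_factory=DataConfig)
    vae: VaeConfig = field(default_factory=VaeConfig)
    reacquisition: ReacquisitionConfig = field(default_factory=ReacquisitionConfig)
    ensemble: EnsembleSection = field(default_factory=EnsembleSection)
    design: DesignConfig = field(default_factory=DesignConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True)
                              .encode()).hexdigest()[:16]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


_SECTION_TYPES = {"data": DataConfig, "vae": VaeConfig,
                  "reacquisition": ReacquisitionConfig, "ensemble": EnsembleSection,
                  "design": DesignConfig, "evaluation": EvaluationConfig}


def _build_section(cls, payload: dict, path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys under {path!r}: {sorted(unknown)}")
    return cls(**payload)


def load_config(path_or_dict) -> RunConfig:
    """Load and schema-validate a YAML config (unknown keys rejected)."""
    if isinstance(path_or_dict, (str, Path)):
        payload = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        payload = dict(path_or_dict)
    top_known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(payload) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
    kwargs = {}
    for key, value in payload.items():
        if key in _SECTION_TYPES:
            kwargs[key] = _build_section(_SECTION_TYPES[key], value or {}, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir, stages=None, force: bool = False) -> Path:
    """Execute fixtures → VAE → reacquisition → ensemble → design → evaluation.

    Stages whose artifact directory already exists are skipped unless
    ``force``; a missing upstream artifact raises an error naming the stage
    to run first.  Returns the run directory.
    """
    from . import design as design_mod
    from . import evaluation as eval_mod
    from . import synthetic
    from .ensemble import EnsembleConfig, EnsembleSurrogate
    from .oracle import DescriptorOracle
    from .reacquisition import (LatentPropertyDataset, make_molecular_pipeline,
                                reacquire, sample_prior_latents)
    from .vae import SgpVae

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGE_IDS)
    manifest_path = outdir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    manifest["config_hash"] = config.config_hash()
    manifest.setdefault("stages", {})
    config.save(outdir / "config.yaml")
    oracle = DescriptorOracle(embed_seed=config.reacquisition.embed_seed)

    def done(stage):
        return (outdir / stage / ".complete").exists()

    def mark(stage, artifacts: dict[str, Path]):
        (outdir / stage / ".complete").touch()
        manifest["stages"][stage] = {
            "seed": stage_seed(config.seed, stage),
            "artifacts": {k: _file_hash(p) for k, p in artifacts.items() if p.exists()},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2))

    # ---- fixtures ----
    fdir = outdir / "fixtures"
    if "fixtures" in stages and (force or not done("fixtures")):
        spec = synthetic.FixtureSpec(config.data.n_molecules, config.data.max_tokens,
                                     seed=stage_seed(config.seed, "fixtures"))
        records, vocab = synthetic.generate_selfies_corpus(
            spec, vocab_max_length=config.data.max_length)
        kept, P, names, units, n_unstable = synthetic.build_labelled_dataset(records, oracle)
        logger.info("fixtures: %d molecules (%d unstable dropped)", len(kept), n_unstable)
        synthetic.write_fixture_files(kept, P, names, fdir, spec)
        mark("fixtures", {"labels": fdir / "labels.csv"})

    # ---- VAE ----
    vdir = outdir / "vae"
    if "vae" in stages and (force or not done("vae")):
        if not (fdir / "labels.csv").exists():
            raise RuntimeError("missing fixtures artifact: run the 'fixtures' stage first")
        import pandas as pd

        from .representation import build_vocabulary, make_record
        df = pd.read_csv(fdir / "labels.csv")
        strings = df["molecule"].tolist()
        names = [c for c in df.columns if c != "molecule"]
        vocab = build_vocabulary(strings, config.data.max_length)
        seed = stage_seed(config.seed, "vae")
        records = []
        for i, s in enumerate(strings):
            from .representation import embed_conformer
            emb = embed_conformer(s, seed=seed + i)
            records.append(make_record(s, vocab, emb.graph if emb.ok else None))
        max_atoms = max((r.graph.n_atoms for r in records if r.graph is not None),
                        default=9)
        model = SgpVae(vocab, max_atoms, names, [""] * len(names),
                       latent_dim=config.vae.latent_dim, hidden=config.vae.hidden,
                       seed=seed)
        model.train(records, df[names].to_numpy(), epochs=config.vae.epochs,
                    batch_size=config.vae.batch_size, lr=config.vae.learning_rate,
                    seed=seed)
        model.save(vdir)
        mark("vae", {"params": vdir / "params.npz"})

    # ---- reacquisition ----
    rdir = outdir / "reacquisition"
    if "reacquisition" in stages and (force or not done("reacquisition")):
        if not (vdir / "params.npz").exists():
            raise RuntimeError("missing VAE artifact: run the 'vae' stage first")
        model = SgpVae.load(vdir)
        seed = stage_seed(config.seed, "reacquisition")
        latents = sample_prior_latents(config.reacquisition.n_pairs,
                                       model.latent_dim, seed)
        decoder, embedder = make_molecular_pipeline(model, oracle,
                                                    config.reacquisition.embed_seed)
        dataset = reacquire(latents, decoder, embedder, oracle, seed=seed)
        logger.info("reacquisition: kept %d/%d pairs (%d unstable)",
                    len(dataset), config.reacquisition.n_pairs, dataset.n_unstable)
        dataset.save(rdir, {"vae_hash": model.config_hash(), "oracle": config.oracle})
        mark("reacquisition", {"latents": rdir / "latents.npy"})

    # ---- ensemble ----
    edir = outdir / "ensemble"
    if "ensemble" in stages and (force or not done("ensemble")):
        if not (rdir / "latents.npy").exists():
            raise RuntimeError("missing reacquisition artifact: run 'reacquisition' first")
        dataset = LatentPropertyDataset.load(rdir)
        seed = stage_seed(config.seed, "ensemble")
        e = config.ensemble
        cfg = EnsembleConfig(e.n_members, tuple(e.hidden_layers),
                             update_probability=e.update_probability, epochs=e.epochs,
                             batch_size=e.batch_size, learning_rate=e.learning_rate,
                             seed=seed)
        model = EnsembleSurrogate(cfg, dataset.latent_dim, dataset.properties.shape[1])
        model.train(dataset)
        model.save(edir, {"dataset_n": len(dataset)})
        mark("ensemble", {"members": edir / "members.npz"})

    # ---- design ----
    ddir = outdir / "design"
    if "design" in stages and (force or not done("design")):
        if not (edir / "members.npz").exists():
            raise RuntimeError("missing ensemble artifact: run 'ensemble' first")
        vae_model = SgpVae.load(vdir)
        surrogate = EnsembleSurrogate.load(edir)
        dataset = LatentPropertyDataset.load(rdir)
        seed = stage_seed(config.seed, "design")
        d = config.design
        grid = design_mod.target_grid(d.target_low, d.target_high, d.n_targets)
        ddir.mkdir(parents=True, exist_ok=True)
        results = []
        for i, t in enumerate(grid):
            req = design_mod.DesignRequest({d.target_property: float(t)}, k=d.k,
                                           steps=d.steps, learning_rate=d.learning_rate,
                                           uncertainty_weight=d.uncertainty_weight,
                                           seed=seed + i)
            res = design_mod.design_molecule(req, surrogate, vae_model.greedy_selfies,
                                             oracle=oracle,
                                             property_names=dataset.property_names)
            res.targets = {d.target_property: float(t)}
            results.append(res)
        frame = eval_mod.results_to_frame(results, targets_of=lambda r: r.targets)
        frame.to_csv(ddir / "designs.csv", index=False)
        mark("design", {"designs": ddir / "designs.csv"})

    # ---- evaluation ----
    gdir = outdir / "evaluation"
    if "evaluation" in stages and (force or not done("evaluation")):
        if not (ddir / "designs.csv").exists():
            raise RuntimeError("missing design artifact: run 'design' first")
        import pandas as pd
        df = pd.read_csv(ddir / "designs.csv")
        gdir.mkdir(parents=True, exist_ok=True)
        report = evaluate_design_frame(df, config, fdir)
        (gdir / "report.json").write_text(json.dumps(report, indent=2))
        mark("evaluation", {"report": gdir / "report.json"})

    return outdir


def evaluate_design_frame(df, config: RunConfig, fixtures_dir) -> dict:
    """Recompute the report metrics from a persisted per-design table."""
    from . import representation
    prop = config.design.target_property
    ocol, scol, tcol = f"oracle_error_{prop}", f"surrogate_error_{prop}", f"target_{prop}"
    stable = df[df[ocol].notna()] if ocol in df else df.iloc[0:0]
    nfp_mae = float(stable[ocol].mean()) if len(stable) else float("nan")
    sur_mae = float(df[scol].mean())
    ids = [representation.canonical_id(s) for s in df["selfies"] if isinstance(s, str)]
    ref_path = config.evaluation.reference_ids_path
    if ref_path:
        reference = set(Path(ref_path).read_text().split())
    else:
        corpus = (Path(fixtures_dir) / "corpus.selfies").read_text().split()
        reference = {representation.canonical_id(s) for s in corpus}
    return {
        "nfp_mae": {prop: nfp_mae},
        "surrogate_mae": {prop: sur_mae},
        "misalignment": {prop: abs(nfp_mae - sur_mae)},
        "novelty_pct": 100.0 * sum(i not in reference for i in ids) / max(len(ids), 1),
        "uniqueness_pct": 100.0 * len(set(ids)) / max(len(ids), 1),
        "n_designs": int(len(df)),
        "n_unstable": int(len(df) - len(stable)),
    }
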