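"""Native forward process (NFP) oracles.

The NFP is the ground-truth map from a molecule to its numeric properties.
At research scale this is conformer generation plus a quantum-chemistry
calculation; everything downstream only requires a callable that takes a
molecule (or conformer) and returns an :class:`OracleResult`, so cheap
desk-scale oracles and an external-program adapter share one contract.

Oracles always report properties in natural units; standardization is the
consumer's job (surrogate training and latent optimization must share one
scaling, which they take from the dataset, not from the oracle).
"""

from __future__ import annotations

import json
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from . import grammar, representation
from .representation import EmbedResult, MoleculeGraph, MoleculeRecord


@dataclass(frozen=True)
class PropertyVector:
    names: tuple[str, ...]
    values: np.ndarray
    units: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        assert values.shape == (len(self.names),) and len(self.units) == len(self.names)
        assert np.isfinite(values).all(), "property values must be finite"
        object.__setattr__(self, "values", values)

    def subset(self, names) -> "PropertyVector":
        idx = [self.names.index(n) for n in names]
        return PropertyVector(tuple(names), self.values[idx], tuple(self.units[i] for i in idx))


@dataclass(frozen=True)
class OracleResult:
    status: str  # "ok" | "unstable"
    properties: PropertyVector | None = None
    reason: str = ""

    def __post_init__(self):
        assert (self.status == "ok") == (self.properties is not None)

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def unstable(reason: str) -> OracleResult:
    return OracleResult("unstable", None, reason)


#: anything that maps a conformer/molecule to an OracleResult satisfies the
#: forward-process contract (e.g. a wrapper around an external QM program)
ConformerOracle = Callable[[MoleculeGraph], OracleResult]


class DescriptorOracle:
    """Desk-scale NFP: three computed molecular descriptors.

    Mirrors the three-property research setting (orbital energies + dipole)
    with molecular weight (Da), Crippen logP and topological polar surface
    area (Å²).  A molecule is *unstable* iff it cannot be interpreted or its
    conformer embedding/relaxation does not converge — the desk-scale mirror
    of a quantum-chemistry calculation failing to converge.

    A molecule arriving *with* a conformation is additionally required to be
    geometrically self-consistent: its heavy-atom strain energy (energy above
    its own force-field minimum) must stay below ``strain_threshold``
    kcal/mol, roughly the room-temperature thermal scale — single-point
    physics on a strained geometry is exactly what fails to converge in the
    reference forward process.
    """

    names = ("mol_weight", "logp", "tpsa")
    units = ("Da", "logP", "A^2")

    def __init__(self, embed_seed: int = 0, require_embedding: bool = True,
                 strain_threshold: float = 2.0):
        self.embed_seed = int(embed_seed)
        self.require_embedding = require_embedding
        self.strain_threshold = float(strain_threshold)

    def _from_mol(self, mol: Chem.Mol) -> OracleResult:
        values = np.array([
            Descriptors.MolWt(mol),
            Crippen.MolLogP(mol),
            Descriptors.TPSA(mol),
        ])
        if not np.isfinite(values).all():
            return unstable("non_finite_descriptors")
        return OracleResult("ok", PropertyVector(self.names, values, self.units))

    def __call__(self, molecule) -> OracleResult:
        """Accepts a MoleculeRecord, a grammar string, or a MoleculeGraph."""
        if isinstance(molecule, MoleculeGraph):
            try:
                mol = representation.graph_to_mol(molecule)
                selfies = grammar.encode(mol)
            except Exception:
                return unstable("uninterpretable_geometry")
            if representation.strain_energy(selfies, molecule.coordinates) > self.strain_threshold:
                return unstable("strained_geometry")
            return self._from_mol(mol)
        selfies = molecule.selfies if isinstance(molecule, MoleculeRecord) else molecule
        mol = grammar.decode(selfies)
        if mol is None:
            return unstable("no_atoms")
        graph = molecule.graph if isinstance(molecule, MoleculeRecord) else None
        if graph is None:
            if self.require_embedding:
                emb: EmbedResult = representation.embed_conformer(selfies, seed=self.embed_seed)
                if not emb.ok:
                    return unstable(emb.reason)
        elif representation.strain_energy(selfies, graph.coordinates) > self.strain_threshold:
            return unstable("strained_geometry")
        return self._from_mol(mol)


class AnalyticOracle:
    """Closed-form test oracle: p = A·z + b (optionally through tanh).

    Used in closed-loop harnesses where the "molecule" is its latent vector,
    so the whole design loop can be verified against linear-algebra ground
    truth.
    """

    def __init__(self, A: np.ndarray, b: np.ndarray | None = None,
                 nonlinearity: str | None = None):
        self.A = np.asarray(A, dtype=float)
        self.b = np.zeros(self.A.shape[0]) if b is None else np.asarray(b, dtype=float)
        if self.b.shape != (self.A.shape[0],):
            raise ValueError("b incompatible with A")
        if nonlinearity not in (None, "tanh"):
            raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
        self.nonlinearity = nonlinearity
        k = self.A.shape[0]
        self.names = tuple(f"p{i + 1}" for i in range(k))
        self.units = ("a.u.",) * k

    def predict(self, Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != self.A.shape[1]:
            raise ValueError(
                f"latent dimension {Z.shape[1]} incompatible with A {self.A.shape}")
        P = Z @ self.A.T + self.b
        if self.nonlinearity == "tanh":
            P = np.tanh(P)
        return P

    def __call__(self, z) -> OracleResult:
        p = self.predict(np.asarray(z, dtype=float).reshape(1, -1))[0]
        return OracleResult("ok", PropertyVector(self.names, p, self.units))


class ExternalCommandOracle:
    """Adapter for a user-supplied forward process.

    Writes the conformer to an SDF file, runs ``command <sdf_path>`` and
    parses JSON ``{"names": [...], "values": [...], "units": [...]}`` from
    stdout.  Any program failure is reported as an unstable outcome with the
    captured reason, never raised.
    """

    def __init__(self, command: list[str], timeout: float = 300.0):
        self.command = list(command)
        self.timeout = timeout

    def __call__(self, molecule) -> OracleResult:
        if isinstance(molecule, MoleculeRecord):
            if molecule.graph is None:
                return unstable("no_conformer")
            records = [molecule]
        elif isinstance(molecule, MoleculeGraph):
            try:
                mol = representation.graph_to_mol(molecule)
                selfies = grammar.encode(mol)
            except Exception:
                return unstable("uninterpretable_geometry")
            records = [representation.make_record(selfies, graph=molecule)]
        else:
            return unstable("unsupported_input")
        with tempfile.TemporaryDirectory() as tmp:
            sdf = Path(tmp) / "conformer.sdf"
            representation.write_sdf(records, sdf)
            try:
                proc = subprocess.run(self.command + [str(sdf)], capture_output=True,
                                      text=True, timeout=self.timeout)
            except Exception as exc:
                return unstable(f"command_error: {exc}")
            if proc.returncode != 0:
                return unstable(f"command_failed: {proc.stderr.strip()[:200]}")
            try:
                payload = json.loads(proc.stdout)
                pv = PropertyVector(tuple(payload["names"]),
                                    np.asarray(payload["values"], dtype=float),
                                    tuple(payload["units"]))
            except Exception as exc:
                return unstable(f"bad_output: {exc}")
            return OracleResult("ok", pv)


def get_oracle(name: str, **kwargs):
    """Config-level oracle selection: descriptors | analytic | external_command."""
    if name == "descriptors":
        return DescriptorOracle(**kwargs)
    if name == "analytic":
        return AnalyticOracle(**kwargs)
    if name == "external_command":
        return ExternalCommandOracle(**kwargs)
    raise ValueError(f"unknown oracle {name!r}")
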