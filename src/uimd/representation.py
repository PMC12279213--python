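"""Molecule records: vocabulary, tokenization, identity, conformers, perturbation.

A molecule is carried in three linked views: the grammar string (primary,
always valid), a fixed-length token sequence for the sequence model, and an
optional 3D heavy-atom graph produced by seeded distance-geometry embedding
plus force-field relaxation.  Embedding failure is a first-class outcome so
that downstream stages can count instability instead of crashing — mirroring
forward processes that do not converge for every structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem, rdDetermineBonds

from . import grammar

logger = logging.getLogger(__name__)

PAD, START, STOP = "[pad]", "[start]", "[stop]"
SPECIAL_TOKENS = (PAD, START, STOP)

#: element alphabet of the default corpora (heavy atoms, hydrogens implicit)
ELEMENTS = ("C", "N", "O", "F")


class TokenizeError(ValueError):
    pass


@dataclass(frozen=True)
class SelfiesVocabulary:
    """Token table: PAD/START/STOP first, then lexicographic grammar symbols."""

    tokens: tuple[str, ...]
    max_length: int
    n_rejected: int = 0

    def __post_init__(self):
        assert self.tokens[:3] == SPECIAL_TOKENS
        assert len(set(self.tokens)) == len(self.tokens)

    @property
    def size(self) -> int:
        return len(self.tokens)

    @property
    def pad_index(self) -> int:
        return 0

    def index(self, symbol: str) -> int:
        try:
            return self.tokens.index(symbol)
        except ValueError:
            raise TokenizeError(f"symbol {symbol!r} not in vocabulary") from None

    def tokenize(self, selfies: str) -> np.ndarray:
        symbols = grammar.split_symbols(selfies)
        if len(symbols) > self.max_length:
            raise TokenizeError(
                f"molecule has {len(symbols)} symbols, exceeds max_length={self.max_length}"
            )
        ids = [self.index(s) for s in symbols]
        ids += [self.pad_index] * (self.max_length - len(ids))
        return np.asarray(ids, dtype=np.int64)

    def detokenize(self, ids) -> str:
        out = []
        for i in ids:
            sym = self.tokens[int(i)]
            if sym in SPECIAL_TOKENS:
                break
            out.append(sym)
        return "".join(out)


def build_vocabulary(molecules: list[str], max_length: int = 32) -> SelfiesVocabulary:
    """Build the token table from a training corpus.

    Molecules that do not fit within ``max_length`` token positions are
    excluded (counted in ``n_rejected`` and logged); the vocabulary covers
    every symbol occurring in the surviving corpus plus the special tokens.
    """
    if not molecules:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    symbols: set[str] = set()
    n_rejected = 0
    for s in molecules:
        syms = grammar.split_symbols(s)
        if len(syms) > max_length:
            n_rejected += 1
            continue
        symbols.update(syms)
    if n_rejected:
        logger.warning("vocabulary build: %d molecules exceed max_length=%d and were excluded",
                       n_rejected, max_length)
    if not symbols:
        raise ValueError("no molecule fits within max_length")
    return SelfiesVocabulary(SPECIAL_TOKENS + tuple(sorted(symbols)), max_length, n_rejected)


@dataclass(frozen=True)
class MoleculeGraph:
    """Heavy-atom 3D graph: element labels and coordinates in Å."""

    atom_types: tuple[str, ...]
    coordinates: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        coords = np.asarray(self.coordinates, dtype=float)
        assert coords.shape == (len(self.atom_types), 3)
        assert np.isfinite(coords).all()
        object.__setattr__(self, "coordinates", coords)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_types)

    def to_padded(self, max_atoms: int, elements=ELEMENTS):
        """(one-hot types [A,E], coords [A,3], mask [A]) padded to max_atoms."""
        e_index = {e: i for i, e in enumerate(elements)}
        onehot = np.zeros((max_atoms, len(elements)))
        coords = np.zeros((max_atoms, 3))
        mask = np.zeros(max_atoms)
        for i, (el, xyz) in enumerate(zip(self.atom_types, self.coordinates)):
            onehot[i, e_index[el]] = 1.0
            coords[i] = xyz
            mask[i] = 1.0
        return onehot, coords, mask


@dataclass(frozen=True)
class MoleculeRecord:
    selfies: str
    canonical_id: str
    tokens: np.ndarray | None = None
    graph: MoleculeGraph | None = None

    def with_graph(self, graph: MoleculeGraph | None) -> "MoleculeRecord":
        return replace(self, graph=graph)


def make_record(selfies: str, vocab: SelfiesVocabulary | None = None,
                graph: MoleculeGraph | None = None) -> MoleculeRecord:
    return MoleculeRecord(
        selfies=selfies,
        canonical_id=canonical_id(selfies),
        tokens=None if vocab is None else vocab.tokenize(selfies),
        graph=graph,
    )


def canonical_id(selfies: str) -> str:
    """Canonical structure string (canonical SMILES) used for identity."""
    smiles = grammar.to_smiles(selfies)
    if smiles is None:
        raise ValueError(f"string derives no atoms: {selfies!r}")
    return smiles


@dataclass(frozen=True)
class EmbedResult:
    ok: bool
    graph: MoleculeGraph | None = None
    reason: str = ""


def embed_conformer(selfies: str, seed: int = 0, ff_max_iters: int = 200) -> EmbedResult:
    """Distance-geometry embedding + MMFF relaxation, seeded.

    Failure (embedding does not converge, force field cannot be set up or does
    not converge within ``ff_max_iters``) is returned as a first-class outcome
    with a reason code rather than raised.
    """
    mol = grammar.decode(selfies)
    if mol is None:
        return EmbedResult(False, reason="no_atoms")
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) % (2**31 - 1)
    conf_id = AllChem.EmbedMolecule(molh, params)
    if conf_id < 0:
        return EmbedResult(False, reason="embed_failed")
    try:
        rc = AllChem.MMFFOptimizeMolecule(molh, maxIters=ff_max_iters)
    except Exception:
        return EmbedResult(False, reason="ff_error")
    if rc == -1:
        return EmbedResult(False, reason="ff_setup_failed")
    if rc == 1:
        return EmbedResult(False, reason="ff_not_converged")
    heavy = Chem.RemoveHs(molh)
    conf = heavy.GetConformer()
    coords = np.array([list(conf.GetAtomPosition(i)) for i in range(heavy.GetNumAtoms())])
    types = tuple(a.GetSymbol() for a in heavy.GetAtoms())
    return EmbedResult(True, MoleculeGraph(types, coords))


def strain_energy(selfies: str, heavy_coords: np.ndarray,
                  ff_max_iters: int = 2000) -> float:
    """Heavy-atom strain (kcal/mol) of a supplied conformation.

    Hydrogens are added geometrically and relaxed with the heavy atoms fixed,
    then the strain is the energy drop from that conformation to a full
    force-field minimization.  A relaxed conformer scores ~0; geometries that
    a quantum single-point would struggle with (displaced atoms, wrong bond
    lengths after an element change) score many kcal/mol.  Returns +inf when
    the force field cannot be set up or the optimizer fails.
    """
    try:
        mol = grammar.decode(selfies)
        if mol is None or mol.GetNumAtoms() != len(heavy_coords):
            return float("inf")
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(np.asarray(heavy_coords, dtype=float)):
            conf.SetAtomPosition(i, [float(v) for v in xyz])
        mol.AddConformer(conf)
        molh = Chem.AddHs(mol, addCoords=True)
        props = AllChem.MMFFGetMoleculeProperties(molh)
        ff = AllChem.MMFFGetMoleculeForceField(molh, props)
        if ff is None:
            return float("inf")
        for i in range(mol.GetNumAtoms()):
            ff.AddFixedPoint(i)
        ff.Minimize(maxIts=ff_max_iters)
        e_fixed = ff.CalcEnergy()
        molh2 = Chem.Mol(molh)
        ff2 = AllChem.MMFFGetMoleculeForceField(
            molh2, AllChem.MMFFGetMoleculeProperties(molh2))
        ff2.Minimize(maxIts=ff_max_iters)
        return e_fixed - ff2.CalcEnergy()
    except Exception:
        return float("inf")


def graph_to_mol(graph: MoleculeGraph, reference: Chem.Mol | None = None) -> Chem.Mol:
    """Re-perceive a molecule from raw heavy-atom geometry.

    Bonds are inferred from interatomic distances (covalent radii).  When the
    perceived connectivity coincides with a supplied ``reference`` topology,
    the reference bond orders are kept (the geometry is consistent with the
    original structure); otherwise single bonds are assumed and the result
    sanitized.  Raises on chemically uninterpretable geometry — the
    desk-scale analogue of a forward process failing to converge on a
    perturbed structure.
    """
    rw = Chem.RWMol()
    for el in graph.atom_types:
        rw.AddAtom(Chem.Atom(el))
    conf = Chem.Conformer(graph.n_atoms)
    for i, xyz in enumerate(graph.coordinates):
        conf.SetAtomPosition(i, [float(x) for x in xyz])
    mol = rw.GetMol()
    mol.AddConformer(conf)
    rdDetermineBonds.DetermineConnectivity(mol)
    perceived = {frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())) for b in mol.GetBonds()}
    if reference is not None and reference.GetNumAtoms() == graph.n_atoms:
        ref_bonds = {
            frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx())): b.GetBondType()
            for b in reference.GetBonds()
        }
        if perceived == set(ref_bonds):
            rw2 = Chem.RWMol(mol)
            for b in rw2.GetBonds():
                b.SetBondType(ref_bonds[frozenset((b.GetBeginAtomIdx(), b.GetEndAtomIdx()))])
            mol = rw2.GetMol()
    for atom in mol.GetAtoms():  # bond perception marks atoms H-complete; undo
        atom.SetNoImplicit(False)
        atom.SetNumRadicalElectrons(0)
    Chem.SanitizeMol(mol)
    return mol


PERTURB_MODES = ("coord_noise", "atom_type_swap", "selfies_swap")


def _tolerant_record(selfies, vocab, graph):
    """Record for a perturbed structure; perturbation may leave the corpus
    vocabulary, in which case the token view is simply absent."""
    try:
        return make_record(selfies, vocab, graph)
    except TokenizeError:
        return make_record(selfies, None, graph)


@dataclass(frozen=True)
class PerturbResult:
    ok: bool
    record: MoleculeRecord | None = None
    reason: str = ""


def perturb(record: MoleculeRecord, mode: str, sigma: float = 0.1, seed: int = 0,
            vocab: SelfiesVocabulary | None = None,
            elements=ELEMENTS) -> PerturbResult:
    """Apply one minimal representation-level perturbation.

    coord_noise     — Gaussian(0, sigma) noise on one randomly chosen atom's
                      3D coordinates; the perturbed geometry is re-interpreted
                      from scratch (failure counts as unstable).
    atom_type_swap  — one randomly chosen atom's element replaced by a
                      different element from the dataset alphabet, bonds kept;
                      valence violations surface as interpretation failure.
    selfies_swap    — one randomly chosen grammar symbol replaced by a
                      different symbol; by the grammar's robustness the result
                      is always a decodable molecule.
    """
    rng = np.random.default_rng(seed)
    if mode not in PERTURB_MODES:
        raise ValueError(f"unknown perturbation mode {mode!r}")

    if mode == "coord_noise":
        if record.graph is None:
            raise ValueError("coord_noise requires a 3D graph")
        coords = record.graph.coordinates.copy()
        i = int(rng.integers(record.graph.n_atoms))
        coords[i] += rng.normal(0.0, sigma, size=3) if sigma > 0 else 0.0
        new_graph = MoleculeGraph(record.graph.atom_types, coords)
        try:
            mol = graph_to_mol(new_graph, reference=grammar.decode(record.selfies))
            selfies = grammar.encode(mol)
        except (Exception):
            return PerturbResult(False, reason="uninterpretable_geometry")
        return PerturbResult(True, _tolerant_record(selfies, vocab, new_graph))

    if mode == "atom_type_swap":
        if record.graph is None:
            raise ValueError("atom_type_swap requires a 3D graph")
        mol = grammar.decode(record.selfies)
        rw = Chem.RWMol(mol)
        i = int(rng.integers(rw.GetNumAtoms()))
        old = rw.GetAtomWithIdx(i).GetSymbol()
        choices = [e for e in elements if e != old]
        new_el = choices[int(rng.integers(len(choices)))]
        rw.ReplaceAtom(i, Chem.Atom(new_el))
        try:
            newmol = rw.GetMol()
            Chem.SanitizeMol(newmol)
            selfies = grammar.encode(newmol)
        except Exception:
            return PerturbResult(False, reason="valence_violation")
        # keep the original geometry with the swapped atom type
        types = list(record.graph.atom_types)
        types[i] = new_el
        new_graph = MoleculeGraph(tuple(types), record.graph.coordinates)
        return PerturbResult(True, _tolerant_record(selfies, vocab, new_graph))

    # selfies_swap
    symbols = grammar.split_symbols(record.selfies)
    i = int(rng.integers(len(symbols)))
    choices = [s for s in grammar.ALPHABET if s != symbols[i]]
    symbols[i] = choices[int(rng.integers(len(choices)))]
    selfies = "".join(symbols)
    if grammar.decode(selfies) is None:
        return PerturbResult(False, reason="no_atoms")
    return PerturbResult(True, _tolerant_record(selfies, vocab, None))


def read_molecule_lines(path) -> list[str]:
    """Read a .smi / .selfies plain-text file (one molecule per line).

    SMILES lines are converted into the grammar; lines that cannot be
    expressed are skipped with a logged count.
    """
    out, n_skipped = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.strip().split()[0] if line.strip() else ""
            if not line:
                continue
            try:
                out.append(line if line.startswith("[") else grammar.from_smiles(line))
            except grammar.GrammarError:
                n_skipped += 1
    if n_skipped:
        logger.warning("read_molecule_lines: skipped %d inexpressible molecules", n_skipped)
    return out


def write_sdf(records: list[MoleculeRecord], path) -> int:
    """Write embedded conformers to an SDF file; returns the number written."""
    writer = Chem.SDWriter(str(path))
    n = 0
    for rec in records:
        if rec.graph is None:
            continue
        mol = grammar.decode(rec.selfies)
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, xyz in enumerate(rec.graph.coordinates[: mol.GetNumAtoms()]):
            conf.SetAtomPosition(i, [float(x) for x in xyz])
        mol.AddConformer(conf)
        mol.SetProp("_Name", rec.canonical_id)
        writer.write(mol)
        n += 1
    writer.close()
    return n
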