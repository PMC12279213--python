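"""Robust molecular string grammar over a small organic alphabet.

A SELFIES-style derivation grammar in which *every* symbol sequence maps to a
chemically valid molecule: atoms carry their bond order as a prefix, and the
decoder clamps each requested bond to the valence still available on the
growing molecule, so no sequence of symbols can over-bond an atom.  Branches
and rings are expressed with `[Branch1]` / `[Ring1]` control symbols followed
by a single index symbol (overloaded from the main alphabet, see
``INDEX_ORDER``) that encodes the branch length or ring reach.

The alphabet is restricted to the neutral organic subset C, N, O, F with
implicit hydrogens — the element set of typical small-molecule design corpora.
Structures are materialized as RDKit molecules, so canonicalization, conformer
embedding and descriptor computation all run on the standard toolkit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.*")

# element -> maximum valence used by the derivation rules (neutral, no radicals)
VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1}

_BOND_PREFIX = {1: "", 2: "=", 3: "#"}
_BOND_TYPE = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}

# atom symbol -> (element, requested bond order to the preceding atom)
ATOM_SYMBOLS = {
    f"[{_BOND_PREFIX[o]}{el}]": (el, o)
    for el in VALENCE
    for o in (1, 2, 3)
    if o <= VALENCE[el]
}

BRANCH = "[Branch1]"
RING_SYMBOLS = {"[Ring1]": 1, "[=Ring1]": 2}

#: full derivation alphabet (order is also the index table for branch/ring Q values)
INDEX_ORDER = [
    "[C]", "[=C]", "[#C]",
    "[N]", "[=N]", "[#N]",
    "[O]", "[=O]",
    "[F]",
    "[Branch1]", "[Ring1]", "[=Ring1]",
]
_INDEX_Q = {s: i for i, s in enumerate(INDEX_ORDER)}
ALPHABET = list(INDEX_ORDER)

_SYMBOL_RE = re.compile(r"\[[^\[\]]*\]")


class GrammarError(ValueError):
    """Raised when a string is not a well-formed symbol sequence or a
    molecule cannot be expressed in this grammar."""


def split_symbols(selfies: str) -> list[str]:
    """Split a grammar string into its bracketed symbols.

    Raises :class:`GrammarError` if the string contains characters outside
    ``[...]`` groups.
    """
    symbols = _SYMBOL_RE.findall(selfies)
    if "".join(symbols) != selfies:
        raise GrammarError(f"not a well-formed symbol string: {selfies!r}")
    return symbols


def _derive(symbols, i, end, attach, elements, bonds, free):
    """Derive ``symbols[i:end]``, attaching the first derived atom to ``attach``.

    Mutates elements/bonds/free in place.  Returns the index where derivation
    stopped (== end unless the chain ran out of valence).
    """
    prev = attach
    while i < end:
        sym = symbols[i]
        if sym in ATOM_SYMBOLS:
            el, order = ATOM_SYMBOLS[sym]
            if prev is None:
                elements.append(el)
                free.append(VALENCE[el])
                prev = len(elements) - 1
            else:
                cap = free[prev]
                if cap == 0:
                    return end  # chain exhausted: remaining symbols are inert
                o = min(order, cap, VALENCE[el])
                elements.append(el)
                free.append(VALENCE[el] - o)
                free[prev] -= o
                bonds.append((prev, len(elements) - 1, o))
                prev = len(elements) - 1
            i += 1
        elif sym == BRANCH:
            if i + 1 >= end:
                return end
            if prev is None or free[prev] == 0:
                i += 2  # inapplicable branch: drop symbol + index, keep content
                continue
            n = _INDEX_Q.get(symbols[i + 1], 0) + 1
            start, stop = i + 2, min(i + 2 + n, end)
            _derive(symbols, start, stop, prev, elements, bonds, free)
            i = stop
        elif sym in RING_SYMBOLS:
            if i + 1 >= end:
                return end
            order = RING_SYMBOLS[sym]
            q = _INDEX_Q.get(symbols[i + 1], 0)
            if prev is not None:
                j = prev - (q + 1)
                exists = any((a == j and b == prev) or (a == prev and b == j) for a, b, _ in bonds)
                if j >= 0 and j != prev and not exists:
                    o = min(order, free[prev], free[j])
                    if o > 0:
                        bonds.append((j, prev, o))
                        free[prev] -= o
                        free[j] -= o
            i += 2
        else:
            i += 1  # unknown / special symbols are inert
    return end


def decode_graph(selfies: str) -> tuple[list[str], list[tuple[int, int, int]]]:
    """Decode a grammar string into (elements, bonds) with bonds (i, j, order)."""
    symbols = split_symbols(selfies)
    elements: list[str] = []
    bonds: list[tuple[int, int, int]] = []
    free: list[int] = []
    _derive(symbols, 0, len(symbols), None, elements, bonds, free)
    return elements, bonds


def decode(selfies: str) -> Chem.Mol | None:
    """Decode a grammar string to a sanitized RDKit molecule.

    Returns None only when the string derives zero atoms (e.g. a sequence of
    bare control symbols); any string containing at least one atom symbol
    yields a valid molecule.
    """
    elements, bonds = decode_graph(selfies)
    if not elements:
        return None
    rw = Chem.RWMol()
    for el in elements:
        rw.AddAtom(Chem.Atom(el))
    for a, b, o in bonds:
        rw.AddBond(a, b, _BOND_TYPE[o])
    mol = rw.GetMol()
    Chem.SanitizeMol(mol)
    return mol


def to_smiles(selfies: str) -> str | None:
    mol = decode(selfies)
    return None if mol is None else Chem.MolToSmiles(mol)


def _bond_order(bond: Chem.Bond) -> int:
    o = int(bond.GetBondTypeAsDouble())
    if o not in (1, 2, 3):
        raise GrammarError(f"unsupported bond order {bond.GetBondTypeAsDouble()}")
    return o


def encode(mol: Chem.Mol) -> str:
    """Encode an RDKit molecule as a grammar string.

    The molecule must be neutral, radical-free and limited to C/N/O/F heavy
    atoms; aromatic systems are kekulized first.  Raises
    :class:`GrammarError` when the structure cannot be expressed (exotic
    elements, charges, or branch/ring indices beyond the index table).
    """
    mol = Chem.RemoveHs(Chem.Mol(mol))
    Chem.Kekulize(mol, clearAromaticFlags=True)
    for atom in mol.GetAtoms():
        if atom.GetSymbol() not in VALENCE:
            raise GrammarError(f"element {atom.GetSymbol()} outside alphabet")
        if atom.GetFormalCharge() != 0 or atom.GetNumRadicalElectrons() != 0:
            raise GrammarError("charged or radical species not supported")
    n = mol.GetNumAtoms()
    if n == 0:
        raise GrammarError("empty molecule")

    order = {1: "", 2: "=", 3: "#"}
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    for b in mol.GetBonds():
        o = _bond_order(b)
        adj[b.GetBeginAtomIdx()].append((b.GetEndAtomIdx(), o))
        adj[b.GetEndAtomIdx()].append((b.GetBeginAtomIdx(), o))
    for nbrs in adj.values():
        nbrs.sort()

    tokens_out: list[str] = []
    derivation_index: dict[int, int] = {}

    # pass 1: recursive DFS so every non-tree edge is a back edge to an
    # ancestor (ancestors are emitted before descendants under any child order)
    tree: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    back_edges: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n)}
    visited = [False] * n
    recorded: set[frozenset] = set()

    def _dfs(u: int, par: int | None) -> None:
        visited[u] = True
        for v, o in adj[u]:
            if not visited[v]:
                tree[u].append((v, o))
                _dfs(v, u)
            elif v != par and frozenset((u, v)) not in recorded:
                recorded.add(frozenset((u, v)))
                back_edges[u].append((v, o))

    _dfs(0, None)
    if not all(visited):
        raise GrammarError("disconnected molecule")

    size = [1] * n

    def _size(u: int) -> int:
        for v, _ in tree[u]:
            size[u] += _size(v)
        return size[u]

    _size(0)

    def _emit(u: int, bond_to_parent: int | None) -> list[str]:
        el = mol.GetAtomWithIdx(u).GetSymbol()
        prefix = "" if bond_to_parent is None else order[bond_to_parent]
        out = [f"[{prefix}{el}]"]
        derivation_index[u] = len(derivation_index)
        for v, o in back_edges[u]:
            q = derivation_index[u] - derivation_index[v] - 1
            if q >= len(INDEX_ORDER):
                raise GrammarError("ring reach exceeds index table")
            if o == 3:
                raise GrammarError("triple-bond ring closure not expressible")
            out += [{1: "[Ring1]", 2: "[=Ring1]"}[o], INDEX_ORDER[q]]
        children = sorted(tree[u], key=lambda vo: (size[vo[0]], vo[0]))
        for k, (v, o) in enumerate(children):
            sub = _emit(v, o)
            if k < len(children) - 1:
                if len(sub) > len(INDEX_ORDER):
                    raise GrammarError("branch length exceeds index table")
                out += [BRANCH, INDEX_ORDER[len(sub) - 1]] + sub
            else:
                out += sub
        return out

    tokens_out = _emit(0, None)
    return "".join(tokens_out)


def from_smiles(smiles: str) -> str:
    """Encode a SMILES string into the grammar (kekulized, implicit H)."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise GrammarError(f"unparseable SMILES: {smiles!r}")
    return encode(mol)


@dataclass(frozen=True)
class RoundTripReport:
    n: int
    n_ok: int
    failures: tuple[str, ...]


def check_round_trip(smiles_list) -> RoundTripReport:
    """Encode→decode each SMILES and compare canonical forms (diagnostic)."""
    failures = []
    for smi in smiles_list:
        ref = Chem.MolToSmiles(Chem.MolFromSmiles(smi))
        try:
            got = to_smiles(from_smiles(smi))
        except GrammarError:
            failures.append(smi)
            continue
        if got != ref:
            failures.append(smi)
    return RoundTripReport(len(smiles_list), len(smiles_list) - len(failures), tuple(failures))
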