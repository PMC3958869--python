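"""Hydrogen-suppressed molecular graphs parsed from a SMILES subset.

The chemical space covered is that of neutral organic molecules built from
C, N, O and the halogens: alkanes, cycloalkanes, benzenoid aromatics and
simple monofunctional benzenes.  Hydrogens are never graph nodes; every
heavy atom carries an implicit-hydrogen count derived from standard
valences.  Aromatic (lowercase) input is Kekulized immediately, so all
downstream code sees explicit alternating single/double bond orders.

The parser deliberately supports only this subset and rejects everything
else (charges, isotopes, stereo markers, bracket atoms, disconnected
fragments) with a positioned error rather than risking a silent mis-parse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

__all__ = [
    "Atom",
    "Bond",
    "Molecule",
    "MolGraphError",
    "SmilesParseError",
    "ValenceError",
    "ConnectivityError",
    "KekulizationError",
    "parse_smiles",
    "hill_formula",
    "molecular_weight",
]

#: valence electrons of the supported elements
VALENCE_ELECTRONS = {"C": 4, "N": 5, "O": 6, "F": 7, "Cl": 7, "Br": 7, "I": 7}
#: standard (neutral, lowest) valence used to assign implicit hydrogens
STANDARD_VALENCE = {"C": 4, "N": 3, "O": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1}
ATOMIC_NUMBER = {"H": 1, "C": 6, "N": 7, "O": 8, "F": 9, "Cl": 17, "Br": 35, "I": 53}
ATOMIC_WEIGHT = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Cl": 35.45,
    "Br": 79.904,
    "I": 126.904,
}


class MolGraphError(ValueError):
    """Base class for molecular-graph construction failures."""


class SmilesParseError(MolGraphError):
    """Unsupported or malformed token in the SMILES input."""

    def __init__(self, message: str, smiles: str, position: int):
        super().__init__(f"{message} at position {position} in {smiles!r}")
        self.smiles = smiles
        self.position = position


class ValenceError(MolGraphError):
    """An atom's bond orders exceed its standard valence."""


class ConnectivityError(MolGraphError):
    """The parsed graph is not a single connected component."""


class KekulizationError(MolGraphError):
    """No alternating single/double assignment exists for the aromatic system."""


@dataclass(frozen=True)
class Atom:
    index: int
    element: str
    implicit_h: int
    aromatic: bool = False

    @property
    def valence_electrons(self) -> int:
        return VALENCE_ELECTRONS[self.element]

    @property
    def atomic_number(self) -> int:
        return ATOMIC_NUMBER[self.element]


@dataclass(frozen=True)
class Bond:
    atom_i: int
    atom_j: int
    order: int  # 1, 2 or 3 (Kekulé orders; no "aromatic" order survives parsing)
    in_ring: bool = False
    aromatic_origin: bool = False


@dataclass
class Molecule:
    """Connected hydrogen-suppressed molecular graph."""

    atoms: list[Atom]
    bonds: list[Bond]
    name: str | None = None
    smiles: str | None = None
    rings: list[list[int]] = field(default_factory=list)

    @property
    def ring_count(self) -> int:
        """Cyclomatic number |bonds| - |atoms| + 1 of the connected graph."""
        return len(self.bonds) - len(self.atoms) + 1

    @property
    def aromatic_ring_count(self) -> int:
        return sum(1 for ring in self.rings if all(self.atoms[i].aromatic for i in ring))

    def neighbors(self, idx: int) -> list[int]:
        out = []
        for b in self.bonds:
            if b.atom_i == idx:
                out.append(b.atom_j)
            elif b.atom_j == idx:
                out.append(b.atom_i)
        return out

    def bonds_at(self, idx: int) -> list[Bond]:
        return [b for b in self.bonds if idx in (b.atom_i, b.atom_j)]

    def degree(self, idx: int) -> int:
        return len(self.neighbors(idx))

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element)
        for b in self.bonds:
            g.add_edge(b.atom_i, b.atom_j, order=b.order)
        return g


_ORGANIC_UPPER = ("Cl", "Br", "C", "N", "O", "F", "I")
_AROMATIC_LOWER = {"c": "C", "n": "N", "o": "O"}
_BOND_ORDERS = {"-": 1, "=": 2, "#": 3}


def _tokenize(smiles: str):
    """Yield (kind, value, position) tokens for the supported subset."""
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if smiles.startswith("Cl", i) or smiles.startswith("Br", i):
            yield "atom", smiles[i : i + 2], i
            i += 2
        elif ch in "CNOFI":
            yield "atom", ch, i
            i += 1
        elif ch in _AROMATIC_LOWER:
            yield "aromatic_atom", ch, i
            i += 1
        elif ch in "-=#":
            yield "bond", ch, i
            i += 1
        elif ch == "(":
            yield "open", ch, i
            i += 1
        elif ch == ")":
            yield "close", ch, i
            i += 1
        elif ch.isdigit():
            yield "ring", ch, i
            i += 1
        elif ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesParseError("malformed %nn ring closure", smiles, i)
            yield "ring", smiles[i + 1 : i + 3], i
            i += 3
        else:
            raise SmilesParseError(f"unsupported token {ch!r}", smiles, i)


def _kekulize(aromatic_atoms: set[int], aromatic_edges: list[tuple[int, int]]) -> set[frozenset]:
    """Assign a Kekulé perfect matching on the aromatic subgraph.

    Deterministic: depth-first search that always extends from the lowest
    unmatched atom index, trying neighbours in index order.  Every aromatic
    atom must end up in exactly one double bond; for benzenoid systems all
    valid assignments yield identical descriptor values downstream.
    """
    adj: dict[int, list[int]] = {a: [] for a in aromatic_atoms}
    for i, j in aromatic_edges:
        adj[i].append(j)
        adj[j].append(i)
    for nbrs in adj.values():
        nbrs.sort()

    def match(unmatched: frozenset) -> set[frozenset] | None:
        if not unmatched:
            return set()
        a = min(unmatched)
        for b in adj[a]:
            if b in unmatched:
                rest = match(unmatched - {a, b})
                if rest is not None:
                    rest.add(frozenset((a, b)))
                    return rest
        return None

    result = match(frozenset(aromatic_atoms))
    if result is None:
        raise KekulizationError(
            "no alternating Kekulé assignment exists for the aromatic system"
        )
    return result


def parse_smiles(smiles: str, name: str | None = None) -> Molecule:
    """Parse a SMILES string of the supported subset into a :class:`Molecule`.

    Supported: atoms C/N/O/F/Cl/Br/I, aromatic c/n/o, branches, ring-closure
    digits (and ``%nn``), bond symbols ``-``/``=``/``#``.  Anything else —
    brackets, charges, stereo, dots — raises :class:`SmilesParseError`.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES", smiles, 0)
    smiles = smiles.strip()

    elements: list[str] = []
    aromatic_flags: list[bool] = []
    edges: list[list] = []  # [i, j, explicit_order|None, position]
    stack: list[int] = []
    prev: int | None = None
    pending_bond: str | None = None
    pending_pos = 0
    ring_open: dict[str, tuple[int, str | None]] = {}

    for kind, value, pos in _tokenize(smiles):
        if kind in ("atom", "aromatic_atom"):
            idx = len(elements)
            if kind == "aromatic_atom":
                elements.append(_AROMATIC_LOWER[value])
                aromatic_flags.append(True)
            else:
                elements.append(value)
                aromatic_flags.append(False)
            if prev is not None:
                edges.append([prev, idx, pending_bond, pos])
            elif pending_bond is not None:
                raise SmilesParseError("bond symbol with no preceding atom", smiles, pending_pos)
            pending_bond = None
            prev = idx
        elif kind == "bond":
            if pending_bond is not None:
                raise SmilesParseError("consecutive bond symbols", smiles, pos)
            pending_bond = value
            pending_pos = pos
        elif kind == "open":
            if prev is None:
                raise SmilesParseError("branch before any atom", smiles, pos)
            stack.append(prev)
        elif kind == "close":
            if not stack:
                raise SmilesParseError("unmatched ')'", smiles, pos)
            if pending_bond is not None:
                raise SmilesParseError("dangling bond symbol before ')'", smiles, pos)
            prev = stack.pop()
        elif kind == "ring":
            if prev is None:
                raise SmilesParseError("ring closure before any atom", smiles, pos)
            if value in ring_open:
                start, open_bond = ring_open.pop(value)
                order = pending_bond if pending_bond is not None else open_bond
                if start == prev:
                    raise SmilesParseError("ring closure to the same atom", smiles, pos)
                edges.append([start, prev, order, pos])
                pending_bond = None
            else:
                ring_open[value] = (prev, pending_bond)
                pending_bond = None

    if stack:
        raise SmilesParseError("unmatched '('", smiles, len(smiles) - 1)
    if ring_open:
        num = next(iter(ring_open))
        raise SmilesParseError(f"unclosed ring bond {num!r}", smiles, len(smiles) - 1)
    if pending_bond is not None:
        raise SmilesParseError("dangling bond symbol", smiles, pending_pos)
    if not elements:
        raise SmilesParseError("no atoms found", smiles, 0)

    n_atoms = len(elements)
    seen = set()
    for i, j, _, pos in edges:
        key = frozenset((i, j))
        if key in seen:
            raise SmilesParseError("duplicate bond", smiles, pos)
        seen.add(key)

    # connectivity (the subset has no '.', so disconnection only arises
    # from pathological inputs, but check anyway)
    g = nx.Graph()
    g.add_nodes_from(range(n_atoms))
    g.add_edges_from((i, j) for i, j, _, _ in edges)
    if n_atoms > 1 and not nx.is_connected(g):
        raise ConnectivityError(f"disconnected molecular graph in {smiles!r}")

    # Kekulize the aromatic subsystem
    aromatic_atoms = {i for i in range(n_atoms) if aromatic_flags[i]}
    aromatic_edges = [
        (i, j)
        for i, j, order, _ in edges
        if order is None and i in aromatic_atoms and j in aromatic_atoms
    ]
    double_edges: set[frozenset] = set()
    if aromatic_atoms:
        covered = {a for e in aromatic_edges for a in e}
        if covered != aromatic_atoms:
            raise KekulizationError(
                f"isolated aromatic atom(s) {sorted(aromatic_atoms - covered)} in {smiles!r}"
            )
        double_edges = _kekulize(aromatic_atoms, aromatic_edges)

    aromatic_edge_keys = {frozenset(e) for e in aromatic_edges}
    bridges = set(frozenset(e) for e in nx.bridges(g)) if edges else set()

    bonds = []
    order_sum = [0] * n_atoms
    for i, j, order, pos in edges:
        key = frozenset((i, j))
        if key in aromatic_edge_keys:
            o = 2 if key in double_edges else 1
            aromatic_origin = True
        else:
            o = _BOND_ORDERS[order] if order is not None else 1
            aromatic_origin = False
        bonds.append(
            Bond(atom_i=i, atom_j=j, order=o, in_ring=key not in bridges,
                 aromatic_origin=aromatic_origin)
        )
        order_sum[i] += o
        order_sum[j] += o

    atoms = []
    for i, el in enumerate(elements):
        h = STANDARD_VALENCE[el] - order_sum[i]
        if h < 0:
            raise ValenceError(
                f"atom {i} ({el}) exceeds its standard valence "
                f"{STANDARD_VALENCE[el]} in {smiles!r}"
            )
        atoms.append(Atom(index=i, element=el, implicit_h=h, aromatic=aromatic_flags[i]))

    rings = [sorted(r) for r in nx.minimum_cycle_basis(g)]
    rings.sort()
    return Molecule(atoms=atoms, bonds=bonds, name=name, smiles=smiles, rings=rings)


def hill_formula(mol: Molecule) -> str:
    """Molecular formula in Hill order (C, H, then other elements A-Z)."""
    counts: dict[str, int] = {}
    h = 0
    for a in mol.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
        h += a.implicit_h
    if h:
        counts["H"] = counts.get("H", 0) + h

    def fmt(el: str) -> str:
        c = counts[el]
        return el if c == 1 else f"{el}{c}"

    parts = []
    for el in ("C", "H"):
        if el in counts:
            parts.append(fmt(el))
            del counts[el]
    parts.extend(fmt(el) for el in sorted(counts))
    return "".join(parts)


def molecular_weight(mol: Molecule) -> float:
    """Molecular weight in g/mol from standard atomic weights (implicit H included)."""
    w = sum(ATOMIC_WEIGHT[a.element] + a.implicit_h * ATOMIC_WEIGHT["H"] for a in mol.atoms)
    return w
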