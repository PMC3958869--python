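"""Molecular descriptors driving the PDMS-water partition model.

Three structure-derived quantities are computed from a hydrogen-suppressed
:class:`~spmekfw.molgraph.Molecule`:

Φ (additive polarizability)
    A group-contribution estimate of molecular polarizability: the dot
    product of atom/bond feature counts with tabulated contribution
    factors.  Aromatic rings enter as three double-bond terms each and no
    cycle term; non-aromatic rings contribute the cycle term.  All
    hydrogens — including O-H and N-H — are counted by default, and
    hydroxyl oxygens take the plain oxygen factor; both conventions are
    forced by back-calculation against the published compound tables and
    can be overridden on the :class:`PolarizabilityScheme`.

¹χ (first-order valence molecular connectivity index)
    The Randić-type bond sum Σ (δᵢ·δⱼ)^-1/2 with Kier-Hall valence deltas:
    δ = (valence electrons − attached hydrogens) for second-row atoms, with
    the higher-row ratio δ = (Zv − h)/(Z − Zv − 1) for Cl, Br and I.
    Bond order never enters the first-order index directly; multiple bonds
    act only through the reduced hydrogen counts.

I (hydrogen-bonding indicator)
    1 when an electronegative atom (N, O, halogen) is attached to a carbon
    that itself carries hydrogen, when the molecule is acetylenic (C≡C), or
    when an aromatic carbon still carries hydrogen; 0 otherwise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

from .molgraph import Atom, Molecule, molecular_weight

__all__ = [
    "DescriptorError",
    "FeatureCounts",
    "PolarizabilityScheme",
    "DescriptorSet",
    "TABLE_FACTORS",
    "default_scheme",
    "valence_delta",
    "chi1",
    "count_features",
    "polarizability",
    "indicator",
    "compute_descriptors",
]

ELECTRONEGATIVE = {"N", "O", "F", "Cl", "Br", "I"}

#: published atom/bond contribution factors for the polarizability scheme
TABLE_FACTORS: dict[str, float] = {
    "carbon": 0.577,
    "hydrogen": -0.120,
    "oxygen": -0.825,
    "hydroxyl": -3.701,
    "chlorine": -0.187,
    "bromine": -0.222,
    "iodine": 0.407,
    "fluorine": -0.570,
    "cycle": -0.952,
    "double_bond": -0.859,
    "triple_bond": -0.109,
    # the published table has no nitrogen row; back-calculation of
    # benzonitrile (0.753) and 4-chloroaniline (-0.022) shows N contributes 0
    "nitrogen": 0.0,
}

_FEATURE_FIELDS = {
    "carbon": "n_carbon",
    "hydrogen": "n_hydrogen",
    "oxygen": "n_oxygen_ether_or_carbonyl",
    "hydroxyl": "n_hydroxyl",
    "nitrogen": "n_nitrogen",
    "chlorine": "n_chlorine",
    "bromine": "n_bromine",
    "iodine": "n_iodine",
    "fluorine": "n_fluorine",
    "cycle": "n_cycle",
    "double_bond": "n_double_bond",
    "triple_bond": "n_triple_bond",
}


class DescriptorError(ValueError):
    """A descriptor cannot be computed for the given molecule."""


@dataclass(frozen=True)
class FeatureCounts:
    """Atom/bond multiplicities consumed by the polarizability scheme."""

    n_carbon: int = 0
    n_hydrogen: int = 0
    n_oxygen_ether_or_carbonyl: int = 0
    n_hydroxyl: int = 0
    n_nitrogen: int = 0
    n_chlorine: int = 0
    n_bromine: int = 0
    n_iodine: int = 0
    n_fluorine: int = 0
    n_cycle: int = 0
    n_double_bond: int = 0
    n_triple_bond: int = 0

    def as_dict(self) -> dict[str, int]:
        return {feat: getattr(self, attr) for feat, attr in _FEATURE_FIELDS.items()}


@dataclass(frozen=True)
class PolarizabilityScheme:
    """Contribution factors plus the counting conventions they are used with.

    The defaults reproduce the published compound tables:

    - ``aromatic_ring_counts_cycle=False``: an aromatic ring contributes
      three double-bond terms and no cycle term.
    - ``count_heteroatom_hydrogens=True``: O-H and N-H hydrogens are
      counted (the published factor table's footnote claims carbon-attached
      only, but the printed Φ of the benzylic alcohols, cresols and
      chlorophenols back-calculate only when all hydrogens count).
    - ``hydroxyl_uses_own_factor=False``: hydroxyl oxygens take the plain
      oxygen factor; set True for the literal factor-table behaviour.
    """

    factors: dict[str, float] = field(default_factory=lambda: dict(TABLE_FACTORS))
    aromatic_ring_counts_cycle: bool = False
    count_heteroatom_hydrogens: bool = True
    hydroxyl_uses_own_factor: bool = False

    def with_factors(self, **overrides: float) -> "PolarizabilityScheme":
        unknown = set(overrides) - set(_FEATURE_FIELDS)
        if unknown:
            raise DescriptorError(f"unknown polarizability feature(s): {sorted(unknown)}")
        return replace(self, factors={**self.factors, **overrides})

    @classmethod
    def from_file(cls, path) -> "PolarizabilityScheme":
        """Load factor overrides from a JSON mapping feature -> factor."""
        with open(path) as fh:
            overrides = json.load(fh)
        return cls().with_factors(**{k: float(v) for k, v in overrides.items()})


def default_scheme() -> PolarizabilityScheme:
    return PolarizabilityScheme()


@dataclass(frozen=True)
class DescriptorSet:
    """Per-compound regression design variables."""

    phi: float
    chi1: float
    indicator: int
    mw: float | None = None
    ws: float | None = None
    log_kow: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {"phi": self.phi, "chi1": self.chi1, "indicator": self.indicator}
        for k in ("mw", "ws", "log_kow"):
            v = getattr(self, k)
            if v is not None:
                d[k] = v
        return d


def valence_delta(mol: Molecule, atom: Atom | int) -> float:
    """Kier-Hall valence delta of an atom.

    Second-row atoms (and F): δ = Zv − h.  Higher-row halogens use the
    ratio (Zv − h)/(Z − Zv − 1), which is what reproduces the published
    connectivity indices of chlorobenzene (2.477) and bromobenzene (2.891).
    """
    if isinstance(atom, int):
        atom = mol.atoms[atom]
    el = atom.element
    if el in ("C", "N", "O", "F"):
        return float(atom.valence_electrons - atom.implicit_h)
    if el in ("Cl", "Br", "I"):
        zv = atom.valence_electrons
        return (zv - atom.implicit_h) / (atom.atomic_number - zv - 1)
    raise DescriptorError(f"no valence delta defined for element {el!r}")


def chi1(mol: Molecule) -> float:
    """First-order valence connectivity index Σ_bonds (δᵢ·δⱼ)^-0.5.

    Each bond enters once regardless of its order.  A molecule with no
    bonds (methane) has ¹χ = 0 by the empty sum.
    """
    deltas = [valence_delta(mol, a) for a in mol.atoms]
    bonded = {b.atom_i for b in mol.bonds} | {b.atom_j for b in mol.bonds}
    for a, d in zip(mol.atoms, deltas):
        if d <= 0 and a.index in bonded:
            raise DescriptorError(
                f"non-positive delta {d} for atom {a.index} ({a.element})"
            )
    return sum(1.0 / math.sqrt(deltas[b.atom_i] * deltas[b.atom_j]) for b in mol.bonds)


def _is_hydroxyl(mol: Molecule, atom: Atom) -> bool:
    return atom.element == "O" and mol.degree(atom.index) == 1 and atom.implicit_h == 1


def count_features(mol: Molecule, scheme: PolarizabilityScheme | None = None) -> FeatureCounts:
    """Tally the atom/bond features of the polarizability scheme.

    Hydroxyl oxygens (one heavy neighbour, one hydrogen) are counted apart
    from ether/carbonyl oxygens; which factor they receive is decided by
    the scheme at dot-product time.  Aromatic rings contribute three
    double-bond terms each; non-aromatic rings contribute the cycle term.
    """
    scheme = scheme or default_scheme()
    counts = dict.fromkeys(_FEATURE_FIELDS.values(), 0)
    element_field = {
        "C": "n_carbon",
        "N": "n_nitrogen",
        "Cl": "n_chlorine",
        "Br": "n_bromine",
        "I": "n_iodine",
        "F": "n_fluorine",
    }
    for a in mol.atoms:
        if a.element == "O":
            key = "n_hydroxyl" if _is_hydroxyl(mol, a) else "n_oxygen_ether_or_carbonyl"
            counts[key] += 1
        else:
            counts[element_field[a.element]] += 1
        if a.element == "C" or scheme.count_heteroatom_hydrogens:
            counts["n_hydrogen"] += a.implicit_h

    n_aromatic = mol.aromatic_ring_count
    counts["n_double_bond"] = 3 * n_aromatic + sum(
        1 for b in mol.bonds if b.order == 2 and not b.aromatic_origin
    )
    counts["n_triple_bond"] = sum(1 for b in mol.bonds if b.order == 3)
    counts["n_cycle"] = mol.ring_count if scheme.aromatic_ring_counts_cycle else mol.ring_count - n_aromatic
    return FeatureCounts(**counts)


def polarizability(mol: Molecule, scheme: PolarizabilityScheme | None = None) -> float:
    """Additive polarizability Φ: feature counts dotted with contribution factors."""
    scheme = scheme or default_scheme()
    fc = count_features(mol, scheme)
    total = 0.0
    for feature, count in fc.as_dict().items():
        if count == 0:
            continue
        if feature == "hydroxyl" and not scheme.hydroxyl_uses_own_factor:
            feature = "oxygen"
        if feature not in scheme.factors:
            raise DescriptorError(f"no contribution factor for feature {feature!r}")
        total += scheme.factors[feature] * count
    return total


def indicator(mol: Molecule) -> int:
    """Hydrogen-bonding indicator variable I ∈ {0, 1}."""
    by_index = {a.index: a for a in mol.atoms}
    for b in mol.bonds:
        ai, aj = by_index[b.atom_i], by_index[b.atom_j]
        for het, c in ((ai, aj), (aj, ai)):
            if het.element in ELECTRONEGATIVE and c.element == "C" and c.implicit_h > 0:
                return 1
        if b.order == 3 and ai.element == "C" and aj.element == "C":
            return 1
    for a in mol.atoms:
        if a.aromatic and a.element == "C" and a.implicit_h > 0:
            return 1
    return 0


def compute_descriptors(
    mol: Molecule,
    scheme: PolarizabilityScheme | None = None,
    ws: float | None = None,
    log_kow: float | None = None,
) -> DescriptorSet:
    """Assemble the full descriptor set for one molecule.

    Water solubility and log Kow are experimental quantities, consumed as
    pass-through inputs, never computed.
    """
    return DescriptorSet(
        phi=polarizability(mol, scheme),
        chi1=chi1(mol),
        indicator=indicator(mol),
        mw=molecular_weight(mol),
        ws=ws,
        log_kow=log_kow,
    )
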