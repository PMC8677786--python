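"""Molecular graphs, ECFP fingerprints and Tanimoto similarity.

This is the descriptor layer of the pipeline: compounds enter as SMILES
strings, are held as light-weight heavy-atom graphs, and are described by
extended connectivity fingerprints (ECFP) — binary vectors whose set bits
flag hashed circular substructures.  Similarity between fingerprints is
measured with the Tanimoto coefficient.

SMILES interpretation is delegated to RDKit behind :func:`parse_smiles`;
the ECFP iteration itself (atom invariants, neighbourhood hashing, folding)
is implemented here so that intermediate identifier sets are inspectable
and the hash is platform-independent.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from rdkit import Chem, RDLogger

RDLogger.DisableLog("rdApp.error")

#: bond-order token used for aromatic bonds (kept distinct from Kekulé 1/2
#: alternation so fingerprints are invariant under atom relabelling)
AROMATIC = 1.5

_BOND_ORDERS = {
    Chem.BondType.SINGLE: 1,
    Chem.BondType.DOUBLE: 2,
    Chem.BondType.TRIPLE: 3,
    Chem.BondType.AROMATIC: AROMATIC,
}

_ORDER_TOKEN = {1: "1", 2: "2", 3: "3", AROMATIC: "ar"}


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be interpreted."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element, formal charge, attached-H count, ring flag."""

    element: str
    charge: int = 0
    n_h: int = 0
    in_ring: bool = False


@dataclass(frozen=True)
class Bond:
    """An undirected bond between atom indices ``a`` and ``b``."""

    a: int
    b: int
    order: float = 1


@dataclass(frozen=True)
class Molecule:
    """Heavy-atom molecular graph.

    Invariants (checked on construction): bond endpoints are valid atom
    indices, no self-bonds, no duplicate bonds.
    """

    atoms: tuple[Atom, ...]
    bonds: tuple[Bond, ...]
    id: str = ""
    source_text: Optional[str] = None

    def __post_init__(self) -> None:
        n = len(self.atoms)
        seen: set[tuple[int, int]] = set()
        for bond in self.bonds:
            if not (0 <= bond.a < n and 0 <= bond.b < n):
                raise ValueError(f"bond endpoint out of range: {bond}")
            if bond.a == bond.b:
                raise ValueError(f"self-bond on atom {bond.a}")
            key = (min(bond.a, bond.b), max(bond.a, bond.b))
            if key in seen:
                raise ValueError(f"duplicate bond {key}")
            seen.add(key)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbors(self, i: int) -> list[tuple[int, float]]:
        """(neighbor index, bond order) pairs of atom ``i``."""
        out = []
        for bond in self.bonds:
            if bond.a == i:
                out.append((bond.b, bond.order))
            elif bond.b == i:
                out.append((bond.a, bond.order))
        return out

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))


@dataclass(frozen=True)
class Fingerprint:
    """Folded binary ECFP: set-bit positions in ``[0, nbits)``."""

    nbits: int
    bits: frozenset[int]
    radius: int

    def __post_init__(self) -> None:
        if self.nbits < 1:
            raise ValueError("nbits must be positive")
        if any(b < 0 or b >= self.nbits for b in self.bits):
            raise ValueError("bit position out of range")

    def to_hex(self) -> str:
        """Hex-encoded bit vector (bit 0 = most significant bit of byte 0)."""
        nbytes = (self.nbits + 7) // 8
        buf = bytearray(nbytes)
        for b in self.bits:
            buf[b // 8] |= 0x80 >> (b % 8)
        return bytes(buf).hex()

    @classmethod
    def from_hex(cls, text: str, nbits: int, radius: int) -> "Fingerprint":
        raw = bytes.fromhex(text)
        bits = frozenset(
            i for i in range(nbits) if raw[i // 8] & (0x80 >> (i % 8))
        )
        return cls(nbits=nbits, bits=bits, radius=radius)


def _prescan_smiles(text: str) -> None:
    """Cheap structural scan that reports the offending position for the
    error classes RDKit does not localise: unclosed branches, unbalanced
    ring-closure digits, unterminated bracket atoms."""
    open_parens: list[int] = []
    ring_open: dict[str, int] = {}
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            end = text.find("]", i)
            if end < 0:
                raise SmilesParseError(
                    f"unterminated bracket atom at position {i}: {text!r}"
                )
            i = end + 1
            continue
        if ch == "(":
            open_parens.append(i)
        elif ch == ")":
            if not open_parens:
                raise SmilesParseError(
                    f"unmatched ')' at position {i}: {text!r}"
                )
            open_parens.pop()
        elif ch == "%":
            token = text[i + 1 : i + 3]
            if len(token) < 2 or not token.isdigit():
                raise SmilesParseError(
                    f"malformed %nn ring closure at position {i}: {text!r}"
                )
            if token in ring_open:
                ring_open.pop(token)
            else:
                ring_open[token] = i
            i += 3
            continue
        elif ch.isdigit():
            if ch in ring_open:
                ring_open.pop(ch)
            else:
                ring_open[ch] = i
        i += 1
    if open_parens:
        raise SmilesParseError(
            f"unclosed branch opened at position {open_parens[-1]}: {text!r}"
        )
    if ring_open:
        token, pos = next(iter(ring_open.items()))
        raise SmilesParseError(
            f"unclosed ring bond '{token}' opened at position {pos}: {text!r}"
        )


def parse_smiles(text: str, id: str = "") -> Molecule:
    """Parse a SMILES string into a :class:`Molecule`.

    Stereochemistry tokens are accepted and ignored (the fingerprint
    iteration is achiral).  Raises :class:`SmilesParseError` on malformed
    input, naming the offending position where it can be localised.
    """
    if not text:
        raise SmilesParseError("empty SMILES string")
    _prescan_smiles(text)
    rdmol = Chem.MolFromSmiles(text)
    if rdmol is None:
        raise SmilesParseError(f"could not parse SMILES {text!r}")
    atoms = tuple(
        Atom(
            element=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            n_h=a.GetTotalNumHs(),
            in_ring=a.IsInRing(),
        )
        for a in rdmol.GetAtoms()
    )
    bonds = []
    for b in rdmol.GetBonds():
        order = _BOND_ORDERS.get(b.GetBondType())
        if order is None:
            raise SmilesParseError(
                f"unsupported bond type {b.GetBondType()} in {text!r}"
            )
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return Molecule(atoms=atoms, bonds=tuple(bonds), id=id, source_text=text)


def _stable_hash(data: str) -> int:
    """64-bit platform-independent hash (blake2b of the UTF-8 bytes)."""
    digest = hashlib.blake2b(data.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big")


def atom_invariant(mol: Molecule, atom_index: int) -> int:
    """Initial (iteration-0) ECFP identifier of an atom.

    Deterministic hash of (element, heavy-atom degree, attached-H count,
    formal charge, ring flag): equal tuples yield equal invariants.
    """
    if not (0 <= atom_index < mol.n_atoms):
        raise IndexError(f"atom index {atom_index} out of range")
    a = mol.atoms[atom_index]
    key = f"{a.element}|{mol.degree(atom_index)}|{a.n_h}|{a.charge}|{int(a.in_ring)}"
    return _stable_hash(key)


def unfolded_identifiers(mol: Molecule, radius: int) -> set[int]:
    """All neighbourhood identifiers from iterations 0..radius (pre-folding).

    Monotone in radius: the set at radius r is a subset of the set at r+1.
    """
    if mol.n_atoms == 0:
        raise ValueError("empty molecule")
    if radius < 0:
        raise ValueError("radius must be non-negative")
    ids = [atom_invariant(mol, i) for i in range(mol.n_atoms)]
    collected: set[int] = set(ids)
    neighbors = [mol.neighbors(i) for i in range(mol.n_atoms)]
    for r in range(1, radius + 1):
        new_ids = []
        for i in range(mol.n_atoms):
            env = sorted((_ORDER_TOKEN[order], ids[j]) for j, order in neighbors[i])
            new_ids.append(_stable_hash(f"{r}|{ids[i]}|{env}"))
        ids = new_ids
        collected.update(ids)
    return collected


def ecfp(mol: Molecule, radius: int = 2, nbits: int = 2048) -> Fingerprint:
    """Extended connectivity fingerprint of a molecule.

    Iteration 0 assigns each atom its :func:`atom_invariant`; iteration r
    re-hashes each atom's previous identifier together with the sorted
    (bond-order token, neighbour identifier) list.  Identifiers from all
    iterations are folded into ``[0, nbits)`` by modulo.  Duplicate
    substructure environments are not removed; folding into a binary
    vector collapses them.  Invariant under atom relabelling.
    """
    if nbits < 2:
        raise ValueError("nbits must be >= 2")
    identifiers = unfolded_identifiers(mol, radius)
    return Fingerprint(
        nbits=nbits,
        bits=frozenset(h % nbits for h in identifiers),
        radius=radius,
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A∩B| / |A∪B| of two fingerprints.

    Both-empty fingerprints return 0.0 by convention.
    """
    if a.nbits != b.nbits:
        raise ValueError(f"nbits mismatch: {a.nbits} != {b.nbits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def compound_key(fp: Fingerprint) -> str:
    """Canonical hashable identity key of a fingerprint.

    Equal fingerprints (same parameters and bits) map to equal keys; the
    key is stable across processes (no dependence on hash randomisation).
    """
    return f"r{fp.radius}n{fp.nbits}:{fp.to_hex()}"


@dataclass(frozen=True)
class ReferenceDrug:
    """One entry of a reference panel: a named, fingerprinted drug."""

    name: str
    molecule: Molecule
    fingerprint: Fingerprint
    approved: bool = True
    in_training: bool = False


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered panel of reference drugs; order is the grouping tie-break."""

    entries: tuple[ReferenceDrug, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(names) != len(set(names)):
            raise ValueError("reference drug names must be unique")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ReferenceDrug]:
        return iter(self.entries)

    @classmethod
    def from_smiles(
        cls,
        rows: Iterable[tuple[str, str, bool, bool]],
        radius: int = 2,
        nbits: int = 2048,
    ) -> "ReferenceSet":
        """Build a panel from (name, smiles, approved, in_training) rows."""
        entries = []
        for name, smiles, approved, in_training in rows:
            mol = parse_smiles(smiles, id=name)
            entries.append(
                ReferenceDrug(
                    name=name,
                    molecule=mol,
                    fingerprint=ecfp(mol, radius=radius, nbits=nbits),
                    approved=bool(approved),
                    in_training=bool(in_training),
                )
            )
        return cls(entries=tuple(entries))
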