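"""Hydrogen-suppressed molecular graphs and atom categorisation.

The electrotopological descriptor operates on the heavy-atom skeleton of a
molecule: atoms are indexed 1..n, bonds are unordered index pairs, and
hydrogens never appear explicitly.  Structures are read with RDKit from
SMILES or MDL MOL/SDF records; the graph kept here is deliberately minimal
(elements, adjacency, optional bond orders and lengths) because the
descriptor itself only consumes adjacency plus externally supplied
electronic-state data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

__all__ = [
    "MoleculeGraph",
    "AtomRole",
    "CarbonCategory",
    "StructureFormatError",
    "DisconnectedStructureError",
    "parse_structure",
    "parse_smiles_file",
    "parse_sdf_file",
    "classify_atoms",
    "neighbors",
    "to_molblock",
]

RDLogger.DisableLog("rdApp.*")


class StructureFormatError(ValueError):
    """Raised when a structure record cannot be parsed."""


class DisconnectedStructureError(ValueError):
    """Raised for multi-fragment inputs; the index is defined for single molecules."""


class CarbonCategory(str, Enum):
    CH3 = "CH3"
    CH2 = "CH2"
    CH = "CH"
    C_QUATERNARY = "C_quaternary"
    HETEROATOM = "heteroatom"


@dataclass(frozen=True)
class AtomRole:
    """Category of one heavy atom.

    Saturated-carbon categories follow heavy-neighbour count (1 -> CH3,
    2 -> CH2, 3 -> CH, 4 -> quaternary); any non-carbon atom is a
    heteroatom.  ``hetero_adjacent`` additionally marks carbons bonded to
    at least one heteroatom — those are the atoms whose SET values are
    scaled by the dipolar function.
    """

    index: int
    category: CarbonCategory
    hetero_adjacent: bool = False


@dataclass(frozen=True)
class MoleculeGraph:
    """Heavy-atom labelled graph with 1-based contiguous indices."""

    elements: tuple[str, ...]
    bonds: frozenset[frozenset[int]]
    bond_orders: Mapping[frozenset[int], float] = field(default_factory=dict)
    bond_lengths: Mapping[frozenset[int], float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        n = len(self.elements)
        if n == 0:
            raise ValueError("empty molecule")
        for pair in self.bonds:
            if len(pair) != 2:
                raise ValueError(f"self-bond or malformed bond: {set(pair)}")
            for i in pair:
                if not (1 <= i <= n):
                    raise ValueError(f"bond references unknown atom index {i}")
        if n > 1 and not self._connected():
            raise DisconnectedStructureError(
                "graph is disconnected; mixtures are not supported"
            )

    def _connected(self) -> bool:
        adj = self.adjacency()
        seen = {1}
        stack = [1]
        while stack:
            for j in adj[stack.pop()]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n_atoms

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def atom_indices(self) -> range:
        return range(1, self.n_atoms + 1)

    def element(self, i: int) -> str:
        self._check_index(i)
        return self.elements[i - 1]

    def adjacency(self) -> dict[int, list[int]]:
        adj: dict[int, list[int]] = {i: [] for i in self.atom_indices}
        for pair in self.bonds:
            a, b = sorted(pair)
            adj[a].append(b)
            adj[b].append(a)
        return {i: sorted(v) for i, v in adj.items()}

    def degree(self, i: int) -> int:
        return len(self.neighbors(i))

    def neighbors(self, i: int) -> tuple[int, ...]:
        self._check_index(i)
        out = []
        for pair in self.bonds:
            if i in pair:
                (j,) = set(pair) - {i}
                out.append(j)
        return tuple(sorted(out))

    def _check_index(self, i: int) -> None:
        if not (1 <= i <= self.n_atoms):
            raise KeyError(f"atom index {i} not in 1..{self.n_atoms}")


def _from_rdkit(mol: "Chem.Mol", name: str = "") -> MoleculeGraph:
    mol = Chem.RemoveHs(mol, sanitize=False)
    frags = Chem.GetMolFrags(mol)
    if len(frags) > 1:
        raise DisconnectedStructureError(
            f"structure {name or '<unnamed>'} has {len(frags)} fragments; "
            "mixtures are not supported"
        )
    heavy = [a for a in mol.GetAtoms() if a.GetAtomicNum() != 1]
    elements = tuple(a.GetSymbol() for a in heavy)
    # RDKit indices are 0-based; the descriptor convention is 1-based.
    remap = {a.GetIdx(): k + 1 for k, a in enumerate(heavy)}
    bonds = set()
    orders: dict[frozenset[int], float] = {}
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if i in remap and j in remap:
            pair = frozenset((remap[i], remap[j]))
            bonds.add(pair)
            orders[pair] = float(b.GetBondTypeAsDouble())
    return MoleculeGraph(
        elements=elements, bonds=frozenset(bonds), bond_orders=orders, name=name
    )


def parse_structure(record: str, fmt: str = "smiles", name: str = "") -> MoleculeGraph:
    """Parse one structure record into a :class:`MoleculeGraph`.

    Parameters
    ----------
    record:
        SMILES string or an MDL MOL block (V2000).
    fmt:
        ``"smiles"`` or ``"mol"``.
    """
    fmt = fmt.lower()
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(record)
    elif fmt in ("mol", "sdf", "molblock"):
        mol = Chem.MolFromMolBlock(record, sanitize=True)
    else:
        raise ValueError(f"unknown structure format {fmt!r}")
    if mol is None:
        raise StructureFormatError(
            f"could not parse {fmt} record: {record.splitlines()[0][:80]!r}"
        )
    return _from_rdkit(mol, name=name)


def parse_smiles_file(path) -> list[MoleculeGraph]:
    """Read a SMILES file: one molecule per line, optional name after whitespace."""
    graphs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else ""
            graphs.append(parse_structure(smiles, "smiles", name=name))
    return graphs


def parse_sdf_file(path) -> list[MoleculeGraph]:
    """Read a multi-record MDL SDF (V2000) file record-by-record."""
    graphs = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for k, mol in enumerate(supplier):
        if mol is None:
            raise StructureFormatError(f"unparseable SDF record #{k + 1} in {path}")
        name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
        graphs.append(_from_rdkit(mol, name=name))
    return graphs


def to_molblock(g: MoleculeGraph) -> str:
    """Serialise a graph back to an MDL MOL block (heavy atoms only)."""
    mol = Chem.RWMol()
    for sym in g.elements:
        atom = Chem.Atom(sym)
        atom.SetNoImplicit(False)
        mol.AddAtom(atom)
    for pair in g.bonds:
        a, b = sorted(pair)
        order = g.bond_orders.get(pair, 1.0)
        bt = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
              3.0: Chem.BondType.TRIPLE}.get(order, Chem.BondType.SINGLE)
        mol.AddBond(a - 1, b - 1, bt)
    m = mol.GetMol()
    Chem.SanitizeMol(m)
    if g.name:
        m.SetProp("_Name", g.name)
    return Chem.MolToMolBlock(m)


def neighbors(g: MoleculeGraph, i: int) -> tuple[int, ...]:
    """Sorted heavy-atom neighbours of atom ``i``."""
    return g.neighbors(i)


def classify_atoms(g: MoleculeGraph) -> list[AtomRole]:
    """Assign each heavy atom its carbon/heteroatom category.

    Carbons are binned by heavy-neighbour count; every non-carbon heavy
    atom is a heteroatom.  Carbons bonded to a heteroatom carry the
    ``hetero_adjacent`` flag on top of their carbon category — that flag
    defines the default set of atoms whose SET values receive the dipolar
    scaling.
    """
    roles: list[AtomRole] = []
    # degree 0 (an isolated carbon, e.g. methane's heavy skeleton) is binned
    # with the terminal CH3 carbons
    by_degree = {0: CarbonCategory.CH3, 1: CarbonCategory.CH3,
                 2: CarbonCategory.CH2, 3: CarbonCategory.CH,
                 4: CarbonCategory.C_QUATERNARY}
    for i in g.atom_indices:
        if g.element(i) != "C":
            roles.append(AtomRole(i, CarbonCategory.HETEROATOM))
            continue
        deg = g.degree(i)
        if deg not in by_degree:
            raise ValueError(f"carbon atom {i} has unsupported heavy degree {deg}")
        adj_het = any(g.element(j) != "C" for j in g.neighbors(i))
        roles.append(AtomRole(i, by_degree[deg], hetero_adjacent=adj_het))
    return roles


def heteroatoms(g: MoleculeGraph) -> tuple[int, ...]:
    """Indices of all non-carbon heavy atoms."""
    return tuple(i for i in g.atom_indices if g.element(i) != "C")


def dipole_scaled_atoms(g: MoleculeGraph) -> frozenset[int]:
    """Default dipole-scaled set: heteroatoms plus carbons bonded to one."""
    het = set(heteroatoms(g))
    scaled = set(het)
    for i in g.atom_indices:
        if g.element(i) == "C" and any(j in het for j in g.neighbors(i)):
            scaled.add(i)
    return frozenset(scaled)
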