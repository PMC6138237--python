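"""Molecular graphs with pharmacophore-point typing.

SMILES strings are parsed (via RDKit) into a light-weight
:class:`MolecularGraph` — an ordered list of heavy atoms plus a bond list —
on which the rest of the package operates.  Each atom can then be labelled
with a subset of six pharmacophore-point (PPP) roles:

===== =======================================
label meaning
===== =======================================
``D`` hydrogen-bond donor
``A`` hydrogen-bond acceptor
``P`` positively ionizable (basic / cationic)
``N`` negatively ionizable (acidic / anionic)
``L`` lipophilic
``R`` aromatic
===== =======================================

The typing rules are deterministic functions of the 2D graph (element,
formal charge, aromaticity, hydrogen count and bonded neighbourhood); no
pH-dependent protonation-state enumeration is performed — molecules are
typed as written.  An atom may carry several labels (an aromatic carbon
with only carbon neighbours is both aromatic and lipophilic, ``{R, L}``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from rdkit import Chem, rdBase

__all__ = [
    "Atom",
    "MolecularGraph",
    "TypedMolecule",
    "SmilesParseError",
    "PPP_LABELS",
    "parse_smiles",
    "assign_ppp",
    "shortest_path_matrix",
    "heavy_atom_count",
    "read_smi",
    "write_smi",
]

#: The closed six-letter pharmacophore-point alphabet, in canonical order.
PPP_LABELS = ("D", "A", "P", "N", "L", "R")

# Route RDKit's C++ log to the python logging module so parse failures can
# be reported with the toolkit's token-position diagnostics.
rdBase.LogToPythonLogger()
_rdkit_logger = logging.getLogger("rdkit")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Atom:
    """A heavy atom: element, charge, aromatic flag and implicit H count."""

    element: str
    formal_charge: int = 0
    aromatic: bool = False
    implicit_h: int = 0

    def __post_init__(self) -> None:
        if self.implicit_h < 0:
            raise ValueError("implicit_h must be non-negative")


@dataclass
class MolecularGraph:
    """Connected heavy-atom graph (largest covalent fragment of the input).

    Bonds are ``(i, j, order)`` triples with ``order`` one of ``1``, ``2``,
    ``3`` or the string ``"aromatic"``.
    """

    atoms: list[Atom]
    bonds: list[tuple[int, int, object]]
    identifier: str = ""

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if n < 1:
            raise ValueError("graph needs at least one heavy atom")
        for i, j, _order in self.bonds:
            if i == j or not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"invalid bond endpoints ({i}, {j})")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def neighbours(self, idx: int) -> list[tuple[int, object]]:
        """Bonded (neighbour index, bond order) pairs of atom ``idx``."""
        out = []
        for i, j, order in self.bonds:
            if i == idx:
                out.append((j, order))
            elif j == idx:
                out.append((i, order))
        return out


@dataclass
class TypedMolecule:
    """A molecular graph plus per-atom pharmacophore-point label sets."""

    graph: MolecularGraph
    ppp: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ppp) != self.graph.n_atoms:
            raise ValueError("one label set per atom required")
        alphabet = set(PPP_LABELS)
        for labels in self.ppp:
            if not set(labels) <= alphabet:
                raise ValueError(f"labels outside {PPP_LABELS}: {set(labels)}")

    @property
    def identifier(self) -> str:
        return self.graph.identifier

    def label_counts(self) -> dict[str, int]:
        """Number of atoms carrying each label (an atom may count twice)."""
        return {
            lab: sum(1 for s in self.ppp if lab in s) for lab in PPP_LABELS
        }


class _CaptureRDKitLog(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.DEBUG)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def parse_smiles(smiles: str, identifier: str = "") -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Aromaticity is perceived and implicit hydrogens assigned by RDKit's
    default sanitisation.  Multi-fragment inputs (salts, counter-ions) are
    reduced to the largest heavy-atom fragment so that autocorrelation
    descriptors are not corrupted by disconnected components.

    Raises
    ------
    SmilesParseError
        If the string is empty or cannot be parsed; the message carries the
        toolkit diagnostic, which names the offending token position.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    capture = _CaptureRDKitLog()
    _rdkit_logger.addHandler(capture)
    try:
        mol = Chem.MolFromSmiles(smiles)
    finally:
        _rdkit_logger.removeHandler(capture)
    if mol is None:
        detail = "; ".join(capture.messages) or "unparsable SMILES"
        raise SmilesParseError(f"cannot parse {smiles!r}: {detail}")

    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) > 1:
        mol = max(frags, key=lambda m: m.GetNumHeavyAtoms())
    if mol.GetNumHeavyAtoms() < 1:
        raise SmilesParseError(f"no heavy atoms in {smiles!r}")

    atoms = [
        Atom(
            element=a.GetSymbol(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            implicit_h=a.GetTotalNumHs(),
        )
        for a in mol.GetAtoms()
    ]
    order_map = {
        Chem.BondType.SINGLE: 1,
        Chem.BondType.DOUBLE: 2,
        Chem.BondType.TRIPLE: 3,
        Chem.BondType.AROMATIC: "aromatic",
    }
    bonds = []
    for b in mol.GetBonds():
        order = order_map.get(b.GetBondType(), 1)
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=atoms, bonds=bonds, identifier=identifier)


def _neighbour_table(graph: MolecularGraph) -> list[list[tuple[int, object]]]:
    table: list[list[tuple[int, object]]] = [[] for _ in graph.atoms]
    for i, j, order in graph.bonds:
        table[i].append((j, order))
        table[j].append((i, order))
    return table


def _is_carbonyl_carbon(graph, nbrs, idx: int) -> bool:
    """C doubly bonded to O (covers ketone/amide/acid/quinone carbons)."""
    if graph.atoms[idx].element != "C":
        return False
    return any(
        order == 2 and graph.atoms[j].element == "O" for j, order in nbrs[idx]
    )


def _is_acid_core(graph, nbrs, idx: int) -> bool:
    """C/S/P centre of a carboxylic, sulfonic or phosphonic acid group."""
    el = graph.atoms[idx].element
    if el not in ("C", "S", "P"):
        return False
    double_o = sum(
        1
        for j, order in nbrs[idx]
        if order == 2 and graph.atoms[j].element == "O"
    )
    required = {"C": 1, "S": 2, "P": 1}[el]
    return double_o >= required


def assign_ppp(graph: MolecularGraph) -> TypedMolecule:
    """Assign pharmacophore-point labels to every atom.

    Rule table (evaluated independently; an atom may match several):

    * ``D`` — N or O bearing at least one hydrogen.
    * ``A`` — any O that is not positively charged; any N that is not
      positively charged, except aromatic N–H (pyrrole-type, its lone pair
      is in the ring) and non-aromatic N bonded to an aromatic atom or a
      carbonyl carbon (aniline/amide nitrogens are poor acceptors).
    * ``P`` — formal charge > 0, or a non-aromatic all-single-bond N with
      at least one H and no adjacent carbonyl (a basic amine).
    * ``N`` — formal charge < 0; the hydroxyl O of a carboxylic, sulfonic
      or phosphonic acid; or a carbonyl O whose acid centre also bears an
      anionic O (both oxygens of a carboxylate are equivalent by
      delocalisation).
    * ``L`` — Cl, Br, I, S, or a carbon whose bonded heavy neighbours are
      all carbon.
    * ``R`` — any aromatic atom.
    """
    nbrs = _neighbour_table(graph)
    ppp: list[frozenset[str]] = []
    for idx, atom in enumerate(graph.atoms):
        labels: set[str] = set()
        el = atom.element
        n_h = atom.implicit_h
        neigh = nbrs[idx]

        if el in ("N", "O") and n_h >= 1:
            labels.add("D")

        if el == "O" and atom.formal_charge <= 0:
            labels.add("A")
        elif el == "N" and atom.formal_charge <= 0:
            aromatic_nh = atom.aromatic and n_h >= 1
            amide_like = any(
                _is_carbonyl_carbon(graph, nbrs, j) for j, _ in neigh
            )
            aniline_like = not atom.aromatic and any(
                graph.atoms[j].aromatic for j, _ in neigh
            )
            if not (aromatic_nh or amide_like or aniline_like):
                labels.add("A")

        if atom.formal_charge > 0:
            labels.add("P")
        elif (
            el == "N"
            and not atom.aromatic
            and all(order == 1 for _, order in neigh)
            and n_h >= 1
            and not any(_is_carbonyl_carbon(graph, nbrs, j) for j, _ in neigh)
        ):
            labels.add("P")

        if atom.formal_charge < 0:
            labels.add("N")
        elif el == "O":
            for j, order in neigh:
                if not _is_acid_core(graph, nbrs, j):
                    continue
                if order == 1 and n_h >= 1:
                    labels.add("N")  # acid hydroxyl
                elif order == 2 and any(
                    graph.atoms[k].element == "O"
                    and graph.atoms[k].formal_charge < 0
                    for k, _ in nbrs[j]
                ):
                    labels.add("N")  # carboxylate carbonyl O

        if el in ("Cl", "Br", "I", "S"):
            labels.add("L")
        elif el == "C" and all(
            graph.atoms[j].element == "C" for j, _ in neigh
        ):
            labels.add("L")

        if atom.aromatic:
            labels.add("R")

        ppp.append(frozenset(labels))
    return TypedMolecule(graph=graph, ppp=ppp)


def shortest_path_matrix(graph: MolecularGraph) -> np.ndarray:
    """All-pairs topological distances (minimal bond counts).

    Returns an ``n × n`` float matrix with zero diagonal; unreachable pairs
    (which cannot occur after largest-fragment selection) are ``inf``.
    """
    n = graph.n_atoms
    rows, cols = [], []
    for i, j, _order in graph.bonds:
        rows += [i, j]
        cols += [j, i]
    adj = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=float
    )
    return shortest_path(adj, method="D", unweighted=True, directed=False)


def heavy_atom_count(graph: MolecularGraph) -> int:
    """Number of non-hydrogen atoms (hydrogens are implicit throughout)."""
    return graph.n_atoms


def read_smi(path) -> list[tuple[str, str]]:
    """Read a .smi file: one ``SMILES<whitespace>identifier`` per line.

    Lines starting with ``#`` and blank lines are ignored.  A missing
    identifier defaults to the 1-based line number.
    """
    records: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            identifier = parts[1].strip() if len(parts) > 1 else str(lineno)
            records.append((smiles, identifier))
    return records


def write_smi(records, path) -> None:
    """Write ``(smiles, identifier)`` pairs as a .smi file."""
    with open(path, "w", encoding="utf-8") as fh:
        for smiles, identifier in records:
            fh.write(f"{smiles}\t{identifier}\n")
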