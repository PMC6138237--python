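"""CATS2 topological pharmacophore autocorrelation descriptors.

The descriptor combinatorially autocorrelates pharmacophore features within
a molecule: for every unordered pair of pharmacophore-point types and every
topological distance d = 0..10 bonds it counts the atom pairs realising
that (type pair, distance) combination.  With 21 unordered type pairs over
{D, A, P, N, L, R} and 11 distance bins the vector has 231 entries.  The
result is alignment-free and deliberately "fuzzy": molecules with little
substructural overlap can still be neighbours in descriptor space if their
pharmacophore-point geometry matches, which is the property the target-
fishing and affinity-regression stages rely on.

Two scalings are provided: ``raw`` pair counts, and the default
``occurrence`` scaling, which divides each entry by the summed incidence
of the two feature types in the molecule (0 when no atom carries either
type), making vectors comparable across molecules of different size.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations_with_replacement

import numpy as np
import pandas as pd

from .molgraph import (
    PPP_LABELS,
    TypedMolecule,
    assign_ppp,
    parse_smiles,
    shortest_path_matrix,
)

__all__ = [
    "PAIR_TYPES",
    "COLUMN_NAMES",
    "N_FEATURES",
    "MAX_DISTANCE",
    "ScalingMode",
    "CatsVector",
    "compute_cats2",
    "featurize_smiles",
    "featurize_batch",
    "write_descriptor_table",
    "read_descriptor_table",
]

#: The 21 unordered pharmacophore-type pairs, lexicographic in D A P N L R.
PAIR_TYPES = tuple(
    a + b for a, b in combinations_with_replacement(PPP_LABELS, 2)
)

MAX_DISTANCE = 10
N_FEATURES = len(PAIR_TYPES) * (MAX_DISTANCE + 1)  # 231

#: Serialisation layout: pair type major, distance minor ("DD_0" .. "RR_10").
COLUMN_NAMES = tuple(
    f"{pair}_{d}" for pair in PAIR_TYPES for d in range(MAX_DISTANCE + 1)
)


class ScalingMode(str, Enum):
    RAW = "raw"
    OCCURRENCE = "occurrence"


@dataclass
class CatsVector:
    """A 231-entry CATS2 descriptor with its scaling mode."""

    values: np.ndarray
    scaling: ScalingMode = ScalingMode.OCCURRENCE
    identifier: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(
                f"CATS2 vector must have {N_FEATURES} entries, "
                f"got shape {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("CATS2 entries must be finite and non-negative")

    def __getitem__(self, key: str) -> float:
        return float(self.values[COLUMN_NAMES.index(key)])

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(COLUMN_NAMES), name=self.identifier)


def compute_cats2(
    mol: TypedMolecule,
    max_distance: int = MAX_DISTANCE,
    scaling: ScalingMode = ScalingMode.OCCURRENCE,
) -> CatsVector:
    """Compute the CATS2 autocorrelation vector of a typed molecule.

    Entry (t1t2, d) counts unordered atom pairs {i, j} at topological
    distance d where one atom carries t1 and the other t2.  At d = 0 an
    atom pairs with itself: it contributes to (t, t) for every label t it
    carries, and to (t1, t2) when it carries both labels.  Pairs at
    distances beyond ``max_distance`` are ignored (not folded into the
    last bin).  Under occurrence scaling each entry is divided by the
    summed incidence of its two types (counting a dual-typed atom once per
    type, so same-type pairs are divided by twice the type's incidence);
    0/0 is defined as 0.
    """
    if max_distance < 0:
        raise ValueError("max_distance must be >= 0")
    scaling = ScalingMode(scaling)
    n = mol.graph.n_atoms
    dist = shortest_path_matrix(mol.graph)

    # incidence matrix: atom x label
    inc = np.zeros((n, len(PPP_LABELS)), dtype=bool)
    for i, labels in enumerate(mol.ppp):
        for lab in labels:
            inc[i, PPP_LABELS.index(lab)] = True
    counts_per_label = inc.sum(axis=0)

    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    values = np.zeros((len(PAIR_TYPES), MAX_DISTANCE + 1))
    for p, pair in enumerate(PAIR_TYPES):
        a = PPP_LABELS.index(pair[0])
        b = PPP_LABELS.index(pair[1])
        pair_mask = (
            np.outer(inc[:, a], inc[:, b]) | np.outer(inc[:, b], inc[:, a])
        )
        for d in range(min(max_distance, MAX_DISTANCE) + 1):
            if d == 0:
                count = int(np.count_nonzero(inc[:, a] & inc[:, b]))
            else:
                count = int(np.count_nonzero(pair_mask & upper & (dist == d)))
            values[p, d] = count

    if scaling is ScalingMode.OCCURRENCE:
        for p, pair in enumerate(PAIR_TYPES):
            denom = (
                counts_per_label[PPP_LABELS.index(pair[0])]
                + counts_per_label[PPP_LABELS.index(pair[1])]
            )
            values[p] = values[p] / denom if denom > 0 else 0.0

    return CatsVector(
        values=values.ravel(), scaling=scaling, identifier=mol.identifier
    )


def featurize_smiles(
    smiles: str,
    identifier: str = "",
    scaling: ScalingMode = ScalingMode.OCCURRENCE,
) -> CatsVector:
    """Parse, type and featurize a single SMILES string."""
    graph = parse_smiles(smiles, identifier=identifier)
    return compute_cats2(assign_ppp(graph), scaling=scaling)


def featurize_batch(
    molecules,
    scaling: ScalingMode = ScalingMode.OCCURRENCE,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Featurize a batch of molecules into a descriptor table.

    Parameters
    ----------
    molecules
        Iterable of :class:`TypedMolecule` or ``(smiles, identifier)``
        pairs.  Identifiers must be unique.

    Returns
    -------
    (table, failures)
        ``table`` — DataFrame indexed by identifier with the 231 named
        descriptor columns, in input order; ``failures`` — list of
        ``(identifier, error message)`` for records that could not be
        processed.  A failing record never aborts the batch.
    """
    rows: list[np.ndarray] = []
    ids: list[str] = []
    failures: list[tuple[str, str]] = []
    seen: set[str] = set()
    for item in molecules:
        if isinstance(item, TypedMolecule):
            identifier = item.identifier
        else:
            _smiles, identifier = item
        if identifier in seen:
            raise ValueError(f"duplicate identifier: {identifier!r}")
        seen.add(identifier)
        try:
            if isinstance(item, TypedMolecule):
                vec = compute_cats2(item, scaling=scaling)
            else:
                vec = featurize_smiles(item[0], identifier, scaling=scaling)
        except Exception as exc:  # error isolation per record
            failures.append((identifier, str(exc)))
            continue
        rows.append(vec.values)
        ids.append(identifier)
    table = pd.DataFrame(
        np.array(rows).reshape(len(rows), N_FEATURES),
        index=pd.Index(ids, name="identifier"),
        columns=list(COLUMN_NAMES),
    )
    return table, failures


def write_descriptor_table(table: pd.DataFrame, path) -> None:
    """Write a descriptor table as CSV (identifier column + 231 columns)."""
    table.to_csv(path, index_label="identifier")


def read_descriptor_table(path) -> pd.DataFrame:
    """Read a descriptor CSV, validating the 231-column census."""
    table = pd.read_csv(path, index_col="identifier")
    missing = [c for c in COLUMN_NAMES if c not in table.columns]
    extra = [c for c in table.columns if c not in COLUMN_NAMES]
    if missing or extra:
        raise ValueError(
            f"descriptor table column mismatch: missing {missing[:3]}..., "
            f"unexpected {extra[:3]}..."
            if missing and extra
            else f"descriptor table column mismatch: "
            f"missing={missing} unexpected={extra}"
        )
    return table[list(COLUMN_NAMES)]
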