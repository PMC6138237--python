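"""Consensus self-organizing-map target fishing.

A jury of Kohonen self-organizing maps (SOMs), identical except for their
random seeds, tessellates the descriptor space of an annotated reference
library.  A query ligand is projected onto each map; the reference ligands
sharing its best-matching unit (BMU) "co-cluster" with it and vote for
their annotated targets, each vote weighted by 1/(1 + Euclidean distance)
so that tight neighbours count more than loose ones.  The per-target
consensus score is the mean vote mass over the jury.

Scores are converted to an empirical confidence — a p-like value — by rank
against a background of decoy queries: p_like = (k + 1)/(n + 1) where k is
the number of decoy scores at least as large as the query's.  Small p_like
therefore means the query's support for a target exceeds almost everything
seen for decoys.  The add-one smoothing keeps p_like in (0, 1].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SomGrid",
    "ReferenceLibrary",
    "BackgroundDistribution",
    "JuryPrediction",
    "train_som",
    "find_bmu",
    "calibrate_background",
    "predict_targets",
    "consensus_scores",
    "TargetFishingModel",
    "TargetFishingResults",
    "save_som",
    "load_som",
]

_FORMAT_VERSION = 1


@dataclass
class SomGrid:
    """A trained SOM: ``(height, width, dim)`` codebook lattice."""

    codebooks: np.ndarray
    topology: str = "toroidal"
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codebooks = np.asarray(self.codebooks, dtype=float)
        if self.codebooks.ndim != 3:
            raise ValueError("codebooks must be (height, width, dim)")
        if not np.all(np.isfinite(self.codebooks)):
            raise ValueError("codebook entries must be finite")
        if self.topology not in ("planar", "toroidal"):
            raise ValueError(f"unknown topology {self.topology!r}")

    @property
    def height(self) -> int:
        return self.codebooks.shape[0]

    @property
    def width(self) -> int:
        return self.codebooks.shape[1]

    @property
    def dim(self) -> int:
        return self.codebooks.shape[2]


@dataclass
class ReferenceLibrary:
    """Annotated reference ligands: descriptor vectors + target sets."""

    identifiers: list[str]
    vectors: np.ndarray
    targets: list[frozenset[str]]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        n = len(self.identifiers)
        if len(set(self.identifiers)) != n:
            raise ValueError("library identifiers must be unique")
        if self.vectors.shape[0] != n or len(self.targets) != n:
            raise ValueError("identifiers, vectors and targets must align")
        self.targets = [frozenset(t) for t in self.targets]
        if any(len(t) == 0 for t in self.targets):
            raise ValueError("every reference ligand needs >= 1 target")

    def __len__(self) -> int:
        return len(self.identifiers)

    @property
    def all_targets(self) -> list[str]:
        return sorted(set().union(*self.targets))

    @classmethod
    def from_frame(cls, table, target_map) -> "ReferenceLibrary":
        """Build from a descriptor DataFrame and an id -> targets mapping."""
        ids = [str(i) for i in table.index]
        targets = [frozenset(target_map[i]) for i in ids]
        return cls(ids, table.to_numpy(dtype=float), targets)


@dataclass
class BackgroundDistribution:
    """Sorted decoy consensus scores used to calibrate p-like values."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.sort(np.asarray(self.scores, dtype=float))
        if self.scores.size < 100:
            raise ValueError(
                f"background needs >= 100 decoy scores, got {self.scores.size}"
            )
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("background scores must be finite")

    def p_like(self, score: float) -> float:
        """(k + 1)/(n + 1) with k = #decoy scores >= ``score``."""
        n = self.scores.size
        k = n - int(np.searchsorted(self.scores, score, side="left"))
        return (k + 1) / (n + 1)


@dataclass
class JuryPrediction:
    """One ranked target hypothesis for a query ligand."""

    target: str
    score: float
    p_like: float
    supporting_neighbours: int

    def __post_init__(self) -> None:
        if not (0.0 < self.p_like <= 1.0):
            raise ValueError("p_like must lie in (0, 1]")


def _grid_distance_sq(height: int, width: int, topology: str) -> np.ndarray:
    """Squared lattice distances between all neuron pairs, (H*W, H*W)."""
    rows, cols = np.divmod(np.arange(height * width), width)
    dr = np.abs(rows[:, None] - rows[None, :])
    dc = np.abs(cols[:, None] - cols[None, :])
    if topology == "toroidal":
        dr = np.minimum(dr, height - dr)
        dc = np.minimum(dc, width - dc)
    return (dr**2 + dc**2).astype(float)


def train_som(
    vectors,
    width: int = 12,
    height: int = 10,
    epochs: int = 20,
    seed: int = 0,
    topology: str = "toroidal",
    learning_rate: tuple[float, float] = (0.5, 0.01),
    sigma: tuple[float | None, float] = (None, 0.5),
) -> SomGrid:
    """Train a SOM by online Kohonen learning.

    Each epoch visits all training vectors in a freshly shuffled order;
    for every vector the best-matching unit is found and all codebooks are
    pulled towards the vector with a Gaussian neighbourhood kernel.  Both
    the learning rate and the neighbourhood width decay linearly across
    epochs (defaults: 0.5 -> 0.01 and max(width, height)/2 -> 0.5).
    Training is bit-reproducible for a fixed seed.
    """
    X = np.asarray(vectors, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training set must be a non-empty 2-D array")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    n, dim = X.shape
    if n < width * height:
        warnings.warn(
            f"{n} training vectors for a {width}x{height} grid; "
            "codebooks may be underdetermined",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    codebooks = rng.uniform(size=(height * width, dim)) * (hi - lo) + lo

    sigma0 = sigma[0] if sigma[0] is not None else max(width, height) / 2.0
    sigma1 = sigma[1]
    lr0, lr1 = learning_rate
    grid_d2 = _grid_distance_sq(height, width, topology)

    for epoch in range(epochs):
        frac = epoch / (epochs - 1) if epochs > 1 else 0.0
        lr = lr0 + (lr1 - lr0) * frac
        sig = sigma0 + (sigma1 - sigma0) * frac
        order = rng.permutation(n)
        for idx in order:
            x = X[idx]
            bmu = int(np.argmin(((codebooks - x) ** 2).sum(axis=1)))
            kernel = np.exp(-grid_d2[bmu] / (2.0 * sig**2))
            codebooks += (lr * kernel)[:, None] * (x - codebooks)

    meta = {
        "epochs": epochs,
        "seed": int(seed),
        "learning_rate": [float(lr0), float(lr1)],
        "sigma": [float(sigma0), float(sigma1)],
        "n_train": int(n),
    }
    return SomGrid(
        codebooks=codebooks.reshape(height, width, dim),
        topology=topology,
        training_meta=meta,
    )


def find_bmu(som: SomGrid, query) -> tuple[int, int]:
    """Best-matching unit: (row, col) of the codebook nearest the query.

    Ties are broken towards the lexicographically smallest coordinate
    (row-major order).
    """
    q = np.asarray(query, dtype=float)
    if q.shape != (som.dim,):
        raise ValueError(
            f"query dimension {q.shape} does not match codebook dim {som.dim}"
        )
    flat = som.codebooks.reshape(-1, som.dim)
    d2 = ((flat - q) ** 2).sum(axis=1)
    bmu = int(np.argmin(d2))  # argmin returns the first (row-major) minimum
    return divmod(bmu, som.width)


def _library_bmus(jury, library: ReferenceLibrary) -> list[np.ndarray]:
    """Per SOM, the flat BMU index of every library vector."""
    out = []
    for som in jury:
        flat = som.codebooks.reshape(-1, som.dim)
        d2 = (
            (library.vectors[:, None, :] - flat[None, :, :]) ** 2
        ).sum(axis=2)
        out.append(np.argmin(d2, axis=1))
    return out


def consensus_scores(
    query,
    jury,
    library: ReferenceLibrary,
    library_bmus: list[np.ndarray] | None = None,
) -> tuple[dict[str, float], dict[str, int]]:
    """Per-target consensus score and co-clustered neighbour counts.

    For each SOM the reference ligands mapping to the query's BMU vote for
    their targets with weight 1/(1 + Euclidean distance to the query); the
    consensus score is the mean vote mass over the jury.
    """
    q = np.asarray(query, dtype=float)
    if library_bmus is None:
        library_bmus = _library_bmus(jury, library)
    support: dict[str, float] = {}
    neighbours: dict[str, set[int]] = {}
    for som, bmus in zip(jury, library_bmus):
        row, col = find_bmu(som, q)
        flat_bmu = row * som.width + col
        members = np.flatnonzero(bmus == flat_bmu)
        for m in members:
            weight = 1.0 / (
                1.0 + float(np.linalg.norm(library.vectors[m] - q))
            )
            for target in library.targets[m]:
                support[target] = support.get(target, 0.0) + weight
                neighbours.setdefault(target, set()).add(int(m))
    n_juror = len(jury)
    scores = {t: s / n_juror for t, s in support.items()}
    counts = {t: len(v) for t, v in neighbours.items()}
    return scores, counts


def calibrate_background(
    jury,
    library: ReferenceLibrary,
    decoys,
) -> BackgroundDistribution:
    """Score decoy queries exactly as real ones; store the sorted scores.

    Each decoy contributes one score: the consensus score of its
    best-supported target (0 if it co-clusters with nothing).
    """
    decoys = np.asarray(decoys, dtype=float)
    if decoys.ndim != 2 or decoys.shape[0] < 100:
        raise ValueError(
            f"calibration needs >= 100 decoys, got {0 if decoys.ndim != 2 else decoys.shape[0]}"
        )
    if not jury:
        raise ValueError("jury must be non-empty")
    bmus = _library_bmus(jury, library)
    scores = np.empty(decoys.shape[0])
    for i, d in enumerate(decoys):
        per_target, _ = consensus_scores(d, jury, library, bmus)
        scores[i] = max(per_target.values()) if per_target else 0.0
    return BackgroundDistribution(scores=scores)


def predict_targets(
    query,
    jury,
    library: ReferenceLibrary,
    background: BackgroundDistribution,
    library_bmus: list[np.ndarray] | None = None,
) -> list[JuryPrediction]:
    """Ranked target hypotheses for a query descriptor vector.

    Returns predictions sorted by ascending p_like, then descending
    consensus score, then target id; an empty list is the valid "no
    co-clustering anywhere" outcome.
    """
    if not jury:
        raise ValueError("jury must be non-empty")
    if len(library) == 0:
        raise ValueError("library must be non-empty")
    scores, counts = consensus_scores(query, jury, library, library_bmus)
    predictions = [
        JuryPrediction(
            target=t,
            score=s,
            p_like=background.p_like(s),
            supporting_neighbours=counts[t],
        )
        for t, s in scores.items()
    ]
    predictions.sort(key=lambda p: (p.p_like, -p.score, p.target))
    return predictions


class TargetFishingModel:
    """Consensus-SOM target fishing over an annotated reference library.

    Parameters
    ----------
    library
        The annotated reference ligands.
    jury_size
        Number of SOMs in the jury; the maps differ only in their seeds.
    width, height, epochs, topology
        SOM lattice and training settings (see :func:`train_som`).
    """

    def __init__(
        self,
        library: ReferenceLibrary,
        jury_size: int = 10,
        width: int = 12,
        height: int = 10,
        epochs: int = 20,
        topology: str = "toroidal",
    ) -> None:
        if jury_size < 1:
            raise ValueError("jury_size must be >= 1")
        self.library = library
        self.jury_size = jury_size
        self.width = width
        self.height = height
        self.epochs = epochs
        self.topology = topology

    def fit(self, seed: int = 0) -> "TargetFishingResults":
        """Train the jury; member seeds are derived from ``seed``."""
        seeds = np.random.SeedSequence(seed).generate_state(self.jury_size)
        jury = [
            train_som(
                self.library.vectors,
                width=self.width,
                height=self.height,
                epochs=self.epochs,
                seed=int(s % (2**31)),
                topology=self.topology,
            )
            for s in seeds
        ]
        return TargetFishingResults(model=self, jury=jury)


class TargetFishingResults:
    """A fitted SOM jury; holds the maps and, once calibrated, the
    decoy background used to turn consensus scores into p-like values."""

    def __init__(self, model: TargetFishingModel, jury: list[SomGrid]) -> None:
        self.model = model
        self.jury = jury
        self.background: BackgroundDistribution | None = None
        self._library_bmus = _library_bmus(jury, model.library)

    def calibrate(self, decoys) -> "TargetFishingResults":
        self.background = calibrate_background(
            self.jury, self.model.library, decoys
        )
        return self

    def predict(self, query) -> list[JuryPrediction]:
        if self.background is None:
            raise RuntimeError(
                "call .calibrate(decoys) before predicting: the p-like "
                "value needs a background distribution"
            )
        return predict_targets(
            query,
            self.jury,
            self.model.library,
            self.background,
            self._library_bmus,
        )

    def quantization_error(self) -> float:
        """Mean distance of library vectors to their BMUs, over the jury."""
        errs = []
        for som in self.jury:
            flat = som.codebooks.reshape(-1, som.dim)
            d2 = (
                (self.model.library.vectors[:, None, :] - flat[None, :, :])
                ** 2
            ).sum(axis=2)
            errs.append(np.sqrt(d2.min(axis=1)).mean())
        return float(np.mean(errs))

    def summary(self) -> str:
        lib = self.model.library
        lines = [
            "Consensus-SOM target fishing",
            "=" * 34,
            f"jury size:           {len(self.jury)}",
            f"grid:                {self.model.width} x {self.model.height} "
            f"({self.model.topology})",
            f"epochs:              {self.model.epochs}",
            f"reference ligands:   {len(lib)}",
            f"annotated targets:   {len(lib.all_targets)}",
            f"quantization error:  {self.quantization_error():.4f}",
            f"background decoys:   "
            f"{self.background.scores.size if self.background else 'not calibrated'}",
        ]
        return "\n".join(lines)


def save_som(som: SomGrid, path) -> None:
    """Serialize a SOM as versioned JSON (text, portable)."""
    payload = {
        "format_version": _FORMAT_VERSION,
        "topology": som.topology,
        "shape": list(som.codebooks.shape),
        "codebooks": som.codebooks.tolist(),
        "training_meta": som.training_meta,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_som(path, expected_dim: int | None = None) -> SomGrid:
    """Load a serialized SOM, refusing mismatched descriptor dimensions."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(
            f"unsupported SOM format version {payload.get('format_version')}"
        )
    codebooks = np.array(payload["codebooks"], dtype=float)
    if expected_dim is not None and codebooks.shape[2] != expected_dim:
        raise ValueError(
            f"descriptor dimension mismatch: model has {codebooks.shape[2]}, "
            f"expected {expected_dim}"
        )
    return SomGrid(
        codebooks=codebooks,
        topology=payload["topology"],
        training_meta=payload.get("training_meta", {}),
    )
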