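"""Synthetic reference libraries, decoys and bioactivity tables.

Curated public bioactivity databases cannot be redistributed or assumed
present, so every stage of the platform is exercised against generated
data whose statistical structure matches what the pipeline assumes:

* **Fixture molecules** — a fixed set of real structures (an ortho-
  naphthoquinone natural product in its quinone and hydroquinone forms,
  its open-chain isomer, and ~20 small probes) covering every
  pharmacophore label, used for descriptor oracle tests.
* **Planted libraries** — clustered descriptor vectors with known
  target assignments: each target is a Gaussian cluster around a sparse
  non-negative centroid, with controllable intra-cluster spread and
  inter-cluster separation.  These probe the SOM target-fishing stage.
* **Simulated bioactivities** — noisy log-affinity labels generated as a
  sparse linear map of descriptor entries, emitted as raw records with
  mixed concentration units and an optional censored fraction, so the
  curation + normalization + regression chain can be validated end to
  end (the latent label is recoverable exactly for noiseless, uncensored
  records).

Vectors are generated directly in descriptor space: this separates
descriptor-engine correctness (checked on the fixture molecules against a
brute-force oracle) from learner correctness (checked on planted
structure).  A small SMILES generator over substituted benzenes and
naphthalenes is provided for end-to-end smoke tests only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .affinity import UNIT_FACTORS, BioactivityRecord
from .cats2 import COLUMN_NAMES, N_FEATURES
from .som import ReferenceLibrary

import pandas as pd

__all__ = [
    "FIXTURE_MOLECULES",
    "generate_fixture_molecules",
    "PlantedLibrarySpec",
    "generate_planted_library",
    "SarSpec",
    "simulate_bioactivities",
    "generate_descriptor_vectors",
    "generate_smiles_library",
]

#: Fixed molecular fixtures.  The first three are the natural-product
#: redox pair (ortho-quinone C15H14O3 / hydroquinone C15H16O3, both 18
#: heavy atoms) and their open-chain constitutional isomer; the probes
#: cover every pharmacophore label in {D, A, P, N, L, R}.
FIXTURE_MOLECULES: tuple[tuple[str, str], ...] = (
    ("beta_lapachone", "CC1(C)CCC2=C(O1)c1ccccc1C(=O)C2=O"),
    ("beta_lapachone_hydroquinone", "CC1(C)CCc2c(O1)c1ccccc1c(O)c2O"),
    ("lapachol", "CC(C)=CCC1=C(O)C(=O)c2ccccc2C1=O"),
    ("ethane", "CC"),
    ("ethanol", "CCO"),
    ("benzene", "c1ccccc1"),
    ("acetate", "CC(=O)[O-]"),
    ("acetic_acid", "CC(=O)O"),
    ("methylammonium", "C[NH3+]"),
    ("methylamine", "CN"),
    ("acetamide", "CC(N)=O"),
    ("phenol", "Oc1ccccc1"),
    ("aniline", "Nc1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("toluene", "Cc1ccccc1"),
    ("chlorobenzene", "Clc1ccccc1"),
    ("benzoic_acid", "OC(=O)c1ccccc1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("thioanisole", "CSc1ccccc1"),
    ("propane", "CCC"),
    ("glycine_zwitterion", "[NH3+]CC(=O)[O-]"),
    ("methanesulfonic_acid", "CS(=O)(=O)O"),
    ("butylamine", "CCCCN"),
    ("anthracene", "c1ccc2cc3ccccc3cc2c1"),
)


def generate_fixture_molecules() -> list[tuple[str, str]]:
    """The fixed fixture set as ``(identifier, smiles)`` pairs."""
    return [(name, smi) for name, smi in FIXTURE_MOLECULES]


@dataclass
class PlantedLibrarySpec:
    """Planted-cluster library parameters.

    ``separation`` is the required minimum pairwise centroid distance in
    units of the intra-cluster spread ``sigma``; at separation >= 5 the
    clusters are essentially non-overlapping and nearest-centroid
    assignment is near-perfect.
    """

    n_targets: int = 5
    ligands_per_target: int = 50
    sigma: float = 0.05
    separation: float = 5.0
    n_active_dims: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1 or self.ligands_per_target < 1:
            raise ValueError("counts must be >= 1")
        if self.separation <= 0:
            raise ValueError("separation factor must be > 0")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def generate_planted_library(
    spec: PlantedLibrarySpec,
) -> tuple[ReferenceLibrary, dict[str, str], np.ndarray]:
    """Generate a reference library of well-separated target clusters.

    Centroids are sparse non-negative vectors (``n_active_dims`` uniform
    entries, rest zero), redrawn up to 100 times until all pairwise
    distances reach ``separation x sigma``.  Members are the centroid
    plus isotropic Gaussian noise, clipped at zero (descriptor
    non-negativity).  Bit-reproducible for a fixed spec.

    Returns the library, the ground-truth ligand -> target map, and the
    centroid matrix.
    """
    rng = np.random.default_rng(spec.seed)
    min_sep = spec.separation * spec.sigma
    centroids = None
    for _attempt in range(100):
        cand = np.zeros((spec.n_targets, N_FEATURES))
        for t in range(spec.n_targets):
            dims = rng.choice(N_FEATURES, size=spec.n_active_dims, replace=False)
            cand[t, dims] = rng.uniform(0.1, 1.0, size=spec.n_active_dims)
        d = np.linalg.norm(cand[:, None, :] - cand[None, :, :], axis=2)
        np.fill_diagonal(d, np.inf)
        if d.min() >= min_sep:
            centroids = cand
            break
    if centroids is None:
        raise RuntimeError(
            f"could not place {spec.n_targets} centroids with pairwise "
            f"distance >= {min_sep:.3g} after 100 attempts"
        )
    ids: list[str] = []
    vectors = np.empty(
        (spec.n_targets * spec.ligands_per_target, N_FEATURES)
    )
    targets: list[frozenset[str]] = []
    truth: dict[str, str] = {}
    row = 0
    for t in range(spec.n_targets):
        target_id = f"T{t + 1}"
        for m in range(spec.ligands_per_target):
            lig_id = f"{target_id}_lig{m + 1:03d}"
            noise = rng.normal(0.0, spec.sigma, size=N_FEATURES)
            vectors[row] = np.clip(centroids[t] + noise, 0.0, None)
            ids.append(lig_id)
            targets.append(frozenset({target_id}))
            truth[lig_id] = target_id
            row += 1
    library = ReferenceLibrary(
        identifiers=ids, vectors=vectors, targets=targets
    )
    return library, truth, centroids


def generate_descriptor_vectors(
    n: int, seed: int = 0, density: float = 0.3
) -> np.ndarray:
    """Random sparse non-negative descriptor-like vectors.

    Entries are uniform on (0, 1) with probability ``density``, else 0 —
    mimicking the sparsity pattern of occurrence-scaled pharmacophore
    autocorrelation vectors.  Used as decoys and as the substrate for
    simulated structure–activity data.
    """
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.0, 1.0, size=(n, N_FEATURES))
    mask = rng.random((n, N_FEATURES)) < density
    return X * mask


@dataclass
class SarSpec:
    """Simulated structure–activity relationship parameters.

    The latent label is ``intercept + sum(weights * X[:, active_indices])``
    plus Gaussian noise, clipped to ``label_range`` — affinities spanning
    several log units, as a useful training set must.  ``unit_mix`` gives
    the probability of each reporting unit; ``censored_fraction`` of
    records are emitted with a ``<`` or ``>`` relation instead of ``=``.

    When no vectors are supplied, compounds are drawn as a mixture of
    ``n_chemotypes`` descriptor clusters (centroid + isotropic noise
    ``chemotype_sigma``): per-target bioactivity sets are dominated by a
    handful of chemical series, not by structurally unrelated singletons,
    and the clustered geometry is what makes per-target regression on a
    few hundred compounds work at all.
    """

    n_compounds: int = 500
    active_indices: tuple[int, ...] = (10, 77, 150)
    weights: tuple[float, ...] = (3.0, -2.5, 2.0)
    intercept: float = 6.0
    noise_sigma: float = 0.3
    label_range: tuple[float, float] = (3.0, 10.0)
    unit_mix: dict = field(default_factory=lambda: {"uM": 0.5, "nM": 0.5})
    censored_fraction: float = 0.0
    n_chemotypes: int = 20
    chemotype_sigma: float = 0.1
    target_id: str = "T_SAR"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.active_indices) != len(self.weights):
            raise ValueError("one weight per active index required")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.censored_fraction < 1.0):
            raise ValueError("censored_fraction must be in [0, 1)")
        total = sum(self.unit_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"unit_mix proportions must sum to 1, got {total}")
        for u in self.unit_mix:
            if u not in UNIT_FACTORS:
                raise ValueError(f"unknown unit {u!r} in unit_mix")


def simulate_bioactivities(
    spec: SarSpec,
    vectors: np.ndarray | None = None,
) -> tuple[list[BioactivityRecord], pd.DataFrame, np.ndarray]:
    """Simulate raw bioactivity records with a recoverable latent signal.

    Returns ``(records, descriptors, latent)``: one record per compound
    with a concentration back-converted from the latent p_Affinity into a
    randomly assigned unit (so ``normalize_affinity`` recovers the latent
    label of every uncensored record to floating-point precision), a
    descriptor table indexed by compound id, and the latent label array.
    Censored records get relation ``<`` (below the reported concentration)
    or ``>`` at random and should be discarded by curation.
    """
    rng = np.random.default_rng(spec.seed)
    if vectors is None:
        centroids = np.zeros((spec.n_chemotypes, N_FEATURES))
        for t in range(spec.n_chemotypes):
            dims = rng.choice(N_FEATURES, size=30, replace=False)
            centroids[t, dims] = rng.uniform(0.1, 1.0, size=30)
        assign = rng.integers(0, spec.n_chemotypes, size=spec.n_compounds)
        vectors = np.clip(
            centroids[assign]
            + rng.normal(0.0, spec.chemotype_sigma,
                         (spec.n_compounds, N_FEATURES)),
            0.0,
            None,
        )
    vectors = np.asarray(vectors, dtype=float)
    n = vectors.shape[0]
    idx = np.array(spec.active_indices, dtype=int)
    w = np.array(spec.weights, dtype=float)
    latent = (
        spec.intercept
        + vectors[:, idx] @ w
        + rng.normal(0.0, spec.noise_sigma, size=n)
    )
    latent = np.clip(latent, *spec.label_range)

    units = list(spec.unit_mix)
    probs = np.array([spec.unit_mix[u] for u in units])
    unit_draw = rng.choice(len(units), size=n, p=probs)
    censored = rng.random(n) < spec.censored_fraction
    endpoints = rng.choice(["IC50", "Ki"], size=n)

    ids = [f"cmp{i + 1:05d}" for i in range(n)]
    records: list[BioactivityRecord] = []
    for i in range(n):
        unit = units[unit_draw[i]]
        molar = 10.0 ** (-latent[i])
        value = molar / UNIT_FACTORS[unit]
        relation = "="
        if censored[i]:
            relation = "<" if rng.random() < 0.5 else ">"
        records.append(
            BioactivityRecord(
                compound_id=ids[i],
                smiles="*",  # synthetic: descriptors supplied directly
                target_id=spec.target_id,
                endpoint=str(endpoints[i]),
                relation=relation,
                value=float(value),
                unit=unit,
            )
        )
    descriptors = pd.DataFrame(
        vectors, index=pd.Index(ids, name="identifier"),
        columns=list(COLUMN_NAMES),
    )
    return records, descriptors, latent


# -- end-to-end smoke-test chemistry ---------------------------------------

_SUBSTITUENTS = ("O", "N", "C(=O)O", "CN", "Cl", "C", "OC", "C(N)=O", "CCN")


def generate_smiles_library(n: int, seed: int = 0) -> list[tuple[str, str]]:
    """Random substituted benzenes/naphthalenes for end-to-end smoke tests.

    This is a tiny structure generator, not a realistic chemistry sampler:
    it exists so that the full SMILES -> descriptor -> model chain can be
    smoke-tested on parseable, typable molecules carrying donor, acceptor,
    charged, lipophilic and aromatic features.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[str, str]] = []
    for i in range(n):
        if rng.random() < 0.5:  # benzene: 4 substitutable middle positions
            slots, head, tail = 4, "c1", "c1"
        else:  # naphthalene: 2 substitutable positions on the first ring
            slots, head, tail = 2, "c1", "c2ccccc2c1"
        n_sub = int(rng.integers(1, slots + 1))
        chosen = set(rng.choice(slots, size=n_sub, replace=False).tolist())
        middle = "".join(
            "c({})".format(
                _SUBSTITUENTS[int(rng.integers(len(_SUBSTITUENTS)))]
            )
            if p in chosen
            else "c"
            for p in range(slots)
        )
        out.append((head + middle + tail, f"smoke{i + 1:04d}"))
    return out
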