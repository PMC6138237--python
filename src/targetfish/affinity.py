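"""Bioactivity curation and variance-penalized affinity regression.

The second, quantitative stage of the platform: heterogeneous bioactivity
records (IC50/EC50/Ki/Kd, mixed units, qualified relations) are curated
into per-target datasets with labels on a common scale,

    p_Affinity = -log10(concentration in mol/L),

and a random-forest regressor is fitted per target on CATS2 descriptors.
A prediction reports the ensemble mean minus the population variance of
the individual tree predictions,

    prediction = mean(trees) - var(trees),

so that queries on which the ensemble disagrees are penalized towards
inactivity.  Penalized estimates below 4.0 (i.e. weaker than 100 uM) are
reported as "<4.0" rather than as a number: in that regime the models are
extrapolating and a point estimate would suggest spurious precision.

Model quality is assessed by stratified k-fold cross-validation with
1-log-unit activity strata, reporting the mean absolute error (MAE) in
log10 units per fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import StratifiedKFold

from .cats2 import COLUMN_NAMES, N_FEATURES, CatsVector, featurize_batch

__all__ = [
    "UNIT_FACTORS",
    "ENDPOINTS",
    "RELATIONS",
    "BioactivityRecord",
    "TargetDataset",
    "CurationReport",
    "PredictionResult",
    "CvReport",
    "normalize_affinity",
    "curate",
    "fit_affinity_model",
    "predict_affinity",
    "cross_validate",
    "ligand_efficiency",
    "AffinityRegression",
    "AffinityRegressionResults",
    "read_bioactivity_table",
    "write_prediction_report",
]

#: Molar conversion factors for the closed unit vocabulary.
UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "μM": 1e-6,  # μM
    "µM": 1e-6,  # µM (micro sign)
    "nM": 1e-9,
    "pM": 1e-12,
}

ENDPOINTS = ("IC50", "EC50", "Ki", "Kd")
RELATIONS = ("=", "<", ">")

#: Reporting floor in p_Affinity units (100 uM).
REPORTING_FLOOR = 4.0

#: Free-energy-per-heavy-atom conversion, ~2.303·R·T at 298 K in kcal/mol.
LE_CONSTANT = 1.37


@dataclass
class BioactivityRecord:
    """One raw bioactivity measurement for a compound against a target."""

    compound_id: str
    smiles: str
    target_id: str
    endpoint: str
    relation: str
    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"unknown endpoint {self.endpoint!r}")
        if self.relation not in RELATIONS:
            raise ValueError(f"unknown relation {self.relation!r}")
        if not self.value > 0:
            raise ValueError("bioactivity value must be positive")
        if self.unit not in UNIT_FACTORS:
            raise ValueError(f"unknown unit {self.unit!r}")


def normalize_affinity(value: float, unit: str, endpoint: str = "IC50") -> float:
    """p_Affinity = -log10 of the measurement converted to mol/L.

    All four endpoint types are normalized identically (the endpoint is
    validated but does not alter the transform), so IC50, EC50, Ki and Kd
    records can be pooled into one model per target.
    """
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    if unit not in UNIT_FACTORS:
        raise ValueError(f"unknown unit {unit!r}")
    if not value > 0:
        raise ValueError(f"affinity value must be positive, got {value}")
    return -math.log10(value * UNIT_FACTORS[unit])


def ligand_efficiency(p_affinity: float, heavy_atoms: int) -> float:
    """Ligand efficiency: 1.37 x p_Affinity / heavy-atom count.

    Units are kcal·mol⁻¹ per heavy atom (1.37 ≈ 2.303·R·T at 298 K in
    kcal/mol, converting a log10 potency into a binding free energy).
    Values above 0.30 are the conventional bar for an efficient ligand
    worth medicinal-chemistry follow-up.
    """
    if heavy_atoms < 1:
        raise ValueError("heavy_atoms must be >= 1")
    return LE_CONSTANT * p_affinity / heavy_atoms


@dataclass
class TargetDataset:
    """Curated per-target training data: one row per compound."""

    target_id: str
    compound_ids: list[str]
    X: np.ndarray
    y: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.compound_ids)
        if self.X.shape != (n, N_FEATURES) or self.y.shape != (n,):
            raise ValueError("X must be (n, 231) and y (n,) aligned to ids")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("p_affinity labels must be finite")

    def __len__(self) -> int:
        return len(self.compound_ids)

    @property
    def label_span(self) -> float:
        return float(self.y.max() - self.y.min())


@dataclass
class CurationReport:
    """Record-level accounting of a curation run."""

    records_read: int = 0
    censored_dropped: int = 0
    parse_failures: int = 0
    duplicates_merged: int = 0
    targets_kept: list[str] = field(default_factory=list)
    targets_skipped: dict[str, str] = field(default_factory=dict)


def curate(
    records,
    min_n: int = 30,
    min_span: float = 2.0,
    descriptors: pd.DataFrame | None = None,
) -> tuple[list[TargetDataset], CurationReport]:
    """Curate raw bioactivity records into per-target training datasets.

    Qualified records (relation ``<`` or ``>``) are dropped — regressing on
    censored values biases the labels.  Surviving records are normalized to
    p_Affinity; replicate measurements of the same compound against the
    same target are aggregated by their median (robust to unit errors).
    A target yields a dataset only if it retains at least ``min_n``
    compounds whose labels span at least ``min_span`` log units — narrow or
    tiny datasets cannot support a useful regression model.

    Compound descriptors are taken from ``descriptors`` (a table indexed
    by compound id) when given, otherwise computed from each record's
    SMILES; compounds that cannot be featurized are dropped and counted.
    """
    report = CurationReport()
    per_pair: dict[tuple[str, str], list[float]] = {}
    smiles_of: dict[str, str] = {}
    for rec in records:
        report.records_read += 1
        if rec.relation != "=":
            report.censored_dropped += 1
            continue
        p_aff = normalize_affinity(rec.value, rec.unit, rec.endpoint)
        per_pair.setdefault((rec.target_id, rec.compound_id), []).append(p_aff)
        smiles_of.setdefault(rec.compound_id, rec.smiles)

    if descriptors is None:
        to_featurize = sorted(smiles_of)
        descriptors, failures = featurize_batch(
            [(smiles_of[cid], cid) for cid in to_featurize]
        )
        report.parse_failures = len(failures)

    by_target: dict[str, list[tuple[str, float]]] = {}
    for (target_id, compound_id), values in sorted(per_pair.items()):
        if len(values) > 1:
            report.duplicates_merged += 1
        if compound_id not in descriptors.index:
            continue
        by_target.setdefault(target_id, []).append(
            (compound_id, float(np.median(values)))
        )

    datasets: list[TargetDataset] = []
    for target_id, entries in sorted(by_target.items()):
        ids = [cid for cid, _ in entries]
        y = np.array([p for _, p in entries])
        if len(ids) < min_n:
            report.targets_skipped[target_id] = (
                f"{len(ids)} compounds < min_n={min_n}"
            )
            continue
        span = float(y.max() - y.min())
        if span < min_span:
            report.targets_skipped[target_id] = (
                f"label span {span:.2f} < min_span={min_span}"
            )
            continue
        X = descriptors.loc[ids].to_numpy(dtype=float)
        datasets.append(
            TargetDataset(
                target_id=target_id,
                compound_ids=ids,
                X=X,
                y=y,
                provenance={
                    "records_read": report.records_read,
                    "compounds": len(ids),
                    "label_span": span,
                },
            )
        )
        report.targets_kept.append(target_id)
    return datasets, report


@dataclass
class PredictionResult:
    """Variance-penalized affinity estimate for one query against one target."""

    mean_p_affinity: float
    variance: float
    target_id: str = ""

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")

    @property
    def penalized(self) -> float:
        return self.mean_p_affinity - self.variance

    @property
    def reportable(self) -> str:
        """One-decimal estimate, floored to "<4.0" below 100 uM potency."""
        if self.penalized < REPORTING_FLOOR:
            return "<4.0"
        return f"{self.penalized:.1f}"


@dataclass
class CvReport:
    """Stratified k-fold cross-validation summary (MAE in log10 units)."""

    fold_maes: np.ndarray
    fold_assignment: np.ndarray

    def __post_init__(self) -> None:
        self.fold_maes = np.asarray(self.fold_maes, dtype=float)
        self.fold_assignment = np.asarray(self.fold_assignment, dtype=int)

    @property
    def k(self) -> int:
        return self.fold_maes.size

    @property
    def mean_mae(self) -> float:
        return float(self.fold_maes.mean())

    @property
    def sd_mae(self) -> float:
        return float(self.fold_maes.std(ddof=1))

    def __str__(self) -> str:
        return (
            f"{self.k}-fold CV: MAE = {self.mean_mae:.3f} "
            f"± {self.sd_mae:.3f} log units"
        )


class AffinityRegression:
    """Per-target random-forest affinity regression on CATS2 descriptors.

    Random forests need no descriptor pre-processing, tolerate the sparse
    non-negative CATS2 entries unscaled, and expose per-tree predictions —
    the spread of which is the only per-query uncertainty available at
    prediction time and is what the penalty term uses.

    Parameters
    ----------
    dataset
        A curated :class:`TargetDataset`.
    n_trees
        Ensemble size (default 500).
    max_features
        Features considered per split; default ``16 = ceil(sqrt(231))``.
    """

    def __init__(
        self,
        dataset: TargetDataset,
        n_trees: int = 500,
        max_features: int = 16,
    ) -> None:
        if n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        self.dataset = dataset
        self.n_trees = n_trees
        self.max_features = max_features

    def fit(self, seed: int = 0) -> "AffinityRegressionResults":
        forest = RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=min(self.max_features, N_FEATURES),
            bootstrap=True,
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )
        forest.fit(self.dataset.X, self.dataset.y)
        return AffinityRegressionResults(model=self, forest=forest, seed=seed)


class AffinityRegressionResults:
    """A fitted per-target forest with variance-penalized prediction."""

    def __init__(
        self, model: AffinityRegression, forest: RandomForestRegressor, seed: int
    ) -> None:
        self.model = model
        self.forest = forest
        self.seed = seed
        self.label_range = (
            float(model.dataset.y.min()),
            float(model.dataset.y.max()),
        )

    @property
    def target_id(self) -> str:
        return self.model.dataset.target_id

    def tree_predictions(self, query) -> np.ndarray:
        """Individual per-tree predictions for one query vector."""
        q = _as_query(query)
        return np.array(
            [tree.predict(q)[0] for tree in self.forest.estimators_]
        )

    def predict(self, query) -> PredictionResult:
        """Ensemble mean, per-tree population variance, and the penalty."""
        preds = self.tree_predictions(query)
        return PredictionResult(
            mean_p_affinity=float(preds.mean()),
            variance=float(preds.var()),
            target_id=self.target_id,
        )

    def summary(self) -> str:
        ds = self.model.dataset
        lines = [
            f"Affinity regression: {self.target_id}",
            "=" * 34,
            f"compounds:        {len(ds)}",
            f"label range:      [{self.label_range[0]:.2f}, "
            f"{self.label_range[1]:.2f}] p_Affinity",
            f"trees:            {self.model.n_trees}",
            f"features/split:   {self.model.max_features}",
            f"seed:             {self.seed}",
        ]
        return "\n".join(lines)


def _as_query(query) -> np.ndarray:
    if isinstance(query, CatsVector):
        q = query.values
    else:
        q = np.asarray(query, dtype=float)
    if q.shape != (N_FEATURES,):
        raise ValueError(
            f"query must have {N_FEATURES} entries, got shape {q.shape}"
        )
    return q.reshape(1, -1)


def fit_affinity_model(
    dataset: TargetDataset, n_trees: int = 500, seed: int = 0
) -> AffinityRegressionResults:
    """Functional wrapper: fit a per-target forest on a curated dataset."""
    return AffinityRegression(dataset, n_trees=n_trees).fit(seed=seed)


def predict_affinity(
    model: AffinityRegressionResults, query
) -> PredictionResult:
    """Functional wrapper around :meth:`AffinityRegressionResults.predict`."""
    return model.predict(query)


def _strata(y: np.ndarray, k: int) -> np.ndarray:
    """1-log-unit activity bins anchored at integers; bins with fewer than
    ``k`` members are merged into their nearest populated neighbour so
    every stratum can appear in every fold."""
    bins = np.floor(y).astype(int)
    while True:
        labels, counts = np.unique(bins, return_counts=True)
        small = labels[counts < k]
        if small.size == 0 or labels.size == 1:
            break
        b = small[0]
        others = labels[labels != b]
        nearest = others[np.argmin(np.abs(others - b))]
        bins[bins == b] = nearest
    return bins


def cross_validate(
    dataset: TargetDataset,
    k: int = 10,
    seed: int = 0,
    n_trees: int = 500,
) -> CvReport:
    """Stratified k-fold cross-validation of a per-target forest.

    Labels are stratified into 1-log-unit bins so every fold sees the full
    activity range; per-fold MAE is computed on the held-out fold with a
    forest trained on the remainder.
    """
    n = len(dataset)
    if n < 2 * k:
        raise ValueError(
            f"cross-validation with k={k} needs at least {2 * k} compounds, "
            f"got {n}"
        )
    bins = _strata(dataset.y, k)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % (2**31))
    fold_maes = np.empty(k)
    assignment = np.empty(n, dtype=int)
    for fold, (train_idx, test_idx) in enumerate(
        splitter.split(dataset.X, bins)
    ):
        assignment[test_idx] = fold
        train = TargetDataset(
            target_id=dataset.target_id,
            compound_ids=[dataset.compound_ids[i] for i in train_idx],
            X=dataset.X[train_idx],
            y=dataset.y[train_idx],
        )
        fitted = AffinityRegression(train, n_trees=n_trees).fit(
            seed=seed + fold
        )
        pred = fitted.forest.predict(dataset.X[test_idx])
        fold_maes[fold] = float(
            np.abs(pred - dataset.y[test_idx]).mean()
        )
    return CvReport(fold_maes=fold_maes, fold_assignment=assignment)


def read_bioactivity_table(path) -> list[BioactivityRecord]:
    """Read a bioactivity CSV/TSV with the canonical seven columns.

    Required header: compound_id, smiles, target_id, endpoint, relation,
    value, unit.  The unit vocabulary is strict (M, mM, uM/μM, nM, pM).
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    required = [
        "compound_id", "smiles", "target_id", "endpoint", "relation",
        "value", "unit",
    ]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"bioactivity table missing columns: {missing}")
    return [
        BioactivityRecord(
            compound_id=row.compound_id,
            smiles=row.smiles,
            target_id=row.target_id,
            endpoint=row.endpoint,
            relation=row.relation,
            value=float(row.value),
            unit=row.unit,
        )
        for row in table.itertuples()
    ]


def write_prediction_report(results: list[PredictionResult], path) -> None:
    """Write predictions as TSV: target, mean, variance, penalized, report."""
    frame = pd.DataFrame(
        {
            "target_id": [r.target_id for r in results],
            "mean": [r.mean_p_affinity for r in results],
            "variance": [r.variance for r in results],
            "penalized": [r.penalized for r in results],
            "reportable": [r.reportable for r in results],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")
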