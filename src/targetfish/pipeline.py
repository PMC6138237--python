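"""End-to-end orchestration: featurize -> target fishing -> affinity triage.

The two stages are complementary: the SOM jury gives a fast qualitative
shortlist with an empirical confidence (p-like value), and the per-target
random-forest regressors then estimate an affinity for every shortlisted
target, penalized by ensemble disagreement.  The final report mirrors a
prediction table: one row per (query, shortlisted target) with the p-like
value and the reportable penalized affinity.

All randomness flows from a single global seed: per-component seeds are
derived with ``numpy.random.SeedSequence`` spawning, so an identical
configuration and seed reproduce the report byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import affinity as aff
from . import cats2, synthetic
from .som import ReferenceLibrary, TargetFishingModel

__all__ = ["RunConfig", "run_pipeline", "derive_seeds"]

logger = logging.getLogger("targetfish")


@dataclass
class RunConfig:
    """Declarative configuration of an end-to-end run."""

    # inputs
    query_smi: str = ""
    library_csv: str = ""
    bioactivity_csv: str = ""
    output_report: str = ""
    # descriptor options
    scaling: str = "occurrence"
    # SOM options
    jury_size: int = 10
    grid_width: int = 12
    grid_height: int = 10
    epochs: int = 20
    n_decoys: int = 200
    shortlist_p: float = 0.05
    # affinity options
    n_trees: int = 500
    min_n: int = 30
    min_span: float = 2.0
    # global
    seed: int = 0
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def derive_seeds(global_seed: int, n: int) -> list[int]:
    """Stable per-component seeds derived from one global seed."""
    return [
        int(s % (2**31))
        for s in np.random.SeedSequence(global_seed).generate_state(n)
    ]


def _read_library(path) -> tuple[pd.DataFrame, dict[str, set[str]]]:
    """Library CSV: identifier, smiles, targets (';'-separated)."""
    table = pd.read_csv(path, dtype=str)
    required = ["identifier", "smiles", "targets"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"library CSV missing columns: {missing}")
    target_map = {
        row.identifier: set(str(row.targets).split(";"))
        for row in table.itertuples()
    }
    pairs = [(row.smiles, row.identifier) for row in table.itertuples()]
    desc, failures = cats2.featurize_batch(pairs)
    for ident, msg in failures:
        logger.warning("library featurization failed for %s: %s", ident, msg)
    return desc, {i: target_map[i] for i in desc.index}


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Execute the full two-stage prediction pipeline.

    Stages: featurize queries and library -> train SOM jury -> calibrate a
    decoy background -> rank targets per query -> shortlist targets with
    p_like at or below ``config.shortlist_p`` -> fit a per-target affinity
    model for every shortlisted target with curated bioactivity data ->
    emit one report row per (query, target).

    Every stage logs its record counts and seeds; any stage failure is
    re-raised annotated with the stage name.
    """
    seeds = derive_seeds(config.seed, 3)
    logger.info("global seed %d -> stage seeds %s", config.seed, seeds)

    stage = "featurize-queries"
    try:
        query_records = []
        if config.query_smi:
            from .molgraph import read_smi

            query_records = read_smi(config.query_smi)
        query_desc, q_failures = cats2.featurize_batch(query_records)
        logger.info(
            "stage %s: read %d, featurized %d, failed %d",
            stage, len(query_records), len(query_desc), len(q_failures),
        )
        if len(query_desc) == 0:
            logger.info("empty query set: emitting empty report")
            report = pd.DataFrame(
                columns=[
                    "query", "target_id", "p_like", "consensus_score",
                    "support", "mean", "variance", "penalized", "reportable",
                ]
            )
            if config.output_report:
                report.to_csv(config.output_report, sep="\t", index=False)
            return report

        stage = "featurize-library"
        lib_desc, target_map = _read_library(config.library_csv)
        library = ReferenceLibrary.from_frame(lib_desc, target_map)
        logger.info(
            "stage %s: %d reference ligands, %d targets",
            stage, len(library), len(library.all_targets),
        )

        stage = "train-som-jury"
        results = TargetFishingModel(
            library,
            jury_size=config.jury_size,
            width=config.grid_width,
            height=config.grid_height,
            epochs=config.epochs,
        ).fit(seed=seeds[0])
        logger.info("stage %s: jury of %d trained (seed %d)",
                    stage, config.jury_size, seeds[0])

        stage = "calibrate-background"
        decoys = synthetic.generate_descriptor_vectors(
            max(config.n_decoys, 100), seed=seeds[1]
        )
        results.calibrate(decoys)
        logger.info("stage %s: %d decoys (seed %d)",
                    stage, decoys.shape[0], seeds[1])

        stage = "curate-bioactivities"
        datasets: dict[str, aff.TargetDataset] = {}
        if config.bioactivity_csv:
            records = aff.read_bioactivity_table(config.bioactivity_csv)
            curated, cur_report = aff.curate(
                records, min_n=config.min_n, min_span=config.min_span
            )
            datasets = {d.target_id: d for d in curated}
            logger.info(
                "stage %s: %d records read, %d censored dropped, "
                "%d targets kept, %d skipped",
                stage, cur_report.records_read, cur_report.censored_dropped,
                len(cur_report.targets_kept), len(cur_report.targets_skipped),
            )

        stage = "predict"
        rows = []
        fitted_cache: dict[str, aff.AffinityRegressionResults] = {}
        for qid in query_desc.index:
            qvec = query_desc.loc[qid].to_numpy(dtype=float)
            predictions = results.predict(qvec)
            shortlist = [
                p for p in predictions if p.p_like <= config.shortlist_p
            ]
            logger.info(
                "query %s: %d targets predicted, %d shortlisted "
                "(p_like <= %.3g)",
                qid, len(predictions), len(shortlist), config.shortlist_p,
            )
            for pred in shortlist:
                row = {
                    "query": qid,
                    "target_id": pred.target,
                    "p_like": pred.p_like,
                    "consensus_score": pred.score,
                    "support": pred.supporting_neighbours,
                    "mean": np.nan,
                    "variance": np.nan,
                    "penalized": np.nan,
                    "reportable": "n.d.",
                }
                if pred.target in datasets:
                    if pred.target not in fitted_cache:
                        fitted_cache[pred.target] = aff.fit_affinity_model(
                            datasets[pred.target],
                            n_trees=config.n_trees,
                            seed=seeds[2],
                        )
                    res = fitted_cache[pred.target].predict(qvec)
                    row.update(
                        mean=res.mean_p_affinity,
                        variance=res.variance,
                        penalized=res.penalized,
                        reportable=res.reportable,
                    )
                rows.append(row)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = pd.DataFrame(
        rows,
        columns=[
            "query", "target_id", "p_like", "consensus_score", "support",
            "mean", "variance", "penalized", "reportable",
        ],
    )
    if config.output_report:
        report.to_csv(
            config.output_report, sep="\t", index=False, float_format="%.6g"
        )
        logger.info("report written to %s (%d rows)",
                    config.output_report, len(report))
    return report
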