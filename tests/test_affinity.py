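"""Affinity normalization, curation, forest regression and CV contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from targetfish import (
    BioactivityRecord,
    PredictionResult,
    TargetDataset,
    cross_validate,
    curate,
    fit_affinity_model,
    ligand_efficiency,
    normalize_affinity,
    predict_affinity,
    AffinityRegression,
)
from targetfish.affinity import (
    read_bioactivity_table,
    write_prediction_report,
    _strata,
)
from targetfish.cats2 import N_FEATURES
from targetfish.synthetic import SarSpec, simulate_bioactivities


def record(cid="c1", value=1.0, unit="uM", relation="=", target="T1",
           endpoint="IC50"):
    return BioactivityRecord(
        compound_id=cid, smiles="CCO", target_id=target, endpoint=endpoint,
        relation=relation, value=value, unit=unit,
    )


class TestNormalizeAffinity:
    def test_published_worked_example(self):
        """0.24 uM potency is 6.6 on the p_Affinity scale (1 decimal)."""
        assert round(normalize_affinity(0.24, "uM", "IC50"), 1) == 6.6

    def test_one_molar_is_zero(self):
        assert normalize_affinity(1, "M", "Ki") == 0.0

    def test_nanomolar_value(self):
        assert normalize_affinity(85.5, "nM", "IC50") == pytest.approx(
            7.07, abs=0.005
        )

    def test_unit_invariance(self):
        assert normalize_affinity(240, "nM", "IC50") == pytest.approx(
            normalize_affinity(0.24, "uM", "IC50")
        )
        assert normalize_affinity(0.24, "μM", "IC50") == pytest.approx(
            normalize_affinity(0.24, "uM", "IC50")
        )

    def test_endpoint_does_not_alter_transform(self):
        vals = {normalize_affinity(5, "nM", e) for e in
                ("IC50", "EC50", "Ki", "Kd")}
        assert len(vals) == 1

    @given(
        c1=st.floats(1e-12, 1e3), factor=st.floats(1.001, 1e6),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_concentration(self, c1, factor):
        assert normalize_affinity(c1 * factor, "M") < normalize_affinity(
            c1, "M"
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            normalize_affinity(-1, "uM")
        with pytest.raises(ValueError):
            normalize_affinity(1, "furlongs")
        with pytest.raises(ValueError):
            normalize_affinity(1, "uM", endpoint="logP")


class TestLigandEfficiency:
    def test_potent_small_molecule_is_efficient(self):
        p_aff = normalize_affinity(0.24, "uM")
        le = ligand_efficiency(p_aff, 18)
        assert le == pytest.approx(0.50, abs=0.005)
        assert le > 0.30

    def test_zero_affinity(self):
        assert ligand_efficiency(0.0, 25) == 0.0

    def test_inverse_proportionality_in_size(self):
        assert ligand_efficiency(6.0, 30) == pytest.approx(
            ligand_efficiency(6.0, 15) / 2
        )

    def test_size_must_be_positive(self):
        with pytest.raises(ValueError):
            ligand_efficiency(6.0, 0)


class TestCurate:
    def desc_table(self, ids):
        import pandas as pd
        from targetfish.cats2 import COLUMN_NAMES

        rng = np.random.default_rng(0)
        return pd.DataFrame(
            rng.uniform(size=(len(ids), N_FEATURES)),
            index=pd.Index(ids, name="identifier"),
            columns=list(COLUMN_NAMES),
        )

    def test_duplicate_aggregation_by_median(self):
        recs = [
            record(value=10.0, unit="uM"),   # p = 5.0
            record(value=1.0, unit="uM"),    # p = 6.0
            record(value=1.0, unit="nM"),    # p = 9.0
        ]
        datasets, report = curate(
            recs, min_n=1, min_span=0.0, descriptors=self.desc_table(["c1"])
        )
        assert datasets[0].y[0] == pytest.approx(6.0)
        assert report.duplicates_merged == 1

    def test_censored_records_dropped(self):
        recs = [record(relation=">"), record(relation="<")]
        datasets, report = curate(
            recs, min_n=1, min_span=0.0, descriptors=self.desc_table(["c1"])
        )
        assert datasets == []
        assert report.censored_dropped == 2

    def test_min_n_filter_reported_as_skipped(self):
        recs = [record(cid=f"c{i}") for i in range(4)]
        datasets, report = curate(
            recs, min_n=5, min_span=0.0,
            descriptors=self.desc_table([f"c{i}" for i in range(4)]),
        )
        assert datasets == []
        assert "T1" in report.targets_skipped
        assert "min_n" in report.targets_skipped["T1"]

    def test_min_span_filter(self):
        recs = [record(cid=f"c{i}", value=1.0 + 0.01 * i) for i in range(5)]
        datasets, report = curate(
            recs, min_n=3, min_span=2.0,
            descriptors=self.desc_table([f"c{i}" for i in range(5)]),
        )
        assert datasets == []
        assert "min_span" in report.targets_skipped["T1"]

    def test_featurization_from_smiles(self):
        recs = [
            record(cid="c1", value=1.0),
            record(cid="c2", value=100.0),
        ]
        datasets, report = curate(recs, min_n=2, min_span=1.0)
        assert len(datasets) == 1
        assert len(datasets[0]) == 2


class TestAffinityModel:
    def constant_dataset(self, c=5.0, n=40):
        rng = np.random.default_rng(1)
        return TargetDataset(
            target_id="T1",
            compound_ids=[f"c{i}" for i in range(n)],
            X=rng.uniform(size=(n, N_FEATURES)),
            y=np.full(n, c),
        )

    def test_constant_labels_zero_variance(self):
        fitted = fit_affinity_model(self.constant_dataset(), n_trees=25,
                                    seed=0)
        res = fitted.predict(np.zeros(N_FEATURES))
        assert res.mean_p_affinity == pytest.approx(5.0)
        assert res.variance == pytest.approx(0.0)
        assert res.penalized == pytest.approx(5.0)
        assert res.reportable == "5.0"

    def test_same_seed_identical_tree_predictions(self):
        ds = self.constant_dataset()
        rng = np.random.default_rng(2)
        ds.y = rng.uniform(4, 8, size=len(ds))
        q = rng.uniform(size=N_FEATURES)
        a = fit_affinity_model(ds, n_trees=30, seed=7).tree_predictions(q)
        b = fit_affinity_model(ds, n_trees=30, seed=7).tree_predictions(q)
        np.testing.assert_array_equal(a, b)

    def test_prediction_within_training_label_range(self):
        ds = self.constant_dataset()
        rng = np.random.default_rng(3)
        ds.y = rng.uniform(4, 9, size=len(ds))
        fitted = fit_affinity_model(ds, n_trees=30, seed=1)
        for q in rng.uniform(-2, 3, size=(20, N_FEATURES)):
            res = predict_affinity(fitted, q)
            assert ds.y.min() <= res.mean_p_affinity <= ds.y.max()
            assert res.variance >= 0
            assert res.penalized <= res.mean_p_affinity

    def test_invalid_tree_count(self):
        with pytest.raises(ValueError):
            AffinityRegression(self.constant_dataset(), n_trees=0)


class TestPredictionResult:
    def test_hand_computed_penalty_floors(self):
        """Per-tree predictions {3.0, 3.4, 3.8}: mean 3.4, population
        variance 0.1067, penalized 3.29 -> below the 4.0 reporting floor."""
        trees = np.array([3.0, 3.4, 3.8])
        res = PredictionResult(
            mean_p_affinity=float(trees.mean()), variance=float(trees.var())
        )
        assert res.mean_p_affinity == pytest.approx(3.4)
        assert res.penalized < 4.0
        assert res.reportable == "<4.0"

    @pytest.mark.parametrize(
        "penalized,expected",
        [(3.95, "<4.0"), (3.999, "<4.0"), (4.0, "4.0"), (4.04, "4.0"),
         (6.42, "6.4")],
    )
    def test_reporting_floor_exact_at_four(self, penalized, expected):
        res = PredictionResult(mean_p_affinity=penalized, variance=0.0)
        assert res.reportable == expected

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            PredictionResult(mean_p_affinity=5.0, variance=-0.1)


class TestCrossValidate:
    def sar_dataset(self, n=200, noise=0.3, seed=0):
        spec = SarSpec(n_compounds=n, noise_sigma=noise, seed=seed)
        records, desc, latent = simulate_bioactivities(spec)
        datasets, _ = curate(records, min_n=10, min_span=1.0,
                             descriptors=desc)
        return datasets[0]

    def test_folds_partition_dataset(self):
        ds = self.sar_dataset()
        report = cross_validate(ds, k=5, seed=1, n_trees=20)
        assert report.fold_assignment.shape == (len(ds),)
        sizes = np.bincount(report.fold_assignment, minlength=5)
        assert sizes.sum() == len(ds)
        assert sizes.max() - sizes.min() <= 1

    def test_stratification_within_one_entry(self):
        ds = self.sar_dataset()
        k = 5
        report = cross_validate(ds, k=k, seed=2, n_trees=20)
        bins = _strata(ds.y, k)
        for b in np.unique(bins):
            in_bin = report.fold_assignment[bins == b]
            counts = np.bincount(in_bin, minlength=k)
            assert counts.max() - counts.min() <= 1

    def test_mean_is_arithmetic_mean_of_folds(self):
        ds = self.sar_dataset()
        report = cross_validate(ds, k=5, seed=3, n_trees=20)
        assert report.mean_mae == pytest.approx(report.fold_maes.mean())
        assert report.k == 5

    def test_too_small_dataset_names_minimum(self):
        ds = self.sar_dataset(n=15)
        with pytest.raises(ValueError, match="20"):
            cross_validate(ds, k=10)

    def test_deterministic_labels_are_learnable(self):
        """Noise-free labels that are an exact function of one descriptor
        entry are recovered with small CV error."""
        spec = SarSpec(n_compounds=400, noise_sigma=0.0, seed=5,
                       active_indices=(10,), weights=(4.0,))
        records, desc, latent = simulate_bioactivities(spec)
        datasets, _ = curate(records, min_n=10, min_span=1.0,
                             descriptors=desc)
        report = cross_validate(datasets[0], k=10, seed=5, n_trees=100)
        assert report.mean_mae < 0.15


class TestBioactivityIO:
    def test_csv_round_trip(self, tmp_path):
        path = tmp_path / "bio.csv"
        path.write_text(
            "compound_id,smiles,target_id,endpoint,relation,value,unit\n"
            "c1,CCO,T1,IC50,=,0.24,uM\n"
            "c2,CC,T1,Ki,>,30,uM\n"
        )
        records = read_bioactivity_table(path)
        assert len(records) == 2
        assert records[0].value == 0.24 and records[0].unit == "uM"
        assert records[1].relation == ">"

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,value\nc1,2\n")
        with pytest.raises(ValueError, match="missing"):
            read_bioactivity_table(path)

    def test_prediction_report_layout(self, tmp_path):
        res = [
            PredictionResult(5.5, 0.2, target_id="T1"),
            PredictionResult(3.8, 0.1, target_id="T2"),
        ]
        path = tmp_path / "pred.tsv"
        write_prediction_report(res, path)
        lines = path.read_text().strip().split("\n")
        assert lines[0].split("\t") == [
            "target_id", "mean", "variance", "penalized", "reportable"
        ]
        assert lines[1].endswith("5.3")
        assert lines[2].endswith("<4.0")
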