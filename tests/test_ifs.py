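import numpy as np
import pytest

from aptaselect import (
    DiscretizationSpec,
    SyntheticSpec,
    cross_validate,
    generate_study,
    make_folds,
    mrmr_list,
    optimal_model,
    run_ifs,
    run_pipeline,
    top_fraction_distribution,
    write_study,
)
from aptaselect.ifs import selected_set_distribution
from aptaselect.models import engine_factory
from aptaselect.mrmr import RankedFeatureList, maxrel_list

from conftest import build_dataset, schema_with_descriptors


class TestRunIFS:
    def test_requested_prefix_count(self, small_dataset):
        ranked = mrmr_list(small_dataset)
        folds = make_folds(small_dataset.y, 10, seed=0)
        result = run_ifs(ranked, small_dataset, engine_factory("nna"), folds, i_max=3)
        assert result.sizes == (1, 2, 3)
        assert len(result.metrics) == 3

    def test_label_leak_curve_starts_at_one(self, rng):
        y = np.array([1] * 20 + [0] * 40)
        X = np.column_stack([y.astype(float), rng.normal(size=(60, 3))])
        # rank and evaluate on raw arrays (run_ifs only needs .X and .y)
        ranked = mrmr_list(X, DiscretizationSpec(mode="quantile"), y=y)
        assert ranked.order[0] == 0
        folds = make_folds(y, 10, seed=0)

        class DS:
            pass

        ds = DS()
        ds.X, ds.y = X, y
        result = run_ifs(ranked, ds, engine_factory("nna"), folds)
        assert result.metrics[0].mcc == 1.0
        assert result.optimal_index == 1

    def test_curve_tail_equals_all_feature_cv(self, small_dataset):
        ranked = mrmr_list(small_dataset)
        folds = make_folds(small_dataset.y, 10, seed=0)
        result = run_ifs(ranked, small_dataset, engine_factory("nna"), folds)
        direct, _ = cross_validate(
            engine_factory("nna"),
            small_dataset.X,
            small_dataset.y,
            ranked.order,
            folds,
        )
        assert result.metrics[-1].mcc == pytest.approx(direct.mcc)

    def test_optimal_index_smallest_on_tie(self):
        from aptaselect.evaluation import MetricsReport
        from aptaselect.ifs import IFSResult

        m = MetricsReport(sn=1, sp=1, acc=1, mcc=0.5)
        res = IFSResult(sizes=(1, 2, 3), metrics=(m, m, m), order=(0, 1, 2))
        assert res.optimal_index == 1

    def test_recovers_planted_feature_count_over_seeds(self):
        hits = 0
        for seed in range(10):
            spec = SyntheticSpec(seed=seed)
            study = generate_study(spec)
            ds = build_dataset(study)
            ranked = mrmr_list(ds)
            folds = make_folds(ds.y, 10, seed=seed)
            result = run_ifs(ranked, ds, engine_factory("nna"), folds)
            lo = spec.n_informative
            hi = spec.n_informative + spec.n_redundant
            hits += bool(lo <= result.optimal_index <= hi)
        assert hits >= 8

    def test_invalid_i_max_rejected(self, small_dataset):
        ranked = mrmr_list(small_dataset)
        folds = make_folds(small_dataset.y, 10, seed=0)
        with pytest.raises(ValueError):
            run_ifs(ranked, small_dataset, engine_factory("nna"), folds, i_max=0)


class TestTypeDistribution:
    def test_study_scale_head_size(self):
        schema = schema_with_descriptors(301)
        order = np.arange(321)
        ranked = RankedFeatureList(
            kind="MaxRel", order=order, scores=np.linspace(1, 0, 321)
        )
        dist = top_fraction_distribution(ranked, schema, fraction=0.10)
        assert dist.head_size == 32
        assert sum(dist.counts.values()) == 32

    def test_fraction_one_reproduces_schema_totals(self, small_dataset):
        ranked = maxrel_list(small_dataset)
        dist = top_fraction_distribution(ranked, small_dataset.schema, fraction=1.0)
        assert dist.counts == small_dataset.schema.category_counts()
        assert all(v == pytest.approx(1.0) for v in dist.proportions.values())

    def test_compound_side_signal_excludes_aptamer_features(self, default_dataset):
        ranked = maxrel_list(default_dataset)
        dist = top_fraction_distribution(ranked, default_dataset.schema, fraction=0.10)
        assert dist.counts["aptamer-mono"] == 0
        assert dist.counts["aptamer-di"] == 0
        assert all(0.0 <= v <= 1.0 for v in dist.proportions.values())

    def test_invalid_fraction_rejected(self, small_dataset):
        ranked = maxrel_list(small_dataset)
        with pytest.raises(ValueError):
            top_fraction_distribution(ranked, small_dataset.schema, fraction=0.0)


class TestOptimalModel:
    def test_selected_set_and_training_fit(self, small_dataset):
        ranked = mrmr_list(small_dataset)
        folds = make_folds(small_dataset.y, 10, seed=0)
        result = run_ifs(ranked, small_dataset, engine_factory("nna"), folds, i_max=5)
        model, names = optimal_model(small_dataset, result, engine_factory("nna"))
        assert len(names) == result.optimal_index
        subset = list(result.optimal_features())
        # leave-one-in: NNA reproduces its own training labels
        preds = model.predict(small_dataset.X[:, subset])
        assert np.array_equal(preds, small_dataset.y)
        dist = selected_set_distribution(subset, small_dataset.schema)
        assert sum(dist.counts.values()) == len(subset)


@pytest.fixture(scope="module")
def study_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("study")
    spec = SyntheticSpec(
        n_compounds=60, n_aptamers=10, n_pairs=90,
        n_informative=3, n_redundant=2, n_noise=7, seed=7,
    )
    write_study(generate_study(spec), outdir)
    return outdir


class TestRunPipeline:
    def _config(self, study_dir, **over):
        cfg = {
            "fasta": str(study_dir / "aptamers.fasta"),
            "descriptors": str(study_dir / "descriptors.tsv"),
            "categories": str(study_dir / "descriptor_categories.yaml"),
            "interactions": str(study_dir / "interactions.tsv"),
            "seed": 11,
            "engines": ["nna"],
            "i_max": 12,
        }
        cfg.update(over)
        return cfg

    def test_two_engines_two_curves(self, study_dir, tmp_path):
        out = tmp_path / "bundle"
        summary = run_pipeline(
            self._config(study_dir, engines=["nna", "rf"]), out
        )
        assert (out / "ifs_curve_nna.tsv").exists()
        assert (out / "ifs_curve_rf.tsv").exists()
        assert (out / "maxrel_list.tsv").exists()
        assert (out / "mrmr_list.tsv").exists()
        assert set(summary["engines"]) == {"nna", "rf"}

    def test_i_max_limits_curve_rows(self, study_dir, tmp_path):
        out = tmp_path / "bundle"
        run_pipeline(self._config(study_dir, i_max=5), out)
        lines = (out / "ifs_curve_nna.tsv").read_text().strip().splitlines()
        assert len(lines) == 6  # header + 5 prefix sizes

    def test_byte_identical_bundles_under_same_seed(self, study_dir, tmp_path):
        out1, out2 = tmp_path / "b1", tmp_path / "b2"
        cfg = self._config(study_dir)
        run_pipeline(cfg, out1)
        run_pipeline(cfg, out2)
        files = sorted(p.name for p in out1.iterdir())
        assert files == sorted(p.name for p in out2.iterdir())
        for name in files:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_stage_error_names_stage(self, study_dir, tmp_path):
        cfg = self._config(study_dir, fasta=str(study_dir / "missing.fasta"))
        with pytest.raises(RuntimeError, match="read_fasta"):
            run_pipeline(cfg, tmp_path / "b")
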