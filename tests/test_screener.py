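import numpy as np
import pandas as pd
import pytest

from metascreener import (BinaryLabels, ContinuousState, ExpressionDataset,
                          RunConfig, cor_metascreener, diff_metascreener,
                          enumerate_pipelines, unsupervised_score)


class TestPipelineEnumeration:
    def test_default_diff_registry_yields_138(self):
        specs = enumerate_pipelines(RunConfig(mode="diff"))
        assert len(specs) == 138

    def test_default_cor_registry_yields_230(self):
        specs = enumerate_pipelines(RunConfig(mode="cor"))
        assert len(specs) == 230

    def test_total_strategies_368(self):
        assert (len(enumerate_pipelines(RunConfig(mode="diff")))
                + len(enumerate_pipelines(RunConfig(mode="cor")))) == 368

    def test_single_scorer_single_test(self):
        specs = enumerate_pipelines(RunConfig(mode="diff", scorers=["zscore"],
                                              diff_tests=["ttest"]))
        assert len(specs) == 1
        assert not specs[0].supervised

    def test_supervised_flag_set(self):
        specs = enumerate_pipelines(RunConfig(mode="diff", scorers=["fgsea", "ora"],
                                              diff_tests=["ttest", "limma"]))
        assert len(specs) == 4
        assert all(s.supervised for s in specs)

    def test_empty_registry_rejected(self):
        with pytest.raises(ValueError):
            enumerate_pipelines(RunConfig(mode="diff", scorers=[]))


class TestDiffScreen:
    def test_planted_recovery(self, tiny_cohort, reduced_diff_config):
        datasets, signatures, truth = tiny_cohort
        table = diff_metascreener(datasets, signatures, reduced_diff_config)
        di = table.di
        activated = [s for s, d in truth.directions.items() if d == 1][0]
        inhibited = [s for s, d in truth.directions.items() if d == -1][0]
        assert di.idxmax() == activated and di[activated] > 0
        assert di.idxmin() == inhibited and di[inhibited] < 0

    def test_deterministic_under_seed(self, tiny_cohort, reduced_diff_config):
        datasets, signatures, _ = tiny_cohort
        t1 = diff_metascreener(datasets, signatures, reduced_diff_config)
        t2 = diff_metascreener(datasets, signatures, reduced_diff_config)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_dataset_order_invariance(self, tiny_cohort, reduced_diff_config):
        datasets, signatures, _ = tiny_cohort
        t1 = diff_metascreener(datasets, signatures, reduced_diff_config)
        t2 = diff_metascreener(datasets[::-1], signatures, reduced_diff_config)
        pd.testing.assert_frame_equal(t1.table, t2.table)

    def test_duplicated_dataset_preserves_di_signs(self, tiny_cohort, reduced_diff_config):
        datasets, signatures, _ = tiny_cohort
        t1 = diff_metascreener(datasets, signatures, reduced_diff_config)
        dup = ExpressionDataset("copy", datasets[0].values, datasets[0].annotation)
        t2 = diff_metascreener(datasets + [dup], signatures, reduced_diff_config)
        strong = t1.di[abs(t1.di) > 0.5].index
        assert (np.sign(t1.di[strong]) == np.sign(t2.di[strong])).all()

    def test_all_datasets_invalid_errors(self, tiny_cohort, reduced_diff_config):
        datasets, signatures, _ = tiny_cohort
        stripped = [ExpressionDataset(d.name, d.values, None) for d in datasets]
        with pytest.raises(ValueError, match="no usable datasets"):
            diff_metascreener(stripped, signatures, reduced_diff_config)


class TestCorScreen:
    def test_planted_recovery(self, tiny_cohort_cont, reduced_cor_config):
        datasets, signatures, truth = tiny_cohort_cont
        table = cor_metascreener(datasets, signatures, reduced_cor_config)
        di = table.di
        activated = [s for s, d in truth.directions.items() if d == 1][0]
        inhibited = [s for s, d in truth.directions.items() if d == -1][0]
        assert di.idxmax() == activated and di[activated] > 0
        assert di.idxmin() == inhibited and di[inhibited] < 0

    def test_state_negation_flips_di_signs(self, tiny_cohort_cont, reduced_cor_config):
        datasets, signatures, _ = tiny_cohort_cont
        t1 = cor_metascreener(datasets, signatures, reduced_cor_config)
        negated = [ExpressionDataset(d.name, d.values,
                                     ContinuousState({s: -v for s, v in d.annotation.values.items()}))
                   for d in datasets]
        t2 = cor_metascreener(negated, signatures, reduced_cor_config)
        np.testing.assert_allclose(t2.di[t1.di.index], -t1.di, atol=1e-6)

    def test_constant_state_dataset_dropped_run_proceeds(self, tiny_cohort_cont,
                                                         reduced_cor_config):
        datasets, signatures, _ = tiny_cohort_cont
        flat = ExpressionDataset("flat", datasets[0].values,
                                 ContinuousState({s: 1.0 for s in datasets[0].samples}))
        t = cor_metascreener(datasets + [flat], signatures, reduced_cor_config)
        assert "flat" not in t.per_dataset
        assert set(t.per_dataset) == {d.name for d in datasets}


class TestUnsupervisedScore:
    def test_contrast_identical_to_training_labels(self, tiny_cohort, reduced_diff_config):
        datasets, signatures, _ = tiny_cohort
        contrasts = {"same": {d.name: d.annotation for d in datasets}}
        tables = unsupervised_score(datasets, signatures, contrasts, reduced_diff_config)
        direct = diff_metascreener(datasets, signatures, reduced_diff_config)
        pd.testing.assert_frame_equal(tables["same"].table, direct.table)

    def test_two_contrasts_give_two_tables(self, tiny_cohort, reduced_diff_config):
        datasets, signatures, _ = tiny_cohort
        flipped = {
            d.name: BinaryLabels({s: ("inhibition" if l == "activation" else "activation")
                                  for s, l in d.annotation.labels.items()})
            for d in datasets}
        contrasts = {"orig": {d.name: d.annotation for d in datasets},
                     "flip": flipped}
        tables = unsupervised_score(datasets, signatures, contrasts, reduced_diff_config)
        assert set(tables) == {"orig", "flip"}
        # flipping every label mirrors the ranking
        np.testing.assert_allclose(tables["flip"].di[tables["orig"].di.index],
                                   -tables["orig"].di, atol=1e-6)

    def test_contrast_with_one_empty_class_drops_dataset(self, tiny_cohort,
                                                         reduced_diff_config):
        datasets, signatures, _ = tiny_cohort
        broken = BinaryLabels({s: "activation" for s in datasets[0].samples})
        contrasts = {"c": {datasets[0].name: broken,
                           datasets[1].name: datasets[1].annotation}}
        tables = unsupervised_score(datasets, signatures, contrasts, reduced_diff_config)
        assert set(tables["c"].per_dataset) == {datasets[1].name}


class TestSupervisedPath:
    def test_supervised_only_run_recovers_planted(self, tiny_cohort):
        datasets, signatures, truth = tiny_cohort
        cfg = RunConfig(mode="diff", seed=3, scorers=["fgsea", "ora"],
                        diff_tests=["ttest"], n_perm_fgsea=300, ora_top_k=50)
        table = diff_metascreener(datasets, signatures, cfg)
        activated = [s for s, d in truth.directions.items() if d == 1][0]
        inhibited = [s for s, d in truth.directions.items() if d == -1][0]
        assert table.di.idxmax() == activated
        assert table.di.idxmin() == inhibited

    def test_mlm_disabled_for_collinear_signatures(self, tiny_cohort, caplog):
        import logging
        datasets, signatures, _ = tiny_cohort
        dup_sets = dict(signatures.sets)
        dup_sets["SIG00_COPY"] = list(signatures["SIG00"])
        from metascreener import SignatureCollection
        sigs = SignatureCollection(dup_sets)
        cfg = RunConfig(mode="diff", seed=3, scorers=["mean", "mlm"],
                        diff_tests=["ttest"])
        with caplog.at_level(logging.INFO, logger="metascreener"):
            diff_metascreener([datasets[0]], sigs, cfg)
        assert any("mlm/mdt disabled" in r.message for r in caplog.records)
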