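"""Fold planning, leakage enforcement, classifier contracts."""

import numpy as np
import pytest

from latentaug import (
    FixtureConfig,
    LeakageError,
    SmallCnn,
    TrainConfig,
    ValidationError,
    generate_fixture_dataset,
    make_fold_plan,
    predict_scores,
    run_experiment,
)
from latentaug.harness import FoldPlan
from latentaug.vae import VaeConfig


class TestFoldPlan:
    def test_grouped_kfold_partitions_patients(self, small_cohort):
        plan = make_fold_plan(small_cohort, "GROUPED_KFOLD", n_folds=4, seed=0)
        all_test = [p for _, _, test in plan.folds for p in test]
        patients = {r.patient_id for r in small_cohort}
        assert sorted(all_test) == sorted(patients)  # each patient tested once

    def test_fellow_eyes_never_straddle(self, small_cohort):
        plan = make_fold_plan(small_cohort, "GROUPED_KFOLD", n_folds=4, seed=1)
        for _, train, test in plan.folds:
            for rec in small_cohort:
                assert (rec.patient_id in train) != (rec.patient_id in test)

    def test_repeated_8020_split_sizes(self, small_cohort):
        plan = make_fold_plan(small_cohort, "REPEATED_8020", n_folds=5, seed=2)
        n_patients = len({r.patient_id for r in small_cohort})
        assert len(plan.folds) == 5
        for _, train, test in plan.folds:
            assert len(test) == int(np.ceil(0.2 * n_patients))
            assert not (train & test)

    def test_deterministic(self, small_cohort):
        a = make_fold_plan(small_cohort, n_folds=4, seed=7)
        b = make_fold_plan(small_cohort, n_folds=4, seed=7)
        assert a.folds == b.folds

    def test_too_few_patients_rejected(self, small_cohort):
        with pytest.raises(ValidationError):
            make_fold_plan(small_cohort[:6], "GROUPED_KFOLD", n_folds=5, seed=0)

    def test_single_class_rejected(self, small_cohort):
        one = [r for r in small_cohort if r.label == "AUTOSOMAL"]
        with pytest.raises(ValidationError):
            make_fold_plan(one, n_folds=2, seed=0)

    def test_overlapping_plan_rejected(self):
        with pytest.raises(ValidationError):
            FoldPlan(
                folds=[(0, frozenset({"P0", "P1"}), frozenset({"P1"}))],
                mode="GROUPED_KFOLD",
                n_folds=1,
                seed=0,
            )


class TestSmallCnn:
    def test_scores_in_unit_interval(self, small_cohort, fast_train_config):
        model = SmallCnn(32, fast_train_config)
        model.fit(small_cohort)
        scores = model.predict_scores(small_cohort)
        assert scores.shape == (len(small_cohort),)
        assert (scores >= 0).all() and (scores <= 1).all()

    def test_eval_mode_deterministic(self, small_cohort, fast_train_config):
        model = SmallCnn(32, fast_train_config)
        model.fit(small_cohort)
        s1 = model.predict_scores(small_cohort[:4])
        s2 = model.predict_scores(small_cohort[:4])
        assert np.array_equal(s1, s2)

    def test_training_deterministic_given_seed(self, small_cohort):
        cfgs = [TrainConfig(epochs=2, seed=5) for _ in range(2)]
        scores = []
        for cfg in cfgs:
            m = SmallCnn(32, cfg)
            m.fit(small_cohort)
            scores.append(m.predict_scores(small_cohort[:6]))
        assert np.array_equal(scores[0], scores[1])

    def test_empty_predict(self, small_cohort, fast_train_config):
        model = SmallCnn(32, fast_train_config)
        model.fit(small_cohort)
        assert predict_scores(model, []) == []

    def test_shape_mismatch_rejected(self, small_cohort, cohort64, fast_train_config):
        model = SmallCnn(32, fast_train_config)
        model.fit(small_cohort)
        with pytest.raises(ValidationError):
            model.predict_scores(cohort64[:1])


class TestRunExperiment:
    @pytest.fixture(scope="class")
    def tiny_setup(self):
        records = generate_fixture_dataset(
            FixtureConfig(n_patients=12, image_side=32, seed=21)
        )
        plan = make_fold_plan(records, n_folds=3, seed=21)
        return records, plan

    def test_gen1_doubles_training_set(self, tiny_setup):
        records, plan = tiny_setup
        vcfg = VaeConfig(input_side=32, epochs=5, latent_dim=8, hidden=64)
        tcfg = TrainConfig(epochs=2)
        base = run_experiment(records, plan, "NONE", tcfg, global_seed=4)
        gen1 = run_experiment(records, plan, "GEN1", tcfg, vae_config=vcfg, global_seed=4)
        for fb, f1 in zip(base.fold_details, gen1.fold_details):
            assert f1["n_train_total"] == 2 * fb["n_train_total"]
            assert fb["n_train_real"] == f1["n_train_real"]

    def test_one_score_per_test_record_per_fold(self, tiny_setup):
        records, plan = tiny_setup
        rep = run_experiment(records, plan, "NONE", TrainConfig(epochs=2), global_seed=1)
        for detail in rep.fold_details:
            fold_preds = [p for p in rep.predictions if p["fold"] == detail["fold"]]
            assert sorted(p["record_id"] for p in fold_preds) == detail["test_record_ids"]
        assert all(0.0 <= p["score"] <= 1.0 for p in rep.predictions)

    def test_synthetic_parents_stay_in_training_split(self, tiny_setup):
        records, plan = tiny_setup
        vcfg = VaeConfig(input_side=32, epochs=5, latent_dim=8, hidden=64)
        rep = run_experiment(
            records, plan, "GEN2", TrainConfig(epochs=2), vae_config=vcfg, global_seed=2
        )
        for detail in rep.fold_details:
            assert set(detail["synthetic_parent_ids"]) <= set(detail["train_record_ids"])
            assert not set(detail["synthetic_parent_ids"]) & set(detail["test_record_ids"])

    def test_patient_straddling_plan_rejected_at_construction(self, tiny_setup):
        records, _ = tiny_setup
        patients = sorted({r.patient_id for r in records})
        with pytest.raises(ValidationError):
            FoldPlan(
                folds=[(0, frozenset(patients[:-1]), frozenset([patients[-1], patients[0]]))],
                mode="REPEATED_8020",
                n_folds=1,
                seed=0,
            )

    def test_synthetic_parent_outside_training_split_raises(self, tiny_setup, monkeypatch):
        """A corrupt expander whose synthetic points at a test record trips
        the hard leakage failure."""
        import latentaug.harness as harness_mod

        records, plan = tiny_setup
        _, _, test_pats = plan.folds[0]
        test_rec = next(r for r in records if r.patient_id in test_pats)

        def corrupt_expander(train_recs, codec, seed=0):
            bad = train_recs[0].with_pixels(train_recs[0].pixels)
            bad.provenance = "SYNTHETIC_GEN1"
            bad.parent_ids = [test_rec.record_id]
            bad.record_id = "corrupt"
            bad.label = test_rec.label
            return list(train_recs) + [bad]

        monkeypatch.setattr(harness_mod, "expand_gen1", corrupt_expander)
        vcfg = VaeConfig(input_side=32, epochs=1, latent_dim=8, hidden=64)
        with pytest.raises(LeakageError):
            run_experiment(
                records, plan, "GEN1", TrainConfig(epochs=1), vae_config=vcfg,
                global_seed=0,
            )

    def test_invalid_expansion_rejected(self, tiny_setup):
        records, plan = tiny_setup
        with pytest.raises(ValidationError):
            run_experiment(records, plan, "GEN3", TrainConfig(epochs=1))

    def test_strong_signal_is_learnable(self):
        """A clearly-above-noise speckle signal on a moderate cohort yields
        pooled AUC well above chance without any expansion."""
        records = generate_fixture_dataset(
            FixtureConfig(n_patients=40, effect_size=1.5, seed=3)
        )
        plan = make_fold_plan(records, n_folds=5, seed=3)
        report = run_experiment(records, plan, "NONE", global_seed=3)
        assert report.pooled_auc > 0.8
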