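"""Split plans, ensemble training, leakage audit, grid search."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from adprog import (
    Ensemble,
    GeneratorConfig,
    ModelSpec,
    TrainingConfig,
    build_cohort_tables,
    default_strata,
    grid_search_architecture,
    grid_spec,
    make_splits,
)
from adprog.training import (
    SplitPlan,
    train_ensemble,
    train_single_model,
)
from sklearn.metrics import roc_auc_score

FAST = TrainingConfig(lr=1e-3, max_epochs=30, patience=3, eval_every=5,
                      n_folds=5, n_inits=2, dtype="float32",
                      delta_t_scale=12.0)


@pytest.fixture(scope="module")
def tiny_tables():
    cfg = GeneratorConfig(n_participants=260, seed=21)
    baseline, labels, _, _ = build_cohort_tables(cfg)
    return baseline, labels


class TestMakeSplits:
    def test_hundred_subjects_give_twenty_test(self):
        ids = [f"p{i}" for i in range(100)]
        strata = pd.Series("all", index=ids)
        plan = make_splits(ids, strata, n_repeats=1, seed=0)
        assert len(plan.repeats[0].test_ids) == 20

    def test_stratified_allocation_within_one_subject(self):
        ids = [f"c{i}" for i in range(60)] + [f"m{i}" for i in range(40)]
        strata = pd.Series(["CN"] * 60 + ["MCI"] * 40, index=ids)
        plan = make_splits(ids, strata, n_repeats=5, seed=1)
        for rep in plan.repeats:
            n_cn = sum(i.startswith("c") for i in rep.test_ids)
            n_mci = sum(i.startswith("m") for i in rep.test_ids)
            assert abs(n_cn - 12) <= 1 and abs(n_mci - 8) <= 1

    def test_determinism_and_fold_partition(self):
        ids = [f"p{i}" for i in range(83)]
        strata = pd.Series(np.where(np.arange(83) % 3 == 0, "A", "B"), index=ids)
        a = make_splits(ids, strata, n_repeats=3, seed=9)
        b = make_splits(ids, strata, n_repeats=3, seed=9)
        assert a.to_json() == b.to_json()
        for rep in a.repeats:
            train = rep.train_ids
            assert set(train) | set(rep.test_ids) == set(ids)
            assert not set(train) & set(rep.test_ids)
            assert sorted(sum(map(list, rep.folds), [])) == sorted(train)

    def test_json_round_trip(self):
        ids = [f"p{i}" for i in range(40)]
        plan = make_splits(ids, pd.Series("s", index=ids), n_repeats=2, seed=3)
        restored = SplitPlan.from_json(plan.to_json())
        assert restored.repeats[1].test_ids == plan.repeats[1].test_ids

    def test_small_strata_merge_into_parent(self, tiny_tables):
        baseline, labels = tiny_tables
        few = baseline.iloc[:40]
        strata = default_strata(few, labels[labels["id"].isin(few["id"])],
                                min_stratum=5)
        # merged strata have no "/" suffix when under-populated
        sizes = strata.value_counts()
        assert (sizes >= 5).all() or any("/" not in s for s in sizes.index)


class TestEnsembleTraining:
    def test_provenance_reports_folds_times_inits(self, tiny_tables):
        baseline, labels = tiny_tables
        plan = make_splits(baseline["id"],
                           default_strata(baseline, labels),
                           n_repeats=1, seed=2)
        preds, rm = train_ensemble(baseline, labels, plan.repeats[0], "nmm",
                                   spec=ModelSpec.desk("nmm"), cfg=FAST)
        assert preds.provenance[0] == FAST.n_folds * FAST.n_inits
        assert rm.ensemble_for(None).member_count == 10

    def test_member_training_is_deterministic(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(60, 10))
        Y = np.eye(3)[rng.integers(0, 3, 60)]
        w = np.ones(60)
        spec = ModelSpec(input_width=10, hidden_layout=((8, 2),))
        args = (X[:40], Y[:40], w[:40], X[40:], Y[40:], w[40:], spec, FAST, 77)
        m1, v1 = train_single_model(*args)
        m2, v2 = train_single_model(*args)
        assert v1 == v2
        for a, b in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_ensemble_average_is_member_order_invariant(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        spec = ModelSpec(input_width=10, hidden_layout=((8, 2),))
        from adprog.models_loss import MLP
        members = [MLP(spec, s) for s in range(4)]
        e1 = Ensemble(members=members, encoder=None, kind="nsm")
        e2 = Ensemble(members=members[::-1], encoder=None, kind="nsm")
        np.testing.assert_allclose(e1.predict_proba_encoded(X),
                                   e2.predict_proba_encoded(X), atol=1e-12)

    def test_separable_toy_problem_reaches_high_auc(self):
        """A nonlinear single-year ensemble separates a linearly separable
        two-class encoding almost perfectly (a logistic fit would)."""
        rng = np.random.default_rng(7)
        X = rng.normal(size=(1100, 113))
        score = X[:, 20] + 0.8 * X[:, 21]
        y = (score > 0).astype(int)
        Y = np.eye(3)[y]
        w = np.ones(1100)
        cfg = dataclasses.replace(FAST, lr=3e-3, max_epochs=800, patience=40)
        # unit-weight loss is ~1e3 times the pipeline's weighted loss, so
        # the L2 coefficient scales up accordingly
        spec = ModelSpec(input_width=113, hidden_layout=((64, 2),),
                         l2_weight=1e-3)
        members = []
        for s in range(2):
            m, _ = train_single_model(X[:800], Y[:800], w[:800],
                                      X[800:1000], Y[800:1000], w[800:1000],
                                      spec, cfg, init_seed=s)
            members.append(m)
        ens = Ensemble(members=members, encoder=None, kind="nsm")
        P = ens.predict_proba_encoded(X[1000:])
        assert roc_auc_score(y[1000:], P[:, 1]) >= 0.95


class TestLeakageAudit:
    def test_encoder_and_weights_ignore_test_rows(self, tiny_tables):
        """Perturbing test participants' features and labels leaves the
        fitted encoder statistics and the weight plan bit-identical."""
        baseline, labels = tiny_tables
        plan = make_splits(baseline["id"],
                           default_strata(baseline, labels),
                           n_repeats=1, seed=4)
        split = plan.repeats[0]
        _, rm = train_ensemble(baseline, labels, split, "nsm",
                               spec=ModelSpec.desk("nsm"), cfg=FAST)

        perturbed = baseline.copy()
        test_mask = perturbed["id"].isin(split.test_ids)
        for col in ("mmse", "age", "csf_abeta"):
            perturbed.loc[test_mask, col] = 999.0
        _, rm2 = train_ensemble(perturbed, labels, split, "nsm",
                                spec=ModelSpec.desk("nsm"), cfg=FAST)
        assert rm.encoder.fingerprint == rm2.encoder.fingerprint
        assert rm.weight_plan.weights == rm2.weight_plan.weights


class TestGridSearch:
    def test_grid_spec_block_rule(self):
        assert grid_spec(64, 1).hidden_layout == ((64, 3),)
        assert grid_spec(128, 2).hidden_layout == ((128, 3), (64, 5))
        assert grid_spec(256, 3).hidden_layout == ((256, 3), (128, 5), (64, 2))
        assert grid_spec(64, 1, multi_year=True).input_width == 114

    def test_singleton_grid_returns_the_candidate(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(50, 10))
        Y = np.eye(3)[rng.integers(0, 3, 50)]
        w = np.ones(50)
        only = ModelSpec(input_width=10, hidden_layout=((8, 2),))
        best, loss = grid_search_architecture(
            [only], X[:30], Y[:30], w[:30], X[30:], Y[30:], w[30:], cfg=FAST)
        assert best == only
        assert np.isfinite(loss)

    def test_argmin_by_validation_loss(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(120, 10))
        y = (X[:, 0] > 0).astype(int)
        Y = np.eye(3)[y]
        w = np.ones(120)
        cfg = dataclasses.replace(FAST, max_epochs=80, patience=10)
        good = ModelSpec(input_width=10, hidden_layout=((16, 2),))
        tiny = ModelSpec(input_width=10, hidden_layout=((1, 1),))
        best, _ = grid_search_architecture(
            [tiny, good], X[:80], Y[:80], w[:80], X[80:], Y[80:], w[80:],
            cfg=cfg)
        assert best == good


def test_training_config_yaml_round_trip():
    cfg = TrainingConfig.reduced(seed=9)
    assert TrainingConfig.from_yaml(cfg.to_yaml()) == cfg
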