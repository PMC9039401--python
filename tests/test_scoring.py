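import numpy as np
import pandas as pd
import pytest

from mirmodulenet.io_expression import ExpressionDataset, PairedOmicsDataset, StarModule
from mirmodulenet.scoring import (
    GroupScoreRecord,
    classification_metrics,
    make_sub_data,
    score_all_groups,
    score_group,
)


def _paired_from(mrna_dict, labels):
    idx = [f"s{i:02d}" for i in range(len(labels))]
    mrna = pd.DataFrame(mrna_dict).T
    mrna.columns = idx
    mirna = pd.DataFrame(
        np.zeros((1, len(idx))) + np.arange(len(idx)), index=["miR-x"], columns=idx
    )
    y = pd.Series(np.asarray(labels, dtype=np.int8), index=idx)
    return PairedOmicsDataset(
        ExpressionDataset(mirna, "miRNA"), ExpressionDataset(mrna, "mRNA"), y
    )


def _module(members, center="miR-x"):
    members = tuple(sorted(members))
    return StarModule(center_mirna=center, seed_mrna=members[0], members=members)


class TestMakeSubData:
    def test_shape_and_column_order(self, small_paired):
        module = StarModule("miR-driver", "gene-t1", ("gene-t1", "gene-t0", "gene-n2"))
        X, y = make_sub_data(small_paired, module)
        assert X.shape == (20, 3)
        assert list(X.columns) == ["gene-t1", "gene-t0", "gene-n2"]
        assert list(y.index) == list(X.index)

    def test_union_of_modules_deduplicates(self, small_paired):
        a = _module(["gene-t0", "gene-t1"], "miR-driver")
        b = _module(["gene-t1", "gene-n0"], "miR-noise1")
        union = _module(sorted(set(a.members) | set(b.members)), "miR-driver")
        X, _ = make_sub_data(small_paired, union)
        assert sorted(X.columns) == ["gene-n0", "gene-t0", "gene-t1"]

    def test_missing_member_rejected(self, small_paired):
        module = _module(["gene-t0", "gene-missing"], "miR-driver")
        with pytest.raises(KeyError):
            make_sub_data(small_paired, module)


class TestClassificationMetrics:
    def test_perfect_prediction_gives_kappa_one(self):
        y = np.array([1, 1, 0, 0, 1, 0])
        m = classification_metrics(y, y, y.astype(float))
        assert m["cohens_kappa"] == pytest.approx(1.0)
        assert m["accuracy"] == m["sensitivity"] == m["specificity"] == 1.0
        assert m["auc"] == 1.0

    def test_confusion_matrix_arithmetic(self):
        y_true = np.array([1, 1, 1, 0, 0, 0])
        y_pred = np.array([1, 1, 0, 0, 0, 1])
        m = classification_metrics(y_true, y_pred, y_pred.astype(float))
        assert m["sensitivity"] == pytest.approx(2 / 3)
        assert m["specificity"] == pytest.approx(2 / 3)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["f_measure"] == pytest.approx(2 / 3)


class TestScoreGroup:
    def test_separable_data_scores_perfectly(self):
        rng = np.random.default_rng(0)
        labels = [1] * 30 + [0] * 30
        offs = 10.0 * np.asarray(labels)
        paired = _paired_from(
            {f"g{j}": offs + rng.normal(size=60) for j in range(3)}, labels
        )
        metrics = score_group(make_sub_data(paired, _module(["g0", "g1", "g2"])), k=5, rng_seed=0)
        assert metrics["auc"] == 1.0
        assert metrics["accuracy"] >= 0.95

    def test_null_feature_auc_near_half(self):
        rng = np.random.default_rng(1)
        aucs = []
        for s in range(10):
            labels = list(rng.permutation([1] * 30 + [0] * 30))
            paired = _paired_from({"g0": rng.normal(size=60)}, labels)
            aucs.append(score_group(make_sub_data(paired, _module(["g0"])), k=5, rng_seed=s)["auc"])
        assert 0.3 <= np.mean(aucs) <= 0.7

    def test_fold_reduction_warns_on_tiny_minority(self):
        rng = np.random.default_rng(2)
        labels = [1] * 3 + [0] * 17
        paired = _paired_from({"g0": rng.normal(size=20)}, labels)
        with pytest.warns(UserWarning, match="reducing inner folds"):
            score_group(make_sub_data(paired, _module(["g0"])), k=5, rng_seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        labels = [1] * 12 + [0] * 12
        paired = _paired_from({f"g{j}": rng.normal(size=24) for j in range(2)}, labels)
        sub = make_sub_data(paired, _module(["g0", "g1"]))
        assert score_group(sub, k=3, rng_seed=9) == score_group(sub, k=3, rng_seed=9)


class TestScoreAllGroups:
    def _records(self, aucs, accs=None):
        accs = accs or [0.5] * len(aucs)
        recs = []
        for i, (auc, acc) in enumerate(zip(aucs, accs)):
            recs.append((f"miR-{chr(97 + i)}", auc, acc))
        return recs

    def test_ranking_by_auc_descending(self):
        rng = np.random.default_rng(4)
        labels = [1] * 20 + [0] * 20
        sig = 5.0 * np.asarray(labels) + rng.normal(size=40)
        paired = _paired_from(
            {"good": sig, "weak": 0.5 * np.asarray(labels) + rng.normal(size=40),
             "noise": rng.normal(size=40)},
            labels,
        )
        modules = [
            _module(["noise"], "miR-noise"),
            _module(["good"], "miR-good"),
            _module(["weak"], "miR-weak"),
        ]
        records = score_all_groups(paired, modules, k=4, rng_seed=0)
        assert records[0].module.center_mirna == "miR-good"
        assert [r.rank for r in records] == [1, 2, 3]
        assert records[0].auc >= records[1].auc >= records[2].auc

    def test_informative_module_outranks_noise_modules(self):
        # planted module beats pure-noise modules in >= 95% of seeds
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(100 + s)
            labels = [1] * 50 + [0] * 50
            y = np.asarray(labels)
            data = {f"sig{j}": 2.0 * y + rng.normal(size=100) for j in range(3)}
            data.update({f"noise{j}": rng.normal(size=100) for j in range(6)})
            paired = _paired_from(data, labels)
            modules = [
                _module([f"sig{j}" for j in range(3)], "miR-planted"),
                _module(["noise0", "noise1", "noise2"], "miR-junkA"),
                _module(["noise3", "noise4", "noise5"], "miR-junkB"),
            ]
            records = score_all_groups(paired, modules, k=5, rng_seed=s)
            wins += records[0].module.center_mirna == "miR-planted"
        assert wins >= 19

    def test_tie_break_alphabetical(self):
        rng = np.random.default_rng(5)
        labels = [1] * 20 + [0] * 20
        shared = 10.0 * np.asarray(labels) + 0.01 * rng.normal(size=40)
        paired = _paired_from({"gA": shared, "gB": shared.copy()}, labels)
        modules = [_module(["gB"], "miR-b"), _module(["gA"], "miR-a")]
        records = score_all_groups(paired, modules, k=4, rng_seed=0)
        # identical features -> identical metrics -> alphabetical order
        assert [r.module.center_mirna for r in records] == ["miR-a", "miR-b"]
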