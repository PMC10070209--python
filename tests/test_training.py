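import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mnox.synthetic_data import (
    REFERENCE_CENTERS, REFERENCE_COUNTS, MixtureSpec, gen_feature_table,
)
from mnox.training import (
    LABELS, LabeledFeatureTable, OxidationModel, TrainingError, curate,
    evaluate, export_dt_rules, fit_dt, fit_gnb, kmeans_relabel, parse_dt_rules,
    predict,
)


def table_from(rows):
    return LabeledFeatureTable(pd.DataFrame(rows, columns=["id", "E", "A", "label"]))


def blob_table(centers=REFERENCE_CENTERS, n=60, sigma=0.005, seed=0):
    """Tight Gaussian blobs at given centers, correctly labeled."""
    rng = np.random.default_rng(seed)
    rows = []
    for lab in LABELS:
        c = np.asarray(centers[lab])
        for k in range(n):
            e, a = c + rng.normal(0, sigma, 2)
            rows.append((f"{lab}{k}", e, a, lab))
    return table_from(rows)


class TestLabeledFeatureTable:
    def test_validation(self):
        with pytest.raises(TrainingError, match="missing columns"):
            LabeledFeatureTable(pd.DataFrame({"id": [1], "E": [2.0]}))
        with pytest.raises(TrainingError, match="labels outside"):
            table_from([("a", 2.0, 2.1, "V")])
        with pytest.raises(TrainingError, match="not unique"):
            table_from([("a", 2.0, 2.1, "II"), ("a", 2.0, 2.2, "III")])

    def test_csv_round_trip(self, tmp_path):
        t = blob_table(n=5)
        t.to_csv(tmp_path / "t.csv")
        back = LabeledFeatureTable.from_csv(tmp_path / "t.csv")
        pd.testing.assert_frame_equal(t.df, back.df)


class TestCurate:
    def test_boundary_exclusive(self):
        df = pd.DataFrame({
            "id": ["a", "b", "c"], "E": [2.0] * 3, "A": [2.1] * 3,
            "label": ["II"] * 3, "r_factor": [0.05, 0.075, 0.10],
        })
        out = curate(LabeledFeatureTable(df), max_r_factor=0.075)
        assert list(out.df["id"]) == ["a"]

    def test_empty_table(self):
        df = pd.DataFrame({"id": [], "E": [], "A": [], "label": [], "r_factor": []})
        assert len(curate(LabeledFeatureTable(df))) == 0

    def test_missing_metadata_errors(self):
        t = blob_table(n=3)
        with pytest.raises(TrainingError, match="r_factor"):
            curate(t, max_r_factor=0.075)
        with pytest.raises(TrainingError, match="error_free"):
            curate(t, max_r_factor=None, require_error_free=True)

    def test_matches_brute_force_filter(self, rng):
        n = 100
        df = pd.DataFrame({
            "id": [f"r{i}" for i in range(n)],
            "E": rng.uniform(1.9, 2.2, n), "A": rng.uniform(2.0, 2.3, n),
            "label": rng.choice(LABELS, n),
            "r_factor": rng.uniform(0.0, 0.15, n),
            "error_free": rng.integers(0, 2, n).astype(bool),
        })
        out = curate(LabeledFeatureTable(df), max_r_factor=0.075,
                     require_error_free=True)
        expected = [i for i in range(n)
                    if df.loc[i, "r_factor"] < 0.075 and df.loc[i, "error_free"]]
        assert list(out.df["id"]) == [f"r{i}" for i in expected]
        # row order preserved
        assert list(out.df["id"]) == sorted(out.df["id"],
                                            key=lambda s: int(s[1:]))


class TestKMeansRelabel:
    def test_recovers_printed_centers(self):
        t = blob_table(sigma=0.005, n=50)
        model, relabeled = kmeans_relabel(t, seed=0)
        for lab in LABELS:
            np.testing.assert_allclose(model.center_of(lab),
                                       REFERENCE_CENTERS[lab], atol=0.01)
        assert (relabeled.df["label"] == t.df["label"]).all()

    def test_exact_fixed_point_three_points(self):
        t = table_from([
            ("a", 2.18, 2.28, "II"), ("b", 2.18, 2.28, "II"),
            ("c", 1.95, 2.26, "III"), ("d", 1.95, 2.26, "III"),
            ("e", 1.91, 2.05, "IV"), ("f", 1.91, 2.05, "IV"),
        ])
        model, _ = kmeans_relabel(t, seed=0)
        got = {tuple(np.round(c, 10)) for c in model.centers}
        assert got == {(2.18, 2.28), (1.95, 2.26), (1.91, 2.05)}

    def test_fixed_point_property(self):
        t = blob_table(sigma=0.02, n=80, seed=4)
        model, relabeled = kmeans_relabel(t, seed=1)
        X = t.X
        assigned = model.assign(X)
        assert (assigned == relabeled.df["label"].to_numpy()).all()
        for idx in range(3):
            lab = model.cluster_to_label[idx]
            members = X[assigned == lab]
            np.testing.assert_allclose(members.mean(axis=0), model.centers[idx],
                                       atol=1e-9)

    def test_idempotent(self):
        t = blob_table(sigma=0.03, n=100, seed=9)
        model1, once = kmeans_relabel(t, seed=5)
        model2, twice = kmeans_relabel(once, seed=5)
        assert (once.df["label"] == twice.df["label"]).all()

    def test_mislabeled_mixture_recovery(self):
        """>= 95% of ground-truth labels recovered at 10% mislabeling."""
        spec = MixtureSpec(counts={"II": 400, "III": 250, "IV": 80},
                           mislabel_rate=0.10, seed=11)
        synth = gen_feature_table(spec)
        _, relabeled = kmeans_relabel(synth.table, seed=0)
        assert synth.label_agreement(relabeled.df["label"]) >= 0.95

    def test_too_few_points(self):
        t = table_from([("a", 2.0, 2.1, "II"), ("b", 2.0, 2.1, "II"),
                        ("c", 2.0, 2.1, "III")])
        with pytest.raises(TrainingError, match="3 distinct"):
            kmeans_relabel(t)


class TestGNB:
    def test_symmetric_1d_boundary(self):
        rows = [(f"a{i}", 1.0 + 0.001 * i, 2.0, "IV") for i in range(5)]
        rows += [(f"b{i}", 2.0 + 0.001 * i, 2.0, "II") for i in range(5)]
        rows += [(f"c{i}", 5.0 + 0.001 * i, 2.0, "III") for i in range(5)]
        model = fit_gnb(table_from(rows))
        assert predict(model, (1.2, 2.0)) == "IV"
        assert predict(model, (1.9, 2.0)) == "II"

    def test_means_match_cluster_centers(self):
        """After full relabeling, class means equal the K-means centers."""
        t = blob_table(sigma=0.02, n=120, seed=2)
        cluster, relabeled = kmeans_relabel(t, seed=0)
        model = fit_gnb(relabeled)
        for i, lab in enumerate(LABELS):
            np.testing.assert_allclose(model.gnb_means[i], cluster.center_of(lab),
                                       atol=1e-9)

    def test_posterior_sums_to_one(self, rng):
        model = fit_gnb(blob_table(n=30))
        X = rng.uniform(1.8, 2.4, size=(50, 2))
        p = model.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_posterior_matches_independent_oracle(self, rng):
        """Prediction equals a scipy.stats.norm posterior computed directly."""
        t = blob_table(sigma=0.04, n=40, seed=8)
        model = fit_gnb(t)
        X = t.X
        y = t.y
        grid = np.stack(np.meshgrid(np.linspace(1.8, 2.4, 100),
                                    np.linspace(1.8, 2.4, 100)), axis=-1).reshape(-1, 2)
        # oracle: per-class sample stats + scipy log pdfs
        scores = []
        for lab in LABELS:
            cls = X[y == lab]
            mu, var = cls.mean(axis=0), cls.var(axis=0, ddof=0)
            prior = len(cls) / len(X)
            lp = (np.log(prior)
                  + norm.logpdf(grid[:, 0], mu[0], np.sqrt(var[0]))
                  + norm.logpdf(grid[:, 1], mu[1], np.sqrt(var[1])))
            scores.append(lp)
        oracle = np.array(LABELS, dtype=object)[np.argmax(np.vstack(scores), axis=0)]
        got = model.predict(grid)
        assert (got == oracle).all()

    def test_variance_floor(self):
        rows = [(f"a{i}", 2.0, 2.0, "II") for i in range(3)]
        rows += [(f"b{i}", 1.9, 2.0, "III") for i in range(3)]
        rows += [(f"c{i}", 1.8, 2.0, "IV") for i in range(3)]
        model = fit_gnb(table_from(rows))
        assert np.all(model.gnb_vars >= 1e-9)

    def test_class_minimum(self):
        rows = [("a", 2.0, 2.0, "II"), ("b", 2.0, 2.0, "II"), ("c", 1.9, 2.0, "III"),
                ("d", 1.9, 2.0, "III"), ("e", 1.8, 2.0, "IV")]
        with pytest.raises(TrainingError, match="IV"):
            fit_gnb(table_from(rows))


class TestDT:
    def test_1d_separable_single_split(self):
        rows = [(f"a{i}", 1.9, 2.0, "IV") for i in range(5)]
        rows += [(f"b{i}", 2.2, 2.0, "II") for i in range(5)]
        # three-class fit needs all labels; keep III far away on A
        rows += [(f"c{i}", 2.05, 3.0, "III") for i in range(5)]
        model = fit_dt(table_from(rows))
        t = table_from(rows)
        assert (model.predict(t.X) == t.y).all()

    def test_predicts_centers_as_own_cluster(self):
        t = blob_table(sigma=0.02, n=100, seed=3)
        cluster, relabeled = kmeans_relabel(t, seed=0)
        model = fit_dt(relabeled)
        for lab in LABELS:
            assert predict(model, cluster.center_of(lab)) == lab

    def test_memorization_bound(self, rng):
        n = 120
        df = pd.DataFrame({
            "id": [f"r{i}" for i in range(n)],
            "E": rng.uniform(1.8, 2.3, n), "A": rng.uniform(1.9, 2.4, n),
            "label": rng.choice(LABELS, n),
        })
        t = LabeledFeatureTable(df)
        model = fit_dt(t)
        assert (model.predict(t.X) == t.y).all()

    def test_grid_agreement_with_sklearn_walk(self):
        """Frozen-tree walker agrees with the live sklearn tree on a grid."""
        from sklearn.tree import DecisionTreeClassifier

        t = blob_table(sigma=0.05, n=60, seed=6)
        model = fit_dt(t, seed=0)
        clf = DecisionTreeClassifier(criterion="entropy", random_state=0)
        clf.fit(t.X, t.y)
        grid = np.stack(np.meshgrid(np.linspace(1.8, 2.4, 100),
                                    np.linspace(1.8, 2.4, 100)), axis=-1).reshape(-1, 2)
        assert (model.predict(grid) == clf.predict(grid)).all()

    def test_single_class_depth_zero(self):
        rows = [(f"a{i}", 2.0 + i * 0.01, 2.1, "III") for i in range(4)]
        model = fit_dt(table_from(rows))
        assert model.dt_leaf_label == ["III"]
        assert predict(model, (1.0, 1.0)) == "III"


class TestPredictAtCenters:
    @pytest.mark.parametrize("kind", ["gnb", "dt"])
    def test_reference_centers_classified(self, kind):
        spec = MixtureSpec(counts={"II": 300, "III": 200, "IV": 60},
                           mislabel_rate=0.08, seed=21)
        synth = gen_feature_table(spec)
        _, relabeled = kmeans_relabel(synth.table, seed=0)
        fit = fit_gnb if kind == "gnb" else fit_dt
        model = fit(relabeled)
        assert predict(model, REFERENCE_CENTERS["II"]) == "II"
        assert predict(model, REFERENCE_CENTERS["IV"]) == "IV"
        assert predict(model, REFERENCE_CENTERS["III"]) == "III"


class TestEvaluate:
    def test_memorizer_diagonal_confusion(self):
        t = blob_table(sigma=0.01, n=40, seed=5)
        res = evaluate("dt", t, scheme="holdout:0.25", seed=0)
        assert res.accuracy == 1.0
        assert np.all(res.confusion == np.diag(np.diag(res.confusion)))

    def test_confusion_conservation(self):
        t = blob_table(sigma=0.08, n=50, seed=7)
        res = evaluate("gnb", t, scheme="holdout:0.2", seed=1)
        assert res.confusion.sum() == int(np.ceil(0.2 * len(t)))

    def test_kfold_returns_fold_scores(self):
        t = blob_table(sigma=0.03, n=50, seed=2)
        res = evaluate("gnb", t, scheme="kfold:10", seed=0)
        assert len(res.fold_scores) == 10
        assert res.fold_mean == pytest.approx(np.mean(res.fold_scores))
        assert res.confusion.sum() == len(t)

    def test_kfold_exceeding_class_count(self):
        t = blob_table(n=4)
        with pytest.raises(TrainingError, match="exceeds"):
            evaluate("gnb", t, scheme="kfold:10")

    def test_holdout_accuracy_near_reference_level(self):
        """GNB on mislabeled synthetic data lands near the mid-90s."""
        accs = []
        for seed in range(10):
            spec = MixtureSpec(mislabel_rate=0.05, seed=seed,
                               counts={"II": 500, "III": 240, "IV": 40})
            synth = gen_feature_table(spec)
            res = evaluate("gnb", synth.table, scheme="holdout:0.25", seed=seed)
            accs.append(res.accuracy)
        assert 0.90 <= np.mean(accs) <= 0.98

    def test_empty_table_error(self):
        df = pd.DataFrame({"id": [], "E": [], "A": [], "label": []})
        with pytest.raises(TrainingError):
            evaluate("gnb", LabeledFeatureTable(df))


class TestRuleExport:
    def test_depth_zero(self):
        rows = [(f"a{i}", 2.0, 2.1, "III") for i in range(3)]
        model = fit_dt(table_from(rows))
        assert export_dt_rules(model) == ["return III"]

    def test_single_split_thresholds(self):
        rows = [(f"a{i}", 1.9, 2.0, "IV") for i in range(5)]
        rows += [(f"b{i}", 2.2, 2.0, "II") for i in range(5)]
        rows += [(f"c{i}", 2.05, 3.0, "III") for i in range(5)]
        model = fit_dt(table_from(rows))
        rules = export_dt_rules(model)
        parsed = parse_dt_rules(rules)
        for orig, back in zip(model.dt_threshold, parsed.dt_threshold):
            if np.isfinite(orig):
                assert back == pytest.approx(orig, abs=1e-9)

    def test_round_trip_predictions(self, rng):
        t = blob_table(sigma=0.06, n=80, seed=13)
        model = fit_dt(t)
        parsed = parse_dt_rules(export_dt_rules(model))
        X = rng.uniform(1.7, 2.5, size=(10_000, 2))
        assert (model.predict(X) == parsed.predict(X)).all()

    def test_gnb_rejected(self):
        with pytest.raises(TrainingError):
            export_dt_rules(fit_gnb(blob_table(n=10)))


class TestSerialization:
    @pytest.mark.parametrize("kind", ["gnb", "dt"])
    def test_json_round_trip(self, tmp_path, kind, rng):
        t = blob_table(sigma=0.04, n=50, seed=1)
        cluster, relabeled = kmeans_relabel(t, seed=0)
        fit = fit_gnb if kind == "gnb" else fit_dt
        from mnox.training import attach_cluster_model

        model = attach_cluster_model(fit(relabeled), cluster)
        path = tmp_path / "model.json"
        model.save(path)
        back = OxidationModel.load(path)
        X = rng.uniform(1.8, 2.4, size=(200, 2))
        assert (model.predict(X) == back.predict(X)).all()
        np.testing.assert_allclose(back.cluster_centers, model.cluster_centers)

    def test_version_check(self, tmp_path):
        with pytest.raises(TrainingError, match="version"):
            OxidationModel.from_dict({"format_version": 99, "kind": "gnb"})


class TestAccuracyOrdering:
    def test_relabeling_improves_both_classifiers(self):
        """Post-clustering accuracies strictly exceed pre-clustering ones."""
        pre = {"gnb": [], "dt": []}
        post = {"gnb": [], "dt": []}
        for seed in range(5):
            spec = MixtureSpec(mislabel_rate=0.08, seed=seed,
                               counts={"II": 600, "III": 290, "IV": 50})
            synth = gen_feature_table(spec)
            _, relabeled = kmeans_relabel(synth.table, seed=seed)
            for kind in ("gnb", "dt"):
                pre[kind].append(
                    evaluate(kind, synth.table, "holdout:0.25", seed=seed).accuracy)
                post[kind].append(
                    evaluate(kind, relabeled, "holdout:0.25", seed=seed).accuracy)
        for kind in ("gnb", "dt"):
            assert np.mean(post[kind]) > np.mean(pre[kind])
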