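import numpy as np
import pandas as pd
import pytest

from nisslcolumn import io_formats as iof
from nisslcolumn import layer_classifier as lc
from nisslcolumn import synthetic_cortex as sc
from conftest import small_spec


def labeled_images(n_images=10, width=300.0, seed0=100):
    """Several independent synthetic columns with ground-truth labels."""
    frames = []
    for i in range(n_images):
        spec = small_spec(seed=seed0 + i, width=width, image_id=f"img_{i}")
        frames.append(sc.sample_cells(spec))
    return pd.concat(frames, ignore_index=True)


@pytest.fixture(scope="module")
def features_labels():
    cells = labeled_images()
    feats = lc.assemble_features(cells)
    return feats, feats["layer_label"].to_numpy()


class TestAssembleFeatures:
    def test_constant_feature_unchanged_by_smoothing(self, rng):
        cells = pd.DataFrame({
            "image_id": "img", "cell_id": [f"c{i}" for i in range(30)],
            "x_um": rng.uniform(0, 100, 30), "y_um": rng.uniform(0, 100, 30),
            "d_max_um": 8.0, "d_min_um": 8.0, "area_um2": 50.0,
            "dist_pia_um": 7.0,
        })
        feats = lc.assemble_features(cells)
        np.testing.assert_allclose(feats["smoothed50_dist_pia_um"], 7.0)
        np.testing.assert_allclose(feats["smoothed50_area_um2"], 50.0)

    def test_two_cells_share_the_mean(self):
        cells = pd.DataFrame({
            "image_id": "img", "cell_id": ["a", "b"],
            "x_um": [0.0, 10.0], "y_um": [0.0, 0.0],
            "d_max_um": [5.0, 5.0], "d_min_um": [5.0, 5.0],
            "area_um2": [10.0, 10.0], "dist_pia_um": [0.0, 10.0],
        })
        feats = lc.assemble_features(cells, radius_um=50.0)
        np.testing.assert_allclose(feats["smoothed50_dist_pia_um"], [5.0, 5.0])

    def test_isolated_cell_keeps_own_value(self):
        cells = pd.DataFrame({
            "image_id": "img", "cell_id": ["a", "b"],
            "x_um": [0.0, 500.0], "y_um": [0.0, 0.0],
            "d_max_um": [5.0, 5.0], "d_min_um": [5.0, 5.0],
            "area_um2": [10.0, 10.0], "dist_pia_um": [3.0, 9.0],
        })
        feats = lc.assemble_features(cells, radius_um=50.0)
        np.testing.assert_allclose(feats["smoothed50_dist_pia_um"], [3.0, 9.0])

    def test_smoothing_matches_bruteforce_radius_scan(self, rng):
        n = 200
        cells = pd.DataFrame({
            "image_id": "img", "cell_id": [f"c{i}" for i in range(n)],
            "x_um": rng.uniform(0, 300, n), "y_um": rng.uniform(0, 300, n),
            "d_max_um": rng.uniform(5, 12, n), "d_min_um": 4.0,
            "area_um2": rng.uniform(10, 100, n),
            "dist_pia_um": rng.uniform(0, 300, n),
        })
        feats = lc.assemble_features(cells, radius_um=50.0)
        xy = cells[["x_um", "y_um"]].to_numpy()
        vals = cells["dist_pia_um"].to_numpy()
        for i in range(n):  # O(n^2) radius scan
            nb = np.hypot(*(xy - xy[i]).T) <= 50.0
            assert feats["smoothed50_dist_pia_um"][i] == pytest.approx(
                vals[nb].mean())


class TestSelectFeatures:
    def test_noise_dropped_and_signal_retained(self, rng):
        n = 2000
        signal = rng.uniform(0, 100, n)
        noise = rng.normal(size=n)
        labels = np.where(signal < 50, "LI", "LV")
        feats = pd.DataFrame({
            "image_id": "img", "x_um": noise, "y_um": rng.normal(size=n),
            "dist_pia_um": signal,
        })
        feats.attrs["feature_names"] = ["x_um", "y_um", "dist_pia_um"]
        selected, table = lc.select_features(feats, labels, model_kind="rf",
                                             seed=0, n_estimators=50)
        assert "dist_pia_um" in selected
        imp = table.set_index("feature")["importance_mean"]
        assert imp["dist_pia_um"] > 0.2
        assert abs(imp["x_um"]) < 0.02

    def test_distance_to_pia_dominates_on_columns(self, features_labels):
        feats, labels = features_labels
        _, table = lc.select_features(feats, labels, model_kind="rf",
                                      seed=0, n_estimators=30)
        top2 = set(table["feature"].iloc[:2])
        assert top2 & {"dist_pia_um", "smoothed50_dist_pia_um", "y_um",
                       "smoothed50_y_um"}

    def test_single_class_rejected(self):
        feats = pd.DataFrame({"image_id": "img", "dist_pia_um": [1.0, 2.0]})
        feats.attrs["feature_names"] = ["dist_pia_um"]
        with pytest.raises(ValueError):
            lc.select_features(feats, np.array(["LI", "LI"]))


class TestTrainEvaluate:
    def test_separable_layers_near_perfect(self):
        # depth alone separates the layers noise-free: expect a diagonal
        # confusion matrix and macro accuracy >= 0.99
        rng = np.random.default_rng(0)
        frames = []
        for i in range(10):
            n = 300
            depth = rng.uniform(0, 700, n)
            labels = np.array(["LI", "LII", "LIII", "LIV", "LV", "LVIa",
                               "LVIb"])[np.minimum(depth // 100, 6).astype(int)]
            frames.append(pd.DataFrame({
                "image_id": f"img_{i}", "dist_pia_um": depth,
                "layer_label": labels}))
        feats = pd.concat(frames, ignore_index=True)
        feats.attrs["feature_names"] = ["dist_pia_um"]
        report = lc.train_evaluate(feats, feats["layer_label"], "knn",
                                   folds=10, seed=0)
        assert report.macro["accuracy"] >= 0.99
        off_diag = report.confusion.sum() - np.trace(report.confusion)
        assert off_diag <= 0.01 * report.confusion.sum()

    def test_shuffled_labels_hit_chance_level(self, features_labels):
        feats, labels = features_labels
        rng = np.random.default_rng(1)
        shuffled = rng.permutation(labels)
        report = lc.train_evaluate(feats, shuffled, "knn", folds=10, seed=0,
                                   selected=["dist_pia_um", "area_um2"])
        k = len(report.classes)
        assert report.macro["accuracy"] == pytest.approx(1 / k, abs=0.05)

    def test_confusion_rows_are_class_supports(self, features_labels):
        feats, labels = features_labels
        report = lc.train_evaluate(feats, labels, "knn", folds=10, seed=0)
        supports = pd.Series(labels).value_counts()
        for cls, row_sum in zip(report.classes, report.confusion.sum(axis=1)):
            assert row_sum == supports[cls]
        assert report.macro["micro_accuracy"] == pytest.approx(
            np.trace(report.confusion) / report.confusion.sum())

    def test_requires_enough_images(self, rng):
        feats = pd.DataFrame({"image_id": "only_one",
                              "dist_pia_um": rng.uniform(0, 1, 50)})
        feats.attrs["feature_names"] = ["dist_pia_um"]
        with pytest.raises(ValueError, match="images"):
            lc.train_evaluate(feats, np.repeat(["LI", "LV"], 25), "knn")


class TestMacroMetricsSupportInvariance:
    def test_duplicating_a_class_leaves_macro_unchanged(self):
        # metrics computed from a pooled confusion matrix: scaling one
        # class's support must not move the macro averages
        conf = np.array([[80, 10, 0], [5, 60, 5], [0, 10, 90]])
        classes = ["LI", "LII", "LIII"]
        base = lc._per_class_metrics(conf, classes)
        conf2 = conf.copy()
        conf2[1] *= 3  # every cell of class LII duplicated three-fold
        dup = lc._per_class_metrics(conf2, classes)
        np.testing.assert_allclose(base["recall"], dup["recall"])
        np.testing.assert_allclose(np.nanmean(base["accuracy"]),
                                   np.nanmean(dup["accuracy"]))


class TestPredict:
    def test_self_prediction_reproduces_separable_labels(self, rng):
        depth = rng.uniform(0, 700, 600)
        labels = np.where(depth < 350, "LI", "LV")
        feats = pd.DataFrame({"image_id": "img", "dist_pia_um": depth,
                              "layer_label": labels})
        feats.attrs["feature_names"] = ["dist_pia_um"]
        model, names = lc.fit(feats, labels, "rf", seed=0, n_estimators=20)
        out = lc.predict(model, feats, names)
        assert (out["predicted_layer"] == labels).all()
        assert (out["predicted_proba"] >= 0.5).all()

    def test_empty_input_gives_empty_output(self, rng):
        depth = rng.uniform(0, 1, 20)
        feats = pd.DataFrame({"image_id": "img", "dist_pia_um": depth})
        feats.attrs["feature_names"] = ["dist_pia_um"]
        model, names = lc.fit(feats, np.repeat(["LI", "LV"], 10), "knn",
                              n_neighbors=3)
        out = lc.predict(model, feats.iloc[:0], names)
        assert len(out) == 0

    def test_prediction_invariant_to_row_order(self, rng):
        depth = rng.uniform(0, 700, 200)
        feats = pd.DataFrame({"image_id": "img", "dist_pia_um": depth})
        feats.attrs["feature_names"] = ["dist_pia_um"]
        labels = np.where(depth < 350, "LI", "LV")
        model, names = lc.fit(feats, labels, "rf", seed=0, n_estimators=20)
        perm = rng.permutation(len(feats))
        out = lc.predict(model, feats, names)["predicted_layer"].to_numpy()
        out_perm = lc.predict(model, feats.iloc[perm], names)[
            "predicted_layer"].to_numpy()
        np.testing.assert_array_equal(out[perm], out_perm)

    def test_missing_feature_is_schema_error(self, rng):
        feats = pd.DataFrame({"image_id": "img", "dist_pia_um": [1.0] * 20})
        feats.attrs["feature_names"] = ["dist_pia_um"]
        model, names = lc.fit(feats, ["LI"] * 10 + ["LV"] * 10, "knn",
                              n_neighbors=3)
        with pytest.raises(iof.SchemaError, match="missing"):
            lc.predict(model, feats.drop(columns=["dist_pia_um"]), names)


class TestParadigms:
    def test_merge_l23_maps_both_classes(self):
        labels = np.array(["LI", "LII", "LIII", "LIV", "LII/III"])
        merged = lc.merge_l23(labels)
        np.testing.assert_array_equal(
            merged, ["LI", "LII/III", "LII/III", "LIV", "LII/III"])
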