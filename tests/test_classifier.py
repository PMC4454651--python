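import json

import numpy as np
import pandas as pd
import pytest
from PIL import Image

from lymphir import (ClassMap, ClassScheme, RoiSet, assemble_training_set,
                     classify_image, predict_labels, render_classmap,
                     spatial_block_split, train_forest)
from lymphir.classifier import read_roi_file, write_roi_file
from lymphir.errors import ConfigurationError, IntegrityError
from lymphir.features import FeatureImage


def _feature_image(rng, rows=12, cols=12, n=3, mask=None):
    values = rng.normal(size=(rows, cols, n))
    if mask is None:
        mask = np.ones((rows, cols), dtype=bool)
    return FeatureImage(values, [f"m{i}" for i in range(n)], mask)


def _two_class_table(rng, n=60, sep=10.0):
    x = rng.normal(size=(n, 3))
    y = np.repeat([1, 2], n // 2)
    x[y == 2, 0] += sep
    df = pd.DataFrame(x, columns=["m0", "m1", "m2"])
    df.insert(0, "label", y)
    return df


class TestRoiFiles:
    def test_run_length_round_trip(self, tmp_path, rng):
        coords_a = np.array([[2, 3], [2, 4], [2, 5], [7, 1]])
        coords_b = np.array([[0, 0], [1, 0], [1, 1]])
        rois = RoiSet([("img1", "T cell", coords_a),
                       ("img1", "other", coords_b)])
        write_roi_file(rois, tmp_path / "r.txt")
        back = read_roi_file(tmp_path / "r.txt")
        assert [(i, c) for i, c, _ in back.entries] == \
            [("img1", "T cell"), ("img1", "other")]
        for (_, _, a), (_, _, b) in zip(rois.entries, back.entries):
            assert set(map(tuple, a)) == set(map(tuple, b))

    def test_overlapping_rois_rejected(self):
        with pytest.raises(IntegrityError):
            RoiSet([("img1", "T cell", np.array([[1, 1], [1, 2]])),
                    ("img1", "other", np.array([[1, 2]]))])

    def test_same_pixel_in_different_images_allowed(self):
        RoiSet([("img1", "T cell", np.array([[1, 1]])),
                ("img2", "T cell", np.array([[1, 1]]))])


class TestAssembleTrainingSet:
    def test_roi_of_five_pixels_gives_five_rows(self, rng):
        fi = _feature_image(rng)
        rois = RoiSet([("img", "T cell", np.array([[0, 0], [0, 1], [1, 0],
                                                   [2, 2], [3, 3]])),
                       ("img", "other", np.array([[5, 5]]))])
        table = assemble_training_set({"img": fi}, rois)
        assert int((table["label"] == 2).sum()) == 5

    def test_below_mask_pixels_excluded(self, rng):
        mask = np.ones((12, 12), dtype=bool)
        mask[0, 0] = False
        fi = _feature_image(rng, mask=mask)
        rois = RoiSet([("img", "T cell", np.array([[0, 0], [0, 1]])),
                       ("img", "other", np.array([[5, 5]]))])
        table = assemble_training_set({"img": fi}, rois)
        assert int((table["label"] == 2).sum()) == 1

    def test_class_with_zero_usable_pixels_is_error(self, rng):
        mask = np.ones((12, 12), dtype=bool)
        mask[3, 3] = False
        fi = _feature_image(rng, mask=mask)
        rois = RoiSet([("img", "T cell", np.array([[3, 3]])),
                       ("img", "other", np.array([[5, 5]]))])
        with pytest.raises(ConfigurationError):
            assemble_training_set({"img": fi}, rois)

    def test_nine_classes_all_present(self, rng):
        fi = _feature_image(rng)
        scheme = ClassScheme()
        rois = RoiSet([("img", name, np.array([[i, j] for j in range(3)]))
                       for i, name in enumerate(scheme.classes)])
        table = assemble_training_set({"img": fi}, rois)
        assert sorted(table["label"].unique()) == list(range(1, 10))

    def test_deterministic_row_order(self, rng):
        fi = _feature_image(rng)
        coords = np.array([[4, 2], [1, 7], [1, 3], [8, 0]])
        rois = RoiSet([("img", "T cell", coords),
                       ("img", "other", np.array([[9, 9]]))])
        table = assemble_training_set({"img": fi}, rois)
        got = table.loc[table["label"] == 2, ["row", "col"]].to_numpy()
        np.testing.assert_array_equal(got, [[1, 3], [1, 7], [4, 2], [8, 0]])


class TestTrainForest:
    def test_separable_classes_train_to_purity(self, rng):
        table = _two_class_table(rng)
        model = train_forest(table, n_trees=10, seed=0)
        pred = predict_labels(model, table[["m0", "m1", "m2"]].to_numpy())
        assert (pred == table["label"].to_numpy()).all()

    def test_same_seed_identical_predictions(self, rng):
        table = _two_class_table(rng, sep=1.0)
        x = rng.normal(size=(50, 3))
        p1 = predict_labels(train_forest(table, 40, seed=5), x)
        p2 = predict_labels(train_forest(table, 40, seed=5), x)
        np.testing.assert_array_equal(p1, p2)

    def test_single_class_table_rejected(self, rng):
        table = _two_class_table(rng)
        with pytest.raises(ConfigurationError):
            train_forest(table[table["label"] == 1], 10, 0)

    def test_oob_accuracy_reported(self, rng):
        model = train_forest(_two_class_table(rng), 40, 0)
        assert 0.9 <= model.oob_accuracy <= 1.0

    def test_model_serialization_round_trip(self, rng, tmp_path):
        from lymphir.classifier import ForestModel
        model = train_forest(_two_class_table(rng), 10, 0)
        model.save(tmp_path / "m.joblib")
        back = ForestModel.load(tmp_path / "m.joblib")
        x = rng.normal(size=(20, 3))
        np.testing.assert_array_equal(predict_labels(back, x),
                                      predict_labels(model, x))


class TestClassifyImage:
    def test_all_masked_gives_all_zero(self, rng):
        model = train_forest(_two_class_table(rng), 5, 0)
        fi = FeatureImage(np.full((4, 4, 3), np.nan), ["m0", "m1", "m2"],
                          np.zeros((4, 4), dtype=bool))
        cmap = classify_image(fi, model)
        assert (cmap.labels == 0).all()

    def test_training_exemplars_memorized(self, rng):
        table = _two_class_table(rng)
        model = train_forest(table, 40, 0)
        x = table[["m0", "m1", "m2"]].to_numpy()
        fi = FeatureImage(x.reshape(6, 10, 3), ["m0", "m1", "m2"],
                          np.ones((6, 10), dtype=bool))
        cmap = classify_image(fi, model)
        np.testing.assert_array_equal(cmap.labels.ravel(),
                                      table["label"].to_numpy())

    def test_votes_match_tree_by_tree_oracle(self, rng):
        table = _two_class_table(rng, sep=0.5)  # overlapping: contested votes
        model = train_forest(table, 11, 3)
        x = rng.normal(size=(40, 3))
        pred = predict_labels(model, x)
        classes = model.estimator.classes_
        oracle = []
        for i in range(40):
            tally = {int(c): 0 for c in classes}
            for tree in model.estimator.estimators_:
                enc = int(tree.predict(x[i:i + 1])[0])
                tally[int(classes[enc])] += 1
            best = max(tally.values())
            oracle.append(min(lbl for lbl, v in tally.items() if v == best))
        np.testing.assert_array_equal(pred, oracle)

    def test_label_zero_exactly_off_mask(self, rng):
        model = train_forest(_two_class_table(rng), 5, 0)
        mask = rng.random((6, 6)) > 0.5
        fi = FeatureImage(rng.normal(size=(6, 6, 3)), ["m0", "m1", "m2"], mask)
        cmap = classify_image(fi, model)
        np.testing.assert_array_equal(cmap.labels == 0, ~mask)
        assert (cmap.labels[mask] > 0).all()

    def test_classification_commutes_with_permutation(self, rng):
        model = train_forest(_two_class_table(rng, sep=1.0), 15, 1)
        values = rng.normal(size=(8, 5, 3))
        fi = FeatureImage(values, ["m0", "m1", "m2"],
                          np.ones((8, 5), dtype=bool))
        cmap = classify_image(fi, model)
        perm = rng.permutation(8)
        fi_p = FeatureImage(values[perm], ["m0", "m1", "m2"],
                            np.ones((8, 5), dtype=bool))
        np.testing.assert_array_equal(classify_image(fi_p, model).labels,
                                      cmap.labels[perm])

    def test_feature_name_mismatch_rejected(self, rng):
        model = train_forest(_two_class_table(rng), 5, 0)
        fi = FeatureImage(rng.normal(size=(2, 2, 3)), ["a", "b", "c"],
                          np.ones((2, 2), dtype=bool))
        with pytest.raises(ConfigurationError):
            classify_image(fi, model)


class TestRenderClassmap:
    def test_png_has_one_color_per_label(self, tmp_path):
        labels = np.array([[0, 1], [2, 3]])
        cmap = ClassMap(labels, ClassScheme())
        render_classmap(cmap, tmp_path / "m.png")
        img = Image.open(tmp_path / "m.png").convert("RGB")
        assert len(set(img.getdata())) == 4

    def test_label_grid_round_trip(self, tmp_path, rng):
        labels = rng.integers(0, 10, size=(7, 9))
        cmap = ClassMap(labels, ClassScheme())
        render_classmap(cmap, tmp_path / "m.png")
        back = ClassMap.load_grid(tmp_path / "m.labels.txt")
        np.testing.assert_array_equal(back.labels, labels)

    def test_sidecar_counts_match_histogram_oracle(self, tmp_path, rng):
        labels = rng.integers(0, 10, size=(20, 20))
        cmap = ClassMap(labels, ClassScheme())
        render_classmap(cmap, tmp_path / "m.png")
        sidecar = json.loads((tmp_path / "m.legend.json").read_text())
        scheme = ClassScheme()
        for lbl in range(1, 10):
            oracle = int(sum(1 for v in labels.ravel() if v == lbl))
            assert sidecar["class_counts"][scheme.classes[lbl - 1]] == oracle


class TestSpatialBlockSplit:
    def test_blocks_are_pure(self):
        test_map = spatial_block_split(64, 64, 16, 0.3, seed=4)
        blocks = test_map.reshape(4, 16, 4, 16)
        for i in range(4):
            for j in range(4):
                block = blocks[i, :, j, :]
                assert block.all() or not block.any()

    def test_fraction_roughly_honored(self):
        test_map = spatial_block_split(256, 256, 16, 0.25, seed=0)
        assert 0.1 < test_map.mean() < 0.4

    def test_deterministic(self):
        a = spatial_block_split(64, 64, 8, 0.5, seed=9)
        b = spatial_block_split(64, 64, 8, 0.5, seed=9)
        np.testing.assert_array_equal(a, b)
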