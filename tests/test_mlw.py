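"""Window extraction, training and prediction of the MLW-MLP."""

import numpy as np
import pytest

from mrept import (ROIMask, ScalarField2D, TrainConfig, WindowSpec,
                   extract_windows, phase_derivatives, predict, train)
from mrept.mlw import TrainedModel, admissible_centers


def _smooth_phase(shape, seed=0, dx=1.875e-3):
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    v = (0.3 * np.sin(xx / 4 + rng.random())
         + 0.2 * np.cos(yy / 5 + rng.random())
         + 0.01 * rng.normal(size=shape))
    return ScalarField2D(v, dx=dx, dy=dx, units="rad")


class TestExtraction:
    def test_13x13_full_mask_yields_25_windows(self):
        phase = _smooth_phase((13, 13))
        ds = extract_windows(phase, ROIMask.full((13, 13)), WindowSpec(p=4))
        assert len(ds) == 25
        assert ds.features.shape == (25, 4 * 81)

    def test_9x9_full_mask_single_window(self):
        phase = _smooth_phase((9, 9))
        ds = extract_windows(phase, ROIMask.full((9, 9)), WindowSpec(p=4))
        assert len(ds) == 1
        assert tuple(ds.centers[0]) == (4, 4)

    def test_too_small_mask_raises(self):
        phase = _smooth_phase((8, 8))
        with pytest.raises(ValueError):
            extract_windows(phase, ROIMask.full((8, 8)), WindowSpec(p=4))

    def test_admissible_centers_match_brute_force(self):
        rng = np.random.default_rng(13)
        spec = WindowSpec(p=2)
        valid = rng.random((14, 14)) > 0.2
        ok = admissible_centers(valid, spec)
        ny, nx = valid.shape
        for i in range(ny):
            for j in range(nx):
                fits = (spec.p <= i < ny - spec.p
                        and spec.p <= j < nx - spec.p)
                ref = fits and valid[i - 2:i + 3, j - 2:j + 3].all()
                assert ok[i, j] == ref

    def test_row_major_ordering_and_targets(self):
        phase = _smooth_phase((15, 15))
        mask = ROIMask.full((15, 15))
        target = ScalarField2D(np.random.default_rng(1).random((15, 15)),
                               units="S/m")
        ds = extract_windows(phase, mask, WindowSpec(p=4), target=target)
        assert np.all(np.diff(ds.centers[:, 0] * 15 + ds.centers[:, 1]) > 0)
        # target patch of first center equals the raw slice
        i, j = ds.centers[0]
        np.testing.assert_array_equal(
            ds.targets[0].reshape(9, 9),
            target.values[i - 4:i + 5, j - 4:j + 5])

    def test_phase_group_is_window_centered(self):
        phase = _smooth_phase((13, 13))
        ds = extract_windows(phase, ROIMask.full((13, 13)), WindowSpec(p=4))
        K = ds.spec.n_voxels
        np.testing.assert_allclose(ds.features[:, :K].mean(axis=1), 0.0,
                                   atol=1e-12)
        raw = extract_windows(phase, ROIMask.full((13, 13)),
                              WindowSpec(p=4), center_phase=False)
        i, j = raw.centers[0]
        np.testing.assert_array_equal(
            raw.features[0, :K].reshape(9, 9),
            phase.values[i - 4:i + 5, j - 4:j + 5])

    def test_feature_group_selector(self):
        phase = _smooth_phase((13, 13))
        ds = extract_windows(phase, ROIMask.full((13, 13)), WindowSpec(p=4),
                             feature_groups=("phi",))
        assert ds.features.shape[1] == 81

    def test_stride_subsamples_centers(self):
        phase = _smooth_phase((17, 17))
        ds = extract_windows(phase, ROIMask.full((17, 17)),
                             WindowSpec(p=4, stride=2))
        assert np.all(ds.centers % 2 == 0)


class TestDihedralAugmentation:
    def test_transform_matches_extraction_from_transformed_image(self):
        # features transformed by each square symmetry must equal (as a
        # multiset over windows) the features extracted from the
        # correspondingly transformed phase image
        from mrept.mlw import _dihedral_ops
        rng = np.random.default_rng(0)
        n = 15
        phase_v = 0.1 * rng.normal(size=(n, n))
        spec = WindowSpec(p=4)
        K = spec.n_voxels
        mask = ROIMask.full((n, n))
        base = extract_windows(ScalarField2D(phase_v, 1e-3, 1e-3, "rad"),
                               mask, spec)
        groups = base.feature_groups
        for opi, (perm, (cx, sx), (cy, sy)) in enumerate(
                _dihedral_ops(spec.side)):
            flip, k = opi >= 4, opi % 4
            img = np.fliplr(phase_v) if flip else phase_v
            img = np.rot90(img, k).copy()
            tds = extract_windows(ScalarField2D(img, 1e-3, 1e-3, "rad"),
                                  mask, spec)
            src = np.empty(4 * K, int)
            sgn = np.ones(4 * K)
            for g, name in enumerate(groups):
                s_name, s = ((cx, sx) if name == "gx"
                             else (cy, sy) if name == "gy" else (name, 1))
                src[g * K:(g + 1) * K] = groups.index(s_name) * K + perm
                sgn[g * K:(g + 1) * K] = s
            tf = base.features[:, src] * sgn
            np.testing.assert_allclose(np.sort(tf.ravel()),
                                       np.sort(tds.features.ravel()),
                                       atol=1e-12)


def _toy_dataset(n_repeat=64, seed=0):
    """Tiny dataset built from one real extraction, repeated."""
    phase = _smooth_phase((9, 9), seed=seed)
    mask = ROIMask.full((9, 9))
    target = ScalarField2D(
        np.random.default_rng(seed + 1).uniform(0.3, 1.8, (9, 9)),
        units="S/m")
    ds = extract_windows(phase, mask, WindowSpec(p=4), target=target)
    ds.features = np.repeat(ds.features, n_repeat, axis=0)
    ds.targets = np.repeat(ds.targets, n_repeat, axis=0)
    ds.centers = np.repeat(ds.centers, n_repeat, axis=0)
    return ds


class TestTraining:
    def test_memorizes_single_repeated_sample(self):
        ds = _toy_dataset()
        cfg = TrainConfig(hidden=(32, 16), epochs=300, batch_size=32,
                          l2=0.0, learning_rate=3e-3, seed=0,
                          val_fraction=0.0, augment_dihedral=False)
        model = train(ds, cfg)
        assert model.history["train_mae"][-1] < 1e-3
        pred = predict(model, ds)
        assert np.abs(pred - ds.targets).mean() < 2e-3

    def test_same_seed_identical_history(self):
        ds = _toy_dataset()
        cfg = TrainConfig(hidden=(16, 8), epochs=5, batch_size=32, seed=3)
        h1 = train(ds, cfg).history["train_mae"]
        h2 = train(ds, cfg).history["train_mae"]
        assert h1 == h2

    def test_zero_targets_drive_weight_norm_down(self):
        from mrept.nn import weight_sq_norm
        ds = _toy_dataset()
        ds.targets = np.zeros_like(ds.targets)
        cfg = TrainConfig(hidden=(16, 8), epochs=40, batch_size=32,
                          l2=1e-3, seed=0, val_fraction=0.0, lr_decay=1.0,
                          augment_dihedral=False)
        model = train(ds, cfg)
        assert model.history["train_mae"][-1] < 0.05

    def test_empty_or_targetless_dataset_rejected(self):
        ds = _toy_dataset()
        ds.targets = None
        with pytest.raises(ValueError):
            train(ds)


@pytest.fixture(scope="module")
def model_and_data():
    ds = _toy_dataset()
    cfg = TrainConfig(hidden=(16, 8), epochs=10, batch_size=32, seed=1)
    return train(ds, cfg), ds


class TestPrediction:
    def test_identical_windows_identical_patches(self, model_and_data):
        model, ds = model_and_data
        pred = predict(model, ds)
        # dataset is a repetition: all rows with equal features agree
        np.testing.assert_array_equal(pred[0], pred[1])

    def test_permutation_equivariance(self, model_and_data):
        model, ds = model_and_data
        rng = np.random.default_rng(2)
        perm = rng.permutation(len(ds))
        from mrept.mlw import WindowDataset
        shuffled = WindowDataset(ds.features[perm], None, ds.centers[perm],
                                 ds.spec, ds.feature_groups, ds.grid_shape,
                                 ds.dx, ds.dy, ds.center_phase)
        np.testing.assert_array_equal(predict(model, shuffled),
                                      predict(model, ds)[perm])

    def test_feature_length_mismatch_rejected(self, model_and_data):
        model, ds = model_and_data
        from mrept.mlw import WindowDataset
        bad = WindowDataset(ds.features[:, :100], None, ds.centers,
                            ds.spec, ("phi",), ds.grid_shape,
                            ds.dx, ds.dy, ds.center_phase)
        with pytest.raises(ValueError):
            predict(model, bad)

    def test_save_load_round_trip(self, model_and_data, tmp_path):
        model, ds = model_and_data
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = TrainedModel.load(path)
        np.testing.assert_array_equal(predict(loaded, ds),
                                      predict(model, ds))
        assert loaded.config.seed == model.config.seed
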