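"""Preprocessing operators checked against scalar oracles and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gradefuse.datatypes import VolumeImage
from gradefuse.exceptions import (ConfigurationError, DegenerateStatisticsError,
                                  InputError, InsufficientNeighborsError,
                                  UnfittableVariableError)
from gradefuse.preprocess import (AugmentationSpec, CategoricalEncoder,
                                  ImputationModel, PreprocessState,
                                  ResamplingSpec, StandardizationStats,
                                  align_temporal, apply_outlier_policy,
                                  augment, extract_roi, flag_outliers,
                                  normalize_intensity, resample_trilinear,
                                  smote_oversample, suppress_artifacts)


def vol(data, spacing=(1, 1, 1)):
    return VolumeImage(np.asarray(data, dtype=float), spacing)


# ---------------------------------------------------------------------------
# resampling (trilinear)
# ---------------------------------------------------------------------------

class TestResample:
    def test_identity_spacing_returns_input(self, rng):
        v = vol(rng.normal(size=(6, 5, 4)))
        out = resample_trilinear(v, ResamplingSpec((1, 1, 1), (1, 1, 1)))
        assert np.allclose(out.data, v.data, atol=1e-12)

    def test_constant_image_stays_constant(self):
        v = vol(np.full((5, 5, 5), 3.7))
        out = resample_trilinear(v, ResamplingSpec((1, 1, 1), (0.7, 1.3, 2.0)))
        assert np.allclose(out.data, 3.7)

    def test_ramp_matches_scalar_weight_formula(self):
        """Half-spacing resampling of a 1D ramp against an independent
        scalar implementation of the interpolation weights."""
        n = 8
        ramp = np.arange(n, dtype=float).reshape(n, 1, 1)
        out = resample_trilinear(vol(ramp), ResamplingSpec((1, 1, 1), (0.5, 1, 1)))
        # independent scalar oracle with the half-pixel convention and
        # edge clamping
        expected = []
        for i in range(out.data.shape[0]):
            x = (i + 0.5) * 0.5 - 0.5            # source coordinate
            x = min(max(x, 0.0), n - 1)
            lo, hi = int(np.floor(x)), min(int(np.floor(x)) + 1, n - 1)
            w = x - np.floor(x)
            expected.append((1 - w) * lo + w * hi)
        assert np.allclose(out.data[:, 0, 0], expected, atol=1e-9)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ConfigurationError):
            ResamplingSpec((1, 1, 1), (0.0, 1, 1))

    def test_band_limited_round_trip_error_is_small(self):
        """Downsample-then-upsample of a smooth phantom has small relative
        L2 error."""
        x = np.linspace(0, np.pi, 16)
        smooth = np.sin(x)[:, None, None] * np.sin(x)[None, :, None] * np.sin(x)[None, None, :]
        v = vol(smooth)
        down = resample_trilinear(v, ResamplingSpec((1, 1, 1), (2, 2, 2)))
        up = resample_trilinear(down, ResamplingSpec((2, 2, 2), (1, 1, 1)))
        rel = np.linalg.norm(up.data - smooth) / np.linalg.norm(smooth)
        assert rel < 0.15


# ---------------------------------------------------------------------------
# intensity normalisation / ROI
# ---------------------------------------------------------------------------

class TestNormalize:
    def test_hand_computed_values(self):
        data = np.zeros((1, 1, 4))
        data[0, 0, :3] = [8, 10, 12]
        mask = np.zeros_like(data)
        mask[0, 0, :3] = 1
        out = normalize_intensity(vol(data), vol(mask))
        # population sd = sqrt(8/3)
        assert np.allclose(out.data[0, 0, :3], [-1.22474487, 0.0, 1.22474487])

    def test_in_mask_statistics_are_standard(self, rng):
        data = rng.normal(5, 3, size=(8, 8, 8))
        mask = (rng.random((8, 8, 8)) > 0.5).astype(float)
        out = normalize_intensity(vol(data), vol(mask))
        vals = out.data[mask > 0]
        assert abs(vals.mean()) < 1e-6 and abs(vals.std() - 1) < 1e-6

    def test_idempotent_and_affine_invariant(self, rng):
        data = rng.normal(size=(6, 6, 6))
        mask = np.ones_like(data)
        once = normalize_intensity(vol(data), vol(mask))
        twice = normalize_intensity(once, vol(mask))
        assert np.allclose(once.data, twice.data, atol=1e-9)
        shifted = normalize_intensity(vol(3.5 * data + 7.0), vol(mask))
        assert np.allclose(shifted.data, once.data, atol=1e-9)

    def test_degenerate_region_raises(self):
        with pytest.raises(DegenerateStatisticsError):
            normalize_intensity(vol(np.ones((3, 3, 3))), vol(np.ones((3, 3, 3))))
        with pytest.raises(DegenerateStatisticsError):
            normalize_intensity(vol(np.ones((3, 3, 3))), vol(np.zeros((3, 3, 3))))


class TestROI:
    def test_identity_and_zero_masks(self, rng):
        data = rng.normal(size=(4, 4, 4))
        assert np.array_equal(extract_roi(vol(data), vol(np.ones_like(data))).image.data, data)
        assert np.all(extract_roi(vol(data), vol(np.zeros_like(data))).image.data == 0)

    def test_checkerboard_matches_elementwise_product(self):
        data = np.arange(64, dtype=float).reshape(4, 4, 4)
        mask = np.indices((4, 4, 4)).sum(axis=0) % 2
        roi = extract_roi(vol(data), vol(mask.astype(float)))
        assert np.array_equal(roi.image.data, data * mask)

    def test_support_containment_property(self, rng):
        data = rng.normal(size=(5, 5, 5)) + 10
        mask = (rng.random((5, 5, 5)) > 0.6).astype(float)
        roi = extract_roi(vol(data), vol(mask))
        assert np.all(roi.image.data[mask == 0] == 0)

    def test_shape_mismatch_and_crop(self, rng):
        with pytest.raises(InputError):
            extract_roi(vol(np.zeros((3, 3, 3))), vol(np.zeros((4, 4, 4))))
        data = rng.normal(size=(8, 8, 8))
        mask = np.zeros((8, 8, 8))
        mask[2:5, 3:6, 1:4] = 1
        roi = extract_roi(vol(data), vol(mask), crop=True, margin=1)
        assert roi.bbox == ((1, 6), (2, 7), (0, 5))
        assert roi.image.data.shape == (5, 5, 5)


class TestArtifactSuppression:
    def test_zero_strength_is_identity(self, rng):
        v = vol(rng.normal(size=(6, 6, 6)))
        assert np.array_equal(suppress_artifacts(v, 0.0).data, v.data)

    def test_constant_is_unchanged(self):
        v = vol(np.full((6, 6, 6), 2.5))
        assert np.allclose(suppress_artifacts(v, 2.0).data, 2.5, atol=1e-9)

    def test_impulse_amplitude_strictly_reduced(self):
        clean = np.zeros((9, 9, 9))
        noisy = clean.copy()
        noisy[4, 4, 4] = 10.0
        out = suppress_artifacts(vol(noisy), 1.0)
        assert np.abs(out.data - clean).max() < 10.0


# ---------------------------------------------------------------------------
# clinical table operators
# ---------------------------------------------------------------------------

class TestImputation:
    def test_global_mean_and_mode(self):
        train = pd.DataFrame({"x": [1.0, 2.0, 3.0, np.nan],
                              "c": ["A", "A", "B", None]})
        model = ImputationModel().fit(train)
        out = model.transform(train)
        assert out["x"].iloc[3] == pytest.approx(2.0)
        assert out["c"].iloc[3] == "A"
        assert not out.isna().any().any()

    def test_observed_cells_unchanged(self):
        table = pd.DataFrame({"x": [1.0, np.nan, 5.0, 2.0]})
        out = ImputationModel().fit(table).transform(table)
        assert list(out["x"][[0, 2, 3]]) == [1.0, 5.0, 2.0]

    def test_no_missing_is_noop(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 4.0]})
        assert ImputationModel().fit(table).transform(table).equals(table)

    def test_entirely_missing_variable_is_unfittable(self):
        with pytest.raises(UnfittableVariableError):
            ImputationModel().fit(pd.DataFrame({"x": [np.nan, np.nan]}))

    def test_knn_strategy_fills_from_neighbors(self):
        train = pd.DataFrame({"x": [0.0, 0.1, 10.0, 10.1],
                              "y": [1.0, np.nan, 21.0, 20.0]})
        out = ImputationModel(strategy="knn", k=1).fit(train).transform(train)
        assert out["y"].iloc[1] == pytest.approx(1.0)   # nearest row in x


class TestStandardization:
    def test_population_sd_hand_values(self):
        train = pd.DataFrame({"x": [2.0, 4.0, 6.0]})
        stats = StandardizationStats().fit(train)
        out = stats.transform(train)
        assert np.allclose(out["x"], [-1.22474487, 0.0, 1.22474487])
        held = stats.transform(pd.DataFrame({"x": [4.0]}))
        assert held["x"].iloc[0] == pytest.approx(0.0)

    def test_idempotent_on_training_split(self):
        train = pd.DataFrame({"x": [1.0, 5.0, 9.0, 2.0]})
        once = StandardizationStats().fit(train).transform(train)
        twice = StandardizationStats().fit(once).transform(once)
        assert np.allclose(once["x"], twice["x"])

    def test_zero_variance_raises_or_drops(self):
        train = pd.DataFrame({"x": [3.0, 3.0, 3.0], "y": [1.0, 2.0, 4.0]})
        with pytest.raises(DegenerateStatisticsError):
            StandardizationStats().fit(train, columns=["x", "y"])
        with pytest.warns(UserWarning):
            stats = StandardizationStats(drop_degenerate=True).fit(
                train, columns=["x", "y"])
        assert "x" not in stats.transform(train).columns


class TestEncoding:
    def test_binary_column_rowwise_sum_one(self):
        train = pd.DataFrame({"c": ["M", "F", "M"]})
        out = CategoricalEncoder().fit(train).transform(train)
        assert set(out.columns) == {"c=F", "c=M"}
        assert (out.sum(axis=1) == 1).all()

    def test_three_level_sorted_vocabulary(self):
        train = pd.DataFrame({"c": ["C", "A", "B"]})
        enc = CategoricalEncoder().fit(train)
        row = enc.transform(pd.DataFrame({"c": ["B"]}))
        assert list(row[["c=A", "c=B", "c=C"]].iloc[0]) == [0.0, 1.0, 0.0]

    def test_unseen_level_maps_to_zeros_with_warning(self):
        enc = CategoricalEncoder().fit(pd.DataFrame({"c": ["A", "B"]}))
        with pytest.warns(UserWarning, match="unseen"):
            out = enc.transform(pd.DataFrame({"c": ["Z"]}))
        assert out[["c=A", "c=B"]].iloc[0].sum() == 0.0


class TestOutliers:
    def test_boxplot_rule_flags_exactly_the_outlier(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 100.0]})
        flags = flag_outliers(table, k=1.5)
        assert list(flags["x"]) == [False, False, False, False, True]

    def test_constant_column_and_infinite_k_flag_nothing(self):
        table = pd.DataFrame({"x": [5.0, 5.0, 5.0, 5.0, 6.0, 4.0, 5.5, 4.5]})
        assert not flag_outliers(pd.DataFrame({"x": [2.0] * 6}), k=1.5).any().any()
        assert not flag_outliers(table, k=np.inf).any().any()

    def test_policies(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0, 100.0]})
        flags = flag_outliers(table, k=1.5)
        as_missing = apply_outlier_policy(table, flags, "missing")
        assert np.isnan(as_missing["x"].iloc[4])
        winsor = apply_outlier_policy(table, flags, "winsorize", k=1.5)
        assert winsor["x"].iloc[4] < 100.0


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _roi(rng, shape=(10, 10, 10)):
    data = rng.normal(size=shape)
    mask = np.zeros(shape)
    mask[2:8, 2:8, 2:8] = 1
    return extract_roi(vol(data), vol(mask))


class TestAugment:
    def test_identity_spec_returns_copy(self, rng):
        roi = _roi(rng)
        out = augment(roi, AugmentationSpec())
        assert np.array_equal(out.image.data, roi.image.data)
        assert out.image.data is not roi.image.data

    def test_fixed_seed_is_deterministic(self, rng):
        roi = _roi(rng)
        spec = AugmentationSpec(flip_axes=(0, 1), rotation_range=15.0,
                                noise_sd=0.05, elastic_amplitude=1.0, seed=9)
        a, b = augment(roi, spec), augment(roi, spec)
        assert np.array_equal(a.image.data, b.image.data)
        assert np.array_equal(a.mask.data, b.mask.data)

    def test_double_flip_recovers_original(self, rng):
        roi = _roi(rng)
        # find a seed whose coin flips the axis; applying the same spec twice
        # then flips twice, an involution
        for seed in range(20):
            spec = AugmentationSpec(flip_axes=(0,), seed=seed)
            once = augment(roi, spec)
            if not np.array_equal(once.image.data, roi.image.data):
                twice = augment(once, spec)
                assert np.allclose(twice.image.data, roi.image.data)
                return
        pytest.fail("no flipping seed found")

    def test_tumor_voxel_count_preserved_under_flip_rotation(self, rng):
        roi = _roi(rng, shape=(14, 14, 14))
        spec = AugmentationSpec(flip_axes=(0, 1, 2), rotation_range=20.0, seed=3)
        out = augment(roi, spec)
        n0, n1 = roi.mask.data.sum(), out.mask.data.sum()
        assert abs(n1 - n0) / n0 < 0.05

    def test_mask_cotransformed_keeps_support(self, rng):
        roi = _roi(rng)
        spec = AugmentationSpec(rotation_range=30.0, elastic_amplitude=1.5, seed=4)
        out = augment(roi, spec)
        assert np.all(out.image.data[out.mask.data == 0] == 0)

    def test_excessive_deformation_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            augment(_roi(rng), AugmentationSpec(elastic_amplitude=50.0))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

class TestSmote:
    def test_midpoint_with_pinned_lambda(self):
        X = np.array([[0.0, 0.0], [2.0, 2.0]])
        y = np.array(["a", "a"])
        out, labels, synth = smote_oversample(X, y, k_neighbors=1,
                                              target_counts={"a": 3}, lam=0.5)
        assert len(out) == 3 and synth.sum() == 1
        assert np.allclose(out[2], [1.0, 1.0])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_collinearity_of_synthetic_points(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(6, 3))
        y = np.array(["a"] * 3 + ["b"] * 3)
        out, labels, synth = smote_oversample(X, y, k_neighbors=2,
                                              target_counts={"a": 6, "b": 6},
                                              seed=seed)
        for x_new, cell in zip(out[synth], labels[synth]):
            cell_pts = X[y == cell]
            residuals = []
            for i in range(len(cell_pts)):
                for j in range(len(cell_pts)):
                    if i == j:
                        continue
                    d = (np.linalg.norm(x_new - cell_pts[i])
                         + np.linalg.norm(x_new - cell_pts[j])
                         - np.linalg.norm(cell_pts[i] - cell_pts[j]))
                    residuals.append(abs(d))
            assert min(residuals) < 1e-9

    def test_three_point_cell_to_six_inside_hull(self, rng):
        X = rng.normal(size=(3, 2))
        y = np.array(["m"] * 3)
        out, labels, synth = smote_oversample(X, y, target_counts={"m": 6}, seed=1)
        assert len(out) == 6 and synth.sum() == 3
        # every synthetic point lies on a segment between two originals
        for x_new in out[synth]:
            on_segment = any(
                abs(np.linalg.norm(x_new - X[i]) + np.linalg.norm(x_new - X[j])
                    - np.linalg.norm(X[i] - X[j])) < 1e-9
                for i in range(3) for j in range(3) if i != j)
            assert on_segment

    def test_singleton_cell_raises(self):
        with pytest.raises(InsufficientNeighborsError):
            smote_oversample(np.zeros((3, 2)), np.array(["a", "a", "b"]),
                             target_counts={"b": 4})


# ---------------------------------------------------------------------------
# temporal alignment
# ---------------------------------------------------------------------------

class TestTemporalAlignment:
    def test_equal_times_always_retained(self):
        res = align_temporal([3.0], [3.0], delta=0.0)
        assert res.pairs == ((0, 0),)

    def test_boundary_is_closed(self):
        res = align_temporal([0.0], [7.0], delta=7.0)
        assert res.pairs == ((0, 0),)
        res = align_temporal([0.0], [7.0001], delta=7.0)
        assert res.pairs == ()

    def test_nearest_in_window_example(self):
        res = align_temporal([0.0], [-10.0, 3.0, 40.0], delta=7.0)
        assert res.pairs == ((0, 1),)
        assert res.unmatched_clinical == (0, 2)

    def test_matches_exhaustive_scan(self, rng):
        t_img = rng.uniform(-30, 30, size=8)
        t_cli = rng.uniform(-30, 30, size=10)
        delta = 5.0
        res = align_temporal(t_img, t_cli, delta)
        for i, ti in enumerate(t_img):
            gaps = np.abs(t_cli - ti)
            if (gaps <= delta).any():
                j_expected = int(np.flatnonzero(gaps <= delta)[
                    np.argmin(gaps[gaps <= delta])])
                assert (i, j_expected) in res.pairs
            else:
                assert i in res.unmatched_imaging


# ---------------------------------------------------------------------------
# fitted-state sidecar
# ---------------------------------------------------------------------------

def test_state_fingerprint_depends_only_on_fitted_statistics(tmp_path):
    train = pd.DataFrame({"x": [1.0, 2.0, 3.0], "c": ["A", "B", "A"]})
    def build(frame):
        imput = ImputationModel().fit(frame)
        std = StandardizationStats().fit(frame[["x"]])
        enc = CategoricalEncoder().fit(frame[["c"]])
        return PreprocessState(imputation=imput, standardization=std, encoder=enc)
    s1, s2 = build(train), build(train.copy())
    assert s1.fingerprint() == s2.fingerprint()
    other = train.copy()
    other.loc[0, "x"] = 99.0
    assert build(other).fingerprint() != s1.fingerprint()
    s1.to_json(tmp_path / "state.json")
    assert (tmp_path / "state.json").exists()
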