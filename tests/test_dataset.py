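"""Dataset building, pairwise normalization, cropping, augmentation, splits."""

import numpy as np
import pytest
from scipy import stats

import srcorrect.wave
from srcorrect.das import ReconGrid, radius_grid
from srcorrect.dataset import (
    TrainingPair,
    augment_flip,
    build_dataset,
    center_crop,
    load_pairs,
    normalize_pair,
    pairs_by_phantom,
    replicate_channels,
    sample_patch,
    save_pairs,
    split_dataset,
)
from srcorrect.errors import ConfigurationError
from srcorrect.phantoms import PhantomSpec
from srcorrect.wave import Medium, SensorRing, Sinogram


def tiny_build_args():
    return dict(
        medium=Medium(),
        ring=SensorRing(n_sensors=8, radius=6e-3, f0=2e6, frac_bw=0.7),
        radii=radius_grid(5.7e-3, 6.3e-3, 0.06e-3),  # 11 radii
        noise_db=-30.0,
        grid=ReconGrid(nx=32, ny=32, dx=1.2e-4, dy=1.2e-4),
        n_t=128,
        fs=12.5e6,
    )


def fake_simulator(counter=None):
    def _sim(p0, medium, ring, n_t, fs, **kw):
        if counter is not None:
            counter.append(1)
        rng = np.random.default_rng(int(p0.values.sum() * 1e6) % (2 ** 31))
        return Sinogram(data=rng.normal(size=(ring.n_sensors, n_t)), fs=fs)

    return _sim


def make_pair(degraded, gt, radius=24.8e-3):
    return TrainingPair(degraded=np.asarray(degraded, float),
                        gt=np.asarray(gt, float), phantom_id="p0",
                        radius_used=radius, noise_seed=0)


class TestBuildDataset:
    def test_pair_count_is_phantoms_times_radii(self, monkeypatch):
        monkeypatch.setattr(srcorrect.wave, "simulate_rf", fake_simulator())
        specs = [PhantomSpec(canvas=32, seed=s, placement_frac=0.4) for s in range(3)]
        pairs = build_dataset(specs, seed=0, **tiny_build_args())
        assert len(pairs) == 33

    def test_rf_simulated_exactly_once_per_phantom(self, monkeypatch):
        calls = []
        monkeypatch.setattr(srcorrect.wave, "simulate_rf", fake_simulator(calls))
        specs = [PhantomSpec(canvas=32, seed=s, placement_frac=0.4) for s in range(3)]
        build_dataset(specs, seed=0, **tiny_build_args())
        assert len(calls) == 3

    def test_same_seed_twice_is_bit_identical(self, monkeypatch, tmp_path):
        monkeypatch.setattr(srcorrect.wave, "simulate_rf", fake_simulator())
        specs = [PhantomSpec(canvas=32, seed=s, placement_frac=0.4) for s in range(2)]
        runs = []
        for k in range(2):
            pairs = build_dataset(specs, seed=11, **tiny_build_args())
            path = tmp_path / f"run{k}.h5"
            save_pairs(path, pairs)
            runs.append(path.read_bytes())
        assert runs[0] == runs[1]

    def test_gt_shared_across_radii_and_degraded_varies(self, monkeypatch):
        monkeypatch.setattr(srcorrect.wave, "simulate_rf", fake_simulator())
        specs = [PhantomSpec(canvas=32, seed=1, placement_frac=0.4)]
        pairs = build_dataset(specs, seed=0, **tiny_build_args())
        for pair in pairs[1:]:
            np.testing.assert_array_equal(pair.gt, pairs[0].gt)
        assert not np.array_equal(pairs[0].degraded, pairs[1].degraded)


class TestNormalizePair:
    def test_linear_ramp_maps_onto_unit_interval(self):
        gt = np.linspace(0.0, 1.0, 10000).reshape(100, 100)
        pair = make_pair(gt.copy(), gt)
        norm, interval = normalize_pair(pair)
        assert interval.lo == pytest.approx(0.005, abs=1e-3)
        assert interval.hi == pytest.approx(0.995, abs=1e-3)
        assert norm.gt.min() == 0.0 and norm.gt.max() == 1.0

    def test_interval_comes_from_gt_not_degraded(self):
        rng = np.random.default_rng(0)
        gt = rng.random((50, 50))
        degraded = gt.copy()
        _, base = normalize_pair(make_pair(degraded, gt))
        degraded_out = degraded.copy()
        degraded_out[0, 0] = 1e6  # outlier in the degraded member only
        _, with_outlier = normalize_pair(make_pair(degraded_out, gt))
        assert with_outlier == base

    def test_constant_gt_flags_and_zeroes(self):
        pair = make_pair(np.random.default_rng(1).random((8, 8)), np.full((8, 8), 0.3))
        norm, interval = normalize_pair(pair)
        assert interval.degenerate
        assert np.all(norm.gt == 0) and np.all(norm.degraded == 0)

    def test_values_clipped_to_unit_interval(self):
        gt = np.linspace(0, 1, 256).reshape(16, 16)
        degraded = gt * 3 - 1
        norm, _ = normalize_pair(make_pair(degraded, gt))
        assert norm.degraded.min() >= 0.0 and norm.degraded.max() <= 1.0


class TestCropsAndPatches:
    def test_512_to_400_center_crop_offsets(self):
        img = np.arange(512 * 512, dtype=float).reshape(512, 512)
        out = center_crop(img, 400)
        assert out.shape == (400, 400)
        assert out[0, 0] == img[56, 56]

    def test_crop_identity_and_idempotence(self):
        img = np.random.default_rng(2).random((64, 64))
        np.testing.assert_array_equal(center_crop(img, 64), img)
        np.testing.assert_array_equal(center_crop(center_crop(img, 48), 32),
                                      center_crop(img, 32))

    def test_crop_too_large_rejected(self):
        with pytest.raises(ConfigurationError):
            center_crop(np.zeros((32, 32)), 64)

    def test_patch_windows_coincide_between_members(self):
        coords = np.arange(400, dtype=float)
        degraded = np.add.outer(coords, coords * 1000)
        pair = make_pair(degraded, degraded.copy())
        out = sample_patch(pair, 224, np.random.default_rng(0))
        np.testing.assert_array_equal(out.degraded, out.gt)
        assert out.gt.shape == (224, 224)

    def test_patch_reproducible_for_fixed_rng(self):
        pair = make_pair(*(np.random.default_rng(1).random((2, 64, 64))))
        a = sample_patch(pair, 32, np.random.default_rng(9))
        b = sample_patch(pair, 32, np.random.default_rng(9))
        np.testing.assert_array_equal(a.gt, b.gt)

    def test_patch_corner_distribution_is_uniform(self):
        """Chi-square test of the top-left corner over all admissible offsets."""
        pair = make_pair(np.add.outer(np.arange(20.0), np.zeros(20)),
                         np.add.outer(np.arange(20.0), np.zeros(20)))
        rng = np.random.default_rng(123)
        counts = np.zeros(13)
        for _ in range(10000):
            out = sample_patch(pair, 8, rng)
            counts[int(out.gt[0, 0])] += 1
        assert stats.chisquare(counts).pvalue > 1e-3


class TestAugmentFlip:
    def test_flip_applied_jointly(self):
        coords = np.add.outer(np.arange(16.0), np.arange(16.0) * 100)
        pair = make_pair(coords, coords.copy())
        rng = np.random.default_rng(5)
        for _ in range(20):
            out = augment_flip(pair, rng)
            np.testing.assert_array_equal(out.degraded, out.gt)

    def test_each_axis_flips_at_rate_half(self):
        probe = np.zeros((4, 4))
        probe[0, 0] = 1.0
        pair = make_pair(probe, probe.copy())
        rng = np.random.default_rng(7)
        n = 10000
        h = v = 0
        for _ in range(n):
            out = augment_flip(pair, rng)
            pos = np.argwhere(out.gt == 1.0)[0]
            h += pos[1] == 3
            v += pos[0] == 3
        assert h / n == pytest.approx(0.5, abs=0.02)
        assert v / n == pytest.approx(0.5, abs=0.02)


class TestReplicateChannels:
    def test_three_identical_channels(self):
        patch = np.random.default_rng(0).random((7, 9))
        out = replicate_channels(patch)
        assert out.shape == (3, 7, 9)
        np.testing.assert_array_equal(out[0], out[1])
        np.testing.assert_array_equal(out[1], out[2])
        np.testing.assert_allclose(out.mean(axis=0), patch, rtol=1e-15)

    def test_zero_patch_gives_zero_channels(self):
        assert np.all(replicate_channels(np.zeros((4, 4))) == 0)


class TestSplitDataset:
    def test_reference_split_sizes(self):
        train, val, test = split_dataset(480, (0.7, 0.2, 0.1), seed=0)
        assert (len(train), len(val), len(test)) == (336, 96, 48)

    def test_ten_phantoms_split_7_2_1(self):
        train, val, test = split_dataset(10, (0.7, 0.2, 0.1), seed=1)
        assert (len(train), len(val), len(test)) == (7, 2, 1)

    def test_subsets_disjoint_and_complete(self):
        train, val, test = split_dataset(50, (0.7, 0.2, 0.1), seed=3)
        union = np.concatenate([train, val, test])
        assert len(set(union.tolist())) == 50

    def test_phantom_level_grouping(self):
        pairs = [TrainingPair(degraded=np.zeros((2, 2)), gt=np.zeros((2, 2)),
                              phantom_id=f"phantom_{i:04d}", radius_used=0.01,
                              noise_seed=0)
                 for i in range(5) for _ in range(3)]
        subset = pairs_by_phantom(pairs, [1, 3])
        assert len(subset) == 6
        assert {p.phantom_id for p in subset} == {"phantom_0001", "phantom_0003"}

    def test_too_few_phantoms_rejected(self):
        with pytest.raises(ConfigurationError):
            split_dataset(2, (0.7, 0.2, 0.1), seed=0)


def test_hdf5_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    pairs = [TrainingPair(degraded=rng.random((8, 8)), gt=rng.random((8, 8)),
                          phantom_id=f"phantom_{i:04d}", radius_used=0.0248 + i * 1e-4,
                          noise_seed=i) for i in range(3)]
    path = tmp_path / "pairs.h5"
    save_pairs(path, pairs)
    loaded = load_pairs(path)
    assert len(loaded) == 3
    for a, b in zip(pairs, loaded):
        np.testing.assert_allclose(a.gt, b.gt, atol=1e-6)
        assert a.phantom_id == b.phantom_id
        assert a.noise_seed == b.noise_seed
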