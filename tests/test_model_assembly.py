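"""Model assembly, daily interpolation, rate fields, time averaging."""

import h5py
import numpy as np
import pytest

import mineralwave as mw
from mineralwave import model_assembly as ma
from mineralwave.mineralization_mcmc import MCMCConfig, PixelSeries, sample_pixel

REF = mw.REFERENCE_MAX_DENSITY


@pytest.fixture(scope="module")
def toy_model(tmp_path_factory):
    """3 specimens x 4 pixels x 5 retained samples, written to HDF5."""
    times = np.array([10.0, 60.0, 120.0])
    cfg = MCMCConfig(n_samples=4000, n_keep=5)
    series, posts = [], []
    rng = np.random.default_rng(0)
    for i in range(4):
        present = np.ones(3, bool)
        if i == 3:
            present[0] = False  # this pixel absent from the youngest specimen
        rho = np.where(present, np.sort(rng.uniform(0.5, 2.5, 3)), 0.0)
        s = PixelSeries(
            location=(float(i), 0.25 * i), times=times, rho_d=rho,
            present=present, sigma=np.full(3, 0.131),
        )
        series.append(s)
        posts.append(sample_pixel(s, cfg, seed=i))
    path = tmp_path_factory.mktemp("model") / "model.h5"
    model = ma.assemble_model(posts, series, output_path=path,
                              edj_bin_mm=0.05, n_depth_bins=4, seed=1)
    return model, path, series


def test_hdf5_schema_and_lossless_roundtrip(toy_model):
    model, path, _ = toy_model
    with h5py.File(path, "r") as f:
        assert set(f.keys()) == {"age_mask", "ages", "locations", "pct_min_samples"}
        np.testing.assert_array_equal(f["age_mask"][()], model.age_mask)
        np.testing.assert_array_equal(f["ages"][()], model.ages)
        np.testing.assert_array_equal(f["locations"][()], model.locations)
        np.testing.assert_array_equal(f["pct_min_samples"][()], model.pct_min_samples)
    back = ma.read_model(path)
    np.testing.assert_array_equal(back.pct_min_samples, model.pct_min_samples)
    assert back.reference_density == model.reference_density


def test_absent_pixel_ages_masked_and_sentineled(toy_model):
    model, _, series = toy_model
    assert model.age_mask.shape == (4, 3)
    assert model.age_mask[3, 0] == 0
    assert np.all(model.pct_min_samples[0, 3, :] == ma.ABSENT_SENTINEL)
    present = model.pct_min_samples[model.age_mask.T.astype(bool), :]
    assert present.min() >= 0.0 and present.max() <= 105.0  # percent scale


def test_stored_samples_monotone_at_present_ages(toy_model):
    model, _, _ = toy_model
    for pix in range(model.n_pixels):
        ages, traj = model.trajectories(pix)
        assert np.all(np.diff(traj, axis=1) >= 1e-5 - 1e-12)


def test_roster_mismatch_rejected(toy_model):
    _, _, series = toy_model
    cfg = MCMCConfig(n_samples=2000, n_keep=5)
    other = PixelSeries(
        location=(9.0, 0.5), times=np.array([5.0, 50.0, 100.0]),
        rho_d=np.array([0.5, 1.0, 2.0]), present=np.ones(3, bool),
        sigma=np.full(3, 0.131),
    )
    posts = [sample_pixel(s, cfg, seed=0) for s in [series[0], other]]
    with pytest.raises(ma.AssemblyError):
        ma.assemble_model(posts, [series[0], other])


def test_planned_estimate_count_from_shape_metadata(tmp_path):
    """The full-scale model (12,000 pixels, 280 days, 100 samples) holds
    336 million daily density estimates, verified on HDF5 shape metadata
    without materializing the data."""
    path = tmp_path / "skeleton.h5"
    with h5py.File(path, "w") as f:
        f.create_dataset("age_mask", shape=(12_000, 45), dtype="u1")
        f.create_dataset("ages", shape=(45,), dtype="f8")
        f.create_dataset("locations", shape=(12_000, 2), dtype="f8")
        f.create_dataset("pct_min_samples", shape=(45, 12_000, 100), dtype="f4")
    assert path.stat().st_size < 10_000_000  # nothing materialized
    with h5py.File(path, "r") as f:
        n_ages, n_pixels, n_keep = f["pct_min_samples"].shape
    assert ma.planned_estimate_count(n_pixels, 280, n_keep) == 336_000_000


def test_interpolate_daily_hits_stored_samples(toy_model):
    model, _, _ = toy_model
    daily = ma.interpolate_daily(model, n_days=150, t_start=0.0, statistic=None)
    days = np.arange(150.0)
    for k, pix in enumerate(daily.pixel_index):
        ages, traj = model.trajectories(int(pix))
        for age, col in zip(ages, np.searchsorted(days, ages)):
            if age in days:
                np.testing.assert_allclose(
                    daily.values[:, k, col], traj[:, list(ages).index(age)]
                )
        assert np.all(np.diff(daily.values[:, k, :], axis=1) >= -1e-12)


def test_interpolate_daily_estimate_count(toy_model):
    model, _, _ = toy_model
    daily = ma.interpolate_daily(model, n_days=150, t_start=0.0, statistic=None)
    assert daily.values.size == ma.planned_estimate_count(
        len(daily.pixel_index), 150, model.n_samples
    )
    assert model.daily_estimate_count(150) == model.n_pixels * 150 * model.n_samples


def test_rate_field_telescoping_and_nonnegative(toy_model):
    model, _, _ = toy_model
    daily = ma.interpolate_daily(model, n_days=150, t_start=0.0)
    field = ma.rate_field(daily, model.edj_bin_mm, model.n_depth_bins)
    assert np.all(field.rates >= -1e-12)
    pct = daily.values / REF * 100.0
    np.testing.assert_allclose(field.rates.sum(axis=1), pct[:, -1], atol=1e-9)
    flat_traj = np.full((2, 10), 50.0)
    const = ma.DailyTrajectories(
        days=np.arange(10.0), values=flat_traj,
        locations=np.array([[0.1, 0.2], [0.2, 0.4]]),
        pixel_index=np.arange(2), reference_density=REF,
    )
    f2 = ma.rate_field(const, 0.1, 4)
    assert np.allclose(f2.rates[:, 1:], 0.0)


def test_time_averaging_step_and_known_ramp():
    days = np.arange(200.0)
    step = np.where(days >= 30, REF, 0.0)[None, :]
    ramp = np.where(
        days < 10, 0.0, np.minimum((days - 10) / 105.88, 1.0) * REF
    )[None, :]  # crosses 0.85*REF at day ~100 -> 90 days averaged
    daily = ma.DailyTrajectories(
        days=days, values=np.vstack([step, ramp]),
        locations=np.array([[1.0, 0.2], [1.0, 0.8]]),
        pixel_index=np.arange(2), reference_density=REF,
    )
    tam = ma.time_averaging_map(daily)
    assert tam.days_averaged[0] == 0.0
    # ~90 days, to within the daily grid resolution (first-nonzero day is
    # quantized up by one day)
    assert tam.days_averaged[1] == pytest.approx(90.0, abs=1.5)


def test_time_averaging_incomplete_flagged():
    days = np.arange(50.0)
    traj = (days / 100.0 * REF)[None, :]  # never reaches 85%
    daily = ma.DailyTrajectories(
        days=days, values=traj, locations=np.array([[1.0, 0.5]]),
        pixel_index=np.arange(1), reference_density=REF,
    )
    tam = ma.time_averaging_map(daily)
    assert not tam.complete[0] and np.isnan(tam.days_averaged[0])


def test_animation_frames(tmp_path, toy_model):
    model, _, _ = toy_model
    daily = ma.interpolate_daily(model, n_days=40, t_start=0.0)
    field = ma.rate_field(daily, model.edj_bin_mm, model.n_depth_bins)
    unblurred = ma.smooth_rate_field(field, 0.0, 0.0)
    np.testing.assert_array_equal(unblurred, field.to_grid())
    blurred = ma.smooth_rate_field(field, 1.0, 8.0)
    assert blurred.shape == unblurred.shape
    # normalized kernel conserves total rate mass away from the boundary
    total_un = unblurred.sum()
    total_bl = ma.smooth_rate_field(field, 1.0, 0.0).sum()
    assert total_bl == pytest.approx(total_un, rel=0.05)
    paths = ma.export_animation_frames(field, tmp_path / "frames", 1.0, 8.0)
    assert len(paths) == field.days.size
    assert all(p.exists() for p in paths)
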