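"""Shared fixtures: synthetic sections and a scaled end-to-end model run.

Expensive artifacts (rendered series, the sampled model) are session-scoped
so every test file reuses one computation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pytest

import mineralwave as mw
from mineralwave.density_calibration import calibrate_section
from mineralwave.growth_curves import SpecimenRecord, fit_growth_curve, reassign_ages
from mineralwave.mineralization_mcmc import MCMCConfig, build_pixel_series, run_all_pixels
from mineralwave import model_assembly as ma
from mineralwave.shape_standardization import flatten, measure_landmarks, trace_edj

logging.getLogger("mineralwave").setLevel(logging.ERROR)

REFERENCE = mw.REFERENCE_MAX_DENSITY


@pytest.fixture(scope="session")
def wave_params() -> mw.WaveModelParams:
    return mw.WaveModelParams()


@pytest.fixture(scope="session")
def truth_default(wave_params) -> mw.SyntheticTruth:
    return mw.simulate_truth(wave_params, pixel_size_mm=0.1, time_step_days=10.0)


@pytest.fixture(scope="session")
def section_120(truth_default) -> mw.ToothSection:
    """Noise-free high-resolution section at 120 days (batch 1 synthetic)."""
    return mw.render_section(
        truth_default, 120.0, mw.SYNTHETIC_CALIBRATIONS[1], noise_frac=0.0, seed=1
    )


@pytest.fixture(scope="session")
def dmap_120(section_120):
    return calibrate_section(section_120, mw.SYNTHETIC_CALIBRATIONS[1])


@pytest.fixture(scope="session")
def flat_120(dmap_120):
    return flatten(dmap_120, trace_edj(dmap_120))


@dataclass
class PipelineRun:
    """Everything the scaled end-to-end run produces."""

    params: mw.WaveModelParams
    ages: list
    sections: list
    truth: mw.SyntheticTruth
    flats: list
    records: list
    extension_fit: object
    config: MCMCConfig
    series: list
    posteriors: list
    usable: list
    model: ma.MineralizationModel
    daily: ma.DailyTrajectories


@pytest.fixture(scope="session")
def pipeline_run(wave_params) -> PipelineRun:
    """Scaled full pipeline: 12 specimens across the M1 formation window,
    5% noise, ~320 pixel locations, 20,000 MCMC samples per pixel."""
    params = wave_params
    ages = list(np.linspace(10.0, 300.0, 12))
    sections, truth = mw.simulate_series(params, ages, seed=11, pixel_size_mm=0.1)
    flats, records = [], []
    for sec in sections:
        dmap = calibrate_section(sec, mw.SYNTHETIC_CALIBRATIONS[sec.batch])
        flat = flatten(dmap, trace_edj(dmap), n_depth_bins=10)
        lm = measure_landmarks(flat)
        flats.append(flat)
        records.append(SpecimenRecord(sec.specimen_id, sec.age_days, lm.e_l))
    fit = fit_growth_curve(
        [(r.chronological_age, r.e_l) for r in records],
        el_max=max(r.e_l for r in records),
        seed=3,
    )
    records = reassign_ages(records, fit.params)
    cfg = MCMCConfig(n_samples=20_000, seed=5)
    series = build_pixel_series(flats, records, cfg, distance_stride=12)
    posteriors, usable = run_all_pixels(series, cfg, progress_every=0)
    model = ma.assemble_model(
        posteriors, usable, edj_bin_mm=flats[0].edj_bin_mm, n_depth_bins=10
    )
    daily = ma.interpolate_daily(model, n_days=420, t_start=-49.0)
    return PipelineRun(
        params=params, ages=ages, sections=sections, truth=truth, flats=flats,
        records=records, extension_fit=fit, config=cfg, series=series,
        posteriors=posteriors, usable=usable, model=model, daily=daily,
    )
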