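"""Reverse correlation, subfield detection, Gaussian fits, ellipse geometry."""

import numpy as np
import pandas as pd
import pytest

from attnrun import grid, rf
from attnrun.geometry import (
    ellipse_disk_distance,
    ellipse_disk_distance_bruteforce,
)


# ---------- eye-movement compensation ----------

def _events(az, el, onset=1.0):
    row, col = grid.nearest_cell(az, el)
    a, e = grid.cell_center(row, col)
    return pd.DataFrame(
        {"onset_s": [onset], "row": [row], "col": [col],
         "azimuth_deg": [a], "elevation_deg": [e], "polarity": ["white"]}
    )


def test_compensation_zero_deviation_is_identity():
    ft = np.arange(100) / 12.85
    ev = _events(52.5, 2.5)
    out = rf.compensate_stimulus_positions(ev, ft, np.zeros(100), np.zeros(100), np.ones(100, bool))
    assert out["azimuth_deg"].iloc[0] == ev["azimuth_deg"].iloc[0]
    assert out["row"].iloc[0] == ev["row"].iloc[0]


def test_compensation_shifts_to_nearest_cell():
    ft = np.arange(100) / 12.85
    ev = _events(52.5, 2.5)
    az_dev = np.full(100, 3.0)
    el_dev = np.full(100, -2.0)
    out = rf.compensate_stimulus_positions(ev, ft, az_dev, el_dev, np.ones(100, bool))
    # +3 az rounds to the next 5-degree column; -2 el stays in the same row
    assert out["col"].iloc[0] == ev["col"].iloc[0] + 1
    assert out["row"].iloc[0] == ev["row"].iloc[0]


def test_compensation_drops_invalid_frames():
    ft = np.arange(100) / 12.85
    ev = _events(52.5, 2.5)
    valid = np.ones(100, bool)
    valid[rf.event_frames([1.0], ft)[0]] = False
    out = rf.compensate_stimulus_positions(ev, ft, np.zeros(100), np.zeros(100), valid)
    assert len(out) == 0


# ---------- reverse correlation ----------

def _toy_maps(seed=0, amp=1.0, n_neurons=1, rf_cell=(6, 10), n_reps=12, noise=0.0):
    """Events at every grid location; responses boxcar-driven at rf_cell."""
    rng = np.random.default_rng(seed)
    frame_rate = 12.85
    events = []
    t = 1.0
    for rep in range(n_reps):
        for r in range(0, grid.N_ROWS, 2):
            for c in range(0, grid.N_COLS, 2):
                events.append((t, r, c))
                t += 0.9
    ev = pd.DataFrame(events, columns=["onset_s", "row", "col"])
    az, el = grid.cell_center(ev["row"], ev["col"])
    ev["azimuth_deg"], ev["elevation_deg"] = az, el
    ev["polarity"] = "white"
    n_frames = int((t + 2) * frame_rate)
    ft = np.arange(n_frames) / frame_rate
    dff = rng.normal(0, noise, (n_neurons, n_frames))
    f = rf.event_frames(ev["onset_s"].to_numpy(), ft)
    hit = (ev["row"] == rf_cell[0]) & (ev["col"] == rf_cell[1])
    for fi in f[hit.to_numpy()]:
        dff[:, fi : fi + 5] += amp
    return dff, ev, ft


def test_reverse_correlation_finds_rf_location():
    dff, ev, ft = _toy_maps(amp=1.0)
    m = rf.reverse_correlate(dff, ev, ft)
    wmap = m.maps["white"][0]
    r, c = np.unravel_index(np.nanargmax(wmap), wmap.shape)
    assert (r, c) == (6, 10)


def test_reverse_correlation_is_linear():
    dff, ev, ft = _toy_maps(amp=1.0)
    m1 = rf.reverse_correlate(dff, ev, ft).maps["white"][0]
    m2 = rf.reverse_correlate(2 * dff, ev, ft).maps["white"][0]
    ok = np.isfinite(m1)
    assert np.allclose(m2[ok], 2 * m1[ok], atol=1e-12)


def test_noise_only_map_is_centred_on_zero():
    dff, ev, ft = _toy_maps(amp=0.0, noise=0.1, seed=3)
    m = rf.reverse_correlate(dff, ev, ft).maps["white"][0]
    vals = m[np.isfinite(m)]
    from scipy.stats import binomtest

    p = binomtest((vals > 0).sum(), vals.size, 0.5).pvalue
    assert p > 0.01


def test_detect_subfields_noiseless_and_classification():
    dff, ev, ft = _toy_maps(amp=1.0, noise=0.02)
    m = rf.reverse_correlate(dff, ev, ft)
    rf.detect_subfields(m)
    assert m.mask["white"][0, 6, 10]
    assert m.subfield_class[0] == "on"


def test_untestable_locations_get_nan_pvalues():
    dff, ev, ft = _toy_maps(amp=1.0, noise=0.02)
    m = rf.reverse_correlate(dff, ev, ft)
    rf.detect_subfields(m)
    # odd rows/cols never stimulated -> untestable
    assert np.isnan(m.pvals["white"][0, 1, 1])


# ---------- Gaussian fitting ----------

def _gauss_map(center=(40.0, -15.0), sig=(8.0, 5.0), rot_deg=20.0, amp=1.0):
    centers = grid.all_cell_centers()
    az = centers[:, 0].reshape(grid.N_ROWS, grid.N_COLS)
    el = centers[:, 1].reshape(grid.N_ROWS, grid.N_COLS)
    th = np.deg2rad(rot_deg)
    u = (az - center[0]) * np.cos(th) + (el - center[1]) * np.sin(th)
    v = -(az - center[0]) * np.sin(th) + (el - center[1]) * np.cos(th)
    return amp * np.exp(-0.5 * ((u / sig[0]) ** 2 + (v / sig[1]) ** 2))


def test_gaussian_fit_recovers_parameters():
    m = _gauss_map()
    mask = m > 0.3
    fit = rf.fit_gaussian_rf(m, mask)
    assert fit.success
    assert np.hypot(fit.center_az - 40, fit.center_el + 15) < 1.0
    assert abs(fit.sigma_major - 8) / 8 < 0.05
    assert abs(fit.sigma_minor - 5) / 5 < 0.05


def test_circular_rf_aspect_ratio_one():
    m = _gauss_map(sig=(6.0, 6.0), rot_deg=0.0)
    fit = rf.fit_gaussian_rf(m, m > 0.3)
    assert abs(fit.aspect_ratio - 1.0) < 0.05


def test_aspect_invariant_under_map_rotation():
    f1 = rf.fit_gaussian_rf(_gauss_map(rot_deg=10), _gauss_map(rot_deg=10) > 0.3)
    f2 = rf.fit_gaussian_rf(_gauss_map(rot_deg=55), _gauss_map(rot_deg=55) > 0.3)
    assert abs(f1.aspect_ratio - f2.aspect_ratio) < 0.05


def test_empty_mask_rejected():
    with pytest.raises(ValueError):
        rf.fit_gaussian_rf(np.zeros((grid.N_ROWS, grid.N_COLS)),
                           np.zeros((grid.N_ROWS, grid.N_COLS), bool))


# ---------- ellipse-disk geometry ----------

def test_ellipse_on_disk_center_overlaps():
    assert ellipse_disk_distance(grid.BR_LOCATION, (8, 5), 0.3, grid.BR_LOCATION) <= 0


def test_collinear_closed_form():
    # circle of radius 4 centred 30 deg from a 15-deg disk: D = 30 - 4 - 15
    d = ellipse_disk_distance((30.0, 0.0), (4.0, 4.0), 0.0, (0.0, 0.0), 15.0)
    assert abs(d - 11.0) < 1e-6


def test_constructed_tangency():
    # circle radius 5 centred exactly 20 deg away from a 15-deg disk
    d = ellipse_disk_distance((20.0, 0.0), (5.0, 5.0), 0.0, (0.0, 0.0), 15.0)
    assert abs(d) < 1e-3


def test_containment_cases_negative():
    # tiny ellipse deep inside the disk
    assert ellipse_disk_distance((1.0, 0.0), (2.0, 1.0), 0.2, (0.0, 0.0), 15.0) < 0
    # huge ellipse containing the whole disk
    assert ellipse_disk_distance((0.0, 0.0), (40.0, 30.0), 0.0, (0.0, 0.0), 15.0) < 0


def test_agrees_with_bruteforce_sampler():
    rng = np.random.default_rng(11)
    for _ in range(100):
        center = rng.uniform(-30, 120, 2)
        a = rng.uniform(2, 30)
        b = rng.uniform(1, a)
        ang = rng.uniform(-np.pi, np.pi)
        disk = rng.uniform(-30, 120, 2)
        r = rng.uniform(5, 25)
        d1 = ellipse_disk_distance(center, (a, b), ang, disk, r)
        d2 = ellipse_disk_distance_bruteforce(center, (a, b), ang, disk, r)
        assert abs(d1 - d2) < 1e-3


def test_degenerate_ellipse_rejected():
    with pytest.raises(ValueError):
        ellipse_disk_distance((0, 0), (0.0, 0.0), 0.0, (10, 10))


def test_compare_rf_between_blocks_identical_maps():
    m = _gauss_map()
    fit = rf.fit_gaussian_rf(m, m > 0.3)
    out = rf.compare_rf_between_blocks(fit, fit, "BR")
    assert out["delta_centroid_dist"] == 0.0
    assert out["delta_aspect"] == 0.0
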