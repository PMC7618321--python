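"""Reverse-correlation receptive-field mapping and Gaussian RF geometry.

Stimulus positions are first compensated for eye movements (events on
frames with pupil deviation above 10 degrees, or otherwise invalid frames,
are dropped).  For every grid location and polarity the median
baseline-subtracted onset response is computed across repetitions; ON/OFF
subfields are detected with a Wilcoxon rank-sum test of each location's
onset responses against the pooled responses at all other locations of the
same polarity, Sidak-corrected across the tested family, requiring a
positive median.  Cells with a single ON or OFF subfield get a rotated 2-D
Gaussian fit whose two-sigma ellipse supplies the signed distance D to the
BR and TL task disks (overlap iff D <= 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import norm, rankdata

from attnrun import grid
from attnrun.geometry import ellipse_disk_distance

POLARITIES = ("white", "black")  # ON, OFF
RESPONSE_FRAMES = 7  # frames covering ~0-0.5 s after onset
BASELINE_FRAMES = 6  # ~470 ms before onset


def event_frames(onsets, frame_times):
    """First imaging frame at or after each onset time."""
    return np.searchsorted(frame_times, np.asarray(onsets) - 1e-9, side="left")


def compensate_stimulus_positions(events, frame_times, pupil_az_dev, pupil_el_dev, valid_rf):
    """Shift event positions by the concurrent pupil deviation.

    Events whose frame is invalid for RF analyses (pupil deviation above
    10 degrees in either axis, or eye closure) are dropped; the remaining
    events are shifted by the deviation and snapped to the nearest grid
    cell.
    """
    ev = events.copy()
    f = np.clip(event_frames(ev["onset_s"].to_numpy(), frame_times), 0, len(frame_times) - 1)
    keep = np.asarray(valid_rf)[f]
    ev = ev[keep].reset_index(drop=True)
    f = f[keep]
    az = ev["azimuth_deg"].to_numpy() + np.asarray(pupil_az_dev)[f]
    el = ev["elevation_deg"].to_numpy() + np.asarray(pupil_el_dev)[f]
    row, col = grid.nearest_cell(az, el)
    ev["row"] = row
    ev["col"] = col
    ev["azimuth_deg"], ev["elevation_deg"] = grid.cell_center(row, col)
    return ev


@dataclass
class RFMap:
    """Per-neuron, per-polarity onset-response maps and subfield detection.

    ``samples[pol][(row, col)]`` is an (n_reps, n_neurons) array of
    baseline-subtracted windowed onset responses.  ``maps[pol]`` is the
    (n_neurons, 14, 22) median map (NaN where a location has no
    repetitions).  ``pvals``/``mask``/``subfield_class`` are filled by
    :func:`detect_subfields`.
    """

    samples: dict
    maps: dict
    counts: dict
    n_neurons: int
    pvals: dict = field(default_factory=dict)
    pvals_adj: dict = field(default_factory=dict)
    mask: dict = field(default_factory=dict)
    subfield_class: np.ndarray = None


def reverse_correlate(
    dff,
    events,
    frame_times,
    response_frames=RESPONSE_FRAMES,
    baseline_frames=BASELINE_FRAMES,
    chunk=2000,
):
    """Median onset-response maps by reverse correlation.

    The response to one event is the mean dF/F over ``response_frames``
    frames from its onset frame minus the median over the
    ``baseline_frames`` preceding frames.
    """
    dff = np.asarray(dff)
    n_neurons, n_frames = dff.shape
    f = event_frames(events["onset_s"].to_numpy(), frame_times)
    ok = (f >= baseline_frames) & (f + response_frames <= n_frames)
    ev = events[ok].reset_index(drop=True)
    f = f[ok]

    resp = np.empty((len(ev), n_neurons))
    for s in range(0, len(ev), chunk):
        fs = f[s : s + chunk]
        widx = fs[:, None] + np.arange(response_frames)[None, :]
        bidx = fs[:, None] - np.arange(baseline_frames, 0, -1)[None, :]
        win = dff[:, widx]  # (n_neurons, m, response_frames)
        base = dff[:, bidx]
        resp[s : s + chunk] = (win.mean(axis=2) - np.median(base, axis=2)).T

    samples, maps, counts = {}, {}, {}
    rows = ev["row"].to_numpy()
    cols = ev["col"].to_numpy()
    pol = ev["polarity"].to_numpy()
    for p in POLARITIES:
        sel = pol == p
        m = np.full((n_neurons, grid.N_ROWS, grid.N_COLS), np.nan)
        c = np.zeros((grid.N_ROWS, grid.N_COLS), dtype=int)
        d = {}
        loc_key = rows[sel] * grid.N_COLS + cols[sel]
        r_sel = resp[sel]
        for key in np.unique(loc_key):
            i, j = divmod(int(key), grid.N_COLS)
            vals = r_sel[loc_key == key]
            d[(i, j)] = vals
            c[i, j] = vals.shape[0]
            m[:, i, j] = np.median(vals, axis=0)
        samples[p] = d
        maps[p] = m
        counts[p] = c
    return RFMap(samples=samples, maps=maps, counts=counts, n_neurons=n_neurons)


def _tie_term(column):
    _, cnt = np.unique(column, return_counts=True)
    cnt = cnt[cnt > 1]
    return float(np.sum(cnt**3 - cnt))


def detect_subfields(rfmap, alpha=0.05, min_reps=3):
    """Rank-sum subfield detection with Sidak correction.

    Each testable location (>= ``min_reps`` repetitions) is compared, per
    neuron and polarity, against the pooled onset responses at all other
    locations of the same polarity (two-sided Wilcoxon rank-sum, normal
    approximation with tie correction), Sidak-corrected over the tested
    family.  A location enters the RF mask when the corrected p-value is
    below ``alpha`` and its median response is positive.
    """
    n = rfmap.n_neurons
    for p in POLARITIES:
        locs = [k for k, v in rfmap.samples[p].items() if v.shape[0] >= min_reps]
        pmat = np.full((n, grid.N_ROWS, grid.N_COLS), np.nan)
        if locs:
            values = np.vstack([rfmap.samples[p][k] for k in locs])  # (N, n)
            labels = np.concatenate(
                [np.full(rfmap.samples[p][k].shape[0], i) for i, k in enumerate(locs)]
            )
            N = values.shape[0]
            ranks = rankdata(values, axis=0)
            n1 = np.bincount(labels, minlength=len(locs)).astype(float)
            r1 = np.zeros((len(locs), n))
            np.add.at(r1, labels, ranks)
            ties = np.array([_tie_term(values[:, j]) for j in range(n)])
            mean1 = n1[:, None] * (N + 1) / 2.0
            var = (
                n1[:, None]
                * (N - n1)[:, None]
                / 12.0
                * ((N + 1) - ties[None, :] / (N * (N - 1)))
            )
            with np.errstate(divide="ignore", invalid="ignore"):
                z = (r1 - mean1) / np.sqrt(var)
            pv = 2.0 * norm.sf(np.abs(z))  # (n_locs, n)
            for i, (r, c) in enumerate(locs):
                pmat[:, r, c] = pv[i]
        rfmap.pvals[p] = pmat
        m = len(locs)
        with np.errstate(invalid="ignore"):
            adj = -np.expm1(m * np.log1p(-np.clip(pmat, 0, 1 - 1e-16))) if m else pmat
        rfmap.pvals_adj[p] = adj
        rfmap.mask[p] = (adj < alpha) & (rfmap.maps[p] > 0)

    on = rfmap.mask["white"].any(axis=(1, 2))
    off = rfmap.mask["black"].any(axis=(1, 2))
    cls = np.full(n, "none", dtype=object)
    cls[on & ~off] = "on"
    cls[off & ~on] = "off"
    cls[on & off] = "both"
    rfmap.subfield_class = cls
    return rfmap


@dataclass
class GaussianRF:
    """Rotated 2-D Gaussian receptive field and its task-location geometry."""

    center_az: float
    center_el: float
    sigma_major: float
    sigma_minor: float
    rotation_rad: float
    amplitude: float
    aspect_ratio: float
    d_br: float
    d_tl: float
    centroid_dist_br: float
    centroid_dist_tl: float
    success: bool = True

    @property
    def two_sigma_axes(self):
        return (2 * self.sigma_major, 2 * self.sigma_minor)


def _gauss2d(coords, amp, x0, y0, sx, sy, theta):
    x, y = coords
    ct, st = np.cos(theta), np.sin(theta)
    u = (x - x0) * ct + (y - y0) * st
    v = -(x - x0) * st + (y - y0) * ct
    return amp * np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))


def fit_gaussian_rf(median_map, mask, disk_radius=grid.TASK_DISK_RADIUS):
    """Fit a rotated 2-D Gaussian to a median onset-response map.

    The mean response outside the RF mask is subtracted first.  Returns a
    :class:`GaussianRF` (success=False on non-convergence or a fit wider
    than the grid).  Distances D to the BR/TL disks use the two-sigma
    ellipse.
    """
    m = np.array(median_map, dtype=float)
    if not mask.any():
        raise ValueError("empty RF mask")
    finite = np.isfinite(m)
    outside = finite & ~mask
    m = m - (m[outside].mean() if outside.any() else 0.0)

    centers = grid.all_cell_centers()
    az = centers[:, 0].reshape(grid.N_ROWS, grid.N_COLS)
    el = centers[:, 1].reshape(grid.N_ROWS, grid.N_COLS)

    w = np.clip(np.where(mask & finite, m, 0.0), 0.0, None)
    wsum = w.sum()
    x0 = float((w * az).sum() / wsum)
    y0 = float((w * el).sum() / wsum)
    s0 = float(np.sqrt((w * ((az - x0) ** 2 + (el - y0) ** 2)).sum() / wsum / 2.0))
    s0 = max(s0, 2.0)
    a0 = float(np.nanmax(np.where(mask, m, np.nan)))

    pts = finite
    p0 = [a0, x0, y0, s0, s0, 0.0]
    lo = [0.0, az.min() - 10, el.min() - 10, 1.0, 1.0, -np.pi]
    hi = [10 * max(a0, 1e-6), az.max() + 10, el.max() + 10, 60.0, 60.0, np.pi]
    try:
        popt, _ = curve_fit(
            _gauss2d,
            (az[pts].ravel(), el[pts].ravel()),
            m[pts].ravel(),
            p0=p0,
            bounds=(lo, hi),
            maxfev=5000,
        )
    except Exception:
        return GaussianRF(np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                          np.nan, np.nan, np.nan, np.nan, success=False)
    amp, x0, y0, sx, sy, theta = popt
    if sy > sx:
        sx, sy = sy, sx
        theta += np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    if sx >= 60.0 - 1e-6:
        return GaussianRF(x0, y0, sx, sy, theta, amp, sx / sy, np.nan, np.nan,
                          np.nan, np.nan, success=False)
    d_br = ellipse_disk_distance((x0, y0), (2 * sx, 2 * sy), theta, grid.BR_LOCATION, disk_radius)
    d_tl = ellipse_disk_distance((x0, y0), (2 * sx, 2 * sy), theta, grid.TL_LOCATION, disk_radius)
    return GaussianRF(
        center_az=float(x0),
        center_el=float(y0),
        sigma_major=float(sx),
        sigma_minor=float(sy),
        rotation_rad=float(theta),
        amplitude=float(amp),
        aspect_ratio=float(sx / sy),
        d_br=float(d_br),
        d_tl=float(d_tl),
        centroid_dist_br=float(np.hypot(x0 - grid.BR_LOCATION[0], y0 - grid.BR_LOCATION[1])),
        centroid_dist_tl=float(np.hypot(x0 - grid.TL_LOCATION[0], y0 - grid.TL_LOCATION[1])),
    )


def fit_all_rfs(rfmap):
    """Gaussian fits for all neurons with a single ON or OFF subfield.

    Returns a DataFrame with one row per fittable neuron.  Neurons with
    both ON and OFF subfields, or none, are skipped.
    """
    rows = []
    for i in range(rfmap.n_neurons):
        cls = rfmap.subfield_class[i]
        if cls not in ("on", "off"):
            continue
        p = "white" if cls == "on" else "black"
        fit = fit_gaussian_rf(rfmap.maps[p][i], rfmap.mask[p][i])
        rows.append(
            {
                "neuron": i,
                "polarity": p,
                "center_az": fit.center_az,
                "center_el": fit.center_el,
                "sigma_major": fit.sigma_major,
                "sigma_minor": fit.sigma_minor,
                "rotation_rad": fit.rotation_rad,
                "amplitude": fit.amplitude,
                "aspect_ratio": fit.aspect_ratio,
                "d_br": fit.d_br,
                "d_tl": fit.d_tl,
                "centroid_dist_br": fit.centroid_dist_br,
                "centroid_dist_tl": fit.centroid_dist_tl,
                "success": fit.success,
            }
        )
    return pd.DataFrame(rows)


def compare_rf_between_blocks(fit_a, fit_b, location="BR"):
    """Signed between-block differences of RF geometry for one neuron.

    Returns (delta centroid distance to the location, delta aspect ratio),
    block A minus block B, plus whether the RF overlaps the location's disk
    in block A (D <= 0).
    """
    if not (fit_a.success and fit_b.success):
        raise ValueError("both block fits must have converged")
    if location == "BR":
        da, db = fit_a.centroid_dist_br, fit_b.centroid_dist_br
        near = fit_a.d_br <= 0
    else:
        da, db = fit_a.centroid_dist_tl, fit_b.centroid_dist_tl
        near = fit_a.d_tl <= 0
    return {
        "delta_centroid_dist": da - db,
        "delta_aspect": fit_a.aspect_ratio - fit_b.aspect_ratio,
        "near": bool(near),
    }
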