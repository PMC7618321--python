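"""Raw-stream conditioning: baseline F0, dF/F0, running speed, pupil, validity.

Converts the raw fluorescence matrix and raw behavioural streams of a session
into the analysis-ready quantities every downstream module consumes:

* per-neuron baseline F0 estimated as the mode of a diffusion-KDE density
  within overlapping chunks of frames, spline-interpolated over the session;
* dF/F0 = (F - F0) / F0;
* running speed smoothed with a 500 ms Savitzky-Golay filter;
* pupil ellipse parameters from binary masks;
* frame-validity masks (eye closure, excessive pupil deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter
from skimage.measure import EllipseModel, find_contours

from attnrun.kde import kde_mode

EYE_CLOSURE_SD = 5.5
PUPIL_DEV_LIMIT_DEG = 10.0


@dataclass
class BaselineEstimate:
    """Chunked-mode baseline for one fluorescence trace."""

    chunk_centers: np.ndarray  # frame indices of chunk centres
    chunk_modes: np.ndarray  # KDE-mode F0 per chunk
    f0: np.ndarray  # interpolated F0 trace, same length as F


def estimate_f0(f_trace, chunk_len=2000, step=500, n_grid=2**12):
    """Baseline F0 of a single fluorescence trace.

    Chunks of ``chunk_len`` frames are taken every ``step`` frames; within
    each chunk the mode of the diffusion-KDE density of the fluorescence
    values is the chunk's F0.  The F0 trace is a cubic spline through the
    chunk modes (at chunk centres) with constant extrapolation beyond the
    first and last centres.
    """
    f = np.asarray(f_trace, dtype=float)
    n = f.size
    if n < chunk_len:
        raise ValueError(f"trace length {n} < chunk length {chunk_len}")
    starts = np.arange(0, n - chunk_len + 1, step)
    if starts[-1] + chunk_len < n:  # cover the tail
        starts = np.append(starts, n - chunk_len)
    centers = starts + chunk_len / 2.0
    modes = np.array([kde_mode(f[s : s + chunk_len], n_grid=n_grid) for s in starts])

    if len(starts) == 1:
        f0 = np.full(n, modes[0])
    else:
        spline = CubicSpline(centers, modes)
        t = np.clip(np.arange(n, dtype=float), centers[0], centers[-1])
        f0 = spline(t)
    return BaselineEstimate(chunk_centers=centers, chunk_modes=modes, f0=f0)


def estimate_f0_matrix(F, chunk_len=2000, step=500, n_grid=2**12):
    """F0 for each row of a neurons x frames matrix."""
    F = np.asarray(F, dtype=float)
    if F.shape[0] == 0:
        return np.empty_like(F)
    return np.vstack([estimate_f0(row, chunk_len, step, n_grid).f0 for row in F])


def compute_dff(F, F0):
    """dF/F0 = (F - F0) / F0 elementwise; requires F0 > 0 everywhere."""
    F = np.asarray(F, dtype=float)
    F0 = np.asarray(F0, dtype=float)
    if F.shape != F0.shape:
        raise ValueError("F and F0 shapes differ")
    if np.any(F0 <= 0):
        raise ValueError("F0 must be positive everywhere")
    return (F - F0) / F0


def filter_running_speed(raw_speed, frame_rate, window_s=0.5, polyorder=3):
    """Savitzky-Golay smoothed running speed.

    The window is the nearest odd number of frames spanning ``window_s``
    seconds at ``frame_rate``.
    """
    speed = np.asarray(raw_speed, dtype=float)
    w = int(round(window_s * frame_rate))
    if w % 2 == 0:
        w += 1
    w = max(w, polyorder + 2)
    if w % 2 == 0:
        w += 1
    if speed.size < w:
        raise ValueError(f"trace length {speed.size} shorter than filter window {w}")
    return savgol_filter(speed, window_length=w, polyorder=polyorder)


def fit_pupil_ellipse(binary_mask):
    """Least-squares ellipse fit to the boundary of a binary pupil mask.

    Returns ``(center, axes, angle, area)`` where ``axes`` are the semi-axes
    (major, minor), ``angle`` is the major-axis rotation in radians and
    ``area = pi * a * b``.  Coordinates are (x, y) = (column, row).
    """
    mask = np.asarray(binary_mask).astype(bool)
    if not mask.any():
        raise ValueError("empty pupil mask")
    contours = find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary found in mask")
    boundary = max(contours, key=len)  # (row, col) points
    if len(boundary) < 5:
        raise ValueError("fewer than 5 boundary points")
    pts = boundary[:, ::-1]  # to (x, y)
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if b > a:
        a, b = b, a
        theta += np.pi / 2
    theta = (theta + np.pi / 2) % np.pi - np.pi / 2
    return (float(xc), float(yc)), (float(a), float(b)), float(theta), float(np.pi * a * b)


@dataclass
class FrameValidity:
    """Per-frame usability flags with reason codes.

    ``valid`` excludes eye-closure frames; ``valid_rf`` additionally excludes
    frames whose pupil deviation exceeds 10 degrees in either axis (used by
    receptive-field analyses).
    """

    valid: np.ndarray
    valid_rf: np.ndarray
    reason: np.ndarray  # '', 'eye_closure', or 'pupil_deviation'


def build_frame_validity(eye_corr, pupil_az_dev, pupil_el_dev,
                         closure_sd=EYE_CLOSURE_SD, dev_limit=PUPIL_DEV_LIMIT_DEG):
    """Frame validity from eye-image correlation and pupil deviation.

    A frame is an eye-closure frame if its 2-D correlation with the average
    eye image falls below the median by more than ``closure_sd`` standard
    deviations; it is additionally invalid for RF analyses if the pupil
    deviates by more than ``dev_limit`` degrees in azimuth or elevation.
    """
    corr = np.asarray(eye_corr, dtype=float)
    az = np.asarray(pupil_az_dev, dtype=float)
    el = np.asarray(pupil_el_dev, dtype=float)
    sd = corr.std()
    closure = corr < (np.median(corr) - closure_sd * sd) if sd > 0 else np.zeros(corr.shape, bool)
    deviation = (np.abs(az) > dev_limit) | (np.abs(el) > dev_limit)
    reason = np.full(corr.shape, "", dtype=object)
    reason[deviation] = "pupil_deviation"
    reason[closure] = "eye_closure"  # closure dominates
    return FrameValidity(valid=~closure, valid_rf=~(closure | deviation), reason=reason)
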