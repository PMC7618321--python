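"""Locally sparse noise stimulus generation.

Each 0.3 s pattern frame shows several 5-degree black or white squares on
the 14 x 22 grid, pairwise separated by at least 25 degrees centre to
centre; the same grid location is never reused within 3 s.  The number of
simultaneous squares per frame is 6 + Binomial(4, (mean-6)/4), giving the
requested mean (7.7 by default) with support {6..10}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from attnrun import grid


@dataclass
class StimulusFrameSet:
    """Timed sparse-noise events on the visual-field grid.

    ``events`` has one row per square: onset_s, row, col, azimuth_deg,
    elevation_deg, polarity ('white' or 'black').
    """

    events: pd.DataFrame
    frame_interval: float = grid.FRAME_INTERVAL_S
    duration_s: float = 0.0
    deg_per_square: float = grid.DEG_PER_SQUARE
    shortfall_frames: int = field(default=0, repr=False)

    @property
    def n_frames(self):
        return int(np.round(self.duration_s / self.frame_interval))

    def counts_per_frame(self):
        """Number of simultaneous squares in each pattern frame."""
        idx = np.round(self.events["onset_s"].to_numpy() / self.frame_interval).astype(int)
        return np.bincount(idx, minlength=self.n_frames)


def _max_packing(centers, min_sep):
    """Greedy raster-order packing size: capacity estimate for feasibility."""
    accepted = []
    for c in centers:
        if all(np.hypot(c[0] - a[0], c[1] - a[1]) >= min_sep for a in accepted):
            accepted.append(c)
    return len(accepted)


def generate_sparse_noise(
    duration_s,
    mean_simultaneous=7.7,
    min_sep_deg=25.0,
    refractory_s=3.0,
    seed=0,
    max_restarts=40,
):
    """Generate a :class:`StimulusFrameSet` for ``duration_s`` seconds.

    Placement is greedy rejection sampling per frame: candidate cells (those
    off refractory) are visited in random order and accepted when at least
    ``min_sep_deg`` from every square already accepted in the frame, with
    restarts until the frame's target count is met.  Raises ``ValueError``
    if the requested count cannot be packed on the grid at all.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if not (6.0 <= mean_simultaneous <= 10.0):
        raise ValueError("mean_simultaneous must lie in [6, 10]")
    centers = grid.all_cell_centers()
    capacity = _max_packing(centers, min_sep_deg)
    if capacity < 10:
        raise ValueError(
            f"infeasible packing: at most {capacity} squares fit with "
            f"min separation {min_sep_deg} deg, but counts up to 10 are drawn"
        )

    rng = np.random.default_rng(seed)
    n_cells = centers.shape[0]
    n_frames = int(np.round(duration_s / grid.FRAME_INTERVAL_S))
    refractory_frames = int(np.ceil(refractory_s / grid.FRAME_INTERVAL_S))
    last_used = np.full(n_cells, -10**9)  # frame index of last onset per cell
    p_extra = (mean_simultaneous - 6.0) / 4.0

    rows_out, cols_out, onsets_out = [], [], []
    shortfall = 0
    for k in range(n_frames):
        target = 6 + rng.binomial(4, p_extra)
        available = np.flatnonzero(k - last_used >= refractory_frames)
        best = []
        for _ in range(max_restarts):
            order = rng.permutation(available)
            accepted = []
            pts = []
            for ci in order:
                c = centers[ci]
                if pts:
                    arr = np.asarray(pts)
                    if np.min(np.hypot(arr[:, 0] - c[0], arr[:, 1] - c[1])) < min_sep_deg:
                        continue
                accepted.append(ci)
                pts.append(c)
                if len(accepted) >= target:
                    break
            if len(accepted) > len(best):
                best = accepted
            if len(best) >= target:
                break
        if len(best) < target:
            shortfall += 1
        for ci in best:
            last_used[ci] = k
            rows_out.append(ci // grid.N_COLS)
            cols_out.append(ci % grid.N_COLS)
            onsets_out.append(k * grid.FRAME_INTERVAL_S)

    rows = np.asarray(rows_out)
    cols = np.asarray(cols_out)
    az, el = grid.cell_center(rows, cols)
    polarity = rng.choice(["black", "white"], size=len(rows))
    events = pd.DataFrame(
        {
            "onset_s": np.asarray(onsets_out),
            "row": rows,
            "col": cols,
            "azimuth_deg": az,
            "elevation_deg": el,
            "polarity": polarity,
        }
    )
    return StimulusFrameSet(events=events, duration_s=duration_s, shortfall_frames=shortfall)
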