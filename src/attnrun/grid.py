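"""Stimulus-grid geometry and task-location constants.

The sparse-noise display is a 14 (elevation) x 22 (azimuth) grid of 5 deg
squares on a grey background.  Azimuth increases leftward from the midline,
elevation increases upward.  The two task locations are circular grating
patches of 30 deg diameter centred at BR (azimuth 36, elevation -18) and
TL (azimuth 93, elevation 18).
"""

from __future__ import annotations

import numpy as np

N_ROWS = 14  # elevation
N_COLS = 22  # azimuth
DEG_PER_SQUARE = 5.0
FRAME_INTERVAL_S = 0.3  # sparse-noise pattern refresh

# grid cell centres (degrees); rows from bottom to top
AZIMUTH_ORIGIN = 2.5
ELEVATION_ORIGIN = -32.5

BR_LOCATION = (36.0, -18.0)  # (azimuth, elevation)
TL_LOCATION = (93.0, 18.0)
TASK_DISK_RADIUS = 15.0  # grating patches are 30 deg diameter

IMAGING_RATE_HZ = 12.85


def cell_center(row, col):
    """Visual-field centre (azimuth, elevation) of grid cell (row, col)."""
    az = AZIMUTH_ORIGIN + DEG_PER_SQUARE * np.asarray(col)
    el = ELEVATION_ORIGIN + DEG_PER_SQUARE * np.asarray(row)
    return az, el


def all_cell_centers():
    """(N_ROWS*N_COLS, 2) array of (azimuth, elevation) centres, row-major."""
    rows, cols = np.mgrid[0:N_ROWS, 0:N_COLS]
    az, el = cell_center(rows.ravel(), cols.ravel())
    return np.column_stack([az, el])


def nearest_cell(azimuth, elevation):
    """Snap visual-field coordinates to the nearest grid cell (row, col)."""
    col = np.clip(np.round((np.asarray(azimuth) - AZIMUTH_ORIGIN) / DEG_PER_SQUARE), 0, N_COLS - 1)
    row = np.clip(
        np.round((np.asarray(elevation) - ELEVATION_ORIGIN) / DEG_PER_SQUARE), 0, N_ROWS - 1
    )
    return row.astype(int), col.astype(int)


def task_location(block_type):
    """Centre of the go/no-go patch for a block type ('BR' or 'TL')."""
    if block_type == "BR":
        return BR_LOCATION
    if block_type == "TL":
        return TL_LOCATION
    raise ValueError(f"unknown block type {block_type!r}")
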