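"""Plate and camera-block geometry shared across modules.

A 96-well plate (8 rows A-H x 12 columns 1-12) is imaged by six cameras
tiled 2 rows x 3 columns, each seeing a 4x4 block of wells.  Camera ids
run 1..6 row-major over the camera tiling, so camera 1 sees A1-D4,
camera 2 sees A5-D8, ..., camera 6 sees E9-H12.

Raster convention used throughout the package: 0-based pixel indices,
origin top-left, y down; well boxes are half-open intervals
``[min, max)`` in both axes.
"""

from __future__ import annotations

import string

PLATE_ROWS = 8
PLATE_COLS = 12
CAMERA_GRID = (2, 3)  # cameras tiled rows x cols over the plate
ROW_LETTERS = string.ascii_uppercase[:PLATE_ROWS]


def well_name(plate_row: int, plate_col: int) -> str:
    """0-based plate (row, col) -> name like 'A1'."""
    if not (0 <= plate_row < PLATE_ROWS and 0 <= plate_col < PLATE_COLS):
        raise ValueError(f"({plate_row}, {plate_col}) outside an 8x12 plate")
    return f"{ROW_LETTERS[plate_row]}{plate_col + 1}"


def camera_block(camera_id: int, grid_rows: int = 4, grid_cols: int = 4) -> list[str]:
    """Row-major well names of the block seen by one camera.

    ``camera_id`` is 1-based, counting row-major over the camera tiling.
    """
    n_cams = CAMERA_GRID[0] * CAMERA_GRID[1]
    if not 1 <= camera_id <= n_cams:
        raise ValueError(f"camera_id must be in 1..{n_cams}")
    cam_r, cam_c = divmod(camera_id - 1, CAMERA_GRID[1])
    names = []
    for r in range(grid_rows):
        for c in range(grid_cols):
            names.append(well_name(cam_r * grid_rows + r, cam_c * grid_cols + c))
    return names


def expand_well_range(text: str, plate_rows: int = PLATE_ROWS,
                      plate_cols: int = PLATE_COLS) -> list[str]:
    """Expand a well-range string into individual well names.

    Accepts inclusive rectangular ranges (``"A1-B12"``, en dash or hyphen)
    and comma-separated lists mixing single wells and ranges.
    """
    wells: list[str] = []
    for token in text.replace("–", "-").split(","):
        token = token.strip()
        if not token:
            continue
        if "-" in token:
            a, b = (t.strip() for t in token.split("-", 1))
            r0, c0 = _parse_well(a)
            r1, c1 = _parse_well(b)
            if r1 < r0 or c1 < c0:
                raise ValueError(f"inverted well range {token!r}")
            for r in range(r0, r1 + 1):
                for c in range(c0, c1 + 1):
                    if r >= plate_rows or c >= plate_cols:
                        raise ValueError(f"range {token!r} exceeds plate")
                    wells.append(well_name(r, c))
        else:
            r, c = _parse_well(token)
            wells.append(well_name(r, c))
    return wells


def _parse_well(name: str) -> tuple[int, int]:
    name = name.strip().upper()
    if len(name) < 2 or name[0] not in ROW_LETTERS or not name[1:].isdigit():
        raise ValueError(f"bad well name {name!r}")
    col = int(name[1:]) - 1
    if not 0 <= col < PLATE_COLS:
        raise ValueError(f"bad well column in {name!r}")
    return ROW_LETTERS.index(name[0]), col
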