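"""Well-lattice detection by tiled-template fitting.

A single camera sees a regular grid of square wells: bright agar squares
framed by darker well-wall shadow bands.  The detector builds a two-level
template (bright inner square on a dark wall band), replicates it on a
lattice parameterised by ``(row_offset, col_offset, row_pitch, col_pitch)``,
and chooses the parameters that minimise the mean absolute intensity
difference between the (min-max normalised) frame and the simulated grid,
using SciPy's differential-evolution optimiser with a fixed seed.  Grid
dimensions (rows x cols of wells) come from configuration, not from the fit.

The objective is evaluated through an integral-image identity: with a
two-level template the pixelwise mean absolute difference reduces to a sum
of box sums over the well interiors, which prefix sums give in O(wells)
per evaluation.  Box edges are rounded to whole pixels, so the fit is
pixel-quantised (adequate here: well boxes are >100 px wide).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import differential_evolution

from .geometry import camera_block

#: Inner well width as a fraction of the lattice pitch (8 mm well on a 9 mm
#: pitch for a square-well 96-well plate, ~0.89; the simulator's default
#: 130/160 = 0.8125 accounts for the shadow band eating into the opening).
DEFAULT_WELL_FRAC = 0.8125


@dataclass(frozen=True)
class WellBox:
    name: str
    x_min: float
    y_min: float
    x_max: float
    y_max: float
    bad_flag: bool = False
    bad_reason: str = ""

    def contains(self, x: float, y: float) -> bool:
        """Half-open membership: walls and the far edges are outside."""
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class WellGrid:
    """Fitted lattice of named well boundaries for one field of view."""

    row_offset: float
    col_offset: float
    row_pitch: float
    col_pitch: float
    grid_rows: int
    grid_cols: int
    wells: tuple[WellBox, ...]
    fit_residual: float = 0.0
    low_confidence: bool = False
    camera_id: int = 1

    def __post_init__(self):
        if len(self.wells) != self.grid_rows * self.grid_cols:
            raise ValueError("wells count must equal grid_rows * grid_cols")
        names = [w.name for w in self.wells]
        if len(set(names)) != len(names):
            raise ValueError("well names must be unique")

    def well(self, name: str) -> WellBox:
        for w in self.wells:
            if w.name == name:
                return w
        raise KeyError(f"no well named {name!r}")

    @property
    def names(self) -> list[str]:
        return [w.name for w in self.wells]

    def to_json(self, path: str | Path | None = None) -> str:
        d = dataclasses.asdict(self)
        d["wells"] = [dataclasses.asdict(w) for w in self.wells]
        s = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @classmethod
    def from_json(cls, source: str | Path) -> "WellGrid":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        d["wells"] = tuple(WellBox(**w) for w in d["wells"])
        return cls(**d)


def build_template(well_size: int, wall_dark_frac: float, pitch: int | None = None) -> np.ndarray:
    """Two-level well template: bright inner square on a darker wall band.

    Values are in [0, 1]; the bright interior is 1.0 and the wall band
    ``1 - wall_dark_frac``.  ``pitch`` defaults to ``well_size / 0.8125``.
    """
    if well_size < 8:
        raise ValueError("well_size must be >= 8 px")
    if not 0.0 <= wall_dark_frac <= 1.0:
        raise ValueError("wall_dark_frac must be in [0, 1]")
    if pitch is None:
        pitch = int(round(well_size / DEFAULT_WELL_FRAC))
    if pitch < well_size:
        raise ValueError("pitch must be >= well_size")
    tpl = np.full((pitch, pitch), 1.0 - wall_dark_frac, dtype=float)
    m = (pitch - well_size) // 2
    tpl[m:m + well_size, m:m + well_size] = 1.0
    return tpl


def render_grid(shape: tuple[int, int], row_offset: float, col_offset: float,
                row_pitch: float, col_pitch: float, grid_rows: int, grid_cols: int,
                well_frac: float = DEFAULT_WELL_FRAC,
                wall_dark_frac: float = 0.5) -> np.ndarray:
    """Tile the well template over a lattice; direct pixelwise rendering."""
    img = np.full(shape, 1.0 - wall_dark_frac, dtype=float)
    for y0, y1, x0, x1 in _well_boxes_px(shape, row_offset, col_offset, row_pitch,
                                         col_pitch, grid_rows, grid_cols, well_frac):
        img[y0:y1, x0:x1] = 1.0
    return img


def _well_boxes_px(shape, row_offset, col_offset, row_pitch, col_pitch,
                   grid_rows, grid_cols, well_frac):
    h, w = shape
    well_h = well_frac * row_pitch
    well_w = well_frac * col_pitch
    boxes = []
    for r in range(grid_rows):
        y0 = int(round(row_offset + r * row_pitch + (row_pitch - well_h) / 2.0))
        y1 = int(round(y0 + well_h))
        for c in range(grid_cols):
            x0 = int(round(col_offset + c * col_pitch + (col_pitch - well_w) / 2.0))
            x1 = int(round(x0 + well_w))
            boxes.append((max(y0, 0), min(y1, h), max(x0, 0), min(x1, w)))
    return boxes


def normalize_minmax(image: np.ndarray) -> np.ndarray:
    """Min-max normalise to [0, 1]; a constant image maps to all zeros."""
    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros_like(img)
    return (img - lo) / (hi - lo)


def grid_objective(image_norm: np.ndarray, params, grid_rows: int, grid_cols: int,
                   well_frac: float = DEFAULT_WELL_FRAC,
                   wall_dark_frac: float = 0.5) -> float:
    """Direct mean-absolute-difference objective (reference implementation).

    Both the frame and the tiled template are min-max normalised before
    differencing, so the comparison is robust to illumination gain and to
    the absolute wall darkness.
    """
    tpl = normalize_minmax(render_grid(image_norm.shape, *params, grid_rows,
                                       grid_cols, well_frac, wall_dark_frac))
    return float(np.mean(np.abs(image_norm - tpl)))


class _FastObjective:
    """Integral-image evaluation of :func:`grid_objective`.

    With a two-level template T (dark everywhere, bright inside well boxes),
    ``mean|I - T| = (sum|I - dark| + sum_boxes(|I - bright| - |I - dark|)) / N``,
    and the per-box sums come from a 2D prefix sum.
    """

    def __init__(self, image_norm, grid_rows, grid_cols, well_frac, wall_dark_frac):
        # after min-max normalising the two-level template, walls sit at 0
        # and well interiors at 1 (a zero-contrast template is all zeros)
        dark = 0.0 if wall_dark_frac > 0 else None
        if dark is None:  # degenerate template: identically zero
            d = np.abs(image_norm)
            s = np.zeros_like(image_norm)
        else:
            d = np.abs(image_norm - dark)
            s = np.abs(image_norm - 1.0) - d
        self.sum_d = float(d.sum())
        self.n = image_norm.size
        self.shape = image_norm.shape
        self.prefix = np.zeros((self.shape[0] + 1, self.shape[1] + 1))
        np.cumsum(np.cumsum(s, axis=0), axis=1, out=self.prefix[1:, 1:])
        self.grid_rows, self.grid_cols = grid_rows, grid_cols
        self.well_frac = well_frac

    def __call__(self, params) -> float:
        total = self.sum_d
        p = self.prefix
        for y0, y1, x0, x1 in _well_boxes_px(self.shape, *params, self.grid_rows,
                                             self.grid_cols, self.well_frac):
            if y1 > y0 and x1 > x0:
                total += p[y1, x1] - p[y0, x1] - p[y1, x0] + p[y0, x0]
        return total / self.n


def default_bounds(shape: tuple[int, int], grid_rows: int, grid_cols: int):
    """Search bounds for (row_offset, col_offset, row_pitch, col_pitch)."""
    h, w = shape
    pr_hi, pc_hi = h / grid_rows, w / grid_cols
    pr_lo, pc_lo = 0.7 * pr_hi, 0.7 * pc_hi
    return [
        (0.0, max(h - grid_rows * pr_lo, 1.0)),
        (0.0, max(w - grid_cols * pc_lo, 1.0)),
        (pr_lo, pr_hi),
        (pc_lo, pc_hi),
    ]


def fit_lattice(image: np.ndarray, grid_rows: int = 4, grid_cols: int = 4,
                bounds=None, seed: int = 0, well_frac: float = DEFAULT_WELL_FRAC,
                wall_dark_frac: float = 0.5, residual_ceiling: float = 0.25,
                camera_id: int = 1, maxiter: int = 150, popsize: int = 24) -> WellGrid:
    """Fit the well lattice to a frame (or static background).

    Returns a :class:`WellGrid` with wells enumerated row-major and named
    after the camera's 4x4 block of the 96-well plate.  If the optimised
    residual exceeds ``residual_ceiling`` the grid is returned with
    ``low_confidence=True`` rather than raising.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2D grayscale")
    if bounds is None:
        bounds = default_bounds(image.shape, grid_rows, grid_cols)
    min_pr, min_pc = bounds[2][0], bounds[3][0]
    if image.shape[0] < grid_rows * min_pr or image.shape[1] < grid_cols * min_pc:
        raise ValueError("image too small to contain the grid at minimum pitch")

    norm = normalize_minmax(image)
    objective = _FastObjective(norm, grid_rows, grid_cols, well_frac, wall_dark_frac)
    result = differential_evolution(
        objective, bounds, seed=seed, maxiter=maxiter, popsize=popsize,
        tol=1e-8, polish=False, init="sobol",
    )
    params = np.asarray(result.x, dtype=float)

    # local +-2 px integer sweep: the objective is pixel-quantised, so this
    # guarantees a local optimum on the pixel lattice
    best_val, best_params = result.fun, params
    deltas = (-2.0, -1.0, 0.0, 1.0, 2.0)
    for d in itertools.product(deltas, repeat=4):
        cand = params + np.array(d)
        if all(lo <= v <= hi for v, (lo, hi) in zip(cand, bounds)):
            v = objective(cand)
            if v < best_val:
                best_val, best_params = v, cand
    row_off, col_off, row_pitch, col_pitch = best_params

    names = camera_block(camera_id, grid_rows, grid_cols)
    wells = []
    well_h, well_w = well_frac * row_pitch, well_frac * col_pitch
    for i, (r, c) in enumerate((r, c) for r in range(grid_rows) for c in range(grid_cols)):
        y0 = row_off + r * row_pitch + (row_pitch - well_h) / 2.0
        x0 = col_off + c * col_pitch + (col_pitch - well_w) / 2.0
        wells.append(WellBox(names[i], x0, y0, x0 + well_w, y0 + well_h))
    return WellGrid(
        row_offset=float(row_off), col_offset=float(col_off),
        row_pitch=float(row_pitch), col_pitch=float(col_pitch),
        grid_rows=grid_rows, grid_cols=grid_cols, wells=tuple(wells),
        fit_residual=float(best_val),
        low_confidence=bool(best_val > residual_ceiling),
        camera_id=camera_id,
    )


def locate_point(grid: WellGrid, x: float, y: float) -> str | None:
    """Name of the well whose half-open box contains (x, y); None on walls/outside."""
    for w in grid.wells:
        if w.contains(x, y):
            return w.name
    return None


def mark_bad_well(grid: WellGrid, name: str, reason: str = "") -> WellGrid:
    """Return a grid with ``name`` flagged bad (idempotent); unknown name raises."""
    if name not in grid.names:
        raise KeyError(f"no well named {name!r}")
    wells = tuple(
        dataclasses.replace(w, bad_flag=True, bad_reason=reason or w.bad_reason)
        if w.name == name else w
        for w in grid.wells
    )
    return dataclasses.replace(grid, wells=wells)


def static_background(frames: np.ndarray, max_frames: int = 100) -> np.ndarray:
    """Median over <= ``max_frames`` evenly spaced frames (removes moving worms)."""
    frames = np.asarray(frames)
    idx = np.linspace(0, len(frames) - 1, min(max_frames, len(frames))).astype(int)
    return np.median(frames[idx], axis=0).astype(frames.dtype)
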