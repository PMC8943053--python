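"""Synthetic plate videos, ROI datasets, feature tables and metadata fixtures.

Everything the analysis modules consume can be generated here with known
ground truth: brightfield-like frames of a square-well plate block seen by
one camera (bright agar squares, dark wall-shadow bands), worm-shaped
moving objects whose motion follows a three-state (forward / backward /
stationary) Markov chain modulated by blue-light pulses, non-worm debris,
labelled 80x80 masked ROI images, strain-structured feature matrices with
missingness, and a mutually consistent set of experiment-record CSVs.

All generators are deterministic functions of their seed: the same seed
yields byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import camera_block
from .io import FrameStore
from .schedule import StimulusSchedule, build_schedule
from .wells import WellBox, WellGrid

MODES = ("fw", "bw", "st")
FW, BW, ST = 0, 1, 2

#: default frame-resolution transition matrix (rows/cols ordered fw, bw, st);
#: sticky states at 25 fps give worm-like bout durations (forward runs ~4 s,
#: reversals ~1.6 s, pauses ~5 s)
DEFAULT_TRANSITIONS = np.array([
    [0.990, 0.002, 0.008],
    [0.020, 0.975, 0.005],
    [0.006, 0.002, 0.992],
])


@dataclass
class PlateConfig:
    """Geometry and rendering of the 4x4 well block seen by one camera."""

    grid_rows: int = 4
    grid_cols: int = 4
    well_pitch: float = 160.0  # px, centre-to-centre
    well_size: float = 130.0  # px, inner bright square
    wall_dark_frac: float = 0.5  # darkening of the wall/shadow band
    image_size: tuple[int, int] = (672, 672)  # (H, W) px
    px_per_mm: float = 80.6  # 12.4 um/px
    row_offset: float | None = None  # top of first pitch cell; None = centred
    col_offset: float | None = None
    bg_level: int = 200  # agar grey level
    worm_level: int = 60  # worm body grey level
    noise_sigma: float = 2.0  # additive gaussian sensor noise, grey levels
    n_debris_per_well: int = 0
    camera_id: int = 1

    def __post_init__(self):
        h, w = self.image_size
        if self.grid_rows * self.well_pitch > h or self.grid_cols * self.well_pitch > w:
            raise ValueError("grid does not fit in image at this pitch")
        if not self.well_size < self.well_pitch:
            raise ValueError("well_size must be < well_pitch")
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be > 0")
        if not 0.0 <= self.wall_dark_frac <= 1.0:
            raise ValueError("wall_dark_frac must be in [0, 1]")
        if self.row_offset is None:
            self.row_offset = (h - self.grid_rows * self.well_pitch) / 2.0
        if self.col_offset is None:
            self.col_offset = (w - self.grid_cols * self.well_pitch) / 2.0

    @property
    def well_frac(self) -> float:
        return self.well_size / self.well_pitch

    def truth_grid(self) -> WellGrid:
        """The exact well lattice used for rendering, as a WellGrid."""
        names = camera_block(self.camera_id, self.grid_rows, self.grid_cols)
        wells, i = [], 0
        for r in range(self.grid_rows):
            for c in range(self.grid_cols):
                y0 = self.row_offset + r * self.well_pitch + (self.well_pitch - self.well_size) / 2.0
                x0 = self.col_offset + c * self.well_pitch + (self.well_pitch - self.well_size) / 2.0
                wells.append(WellBox(names[i], x0, y0, x0 + self.well_size, y0 + self.well_size))
                i += 1
        return WellGrid(
            row_offset=self.row_offset, col_offset=self.col_offset,
            row_pitch=self.well_pitch, col_pitch=self.well_pitch,
            grid_rows=self.grid_rows, grid_cols=self.grid_cols,
            wells=tuple(wells), camera_id=self.camera_id,
        )


@dataclass
class WormKinematics:
    """Worm shape and three-state motion model at frame resolution.

    The light effect multiplies the transition probabilities into the
    forward state by ``light_bias`` during light-on intervals, then
    renormalises each row.
    """

    n_worms_per_well: int = 3
    body_length: float = 80.0  # px (~1 mm adult at 12.4 um/px)
    worm_width: float = 7.0  # px
    undulation_amplitude: float = 6.0  # px
    undulation_wavelength: float = 40.0  # px
    mode_transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    light_bias: float = 1.0
    speed_fw: float = 24.0  # px/s
    speed_bw: float = 16.0  # px/s
    heading_diffusion: float = 0.5  # rad / sqrt(s)
    wall_turn_rate: float = 8.0  # rad/s steering away from well walls
    frame_rate: float = 25.0

    def __post_init__(self):
        P = np.asarray(self.mode_transition_matrix, dtype=float)
        if P.shape != (3, 3) or np.any(P < 0):
            raise ValueError("mode_transition_matrix must be 3x3 nonnegative")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must sum to 1")
        if self.speed_fw < 0 or self.speed_bw < 0:
            raise ValueError("speeds must be >= 0")
        if self.light_bias < 0:
            raise ValueError("light_bias must be >= 0")
        self.mode_transition_matrix = P

    def biased_matrix(self) -> np.ndarray:
        """Transition matrix during light-on (bias into fw, rows renormalised)."""
        P = self.mode_transition_matrix.copy()
        P[:, FW] *= self.light_bias
        return P / P.sum(axis=1, keepdims=True)

    def stationary_distribution(self, biased: bool = False) -> np.ndarray:
        """Stationary distribution of the (optionally biased) chain."""
        P = self.biased_matrix() if biased else self.mode_transition_matrix
        vals, vecs = np.linalg.eig(P.T)
        v = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
        return v / v.sum()


@dataclass
class GroundTruth:
    """Per-object truth for one simulated session."""

    grid: WellGrid
    worms: pd.DataFrame  # worm_id, well, frame, x, y, mode
    midlines: np.ndarray  # (n_worms, n_frames, n_pts, 2) float32, (x, y), head first
    worm_wells: dict[int, str]
    debris: pd.DataFrame  # object_id, well, x, y, kind
    modes: np.ndarray  # (n_worms, n_frames) int codes
    light_on: np.ndarray  # (n_frames,) bool


def _disk_offsets(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    dy, dx = np.mgrid[-r:r + 1, -r:r + 1]
    keep = dy * dy + dx * dx <= radius * radius
    return np.stack([dy[keep], dx[keep]], axis=1)


def _stamp_points(frame: np.ndarray, pts_xy: np.ndarray, offsets: np.ndarray, value: int):
    """Paint disks of ``offsets`` footprint at each (x, y) point."""
    pts = np.round(pts_xy).astype(int)
    yy = pts[:, 1][:, None] + offsets[None, :, 0]
    xx = pts[:, 0][:, None] + offsets[None, :, 1]
    h, w = frame.shape
    np.clip(yy, 0, h - 1, out=yy)
    np.clip(xx, 0, w - 1, out=xx)
    frame[yy.ravel(), xx.ravel()] = value


def _worm_midline(cx, cy, theta, phase, kin: WormKinematics, n_pts: int = 49) -> np.ndarray:
    """Sinusoidal midline, head first (head at the leading end of the axis)."""
    s = np.linspace(kin.body_length / 2.0, -kin.body_length / 2.0, n_pts)
    lateral = kin.undulation_amplitude * np.sin(
        2 * np.pi * s / kin.undulation_wavelength + phase)
    ux, uy = np.cos(theta), np.sin(theta)
    nx, ny = -uy, ux
    x = cx + ux * s + nx * lateral
    y = cy + uy * s + ny * lateral
    return np.stack([x, y], axis=1)


def _evolve_modes(kin: WormKinematics, light_on: np.ndarray, n_worms: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Markov mode sequences (n_worms, n_frames); bias applied on light-on frames."""
    n_frames = len(light_on)
    P_off = kin.mode_transition_matrix
    P_on = kin.biased_matrix()
    cum_off, cum_on = P_off.cumsum(axis=1), P_on.cumsum(axis=1)
    pi0 = kin.stationary_distribution()
    modes = np.empty((n_worms, n_frames), dtype=np.int8)
    modes[:, 0] = rng.choice(3, size=n_worms, p=pi0)
    u = rng.random((n_worms, n_frames))
    for t in range(1, n_frames):
        cum = cum_on if light_on[t] else cum_off
        rows = cum[modes[:, t - 1]]
        modes[:, t] = (u[:, t, None] > rows).sum(axis=1)
    return modes


def simulate_modes(kin: WormKinematics, n_wells: int, n_frames: int,
                   schedule: StimulusSchedule | None, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Mode sequences only (no rendering): (modes[n_wells*n_worms, T], light_on[T]).

    A lightweight path for motion-mode statistics at population scale.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / kin.frame_rate
    light_on = (np.array([schedule.is_on(ti) for ti in t], dtype=bool)
                if schedule is not None else np.zeros(n_frames, dtype=bool))
    modes = _evolve_modes(kin, light_on, n_wells * kin.n_worms_per_well, rng)
    return modes, light_on


def render_background(plate: PlateConfig) -> np.ndarray:
    """Noise-free plate background: bright wells, dark wall bands (uint8)."""
    h, w = plate.image_size
    wall = int(round(plate.bg_level * (1.0 - plate.wall_dark_frac)))
    img = np.full((h, w), wall, dtype=np.uint8)
    for box in plate.truth_grid().wells:
        img[int(round(box.y_min)):int(round(box.y_max)),
            int(round(box.x_min)):int(round(box.x_max))] = plate.bg_level
    return img


def _place_debris(plate: PlateConfig, rng: np.random.Generator):
    """Static non-worm objects: gaussian-ish blobs, straight scratches,
    well-corner crescents (the morphologies a worm classifier must reject)."""
    records, draw_ops = [], []
    kinds = ("blob", "scratch", "crescent")
    oid = 0
    for box in plate.truth_grid().wells:
        for k in range(plate.n_debris_per_well):
            kind = kinds[(oid + k) % 3]
            margin = 20
            x = rng.uniform(box.x_min + margin, box.x_max - margin)
            y = rng.uniform(box.y_min + margin, box.y_max - margin)
            if kind == "blob":
                r = rng.uniform(6.0, 9.0)
                pts = np.array([[x, y]])
                draw_ops.append((pts, _disk_offsets(r)))
            elif kind == "scratch":
                ang = rng.uniform(0, np.pi)
                length = rng.uniform(35, 60)
                s = np.linspace(-length / 2, length / 2, 40)
                pts = np.stack([x + s * np.cos(ang), y + s * np.sin(ang)], axis=1)
                draw_ops.append((pts, _disk_offsets(1.75)))
            else:  # crescent hugging the well corner
                cx, cy = box.x_min + 14, box.y_min + 14
                ang = np.linspace(0, np.pi / 2, 30)
                pts = np.stack([cx + 16 * np.cos(ang), cy + 16 * np.sin(ang)], axis=1)
                x, y = cx, cy
                draw_ops.append((pts, _disk_offsets(3.0)))
            records.append({"object_id": oid, "well": box.name, "x": float(pts[:, 0].mean()),
                            "y": float(pts[:, 1].mean()), "kind": kind})
            oid += 1
    return pd.DataFrame(records, columns=["object_id", "well", "x", "y", "kind"]), draw_ops


def simulate_session(plate: PlateConfig, worms: WormKinematics,
                     schedule: StimulusSchedule, seed: int,
                     n_midline_pts: int = 49) -> tuple[FrameStore, GroundTruth]:
    """Render a full session and return frames plus per-object ground truth.

    Worm centroids are confined to their well's inner square (reflective
    boundaries with a body-sized margin); per-frame motion modes evolve by
    the Markov chain, with the light bias applied during light-on frames.
    """
    if schedule.total_duration <= 0:
        raise ValueError("schedule duration must be > 0")
    if worms.body_length + 2 * (worms.undulation_amplitude + worms.worm_width) \
            >= plate.well_size:
        raise ValueError(
            f"worms of body_length {worms.body_length} px cannot fit a "
            f"{plate.well_size} px well")
    # confine the *centroid* well inside the inner square; the body may
    # overhang into the wall shadow, as real worms touch the walls
    margin = worms.body_length / 4.0 + worms.worm_width
    if 2 * margin >= plate.well_size:
        raise ValueError("well too small for the configured worm geometry")

    rng = np.random.default_rng(seed)
    grid = plate.truth_grid()
    n_frames = int(round(schedule.total_duration * worms.frame_rate))
    dt = 1.0 / worms.frame_rate
    t = np.arange(n_frames) * dt
    light_on = np.array([schedule.is_on(ti) for ti in t], dtype=bool)

    n_wells = plate.grid_rows * plate.grid_cols
    n_worms = n_wells * worms.n_worms_per_well
    worm_wells = {}
    cx = np.empty(n_worms)
    cy = np.empty(n_worms)
    lo_x = np.empty(n_worms)
    hi_x = np.empty(n_worms)
    lo_y = np.empty(n_worms)
    hi_y = np.empty(n_worms)
    wid = 0
    for box in grid.wells:
        for _ in range(worms.n_worms_per_well):
            worm_wells[wid] = box.name
            lo_x[wid], hi_x[wid] = box.x_min + margin, box.x_max - margin
            lo_y[wid], hi_y[wid] = box.y_min + margin, box.y_max - margin
            cx[wid] = rng.uniform(lo_x[wid], hi_x[wid])
            cy[wid] = rng.uniform(lo_y[wid], hi_y[wid])
            wid += 1
    theta = rng.uniform(0, 2 * np.pi, n_worms)
    phase = rng.uniform(0, 2 * np.pi, n_worms)

    modes = _evolve_modes(worms, light_on, n_worms, rng)
    turn_noise = rng.normal(0.0, worms.heading_diffusion * np.sqrt(dt), (n_worms, n_frames))

    background = render_background(plate)
    debris, debris_ops = _place_debris(plate, rng)
    for pts, offs in debris_ops:
        _stamp_points(background, pts, offs, plate.worm_level)

    worm_offs = _disk_offsets(worms.worm_width / 2.0)
    frames = np.empty((n_frames,) + plate.image_size, dtype=np.uint8)
    midlines = np.empty((n_worms, n_frames, n_midline_pts, 2), dtype=np.float32)
    noise = rng.normal(0.0, plate.noise_sigma, frames.shape) if plate.noise_sigma > 0 else None

    speed = np.zeros(3)
    speed[FW], speed[BW] = worms.speed_fw, -worms.speed_bw
    phase_rate = 2 * np.pi * worms.speed_fw / worms.undulation_wavelength

    rows = []
    for f in range(n_frames):
        moving = modes[:, f] != ST
        v = speed[modes[:, f]] * dt
        nx = cx + v * np.cos(theta)
        ny = cy + v * np.sin(theta)
        out = (nx < lo_x) | (nx > hi_x) | (ny < lo_y) | (ny > hi_y)
        if out.any():
            # steer smoothly towards the well centre (bodies turn, they do
            # not teleport); for backward motion the displacement, not the
            # heading, must point inward
            desired = np.arctan2((lo_y + hi_y) / 2 - cy, (lo_x + hi_x) / 2 - cx)
            desired = np.where(v >= 0, desired, desired + np.pi)
            delta = (desired - theta + np.pi) % (2 * np.pi) - np.pi
            max_turn = worms.wall_turn_rate * dt
            theta[out] += np.clip(delta, -max_turn, max_turn)[out]
            nx = cx + v * np.cos(theta)
            ny = cy + v * np.sin(theta)
        cx = np.clip(nx, lo_x, hi_x)
        cy = np.clip(ny, lo_y, hi_y)
        theta += np.where(moving, turn_noise[:, f], 0.0)
        phase -= np.where(moving, np.sign(v) * phase_rate * dt, 0.0)

        frame = background.copy()
        for w in range(n_worms):
            ml = _worm_midline(cx[w], cy[w], theta[w], phase[w], worms, n_midline_pts)
            midlines[w, f] = ml
            _stamp_points(frame, ml, worm_offs, plate.worm_level)
        if noise is not None:
            frame = np.clip(frame.astype(np.int16) + np.round(noise[f]).astype(np.int16),
                            0, 255).astype(np.uint8)
        frames[f] = frame
        rows.append(pd.DataFrame({
            "worm_id": np.arange(n_worms), "frame": f,
            "x": cx.copy(), "y": cy.copy(),
            "mode": [MODES[m] for m in modes[:, f]],
        }))

    worms_df = pd.concat(rows, ignore_index=True)
    worms_df["well"] = worms_df["worm_id"].map(worm_wells)
    index = pd.DataFrame({"frame_number": np.arange(n_frames), "timestamp_s": t})
    store = FrameStore(frames=frames, index=index, frame_rate=worms.frame_rate,
                       px_per_mm=plate.px_per_mm, camera_id=plate.camera_id,
                       schedule=schedule)
    truth = GroundTruth(grid=grid, worms=worms_df, midlines=midlines,
                        worm_wells=worm_wells, debris=debris, modes=modes,
                        light_on=light_on)
    return store, truth


# ---------------------------------------------------------------------------
# ROI dataset


def make_roi_dataset(n_per_class: int, seed: int, size: int = 80,
                     bg_level: int = 200, worm_level: int = 60,
                     wall_level: int = 100, halo: int = 5,
                     noise_sigma: float = 2.0) -> tuple[np.ndarray, np.ndarray]:
    """Labelled masked ROI images: (images (2n, size, size) uint8, labels (2n,)).

    Label 1 = worm (curved undulating filament), 0 = non-worm (gaussian
    blob, straight scratch, or corner crescent).  Pixels outside a halo
    around the object are set to exactly 0, mimicking the masking step of
    the tracker.  Images carry the same sensor noise as rendered sessions,
    and a fraction of objects sit next to a dark well-wall band, as they
    do in cropped tracking ROIs.  Classes are balanced and the label
    vector is the same for every seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    images = np.empty((2 * n_per_class, size, size), dtype=np.uint8)
    labels = np.empty(2 * n_per_class, dtype=np.int64)
    from scipy.ndimage import distance_transform_edt

    for i in range(2 * n_per_class):
        label = i % 2
        img = np.full((size, size), bg_level, dtype=np.uint8)
        # some objects sit against a wall-shadow band, as in real crops
        near_wall = rng.random() < 0.4
        cx0 = cy0 = size / 2.0
        if near_wall:
            band = int(rng.uniform(8, 20))
            edge = rng.integers(4)
            if edge == 0:
                img[:band, :] = wall_level
                cy0 = band + rng.uniform(5, 15)
            elif edge == 1:
                img[-band:, :] = wall_level
                cy0 = size - band - rng.uniform(5, 15)
            elif edge == 2:
                img[:, :band] = wall_level
                cx0 = band + rng.uniform(5, 15)
            else:
                img[:, -band:] = wall_level
                cx0 = size - band - rng.uniform(5, 15)
        if label == 1:
            length = rng.uniform(0.6, 0.95) * size
            kin = WormKinematics(
                body_length=length,
                worm_width=rng.uniform(5.0, 8.0),
                undulation_amplitude=rng.uniform(4.0, 8.0),
                undulation_wavelength=rng.uniform(0.4, 0.6) * length,
            )
            ml = _worm_midline(cx0, cy0, rng.uniform(0, np.pi),
                               rng.uniform(0, 2 * np.pi), kin)
            # gentle overall bend so worms are curved, not straight
            bend = rng.uniform(-0.25, 0.25)
            s = np.linspace(-1, 1, len(ml))
            ml[:, 0] += bend * length / 2 * s ** 2 * np.sin(rng.uniform(0, np.pi))
            _stamp_points(img, ml, _disk_offsets(kin.worm_width / 2), worm_level)
        else:
            kind = (i // 2) % 3
            if kind == 0:  # blob
                r = rng.uniform(5.0, 12.0)
                _stamp_points(img, np.array([[cx0 + rng.uniform(-5, 5),
                                              cy0 + rng.uniform(-5, 5)]]),
                              _disk_offsets(r), worm_level)
            elif kind == 1:  # straight scratch
                ang = rng.uniform(0, np.pi)
                length = rng.uniform(0.5, 0.9) * size
                s = np.linspace(-length / 2, length / 2, 60)
                pts = np.stack([cx0 + s * np.cos(ang), cy0 + s * np.sin(ang)], axis=1)
                # scratches are thin marks in the agar, clearly narrower
                # than a worm body (width <= 4 px vs >= 5 px)
                _stamp_points(img, pts, _disk_offsets(rng.uniform(1.0, 2.0)), worm_level)
            else:  # crescent / edge artefact
                r = rng.uniform(15, 30)
                a0 = rng.uniform(0, 2 * np.pi)
                ang = np.linspace(a0, a0 + rng.uniform(1.0, 2.0), 50)
                pts = np.stack([cx0 + r * np.cos(ang), cy0 + r * np.sin(ang)], axis=1)
                _stamp_points(img, pts, _disk_offsets(rng.uniform(2.0, 3.5)), worm_level)
        obj = img == worm_level
        if noise_sigma > 0:
            img = np.clip(img.astype(np.int16)
                          + np.round(rng.normal(0, noise_sigma, img.shape)).astype(np.int16),
                          1, 255).astype(np.uint8)  # keep unmasked pixels nonzero
        dist = distance_transform_edt(~obj)
        img[dist > halo] = 0
        images[i] = img
        labels[i] = label
    return images, labels


# ---------------------------------------------------------------------------
# feature tables

PERIODS = ("prestim", "bluelight", "poststim")


def make_feature_table(n_strains: int, wells_per_strain: int, n_features: int,
                       effect_size: float, missing_frac: float, seed: int):
    """Strain-structured feature table with known labels.

    ``n_features`` is the per-period width; the three recording periods are
    concatenated, so the table has ``3 * n_features`` columns.  Per
    (strain, feature) mean shifts are drawn once with scale ``effect_size``
    on top of unit residual noise; missing entries are placed uniformly at
    random.
    """
    from .features import FeatureTable

    if n_strains < 1 or wells_per_strain < 1 or n_features < 1:
        raise ValueError("counts must be >= 1")
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_rows = n_strains * wells_per_strain
    n_cols = 3 * n_features
    strains = np.repeat([f"strain_{i:02d}" for i in range(n_strains)], wells_per_strain)
    shifts = rng.normal(0.0, 1.0, (n_strains, n_cols)) * effect_size
    values = shifts[np.repeat(np.arange(n_strains), wells_per_strain)] \
        + rng.normal(0.0, 1.0, (n_rows, n_cols))
    mask = rng.random((n_rows, n_cols)) < missing_frac
    values = values.astype(float)
    values[mask] = np.nan

    cols = [f"feat_{j:04d}_{p}" for p in PERIODS for j in range(n_features)]
    idx = pd.Index([f"well_{i:04d}" for i in range(n_rows)], name="well_id")
    vdf = pd.DataFrame(values, index=idx, columns=cols)
    mdf = pd.DataFrame(mask, index=idx, columns=cols)
    row_meta = pd.DataFrame({"strain": strains, "bad_well": False}, index=idx)
    col_meta = pd.DataFrame({
        "period": np.repeat(PERIODS, n_features),
        "base_feature": [f"feat_{j:04d}" for _ in PERIODS for j in range(n_features)],
    }, index=pd.Index(cols))
    table = FeatureTable(values=vdf, mask=mdf, row_meta=row_meta, col_meta=col_meta)
    return table, pd.Series(strains, index=idx, name="strain")


def make_screen_table(n_compounds: int, wells_per_compound: int, n_features: int,
                      n_days: int, effect_size: float, day_sd: float, seed: int,
                      n_hit_features: int = 0, control: str = "DMSO"):
    """Compound-screen table with a shared-day random effect and known hits.

    Rows are wells of ``n_compounds`` treatments plus an equally sized
    control group, spread over ``n_days`` imaging days.  Day effects are
    drawn per (day, feature) with sd ``day_sd`` and added to every well
    imaged that day; the first ``n_hit_features`` features of each compound
    receive a mean shift of ``effect_size``.
    """
    from .features import FeatureTable

    rng = np.random.default_rng(seed)
    groups = [control] + [f"cmpd_{i:02d}" for i in range(n_compounds)]
    rows, labels, days = [], [], []
    day_eff = rng.normal(0.0, day_sd, (n_days, n_features))
    for g in groups:
        for w in range(wells_per_compound):
            day = w % n_days
            x = rng.normal(0.0, 1.0, n_features) + day_eff[day]
            if g != control and n_hit_features > 0:
                x[:n_hit_features] += effect_size
            rows.append(x)
            labels.append(g)
            days.append(f"day_{day}")
    values = np.asarray(rows)
    idx = pd.Index([f"well_{i:04d}" for i in range(len(rows))], name="well_id")
    cols = [f"feat_{j:04d}" for j in range(n_features)]
    vdf = pd.DataFrame(values, index=idx, columns=cols)
    mdf = pd.DataFrame(False, index=idx, columns=cols)
    row_meta = pd.DataFrame({"compound": labels, "day": days, "bad_well": False}, index=idx)
    col_meta = pd.DataFrame({"period": "bluelight", "base_feature": cols}, index=pd.Index(cols))
    return FeatureTable(values=vdf, mask=mdf, row_meta=row_meta, col_meta=col_meta)


# ---------------------------------------------------------------------------
# metadata fixtures

WORMSORTER_COLUMNS = ["imaging_plate_id", "well_range", "worm_strain", "media_type",
                      "bacteria_strain"]
MANUAL_METADATA_COLUMNS = ["date_yyyymmdd", "run_number", "imaging_plate_id",
                           "instrument_name", "temperature_c", "humidity_percent"]
SOURCEPLATE_COLUMNS = ["source_plate_id", "well_name", "compound_name",
                       "compound_concentration", "concentration_units"]
ROBOTLOG_COLUMNS = ["source_plate_id", "source_well", "imaging_plate_id", "imaging_well"]
IMAGING2SOURCE_COLUMNS = ["imaging_plate_id", "source_plate_id"]
VIDEO_INDEX_COLUMNS = ["video_filename", "run_number", "instrument_name", "camera_id"]

FINAL_METADATA_COLUMNS = [
    "video_filename", "well_name", "imaging_plate_id", "run_number",
    "instrument_name", "camera_id", "date_yyyymmdd", "worm_strain", "media_type",
    "bacteria_strain", "compound_name", "compound_concentration",
    "concentration_units", "source_plate_id", "source_well",
]


def make_metadata_fixtures(seed: int, shuffle: bool = True,
                           with_compounds: bool = True) -> dict[str, pd.DataFrame]:
    """Mutually consistent experiment-record CSV fixtures plus the expected
    merged table.

    Returns a dict with keys ``wormsorter``, ``manual_metadata``,
    ``sourceplate``, ``robotlog``, ``imaging2source``, ``videos`` and
    ``expected`` (the oracle FinalMetadata, one row per (video, well),
    16 wells per video).  With ``shuffle`` the robot log records a seeded
    column permutation between source and imaging plates; without
    compounds the compound columns of the expected table are empty.
    """
    rng = np.random.default_rng(seed)
    date = "20220315"
    rig = "HYDRA01"
    plates = ["IP001", "IP002"]
    strain_blocks = {
        "IP001": [("A1-D12", "N2"), ("E1-H12", "CB4856")],
        "IP002": [("A1-B12", "N2"), ("C1-F12", "MY16"), ("G1-H12", "JU775")],
    }
    wormsorter = pd.DataFrame(
        [{"imaging_plate_id": p, "well_range": rng_, "worm_strain": s,
          "media_type": "NGM_low_peptone", "bacteria_strain": "OP50"}
         for p in plates for rng_, s in strain_blocks[p]],
        columns=WORMSORTER_COLUMNS)

    manual = pd.DataFrame(
        [{"date_yyyymmdd": date, "run_number": i + 1, "imaging_plate_id": p,
          "instrument_name": rig, "temperature_c": 20.0, "humidity_percent": 45.0}
         for i, p in enumerate(plates)],
        columns=MANUAL_METADATA_COLUMNS)

    videos = pd.DataFrame(
        [{"video_filename": f"{date}_run{run}_{rig}_cam{cam}.mp4",
          "run_number": run, "instrument_name": rig, "camera_id": cam}
         for run in (1, 2) for cam in range(1, 7)],
        columns=VIDEO_INDEX_COLUMNS)

    from .geometry import PLATE_COLS, PLATE_ROWS, well_name

    sourceplate = robotlog = imaging2source = None
    compound_of: dict[tuple[str, str], tuple] = {}
    if with_compounds:
        compounds = ["aldicarb", "levamisole", "ivermectin", "none"]
        src_rows = []
        for c in range(PLATE_COLS):
            name = compounds[c % len(compounds)]
            for r in range(PLATE_ROWS):
                if name != "none":
                    src_rows.append({"source_plate_id": "SP001",
                                     "well_name": well_name(r, c),
                                     "compound_name": name,
                                     "compound_concentration": float(10 * (c % 3 + 1)),
                                     "concentration_units": "uM"})
        sourceplate = pd.DataFrame(src_rows, columns=SOURCEPLATE_COLUMNS)
        src_lookup = {row["well_name"]: row for row in src_rows}
        perm = rng.permutation(PLATE_COLS) if shuffle else np.arange(PLATE_COLS)
        rl_rows = []
        for c in range(PLATE_COLS):
            for r in range(PLATE_ROWS):
                s_well = well_name(r, c)
                i_well = well_name(r, int(perm[c]))
                rl_rows.append({"source_plate_id": "SP001", "source_well": s_well,
                                "imaging_plate_id": "IP001", "imaging_well": i_well})
                src = src_lookup.get(s_well)
                compound_of[("IP001", i_well)] = (
                    (src["compound_name"], src["compound_concentration"],
                     src["concentration_units"], "SP001", s_well)
                    if src else (np.nan, np.nan, np.nan, "SP001", s_well))
        robotlog = pd.DataFrame(rl_rows, columns=ROBOTLOG_COLUMNS)

    strain_of: dict[tuple[str, str], str] = {}
    from .geometry import expand_well_range
    for p in plates:
        for rng_, s in strain_blocks[p]:
            for wname in expand_well_range(rng_):
                strain_of[(p, wname)] = s

    exp_rows = []
    run_of_plate = {p: i + 1 for i, p in enumerate(plates)}
    for p in plates:
        run = run_of_plate[p]
        for cam in range(1, 7):
            vid = f"{date}_run{run}_{rig}_cam{cam}.mp4"
            for wname in camera_block(cam):
                comp = compound_of.get((p, wname), (np.nan,) * 5)
                exp_rows.append({
                    "video_filename": vid, "well_name": wname, "imaging_plate_id": p,
                    "run_number": run, "instrument_name": rig, "camera_id": cam,
                    "date_yyyymmdd": date, "worm_strain": strain_of[(p, wname)],
                    "media_type": "NGM_low_peptone", "bacteria_strain": "OP50",
                    "compound_name": comp[0], "compound_concentration": comp[1],
                    "concentration_units": comp[2], "source_plate_id": comp[3],
                    "source_well": comp[4],
                })
    expected = pd.DataFrame(exp_rows, columns=FINAL_METADATA_COLUMNS)
    expected = expected.sort_values(["video_filename", "well_name"]).reset_index(drop=True)

    return {
        "wormsorter": wormsorter,
        "manual_metadata": manual,
        "sourceplate": sourceplate,
        "robotlog": robotlog,
        "imaging2source": imaging2source,
        "videos": videos,
        "expected": expected,
    }
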