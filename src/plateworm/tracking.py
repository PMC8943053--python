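"""Contrast-based segmentation, frame masking, track linking and motion modes.

Putative worm objects are dark connected components within user-defined
area bounds.  Detections are linked frame-to-frame by greedy nearest
neighbour; a missed detection closes the track (identity is never bridged
across gaps, so the number of tracks typically exceeds the number of
worms).  Per-frame motion mode (forward / backward / stationary) comes
from the centroid velocity projected on the tail-to-head midline axis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import distance_transform_edt
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import skeletonize

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    threshold: float | None = 80.0  # absolute grey level; None = Otsu on well interiors
    min_area: int = 80
    max_area: int = 2500


@dataclass
class PutativeObject:
    frame_number: int
    centroid: tuple[float, float]  # (x, y)
    area: int
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)
    mask: np.ndarray  # bool, local to bbox
    midline: np.ndarray | None = None  # (n, 2) float (x, y); head first once resolved


@dataclass
class Track:
    track_id: int
    objects: list[PutativeObject] = field(default_factory=list)
    modes: list[str | None] | None = None
    well: str | None = None
    well_bad: bool = False
    worm_prob_median: float | None = None
    is_worm: bool | None = None

    @property
    def frames(self) -> np.ndarray:
        return np.array([o.frame_number for o in self.objects])

    @property
    def centroids(self) -> np.ndarray:
        return np.array([o.centroid for o in self.objects], dtype=float)

    def __len__(self) -> int:
        return len(self.objects)


def auto_threshold(frame: np.ndarray, grid) -> float:
    """Otsu threshold computed over well interiors only."""
    pix = []
    for box in grid.wells:
        pix.append(frame[int(box.y_min):int(box.y_max),
                         int(box.x_min):int(box.x_max)].ravel())
    return float(threshold_otsu(np.concatenate(pix)))


def _order_skeleton(coords: np.ndarray) -> np.ndarray:
    """Order skeleton pixels into a polyline by walking from an endpoint."""
    if len(coords) <= 2:
        return coords.astype(float)
    coord_set = {tuple(c) for c in map(tuple, coords)}
    nbrs = {}
    for y, x in coord_set:
        nbrs[(y, x)] = [
            (y + dy, x + dx)
            for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dy or dx) and (y + dy, x + dx) in coord_set
        ]
    endpoints = [p for p, n in nbrs.items() if len(n) == 1]
    start = min(endpoints) if endpoints else min(coord_set)
    path, seen = [start], {start}
    while True:
        nxt = [p for p in nbrs[path[-1]] if p not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation for smoother paths
        nxt.sort(key=lambda p: (abs(p[0] - path[-1][0]) + abs(p[1] - path[-1][1])))
        path.append(nxt[0])
        seen.add(nxt[0])
    return np.array(path, dtype=float)


def segment_frame(frame: np.ndarray, params: SegmentationParams,
                  frame_number: int = 0, grid=None,
                  compute_midline: bool = True) -> list[PutativeObject]:
    """Detect dark connected components within the configured area bounds."""
    if frame.dtype != np.uint8:
        raise ValueError("frame must be 8-bit grayscale")
    thr = params.threshold if params.threshold is not None else auto_threshold(frame, grid)
    binary = frame < thr
    lab = label(binary, connectivity=2)
    objects = []
    for region in regionprops(lab):
        if not params.min_area <= region.area <= params.max_area:
            continue
        cy, cx = region.centroid
        midline = None
        if compute_midline:
            skel = skeletonize(region.image)
            coords = np.argwhere(skel)
            if len(coords) >= 2:
                path = _order_skeleton(coords)  # (n, 2) as (row, col), local
                midline = np.stack([path[:, 1] + region.bbox[1],
                                    path[:, 0] + region.bbox[0]], axis=1)
        objects.append(PutativeObject(
            frame_number=frame_number, centroid=(cx, cy), area=int(region.area),
            bbox=tuple(region.bbox), mask=region.image.copy(), midline=midline))
    return objects


def _union_mask(shape: tuple[int, int], objects: list[PutativeObject]) -> np.ndarray:
    union = np.zeros(shape, dtype=bool)
    for o in objects:
        r0, c0, r1, c1 = o.bbox
        union[r0:r1, c0:c1] |= o.mask
    return union


def mask_frame(frame: np.ndarray, objects: list[PutativeObject], halo: float) -> np.ndarray:
    """Zero every pixel farther than ``halo`` from all object masks."""
    out = frame.copy()
    if not objects:
        out[:] = 0
        return out
    union = _union_mask(frame.shape, objects)
    dist = distance_transform_edt(~union)
    out[dist > halo] = 0
    return out


def extract_roi(frame: np.ndarray, obj: PutativeObject, size: int = 80,
                halo: float = 5.0) -> np.ndarray:
    """Masked square crop centred on the object (zero-padded at frame edges)."""
    masked = mask_frame(frame, [obj], halo)
    cx, cy = (int(round(v)) for v in obj.centroid)
    half = size // 2
    roi = np.zeros((size, size), dtype=frame.dtype)
    y0, y1 = cy - half, cy - half + size
    x0, x1 = cx - half, cx - half + size
    sy0, sx0 = max(y0, 0), max(x0, 0)
    sy1, sx1 = min(y1, frame.shape[0]), min(x1, frame.shape[1])
    roi[sy0 - y0:sy1 - y0, sx0 - x0:sx1 - x0] = masked[sy0:sy1, sx0:sx1]
    return roi


def link_tracks(objects_per_frame: list[list[PutativeObject]],
                max_step: float) -> list[Track]:
    """Greedy nearest-neighbour linking between consecutive frames.

    Pairs farther apart than ``max_step`` stay unmatched; unmatched
    detections start new tracks; tracks never merge, and a frame without a
    match closes the track for good.
    """
    tracks: list[Track] = []
    active: list[Track] = []
    next_id = 0
    prev_frame_number = None
    for dets in objects_per_frame:
        if not dets:
            active = []
            continue
        fn = dets[0].frame_number
        live = [t for t in active
                if t.objects[-1].frame_number == prev_frame_number] if prev_frame_number is not None else []
        assigned_t, assigned_d = set(), set()
        if live:
            last = np.array([t.objects[-1].centroid for t in live])
            cur = np.array([d.centroid for d in dets])
            dist = np.linalg.norm(last[:, None, :] - cur[None, :, :], axis=2)
            order = np.dstack(np.unravel_index(np.argsort(dist, axis=None), dist.shape))[0]
            for ti, di in order:
                if dist[ti, di] > max_step:
                    break
                if ti in assigned_t or di in assigned_d:
                    continue
                live[ti].objects.append(dets[di])
                assigned_t.add(ti)
                assigned_d.add(di)
        new_active = [t for i, t in enumerate(live) if i in assigned_t]
        for di, d in enumerate(dets):
            if di not in assigned_d:
                t = Track(track_id=next_id, objects=[d])
                next_id += 1
                tracks.append(t)
                new_active.append(t)
        active = new_active
        prev_frame_number = fn
    return tracks


def resolve_head_tail(track: Track) -> Track:
    """Fix midline orientation: consistent along the track, head leading
    during forward motion (majority direction of travel); ties are stable."""
    objs = [o for o in track.objects if o.midline is not None and len(o.midline) >= 2]
    if not objs:
        return track
    prev = None
    for o in objs:
        ml = o.midline
        if prev is not None:
            n = min(len(ml), len(prev))
            a = np.linalg.norm(_resample(ml, n) - _resample(prev, n))
            b = np.linalg.norm(_resample(ml[::-1], n) - _resample(prev, n))
            if b < a:
                o.midline = ml[::-1].copy()
        prev = o.midline
    total = 0.0
    for o0, o1 in zip(track.objects, track.objects[1:]):
        if o0.midline is None or len(o0.midline) < 2:
            continue
        axis = o0.midline[0] - o0.midline[-1]
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            continue
        step = np.array(o1.centroid) - np.array(o0.centroid)
        total += float(step @ (axis / nrm))
    if total < 0:
        for o in track.objects:
            if o.midline is not None:
                o.midline = o.midline[::-1].copy()
    return track


def _resample(polyline: np.ndarray, n: int) -> np.ndarray:
    d = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(polyline, axis=0), axis=1))])
    if d[-1] == 0:
        return np.repeat(polyline[:1], n, axis=0)
    s = np.linspace(0, d[-1], n)
    return np.stack([np.interp(s, d, polyline[:, i]) for i in range(2)], axis=1)


def midline_length(midline: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(midline, axis=0), axis=1).sum())


def classify_motion(track: Track, frame_rate: float, v_stat: float = 0.1,
                    smooth_window_s: float = 0.4,
                    body_length: float | None = None) -> list[str | None]:
    """Per-frame motion modes from signed, smoothed centroid speed.

    Signed speed is the centroid velocity projected on the tail-to-head
    midline axis (head-first midline convention), smoothed over a centred
    window; ``|v| < v_stat * body_length`` is stationary, otherwise the
    sign gives forward/backward.  Frames without a midline get ``None``.
    """
    n = len(track.objects)
    win = max(1, int(round(smooth_window_s * frame_rate)))
    win += (win + 1) % 2  # force odd for a centred window
    if n < win:
        raise ValueError(f"track length {n} below smoothing window {win}")
    if body_length is None:
        lengths = [midline_length(o.midline) for o in track.objects
                   if o.midline is not None and len(o.midline) >= 2]
        if not lengths:
            raise ValueError("no midlines available to estimate body length")
        body_length = float(np.median(lengths))

    c = track.centroids
    vel = np.gradient(c, axis=0) * frame_rate  # central differences, px/s
    signed = np.full(n, np.nan)
    for i, o in enumerate(track.objects):
        if o.midline is None or len(o.midline) < 2:
            continue
        axis = o.midline[0] - o.midline[-1]
        nrm = np.linalg.norm(axis)
        if nrm == 0:
            continue
        signed[i] = vel[i] @ (axis / nrm)

    # centred moving average over defined samples
    smoothed = np.full(n, np.nan)
    half = win // 2
    for i in range(n):
        seg = signed[max(0, i - half):i + half + 1]
        if np.any(np.isfinite(seg)):
            smoothed[i] = np.nanmean(seg)

    thr = v_stat * body_length
    modes: list[str | None] = []
    for v in smoothed:
        if not np.isfinite(v):
            modes.append(None)
        elif abs(v) < thr:
            modes.append("st")
        else:
            modes.append("fw" if v > 0 else "bw")
    track.modes = modes
    return modes


def assign_tracks(tracks: list[Track], grid) -> tuple[list[Track], int]:
    """Attach well names by the track's median centroid; discard wall tracks.

    Returns (kept tracks, number of discarded tracks).  Tracks in
    bad-flagged wells are kept but carry ``well_bad=True``.
    """
    from .wells import locate_point

    kept, discarded = [], 0
    for t in tracks:
        med = np.median(t.centroids, axis=0)
        name = locate_point(grid, float(med[0]), float(med[1]))
        if name is None:
            discarded += 1
            continue
        t.well = name
        t.well_bad = grid.well(name).bad_flag
        kept.append(t)
    if discarded:
        logger.info("assign_tracks: discarded %d track(s) on walls/outside", discarded)
    return kept, discarded
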