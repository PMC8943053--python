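"""Shared fixtures: simulated sessions and tracked objects.

Everything is generated programmatically with fixed seeds; the heavier
artefacts (rendered sessions, tracked sessions) are session-scoped so the
cost is paid once.
"""

from __future__ import annotations

import numpy as np
import pytest

from plateworm.schedule import build_schedule
from plateworm.synthetic import PlateConfig, WormKinematics, simulate_session
from plateworm.tracking import (SegmentationParams, assign_tracks, classify_motion,
                                link_tracks, resolve_head_tail, segment_frame)


@pytest.fixture(scope="session")
def short_session():
    """10 s single-worm-per-well session with one debris object per well."""
    sched = build_schedule("custom", pulses=[], total_duration=10.0)
    plate = PlateConfig(n_debris_per_well=1)
    kin = WormKinematics(n_worms_per_well=1)
    store, truth = simulate_session(plate, kin, sched, seed=11)
    return store, truth, kin


@pytest.fixture(scope="session")
def tracked_session(short_session):
    """Segmented, linked, well-assigned and mode-classified tracks."""
    store, truth, kin = short_session
    params = SegmentationParams()
    per_frame = [segment_frame(f, params, frame_number=i)
                 for i, f in enumerate(store.frames)]
    tracks = link_tracks(per_frame, max_step=20.0)
    kept, discarded = assign_tracks(tracks, truth.grid)
    for t in kept:
        if len(t) >= 11:
            resolve_head_tail(t)
            try:
                classify_motion(t, store.frame_rate)
            except ValueError:  # e.g. point-like debris without a midline
                t.modes = [None] * len(t)
    return store, truth, per_frame, kept, discarded


def match_truth_object(track, truth):
    """(kind, record) of the nearest ground-truth object at the track middle."""
    mid = track.objects[len(track) // 2]
    tw = truth.worms[truth.worms.frame == mid.frame_number]
    d_worm = np.hypot(tw.x - mid.centroid[0], tw.y - mid.centroid[1])
    best_worm = d_worm.min() if len(d_worm) else np.inf
    td = truth.debris
    d_deb = (np.hypot(td.x - mid.centroid[0], td.y - mid.centroid[1])
             if len(td) else np.array([np.inf]))
    if best_worm <= d_deb.min():
        return "worm", tw.loc[d_worm.idxmin()]
    return "debris", td.loc[d_deb.idxmin()]
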