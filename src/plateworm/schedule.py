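"""Photostimulation schedules.

A schedule is an ordered list of (label, duration, intensity) segments,
``label`` being ``"off"`` or ``"on"``.  Two named protocols are provided:

``standard``
    Three sequential videos: a 5 min pre-stimulus recording, a 6 min
    stimulus recording with 10 s blue-light pulses at 100% intensity
    starting at the 60, 160 and 260 s mark, and a 5 min post-stimulus
    recording (16 min total).

``serial``
    A single continuous recording: 5 min off, twenty repeats of
    (10 s on at 100%, 90 s off), then 5 min off (43 min 20 s total).

All interval logic is half-open: a pulse spanning ``[start, end)`` is on at
``start`` and off at ``end``.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class Segment:
    label: str  # "off" | "on"
    duration: float  # seconds
    intensity: float = 0.0  # percent, 0-100

    def __post_init__(self):
        if self.label not in ("off", "on"):
            raise ValueError(f"segment label must be 'off' or 'on', got {self.label!r}")
        if self.duration <= 0:
            raise ValueError("segment duration must be > 0")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered light-on/off segments plus video boundaries."""

    segments: tuple[Segment, ...]
    video_boundaries: tuple[float, ...] = field(default=())
    kind: str = "custom"

    def __post_init__(self):
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        # overlap is impossible for sequential segments; validate pulse sanity
        for seg in self.segments:
            if seg.duration <= 0:
                raise ValueError("segment duration must be > 0")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration for s in self.segments))

    @property
    def pulses(self) -> list[tuple[float, float]]:
        """(start, end) of every light-on interval, in seconds."""
        out, t = [], 0.0
        for seg in self.segments:
            if seg.label == "on":
                out.append((t, t + seg.duration))
            t += seg.duration
        return out

    @property
    def n_pulses(self) -> int:
        return len(self.pulses)

    def is_on(self, t: float) -> bool:
        """Light state at time ``t`` (half-open segments)."""
        acc = 0.0
        for seg in self.segments:
            if acc <= t < acc + seg.duration:
                return seg.label == "on"
            acc += seg.duration
        return False

    def total_on_time(self) -> float:
        return float(sum(s.duration for s in self.segments if s.label == "on"))

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "segments": [
                {"label": s.label, "duration": s.duration, "intensity": s.intensity}
                for s in self.segments
            ],
            "video_boundaries": list(self.video_boundaries),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusSchedule":
        return cls(
            segments=tuple(
                Segment(s["label"], float(s["duration"]), float(s.get("intensity", 0.0)))
                for s in d["segments"]
            ),
            video_boundaries=tuple(d.get("video_boundaries", ())),
            kind=d.get("kind", "custom"),
        )


def build_schedule(kind: str = "standard", pulses: list[tuple[float, float, float]] | None = None,
                   total_duration: float | None = None) -> StimulusSchedule:
    """Build a named or custom photostimulation schedule.

    Parameters
    ----------
    kind:
        ``"standard"``, ``"serial"`` or ``"custom"``.
    pulses:
        For ``custom``: list of (start_s, duration_s, intensity_pct).
    total_duration:
        For ``custom``: total recording length in seconds.
    """
    if kind == "standard":
        segs = [Segment("off", 300.0)]
        # 6 min stimulus video, pulses start at 60, 160, 260 s into it
        t = 300.0
        for start in (60.0, 160.0, 260.0):
            gap = (300.0 + start) - t
            if gap > 0:
                segs.append(Segment("off", gap))
            segs.append(Segment("on", 10.0, 100.0))
            t = 300.0 + start + 10.0
        segs.append(Segment("off", 660.0 - t))  # to end of stimulus video
        segs.append(Segment("off", 300.0))  # post-stimulus video
        return StimulusSchedule(tuple(segs), video_boundaries=(0.0, 300.0, 660.0, 960.0),
                                kind="standard")
    if kind == "serial":
        segs = [Segment("off", 300.0)]
        for _ in range(20):
            segs.append(Segment("on", 10.0, 100.0))
            segs.append(Segment("off", 90.0))
        segs.append(Segment("off", 300.0))
        total = sum(s.duration for s in segs)
        return StimulusSchedule(tuple(segs), video_boundaries=(0.0, total), kind="serial")
    if kind == "custom":
        if pulses is None or total_duration is None:
            raise ValueError("custom schedule needs pulses and total_duration")
        pulses = sorted(pulses)
        for (s0, d0, _), (s1, _, _) in zip(pulses, pulses[1:]):
            if s0 + d0 > s1:
                raise ValueError("overlapping pulses in custom schedule")
        segs, t = [], 0.0
        for start, dur, inten in pulses:
            if start + dur > total_duration:
                raise ValueError("pulse extends beyond total_duration")
            if start > t:
                segs.append(Segment("off", start - t))
            segs.append(Segment("on", dur, inten))
            t = start + dur
        if t < total_duration:
            segs.append(Segment("off", total_duration - t))
        return StimulusSchedule(tuple(segs), video_boundaries=(0.0, total_duration),
                                kind="custom")
    raise ValueError(f"unknown schedule kind {kind!r}")
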