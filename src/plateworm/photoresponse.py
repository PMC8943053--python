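"""Time-resolved motion-mode statistics under photostimulation.

The population readout is the fraction of tracked worms in each motion
mode (forward / backward / stationary) at each time point in each well:
counts divided by the total number of tracked worms at that time point in
that well.  Time points with zero tracked worms are undefined (excluded,
never imputed as zero).  Well-averaged curves carry 95% confidence
intervals from a nonparametric bootstrap over wells (resampling with
replacement).  Pulse-locked summaries: the per-pulse response delta
(mean over the 10 s just after the end of each stimulus minus the 10 s
just before) and the baseline shift (final 5 min minus initial 5 min).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .schedule import StimulusSchedule, build_schedule  # noqa: F401 (re-export)
from .synthetic import BW, FW, MODES, ST
from .tracking import Track

UNDEF = -1
_MODE_CODE = {m: i for i, m in enumerate(MODES)}
#: tie priority for the prevalent-mode rule: stationary wins, then forward
_TIE_PRIORITY = (ST, FW, BW)


@dataclass
class MotionFractionSeries:
    """Per-well, per-timepoint mode fractions.

    ``fractions`` has shape (3, n_wells, n_times) ordered (fw, bw, st),
    NaN where no worms were tracked; ``counts`` holds the number of
    tracked worms behind each (well, time) entry.
    """

    times: np.ndarray
    wells: list[str]
    fractions: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        ok = self.counts > 0
        total = np.nansum(self.fractions, axis=0)
        if ok.any() and not np.allclose(total[ok], 1.0, atol=1e-9):
            raise ValueError("mode fractions must sum to 1 where defined")


def mode_fractions_from_arrays(modes: np.ndarray, worm_wells: list[str],
                               times: np.ndarray) -> MotionFractionSeries:
    """Fractions from per-worm mode code arrays (UNDEF = not tracked).

    ``modes``: (n_worms, n_times) int codes; ``worm_wells``: well name per worm.
    """
    wells = sorted(set(worm_wells))
    widx = {w: i for i, w in enumerate(wells)}
    n_w, n_t = len(wells), modes.shape[1]
    counts_by_mode = np.zeros((3, n_w, n_t))
    for worm, well in enumerate(worm_wells):
        row = modes[worm]
        for m in range(3):
            counts_by_mode[m, widx[well]] += row == m
    total = counts_by_mode.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, counts_by_mode / np.where(total > 0, total, 1), np.nan)
    return MotionFractionSeries(times=np.asarray(times, dtype=float), wells=wells,
                                fractions=frac, counts=total.astype(int))


def mode_fractions(tracks: list[Track], times: np.ndarray,
                   exclude_bad: bool = True) -> MotionFractionSeries:
    """Fractions from classified tracks (``modes`` set, wells assigned)."""
    tracks = [t for t in tracks if t.well is not None
              and not (exclude_bad and t.well_bad)]
    if not tracks:
        raise ValueError("no usable tracks")
    n_t = len(times)
    rows, wells_of = [], []
    for t in tracks:
        if t.modes is None:
            raise ValueError("tracks must have per-frame modes")
        row = np.full(n_t, UNDEF, dtype=np.int8)
        for o, m in zip(t.objects, t.modes):
            if m is not None and o.frame_number < n_t:
                row[o.frame_number] = _MODE_CODE[m]
        rows.append(row)
        wells_of.append(t.well)
    return mode_fractions_from_arrays(np.stack(rows), wells_of, times)


def aggregate_bootstrap(series: MotionFractionSeries, n_boot: int = 1000,
                        seed: int = 0) -> dict:
    """Well-averaged mean curve with percentile-bootstrap 95% CI per mode.

    Wells are resampled with replacement; the CI is the 2.5/97.5
    percentile band of the resampled means.  Requires at least two wells.
    """
    n_wells = len(series.wells)
    if n_wells < 2:
        raise ValueError("bootstrap aggregation needs at least 2 wells")
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(series.fractions, axis=1)
        idx = rng.integers(0, n_wells, size=(n_boot, n_wells))
        boots = np.nanmean(series.fractions[:, idx, :], axis=2)  # (3, n_boot, T)
        lo = np.nanpercentile(boots, 2.5, axis=1)
        hi = np.nanpercentile(boots, 97.5, axis=1)
    return {"times": series.times, "mean": mean, "ci_low": lo, "ci_high": hi,
            "n_wells": n_wells, "n_boot": n_boot}


def downsample_prevalent(modes: np.ndarray, frame_rate: float,
                         window_s: float = 2.0) -> np.ndarray:
    """Prevalent-mode downsampling to nonoverlapping windows (default 0.5 Hz).

    Per window the modal mode wins; ties break by stationary > forward >
    backward (no movement claimed on ties).  Windows with no defined
    sample are undefined.
    """
    wpf = window_s * frame_rate
    if abs(wpf - round(wpf)) > 1e-9:
        raise ValueError("window must be a whole number of frames")
    wpf = int(round(wpf))
    was_1d = np.ndim(modes) == 1
    modes = np.atleast_2d(modes)
    n_win = modes.shape[1] // wpf
    out = np.full((modes.shape[0], n_win), UNDEF, dtype=np.int8)
    for k in range(n_win):
        chunk = modes[:, k * wpf:(k + 1) * wpf]
        counts = np.stack([(chunk == m).sum(axis=1) for m in range(3)])  # (3, n_worms)
        best = np.full(modes.shape[0], UNDEF, dtype=np.int8)
        best_count = np.zeros(modes.shape[0], dtype=int)
        for m in _TIE_PRIORITY:
            better = counts[m] > best_count
            best[better] = m
            best_count[better] = counts[m][better]
        out[:, k] = best
    return out[0] if was_1d else out


def _window_mean(mean_series: np.ndarray, times: np.ndarray,
                 t0: float, t1: float) -> np.ndarray:
    """Per-mode mean over the half-open window (t0, t1]; NaNs excluded."""
    sel = (times > t0) & (times <= t1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mean_series[:, sel], axis=1)


def pulse_response_delta(mean_series: np.ndarray, times: np.ndarray,
                         schedule: StimulusSchedule,
                         window: float = 10.0) -> tuple[np.ndarray, list[int]]:
    """Per-pulse evoked response: the window just before the end of each
    stimulus minus the window just after it.

    The pre-end window samples the stimulus-elevated level, the post-end
    window the recovered level, so a positive forward-mode delta means the
    pulse evoked extra forward locomotion.  Windows are half-open:
    ``(end-window, end]`` minus ``(end, end+window]``.  Pulses whose post
    window extends past the recording are skipped with a warning.
    Returns (deltas (n_used, 3), pulse indices used).
    """
    deltas, used = [], []
    for i, (_, end) in enumerate(schedule.pulses):
        if end + window > times[-1] + 1e-9 or end - window < times[0] - 1e-9:
            warnings.warn(f"pulse {i}: response window extends past recording; skipped")
            continue
        before = _window_mean(mean_series, times, end - window, end)
        after = _window_mean(mean_series, times, end, end + window)
        deltas.append(before - after)
        used.append(i)
    return np.array(deltas).reshape(-1, 3), used


def baseline_shift(mean_series: np.ndarray, times: np.ndarray,
                   schedule: StimulusSchedule | None = None,
                   window: float = 300.0) -> np.ndarray:
    """Per-mode difference between the final and initial 5 min windows."""
    span = times[-1] - times[0]
    if span < 2 * window:
        raise ValueError(f"recording ({span:.0f} s) shorter than two "
                         f"{window:.0f} s windows")
    first = _window_mean(mean_series, times, times[0] - 1e-9, times[0] + window)
    last = _window_mean(mean_series, times, times[-1] - window, times[-1])
    return last - first
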