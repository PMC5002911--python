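"""VOI time-course extraction and percent-change normalization.

The cuff paradigm has three phases on one time axis: rest (baseline),
arterial occlusion (ischemia), and reactive hyperemia after rapid cuff
deflation.  Muscle signal is summarized per frame as the unweighted mean
over the VOI's voxels, then expressed as percent change from the mean
baseline signal intensity::

    pct(t) = 100 * (SI(t) - SI_baseline) / SI_baseline

The first few baseline frames are discarded from the baseline statistic by
default to skip T1 saturation transients at the start of the acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, MaskError, ProtocolError
from .io import BoldSeries, VoiLabelMap

_REL_STEP_TOL = 1e-6


@dataclass(frozen=True)
class ProtocolTiming:
    """The three-phase cuff paradigm on a time axis.

    Defaults encode a 15-minute acquisition at TR = 3 s: 5 min baseline,
    5 min occlusion, 5 min reactive hyperemia after deflation.

    Parameters
    ----------
    baseline_start, occlusion_start, deflation_time, end_time:
        Phase boundaries in seconds.  A frame belongs to the phase whose
        half-open window ``[start, next_start)`` contains its center.
    tr:
        Seconds per volume.
    baseline_discard:
        Number of initial baseline frames excluded from the baseline
        statistic (saturation transients); at least 3 baseline frames must
        remain.
    """

    baseline_start: float = 0.0
    occlusion_start: float = 300.0
    deflation_time: float = 600.0
    end_time: float = 900.0
    tr: float = 3.0
    baseline_discard: int = 5

    def __post_init__(self) -> None:
        if not (self.baseline_start < self.occlusion_start < self.deflation_time < self.end_time):
            raise ProtocolError(
                "phase boundaries must be ordered baseline < occlusion < deflation < end, got "
                f"({self.baseline_start}, {self.occlusion_start}, "
                f"{self.deflation_time}, {self.end_time})"
            )
        if not self.tr > 0:
            raise ProtocolError(f"nonpositive TR: {self.tr}")
        if self.baseline_discard < 0:
            raise ProtocolError(f"negative baseline_discard: {self.baseline_discard}")
        n_baseline = int(self.baseline_mask(self.frame_centers()).sum())
        if n_baseline - self.baseline_discard < 3:
            raise ProtocolError(
                f"baseline_discard={self.baseline_discard} leaves fewer than 3 of the "
                f"{n_baseline} baseline frames"
            )

    @property
    def n_frames(self) -> int:
        """Number of frames covering ``[baseline_start, end_time)``."""
        return int(round((self.end_time - self.baseline_start) / self.tr))

    def frame_centers(self) -> np.ndarray:
        return self.baseline_start + (np.arange(self.n_frames) + 0.5) * self.tr

    def baseline_mask(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return (times >= self.baseline_start) & (times < self.occlusion_start)

    def occlusion_mask(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return (times >= self.occlusion_start) & (times < self.deflation_time)

    def hyperemia_mask(self, times: np.ndarray) -> np.ndarray:
        times = np.asarray(times, dtype=float)
        return (times >= self.deflation_time) & (times < self.end_time)


def _check_time_axis(times: np.ndarray, what: str) -> None:
    if times.ndim != 1 or times.size < 1:
        raise DataError(f"{what}: times must be a non-empty 1-D array")
    if times.size >= 2:
        steps = np.diff(times)
        if (steps <= 0).any():
            raise DataError(f"{what}: times must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=_REL_STEP_TOL, atol=0):
            raise DataError(f"{what}: times must have a constant step")


@dataclass(frozen=True)
class RawTimeCourse:
    """Per-VOI mean signal intensity over time (scanner units)."""

    muscle: str
    times: np.ndarray
    si: np.ndarray
    n_voxels: int

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        si = np.asarray(self.si, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "si", si)
        _check_time_axis(times, f"RawTimeCourse({self.muscle})")
        if si.shape != times.shape:
            raise DataError("times and si must have equal length")
        if self.n_voxels < 1:
            raise DataError("n_voxels must be >= 1")

    @property
    def tr(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class NormalizedTimeCourse:
    """Percent change from baseline per frame, with the baseline statistics."""

    muscle: str
    times: np.ndarray
    pct: np.ndarray
    baseline_si: float
    baseline_sd: float

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        pct = np.asarray(self.pct, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "pct", pct)
        _check_time_axis(times, f"NormalizedTimeCourse({self.muscle})")
        if pct.shape != times.shape:
            raise DataError("times and pct must have equal length")
        if not self.baseline_si > 0:
            raise DataError(f"baseline_si must be positive, got {self.baseline_si}")
        if self.baseline_sd < 0:
            raise DataError("baseline_sd must be >= 0")

    @property
    def tr(self) -> float:
        if self.times.size < 2:
            raise DataError("single-frame time course has no defined TR")
        return float(self.times[1] - self.times[0])

    def restricted_to(self, mask: np.ndarray) -> "NormalizedTimeCourse":
        """Contiguous sub-course selected by a boolean mask over frames."""
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise DataError(f"{self.muscle}: empty frame selection")
        if idx.size > 1 and not (np.diff(idx) == 1).all():
            raise DataError("frame selection must be contiguous")
        return replace(self, times=self.times[mask], pct=self.pct[mask])


def extract_voi_timecourse(series: BoldSeries, mask: VoiLabelMap, muscle: str) -> RawTimeCourse:
    """Mean signal over all voxels of one muscle label, per frame.

    The mean is unweighted across voxels.  Raises ``MaskError`` for a muscle
    missing from the legend or an empty VOI.
    """
    label = mask.label_of(muscle)
    sel = mask.labels == label
    n_vox = int(sel.sum())
    if n_vox == 0:
        raise MaskError(f"empty VOI: label {label} ({muscle}) marks no voxels")
    si = np.asarray(series.voxels[sel], dtype=np.float64).mean(axis=0)
    return RawTimeCourse(muscle=muscle, times=series.frame_times, si=si, n_voxels=n_vox)


def percent_change_normalize(
    raw: RawTimeCourse,
    timing: ProtocolTiming,
    detrend_baseline: bool = False,
) -> NormalizedTimeCourse:
    """Express a raw time course as percent change from resting baseline.

    The baseline signal intensity is the mean over the baseline-phase frames
    after dropping the first ``timing.baseline_discard`` of them.  With
    ``detrend_baseline`` a linear drift fitted on those baseline frames is
    removed from the whole series before normalizing (off by default: the
    standard analysis applies no drift correction).
    """
    base_idx = np.flatnonzero(timing.baseline_mask(raw.times))
    if base_idx.size == 0:
        raise ProtocolError(f"{raw.muscle}: series does not cover the baseline window")
    use_idx = base_idx[timing.baseline_discard:]
    if use_idx.size < 3:
        raise ProtocolError(
            f"{raw.muscle}: only {use_idx.size} usable baseline frames after discarding "
            f"{timing.baseline_discard}; need >= 3"
        )
    si = raw.si.astype(float)
    if detrend_baseline:
        slope, intercept = np.polyfit(raw.times[use_idx], si[use_idx], 1)
        si = si - slope * (raw.times - np.mean(raw.times[use_idx]))
    baseline_si = float(si[use_idx].mean())
    if baseline_si <= 0:
        raise DataError(f"{raw.muscle}: nonpositive baseline SI ({baseline_si})")
    baseline_sd = float(si[use_idx].std(ddof=1))
    pct = 100.0 * (si - baseline_si) / baseline_si
    return NormalizedTimeCourse(
        muscle=raw.muscle,
        times=raw.times,
        pct=pct,
        baseline_si=baseline_si,
        baseline_sd=baseline_sd,
    )


def window_frames(window_s: float, tr: float) -> int:
    """Window length in frames: ``max(1, round(window_s / tr))``.

    At TR = 3 s the protocol's 3-second average is a single frame.
    """
    if not window_s >= 0:
        raise DataError(f"window must be >= 0 s, got {window_s}")
    return max(1, int(round(window_s / tr)))


def rolling_average(ntc: NormalizedTimeCourse, window_s: float) -> NormalizedTimeCourse:
    """Trailing rolling mean of ``w = max(1, round(window_s/tr))`` frames.

    Output value ``i`` is the mean of frames ``[i, i+w-1]`` and is
    timestamped at the center of that window, so the output has
    ``nt - w + 1`` frames.
    """
    if not window_s > 0:
        raise DataError(f"window must be positive, got {window_s} s")
    w = window_frames(window_s, ntc.tr)
    n = ntc.pct.size
    if w > n:
        raise DataError(f"window of {w} frames longer than series of {n} frames")
    smoothed = np.lib.stride_tricks.sliding_window_view(ntc.pct, w).mean(axis=-1)
    times = ntc.times[: n - w + 1] + 0.5 * (w - 1) * ntc.tr
    return replace(ntc, times=times, pct=smoothed)
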