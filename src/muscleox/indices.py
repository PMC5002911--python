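"""The four dynamic BOLD indices of the cuff occlusion / reactive hyperemia paradigm.

Given a percent-change time course and the protocol timing:

* **MIV** (minimum ischemic value, %): lowest short-window average during
  cuff occlusion.
* **PHV** (peak hyperemic value, %): highest short-window average after cuff
  deflation; the window defaults to 3 s, which at TR = 3 s is one frame.
* **TTP** (time to peak, s): time from cuff deflation to the center of the
  first maximal window.
* **TTR** (time to recovery, s): time from deflation until the unsmoothed
  signal first returns to its baseline level (0 %), linearly interpolated
  between the bracketing frame centers.  A series that never recovers before
  the end of the acquisition carries ``recovered=False`` and ``ttr=None``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .timecourse import NormalizedTimeCourse, ProtocolTiming, rolling_average

_EPS = 1e-9


@dataclass(frozen=True)
class BoldIndices:
    """The four scalar indices for one VOI.

    ``ttr`` is ``None`` when the signal did not return to baseline before
    the end of the acquisition (``recovered=False``); cohort statistics must
    average TTR over recovered cases only.
    """

    phv: float
    ttp: float
    miv: float
    ttr: float | None
    recovered: bool
    muscle: str = ""

    def __post_init__(self) -> None:
        if self.phv < self.miv:
            raise DataError(f"phv ({self.phv}) must be >= miv ({self.miv})")
        if self.ttp < 0:
            raise DataError(f"ttp must be >= 0, got {self.ttp}")
        if self.recovered:
            if self.ttr is None:
                raise DataError("recovered=True requires a ttr value")
            if self.ttr < self.ttp - _EPS:
                raise DataError(f"ttr ({self.ttr}) must be >= ttp ({self.ttp})")
        elif self.ttr is not None:
            raise DataError("recovered=False requires ttr=None")


def compute_phv_ttp(
    pct: NormalizedTimeCourse,
    timing: ProtocolTiming,
    window_s: float = 3.0,
) -> tuple[float, float]:
    """Peak hyperemic value and time to peak.

    The post-deflation segment is smoothed with a trailing ``window_s``
    rolling mean; PHV is its maximum and TTP the center timestamp of the
    first maximal window minus the deflation time (ties resolve to the
    earliest window, making TTP deterministic).
    """
    post = pct.times >= timing.deflation_time - _EPS
    if not post.any():
        raise DataError(f"{pct.muscle}: no frames after cuff deflation")
    seg = rolling_average(pct.restricted_to(post), window_s)
    i = int(np.argmax(seg.pct))
    phv = float(seg.pct[i])
    ttp = float(seg.times[i] - timing.deflation_time)
    return phv, ttp


def compute_miv(
    pct: NormalizedTimeCourse,
    timing: ProtocolTiming,
    window_s: float = 3.0,
) -> float:
    """Minimum ischemic value: lowest rolling-average over the occlusion window.

    The same short window as PHV is applied for symmetry and noise
    robustness; pass ``window_s=0`` for the single-frame minimum.
    """
    occ = timing.occlusion_mask(pct.times)
    if not occ.any():
        raise DataError(f"{pct.muscle}: no frames in the occlusion window")
    seg = pct.restricted_to(occ)
    if window_s > 0:
        seg = rolling_average(seg, window_s)
    return float(seg.pct.min())


def compute_ttr(
    pct: NormalizedTimeCourse,
    timing: ProtocolTiming,
    ttp: float,
    threshold: float = 0.0,
) -> tuple[float | None, bool]:
    """Time to recovery: first return of the unsmoothed signal to baseline.

    Scans the unsmoothed percent-change values forward from the peak (the
    first frame at or after ``deflation + ttp``) for the first frame at or
    below ``threshold`` (0 % = the baseline level by construction).  The
    crossing time is linearly interpolated between the bracketing frame
    centers.  Returns ``(ttr, True)`` on recovery, ``(None, False)`` if the
    signal stays above threshold until the end of the acquisition.
    """
    post = pct.times >= timing.deflation_time - _EPS
    if not post.any():
        raise DataError(f"{pct.muscle}: no frames after cuff deflation")
    seg = pct.restricted_to(post)
    start_candidates = np.flatnonzero(seg.times >= timing.deflation_time + ttp - _EPS)
    start = int(start_candidates[0]) if start_candidates.size else int(seg.times.size - 1)
    below = np.flatnonzero(seg.pct[start:] <= threshold)
    if below.size == 0:
        return None, False
    j = start + int(below[0])
    if j == start:
        t_cross = float(seg.times[j])
    else:
        p0, p1 = float(seg.pct[j - 1]), float(seg.pct[j])
        t0, t1 = float(seg.times[j - 1]), float(seg.times[j])
        t_cross = t0 + (t1 - t0) * (p0 - threshold) / (p0 - p1)
    return t_cross - timing.deflation_time, True


def compute_indices(
    pct: NormalizedTimeCourse,
    timing: ProtocolTiming,
    window_s: float = 3.0,
    smooth_miv: bool = True,
    recovery_threshold: float = 0.0,
) -> BoldIndices:
    """All four indices for one normalized time course.

    Composes :func:`compute_phv_ttp`, :func:`compute_miv` and
    :func:`compute_ttr`; errors from the components propagate.
    """
    phv, ttp = compute_phv_ttp(pct, timing, window_s=window_s)
    miv = compute_miv(pct, timing, window_s=window_s if smooth_miv else 0.0)
    ttr, recovered = compute_ttr(pct, timing, ttp, threshold=recovery_threshold)
    return BoldIndices(
        phv=phv, ttp=ttp, miv=miv, ttr=ttr, recovered=recovered, muscle=pct.muscle
    )
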