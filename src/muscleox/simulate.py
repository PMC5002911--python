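"""Ground-truthed synthetic data: ideal response curves, 4-D calf phantoms,
and study-shaped cohorts.

The generative curve is piecewise and continuous: zero at rest, a
saturating exponential decline toward the minimum ischemic value during
cuff occlusion, a half-cosine rise from the value at deflation to the peak
hyperemic value over the time-to-peak, and a half-cosine decay back to
baseline at the time-to-recovery.  Half-cosines place the peak at TTP and
the zero crossing at TTR exactly, so every truth parameter is recoverable
from the noise-free curve by definition.  Frame noise is white Gaussian in
percent units (an acknowledged simplification of physiologic BOLD noise).

The 4-D phantom paints four non-overlapping elliptic muscle regions on a
calf-like disc, modulates each region's baseline intensity by its muscle
curve, and adds per-voxel Gaussian background noise; it returns a
coregistered series + label map + truth table so the whole extraction
pipeline can be validated end to end.

Cohort simulation draws per-subject truth parameters from group-level
truncated-normal distributions, adds within-subject visit-to-visit
variation (controls are imaged twice), couples jump distances to the
gastrocnemius PHV truth at a configurable correlation, and then runs each
subject's curves through the actual estimation pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import GROUPS, PARAMETERS, SubjectRecord
from .errors import DataError
from .indices import BoldIndices, compute_indices
from .io import MUSCLES, BoldSeries, VoiLabelMap
from .timecourse import NormalizedTimeCourse, ProtocolTiming


@dataclass(frozen=True)
class CurveTruth:
    """Generative parameters of one muscle's response curve.

    ``tau_isch`` is the ischemic time constant; ``None`` means one fifth of
    the occlusion duration, which brings the ischemic plateau to > 99 % of
    ``miv`` by deflation.  ``noise_sd`` is per-frame white Gaussian noise in
    percent; ``drift`` a linear trend in %/min.
    """

    phv: float  # %
    ttp: float  # s after deflation
    miv: float  # %
    ttr: float  # s after deflation
    tau_isch: float | None = None
    noise_sd: float = 0.0
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.phv > 0 > self.miv):
            raise DataError(f"need phv > 0 > miv, got phv={self.phv}, miv={self.miv}")
        if not (0 < self.ttp < self.ttr):
            raise DataError(f"need 0 < ttp < ttr, got ttp={self.ttp}, ttr={self.ttr}")
        if self.tau_isch is not None and not self.tau_isch > 0:
            raise DataError(f"tau_isch must be positive, got {self.tau_isch}")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")


def _tau(truth: CurveTruth, timing: ProtocolTiming) -> float:
    return truth.tau_isch or (timing.deflation_time - timing.occlusion_start) / 5.0


def ideal_curve(truth: CurveTruth, timing: ProtocolTiming, t):
    """Noise-free percent-change value(s) at time(s) ``t`` (seconds).

    Continuous everywhere; raises for ``t`` outside the acquisition or a
    recovery time beyond the hyperemia phase.
    """
    t_arr = np.asarray(t, dtype=float)
    if (t_arr < timing.baseline_start - 1e-9).any() or (t_arr > timing.end_time + 1e-9).any():
        raise DataError(
            f"t outside [{timing.baseline_start}, {timing.end_time}] s"
        )
    if timing.deflation_time + truth.ttr > timing.end_time + 1e-9:
        raise DataError(
            f"ttr={truth.ttr} s extends past the end of the hyperemia phase "
            f"({timing.end_time - timing.deflation_time} s)"
        )
    tau = _tau(truth, timing)
    occ, defl = timing.occlusion_start, timing.deflation_time
    v_defl = truth.miv * (1.0 - math.exp(-(defl - occ) / tau))
    out = np.zeros_like(t_arr)
    m = (t_arr >= occ) & (t_arr < defl)
    out[m] = truth.miv * (1.0 - np.exp(-(t_arr[m] - occ) / tau))
    m = (t_arr >= defl) & (t_arr < defl + truth.ttp)
    out[m] = v_defl + (truth.phv - v_defl) * 0.5 * (
        1.0 - np.cos(np.pi * (t_arr[m] - defl) / truth.ttp)
    )
    m = (t_arr >= defl + truth.ttp) & (t_arr < defl + truth.ttr)
    out[m] = truth.phv * 0.5 * (
        1.0 + np.cos(np.pi * (t_arr[m] - defl - truth.ttp) / (truth.ttr - truth.ttp))
    )
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def simulate_timecourse(
    truth: CurveTruth,
    timing: ProtocolTiming = ProtocolTiming(),
    rng: np.random.Generator | None = None,
    muscle: str = "synthetic",
) -> tuple[NormalizedTimeCourse, CurveTruth]:
    """Sample the ideal curve at frame centers, add noise and drift.

    Deterministic for a fixed ``truth.seed`` (or a caller-supplied ``rng``).
    ``baseline_si`` of the returned course is a nominal 100 scanner units.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    times = timing.frame_centers()
    pct = ideal_curve(truth, timing, times)
    if truth.drift != 0.0:
        pct = pct + truth.drift * (times - times[0]) / 60.0
    if truth.noise_sd > 0:
        pct = pct + rng.normal(0.0, truth.noise_sd, size=times.size)
    ntc = NormalizedTimeCourse(
        muscle=muscle, times=times, pct=pct, baseline_si=100.0, baseline_sd=truth.noise_sd
    )
    return ntc, truth


# --- 4-D phantom ----------------------------------------------------------

#: Elliptic muscle regions in mm relative to the calf center:
#: (center_x, center_y, semi_axis_x, semi_axis_y).
MUSCLE_GEOMETRY_MM: dict[str, tuple[float, float, float, float]] = {
    "gastrocnemius": (0.0, 25.0, 16.0, 12.0),
    "soleus": (0.0, -25.0, 16.0, 12.0),
    "anterior_tibialis": (-25.0, 0.0, 16.0, 12.0),
    "peroneus_longus": (25.0, 0.0, 16.0, 12.0),
}

_CALF_SEMI_AXES_MM = (55.0, 55.0)


def default_muscle_truths() -> dict[str, CurveTruth]:
    """Default per-muscle truths: typical resting-subject index magnitudes."""
    return {
        "gastrocnemius": CurveTruth(phv=7.4, ttp=28.5, miv=-13.3, ttr=129.4),
        "soleus": CurveTruth(phv=12.9, ttp=21.0, miv=-12.4, ttr=134.1),
        "anterior_tibialis": CurveTruth(phv=7.7, ttp=26.3, miv=-7.5, ttr=136.5),
        "peroneus_longus": CurveTruth(phv=9.2, ttp=25.1, miv=-9.4, ttr=140.6),
    }


@dataclass
class PhantomSpec:
    """Geometry and generative parameters of a digital calf phantom.

    Defaults emulate the acquisition this pipeline targets: 128 x 64
    in-plane matrix over a 360 x 180 mm field of view (2.8125 mm in-plane),
    six 5-mm slices, 300 frames at TR = 3 s.
    """

    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    shape: tuple[int, int, int] = (128, 64, 6)
    voxel_size: tuple[float, float, float] = (2.8125, 2.8125, 5.0)
    s0_muscle: float = 480.0  # baseline intensity of muscle tissue, scanner units
    s0_tissue: float = 320.0  # non-muscle calf tissue
    truths: dict[str, CurveTruth] = field(default_factory=default_muscle_truths)
    noise_sd: float = 0.0  # per-voxel Gaussian background noise, scanner units
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.shape) < 1:
            raise DataError(f"phantom dims must be positive, got {self.shape}")
        if self.s0_muscle <= 0 or self.s0_tissue <= 0:
            raise DataError("baseline intensities must be positive")
        if self.noise_sd < 0:
            raise DataError("noise_sd must be >= 0")
        unknown = set(self.truths) - set(MUSCLE_GEOMETRY_MM)
        if unknown:
            raise DataError(f"no geometry for muscles {sorted(unknown)}")


def _ellipse_mask(spec: PhantomSpec, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    nx, ny, _ = spec.shape
    vx, vy, _ = spec.voxel_size
    x = (np.arange(nx) - (nx - 1) / 2.0) * vx
    y = (np.arange(ny) - (ny - 1) / 2.0) * vy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    return ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0


def simulate_phantom(
    spec: PhantomSpec = None,
) -> tuple[BoldSeries, VoiLabelMap, pd.DataFrame]:
    """Build a coregistered (series, label map, truth table) triple.

    Every voxel of a muscle region follows that muscle's (possibly noisy)
    curve coherently, scaled by ``s0_muscle``; non-muscle calf tissue is
    constant ``s0_tissue``; everything sits on independent per-voxel
    Gaussian background noise of SD ``noise_sd``.
    """
    if spec is None:
        spec = PhantomSpec()
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    nt = spec.timing.n_frames

    calf2d = _ellipse_mask(spec, 0.0, 0.0, *_CALF_SEMI_AXES_MM)
    muscles = [m for m in MUSCLES if m in spec.truths] or sorted(spec.truths)
    masks2d = {m: _ellipse_mask(spec, *MUSCLE_GEOMETRY_MM[m]) for m in muscles}
    stacked = np.stack(list(masks2d.values()), axis=0)
    if (stacked.sum(axis=0) > 1).any():
        raise DataError("muscle regions overlap for this spec")

    labels = np.zeros(spec.shape, dtype=np.int16)
    legend = {}
    for i, m in enumerate(muscles, start=1):
        labels[masks2d[m][:, :, None] & np.ones(nz, bool)] = i
        legend[i] = m

    data = np.zeros((nx, ny, nz, nt), dtype=np.float32)
    if spec.noise_sd > 0:
        data += rng.standard_normal(data.shape, dtype=np.float32) * np.float32(spec.noise_sd)
    tissue = calf2d[:, :, None] & (labels == 0)
    data[tissue] += np.float32(spec.s0_tissue)

    rows = []
    for i, m in enumerate(muscles, start=1):
        ntc, truth = simulate_timecourse(spec.truths[m], spec.timing, rng=rng, muscle=m)
        signal = (spec.s0_muscle * (1.0 + ntc.pct / 100.0)).astype(np.float32)
        data[labels == i] += signal[None, :]
        rows.append(
            {
                "muscle": m,
                "label": i,
                "n_voxels": int((labels == i).sum()),
                "phv_true": truth.phv,
                "ttp_true": truth.ttp,
                "miv_true": truth.miv,
                "ttr_true": truth.ttr,
                "tau_isch": _tau(truth, spec.timing),
                "noise_sd_pct": truth.noise_sd,
            }
        )

    series = BoldSeries(voxels=data, voxel_size=spec.voxel_size, tr=spec.timing.tr)
    mask = VoiLabelMap(labels=labels, legend=legend, voxel_size=spec.voxel_size)
    return series, mask, pd.DataFrame(rows)


# --- cohort ---------------------------------------------------------------

#: Admissible truth ranges used to truncate population sampling, per
#: parameter (physiologically plausible bounds for this paradigm).
ADMISSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "phv": (0.5, 60.0),
    "miv": (-40.0, -0.5),
    "ttp": (6.0, 120.0),
    "ttr": (15.0, 294.0),
}


def default_cohort_moments() -> dict[tuple[str, str, str], tuple[float, float]]:
    """Population (mean, SD) per (group, muscle, parameter).

    PHV differs by training status (athletes above sedentary controls);
    the ischemic depth and the two timing parameters are common across
    groups, reflecting a cohort in which only the hyperemic peak separates
    trained and untrained subjects.
    """
    phv = {
        "gastrocnemius": {"linemen": (15.8, 9.1), "backs_receivers": (17.9, 5.1), "controls": (7.4, 3.5)},
        "soleus": {"linemen": (25.9, 11.5), "backs_receivers": (22.0, 9.4), "controls": (12.9, 5.8)},
        "anterior_tibialis": {"linemen": (12.8, 5.3), "backs_receivers": (12.6, 3.9), "controls": (7.7, 4.0)},
        "peroneus_longus": {"linemen": (14.1, 6.9), "backs_receivers": (11.7, 4.6), "controls": (9.0, 4.9)},
    }
    shared = {
        "gastrocnemius": {"miv": (-13.3, 4.3), "ttp": (28.5, 5.6), "ttr": (129.4, 28.5)},
        "soleus": {"miv": (-12.4, 6.4), "ttp": (21.0, 2.8), "ttr": (134.1, 21.5)},
        "anterior_tibialis": {"miv": (-7.5, 3.4), "ttp": (26.3, 5.0), "ttr": (136.5, 40.2)},
        "peroneus_longus": {"miv": (-9.4, 5.5), "ttp": (25.1, 6.6), "ttr": (140.6, 48.4)},
    }
    moments = {}
    for muscle in MUSCLES:
        for group in GROUPS:
            moments[(group, muscle, "phv")] = phv[muscle][group]
            for param in ("miv", "ttp", "ttr"):
                moments[(group, muscle, param)] = shared[muscle][param]
    return moments


def default_jump_moments() -> dict[str, dict[str, tuple[float, float]]]:
    """Maximal jump (mean, SD) in cm per group and measure."""
    return {
        "linemen": {"vertical": (56.6, 6.5), "broad": (239.3, 12.8)},
        "backs_receivers": {"vertical": (72.8, 5.1), "broad": (273.2, 12.3)},
        "controls": {"vertical": (50.7, 8.1), "broad": (201.6, 32.3)},
    }


@dataclass
class CohortSpec:
    """Generative description of a simulated study cohort.

    ``within_subject_frac`` scales the population SD to obtain the
    visit-to-visit within-subject SD; ``rho_vertical``/``rho_broad`` couple
    the jump distances to the gastrocnemius PHV truth within each group.
    With ``simulate_curves`` each subject's indices are *estimated* by
    running a noisy simulated curve through the extraction pipeline;
    otherwise the per-visit truth parameters are recorded directly
    (index-level mode for large Monte-Carlo designs).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {"linemen": 12, "backs_receivers": 11, "controls": 10}
    )
    muscles: tuple[str, ...] = MUSCLES
    moments: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=default_cohort_moments
    )
    jump_moments: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_jump_moments
    )
    rho_vertical: float = 0.56
    rho_broad: float = 0.47
    within_subject_frac: float = 0.3
    control_visits: int = 2
    noise_sd: float = 1.0  # per-frame curve noise, % units
    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    simulate_curves: bool = True
    window_s: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise DataError(f"unknown group {g!r}")
            if n < 2:
                raise DataError(f"group {g!r} size must be >= 2, got {n}")
        for rho in (self.rho_vertical, self.rho_broad):
            if abs(rho) > 1:
                raise DataError(f"|rho| must be <= 1, got {rho}")
        if self.within_subject_frac < 0 or self.noise_sd < 0:
            raise DataError("SD scales must be >= 0")
        if self.control_visits not in (1, 2):
            raise DataError("control_visits must be 1 or 2")


def _truncnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    if sd == 0:
        if not lo <= mean <= hi:
            raise DataError(f"degenerate draw at {mean} outside [{lo}, {hi}]")
        return mean
    a, b = (lo - mean) / sd, (hi - mean) / sd
    if a >= b:
        raise DataError(f"empty admissible region [{lo}, {hi}] for mean={mean}, sd={sd}")
    return float(sps.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def _visit_params(
    rng: np.random.Generator,
    subject_truth: dict[str, float],
    within_sd: dict[str, float],
    max_ttr: float,
) -> dict[str, float]:
    out = {}
    for param in PARAMETERS:
        lo, hi = ADMISSIBLE_RANGES[param]
        v = subject_truth[param] + (
            rng.normal(0.0, within_sd[param]) if within_sd[param] > 0 else 0.0
        )
        out[param] = min(max(v, lo), hi)
    out["ttr"] = min(max(out["ttr"], out["ttp"] + 6.0), max_ttr)
    return out


def simulate_cohort(spec: CohortSpec = None, rng: np.random.Generator | None = None) -> list[SubjectRecord]:
    """Draw a full study cohort; deterministic per ``spec.seed``.

    Controls get ``spec.control_visits`` visits sharing the subject truth
    plus within-subject variation; athletes one visit.  Jump distances are
    correlated with the gastrocnemius PHV truth at the requested rho.
    """
    if spec is None:
        spec = CohortSpec()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    max_ttr = spec.timing.end_time - spec.timing.deflation_time - 2 * spec.timing.tr
    records: list[SubjectRecord] = []
    for group in GROUPS:
        n = spec.group_sizes.get(group, 0)
        for k in range(n):
            sid = f"{group}_{k + 1:02d}"
            truth: dict[str, dict[str, float]] = {}
            within: dict[str, dict[str, float]] = {}
            for muscle in spec.muscles:
                t, w = {}, {}
                for param in PARAMETERS:
                    mean, sd = spec.moments[(group, muscle, param)]
                    lo, hi = ADMISSIBLE_RANGES[param]
                    t[param] = _truncnorm(rng, mean, sd, lo, hi)
                    w[param] = spec.within_subject_frac * sd
                t["ttr"] = min(max(t["ttr"], t["ttp"] + 6.0), max_ttr)
                truth[muscle], within[muscle] = t, w

            jumps: dict[str, float | None] = {"vertical": None, "broad": None}
            if "gastrocnemius" in spec.muscles:
                g_mean, g_sd = spec.moments[(group, "gastrocnemius", "phv")]
                z = (truth["gastrocnemius"]["phv"] - g_mean) / g_sd if g_sd > 0 else 0.0
                for measure, rho in (("vertical", spec.rho_vertical), ("broad", spec.rho_broad)):
                    j_mean, j_sd = spec.jump_moments[group][measure]
                    zj = rho * z + math.sqrt(max(0.0, 1 - rho**2)) * rng.standard_normal()
                    jumps[measure] = j_mean + j_sd * zj

            visits = range(1, (spec.control_visits if group == "controls" else 1) + 1)
            for visit in visits:
                indices: dict[str, BoldIndices] = {}
                for muscle in spec.muscles:
                    params = _visit_params(rng, truth[muscle], within[muscle], max_ttr)
                    if spec.simulate_curves:
                        ct = CurveTruth(
                            phv=params["phv"],
                            ttp=params["ttp"],
                            miv=params["miv"],
                            ttr=params["ttr"],
                            noise_sd=spec.noise_sd,
                        )
                        ntc, _ = simulate_timecourse(ct, spec.timing, rng=rng, muscle=muscle)
                        indices[muscle] = compute_indices(
                            ntc, spec.timing, window_s=spec.window_s
                        )
                    else:
                        indices[muscle] = BoldIndices(
                            phv=params["phv"],
                            ttp=params["ttp"],
                            miv=params["miv"],
                            ttr=params["ttr"],
                            recovered=True,
                            muscle=muscle,
                        )
                records.append(
                    SubjectRecord(
                        subject_id=sid,
                        group=group,
                        visit=visit,
                        indices=indices,
                        vertical_jump=jumps["vertical"],
                        broad_jump=jumps["broad"],
                    )
                )
    return records
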