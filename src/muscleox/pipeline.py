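"""End-to-end orchestration: subject-level index tables and cohort-level
statistics, with deterministic CSV/JSON outputs.

Display CSVs round indices and CVs to one decimal, correlations to two and
p-values to three; a parallel JSON keeps full precision together with the
run configuration, its hash and the seed, so any run can be reproduced from
the JSON alone.  Nothing is written unless the whole computation succeeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    PARAMETERS,
    group_muscle_anova,
    jump_correlation,
    records_from_frame,
    repeatability_table,
)
from .errors import ConfigError, DataError, StatsError
from .indices import compute_indices
from .io import read_bold_series, read_legend, read_voi_labels, validate_alignment
from .timecourse import ProtocolTiming, extract_voi_timecourse, percent_change_normalize

log = logging.getLogger("muscleox")

REPEATABILITY_COLUMNS = [
    "muscle", "parameter",
    "visit1_mean", "visit1_sd", "visit1_cv",
    "visit2_mean", "visit2_sd", "visit2_cv",
    "paired_p", "n_pairs",
]


@dataclass
class RunConfig:
    """Paths, protocol timing and analysis options for one run."""

    series_path: str | None = None
    mask_path: str | None = None
    legend_path: str | None = None
    subject_table: str | None = None
    output_dir: str = "."
    timing: ProtocolTiming = field(default_factory=ProtocolTiming)
    window_s: float = 3.0
    smooth_miv: bool = True
    recovery_threshold: float = 0.0
    detrend_baseline: bool = False
    alpha: float = 0.05
    posthoc: str = "tukey"
    paired_method: str = "ttest"
    exclusions: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.posthoc not in ("tukey", "bonferroni"):
            raise ConfigError(f"posthoc must be 'tukey' or 'bonferroni', got {self.posthoc!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        timing = ProtocolTiming(**raw.pop("timing", {}))
        try:
            return cls(timing=timing, **raw)
        except TypeError as exc:
            raise ConfigError(f"bad config key: {exc}") from exc

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def require(self, *names: str) -> None:
        """Check that the named paths are set and exist, before any computation."""
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config is missing required path {name!r}")
            if not Path(value).exists():
                raise ConfigError(f"{name} does not exist: {value}")


def _provenance(config: RunConfig) -> dict:
    return {
        "package": "muscleox",
        "version": __version__,
        "config": config.as_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }


def run_subject(config: RunConfig, write: bool = True) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze one subject: per-muscle BOLD indices plus time-course data.

    Returns ``(indices_df, timecourse_df)`` and, when ``write`` is set,
    deposits ``indices.csv`` (1-decimal display), ``indices.json`` (full
    precision + provenance) and ``timecourses.csv`` in the output directory.
    Outputs are deterministic given the inputs; nothing is written if any
    muscle fails.
    """
    config.require("series_path", "mask_path", "legend_path")
    series = read_bold_series(config.series_path)
    if abs(series.tr - config.timing.tr) > 1e-6:
        raise DataError(
            f"series TR {series.tr} s disagrees with protocol TR {config.timing.tr} s"
        )
    legend = read_legend(config.legend_path)
    mask = read_voi_labels(config.mask_path, legend)
    validate_alignment(series, mask)
    log.info("run_subject config=%s seed=%d", config.config_hash(), config.seed)

    muscles = [legend[k] for k in sorted(legend) if legend[k] != "other"]
    idx_rows, tc_rows = [], []
    for muscle in muscles:
        raw = extract_voi_timecourse(series, mask, muscle)
        ntc = percent_change_normalize(raw, config.timing, detrend_baseline=config.detrend_baseline)
        idx = compute_indices(
            ntc,
            config.timing,
            window_s=config.window_s,
            smooth_miv=config.smooth_miv,
            recovery_threshold=config.recovery_threshold,
        )
        idx_rows.append(
            {
                "muscle": muscle,
                "phv": idx.phv,
                "ttp": idx.ttp,
                "miv": idx.miv,
                "ttr": idx.ttr,
                "recovered": idx.recovered,
                "n_voxels": raw.n_voxels,
                "baseline_si": ntc.baseline_si,
                "baseline_sd": ntc.baseline_sd,
            }
        )
        for t, si, pct in zip(raw.times, raw.si, ntc.pct):
            tc_rows.append({"muscle": muscle, "time_s": t, "si": si, "pct": pct})
    indices_df = pd.DataFrame(idx_rows)
    timecourse_df = pd.DataFrame(tc_rows)

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        display = indices_df.copy()
        for col in ("phv", "ttp", "miv", "ttr", "baseline_si", "baseline_sd"):
            display[col] = display[col].round(1)
        display.to_csv(out / "indices.csv", index=False)
        timecourse_df.to_csv(out / "timecourses.csv", index=False)
        payload = {
            "provenance": _provenance(config),
            "indices": indices_df.to_dict(orient="records"),
        }
        (out / "indices.json").write_text(json.dumps(payload, indent=2, default=float) + "\n")
        if config.make_plots:
            _plot_timecourses(timecourse_df, config.timing, out / "timecourses.png")
    return indices_df, timecourse_df


def _plot_timecourses(tc: pd.DataFrame, timing: ProtocolTiming, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for muscle, sub in tc.groupby("muscle"):
        ax.plot(sub["time_s"], sub["pct"], label=muscle, lw=1)
    for t, lbl in ((timing.occlusion_start, "cuff inflation"), (timing.deflation_time, "cuff deflation")):
        ax.axvline(t, color="k", ls="--", lw=0.8)
        ax.annotate(lbl, (t, ax.get_ylim()[1]), fontsize=8, rotation=90, va="top")
    ax.axhline(0, color="gray", lw=0.5)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("BOLD signal change (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def repeatability_frame(results) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(r) for r in results], columns=REPEATABILITY_COLUMNS)


def group_stats_frame(results) -> pd.DataFrame:
    rows = []
    for res in results:
        for cell, s in res.cells.items():
            rows.append(
                {
                    "factor": res.factor,
                    "stratum": res.stratum,
                    "parameter": res.parameter,
                    "cell": cell,
                    "n": s.n,
                    "mean": s.mean,
                    "sd": s.sd,
                    "normality_p": s.normality_p,
                    "anova_f": res.anova_f,
                    "anova_p": res.anova_p,
                    "posthoc_p": float("nan"),
                }
            )
        if res.posthoc:
            for (a, b), p in res.posthoc.items():
                rows.append(
                    {
                        "factor": res.factor,
                        "stratum": res.stratum,
                        "parameter": res.parameter,
                        "cell": f"{a} vs {b}",
                        "n": float("nan"),
                        "mean": float("nan"),
                        "sd": float("nan"),
                        "normality_p": float("nan"),
                        "anova_f": res.anova_f,
                        "anova_p": res.anova_p,
                        "posthoc_p": p,
                    }
                )
    return pd.DataFrame(rows)


def run_cohort(config: RunConfig, write: bool = True) -> dict[str, pd.DataFrame]:
    """Cohort statistics from a per-subject index table (CSV).

    Emits a repeatability table (when controls have two visits), group and
    muscle comparisons per parameter (when more than one group/muscle is
    present), and PHV-vs-jump correlations; components that are not
    assessable on the given table are skipped with a logged notice rather
    than failing the run.
    """
    config.require("subject_table")
    df = pd.read_csv(config.subject_table)
    records = records_from_frame(df, exclusions=config.exclusions)
    log.info("run_cohort config=%s seed=%d n_records=%d", config.config_hash(), config.seed, len(records))
    results: dict[str, pd.DataFrame] = {}

    try:
        rep = repeatability_table(records, paired_method=config.paired_method)
        results["repeatability"] = repeatability_frame(rep)
    except StatsError as exc:
        log.warning("repeatability skipped: %s", exc)

    anova_frames = []
    for param in PARAMETERS:
        try:
            anova_frames.append(group_stats_frame(
                group_muscle_anova(records, param, alpha=config.alpha, posthoc=config.posthoc)
            ))
        except StatsError as exc:
            log.warning("ANOVA for %s skipped: %s", param, exc)
    if anova_frames:
        results["group_stats"] = pd.concat(anova_frames, ignore_index=True)

    corr_rows = []
    muscles = sorted({m for r in records for m in r.indices})
    for muscle in muscles:
        for measure in ("vertical", "broad"):
            try:
                c = jump_correlation(records, muscle, measure)
                corr_rows.append(dataclasses.asdict(c))
            except StatsError as exc:
                log.warning("correlation %s/%s skipped: %s", muscle, measure, exc)
    if corr_rows:
        results["correlations"] = pd.DataFrame(corr_rows)

    if write:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if "repeatability" in results:
            disp = results["repeatability"].copy()
            for col in disp.columns:
                if col.startswith("visit"):
                    disp[col] = disp[col].round(1)
            disp["paired_p"] = disp["paired_p"].round(3)
            disp.to_csv(out / "repeatability.csv", index=False)
        if "group_stats" in results:
            disp = results["group_stats"].copy()
            for col in ("mean", "sd"):
                disp[col] = disp[col].round(1)
            for col in ("normality_p", "anova_p", "posthoc_p"):
                disp[col] = disp[col].round(3)
            disp["anova_f"] = disp["anova_f"].round(2)
            disp.to_csv(out / "group_stats.csv", index=False)
        if "correlations" in results:
            disp = results["correlations"].copy()
            disp["r"] = disp["r"].round(2)
            disp["p"] = disp["p"].round(3)
            disp.to_csv(out / "correlations.csv", index=False)
        payload = {"provenance": _provenance(config)}
        for name, frame in results.items():
            payload[name] = frame.to_dict(orient="records")
        (out / "cohort_results.json").write_text(
            json.dumps(payload, indent=2, default=_jsonable) + "\n"
        )
    return results


def _jsonable(obj):
    if isinstance(obj, float):
        return obj
    return str(obj)
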