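"""Wheel-running actigraphy: ingest, actograms, and episode detection.

Long-term wheel-running records from nocturnal rodents are screened for two
kinds of spontaneous mood-episode-like events:

* **hyperactivity bouts (HABs)** — mania-like periods of at least 6 h in
  which running is an outlier relative to the animal's own activity
  distribution, often spilling into the light (rest) phase;
* **depression-like episodes (DEs)** — spans of at least 14 consecutive days
  in which daily running falls well below the animal's baseline, typically
  with a circadian phase delay (running persisting into the morning light
  phase, quantified by the *delayed activity index*).

Both detectors are quantile-based and therefore invariant to rescaling the
counts by a positive constant.  Time is handled in Zeitgeber time (ZT): ZT0
is lights-on and also the day boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .stats import (
    DegenerateDataError,
    TestResult,
    mann_whitney_u,
    wilcoxon_signed_rank,
)

__all__ = [
    "ActivitySeries",
    "EpisodeCall",
    "DailySummary",
    "HabParams",
    "DeParams",
    "read_activity_csv",
    "write_activity_csv",
    "daily_summaries",
    "build_double_plotted_actogram",
    "detect_habs",
    "detect_hypoactivity_episodes",
    "delayed_activity_index",
    "episode_frequency",
    "compare_groups",
]

DAYS_PER_SIX_MONTHS = 183  # normalization used for episode frequencies


@dataclass
class ActivitySeries:
    """One animal's binned wheel-revolution counts.

    ``counts`` is a float vector (revolutions per bin) with NaN marking
    missing bins.  By convention bin 0 starts at ZT0 (lights-on); the light
    phase covers ZT0..light_hours.
    """

    subject_id: str
    counts: np.ndarray
    bin_minutes: int = 6
    sex: str = "unknown"
    genotype: str = "unknown"
    diet: str = "unknown"
    light_hours: float = 12.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if 1440 % self.bin_minutes != 0:
            raise ValueError("bin_minutes must divide 1440")
        valid = self.counts[~np.isnan(self.counts)]
        if (valid < 0).any():
            raise ValueError("counts must be nonnegative")
        if not 0 < self.light_hours < 24:
            raise ValueError("light phase duration must lie in (0, 24) hours")

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.bin_minutes

    @property
    def bins_per_hour(self) -> float:
        return 60.0 / self.bin_minutes

    @property
    def n_days(self) -> int:
        return len(self.counts) // self.bins_per_day

    def zt_hours(self) -> np.ndarray:
        """ZT hour of each bin start."""
        return (np.arange(len(self.counts)) * self.bin_minutes / 60.0) % 24.0

    def is_light(self) -> np.ndarray:
        return self.zt_hours() < self.light_hours

    def whole_days(self) -> "ActivitySeries":
        """Trim trailing bins so the series spans whole days."""
        n = self.n_days * self.bins_per_day
        if n == len(self.counts):
            return self
        warnings.warn(
            f"{self.subject_id}: trimming {len(self.counts) - n} trailing bins "
            "to whole days",
            stacklevel=2,
        )
        return replace(self, counts=self.counts[:n].copy())


@dataclass(frozen=True)
class EpisodeCall:
    """A detected episode, half-open in bins for HABs and days for DEs."""

    kind: str  # "HAB" or "DEPRESSION_LIKE"
    start_bin: int
    end_bin: int
    duration_hours: float
    score: float

    @property
    def duration_days(self) -> float:
        return self.duration_hours / 24.0


@dataclass(frozen=True)
class DailySummary:
    day_index: int
    total_counts: float
    light_phase_counts: float
    dark_phase_counts: float
    delayed_activity: float  # morning-light fraction; NaN if day total is 0


@dataclass
class HabParams:
    """Hyperactivity-bout detector parameters.

    Activity is summed in rolling windows of ``window_hours``; a window is
    flagged when its sum exceeds the animal's own Tukey fence
    (Q3 + fence_k * IQR of all callable window sums).  Maximal runs of
    flagged windows, merged across gaps of at most ``merge_gap_hours``, are
    episodes if the union of their bins spans at least ``min_duration_hours``
    (closed bound: exactly 6 h qualifies).
    """

    window_hours: float = 1.0
    fence_k: float = 1.5
    merge_gap_hours: float = 1.0
    min_duration_hours: float = 6.0
    max_missing_frac: float = 0.2


@dataclass
class DeParams:
    """Depression-like episode detector parameters.

    Daily totals are smoothed with a ``smooth_days``-point centered moving
    average; days below (1 - delta) times the baseline (median smoothed daily
    total, re-estimated once excluding candidate episode days) are flagged,
    and runs of at least ``min_duration_days`` consecutive flagged days are
    episodes.
    """

    delta: float = 0.3
    smooth_days: int = 3
    min_duration_days: int = 14


# ---------------------------------------------------------------------------
# I/O


def write_activity_csv(series: ActivitySeries, path) -> None:
    """Write counts CSV plus a YAML metadata sidecar (<path>.meta.yaml)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "subject_id": series.subject_id,
            "bin_index": np.arange(len(series.counts)),
            "counts": series.counts,
        }
    )
    df.to_csv(path, index=False)
    meta = {
        "subject_id": series.subject_id,
        "bin_minutes": int(series.bin_minutes),
        "sex": series.sex,
        "genotype": series.genotype,
        "diet": series.diet,
        "light_hours": float(series.light_hours),
    }
    with open(str(path) + ".meta.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)


def read_activity_csv(path, meta_path=None) -> ActivitySeries:
    """Read a counts CSV (columns subject_id, bin_index, counts) and its
    metadata sidecar.  Gaps in bin_index become NaN (missing), never zero."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else Path(str(path) + ".meta.yaml")
    df = pd.read_csv(path)
    required = {"subject_id", "bin_index", "counts"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    idx = df["bin_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        row = int(np.argmax(np.diff(idx) <= 0)) + 1
        raise ValueError(f"{path}: non-monotone bin_index at row {row}")
    neg = df.index[df["counts"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative count at row {int(neg[0])}")
    counts = np.full(int(idx[-1]) + 1, np.nan)
    counts[idx.astype(int)] = df["counts"].to_numpy(dtype=float)
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    return ActivitySeries(
        subject_id=str(meta.get("subject_id", df["subject_id"].iloc[0])),
        counts=counts,
        bin_minutes=int(meta.get("bin_minutes", 6)),
        sex=str(meta.get("sex", "unknown")),
        genotype=str(meta.get("genotype", "unknown")),
        diet=str(meta.get("diet", "unknown")),
        light_hours=float(meta.get("light_hours", 12.0)),
    )


# ---------------------------------------------------------------------------
# summaries and actograms


def daily_summaries(series: ActivitySeries, morning_hours: float = 6.0) -> list[DailySummary]:
    """Per-day totals, light/dark split, and the per-day delayed-activity
    fraction (activity in ZT0..morning_hours over the day total)."""
    s = series.whole_days()
    bpd = s.bins_per_day
    counts = np.nan_to_num(s.counts, nan=0.0).reshape(s.n_days, bpd)
    light = s.is_light()[:bpd]
    morning = s.zt_hours()[:bpd] < morning_hours
    out = []
    for d in range(s.n_days):
        total = counts[d].sum()
        lp = counts[d][light].sum()
        da = counts[d][morning].sum() / total if total > 0 else float("nan")
        out.append(
            DailySummary(
                day_index=d,
                total_counts=float(total),
                light_phase_counts=float(lp),
                dark_phase_counts=float(total - lp),
                delayed_activity=float(da),
            )
        )
    return out


def build_double_plotted_actogram(series: ActivitySeries) -> np.ndarray:
    """Days x (2 * bins/day) matrix: row *i* is day *i* followed by day *i+1*
    (the standard double plot); the final row pads the absent day with NaN."""
    s = series.whole_days()
    if s.n_days < 2:
        raise ValueError("double-plotted actogram needs at least 2 whole days")
    bpd = s.bins_per_day
    days = s.counts[: s.n_days * bpd].reshape(s.n_days, bpd)
    right = np.vstack([days[1:], np.full((1, bpd), np.nan)])
    return np.hstack([days, right])


# ---------------------------------------------------------------------------
# hyperactivity bouts


def _rolling_window_sums(counts: np.ndarray, w: int, max_missing_frac: float):
    """Sums of each length-w window (NaN treated as 0) plus a callability
    mask: windows with more than ``max_missing_frac`` missing bins are
    excluded from both the reference distribution and flagging."""
    filled = np.nan_to_num(counts, nan=0.0)
    kernel = np.ones(w)
    sums = np.convolve(filled, kernel, mode="valid")
    miss = np.convolve(np.isnan(counts).astype(float), kernel, mode="valid")
    callable_mask = miss / w <= max_missing_frac
    return sums, callable_mask


def _flagged_runs(flags: np.ndarray, max_gap: int):
    """Maximal runs of True, merging runs separated by <= max_gap False."""
    idx = np.flatnonzero(flags)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[s]), int(idx[e])) for s, e in zip(starts, ends)]


def detect_habs(series: ActivitySeries, params: HabParams | None = None) -> list[EpisodeCall]:
    """Detect hyperactivity bouts against the animal's own outlier fence.

    Requires at least 14 days of recording so that the reference
    distribution of window sums is the animal's, not the episode's.
    """
    params = params or HabParams()
    s = series.whole_days()
    if s.n_days < 14:
        raise ValueError("HAB detection needs >= 14 days of recording")
    valid = s.counts[~np.isnan(s.counts)]
    if valid.size and valid.max() == 0:
        return []
    w = int(round(params.window_hours * s.bins_per_hour))
    if w < 1:
        raise ValueError("window shorter than one bin")
    sums, callable_mask = _rolling_window_sums(s.counts, w, params.max_missing_frac)
    ref = sums[callable_mask]
    if ref.size == 0:
        raise ValueError("no callable windows")
    q1, q3 = np.percentile(ref, [25, 75])
    iqr = q3 - q1
    if iqr <= 0:
        raise DegenerateDataError("reference IQR is zero: outlier fence undefined")
    fence = q3 + params.fence_k * iqr
    flags = (sums > fence) & callable_mask
    max_gap = int(round(params.merge_gap_hours * s.bins_per_hour))
    calls = []
    for run_start, run_end in _flagged_runs(flags, max_gap):
        start_bin = run_start
        end_bin = run_end + w  # union of flagged windows, half-open
        duration_h = (end_bin - start_bin) * s.bin_minutes / 60.0
        if duration_h < params.min_duration_hours:
            continue
        peak = float(sums[run_start : run_end + 1].max())
        calls.append(
            EpisodeCall(
                kind="HAB",
                start_bin=start_bin,
                end_bin=end_bin,
                duration_hours=duration_h,
                score=(peak - fence) / iqr,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# depression-like episodes


def _smooth(daily: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return daily.astype(float)
    pad = k // 2
    padded = np.pad(daily.astype(float), pad, mode="edge")
    return np.convolve(padded, np.ones(k) / k, mode="valid")


def _runs_at_least(flags: np.ndarray, min_len: int):
    runs = _flagged_runs(flags, max_gap=0)
    return [(s, e) for s, e in runs if e - s + 1 >= min_len]


def detect_hypoactivity_episodes(
    series: ActivitySeries, params: DeParams | None = None
) -> list[EpisodeCall]:
    """Detect multi-week hypoactivity (depression-like) episodes.

    Smoothed daily totals below (1 - delta) * baseline for at least 14
    consecutive days constitute an episode; the baseline (median smoothed
    daily total) is re-estimated once excluding initially flagged candidate
    days so long episodes do not drag it down.  Requires >= 8 weeks of data.
    """
    params = params or DeParams()
    s = series.whole_days()
    if s.n_days < 56:
        raise ValueError("hypoactivity detection needs >= 8 weeks of recording")
    daily = np.array([d.total_counts for d in daily_summaries(s)])
    smoothed = _smooth(daily, params.smooth_days)
    baseline = float(np.median(smoothed))
    if baseline <= 0:
        raise DegenerateDataError("baseline median daily activity is zero")
    flags = smoothed < (1.0 - params.delta) * baseline
    candidate_days = np.zeros_like(flags)
    for a, b in _runs_at_least(flags, params.min_duration_days):
        candidate_days[a : b + 1] = True
    if candidate_days.any() and not candidate_days.all():
        baseline = float(np.median(smoothed[~candidate_days]))
        if baseline <= 0:
            raise DegenerateDataError("re-estimated baseline is zero")
        flags = smoothed < (1.0 - params.delta) * baseline
    calls = []
    bpd = s.bins_per_day
    for a, b in _runs_at_least(flags, params.min_duration_days):
        deficit = float(np.mean(1.0 - smoothed[a : b + 1] / baseline))
        calls.append(
            EpisodeCall(
                kind="DEPRESSION_LIKE",
                start_bin=a * bpd,
                end_bin=(b + 1) * bpd,
                duration_hours=(b - a + 1) * 24.0,
                score=deficit,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# circadian disturbance index and frequencies


def delayed_activity_index(
    series: ActivitySeries,
    day_window: tuple[int, int] | None = None,
    morning_hours: float = 6.0,
) -> float:
    """Mean daily fraction of activity falling in the first ``morning_hours``
    of the light phase (ZT0..morning_hours) over ``day_window`` (half-open
    day indices; whole record if None).  NaN (flagged undefined) when every
    day in the window has zero activity."""
    summaries = daily_summaries(series, morning_hours=morning_hours)
    if day_window is not None:
        a, b = day_window
        if not 0 <= a < b <= len(summaries):
            raise ValueError("day_window outside the recording")
        summaries = summaries[a:b]
    vals = np.array([d.delayed_activity for d in summaries])
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return float(vals.mean())


def episode_frequency(calls: list[EpisodeCall], observed_days: float) -> float:
    """Episodes per 6 months (183 observed days)."""
    if observed_days <= 0:
        raise ValueError("observed_days must be positive")
    return len(calls) * DAYS_PER_SIX_MONTHS / observed_days


def compare_groups(values_a, values_b, paired: bool = False) -> TestResult:
    """Group comparison used for episode frequencies and circadian indices:
    Mann-Whitney U between groups, Wilcoxon signed-rank within animals."""
    if paired:
        return wilcoxon_signed_rank(values_a, values_b)
    if len(values_a) < 2 or len(values_b) < 2:
        raise ValueError("need at least 2 animals per group")
    return mann_whitney_u(values_a, values_b)


def plot_actogram(series: ActivitySeries, path) -> None:
    """Save a double-plotted actogram raster as an image (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = build_double_plotted_actogram(series)
    fig, ax = plt.subplots(figsize=(8, max(2, mat.shape[0] * 0.06)))
    ax.imshow(
        np.nan_to_num(mat, nan=0.0),
        aspect="auto",
        cmap="Greys",
        interpolation="nearest",
    )
    ax.set_xlabel("ZT (double-plotted, 48 h)")
    ax.set_ylabel("day")
    ax.set_title(series.subject_id)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
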