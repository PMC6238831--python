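"""Dated wound measurements, healing trajectory, and reminder scheduling.

The clinically meaningful outputs are the ulcer area in cm² (via the fiducial
scale), the ulcer/foot area ratio (scale-free, robust to camera distance),
and the 4-week percent area reduction: a >50% reduction in ulcer area within
the first 4 weeks of care is an established surrogate marker of effective
diabetic-foot-ulcer healing, and the assessment classifies a series as
on-track on that strict threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path

import pandas as pd

from .calibration import ScaleEstimate, px_area_to_cm2
from .config import DEFAULT_CONFIG, PipelineConfig
from .errors import ContainmentViolation, NoAssessmentPoint, ZeroBaseline
from .foot import FootSegmentation
from .ulcer import UlcerSegmentation

CSV_COLUMNS = [
    "date",
    "ulcer_area_px",
    "foot_area_px",
    "pixels_per_cm",
    "ulcer_area_cm2",
    "area_ratio",
]

DEFAULT_REMINDER_MESSAGE = "Time to check your foot"


@dataclass
class WoundMeasurement:
    date: date
    ulcer_area_px: int
    foot_area_px: int
    pixels_per_cm: float
    ulcer_area_cm2: float
    area_ratio: float


@dataclass
class ProgressSeries:
    """Measurements sorted by strictly increasing date."""

    measurements: list[WoundMeasurement]

    def __post_init__(self):
        dates = [m.date for m in self.measurements]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValueError("measurement dates must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ProgressSeries":
        df = pd.read_csv(path, parse_dates=["date"])
        ms = [
            WoundMeasurement(
                date=row["date"].date(),
                ulcer_area_px=int(row["ulcer_area_px"]),
                foot_area_px=int(row["foot_area_px"]),
                pixels_per_cm=float(row["pixels_per_cm"]),
                ulcer_area_cm2=float(row["ulcer_area_cm2"]),
                area_ratio=float(row["area_ratio"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(sorted(ms, key=lambda m: m.date))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "date": m.date.isoformat(),
                    "ulcer_area_px": m.ulcer_area_px,
                    "foot_area_px": m.foot_area_px,
                    "pixels_per_cm": m.pixels_per_cm,
                    "ulcer_area_cm2": m.ulcer_area_cm2,
                    "area_ratio": m.area_ratio,
                }
                for m in self.measurements
            ],
            columns=CSV_COLUMNS,
        ).to_csv(path, index=False)


@dataclass
class HealingAssessment:
    baseline_date: date
    baseline_area_cm2: float
    assessment_date: date
    assessment_area_cm2: float
    percent_reduction: float
    on_track: bool


@dataclass
class ReminderConfig:
    interval: timedelta
    anchor: datetime
    message: str = DEFAULT_REMINDER_MESSAGE

    def __post_init__(self):
        if self.interval <= timedelta(0):
            raise ValueError("interval must be positive")


def measure(
    ulcer_seg: UlcerSegmentation,
    foot_seg: FootSegmentation,
    scale: ScaleEstimate,
    when: date,
) -> WoundMeasurement:
    """Combine the segmentations and scale into one dated measurement."""
    if (ulcer_seg.ulcer_mask & ~foot_seg.foot_mask).any():
        raise ContainmentViolation("ulcer pixels outside the foot silhouette")
    ulcer_px = ulcer_seg.n_ulcer_px
    foot_px = foot_seg.foot_area_px
    return WoundMeasurement(
        date=when,
        ulcer_area_px=ulcer_px,
        foot_area_px=foot_px,
        pixels_per_cm=scale.pixels_per_cm,
        ulcer_area_cm2=px_area_to_cm2(ulcer_px, scale),
        area_ratio=ulcer_px / foot_px,
    )


def assess_healing(
    series: ProgressSeries, config: PipelineConfig = DEFAULT_CONFIG
) -> HealingAssessment:
    """4-week healing assessment against the >50% area-reduction marker.

    Baseline is the earliest measurement (start of care). The assessment
    point is the measurement nearest baseline + 28 days, accepted only within
    ±3 days (days 25-31); the earlier measurement wins a distance tie.
    ``on_track`` requires percent_reduction strictly greater than 50.
    """
    if len(series.measurements) < 2:
        raise NoAssessmentPoint("need a baseline and at least one later measurement")
    baseline = series.measurements[0]
    target = baseline.date + timedelta(days=config.assessment_day)
    window = timedelta(days=config.assessment_window_days)
    candidates = [
        m
        for m in series.measurements[1:]
        if abs(m.date - target) <= window
    ]
    if not candidates:
        lo = target - window
        hi = target + window
        raise NoAssessmentPoint(f"no measurement between {lo} and {hi}")
    best = min(candidates, key=lambda m: (abs(m.date - target), m.date))
    if baseline.ulcer_area_cm2 <= 0:
        raise ZeroBaseline("baseline area is zero")
    reduction = (
        100.0
        * (baseline.ulcer_area_cm2 - best.ulcer_area_cm2)
        / baseline.ulcer_area_cm2
    )
    return HealingAssessment(
        baseline_date=baseline.date,
        baseline_area_cm2=baseline.ulcer_area_cm2,
        assessment_date=best.date,
        assessment_area_cm2=best.ulcer_area_cm2,
        percent_reduction=reduction,
        on_track=reduction > config.on_track_reduction_pct,
    )


def percent_change_curve(series: ProgressSeries) -> list[tuple[date, float]]:
    """Each measurement's area as a percentage of baseline; first entry 100."""
    if not series.measurements:
        raise ValueError("empty series")
    baseline = series.measurements[0].ulcer_area_cm2
    if baseline <= 0:
        raise ZeroBaseline("baseline area is zero")
    return [
        (m.date, 100.0 * m.ulcer_area_cm2 / baseline) for m in series.measurements
    ]


def next_reminder(config: ReminderConfig, now: datetime) -> datetime:
    """First due time anchor + k·interval strictly after ``now`` (k >= 1)."""
    elapsed = now - config.anchor
    # floor division makes k = m+1 when now sits exactly on due time m
    k = max(1, elapsed // config.interval + 1)
    return config.anchor + k * config.interval


def plot_progress(series: ProgressSeries, path: str | Path) -> None:
    """Two-panel progress chart: area in cm² and percent of baseline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dates = [m.date for m in series.measurements]
    areas = [m.ulcer_area_cm2 for m in series.measurements]
    curve = percent_change_curve(series)
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(6, 6), sharex=True)
    ax1.plot(dates, areas, "o-", color="tab:red")
    ax1.set_ylabel("ulcer area (cm²)")
    ax1.grid(True, alpha=0.3)
    ax2.plot([d for d, _ in curve], [p for _, p in curve], "o-", color="tab:blue")
    ax2.axhline(50.0, color="gray", linestyle="--", label="50% of baseline")
    ax2.set_ylabel("% of baseline area")
    ax2.set_xlabel("date")
    ax2.legend()
    ax2.grid(True, alpha=0.3)
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
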