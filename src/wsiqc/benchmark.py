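"""Slide-quality benchmarking statistics.

Aggregates per-slide artifact burdens (percent of tissue area occupied by
artifacts, overall or per class) into the three benchmark views used for
quality monitoring:

* ranking of institutes by mean artifact burden, with Tukey box-plot
  statistics per institute (median, quartiles, 1.5*IQR whiskers, outliers);
* paired scanner comparison — the same slides digitised on two scanners —
  with the mean paired difference and its 95% Student-t confidence
  interval;
* temporal monitoring by year, month, week, or day.

Quartiles use linear interpolation (numpy's default, type 7); whiskers
extend to the furthest datum within 1.5*IQR of the quartiles and outliers
lie strictly beyond the whiskers. These conventions are fixed because the
whisker and outlier sets depend on them.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError, DomainError, PairingError
from .pipeline import SlideSummary

__all__ = [
    "SlideRecord",
    "GroupStats",
    "ScannerComparison",
    "group_stats",
    "institute_stats",
    "scanner_compare",
    "temporal_stats",
    "write_report",
    "records_to_frame",
    "read_records_csv",
    "write_records_csv",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = (
    "fold",
    "dark_spot_foreign",
    "pen_marking",
    "air_bubble_edge",
    "out_of_focus",
    "any_artifact",
)


@dataclass
class SlideRecord:
    """One slide's QC summary plus its provenance (institute, scanner, date)."""

    slide_id: str
    institute_id: str
    scanner_id: str
    date: str  # ISO-8601
    summary: SlideSummary

    def metric(self, name: str) -> float:
        if name == "any_artifact":
            return self.summary.any_artifact_pct
        if name == "artifact_free":
            return self.summary.artifact_free_pct
        if name in self.summary.class_pct:
            return self.summary.class_pct[name]
        raise DomainError(f"unknown metric {name!r}")


@dataclass
class GroupStats:
    """Tukey box-plot statistics of one group of slides."""

    key: str
    n: int
    mean: float
    median: float
    q1: float
    q3: float
    iqr: float
    whisker_low: float
    whisker_high: float
    outliers: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def group_stats(key: str, values: Sequence[float]) -> GroupStats:
    """Box-plot statistics for one group (linear-interpolation quartiles)."""
    vals = np.asarray(values, dtype=np.float64)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise DataError(f"group {key!r} has no valid values")
    q1, q3 = np.percentile(vals, [25, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
    whisker_low = float(inside.min())
    whisker_high = float(inside.max())
    outliers = sorted(float(v) for v in vals[(vals < whisker_low) | (vals > whisker_high)])
    return GroupStats(
        key=key,
        n=int(vals.size),
        mean=float(vals.mean()),
        median=float(np.median(vals)),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        whisker_low=whisker_low,
        whisker_high=whisker_high,
        outliers=outliers,
    )


def institute_stats(
    records: Sequence[SlideRecord], metric: str = "any_artifact"
) -> list[GroupStats]:
    """Per-institute statistics ranked ascending by mean artifact burden."""
    if not records:
        raise DataError("no records")
    groups: dict[str, list[float]] = {}
    for rec in records:
        groups.setdefault(rec.institute_id, []).append(rec.metric(metric))
    out = [group_stats(k, v) for k, v in groups.items()]
    out.sort(key=lambda g: g.mean)
    return out


@dataclass
class ScannerComparison:
    """Paired scanner comparison on the same physical slides."""

    scanner_a: str
    scanner_b: str
    points: list[tuple[float, float]]  # (metric on A, metric on B) per slide
    mean_diff: float  # mean of B - A
    ci_low: float
    ci_high: float
    n: int


def scanner_compare(
    records: Sequence[SlideRecord], metric: str = "any_artifact"
) -> ScannerComparison:
    """Mean paired difference (B - A) with its 95% Student-t interval.

    Every slide must appear exactly once per scanner; swapping the two
    scanners negates the estimate and mirrors the interval. With zero
    variance (e.g. identical pairs) the interval collapses to a point.
    """
    scanners = sorted({rec.scanner_id for rec in records})
    if len(scanners) != 2:
        raise PairingError(f"need exactly 2 scanners, got {scanners}")
    a_id, b_id = scanners
    by_slide: dict[str, dict[str, float]] = {}
    for rec in records:
        by_slide.setdefault(rec.slide_id, {})[rec.scanner_id] = rec.metric(metric)
    points = []
    for slide_id, vals in sorted(by_slide.items()):
        if set(vals) != {a_id, b_id}:
            raise PairingError(f"slide {slide_id!r} missing a scanner")
        points.append((vals[a_id], vals[b_id]))
    n = len(points)
    if n < 2:
        raise PairingError("need at least 2 paired slides")
    diffs = np.array([b - a for a, b in points])
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return ScannerComparison(
        scanner_a=a_id,
        scanner_b=b_id,
        points=points,
        mean_diff=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        n=n,
    )


_GRANULARITY = ("year", "month", "week", "day")


def temporal_stats(
    records: Sequence[SlideRecord],
    granularity: str = "year",
    metric: str = "any_artifact",
) -> list[GroupStats]:
    """Time-ordered group statistics (records with unparseable dates are
    rejected with a log entry)."""
    if granularity not in _GRANULARITY:
        raise DomainError(f"granularity must be one of {_GRANULARITY}")
    if not records:
        raise DataError("no records")
    groups: dict[tuple, list[float]] = {}
    labels: dict[tuple, str] = {}
    for rec in records:
        ts = pd.to_datetime(rec.date, errors="coerce")
        if pd.isna(ts):
            logger.warning("record %s: unparseable date %r, skipped", rec.slide_id, rec.date)
            continue
        if granularity == "year":
            key, label = (ts.year,), str(ts.year)
        elif granularity == "month":
            key, label = (ts.year, ts.month), f"{ts.year}-{ts.month:02d}"
        elif granularity == "week":
            iso = ts.isocalendar()
            key, label = (iso.year, iso.week), f"{iso.year}-W{iso.week:02d}"
        else:
            key, label = (ts.year, ts.month, ts.day), ts.strftime("%Y-%m-%d")
        groups.setdefault(key, []).append(rec.metric(metric))
        labels[key] = label
    if not groups:
        raise DataError("no records with parseable dates")
    return [group_stats(labels[k], groups[k]) for k in sorted(groups)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def records_to_frame(records: Sequence[SlideRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row = {
            "slide_id": rec.slide_id,
            "institute_id": rec.institute_id,
            "scanner_id": rec.scanner_id,
            "date": rec.date,
            "tissue_area_mm2": rec.summary.tissue_area_mm2,
            "artifact_free": rec.summary.artifact_free_pct,
            "any_artifact": rec.summary.any_artifact_pct,
        }
        row.update(rec.summary.class_pct)
        rows.append(row)
    return pd.DataFrame(rows)


def write_records_csv(records: Sequence[SlideRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path: str | Path) -> list[SlideRecord]:
    df = pd.read_csv(path, dtype={"slide_id": str, "institute_id": str, "scanner_id": str})
    out = []
    for _, row in df.iterrows():
        class_pct = {c: float(row[c]) for c in METRIC_COLUMNS if c != "any_artifact"}
        summary = SlideSummary(
            slide_id=str(row["slide_id"]),
            tissue_area_mm2=float(row.get("tissue_area_mm2", float("nan"))),
            class_pct=class_pct,
            artifact_free_pct=float(row["artifact_free"]),
            any_artifact_pct=float(row["any_artifact"]),
        )
        out.append(
            SlideRecord(
                slide_id=str(row["slide_id"]),
                institute_id=str(row["institute_id"]),
                scanner_id=str(row["scanner_id"]),
                date=str(row["date"]),
                summary=summary,
            )
        )
    return out


def write_report(
    stats: Sequence[GroupStats],
    out_dir: str | Path,
    metric: str = "any_artifact",
    title: str = "slide quality",
) -> dict[str, Path]:
    """CSV + JSON twins of the statistics plus a box-plot figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [g.to_dict() for g in stats]
    df = pd.DataFrame([{k: v for k, v in r.items() if k != "outliers"} for r in rows])
    csv_path = out_dir / f"stats_{metric}.csv"
    df.to_csv(csv_path, index=False)
    json_path = out_dir / f"stats_{metric}.json"
    json_path.write_text(json.dumps({"metric": metric, "groups": rows}, indent=1))

    fig, ax = plt.subplots(figsize=(max(4, 0.8 * len(stats)), 4))
    bxp = [
        {
            "label": g.key,
            "mean": g.mean,
            "med": g.median,
            "q1": g.q1,
            "q3": g.q3,
            "whislo": g.whisker_low,
            "whishi": g.whisker_high,
            "fliers": g.outliers,
        }
        for g in stats
    ]
    ax.bxp(bxp, showmeans=True)
    ax.set_ylabel(f"{metric} (% of tissue area)")
    ax.set_title(title)
    fig.tight_layout()
    fig_path = out_dir / f"stats_{metric}.png"
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)
    return {"csv": csv_path, "json": json_path, "figure": fig_path}
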