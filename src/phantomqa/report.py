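"""Session reports: aggregation, pass thresholds, serialization, trending.

A :class:`QAReport` collects every metric measured in one QA session,
applies configurable pass thresholds, and serializes to JSON losslessly.
:func:`trend` assembles a control chart for one metric across sessions,
with mean +- 3 sigma limits estimated from a baseline window of early
sessions.

The shipped default thresholds follow common accreditation practice (MTF
representative value >= 0.8 as the vendor recommends; geometric error
within +-2 mm; thickness error within +-0.7 mm; PIU floor 82) but are
plain configuration, never policy baked into the measurement code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable

from .geometry import GeometricMeasurement
from .resolution import MtfResult, AcrResolutionResult
from .slices import RampMeasurement, AlignmentResult
from .uniformity import UniformityResult

__all__ = ["Thresholds", "MetricRecord", "QAReport", "TrendSeries", "build_report", "trend"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class Thresholds:
    mtf_min: float = 0.8
    geometric_error_mm: float = 2.0
    thickness_error_mm: float = 0.7
    piu_min: float = 82.0
    avg_std_percent_max: float | None = None  # no consensus limit; report only
    marker_percent_min: float | None = None


@dataclass(frozen=True)
class MetricRecord:
    test: str  # geometry | mtf | acr_resolution | thickness | alignment | uniformity
    metric_id: str
    value: float | None
    expected: float | None = None
    error: float | None = None
    passed: bool | None = None  # None = informational / not thresholded
    note: str | None = None


@dataclass
class QAReport:
    session: dict[str, Any] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    results: list[MetricRecord] = field(default_factory=list)
    schema_version: int = SCHEMA_VERSION

    @property
    def overall_pass(self) -> bool:
        flags = [r.passed for r in self.results if r.passed is not None]
        return all(flags) if flags else True

    def metrics(self) -> dict[str, float]:
        return {r.metric_id: r.value for r in self.results if r.value is not None}

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return {
            "schema_version": self.schema_version,
            "session": dict(self.session),
            "thresholds": asdict(self.thresholds),
            "overall_pass": self.overall_pass,
            "results": [asdict(r) for r in self.results],
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "QAReport":
        return cls(
            session=dict(d.get("session", {})),
            thresholds=Thresholds(**d["thresholds"]),
            results=[MetricRecord(**r) for r in d["results"]],
            schema_version=int(d.get("schema_version", SCHEMA_VERSION)),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "QAReport":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def _records_for(result: Any, thr: Thresholds) -> list[MetricRecord]:
    if isinstance(result, GeometricMeasurement):
        if result.measured_mm is None:
            return [MetricRecord("geometry", f"geometry/{result.path_id}", None,
                                 expected=result.expected_mm, note=result.warning or "not measured")]
        return [MetricRecord(
            "geometry", f"geometry/{result.path_id}", result.measured_mm,
            expected=result.expected_mm, error=result.error_mm,
            passed=abs(result.error_mm) <= thr.geometric_error_mm,
        )]
    if isinstance(result, MtfResult):
        return [MetricRecord(
            "mtf", f"mtf/zone{result.zone_id}/{result.direction}", result.mtf,
            passed=result.mtf >= thr.mtf_min,
            note=None if result.valid else "pattern warped by local distortion; value may not reflect true resolution",
        )]
    if isinstance(result, AcrResolutionResult):
        return [MetricRecord(
            "acr_resolution", f"acr_resolution/{result.direction}",
            result.resolved_pitch_mm,
            note="no pitch resolved" if result.resolved_pitch_mm is None else None,
        )]
    if isinstance(result, RampMeasurement):
        return [MetricRecord(
            "thickness", f"thickness/zone{result.zone_id}/{result.ramp_id}",
            result.thickness_mm, expected=result.nominal_mm, error=result.error_mm,
            passed=abs(result.error_mm) <= thr.thickness_error_mm,
        )]
    if isinstance(result, AlignmentResult):
        records = []
        if result.offset_mm is not None:
            records.append(MetricRecord("alignment", "alignment/slice_offset", result.offset_mm))
        if result.markers_expected:
            passed = None
            if thr.marker_percent_min is not None:
                passed = result.percent_visible >= thr.marker_percent_min
            records.append(MetricRecord(
                "alignment", "alignment/percent_visible", result.percent_visible, passed=passed,
            ))
        return records
    if isinstance(result, UniformityResult):
        if result.method == "PIU":
            return [MetricRecord("uniformity", "uniformity/piu", result.piu,
                                 passed=result.piu >= thr.piu_min)]
        passed = None
        if thr.avg_std_percent_max is not None:
            passed = result.avg_std_percent <= thr.avg_std_percent_max
        return [MetricRecord("uniformity", "uniformity/avg_std_percent",
                             result.avg_std_percent, passed=passed, note=result.warning)]
    raise TypeError(f"unsupported result type {type(result).__name__}")


def build_report(
    results: Iterable[Any],
    thresholds: Thresholds | None = None,
    session: dict[str, Any] | None = None,
) -> QAReport:
    """Aggregate metric results into a session report with pass flags.

    Pass flags are pure functions of (value, threshold); tests that were not
    run are simply absent and do not affect the overall verdict.
    """
    thr = thresholds or Thresholds()
    results = list(results)
    if not results:
        raise ValueError("cannot build a report from zero results")
    records = []
    for r in results:
        records.extend(_records_for(r, thr))
    return QAReport(session=session or {}, thresholds=thr, results=records)


# ---------------------------------------------------------------------------
# trending
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendSeries:
    metric_id: str
    dates: tuple[str, ...]
    values: tuple[float, ...]
    mean: float | None
    lower: float | None  # mean - 3 sigma of the baseline window
    upper: float | None
    flags: tuple[bool, ...]  # True = out of control limits
    note: str | None = None


def trend(reports: list[QAReport], metric_id: str, baseline_n: int = 10) -> TrendSeries:
    """Chronological control chart of one metric across session reports.

    Control limits are mean +- 3 sigma of the first ``baseline_n`` sessions;
    with fewer than 3 sessions carrying the metric the limits are undefined
    and flagging is suppressed with a notice.
    """
    points = []
    for rep in reports:
        date = str(rep.session.get("date", ""))
        val = rep.metrics().get(metric_id)
        if val is not None:
            points.append((date, float(val)))
    if len(points) < 2:
        raise LookupError(f"metric {metric_id!r} present in fewer than 2 reports")
    points.sort(key=lambda p: p[0])
    dates = tuple(p[0] for p in points)
    if len(set(dates)) != len(dates):
        raise ValueError("session dates must be strictly increasing")
    values = tuple(p[1] for p in points)
    base = values[: min(baseline_n, len(values))]
    if len(base) < 3:
        return TrendSeries(metric_id, dates, values, None, None, None,
                           flags=tuple(False for _ in values),
                           note="too few sessions for control limits; flagging suppressed")
    import statistics

    mean = statistics.fmean(base)
    sigma = statistics.pstdev(base)
    lo, hi = mean - 3 * sigma, mean + 3 * sigma
    flags = tuple(not (lo <= v <= hi) for v in values)
    return TrendSeries(metric_id, dates, values, mean, lo, hi, flags)
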