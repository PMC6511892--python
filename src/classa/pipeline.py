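"""End-to-end orchestration: windowed metrics over a record, epoch
segmentation, trajectory averaging and multi-subject studies.

The published analysis geometry is:

* RAS, PQ1, PQ2,4 -- 10-s windows, 1-s increment, original temporal scale
  (40 samples of the 4-Hz resampled signal per window);
* PQ3 -- 60-s windows, 1-s increment, coarse-grained at tau = 7 before the
  quadrant count (34 coarse samples per window);
* HR, SDNN, aLF, aHF, nLF, nHF, SE, PE -- 5-min windows, 1-s increment.

Outliers are replaced inside each analysis window before any metric is
computed.  Metric values are indexed by their window *start* time; a window
belongs to the protocol epoch containing its start (windows straddling an
epoch boundary count toward the epoch they start in; a "contained"
assignment rule is available).  Five-minute windows necessarily mix epochs
near boundaries -- an unavoidable consequence of windows longer than the
inter-epoch margins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from . import sodp as sodp_mod
from . import traditional as trad
from .config import AnalysisConfig
from .preprocess import (
    RRSeries,
    UniformHRV,
    WindowSpec,
    replace_outliers,
    replace_outliers_batch,
    resample_uniform,
)
from .stats import EpochSummary, TestReport, pairwise_epoch_tests

__all__ = [
    "ProtocolConfig",
    "MetricSeries",
    "Trajectory3D",
    "run_record",
    "segment_by_epoch",
    "epoch_means",
    "average_trajectory",
    "summarize_study",
    "run_stress_contrasts",
    "CLASSA_METRICS",
    "TRADITIONAL_METRICS",
]

CLASSA_METRICS = ("ras", "pq1", "pq24", "pq3")
TRADITIONAL_METRICS = ("hr", "sdnn", "alf", "ahf", "nlf", "nhf", "se", "pe")

#: the two published stress-vs-no-stress epoch contrasts
STRESS_PAIRS = [("rest", "arithmetic"), ("meditation1", "exercise")]


@dataclass
class ProtocolConfig:
    """Ordered epochs (label, duration in s) separated by fixed gaps."""

    epochs: list[tuple[str, float]] = field(
        default_factory=lambda: [
            ("rest", 900.0),
            ("arithmetic", 900.0),
            ("meditation1", 900.0),
            ("exercise", 900.0),
            ("meditation2", 900.0),
        ]
    )
    gap: float = 60.0

    def __post_init__(self) -> None:
        if any(d <= 0 for _, d in self.epochs):
            raise ValueError("epoch durations must be positive")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.epochs) + self.gap * (len(self.epochs) - 1)

    def intervals(self) -> list[tuple[str, float, float]]:
        """[(label, start_s, end_s)] of the epochs, gaps excluded."""
        out = []
        t = 0.0
        for label, d in self.epochs:
            out.append((label, t, t + d))
            t += d + self.gap
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProtocolConfig":
        """Build from an annotation table with columns label,start_s,end_s;
        the gap is inferred from consecutive epochs (0 if contiguous)."""
        df = df.sort_values("start_s").reset_index(drop=True)
        epochs = [
            (str(r.label), float(r.end_s - r.start_s)) for r in df.itertuples()
        ]
        gap = 0.0
        if len(df) > 1:
            gap = float(df.start_s.iloc[1] - df.end_s.iloc[0])
        return cls(epochs=epochs, gap=max(gap, 0.0))


@dataclass
class MetricSeries:
    """One metric sampled over sliding windows, indexed by window start."""

    metric_name: str
    times: np.ndarray
    values: np.ndarray
    window_spec: WindowSpec

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must align")

    def __len__(self) -> int:
        return self.times.size


@dataclass
class Trajectory3D:
    """Non-overlapping 30-s block averages of (PQ1, PQ2,4, PQ3)."""

    times: np.ndarray
    pq1: np.ndarray
    pq24: np.ndarray
    pq3: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "pq1": self.pq1, "pq24": self.pq24, "pq3": self.pq3}
        )


def _window_matrix(x: UniformHRV, length_s: float, step_s: float) -> tuple[np.ndarray, np.ndarray]:
    """(window matrix, start times); empty when the record is too short."""
    n_len = int(round(length_s * x.rate))
    n_step = int(round(step_s * x.rate))
    if len(x) < n_len:
        return np.empty((0, n_len)), np.empty(0)
    W = sliding_window_view(x.values, n_len)[::n_step]
    starts = x.start_time + np.arange(W.shape[0]) * n_step / x.rate
    return np.ascontiguousarray(W), starts


def run_record(
    rr: RRSeries,
    config: AnalysisConfig | None = None,
    metrics: tuple[str, ...] = ("classa", "traditional"),
) -> dict[str, MetricSeries]:
    """Compute every requested metric series for one record.

    ``metrics`` selects the metric families: ``"classa"`` (RAS, PQ1, PQ2,4
    from short windows; PQ3 from long coarse-grained windows) and/or
    ``"traditional"`` (the eight 5-min-window comparison metrics).  Series
    the record is too short for are omitted with a warning.
    """
    cfg = config or AnalysisConfig()
    pc, cc, tc = cfg.preprocess, cfg.classa, cfg.traditional
    x = resample_uniform(rr, rate=pc.rate, interpolation=pc.interpolation)
    out: dict[str, MetricSeries] = {}

    if "classa" in metrics:
        spec_short = WindowSpec(cc.short_window, cc.step)
        W, starts = _window_matrix(x, cc.short_window, cc.step)
        if W.shape[0]:
            Wc = replace_outliers_batch(W, pc.fence)
            ras, pq1, pq24, _ = sodp_mod.classa_batch(Wc, cc.denominator)
            for name, vals in (("ras", ras), ("pq1", pq1), ("pq24", pq24)):
                out[name] = MetricSeries(name, starts, vals, spec_short)
        else:
            warnings.warn("record too short for the short ClassA window")
        spec_long = WindowSpec(cc.long_window, cc.step, scale=cc.tau)
        W, starts = _window_matrix(x, cc.long_window, cc.step)
        if W.shape[0]:
            Wc = replace_outliers_batch(W, pc.fence)
            pq3 = sodp_mod.q3_proportion_batch(Wc, cc.tau, cc.denominator)
            out["pq3"] = MetricSeries("pq3", starts, pq3, spec_long)
        else:
            warnings.warn("record too short for the long (PQ3) window")

    if "traditional" in metrics:
        spec_trad = WindowSpec(tc.window, tc.step)
        W, starts = _window_matrix(x, tc.window, tc.step)
        if W.shape[0] == 0:
            warnings.warn("record too short for the traditional 5-min window")
        else:
            Wc = replace_outliers_batch(W, pc.fence)
            params = tc.entropy_params()
            rows = {name: np.empty(W.shape[0]) for name in TRADITIONAL_METRICS}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for i in range(Wc.shape[0]):
                    win = UniformHRV(Wc[i], rate=x.rate, start_time=starts[i])
                    m = trad.compute_all(win, params)
                    rows["hr"][i] = m.hr
                    rows["sdnn"][i] = m.sdnn
                    rows["alf"][i] = m.bands.aLF
                    rows["ahf"][i] = m.bands.aHF
                    rows["nlf"][i] = m.bands.nLF
                    rows["nhf"][i] = m.bands.nHF
                    rows["se"][i] = m.se
                    rows["pe"][i] = m.pe
            for name in TRADITIONAL_METRICS:
                out[name] = MetricSeries(name, starts, rows[name], spec_trad)
    return out


def epoch_means(
    series: MetricSeries,
    protocol: ProtocolConfig,
    assignment: str = "start",
) -> dict[str, float]:
    """Per-epoch mean of a metric series for one record.

    ``assignment="start"`` places a window in the epoch containing its
    start time; ``"contained"`` requires the whole window inside the epoch.
    Gap windows are discarded.  Epochs with no windows get nan (warned).
    """
    out: dict[str, float] = {}
    wlen = series.window_spec.length
    for label, s, e in protocol.intervals():
        if assignment == "start":
            m = (series.times >= s) & (series.times < e)
        elif assignment == "contained":
            m = (series.times >= s) & (series.times + wlen <= e)
        else:
            raise ValueError(f"unknown assignment rule {assignment!r}")
        if not m.any():
            warnings.warn(f"epoch {label!r} contains no {series.metric_name} windows")
            out[label] = float("nan")
        else:
            out[label] = float(np.nanmean(series.values[m]))
    return out


def segment_by_epoch(
    series_per_record: list[MetricSeries],
    protocol: ProtocolConfig,
    assignment: str = "start",
) -> list[EpochSummary]:
    """Epoch summaries of one metric across records (one mean per record)."""
    if not series_per_record:
        raise ValueError("no series given")
    name = series_per_record[0].metric_name
    means = [epoch_means(s, protocol, assignment) for s in series_per_record]
    return [
        EpochSummary(name, label, np.array([m[label] for m in means]))
        for label, _, _ in protocol.intervals()
    ]


def _block_average(series: MetricSeries, t0: float, t1: float, block: float):
    m = (series.times >= t0) & (series.times < t1)
    t = series.times[m] - t0
    v = series.values[m]
    idx = np.floor(t / block).astype(int)
    n_full = int((t1 - t0) // block)
    centers, means = [], []
    for b in range(n_full):
        mb = idx == b
        if not mb.any():
            continue
        centers.append(t0 + (b + 0.5) * block)
        means.append(float(np.nanmean(v[mb])))
    return centers, means


def average_trajectory(
    pq1: MetricSeries,
    pq24: MetricSeries,
    pq3: MetricSeries,
    block: float = 30.0,
    protocol: ProtocolConfig | None = None,
) -> Trajectory3D:
    """Non-overlapping block averages of the three quadrant proportions.

    With a protocol, blocks are aligned to each epoch's start (so per-epoch
    trajectories are comparable across epochs); otherwise to the series
    start.  Trailing partial blocks are dropped.  Block centres are kept
    only where all three series have data.
    """
    if protocol is not None:
        spans = [(s, e) for _, s, e in protocol.intervals()]
    else:
        if len(pq1) == 0:
            return Trajectory3D(np.empty(0), np.empty(0), np.empty(0), np.empty(0))
        t0 = min(pq1.times[0], pq24.times[0], pq3.times[0])
        # the last window covers one full step beyond its start time
        step = pq1.window_spec.step
        t1 = max(pq1.times[-1], pq24.times[-1], pq3.times[-1]) + step
        spans = [(t0, t1)]
    times, v1, v24, v3 = [], [], [], []
    for s, e in spans:
        c1, m1 = _block_average(pq1, s, e, block)
        c24, m24 = _block_average(pq24, s, e, block)
        c3, m3 = _block_average(pq3, s, e, block)
        common = sorted(set(c1) & set(c24) & set(c3))
        for c in common:
            times.append(c)
            v1.append(m1[c1.index(c)])
            v24.append(m24[c24.index(c)])
            v3.append(m3[c3.index(c)])
    return Trajectory3D(np.array(times), np.array(v1), np.array(v24), np.array(v3))


# ---------------------------------------------------------------------------
# multi-record studies

def summarize_study(
    records: list[dict[str, MetricSeries]],
    protocol: ProtocolConfig,
    metric_names: tuple[str, ...] | None = None,
    assignment: str = "start",
) -> dict[str, list[EpochSummary]]:
    """Epoch summaries for every metric across a set of analysed records."""
    if metric_names is None:
        metric_names = tuple(records[0].keys())
    out = {}
    for name in metric_names:
        out[name] = segment_by_epoch(
            [rec[name] for rec in records if name in rec], protocol, assignment
        )
    return out


def run_stress_contrasts(
    summaries: dict[str, list[EpochSummary]],
    family_alpha: float = 0.05,
    pairs: list[tuple[str, str]] | None = None,
) -> dict[str, list[TestReport]]:
    """The two stress-vs-no-stress pairwise tests for every metric."""
    pairs = pairs or STRESS_PAIRS
    return {
        name: pairwise_epoch_tests(s, pairs, family_alpha)
        for name, s in summaries.items()
    }
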