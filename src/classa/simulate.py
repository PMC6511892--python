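"""Synthetic RR-interval generation with controlled autonomic-like structure.

Real HRV mixes oscillations in the LF (0.04-0.15 Hz) and HF (0.15-0.4 Hz)
bands with slow trends (cardiac acceleration or deceleration) and beat-level
noise.  The generator reproduces exactly those ingredients and nothing more:

    RR(t) = mean_rr + trend_slope * t
            + lf_amp * sin(2 pi lf_freq t)
            + hf_amp * sin(2 pi hf_freq t)
            + gaussian noise (sd = noise_sd, per beat)

sampled at successive beat times, each beat advanced by the current RR.
Within an epoch, t is measured from the epoch start, so ``mean_rr`` is the
epoch's starting level and ``trend_slope`` carries any drift across it.

:func:`simulate_protocol` strings per-epoch specs together into a
stress-protocol record (default: five 15-min epochs -- rest, arithmetic,
meditation1, exercise, meditation2 -- separated by 1-min gaps) with
continuous beat times and a ground-truth epoch annotation table.
:func:`stress_protocol_spec` provides the default stressed parameterisation:
stress epochs (arithmetic, exercise) start at a shorter RR with the HF
amplitude reduced (vagal withdrawal) and a negative trend slope (progressive
cardiac acceleration); exercise additionally damps overall variability, as
seen in stress recordings where SDNN collapses during exercise.

:func:`fixture_library` returns small deterministic RR fixtures (ramps,
constants, alternation, single sinusoids, seeded noise) used throughout the
test-suite; they are generated, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pipeline import ProtocolConfig
from .preprocess import RR_FLOOR, RRSeries

__all__ = [
    "SimSpec",
    "ProtocolSimSpec",
    "simulate_rr",
    "simulate_protocol",
    "stress_protocol_spec",
    "fixture_library",
]


@dataclass
class SimSpec:
    """Parameters of one simulated RR segment.

    Units: seconds for durations/amplitudes, Hz for frequencies,
    seconds-per-second for ``trend_slope`` (negative = cardiac
    acceleration, i.e. RR shrinking over the segment).
    """

    duration: float = 300.0
    mean_rr: float = 0.85
    lf_amp: float = 0.02
    hf_amp: float = 0.03
    lf_freq: float = 0.1
    hf_freq: float = 0.3
    trend_slope: float = 0.0
    noise_sd: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.mean_rr <= 0:
            raise ValueError("duration and mean_rr must be positive")
        if not 0.04 <= self.lf_freq <= 0.15:
            raise ValueError("lf_freq outside the 0.04-0.15 Hz LF band")
        if not 0.15 <= self.hf_freq <= 0.4:
            raise ValueError("hf_freq outside the 0.15-0.4 Hz HF band")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _segment_intervals(
    spec: SimSpec, rng: np.random.Generator, t_start: float
) -> tuple[list[float], list[float], float]:
    """Generate one segment's beats; returns (intervals, beat_times, t_end)."""
    intervals: list[float] = []
    beat_times: list[float] = []
    t = t_start
    end = t_start + spec.duration
    clipped = False
    while True:
        tl = t - t_start  # epoch-local time drives the deterministic part
        rr = (
            spec.mean_rr
            + spec.trend_slope * tl
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * tl)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * tl)
        )
        if spec.noise_sd > 0:
            rr += rng.normal(0.0, spec.noise_sd)
        if rr < RR_FLOOR:
            rr = RR_FLOOR
            clipped = True
        if t + rr > end:
            break
        t += rr
        intervals.append(rr)
        beat_times.append(t)
    if clipped:
        import warnings

        warnings.warn("simulated RR hit the positivity floor and was clipped")
    return intervals, beat_times, end


def simulate_rr(spec: SimSpec, rng: np.random.Generator | None = None) -> RRSeries:
    """Simulate a single-segment RR series; reproducible from ``spec.seed``."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    intervals, beat_times, _ = _segment_intervals(spec, rng, 0.0)
    if len(intervals) < 2:
        raise ValueError("segment too short to contain two beats")
    return RRSeries(
        intervals=np.array(intervals),
        beat_times=np.array(beat_times),
        source_id=f"sim(seed={spec.seed})",
    )


@dataclass
class ProtocolSimSpec:
    """Per-epoch simulation specs following a protocol layout.

    ``epoch_specs`` pairs each protocol epoch label with its
    :class:`SimSpec` (the spec's ``duration`` is overridden by the protocol
    epoch duration); ``gap_spec`` fills the inter-epoch intervals.
    """

    epoch_specs: list[tuple[str, SimSpec]]
    gap_spec: SimSpec = field(default_factory=SimSpec)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)

    def __post_init__(self) -> None:
        labels = [label for label, _ in self.epoch_specs]
        if labels != [label for label, _ in self.protocol.epochs]:
            raise ValueError("epoch_specs labels must match the protocol epochs")


def stress_protocol_spec(
    protocol: ProtocolConfig | None = None,
) -> ProtocolSimSpec:
    """Default stressed parameterisation of the five-epoch protocol.

    Rest and meditation epochs share a calm baseline (RR 0.85 s, HF
    modulation 30 ms).  The mental-stress epoch (arithmetic) starts at a
    shorter RR with the HF amplitude halved and a mild acceleration trend;
    the physical-stress epoch (exercise) starts shorter still, with HF
    withdrawal, globally damped variability and a stronger acceleration
    trend.  Magnitudes are chosen to resemble seated stress-test recordings
    (resting HR ~70 bpm rising towards ~100 bpm under exercise).
    """
    protocol = protocol or ProtocolConfig()
    calm = SimSpec(mean_rr=0.85, lf_amp=0.02, hf_amp=0.03, noise_sd=0.01)
    arithmetic = SimSpec(
        mean_rr=0.78,
        lf_amp=0.02,
        hf_amp=0.015,
        noise_sd=0.01,
        trend_slope=-2.0e-4,
    )
    exercise = SimSpec(
        mean_rr=0.68,
        lf_amp=0.012,
        hf_amp=0.006,
        noise_sd=0.006,
        trend_slope=-3.0e-4,
    )
    by_label = {
        "rest": calm,
        "arithmetic": arithmetic,
        "meditation1": calm,
        "exercise": exercise,
        "meditation2": replace(calm, trend_slope=1.0e-4),
    }
    specs = [(label, by_label.get(label, calm)) for label, _ in protocol.epochs]
    return ProtocolSimSpec(epoch_specs=specs, gap_spec=calm, protocol=protocol)


def simulate_protocol(
    pspec: ProtocolSimSpec, seed: int | None = None
) -> tuple[RRSeries, pd.DataFrame]:
    """Simulate a full protocol record.

    Beats are generated continuously over the whole record: each beat takes
    its parameters from the segment (epoch or gap) its onset falls in, with
    the segment-local clock driving trend and oscillation phases.  Epoch
    boundaries therefore sit exactly at the protocol's nominal times.
    Returns the RR series and a ground-truth annotation table with columns
    ``label, start_s, end_s`` (epochs only; gaps are unlabeled).
    """
    rng = np.random.default_rng(seed)
    protocol = pspec.protocol
    # timeline of (start, end, spec); gaps interleaved
    segments: list[tuple[float, float, SimSpec]] = []
    rows = []
    t = 0.0
    for i, ((label, spec), (_, duration)) in enumerate(
        zip(pspec.epoch_specs, protocol.epochs)
    ):
        segments.append((t, t + duration, spec))
        rows.append({"label": label, "start_s": t, "end_s": t + duration})
        t += duration
        if i < len(protocol.epochs) - 1 and protocol.gap > 0:
            segments.append((t, t + protocol.gap, pspec.gap_spec))
            t += protocol.gap
    total = t

    intervals: list[float] = []
    beat_times: list[float] = []
    t = 0.0
    seg_idx = 0
    clipped = False
    while True:
        while seg_idx < len(segments) - 1 and t >= segments[seg_idx][1]:
            seg_idx += 1
        s0, _, spec = segments[seg_idx]
        tl = t - s0
        rr = (
            spec.mean_rr
            + spec.trend_slope * tl
            + spec.lf_amp * np.sin(2 * np.pi * spec.lf_freq * tl)
            + spec.hf_amp * np.sin(2 * np.pi * spec.hf_freq * tl)
        )
        if spec.noise_sd > 0:
            rr += rng.normal(0.0, spec.noise_sd)
        if rr < RR_FLOOR:
            rr = RR_FLOOR
            clipped = True
        if t + rr > total:
            break
        t += rr
        intervals.append(rr)
        beat_times.append(t)
    if clipped:
        import warnings

        warnings.warn("simulated RR hit the positivity floor and was clipped")
    rr_series = RRSeries(
        intervals=np.array(intervals),
        beat_times=np.array(beat_times),
        source_id=f"sim-protocol(seed={seed})",
    )
    return rr_series, pd.DataFrame(rows)


def fixture_library(
    n: int = 120, rr0: float = 0.8, seed: int = 2024
) -> dict[str, RRSeries]:
    """Deterministic RR fixtures exercising every analytic regime.

    * ``linear_up`` / ``linear_down``: RR ramping between 0.8 and 1.0 s
      (strictly monotone -> all SODP points in Q1 / Q3);
    * ``constant``: all intervals equal (degenerate SODP, SDNN 0);
    * ``alternating``: RR toggling 0.7/0.9 s (balanced, Q2/Q4-dominant);
    * ``sine_lf`` / ``sine_hf``: a single 0.1 Hz / 0.3 Hz modulation,
      amplitude 0.05 s, 320 s long (spectral band recovery);
    * ``white_noise``: seeded gaussian perturbations around ``rr0``.
    """
    ramp_up = np.linspace(rr0, 1.0, n)
    ramp_down = ramp_up[::-1].copy()
    alternating = np.where(np.arange(n) % 2 == 0, 0.7, 0.9)
    rng = np.random.default_rng(seed)
    noise = np.clip(rr0 + rng.normal(0.0, 0.05, size=n), RR_FLOOR, None)

    def sine(freq: float) -> RRSeries:
        intervals = []
        t = 0.0
        while t < 320.0:
            rr = rr0 + 0.05 * np.sin(2 * np.pi * freq * t)
            t += rr
            intervals.append(rr)
        return RRSeries(np.array(intervals), source_id=f"sine_{freq:g}Hz")

    return {
        "linear_up": RRSeries(ramp_up, source_id="linear_up"),
        "linear_down": RRSeries(ramp_down, source_id="linear_down"),
        "constant": RRSeries(np.full(n, rr0), source_id="constant"),
        "alternating": RRSeries(alternating, source_id="alternating"),
        "sine_lf": sine(0.1),
        "sine_hf": sine(0.3),
        "white_noise": RRSeries(noise, source_id="white_noise"),
    }
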