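"""Thermal stimulus generation for the offset-analgesia (OA) paradigm.

An OA trial drives the skin with a contact thermode through a fixed
temporal pattern: a 32 °C baseline, a ramp to a 45 °C plateau, three
plateau phases (T1 at 45 °C, T2 at 47 °C, T3 back at 45 °C) and a final
ramp down.  The small 47 → 45 °C offset at the start of T3 triggers the
disproportionate drop in perceived pain that defines offset analgesia.

Three stimulus conditions are provided:

``conventional``
    the standard OA pattern; T3 is a clean 45 °C plateau.
``noise_seq1`` / ``noise_seq2``
    identical outside T3; during T3 the commanded temperature fluctuates
    at 3 Hz between 44 and 46 °C following a seeded random disturbance
    sequence (trapezoid pulses, ramps at ~10 °C/s).
``constant``
    the familiarization stimulus; the temperature stays at the 45 °C
    plateau through all three phases.

All traces are sampled on a uniform grid and carry per-sample phase
labels, so downstream models and rating-window aggregation can address
phases by name rather than by hard-coded times.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

__all__ = [
    "PHASES",
    "SEQ1_SEED",
    "SEQ2_SEED",
    "Protocol",
    "NoiseSpec",
    "StimulusTrace",
    "RatingSchedule",
    "build_conventional",
    "build_noise",
    "build_constant",
    "phase_stats",
    "rating_schedule",
    "noise_spec_for_sequence",
]

#: Phase labels in temporal order.
PHASES = (
    "baseline",
    "ramp_up",
    "T1",
    "ramp_T2",
    "T2",
    "ramp_T3",
    "T3",
    "ramp_down",
)

#: Library-fixed seeds defining disturbance sequences #1 and #2.  The study
#: used two particular realizations of the 3 Hz disturbance; the realized
#: sample paths are not published, so these two seeds define the package's
#: stand-in sequences.  They are constants of the library, not tunables.
SEQ1_SEED = 101
SEQ2_SEED = 202


@dataclass(frozen=True)
class Protocol:
    """Temporal protocol of one trial.

    Temperatures in °C, durations in seconds.  Defaults encode the
    standard OA paradigm: 5 s baseline at 32 °C, ramps at 6 °C/s,
    T1 = 5 s at 45 °C, T2 = 5 s at 47 °C, T3 = 15 s at 45 °C.
    """

    baseline_temp: float = 32.0
    plateau_temp: float = 45.0
    peak_temp: float = 47.0
    ramp_rate: float = 6.0
    baseline_hold_s: float = 5.0
    t1_s: float = 5.0
    t2_s: float = 5.0
    t3_s: float = 15.0
    sample_rate_hz: float = 30.0

    def __post_init__(self) -> None:
        for name in ("baseline_hold_s", "t1_s", "t2_s", "t3_s"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.ramp_rate <= 0:
            raise ConfigurationError("ramp_rate must be > 0")
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be > 0")
        if not (self.peak_temp > self.plateau_temp > self.baseline_temp):
            raise ConfigurationError(
                "temperatures must satisfy peak > plateau > baseline"
            )

    # -- derived timing ------------------------------------------------
    @property
    def ramp_up_s(self) -> float:
        return (self.plateau_temp - self.baseline_temp) / self.ramp_rate

    @property
    def ramp_t2_s(self) -> float:
        return (self.peak_temp - self.plateau_temp) / self.ramp_rate

    @property
    def ramp_t3_s(self) -> float:
        return (self.peak_temp - self.plateau_temp) / self.ramp_rate

    @property
    def ramp_down_s(self) -> float:
        return (self.plateau_temp - self.baseline_temp) / self.ramp_rate

    def phase_durations(self) -> dict[str, float]:
        """Duration of each phase, in temporal order."""
        return {
            "baseline": self.baseline_hold_s,
            "ramp_up": self.ramp_up_s,
            "T1": self.t1_s,
            "ramp_T2": self.ramp_t2_s,
            "T2": self.t2_s,
            "ramp_T3": self.ramp_t3_s,
            "T3": self.t3_s,
            "ramp_down": self.ramp_down_s,
        }

    def phase_bounds(self) -> dict[str, tuple[float, float]]:
        """(onset, offset) of each phase; t = 0 at trial onset."""
        bounds: dict[str, tuple[float, float]] = {}
        t = 0.0
        for name, dur in self.phase_durations().items():
            bounds[name] = (t, t + dur)
            t += dur
        return bounds

    def phase_onset(self, phase: str) -> float:
        try:
            return self.phase_bounds()[phase][0]
        except KeyError:
            raise InputError(f"unknown phase {phase!r}") from None

    @property
    def total_duration_s(self) -> float:
        return sum(self.phase_durations().values())


@dataclass(frozen=True)
class NoiseSpec:
    """Specification of the 3 Hz temperature disturbance applied in T3.

    The disturbance is a sequence of trapezoid pulses: at ``level_rate_hz``
    a new target level is drawn (uniform on [center - half_range,
    center + half_range] by default, or from the three levels
    {center - half_range, center, center + half_range}); the temperature
    ramps to it at ``ramp_rate`` °C/s and holds until the next level
    change.  With the defaults a full-range 2 °C swing ramps in 200 ms
    and typical ~0.7 °C steps in ~70 ms, leaving holds of ~200-270 ms
    within each 1/3 s cycle.  The last cycle always returns to
    ``center_temp`` so that the down-ramp after T3 is identical across
    conditions.
    """

    center_temp: float = 45.0
    half_range: float = 1.0
    level_rate_hz: float = 3.0
    ramp_rate: float = 10.0
    hold_ms: float = 200.0
    ramp_ms: float = 100.0
    seed: int = SEQ1_SEED
    distribution: str = "uniform_continuous"

    def __post_init__(self) -> None:
        if self.half_range <= 0 or self.level_rate_hz <= 0 or self.ramp_rate <= 0:
            raise ConfigurationError("half_range, level_rate_hz, ramp_rate must be > 0")
        if self.distribution not in ("uniform_continuous", "three_level"):
            raise ConfigurationError(f"unknown distribution {self.distribution!r}")
        lo, hi = self.center_temp - self.half_range, self.center_temp + self.half_range
        if lo < 44.0 - 1e-9 or hi > 46.0 + 1e-9:
            raise ConfigurationError("disturbance range must stay within [44, 46] °C")

    @property
    def low(self) -> float:
        return self.center_temp - self.half_range

    @property
    def high(self) -> float:
        return self.center_temp + self.half_range

    def draw_levels(self, n: int) -> np.ndarray:
        """Draw ``n`` disturbance levels (seeded, reproducible)."""
        rng = np.random.default_rng(self.seed)
        if self.distribution == "uniform_continuous":
            return rng.uniform(self.low, self.high, size=n)
        return rng.choice([self.low, self.center_temp, self.high], size=n)


def noise_spec_for_sequence(sequence: int, **overrides) -> NoiseSpec:
    """NoiseSpec for the library's fixed disturbance sequence #1 or #2."""
    if sequence not in (1, 2):
        raise ConfigurationError("sequence must be 1 or 2")
    seed = SEQ1_SEED if sequence == 1 else SEQ2_SEED
    return NoiseSpec(seed=seed, **overrides)


@dataclass(frozen=True)
class RatingSchedule:
    """Absolute beep times (s from trial onset) at which pain is rated.

    ``ref_time`` cues the reference (no report); R0 probes the hot T2
    phase; R1-R3 probe the T3 recovery at 5, 10 and 15 s after T3 onset.
    ``window_s`` is the length of the aggregation window ending at each
    rating time; 0 means single-sample.
    """

    ref_time: float
    r0_time: float
    r1_time: float
    r2_time: float
    r3_time: float
    window_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.r1_time < self.r2_time < self.r3_time):
            raise ConfigurationError("rating times must satisfy r1 < r2 < r3")
        if self.window_s < 0:
            raise ConfigurationError("window_s must be >= 0")

    @property
    def rating_times(self) -> dict[str, float]:
        return {
            "R0": self.r0_time,
            "R1": self.r1_time,
            "R2": self.r2_time,
            "R3": self.r3_time,
        }


def rating_schedule(protocol: Protocol, window_s: float = 1.0) -> RatingSchedule:
    """Beep schedule: Ref at T1 onset + 4 s, R0 at T2 onset + 4 s,
    R1/R2/R3 at T3 onset + 5/10/15 s."""
    b = protocol.phase_bounds()
    t3_on = b["T3"][0]
    return RatingSchedule(
        ref_time=b["T1"][0] + 4.0,
        r0_time=b["T2"][0] + 4.0,
        r1_time=t3_on + 5.0,
        r2_time=t3_on + 10.0,
        r3_time=t3_on + 15.0,
        window_s=window_s,
    )


@dataclass
class StimulusTrace:
    """A sampled temperature time series with per-sample phase labels."""

    time: np.ndarray
    temp: np.ndarray
    phase: np.ndarray
    condition: str
    seed: Optional[int] = None
    protocol: Optional[Protocol] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.phase = np.asarray(self.phase, dtype=object)
        if not (len(self.time) == len(self.temp) == len(self.phase)):
            raise InputError("time, temp and phase must have equal length")
        if len(self.time) >= 2:
            steps = np.diff(self.time)
            if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=1e-6):
                raise InputError("time grid must be strictly increasing and uniform")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    def phase_mask(self, phase: str) -> np.ndarray:
        mask = self.phase == phase
        if not mask.any():
            raise InputError(f"phase {phase!r} not present in trace")
        return mask

    def phase_temp(self, phase: str) -> np.ndarray:
        return self.temp[self.phase_mask(phase)]

    # -- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "temp_c": self.temp,
                "phase": self.phase.astype(str),
                "condition": self.condition,
                "seed": "" if self.seed is None else self.seed,
            }
        )

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "StimulusTrace":
        df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
        required = {"time_s", "temp_c", "phase", "condition"}
        if not required.issubset(df.columns):
            raise InputError(f"trace CSV must contain columns {sorted(required)}")
        seed_col = df["seed"].iloc[0] if "seed" in df.columns else ""
        seed = None if seed_col in ("", None) else int(seed_col)
        return cls(
            time=df["time_s"].to_numpy(),
            temp=df["temp_c"].to_numpy(),
            phase=df["phase"].to_numpy(dtype=object),
            condition=str(df["condition"].iloc[0]),
            seed=seed,
        )


# ---------------------------------------------------------------------
# trace construction
# ---------------------------------------------------------------------

def _grid(protocol: Protocol) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample times and per-sample phase labels."""
    dt = 1.0 / protocol.sample_rate_hz
    total = protocol.total_duration_s
    n = int(round(total / dt)) + 1
    time = np.arange(n) * dt
    bounds = protocol.phase_bounds()
    phase = np.empty(n, dtype=object)
    names = list(bounds)
    onsets = np.array([bounds[p][0] for p in names])
    # each sample belongs to the last phase whose onset is <= t (within
    # half a sample of rounding slack); the final sample closes ramp_down
    idx = np.searchsorted(onsets, time + 1e-9, side="right") - 1
    idx = np.clip(idx, 0, len(names) - 1)
    for i, k in enumerate(idx):
        phase[i] = names[k]
    return time, phase

def _conventional_breakpoints(protocol: Protocol) -> tuple[np.ndarray, np.ndarray]:
    b = protocol.phase_bounds()
    p = protocol
    pts = [
        (0.0, p.baseline_temp),
        (b["ramp_up"][0], p.baseline_temp),
        (b["ramp_up"][1], p.plateau_temp),
        (b["ramp_T2"][0], p.plateau_temp),
        (b["ramp_T2"][1], p.peak_temp),
        (b["ramp_T3"][0], p.peak_temp),
        (b["ramp_T3"][1], p.plateau_temp),
        (b["ramp_down"][0], p.plateau_temp),
        (b["ramp_down"][1], p.baseline_temp),
    ]
    t, v = zip(*pts)
    return np.array(t), np.array(v)


def build_conventional(protocol: Protocol) -> StimulusTrace:
    """Standard OA stimulus: T1 at plateau, T2 at peak, clean T3 plateau."""
    time, phase = _grid(protocol)
    bt, bv = _conventional_breakpoints(protocol)
    temp = np.interp(time, bt, bv)
    return StimulusTrace(time, temp, phase, condition="conventional", protocol=protocol)


def build_constant(protocol: Protocol) -> StimulusTrace:
    """Familiarization stimulus: plateau temperature through T1-T3.

    Phase boundaries (and hence the beep schedule) are kept identical to
    the conventional stimulus; the internal "ramp" segments carry zero
    slope.
    """
    time, phase = _grid(protocol)
    b = protocol.phase_bounds()
    p = protocol
    bt = np.array([0.0, b["ramp_up"][0], b["ramp_up"][1], b["ramp_down"][0], b["ramp_down"][1]])
    bv = np.array([p.baseline_temp, p.baseline_temp, p.plateau_temp, p.plateau_temp, p.baseline_temp])
    temp = np.interp(time, bt, bv)
    return StimulusTrace(time, temp, phase, condition="constant", protocol=protocol)


def _noise_breakpoints(
    protocol: Protocol, noise: NoiseSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Breakpoints of the trapezoid disturbance waveform over T3."""
    t3_on, t3_off = protocol.phase_bounds()["T3"]
    cycle = 1.0 / noise.level_rate_hz
    n_cycles = int(round((t3_off - t3_on) * noise.level_rate_hz))
    levels = noise.draw_levels(n_cycles)
    levels[-1] = noise.center_temp  # return to plateau for a shared down-ramp
    bt: list[float] = [t3_on]
    bv: list[float] = [protocol.plateau_temp]
    prev = protocol.plateau_temp
    for k, level in enumerate(levels):
        start = t3_on + k * cycle
        ramp = min(abs(level - prev) / noise.ramp_rate, cycle)
        if start > bt[-1]:
            bt.append(start)
            bv.append(prev)
        bt.append(start + ramp)
        bv.append(level)
        prev = level
    if t3_off > bt[-1]:
        bt.append(t3_off)
        bv.append(prev)
    return np.array(bt), np.array(bv)


def build_noise(
    protocol: Protocol, noise: NoiseSpec, condition: Optional[str] = None
) -> StimulusTrace:
    """OA stimulus with the 3 Hz disturbance during T3.

    Identical to :func:`build_conventional` outside T3 (same grid, same
    samples).  The same seed always yields a bit-identical trace.
    """
    if protocol.sample_rate_hz < 2 * noise.level_rate_hz:
        raise ConfigurationError(
            "sample_rate_hz must be at least twice the disturbance level rate"
        )
    if protocol.sample_rate_hz < 1000.0 / noise.ramp_ms:
        raise ConfigurationError("sample rate too low to resolve disturbance ramps")
    base = build_conventional(protocol)
    bt, bv = _noise_breakpoints(protocol, noise)
    t3_on, t3_off = protocol.phase_bounds()["T3"]
    temp = base.temp.copy()
    in_t3 = base.phase == "T3"
    temp[in_t3] = np.interp(base.time[in_t3], bt, bv)
    if condition is None:
        condition = {SEQ1_SEED: "noise_seq1", SEQ2_SEED: "noise_seq2"}.get(
            noise.seed, f"noise_seed{noise.seed}"
        )
    return StimulusTrace(
        base.time, temp, base.phase, condition=condition, seed=noise.seed,
        protocol=protocol,
    )


def phase_stats(trace: StimulusTrace, phase: str) -> dict[str, float]:
    """Mean and population SD (ddof=0) of temperature over one phase."""
    temps = trace.phase_temp(phase)
    return {"mean": float(np.mean(temps)), "sd": float(np.std(temps))}
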