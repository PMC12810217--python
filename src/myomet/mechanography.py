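"""Countermovement-jump mechanography from vertical ground-reaction force.

The analysis chain mirrors standard force-plate practice: body mass from
the quiet-standing force (weight / 9.81 m s^-2), net centre-of-mass
acceleration a(t) = F(t)/m - g, velocity by trapezoidal integration from
rest, instantaneous power P(t) = F(t) * v(t), and the peak power reached
before take-off.  The per-subject peak power is the median over the three
recorded jumps.

Note the net acceleration subtracts gravity: integrating the raw F/m would
give a non-zero velocity during quiet standing, which is unphysical.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid

GRAVITY = 9.81  # m s^-2
#: Force below this is treated as loss of ground contact.
DEFAULT_TAKEOFF_THRESHOLD_N = 10.0
#: Quiet-standing window (s) used for body mass by default.
DEFAULT_QUIET_WINDOW = (0.2, 0.9)
#: Maximum force SD (N) for a window to count as quiet standing.
QUIET_SD_LIMIT_N = 5.0


class MechanographyError(ValueError):
    """Invalid force trace or analysis failure."""


@dataclass(frozen=True)
class ForceTrace:
    """Uniformly sampled vertical ground-reaction force."""

    force_n: np.ndarray
    sample_rate_hz: float
    subject_id: str = ""

    def __post_init__(self):
        force = np.asarray(self.force_n, dtype=float).reshape(-1)
        object.__setattr__(self, "force_n", force)
        if self.sample_rate_hz <= 0:
            raise MechanographyError("sample rate must be positive")
        if (force < 0).any():
            raise MechanographyError("negative forces in trace")
        if len(force) < 2 * self.sample_rate_hz:
            raise MechanographyError("trace shorter than 2 s")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.force_n)) / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return len(self.force_n) / self.sample_rate_hz


@dataclass(frozen=True)
class JumpResult:
    """Outcome of one countermovement jump analysis."""

    body_mass_kg: float
    peak_power_kw: float
    takeoff_index: int
    peak_index: int
    power_trace_w: np.ndarray
    velocity_trace_ms: np.ndarray

    def __post_init__(self):
        if self.peak_power_kw < 0:
            raise MechanographyError("negative peak power")
        if not 0 <= self.takeoff_index < len(self.power_trace_w):
            raise MechanographyError("takeoff index outside trace")
        if self.peak_index > self.takeoff_index:
            raise MechanographyError("power peak after take-off")


def body_mass(
    trace: ForceTrace, quiet_window: tuple[float, float] = DEFAULT_QUIET_WINDOW
) -> float:
    """Body mass (kg) from the mean quiet-standing force divided by 9.81.

    The window (seconds) must lie in the pre-movement segment, span at
    least 0.5 s, and be quiet (force SD <= 5 N).
    """
    t0, t1 = quiet_window
    if t1 - t0 < 0.5:
        raise MechanographyError("quiet window must span at least 0.5 s")
    i0 = int(round(t0 * trace.sample_rate_hz))
    i1 = int(round(t1 * trace.sample_rate_hz))
    if i0 < 0 or i1 > len(trace.force_n):
        raise MechanographyError("quiet window outside trace")
    seg = trace.force_n[i0:i1]
    if seg.std() > QUIET_SD_LIMIT_N:
        raise MechanographyError(
            f"window not quiet: force SD {seg.std():.1f} N exceeds {QUIET_SD_LIMIT_N} N"
        )
    return float(seg.mean() / GRAVITY)


def com_velocity(trace: ForceTrace, mass_kg: float) -> np.ndarray:
    """Centre-of-mass velocity (m/s) by trapezoidal integration from rest.

    a(t) = F(t)/m - g; v starts at 0 at the beginning of the (quiet) trace.
    """
    if mass_kg <= 0:
        raise MechanographyError("mass must be positive")
    accel = trace.force_n / mass_kg - GRAVITY
    return cumulative_trapezoid(accel, dx=1.0 / trace.sample_rate_hz, initial=0.0)


def peak_power(
    trace: ForceTrace,
    mass_kg: float | None = None,
    takeoff_threshold_n: float = DEFAULT_TAKEOFF_THRESHOLD_N,
    quiet_window: tuple[float, float] = DEFAULT_QUIET_WINDOW,
) -> JumpResult:
    """Analyse one jump: power trace and the peak power reached before launch.

    P(t) = F(t) * v(t); take-off is the first sample with force below the
    threshold (default 10 N); the peak is searched at or before take-off
    and reported in kW.
    """
    if mass_kg is None:
        mass_kg = body_mass(trace, quiet_window)
    below = np.flatnonzero(trace.force_n < takeoff_threshold_n)
    if not len(below):
        raise MechanographyError("no takeoff: force never falls below threshold")
    takeoff = int(below[0])
    v = com_velocity(trace, mass_kg)
    power = trace.force_n * v
    peak_idx = int(np.argmax(power[: takeoff + 1]))
    return JumpResult(
        body_mass_kg=float(mass_kg),
        peak_power_kw=float(power[peak_idx] / 1000.0),
        takeoff_index=takeoff,
        peak_index=peak_idx,
        power_trace_w=power,
        velocity_trace_ms=v,
    )


def median_peak_power(results: Sequence[JumpResult]) -> float:
    """Median peak power (kW) over repeated jumps (protocol: three)."""
    if not results:
        raise MechanographyError("no jump results")
    return float(np.median([r.peak_power_kw for r in results]))


# ---------------------------------------------------------------------------
# Force-trace CSV: '# sample_rate_hz: <rate>' metadata line, then
# 'time_s,force_n' header and one row per sample.
# ---------------------------------------------------------------------------


def write_force_trace(trace: ForceTrace, path: str | Path) -> None:
    path = Path(path)
    lines = [f"# sample_rate_hz: {trace.sample_rate_hz}"]
    if trace.subject_id:
        lines.append(f"# subject_id: {trace.subject_id}")
    lines.append("time_s,force_n")
    for t, f in zip(trace.times_s, trace.force_n):
        lines.append(f"{t:.6f},{f:.3f}")
    path.write_text("\n".join(lines) + "\n")


def read_force_trace(path: str | Path) -> ForceTrace:
    path = Path(path)
    rate = None
    subject = ""
    forces: list[float] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("#").partition(":")
                key = key.strip()
                if key == "sample_rate_hz":
                    rate = float(val)
                elif key == "subject_id":
                    subject = val.strip()
                continue
            if line.startswith("time_s"):
                continue
            cols = line.split(",")
            forces.append(float(cols[-1]))
    if rate is None:
        raise MechanographyError(f"{path}: missing sample_rate_hz metadata line")
    return ForceTrace(np.asarray(forces), rate, subject_id=subject)
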