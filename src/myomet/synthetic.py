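"""Synthetic-cohort generation with known ground truth.

Every input the analysis pipeline consumes can be generated here: muscle
voxel maps with a periphery-fattier-than-centre fat-fraction field, jump
ground-reaction-force traces with a closed-form centre-of-mass trajectory
(hence an analytic peak power), three-peak 1H FIDs with known amplitudes,
and whole four-group cohorts (young/old x athlete/control) parameterised
by the published group summaries in :mod:`myomet.reference`.

All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from . import reference
from .mechanography import GRAVITY, ForceTrace
from .morphometry import (
    DEFAULT_VOXEL_DIMS,
    MuscleVoxelMap,
    shell_centre_partition,
)
from .spectroscopy import DEFAULT_PPM, FidRecord, PeakModel, model_fid


class SyntheticError(ValueError):
    """Invalid generator specification."""


# ---------------------------------------------------------------------------
# Muscle voxel maps
# ---------------------------------------------------------------------------


def _rasterize(rx: float, n_slices: int, aspect: float, taper: float) -> np.ndarray:
    """Voxel (i, j, k) table of an elliptic cylinder with tapered end slices."""
    ry = aspect * rx
    cx = int(np.ceil(rx)) + 1
    cy = int(np.ceil(ry)) + 1
    x = np.arange(2 * cx + 1)
    y = np.arange(2 * cy + 1)
    xx, yy = np.meshgrid(x, y, indexing="ij")
    rows = []
    for s in range(n_slices):
        scale = taper if s in (0, n_slices - 1) else 1.0
        a, b = max(rx * scale, 0.5), max(ry * scale, 0.5)
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        ij = np.argwhere(mask)
        rows.append(np.column_stack([ij, np.full(len(ij), s)]))
    return np.concatenate(rows)


def generate_muscle_map(
    name: str,
    volume_ml: float,
    shell_ff_pct: float,
    centre_ff_pct: float,
    *,
    noise_sd: float = 1.0,
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
    subject_id: str = "",
    group: str = "",
    aspect: float = 0.7,
    taper: float = 0.6,
    volume_rtol: float = 0.02,
) -> MuscleVoxelMap:
    """Generate a connected tubular muscle map with a radial FF gradient.

    The shape is an elliptic cylinder (in-plane aspect ``aspect``) with
    tapered end slices, rasterised on the anisotropic grid so the voxel
    count times the voxel volume lands within ``volume_rtol`` (2%) of the
    nominal volume.  The fat-fraction field is ``centre_ff_pct`` deep
    inside and ``shell_ff_pct`` on the peripheral shell (end slices plus
    the two-voxel in-plane ring, matching the shell/centre partition rule
    so the generating means are exactly recoverable without noise), plus
    Gaussian noise, clipped to [0, 100] and quantised to the 0.1% export
    precision.
    """
    for v, what in ((shell_ff_pct, "shell"), (centre_ff_pct, "centre")):
        if not 0 <= v <= 100:
            raise SyntheticError(f"{what} FF outside [0, 100]")
    if noise_sd < 0:
        raise SyntheticError("noise_sd must be >= 0")
    dx, dy, dz = voxel_dims
    voxvol = dx * dy * dz
    n_target = volume_ml * 1000.0 / voxvol
    if n_target < 1:
        raise SyntheticError(
            f"nominal volume {volume_ml} ml is smaller than one voxel ({voxvol / 1000:.4f} ml)"
        )
    # heuristic elongation: muscle length about 3x its in-plane diameter
    rx0 = (n_target * dz / (6.0 * aspect * np.pi * dx)) ** (1.0 / 3.0) * 1.2
    n_slices = max(3, int(round(6.0 * rx0 * dx / dz)))

    def count(rx: float) -> int:
        return len(_rasterize(rx, n_slices, aspect, taper))

    lo, hi = 0.3, max(2.0, 2.5 * rx0)
    while count(hi) < n_target:
        hi *= 1.5
        if hi > 1e4:  # pragma: no cover - absurd volume
            raise SyntheticError("cannot bracket nominal volume")
    best_rx, best_err = hi, abs(count(hi) - n_target)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        c = count(mid)
        err = abs(c - n_target)
        if err < best_err:
            best_rx, best_err = mid, err
        if c < n_target:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    if best_err > volume_rtol * n_target:
        raise SyntheticError(
            f"cannot rasterise {volume_ml} ml within {volume_rtol:.0%} on this grid "
            f"(best voxel-count error {best_err / n_target:.1%})"
        )
    ijk = _rasterize(best_rx, n_slices, aspect, taper)
    shape = MuscleVoxelMap(
        ijk=ijk,
        ff=np.zeros(len(ijk)),
        voxel_dims=voxel_dims,
        muscle_name=name,
        subject_id=subject_id,
        group=group,
    )
    part = shell_centre_partition(shape)
    ff = np.full(len(ijk), float(centre_ff_pct))
    ff[part.shell_idx] = shell_ff_pct
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(seed)
        ff = ff + rng.normal(0.0, noise_sd, size=len(ff))
    ff = np.clip(ff, 0.0, 100.0)
    ff = np.round(ff, 1)  # export precision is 0.1%
    return replace(shape, ff=ff)


# ---------------------------------------------------------------------------
# Countermovement-jump traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class JumpSpec:
    """Parameters of one synthetic countermovement jump.

    The centre-of-mass trajectory is quiet standing, a sinusoidal
    countermovement dip of ``dip_depth_m``, a sinusoidal push of
    ``push_duration_s`` that returns the CoM to standing height, and a
    short linear force release to zero (take-off), followed by flight.
    ``dip_duration_s`` defaults so the peak downward acceleration is
    0.7 g, keeping the force positive throughout the dip.
    """

    body_mass_kg: float
    dip_depth_m: float = 0.30
    push_duration_s: float = 0.28
    dip_duration_s: float | None = None
    sample_rate_hz: float = 800.0
    quiet_duration_s: float = 1.0
    release_duration_s: float = 0.05
    noise_sd_n: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.body_mass_kg <= 0:
            raise SyntheticError("mass must be positive")
        if self.dip_depth_m <= 0:
            raise SyntheticError("dip depth must be positive")
        if self.push_duration_s <= 0 or self.release_duration_s <= 0:
            raise SyntheticError("phase durations must be positive")
        if self.sample_rate_hz <= 0:
            raise SyntheticError("sample rate must be positive")
        if self.quiet_duration_s < 1.0:
            raise SyntheticError("need at least 1 s of quiet standing")


@dataclass(frozen=True)
class JumpGroundTruth:
    """Analytic kinematics of a generated jump, evaluated at sample times."""

    velocity_ms: np.ndarray
    power_w: np.ndarray
    peak_power_kw: float
    takeoff_time_s: float
    takeoff_velocity_ms: float
    flight_height_m: float


def _jump_profile(spec: JumpSpec):
    """Closed-form (force, velocity) functions of time for a jump spec."""
    m, g = spec.body_mass_kg, GRAVITY
    dip, t_q = spec.dip_depth_m, spec.quiet_duration_s
    t_d = spec.dip_duration_s
    if t_d is None:
        t_d = float(np.sqrt(2.0 * np.pi * dip / (0.7 * g)))
    amp_dip = 2.0 * np.pi * dip / t_d**2
    if amp_dip >= g:
        raise SyntheticError(
            f"dip of {dip} m in {t_d:.2f} s needs a downward acceleration of "
            f"{amp_dip:.1f} m/s^2 >= g: force would go negative before flight"
        )
    t_p, t_r = spec.push_duration_s, spec.release_duration_s
    amp_push = np.pi * dip / t_p**2
    omega_d = 2.0 * np.pi / t_d
    omega_p = np.pi / t_p
    v_push_end = 2.0 * amp_push * t_p / np.pi
    v_to = v_push_end - g * t_r / 2.0
    if v_to <= 0:
        raise SyntheticError("release longer than the push can sustain: no take-off")
    t0_dip = t_q
    t0_push = t_q + t_d
    t0_rel = t0_push + t_p
    t_takeoff = t0_rel + t_r

    def accel(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a = np.zeros_like(t)
        u = t - t0_dip
        in_dip = (t >= t0_dip) & (t < t0_push)
        a[in_dip] = -amp_dip * np.sin(omega_d * u[in_dip])
        u = t - t0_push
        in_push = (t >= t0_push) & (t < t0_rel)
        a[in_push] = amp_push * np.sin(omega_p * u[in_push])
        u = t - t0_rel
        in_rel = (t >= t0_rel) & (t < t_takeoff)
        a[in_rel] = -g * u[in_rel] / t_r
        a[t >= t_takeoff] = -g
        return a

    def velocity(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        v = np.zeros_like(t)
        u = t - t0_dip
        in_dip = (t >= t0_dip) & (t < t0_push)
        v[in_dip] = (amp_dip / omega_d) * (np.cos(omega_d * u[in_dip]) - 1.0)
        u = t - t0_push
        in_push = (t >= t0_push) & (t < t0_rel)
        v[in_push] = (amp_push / omega_p) * (1.0 - np.cos(omega_p * u[in_push]))
        u = t - t0_rel
        in_rel = (t >= t0_rel) & (t < t_takeoff)
        v[in_rel] = v_push_end - g * u[in_rel] ** 2 / (2.0 * t_r)
        u = t - t_takeoff
        post = t >= t_takeoff
        v[post] = v_to - g * u[post]
        return v

    def force(t: np.ndarray) -> np.ndarray:
        f = m * (GRAVITY + accel(t))
        return np.where(np.asarray(t) >= t_takeoff, 0.0, np.clip(f, 0.0, None))

    return force, velocity, t_takeoff, v_to


def analytic_peak_power(spec: JumpSpec, dt: float = 2e-5) -> float:
    """Peak of F(t)*v(t) before take-off from the closed-form trajectory (kW)."""
    force, velocity, t_takeoff, _ = _jump_profile(spec)
    t_q = spec.quiet_duration_s
    t = np.arange(t_q, t_takeoff, dt)
    return float((force(t) * velocity(t)).max() / 1000.0)


def generate_jump_trace(spec: JumpSpec) -> tuple[ForceTrace, JumpGroundTruth]:
    """Sample a jump's ground-reaction force and return it with ground truth.

    The trace starts with >= 1 s of quiet standing at mass x 9.81 N, force
    is clipped at exactly 0 during flight (take-off is where the clipping
    starts), and the ground-truth peak power comes from the closed-form
    trajectory evaluated on a dense grid, not from the sampled trace.
    """
    force, velocity, t_takeoff, v_to = _jump_profile(spec)
    flight = 2.0 * v_to / GRAVITY
    total = t_takeoff + flight + 0.05
    t = np.arange(0.0, total, 1.0 / spec.sample_rate_hz)
    f = force(t)
    if spec.noise_sd_n > 0:
        rng = np.random.default_rng(spec.seed)
        contact = f > 0
        f = np.where(contact, np.clip(f + rng.normal(0, spec.noise_sd_n, len(f)), 0, None), f)
    v = velocity(t)
    power = f * v
    truth = JumpGroundTruth(
        velocity_ms=v,
        power_w=power,
        peak_power_kw=analytic_peak_power(spec),
        takeoff_time_s=t_takeoff,
        takeoff_velocity_ms=v_to,
        flight_height_m=v_to**2 / (2.0 * GRAVITY),
    )
    return ForceTrace(f, spec.sample_rate_hz), truth


def calibrate_dip_for_power(
    body_mass_kg: float,
    target_peak_power_kw: float,
    push_duration_s: float = 0.28,
    dip_bounds_m: tuple[float, float] = (0.06, 0.65),
    **spec_kwargs,
) -> JumpSpec:
    """Solve for the dip depth whose analytic peak power matches a target.

    Peak power grows monotonically with dip depth at fixed push duration;
    the target is clipped into the achievable range (with a warning) before
    root finding.
    """

    def peak(dip: float) -> float:
        return analytic_peak_power(
            JumpSpec(body_mass_kg, dip_depth_m=dip, push_duration_s=push_duration_s,
                     **spec_kwargs)
        )

    lo, hi = dip_bounds_m
    p_lo, p_hi = peak(lo), peak(hi)
    target = target_peak_power_kw
    if not p_lo <= target <= p_hi:
        clipped = float(np.clip(target, p_lo * 1.001, p_hi * 0.999))
        warnings.warn(
            f"target {target:.2f} kW outside achievable [{p_lo:.2f}, {p_hi:.2f}] kW "
            f"for {body_mass_kg:.0f} kg; using {clipped:.2f} kW",
            stacklevel=2,
        )
        target = clipped
    dip = brentq(lambda d: peak(d) - target, lo, hi, xtol=1e-6)
    return JumpSpec(body_mass_kg, dip_depth_m=float(dip),
                    push_duration_s=push_duration_s, **spec_kwargs)


# ---------------------------------------------------------------------------
# MRS FIDs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MrsSpec:
    """Parameters of a synthetic three-resonance soleus 1H FID."""

    amplitudes: tuple[float, float, float] = (90.0, 7.0, 3.0)
    ppm: tuple[float, float, float] = DEFAULT_PPM
    dampings: tuple[float, float, float] = (20.0, 50.0, 25.0)
    spectrometer_frequency_mhz: float = 123.25
    bandwidth_hz: float = 2000.0
    n_points: int = 1024
    reference_ppm: float = 4.7
    phase_rad: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(a < 0 for a in self.amplitudes):
            raise SyntheticError("amplitudes must be >= 0")
        if not self.ppm[1] > self.ppm[2]:
            raise SyntheticError("EMCL shift must exceed IMCL shift")
        if self.bandwidth_hz <= 0 or self.n_points <= 0:
            raise SyntheticError("bandwidth and n_points must be positive")
        if any(d <= 0 for d in self.dampings):
            raise SyntheticError("dampings must be positive")
        if self.noise_sd < 0:
            raise SyntheticError("noise_sd must be >= 0")

    def peak_model(self) -> PeakModel:
        return PeakModel(
            amplitudes=self.amplitudes,
            ppm=self.ppm,
            dampings=self.dampings,
            phase_rad=self.phase_rad,
        )


def generate_fid(spec: MrsSpec, subject_id: str = "") -> tuple[FidRecord, PeakModel]:
    """Synthesise a damped-exponential FID plus its generating peak model.

    FID_n = sum_k A_k exp(-d_k t_n) exp(i 2 pi f_k t_n), with f_k from the
    ppm offsets relative to the reference, plus circularly-symmetric
    complex Gaussian noise: ``noise_sd`` is the SD of the complex noise
    (sqrt(E|z|^2)), i.e. noise_sd/sqrt(2) per real/imaginary component.
    """
    t = np.arange(spec.n_points) / spec.bandwidth_hz
    truth = spec.peak_model()
    sig = model_fid(truth, t, spec.spectrometer_frequency_mhz, spec.reference_ppm)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        comp_sd = spec.noise_sd / np.sqrt(2.0)
        sig = sig + rng.normal(0, comp_sd, spec.n_points) + 1j * rng.normal(
            0, comp_sd, spec.n_points
        )
    fid = FidRecord(
        samples=sig,
        bandwidth_hz=spec.bandwidth_hz,
        spectrometer_frequency_mhz=spec.spectrometer_frequency_mhz,
        reference_ppm=spec.reference_ppm,
        subject_id=subject_id,
    )
    return fid, truth


# ---------------------------------------------------------------------------
# Whole cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupDescriptor:
    """One subject group: label, size and anthropometric distributions."""

    label: str
    n: int
    age_y: tuple[float, float]
    height_cm: tuple[float, float]
    mass_kg: tuple[float, float]

    def __post_init__(self):
        if self.n < 1:
            raise SyntheticError("group size must be >= 1")
        for mean, sd in (self.age_y, self.height_cm, self.mass_kg):
            if sd < 0:
                raise SyntheticError("SDs must be >= 0")


@dataclass(frozen=True)
class MuscleDescriptor:
    """One muscle: per-group nominal volume and shell/centre FF distributions."""

    name: str
    volume_ml: dict
    shell_ff: dict  # group -> (mean, sd), percent
    centre_ff: dict  # group -> (mean, sd), percent

    def __post_init__(self):
        for group, (mean, sd) in {**self.shell_ff, **self.centre_ff}.items():
            if not 0 <= mean <= 100:
                raise SyntheticError(f"{self.name}/{group}: FF mean outside [0, 100]")
            if sd < 0:
                raise SyntheticError(f"{self.name}/{group}: negative FF SD")
        for group, v in self.volume_ml.items():
            if v <= 0:
                raise SyntheticError(f"{self.name}/{group}: volume must be positive")


@dataclass(frozen=True)
class CohortSpec:
    """Full description of a synthetic four-group cohort."""

    groups: tuple[GroupDescriptor, ...]
    muscles: tuple[MuscleDescriptor, ...]
    voxel_dims: tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    ff_noise_sd: float = 1.0
    power_lines: dict = field(default_factory=lambda: reference.POWER_VOLUME_LINES)
    power_residual_sd_kw: dict = field(
        default_factory=lambda: {"young": 0.33, "old": 0.38}
    )
    mrs_lipid_pct: dict = field(default_factory=lambda: reference.MRS_LIPID_PCT)
    mrs_noise_sd: float = 0.5
    push_duration_s: float = 0.28
    n_jumps: int = 3
    seed: int = 0

    def __post_init__(self):
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise SyntheticError("duplicate group labels")


@dataclass
class SubjectBundle:
    """All generated inputs and ground truth for one subject."""

    subject_id: str
    group: str
    age_y: float
    height_cm: float
    mass_kg: float
    maps: dict
    jump_traces: list
    jump_truths: list
    fid: FidRecord
    mrs_truth: PeakModel
    nominal_composite_volume_ml: float
    target_peak_power_kw: float


@dataclass
class CohortBundle:
    spec: CohortSpec
    subjects: list

    def table(self):
        """Subject table: subject_id, group, age_y, height_cm, mass_kg."""
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "subject_id": s.subject_id,
                    "group": s.group,
                    "age_y": round(s.age_y, 1),
                    "height_cm": round(s.height_cm, 1),
                    "mass_kg": round(s.mass_kg, 1),
                }
                for s in self.subjects
            ]
        )


def default_cohort_spec(
    voxel_dims: tuple[float, float, float] = (2.34, 2.34, 10.0),
    n_per_group: dict | int | None = None,
    seed: int = 0,
) -> CohortSpec:
    """The built-in cohort: published anthropometrics, jumping muscles with
    published shell/centre FF, composite volumes split by fixed anatomical
    fractions, and published power-volume regression lines.

    The default grid is coarsened 2x in plane and in slice thickness so a
    full 43-subject cohort stays cheap; pass the scanner dims
    (1.17, 1.17, 5.0) for single-muscle studies.
    """
    groups = []
    for label in reference.GROUPS:
        a = reference.ANTHROPOMETRICS[label]
        n = a["n"]
        if isinstance(n_per_group, int):
            n = n_per_group
        elif isinstance(n_per_group, dict):
            n = n_per_group.get(label, n)
        groups.append(
            GroupDescriptor(label, n, a["age_y"], a["height_cm"], a["mass_kg"])
        )
    muscles = []
    for name, frac in reference.JUMPING_MUSCLE_FRACTIONS.items():
        ff = reference.SHELL_CENTRE_FF[name]
        muscles.append(
            MuscleDescriptor(
                name=name,
                volume_ml={
                    g: frac * reference.JUMPING_COMPOSITE[g]["volume_ml"][0]
                    for g in reference.GROUPS
                },
                shell_ff={g: ff[g][:2] for g in reference.GROUPS},
                centre_ff={g: ff[g][2:4] for g in reference.GROUPS},
            )
        )
    return CohortSpec(
        groups=tuple(groups), muscles=tuple(muscles), voxel_dims=voxel_dims, seed=seed
    )


def _age_class(label: str) -> str:
    return "old" if label.startswith("old") else "young"


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate one bundle per subject: maps, jump traces, FID, ground truth.

    Per-subject draws use the group's mean/SD.  A single multiplicative
    volume scale per subject (CV of the group's composite volume) keeps
    muscle volumes correlated within a subject, as they are in vivo; jump
    peak power is drawn around the age group's power-volume regression
    line and the jump trace is calibrated to deliver exactly that power.
    """
    root = np.random.SeedSequence(spec.seed)
    subjects: list[SubjectBundle] = []
    composite_means = {
        g.label: sum(m.volume_ml[g.label] for m in spec.muscles) for g in spec.groups
    }
    for group in spec.groups:
        label = group.label
        age_class = _age_class(label)
        line = spec.power_lines[age_class]
        comp_ref = reference.JUMPING_COMPOSITE.get(label)
        cv = (
            comp_ref["volume_ml"][1] / comp_ref["volume_ml"][0]
            if comp_ref
            else 0.15
        )
        for i in range(group.n):
            sid = f"{label}_{i + 1:02d}"
            rng = np.random.default_rng(root.spawn(1)[0])
            age = rng.normal(*group.age_y)
            height = rng.normal(*group.height_cm)
            mass = float(np.clip(rng.normal(*group.mass_kg), 45.0, 150.0))
            scale = max(rng.normal(1.0, cv), 0.3)
            maps = {}
            comp_nominal = 0.0
            i_offset = 0  # stack muscles along i so segmentations are disjoint
            for m in spec.muscles:
                jitter = max(rng.normal(1.0, 0.03), 0.5)
                vol = m.volume_ml[label] * scale * jitter
                comp_nominal += vol
                centre = max(rng.normal(*m.centre_ff[label]), 0.2)
                shell = max(rng.normal(*m.shell_ff[label]), centre + 0.2)
                mm = generate_muscle_map(
                    m.name,
                    vol,
                    shell_ff_pct=min(shell, 100.0),
                    centre_ff_pct=min(centre, 100.0),
                    noise_sd=spec.ff_noise_sd,
                    voxel_dims=spec.voxel_dims,
                    rng=rng,
                    subject_id=sid,
                    group=label,
                )
                shifted = mm.ijk.copy()
                shifted[:, 0] += i_offset
                mm = replace(mm, ijk=shifted)
                i_offset = int(shifted[:, 0].max()) + 3
                maps[m.name] = mm
            target_kw = (
                line["intercept_kw"]
                + line["slope_w_per_ml"] * comp_nominal / 1000.0
                + rng.normal(0.0, spec.power_residual_sd_kw[age_class])
            )
            target_kw = max(target_kw, 0.5)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # rare out-of-range targets clip
                base = calibrate_dip_for_power(
                    mass, target_kw, push_duration_s=spec.push_duration_s
                )
            traces, truths = [], []
            for j, factor in enumerate((1.0, 0.99, 1.01)[: spec.n_jumps]):
                jump_spec = replace(base, dip_depth_m=base.dip_depth_m * factor,
                                    seed=int(rng.integers(2**31)))
                trace, truth = generate_jump_trace(jump_spec)
                traces.append(replace(trace, subject_id=sid))
                truths.append(truth)
            lip = spec.mrs_lipid_pct[label]
            emcl = max(rng.normal(*lip["emcl"]), 0.1)
            imcl = max(rng.normal(*lip["imcl"]), 0.1)
            emcl = max(emcl, imcl + 0.3)  # EMCL distinctly above IMCL
            water = 100.0 - emcl - imcl
            fid, mrs_truth = generate_fid(
                MrsSpec(
                    amplitudes=(water, emcl, imcl),
                    noise_sd=spec.mrs_noise_sd,
                    seed=int(rng.integers(2**31)),
                ),
                subject_id=sid,
            )
            subjects.append(
                SubjectBundle(
                    subject_id=sid,
                    group=label,
                    age_y=age,
                    height_cm=height,
                    mass_kg=mass,
                    maps=maps,
                    jump_traces=traces,
                    jump_truths=truths,
                    fid=fid,
                    mrs_truth=mrs_truth,
                    nominal_composite_volume_ml=comp_nominal,
                    target_peak_power_kw=float(target_kw),
                )
            )
    ids = [s.subject_id for s in subjects]
    if len(set(ids)) != len(ids):
        raise SyntheticError("duplicate subject identifiers")
    return CohortBundle(spec=spec, subjects=subjects)


def simulate_power_volume(
    n: int,
    slope_w_per_ml: float,
    intercept_kw: float,
    volume_mean_ml: float,
    volume_sd_ml: float,
    residual_sd_kw: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (volume, peak power) pairs around a power-volume regression line."""
    v = rng.normal(volume_mean_ml, volume_sd_ml, n)
    v = np.clip(v, 500.0, None)
    p = intercept_kw + slope_w_per_ml * v / 1000.0 + rng.normal(0, residual_sd_kw, n)
    return v, p
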