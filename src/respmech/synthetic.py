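"""Synthetic trial generation with known ground truth.

No public dataset of trunk-surface optical markers during slow whole-body
movement exists for this pipeline, so every stage is validated against
simulated trials whose generating parameters are known exactly:

* a 4-ring x 8-column trunk whose ring cross-sections breathe with a
  raised-cosine waveform — the ring scale factors are solved in closed form
  so each compartment band's volume excursion equals its configured share of
  the tidal volume, and the per-frame band volumes are known analytically
  (prismatoid formula), never measured from the mesh being tested;
* an articulated 14-segment stick body with programmed tri-planar joint
  oscillations; the root translation is solved so the model COM follows the
  programmed trajectory exactly:  COM X = (1 - kappa) * independent sway +
  kappa * (scaled breathing signal), with the coupling coefficient kappa in
  [0, 1] the dial the coupling stage is tested against;
* force-plate channels whose moments are synthesized from a COP that tracks
  the ground-truth COM projection, and EMG channels made of band-limited
  noise bursts phase-locked to the movement cycles;
* a two-group cohort generator producing participant-level outcome tables
  (normal except log-normal tidal volume, to exercise both Shapiro-Wilk
  routes) with configurable group shifts.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps

from .chestwall import COMPARTMENTS, VolumeSeries
from .mocap_io import (
    EmgRecord,
    EventTable,
    ForcePlateRecord,
    MarkerTrajectorySet,
    MUSCLES,
    TrialBundle,
    synchronize,
)
from .posture import ComTrajectory, default_segment_model, whole_body_com

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "SyntheticTrial",
    "breathing_waveform",
    "generate_trunk",
    "generate_body",
    "generate_plate_and_emg",
    "generate_trial",
    "generate_cohort",
]

GRAVITY = 9.81  # m/s^2


@dataclass
class SyntheticConfig:
    """Generating parameters of one synthetic trial.

    Defaults emulate the study conditions: a 100 Hz kinematic system with
    1000 Hz plates and EMG; an older-adult cohort breathing slowly and
    deeply during slow multi-directional movement (breathing ~15 breaths/min
    with inspiration shorter than expiration, tidal volume 0.8 L carried
    mostly by the lower thorax); slow centimetre-scale sway; three movement
    cycles per trial.
    """

    duration: float = 30.0  # s
    marker_rate: float = 100.0
    plate_rate: float = 1000.0
    emg_rate: float = 1000.0
    # breathing
    breathing_rate_bpm: float = 15.0
    ti_te_ratio: float = 0.67  # Ti / Te
    tidal_volume: float = 0.8  # L
    compartment_weights: tuple[float, float, float] = (0.25, 0.45, 0.30)
    # sway (m) and its quasi-periodic frequencies (Hz) per axis
    sway_amplitude: tuple[float, float, float] = (0.03, 0.02, 0.01)
    sway_frequency: tuple[float, float, float] = (0.10, 0.13, 0.17)
    # coupling: fraction of the X COM displacement driven by breathing
    kappa: float = 0.0
    # movement cycles and programmed joint oscillation amplitudes (deg,
    # half-range) per joint: (sagittal, frontal, transverse)
    n_cycles: int = 3
    movement: str = "WHM"
    joint_amplitudes: dict = field(
        default_factory=lambda: {
            "hip": (25.0, 10.0, 8.0),
            "knee": (30.0, 8.0, 5.0),
            "ankle": (15.0, 10.0, 6.0),
        }
    )
    # anthropometry (cohort means) and noise
    stature_mm: float = 1680.0
    mass_kg: float = 69.0
    marker_noise_mm: float = 0.5  # typical optical residual
    emg_noise_mv: float = 0.01
    emg_burst_mv: float = 0.2
    emg_reference_peak_mv: float = 0.5
    cop_noise_m: float = 0.0005
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.marker_rate, self.plate_rate, self.emg_rate):
            if not rate > 0:
                raise ValueError("all rates must be > 0")
        if abs(sum(self.compartment_weights) - 1.0) > 1e-9:
            raise ValueError("compartment weights must sum to 1")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")

    @property
    def breath_period(self) -> float:
        return 60.0 / self.breathing_rate_bpm

    @property
    def Ti(self) -> float:
        return self.breath_period * self.ti_te_ratio / (1.0 + self.ti_te_ratio)

    @property
    def Te(self) -> float:
        return self.breath_period / (1.0 + self.ti_te_ratio)


@dataclass
class GroundTruth:
    """Configured parameters echoed alongside analytic per-frame signals."""

    config: SyntheticConfig
    analytic_volume: VolumeSeries  # closed-form band volumes, L
    com: ComTrajectory  # programmed COM trajectory, m
    cop: np.ndarray  # programmed COP (n_plate, 2), m
    joint_rom: dict[str, dict[str, float]]  # joint -> plane -> deg
    cycle_windows: list[tuple[float, float]]

    def to_json(self) -> str:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(self.config).items()
            },
            "joint_rom": self.joint_rom,
            "cycle_windows": [list(w) for w in self.cycle_windows],
        }
        return json.dumps(payload, indent=2)


@dataclass
class SyntheticTrial:
    bundle: TrialBundle
    truth: GroundTruth


# ---------------------------------------------------------------------------
# breathing waveform
# ---------------------------------------------------------------------------


def breathing_waveform(t: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    """Piecewise raised-cosine breathing drive in [0, 1].

    Starts at a trough; rises over Ti as ``(1 - cos(pi u / Ti)) / 2`` and
    falls over Te as the mirror image.  Differentiable, with unambiguous
    peaks at ``k T + Ti``.
    """
    period = config.breath_period
    ti = config.Ti
    u = np.mod(t, period)
    rising = u < ti
    w = np.empty_like(u)
    w[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / ti))
    w[~rising] = 0.5 * (1.0 + np.cos(np.pi * (u[~rising] - ti) / config.Te))
    return w


# ---------------------------------------------------------------------------
# trunk
# ---------------------------------------------------------------------------

# trunk geometry (mm): ring heights cranial -> caudal and elliptic section
RING_Z = (1400.0, 1250.0, 1100.0, 950.0)
ELLIPSE_A = 140.0  # anteroposterior semi-axis
ELLIPSE_B = 100.0  # mediolateral semi-axis
N_COLS = 8


def _octagon_area(a: float, b: float, cols: int) -> float:
    """Area of the polygon inscribed in the (a, b) ellipse with ``cols``
    equally-spaced parametric vertices."""
    return 0.5 * cols * math.sin(2.0 * math.pi / cols) * a * b


def _solve_ring_amplitudes(config: SyntheticConfig) -> np.ndarray:
    """Ring scale amplitudes alpha_r with alpha_0 = 0 (the sternal-notch
    ring barely moves) such that each band's volume excursion at full
    inspiration equals its configured share of the tidal volume.

    Band volume between rings r, r+1 with scales s_r = 1 + alpha_r w is the
    prismatoid ``V = h A (s_r^2 + s_r s_{r+1} + s_{r+1}^2) / 3``, so the
    excursion condition is a quadratic in alpha_{r+1} given alpha_r and is
    solved ring by ring in closed form.
    """
    area = _octagon_area(ELLIPSE_A, ELLIPSE_B, N_COLS)
    alphas = [0.0]
    for k, weight in enumerate(config.compartment_weights):
        h = RING_Z[k] - RING_Z[k + 1]
        target_mm3 = weight * config.tidal_volume * 1e6
        c = 3.0 * target_mm3 / (h * area)
        a = alphas[-1]
        disc = (a + 3.0) ** 2 - 4.0 * (a * a + 3.0 * a - c)
        if disc < 0:
            raise ValueError("tidal volume unreachable for this trunk geometry")
        alphas.append((-(a + 3.0) + math.sqrt(disc)) / 2.0)
    return np.asarray(alphas)


def _band_volume_mm3(h: float, area: float, s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    return h * area * (s0 * s0 + s0 * s1 + s1 * s1) / 3.0


def generate_trunk(
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    center: np.ndarray | None = None,
) -> tuple[MarkerTrajectorySet, VolumeSeries]:
    """Chest-wall markers plus the analytic compartment volume series.

    ``center`` optionally translates the whole trunk per frame (shape
    ``(n, 3)``, mm) — enclosed volumes are translation invariant, so the
    analytic series is unaffected.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = int(round(config.duration * config.marker_rate)) + 1
    t = np.arange(n) / config.marker_rate
    w = breathing_waveform(t, config)
    alphas = _solve_ring_amplitudes(config)
    scales = 1.0 + np.outer(w, alphas)  # (n, 4)

    theta = 2.0 * np.pi * np.arange(N_COLS) / N_COLS
    base = np.stack(
        [ELLIPSE_A * np.cos(theta), ELLIPSE_B * np.sin(theta)], axis=1
    )  # (8, 2)
    pos = np.empty((n, 4 * N_COLS, 3))
    for r in range(4):
        ring = scales[:, r, None, None] * base[None, :, :]  # (n, 8, 2)
        pos[:, r * N_COLS : (r + 1) * N_COLS, :2] = ring
        pos[:, r * N_COLS : (r + 1) * N_COLS, 2] = RING_Z[r]
    if center is not None:
        pos += center[:, None, :]
    if config.marker_noise_mm > 0:
        pos = pos + rng.normal(0.0, config.marker_noise_mm, pos.shape)
    labels = [f"CW_{r}_{c}" for r in range(4) for c in range(N_COLS)]
    markers = MarkerTrajectorySet(labels, pos, config.marker_rate)

    area = _octagon_area(ELLIPSE_A, ELLIPSE_B, N_COLS)
    comps = {}
    for k, name in enumerate(COMPARTMENTS):
        h = RING_Z[k] - RING_Z[k + 1]
        comps[name] = _band_volume_mm3(h, area, scales[:, k], scales[:, k + 1]) / 1e6
    total = sum(comps.values())
    analytic = VolumeSeries(time=t, total=total, compartments=comps,
                            valid_mask=np.ones(n, dtype=bool))
    return markers, analytic


# ---------------------------------------------------------------------------
# body
# ---------------------------------------------------------------------------

# stick-body dimensions as fractions of stature
_DIM = {
    "thigh": 0.245, "shank": 0.246, "foot": 0.10,
    "trunk": 0.30, "head": 0.13, "upper_arm": 0.186, "forearm": 0.146,
    "hand": 0.06, "hip_half_width": 0.05, "shoulder_half_width": 0.12,
}

#: triad marker names per lower-limb segment: (proximal joint, distal joint,
#: lateral cluster marker); the pelvis triad closes the hip joint.
JOINT_TRIADS = {
    "pelvis": ("SACR", "PELVD", "PELVL"),
    "thigh_R": ("RHIP", "RKNE", "RTHI"),
    "shank_R": ("RKNE", "RANK", "RSHA"),
    "foot_R": ("RANK", "RTOE", "RFOO"),
    "thigh_L": ("LHIP", "LKNE", "LTHI"),
    "shank_L": ("LKNE", "LANK", "LSHA"),
    "foot_L": ("LANK", "LTOE", "LFOO"),
}


def _cardan_matrix(sag: np.ndarray, fro: np.ndarray, tra: np.ndarray) -> np.ndarray:
    """Intrinsic X-Y-Z rotation matrices from per-frame angles (rad)."""
    from scipy.spatial.transform import Rotation

    return Rotation.from_euler("XYZ", np.stack([sag, fro, tra], axis=1)).as_matrix()


def _lowpass_noise(rng, n: int, rate: float, cutoff: float) -> np.ndarray:
    """Unit-variance low-pass filtered Gaussian noise (quasi-random sway)."""
    x = rng.standard_normal(n)
    sos = sps.butter(2, cutoff, btype="low", fs=rate, output="sos")
    y = sps.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def generate_body(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[MarkerTrajectorySet, ComTrajectory, dict[str, dict[str, float]]]:
    """Whole-body markers, ground-truth COM and programmed joint ROMs.

    Lower-limb segments carry marker triads so segment frames — and hence
    the programmed tri-planar joint angles — are exactly recoverable.  The
    root translation is solved so that the segment-model COM equals the
    programmed trajectory: X mixes independent sway with the breathing
    drive according to ``kappa``, Y and Z are pure sway.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = int(round(config.duration * config.marker_rate)) + 1
    t = np.arange(n) / config.marker_rate
    rate = config.marker_rate
    s = config.stature_mm

    # programmed COM targets (m, about a standing reference)
    w = breathing_waveform(t, config)
    breath_drive = w - w.mean()
    bsd = breath_drive.std()
    if bsd > 0:
        breath_drive = breath_drive / bsd
    targets = []
    for ax in range(3):
        amp, freq = config.sway_amplitude[ax], config.sway_frequency[ax]
        phase = rng.uniform(0.0, 2.0 * np.pi)
        sway = np.sin(2.0 * np.pi * freq * t + phase) / math.sqrt(0.5)
        sway = 0.7 * sway + 0.3 * _lowpass_noise(rng, n, rate, 0.15)
        if ax == 0:
            mix = (1.0 - config.kappa) * sway + config.kappa * breath_drive
        else:
            mix = sway
        targets.append(amp * mix)
    com_target = np.stack(targets, axis=1)  # (n, 3) m, zero-mean-ish

    # joint angle programs: sinusoids at the movement-cycle frequency with
    # plane-specific phases; both sides share the program mirrored in sign
    f_cycle = config.n_cycles / config.duration
    angles: dict[str, np.ndarray] = {}
    rom: dict[str, dict[str, float]] = {}
    for joint, amps in config.joint_amplitudes.items():
        phases = {"sagittal": 0.0, "frontal": np.pi / 3, "transverse": 2 * np.pi / 3}
        cols = []
        rom[joint] = {}
        for (plane, ph), amp in zip(phases.items(), amps):
            cols.append(np.radians(amp) * np.sin(2 * np.pi * f_cycle * t + ph))
            rom[joint][plane] = 2.0 * amp  # peak-to-peak, deg
        angles[joint] = np.stack(cols, axis=1)

    # forward kinematics (mm), root at origin; Z up, X anterior, Y to the left
    lab: dict[str, np.ndarray] = {}
    hipw = _DIM["hip_half_width"] * s
    l_thigh, l_shank, l_foot = (_DIM[k] * s for k in ("thigh", "shank", "foot"))
    pelvis_R = np.broadcast_to(np.eye(3), (n, 3, 3))
    lab["SACR"] = np.zeros((n, 3))
    lab["PELVD"] = np.tile([0.0, 0.0, -80.0], (n, 1))
    lab["PELVL"] = np.tile([60.0, 0.0, -80.0], (n, 1))
    for side, sign in (("R", -1.0), ("L", 1.0)):
        hip = np.tile([0.0, sign * hipw, 0.0], (n, 1))
        r_thigh = _cardan_matrix(*(angles["hip"][:, i] for i in range(3)))
        knee = hip + np.einsum("nij,j->ni", r_thigh, [0.0, 0.0, -l_thigh])
        r_shank = np.einsum(
            "nij,njk->nik", r_thigh,
            _cardan_matrix(*(angles["knee"][:, i] for i in range(3))),
        )
        ank = knee + np.einsum("nij,j->ni", r_shank, [0.0, 0.0, -l_shank])
        r_foot = np.einsum(
            "nij,njk->nik", r_shank,
            _cardan_matrix(*(angles["ankle"][:, i] for i in range(3))),
        )
        toe = ank + np.einsum("nij,j->ni", r_foot, [0.0, 0.0, -l_foot])
        lab[f"{side}HIP"] = hip
        lab[f"{side}KNE"] = knee
        lab[f"{side}ANK"] = ank
        lab[f"{side}TOE"] = toe
        lab[f"{side}THI"] = knee + np.einsum("nij,j->ni", r_thigh, [70.0, 0.0, 0.0])
        lab[f"{side}SHA"] = ank + np.einsum("nij,j->ni", r_shank, [70.0, 0.0, 0.0])
        lab[f"{side}FOO"] = toe + np.einsum("nij,j->ni", r_foot, [40.0, 0.0, 0.0])
    # static upper body (hangs with the root)
    trunk_l = _DIM["trunk"] * s
    lab["C7"] = np.tile([0.0, 0.0, trunk_l], (n, 1))
    lab["HEADT"] = np.tile([0.0, 0.0, trunk_l + _DIM["head"] * s], (n, 1))
    shw = _DIM["shoulder_half_width"] * s
    for side, sign in (("R", -1.0), ("L", 1.0)):
        sho = np.tile([0.0, sign * shw, trunk_l], (n, 1))
        elb = sho + [0.0, 0.0, -_DIM["upper_arm"] * s]
        wri = elb + [0.0, 0.0, -_DIM["forearm"] * s]
        fin = wri + [0.0, 0.0, -_DIM["hand"] * s]
        lab[f"{side}SHO"], lab[f"{side}ELB"] = sho, elb
        lab[f"{side}WRI"], lab[f"{side}FIN"] = wri, fin

    labels = list(lab)
    pos = np.stack([lab[k] for k in labels], axis=1)
    model = default_segment_model()
    zero_root = MarkerTrajectorySet(labels, pos, rate)
    com0 = whole_body_com(zero_root, model).com  # m, pose-dependent part
    # COM is translation-equivariant: shift the root so COM hits the target
    standing_height = np.array([0.0, 0.0, 0.55 * s / 1000.0])  # pelvis ref, m
    root_m = com_target + standing_height - com0
    pos = pos + 1000.0 * root_m[:, None, :]
    if config.marker_noise_mm > 0:
        pos = pos + rng.normal(0.0, config.marker_noise_mm, pos.shape)
    markers = MarkerTrajectorySet(labels, pos, rate)
    com_truth = ComTrajectory(time=t, com=com_target + standing_height)
    return markers, com_truth, rom


# ---------------------------------------------------------------------------
# plate and EMG
# ---------------------------------------------------------------------------


def generate_plate_and_emg(
    config: SyntheticConfig,
    com_truth: ComTrajectory,
    rng: np.random.Generator | None = None,
) -> tuple[ForcePlateRecord, EmgRecord]:
    """Force-plate and EMG channels consistent with the ground-truth COM.

    Fz carries body weight plus the vertical inertial force m * z''; plate
    moments are synthesized by inverting the COP equations from a COP that
    tracks the COM's horizontal projection (plus optional noise).  EMG is
    band-limited noise amplitude-modulated by raised-cosine bursts
    phase-locked to the movement cycles, one phase offset per muscle.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = int(round(config.duration * config.plate_rate)) + 1
    t = np.arange(n) / config.plate_rate
    com = np.stack(
        [np.interp(t, com_truth.time, com_truth.com[:, i]) for i in range(3)], axis=1
    )
    m = config.mass_kg
    zacc = np.gradient(np.gradient(com[:, 2], t), t)
    fz = m * (GRAVITY + zacc)
    cop = com[:, :2].copy()
    if config.cop_noise_m > 0:
        cop += rng.normal(0.0, config.cop_noise_m, cop.shape)
    forces = np.zeros((n, 3))
    forces[:, 2] = fz
    moments = np.zeros((n, 3))
    moments[:, 0] = cop[:, 1] * fz  # Mx =  cop_y * Fz
    moments[:, 1] = -cop[:, 0] * fz  # My = -cop_x * Fz
    plate = ForcePlateRecord(forces=forces, moments=moments, rate=config.plate_rate)

    ne = int(round(config.duration * config.emg_rate)) + 1
    te = np.arange(ne) / config.emg_rate
    f_cycle = config.n_cycles / config.duration
    sos = sps.butter(4, [20.0, min(450.0, 0.45 * config.emg_rate)],
                     btype="bandpass", fs=config.emg_rate, output="sos")
    channels = {}
    for i, muscle in enumerate(MUSCLES):
        for j, side in enumerate(("R", "L")):
            phase = 2.0 * np.pi * (i / len(MUSCLES) + 0.5 * j)
            envelope = np.clip(np.sin(2.0 * np.pi * f_cycle * te + phase), 0.0, None)
            carrier = sps.sosfiltfilt(sos, rng.standard_normal(ne))
            carrier /= max(np.abs(carrier).max(), 1e-12)
            noise = rng.normal(0.0, config.emg_noise_mv, ne)
            channels[f"{muscle}_{side}"] = config.emg_burst_mv * envelope * carrier + noise
    emg = EmgRecord(
        channels=channels, rate=config.emg_rate,
        reference_peak={k: config.emg_reference_peak_mv for k in channels},
    )
    return plate, emg


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------


def generate_trial(config: SyntheticConfig) -> SyntheticTrial:
    """A complete aligned synthetic trial with its ground truth."""
    rng = np.random.default_rng(config.seed)
    body, com_truth, rom = generate_body(config, rng)
    # trunk rides on the upper body: centre it under C7, following the sway
    c7 = body.get("C7")
    center = c7 - np.array([0.0, 0.0, float(c7[0, 2])])  # keep ring heights
    trunk, analytic = generate_trunk(config, rng, center=center)
    all_markers = MarkerTrajectorySet(
        trunk.labels + body.labels,
        np.concatenate([trunk.positions, body.positions], axis=1),
        config.marker_rate,
    )
    plate, emg = generate_plate_and_emg(config, com_truth, rng)
    cycle_len = config.duration / config.n_cycles
    windows = [(i * cycle_len, (i + 1) * cycle_len) for i in range(config.n_cycles)]
    events = EventTable(cycles={config.movement: windows})
    bundle = synchronize(all_markers, plate, emg, events,
                         analysis_rate=config.marker_rate)
    cop_truth = com_truth.com[:, :2]
    truth = GroundTruth(
        config=config, analytic_volume=analytic, com=com_truth,
        cop=cop_truth, joint_rom=rom, cycle_windows=windows,
    )
    return SyntheticTrial(bundle=bundle, truth=truth)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

#: Baseline (beginner-group) outcome distributions: (mean, sd, family,
#: log-normal?).  Magnitudes sit in the ranges the movements produce.
COHORT_OUTCOMES: dict[str, tuple[float, float, str, bool]] = {
    "inspiratory_time_s": (0.85, 0.30, "respiratory", False),
    "expiratory_time_s": (1.00, 0.45, "respiratory", False),
    "max_respiratory_volume_L": (0.85, 0.25, "respiratory", True),
    "lower_thoracic_contribution_pct": (38.0, 6.0, "respiratory", False),
    "knee_sagittal_rom_deg": (70.0, 15.0, "rom", False),
    "ankle_frontal_rom_deg": (24.0, 6.0, "rom", False),
    "hip_sagittal_rom_deg": (42.0, 18.0, "rom", False),
    "cop_range_x_m": (0.040, 0.010, "cop", False),
    "cop_range_y_m": (0.030, 0.008, "cop", False),
    "iemg_norm_TA": (0.30, 0.10, "emg", False),
    "ccf_x": (0.72, 0.14, "coupling", False),
    "ccf_z": (0.70, 0.15, "coupling", False),
}


def generate_cohort(
    n_per_group: int = 21,
    effect_spec: dict[str, float] | None = None,
    seed: int = 0,
    outcomes: dict[str, tuple[float, float, str, bool]] | None = None,
):
    """Two-group participant-level outcome table.

    Returns a long-format pandas DataFrame with columns ``outcome, family,
    group, participant, value``.  ``effect_spec`` maps outcome names to the
    additive shift applied to the LP group (native units); everything else
    is drawn from the shared baseline distribution, so an empty spec is an
    all-null cohort.  Tidal volume is log-normal; all other outcomes are
    normal — both Shapiro-Wilk routes get exercised.
    """
    import pandas as pd

    if n_per_group < 2:
        raise ValueError("need at least 2 participants per group")
    effect_spec = effect_spec or {}
    outcomes = outcomes or COHORT_OUTCOMES
    unknown = set(effect_spec) - set(outcomes)
    if unknown:
        raise KeyError(f"effect_spec names unknown outcomes: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    rows = []
    for outcome, (mean, sd, family, lognormal) in outcomes.items():
        shift = effect_spec.get(outcome, 0.0)
        for group in ("LP", "BP"):
            mu = mean + (shift if group == "LP" else 0.0)
            if lognormal:
                sigma2 = math.log1p((sd / mu) ** 2)
                draws = rng.lognormal(
                    math.log(mu) - sigma2 / 2.0, math.sqrt(sigma2), n_per_group
                )
            else:
                draws = rng.normal(mu, sd, n_per_group)
            for p, v in enumerate(draws):
                rows.append((outcome, family, group, f"{group}{p:02d}", float(v)))
    return pd.DataFrame(rows, columns=["outcome", "family", "group", "participant", "value"])
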