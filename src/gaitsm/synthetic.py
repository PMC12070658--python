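"""Seeded synthetic gait cohorts: raw IMU channels, kinematics, positions,
events and passes, with a controllable pathology-severity parameter.

The generator emulates the structure of overground walking trials: cyclic
multi-channel signals built from fixed Fourier templates per sensor
location, cycle-duration variability, subject-level random effects, and a
deviation parameter d in [0, 1] that jointly deforms the sensor signals and
the kinematic curves (amplitude scaling, phase shift, inter-cycle asymmetry
and noise inflation).  d = 0 reproduces the template process plus noise;
larger d moves every deviation measure away from normative gait.  It is a
statistical stand-in for pathological gait, not a biomechanical model.

Templates and deviation directions are fixed library constants derived from
a frozen seed, so scores on the synthetic world are stable across releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import SENSOR_LOCATIONS, TrialRecording
from .gps import GPS_VARIABLES

__all__ = [
    "CohortSpec",
    "SubjectProfile",
    "generate_subject",
    "generate_cohort",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_DEVIATION_RANGES",
]

_TEMPLATE_SEED = 715517  # frozen: defines the versioned template library
_N_HARMONICS = 5

#: per-side kinematic streams needed by the parameter measures
SIDE_KINEMATICS = ("shank_angle", "ankle_abduction")

_KIN_AMPLITUDE = {
    "pelvic_tilt": 4.0,
    "pelvic_obliquity": 5.0,
    "pelvic_rotation": 7.0,
    "hip_flexion": 30.0,
    "hip_abduction": 8.0,
    "hip_rotation": 9.0,
    "knee_flexion": 55.0,
    "ankle_dorsiflexion": 15.0,
    "foot_progression": 8.0,
    "shank_angle": 50.0,
    "ankle_abduction": 8.0,
}


def _build_templates():
    rng = np.random.default_rng(_TEMPLATE_SEED)
    sig = {}
    for loc in SENSOR_LOCATIONS:
        scale = np.array([2.0, 2.0, 2.5, 1.2, 1.2, 1.5])[:, None]  # acc m/s^2, gyr rad/s
        decay = 1.0 / np.arange(1, _N_HARMONICS + 1)[None, :]
        sig[loc] = {
            "a": rng.normal(0, 1, (6, _N_HARMONICS)) * scale * decay,
            "b": rng.normal(0, 1, (6, _N_HARMONICS)) * scale * decay,
            "baseline": rng.normal(0, 0.5, 6) * np.array([1, 1, 1, 0.2, 0.2, 0.2]),
            # fixed deviation directions: how d deforms this location's channels
            "amp_dir": rng.uniform(0.15, 0.45, 6) * rng.choice([-1, 1], 6),
            "phase_dir": rng.uniform(0.02, 0.08, 6) * rng.choice([-1, 1], 6),
        }
    kin = {}
    for var, amp in _KIN_AMPLITUDE.items():
        decay = 1.0 / np.arange(1, 4)
        kin[var] = {
            "mean": rng.normal(0, amp / 3),
            "a": rng.normal(0, 1, 3) * amp / 2 * decay,
            "b": rng.normal(0, 1, 3) * amp / 2 * decay,
            "amp_dir": rng.uniform(0.1, 0.3) * rng.choice([-1, 1]),
            "phase_dir": rng.uniform(0.01, 0.05) * rng.choice([-1, 1]),
            # constant offset reached at d = 1, degrees
            "offset_dir": rng.uniform(2.0, 5.0) * rng.choice([-1, 1]),
        }
    return sig, kin


SIGNAL_TEMPLATES, KINEMATIC_TEMPLATES = _build_templates()

DEFAULT_GROUP_SIZES = {"TT": 10, "TF": 7, "VN": 6, "LS": 3}
DEFAULT_DEVIATION_RANGES = {
    "TT": (0.15, 0.45),
    "TF": (0.25, 0.60),
    "VN": (0.50, 0.90),
    "LS": (0.35, 0.75),
}


@dataclass
class SubjectProfile:
    """Per-subject deformation: identity at d = 0, growing with severity d."""

    participant_id: str
    group: str
    d: float
    prosthetic_side: str = "none"
    base_cycle_s: float = 1.1
    cycle_jitter_cv: float = 0.02
    # per-subject random effects (drawn once per subject)
    amp_u: dict = field(default_factory=dict)  # location -> (6,)
    phase_w: dict = field(default_factory=dict)  # location -> (6,)
    kin_u: dict = field(default_factory=dict)  # variable -> float
    asymmetry: float = 0.0
    stride_length_m: float = 1.30
    swing_apex_m: float = 0.12
    stance_fraction: float = 0.60

    @classmethod
    def draw(
        cls,
        participant_id: str,
        group: str,
        d: float,
        seed: int,
        prosthetic_side: str = "none",
    ) -> "SubjectProfile":
        if not 0.0 <= d <= 1.0:
            raise ValueError("deviation d must lie in [0, 1]")
        rng = np.random.default_rng(seed)
        return cls(
            participant_id=participant_id,
            group=group,
            d=float(d),
            prosthetic_side=prosthetic_side,
            base_cycle_s=1.1 * (1 + 0.05 * rng.normal()) + 0.10 * d,
            cycle_jitter_cv=0.02 + 0.04 * d,
            amp_u={loc: rng.normal(0, 0.10, 6) for loc in SENSOR_LOCATIONS},
            phase_w={loc: rng.normal(0, 0.015, 6) for loc in SENSOR_LOCATIONS},
            kin_u={v: rng.normal(0, 0.15) for v in KINEMATIC_TEMPLATES},
            asymmetry=0.15 * d * (1 + 0.2 * rng.normal()),
            stride_length_m=1.30 * (1 - 0.25 * d) * (1 + 0.05 * rng.normal()),
            swing_apex_m=0.12 * (1 - 0.30 * d) * (1 + 0.05 * rng.normal()),
            stance_fraction=float(np.clip(0.60 + 0.04 * d * rng.normal(), 0.5, 0.72)),
        )


def _harmonics(phase: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Evaluate sum_h a_h cos(2 pi h phase) + b_h sin(...); a, b are (..., H)."""
    H = a.shape[-1]
    ang = 2 * np.pi * np.outer(np.arange(1, H + 1), phase)  # (H, T)
    return a @ np.cos(ang) + b @ np.sin(ang)


def _kin_curve(
    var: str, phase: np.ndarray, profile: SubjectProfile, cycle_amp: float = 1.0
) -> np.ndarray:
    t = KINEMATIC_TEMPLATES[var]
    d = profile.d
    amp = (1 + d * (t["amp_dir"] + 0.5 * profile.kin_u[var])) * cycle_amp
    ph = phase + d * t["phase_dir"]
    curve = t["mean"] + amp * _harmonics(ph, np.atleast_2d(t["a"]), np.atleast_2d(t["b"]))[0]
    return curve + d * t["offset_dir"]


def generate_subject(
    profile: SubjectProfile,
    n_cycles: int,
    seed: int,
    rate: float = 100.0,
    n_passes: int = 2,
    acc_noise: float = 0.15,
    gyr_noise: float = 0.08,
    kin_noise: float = 1.0,
    pos_noise: float = 0.002,
    cycle_amp_cv: float = 0.06,
    cycle_phase_sd: float = 0.01,
) -> TrialRecording:
    """Generate one subject's trial with exactly ``n_cycles`` retainable cycles.

    Cycles are delimited by the subject's segmenting-side foot contacts; each
    pass carries two extra cycles so that end-of-pass exclusion leaves the
    requested count.  Noise SDs are at d = 0 and inflate by (1 + 0.5 d).

    Besides sample noise, the signals carry stride-to-stride waveform
    variability — a per-cycle amplitude factor (CV ``cycle_amp_cv``) and a
    per-cycle phase jitter (SD ``cycle_phase_sd`` of the cycle) — without
    which consecutive cycles would be near-identical copies of the template,
    unlike any real gait recording.  Kinematic curves stay exactly
    template-plus-noise at d = 0; their per-cycle amplitude variability is
    proportional to d.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    rng = np.random.default_rng(seed)
    d = profile.d
    noise_gain = 1 + 0.5 * d
    side = profile.prosthetic_side if profile.prosthetic_side in ("left", "right") else "left"
    other = "right" if side == "left" else "left"

    per_pass = np.full(n_passes, n_cycles // n_passes)
    per_pass[: n_cycles % n_passes] += 1
    gap = int(round(1.0 * rate))  # quiet standing between passes
    tail = int(round(0.2 * rate))

    sensors = {loc: [] for loc in SENSOR_LOCATIONS}
    kinematics = {v: [] for v in list(GPS_VARIABLES)}
    for v in SIDE_KINEMATICS:
        kinematics[f"{v}_left"] = []
        kinematics[f"{v}_right"] = []
    positions = {"ankle_left": [], "ankle_right": []}
    events, toe_offs, passes = [], [], []
    cursor = 0
    x_forward = {"left": 0.0, "right": 0.0}
    global_cycle = 0

    for m in per_pass:
        n_gen = int(m) + 2
        durations = profile.base_cycle_s * (
            1 + profile.cycle_jitter_cv * rng.standard_normal(n_gen)
        )
        n_samp = np.maximum(np.round(durations * rate).astype(int), 40)
        pass_start = cursor
        seg_contacts, seg_toeoffs = [], []  # (index, side)
        blocks = {loc: [] for loc in SENSOR_LOCATIONS}
        kin_blocks = {v: [] for v in kinematics}
        pos_blocks = {"ankle_left": [], "ankle_right": []}
        local = 0
        for k in range(n_gen):
            T = n_samp[k]
            phase = np.arange(T) / T
            asym = 1 + profile.asymmetry * (1 if (global_cycle + k) % 2 == 0 else -1)
            cyc_phase = cycle_phase_sd * noise_gain * rng.standard_normal()
            kin_amp = 1 + 0.05 * d * rng.standard_normal()
            for loc in SENSOR_LOCATIONS:
                t = SIGNAL_TEMPLATES[loc]
                cyc_amp = 1 + cycle_amp_cv * noise_gain * rng.standard_normal()
                amp = (1 + d * (t["amp_dir"] + profile.amp_u[loc]))[:, None] * asym * cyc_amp
                ph = (
                    phase[None, :]
                    + (d * (t["phase_dir"] + profile.phase_w[loc]))[:, None]
                    + cyc_phase
                )
                block = np.empty((6, T))
                for c in range(6):
                    block[c] = _harmonics(ph[c], t["a"][c : c + 1], t["b"][c : c + 1])[0]
                block = t["baseline"][:, None] + amp * block
                noise_sd = np.array([acc_noise] * 3 + [gyr_noise] * 3) * noise_gain
                block += noise_sd[:, None] * rng.standard_normal((6, T))
                blocks[loc].append(block)
            for v in GPS_VARIABLES:
                kin_blocks[v].append(
                    _kin_curve(v, phase, profile, kin_amp)
                    + kin_noise * noise_gain * rng.standard_normal(T)
                )
            for v in SIDE_KINEMATICS:
                for sname, shift in ((side, 0.0), (other, 0.5)):
                    kin_blocks[f"{v}_{sname}"].append(
                        _kin_curve(v, (phase + shift) % 1.0, profile, kin_amp)
                        + kin_noise * noise_gain * rng.standard_normal(T)
                    )
            for sname, shift in ((side, 0.0), (other, 0.5)):
                pos_blocks[f"ankle_{sname}"].append(
                    _ankle_cycle(phase + shift, profile, x_forward, sname, pos_noise, rng)
                )
            seg_contacts.append((pass_start + local, side))
            contra = pass_start + local + int(round(0.5 * T * (1 + 0.05 * d)))
            seg_contacts.append((min(contra, pass_start + local + T - 1), other))
            to_idx = pass_start + local + int(round(profile.stance_fraction * T))
            seg_toeoffs.append((min(to_idx, pass_start + local + T - 1), side))
            to_contra = contra + int(round(profile.stance_fraction * T))
            seg_toeoffs.append((to_contra, other))
            local += T
        # closing same-side contact at the end of the final cycle
        seg_contacts.append((pass_start + local, side))
        pass_len = local + tail
        passes.append((pass_start, pass_start + pass_len))
        events.extend([(i, s) for i, s in seg_contacts if i < pass_start + pass_len])
        toe_offs.extend([(i, s) for i, s in seg_toeoffs if i < pass_start + pass_len])
        global_cycle += n_gen

        # assemble pass blocks + tail + inter-pass gap of quiet standing
        for loc in SENSOR_LOCATIONS:
            sigblock = np.concatenate(blocks[loc], axis=1)
            base = SIGNAL_TEMPLATES[loc]["baseline"][:, None]
            quiet = base + 0.02 * rng.standard_normal((6, tail + gap))
            sensors[loc].append(np.concatenate([sigblock, quiet], axis=1))
        for v in kinematics:
            stream = np.concatenate(kin_blocks[v])
            hold = stream[-1] + 0.1 * rng.standard_normal(tail + gap)
            kinematics[v].append(np.concatenate([stream, hold]))
        for key in positions:
            stream = np.concatenate(pos_blocks[key], axis=1)
            hold = stream[:, -1:] + 0.0005 * rng.standard_normal((3, tail + gap))
            positions[key].append(np.concatenate([stream, hold], axis=1))
        cursor = pass_start + pass_len + gap

    rec = TrialRecording(
        participant_id=profile.participant_id,
        group=profile.group,
        rate=rate,
        sensors={loc: np.concatenate(sensors[loc], axis=1) for loc in SENSOR_LOCATIONS},
        kinematics={v: np.concatenate(kinematics[v]) for v in kinematics},
        positions={k: np.concatenate(positions[k], axis=1) for k in positions},
        events=sorted(events),
        toe_offs=sorted(toe_offs),
        passes=passes,
        prosthetic_side=profile.prosthetic_side,
        meta={
            "deviation": d,
            "seed": int(seed),
            "base_cycle_s": profile.base_cycle_s,
            "stride_length_m": profile.stride_length_m,
            "swing_apex_m": profile.swing_apex_m,
            "stance_fraction": profile.stance_fraction,
            "n_cycles_requested": int(n_cycles),
        },
    )
    return rec.validate()


def _ankle_cycle(
    phase: np.ndarray,
    profile: SubjectProfile,
    x_forward: dict,
    side: str,
    pos_noise: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """3 x T ankle trajectory for one cycle: planted in stance, arc in swing.

    ``phase`` may exceed 1 for the phase-shifted contralateral side; the
    completed-stride carry keeps the forward coordinate continuous across
    the wrap.
    """
    st = profile.stance_fraction
    wrapped = np.mod(phase, 1.0)
    carry = np.floor(phase)
    swing = np.clip((wrapped - st) / (1 - st), 0.0, 1.0)
    prog = swing**2 * (3 - 2 * swing)  # smoothstep forward progression
    x = x_forward[side] + profile.stride_length_m * (prog + carry)
    x_forward[side] = x_forward[side] + profile.stride_length_m
    z = 0.08 + profile.swing_apex_m * np.sin(np.pi * swing) ** 2
    y = (0.10 if side == "right" else -0.10) + 0.01 * np.sin(2 * np.pi * wrapped)
    out = np.vstack([x, np.full_like(x, 0.0) + y, z])
    return out + pos_noise * rng.standard_normal(out.shape)


def deviation_grid_cohort(
    n_control: int = 10,
    n_patient: int = 16,
    cycles_control: int = 14,
    cycles_patient: int = 50,
    seed: int = 0,
) -> list[TrialRecording]:
    """Small cohort with patient severities on an even grid spanning [0, 1].

    Controls are at d = 0; patient i gets d = i / (n_patient - 1) and a
    rotating subgroup label, so the full study design (correlations against
    severity, subgroup testing) can run at reduced size.
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_control + n_patient)
    recs = []
    for i in range(n_control):
        seeds = children[i].generate_state(2) % (2**31)
        prof = SubjectProfile.draw(f"AB{i+1:02d}", "AB", 0.0, int(seeds[0]), "none")
        recs.append(generate_subject(prof, cycles_control, int(seeds[1]), n_passes=2))
    groups = list(DEFAULT_GROUP_SIZES)
    for i in range(n_patient):
        seeds = children[n_control + i].generate_state(2) % (2**31)
        d = i / max(n_patient - 1, 1)
        g = groups[i % len(groups)]
        side = "left" if i % 2 == 0 else "right"
        prof = SubjectProfile.draw(f"{g}{i+1:02d}", g, d, int(seeds[0]), side)
        recs.append(generate_subject(prof, cycles_patient, int(seeds[1]), n_passes=3))
    return recs


@dataclass
class CohortSpec:
    """Cohort layout: sizes, per-group severity distributions, cycle counts."""

    n_control: int = 30
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    deviation_ranges: dict = field(default_factory=lambda: dict(DEFAULT_DEVIATION_RANGES))
    cycles_patient: int = 110
    cycles_control: int = 60
    n_bilateral: int = 3
    n_passes_patient: int = 4
    n_passes_control: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or any(n < 1 for n in self.group_sizes.values()):
            raise ValueError("all cohort counts must be >= 1")
        for g, (lo, hi) in self.deviation_ranges.items():
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"deviation range for {g} must lie in [0, 1]")


def generate_cohort(spec: CohortSpec) -> list[TrialRecording]:
    """Generate controls (d = 0) and patient subgroups with drawn severities."""
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    recs: list[TrialRecording] = []
    patients = [(g, i) for g, n in spec.group_sizes.items() for i in range(n)]
    bilateral = set(
        rng.choice(len(patients), size=min(spec.n_bilateral, len(patients)), replace=False)
    )
    children = root.spawn(spec.n_control + len(patients))
    ci = 0
    for i in range(spec.n_control):
        seeds = children[ci].generate_state(2) % (2**31)
        ci += 1
        prof = SubjectProfile.draw(f"AB{i+1:02d}", "AB", 0.0, int(seeds[0]), "none")
        recs.append(
            generate_subject(
                prof, spec.cycles_control, int(seeds[1]), n_passes=spec.n_passes_control
            )
        )
    for j, (g, i) in enumerate(patients):
        seeds = children[ci].generate_state(3) % (2**31)
        ci += 1
        lo, hi = spec.deviation_ranges[g]
        d = float(np.random.default_rng(seeds[0]).uniform(lo, hi))
        pside = "bilateral" if j in bilateral else ("left" if j % 2 == 0 else "right")
        prof = SubjectProfile.draw(f"{g}{i+1:02d}", g, d, int(seeds[1]), pside)
        recs.append(
            generate_subject(
                prof, spec.cycles_patient, int(seeds[2]), n_passes=spec.n_passes_patient
            )
        )
    return recs
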