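"""Gait Profile Score from time-normalized kinematic curves.

Each gait cycle's kinematic variables are linearly resampled to 51 points
(2% increments of the cycle).  The Gait Variable Score of variable v is the
RMS difference between the subject curve and the normative mean curve over
the 51 points; the GPS is the RMS of the GVS values over the variable set.
A participant's GPS is the mean over their sampled cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import TrialRecording, cycle_index_pairs, resolve_side

__all__ = [
    "GPS_VARIABLES",
    "KinematicCycle",
    "extract_kinematic_cycles",
    "control_mean_cycle",
    "gps_cycle",
    "gps_participant",
]

#: default single-side variable set (prosthetic side; sides averaged for bilateral)
GPS_VARIABLES = (
    "pelvic_tilt",
    "pelvic_obliquity",
    "pelvic_rotation",
    "hip_flexion",
    "hip_abduction",
    "hip_rotation",
    "knee_flexion",
    "ankle_dorsiflexion",
    "foot_progression",
)

N_POINTS = 51  # 0%..100% of the gait cycle in 2% increments


@dataclass
class KinematicCycle:
    """One cycle's kinematic curves: variable -> 51-point array in degrees."""

    curves: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for v, c in self.curves.items():
            c = np.asarray(c, dtype=float)
            if c.shape != (N_POINTS,):
                raise ValueError(f"curve '{v}' must have {N_POINTS} points")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"curve '{v}' contains non-finite values")
            self.curves[v] = c

    @property
    def variables(self) -> list[str]:
        return sorted(self.curves)


def extract_kinematic_cycles(
    rec: TrialRecording,
    pairs: list[tuple[int, int]] | None = None,
    side: str = "prosthetic",
    variables: tuple[str, ...] = GPS_VARIABLES,
) -> list[KinematicCycle]:
    """Time-normalize each cycle's kinematic streams to 51 points."""
    s = resolve_side(rec, side)
    if pairs is None:
        pairs = [(a, b) for a, b, _ in cycle_index_pairs(rec, s)]
    missing = [v for v in variables if v not in rec.kinematics]
    if missing:
        raise ValueError(f"missing kinematic stream(s): {missing}")
    phase = np.linspace(0.0, 1.0, N_POINTS)
    out = []
    for a, b in pairs:
        t = np.linspace(0.0, 1.0, b - a)
        out.append(
            KinematicCycle(
                {v: np.interp(phase, t, rec.kinematics[v][a:b]) for v in variables}
            )
        )
    return out


def control_mean_cycle(cycles: list[KinematicCycle]) -> KinematicCycle:
    """Pointwise mean curves of the normative cycle set."""
    if not cycles:
        raise ValueError("empty cycle list")
    variables = cycles[0].variables
    return KinematicCycle(
        {v: np.mean([c.curves[v] for c in cycles], axis=0) for v in variables}
    )


def gps_cycle(subject: KinematicCycle, control_mean: KinematicCycle) -> float:
    """GPS of one cycle: RMS over variables of the per-variable RMS deviation."""
    if subject.variables != control_mean.variables:
        raise ValueError(
            f"variable sets differ: {subject.variables} vs {control_mean.variables}"
        )
    gvs = [
        float(np.sqrt(np.mean((subject.curves[v] - control_mean.curves[v]) ** 2)))
        for v in subject.variables
    ]
    return float(np.sqrt(np.mean(np.square(gvs))))


def gps_participant(
    cycles: list[KinematicCycle], control_mean: KinematicCycle
) -> float:
    """Participant GPS: arithmetic mean of per-cycle GPS over sampled cycles."""
    if not cycles:
        raise ValueError("empty cycle list")
    return float(np.mean([gps_cycle(c, control_mean) for c in cycles]))
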