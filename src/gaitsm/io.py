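"""Trial recordings, downsampling, gait-cycle segmentation and normative-set assembly.

A trial is one participant's walking session: multi-location IMU blocks
(tri-axial accelerometer in m/s^2 and gyroscope in rad/s at 100 Hz),
kinematic angle streams in degrees, 3-D marker positions in metres,
foot-contact events and half-open pass ranges.  Signals are analysed at a
40 Hz working rate; a gait cycle runs from one foot contact to the next
ipsilateral contact, and the first and last cycle of every pass are
discarded as acceleration/deceleration.

Indexing convention (used everywhere in the package): 0-based sample
indices at the recording's native rate; passes are half-open
``[start, end)`` ranges.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "SchemaError",
    "EmptyCycleSetError",
    "InsufficientCyclesError",
    "TrialRecording",
    "GaitCycleSet",
    "SensorConfiguration",
    "SENSOR_CONFIGURATIONS",
    "SENSOR_LOCATIONS",
    "load_trial",
    "write_trial",
    "downsample",
    "cycle_index_pairs",
    "segment_cycles",
    "sample_cycles",
    "build_normative_set",
]


class SchemaError(ValueError):
    """A trial file or recording violates the documented schema."""


class EmptyCycleSetError(ValueError):
    """Segmentation produced no qualifying gait cycles."""


class InsufficientCyclesError(ValueError):
    """Fewer cycles available than requested."""


SENSOR_LOCATIONS = (
    "pelvis",
    "left_upper_leg",
    "right_upper_leg",
    "left_lower_leg",
    "right_lower_leg",
)

#: channel suffixes within one sensor location block, in storage order
CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


@dataclass(frozen=True)
class SensorConfiguration:
    """A named set of sensor locations whose 6-channel blocks are stacked.

    The single pelvis sensor yields 6 x T training arrays; the combined
    upper-leg and lower-leg configurations stack left and right blocks
    into 12 x T arrays.
    """

    name: str
    locations: tuple[str, ...]

    @property
    def stacked_dim(self) -> int:
        return 6 * len(self.locations)

    def channel_labels(self) -> list[str]:
        return [f"{loc}_{ch}" for loc in self.locations for ch in CHANNELS]


SENSOR_CONFIGURATIONS: dict[str, SensorConfiguration] = {
    "pelvis": SensorConfiguration("pelvis", ("pelvis",)),
    "upper_legs": SensorConfiguration("upper_legs", ("left_upper_leg", "right_upper_leg")),
    "lower_legs": SensorConfiguration("lower_legs", ("left_lower_leg", "right_lower_leg")),
}


@dataclass
class TrialRecording:
    """One participant's trial: signals, kinematics, positions, events, passes."""

    participant_id: str
    group: str  # TT, TF, VN, LS or AB
    rate: float
    sensors: dict[str, np.ndarray]  # location -> (6, T) block
    kinematics: dict[str, np.ndarray] = field(default_factory=dict)  # var -> (T,) degrees
    positions: dict[str, np.ndarray] = field(default_factory=dict)  # marker -> (3, T) metres
    events: list[tuple[int, str]] = field(default_factory=list)  # (sample index, side)
    toe_offs: list[tuple[int, str]] = field(default_factory=list)
    passes: list[tuple[int, int]] = field(default_factory=list)  # half-open [start, end)
    prosthetic_side: str = "none"  # left, right, bilateral or none
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return next(iter(self.sensors.values())).shape[1]

    def validate(self) -> "TrialRecording":
        if self.rate <= 0:
            raise SchemaError("rate must be positive")
        if not self.sensors:
            raise SchemaError("recording has no sensor blocks")
        T = None
        for loc, block in self.sensors.items():
            block = np.asarray(block, dtype=float)
            if block.ndim != 2 or block.shape[0] != 6:
                raise SchemaError(f"sensor block '{loc}' is not 6 x T")
            if not np.all(np.isfinite(block)):
                raise SchemaError(f"sensor block '{loc}' contains non-finite samples")
            if T is None:
                T = block.shape[1]
            elif block.shape[1] != T:
                raise SchemaError(f"sensor block '{loc}' length differs from other blocks")
            self.sensors[loc] = block
        for name, stream in self.kinematics.items():
            stream = np.asarray(stream, dtype=float)
            if stream.shape != (T,):
                raise SchemaError(f"kinematic stream '{name}' length differs from signals")
            if not np.all(np.isfinite(stream)):
                raise SchemaError(f"kinematic stream '{name}' contains non-finite samples")
            self.kinematics[name] = stream
        for name, block in self.positions.items():
            block = np.asarray(block, dtype=float)
            if block.shape != (3, T):
                raise SchemaError(f"position stream '{name}' is not 3 x T")
            self.positions[name] = block
        for start, end in self.passes:
            if not (0 <= start < end <= T):
                raise SchemaError(f"pass [{start}, {end}) outside recording of length {T}")
        idx = [i for i, _ in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise SchemaError("event indices are not strictly increasing")
        for i, side in self.events:
            if not any(s <= i < e for s, e in self.passes):
                raise SchemaError(f"event at sample {i} ({side}) lies outside every pass")
        return self


@dataclass
class GaitCycleSet:
    """Variable-length gait cycles at the working rate, with per-cycle metadata.

    ``meta`` records, per cycle: duration in seconds, the pass index, and the
    raw-rate start/end indices so kinematic and parameter extraction can be
    driven from the same sampled cycles.
    """

    cycles: list[np.ndarray]  # each (channels, t)
    channel_labels: list[str]
    participant_id: str
    rate: float = 40.0
    meta: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if any(c.shape[1] < 2 for c in self.cycles):
            raise ValueError("every cycle must have at least 2 samples")
        dims = {c.shape[0] for c in self.cycles}
        if len(dims) > 1:
            raise ValueError("channel count differs across cycles")

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    @property
    def n_channels(self) -> int:
        return self.cycles[0].shape[0] if self.cycles else len(self.channel_labels)

    def frames(self) -> np.ndarray:
        """All cycles concatenated along time, as (total_frames, channels)."""
        return np.concatenate([c.T for c in self.cycles], axis=0)

    def subset(self, indices: Sequence[int]) -> "GaitCycleSet":
        return GaitCycleSet(
            cycles=[self.cycles[i] for i in indices],
            channel_labels=list(self.channel_labels),
            participant_id=self.participant_id,
            rate=self.rate,
            meta=[self.meta[i] for i in indices] if self.meta else [],
        )


# ---------------------------------------------------------------------------
# file I/O: one tabular CSV per trial + JSON sidecar for events/passes/metadata


def write_trial(rec: TrialRecording, path: str | Path) -> None:
    """Write a trial as ``<path>.csv`` (signals) plus ``<path>.json`` (sidecar)."""
    path = Path(path)
    T = rec.n_samples
    cols: dict[str, np.ndarray] = {"time_s": np.arange(T) / rec.rate}
    for loc in rec.sensors:
        for k, ch in enumerate(CHANNELS):
            cols[f"{loc}_{ch}"] = rec.sensors[loc][k]
    for name, stream in rec.kinematics.items():
        cols[f"kin_{name}"] = stream
    for name, block in rec.positions.items():
        for k, ax in enumerate("xyz"):
            cols[f"pos_{name}_{ax}"] = block[k]
    pd.DataFrame(cols).to_csv(path.with_suffix(".csv"), index=False, float_format="%.9g")
    sidecar = {
        "participant_id": rec.participant_id,
        "group": rec.group,
        "rate": rec.rate,
        "prosthetic_side": rec.prosthetic_side,
        "events": [[int(i), s] for i, s in rec.events],
        "toe_offs": [[int(i), s] for i, s in rec.toe_offs],
        "passes": [[int(a), int(b)] for a, b in rec.passes],
        "meta": _json_safe(rec.meta),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_trial(path: str | Path) -> TrialRecording:
    """Load a trial written by :func:`write_trial`; validates all invariants."""
    path = Path(path)
    csv_path, json_path = path.with_suffix(".csv"), path.with_suffix(".json")
    if not csv_path.exists():
        raise SchemaError(f"trial table not found: {csv_path}")
    if not json_path.exists():
        raise SchemaError(f"trial sidecar not found: {json_path}")
    df = pd.read_csv(csv_path)
    side = json.loads(json_path.read_text())

    sensors: dict[str, np.ndarray] = {}
    for loc in SENSOR_LOCATIONS:
        names = [f"{loc}_{ch}" for ch in CHANNELS]
        present = [n for n in names if n in df.columns]
        if not present:
            continue
        if len(present) < 6:
            missing = sorted(set(names) - set(present))
            raise SchemaError(f"sensor '{loc}' missing channels: {missing}")
        sensors[loc] = df[names].to_numpy().T
    kinematics = {
        c[len("kin_"):]: df[c].to_numpy() for c in df.columns if c.startswith("kin_")
    }
    positions: dict[str, np.ndarray] = {}
    pos_names = sorted({c[len("pos_"):-2] for c in df.columns if c.startswith("pos_")})
    for name in pos_names:
        positions[name] = df[[f"pos_{name}_{ax}" for ax in "xyz"]].to_numpy().T
    rec = TrialRecording(
        participant_id=str(side["participant_id"]),
        group=str(side["group"]),
        rate=float(side["rate"]),
        sensors=sensors,
        kinematics=kinematics,
        positions=positions,
        events=[(int(i), str(s)) for i, s in side.get("events", [])],
        toe_offs=[(int(i), str(s)) for i, s in side.get("toe_offs", [])],
        passes=[(int(a), int(b)) for a, b in side.get("passes", [])],
        prosthetic_side=str(side.get("prosthetic_side", "none")),
        meta=side.get("meta", {}),
    )
    return rec.validate()


def _json_safe(obj):
    if isinstance(obj, Mapping):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    return obj


# ---------------------------------------------------------------------------
# downsampling


def downsample(block: np.ndarray, from_rate: float, to_rate: float) -> np.ndarray:
    """Anti-aliased downsampling of a channels x time block.

    Zero-phase polyphase resampling (symmetric FIR anti-alias filter) on the
    rational approximation of ``to_rate / from_rate`` — 100 -> 40 Hz is the
    non-integer ratio 2/5.  The polyphase filter keeps the passband flat
    (band-limited content preserved within a percent) where an IIR low-pass
    plus linear interpolation would droop well below the cutoff.  Output
    length is ``floor(T * to_rate / from_rate)``.
    """
    if to_rate <= 0 or from_rate <= 0:
        raise ValueError("rates must be positive")
    if to_rate > from_rate:
        raise ValueError("upsampling is not supported")
    block = np.atleast_2d(np.asarray(block, dtype=float))
    T = block.shape[1]
    if from_rate == to_rate:
        return block.copy()
    frac = Fraction(to_rate / from_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    # remove per-channel mean so DC passes through exactly (no polyphase ripple)
    m = block.mean(axis=1, keepdims=True)
    out = _sig.resample_poly(block - m, up, down, axis=1, padtype="line") + m
    n_out = int(np.floor(T * to_rate / from_rate))
    return out[:, :n_out]


# ---------------------------------------------------------------------------
# segmentation


def cycle_index_pairs(
    rec: TrialRecording, side: str
) -> list[tuple[int, int, int]]:
    """Raw-rate (start, end, pass_id) for every retained same-side gait cycle.

    Within each pass, consecutive same-side foot contacts delimit cycles; the
    first and last cycle of the pass are dropped.  Used by signal, kinematic
    and parameter extraction alike so all measures see the same cycles.
    """
    pairs: list[tuple[int, int, int]] = []
    for p, (start, end) in enumerate(rec.passes):
        contacts = [i for i, s in rec.events if s == side and start <= i < end]
        cyc = list(zip(contacts, contacts[1:]))
        pairs.extend((a, b, p) for a, b in cyc[1:-1])
    return pairs


def resolve_side(rec: TrialRecording, side: str = "prosthetic") -> str:
    """Map the side rule to 'left'/'right' for one recording.

    ``prosthetic`` uses the prosthetic side for unilateral users and falls
    back to 'left' for bilateral users and controls (whose parameter values
    are side-averaged elsewhere, per the bilateral rule).
    """
    if side in ("left", "right"):
        return side
    if side != "prosthetic":
        raise ValueError(f"unknown side rule: {side!r}")
    if rec.prosthetic_side in ("left", "right"):
        return rec.prosthetic_side
    return "left"


def segment_cycles(
    rec: TrialRecording,
    side: str,
    config: SensorConfiguration,
    to_rate: float = 40.0,
) -> GaitCycleSet:
    """Segment a recording into same-side gait cycles of stacked config channels.

    Signals are downsampled to the working rate first; raw-rate event indices
    are mapped onto the working-rate grid by time.
    """
    side = resolve_side(rec, side)
    missing = [loc for loc in config.locations if loc not in rec.sensors]
    if missing:
        raise SchemaError(f"recording lacks sensor location(s): {missing}")
    stacked = np.vstack([rec.sensors[loc] for loc in config.locations])
    work = downsample(stacked, rec.rate, to_rate)
    ratio = to_rate / rec.rate
    pairs = cycle_index_pairs(rec, side)
    cycles, meta = [], []
    for a, b, p in pairs:
        a40, b40 = int(np.floor(a * ratio)), int(np.floor(b * ratio))
        b40 = min(b40, work.shape[1])
        if b40 - a40 < 2:
            continue
        cycles.append(work[:, a40:b40].copy())
        meta.append(
            {"duration": (b - a) / rec.rate, "pass": p, "start": a, "end": b, "side": side}
        )
    if not cycles:
        raise EmptyCycleSetError(
            f"no qualifying {side}-side cycles in any pass of {rec.participant_id}"
        )
    return GaitCycleSet(
        cycles=cycles,
        channel_labels=config.channel_labels(),
        participant_id=rec.participant_id,
        rate=to_rate,
        meta=meta,
    )


def sample_cycles(cycles: GaitCycleSet, n: int, seed: int) -> GaitCycleSet:
    """Draw ``n`` cycles uniformly without replacement (seeded, order-normalized)."""
    if n > cycles.n_cycles:
        raise InsufficientCyclesError(
            f"requested {n} cycles but only {cycles.n_cycles} available "
            f"for {cycles.participant_id}"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(cycles.n_cycles, size=n, replace=False))
    return cycles.subset(idx.tolist())


def build_normative_set(
    controls: Iterable[GaitCycleSet], n_per: int = 10, seed: int = 0
) -> GaitCycleSet:
    """Aggregate ``n_per`` sampled cycles per able-bodied participant.

    The aggregate is the reference every gait-quality measure scores against.
    """
    controls = list(controls)
    if not controls:
        raise ValueError("no control cycle sets given")
    ss = np.random.SeedSequence(seed).spawn(len(controls))
    cycles, meta = [], []
    labels = list(controls[0].channel_labels)
    for cs, child in zip(controls, ss):
        if cs.n_cycles < n_per:
            raise InsufficientCyclesError(
                f"control {cs.participant_id} has {cs.n_cycles} cycles < n_per={n_per}"
            )
        if cs.channel_labels != labels:
            raise ValueError("control cycle sets have mismatched channels")
        sub = sample_cycles(cs, n_per, int(child.generate_state(1)[0] % (2**31)))
        for c, m in zip(sub.cycles, sub.meta or [{}] * n_per):
            cycles.append(c)
            meta.append({**m, "source": cs.participant_id})
    return GaitCycleSet(
        cycles=cycles,
        channel_labels=labels,
        participant_id="normative",
        rate=controls[0].rate,
        meta=meta,
    )
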