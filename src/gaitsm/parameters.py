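"""Parameter-based comparator scores: INI (PCA normalcy index) and MGS.

The INI summarises 9 gait parameters per cycle — 3 spatiotemporal (gait
cycle duration GD, stride length SL, percentage swing phase PSP) and 6
kinematic (maximum ankle velocity MV, maximum ankle height MH, horizontal
displacement at MH MHD, maximum ankle abduction MAB / adduction MAD, shank
swing range of motion SRM) — as a PCA-space distance from the normative
distribution.

The MGS groups signal and spatiotemporal parameters into six gait aspects
(amplitude, temporal, distribution, complexity, symmetry, regularity),
selects one parameter per aspect by PCA loading, and averages capped
|z|-deviations from the normative set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats as _st

from .io import GaitCycleSet, TrialRecording, cycle_index_pairs, resolve_side

__all__ = [
    "INI_PARAMETERS",
    "GaitParameters",
    "extract_ini_parameters",
    "ini_parameter_table",
    "PCABasis",
    "fit_pca_basis",
    "ini_score",
    "MGSRegistry",
    "DEFAULT_MGS_REGISTRY",
    "mgs_parameters",
    "mgs_score",
]

INI_PARAMETERS = ("GD", "SL", "PSP", "MV", "MH", "MHD", "MAB", "MAD", "SRM")


@dataclass(frozen=True)
class GaitParameters:
    """The 9 INI gait parameters for one gait cycle."""

    GD: float  # gait cycle duration, s
    SL: float  # stride length, m
    PSP: float  # percentage swing phase, %
    MV: float  # maximum ankle velocity, m/s
    MH: float  # maximum ankle height, m
    MHD: float  # ankle horizontal displacement at MH, m
    MAB: float  # maximum ankle abduction, deg
    MAD: float  # maximum ankle adduction, deg
    SRM: float  # shank range of motion in swing, deg

    def __post_init__(self) -> None:
        if self.GD <= 0:
            raise ValueError("GD must be positive")
        if not 0 < self.PSP < 100:
            raise ValueError("PSP must lie strictly between 0 and 100")
        for name in ("SL", "MV", "MH"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in INI_PARAMETERS], dtype=float)


def _cycle_toe_off(rec: TrialRecording, side: str, start: int, end: int) -> int:
    cand = [i for i, s in rec.toe_offs if s == side and start < i < end]
    if not cand:
        raise ValueError(f"PSP blocked: no {side} toe-off inside cycle [{start}, {end})")
    return cand[0]


def extract_ini_parameters(
    rec: TrialRecording, start: int, end: int, side: str
) -> GaitParameters:
    """Extract the 9 INI parameters for one raw-rate cycle [start, end) on one side."""
    ankle_key = f"ankle_{side}"
    if ankle_key not in rec.positions:
        raise ValueError(f"SL/MV/MH/MHD blocked: missing position stream '{ankle_key}'")
    shank_key = f"shank_angle_{side}"
    if shank_key not in rec.kinematics:
        raise ValueError(f"SRM blocked: missing kinematic stream '{shank_key}'")
    abd_key = f"ankle_abduction_{side}"
    if abd_key not in rec.kinematics:
        raise ValueError(f"MAB/MAD blocked: missing kinematic stream '{abd_key}'")

    rate = rec.rate
    GD = (end - start) / rate
    toe_off = _cycle_toe_off(rec, side, start, end)
    PSP = 100.0 * (end - toe_off) / (end - start)

    P = rec.positions[ankle_key][:, start:end]  # axes: 0 forward, 1 lateral, 2 vertical
    SL = float(P[0, -1] - P[0, 0])
    vel = np.gradient(P, axis=1) * rate
    MV = float(np.linalg.norm(vel, axis=0).max())
    z = P[2]
    z0 = float(z.min())
    apex = int(z.argmax())
    MH = float(z[apex] - z0)
    MHD = float(P[0, apex] - P[0, 0])

    abd = rec.kinematics[abd_key][start:end]
    MAB = float(abd.max())
    MAD = float(-abd.min())

    shank = rec.kinematics[shank_key][toe_off:end]
    SRM = float(shank.max() - shank.min())
    return GaitParameters(GD, max(SL, 0.0), PSP, MV, MH, MHD, MAB, MAD, SRM)


def ini_parameter_table(
    rec: TrialRecording,
    pairs: list[tuple[int, int]] | None = None,
    side: str = "prosthetic",
) -> pd.DataFrame:
    """Per-cycle 9-parameter table for one participant.

    For bilateral prosthetic users the left and right parameter values are
    averaged cycle-by-cycle (cycle lists truncated to the shorter side).
    """
    if rec.prosthetic_side == "bilateral" and side == "prosthetic":
        tables = []
        for s in ("left", "right"):
            pr = [(a, b) for a, b, _ in cycle_index_pairs(rec, s)]
            tables.append(_side_table(rec, pr, s))
        n = min(len(t) for t in tables)
        return (tables[0].iloc[:n].reset_index(drop=True)
                + tables[1].iloc[:n].reset_index(drop=True)) / 2.0
    s = resolve_side(rec, side)
    if pairs is None:
        pairs = [(a, b) for a, b, _ in cycle_index_pairs(rec, s)]
    return _side_table(rec, pairs, s)


def _side_table(rec: TrialRecording, pairs: list[tuple[int, int]], side: str) -> pd.DataFrame:
    rows = [extract_ini_parameters(rec, a, b, side).as_array() for a, b in pairs]
    return pd.DataFrame(rows, columns=list(INI_PARAMETERS))


@dataclass
class PCABasis:
    """Normative PCA basis: parameter means/SDs, eigenvalues and eigenvectors."""

    mean: np.ndarray
    std: np.ndarray
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # columns, orthonormal
    columns: list[str] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


def fit_pca_basis(normative: pd.DataFrame) -> PCABasis:
    """PCA of the z-scored normative parameter table (correlation-matrix PCA)."""
    X = normative.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=1)
    if np.any(std == 0):
        bad = [c for c, s in zip(normative.columns, std) if s == 0]
        raise ValueError(f"zero normative SD for parameter(s): {bad}")
    Z = (X - mean) / std
    C = np.atleast_2d(np.cov(Z, rowvar=False, ddof=1))
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    return PCABasis(
        mean=mean,
        std=std,
        eigenvalues=np.clip(w[order], 0.0, None),
        eigenvectors=V[:, order],
        columns=list(normative.columns),
    )


def ini_score(
    params: pd.DataFrame | np.ndarray, basis: PCABasis, whiten: bool = True
) -> float:
    """INI: mean over cycles of the PCA-space distance to the normative mean.

    Each cycle's parameters are z-scored by the normative statistics,
    projected onto the eigenvectors and (by default) scaled by
    1/sqrt(eigenvalue) so the score equals the Mahalanobis distance to the
    normative distribution; the participant score averages over cycles.
    """
    X = params.to_numpy(dtype=float) if isinstance(params, pd.DataFrame) else np.atleast_2d(params)
    Z = (X - basis.mean) / basis.std
    proj = Z @ basis.eigenvectors
    if whiten:
        lam = basis.eigenvalues
        if np.any(lam < 1e-12):
            raise ValueError("near-zero eigenvalue: normative parameters are rank-deficient")
        proj = proj / np.sqrt(lam)
    return float(np.linalg.norm(proj, axis=1).mean())


# ---------------------------------------------------------------------------
# MGS


@dataclass(frozen=True)
class MGSRegistry:
    """Aspect -> parameter-name registry for the MGS.

    The six aspects follow the published construction; the default parameter
    inventory is this package's documented approximation (the source
    inventory is not reproduced here) and is fully configurable.
    """

    aspects: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        for a, params in self.aspects.items():
            if not params:
                raise ValueError(f"aspect '{a}' has no parameters")

    @property
    def parameters(self) -> list[str]:
        return [p for params in self.aspects.values() for p in params]


DEFAULT_MGS_REGISTRY = MGSRegistry(
    aspects={
        "amplitude": ("signal_rms", "signal_range"),
        "temporal": ("cadence", "swing_percent"),
        "distribution": ("signal_skew", "signal_kurtosis"),
        "complexity": ("sample_entropy",),
        "symmetry": ("step_time_ratio",),
        "regularity": ("stride_autocorrelation",),
    }
)


def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2, max_len: int = 1200) -> float:
    """Sample entropy SampEn(m, r = r_frac * SD) of a 1-D series (length-capped)."""
    x = np.asarray(x, dtype=float)[:max_len]
    n = x.size
    r = r_frac * x.std()
    if n <= m + 1 or r == 0:
        return 0.0

    def _count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distance template matches, excluding self-matches
        d = np.abs(emb[:, None, :] - emb[None, :, :]).max(axis=2)
        hits = (d <= r).sum() - emb.shape[0]
        return int(hits)

    B = _count(m)
    A = _count(m + 1)
    if B == 0 or A == 0:
        return 0.0
    return float(-np.log(A / B))


def mgs_parameters(
    rec: TrialRecording,
    cycles: GaitCycleSet,
) -> pd.Series:
    """MGS parameter vector for one participant from their sampled cycles.

    Signal parameters use the cycle set's stacked channels at the working
    rate; temporal/symmetry parameters use the foot-contact events.
    """
    frames = cycles.frames()  # (T, channels)
    centred = frames - frames.mean(axis=0)
    out: dict[str, float] = {}
    out["signal_rms"] = float(np.sqrt(np.mean(centred**2)))
    out["signal_range"] = float(np.mean(frames.max(axis=0) - frames.min(axis=0)))
    durations = [m["duration"] for m in cycles.meta] if cycles.meta else None
    if durations:
        out["cadence"] = 120.0 / float(np.mean(durations))  # steps/min, 2 steps per cycle
    else:
        out["cadence"] = np.nan
    out["swing_percent"] = _mean_swing_percent(rec)
    out["signal_skew"] = float(np.mean(_st.skew(frames, axis=0)))
    out["signal_kurtosis"] = float(np.mean(_st.kurtosis(frames, axis=0)))
    out["sample_entropy"] = _sample_entropy(frames[:, 0])
    out["step_time_ratio"] = _step_time_ratio(rec)
    out["stride_autocorrelation"] = _stride_autocorrelation(cycles)
    return pd.Series(out)


def _mean_swing_percent(rec: TrialRecording) -> float:
    vals = []
    for side in ("left", "right"):
        for a, b, _ in cycle_index_pairs(rec, side):
            cand = [i for i, s in rec.toe_offs if s == side and a < i < b]
            if cand:
                vals.append(100.0 * (b - cand[0]) / (b - a))
    return float(np.mean(vals)) if vals else np.nan


def _step_time_ratio(rec: TrialRecording) -> float:
    """Mean left-step time over mean right-step time (1 = symmetric)."""
    left_steps, right_steps = [], []
    for start, end in rec.passes:
        ev = [(i, s) for i, s in rec.events if start <= i < end]
        for (i1, s1), (i2, s2) in zip(ev, ev[1:]):
            if s1 == s2:
                continue
            dt = (i2 - i1) / rec.rate
            (left_steps if s2 == "left" else right_steps).append(dt)
    if not left_steps or not right_steps:
        return np.nan
    return float(np.mean(left_steps) / np.mean(right_steps))


def _stride_autocorrelation(cycles: GaitCycleSet) -> float:
    """Normalized autocorrelation of the first channel at one mean stride lag."""
    x = np.concatenate([c[0] for c in cycles.cycles])
    lag = int(round(np.mean([c.shape[1] for c in cycles.cycles])))
    if lag <= 0 or lag >= x.size:
        return np.nan
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return np.nan
    return float(np.dot(x[:-lag], x[lag:]) / denom)


def mgs_score(
    param_table: pd.DataFrame,
    registry: MGSRegistry = DEFAULT_MGS_REGISTRY,
    normative_rows: list | None = None,
    z_cap: float = 3.0,
) -> tuple[pd.Series, pd.DataFrame, dict[str, str]]:
    """MGS overall and per-aspect scores for every row of a parameter table.

    PCA (correlation) on the normative rows retains components with
    eigenvalue >= 1; per aspect the parameter with the highest absolute
    correlation with any retained component is kept; retained parameters are
    z-scored against the normative mean/SD and mapped to [0, 1] via
    min(|z|, z_cap)/z_cap; aspect scores average their retained parameters
    and the overall score averages the aspects.

    Returns (overall per participant, aspect-score table, selected
    parameter per aspect).
    """
    cols = [p for p in registry.parameters if p in param_table.columns]
    missing = set(registry.parameters) - set(cols)
    table = param_table[cols].astype(float)
    if normative_rows is None:
        normative_rows = list(table.index)
    norm = table.loc[normative_rows].dropna()
    if len(norm) < 2:
        raise ValueError("need at least 2 normative rows")
    basis = fit_pca_basis(norm)
    retained_comps = np.flatnonzero(basis.eigenvalues >= 1.0)
    # correlation of (z-scored) parameter k with component p: loading * sqrt(eigenvalue)
    corr = np.abs(
        basis.eigenvectors[:, retained_comps]
        * np.sqrt(basis.eigenvalues[retained_comps])
    )
    importance = corr.max(axis=1) if retained_comps.size else np.zeros(len(cols))
    selection: dict[str, str] = {}
    for aspect, params in registry.aspects.items():
        idx = [cols.index(p) for p in params if p in cols]
        if not idx:
            warnings.warn(f"MGS aspect '{aspect}' has no available parameter "
                          f"(missing: {sorted(missing)}); omitted", RuntimeWarning)
            continue
        selection[aspect] = cols[idx[int(np.argmax(importance[idx]))]]
    z = (table - basis.mean) / basis.std
    dev = np.minimum(z.abs(), z_cap) / z_cap
    aspect_scores = pd.DataFrame(
        {aspect: dev[param] for aspect, param in selection.items()},
        index=table.index,
    )
    overall = aspect_scores.mean(axis=1)
    overall.name = "MGS"
    return overall, aspect_scores, selection
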