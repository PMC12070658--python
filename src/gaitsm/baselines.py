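"""Signal-based comparator scores: Movement Deviation Profile (SOM) and DTW.

The MDP trains a self-organizing map on normative sensor frames; a cycle's
score is the mean Euclidean distance of its frames to their best-matching
units.  The DTW score is the mean multivariate dynamic-time-warping distance
between every participant cycle and every normative cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .io import GaitCycleSet

__all__ = [
    "SOMCodebook",
    "fit_som",
    "quantization_error",
    "mdp_score",
    "mdp_participant",
    "dtw_distance",
    "dtw_score",
]


@dataclass
class SOMCodebook:
    """Trained self-organizing map: node grid plus codebook vectors."""

    grid: tuple[int, int]
    codebook: np.ndarray  # (rows * cols, d)
    config: dict = field(default_factory=dict)

    @property
    def dim(self) -> int:
        return self.codebook.shape[1]

    def bmu(self, frames: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Best-matching unit index and distance for each frame (n, d)."""
        D = cdist(np.atleast_2d(frames), self.codebook)
        idx = D.argmin(axis=1)
        return idx, D[np.arange(len(idx)), idx]


def fit_som(
    frames: np.ndarray,
    grid: tuple[int, int] = (10, 10),
    n_epochs: int = 50,
    lr: tuple[float, float] = (0.5, 0.01),
    sigma: tuple[float, float] | None = None,
    seed: int = 0,
) -> SOMCodebook:
    """Online Kohonen training on normative frames.

    Learning rate and Gaussian neighborhood width both decay linearly across
    epochs (defaults 0.5 -> 0.01 and half the larger grid side -> 0.5).
    Codebook initialised by sampling training frames.
    """
    frames = np.asarray(frames, dtype=float)
    r, c = grid
    n_nodes = r * c
    if frames.shape[0] < n_nodes:
        raise ValueError(f"need at least {n_nodes} frames to fit a {r}x{c} SOM")
    rng = np.random.default_rng(seed)
    codebook = frames[rng.choice(frames.shape[0], size=n_nodes, replace=False)].copy()
    initial_qe = float(cdist(frames, codebook).min(axis=1).mean())
    # node coordinates on the grid, for the neighborhood function
    coords = np.array([(i, j) for i in range(r) for j in range(c)], dtype=float)
    grid_d2 = cdist(coords, coords, "sqeuclidean")
    if sigma is None:
        sigma = (max(r, c) / 2.0, 0.5)
    lr0, lr1 = lr
    s0, s1 = sigma
    for epoch in range(n_epochs):
        frac = epoch / max(n_epochs - 1, 1)
        eta = lr0 + (lr1 - lr0) * frac
        sig = s0 + (s1 - s0) * frac
        order = rng.permutation(frames.shape[0])
        for x in frames[order]:
            d2 = np.einsum("nd,nd->n", codebook - x, codebook - x)
            b = int(d2.argmin())
            h = np.exp(-grid_d2[b] / (2.0 * sig**2))
            codebook += (eta * h)[:, None] * (x - codebook)
    som = SOMCodebook(
        grid=grid,
        codebook=codebook,
        config={"n_epochs": n_epochs, "lr": lr, "sigma": (s0, s1), "seed": int(seed)},
    )
    som.config["initial_qe"] = initial_qe
    som.config["final_qe"] = quantization_error(frames, som)
    return som


def quantization_error(frames: np.ndarray, som: SOMCodebook) -> float:
    """Mean distance of frames to their best-matching units."""
    _, dist = som.bmu(frames)
    return float(dist.mean())


def mdp_score(cycle: np.ndarray, som: SOMCodebook) -> float:
    """Mean BMU distance across the time points of one channels x time cycle."""
    cycle = np.asarray(cycle, dtype=float)
    if cycle.shape[0] != som.dim:
        raise ValueError(
            f"cycle has {cycle.shape[0]} channels but codebook dimension is {som.dim}"
        )
    _, dist = som.bmu(cycle.T)
    return float(dist.mean())


def mdp_participant(cycles: GaitCycleSet, som: SOMCodebook) -> float:
    """Participant MDP: mean of per-cycle scores over the sampled cycles."""
    if cycles.n_cycles == 0:
        raise ValueError("empty cycle set")
    return float(np.mean([mdp_score(c, som) for c in cycles.cycles]))


# ---------------------------------------------------------------------------
# dynamic time warping

try:  # jitted DP kernel; pure-numpy fallback keeps the package importable
    from numba import njit as _njit

    @_njit(cache=True)
    def _dtw_acc(D):  # pragma: no cover - exercised via dtw_distance
        n, m = D.shape
        acc = np.empty((n, m))
        acc[0, 0] = D[0, 0]
        for i in range(1, n):
            acc[i, 0] = acc[i - 1, 0] + D[i, 0]
        for j in range(1, m):
            acc[0, j] = acc[0, j - 1] + D[0, j]
        for i in range(1, n):
            for j in range(1, m):
                best = acc[i - 1, j - 1]
                if acc[i - 1, j] < best:
                    best = acc[i - 1, j]
                if acc[i, j - 1] < best:
                    best = acc[i, j - 1]
                acc[i, j] = D[i, j] + best
        return acc[n - 1, m - 1]

except ImportError:  # pragma: no cover

    def _dtw_acc(D):
        n, m = D.shape
        acc = np.full((n + 1, m + 1), np.inf)
        acc[0, 0] = 0.0
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                acc[i, j] = D[i - 1, j - 1] + min(
                    acc[i - 1, j - 1], acc[i - 1, j], acc[i, j - 1]
                )
        return acc[n, m]


def dtw_distance(seq_a: np.ndarray, seq_b: np.ndarray) -> float:
    """Multivariate DTW distance with Euclidean frame distance.

    Classic dynamic programming, symmetric steps (diagonal/vertical/
    horizontal), unconstrained warping window; the distance is the summed
    frame distance along the optimal path, zero iff the sequences are
    identical.
    """
    a = np.atleast_2d(np.asarray(seq_a, dtype=float))
    b = np.atleast_2d(np.asarray(seq_b, dtype=float))
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ValueError("DTW of an empty sequence is undefined")
    if a.shape[0] != b.shape[0]:
        raise ValueError("sequences must share channel count")
    D = cdist(a.T, b.T)
    return float(_dtw_acc(D))


def dtw_score(cycles: GaitCycleSet, normative: GaitCycleSet) -> float:
    """Mean DTW distance over the full participant x normative cycle cross product."""
    if cycles.n_cycles == 0 or normative.n_cycles == 0:
        raise ValueError("empty cycle set")
    total = 0.0
    for ca in cycles.cycles:
        for cb in normative.cycles:
            total += dtw_distance(ca, cb)
    return total / (cycles.n_cycles * normative.n_cycles)
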