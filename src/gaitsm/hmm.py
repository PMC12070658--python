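"""Gaussian-HMM gait models and the sparsity-based similarity score (HMM-SM).

A participant's sampled gait cycles are turned into multi-cycle sequences by
a sliding window (groups of 10 cycles concatenated along time), an ergodic
Gaussian-emission HMM ``lambda_p`` is fitted by EM, and gait quality is the
similarity ``S(lambda_p || lambda_control)`` to the HMM fitted on the
aggregated able-bodied reference cycles.

The similarity of two HMMs is computed from the state-correspondence matrix
``Q`` whose entries ``q_ij = exp(-D_sym(b_a[i], b_b[j]) / tau)`` kernelise
the symmetric Kullback-Leibler divergence between emission Gaussians.  With
``H`` the normalized Gini sparsity index,

    S(a||b) = 1/2 [ mean_i H(row_i of Q) + mean_j H(col_j of Q) ]

so S is 1 when states correspond one-to-one (Q is a permutation-like one-hot
pattern) and 0 when every pair of states looks alike (Q constant).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg as _la

from .io import GaitCycleSet

# hmmlearn logs a line per non-monotone EM step; restarts make these routine
logging.getLogger("hmmlearn.base").setLevel(logging.ERROR)

__all__ = [
    "GaussianHMM",
    "SimilarityScore",
    "make_training_windows",
    "fit_hmm",
    "symmetric_kl_gaussian",
    "correspondence_matrix",
    "gini_sparsity",
    "hmm_similarity_score",
    "hmm_sm_participant",
]


@dataclass
class GaussianHMM:
    """An N-state HMM with full-covariance Gaussian emissions.

    ``transmat`` is the N x N matrix A (rows sum to 1), ``means``/``covars``
    the emission parameters (mu_i, Sigma_i), ``startprob`` the initial state
    distribution pi.
    """

    transmat: np.ndarray  # (N, N)
    means: np.ndarray  # (N, d)
    covars: np.ndarray  # (N, d, d)
    startprob: np.ndarray  # (N,)
    log_likelihood: float | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def validate(self, covariance_floor: float = 1e-9) -> "GaussianHMM":
        if not np.allclose(self.transmat.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("rows of the transition matrix must sum to 1")
        if not np.isclose(self.startprob.sum(), 1.0, atol=1e-9):
            raise ValueError("initial distribution must sum to 1")
        for i, S in enumerate(self.covars):
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError(f"covariance of state {i} is not symmetric")
            if np.linalg.eigvalsh(S).min() < covariance_floor * (1 - 1e-6):
                raise ValueError(f"covariance of state {i} is below the floor")
        return self

    def to_dict(self) -> dict:
        return {
            "transmat": self.transmat.tolist(),
            "means": self.means.tolist(),
            "covars": self.covars.tolist(),
            "startprob": self.startprob.tolist(),
            "log_likelihood": self.log_likelihood,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianHMM":
        return cls(
            transmat=np.asarray(d["transmat"], dtype=float),
            means=np.asarray(d["means"], dtype=float),
            covars=np.asarray(d["covars"], dtype=float),
            startprob=np.asarray(d["startprob"], dtype=float),
            log_likelihood=d.get("log_likelihood"),
            meta=d.get("meta", {}),
        )


@dataclass(frozen=True)
class SimilarityScore:
    """HMM-SM score in [0, 1]; higher means closer to normative gait."""

    S: float
    config: str = ""
    participant_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.S <= 1.0:
            raise ValueError("similarity score must lie in [0, 1]")


def make_training_windows(
    cycles: GaitCycleSet | Sequence[np.ndarray], window: int = 10, stride: int = 1
) -> list[np.ndarray]:
    """Sliding-window groups of ``window`` cycles concatenated along time."""
    blocks = cycles.cycles if isinstance(cycles, GaitCycleSet) else list(cycles)
    n = len(blocks)
    if n < window:
        raise ValueError(f"need at least {window} cycles, got {n}")
    return [
        np.concatenate(blocks[i : i + window], axis=1)
        for i in range(0, n - window + 1, stride)
    ]


def fit_hmm(
    sequences: Sequence[np.ndarray],
    n_states: int = 5,
    seed: int = 0,
    n_restarts: int = 5,
    n_iter: int = 200,
    tol: float = 1e-4,
    covariance_floor: float = 1e-6,
) -> GaussianHMM:
    """EM-fit an ergodic full-covariance Gaussian HMM; best of seeded restarts.

    ``sequences`` are channels x time arrays.  Each seeded restart starts EM
    from a k-means partition of the frames — cluster centroids as means and
    *per-cluster* covariances (a global-covariance start drowns the cluster
    structure and lets EM merge well-separated states) with the transition
    matrix estimated from cluster-label transitions.  The restart with the
    highest final log-likelihood is retained, and a diagonal covariance
    floor makes degenerate (constant) input yield a floored model instead
    of a crash.
    """
    from hmmlearn.hmm import GaussianHMM as _HmmlearnGaussianHMM

    X = np.concatenate([np.asarray(s, dtype=float).T for s in sequences], axis=0)
    lengths = [np.asarray(s).shape[1] for s in sequences]
    d = X.shape[1]
    if X.shape[0] < n_states + 1:
        raise ValueError("too few frames to fit the requested number of states")
    restart_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_restarts)
    best, best_ll = None, -np.inf
    for rs in restart_seeds:
        model = _HmmlearnGaussianHMM(
            n_components=n_states,
            covariance_type="full",
            n_iter=n_iter,
            tol=tol,
            min_covar=covariance_floor,
            random_state=int(rs),
            init_params="",
        )
        # scalar covars_prior would be added to every entry (rank-1, singular
        # for degenerate input); an identity prior keeps the M-step SPD
        model.covars_prior = 1e-2 * np.eye(d)
        _kmeans_init(model, X, lengths, n_states, int(rs), covariance_floor)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model.fit(X, lengths)
            except (ValueError, _la.LinAlgError):
                continue
        ll = model.monitor_.history[-1] if model.monitor_.history else -np.inf
        if ll > best_ll:
            best, best_ll = model, ll
    if best is None:
        raise RuntimeError("all EM restarts failed")
    if not best.monitor_.converged:
        warnings.warn("EM did not converge within the iteration budget", RuntimeWarning)
    covars = np.array([_floor_spd(S, covariance_floor) for S in best.covars_])
    transmat = best.transmat_ / best.transmat_.sum(axis=1, keepdims=True)
    startprob = best.startprob_ / best.startprob_.sum()
    return GaussianHMM(
        transmat=transmat,
        means=best.means_.copy(),
        covars=covars,
        startprob=startprob,
        log_likelihood=float(best_ll),
        meta={
            "n_states": n_states,
            "seed": int(seed),
            "n_restarts": int(n_restarts),
            "n_iter": int(n_iter),
            "tol": tol,
            "converged": bool(best.monitor_.converged),
            "dim": int(d),
        },
    )


def _kmeans_init(model, X, lengths, n_states, seed, floor):
    """Seed an hmmlearn model from a k-means partition of the frames."""
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=n_states, n_init=1, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        labels = km.fit_predict(X)
    d = X.shape[1]
    model.n_features = d  # normally set by hmmlearn's own _init
    global_cov = np.atleast_2d(np.cov(X, rowvar=False)) + floor * np.eye(d)
    covars = np.empty((n_states, d, d))
    for k in range(n_states):
        members = X[labels == k]
        if members.shape[0] > d:
            covars[k] = _floor_spd(
                np.atleast_2d(np.cov(members, rowvar=False)), floor
            )
        else:  # thin cluster: fall back on the global scale
            covars[k] = global_cov
    # sticky structure straight from the label sequence (add-one smoothed),
    # skipping the joins between independent training sequences
    trans = np.ones((n_states, n_states))
    stop = np.cumsum(lengths)
    joins = set(stop[:-1])
    for t in range(len(labels) - 1):
        if t + 1 in joins:
            continue
        trans[labels[t], labels[t + 1]] += 1
    model.startprob_ = np.full(n_states, 1.0 / n_states)
    model.transmat_ = trans / trans.sum(axis=1, keepdims=True)
    model.means_ = km.cluster_centers_.copy()
    model.covars_ = covars


def _floor_spd(S: np.ndarray, floor: float) -> np.ndarray:
    """Symmetrise and lift the spectrum so the smallest eigenvalue is >= floor."""
    S = 0.5 * (S + S.T)
    mineig = np.linalg.eigvalsh(S).min()
    if mineig < floor:
        S = S + (floor - mineig) * np.eye(S.shape[0])
    return S


def symmetric_kl_gaussian(
    b1: tuple[np.ndarray, np.ndarray], b2: tuple[np.ndarray, np.ndarray]
) -> float:
    """Symmetric KL divergence KL(b1||b2) + KL(b2||b1) of two Gaussians.

    Closed form: D_sym = 1/2 [ tr(S2^-1 S1) + tr(S1^-1 S2) - 2 d
    + (mu1 - mu2)^T (S1^-1 + S2^-1) (mu1 - mu2) ].
    """
    mu1, S1 = np.atleast_1d(np.asarray(b1[0], float)), np.atleast_2d(np.asarray(b1[1], float))
    mu2, S2 = np.atleast_1d(np.asarray(b2[0], float)), np.atleast_2d(np.asarray(b2[1], float))
    if mu1.shape != mu2.shape or S1.shape != S2.shape:
        raise ValueError("Gaussians have mismatched dimensions")
    d = mu1.shape[0]
    try:
        c1 = _la.cho_factor(S1)
        c2 = _la.cho_factor(S2)
    except _la.LinAlgError as err:
        raise ValueError("singular covariance in symmetric KL") from err
    inv1 = _la.cho_solve(c1, np.eye(d))
    inv2 = _la.cho_solve(c2, np.eye(d))
    diff = mu1 - mu2
    val = 0.5 * (
        np.trace(inv2 @ S1)
        + np.trace(inv1 @ S2)
        - 2 * d
        + diff @ (inv1 + inv2) @ diff
    )
    return float(max(val, 0.0))


def divergence_matrix(lam_a: GaussianHMM, lam_b: GaussianHMM) -> np.ndarray:
    """Pairwise symmetric-KL divergences between the two models' emissions."""
    if lam_a.dim != lam_b.dim:
        raise ValueError(f"observation dimensions differ: {lam_a.dim} vs {lam_b.dim}")
    M, Mp = lam_a.n_states, lam_b.n_states
    D = np.empty((M, Mp))
    for i in range(M):
        for j in range(Mp):
            D[i, j] = symmetric_kl_gaussian(
                (lam_a.means[i], lam_a.covars[i]), (lam_b.means[j], lam_b.covars[j])
            )
    return D


def correspondence_matrix(
    lam_a: GaussianHMM,
    lam_b: GaussianHMM,
    tau: float = 1.0,
    weight_stationary: bool = False,
) -> np.ndarray:
    """State-correspondence matrix Q with q_ij = exp(-D_sym(b_a[i], b_b[j]) / tau).

    ``weight_stationary`` optionally multiplies Q elementwise by the outer
    product of the two initial-state distributions (off by default; the
    similarity below is defined on the emissions alone).
    """
    if lam_a.dim != lam_b.dim:
        raise ValueError(
            f"observation dimensions differ: {lam_a.dim} vs {lam_b.dim}"
        )
    if tau <= 0:
        raise ValueError("kernel scale tau must be positive")
    M, Mp = lam_a.n_states, lam_b.n_states
    Q = np.exp(-divergence_matrix(lam_a, lam_b) / tau)
    if weight_stationary:
        Q = Q * np.outer(lam_a.startprob, lam_b.startprob) * (M * Mp)
    return Q


def gini_sparsity(u: np.ndarray) -> float:
    """Normalized Gini index of a non-negative vector: 0 (uniform) to 1 (one-hot).

    With u sorted ascending and N entries,
    G = 1 - 2 sum_k (u_k / ||u||_1) (N - k + 1/2)/N, scaled by N/(N-1) so a
    one-hot vector scores exactly 1.
    """
    u = np.asarray(u, dtype=float).ravel()
    if u.size < 2:
        raise ValueError("sparsity needs at least 2 entries")
    if np.any(u < 0):
        raise ValueError("sparsity is defined for non-negative vectors")
    total = u.sum()
    if total == 0:
        raise ValueError("sparsity of the all-zero vector is undefined")
    N = u.size
    s = np.sort(u) / total
    k = np.arange(1, N + 1)
    G = 1.0 - 2.0 * np.sum(s * (N - k + 0.5) / N)
    return float(np.clip(G * N / (N - 1), 0.0, 1.0))


def hmm_similarity_score(
    lam_a: GaussianHMM,
    lam_b: GaussianHMM,
    tau: float = 1.0,
    weight_stationary: bool = False,
) -> float:
    """Sparsity-based similarity S(lam_a || lam_b) in [0, 1].

    Mean normalized-Gini sparsity of the rows and of the columns of the
    state-correspondence matrix, averaged.  Symmetric in its arguments and
    invariant to relabelling of states in either model.

    The Gini index is invariant to scaling a vector, so each row and column
    is evaluated with its exponent shifted by its smallest divergence; this
    equals the sparsity of the raw kernel values but cannot underflow to an
    all-zero vector when divergences are large relative to ``tau``.
    """
    D = divergence_matrix(lam_a, lam_b)
    if weight_stationary:
        W = np.outer(lam_a.startprob, lam_b.startprob)
        row_H = np.mean(
            [gini_sparsity(np.exp(-(r - r.min()) / tau) * w)
             for r, w in zip(D, W)]
        )
        col_H = np.mean(
            [gini_sparsity(np.exp(-(c - c.min()) / tau) * w)
             for c, w in zip(D.T, W.T)]
        )
    else:
        row_H = np.mean([gini_sparsity(np.exp(-(r - r.min()) / tau)) for r in D])
        col_H = np.mean([gini_sparsity(np.exp(-(c - c.min()) / tau)) for c in D.T])
    return float(0.5 * (row_H + col_H))


def hmm_sm_participant(
    cycles: GaitCycleSet,
    lam_control: GaussianHMM,
    channel_mean: np.ndarray | None = None,
    channel_std: np.ndarray | None = None,
    config_name: str = "",
    window: int = 10,
    stride: int = 1,
    n_states: int = 5,
    seed: int = 0,
    tau: float = 1.0,
    **fit_kwargs,
) -> SimilarityScore:
    """Fit lambda_p on a participant's windowed cycles and score it against
    lambda_control.

    ``channel_mean``/``channel_std`` are the normative per-channel statistics
    used to z-normalize frames before training (the same normalisation the
    control model was trained under).
    """
    seqs = make_training_windows(cycles, window=window, stride=stride)
    if channel_mean is not None:
        seqs = [zscore_block(s, channel_mean, channel_std) for s in seqs]
    lam_p = fit_hmm(seqs, n_states=n_states, seed=seed, **fit_kwargs)
    S = hmm_similarity_score(lam_p, lam_control, tau=tau)
    return SimilarityScore(S=S, config=config_name, participant_id=cycles.participant_id)


def calibrate_tau(lam_control: GaussianHMM, contrast: float = 100.0) -> float:
    """Self-calibration of the kernel scale tau from the control model.

    Symmetric-KL divergences between full-covariance Gaussian states scale
    with the data (dimension, normalisation, within-state variance), so a
    fixed tau is meaningless across data sets.  The reference scale chosen
    here is the control model's own state structure: tau is set so that a
    typical pair of *distinct* normative states (median off-diagonal
    divergence) maps to a correspondence ``1/contrast`` — two orders of
    magnitude below a perfect match by default.  States as separable as the
    normative states then contribute nothing to a row's mass (keeping the
    self-similarity near 1), while a deviated state whose best and
    second-best matches begin to blur on this scale visibly reduces the
    sparsity of Q.
    """
    if contrast <= 1:
        raise ValueError("contrast must exceed 1")
    D = divergence_matrix(lam_control, lam_control)
    off = D[~np.eye(lam_control.n_states, dtype=bool)]
    if off.size == 0:
        raise ValueError("control model has a single state; tau is undefined")
    return float(max(np.median(off) / np.log(contrast), 1e-3))


def zscore_block(block: np.ndarray, mean: np.ndarray, std: np.ndarray) -> np.ndarray:
    """Per-channel z-normalisation of a channels x time block."""
    mean = np.asarray(mean, float).reshape(-1, 1)
    std = np.asarray(std, float).reshape(-1, 1)
    std = np.where(std > 0, std, 1.0)
    return (np.asarray(block, float) - mean) / std


def channel_stats(cycles: GaitCycleSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and SD over all frames of a cycle set."""
    frames = cycles.frames()
    return frames.mean(axis=0), frames.std(axis=0)
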