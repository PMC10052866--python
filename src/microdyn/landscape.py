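"""Pairwise maximum-entropy (Ising-type) energy landscapes over binary
community states.

A community of S taxa has 2^S presence/absence states sigma.  The model
assigns each state an energy

    H(sigma) = - sum_i h_i sigma_i - sum_{i<j} J_ij sigma_i sigma_j

and a stationary probability p(sigma) = exp(-H)/Z.  Biases ``h_i`` capture
the net effect of implicit abiotic factors on taxon i; couplings ``J_ij``
capture pairwise co-occurrence.  States on the single-bit-flip assembly
graph whose energy is below all S neighbors are the stable states; basins
of attraction follow steepest descent.  Two early-warning indices derive
from the landscape: the energy gap to the local minimum and the Shannon
entropy of random-walk destinations (stable-state entropy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .tables import AbundanceTable

MAX_EXACT_S = 20


class LandscapeError(RuntimeError):
    pass


def enumerate_states(s: int) -> np.ndarray:
    """All 2^S binary states; row k has bit i = (k >> i) & 1."""
    if s > MAX_EXACT_S:
        raise LandscapeError(f"S={s} exceeds exact enumeration cap {MAX_EXACT_S}")
    k = np.arange(2**s, dtype=np.int64)
    return ((k[:, None] >> np.arange(s)) & 1).astype(np.int8)


def state_index(state: np.ndarray) -> int:
    state = np.asarray(state)
    return int((state.astype(np.int64) << np.arange(len(state))).sum())


def energy(state: np.ndarray, h: np.ndarray, J: np.ndarray) -> float:
    """H(sigma) = -sum_i h_i sigma_i - sum_{i<j} J_ij sigma_i sigma_j."""
    state = np.asarray(state, dtype=float)
    if state.shape != np.shape(h):
        raise ValueError("state length must match model size S")
    return float(-(h @ state) - 0.5 * state @ J @ state)


def state_energies(states: np.ndarray, h: np.ndarray, J: np.ndarray) -> np.ndarray:
    """Vectorized energies for a (n, S) state matrix."""
    s = states.astype(float)
    return -(s @ h) - 0.5 * np.einsum("ki,ij,kj->k", s, J, s)


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------

@dataclass
class BinaryCommunityMatrix:
    """Samples x taxa presence/absence matrix after occurrence filtering."""

    matrix: np.ndarray
    taxon_ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be binary")

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[1]


def binarize(
    table: AbundanceTable,
    lower: float = 0.02,
    upper: float = 0.98,
    presence_threshold: float = 0.0,
    treatment=None,
    replicates=None,
) -> BinaryCommunityMatrix:
    """Presence/absence matrix keeping taxa occurring in [lower, upper] of samples.

    Presence means concentration strictly above ``presence_threshold``
    (detection limit; 0 in the data does not necessarily mean true absence).
    Occurrence-frequency bounds are inclusive.
    """
    sub = table
    if treatment is not None or replicates is not None:
        sub = table.subset(treatment=treatment, replicates=replicates)
    piv = sub.data.pivot_table(
        index=["treatment", "replicate", "day"],
        columns="taxon_id",
        values="abundance",
        fill_value=0.0,
    )
    pres = (piv.to_numpy() > presence_threshold).astype(np.int8)
    freq = pres.mean(axis=0)
    keep = (freq >= lower) & (freq <= upper)
    if not keep.any():
        raise LandscapeError("no taxa retained by the occurrence filter")
    return BinaryCommunityMatrix(
        matrix=pres[:, keep],
        taxon_ids=[t for t, k in zip(piv.columns.tolist(), keep) if k],
        provenance={
            "treatment": treatment,
            "replicates": list(replicates) if replicates is not None else None,
            "n_samples": int(pres.shape[0]),
        },
    )


# ---------------------------------------------------------------------------
# the pairwise maximum-entropy estimator
# ---------------------------------------------------------------------------

class PairwiseMaxEnt(BaseEstimator):
    """Pairwise maximum-entropy model fit by moment-matching gradient ascent.

    Parameters are updated multiplicatively on the log scale,

        h_i  <- h_i  + alpha * log(<sigma_i>  / <sigma_i>*)
        J_ij <- J_ij + alpha * log(<sigma_i sigma_j> / <sigma_i sigma_j>*)

    where empirical moments ``<.>`` come from the data (with a
    0.5/(n+1)-style pseudocount so zero co-occurrence stays finite) and
    model moments ``<.>*`` are computed by exact enumeration of all 2^S
    states.  Iteration stops when the largest absolute log moment ratio
    falls below ``tol`` or at ``max_iter``.

    Attributes
    ----------
    h_ : (S,) ndarray of fitted biases
    J_ : (S, S) symmetric zero-diagonal ndarray of fitted couplings
    n_iter_ : iterations used
    max_abs_log_ratio_ : final convergence measure
    converged_ : bool
    """

    def __init__(self, learning_rate: float = 0.1, max_iter: int = 50_000,
                 tol: float = 1e-4):
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        X = np.asarray(X.matrix if isinstance(X, BinaryCommunityMatrix) else X)
        if not np.isin(X, (0, 1)).all():
            raise ValueError("X must be a binary samples x taxa matrix")
        n, s = X.shape
        if s > MAX_EXACT_S:
            raise LandscapeError(f"S={s} exceeds exact enumeration cap {MAX_EXACT_S}")
        Xf = X.astype(float)
        # empirical moments with pseudocount shrinkage (count + 0.5)/(n + 1)
        emp_m1 = (Xf.sum(axis=0) + 0.5) / (n + 1)
        emp_m2 = (Xf.T @ Xf + 0.5) / (n + 1)
        iu = np.triu_indices(s, k=1)

        states = enumerate_states(s)
        sf = states.astype(float)
        h = np.zeros(s)
        J = np.zeros((s, s))
        alpha = self.learning_rate
        max_ratio = np.inf
        it = 0
        for it in range(1, self.max_iter + 1):
            e = state_energies(states, h, J)
            logp = -e - (-e).max()
            p = np.exp(logp)
            p /= p.sum()
            mod_m1 = p @ sf
            mod_m2 = (sf * p[:, None]).T @ sf
            log_r1 = np.log(emp_m1 / mod_m1)
            log_r2 = np.log(emp_m2[iu] / mod_m2[iu])
            max_ratio = max(np.abs(log_r1).max(), np.abs(log_r2).max())
            if not np.isfinite(max_ratio):
                raise LandscapeError(f"maxent fit diverged at iteration {it}")
            if max_ratio < self.tol:
                break
            h = h + alpha * log_r1
            J[iu] = J[iu] + alpha * log_r2
            J[(iu[1], iu[0])] = J[iu]
        self.h_ = h
        self.J_ = J
        self.S_ = s
        self.n_iter_ = it
        self.max_abs_log_ratio_ = float(max_ratio)
        self.converged_ = bool(max_ratio < self.tol)
        self.empirical_moments_ = (emp_m1, emp_m2)
        return self

    # -- landscape queries -------------------------------------------------
    def _check(self):
        if not hasattr(self, "h_"):
            raise LandscapeError("model is not fitted")

    def energy(self, state) -> float:
        self._check()
        return energy(state, self.h_, self.J_)

    def state_probabilities(self) -> np.ndarray:
        """p over all 2^S states, index k encodes bits (k >> i) & 1."""
        self._check()
        e = state_energies(enumerate_states(self.S_), self.h_, self.J_)
        logp = -e - (-e).max()
        p = np.exp(logp)
        return p / p.sum()

    def set_parameters(self, h, J) -> "PairwiseMaxEnt":
        """Install known (h, J) directly (ground-truth or serialized models)."""
        h = np.asarray(h, dtype=float)
        J = np.asarray(J, dtype=float)
        if J.shape != (len(h), len(h)) or not np.allclose(J, J.T) or \
                not np.allclose(np.diag(J), 0):
            raise ValueError("J must be symmetric, zero-diagonal, matching h")
        self.h_, self.J_, self.S_ = h, J, len(h)
        self.n_iter_, self.max_abs_log_ratio_, self.converged_ = 0, 0.0, True
        return self


# ---------------------------------------------------------------------------
# minima, basins, warning indices
# ---------------------------------------------------------------------------

def _neighbor_indices(s: int) -> np.ndarray:
    """(2^S, S) array: neighbor_indices[k, i] = k with bit i flipped."""
    k = np.arange(2**s, dtype=np.int64)[:, None]
    return k ^ (1 << np.arange(s, dtype=np.int64))


def find_stable_states(model: PairwiseMaxEnt) -> list[np.ndarray]:
    """States whose energy is strictly below all S single-flip neighbors."""
    model._check()
    states = enumerate_states(model.S_)
    e = state_energies(states, model.h_, model.J_)
    nb = _neighbor_indices(model.S_)
    is_min = (e[:, None] < e[nb]).all(axis=1)
    return [states[k].copy() for k in np.flatnonzero(is_min)]


def basin_of(state, model: PairwiseMaxEnt) -> np.ndarray:
    """Steepest-descent terminal state; ties go to the lowest flipped bit."""
    model._check()
    cur = np.asarray(state, dtype=np.int8).copy()
    e_cur = model.energy(cur)
    visited = set()
    while True:
        key = state_index(cur)
        if key in visited:
            raise AssertionError("cycle under strict steepest descent")
        visited.add(key)
        best_e, best_i = e_cur, -1
        for i in range(model.S_):
            cur[i] ^= 1
            e_n = model.energy(cur)
            cur[i] ^= 1
            if e_n < best_e:  # strict; first (lowest-index) winner kept on ties
                best_e, best_i = e_n, i
        if best_i < 0:
            return cur
        cur[best_i] ^= 1
        e_cur = best_e


def basin_labels(model: PairwiseMaxEnt) -> np.ndarray:
    """Basin label (index of the terminal minimum state) for all 2^S states."""
    model._check()
    s = model.S_
    states = enumerate_states(s)
    e = state_energies(states, model.h_, model.J_)
    nb = _neighbor_indices(s)
    nb_e = e[nb]
    # steepest single-flip descent target per state (self if local min)
    best = nb_e.argmin(axis=1)
    improves = nb_e[np.arange(len(e)), best] < e
    nxt = np.where(improves, nb[np.arange(len(e)), best], np.arange(len(e)))
    labels = np.arange(len(e))
    # iterate pointer-jumping until fixed point
    while True:
        new = nxt[labels]
        if np.array_equal(new, labels):
            return labels
        labels = new


def energy_gap(state, model: PairwiseMaxEnt) -> float:
    """H(state) - H(local minimum of its basin); nonnegative."""
    return model.energy(state) - model.energy(basin_of(state, model))


def stable_state_entropy(
    state,
    model: PairwiseMaxEnt,
    n_walks: int = 1000,
    max_steps: int | None = None,
    seed: int | np.random.Generator = 0,
) -> float:
    """Shannon entropy (nats) of random-walk destination minima.

    Each walk proposes a uniformly random single-bit flip and accepts with
    Metropolis probability min(1, exp(-dH)); it stops on reaching a local
    minimum (or is mapped there by steepest descent after ``max_steps``).
    """
    model._check()
    if n_walks < 1:
        raise ValueError("n_walks must be >= 1")
    s = model.S_
    states = enumerate_states(s)
    e = state_energies(states, model.h_, model.J_)
    nb = _neighbor_indices(s)
    is_min = (e[:, None] < e[nb]).all(axis=1)
    if not is_min.any():
        raise LandscapeError("landscape has no strict minima")
    labels = basin_labels(model)
    if max_steps is None:
        max_steps = 100 * s
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start = state_index(np.asarray(state, dtype=np.int8))
    dest = np.empty(n_walks, dtype=np.int64)
    for w in range(n_walks):
        cur = start
        for _ in range(max_steps):
            if is_min[cur]:
                break
            i = rng.integers(s)
            cand = cur ^ (1 << i)
            d_h = e[cand] - e[cur]
            if d_h <= 0 or rng.random() < np.exp(-d_h):
                cur = cand
        dest[w] = labels[cur]  # maps non-minima by steepest descent
    _, counts = np.unique(dest, return_counts=True)
    q = counts / counts.sum()
    return float(-(q * np.log(q)).sum())


def landscape_summary(model: PairwiseMaxEnt) -> pd.DataFrame:
    """Per-state table: bitstring, energy, basin label, is_minimum (S <= 12)."""
    model._check()
    s = model.S_
    states = enumerate_states(s)
    e = state_energies(states, model.h_, model.J_)
    nb = _neighbor_indices(s)
    is_min = (e[:, None] < e[nb]).all(axis=1)
    labels = basin_labels(model)
    if s <= 12:
        idx = np.arange(2**s)
    else:
        idx = np.flatnonzero(is_min)
    bits = ["".join(str(b) for b in states[k]) for k in idx]
    return pd.DataFrame(
        {
            "state": bits,
            "energy": e[idx],
            "basin": labels[idx],
            "is_minimum": is_min[idx],
        }
    )
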