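"""Jacobian-based stability indices from multivariate S-maps.

A convergent-cross-mapping (CCM) screen selects causally coupled taxa; a
multivariate S-map then fits, at each time point, a locally weighted linear
model of every taxon's next-day abundance on the current abundances of the
selected set.  The coefficient rows form a time-varying Jacobian J(t) whose
dominant eigenvalue modulus gives the local Lyapunov stability (tipping
value 1: < 1 converging, > 1 diverging) and whose trace gives the local
structural stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import edm
from .tables import AbundanceTable


@dataclass
class CcmResult:
    driver: object
    response: object
    rho_min: float
    rho_max: float
    converged: bool


def _cross_map_rho(
    target_emb: np.ndarray,
    driver_vals: np.ndarray,
    library_size: int,
    rng: np.random.Generator,
    n_boot: int = 10,
    E: int = 2,
    exclusion_radius: int = 10,
) -> float:
    """Mean simplex cross-map skill at one library size.

    Neighbors within ``exclusion_radius`` time steps of the prediction
    point are excluded (Theiler window), so autocorrelation alone cannot
    mimic causal coupling.
    """
    n = len(target_emb)
    k = E + 1
    rhos = []
    for _ in range(n_boot):
        lib = rng.choice(n, size=library_size, replace=False)
        preds, obs = [], []
        for t in range(n):
            usable = lib[np.abs(lib - t) > exclusion_radius]
            if len(usable) < k:
                continue
            d = np.linalg.norm(target_emb[usable] - target_emb[t], axis=1)
            nn = usable[np.argsort(d, kind="stable")[:k]]
            dn = np.linalg.norm(target_emb[nn] - target_emb[t], axis=1)
            if dn[0] == 0:
                preds.append(driver_vals[nn[dn == 0]].mean())
            else:
                w = np.exp(-dn / dn[0])
                preds.append(float(w @ driver_vals[nn] / w.sum()))
            obs.append(driver_vals[t])
        if len(preds) < 3 or np.std(preds) == 0 or np.std(obs) == 0:
            rhos.append(0.0)
        else:
            rhos.append(float(np.corrcoef(preds, obs)[0, 1]))
    return float(np.mean(rhos))


def ccm_screen(
    series: dict,
    target,
    candidates=None,
    library_sizes=(10, None),
    E: int = 2,
    margin: float = 0.1,
    rho_threshold: float = 0.2,
    seed: int = 0,
) -> list[CcmResult]:
    """CCM from the target's embedding onto each candidate's values.

    ``series`` maps taxon -> 1-D array (one replicate, aligned days).  A
    candidate is accepted as causal iff cross-map skill rho increases with
    library size by at least ``margin`` and exceeds ``rho_threshold``.
    Results are ranked by rho at the largest library.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(series[target], dtype=float)
    vecs, ts = edm.embed_series(x, E)
    candidates = [c for c in (candidates or series) if c != target]
    lo = library_sizes[0]
    hi = library_sizes[1] if library_sizes[1] is not None else len(vecs)
    hi = min(hi, len(vecs))
    if lo >= hi or hi > len(vecs):
        raise edm.EdmError(
            f"library sizes ({lo}, {hi}) incompatible with {len(vecs)} embedded points"
        )
    out = []
    for cand in candidates:
        y = np.asarray(series[cand], dtype=float)[ts]
        rho_lo = _cross_map_rho(vecs, y, lo, rng, E=E)
        rho_hi = _cross_map_rho(vecs, y, hi - 1, rng, E=E)
        conv = (rho_hi - rho_lo >= margin) and (rho_hi > rho_threshold)
        out.append(CcmResult(cand, target, rho_lo, rho_hi, conv))
    out.sort(key=lambda r: r.rho_max, reverse=True)
    return out


@dataclass
class JacobianSeries:
    days: np.ndarray
    matrices: np.ndarray  # (T, m, m)
    taxa: list
    theta: float


def multivariate_smap_jacobian(
    target_states: np.ndarray,
    reference_states: np.ndarray,
    reference_next: np.ndarray,
    theta: float = 0.0,
    days=None,
    taxa=None,
) -> JacobianSeries:
    """Estimate J(t) with entry (i, j) = d x_i(t+1) / d x_j(t).

    ``target_states`` is (T, m): the multivariate (z-scored) state of the
    target replicate at each time.  ``reference_states`` / ``reference_next``
    are (N, m) current/next-day state pairs pooled from the reference
    replicates.  Row i of J(t) holds the S-map coefficients (intercept
    dropped) of the regression of x_i(t+1) on x(t), locally weighted around
    the target state at time t.
    """
    target_states = np.atleast_2d(np.asarray(target_states, dtype=float))
    m = target_states.shape[1]
    if reference_states.shape[0] <= m + 1:
        raise edm.EdmError(
            f"{reference_states.shape[0]} reference points cannot support "
            f"{m}-taxon Jacobians; shrink the taxon set"
        )
    mats = np.empty((len(target_states), m, m))
    for i in range(m):
        model = edm.SMap(theta=theta).fit(reference_states, reference_next[:, i])
        C = model.local_coefficients(target_states)
        mats[:, i, :] = C[:, 1:]
    return JacobianSeries(
        days=np.asarray(days) if days is not None else np.arange(len(target_states)),
        matrices=mats,
        taxa=list(taxa) if taxa is not None else list(range(m)),
        theta=theta,
    )


def local_lyapunov_stability(J: np.ndarray) -> float:
    """Absolute value of the dominant eigenvalue of J."""
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian has non-finite entries")
    return float(np.abs(np.linalg.eigvals(J)).max())


def local_structural_stability(J: np.ndarray) -> float:
    """Trace of J (sum of diagonal elements)."""
    J = np.asarray(J, dtype=float)
    if not np.all(np.isfinite(J)):
        raise ValueError("Jacobian has non-finite entries")
    return float(np.trace(J))


def select_jacobian_taxa(
    table: AbundanceTable,
    treatment,
    m: int = 8,
    ccm_results: list[CcmResult] | None = None,
) -> list:
    """Top-m taxa by mean relative abundance, intersected with CCM-converged."""
    rel = table.relative().data
    rel = rel[rel["treatment"] == treatment]
    ranked = (
        rel.groupby("taxon_id")["abundance"].mean().sort_values(ascending=False)
    )
    top = ranked.index.tolist()[:m]
    if ccm_results:
        causal = {r.driver for r in ccm_results if r.converged} | {
            r.response for r in ccm_results if r.converged
        }
        inter = [t for t in top if t in causal]
        if inter:
            top = inter
    return top


def stability_table(
    table: AbundanceTable,
    treatment,
    taxa=None,
    m: int = 8,
    theta: float = 0.0,
    targets=None,
) -> pd.DataFrame:
    """Per-day Lyapunov and structural stability, leave-one-replicate-out.

    For each target replicate, the current/next state pairs of the other
    replicates form the reference database for the multivariate S-map.
    """
    reps = table.replicates(treatment)
    if len(reps) < 2:
        raise ValueError("need >= 2 replicates")
    targets = list(targets) if targets is not None else reps
    taxa = list(taxa) if taxa is not None else select_jacobian_taxa(table, treatment, m=m)
    # z-score each taxon within each replicate
    states = {}
    for rep in reps:
        wide = table.wide(treatment, rep)
        cols = []
        for t in taxa:
            z, _, _, const = edm.zstandardize(wide[t].to_numpy(dtype=float))
            cols.append(z)
        states[rep] = (wide.index.to_numpy(), np.column_stack(cols))
    rows = []
    for target_rep in targets:
        days_t, x_t = states[target_rep]
        ref_cur, ref_nxt = [], []
        for rep in reps:
            if rep == target_rep:
                continue
            _, x_r = states[rep]
            ref_cur.append(x_r[:-1])
            ref_nxt.append(x_r[1:])
        jac = multivariate_smap_jacobian(
            x_t, np.vstack(ref_cur), np.vstack(ref_nxt), theta=theta,
            days=days_t, taxa=taxa,
        )
        for day, J in zip(jac.days, jac.matrices):
            rows.append(
                (treatment, target_rep, int(day),
                 local_lyapunov_stability(J), local_structural_stability(J),
                 len(taxa), theta)
            )
    return pd.DataFrame(
        rows,
        columns=["treatment", "replicate", "day", "lyapunov", "structural", "m", "theta"],
    )
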