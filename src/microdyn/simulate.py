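"""Synthetic microcosm communities, sequencing reads, and Ising samples.

Emulates the statistical structure of daily-sampled continuous-culture
microbiome experiments: replicate communities following stochastic
generalized Lotka-Volterra (gLV) dynamics with a daily 20% medium
replacement, multinomial amplicon sequencing with internal spike-in
standards, and exact samplers for pairwise maximum-entropy ground truths
used in parameter-recovery experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import AbundanceTable

#: Spike-in copy concentrations (nM) of the five internal standards.
DEFAULT_SPIKE_NM = (0.1, 0.05, 0.02, 0.01, 0.005)

EXTINCTION_FLOOR = 1e-10


class TrajectoryError(RuntimeError):
    """Raised when a simulated trajectory becomes non-finite."""


@dataclass
class GLVParams:
    """Parameters of the discrete-day stochastic gLV simulator.

    The daily update is one Euler-Maruyama step of
    ``dN_i/dt = N_i (r_i + sum_j a_ij N_j)`` (dt = 1 day) with lognormal
    multiplicative process noise, followed by replacement of a fraction
    ``dilution_fraction`` of the culture (multiplying all abundances by
    ``1 - dilution_fraction``).

    Attributes
    ----------
    growth_rates : (n_taxa,) array, 1/day
    interactions : (n_taxa, n_taxa) array
        Per-capita effect of taxon j on taxon i, 1/(abundance*day).
        Diagonal entries are self-limitation terms.
    noise_sd : float
        SD of the process noise on log abundance (lognormal multiplicative).
    dilution_fraction : float in [0, 1]
        Fraction of culture replaced daily (default 0.2 = 200 of 1000 uL).
    perturb_day, perturb_factors : optional
        Multiply abundances by ``perturb_factors`` right after the update of
        day ``perturb_day`` (used to induce a state shift in fixtures).
    """

    n_taxa: int
    growth_rates: np.ndarray
    interactions: np.ndarray
    noise_sd: float = 0.0
    dilution_fraction: float = 0.2
    n_replicates: int = 1
    n_days: int = 110
    seed: int = 0
    init_abundance: np.ndarray | None = None
    init_jitter: float = 0.1
    perturb_day: int | None = None
    perturb_factors: np.ndarray | None = None
    perturb_add: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.growth_rates = np.asarray(self.growth_rates, dtype=float)
        self.interactions = np.asarray(self.interactions, dtype=float)
        if self.growth_rates.shape != (self.n_taxa,):
            raise ValueError("growth_rates must have length n_taxa")
        if self.interactions.shape != (self.n_taxa, self.n_taxa):
            raise ValueError("interactions must be square n_taxa x n_taxa")
        if not 0.0 <= self.dilution_fraction <= 1.0:
            raise ValueError("dilution_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.init_abundance is not None:
            self.init_abundance = np.asarray(self.init_abundance, dtype=float)
            if self.init_abundance.shape != (self.n_taxa,):
                raise ValueError("init_abundance must have length n_taxa")
        if self.perturb_factors is not None:
            self.perturb_factors = np.asarray(self.perturb_factors, dtype=float)
            if self.perturb_factors.shape != (self.n_taxa,):
                raise ValueError("perturb_factors must have length n_taxa")
        if self.perturb_add is not None:
            self.perturb_add = np.asarray(self.perturb_add, dtype=float)
            if self.perturb_add.shape != (self.n_taxa,):
                raise ValueError("perturb_add must have length n_taxa")


def glv_step(n: np.ndarray, params: GLVParams, rng: np.random.Generator) -> np.ndarray:
    """One day of gLV dynamics: Euler step, noise, dilution, extinction floor."""
    with np.errstate(over="ignore", invalid="ignore"):
        growth = n * (params.growth_rates + params.interactions @ n)
        n = n + growth
    n = np.maximum(n, 0.0)
    if params.noise_sd > 0:
        eps = rng.standard_normal(n.shape)
        n = n * np.exp(params.noise_sd * eps - 0.5 * params.noise_sd**2)
    n = n * (1.0 - params.dilution_fraction)
    n[n < EXTINCTION_FLOOR] = 0.0
    return n


def simulate_glv(params: GLVParams, treatment: str = "synthetic") -> AbundanceTable:
    """Simulate replicate community time series under the gLV model.

    Returns a long-format :class:`AbundanceTable` with days 1..n_days for
    each replicate 1..n_replicates.  Identical seeds give identical tables.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    for rep in range(1, params.n_replicates + 1):
        if params.init_abundance is not None:
            n = params.init_abundance.copy()
        else:
            n = np.full(params.n_taxa, 0.1)
        if params.init_jitter > 0:
            n = n * np.exp(params.init_jitter * rng.standard_normal(params.n_taxa))
        for day in range(1, params.n_days + 1):
            n = glv_step(n, params, rng)
            if params.perturb_day is not None and day == params.perturb_day:
                if params.perturb_factors is not None:
                    n = n * params.perturb_factors
                if params.perturb_add is not None:
                    n = n + params.perturb_add
                n[n < EXTINCTION_FLOOR] = 0.0
            if not np.all(np.isfinite(n)):
                bad = int(np.flatnonzero(~np.isfinite(n))[0])
                raise TrajectoryError(
                    f"non-finite abundance for taxon {bad} on day {day} "
                    f"(replicate {rep}); adjust growth/interaction scales"
                )
            for i in range(params.n_taxa):
                rows.append((treatment, rep, day, f"T{i:03d}", n[i]))
    df = pd.DataFrame(rows, columns=["treatment", "replicate", "day", "taxon_id", "abundance"])
    return AbundanceTable(df)


# ---------------------------------------------------------------------------
# sequencing-read simulation with spike-in standards
# ---------------------------------------------------------------------------

@dataclass
class SpikeInSet:
    """Internal standards with known copy concentrations (nM), descending."""

    concentrations: np.ndarray = field(
        default_factory=lambda: np.asarray(DEFAULT_SPIKE_NM)
    )
    labels: tuple = ("STD1", "STD2", "STD3", "STD4", "STD5")

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if len(self.labels) != len(self.concentrations):
            raise ValueError("labels and concentrations must align")
        if np.any(self.concentrations <= 0):
            raise ValueError("spike concentrations must be positive")
        if np.any(np.diff(self.concentrations) >= 0):
            raise ValueError("spike concentrations must be strictly decreasing")


@dataclass
class ReadTable:
    """Multinomial sequencing reads: taxon reads plus separate spike reads."""

    taxon_reads: pd.DataFrame  # treatment, replicate, day, taxon_id, reads
    spike_reads: pd.DataFrame  # treatment, replicate, day, spike_id, reads, known_nM


def simulate_reads(
    abundance: AbundanceTable,
    spikes: SpikeInSet | None = None,
    reads_per_sample: int = 20_000,
    copies_per_read_unit: float = 1.0,
    seed: int = 0,
) -> ReadTable:
    """Draw multinomial reads per sample over taxa and spike-in standards.

    Read probabilities are proportional to taxon copy concentration and to
    ``spike concentration * copies_per_read_unit``.  Summed reads equal
    ``reads_per_sample`` for every sample; an all-zero community assigns all
    reads to the spikes.
    """
    if reads_per_sample < 0:
        raise ValueError("reads_per_sample must be nonnegative")
    spikes = spikes or SpikeInSet()
    rng = np.random.default_rng(seed)
    taxa = abundance.taxa
    trows, srows = [], []
    grouped = abundance.data.groupby(["treatment", "replicate", "day"], sort=True)
    for (treat, rep, day), sub in grouped:
        conc = sub.set_index("taxon_id")["abundance"].reindex(taxa).fillna(0.0).to_numpy()
        weights = np.concatenate([conc, spikes.concentrations * copies_per_read_unit])
        total = weights.sum()
        if total <= 0:
            raise ValueError("sample has zero taxon and spike mass")
        counts = (
            rng.multinomial(reads_per_sample, weights / total)
            if reads_per_sample > 0
            else np.zeros(len(weights), dtype=int)
        )
        for tid, c in zip(taxa, counts[: len(taxa)]):
            trows.append((treat, rep, day, tid, int(c)))
        for lab, nm, c in zip(spikes.labels, spikes.concentrations, counts[len(taxa):]):
            srows.append((treat, rep, day, lab, int(c), nm))
    taxon_df = pd.DataFrame(
        trows, columns=["treatment", "replicate", "day", "taxon_id", "reads"]
    )
    spike_df = pd.DataFrame(
        srows, columns=["treatment", "replicate", "day", "spike_id", "reads", "known_nM"]
    )
    return ReadTable(taxon_df, spike_df)


# ---------------------------------------------------------------------------
# Ising / pairwise maximum-entropy ground-truth sampling
# ---------------------------------------------------------------------------

@dataclass
class IsingSpec:
    """Ground-truth biases h and couplings J for recovery experiments."""

    h: np.ndarray
    J: np.ndarray
    n_samples: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        self.h = np.asarray(self.h, dtype=float)
        self.J = np.asarray(self.J, dtype=float)
        s = len(self.h)
        if self.J.shape != (s, s):
            raise ValueError("J must be square matching h")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if not np.allclose(np.diag(self.J), 0):
            raise ValueError("J must have zero diagonal")


def sample_ising(
    spec: IsingSpec,
    mode: str = "exact",
    burn_in: int = 1000,
    thin: int = 10,
) -> np.ndarray:
    """Draw binary community states from p(state) = exp(-H)/Z.

    ``exact`` mode enumerates all 2^S states (S <= 20) and draws i.i.d.
    samples; ``gibbs`` runs single-site heat-bath sweeps with the stated
    burn-in and thinning.
    """
    from .landscape import enumerate_states, state_energies

    s = len(spec.h)
    rng = np.random.default_rng(spec.seed)
    if mode == "exact":
        if s > 20:
            raise ValueError(
                f"S={s} too large for exact enumeration (max 20); use mode='gibbs'"
            )
        states = enumerate_states(s)
        e = state_energies(states, spec.h, spec.J)
        logp = -e - (-e).max()
        p = np.exp(logp)
        p /= p.sum()
        idx = rng.choice(len(states), size=spec.n_samples, p=p)
        return states[idx].copy()
    if mode == "gibbs":
        state = (rng.random(s) < 0.5).astype(np.int8)
        out = np.empty((spec.n_samples, s), dtype=np.int8)
        n_sweeps = burn_in + spec.n_samples * thin
        k = 0
        for sweep in range(n_sweeps):
            for i in range(s):
                # conditional field on site i given the rest
                field_i = spec.h[i] + spec.J[i] @ state
                p1 = 1.0 / (1.0 + np.exp(-field_i))
                state[i] = 1 if rng.random() < p1 else 0
            if sweep >= burn_in and (sweep - burn_in) % thin == 0 and k < spec.n_samples:
                out[k] = state
                k += 1
        return out[:k] if k < spec.n_samples else out
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# named fixtures: frozen study-condition parameterizations
# ---------------------------------------------------------------------------

def fixture_params(name: str, **overrides) -> GLVParams:
    """Frozen simulator parameterizations for the three dynamical regimes.

    - ``"stable"``: a 5-taxon community with a single stable equilibrium.
    - ``"chaotic4"``: 4 competing taxa whose daily map is in the chaotic
      regime (logistic-like per-taxon maps with mixed-sign coupling).
    - ``"bistable"``: two mutually inhibiting 3-taxon guilds (founder
      control) with a mid-series pulse perturbation that induces a shift
      between the alternative states.
    """
    if name == "stable":
        n = 5
        r = np.array([0.9, 0.8, 0.85, 0.75, 0.7])
        a = -0.05 * np.ones((n, n)) - np.diag(0.85 * np.ones(n))
        params = GLVParams(
            n_taxa=n,
            growth_rates=r,
            interactions=a,
            noise_sd=0.05,
            dilution_fraction=0.2,
            n_replicates=8,
            n_days=110,
            seed=11,
        )
    elif name == "chaotic4":
        n = 4
        # per-taxon map N -> 0.8 * N * (1 + r (1 - N)) is conjugate to the
        # logistic map with mu = 0.8 (1 + r); r = 3.8 puts mu = 3.84 in the
        # chaotic band, and weak mixed-sign coupling makes the flow 4-D.
        r = np.array([3.8, 3.7, 3.75, 3.65])
        a = np.array(
            [
                [-3.8, -0.10, 0.05, -0.05],
                [0.06, -3.7, -0.08, 0.04],
                [-0.05, 0.07, -3.75, -0.09],
                [0.04, -0.06, 0.08, -3.65],
            ]
        )
        params = GLVParams(
            n_taxa=n,
            growth_rates=r,
            interactions=a,
            noise_sd=0.01,
            dilution_fraction=0.2,
            n_replicates=8,
            n_days=110,
            seed=7,
            init_abundance=np.array([0.3, 0.4, 0.5, 0.6]),
            init_jitter=0.2,
        )
    elif name == "bistable":
        # resident guild A (taxa 0-2) holds invader guild B (taxa 3-5)
        # slightly above replacement, so B grows slowly from far below the
        # sequencing detection limit, flickers into detectability during
        # the run-up, and finally flips the community into the B-dominated
        # state through a positive feedback (A is then excluded).  Flip
        # timing varies stochastically across replicates.
        n = 6
        r = np.full(n, 1.2)
        a = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    a[i, j] = -1.0
                elif (i < 3) == (j < 3):
                    a[i, j] = -0.2
                elif i < 3:
                    a[i, j] = -1.3  # A strongly suppressed by B
                else:
                    a[i, j] = -0.38  # B weakly suppressed by A
        params = GLVParams(
            n_taxa=n,
            growth_rates=r,
            interactions=a,
            noise_sd=0.25,
            dilution_fraction=0.2,
            n_replicates=8,
            n_days=110,
            seed=3,
            init_abundance=np.array([0.5, 0.45, 0.4, 2e-5, 2e-5, 2e-5]),
            init_jitter=0.1,
        )
    else:
        raise ValueError(f"unknown fixture {name!r}")
    for k, v in overrides.items():
        setattr(params, k, v)
    params.__post_init__()
    return params


def simulate_fixture(name: str, **overrides) -> AbundanceTable:
    """Simulate one of the named fixtures; treatment label = fixture name."""
    return simulate_glv(fixture_params(name, **overrides), treatment=name)
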