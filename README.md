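# microdyn

Tools for describing — and anticipating — abrupt shifts in microbiome time
series.

Microbial communities under constant conditions can still undergo sudden,
large compositional turnover (collapse, dysbiosis-like shifts).  `microdyn`
implements two complementary frameworks for analyzing densely sampled,
replicated community time series and extracting early-warning signals of
such shifts:

1. **Energy landscapes (statistical physics).**  Presence/absence community
   states `σ ∈ {0,1}^S` are modeled with a pairwise maximum-entropy
   (Ising-type) model,

   `H(σ) = − Σᵢ hᵢ σᵢ − Σ_{i<j} J_{ij} σᵢ σⱼ`,  `p(σ) = e^{−H(σ)} / Z`,

   fit by moment-matching gradient updates (`h ← h + α log⟨σᵢ⟩/⟨σᵢ⟩*`,
   α = 0.1, ≤ 50,000 iterations).  Local minima of `H` on the single-flip
   assembly graph are the community's stable states; two warning indices
   follow: the **energy gap** `H(σ_t) − H(σ_min)` to the bottom of the
   current basin, and the **stable-state entropy**, the Shannon entropy of
   the minima reached by Metropolis random walks started from the current
   state.

2. **Empirical dynamic modeling (nonlinear mechanics).**  Each taxon's
   z-scored abundance is delay-embedded (Takens, τ = 1, E ∈ 1..20) in a
   leave-one-replicate-out design; forecasts come from **simplex
   projection** (E+1 nearest neighbors) or the **S-map**
   (`w(d) = exp(−θd/d̄)`, θ on the grid {0, 0.001, …, 8}, SVD least
   squares).  Multivariate S-map coefficient rows estimate the time-varying
   Jacobian `J(t)`; its dominant-eigenvalue modulus is the **local Lyapunov
   stability** (tipping value 1) and its trace the **local structural
   stability**.  A CCM screen selects causally coupled taxa.

Downstream, each index at day *t* is paired with realized **abruptness**
(Bray-Curtis dissimilarity between the mean compositions of the 5-day
windows `[t−4, t]` and `[t+p, t+p+4]`; > 0.5 = abrupt shift), scored by
per-replicate regressions with BH-FDR control and by ROC/AUC with
Youden-index thresholds.

The package also ships the front of the pipeline: a stochastic
generalized Lotka-Volterra microcosm simulator (daily 20% dilution, three
frozen regimes: `stable`, `chaotic4`, `bistable`), multinomial amplicon
sequencing with five spike-in standards (0.1, 0.05, 0.02, 0.01, 0.005 nM),
per-sample calibration curves converting reads to copy concentrations, and
the standard quality filters (Pearson r < 0.7 and < 350 reads drop samples;
single missing days are mean-interpolated; taxa need ≥ 5 presences in some
replicate).

## Worked example

```python
from microdyn import (simulate_fixture, simulate_reads, SpikeInSet,
                      calibrate_reads, binarize, PairwiseMaxEnt,
                      find_stable_states, energy_gap, stable_state_entropy)
from microdyn.metrics import abruptness_table

truth = simulate_fixture("bistable", n_replicates=4, n_days=90)
reads = simulate_reads(truth, SpikeInSet(), reads_per_sample=20_000, seed=1)
table, qc = calibrate_reads(reads)

ab = abruptness_table(table, p=7)
print(ab.loc[ab.groupby("replicate")["abruptness"].idxmax(),
             ["replicate", "t", "abruptness"]])
#  replicate   t  abruptness
#          1  51        0.89
#          2  68        0.82
#          3  64        0.85
#          4  76        0.75

bcm = binarize(table, treatment="bistable", replicates=[2, 3, 4])
model = PairwiseMaxEnt().fit(bcm)
print(["".join(map(str, m)) for m in find_stable_states(model)])
# ['111100', '000111', '111111']
```

Each replicate community undergoes one abrupt shift (abruptness peaks of
0.75–0.89, i.e. > 75% compositional turnover over the 7-day horizon), at a
different day in each replicate.  The landscape fit on the other three
replicates recovers the two guild-dominated stable states plus the
transitional all-present state.  The warning indices for replicate 1:

```python
wide = table.wide("bistable", 1)
pres = (wide[bcm.taxon_ids] > 0).astype(int)
for day in (9, 30, 80):
    s = pres.loc[day].to_numpy()
    print(day, energy_gap(s, model),
          stable_state_entropy(s, model, n_walks=1000, seed=0))
# 9   3.04  0.69    <- run-up: invader flickering at the detection limit
# 30  0.0   0.0     <- settled in the resident basin
# 80  0.0   0.0     <- relaxed in the post-shift basin
```

A stable-state entropy near ln 2 ≈ 0.69 says random walks from the current
state end in either basin equally often — the community sits on a ridge of
the landscape.

A CLI mirrors the pipeline stages
(`microdyn simulate | calibrate | metrics | landscape | forecast |
stability | signals | all`); see `microdyn --help`.

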