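# Methods

This note documents the models, numerical choices and limitations behind
`microdyn`.  Symbols follow the field's standard notation: `σ` a binary
community state, `h`/`J` maximum-entropy parameters, `E` embedding
dimension, `θ` S-map nonlinearity, `p` forecast horizon in days.

## Synthetic microcosms

The simulator emulates replicated continuous-culture experiments sampled
every 24 h: the daily update is one Euler-Maruyama step (dt = 1 day) of
the generalized Lotka-Volterra system `dNᵢ/dt = Nᵢ (rᵢ + Σⱼ aᵢⱼ Nⱼ)`,
followed by lognormal multiplicative process noise
(`exp(ε·sd − sd²/2)`, mean-preserving) and a batch transfer that multiplies
all abundances by `1 − dilution_fraction` (default 0.2, i.e. 200 of
1000 µL replaced daily).  Abundances below 1e−10 are set to 0: this avoids
denormal drift and creates genuine absences for binarization.  Process
noise is multiplicative because population fluctuations are
scale-proportional and nonnegativity must be preserved.

Three frozen fixtures span the dynamical regimes the analyses target:

- **`stable`** — 5 weakly competing taxa with strong self-limitation; a
  single stochastically perturbed equilibrium.
- **`chaotic4`** — 4 taxa whose per-taxon daily map
  `N → 0.8·N·(1 + r(1 − N))` is conjugate to a logistic map with
  µ = 0.8(1+r) ≈ 3.84 (chaotic band), coupled by weak mixed-sign
  interactions.  Boundedness and a positive largest Lyapunov exponent are
  verified by a two-trajectory divergence test.
- **`bistable`** — a resident 3-taxon guild holds an invading guild
  slightly *above* replacement, so the invader grows slowly from far below
  the sequencing detection limit, flickers into detectability during the
  run-up, and eventually flips the community through a positive feedback
  (the resident is then excluded).  Flip timing varies stochastically
  across replicates (roughly days 45–80 at the default seed).  This design
  was chosen over an externally forced shift because an exogenous pulse
  has no precursor: endogenous, noise-triggered escapes are what give
  early-warning indices something to detect.

Sequencing is multinomial per sample over taxa plus five spike-in
standards at 0.1, 0.05, 0.02, 0.01 and 0.005 nM (20-fold gradient), with
read probabilities proportional to copy concentration.  Default depth is
20,000 reads/sample, a realistic order for multiplexed amplicon runs; the
detection limit this induces (≈ 1 read ↔ ~1e−4 abundance units here) is
what makes low-abundance presence flicker, and it is load-bearing for the
landscape indices.  No sequence-level error, chimeras or PCR-cycle effects
are modeled, so calibration tests quantify only multinomial counting
error — real amplicon data adds taxon-specific amplification bias the
generator does not emulate.

Ising ground truths for recovery experiments are sampled exactly
(enumeration of all 2^S states, S ≤ 20) or by single-site heat-bath Gibbs
sweeps (burn-in 1000 sweeps, thinning 10) above that.

## Calibration and quality control

Per-sample calibration curves regress spike reads on known nM **through
the origin** (zero copies must imply zero expected reads; an intercept
option was considered and rejected because negative intercepts produce
negative concentrations at low reads).  Concentration = reads / slope.
The Pearson correlation of the curve is reported alongside; correlation
of a constant vector is defined as 0 so that broken curves are dropped
rather than propagating NaN.  Samples are removed when r < 0.7 or total
taxon reads < 350 — strict inequalities, so boundary values are kept.
Missing days are filled by linear interpolation between flanking observed
values (single interior gaps therefore get the flanking mean); gaps at
series ends copy the nearest value.  All filled points are flagged.  Taxa
are retained only if present in ≥ 5 samples of at least one replicate.

## Abruptness

Abruptness(t, p) is the Bray-Curtis dissimilarity between the mean
*relative* composition over days [t−4, t] and over [t+p, t+p+4].
Averaging is done on per-day renormalized compositions, making the
statistic invariant to per-sample scale (sequencing depth, total biomass);
the alternative (average raw abundances, then normalize) is exposed via
the underlying helpers but not default.  A value > 0.5 (strict) labels an
abrupt change: more than half the composition turned over.  Windows are
exactly 5 days; a time point with incomplete windows is invalid rather
than computed on a shrunken window.

## Energy landscape analysis

Taxa present in 2–98% of samples (inclusive) enter the binary matrix;
presence means concentration strictly above `presence_threshold`
(default 0 — a zero in calibrated data need not mean true absence, so the
threshold is exposed).  The pairwise maximum-entropy model is fit by the
multiplicative gradient rule with learning rate α = 0.1, iteration cap
50,000 and an additional convergence tolerance of 1e−4 on the largest
absolute log moment ratio.  Model moments are exact enumeration sums
`⟨σᵢ⟩* = Σ_k σᵢ^{(k)} p(σ^{(k)})`.  Empirical moments use the shrinkage
`(count + 0.5)/(n + 1)` so that never-observed co-occurrences do not send
log-ratio updates to −∞.  Exact enumeration caps S at 20 (2^20 ≈ 1e6
states); larger communities must be pre-reduced (e.g. top-prevalence
selection, as the Jacobian module does).

Stable states are strict single-flip minima of `H`; basins follow
steepest descent with ties broken toward the lowest flipped-bit index
(flat regions therefore have no minima and descend deterministically).
The **energy gap** is `H(σ) − H(basin minimum)`.  The **stable-state
entropy** runs `n_walks` (default 1000) random walks: each step proposes
one uniformly random bit flip and accepts with Metropolis probability
`min(1, e^{−ΔH})`; a walk stops at a local minimum or after `max_steps`
(default 100·S; the remainder is mapped by steepest descent).  The
entropy is `−Σ q_m ln q_m` over destination frequencies.  The acceptance
rule and termination protocol are this package's choice (the literature
varies); both are configurable, and all walks are seeded.

For warning-signal use, the landscape for a target replicate is always
fit on the *other* replicates of the same treatment
(leave-one-replicate-out), so the index never sees its own trajectory.

## Empirical dynamic modeling

Abundances are z-scored per (taxon, replicate); constant series are
flagged and excluded from embeddings rather than mapped to NaN.  Delay
vectors `z(t) = (x(t), x(t−1), …, x(t−E+1))`, τ = 1, never span a
replicate boundary, and a target replicate is never part of its own
reference library.  E is selected in 1..20 by minimizing RMSE of
pre-run 1-step forecasts (ties → smallest E); selection at the forecast
horizon instead of p = 1 is available via configuration.

Simplex projection uses the E+1 nearest neighbors with weights
`exp(−dᵢ/d_min)`; when the query coincides with reference points
(d_min = 0) the zero-distance neighbors share uniform weight.  The S-map
solves, per query, the weighted linear system `b = AC` by SVD least
squares with `w(d) = exp(−θ d / d̄)`, `d̄` the mean query-to-library
distance, and an intercept column; θ = 0 reduces exactly to one global
OLS regression (tested to 1e−8).  θ is chosen on the fixed grid
{0, 0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1, 2, 4, 8} by forecast RMSE, ties
toward smaller θ, so a taxon is called "nonlinear" only when local
weighting genuinely improves prediction.

Community-level forecasts de-standardize per-taxon predictions, floor
negatives at zero (the model is unconstrained; the composition is not),
renormalize, and score per-day Bray-Curtis error against the observed
composition.  Forecast R² is the coefficient of determination
`1 − SS_res/SS_tot` (not squared correlation — it penalizes bias);
QC-dropped days never enter any skill statistic.

## Jacobians and stability indices

The CCM screen cross-maps the target taxon's embedding onto each
candidate's values at a small and a large library size; a Theiler
exclusion window (10 days) removes temporally adjacent neighbors so
autocorrelation alone cannot mimic coupling.  Convergence requires
Δρ ≥ 0.1 and ρ_max > 0.2 (configurable).  The Jacobian taxon set defaults
to the top-8 taxa by mean relative abundance intersected with the
CCM-converged set — the selection rule is a package choice, exposed as
configuration.

Row i of `J(t)` holds the S-map coefficients (intercept dropped) of the
regression of `xᵢ(t+1)` on the full current state `x(t)`, locally
weighted around the target state at t, with current/next-day state pairs
of the other replicates as the library.  Local Lyapunov stability is
`max |eig J(t)|` (< 1 converging, > 1 diverging); local structural
stability is `tr J(t)`.  The pipeline default θ for Jacobians is 1.0:
θ = 0 would produce one global, time-constant Jacobian, which defeats a
*local* stability index.  Jacobians are estimated on z-scored abundances;
eigenvalues are only approximately invariant to per-variable rescaling,
a known caveat of this estimator.

## Warning-signal evaluation

Each index at day t joins the realized abruptness(t, p = 7); labels are
abruptness > 0.5.  Per-replicate OLS regressions of abruptness on each
index are corrected by Benjamini-Hochberg FDR across replicates × indices
within a treatment (q < 0.05).  ROC curves sweep the unique scores with
"positive iff score ≥ threshold" — all four indices signal instability
when high — and AUC is the trapezoidal integral, identical to the
normalized Mann-Whitney statistic.  The Youden threshold maximizes
sensitivity + specificity − 1; ties resolve toward the lower (more
sensitive) threshold, and the returned cut is the midpoint between the
optimal score and the next lower distinct score for stability.  Pooled
thresholds concatenate (score, label) pairs across treatments before the
sweep.  ROC analysis refuses single-class inputs, reporting both class
counts.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: fixtures with 4–8
replicates of 40–110 days and 4–6 taxa, maximum-entropy models at S ≤ 8
against exhaustive oracles, 500-step series for Jacobian recovery, and
20,000 exact Ising samples for parameter recovery.  These sizes keep every
oracle exact and every Monte-Carlo bound tight while exercising the same
code paths as full-scale data.  All stochastic operations take explicit
seeds or `numpy.random.Generator` instances; the pipeline derives every
stream from the single config seed and stamps artifacts with the config
hash, so a fixed configuration reproduces byte-identical outputs.

## Known limitations

- Passing tests demonstrate correctness of the machinery on data whose
  generating assumptions (multinomial reads, gLV dynamics, fixed
  landscape) are exactly those of the models; real microbiome data adds
  amplification bias, copy-number variation across taxa, and
  environmental nonstationarity that none of the indices can see.
- Extinction creates forbidden (one-way) transitions that the symmetric
  assembly-graph walk ignores.
- The exact-enumeration core limits the landscape to ≤ 20 taxa; there is
  no mean-field or MCMC fitting fallback for larger communities.
- No surrogate-based significance testing of warning indices, and no
  regularized or multiview S-map variants.
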