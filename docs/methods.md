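# Methods

`statedyn` analyses multi-ROI time series from blocked-stimulation fMRI
experiments by decomposing each run into a small number of latent brain
states, then characterising those states temporally (occupancy, switching),
spatially (activation, functional connectivity) and predictively (decoding
of the stimulation condition). This note records the models, the estimation
choices, the synthetic-data generator that defines the test conditions, and
the known limitations.

## Signal model and normalization

Input runs are `time x ROI` matrices sampled at a fixed repetition time
(default 1 s). For iron-oxide contrast-agent (CBV-weighted) fMRI, raw
signals are converted to percent change from a pre-stimulation baseline,
sign-inverted (a CBV signal decrease indexes an activity increase), and
z-scored per ROI over the run. The baseline window defaults to the final
60 s of the rest prefix — the only window guaranteed to be free of
stimulation effects. Z-scoring is per subject; a cross-subject variant
would couple subjects through a shared scale and is intentionally not the
default.

## The switching-state model

Each subject's run is modelled as a hidden Markov chain `z_t` over at most
`k_max` (default 10) latent states. The observed signal mixes two kinds of
temporal structure: slow dynamics shared by all states (hemodynamic
filtering, within-state fluctuation) and state-specific levels and
covariances. The model separates them explicitly. A diagonal per-channel
autoregressive operator of order `ar_order` (default 2) is estimated once
from the pooled cohort by least squares and used to prewhiten every run:

    e_t = y_t − Σ_l a_l ∘ y_{t−l}

The switching chain is then inferred from the innovations, which are
conditionally Gaussian given the state:

    e_t | z_t = k  ~  N(c_k, Q_k)

Sharing the dynamics across states is an identifiability decision, not a
convenience. Two failure modes bracket it: if every state carries free
unconstrained dynamics, a single near-unit-root state explains any smooth
series and the switching structure collapses (we observed exactly this —
the collapsed solution attains a higher variational bound than the planted
solution from any initialization); if the dynamics are ignored entirely,
consecutive autocorrelated samples masquerade as extra states and the
state count inflates. The shared-operator factorisation sits between the
two: temporal smoothness is explained once, state identity carries the
rest. Setting `ar_order = 0` disables whitening and reduces the model
exactly to a Gaussian-mixture hidden Markov model, which is the regime the
oracle-equivalence tests exercise.

Because the initial pooled autoregressive fit absorbs some sustained
state structure (block-locked level changes inflate apparent persistence),
the operator is re-estimated on state-mean-removed residuals after a first
fit and the model refitted; `ar_refinements` (default 2) controls the
number of passes.

### Variational inference and automatic relevance determination

Inference is conjugate coordinate-ascent variational Bayes: Dirichlet
posteriors on the initial distribution and the transition rows,
Normal–Wishart posteriors on each state's innovation mean and precision,
and exact forward–backward smoothing of the chain under expected
log-parameters (per-step scaling constants retained for the evidence
term). The evidence lower bound is evaluated each iteration and is
non-decreasing up to floating-point error; convergence is declared at a
relative change below `elbo_tolerance` (default 1e-6). Fitting restarts
`n_restarts` times (default 5) from k-means-seeded responsibilities and
keeps the highest-bound solution. Fitting is at the group level on
subject-concatenated data with chain resets at subject boundaries;
per-subject posteriors come from the shared parameter posterior.

The state count is learned by automatic relevance determination: sparse
Dirichlet concentrations (default 1/k_max on the initial distribution and
on every transition row) plus the emission-parameter complexity cost drive
unused states' expected mass toward zero. A state is
*effective* if its expected share of samples exceeds `prune_threshold`
(default 1/(10·k_max)) and it is dominant for at least one sample of at
least one subject. The Wishart prior expects unit-scale precision — a
deliberately conservative choice for innovation-scale data; a prior
rescaled to the innovation variance removes the per-state complexity cost
and demonstrably over-segments.

### Reported state parameters

State summaries on the signal scale are posterior-weighted moments of the
original (unwhitened) series: activation means `μ_k = Σ_t γ_tk y_t / Σ_t
γ_tk`, state covariances as the γ-weighted second moments, per-state lag-1
propagation matrices `A_k` by γ-weighted least squares on within-state
fluctuations, and innovation covariances `Q_k = Σ_k − A_k Σ_k A_kᵀ`.
Weighted data moments rather than filter-mapped innovation parameters are
reported because the whitening filter's DC gain is small (~0.1–0.2), so
inverting it would amplify estimation noise ~5–10×; the weighted moments
are directly comparable with condition-averaged data.

## Derived statistics

- **Occupancy**: fraction of condition samples (ON vs OFF; rest pooled with
  OFF by default, configurable) in which each state is the argmax-posterior
  (dominant) state. Ties break toward the lower state index.
- **Role assignment**: OFF state = group-mean occupancy argmax during OFF;
  ON state = argmax during ON. If one state wins both conditions
  (design-independent regime) the ON role is left unassigned and flagged.
  The Transition role goes to the state most often traversed between the
  OFF and ON states at stimulation boundaries (path dominance).
- **Boundary switching**: within ±10 s (default) of each boundary, one-step
  transitions of the dominant sequence are tallied per direction (each
  transition counted once even when windows overlap); each boundary's
  OFF→ON (or reverse) traversal is classified direct / via-Transition /
  multi-hop, with incomplete traversals counted separately. The estimator
  pools transitions within subject across boundaries.
- **Contrasts**: per-subject state activation and connectivity are
  posterior-weighted (soft) estimates; hard-assignment (dominant-state
  masked) connectivity is computed alongside as a validation, with the
  median per-link absolute difference as the agreement score. Group
  comparisons are paired two-tailed t-tests across subjects
  (Benjamini–Hochberg FDR over ROIs for activation, over all unordered ROI
  pairs for connectivity; connectivity tested on Fisher-z transformed
  correlations, values clipped just inside ±1 before the transform).
  Default significance levels: 0.05 for occupancy comparisons, 0.01 for
  activation/connectivity contrasts.
- **Decoding**: a linear SVM (C = 1, class weights balanced) on
  per-timepoint state-posterior vectors, leave-one-subject-out (timepoint
  folds would leak autocorrelation), scored by balanced accuracy because
  ON samples are a minority of the blocked design while the chance level
  of interest is 50%. Block-level majority-vote accuracy is reported
  alongside. Significance: permutation of block-level condition labels
  within subject (preserving block structure and the block-label counts),
  full re-run of the cross-validation per permutation, `p = (1 + #{null ≥
  observed}) / (1 + n_permutations)`; an exhaustive mode enumerates all
  distinct within-subject assignments for small designs.

## The synthetic cohort generator

The generator defines the conditions under which the pipeline is tested:
a 1160 s run at 1 s repetition time (360 s rest, then 8 epochs of 20 s ON
/ 80 s OFF), 9 ROIs (anterior insula, prelimbic, cingulate, six
retrosplenial subdivisions ordered anterior→posterior), 9 experimental and
7 control subjects.

Experimental subjects express an OFF state through no-stimulation periods,
a short-lived Transition state after every boundary (both directions), and
an ON state for the remainder of each ON block. The ON state elevates AI
and PrL, suppresses anterior-to-mid RSC, decouples AI from anterior RSC
and strengthens PrL–Cg coupling; the Transition state strongly suppresses
anterior-mid RSC, activates posterior RSC and strengthens AI–mid-RSC
coupling. Signs and orderings of these effects are fixed; magnitudes are
free parameters of the generator. Controls express the baseline state plus
two generic nuisance states with slow design-independent Markov switching
biased toward baseline (three states, matching what unstimulated animals
typically resolve to).

Within a state run the signal fluctuates around the state mean as a
stationary AR(1) (coefficient 0.6, 0.4 for the Transition state) with the
state's covariance. The within-state covariance scale is 0.2 z-units², so
state contrasts (means up to ~0.8 z-units) clearly dominate within-state
noise — mirroring the near-saturated state posterior time courses that
blocked optogenetic stimulation elicits; a substantially noisier setting
would make the planted states close to undetectable at a 1 s repetition
time and would emulate no regime in which this analysis is used. White
observation noise (0.1 z-units) is added, the state sequence is shifted by
the 2 s hemodynamic lag (the stored ground truth is the shifted sequence
actually expressed in the signal), the series is smoothed with a 2 s FWHM
temporal Gaussian, and finally z-scored per ROI. The per-ROI normalization
offset and scale are stored with the ground truth so planted parameters
can be expressed in the z-units the model sees.

Transition dwells are jittered with a geometric tail truncated below at 3
samples (mean = `transition_dwell`, default 5 s). The truncation keeps the
jitter small relative to the mean and ensures a planted dwell outlives the
smoothing kernel: with an untruncated geometric, ~40% of dwells last ≤2
samples and are erased by the 2 s smoothing, which caps even an oracle
decoder (true parameters given) at a mean adjusted Rand index of ~0.91.

Hemodynamic realism is deliberately a lag plus Gaussian smoothing rather
than a full hemodynamic response model: the analysis operates at state
timescales of tens of seconds, and this choice keeps every planted
quantity analytically checkable.

What passing tests on this generator do *not* show: robustness to
physiological noise structure (cardiac/respiratory), motion artifacts,
vascular heterogeneity across ROIs, inter-subject variability in effect
topography, or deviations from Gaussian innovation statistics in real CBV
data.

## Numerical choices and degenerate inputs

- Forward–backward runs in scaled linear space with per-step normalization;
  posterior rows and pairwise slabs are normalized to 1 within 1e-10.
- Singular precision updates are ridge-regularized (relative ridge 1e-6)
  and logged; correlations of ±1 are clipped before the Fisher transform.
- Dominant-state ties break toward the lower state index and are logged.
- Constant channels, zero baselines, ragged tables, duplicated ROI labels,
  mismatched lengths, subjects missing a condition class, and all-constant
  decoder features are rejected with messages naming the offender.
- All randomness flows from explicit seeds; per-subject and per-stage seeds
  derive deterministically from one master seed, so a pipeline
  configuration reproduces byte-identical reports.

## Problem sizes used by the test and acceptance suites

Full-scale checks (state recovery, roles, switching paths, contrasts,
decoding) run on the default cohort above. Calibration suites use reduced
conditions chosen so their statistical targets remain meaningful: the
chance-level decoding suite uses 20 design-independent cohorts of 4
subjects, 5 ROIs and 300-sample runs (separable state specs driven by
design-independent switching); type-I-error calibration uses 200 cohorts
of 6 subjects with identical state specifications and ground-truth state
weights; permutation-calibration uses 100 cohorts with 39 within-subject
block permutations each. Fewer ROIs in reduced suites keep the per-state
parameter cost commensurate with the shorter runs.

## Known limitations

- With ~7% of samples in a short-lived Transition state, the variational
  bound's preference between "three states" and "Transition absorbed into
  ON" is decided by a margin of order 10 nats out of tens of thousands;
  on some cohort realizations the absorbed solution wins and the effective
  state count reads 2. The boundary-path and role analyses still identify
  a Transition state in those fits, but its parameter estimates are then
  contaminated.
- The adjusted Rand index between recovered and planted sequences is
  bounded near ~0.91 by the study conditions themselves (2 s smoothing,
  2 s lag, 1 s sampling): even decoding with the true parameters cannot
  place state boundaries more precisely than the smoothing kernel allows.
- The shared-dynamics factorisation assumes all states ride on similar
  temporal smoothness; strongly state-dependent hemodynamics would violate
  it.
- Group-level fitting assumes states are spatially homogeneous across
  subjects up to the per-subject z-scoring.
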