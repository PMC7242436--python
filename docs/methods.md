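# Methods

## Model

Discrete EHR observations for D patients over T data types, plus L lab
tests with V_l result states each.  Global parameters per topic
k ∈ 1..K: feature distributions φ_k^(t) ~ Dir(β_t) per type, result
distributions η_lk ~ Dir(ζ_l) and observation probabilities
ψ_lk ~ Beta(a_l, b_l) per lab.  Per patient: θ_j ~ Dir(α); tokens
z_ij ~ Mul(θ_j), x_ij ~ Mul(φ_z^(t)); labs h_lj ~ Mul(θ_j),
r_lj ~ Bernoulli(ψ_{l,h}), and y_lj ~ Mul(η_{l,h}) recorded only when
r_lj = 1.

The key assumption is conditional independence of *whether* a lab is
taken and *what* it shows, given the latent topic.  Missingness is
therefore non-random (it depends on the latent disease state) but
ignorable once the topic is known; an unmeasured lab is itself evidence
about h through 1 − ψ.  Every (lab, patient) pair has exactly one
indicator r ∈ {0, 1}; observed pairs may carry frequencies over several
result states (repeated measurements within an admission), which enter
the likelihood as count weights on a shared per-pair topic variable.

## Collapsed variational inference

θ, φ, η, ψ are conjugate and integrated out.  The collapsed joint is a
product of Dirichlet-multinomial and Beta-Bernoulli Gamma-function
ratios over the sufficient statistics

- n_jk (token mass of patient j on topic k), n_wk^(t) (feature mass),
- m_jk (lab mass of patient j), m_lkv (lab-state mass),
- p_lk (observed exposure), q_lk (unobserved exposure).

Inference maintains a categorical q(z), q(h) per record — γ per distinct
(patient, type, feature) record weighted by its count (identical tokens
receive identical updates, so storage is per distinct record), λ per
observed lab record, and π jointly over (topic, state) per unobserved
pair — plus expectations of the statistics above.  The zero-order
(CVB0) update for a record is a product of ratios of smoothed expected
counts with the record's own current contribution removed:

    γ'_k ∝ (α_k + ñ_jk^− + m̃_jk) (β_tw + ñ_wk^−) / (Σ_w β + ñ_·k^−)

and analogously for λ (with the η ratio and the observed Beta odds
(a + p̃^−) / (a + p̃^− + b + q̃)) and for π (with the unobserved odds
(b + q̃^−) / (a + p̃ + b + q̃^−), normalized jointly over topic and
state).  Exclusions: a token record excludes its own count-weighted γ
from both the patient-local and global token statistics; a lab record
excludes its lab's entire per-patient mass from m̃_jk and p̃/q̃ (one
h per pair) but only its own (l, j, v) contribution from m̃_lkv.

Bookkeeping: updates are sequential (Gauss-Seidel) — subtract own
contribution, update, write back — with exclusions clipped at zero
against floating-point drift, and a full from-scratch recomputation of
all statistics once per sweep cancels accumulated error.  Sweep order is
deterministic: patients in index order; within a patient, token records
(type, then feature), observed lab records grouped by lab, then
unobserved labs.  Products are evaluated in linear space with per-record
renormalization (the factors are ratios of smoothed counts, bounded away
from under/overflow at these scales); only likelihood evaluation uses
log space.  The sweep is a single compiled (numba) kernel; a scalar-loop
reference implementation of every update and statistic lives in
`mixehr.oracles` and the test suite verifies agreement to 1e-10.

Posterior-mean estimates: θ̂_jk ∝ α_k + ñ_jk + m̃_jk (the collapsed
likelihood pools token and lab assignments in one Dirichlet posterior;
`include_lab_mass=False` drops the lab term), φ̂, η̂, ψ̂ are the
corresponding smoothed ratios.

## Empirical-Bayes hyperparameters

Each Dirichlet concentration follows the Minka digamma fixed point with
Gamma(shape, rate) prior terms, e.g. for β_wt with counts n_wk over K
groups:

    β* = (shape − 1 + β [Σ_k Ψ(β + n_wk) − K Ψ(β)])
         / (rate + Σ_k Ψ(Σ_w β + n_·k) − K Ψ(Σ_w β))

whose fixed point is a stationary point of the collapsed log-likelihood
plus log prior (verified against per-coordinate 1-D search).  At zero
counts the digamma terms cancel *exactly* and the update returns
(shape − 1)/rate.  The Beta shapes a_l, b_l use the paired analogue with
(p, q) masses.  Updates run every 5 sweeps after a 10-sweep burn-in
(configurable) and are floored at 1e-6.  Default priors are weakly
informative Gamma(1, 1).

## Training loop and stopping

EM alternates a full E-sweep, a statistics refresh, and (periodically)
the hyperparameter fixed points.  The monitored quantity is the
predictive log-likelihood of the training data under current estimates.
Stopping: relative change < 1e-4, but never before `min_sweeps` = 10
sweeps and always within `max_sweeps` = 500.  The minimum matters: on a
monitored value of magnitude ~1e4–1e5 a relative tolerance of 1e-4 can
be met after two sweeps while the optimizer is still climbing steeply;
without the guard, small cross-validation trainings silently underfit.
CVB0 is not provably monotone; the tests assert finiteness everywhere
and start-to-end improvement, not per-sweep monotonicity.

## Stochastic inference (SCVB0)

Global statistics are interpolated with scaled minibatch estimates:

    ñ ← (1 − ρ) ñ + ρ (D/D') Σ_batch c γ,   m̃ analogously,

with the Beta masses p̃, q̃ interpolated at the same rate (leaving them
stale while m̃ moves would distort the observed/unobserved odds).  The
D/D' scaling is applied inside the minibatch estimate so the
interpolation mixes same-scale quantities; an unscaled mode exists
behind a flag.  ρ is fixed (default 0.5) or Robbins-Monro
ρ_s = (s + τ)^(−κ).

Per-patient assignments are never materialized outside the current
batch.  Each batch patient gets fresh perturbed-uniform assignments,
refined by a few local sweeps of the *same* compiled kernel against a
working copy of the global statistics; the subtraction of the record's
own current contribution from the interpolated globals (clipped at zero)
is an approximation — per-record contributions are not identifiable
inside an interpolated statistic — and is exact in the full-batch case.
With D' = D and ρ = 1 one stochastic step therefore reproduces a batch
sweep's refreshed statistics to machine precision, which the tests
assert.  After training, every patient's θ̂ is obtained by fold-in
against the final globals.  The likelihood trace monitors a fixed seeded
subset of patients under a 50/50 feature split.

## Prediction and imputation

*Fold-in*: patient-local CVB0 updates against frozen φ̂, η̂, ψ̂ (the
ratios of smoothed global counts reduce exactly to these), 10 sweeps.
By default only observed tokens and lab records enter, so an empty
record returns the prior mean α/Σα.  `include_missing_labs=True`
additionally treats absent labs as genuinely not taken (r = 0 evidence
through 1 − ψ̂); this is the mode under which folding in a training
patient reproduces their training θ̂ (to < 0.02 total variation at
D = 100; at fixture scale, D = 6, the patient's own share of the global
counts inside φ̂ biases any fold-in and only ~0.08 is attainable).  The
default stays observed-only because a *new* patient's absent labs may
simply be unlinked records, and because imputation masks a lab that was
in fact measured — treating it as r = 0 would inject false evidence.

*Held-out predictive likelihood* of a record half: token term
Σ c log Σ_k θ̂ φ̂; observed-lab term Σ y log Σ_k θ̂ ψ̂ η̂ — the
probability the generative process assigns to an observed result.  An
alternative mode replaces the product ψ̂ η̂ by the sum ψ̂ + η̂
(`lab_term="sum"`); the product is the default as the generatively
coherent form.  Cross-validation over a K grid: seeded patient folds;
each held-out patient's features split 50/50 stratified per data type
(labs split at the lab level so a pair's states stay together), mixture
inferred from one half, the other half scored.

*kNN*: Euclidean distance between mixtures, ties broken by ascending
patient index.  Code prediction: mean binarized presence among k = 100
neighbours, classification threshold 1/k.  Presence is binarized
because prediction is evaluated as classification.  Lab imputation:
fold in without the target lab, take the k = 25 nearest training
patients having that lab observed, and average their *normalized*
result-state frequencies (normalization prevents heavy-utilization
neighbours from dominating the average).

*Topic-embedding analysis*: a code's embedding is its row of φ̂ (raw,
not renormalized over topics; a flag renormalizes).  Pairwise Pearson
correlations over the K topic dimensions; significance by shuffling the
target code's K entries (n_perm permutations, per-code null, add-one
p-value so p_min = 1/(1 + n_perm), two-sided on |r| by default).  With
per-code nulls, p is not guaranteed monotone in |r| across codes whose
comparison vectors differ; it is monotone within any shared null.

## Synthetic data: what it does and does not emulate

The generator samples exactly the generative process above, so it
reproduces the *structural* features of EHR data the model addresses:
multiple typed vocabularies, sparse long-format counts, per-lab state
frequencies, and topic-dependent missingness.  It does not emulate
longitudinal visit structure, code ontologies, note tokenization
artifacts, or model misspecification (real notes are not multinomial
draws).  Passing recovery tests therefore demonstrates correctness of
the inference under the model's own assumptions — not robustness to
their violation.  One observed lab draws a single result by default;
`result_draws=λ` switches to 1 + Poisson(λ) repeated measurements.

## Study designs used by tests and `scripts/acceptance.py`

All sizes were chosen as the smallest instances at which the measured
quantities are stable across seeds; each benchmark runs in seconds on
one CPU.

- **Recovery** — D=500, K=3, two types W=(60, 40), 40 tokens/patient
  each, L=10 binary labs; α=0.5, β=0.1 (sparse, well-separated topic
  profiles), ζ=0.5, a=b=1.  Measured: best-permutation mean cosine of
  φ̂ columns vs truth (matched by linear assignment on the per-type
  mean cosine matrix) and mean |ψ̂ − ψ|.
- **Model selection** — D=240, K_true=3, W=(40, 30), 30 tokens/type,
  L=4; grid {1, 3, 8}, 2 folds.
- **Imputation** — D=1000 (800 train / 200 test), K=3, L=12 binary
  labs, α=0.2, ζ=0.15, 40 tokens/type.  The sharp η and concentrated θ
  realize the premise of the study — lab behaviour that actually
  depends on the latent topic.  With diffuse η a substantial fraction
  of labs end up favouring the same state under every topic, and no
  method can beat the marginal majority for them; the design exists to
  measure the imputation machinery, not that degeneracy.  Measured:
  argmax-state accuracy of 25-NN imputation vs the patient's own masked
  record, against the global majority state per lab.
- **Code prediction** — D=1000 (800/200), K=3, α=0.3; the 10 most
  prevalent type-0 codes with training prevalence in [5%, 50%]; each
  masked per test patient, scored by 100-NN presence; median per-code
  AUROC.
- **Calibration** — 150 independent uniform-random embeddings, K=10,
  n_perm=999; KS distance of the 149 p-values from uniform (the 95%
  critical value at n=149 is ≈0.11).

## Numerical choices and degenerate inputs

1-based indices exist only in files; everything in memory is 0-based.
K=1 degenerates to closed forms (all assignments 1.0; φ̂ is the
Dirichlet-smoothed empirical distribution, exactly).  Patients with no
observations are valid (θ̂ is the prior mean).  Corpora with L=0 or
empty test corpora are valid (lab statistics empty; predictive
likelihood 0).  Zero predictive probability returns −inf with a
diagnostic naming the record.  Tie-breaks (kNN, argmax states) resolve
to the lowest index.  Model JSON round-trips floats exactly.

## Limitations

Batch memory is O(distinct records × K); the stochastic path exists for
corpora where that fails.  The permutation test treats topic dimensions
as exchangeable under the null, which ignores their compositional
coupling.  Hyperparameter updates share one Gamma prior per family, not
per coordinate.  No modelling of admission sequences or time.
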