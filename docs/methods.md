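# Methods

## Problem setting

`crossrbm` addresses cross-subject neural decoding: a linear classifier
(decoder) is trained on one subject's neural feature vectors, but the trials
to be decoded come from a *different* subject whose feature space has its own
geometry. Applied directly, the source decoder performs near chance, because
class-conditional clusters occupy essentially arbitrary regions of each
subject's feature space even when every subject is individually highly
separable. The package learns a joint generative model of all subjects'
features and uses conditional sampling in that model to *transfer* a target
subject's trial into the source subject's space before decoding.

The motivating data are spike-resolved EMG recordings of the complete flight
motor program of hawk moths: 10 muscles (left/right DLM, DVM, 3AX, BA, SA),
trials segmented at wing strokes of 50–70 ms, six visual-stimulus classes
(pitch/roll/yaw, two directions each), roughly 2,500 trials per animal across
nine animals. The package never requires that archive: its synthetic-data
module generates data with the same statistical structure, and all tests run
on it.

## Model

The joint density of the concatenated visible vector
x = (x_1, …, x_M) ∈ R^D (one block per subject, D = Σ_m D_m) and binary
hidden units h ∈ {0,1}^H is a Gauss–Bernoulli restricted Boltzmann machine:

    p(x, h; θ) ∝ exp(−E(x, h; θ)),
    E(x, h; θ) = ½ (x−c)ᵀ Λ (x−c) − hᵀ W Λ x − bᵀ h,

with θ = {W ∈ R^{H×D}, b ∈ R^H, c ∈ R^D, Λ = diag(λ), λ > 0}. The visible
precision λ is learnable; freezing it at 1 recovers the common unit-variance
variant (exposed as the `freeze_lambda` training flag rather than a separate
model class). The conditionals factorize:

    p(h | x) = Bernoulli(σ(WΛx + b)),      p(x | h) = N(Wᵀh + c, Λ⁻¹),

and marginalizing h analytically gives the free energy

    F(x) = ½ (x−c)ᵀ Λ (x−c) − Σ_j softplus((WΛx + b)_j),

so p(x) ∝ exp(−F(x)). The sigmoid/softplus argument is WΛx + b everywhere —
in the conditionals, the free energy, the score, and every gradient.

## Training

Two estimators share one minibatch/optimizer loop (`training.train`):

**Score matching (FD).** Minimizing the Fisher divergence between model and
data reduces to minimizing the empirical mean of the Hyvärinen score
s_F(x) = ½‖∇_x log p‖² + Δ_x log p, which for this model is closed-form:

    s_F(x) = ½ ‖Λ(Wᵀσ + c − x)‖² + tr(−Λ + ΛWᵀ diag(σ′) W Λ),
    σ = σ(WΛx + b).

Neither the objective nor its parameter gradients involve the partition
function or any sampling; a unit test asserts by instrumentation that FD
training never touches the Gibbs sampler. The parameter gradients were
derived by differentiating this expression block by block; the binding
correctness contract is agreement with central finite differences of the
scalar objective, which the test suite enforces to 1e−4 relative on every
block.

**Contrastive divergence (CD-k).** The log-likelihood gradient is
∇_θ F(x) − E_p[∇_θ F(x)]; the intractable model expectation is estimated at
chain states obtained by k Gibbs sweeps (h then x) started from the
minibatch, k = 1 by default. ∇_θ F is closed-form. Because CD's true
objective is implicit, the loss trace logs a 1-sweep reconstruction MSE and
the data/model free-energy gap for monitoring only; neither is optimized.

Shared loop choices:

* **Optimizer** Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8), learning rate 0.005,
  minibatch 150, 350 epochs by default — the protocol's published settings.
  A fixed epoch budget is used instead of a stopping rule.
* **Positivity of λ** is preserved by letting the optimizer act on log λ
  (gradients mapped by the chain rule), clipped to [1e−6, 1e6].
* **Initialization** (the estimators are silent on it): W ~ N(0, 0.01²),
  b = 0, c = training-data mean, λ = 1/training-data variance clipped to
  [1e−3, 1e3] — the Gaussian part starts at its moment-matched optimum.
* **Minibatches** are drawn without replacement and reshuffled each epoch
  from the run seed; a trailing partial batch is dropped.
* Numerically stable sigmoid/softplus (`scipy.special.expit`,
  `np.logaddexp`) keep free energies finite at noise-initialized states;
  a non-finite objective aborts with a diagnostic rather than training on.

## Cross-subject mapping

Training rows pair trials across subjects *within* stimulus class: for each
class, every subject contributes trials drawn without replacement until its
pool is exhausted (then with replacement) up to the largest per-subject class
count. Pairing is drawn once per train/test split, not per epoch. One RBM
trained on the full roster serves every target/source partition without
retraining.

At test time (`cross_subject_map`), the visible vector is initialized with
the target subject's features in the target slices and standard-normal noise
elsewhere, then k ≥ 1 Gibbs sweeps are run. Defaults and variants:

* **k = 1** by default; with one sweep the hidden code is read from the
  initialized vector and the source slices are generated once.
* **clamp = "clamped"** re-imposes the target features after every visible
  update. This is the exact Gibbs sampler for p(x_S | x_T) and coincides
  with the unclamped (full-resample) chain at k = 1 — asserted bitwise in
  tests. The unclamped chain is also provided; for large k it forgets x_T,
  which is why clamped is the default for k > 1.
* **mode = "mean_readout"** replaces the final visible draw by the
  conditional mean Wᵀh + c on the source slices (the maximizing readout of
  the conditional Gaussian), reducing decoder-input variance; `"sampled"`
  keeps the draw.

Subjects that are neither target nor source are not marginalized over; the
roster is assumed to be exactly the union of the two roles (slices outside
the target set are initialized with noise and resampled).

## Feature extraction

Each muscle's spike train is smoothed with a Gaussian kernel,
x(t) = Σ_n exp(−(t − t_n)²/(2σ²)), on the grid t = 0, 1/fs, …,
(round(τ·fs)−1)/fs, with wing-stroke cut-off τ = 60 ms, bandwidth
σ = 2.5 ms, and spikes at t_n > τ discarded (t_n = τ kept). The sampling
frequency is not part of the published protocol; the default fs = 1 kHz
resolves the 2.5-ms bandwidth comfortably and gives 60 samples per muscle,
raw dimension 600. Missing muscles are zero-filled; the 10 traces are
concatenated in fixed roster order; per-subject PCA (fit on the training
split only) retains P = 10 modes, with component signs fixed so the
largest-magnitude loading is positive. Features are then z-scored per
dimension with training-split statistics before RBM training (a conditioning
choice, recorded in config and toggleable; the decoder trains in the same
space, so no inverse transform is needed). Whether the published pipeline
z-scored is unstated.

## Evaluation harness

Scenario I: one source, all other subjects are targets mapped into its
space. Scenario II: one target, mapped jointly into all other subjects'
spaces and decoded by each subject's own decoder. Benchmarks per pair:
subject-specific (upper bound), no-transfer (lower bound, ≈ 1/6 for six
balanced classes), RBM-FD, RBM-CD, and a plug-in hook for external
alignment methods (e.g. hierarchical Wasserstein alignment) exposing
`fit(source_X, source_y, target_X)` / `transform`; none is bundled.

At evaluation time each test trial is mapped on its own: the trial's
subject is the sole target, every other subject plays the source role
(their slices start as noise), and the slice of the subject whose decoder
is being scored is read out. This keeps the roster equal to the union of
the two roles — no trial-level correspondence across test subjects is
assumed, since none exists.

Each repeat re-splits every subject ω/(1−ω) (ω = 0.5), stratified by class
to prevent class dropout at small per-class counts, re-fits z-scoring,
decoders, and the RBMs, and records micro-averaged 0/1 accuracy (classes are
balanced). Default 100 repeats with per-repeat seeds derived from a master
seed via `SeedSequence`; summaries report the mean and 2.5/97.5 percentile
interval. The decoder is LDA (shared within-class covariance); a singular
pooled covariance falls back to a logged ridge shrinkage.

## Synthetic data

`gen_features` draws K = 6 shared latent class means as vertices of a
regular simplex with unit circumradius scaled by `class_separation`
(default 4.0 = 8 × the default noise SD 0.5, i.e. strongly separable
within subject), applies a subject-specific map — random rotation
(default), affine (rotation·scale + shift), or affine followed by tanh on a
random half of the dimensions — and adds isotropic Gaussian noise. Random
orthogonal mixing makes the expected no-transfer accuracy chance while
leaving within-subject geometry intact; the tanh warp provides the
non-linear stress case where linear alignment should underperform.

`gen_spikes` emulates the raw recordings' shape: per (class, muscle)
template spike phases placed in class-specific slots (slot assignment
permuted per muscle so the 10-muscle pattern separates classes by several
kernel bandwidths), per-trial phase jitter (SD 1 ms), spike drop/add at 5%,
a per-subject phase offset per muscle (SD 1.5 ms), wing-stroke lengths
uniform on 50–70 ms, and missing muscles masked at probability 0.1 capped
at two per subject.

What the generator does *not* emulate: spike-count/rate codes, temporal
correlations across muscles beyond the shared template, non-stationarity
across a session, and any torque/kinematic output. Passing tests therefore
demonstrate that the machinery is correct under the model's own assumptions
(shared class structure, subject-specific geometry), not that the method
succeeds on any particular real recording.

## Problem sizes used in the checks

The automated checks run the full protocol at reduced size, a deliberate
package choice so the whole suite runs on a laptop: the chance-floor
computation uses 9 subjects × 100 trials/class with 20 repeats of the
50/50 split; the transfer-lift check uses 4 subjects × 60 trials/class,
FD training for 150 epochs, 20 repeats. The 9-subject, 100-repeat,
350-epoch protocol is available unchanged through `EvalConfig` /
`crossrbm evaluate`.

## Known limitations

* Exact oracles (partition function, visible-marginal mixture) enumerate
  the hidden layer and are restricted to H ≤ 12; they exist for testing,
  the method itself never needs the partition function.
* Score matching is insensitive to the relative weights of well-separated
  modes; with very large class separation the learned mixture weights may
  be off even when the class means (which drive the mapping) are captured.
* CD-k is a biased estimator of the likelihood gradient for finite k; no
  persistent-chain or tempering variants are provided.
* The evaluation harness assumes every subject observes every class
  (within-class pairing fails loudly otherwise).
* HiWA and other alignment baselines are integration points, not
  implementations.
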