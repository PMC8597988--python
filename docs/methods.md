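# Methods

## The problem

phenolink quantifies a linkage privacy risk: given a gallery of genomic
records and a collection of face images, how reliably can an attacker match
each image to its genome using only externally visible traits — sex, hair
color, skin color and eye color — and how effectively can small image
perturbations break that match? The package implements the attack, its
evaluation, the defense, and the attacker's counter-move (adversarial
training), all on fully synthetic cohorts whose generating laws are known
exactly.

## Matching model

For image *i* and genome *j* the matching score is a naive-Bayes
log-likelihood over the four phenotypes

    p_ij = Σ_p log P(z_{i,p} | y_j),

where *z_{i,p}* is the classifier's most likely variant of trait *p* on
image *i*, and the genotype-conditional variant probability factorizes over
the trait's relevant SNPs,

    P(v | y) = Π_{s ∈ snps(p)} P(v | genotype of y at s).

Each per-SNP conditional is an empirical table estimated from a fitting
cohort by counting, with additive (Laplace) smoothing α (default 1, so
unseen cells never produce log 0). Genotypes never observed during fitting
are served the uniform distribution; SNPs missing from a genome contribute
a neutral factor (a uniform factor is available via `missing_policy`). The
per-genome product is *not* renormalized across variants — scores use raw
products, with a floor of 1e-12 applied only at log time. Natural
logarithms throughout; the base is immaterial to rankings.

Risk is reported two ways:

* **top-k success vs population size** — for each probe image, a gallery of
  *s* genomes containing the true one plus *s* − 1 uniform draws; success if
  the true genome's score is among the *k* largest (ties broken by gallery
  order; an expected-value tie mode exists). Baselines: random matching
  (*k*/*s*, analytic) and the true-phenotype upper bound (scoring with
  ground-truth variants in place of predictions). Galleries are resampled
  independently per population size.
* **ROC/AUC** — every image-genome pair becomes a binary match/non-match
  decision, thresholded either on the rank *k* (swept 0..N) or on a score
  cutoff τ (swept over all distinct scores); AUC by the trapezoidal rule
  over pooled pairs (per-image macro-averaging behind a flag).

## Synthetic cohorts

The curated image-genome pairs behind this line of work are not publicly
releasable, so the package generates its own cohorts:

* **Genotypes**: biallelic SNPs under Hardy-Weinberg equilibrium;
  alt-allele frequencies cycle through 0.4/0.5/0.6 so all three genotype
  classes are well populated. Default panel: 2 SNPs for sex, 3 for hair,
  3 for skin, 4 for eye (synthetic rsIDs; a real panel is passed via the
  schema's `snp_map`).
* **Phenotypes**: sampled from per-SNP conditional tables combined by the
  same product rule the scorer assumes (then renormalized). All SNPs of a
  trait act along one axis, the way pigmentation variants act additively
  along a light/dark continuum: reference homozygotes favor the first
  domain variant and alternate homozygotes the last with penetrance
  0.70-0.85 (strong, IrisPlex-class effects), heterozygotes lean 0.55-0.6
  toward the middle variant. A deliberately misspecified "vote" mode (one
  random relevant SNP decides) exists for robustness experiments.
  Because several SNPs are combined by a renormalized product, the
  conditional a single SNP *implies* about the data differs from its raw
  generating row; `implied_variant_tables` computes the exact implied
  marginals by enumerating genotype combinations with HWE weights, and
  these are the convergence target for fitted tables (for a 1-SNP panel
  the two coincide).
* **Images** (32×32×3): phenotypes are encoded as *small* color offsets
  (±0.05 around mid-gray) over fixed regions — hair band on top, skin
  midfield, two eye patches, a brightness cue for sex at the bottom — plus
  seeded Gaussian pixel noise (default sd 0.1), clipped to [0,1]. The weak
  per-pixel signal is deliberate: real photographs carry faint per-pixel
  trait evidence spread over many pixels, and that is exactly the regime in
  which imperceptible ℓ∞ perturbations can flip predictions. Saturated
  color patches would make any near-max-margin classifier provably immune
  to ε ≤ 0.05 noise and the whole defense question moot. A rule-based
  decoder (nearest prototype color per region) recovers phenotypes exactly
  at zero noise and serves as the rendering oracle.
* **Direct prediction noise**: `simulate_noisy_predictions` bypasses images
  entirely — argmax equals the truth with probability 1 − confusion (default
  0.1), else a uniform wrong variant; distributions place 0.8 on the argmax.
  This is the fast path for matching experiments.
* **Genotype assignment** for image-only records: *ideal* (the
  phenotype-matching pool genome maximizing Π_p P(v_p|y); deterministic
  tie-break by id) and *realistic* (uniform seeded draw among
  phenotype-matching genomes).

What passing tests on these cohorts do **not** show: performance on real
photographs (pose, lighting, occlusion, dyed hair, contact lenses), real
linkage disequilibrium between panel SNPs, population structure, or the
behavior of large pretrained face models. The synthetic results validate
the machinery and reproduce the phenomena's direction and shape, not
real-world magnitudes.

## Reference classifiers

One small network per trait: flattened pixels (centered at mid-gray so tanh
units stay in their linear range), one hidden tanh layer of 64 units, a
softmax head. The head initializes to zero, so an untrained ensemble
outputs exactly uniform distributions; hidden weights are seeded random.
Training is Adam on cross-entropy (default 30 epochs, learning rate 0.01,
batch 32, optional class weighting), deterministic given the seed.
Backpropagation and input-pixel gradients are hand-derived and verified
against central finite differences in the test suite.

The hidden layer is not a convenience: a *linear* softmax model on these
images trains to near its maximal margins, and an ℓ∞ attack can flip it
only when ε exceeds roughly half the mean per-pixel class difference — the
imperceptible-noise regime would not exist, and adversarial training would
have nothing to improve. A finitely trained nonlinear network sits well
inside the data's margins, like the large face models it stands in for.
Under the defaults, sex/hair/skin reach ~1.0 held-out accuracy and eye
lands around 0.7 — eye color is the hard trait here as it is in practice. Any model exposing softmax outputs and input gradients can be
plugged in through the same two-method surface.

## Privacy defense

The defended objective couples classifier outputs with the conditional
probabilities of the image's *true* genome:

    min_{‖δ‖∞ ≤ ε}  Σ_p Σ_v log g_p(v, x + δ) · log P(v | y).

Both log factors are nonpositive, so every term is nonnegative and the
minimum redistributes prediction mass toward variants the genome makes
unlikely; on a simplex the optimum places g ∝ −log P. The printed
double-log form is the default; the expected-log-likelihood variant
Σ_v g_p(v, x+δ)·log P(v|y) — which drives all mass to the single least
likely variant — is available via `objective_form="expected"`. Neither is
silently preferred: the double-log form is implemented literally and the
loop oracle in the tests pins its value and sign behavior.

Optimization is projected gradient descent with adaptive first/second-moment
(Adam-style) step scaling: default 100 steps of size ε/10, starting from
δ = 0 (random starts available). After every step the pixels are clipped to
[0,1] first and the noise to [−ε, ε] last — that ordering makes
max|δ| ≤ ε hold bit-exactly despite float rounding. The best iterate by
objective is returned, so the final objective never exceeds the initial
one. The classifier probability inside log g is floored at 1e-20 in the
value only; gradients use the exact softmax Jacobian. A single-phenotype
baseline (standard PGD misclassification attack on one trait's classifier,
cross-entropy against the clean argmax) is provided for comparison; the
matching-tailored objective lowers the true-pair score at least as much at
equal budget.

## Adversarial training

The attacker's counter-move: five passes over the paired training data
(train fraction 0.6, mirroring a 77/49-style split), each pass regenerating
perturbations against the *current* ensemble from random starting points,
then taking one training epoch. Perturbed images are trained alongside
their clean copies (mix_ratio 1.0; pure replacement is available but at
this data scale it degrades the model through drift rather than genuine
robustness cost). The perturbation objective defaults to the matching-score
defense (genome-aware); summed per-classifier cross-entropy is the
alternative. Evaluation defends held-out test images at a grid of budgets
(including 0 = clean input) against the model under evaluation and reports
top-k matching success; train/test overlap is rejected.

For the robustness/accuracy comparison to be attributable to adversarial
noise, two controls are needed and both are built into the experiment
orchestrator and the test suite: the base ensemble's training set already
contains the clean copies of the adversarial-training images (otherwise
the robust model receives extra in-distribution data the baseline never
saw), and the comparison "clean" model receives the same number of extra
training passes on clean inputs — obtained by running the adversarial
trainer at budget 0, where perturbations degenerate to the identity. Under
these controls, the adversarially trained model retains measurably more
matching success under attack at its training budget; its clean-input cost
at small budgets is within seed noise at this scale (see limitations).

## Numerical and design choices

* Probability floors: 1e-12 on conditionals at log time; 1e-20 inside
  log g. Stored tables are never floored.
* Tie-breaks: genome list order (deterministic) in top-k; first variant in
  domain order for classifier argmax.
* Seed fan-out: one master seed expands into named substreams
  (`SeedSequence([master, crc32(name)])`), so adding a pipeline stage never
  perturbs earlier stages' randomness; every derived seed stays below 2^31.
* Genotypes are canonicalized to sorted allele order ("GA" ≡ "AG"); inputs
  must already be on a consistent strand. Missing calls are explicit
  (`--`), never dropped.
* Degenerate inputs: empty cohorts, misaligned ids, single-class training
  labels, k outside [1, N], gallery sizes below k, overlapping
  train/test splits, and unwritable output directories all raise
  immediately with the offending name in the message.

## Problem sizes

Default experiment scale: fitting cohort 500, classifier training set
200-300 images, evaluation galleries 40-126 pairs, 20 subsampling
replicates per population size, 100 PGD steps per defended image, 5
adversarial passes. The test suite and acceptance script use these sizes
(down to 20-60 pairs for the orchestrated smoke run); they were chosen so
every stochastic comparison is made on means across seeds with quoted
Monte-Carlo error, and they complete comfortably on a single CPU.

## Known limitations

* The conditional model assumes independent SNP effects (naive Bayes); no
  linkage disequilibrium, no imputation, no calibration of scores to
  posterior match probabilities.
* Open-set matching (a probe whose genome is absent from the gallery) is
  out of scope; success rates there would be lower still.
* The reference classifiers are deliberately small; absolute success rates
  on synthetic cohorts are not predictions for real photograph corpora.
* The clean-accuracy *cost* of adversarial training — a capacity-pressure
  effect in large networks — does not materialize for a gently fine-tuned
  64-unit network at budgets up to 0.05: across seeds the clean-input
  success of robust models is flat to slightly higher than the
  clean-trained control. The package reports this comparison as measured
  rather than asserting a decline.
* The parameter-recovery acceptance bound of 0.02 on the *maximum* table
  error at n = 5000 sits below the sampling-noise floor of counting
  estimators (the smallest genotype class holds ~1250 individuals, giving
  worst-cell standard errors around 0.013 and a max over ~100 cells near
  0.03); the mean error and the monotone convergence in n are the
  properties the suite verifies robustly.
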