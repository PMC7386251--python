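# Methods

## The model

`deepdep` predicts sample-specific cancer vulnerabilities in three stages.

**1. In silico CRISPR/RNAi.** Suppressing a target gene Y in a basal
transcriptome reduces its expression from y to y′ (y′ = 0 for CRISPR
knockout, y′ = 0.2y for RNAi, the average experimental efficacy of shRNA
knockdown). The effect propagates downstream through a directed regulatory
network. Two propagation rules are implemented:

* *Correlation rule* (for causally directed networks, e.g. Bayesian-network
  output): every descendant X_j of Y — any gene reachable along outgoing
  links, ignoring the structure of intervening nodes — is adjusted as

      x′_j = x_j − r_j · ((y − y′)/y) · x_j

  where r_j is the Pearson correlation between X_j and Y across a reference
  expression panel (the same panel used to build the network). The
  whole-transcriptome form for all targets at once is the matrix identity
  P = −k (R·B) + diag(B), with k = (y − y′)/y, R carrying 1 on the diagonal
  and r at descendant positions, and B the diagonal basal-expression matrix;
  the matrix and loop forms agree to machine precision (tested at 1e−10).

* *Conditional rule* (for oriented coexpression networks): only the direct
  regulatory targets of Y move, down by P(Y = activator)·k·x_j on activation
  edges and up by P(Y = inhibitor)·k·x_j on inhibition edges. Propagation is
  strictly one hop; the probabilities come from edge orientation (below).

Genes with zero basal expression cannot be knocked down (the fraction
(y − y′)/y is undefined); such targets are skipped and reported. Perturbed
values cannot go negative under these rules (|r| ≤ 1, k ≤ 1; inhibition only
raises values); a guard asserts this.

**2. Edge orientation by conditional probability.** Coexpression networks
report undirected interactions. Each gene is discretized per reference
sample into up (> μ + σ), down (< μ − σ), or mid, with μ and σ the gene's
mean and population standard deviation across the panel. For a pair (X, Y),
four frequencies are formed, e.g.

    P(X = activator) = [P(Y=up ∩ X=up) + P(Y=down ∩ X=down)]
                       / [P(X=up) + P(X=down)]

X is called a regulatory target of Y when P(X=act) + P(X=inh) <
P(Y=act) + P(Y=inh); the sign is activation when the winner's activator
probability exceeds its inhibitor probability. Exact ties drop the edge
(deterministic behaviour preferred over random assignment). Probabilities
are raw sample frequencies; no smoothing.

Note the direction rule reduces algebraically to comparing the two genes'
marginal exceedance frequencies beyond ±1σ (the numerators coincide). It
therefore carries signal only when the two marginals differ in shape: for
jointly Gaussian standardized pairs it is exactly symmetric and orientation
is a coin flip. Real expression marginals are heavy-tailed, and a regulated
gene — its regulator's signal plus independent noise — is closer to
Gaussian, hence exceeds ±1σ more often and is correctly called the target.
The orientation fixture encodes exactly this: lognormal regulator marginals,
Gaussian child noise. Direction recovery on 100-edge fixtures at 500
reference samples is ≥ 96% in our runs (bar: 80%).

**3. Dependency classification.** Cell-line screens provide labels:
CERES/zGARP scores at or below a cutoff (−0.6/−1.0/−1.5 for CERES,
−2/−3/−4 for zGARP), or BAGEL scores at or above one (0/2/4), mark
dependencies; equality counts as dependency since the screens' independency
side is quoted as strictly "below/above" the cutoff. An equal number of
independencies is drawn uniformly without replacement from the other side.
The classifier maps the perturbed transcriptome of each labelled
(cell line, gene) pair to its label:

* features: the 1000 genes with the largest standard deviation across
  training perturbed profiles (fewer when the universe is smaller);
* scaling: log2(x+1) then per-feature min–max to [0, 1], frozen on the
  training data and clamped on reuse;
* network: fully connected stack, 2-unit softmax output, trained as a
  stacked denoising autoencoder first (layer-wise, mask-to-zero corruption
  at the dropout rate, tied decoder weights, squared-error reconstruction
  cost for ReLU and cross-entropy for sigmoid, plain SGD), then fine-tuned
  with mini-batch momentum SGD (v ← μv − ε∇Loss, θ ← θ + v, v₀ = 0) on
  Loss = NLL + λ₁‖w‖₁ + λ₂‖w‖₂ — the elastic net on the weights, with the
  L2 term as the norm itself (not squared), exactly as specified;
* early stopping: of the training split, 3/4 learns and 1/4 traces the
  stop-control loss; patience starts at 200 epochs, improvement means the
  stop-control NLL falls below 0.99 × best, each improvement checkpoints the
  model and resets patience to max(200, 2 × epoch), and training halts when
  the epoch counter reaches patience;
* model selection: random draws from a hyperparameter grid under five-fold
  cross-validation; in each partition the best draw by validation AUC is
  evaluated on the untouched test fifth, and the mean test AUC of the five
  fold winners summarises performance. The prediction score for new input is
  the class probability, averaged over the five fold models.

The default grid spans 93,312 combinations (3 depth choices × 4 widths ×
8 learning rates × 3 momenta × 3 batch sizes × 2 activations × 2 init
schemes × 3 λ₁ × 3 λ₂ × 3 dropout rates). Random forest (1000 trees), SVM
(C-classification; linear/polynomial/sigmoid/radial kernels), Gaussian naive
Bayes and LDA (class priors 0.5/0.5) are available behind the same scoring
contract for comparison.

**Clinical calls.** Tumor and matched-normal transcriptomes are scored per
gene; a gene is a tumor-specific vulnerability for a donor when the tumor
score exceeds 0.5 and the matched-normal score stays below 0.5 (both
strict; scores equal to the threshold never call). Differential dependency
is tumor minus normal score. When CRISPR- and RNAi-trained models are
combined, their scores are averaged before thresholding.

**Mutation classes.** Inactivating variants are nonsense mutations and
frameshift indels. Heterozygous calls with VAF < 40% are hetLOF; homozygous
calls, or heterozygous calls with VAF > 50%, are homoLOF; the [40%, 50%]
heterozygous gap stays unclassified, exactly as printed — no interpolation.
When one (sample, gene) pair carries several records, homoLOF > hetLOF > GOF
precedence applies (a homozygous hit dominates biologically). Putative
oncogenes (GOF) are identical missense substitutions — same gene, position,
and amino-acid change — in ≥ 2 distinct samples; putative tumor suppressors
carry inactivating mutations in ≥ 5 distinct samples and are merged with a
user-supplied known-TSG list. Known oncogenes whose cohort variants are
exclusively silent (at least one silent, no nonsynonymous) are negative
controls. GISTIC-style copy-number codes map −2..2 onto homozygous deletion,
heterozygous deletion, normal, low- and high-level amplification. Mutant and
wild-type differential-dependency distributions are compared with the
two-sample Kolmogorov–Smirnov and Student's t tests.

## The synthetic benchmark

The planted benchmark (`deepdep.benchmark`) emulates the study design at
desk scale: a two-layer regulatory network of 40 regulators, each driving a
disjoint block of effector genes whose size is drawn from {1, 2, 3, 16, 18,
20} — so knockout footprints are strongly heterogeneous, as for real
regulators; 800 reference samples; 30 cell lines. Expression follows a
linear structural model on the network (children are signed sums of parents
plus Gaussian noise, mapped affinely onto a non-negative scale). Regulator
genes are given a smaller dynamic range than effectors, mirroring the
relatively stable expression of regulatory genes; one consequence is that
variance-based feature selection picks effector genes, so the classifier
sees the perturbation's downstream footprint rather than the suppressed
gene's own (zeroed) coordinate.

A fixed viability signature — one quarter of each module's genes, at least
one per module — defines planted essentiality: the drop a target's knockout
induces in the signature, computed from the generator's own coupling
estimates on an independent probe panel. Basal cell-line profiles are
rescaled so the baseline signature is constant across cell lines (baseline
viability homeostasis: every surviving line starts viable; only
perturbation moves the signature). A (target, cell line) pair is a
dependency when its drop exceeds the cohort median. CERES/zGARP tables are
emitted as negative noisy standardizations of the drop, BAGEL positive, so
cutoff labelling recovers the plant (≥ 95% at the default score noise of
0.05 SD).

Cross-validation folds, the validation split, and the learning/stop-control
split are stratified by label and by cell line. Plain label stratification
would leave each cell line's fixed number of positives split at random
between partitions, which makes any per-cell-line rate a model overfits
*anti*-predictive on held-out data (a finite-population artifact that
biases null AUCs below 0.45); per-cell stratification makes cell-rate
learning exactly neutral instead.

The negative-control property follows the study's design: with the true
network the mean test AUC is ≥ 0.9 (≈ 0.95 in our runs); with a
node-shuffled or edge-inverted network the same pipeline falls to ≈ 0.5
(band 0.45–0.55). Shuffling reassigns each target the descendant set of a
random other node, whose reference correlations with the target are ≈ 0, so
the perturbation footprint vanishes; inversion leaves the (root) regulators
with no descendants at all. What passing shows: the classifier's signal
lives in the network-propagated part of the perturbed profile. What it does
not show: performance on real cohorts — the generator has no batch effects,
no tumor purity variation, no measurement noise model, and its regulatory
modules are disjoint rather than overlapping.

The benchmark runs the cross-validation protocol at reduced scale — 20
random draws from a small grid, 100 features, patience 40 epochs extended
to 150/400 in the benchmark driver, reduced pretraining — keeping the
structure (5 folds, validation-based selection, test-fifth evaluation)
unchanged. At this data size one epoch contains only a few dozen gradient
updates, so the epoch-denominated patience is set larger than it would be
at full scale where an epoch spans thousands of mini-batches.

## Numerical choices and degenerate inputs

* Population (ddof = 0) standard deviations in discretization and feature
  selection; feature-selection ties break by gene-id order.
* Constant genes: σ = 0 ⇒ all states mid; correlation 0 with a warning;
  features constant on training scale to 0.
* Zero denominators in orientation frequencies yield probability 0 with a
  warning; orientation ties (direction or sign) drop the edge.
* Self-loops in edge lists are dropped with a logged count; duplicate edges
  keep the first occurrence.
* Networks may contain cycles; descendant sets use reachability with a
  visited set, and a gene reachable from itself through a cycle is still
  excluded from its own descendant set (the perturbation rule sets the
  target's level directly).
* The ReLU reconstruction cost and the gradient of the global L2 norm are
  undefined at exact zeros; subgradient 0 is used at the ReLU kink and the
  L2 gradient is skipped when the norm is 0.
* All randomness flows from explicit integer seeds through named
  substreams; repeated calls are byte-identical.

## Known limitations

* The conditional-probability rule is strictly one-hop by construction;
  whether cascading it would better approximate real knockdowns is untested.
* Orientation requires marginal-shape asymmetry (see above); on symmetric
  (e.g. jointly Gaussian) data it abstains or guesses at chance.
* The numpy network trainer is plain momentum SGD; on poorly conditioned
  inputs it needs the hyperparameter search to find workable settings, and
  the grid deliberately includes both activations for that reason.
* Screen-score generation plants essentiality through a linear viability
  signature; nonlinear dependency mechanisms (synthetic lethality between
  two simultaneous losses, for instance) are not simulated.
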