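# Methods

This note records the modeling choices behind `strainrec`, the reasoning
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Imputation model

Each gene is modeled independently. The predictor is not variant state but
the donor panel itself: for donor *i*, feature *j* is
`F_ij = w_ij * y_j`, where `y_j` is donor *j*'s observed expression and
`w_i.` are donor *i*'s normalized local-similarity weights over a 400 kb
window around the gene's cis-eQTL variant, with the self-weight zeroed
(leave-self-out) so the diagonal never lets a donor predict itself during
training. A strain is imputed by building the identical features from its
own genotypes: `intercept + sum_j w_tj * y_j * beta_j`. The model is a
ridge regression with intercept because donor features are strongly
collinear by construction (nearby donors share haplotypes).

Assumptions worth stating explicitly:

- expression of a gene is driven by a *local* regulatory region; one
  anchoring cis variant (max |Pearson r| within ±1 Mb of the TSS, ties to
  the lowest position) is enough to place the window;
- local identity-by-state on the dosage scale is a usable proxy for
  regulatory-haplotype sharing: distance is the mean of `|d_a - d_b| / 2`
  over pairwise-complete window variants, so it is symmetric, bounded in
  [0, 1], and tolerant of missing genotypes without imputing them;
- similarity translates to weight as `(1 - d)^kappa`, normalized to sum to
  one. `kappa` (default 1) sharpens the weighting; the default is the
  simplest monotone map. If every donor is maximally distant or undefined,
  weights fall back to uniform so every strain remains imputable (logged).

Expression is modeled on its input scale; no rank or quantile
normalization is applied. The downstream score is a rank correlation, so
any strictly monotone rescaling of expression leaves recommendations
unchanged (tested exactly).

## Numerical choices

- Ridge is solved in closed form on centered data via one SVD per training
  set; the whole 50-point penalty grid (log-spaced in [1e-3, 1e3]) is then
  obtained by rescaling singular values, which makes grid cross-validation
  cheap. Coefficients agree with the normal-equations solution and with
  scikit-learn's `Ridge` to 1e-6 (tested on random instances).
- Cross-validation uses 5 folds from a seeded permutation; the fold seed is
  part of the model metadata, so retraining is bit-reproducible. The
  selected λ minimizes mean CV squared error; `cv_r2 = 1 - mse/var(y)`.
- Degenerate genes (no polymorphic cis variant, all-zero features, or
  constant expression) fall back to a donor-mean predictor or are dropped
  from the resource with a logged count.
- The gene-model store is JSON; floats are serialized via `repr` shortest
  round-trip, so save/load is bit-exact. Expression TSVs are reloaded with
  the `round_trip` float parser for the same reason.
- Window bounds are inclusive on both ends with 1-based positions;
  "400 kb window" is read as ±200 kb around the anchoring variant.
- Exact |r| ties in the eQTL scan resolve to the lowest position; exact
  score ties in ranking resolve lexicographically by strain id; exact
  score ties within a benchmarked pair abstain. All three rules exist only
  to make outputs deterministic.

## Vulnerability score and FPR

The score is Spearman's ρ (average ranks for ties) between the harmonized
signature scores and the strain's imputed expression at those genes.
Signatures must have at least 3 genes and non-constant scores; harmonization
is ortholog translation (one-to-many mappings fan out), max-|score|
deduplication (ties keep the first entry seen), then filtering to the
resource.

The null model draws B = 4,000 scores: pick a strain uniformly, sample *n*
genes from it uniformly without replacement, correlate those values with
the observed score vector. Two deliberate details:

- **One shared null per signature.** The procedure never uses the focal
  strain's identity, so its distribution is strain-independent; computing
  it once per signature is distributionally identical and B-fold cheaper.
- **Random-order pairing.** Each sampled gene subset is paired with the
  score vector in sampling order, not in resource order. Sorted subsets of
  a shared gene pool are not exchangeable against a fixed score vector;
  when *n* is a sizable fraction of the resource that pairing acquires a
  per-signature bias (observed FPRs up to ~0.76 on a small resource).
  Random-order pairing keeps the null centered.

The FPR is `(k + 1) / (B + 1)` with `k` the count of null scores at least
as extreme as ρ in ρ's own direction (right tail for vulnerable, left for
resilient). The smoothing keeps FPR strictly positive. **Calibration
property:** because the tail is chosen by the observed sign, the FPR of a
truly null strain is distributed approximately Uniform(0, 0.5], so the
fraction of null strains at FPR ≤ α is ~2α, not α (measured 9.6% at
α = 0.05 and 19.7% at α = 0.10 over 400 null-signature replicates on the
default synthetic resource). Users who need a marginal type-I rate of α
should threshold at α/2; the package reports the directional FPR as
defined.

## Benchmarking

A strain pair is scored only when both FPRs pass the threshold (default
0.05); the higher-scoring strain is predicted more vulnerable. Per-disease
sensitivity is correct/(correct + incorrect); abstentions never enter
denominators. Phenotype terms map to diseases through a local table; a term
mapped to several diseases contributes its comparisons to each of them.
Disease-level results are macro-averaged with a Normal 95% CI
(`mean ± z * sd / sqrt(N)`; undefined for a single disease, zero-width
when all sensitivities agree). Categories follow fixed bands:
high ≥ 90%, moderate [70, 90)%, low (50, 70)%, poor ≤ 50%.

The "insufficient gene set" rule — abstain a whole (gene set, study) block
when the study's top-scoring strain fails the threshold — is implemented
behind `drop_insufficient` (default off) because its intended scope is
ambiguous; the flag makes both readings available.

## What the synthesizer emulates

Defaults: 8 founders, 185 donors, 40 strains, 300 genes, 2,000 variants on
one 20 Mb chromosome, donor founder-segment lengths exponential with mean
2 Mb, founder alternate-allele frequency uniform in [0.1, 0.9], one planted
cis-eQTL per gene (|β| = 1, random sign, planted at a variant that
segregates in the panel) with Gaussian residual sd 0.2, gene baselines
N(8, 0.5²) on a log2-like scale. These sizes keep roughly 40 variants per
400 kb window and let the full pipeline (simulate → train → impute → plant
→ recommend → benchmark) run in well under a minute on one CPU; the test
suite reuses one default-scale study and a trimmed 60-donor/12-strain
variant.

Planted signatures take a target strain's imputed expression at a random
gene subset (default 100 genes), subtract its scalar mean (rank-preserving,
so the noiseless signature scores its target exactly 1), and add Gaussian
noise expressed as a fraction of the score spread. The gene-baseline spread
(0.5) is deliberately comparable to the genetic effect scale: baseline
variation carries no strain information, and if it dominated the score
scale, relative signature noise would drown the between-strain differences
the benchmark is supposed to measure. Validation records order each pair by
noise-free resemblance to the planted signature and flip the observation
with probability `flip_prob`; flip-recovery experiments run at signature
noise 0 so that measured sensitivity isolates the flip rate itself.

What passing these benchmarks does *not* show: the generator has a single
chromosome, no recombination map, no selection or population structure
beyond the founder mosaic, additive single-variant cis effects only, no
trans effects, no tissue or environment specificity, and signatures derived
from the same resource being scored. Real disease gene sets are noisier and
can be biased in ways the planted construction is not, so synthetic
sensitivities bound what the machinery can do when its assumptions hold —
they are not estimates of performance on curated literature data.

## Known limitations

- The anchoring cis variant is chosen by a marginal scan; perfectly linked
  variants are indistinguishable, and the window then only needs to cover
  the right haplotype block, not the true causal site.
- The similarity-weighted feature construction shrinks every strain toward
  the donor panel; strains outside the donors' haplotype space revert to
  near-uniform weights and hence toward the panel mean.
- The directional FPR is not a two-sided p-value and is deliberately not
  multiplicity-adjusted across strains.
- Virtual F1s average parental dosages; dominance and parent-of-origin
  effects are out of scope.
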