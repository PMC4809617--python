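# Methods

## The inference problem

We want, from a set of 100-kb windows of phased haplotypes, (i) the
three effective population sizes of a piecewise-constant history and
(ii) a per-window selection call. The history has epochs
[0, t₁), [t₁, t₂), [t₂, ∞) backwards in time with sizes
Nᵢ = λᵢ·N_ref; the defaults t₁ = 0.5 and t₂ = 5 (coalescent units of
4·N_ref generations), N_ref = 100,000 and μ = r = 8.4×10⁻⁹ per bp per
generation describe an African *Drosophila melanogaster*-like setting.
Because no tractable likelihood exists for such histories jointly with
selection, inference is simulation-based: draw parameters from priors
(λ₁ ~ U(3,14), λ₂ ~ U(0.5,6), λ₃ ~ U(2,10)), simulate data, summarize,
and train a regression/classification network on the
(summaries → parameters) pairs.

Selection classes per region: **neutral**; **hard sweep** (positive
selection on a de-novo mutation); **soft sweep** (positive selection on
standing variation starting at frequency 0.001); **balancing**
(heterozygote advantage). Selected classes use
s ∈ {0.01, 0.02, 0.05, 0.1} (cycled evenly within a class), selection
onset 0.005 coalescent units before present, and a selected site placed
uniformly in the middle 20% of the region. The onset is recent enough
that weak sweeps are often incomplete at sampling time, which is what
makes low-frequency sweeps resemble neutrality. Simulations in which
the beneficial allele is lost are redrawn (budget 1,000 retries); the
realized present-day allele frequency is recorded with each region.

## Forward simulator

`demosel.wrightfisher` implements a discrete-generation haploid
Wright–Fisher population of M = 2N sequences, which reproduces the
coalescent scalings of ms/msms exactly (pairwise coalescence time M
generations; θ = 4NμL = 2Mu; one coalescent unit = 2·M_ref
generations). Reproduction is multinomial; directional selection
weights parent choice by 1+s for carriers; balancing selection samples
mating pairs and accepts them with probability proportional to the
fitness of the genotype they form at the selected site (1+s when the
gametes differ). Recombination is a single crossover per meiosis with
probability r·L; mutation is infinite-sites at rate u = μ·L per
sequence per generation, at integer bp positions.

**Rescaling.** Simulating N ≈ 10⁵–10⁶ forward is impossible at desk
scale, so the population is rescaled by Q: N/Q individuals with μ, r, s
multiplied by Q, preserving θ, ρ and 2Ns. The default rescaled baseline
is N_ref,resc = 1000 (Q = 100); a floor of 50 is enforced. Rescaling is
an approximation: it is accurate while s·Q ≪ 1 and degrades for strong
selection, where the rescaled sweep completes in very few generations
and accumulates less recombination than the unrescaled sweep would.

**Burn-in and epochs.** The ancient epoch is equilibrated from a
monomorphic start for `burn_in_mult` × M₃ generations (default 8; the
expected TMRCA of a large sample is ≈ 2·M₃, so 8×M₃ leaves negligible
truncation bias — the neutral calibration tests verify this against
the Watterson prediction E[S] = θ·Σ1/i and the neutral folded SFS).
Epoch lengths follow from t₁, t₂; the selection phase occupies the last
`onset`·2·M_ref generations, restarted from a snapshot on allele loss.

Haplotypes are bit-packed (64 sites/word) and the generation kernel is
numba-compiled; a desk-scale region simulates in ~0.2 s.

## Summary statistics

345 statistics, every one normalized into [0, 1], computed on the
close/mid/far subregion layout described in the README. Details and
conventions:

* **S**: min(S, 5000)/5000 per subregion.
* **Tajima's D** with the standard 1989 variance estimator
  (a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂); normalized as clamp((D+3)/6, 0, 1);
  D := 0 when S = 0 (value 0.5).
* **Folded SFS**: ηᵢ = sites with minor-allele count i, i = 1..n/2,
  normalized by Ση; all-zero when S = 0.
* **BET** (lengths between adjacent segregating sites): gaps within
  each contiguous bp interval of the subregion, 16 bins with starts
  0, 20, …, 300 (last open-ended), **divided by S** (so the block sums
  to (S−1)/S, not 1 — this follows the printed definition of the
  statistic rather than a gap-count normalization).
* **IBS**: for every haplotype pair, maximal runs identical at every
  segregating site, delimited exclusively by mismatch sites and by the
  interval boundaries (a mismatch at bp p inside [a, b) yields tracts
  p−a and b−p−1). 30 bins with starts i·5000/29, last open-ended,
  normalized by tract count. Identical pairs contribute one
  full-interval tract, so this block is defined even when S = 0.
* **LD**: D_AB = p_AB − p_A·p_B between one site in the close subregion
  and one site in the target subregion (site pairs i < j within close),
  derived-allele coding; 16 bins — (−∞, −0.05), fourteen equal bins
  spanning [−0.05, 0.2), [0.2, ∞). Blocks with more than 10⁵ pairs are
  deterministically subsampled.
* **H1/H12/H2** over close-subregion haplotype classes:
  H1 = Σpᵢ², H12 = (p₁+p₂)² + Σ_{i≥3}pᵢ², H2 = H1 − p₁²; (1, 1, 0)
  when the close subregion is invariant.

The featurizer is invariant to haplotype row order and to reversing the
region end-for-end (the subregion layout is symmetric), properties the
test suite asserts. Every statistic is also checked against an
independent plain-loop implementation on small matrices.

**Missing data** (real-data path): within each 100-kb window group the
100 most complete samples are retained; sites with fewer than 100
non-missing calls among them are dropped; allele counts use the first
100 called samples per site; pairwise statistics (π, IBS, LD) use
pairwise-complete observations; haplotype classes for H statistics use
rows fully called over the close subregion.

## Network and training

Logistic hidden layers (default 25·25·10; the pretraining comparison
uses a deeper 64·42·28·18·12·8 stack), output head = 3 linear nodes for
the min–max-normalized λᵢ plus a 4-class softmax. Joint cost = mean
squared-error head + mean cross-entropy head (equal weight, exposed as
`regression_weight`) + weight decay λ = 10⁻⁴ on the final layer only.
Gradients by backpropagation (finite-difference-verified to 10⁻⁶);
optimization by full-batch L-BFGS.

**Pretraining.** Each hidden layer is initialized by a sparse
autoencoder trained on the previous layer's representations: cost =
mean ½‖x̂−x‖² + β·ΣKL(ρ‖ρ̂ⱼ) + (λ/2)(‖W₁‖² + ‖W₂‖²), decoder discarded.
Defaults β = 3, ρ = 0.25, both config-exposed. ρ = 0.25 rather than the
textbook 0.1: these features have low variance, and a 0.1 target drives
hidden activations nearly constant, after which fine-tuning collapses
to single-class prediction on a substantial fraction of seeds. The
output layer starts at 0.01×N(0, 1), seeded.

**Numerical choices.** L-BFGS tolerances are tightened to
ftol = 10⁻¹³, gtol = 10⁻¹⁰: with a small output-layer initialization
the first iterations sit on a flat "predict the class prior" plateau
and scipy's defaults declare convergence there. ρ̂ is clamped to
[10⁻¹⁰, 1−10⁻¹⁰] to keep the KL term finite. Fine-tuning returns the
initialization if the optimizer fails to improve on it. Training is
deterministic given the seed.

**Random-initialization baseline.** The pretraining comparison
contrasts autoencoder initialization with *naive* 0.01-Gaussian random
weights — the classical initialization under which deep logistic nets
stall on the single-class plateau. That stall is precisely the
phenomenon the comparison documents; a modern Glorot-uniform
initialization (also provided, and the default elsewhere) largely
removes it on this problem.

## Prediction, uncertainty, misspecification

Three estimators per demography: *average-stat* (mean feature vector →
one forward pass, usually the most accurate), *final* (per-region
predictions averaged, with across-region std and empirical 2.5/97.5
percentiles by linear interpolation), *neutral-regions* (final,
restricted to regions called neutral; falls back to all regions with a
warning if none are). The percentile interval is an across-region
spread, not a calibrated posterior, and is reported as such. Selection
calls take the softmax argmax; exact ties call the lowest class index
and are logged. A region whose normalized size prediction leaves [0, 1]
for *any* size is flagged as outside the simulated training range and
excluded from demography averaging (with a fallback if all regions are
flagged).

## Statistic importance

*Permutation*: permute one statistic's column across test datasets
(seeded), record the increase in mean relative size error per Nᵢ and in
misclassification rate. *Perturbation*: shift one statistic by ±δ
(default 0.05 on the feature scale, clamped), record the mean absolute
change in the normalized size outputs and in the class probabilities.
Top-k (default 25) per output, plus the 4-way membership matrix. The
perturbation scheme is this package's own documented protocol; the
accuracy metrics mirror the evaluation metrics (relative error,
misclassification). Both methods are deterministic given seed and δ.

## Reduced-scale reference study

The full-scale design (2,500 demographies × 160 regions, θ ≈ 336·λ₁
per region, weeks of CPU) is expressible in `default_config()` but not
runnable on a desk. `small_reference_config()` defines the conditions
used by the test suite and `scripts/acceptance.py`:

* 100 demographies × 16 regions (4 per selection class), split 75/25 by
  demography;
* rescaled baseline N_ref,resc = 75, burn-in 5×M₃;
* μ = r = 5×10⁻¹¹ (θ ≈ 2·λ₁ per 100-kb region, S ≈ 50–120 segregating
  sites) — about 1/170 of the full-scale mutation supply;
* unchanged: priors, epoch times, n = 100, L = 100 kb, selection
  classes, s values, onset, selected-site placement;
* training to effective convergence (800 L-BFGS iterations for the
  3-hidden-layer reference model; matched 400-iteration budgets in the
  initialization comparison).

What this reduced study *shows*: the direction of the full-scale
findings — the ancient size N₃ is the least accurately estimated;
neutral regions are the easiest class; incomplete (low-frequency)
sweeps are the ones misclassified as neutral; autoencoder pretraining
rescues a deep net that naive random initialization leaves degenerate.

What it *cannot* show: the full-scale error magnitudes (with 170× less
mutation information per region, relative errors sit near 0.25–0.5
rather than 0.05–0.49, and misclassification near 0.6 rather than
0.062). Two desk-scale artifacts deserve emphasis: (i) at a rescaled
present-day population of a few hundred, a soft sweep starting at
frequency 0.001 begins from 1–2 copies — operationally almost a hard
sweep — so the hard/soft distinction largely vanishes; (ii) strong
rescaled selection (s·Q ≫ 1) compresses sweeps into a couple of
generations, so within-sweep recombination, and hence the close/mid/far
contrast, is weaker than at full scale. The simulator-calibration tests
(Watterson/SFS at θ = 8, sweep diversity contrast at milder rescaling)
are run under conditions chosen so the quantity being checked is not
dominated by these artifacts.

Real-data windowing follows the 20-kb/5-window sliding design: each
100-kb group is featurized with the middle window as the close
subregion, and classification is attributed to that middle window.
Groups extending past the contig end are skipped and logged.

## Known limitations

* No structured-coalescent sweep machinery, gene conversion, or
  variable recombination maps; single crossover per meiosis.
* Rescaling artifacts under strong selection, as above.
* The balancing-selection start frequency is not specified by the
  class definitions; standing variation at 0.001 (as for soft sweeps)
  is used, since a single-copy heterozygote-advantage allele at desk
  scale is almost always lost immediately.
* The percentile intervals are descriptive spreads; no posterior is
  provided.
* ms-format ingest maps fractional positions to bp by floor(p·L) and
  resolves collisions by +1-bp nudges; round-tripping is exact for
  bp-resolution data but collision nudges are not invertible.
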