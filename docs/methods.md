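# Methods

`tumevol` infers ongoing subclonal selection from the variant-allele-frequency
(VAF) distribution of a single bulk-sequenced tumour biopsy. It is a
synthetic-supervised (simulation-based, amortized) method: labelled VAF
distributions are simulated under explicit models of tumour evolution and
sequencing noise, a multi-task 1D convolutional network is trained on them,
and inference on a new sample is a handful of stochastic forward passes.
This note documents the models, the parameter choices, the numerical
shortcuts, and what the synthetic data do and do not capture.

## Evolutionary models

### Stochastic selection simulator (`sim_selection`)

Tumours under positive selection are grown from one founder cell to
`n_final` cells with a rejection-kinetic Monte Carlo branching process: a
cell is drawn uniformly, and divides (dies) with probability
`b_i / (b_max + d)` (`d / (b_max + d)`). Every daughter draws
`Poisson(mu)` new mutations. Each new mutation is a driver with probability
`p_driver` until `max_drivers = 3` driver events have occurred; a driver
draws `s ~ Exponential(s_mean)` and multiplies the lineage's net growth rate
`b - d` by `1 + s`, so lineage fitness is `prod(1 + s_i)` (multiplicative
epistasis-free fitness). Cells reference a genotype table (one entry per
mutation-carrying daughter), keeping memory linear in genotypes rather than
mutations; per-mutation true VAFs are `subtree cell count / 2N` on a diploid
heterozygous background, and clonal (founder) mutations sit at exactly 0.5.

Defaults `b = ln 2`, `d = 0`, `N = 1000` make a tumour grow in ~10
population doublings. The VAF distribution carries no information about
absolute population size, so a small `N` reproduces the shape of empirical
VAF distributions at a small fraction of the cost; the price is that
fitness and emergence time are expressed on the simulated clock and must be
rescaled for real tumours (see Rescaling).

**Labels.** A detectable subclone is a driver lineage whose VAF lies in
[0.10, 0.40] (20–80% cellular fraction): below that band subclonal peaks
merge with the neutral tail, above it with the clonal cluster. Lineages
closer than 0.05 VAF are indistinguishable in a one-dimensional VAF
histogram and are merged (single linkage, reported at the largest lineage's
VAF). Whether nested driver lineages count separately is decided purely by
this VAF-distance rule. Simulations with more than two detectable
subclones cannot be expressed in the 0/1/2 label scheme and are flagged
unusable (and regenerated during dataset construction).

### Neutral generative sampler (`sim_neutral`)

Neutral tumours are *sampled*, not simulated: the non-clonal part of a
neutral VAF distribution follows a Pareto law
`f(x | alpha, m) = alpha m^alpha x^-(alpha+1)`, and a stochastic neutral
simulation at small `N` would occasionally produce drift-born pseudo-
subclones, contaminating the neutral class. A neutral tumour is a Pareto
tail (draws above 0.5 resampled) plus a clonal point mass; all clonal-peak
dispersion comes from the read-noise model. Two perturbations emulate real
biopsies: with probability `p_trim <= 0.1` the tail below a random
`trim_f ~ U(0.10, 0.30)` is removed (many real samples lack a visible
tail), and the clonal cluster is shifted to `U(0.45, 0.50)` (emulating
modest purity mis-estimates), biasing the classifier toward parsimony.

The Pareto shape is drawn from a log-normal with median 1.0 (sigma 0.5)
truncated to [0.5, 3] — a documented stand-in for shape distributions
fitted to patient cohorts, centred on the theoretical neutral exponent;
a user-supplied table of empirical shapes can be passed instead. The scale
is set to the minimum non-clonal true frequency of the paired selection
simulation, which is also the maximum-likelihood convention for fitting a
Pareto scale to data.

**Pairing.** Selection and neutral tumours are generated in pairs sharing
the clonal mutation count, the total assigned mutation count (the neutral
tail size equals the selection arm's non-clonal count, before any trim) and
the identical sequencing parameters. A classifier therefore cannot separate
the classes by burden or noise level; only the distribution's shape is
informative.

## Virtual biopsy (`biopsy`)

Per mutation: depth `D_obs ~ Binomial(N, D/N)` with `D` the target mean
depth and `N` the depth pool (the simulated population size by default);
alt reads `R_obs ~ BetaBinomial(D_obs, p, rho)` with
`p = VAF_true * purity`. The beta-binomial uses the intraclass-correlation
parameterization `a = p(1-rho)/rho`, `b = (1-p)(1-rho)/rho`, giving
`Var(R) = n p (1-p) (1 + (n-1) rho)` and collapsing exactly to a binomial
at `rho = 0` (conventions differ across packages, so this is stated
explicitly). Purity acts as frequency dilution before read sampling
(normal cells contribute reference reads only). Mutations with fewer than
`min_alt_reads = 2` alt reads are uncallable and dropped; the threshold is
configurable and recorded in outputs.

**Detection floor (bulk generation only).** Exponential growth yields
~`2 mu (N-1)` mutations per tumour, the vast majority at frequencies far
below what any histogram bin can see (the featurization cutoff is >= 0.02,
typically ~0.03–0.06). Dataset generators therefore skip read sampling for
mutations whose diluted true frequency is below 0.004. At the training
depth ranges the probability that such a mutation would have exceeded the
featurization cutoff is of order 1e-3 or less, and the same floor applies
to both arms of every pair, so feature distributions are unaffected to well
below their sampling noise. `virtual_biopsy` itself defaults to the exact
(floor-free) behaviour. For the same reason, the paired neutral tail is
instantiated only above the floor, using the fact that a Pareto conditioned
on exceeding a threshold is a Pareto with that threshold as scale, with a
binomially-thinned count.

## Input representation (`features`)

Observed VAFs are binned into fixed-range histograms over [0.02, 0.50] at
two resolutions, k = 64 and k = 128 (bin width `0.48 / k`), concatenated
into a length-192 vector. To condition the model on sequencing depth,
mutations below `f_alt + 2 sqrt(f_alt (1 - f_alt) / c)` are excluded, where
`f_alt = min_alt_reads / c` and `c` is the mean depth — the minimum callable
frequency plus two binomial standard deviations. Histograms are raw counts
by default (a density-normalized mode exists behind a flag; models record
which convention they were trained with). The network applies `log1p` to
count inputs internally as a scale stabilizer; this is a model-side choice,
not part of the featurization contract.

Tumour-adapted Tajima's D and Fay & Wu's H are provided as summary
statistics: the effective number of sampled chromosomes is `round(mean
depth)`, and somatic VAFs are treated as derived-allele frequencies (the
reference genome is ancestral; no folding). These conventions are this
package's; they matter only for comparability across samples.

## Models and training (`netmodel`, numpy core in `nn`)

Three roles share one architecture family: `M_ms` (classification:
P(Selection) and 0/1/2 subclones), `M_1s` (one subclone VAF), `M_2s` (two
subclone VAFs, reported descending). Each histogram resolution has its own
convolutional trunk (Conv1d -> Hardswish -> Dropout(0.5) [-> AvgPool]);
trunks are flattened, concatenated and fed to per-task fully-connected
branches (Dense -> Hardswish -> Dropout(0.5) -> Dense). Kernel widths are
odd (1–17), channels 4–32, 1–20 conv layers; dropout is fixed at 0.5 after
every hidden layer because prediction-time dropout is the uncertainty
mechanism. The neural-network core (convolutions with hand-written
backward passes, Adam, the losses) is implemented in numpy in single
precision.

Training uses Adam, batch size 256, cross-entropy for classification
(binary term carrying a configurable positive-class penalty; the default
penalty 2.0 halves the positive-class weight, trading recall for precision
— the direction preferred when false selection calls are the costly error)
and L1 loss for regression. Early stopping monitors a 10% validation split
at a cadence of one evaluation per 20,000 training simulations (or per
epoch when the data are smaller), restoring the best weights. Positive
simulations can be rebalanced to uniform counts per subclone frequency
(rounded to 0.01), and two-subclone simulations to uniform counts per
inter-subclone distance after removing pairs closer than 0.05 VAF; only
positive simulations train `M_1s`/`M_2s`.

**Uncertainty and calls.** Prediction keeps dropout active: T = 50
stochastic passes give an approximate posterior per output, summarized by
its mean and 89% equal-tailed interval (empirical 5.5%/94.5% quantiles).
Selection is called only if the interval's lower bound for P(Selection)
exceeds 0.5; otherwise the sample is neutral with zero subclones regardless
of the subclone head. Under selection the subclone count takes the class
whose lower bound exceeds 0.5; if both or neither qualify, ties fall toward
fewer subclones (argmax of class means as fallback). This is deliberately
conservative: broad posteriors default to neutrality.

## Post-processing of empirical samples (`postprocess`, `cli`)

VAFs from diploid segments are corrected as `VAF / purity`. Because purity
estimates themselves err, a peak-finding adjustment follows: a Gaussian KDE
(Silverman bandwidth, 512-point grid on [0.05, 1.0]) is evaluated, local
maxima located, and the peak closest to 0.5 taken as the clonal-cluster
candidate (ties toward the higher VAF). If it lies above 0.35 — where it
can only plausibly be a misplaced clonal cluster — a Gaussian is fitted to
the VAFs within ±0.1 of the peak and all VAFs are multiplied by
`0.5 / fitted mean`; otherwise the sample is left unchanged with a warning.
Samples below 100 mutations are left unadjusted and flagged; runs flag (or
refuse, under `--strict`) samples with fewer than 100 mutations or below
60x mean effective coverage (purity x depth), the inclusion rules used for
patient biopsies.

Mutations are then clustered *outward* from the predicted subclone
frequencies without any mixture-model fitting: subclone `q` claims
`q ± eps sqrt(q(1-q)/c)` (eps = 2 binomial standard deviations at mean
depth `c`), the clonal cluster claims the same window around 0.5, gaps
split at the midpoint of facing window edges (which is the overlap midpoint
when windows intersect), and everything below the lowest window is neutral
tail. An optional Gaussian-mixture refinement seeds means at the subclone
frequencies and 0.5.

**Rescaling.** With tumour age in doublings
`t_end = log2((1 - f_sub) N_end)`, emergence times rescale linearly in log
population size, `t_s^R = t_s log(N_real)/log(N_sim)`, and fitness rescales
so the subclone reaches the same frequency over the rescaled interval:
`w_R = 1 + (w - 1)(t_end - t_s)/(t_end^R - t_s^R)`, with `N_real = 1e10`
as the default realistic tumour size.

## Transfer learning (`transfer`)

The target domain replaces stochastic driver arrival with a
deterministically initiated subclone: birth 1, death 0.2, `N = 1e4`,
500 clonal mutations; when the population first reaches `2^t_s` cells one
random cell's lineage gets its net growth rate multiplied by the fitness
`w = 1 + s`. The new tasks are mutation rate, subclone fitness, emergence
time (doublings) and cellular fraction (subclone VAF x 2); emergence time
is operationalized as `log2(population size at initiation)` so it composes
with the rescaling formulas. An extinct or never-initiated subclone yields
cellular fraction 0 (flagged, not an error).

Only a band of (fitness, t_s) combinations yields detectable subclones, so
training parameters come from a noisy Gaussian-process regression of
viable `t_s` on fitness (kernels: RBF with length scale 100 + dot-product +
white noise, alpha 1e-6), fitted on a 150-simulation pilot grid with inputs
standardized (the stated kernel scales therefore act on z-scores — an
interpretation, recorded here). Fitness is drawn uniformly over the viable
range and `t_s` from the GP's noisy predictive distribution; the noise is
what spreads sampled subclones across the whole frequency band.

*Architecture renovation* concatenates the convolutional trunks of the
trained `M_ms` and `M_1s` models (weights copied verbatim — trunks may have
different channel counts, recorded per trunk in the checkpoint spec),
discards their branches, and attaches four fresh fully-connected branches.
Fine-tuning minimizes L1 on all four tasks. Mutation rate, emergence time
and cellular fraction regress on their natural scale (scaled to order
one); fitness regresses in *log space*, because its evaluation metric is a
percentage error and an L1 loss matches relative error on the log scale
(for emergence time the linear scale proved better balanced across the
viable band). Trunks remain trainable at a 10x reduced learning rate by
default (freezing is a flag — whether the original procedure froze them is
not knowable from the outside, so both are supported). Fine-tuning keeps
the three best validation checkpoints and cycles them across the
stochastic prediction passes (snapshot ensembling): Monte Carlo dropout
already averages over subnetworks, and widening the averaged hypothesis
set damps the checkpoint-to-checkpoint swings in the low-fitness bias at
no extra cost. At prediction time dropout is active only on the new
branches; the pre-trained trunks run deterministically, and log-space
heads are averaged in log space over the T passes (the geometric mean —
the plain average of raw network outputs). A residual systematic bias in
the mutation-rate output is removed by a degree-2 polynomial ridge
regression fitted on 1000 calibration simulations and stored with the
model.

## Desk-scale study conditions

The full-scale study behind this method trained on tens of millions of
simulations with large hyperparameter searches. This package's default
validation suite runs on one CPU in tens of minutes, at sizes chosen as the
smallest that keep the scientific signal stable:

| quantity | desk value |
|---|---|
| paired training simulations (classifier) | 12,500 pairs = 25,000 samples |
| extra pairs for frequency regression | 10,000 (positive arms) |
| frequency-regression models | 2 independently trained replicas, ensembled |
| clean-sequencing conditions | depth U(100, 150), rho U(0, 0.003) |
| broad-conditions classifier | 5,000 pairs, depth U(20, 250), rho U(0, 0.3) |
| robustness grid | 2,000 neutral tumours, purity U(0.2, 1), depth U(20, 200), rho 0.03, ±25% purity error |
| transfer fine-tuning / held-out / calibration | 25,000 / 5,000 / 1,000 simulations |
| transfer fine-tuning budget | 20 epochs, patience 5, trunk rate x0.1 |
| viable-parameter pilot grid | 300 simulations |
| MC dropout passes (bulk evaluation) | 50 |

Two classifiers are trained because the package's evaluation spans two
noise regimes: the clean-sequencing model is scored on held-out AUROC and
frequency MAE at its own conditions, while the broad-conditions model —
the desk analogue of a model trained across the full noise range — handles
impure, overdispersed samples whose purity-corrected clusters are far wider
than anything in the clean training distribution.

Sampling ranges with rationale (the full-scale study's parameter tables are
not reproduced here; these are this package's defaults):

* `mutation_rate ~ LogUniform(5, 100)` per genome per division — spans
  typical whole-genome somatic burdens up to hypermutator-adjacent rates;
  log-uniform weights decades evenly.
* `p_driver ~ LogUniform(1e-5, 1e-3)` — at ~2 mu (N-1) mutation events this
  yields order 0.1–10 driver events per tumour, so detectable subclones are
  common but not guaranteed.
* `s_mean ~ U(0.5, 3)` — at N = 1000 a subclone must sweep within ~10
  doublings to become detectable, requiring coefficients of order one
  (small-population selection coefficients are not comparable to organismal
  ones; rescaling maps them back).
* `n_clonal ~ U(200, 2000)` — typical diploid clonal burdens at
  whole-genome scale.
* transfer `mutation_rate ~ LogUniform(5, 100)`, depth U(75, 200),
  rho U(0, 0.003), pilot fitness U(1.2, 8) and t_s U(1, 12).

Training-set generation conditions the selection arm on carrying 1–2
detectable subclones (parameter draws that fail to produce one after eight
attempts are redrawn), so the paired classes stay balanced; the neutral arm
of every pair is kept regardless.

## Numerical choices

* Single precision throughout the network; gradients verified against
  numerical differentiation at float32 tolerances.
* Simulators are numba-compiled; fixed seeds give bit-identical tumours.
  Extinction (death rate > 0) retries with a fresh stream, capped at 100.
* The `0.004` detection floor and the truncated-Pareto pairing fast path
  (above) are the only approximations in data generation, and both are
  disabled by default in the public `virtual_biopsy` / `generate_neutral`
  APIs. At the clean-sequencing depths (<= 150x) the floor is
  quantitatively leak-free. At the transfer depths the highest-depth tail
  (>= ~150x) loses part of the sub-floor leakage that would populate the
  lowest one or two histogram bins (measured: ~2-3% of the total histogram
  count at 200x and high mutation rate); the same floor applies to
  training, calibration and held-out data alike, so evaluations remain
  internally consistent.
* KDE peak finding uses first-derivative sign changes on the evaluated
  grid; the Gaussian clonal fit uses the sample mean/SD of VAFs within
  ±0.1 of the peak.
* Equal-tailed intervals use linear-interpolation empirical quantiles; the
  summary clamps the interval to contain the mean (degenerate draw sets).

## What the synthetic data do not capture

Simulations assume copy-neutral diploid heterozygous SNVs, a single
well-mixed exponentially growing population, complete sampling of the
tumour (no spatial structure or biopsy geography), purity-independent
depth, and mutation-independent read noise. Passing the package's checks
therefore demonstrates that the method recovers evolutionary signal *under
its own generative assumptions* — it does not validate robustness to
mis-called copy number, spatial sampling bias, mapping artefacts, or
clustered mutational processes. The conservative calling rule and the QC
filters (>= 100 mutations, >= 60x effective coverage) are the guard rails
for real data, not a substitute for those validations.

## Known limitations

* Two detectable subclones is the expressivity ceiling; three or more in
  the window are flagged, not modelled.
* At desk scale the two-subclone class is rare (~10% of positive pairs) and
  the classifier essentially never calls it; the two-subclone regression
  head is trained and tested but its calls contribute little.
* Frequency estimates degrade at the detectability-band edges (subclones
  near 0.10 merge with the tail, near 0.40 with the clonal cluster); the
  conditional MAE is dominated by those edges. At the desk training sizes
  the correct-call-conditional MAE centres near 0.032 and improves by only
  ~0.002 per doubling of regression training data, so results a few
  thousandths either side of 0.03 are expected run to run; the two-replica
  ensemble is there to keep that number stable rather than lucky.
* Transfer estimates for fitness and emergence time are only meaningful
  for detectable subclones; outside the band errors grow without bound by
  construction.
* Within the detectable band, fitness and emergence time are weakly
  identified from a single VAF histogram: viable (fitness, t_s)
  combinations trade off almost deterministically at a given subclone
  frequency, so desk-scale models regress toward the band's conditional
  mean. Median percentage errors sit near zero, but the *mean* percentage
  error for these two tasks is inflated by the band edges and hovers
  around +-10% at the desk training size, varying by a few points with the
  seed; full-scale training and wide architecture searches are what push
  it decisively below that level.
* The Pareto shape sampling distribution is a documented stand-in, not an
  empirical cohort fit.
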