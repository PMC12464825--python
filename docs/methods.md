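# Methods

This note records the models, conventions and design choices behind
`ladkit`, in the order data flows through the pipeline.

## Coordinates, bins and missing data

All genomic arithmetic is 0-based, half-open. A genome is binned from
position 0 in fixed-width bins (default 20 kb); the final bin of a
chromosome may be partial and is kept, flagged only by its width —
downstream per-bin statistics treat it like any other bin. Missing values
are NaN and propagate; nothing is imputed. BED output follows BED
conventions (the BED score column carries the LAD score × 1000 clipped to
[0, 1000]; exact scores go to a companion TSV).

## Normalization

Reads are counted into bins after a MAPQ ≥ 10 filter; callers supply one
assigned coordinate per read (for real pA-DamID data that is the GATC
fragment end; the synthetic generator emits bin counts directly, so
fragment-end logic lives outside the package). Each library is scaled to
1 million reads and the track is

log2((ab_cpm + 1) / (dam_cpm + 1)).

The pseudocount of 1 floors empty bins at log2(1/1) = 0 and makes the
transform antisymmetric under swapping the antibody and Dam samples.
Z-scaling is computed genome-wide over non-missing bins and is idempotent;
replicate averaging is a per-bin mean that skips missing values, leaving a
bin missing only when all replicates miss it. Whether z-scaling happens per
replicate before averaging or on the averaged track is exposed to the
caller; the pipeline default is per replicate, then average.

## Two-state HMM segmentation

The normalized (usually z-scaled, replicate-averaged control) track is
modelled by a two-state homogeneous HMM. Emissions are Student-t with
df = 3 by default — heavy tails keep isolated outlier bins from dragging a
state's location — with a Gaussian alternative. df is fixed, not
estimated. Fitting is Baum–Welch with scaled forward–backward recursions;
for the t emission the M-step uses the standard latent-scale weights
u = (ν+1)/(ν + z²), which preserves EM's monotone likelihood. Missing bins
receive unit emission likelihood, so the chain crosses them on transition
probabilities alone.

Initialization is deterministic: state locations at the 25th/75th
percentiles of the data, both scales at the overall SD, stay-probability
0.99, uniform start. Two well-separated states need no random restarts.
Identifiability is enforced after fitting by ordering locations — the
higher-location state is the LAD ("inside") state, so negating a track
swaps labels but yields identical boundaries. Convergence is declared when
the log-likelihood improves by less than 1e-6 (default cap 500 iterations;
non-convergence returns the current model with a warning). A scale floor of
1e-4 guards degenerate zero-variance blocks; tracks with overall SD below
1e-10 are rejected.

Segmentation is per chromosome by Viterbi decoding; runs of equal state
become domains, and runs shorter than `min_bins` are iteratively absorbed
into their neighbours (shortest first). Domains are called once on the
control average track and those coordinates are reused for every sample.
The per-domain LAD score is the mean non-missing z value over the domain's
bins.

## Differential LAD testing

Each LAD contributes one score per sample; the design has two conditions
with ≥ 2 replicates each. The test adapts the voom/limma machinery to
continuous domain scores (no counts, no library-size offsets):

1. **Trend.** Per LAD, the two-group residual variance s² (pooled, df =
   n₁+n₂−2) is computed; lowess (span 0.5) of √(residual SD) against the
   row mean score gives the mean–variance trend. Evaluation interpolates
   linearly and extrapolates flat; with fewer than 20 rows of positive
   residual variance the trend falls back to the constant pooled SD.
   Precision weights use the trend at the row mean (not per fitted value):
   in a two-group design the two choices coincide in expectation, and the
   row-mean form keeps the weighted t equal to the ordinary t within a row.
2. **Moderation.** Residual variances are expressed relative to the
   squared trend and shrunk toward a prior: the prior df d₀ and prior
   variance s₀² come from method-of-moments matching on log s²
   (digamma/trigamma; the trigamma equation is inverted by Newton
   iteration). If the observed spread of log s² does not exceed pure
   sampling spread, d₀ = ∞ and all variances shrink fully to the trend.
   The moderated t is delta / √(s²_post(1/n₁+1/n₂)) with df = d_resid + d₀.
3. **Calling.** Two-sided p from the t distribution, Benjamini–Hochberg
   across all tested LADs (via `statsmodels.multipletests`), gain/loss at
   adjusted p < 0.05 by the sign of delta. LADs with any missing sample
   score are excluded and reported.

Setting the prior df to 0 disables moderation and reproduces the ordinary
weighted two-sample t exactly — a useful oracle check. The statistic is
scale-equivariant: multiplying all scores by a constant changes nothing.

One caveat worth knowing: when a perturbation moves a sizeable one-sided
portion of the genome (say 20% of LADs losing contrast), per-sample
z-scaling re-centres the perturbed tracks and every *unaffected* LAD drifts
slightly upward, producing compensatory "gain" calls. This compositional
artifact is inherent to z-score normalization, not to the test; the
acceptance script therefore scores loss calls against the injected losses
and reports gains separately.

## Spike-in calibration

Per sample, the spike-species log-ratio track (recommended bin size 250 kb,
because spike reads are sparse and larger bins stabilize the estimates;
at least 20 non-missing spike bins are required) yields offset b = spike
mean and scale a = spike SD. The full affine transform (x − b)/a — offset
and scale, since the spike is converted to a z-score — is then applied to
the target-species track, which is never re-centred on its own statistics.
Calibrating the spike track by its own factors is exactly the z-scale
operation, which ties the two modules together in tests. Factors are per
sample; no pooling. Species assignment in synthetic data is by label; for
real competitively aligned BAMs it is by reference-name prefix, with the
MAPQ ≥ 10 filter guaranteeing species-unique alignments.

## Border profiles

LAD flanks are border points. A flank within 50 kb of a chromosome end is
a chromosome end, not a border; a flank adjacent to any domain (the LAD
itself or the neighbouring iLAD) shorter than 50 kb is dropped, since such
domains span only a couple of bins. Each genomic bin is assigned to its
single closest border by bin-centre distance — an exact tie goes to the
lower-coordinate border (the tie rule is an artifact decision; ties are
knife-edge events) — so no position is counted twice. The relative
position is the offset of the bin's LAD-facing edge from the border,
signed positive into the LAD (the innermost adjacent LAD bin sits at 0),
and bins farther than the window (default 500 kb) from every border are
unassigned. The profile reports, per relative position, the mean and a
normal-theory 95% CI (mean ± 1.96·SE, defined where n ≥ 2).

## Partition metrics

- **Differential track**: per-bin perturbed − control; inputs are taken as
  z-scores (callers may ask the function to z-scale raw inputs first).
- **De-partitioning slope**: OLS of the differential on the control track,
  with Pearson r and its exact t-transform p. If the perturbation shrinks
  contrast toward the mean by factor k, the noise-free slope is −k; with
  noisy tracks the estimate is steeper than −k because the control appears
  on both axes (regression to the mean) — comparisons between conditions
  measured at similar noise remain valid, but the slope should not be read
  as an unbiased estimate of k.
- **Bimodality**: the verdict is an artifact metric (density plots name no
  statistic): 1- vs 2-component Gaussian mixture BIC plus Ashman's
  D = √2·|μ₁−μ₂|/√(σ₁²+σ₂²), declared bimodal when BIC prefers two
  components and D > 2. D is scale-free, so the verdict is affine
  invariant. A vanishing component (< 2% weight) is degenerate and yields
  a unimodal verdict with a flag.
- **Domain-score comparison**: Welch's t or two-sided Wilcoxon rank-sum
  between LAD and iLAD score lists. Trimming the top/bottom 0.5 percentile
  affects only the returned plotting lists, never the test.
- **Genomic overlap**: exact base-pair intersection reported in Mb
  (symmetric), plus a two-sided Fisher exact test on the 2×2 table of
  fixed-width genome bins classified by membership in each set (the paper
  tests binned sets; the bin is the natural unit). Self-overlap yields an
  infinite odds ratio, reported as +inf; an empty set skips the test with
  a flag.
- **Track correlation**: Pearson over pairwise non-missing bins, with an
  optional boolean concordance mask (e.g. dropping bins whose control
  state disagrees between cell lines).

## Nucleosome linkers and pile-ups

Dyads are assigned to the domain containing them; pairs spanning a domain
boundary are dropped (the conservative reading of intersect-then-pair).
For consecutive within-domain dyads at distance d: if d > 100 bp a full
nucleosome lies between the centres and the linker is d − 147; otherwise
the linker is d itself. Only linkers in [1, 100] bp are retained, grouped
by state. The retained lists are translation invariant by construction.

The scale-regions pile-up treats the track as piecewise constant with
missing (and beyond-chromosome) positions as zero. Flank columns have
native width bs (default 10 kb over 500-kb flanks); the domain body is
divided into body/bs (default 100) equal sub-intervals, each averaged with
area weighting — every output cell is the exact integral of the
piecewise-constant signal over its span divided by the span. Defaults give
50 + 100 + 50 = 200 columns. Domains shorter than one output bin resample
degenerately (flagged). `skip_zeros` optionally drops all-zero rows.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
sequencing reads:

- **Domains**: alternating LAD/iLAD with geometric lengths in bin units
  (mean 1 Mb by default) — the length law implied by the Markov
  segmentation model. Each chromosome is tiled exactly; the initial state
  is a fair coin flip.
- **Counts**: Dam counts are negative binomial (gamma–Poisson; Poisson at
  dispersion 0, default dispersion 0.05) around a log-normal random-walk
  accessibility background shared by the antibody and Dam samples of a
  pair — so Dam normalization has real work to do. Antibody means multiply
  that background by 2^(latent contrast + ε), where the latent contrast is
  μ_LAD = +1 / μ_iLAD = −1 by default and ε ~ N(0, σ_bin²) with
  σ_bin = 0.3 is drawn independently per replicate and bin, acting as
  replicate-level biological noise. Library depths default to 10⁶ reads.
- **Perturbation**: the perturbed condition's latent contrast is shrunk
  toward the genome mean by (1 − k) (de-partitioning) and chosen domain
  subsets receive additive shifts; the affected domain identities are part
  of the ground truth.
- **Spike-in**: a separate spike genome whose latent contrast is drawn once
  and shared by all samples (the calibration method's premise that all
  spike-ins come from one biological sample). Spike library depth is
  f/(1−f) of the target depth, so spike reads are a fraction f (default
  0.20) of each library.
- **Dyads**: within each domain, centres are laid down at the state's
  nucleosome repeat length (plus Gaussian jitter, truncated at 148 bp so
  nucleosomes never overlap); repeat lengths ≤ 147 bp are rejected.

Everything is deterministic given the config seed. What the generator does
*not* model: GATC fragment structure and sequence bias, mappability,
copy-number variation, inter-replicate accessibility correlation, diploid
genomes, cell-cycle or cell-type heterogeneity. Passing tests therefore
demonstrate algorithmic correctness under the assumed statistical
structure, not robustness to every artifact of real libraries.

## Problem sizes in tests and the acceptance script

The acceptance script runs three studies, sized to execute in seconds while
giving stable statistics: a 2 × 30 Mb genome at 20-kb bins (3000 bins,
4 replicates per condition) for segmentation, de-partitioning (k = 0.30)
and linker analysis; the same genome with 20% of LADs shifted by −1 for
differential calling; and a 20-Mb genome with halved perturbed contrast,
deep libraries (2 × 10⁶) and low noise (σ_bin = 0.15, dispersion 0.01) for
the calibration comparison — the calibration demonstration needs the
contrast spread to dominate bin noise, otherwise even naive z-scaling
partially reveals the change. HMM recovery tests use 50 000-bin sequences;
null-calibration tests of the differential module use 500–10 000 LADs with
4 vs 4 replicates.

## Known limitations

- The HMM has exactly two states and no explicit duration modelling;
  domain lengths are implicitly geometric.
- t-emission df is fixed at 3, not estimated.
- The differential model handles exactly two conditions, no covariates,
  and tests domains, not bins.
- Compositional effects of z-scaling (see above) can produce compensatory
  calls under strongly one-sided perturbations.
- The de-partitioning slope is attenuated/inflated by measurement noise as
  described and should be compared across conditions, not read absolutely.
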