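# Methods

## Demographic model and simulator

The core object is a piecewise-constant multi-population coalescent with
migration.  Populations carry diploid sizes per epoch; split events are
merges looking backward in time (the derived deme's lineages join the
ancestral deme); migration is parameterized backward: `m[i][j]` is the
per-generation probability that a lineage currently in deme *i* traces to
deme *j*, so a forward-time rate "from X to Y" enters as `m[Y][X]`.  This is
the convention of standard SFS-inference software, and the simulator agrees
with an independent coalescent implementation (msprime) to total-variation
distance < 0.01 on expected joint spectra at 10⁵ replicates.

Simulation is an exact Gillespie algorithm over epochs (numba-compiled):
within an epoch, pairwise coalescence in deme *i* occurs at rate
k(k−1)/(4Nᵢ) and migration at rate k·m[i][j]; epoch boundaries re-set sizes,
matrices and merges.  Each replicate reseeds the generator from a
counter-derived substream, so any window is reproducible in isolation and
parameter evaluations can share random numbers.

Unprinted pieces of the published fit are fixed once as package conventions:
the merged Northern ancestor keeps Ne-N between the two splits and exchanges
migrants with S at the N↔S rates; the ancestral size applies from the deep
split backward.  The outgroup (a *P. tremula*-like lineage used only for
polarization) splits 5 Myr ago with Ne 100,000 — a round, literature-scale
figure for *Populus* interspecific divergence; polarization quality, not the
outgroup's own history, is what matters downstream.

For genotype-level work a structure-preserving diffusion rescaling is
available (`scaled_model`): dividing all sizes and times by a factor k and
multiplying migration rates by k leaves the genealogy distribution unchanged
up to a global time contraction, so F_ST, SFS shape and every relative
statistic are invariant while per-site diversity shrinks by k.  This matters
because the fitted ancestral size implies ~0.4 differences per site to the
root — enough to saturate a discrete 10-kb infinite-sites window — so the
windowed-scan demonstrations run at 1/50 scale while SFS-based inference
(which never materializes positions) uses the fitted parameters directly.

Mutations follow infinite sites: Poisson numbers proportional to branch
length, distinct uniform positions per window, derived allele carried by the
branch's descendants; REF is ancestral by construction and the truth file
records it.  Windows are independent non-recombining loci by default —
the standard SFS-block idealization.  Real chromosomes recombine within
10 kb, so linked-site correlations here are stronger than in real data;
SFS expectations are unaffected (they depend only on marginal genealogies),
but window-level variances are somewhat larger than a recombining genome
would show.  Intra-window recombination is available (opt-in) as a
Hudson-style ancestral-recombination walk over a 50-segment grid per window
— breakpoints fall between segments, each segment keeping its own marginal
tree — used for LD and ρ̂ validation where only orderings across ρ are
asserted.  The scaled ρ = 4Nc of a window is converted to a per-bp crossover
probability with the first sampled population's current size.

## Composite-likelihood inference

Expected spectra are Monte-Carlo branch-length tensors: each branch adds its
length (in generations) to the joint derived-count class of its descendant
set, jointly over all sampled populations, so one pass yields every pairwise
2D-SFS.  Observed spectra tally derived counts from called genotypes; sites
with missing calls are hypergeometrically down-projected to a fixed
per-population haplotype count (default: the smallest complete count), and
unfolded spectra use only outgroup-polarizable sites.

Two conditionings are provided:

- `composite_loglik` — multinomial over polymorphic classes only.  This is
  the natural choice when only SFS *shape* is trusted (e.g. ascertainment on
  segregating sites), but it cannot identify a lone population's Ne at all
  (the neutral 1/i shape is size-free) and leaves weakly coupled sizes —
  notably Ne-C under the strong S→C migration of this design — with a broad,
  noise-dominated profile.
- `composite_loglik_full` — conditions on total sequence length: a sequenced
  site is polymorphic in class c with probability ≈ μ·L_c (L_c the expected
  branch generations of class c) and monomorphic otherwise.  Absolute θ then
  anchors every size.  The parameter-recovery protocol uses this form, which
  is also how the field's standard SFS tools compute their likelihoods.

The Monte-Carlo likelihood surface is noisy, and naively its maximizer is
biased: E[n log p̂] penalizes classes in proportion to their relative
Monte-Carlo variance (a Jensen effect that shrinks roughly as 1/replicates).
All optimizers are therefore derivative-free with common random numbers
(identical simulation seeds at every θ), and the profile protocol spends
replicates adaptively: a wide 9-point geometric grid at 20,000 replicates
per point, then re-gridded brackets around the running best at 200,000 and
800,000 replicates, ending with a quadratic refinement in log θ.  Expected
proportions are floored at 1/(10·reps·classes) so Monte-Carlo zeros never
produce −∞.  Multi-parameter fits use conditional (coordinate) maximization
over shrinking per-parameter grids; AIC and Akaike weights rank model
families.  Parametric bootstrap re-simulates at the fitted model and refits,
reporting 2.5/97.5 percentile intervals with non-converged refits counted
and excluded.

The parameter-recovery protocol simulates millions of 10-kb windows (8
haplotypes per population; 4M in the reproduction script, 6M in the test
suite).  The study's own SFS drew on a whole-genome, recombining SNP set;
with non-recombining blocks the effective sample is the block count, so
matching that information content takes many more blocks than the study's
physical window count.  One-parameter profiles need per-parameter noise well
under the published bootstrap widths (the narrowest spans about ±1% and sits
asymmetrically around the point estimate), and at these sizes the residual
profile scatter is a few tenths of a percent — part dataset sampling noise,
part Monte-Carlo floor — while the full six-parameter run stays near ten
minutes on one CPU.  The pairwise composite (not the full 3D tensor) is used
throughout: the 729-cell joint tensor spreads replicates too thin and
inflates the Monte-Carlo floor.

## Window statistics

All diversity quantities are per callable site (the synthetic callable
length equals the window span).  θ_W uses each site's own sample-size
harmonic number under missingness; the neutrality tests (Tajima's D with the
standard variance constants, Fay & Wu's H = π − θ_H, Fu & Li's D from
derived singletons) use only sites with complete data since their constants
assume one n, and H and Fu & Li's D require polarization.  Undefined
statistics are NaN, never 0, and NaNs are excluded from summaries and rank
tests; Tajima's D has a small negative finite-sample expectation even under
neutrality, which the tests acknowledge by checking the mean-zero identity
E[π] = E[θ_W] instead.

F_ST is Weir–Cockerham (1984) by default with Hudson (Bhatia et al. 2013) as
the alternative; windows and genome-wide values aggregate variance
components as ratio-of-sums — mean-of-ratios is biased at low S.  d_xy uses
sample allele frequencies and callable-length normalization (the published
analysis weighted by genotype-likelihood posteriors; called-genotype
computation is the documented divergence here), RND divides by the focal
population's outgroup d_xy, and PBS clamps F_ST ≥ 1 to 1−10⁻⁹ with a
warning (slightly negative window F_ST is floored at 0 before the log).
Site classes (fixed difference / shared / private / monomorphic) come from
polarized derived frequencies.

LD uses haplotype r² (the synthetic data are phased; unphased input falls
back to dosage correlation) over pairs farther apart than 1 kb, with windows
thinned to ≤400 SNPs for the quadratic pair cost.  ρ̂ per window is a
least-squares fit of the binned r²-decay to the Hill–Weir (1988)
sample-size-adjusted E[r²] curve — a deliberately simple moment estimator
whose claims are limited to orderings and rank correlations across windows,
not absolute calibration; ρ̂/θ_π is reported alongside.  PCA operates on
mean-imputed centered dosages via SVD.

## Outlier and gene tests

High-differentiation candidates combine the empirical top-1% F_ST cut
(nearest-rank threshold, boundary ties included) with negative Tajima's D —
"negative in either focal population" by default, configurable to
both/focal, since the published rule does not name the population.  The
simulation null re-simulates windows under the fitted demography, computes
F_ST identically, and assigns two-tailed add-one Monte-Carlo p-values
(r+1)/(n+1) with Benjamini–Hochberg FDR per tail; one simulated pool serves
all windows (an exchangeable null).  Under the null the p-values are uniform
(KS-tested) and the q < 0.01 candidate rate stays at its nominal level.

Gene calls take BED intervals (no annotation database): A = sites
polymorphic in the focal population inside the gene, B = sites with per-site
Hudson F_ST > 0.95 between the focal population and the pooled others, HKA
compares A/B to the genome-wide ratio by Pearson chi-square (1 df,
expected-count < 5 flagged), and positive selection requires HKA p < .01
plus PBS at or above the nearest-rank 95th percentile.  Wilcoxon rank-sum
contrasts (exact enumeration when both groups ≤ 8, tie-corrected normal
approximation otherwise) compare outlier windows with the background.

## Numerical and degenerate-input choices

Seeds are single integers; every stage derives per-window substreams below
2³¹ by fixed affine mixing, so identical configuration and seed give
byte-identical outputs (the VCF writer emits no timestamps).  The bitmask
genotype path supports ≤ 64 haplotypes; empty windows, monomorphic windows
and empty outlier sets flow through as NaN/empty rows rather than errors.
Filter order is fixed (multi-allelic → GQ masking → indel flanks →
missingness) and the indel rule is read as "remove SNPs within 5 bp of an
indel", the conventional interpretation of an ambiguous protocol sentence;
the missingness threshold counts genotypes after GQ masking across the whole
sample set.

## Limitations

The synthetic generator omits sequencing error, genotype-likelihood
uncertainty, reference bias and real annotation, so passing tests certify
the statistical machinery, not robustness to those artifacts.  The published
real-data headline numbers (genome-wide F_ST 0.264/0.240/0.091, SNP and
outlier counts, selected-gene totals) depend on the deposited reads and are
represented here only as qualitative orderings on synthetic data — e.g.
F_ST(N,S) > F_ST(S,C) > F_ST(N,C) under the fitted model.  The twenty
screened demographic parameterizations are represented by five family
templates; exact per-model settings are not recoverable from the published
description.  Bottleneck templates default to round fractions of the
current sizes and are fitting *templates*, not published values.
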