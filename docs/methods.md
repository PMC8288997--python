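# Methods

`declinescan` implements a conservation-genomics workflow for detecting and
characterizing recent population decline from diploid resequencing data:
variant filtering, windowed heterozygosity, runs of homozygosity (ROH) with
inbreeding dating, linkage disequilibrium (LD) decay, population structure
(PCA, neighbor-joining trees, median-joining haplotype networks),
joint-site-frequency-spectrum (SFS) demographic inference, and
deleterious-load statistics. Every stage can be driven by the package's own
synthetic-data generators, so the full pipeline is testable without access
to any particular study's raw sequencing data.

## Coalescent simulator

The generator at the core of both the synthetic data and the demographic
inference is a structured-coalescent simulator over independent,
non-recombining loci. Backwards in time, lineages coalesce within a
population at rate k(k-1)/(4N) per generation (N = diploid effective size,
k = lineages present), migrate between populations at the per-generation
per-lineage rates of a (possibly epoch-wise) backward migration matrix, and
are moved wholesale at population-split events; a split also deactivates
the derived population, so no lineage can migrate into a deme that does not
yet exist pastwards of its origin. Population sizes are piecewise constant
between user-declared epoch boundaries. Mutations follow the infinite-sites
model: Poisson-distributed on branches in proportion to branch length, one
per site, with the ancestral allele recorded (REF). Times are in
generations throughout; years appear only when reporting (default
generation time 1 yr). The default mutation rate is 1.47e-8 per site per
generation.

The simulator is validated against msprime as an independent oracle: mean
total branch length agrees within Monte-Carlo error (about 1%) across split
models with and without migration, and single-population output reproduces
Watterson's E[S] and the 1/i unfolded-SFS law.

Recombination is modeled only in the pedigree generator; coalescent loci
are exchangeable and unlinked. This is sufficient for SFS-based inference
(which treats sites as independent) but means LD and ROH behavior must be
exercised on pedigree output, which is how the test suite does it.

## Pedigree simulator and the inbreeding-age formula

The pedigree generator drops whole genomes through an explicit mating plan.
Gametes are formed with Poisson crossovers (no interference) at
map-length/100 expected crossovers per meiosis; founder haplotypes carry
unique labels, so autozygosity is identity of labels, and the simulator
returns the exact identity-by-descent (IBD) tracts alongside marker
genotypes. Physical and genetic coordinates are linked by a configurable
constant, default 1 cM/Mb — the same approximation the ROH-dating formula
uses in the analysis direction.

A consanguineous loop in which the inbred individual sits g generations
below the shared ancestor couple contains 2g meioses, so an autozygous
tract has expected genetic length 100/(2g) cM. The analysis-side formula

    g = 100 / (2 x ROH_length_cM)

inverts this. The loop is closed in the acceptance suite with a
first-cousin pedigree (g = 3): its inbreeding coefficient of 1/16 yields
enough autozygous tracts over 200 replicates x two 100-cM chromosomes for
a stable mean (deeper loops halve F four-fold per generation, leaving too
few tracts at this scale), and the mean detected long-ROH length recovers
g within 25%. Worked values: 2.5 cM -> 20 generations; 1 cM -> 50.

Marker allele frequencies are drawn uniform on (0.05, 0.95), giving a
heterozygous-marker density of roughly one in three outside IBD tracts, so
chance runs of homozygosity are short relative to the IBD tracts of
interest at the default 20-kb marker spacing.

## Sequencing noise

Per-genotype read depth is a gamma-Poisson mixture with mean `mean_depth`
and variance mean x (1 + `depth_dispersion`); allele depths at
heterozygotes are binomial around one half, with sequencing errors flipping
reads at `base_error_rate`; site base quality derives from the error rate
and mapping quality is drawn from a configurable categorical distribution.
Zero-depth genotypes become missing — missing is always a distinct code,
never conflated with homozygous reference. All generators are
bit-reproducible under a fixed seed (byte-identical VCF on rerun).

## Variant filtering

Filters run in a fixed order — scaffold, site quality, depth percentiles,
allele balance — and each stage logs its removals; per-stage counts sum to
input minus output. Conventions that move counts at the margins:

* Allele balance acts per heterozygous genotype: a het whose minor-allele
  read fraction is below 20% is set missing (not the whole site), with an
  inclusive boundary at exactly 0.20. Zero-depth hets are set missing and
  counted separately. A site is dropped only when no called genotype
  remains.
* Depth percentiles (2.5% / 97.5%) use the nearest-rank convention over
  total site depth summed across samples; a per-individual mode exists.
  Re-filtering filtered output is deliberately not idempotent (the depth
  distribution shifts); quality and scaffold filters are idempotent.
* Site quality: base or mapping quality strictly below 20 removes the
  site; missing quality fields count as failing.
* Scaffolds shorter than 100 kb are excluded, as are any explicitly listed
  labels (the label list stands in for alignment-based sex-scaffold
  detection, which is out of scope).

## Heterozygosity

Per individual, He in non-overlapping 50-kb windows is the count of
heterozygous genotypes divided by the window span (not by callable sites; a
callable-sites denominator is available behind a flag). Terminal partial
windows are flagged and excluded from population means to avoid length
bias. Group comparisons use the two-sided Wilcoxon rank-sum test: exact
permutation null when both groups have at most 9 observations without ties,
normal approximation with tie correction otherwise; two identical constant
groups return p = 1 by convention.

## ROH and LD

ROH detection finds maximal runs of homozygous calls (at most `max_het`
embedded heterozygotes, zero by default) spanning at least 10 kb, with
coordinates from the first to the last SNP of the run — not extended to
midpoints between flanking SNPs, a choice that shifts lengths by up to one
inter-SNP gap and is therefore stated here. Missing genotypes neither break
a run nor count toward its SNP support. The SNP-count rule is exposed in
both conventions: `snp_rule="min"` (default) keeps runs supported by at
least 20 SNPs, the standard convention; `snp_rule="max"` keeps runs with
fewer than 20 SNPs, an upper-bound variant for sparse marker sets. The
detector is verified equal to an exhaustive O(n^2) scan on randomized
inputs. Summaries report medium [100 kb, 1 Mb) and long [1 Mb, inf) classes
as Mb totals and genome fractions.

Unphased r^2 is the squared Pearson correlation of alt-allele dosages
(pairwise-complete over missing data); phased mode computes
r^2 = D^2/(p1 q1 p2 q2) from haplotype frequencies. The decay curve bins
pairwise r^2 by distance and reports the first bin whose mean drops below
0.2. LD thinning is greedy left-to-right: a site is dropped when its r^2
with any retained site within the window strictly exceeds the threshold,
a post-condition checked by brute force in the tests.

## Trees, PCA, networks

K2P distance: d = -(1/2) ln[(1 - 2P - Q) sqrt(1 - 2Q)] with transition and
transversion proportions P, Q over columns where both sequences carry an
unambiguous base; a non-positive log argument raises a saturation error
reporting the counts. Neighbor-joining follows Saitou-Nei with the standard
Q-criterion; ties are broken by the lexicographically lowest label pair
(deterministic output), and negative branch lengths are clamped to zero
with the difference moved to the sister branch. Additive matrices are
recovered exactly (verified against random trees and cross-checked against
scikit-bio's implementation). Bootstrap support resamples columns with
replacement and reports the fraction of replicate trees containing each
reference bipartition; replicates whose distances saturate are skipped and
excluded from the denominator.

PCA normalizes each biallelic site by centering at the mean dosage and
scaling by sqrt(p(1-p)); monomorphic sites are dropped and missing
genotypes contribute zero after centering. Axis k is tested against the
Tracy-Widom (beta = 1) law after normalizing the leading residual
eigenvalue by the Patterson moment formulas

    mu    = (sqrt(n'-1) + sqrt(m))^2 / n'
    sigma = (sqrt(n'-1) + sqrt(m)) / n' * (1/sqrt(n'-1) + 1/sqrt(m))^(1/3)

with m the residual eigenvalue count. For the effective marker count n'
the package defaults to the actual number of markers used, which assumes
LD-thinned input: in null calibrations (binomial genotypes, independent
sites) this gives uniform p-values, whereas estimating n' from the first
two spectral moments proved badly anti-conservative under the same nulls
(the estimator runs about two-fold high, pushing every null p toward zero);
the spectral estimator remains available as `n_eff_mode="moments"` for
data with residual LD. Tail probabilities of TW1 come from the Chiani
shifted-gamma approximation (shape 46.446, scale 0.18605, shift -9.84801),
accurate to about 1e-4 over the relevant range.

The median-joining network iterates minimum-spanning-network construction
(Kruskal keeping all within-weight-class ties, plus an `epsilon` slack)
with consensus (majority-per-column) median vectors of triplets adjacent in
the network; new medians with minimal connection cost (within `epsilon`)
are added until no candidates remain. Obsolete medians are then pruned: a
median vector is kept only while it strictly shortens the minimum spanning
structure over the node set, which both removes degree-<3 medians and
guarantees the network is never longer than the spanning tree of the
observed haplotypes. On small instances (up to 5 haplotypes, 6 segregating
sites) the result matches a brute-force minimal Steiner network by
exhaustive enumeration. Sample multiplicities are carried on nodes for
plotting but never influence the algorithm.

## Joint-SFS demographic inference

Polarization: sites where the outgroup is heterozygous or missing are
removed; the ancestral state is the homozygous outgroup allele and the
derived allele increments cell (i, j) for i derived copies in population 1
and j in population 2; cell (0,0) is masked, and exclusions
(outgroup-unusable, unpolarizable, ingroup-missing) are counted. With a
perfect outgroup the result equals the truth-polarized spectrum from the
simulator's recorded ancestral alleles, exactly.

Expected spectra under a model come from the simulator via the
branch-length estimator: the probability of configuration (i, j) is
proportional to the mean total branch length subtending i + j leaves of the
respective populations. This is an unbiased Monte-Carlo estimator of the
same quantity a mutation-dropping scheme targets, at a fraction of the
variance per genealogy.

The composite log-likelihood over normalized cell probabilities is
CL = sum m_ij ln max(p_ij, pseudo), natural log, with zero cells floored at
pseudo ~ 1/(10 x cells x sites) to stay finite. A shape-only CL cannot
separate absolute sizes from times, so model fitting defaults to the
Poisson objective: expected per-cell SNP counts
lambda_ij = mu x L x E[branch length], CL = sum m_ij ln lambda_ij -
lambda_ij, which pins the absolute scale through the observed number of
polymorphic sites under the fixed mutation rate. The multinomial objective
remains available.

Fitting is bounded, multi-stage, and uses common random numbers (the same
genealogy seeds at every evaluation) to freeze the Monte-Carlo noise into a
smooth surface:

1. a Sobol scan of the parameter box at the base simulation count;
2. Nelder-Mead (or cyclic one-dimensional "ECM-like" maximizations,
   20-40 cycles) from the best scan points at 10x simulations;
3. response-surface refinement: the likelihood is evaluated at Sobol points
   in a local box with *independent* seeds, a full quadratic is fit by
   least squares, and its constrained maximizer re-centers the box —
   repeated while the maximizer lands on the box edge (walking along soft
   ridges), then once more with a halved box.

Stage 3 exists because frozen common-random-number noise displaces the
optimum of the surface along weakly-identified ridges (here the split-time
/ migration trade-off); regression over independently-seeded points
averages that noise away instead of freezing it. Sizes and times are
searched on log scale, migration on linear scale.

AIC = 2k - 2 CL with natural logs. Because Monte-Carlo CLs from separate
optimizer runs carry independent evaluation noise larger than the AIC
penalty, model comparison re-evaluates every candidate model's CL at its
point estimates under one shared set of genealogy seeds, averaged over
several seeds (`revalidate_cl`), before ranking. Confidence intervals are
parametric-bootstrap percentiles: spectra re-simulated under the point
estimates, each refit (keeping the better of the configured refits), with
flags for unreliable (> 20% non-converged refits) and degenerate
(< 10 bootstrap spectra) intervals.

Desk-scale study conditions used by the tests and the acceptance script
(in place of production-scale runs of the source method): two populations
of 4 diploids each, 2000 loci of 10 kb for parameter recovery
(truth Ne = 5000, T = 3000 generations, m = 1e-4, i.e. 4Nm = 2); model
selection uses 2 + 2 diploids and 3000 loci of 1 kb — short loci keep
within-locus SNP correlation negligible, matching the independent-sites
assumption of the composite likelihood (with long multi-SNP loci the
spurious-parameter gain of a nested alternative is overdispersed beyond the
AIC penalty, and AIC over-selects; this is a property of composite
likelihoods, not of the optimizer). Recovery of (Ne, T, m) is within 25%
on every seed tried, typically within 5-20%.

## Genetic load

Ancestral states for load analyses use the two-species rule: the allele
homozygous in more than half of the focal species' individuals (strict;
`count_mode="chromosomes"` switches the criterion to allele frequency
> 50%) that is also the fixed homozygous state of the sister species.
Sites failing either condition are excluded with reasons counted.

Coding effects are classified against single-transcript gene models in
transcript orientation (reverse-complement on the minus strand) with the
standard genetic code: stop-gained is nonsense; amino-acid change is
missense; silent is synonymous; variants within the canonical 2-bp
intronic donor/acceptor windows (configurable) are splice-disrupting.
Nonsense and splice-disrupting form the loss-of-function (LOF) class.
Missense severity uses the Grantham physicochemical distance; scores >= 150
are flagged deleterious. The canonical published 190-pair matrix is the
authoritative lookup; recomputing the distance from the published
composition/polarity/volume constants agrees within one rounding unit for
188 of 190 pairs (Asp-Trp and Glu-Asn are known departures of the original
table from its own formula, and are kept at their published values).

The load statistic per individual and category is
2 x Hom / (2 x Hom + Het) over derived genotypes (two derived copies per
homozygous site, one per heterozygous site); it is undefined (NaN) for an
individual carrying no derived allele in the category. Gene-level burden
counts distinct genes with at least one homozygous-derived deleterious
variant inside one of the individual's ROHs. Population screens keep
variants with |derived-allele-frequency difference| strictly greater than
0.2, frequencies computed from non-missing genotypes only.

## Pipeline

`run_pipeline` executes filter -> diversity -> ROH/LD -> structure ->
demography -> load from one validated config (file inputs or a synthetic
scenario block), writing every artifact plus a JSON manifest with SHA-256
hashes, stage parameters and stage seeds. The global seed is split
deterministically per stage name, so toggling one stage never changes
another's randomness; reruns of an identical config produce hash-identical
manifests. A stage with missing inputs (e.g. no gene models) is skipped
with a logged reason; a failure halts the run naming the stage and leaving
the partial manifest. Internally all coordinates are 0-based half-open;
VCF and GFF3 conversion happens at the I/O boundary.

## What the synthetic data do not capture

The generators emulate the statistical structure the analyses assume —
not raw sequencing. There is no read-level simulation (no FASTQ/BAM, no
alignment or duplicate artifacts), no selection, no recombination within
coalescent loci (no ancestral recombination graph), and gene models are
single-transcript with clean splice sites. Passing tests therefore
demonstrate correctness of the implemented statistics under their own
model assumptions and calibrated behavior at desk scale; they do not
certify robustness to alignment artifacts, reference bias, or
recombination-rate variation in real data.

## Numerical choices and degenerate inputs

Tolerances: NM stages stop at xatol ~ 1e-3 (log-parameter units) or a
0.05-CL-unit plateau; the quadratic refinement validates candidate optima
at 4x simulations before accepting them. Percentiles are nearest-rank.
Boundary conventions are inclusive for the 20% allele-balance fraction,
strict for the >50% ancestral-majority rule and the >0.2 frequency
difference. Degenerate inputs are defined rather than accidental: empty
groups raise, identical constant groups compare at p = 1, zero-length ROHs
cannot be dated (error), monomorphic locus pairs are skipped and counted in
LD, fewer than 40 sites triggers a depth-percentile instability warning,
and an unreachable coalescence (populations never connected by migration or
splits) raises an error naming the populations.
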