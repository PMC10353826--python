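# Methods

`selfingpop` re-implements, as a tested library, the computational stages of
a population-genomic analysis of a panel of highly self-fertilizing plant
strains: masked pairwise distances and structure, windowed diversity and
differentiation statistics, a composite-likelihood sweep scan with
simulation-based thresholds, a forward simulator of hard sweeps under
partial selfing, a PCA-based differentiation-outlier scan, and a gene-level
truncation-allele caller.  This note records the models, the parameter
choices that matter, the numerical conventions, and what the synthetic
experiments do and do not demonstrate.

## Data model and conventions

Strains are treated as haploid: in a predominantly selfing species each
strain contributes a single genome, so diploid VCF genotypes collapse as
0/0 → 0 and 1/1 → 1.  Residual heterozygous calls are ambiguous under this
treatment; the default maps them to missing, configurable to either
homozygote.  All internal coordinates are 1-based inclusive (VCF
convention); BED masks are converted on read and merged.  Pairwise r² is the
squared Pearson correlation of haploid allele indicators over
pairwise-complete observations.

## Masked pairwise genetic distances

The distance between two strains is (number of sites where both calls are
known and differ) / (number of genome positions unmasked in both strains).
The denominator needs per-sample masks and chromosome lengths; without
masks the package falls back to the jointly observed SNP count (a different,
larger-valued statistic — only comparable within one analysis).  Pairs with
no joint coverage are NaN, never 0, and are excluded (with a log record)
from MDS and clustering rather than imputed.

Relatedness filtering walks pairs in ascending distance; at or below the
threshold (default 0.0007, the regime of recent common selfing descent) the
member with more missing data is removed, ties broken by lexicographically
later sample id, making reruns deterministic.  The retained set is maximal:
re-adding any removed strain re-creates a close pair.

Classical MDS is Torgerson double-centering of squared distances with an
eigendecomposition; coordinates come from the top-k non-negative
eigenvalues.  Hierarchical clustering defaults to complete linkage
(configurable to average/single).  Mode detection of the distance
distribution uses a Gaussian KDE with Silverman's bandwidth and reports
local maxima whose basin mass exceeds 1% of pairs; bin width, bandwidth and
linkage are all free choices documented here because the upstream analysis
did not fix them.

## Diversity statistics

Windows tile each chromosome half-open, `[start, start+span)`, starting at
position 1.  Per-site nucleotide diversity uses pairwise-complete sample
sizes, 2c(n_s−c)/(n_s(n_s−1)); the window denominator is the masked-aware
callable-position count when masks are supplied (positions unmasked in
every sample), else the plain window length.  Tajima's D uses the canonical
1989 constants on complete-case sites (so n is fixed within a window) and
is reported as missing, never 0, for windows without segregating sites.
The Weir & Cockerham (1984) estimator treats haploid strains as homozygous
diploids (observed heterozygosity 0) and reports the weighted window
estimate Σa/Σ(a+b+c); an optional per-window SNP floor (700, matching the
practice of excluding alignment-gap windows) drops sparse windows.  Sites
with missing calls are dropped for the SFS and FST (explicit
complete-case); both all-site and complete-case behaviour are available for
π via the pairwise-complete rule.  Exon or pericentromere exclusion is a
generic interval-exclusion step consuming a BED-derived interval list.

Polarization flips sites where the outgroup carries the alternate allele
and drops sites with missing or third-state outgroup calls (counted).

## Composite-likelihood sweep scan

The scan follows the star-like hard-sweep approximation: at recombination
distance d from a sweep of strength α, each of the n sampled lineages
escapes the sweep independently with p_e = 1 − exp(−αd); non-escapees
coalesce into the single sweeping ancestor.  With k escapees the ancestral
sample holds m = k + [k<n] lineages whose derived count j′ follows
hypergeometric downsampling of the background spectrum q from n to m; the
ancestor is derived with probability j′/m, giving a modern count
b = j′ + (n−k−1) if derived, else j′.  The transition matrix M[k, b] is
precomputed once per background spectrum, so evaluating the model for any
(d, α) is a binomial mixture over k.  CLR(x) = 2[max_α Σᵢ wᵢ log P(bᵢ|dᵢ,α)
− Σᵢ wᵢ log q_{bᵢ}], with the background itself always a candidate (CLR ≥ 0).
Weights default to 1; monomorphic positions can enter the scan as grid
sites each standing for the invariant positions between observed SNPs
(`scan_sites_from_matrix`), which mirrors running the scan "including
monomorphic sites" without enumerating every base.  When invariant classes
are excluded, both q and the sweep spectrum are renormalized over 1..n−1.

Distances are physical by default (α absorbs a uniform rate); a
piecewise-constant map (arm vs pericentromere rates) can be supplied so the
scan works in recombination distance.  The α grid is 40 log-spaced values
spanning "1% escape at the largest site distance" to "99% escape at the
smallest site gap" — wide enough to bracket any realizable footprint.
Thresholds are the 95th percentile (linear interpolation) of per-replicate
maximum CLR over neutral simulations.

## Forward simulation of sweeps under partial selfing

A diploid Wright–Fisher population of N individuals evolves on one
chromosome.  Each offspring selfs with probability σ (default 0.95), else
draws two random parents; viability selection on the selected site uses
fitnesses 1, 1+hs, 1+s (rejection against the maximum fitness), with h = 0
by default (recessive beneficial).  Gametes draw crossovers Poisson per map
segment with uniform breakpoints, and new neutral mutations at rate μ per
bp (infinite sites, continuous positions; collisions are measure-zero and
deduplicated on integer export).  The selected allele enters as a single
copy t_intro generations before present; runs that lose it or end below the
acceptance frequency (0.7931, the empirical carrier frequency of the focal
truncation allele) are discarded and re-run with a fresh random substream.
Retries reuse the replicate's neutral burn-in state — only the sweep phase
is conditioned — which is an efficiency choice, not a change of the
conditional distribution being sampled.

Burn-in runs 10·N generations of neutral forward evolution from an empty
population instead of coalescent recapitation; equilibrium is verified by
the Watterson-expectation check in the test suite.  The neutral burn-in
prunes fixed derived columns (making its end state the polarization
baseline); the sweep phase keeps them, because alleles dragged to fixation
by hitchhiking are part of the footprint signal an outgroup-polarized scan
sees.

Full-scale parameters follow the study system: chromosome length
18,747,412 bp; arm recombination rate 9.944×10⁻⁸ and pericentromere
4.945×10⁻⁹ per bp per generation; μ = 4×10⁻⁹; selected site at
11,100,000 bp at the distal pericentromere edge; onset grid 16,030 down to
1,030 generations; selection grid 0.001/0.01/0.1; 12 replicates per cell.
The census size is not printed in the source material; the package sets
N = 60,000 so that the selfing-adjusted effective size N/(1+F) ≈ 31,000
reproduces the focal population's observed per-site diversity
(π ≈ 5×10⁻⁴ at μ = 4×10⁻⁹).  The pericentromere span (5.0–11.2 Mb) is
likewise a package choice consistent with the selected site sitting at its
distal edge.

Desk-scale work uses population rescaling by Q (N→N/Q, gen→gen/Q, s→sQ,
μ→μQ, r→rQ; θ and ρ invariant), default Q = 120 giving N = 500.  Rescaling
compresses sweep durations toward the outcrossing timescale (an outcross
every ~1/(1−σ) = 20 generations), which distorts the escape process for
strongly selected alleles — rescaled sweeps finishing in fewer generations
than an outcrossing interval drag essentially the whole chromosome.  Two
presets manage this: `desk_preset` shrinks the full-scale chromosome
(coordinates proportionally, rates by Q only) and is intended for
diversity-level work; `footprint_preset` is a uniform-map chromosome with a
centred selected site used by the footprint and localization experiments.
The experiment drivers state their problem sizes explicitly: 20 neutral
burn-in replicates of a 200 kb chromosome shared by the calibration and
localization experiments, and 5 replicates × 3 selection coefficients on a
100 kb chromosome with a 10× map for the footprint-vs-s experiment (the
larger map keeps even the strongest sweep's footprint inside the
chromosome).

## Sweep-footprint estimators

The window rule takes the mean diversity of windows inside a distal
reference region as a threshold and reports the maximal contiguous run of
windows strictly below it containing the selected site's window; ties count
as not swept, and a selected window at or above threshold yields size 0
with a flag.  The piecewise-linear estimator fits, per flank, a flat
baseline, a linear ramp descending toward the valley and a flat floor
(breakpoints grid-searched over window positions, levels in closed form);
the two outer breakpoints delimit the footprint, and a flank whose ramp
fails an F-test against the flat fit (α = 0.05) puts its boundary at the
chromosome end, flagged.  A single-breakpoint hinge cannot represent a
valley with a floor, so the three-segment flank model is the consistent
reading of "piecewise-linear regression of diversity on position".

The monotonicity experiment additionally guards the window rule's
assumption: if the reference region itself lost more than half of its
pre-sweep diversity (measured against the same replicate's burn-in state),
the footprint is recorded as chromosome-sized, because no unswept baseline
exists within the replicate.

## Sweep-localization experiment

Each replicate conditions a sweep (s = 0.001 full-scale, onset 8,400
generations ≈ 70 rescaled) to end at or above the empirical 79.31%
frequency — the scanned sweep is typically still segregating, as in the
study population — then scans a 40-haplotype polarized sample (fixed
derived sites retained, monomorphic grid sites included) over interior test
positions (5–95% of the chromosome, avoiding one-sided edge windows).  The
background spectrum is pooled over the pre-sweep states of all replicates
with 0.5 pseudocounts on variant classes: the analog of the precomputed
genome-wide spectrum the scan expects, since a single short chromosome
whose swept fraction is large would contaminate its own background.  A
replicate counts as localized when the global CLR argmax falls within 10%
of the chromosome length of the true site.  Under 95% selfing, neutral
haplotype blocks produce sweep-like CLR peaks (the known confounder in
selfers — also the reason the original analysis calibrated significance on
neutral simulations), so localization is a statistical property, not a
per-replicate guarantee.

## PCA differentiation-outlier scan

Genotypes are centered and scaled by √(p(1−p)) with mean imputation of
missing entries; a truncated SVD (optionally after greedy LD clumping at
r² = 0.1) yields K orthonormal score vectors.  Every site — clumped or
not — is regressed on the scores; the K z-scores are summarized by a
Mahalanobis distance with a zero centre (the z-scores are centred under
the null by construction, and a zero centre makes the statistic invariant
to per-site allele flips).  The default robust scale is a per-component
median-|z|/0.6745; a full second-moment covariance is optional.  The
genomic inflation factor λ = median(stat)/median(χ²_K) recalibrates the
χ²_K upper-tail p-values.  Because empirical p-value distributions of such
scans on structured panels are U-shaped, the primary output is the
rank-based top-k set (default k = 1,000); p-values are secondary.  K is an
explicit argument — choosing it from a scree plot is the analyst's
judgment, not automated here.  Outlier-region PCA re-fits on the outlier
sites only, without clumping, and labels samples by user-supplied
half-plane rules ("PC1 < 0 and PC2 > 0.07"), first match wins, "other"
otherwise.

## Truncation-allele caller

A strain's allele is rebuilt by applying its variants left-to-right with
offset bookkeeping (ref fields validated; overlaps rejected), splicing the
(possibly shifted) CDS — interval edges deleted by indels move inward,
insertions inside intervals are retained — and translating to the first
stop.  Classification: truncated if a variant hits the two intronic bases
at an exon-intron boundary (canonical GT/AG positions), alters the ATG, or
the product is strictly shorter than 90% of the reference protein (exactly
90% stays functional — the boundary is flagged as a choice, not an
inference).  Cause precedence is start_loss > splice_site >
premature_stop/short_protein; frameshifts classify by their downstream
consequence.  Truncated alleles are named prefix + genomic position of the
causal polymorphism (the 5′-most variant that alone truncates, falling
back to the 5′-most variant for combination effects).

## Synthetic data

The Balding–Nichols generator draws, per site, an ancestral frequency
p ~ U(0.05, 0.95) (bounded away from 0/1 so small panels keep all classes),
per-population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F the target
FST (F = 0 short-circuits to p exactly), haploid Bernoulli alleles, and
i.i.d. missingness.  The relict panel gives two ordinary groups and a
diverged subgroup calibrated so same-group distances sit near 0.004 and
relict-involving pairs near 0.008 (the divergent-founder site count is
exact, not binomial, to keep the modes on target).  Mask fixtures place
random intervals to a target density; the toy gene fixture designs a
three-exon, 199-residue gene whose strain set covers every classification
branch, including a frameshift whose shifted reading frames hit designed
stop codons and a late stop leaving a 91%-length (functional) product.
Both strands are supported by exact mirroring.  All generators are
bit-reproducible from (config, seed) and writable in the standard formats
their consumers read.

What these fixtures do not emulate: linkage disequilibrium within
populations (Balding–Nichols sites are independent), mutation-model detail
(no triallelics, no indel spectrum), gene conversion, or real missingness
structure (which is depth- and repeat-correlated, not i.i.d.).  Passing
tests therefore demonstrate correctness of the estimators under their own
assumptions and recovery of known truth, not robustness to every artifact
of real resequencing data.

## Numerical choices and limitations

- The simulator's per-generation engine is vectorized with two numba
  kernels (gamete transmission; mutation merge), verified against naive
  references in the suite.  Determinism is exact given (params, seed).
- Escape-probability overflow in the sweep model clamps αd at 700 before
  exponentiation; spectra are clipped at 1e-300 before logs.
- MDS truncates k to the number of positive eigenvalues (warning).
- The window-rule footprint uses strict inequality (ties = not swept).
- Percentiles use numpy's linear interpolation.
- Proportions round half-up (decimal arithmetic, not banker's rounding).
- Q-rescaling at Q = 120 is aggressive; it preserves θ, ρ and expected
  diversity (verified by the calibration experiment) but compresses sweep
  durations relative to the outcrossing interval, making desk footprints
  blockier and whole-chromosome hitchhiking more likely than at full
  scale.  Conclusions about footprint sizes at desk scale are therefore
  qualitative (ordering, trends), never quantitative transfers to the
  full-scale system.
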