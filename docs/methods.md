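# Methods

## The analysis

popgenpipe implements the classic polymorphism-versus-divergence toolkit
for a small diploid cohort aligned to a reference, with an outgroup
genome and annotation. The central idea is to contrast putatively
selected site classes (0-fold degenerate exonic sites, conserved
noncoding elements) with matched neutral standards (4-fold degenerate
sites, CNE flanking sequence): purifying selection depresses both
diversity π and divergence *d*, but because slightly deleterious alleles
can segregate while almost never fixing, the ratio π/*d* is *elevated*
at selected sites relative to neutral ones whenever weak effects
dominate. Tajima's *D* adds an orthogonal axis: a recent population
contraction removes rare variants preferentially and pushes *D* upward,
toward or past zero.

### Filter stack

All denominators derive from a callability mask. A site passes iff, in
order:

1. site QUAL ≥ 23 (applied to variant and invariant sites alike — the
   threshold is meant to be chosen from the invariant-site score
   distribution, which implies both are scored);
2. inbreeding coefficient F = 1 − H_obs/H_exp ≥ −0.8, evaluated only
   when ≥ 10 samples are called (fewer calls → F is absent, the filter
   abstains). Exclusively heterozygous sites (F = −1) are collapsed
   paralog candidates;
3. each called sample's depth within 25–300 % of that sample's modal
   coverage — offending *samples* are set missing rather than failing
   the site, keeping the per-sample and site-level filters composable;
4. the mean over all samples of depth/modal within 50–140 %;
5. ≥ 3 of 12 samples still called.

Positionally applied, independent of genotypes: indel flanks (deletion
of length L at [p, p+L−1] masks [p−1, p+L]; insertion of length L
between p and p+1 masks [p−L, p+1+L] — the insert has no reference span,
so the mask is symmetric about the insertion point and its width is
configurable), CpG-prone positions (preceded by C or followed by G in
*any* of the supplied sequences), and optionally the proximity filter:
any variant with another *original* variant closer than md = 5 bp is
removed, with no cascade (removals never rescue neighbours) — it guards
against misalignment clusters and is applied only to analyses that are
sensitive to false positives. The mask records the first failing reason
per site, so #pass + #fail always equals the positions considered and
filter monotonicity can be audited from the stage log.

Modal coverage ties break to the smaller depth (conservative against
duplications). Multi-allelic SNVs fail with their own reason: the folded
SFS machinery downstream assumes biallelic sites.

### Site classes

Transcripts contribute only when complete: assembled CDS (minus-strand
transcripts reverse-complemented) starts with ATG, ends in a stop, has
length divisible by 3, no internal stop. Degeneracy at each codon
position is the count of synonymous single-base substitutions, mapped
0 → fold0, 1 → fold2, 3 → fold4; 3-fold positions (e.g. Ile third
positions) fit none of the reported classes and are excluded. A
position keeps its class only if *all* valid transcripts containing it
agree; disagreement or coverage only by invalid transcripts are distinct
exclusion reasons. Stop codons are treated as encoding a 24th "amino
acid", so the terminal stop's third position can be 2-fold.

CNE sets come in three variants: `noOverlap` (exon-overlapping segments
trimmed away, possibly splitting an element), `strict` (any overlapping
element dropped), `noOverlap_lt1kb` (noOverlap, elements ≥ 1 kb dropped;
the default for within-CNE statistics since rare long, weakly conserved
elements would otherwise dominate). The neutral flank reference for a
CNE [s, e) of length L is [s−500−⌈L/2⌉, s−500) plus [e+500, e+500+⌊L/2⌋)
— anchored exactly at 500 bp, ceil upstream / floor downstream for odd L
— minus anything overlapping exons or any element of the full noOverlap
set. Flanks are not slid outward when masked; a fully masked flank is
simply absent.

### Statistics

Per-site heterozygosity is 2j(n−j)/(n(n−1)) with j the minor-allele
count among n called alleles; class π divides the sum over segregating
sites by *all* accessible class sites, so per-site rates are comparable
across classes. Divergence compares the outgroup base to the ingroup
major allele (ties to the reference allele); positions without an
outgroup base drop out of numerator and denominator.

Because the 3-of-12 calling threshold leaves n varying across sites,
spectra are projected to a common haploid size n_proj (default 6 =
2 × min_called; 24 when call rates allow) by hypergeometric
downsampling, folding after projection; expected counts accumulate as
real numbers and each site's projection mass sums to 1. Tajima's *D*
uses the standard a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂ constants on the
projected spectrum; S = 0 is an explicit error, not 0.

Bootstrap intervals are percentile (not BCa), 1,000 replicates,
resampling transcripts for exonic classes and nonempty 1 Mb windows for
CNE classes; an error is raised if the statistic is undefined in more
than 10 % of replicates.

μ = d/(2·T·g) converts neutral divergence over a split of T years at g
generations/year into a per-generation rate (two lineages accumulate
substitutions); Nₑ = π/(4μ). Both are straight inversions of neutral
theory identities and inherit all of their assumptions (neutrality of
the reference class, clocklike divergence, equilibrium).

### Flank profiles and blurring

Each eligible site — mask-passing, not inside a feature, not a member of
another analysis class — is counted once, in the bin of its distance to
the *nearest* feature. Distances are base-to-base (a site or element
edge immediately adjacent to a feature has distance 1) and bin b covers
(b·w, (b+1)·w]. Defaults: 1 kb bins to 100 kb for exon flanks, 100 bp
bins to 5 kb (or 20 kb) for CNE flanks.

The CNE→exon distance kernel is the normalized histogram (100 bp bins,
capped at 200 kb) of each CNE's distance to its nearest exon. Convolving
the 100 bp-binned exon-flank π profile with it — out[i] = Σ_k kernel[k]
· in[i+k], input right-padded with the mean π over the 60–100 kb range —
predicts the diversity reduction CNE flanks would show if it were caused
solely by CNEs sitting near exons. Far-field slopes (weighted OLS of
per-bin π on bin midpoints over 5–20 kb, weights = site counts) make the
comparison quantitative.

### LD decay

r² between two sites is the squared Pearson correlation of diploid
dosage vectors over samples called at both (no phasing); pairs with
fewer than two complete observations or a constant vector are skipped
and counted. Around each focal SNP, partners within 40 kb (20 kb for
high-diversity cohorts) pool into 20 bp bins. With all SNPs focal each
unordered pair counts once; with a restricted focal set (exonic / CNE
SNPs) both directions are scanned but focal–focal pairs still count
once. If one focal window exceeds n_max pairs (default 750) they are
subsampled without replacement, seeded.

Curve fits minimize pair-count-weighted least squares. The stretched
exponential g(x) = (a−c)·exp(−(x/b)^d) + c arises naturally when LD
decay is a mixture of exponentials with varying local recombination
rates; it is fitted from a deterministic multistart grid
(b ∈ {100, 300, 1000, 3000, 10000} bp × d ∈ {0.3, 0.5, 0.7, 0.9})
because these fits are badly initialization-sensitive, with b optimized
on a log scale and bounds 0 < d ≤ 1, c ≥ 0. Refits with d pinned at 0.5
make b comparable across cohorts. Two identifiability guards keep the
near-flat (null) regime sane: c may not exceed the observed curve
maximum, and b may not exceed 10× the data span (beyond which the model
is indistinguishable from a line). The offset's sampling floor for n
diploids is 1/(n−1); on permuted genotypes the fitted c should sit
there.

### Export encodings

The diploid heterozygosity track is encoded per 100 bp bin as K (≥ 1
het), T (none), or N (< 10 % of the bin called), FASTA-like, wrapped at
60 columns — the input format of sequential-coalescent demographic
inference. Genotype-quality (≥ 20) and cohort-calledness (≥ 10/12)
prerequisites are the caller's responsibility upstream. The DFE input
file carries a dataset count, the haploid sample size, neutral then
selected folded spectra padded with zeros to n+1 entries, and
`class n_sites n_diffs` divergence lines; counts are integerized by
largest-remainder rounding, which preserves totals, and the format is
validated by round-trip (program-version conventions for the divergence
block vary).

## The simulator

A forward Wright–Fisher model, chosen over coalescent machinery so
selection and demography compose without approximation: discrete
generations, diploid sizes per epoch (most ancient first; the oldest
epoch runs ≥ 10·N generations as burn-in), Poisson(μL) mutations per
gamete at uniform positions with infinite-sites approximated by
flip-on-remutation (keeps every site biallelic, matching the pipeline's
assumptions), Poisson(rL) crossovers per gamete, and viability selection
multiplicative across sites with semidominance h = 0.5 fixed
(fitness ∏(1 − s·dosage/2)).

The outgroup is emitted independently as a Jukes–Cantor process with
per-site load 2μ·t_split (observed difference probability
(3/4)(1 − e^(−(8/3)μt)), saturating at 3/4). At selected positions the
substitution rate is multiplied by the relative fixation probability of
a semidominant deleterious allele, γ/(e^γ − 1) with γ = Nₑs — Kimura's
result — so selected classes show the d-suppression the analysis is
meant to detect. Within `simulate_cohort`, selection follows codon
degeneracy of the generated reference (0-fold s, 2-fold s/2, 4-fold 0,
CNE s), which is what makes 4-fold sites and CNE flanks behave as
neutral standards.

Default study conditions (`CohortConfig`): 12 diploids sampled from a
population of 120 that contracted 10-fold to 12 for ~12 generations
(about one bottleneck-N — long enough to distort the folded SFS upward,
short enough not to re-equilibrate at the small size); per-site
θ = 4Nμ = 0.0015; ρ = θ; Nₑs ≈ 5 on 0-fold and CNE positions; CNEs
placed near exons with probability 0.5 at exponential (2 kb) gaps, to
exercise the blurring analysis; neutral outgroup divergence 14.2 %.
Cohort noise: per-sample-site depth ~ NegBin(mean 30, dispersion 5),
site QUAL ~ mixture(3 % U[5, 22], 97 % U[30, 1000]), genotypes masked
missing at 2 % — invented distributions whose only job is to give every
filter something to reject.

**What the generator does not emulate:** alignment and calling error
(QUAL/depth are independent of genotype truth), linked-selection
geometry at real genomic scales, gene conversion, mutation-rate
heterogeneity (CpG effects exist only through the masking filter),
population structure, and chromosome-scale lengths. Passing tests
therefore validate the *estimators and their calibration* on data whose
generative process is known, not the biological claims one would make
from real cohorts.

## Problem sizes and numerical choices

Replicate checks use 2 kb loci (N = 100–120, θ = 0.005/site, 200
neutral replicates, 100 paired contraction replicates, 100 selection
replicates); end-to-end runs use 60–300 kb cohorts. These sizes put
coalescent-expectation checks within a few percent while keeping the
suite and the acceptance script in the minutes range. Bootstrap default
stays at 1,000 replicates. Curve-fit tolerances: kernel weights must
sum to 1 within 1e-9; noiseless parameter recovery is asserted at 1e-4
relative; dual-implementation oracles at 1e-12.

Degenerate inputs are errors, not silent zeros: Tajima's *D* with S = 0,
class π with no accessible sites, divergence with no outgroup-covered
sites, modal coverage with all mass at depth 0, LD fits with too few
nonempty bins.

## Known limitations

- Tajima's *D* under variable per-site n is computed on the projected
  spectrum; per-n stratification or complete-case restriction would give
  slightly different values (the choice is configurable via n_proj).
- The insertion-mask span rule is one reading of an ambiguous
  convention; it is configurable at the record level.
- The n_max pair budget is applied per focal-SNP window; other readings
  (per window side, global) would change bin occupancy at high SNP
  density.
- The fixation-rate scaling of outgroup divergence treats selected sites
  independently; linked effects on divergence are absent.
- `run_pipeline` assumes one chromosome per FASTA record and analyses
  the first; multi-chromosome inputs are handled by running per
  chromosome.
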