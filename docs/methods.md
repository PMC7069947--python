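# Methods

`tetradiv` re-implements, as a tested pipeline on synthetic data, the
analysis chain used to characterise genetic diversity in a recently formed
allotetraploid crop: subgenome partitioning of an assembly by parental
k-mer sharing, homoeolog-aware variant calling for reduced-representation
(GBS) data, population diversity statistics, and coalescent simulation of
single-founder demographic scenarios.

## The problem

An allotetraploid carries two diverged subgenomes (here called *canephora*
and *eugenioides* after the model system's progenitors). When short reads
from the tetraploid are aligned to a single subgenome, every fixed
difference between subgenomes (a **hemi-SNP**) produces a spurious
"heterozygous" signal at ~0.5 allele fraction in every individual. Unless
masked, these dominate the variant list and swamp the species' real — and
in this system extremely low — allelic variation.

## Subgenome partitioning (`kmer_subgenome`)

Scaffolds are classified by comparing their distinct canonical 51-mers
(repeat-masked windows excluded: any window touching a lower-case or N base
is skipped) against k-mer profiles from reads of the two parental species.
A scaffold is assigned to the parent sharing more 51-mers; it stays
unassigned if fewer than 1,000 k-mers are available or the shared counts
differ by less than 10% relative (`|a−b|/max(a,b)`, which is scale-free;
ties give 0 and are unassigned). Sharing is presence-based (a k-mer counts
as shared if the parent profile contains it at all).

Sequencing depth is estimated from the k-mer spectrum as
`N = M·L/(L−K+1)` with `M` the modal k-mer multiplicity above a
low-multiplicity error cutoff (default 5), `L` the read length and `K` the
k-mer size; genome size is sequencing yield divided by `N`. The modal peak
of a wide multiplicity distribution is intrinsically jittery at low
coverage; the closure test therefore uses uniformly tiled reads, for which
the identity is exact up to edge effects.

## Composite references and replacement detection (`homoeo_reference`)

Hemi-SNPs are detected from pileups of tetraploid reads against one
subgenome: depth ≥ 50 and allele fraction in the **closed** interval
[0.25, 0.75] (the bounds are read as inclusive). Substituting the
alternative allele at each such site into the other subgenome yields its
*homoeologous complement*; a composite reference is the native subgenome +
the complement of the other (ids suffixed `_homoeocomp` so provenance
survives plain FASTA) + unassigned scaffolds. Reads from either subgenome
then find a near-exact target, so hemi-SNPs stop surfacing as variants.

A homoeologous replacement (one subgenome's segment overwritten by its
homoeolog, leaving four identical copies) is detected from matched 2-kb
window tracks: a maximal run where the smoothed donor/recipient coverage
ratio is ≥ 1.5 **and** hemi-SNP density is ≤ 10% of the genome median, of
length ≥ 100 kb. Smoothing is a 25-window (50 kb) moving average — a
simpler, testable stand-in for spline smoothing that is equivalent at
segment scale. The coverage ratio alone bleeds ~half the smoothing support
past a boundary; the hemi-density condition is sharp at window resolution,
so the intersection recovers boundaries to ±1 window. The thresholds are
not prescribed anywhere; they were chosen once to recover a ~1 Mb event
robustly at 30× per-subgenome depth and are exposed in
`ReplacementParams`.

## Genotype calling and the filter cascade (`gbs_variants`)

Per genotype: depth < 10 → missing; allele fraction in the closed band
[0.25, 0.75] → heterozygous; outside the band the call is homozygous when
the minor-allele reads are within an error allowance (≤ 1 read or ≤ 10% of
depth, whichever is larger — the depth-10 rule is applied per genotype, as
stack-based callers do), otherwise missing. Calls from the two composite
references are merged keeping only native-scaffold sites; then, in order:

1. locus presence — ≥ ⌈r·n⌉ genotyped individuals (r = 0.75 or 0.50);
2. residual homoeologous — all non-missing eugenioides calls hom-ref and
   all canephora hom-alt, or mirrored (both species need ≥ 1 call);
3. parent-missing/het — both parent species entirely missing and > 95%
   heterozygous arabica calls;
4. reference-panel — ≥ 7 of the 8 Bourbon/Typica accessions missing.

The three species-aware predicates are logically independent, so the final
retained set does not depend on their order (tested). Informative
nucleotides — the π denominator — are the summed lengths of retained loci
(73 bp or 30 bp stacks depending on the run configuration), not the SNP
count; this is what puts π on the 10⁻⁴ scale.

## Diversity statistics (`popgen_stats`)

Site π is the unbiased pairwise estimator `2·p̂·q̂·n/(n−1)` on non-missing
allele counts; total π divides the per-site sum by informative
nucleotides. Tajima's D uses the 1989 constants; with missing data θ_W
sums `1/a₁(n_s)` per segregating site and the variance constants use the
rounded mean site-wise n (for complete data this is the textbook
computation, and the oracle tests compare at 1e-10 on complete matrices).
S = 0 yields a flagged NaN, never zero. Private alleles are counted at the
individual level (the minor allele carried by exactly one individual, het
or hom). The Hardy–Weinberg test is the exact conditional (Levene)
enumeration, no mid-p, α = 0.05; classification direction compares
observed to expected heterozygotes, and class fractions are reported over
variants carried by ≥ 2 individuals (the test has no power on
singletons). PCA mean-imputes missing dosages per site and
eigendecomposes the centered 0/1/2 matrix; all other statistics use
per-site complete cases.

## Synthetic data (`synthetic_data`)

The generators define the study conditions:

* **Parents**: i.i.d. random sequence; per-base independent substitutions
  at d = 3.1×10⁻² (multiple hits negligible at this divergence);
  repeat intervals (default 2 kb) lower-cased at shared coordinates.
* **Tetraploid**: homoeologous scaffold pairs over identical coordinates;
  `plant_replacement` overwrites a recipient span with the donor homoeolog
  and records the truth.
* **Pileups/coverage**: Poisson(mean depth) per subgenome per site,
  binomial allele split with 0.002 error; a replacement span contributes
  ~0 reads on the recipient and doubles the donor's coverage.
* **Panels**: three species (736 arabica / 35 canephora / 10 eugenioides
  by default) with target π of 2.3×10⁻⁴ / 2.6×10⁻³ / 1.1×10⁻³ over a
  193,873-base surveyed footprint. Outcrossing parents draw site
  frequencies from a rare-skewed Beta solved to hit the target mean
  heterozygosity. The arabica spectrum is a two-component mixture: 84% of
  sites are young private mutations (exactly one carrier individual, 15%
  of the time two) and the rest draw from a symmetric Beta whose shape is
  solved so expected heterozygosity still matches the target. A single
  Beta cannot reproduce both the mean diversity and the observed
  singleton dominance at this sample size — the real spectrum is bimodal —
  and the mixture yields ~73% private sites and ~81% MAF < 0.05,
  matching the study's qualitative structure. Selfing applies the
  equilibrium inbreeding transform (heterozygote → homozygote with
  probability 1 − 2^(−g); default g = 5 for arabica, 0 for the parents;
  no selfing rate is reported for the real panels, so it is a free
  parameter). Missingness is uniform per call (default 20%). Residual
  homoeologous artifacts are planted to satisfy the filter's
  fixed-difference predicate exactly, with truth labels.
* **Dual-reference GBS experiment**: allele depths for a whole genotyping
  run against both composite references, with truth per site (true SNP /
  cleanly absorbed hemi site / residual artifact at a configurable rate,
  default 5%).

What the generators do **not** emulate: read-level errors and quality
strings, indels, linkage between panel sites, population structure within
species, informative missingness, repeat families with biological
structure. Passing tests show the decision rules and estimators behave as
specified under these idealised conditions, not that any particular real
dataset would yield the same numbers.

## Founder-model simulations (`demographic_sim`)

One panmictic diploid population represents one subgenome (subgenomes do
not recombine with each other, so one suffices for per-base statistics).
Forward in time: a single founder (size 1) grows exponentially to the
final size N_e over 200 generations, then stays constant; variants:
a bottleneck 1,000 years ago recovering exponentially to N_e
(size fraction 0.01 by default), or a recent cultivation expansion from
N_e to 500,000 beginning ~0.4 kya (80 generations), exponential by
default. Generation time is 5 years (0.2 generations/year); recombination
10⁻⁸; mutation 6.5×10⁻¹⁰–3.25×10⁻⁸ per base per generation; 700 diploid
samples on 5 Mb, 10 replicates per scenario.

The founder contributes zero diversity: the pre-founding size is 1, and
mutations are only placed on branch segments younger than the founding
time, so every polymorphism postdates polyploidization (the maximum
mutation age is asserted in tests). The default grid is
{10, 20 ky} × {N_e 10k, 50k} with constant size after growth; the printed
diversity range of these four models matches the closed form
2μ·2N_e(1−e^(−T·g/2N_e)) and, for N_e → ∞, the star-genealogy anchor
π → 2μ·T·g. The expansion scenario uses the (10 ky, N_e = 50k) base with
exponential growth over the last 80 generations; this reproduces the
reported ~42% private-SNP fraction while leaving π unchanged, whereas an
instantaneous jump on the 10k base yields ~52% — the gradual reading is
therefore the default, with the base model and `instantaneous` mode still
configurable. The coalescent is random-mating (no selfing parameter is
given for these scenarios), a caveat when comparing private fractions with
a highly autogamous sample.

π is computed over the 1,400 sampled haplotypes (tskit's site diversity);
the private fraction counts segregating sites whose derived allele is
carried by exactly one individual (1 or 2 copies); replicates without
segregating sites are excluded from the private-fraction mean and logged.
Scenario run times are seconds to ~20 s per replicate on one CPU at these
sizes.

## Numerical and degenerate-input choices

* Coordinates are 0-based half-open everywhere in memory; VCF output is
  1-based.
* `modal_coverage` breaks ties toward the smaller multiplicity.
* Classification with both shared counts zero is unassigned.
* The VCF writer stores the informative-nucleotide count as a header line
  so genotype matrices round-trip losslessly.
* All generators and simulators draw from `numpy.random.default_rng` /
  msprime seeded generators; identical seeds give identical outputs
  bit-for-bit, and derived seeds stay below 2³¹.

## Known limitations

Alignment itself is abstracted to pileup and depth tables — mapping
artifacts beyond the modelled mismap/residual channels are out of scope.
The per-genotype depth rule is one reading of the depth-10 filter (the
per-site reading would be stricter). HWE class percentages depend on the
unspecified test and α of the original analysis and are treated as
qualitative only. The k-mer counter is a plain Python dictionary —
adequate for the megabase-scale synthetic genomes used here, not for
multi-gigabase assemblies.
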