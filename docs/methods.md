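# Methods

## Problem and model

`rohscan` analyses runs of homozygosity (ROH) — contiguous stretches of a
diploid genome in which every genotyped site is homozygous — in dense,
resequencing-derived SNP genotypes of a small population. ROH arise when
both parental haplotypes descend from a recent common ancestor
(autozygosity); their number, length distribution and genomic placement
carry information about inbreeding history and selection. The package
covers four linked analyses:

1. **ROH calling** per individual with a sliding-window homozygosity scan;
2. **summaries**: length-class tables, per-chromosome ROH load, and the
   genomic inbreeding coefficient `F_ROH = L_ROH / L_genome`, where `L_ROH`
   is an individual's total ROH length and `L_genome` the SNP-covered
   autosomal span (per chromosome, last SNP − first SNP + 1, summed);
3. **ROH islands**: per-SNP incidence (the proportion of individuals whose
   ROH covers the SNP), a threshold (fixed proportion or top-q empirical
   quantile), and merging of above-threshold SNPs into islands;
4. **annotation**: island × gene-model interval intersection.

## The window scan

The caller follows the widely used windowed-scan design of PLINK's
`--homozyg` family. For each sample and chromosome:

- every window of `window_snps` consecutive SNPs (default 50) fully inside
  the chromosome is flagged homozygous when its heterozygous calls ≤
  `window_max_het` (default 1) and missing calls ≤ `window_max_missing`
  (default 5). A chromosome shorter than one window is evaluated as a
  single window over all its SNPs, so small fixtures are not silently
  dropped.
- each SNP is scored by the fraction of flagged windows covering it and is
  *eligible* when that fraction ≥ `snp_hit_threshold` (default 0.05).
- maximal runs of consecutive eligible SNPs — split wherever adjacent SNPs
  are more than `max_gap_bp` apart (default 1 Mb) — become segments if they
  hold ≥ `min_snps` SNPs (default 100), span ≥ `min_length_bp`
  (default 1 Mb) and have ≤ `min_density_bp_per_snp` bp per SNP
  (default 50 kb).

Segment endpoints are the positions of the first and last SNP of the run
(not window edges), so `length_bp = end − start + 1` is well defined from
the data. Missing calls count toward a segment's SNP total but not as
heterozygous. Defaults for the quantities the scan criteria do not fix
(window size, hit threshold, density, gap) are the established defaults of
the named tool family, and all are explicit `ROHParameters` fields.

The 1 Mb minimum-length default targets recent autozygosity; analyses of
shorter, older ROH (length classes from 100 kb up) use the same caller with
`min_length_bp=100_000`. Both profiles are exercised in the tests.

A deliberately naive oracle (`brute_force_roh`) re-derives the identical
contract with explicit Python loops — every window recounted, every SNP's
hit fraction rebuilt by scanning all windows — and the test suite asserts
exact segment-list equality between the two routes on randomized instances.

### Boundary resolution

A window-based caller cannot localise a tract edge precisely: a segment
extends past the true autozygosity boundary until enough flanking
heterozygotes accumulate. With a 1-het window allowance and hit threshold
0.05, the expected overhang is roughly the distance to the *second*
flanking heterozygote minus three SNPs — ≈ `2/h − 3` SNPs at background
heterozygosity `h` per site (about five SNPs at `h = 0.25`). Island edges
inherit this smear: at a 30% incidence threshold the boundary lands where
the probability of at most one heterozygote among `k+3` flanking SNPs
crosses ≈ 0.3, i.e. roughly 4–10 SNP spacings outside the true edge.
This is an information limit of the scan, not an implementation artefact;
the acceptance suite measures it rather than hiding it.

## Synthetic genomes

The generator (`rohscan.simulate`) emulates a small, strongly inbred
population genotyped by ~10× resequencing. Defaults: 20 samples, two
chromosomes (20 Mb + 15 Mb), mean SNP spacing 500 bp (geometric
inter-SNP distances), target autozygous fraction 0.5 per sample, tract
lengths exponential with mean 2 Mb floored at 100 kb, heterozygous-error
rate 0.001 inside tracts, missing rate 0.002, background heterozygosity
0.25 outside tracts, site QUAL uniform on [20, 60]. These mirror the kind
of population the pipeline is aimed at — a conserved local pig breed with
mean F_ROH near 0.5, genome scaled down ~70× for desk-scale runs — with
one exception: mean SNP spacing is 500 bp rather than the ~115 bp of a
full 21M-SNP callset, keeping simulated matrices small without changing
any window-scan behaviour that depends on SNP counts.

Background heterozygosity 0.25 is the neutral-coalescent expectation for
per-site heterozygosity at sites ascertained as segregating in 20 diploids
(≈ 0.23), rounded.

**Tract placement.** Per sample and chromosome, tract lengths are drawn
(exponential, floored, last one trimmed) until they sum to exactly
`round(target × chromosome_length)`; the tracts are then separated by
Dirichlet-distributed gaps over the remaining free space. This makes the
realised autozygous fraction equal to the target up to integer rounding,
guarantees non-overlap by construction, and remains well defined at any
target up to 1 (where rejection-based placement would thrash). Fixed
`implant_regions` (a region plus a carrier fraction) are placed first and
background tracts fill the complement, which is how common-ROH/island
scenarios are built.

**What the generator does not model:** pedigrees, recombination, linkage
disequilibrium beyond tract structure, allele-frequency spectra (alleles
are fixed A/G; only zygosity matters to the caller), and base-level
sequencing error. Passing tests therefore demonstrate correctness of the
scan, summaries and interval logic under controlled autozygosity — not
robustness to LD pruning choices, call-rate structure, or caller-specific
genotype error patterns in real data.

## Numerical and convention choices

- Internal coordinates are 1-based inclusive (VCF convention); BED I/O
  converts at the boundary. Chromosome names are normalised by stripping a
  `chr` prefix; the autosome allow-list defaults to `1`–`18` (pig).
- Site-quality filtering drops sites with `QUAL < min_site_quality`
  (default 10); a missing QUAL fails any positive threshold. Non-biallelic
  and non-SNP records are dropped, not split.
- Length classes are half-open in kb — `[100, 500)`, `[500, 1000)`,
  `[1000, ∞)` — so a segment of exactly 500 kb falls in the middle class.
  Percentages are rounded half-up to 2 decimals. The per-class "genome
  coverage" column divides the class's *pooled* segment length (all samples)
  by `L_genome` once; with many samples at high inbreeding this pooled
  figure can exceed 100% — it is a population total, not a per-individual
  fraction (per-individual coverage is what `F_ROH` reports).
- The island quantile threshold uses the nearest-rank rule (the
  `ceil(p·n)`-th order statistic) — deterministic, no interpolation. Both
  a fixed threshold (default 0.30) and the top-1% quantile mode are
  first-class because both conventions are in circulation; the default
  profile uses fixed 0.30.
- Island merging tolerates `max_gap_snps` below-threshold SNPs inside a
  run (default 0) and requires `min_snps` above-threshold members
  (default 2). Gap SNPs extend an island's span but are not members.
- Gene–island overlap is ≥ 1 bp on closed intervals
  (`min(ends) − max(starts) + 1`), the weakest defensible reading of
  "harboured"; full containment is available as an option. Strand is
  ignored. Note that published gene "sizes" sometimes follow an
  `end − start` difference convention, one base less than the inclusive
  interval length this package reports.
- The pipeline manifest records versions, parameters, seed and SHA-256
  checksums but no timestamps, so identical configs and inputs reproduce
  byte-identical output trees.

## Problem sizes

Simulated validation scenarios use single chromosomes of 20 Mb at 500 bp
spacing (≈ 40k SNPs) with 10–20 samples, five replicate seeds for
inbreeding-coefficient recovery, 100 randomized instances of ≤ 300 SNPs
for caller/oracle equivalence, and 200 × 200 random intervals for the
overlap oracle. These sizes give stable estimates (F_ROH recovery error
≲ 0.005 against targets of 0.2 and 0.5) while keeping a full test run in
seconds.

## Known limitations

- Boundary placement of segments and islands is resolution-limited as
  described above; downstream interval overlaps inherit that uncertainty.
- Background autozygosity can, by chance, stack enough individuals at one
  locus to cross a fixed incidence threshold and create a spurious island;
  with 20 samples at 5% background this is rare but not impossible.
- The caller is purely zygosity-based: no allele frequencies, no LD model,
  no HMM smoothing; it reproduces the windowed-scan family of methods, not
  likelihood-based ROH callers.
- Ploidy other than 2 and sex chromosomes are out of scope.
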