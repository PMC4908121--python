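# Methods

## Simulation model

**Population.** Each reference contig receives an independent neutral
coalescent genealogy of `2·n_individuals` haplotypes (msprime, no
recombination within a contig, free recombination between contigs — the
"independent loci" treatment appropriate for short GBS fragments). Mutations
are placed at discrete positions at rate θ/4 per base per 4N generations
(`theta_per_site` = 4Nμ); sites struck more than once are discarded, so the
realised model is infinite-sites to a very good approximation. The reference
base at a variant position is the ancestral allele; the derived allele is
drawn uniformly from the other three bases. Haplotypes `2i, 2i+1` pair into
diploid individual `i`. With `n_demes > 1`, demes of population size N split
from a common ancestor `deme_split_time` × 2N generations ago (or exchange
migrants at scaled rate 4Nm); individuals are assigned to demes in
contiguous blocks.

**Reference and digestion.** Contigs are uniform-composition random DNA.
Restriction sites are all forward-strand matches of the IUPAC motif
(default `GCWGC`, the ApeKI site; its reverse complement is itself, so
forward scanning is complete). Each cut site defines one tag locus of
`tag_length` (default 64) bp on each side; windows crossing a contig end
are discarded. Reads from both flanks are emitted in forward-strand
orientation — in a real library the left-flank fragment would be sequenced
from the reverse strand, but both callers search both strands, so nothing
downstream depends on this simplification.

**Reads.** Per sample × tag locus, read count is negative-binomial
(gamma–Poisson) with mean `mean_depth` and shape `depth_dispersion`; each
read picks one of the two haplotypes uniformly. If a variant destroys the
motif on a haplotype, that haplotype emits no reads at the adjacent loci
(allelic dropout): a heterozygote loses half its coverage and is seen as
homozygous for the surviving allele, and a dropout homozygote goes missing
entirely. Sequencing errors flip each base — barcode included, so
demultiplexing loss is realistic — to a uniformly chosen different base
with probability `seq_error_rate`. With probability `pcr_duplicate_rate` a
read is emitted twice; the duplicate is an exact post-error copy (PCR
duplicates share their template). Base qualities are constant Q30: the
tag-pair caller ignores qualities entirely, and a constant claimed quality
alongside a configurable true error rate deliberately reproduces the mild
miscalibration of real instruments.

The negative-binomial depth model is this package's stand-in for the
unknown empirical depth distribution of real libraries; nothing downstream
assumes it beyond overdispersion.

**What the generator does not emulate.** No indels, no paired-end reads, no
methylation-driven enrichment of cut sites in genic regions, no
base-quality variation along the read, no index hopping. Passing tests
therefore show that the *pipelines'* behaviour under the stated noise
processes matches expectation; they do not certify performance on real
libraries with structured error profiles.

## Tag-pair caller

Reads with a perfect barcode prefix and no N in the following 64 bases are
trimmed to exactly 64 bases. Unique tags seen ≥ `min_tag_count` (default 5)
times across all samples form the catalog. Candidate SNPs are *reciprocal*
pairs: tags at Hamming distance 1, each being the other's only distance-1
partner in the catalog (found by masked-position bucketing, near-linear in
catalog size). A pair passes the ETR test iff
`min(total_a, total_b) / (total_a + total_b) ≥ ETR` (default 0.03). The
acceptance formula is never spelled out by the pipelines this emulates; the
global minor-tag fraction is the minimal rule with the documented property
that true low-frequency variants fall below it.

Genotypes come from binomial likelihoods with a constant per-read error
rate e (default 0.01, configurable, deliberately decoupled from the
simulator's true rate): for per-sample counts (k_a, k_b), n = k_a+k_b,

    L(hom_a) = C(n,k_b)·(1−e)^k_a·e^k_b      L(hom_b) symmetric
    L(het)   = C(n,k_a)·(1/2)^n

with argmax assignment, ties toward het, and n = 0 missing. This standard
GBS genotype model is declared as this package's interpretation — the
original pipeline cites a formula in an out-of-print reference.

Site filters, in catalog order: MAF ≥ 0.05 on called genotypes; site depth
≤ the median depth over sites surviving the MAF filter (the median is
recomputed per run and logged); missing fraction strictly < 0.10.

One SNP per 64 bp tag is structural: a tag window segregating two or more
variants produces ≥3 haplotype tags, reciprocity fails, and the locus is
lost. Likewise a heterozygote whose second haplotype carries additional
in-tag variants is counted as homozygous — its other tag is simply a
different catalog entry. Both behaviours are properties of the pair
representation, reproduced deliberately.

## Mapping caller

Reads are demultiplexed, end-trimmed at Q<20, dropped below 35 bp or mean
Q<30, and mapped ungapped to the reference by seed-and-verify: every
16-mer of the reference is indexed; a read is seeded at offsets 0, 16, 32,…
and len−16 in both orientations and every candidate verified by Hamming
count. For 64-bp reads and ≤3 mismatches the pigeonhole principle makes the
search exhaustive. Among equally best placements the first by (contig,
position) is chosen and the count retained; multi-placement reads feed the
MQ0 counter at every site they cover.

Genotype likelihoods use per-base error e from the base quality: a base
contributes (1−e) to a matching homozygote, e/3 to a non-matching one and
(1−e)/2 + e/6 to a heterozygote carrying it. Assignment maximises
likelihood × prior with prior heterozygosity 0.001 (hom-alt 0.0005), the
convention of mapping-based callers — a pure maximum-likelihood rule would
call a heterozygote from a single erroneous read at any depth ≤ ~11 and
flood the site list. Site QUAL is evidence only: −10·log₁₀ of the
flat-prior normalized probability that all covered samples are homozygous
reference. QD divides QUAL by the summed depth of variant-carrying samples.

Filters, in order: (1) SNP cluster — every site inside any 10-bp window
holding >3 sites is voided (idempotent by construction); (2) remove sites
with MQ0 ≥ 4 *and* MQ0/DP > 0.1; (3) remove QUAL ≤ 60; (4) remove QD at or
below its empirical 5% quantile, recomputed per run and logged (the
published absolute threshold is dataset-specific); (5) keep site depth ≤
the median over surviving sites; (6) keep missing fraction ≤ 0.10. QUAL/QD
thresholds are applied sequentially as listed. No indel realignment exists
because the simulation is indel-free.

## Statistics battery

* **Folded SFS** — minor-allele counts over non-missing chromosomes. Under
  missing data, sites are hypergeometrically down-projected to a common
  chromosome count (the 90% quantile of per-site non-missing counts; sites
  below it are dropped); a `raw` per-site tally is available by flag.
* **Equilibrium expectation** — E[ξ_i] ∝ 1/i folded to
  φ_i ∝ (1/i + 1/(n−i))/(1+δ_{i,n−i}), normalised to the observed S.
  Normalisation by S (rather than by θ̂ from π) is this package's choice.
* **θ̂_W, θ̂_π, Tajima's D** — θ̂_W = S/a₁; θ̂_π sums 2p(1−p)·n/(n−1) with
  site-specific non-missing n; D uses the Tajima (1989) constants with
  n = 2 × samples (call sets are filtered to <10% missingness, so the
  approximation is mild; truth matrices are complete and exact). Both
  dataset totals and per-site values are reported. D is undefined at S=0.
* **Heterozygosity** — per locus, H_obs = fraction of heterozygous calls,
  H_exp = 2p(1−p).
* **F-statistics** — Weir–Cockerham (1984) variance components a, b, c per
  locus; F_ST = a/(a+b+c), F_IS = 1 − c/(b+c); multi-locus estimates are
  ratios of summed components; monomorphic loci are excluded and counted.
  The estimator choice is fixed here (the emulated study names only an R
  package) and recorded in report metadata.
* **PCA** — mean-imputed, mean-centred columns scaled by √(p̂(1−p̂)) with
  the shrunk frequency p̂ = (1+Σg)/(2+2n); eigen-decomposition of the
  sample covariance; deterministic sign convention. When two PCA solutions
  are compared, the leading axes are first aligned by orthogonal Procrustes
  rotation: with three symmetric clusters the PC1/PC2 eigenvalues are
  nearly degenerate and the within-plane rotation is arbitrary, so per-axis
  correlations without alignment are meaningless.
* **Admixture** — X ≈ Q·F on dosages/2, alternating regularised least
  squares with Q rows projected to the simplex and F clipped to [0,1];
  10 random restarts, convergence at relative fit change < 1e-6 or 500
  iterations; best restart kept; a final Q refresh given F makes identical
  samples receive identical rows. No automatic choice of K is provided.
* **Between-dataset p-values** — two-sided Wilcoxon rank-sum on per-locus
  values, uncorrected (four descriptive statistics); the emulated study
  prints p-values without naming a test, so the choice is recorded in the
  report metadata.

## Study conditions (src/gbscompare/scenarios.py)

* **Bias experiment**: 40 diploids, 170 × 1 kb contigs (≈600 tag loci,
  ≥1500 true SNPs inside tags), θ = 0.01/bp, depth 8 (shape 10), error
  0.005, 5% PCR duplicates, dropout on. Depth and missingness match the
  5–10× regime typical of population GBS; θ is at the high end so that the
  tag windows carry enough segregating sites at desk scale.
* **Recovery**: 12 diploids, depth 30, zero error, no duplication, dropout
  off — the regime in which both callers must reproduce truth exactly.
* **Equilibrium calibration**: 25 diploids, 2000 × 100 bp independent loci,
  θ = 0.0025/bp (≈1 SNP per locus). The chi-square goodness of fit assumes
  independent sites; long non-recombining contigs share genealogies and
  overdisperse the SFS bins, so the calibration deliberately uses many
  small loci.
* **Structure**: 3 demes × 10 diploids, split 0.3 × 2N generations
  (realised multi-locus F_ST ≈ 0.2), 250 contigs, depth 12, error 0.003.

Problem sizes are chosen so each experiment runs in well under a minute on
one CPU while leaving clear statistical margins.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; VCF output is 1-based v4.2 with
`./.` for missing. The missing-genotype sentinel is a named constant, never
used in arithmetic. Likelihoods are computed in log space. Lexicographic
ordering fixes tag_a/allele_a in a pair; a deterministic seed tree
(`numpy.random.SeedSequence`) drives every random draw, so fixed-seed runs
are byte-identical. Degenerate inputs (θ = 0, empty catalogs, S = 0,
all-monomorphic matrices, single demes) either return well-defined empty/NaN
results or raise `ValueError` with a plain message, as documented per
function.

## Known limitations

* The tag-pair caller implements pairs only, not larger tag networks;
  loci with >2 haplotype tags are dropped rather than resolved.
* Tajima's D on matrices with missing data mixes a fixed-n normalisation
  with site-wise frequencies; at the ≤10% missingness enforced by both
  pipelines the effect is negligible but it is not an exact estimator.
* The mapping-caller QUAL is a per-sample product of normalized
  likelihoods, not a full joint allele-frequency model; its absolute scale
  differs from production callers even though threshold behaviour is
  comparable.
* Hypergeometric SFS projection discards sites below the projection depth
  instead of imputing them.
* The admixture solver is a projected ALS, adequate for well-separated
  demes; it is not a drop-in replacement for sparse-NMF software at weak
  divergence.
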