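# gbscompare

Genotyping-by-sequencing (GBS) gives cheap reduced-representation genotypes
for species without a reference genome, but the SNPs you get depend strongly
on how you call them. `gbscompare` simulates a complete GBS experiment with
known truth and pushes the same reads through two calling strategies:

* a **reference-free tag-pair caller** in the style of network-based GBS
  pipelines: unique 64-bp read "tags" are catalogued, tags that differ at
  exactly one base and are each other's only 1-mismatch partner become
  candidate SNPs, and a pair is accepted only if its minor tag carries at
  least an *error tolerance rate* (ETR, default 3%) of the pair's reads;
* a **reference-mapping caller** in the style of transcriptome-mapping
  pipelines: quality-trimmed reads are mapped with at most 3 mismatches,
  diploid genotypes are called from quality-aware likelihoods, and sites are
  filtered on SNP clustering, mapping ambiguity (MQ0), QUAL, QD, depth and
  missingness.

Both call sets then go through the same population-genetics battery — folded
site frequency spectrum (SFS) and its neutral equilibrium expectation,
Watterson's θ̂_W = S/a₁ and the pairwise θ̂_π, Tajima's D, observed/expected
heterozygosity, Weir–Cockerham (1984) F_IS/F_ST, PCA with Patterson
normalisation, and NMF-style admixture — and are benchmarked against the
simulation truth.

The package exists to demonstrate, under controlled conditions, a real and
consequential ascertainment bias: an ETR threshold (and a MAF floor)
systematically discards rare variants, which inflates Tajima's D and
heterozygosity and distorts F-statistics, **while leaving population-structure
inference (PCA, admixture) essentially untouched**, because structure is
driven by common variants.

## Worked example

```python
from gbscompare.scenarios import bias_scenario
from gbscompare.sim import simulate, truth_at_tag_loci
from gbscompare.tagcaller import call_uneak
from gbscompare.mapcaller import call_tm
from gbscompare.popgen import tajimas_d

ref, truth, reads, key = simulate(bias_scenario(seed=11))
truth_tags = truth_at_tag_loci(truth, ref)   # 1730 true SNPs inside tag loci
uneak = call_uneak(reads, key)               # ETR 0.03, MAF 0.05, DP median, NA < 0.1
tm = call_tm(reads, key, ref)                # cluster, MQ0, QUAL, QD, DP, NA filters

print(tajimas_d(truth_tags).tajimas_d)       # -0.016  (neutral truth ~ 0)
print(tajimas_d(uneak.genotypes).tajimas_d)  #  1.531  (rare variants ascertained away)
print(tajimas_d(tm.genotypes).tajimas_d)     # -0.593  (rare variants kept, plus a few
                                             #          error-derived singletons)
```

The simulation is 40 diploids over 170 kb of reference (≈600 tag loci),
mean depth 8, 0.5% per-base sequencing error, 5% PCR duplicates and allelic
dropout at mutated restriction sites. The tag-pair call set retains no site
whose minor tag fraction is below the ETR and recalls 0% of singleton/
doubleton truth variants, against 29% for the mapping caller — hence the
strongly positive D on neutral data. Running the same two call sets through
PCA and K=3 admixture on a three-deme simulation (F_ST ≈ 0.2) assigns ≥95%
of individuals to the same clusters either way.

A command-line interface wraps the same stages:

```bash
gbscompare simulate  --config sim.cfg --out run/sim
gbscompare call-uneak --fastq run/sim/reads.fastq --key run/sim/barcode_key.tsv --out run/uneak
gbscompare call-tm    --fastq run/sim/reads.fastq --key run/sim/barcode_key.tsv \
                      --ref run/sim/reference.fasta --out run/tm
gbscompare stats      --vcf run/uneak/uneak.vcf --k 3 --seed 1 --out run/stats
gbscompare compare    --uneak run/uneak --tm run/tm --out run/compare
# or all at once:
gbscompare run-all    --config sim.cfg --out run
```

Every stage writes a `manifest.json` echoing its parameters and seed;
fixed-seed reruns are byte-identical.

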