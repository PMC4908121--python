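"""Standard simulation scenarios used by the comparison experiments.

These configurations define the study conditions once — sample sizes,
depths, error rates, divergence — so that tests, scripts and documentation
all run the same experiments. See docs/methods.md for the rationale behind
each value.
"""

from __future__ import annotations

from .sim import SimConfig

#: Matched "realistic" GBS experiment for the headline ascertainment-bias
#: comparison: 40 diploids, ~170 kb of reference in 1 kb contigs (≈600 tag
#: loci, ≥1500 true SNPs inside tags), mean depth 8 with moderate
#: overdispersion, 0.5% per-base sequencing error, 5% PCR duplication,
#: allelic dropout on.
def bias_scenario(seed: int = 11) -> SimConfig:
    return SimConfig(
        n_individuals=40,
        n_contigs=170,
        contig_length=1000,
        theta_per_site=0.01,
        mean_depth=8.0,
        depth_dispersion=10.0,
        seq_error_rate=0.005,
        pcr_duplicate_rate=0.05,
        seed=seed,
    )


#: Error-free, high-depth, dropout-free conditions under which both callers
#: must recover truth exactly at discoverable sites.
def recovery_scenario(seed: int = 7) -> SimConfig:
    return SimConfig(
        n_individuals=12,
        n_contigs=30,
        contig_length=1000,
        theta_per_site=0.005,
        mean_depth=30.0,
        depth_dispersion=20.0,
        seq_error_rate=0.0,
        pcr_duplicate_rate=0.0,
        allelic_dropout=False,
        seed=seed,
    )


#: Single-deme equilibrium population with ≥2000 segregating sites spread
#: over many short, freely recombining loci (~1 SNP per locus, so sites are
#: effectively independent), for calibrating the simulator against the
#: neutral folded-SFS expectation.
def equilibrium_scenario(seed: int = 3) -> SimConfig:
    return SimConfig(
        n_individuals=25,
        n_contigs=2000,
        contig_length=100,
        theta_per_site=0.0025,
        tag_length=50,
        seed=seed,
    )


#: Three demes split deeply enough for F_ST ≈ 0.2, the regime in which both
#: call sets should still agree on population structure.
def structure_scenario(seed: int = 5) -> SimConfig:
    return SimConfig(
        n_individuals=30,
        n_demes=3,
        deme_split_time=0.3,
        n_contigs=250,
        contig_length=1000,
        theta_per_site=0.004,
        mean_depth=12.0,
        depth_dispersion=10.0,
        seq_error_rate=0.003,
        pcr_duplicate_rate=0.05,
        seed=seed,
    )
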