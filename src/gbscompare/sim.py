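"""Simulation of genotyping-by-sequencing (GBS) experiments with known truth.

The generator emulates a reduced-representation library: a multi-contig
reference (standing in for a transcriptome-like assembly), a neutral
equilibrium diploid population (optionally structured into demes that split
from a common ancestor), ApeKI-motif (GCWGC) restriction digestion, 64-bp
tag loci flanking each cut site, and multiplexed single-end reads with inline
barcodes, per-base sequencing error, negative-binomial coverage
overdispersion, optional PCR duplication, and allelic dropout whenever a
mutation destroys a cut-site motif on a haplotype.

Every random draw descends from ``SimConfig.seed``; a fixed seed yields
byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd

from .genotypes import SITE_COLUMNS, GenotypeMatrix
from .io import FastqRead, _check_barcodes

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_TO_CODE = {65: 0, 67: 1, 71: 2, 84: 3}

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(len(seq), dtype=np.uint8)
    for byte, code in _BASE_TO_CODE.items():
        out[raw == byte] = code
    return out


def decode_seq(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def motif_matches(window: str, motif: str) -> bool:
    """True if ``window`` matches the IUPAC ``motif`` exactly (same length)."""
    if len(window) != len(motif):
        return False
    return all(b in IUPAC[m] for b, m in zip(window, motif))


def find_motif_positions(seq: str, motif: str) -> list[int]:
    """All 0-based forward-strand occurrences of an IUPAC motif."""
    for m in motif:
        if m not in IUPAC:
            raise ValueError(f"invalid IUPAC code {m!r} in motif")
    k = len(motif)
    return [i for i in range(len(seq) - k + 1) if motif_matches(seq[i : i + k], motif)]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Parameters of one simulated GBS experiment.

    Population parameters are coalescent-scaled: ``theta_per_site`` is 4Nμ per
    base pair, ``deme_split_time`` is in units of 2N generations and
    ``migration_rate`` is the scaled island-model rate 4Nm.
    """

    n_individuals: int
    n_contigs: int
    contig_length: int
    theta_per_site: float
    n_demes: int = 1
    deme_split_time: float | None = None
    migration_rate: float | None = None
    motif: str = "GCWGC"
    tag_length: int = 64
    mean_depth: float = 10.0
    depth_dispersion: float = 10.0
    seq_error_rate: float = 0.0
    pcr_duplicate_rate: float = 0.0
    allelic_dropout: bool = True
    barcode_set: list[str] | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if self.theta_per_site < 0:
            raise ValueError("theta_per_site must be non-negative")
        if self.n_contigs <= 0 or self.contig_length <= 0:
            raise ValueError("need at least one contig of positive length")
        if self.tag_length > self.contig_length:
            raise ValueError("tag_length exceeds contig_length")
        for name in ("seq_error_rate", "pcr_duplicate_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_demes > 1 and self.deme_split_time is None and self.migration_rate is None:
            raise ValueError("structured model needs deme_split_time or migration_rate")
        if self.barcode_set is not None:
            if len(self.barcode_set) < self.n_individuals:
                raise ValueError("fewer barcodes than individuals")
            _check_barcodes(self.barcode_set[: self.n_individuals])

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i:03d}" for i in range(self.n_individuals)]

    @property
    def deme_labels(self) -> list[str]:
        """Deme label per individual: contiguous near-even blocks, matching
        the order the coalescent sampler emits individuals."""
        base, extra = divmod(self.n_individuals, self.n_demes)
        labels = []
        for d in range(self.n_demes):
            labels += [f"D{d}"] * (base + (1 if d < extra else 0))
        return labels


def default_barcodes(n: int, length: int = 6, seed: int = 7) -> list[str]:
    """``n`` distinct fixed-length barcodes (equal length ⇒ non-prefix)."""
    if n > 4**length:
        raise ValueError("barcode space too small")
    rng = np.random.default_rng(seed)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = decode_seq(rng.integers(0, 4, size=length).astype(np.uint8))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


# ---------------------------------------------------------------------------
# Reference and digestion
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """Reference contigs plus their restriction map.

    ``tag_loci`` columns: locus_id, contig, start, end, cut_pos, side
    (0-based half-open windows, each fully inside its contig).
    """

    contigs: dict[str, str]
    cut_sites: dict[str, list[int]]
    tag_loci: pd.DataFrame
    motif: str
    tag_length: int

    def contig_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")


def read_fasta(path) -> dict[str, str]:
    contigs: dict[str, str] = {}
    name, chunks = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    contigs[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line.upper())
    if name is not None:
        contigs[name] = "".join(chunks)
    return contigs


def generate_reference(config: SimConfig) -> ReferenceSet:
    """Random uniform-composition contigs, digested with the config motif."""
    ss = np.random.SeedSequence([config.seed, 0x5EF])
    rng = np.random.default_rng(ss)
    contigs = {
        f"ctg{i:04d}": decode_seq(
            rng.integers(0, 4, size=config.contig_length).astype(np.uint8)
        )
        for i in range(config.n_contigs)
    }
    return digest_reference(contigs, config.motif, config.tag_length)


def digest_reference(
    contigs: dict[str, str], motif: str = "GCWGC", tag_length: int = 64
) -> ReferenceSet:
    """Find all forward-strand motif sites and define flanking tag loci.

    One tag locus is laid on each side of each cut site ([c−L, c) and
    [c, c+L)); windows that would cross a contig end are discarded, and
    loci duplicated by position are emitted once.
    """
    if not contigs:
        raise ValueError("empty reference")
    for name, seq in contigs.items():
        if len(motif) > len(seq):
            raise ValueError(f"motif longer than contig {name}")
    cut_sites: dict[str, list[int]] = {}
    rows = []
    seen: set[tuple[str, int, int]] = set()
    for name in contigs:
        seq = contigs[name]
        cuts = find_motif_positions(seq, motif)
        cut_sites[name] = cuts
        for c in cuts:
            for side, start in (("left", c - tag_length), ("right", c)):
                end = start + tag_length
                if start < 0 or end > len(seq):
                    continue
                key = (name, start, end)
                if key in seen:
                    continue
                seen.add(key)
                rows.append(
                    {
                        "locus_id": f"{name}:{start}-{end}",
                        "contig": name,
                        "start": start,
                        "end": end,
                        "cut_pos": c,
                        "side": side,
                    }
                )
    tag_loci = pd.DataFrame(
        rows, columns=["locus_id", "contig", "start", "end", "cut_pos", "side"]
    )
    return ReferenceSet(
        contigs=contigs,
        cut_sites=cut_sites,
        tag_loci=tag_loci,
        motif=motif,
        tag_length=tag_length,
    )


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


@dataclass
class Truth:
    """Ground truth of one simulated experiment.

    ``haplotypes`` maps contig -> (positions, H) with H of shape
    (2·n_individuals, S_contig) holding 0 (ref) / 1 (alt); diploids pair
    haplotypes (2i, 2i+1). ``dropout`` lists (contig, cut_pos, hap) triples
    where a variant destroys the restriction motif on that haplotype.
    """

    variants: pd.DataFrame
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    genotypes: GenotypeMatrix
    dropout: pd.DataFrame
    config: SimConfig = field(repr=False)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def true_folded_sfs(self):
        from .popgen import folded_sfs

        return folded_sfs(self.genotypes)

    def dropout_haps(self) -> set[tuple[str, int, int]]:
        return {
            (r.contig, int(r.cut_pos), int(r.hap))
            for r in self.dropout.itertuples(index=False)
        }


def _demography(config: SimConfig) -> msprime.Demography | None:
    if config.n_demes <= 1:
        return None
    demo = msprime.Demography()
    for d in range(config.n_demes):
        demo.add_population(name=f"D{d}", initial_size=1.0)
    if config.deme_split_time is not None:
        demo.add_population(name="ANC", initial_size=1.0)
        # split time is in units of 2N generations; N = 1 here
        demo.add_population_split(
            time=2.0 * config.deme_split_time,
            derived=[f"D{d}" for d in range(config.n_demes)],
            ancestral="ANC",
        )
    if config.migration_rate is not None:
        # scaled 4Nm -> per-generation fraction with N = 1
        demo.set_migration_rate(None, None, config.migration_rate / 4.0)
    return demo


def simulate_population(config: SimConfig, ref: ReferenceSet | None = None) -> Truth:
    """Neutral coalescent simulation of the diploid sample over all contigs.

    Each contig gets an independent genealogy (free recombination between
    contigs, none within); mutations follow an infinite-sites approximation —
    discrete positions, sites struck more than once are discarded. The
    reference base at each variant position is the ancestral allele; the
    derived allele is drawn uniformly from the other three bases.
    """
    if ref is None:
        ref = generate_reference(config)
    ss = np.random.SeedSequence([config.seed, 0x90B])
    children = ss.spawn(config.n_contigs + 1)
    alt_rng = np.random.default_rng(children[-1])

    demo = _demography(config)
    if demo is None:
        samples: object = config.n_individuals
    else:
        counts: dict[str, int] = {}
        for lbl in config.deme_labels:
            counts[lbl] = counts.get(lbl, 0) + 1
        samples = [
            msprime.SampleSet(k, population=lbl, ploidy=2) for lbl, k in counts.items()
        ]

    n_hap = 2 * config.n_individuals
    rows = []
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    geno_cols = []
    for ci, name in enumerate(ref.contigs):
        seq = ref.contigs[name]
        seeds = children[ci].generate_state(2) % (2**31 - 2) + 1
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demo,
            population_size=None if demo is not None else 1.0,
            sequence_length=len(seq),
            recombination_rate=0.0,
            ploidy=2,
            random_seed=int(seeds[0]),
        )
        if config.theta_per_site > 0:
            mts = msprime.sim_mutations(
                ts,
                rate=config.theta_per_site / 4.0,
                random_seed=int(seeds[1]),
                model=msprime.BinaryMutationModel(),
                discrete_genome=True,
            )
        else:
            mts = ts
        positions, columns = [], []
        for var in mts.variants():
            site = var.site
            if len(site.mutations) != 1:  # infinite-sites: drop recurrent hits
                continue
            g = var.genotypes.astype(np.uint8)
            if g.min() == g.max():
                continue
            positions.append(int(site.position))
            columns.append(g)
        # discrete positions can collide after rounding only if the same int
        # position appears twice, which discrete_genome=True already prevents
        pos_arr = np.asarray(positions, dtype=int)
        H = (
            np.asarray(columns, dtype=np.uint8).T
            if columns
            else np.zeros((n_hap, 0), dtype=np.uint8)
        )
        order = np.argsort(pos_arr, kind="stable")
        pos_arr, H = pos_arr[order], H[:, order]
        haplotypes[name] = (pos_arr, H)
        for p, col in zip(pos_arr, H.T):
            ref_base = seq[p]
            others = [b for b in "ACGT" if b != ref_base]
            alt_base = others[alt_rng.integers(0, 3)]
            rows.append(
                {
                    "site_id": f"{name}:{p}",
                    "contig": name,
                    "pos": int(p),
                    "ref": ref_base,
                    "alt": alt_base,
                }
            )
            geno_cols.append(col[0::2] + col[1::2])

    variants = pd.DataFrame(rows, columns=SITE_COLUMNS)
    G = (
        np.asarray(geno_cols, dtype=np.int8).T
        if geno_cols
        else np.zeros((config.n_individuals, 0), dtype=np.int8)
    )
    genotypes = GenotypeMatrix(
        samples=config.sample_names,
        sites=variants.copy(),
        G=G,
        demes=config.deme_labels if config.n_demes > 1 else None,
    )
    dropout = _find_dropout(variants, haplotypes, ref)
    return Truth(
        variants=variants,
        haplotypes=haplotypes,
        genotypes=genotypes,
        dropout=dropout,
        config=config,
    )


def _find_dropout(
    variants: pd.DataFrame,
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]],
    ref: ReferenceSet,
) -> pd.DataFrame:
    """Haplotypes whose motif window no longer matches after applying variants."""
    rows = []
    var_by_contig = dict(tuple(variants.groupby("contig", sort=False))) if len(variants) else {}
    k = len(ref.motif)
    for name, cuts in ref.cut_sites.items():
        if name not in var_by_contig:
            continue
        vdf = var_by_contig[name]
        pos_arr, H = haplotypes[name]
        pos_to_col = {int(p): j for j, p in enumerate(pos_arr)}
        seq = ref.contigs[name]
        for c in cuts:
            in_window = vdf[(vdf["pos"] >= c) & (vdf["pos"] < c + k)]
            if in_window.empty:
                continue
            for hap in range(H.shape[0]):
                window = list(seq[c : c + k])
                changed = False
                for r in in_window.itertuples(index=False):
                    if H[hap, pos_to_col[int(r.pos)]] == 1:
                        window[int(r.pos) - c] = r.alt
                        changed = True
                if changed and not motif_matches("".join(window), ref.motif):
                    rows.append({"contig": name, "cut_pos": c, "hap": hap})
    return pd.DataFrame(rows, columns=["contig", "cut_pos", "hap"])


def truth_at_tag_loci(truth: Truth, ref: ReferenceSet) -> GenotypeMatrix:
    """Truth genotypes restricted to variants inside any tag locus."""
    keep = np.zeros(len(truth.variants), dtype=bool)
    loci_by_contig = dict(tuple(ref.tag_loci.groupby("contig", sort=False)))
    for idx, r in enumerate(truth.variants.itertuples(index=False)):
        loci = loci_by_contig.get(r.contig)
        if loci is None:
            continue
        if ((loci["start"] <= r.pos) & (r.pos < loci["end"])).any():
            keep[idx] = True
    return truth.genotypes.take_sites(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# Read generation
# ---------------------------------------------------------------------------


def _haplotype_tag_sequences(
    seq: str,
    start: int,
    end: int,
    pos_arr: np.ndarray,
    H: np.ndarray,
    alt_by_pos: dict[int, str],
) -> list[np.ndarray]:
    """Per-haplotype encoded tag sequence for window [start, end)."""
    base = encode_seq(seq[start:end])
    in_win = np.flatnonzero((pos_arr >= start) & (pos_arr < end))
    n_hap = H.shape[0]
    if in_win.size == 0:
        return [base] * n_hap
    out: list[np.ndarray] = []
    cache: dict[bytes, np.ndarray] = {}
    for hap in range(n_hap):
        pattern = H[hap, in_win].tobytes()
        cached = cache.get(pattern)
        if cached is None:
            tag = base.copy()
            for j in in_win:
                if H[hap, j] == 1:
                    p = int(pos_arr[j])
                    tag[p - start] = encode_seq(alt_by_pos[p])[0]
            cache[pattern] = tag
            cached = tag
        out.append(cached)
    return out


def generate_reads(
    truth: Truth, ref: ReferenceSet, config: SimConfig
) -> tuple[list[FastqRead], dict[str, str]]:
    """Multiplexed single-end reads for every sample × tag locus.

    Depth per sample × locus is negative-binomial (gamma-Poisson) with mean
    ``mean_depth`` and shape ``depth_dispersion``; reads pick one of the two
    haplotypes uniformly, and reads assigned to a haplotype whose cut site is
    destroyed are not emitted (allelic dropout halves coverage). Sequencing
    errors flip each base — barcode bases included — to a uniform different
    base with probability ``seq_error_rate``; PCR duplicates append an exact
    copy of the post-error read. Qualities are constant Q30.
    """
    barcodes = config.barcode_set or default_barcodes(
        config.n_individuals, seed=config.seed + 101
    )
    barcodes = barcodes[: config.n_individuals]
    _check_barcodes(barcodes)
    key = dict(zip(config.sample_names, barcodes))

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x2EAD]))
    dropped = truth.dropout_haps() if config.allelic_dropout else set()
    alt_by_contig: dict[str, dict[int, str]] = {}
    for r in truth.variants.itertuples(index=False):
        alt_by_contig.setdefault(r.contig, {})[int(r.pos)] = r.alt

    reads: list[FastqRead] = []
    shape = config.depth_dispersion
    for locus in ref.tag_loci.itertuples(index=False):
        if locus.end - locus.start < config.tag_length:
            raise ValueError(f"locus {locus.locus_id} shorter than tag_length")
        pos_arr, H = truth.haplotypes[locus.contig]
        tags = _haplotype_tag_sequences(
            ref.contigs[locus.contig],
            locus.start,
            locus.end,
            pos_arr,
            H,
            alt_by_contig.get(locus.contig, {}),
        )
        for i, sample in enumerate(config.sample_names):
            lam = rng.gamma(shape, config.mean_depth / shape)
            n = rng.poisson(lam)
            if n == 0:
                continue
            hap_choice = rng.integers(0, 2, size=n)
            bc_codes = encode_seq(key[sample])
            for serial in range(n):
                hap = 2 * i + int(hap_choice[serial])
                if (locus.contig, int(locus.cut_pos), hap) in dropped:
                    continue
                codes = np.concatenate([bc_codes, tags[hap]])
                if config.seq_error_rate > 0:
                    err = rng.random(codes.size) < config.seq_error_rate
                    if err.any():
                        codes = codes.copy()
                        shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
                        codes[err] = (codes[err] + shift) % 4
                seq = decode_seq(codes)
                qual = "?" * len(seq)
                rid = f"{sample}/{locus.locus_id}/h{hap}/{serial}"
                reads.append(FastqRead(id=rid, seq=seq, qual=qual))
                if config.pcr_duplicate_rate > 0 and rng.random() < config.pcr_duplicate_rate:
                    reads.append(FastqRead(id=rid + ":dup", seq=seq, qual=qual))
    return reads, key


def simulate(config: SimConfig) -> tuple[ReferenceSet, Truth, list[FastqRead], dict[str, str]]:
    """Full simulation: reference, population truth, reads, barcode key."""
    ref = generate_reference(config)
    truth = simulate_population(config, ref)
    reads, key = generate_reads(truth, ref, config)
    return ref, truth, reads, key
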