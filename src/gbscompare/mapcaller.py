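"""Reference-mapping SNP caller: quality trim → ungapped map (≤3 mismatches)
→ pileup with quality-aware diploid genotype likelihoods → site filters.

Mapping is exact seed-and-verify: reads are seeded with non-overlapping
16-mers against an index of all reference 16-mers on both strands, and each
candidate placement is verified by Hamming count. For reads of 64 bp and
``max_mismatch`` = 3 the pigeonhole principle makes the search exhaustive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, SITE_COLUMNS, GenotypeMatrix
from .io import FastqRead, read_fastq
from .sim import ReferenceSet, encode_seq

SEED_K = 16


# ---------------------------------------------------------------------------
# Quality trimming
# ---------------------------------------------------------------------------


def quality_trim(
    reads: list[FastqRead],
    min_end_quality: int = 20,
    min_length: int = 35,
    min_mean_quality: float = 30.0,
) -> list[FastqRead]:
    """Trim low-quality read ends and drop short or low-mean-quality reads.

    Leading and trailing bases with Phred quality below ``min_end_quality``
    are removed; reads shorter than ``min_length`` after trimming, or with
    mean quality below ``min_mean_quality``, are dropped.
    """
    out: list[FastqRead] = []
    for r in reads:
        q = r.qualities()
        lo, hi = 0, len(q)
        while lo < hi and q[lo] < min_end_quality:
            lo += 1
        while hi > lo and q[hi - 1] < min_end_quality:
            hi -= 1
        if hi - lo < min_length:
            continue
        if q[lo:hi].mean() < min_mean_quality:
            continue
        out.append(FastqRead(id=r.id, seq=r.seq[lo:hi], qual=r.qual[lo:hi]))
    return out


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """Chosen placement of one read (ungapped, forward or reverse strand)."""

    read_index: int
    sample: str
    contig: str
    start: int  # 0-based on the forward strand
    strand: str  # "+" or "-"
    mismatches: int
    n_equally_best_placements: int

    @property
    def unique(self) -> bool:
        return self.n_equally_best_placements == 1


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1].astype(np.uint8)


class ReadMapper:
    """Exhaustive ungapped mapper over a small reference.

    Indexes every forward-strand 16-mer; a read is queried in both
    orientations with seeds at offsets 0, 16, 32, … and len−16, and every
    seeded placement is Hamming-verified. All placements with at most
    ``max_mismatch`` mismatches are found for reads of ≥ (max_mismatch+1)·16
    bases; the best (fewest-mismatch) placements are retained, ties resolved
    to the first by (contig order, position, strand).
    """

    def __init__(self, contigs: dict[str, str], max_mismatch: int = 3):
        self.max_mismatch = max_mismatch
        self.contig_names = list(contigs)
        self.codes = {name: encode_seq(seq) for name, seq in contigs.items()}
        self._index: dict[bytes, list[tuple[int, int]]] = {}
        for ci, name in enumerate(self.contig_names):
            arr = self.codes[name]
            for p in range(len(arr) - SEED_K + 1):
                self._index.setdefault(arr[p : p + SEED_K].tobytes(), []).append((ci, p))

    def placements(self, codes: np.ndarray) -> list[tuple[int, int, str, int]]:
        """All (contig_idx, start, strand, mismatches) with mm ≤ max_mismatch."""
        L = codes.size
        if L < SEED_K:
            return []
        found: dict[tuple[int, int, str], int] = {}
        for strand, oriented in (("+", codes), ("-", revcomp_codes(codes))):
            offsets = list(range(0, L - SEED_K + 1, SEED_K))
            if offsets[-1] != L - SEED_K:
                offsets.append(L - SEED_K)
            seen_starts: set[tuple[int, int]] = set()
            for off in offsets:
                for ci, p in self._index.get(oriented[off : off + SEED_K].tobytes(), ()):
                    start = p - off
                    if start < 0 or (ci, start) in seen_starts:
                        continue
                    seen_starts.add((ci, start))
                    ref = self.codes[self.contig_names[ci]]
                    if start + L > ref.size:
                        continue
                    mm = int(np.count_nonzero(ref[start : start + L] != oriented))
                    if mm <= self.max_mismatch:
                        found[(ci, start, strand)] = mm
        return [(ci, s, st, mm) for (ci, s, st), mm in found.items()]

    def map_read(self, seq: str) -> tuple[tuple[int, int, str, int], int] | None:
        """Best placement and the count of equally best placements, or None."""
        plc = self.placements(encode_seq(seq))
        if not plc:
            return None
        best_mm = min(mm for *_, mm in plc)
        best = sorted(
            (p for p in plc if p[3] == best_mm),
            key=lambda p: (p[0], p[1], 0 if p[2] == "+" else 1),
        )
        return best[0], len(best)


def map_reads(
    reads: list[tuple[str, FastqRead]],
    ref: ReferenceSet | dict[str, str],
    max_mismatch: int = 3,
) -> tuple[list[Alignment], list[FastqRead]]:
    """Map (sample, read) pairs; unmapped reads are removed.

    Returns the chosen alignments plus the mapped reads in matching order.
    """
    contigs = ref.contigs if isinstance(ref, ReferenceSet) else ref
    mapper = ReadMapper(contigs, max_mismatch)
    alignments: list[Alignment] = []
    mapped_reads: list[FastqRead] = []
    for sample, read in reads:
        hit = mapper.map_read(read.seq)
        if hit is None:
            continue
        (ci, start, strand, mm), n_best = hit
        alignments.append(
            Alignment(
                read_index=len(mapped_reads),
                sample=sample,
                contig=mapper.contig_names[ci],
                start=start,
                strand=strand,
                mismatches=mm,
                n_equally_best_placements=n_best,
            )
        )
        mapped_reads.append(read)
    return alignments, mapped_reads


# ---------------------------------------------------------------------------
# Pileup and genotype calling
# ---------------------------------------------------------------------------


@dataclass
class TmCallSet:
    """Reference-coordinate call set: genotypes, per-site annotations, report."""

    genotypes: GenotypeMatrix
    depths: np.ndarray  # samples × sites
    site_info: pd.DataFrame  # DP, MQ0, QUAL, QD per site
    params: dict = field(default_factory=dict)
    report: pd.DataFrame | None = None

    @property
    def n_sites(self) -> int:
        return self.genotypes.n_sites

    def take_sites(self, index: np.ndarray) -> "TmCallSet":
        index = np.asarray(index)
        return TmCallSet(
            genotypes=self.genotypes.take_sites(index),
            depths=self.depths[:, index].copy(),
            site_info=self.site_info.iloc[index].reset_index(drop=True),
            params=dict(self.params),
            report=self.report,
        )


def pileup_and_call(
    alignments: list[Alignment],
    reads: list[FastqRead],
    ref: ReferenceSet | dict[str, str],
    samples: list[str],
    het_prior: float = 1e-3,
) -> TmCallSet:
    """Diploid genotype likelihoods from an ungapped pileup.

    Per base with error probability e (from its Phred quality) the
    likelihood contributions are (1−e) for a matching homozygote, e/3 for a
    non-matching one and (1−e)/2 + e/6 for a heterozygote carrying the base.
    Genotypes maximise likelihood × prior with prior heterozygosity
    ``het_prior`` (hom-alt prior ``het_prior``/2), the convention of
    standard mapping-based callers. A site is emitted when at least one
    sample is called non-reference; the alternate allele is the most
    frequent non-reference base. QUAL is −10·log10 of the posterior
    probability that every sample is homozygous reference; QD divides QUAL
    by the total depth of variant-carrying samples.
    """
    contigs = ref.contigs if isinstance(ref, ReferenceSet) else ref
    sample_index = {s: i for i, s in enumerate(samples)}
    n_samples = len(samples)
    by_contig: dict[str, list[Alignment]] = {}
    for aln in alignments:
        by_contig.setdefault(aln.contig, []).append(aln)

    log_half = np.log(0.5)
    pi_het = het_prior
    pi_hom_alt = het_prior / 2.0
    log_priors = np.log([1.0 - pi_het - pi_hom_alt, pi_het, pi_hom_alt])

    rows = []
    geno_cols, depth_cols = [], []
    for contig in contigs:
        if contig not in by_contig:
            continue
        ref_codes = encode_seq(contigs[contig])
        L = ref_codes.size
        # per (sample, base, pos): read count and the three log-likelihood
        # accumulators (match, mismatch, het-carrier)
        cnt = np.zeros((n_samples, 4, L), dtype=np.int32)
        log_match = np.zeros((n_samples, 4, L), dtype=np.float64)
        log_mismatch = np.zeros((n_samples, 4, L), dtype=np.float64)
        log_het = np.zeros((n_samples, 4, L), dtype=np.float64)
        mq0 = np.zeros(L, dtype=np.int32)
        for aln in by_contig[contig]:
            read = reads[aln.read_index]
            codes = encode_seq(read.seq)
            e = 10.0 ** (-read.qualities() / 10.0)
            if aln.strand == "-":
                codes = revcomp_codes(codes)
                e = e[::-1]
            si = sample_index[aln.sample]
            span = slice(aln.start, aln.start + codes.size)
            pos = np.arange(aln.start, aln.start + codes.size)
            cnt[si, codes, pos] += 1
            log_match[si, codes, pos] += np.log1p(-e)
            log_mismatch[si, codes, pos] += np.log(e / 3.0)
            log_het[si, codes, pos] += np.log((1.0 - e) / 2.0 + e / 6.0)
            if aln.n_equally_best_placements > 1:
                mq0[span] += 1

        total_cnt = cnt.sum(axis=0)  # 4 × L
        pooled_depth = total_cnt.sum(axis=0)
        nonref = total_cnt.copy()
        nonref[ref_codes, np.arange(L)] = 0
        cand = np.flatnonzero(nonref.sum(axis=0) > 0)
        for p in cand:
            r = int(ref_codes[p])
            a = int(np.argmax(nonref[:, p]))
            others = [b for b in range(4) if b not in (r, a)]
            # per-sample log-likelihoods of hom-ref / het / hom-alt
            ll = np.zeros((n_samples, 3))
            ll[:, 0] = log_match[:, r, p] + log_mismatch[:, a, p]
            ll[:, 1] = log_het[:, r, p] + log_het[:, a, p]
            ll[:, 2] = log_mismatch[:, r, p] + log_match[:, a, p]
            for b in others:
                ll += log_mismatch[:, b, p][:, None]
            post = ll + log_priors
            geno = post.argmax(axis=1).astype(np.int8)
            depth = cnt[:, :, p].sum(axis=1)
            geno[depth == 0] = MISSING
            if not (geno > 0).any():
                continue
            # QUAL: normalized (flat-prior) probability all samples are
            # hom-ref — evidence only; the prior weights assignment above
            m = ll.max(axis=1, keepdims=True)
            norm = m[:, 0] + np.log(np.exp(ll - m).sum(axis=1))
            log_p0 = float(np.sum((ll[:, 0] - norm)[depth > 0]))
            qual = -10.0 * log_p0 / np.log(10.0)
            carriers = depth[geno > 0].sum()
            qd = qual / carriers if carriers > 0 else float("nan")
            rows.append(
                {
                    "site_id": f"{contig}:{p}",
                    "contig": contig,
                    "pos": int(p),
                    "ref": "ACGT"[r],
                    "alt": "ACGT"[a],
                    "DP": int(pooled_depth[p]),
                    "MQ0": int(mq0[p]),
                    "QUAL": float(qual),
                    "QD": float(qd),
                }
            )
            geno_cols.append(geno)
            depth_cols.append(depth)

    info = pd.DataFrame(rows, columns=SITE_COLUMNS + ["DP", "MQ0", "QUAL", "QD"])
    sites = info[SITE_COLUMNS].copy()
    G = np.asarray(geno_cols, dtype=np.int8).T if geno_cols else np.zeros((n_samples, 0), np.int8)
    D = np.asarray(depth_cols, dtype=np.int64).T if depth_cols else np.zeros((n_samples, 0), np.int64)
    return TmCallSet(
        genotypes=GenotypeMatrix(samples=list(samples), sites=sites, G=G),
        depths=D,
        site_info=info,
        params={"het_prior": het_prior},
    )


# ---------------------------------------------------------------------------
# Site filters
# ---------------------------------------------------------------------------


def snp_cluster_mask(site_info: pd.DataFrame, window: int = 10, max_in_window: int = 3) -> np.ndarray:
    """True for sites lying in any ``window``-bp window holding more than
    ``max_in_window`` sites (all sites of such a window are voided)."""
    bad = np.zeros(len(site_info), dtype=bool)
    for _, grp in site_info.groupby("contig", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        j = 0
        for i in range(len(pos)):
            while pos[i] - pos[j] >= window:
                j += 1
            if i - j + 1 > max_in_window:
                bad[idx[j : i + 1]] = True
    return bad


def filter_tm(
    callset: TmCallSet,
    cluster_window: int = 10,
    cluster_max: int = 3,
    mq0_min: int = 4,
    mq0_frac: float = 0.1,
    qual_min: float = 60.0,
    qd_quantile: float = 0.05,
    na_max: float = 0.1,
) -> TmCallSet:
    """The mapping pipeline's site filters, applied in order.

    (1) SNP cluster: void every site in a 10-bp window holding > 3 sites;
    (2) hard-to-validate: remove when MQ0 ≥ 4 and MQ0/DP > 0.1;
    (3) remove QUAL ≤ 60; (4) remove QD at or below its empirical 5%
    quantile (recomputed per run and logged); (5) keep site depth ≤ the
    median over surviving sites; (6) keep missing fraction ≤ 0.1.
    """
    n0 = callset.n_sites
    stages: list[tuple[str, int]] = [("input", n0)]

    bad = snp_cluster_mask(callset.site_info, cluster_window, cluster_max)
    cs = callset.take_sites(np.flatnonzero(~bad))
    stages.append(("SnpCluster", cs.n_sites))

    info = cs.site_info
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = info["MQ0"].to_numpy() / info["DP"].to_numpy()
    hard = (info["MQ0"].to_numpy() >= mq0_min) & (frac > mq0_frac)
    cs = cs.take_sites(np.flatnonzero(~hard))
    stages.append(("HardToValidate", cs.n_sites))

    cs = cs.take_sites(np.flatnonzero(cs.site_info["QUAL"].to_numpy() > qual_min))
    stages.append(("LowQual", cs.n_sites))

    qd = cs.site_info["QD"].to_numpy()
    if qd_quantile > 0 and len(qd):
        qd_thresh = float(np.nanquantile(qd, qd_quantile))
    else:
        qd_thresh = float("-inf")
    cs = cs.take_sites(np.flatnonzero(qd > qd_thresh))
    stages.append(("LowQD", cs.n_sites))

    dp = cs.site_info["DP"].to_numpy()
    dp_max = float(np.median(dp)) if len(dp) else float("nan")
    cs = cs.take_sites(np.flatnonzero(dp <= dp_max))
    stages.append(("HighDP", cs.n_sites))

    na = cs.genotypes.missing_fraction()
    cs = cs.take_sites(np.flatnonzero(na <= na_max))
    stages.append(("HighNA", cs.n_sites))

    report = pd.DataFrame(
        [
            {"stage": name, "removed": prev - n, "remaining": n}
            for (name, n), (_, prev) in zip(stages, [("", n0)] + stages[:-1])
        ]
    )
    cs.params = {
        **callset.params,
        "qual_min": qual_min,
        "qd_threshold": qd_thresh,
        "dp_max": dp_max,
        "na_max": na_max,
        "mq0_min": mq0_min,
        "mq0_frac": mq0_frac,
        "cluster": f"{cluster_max}/{cluster_window}bp",
    }
    cs.report = report
    return cs


def demultiplex_reads(
    reads: list[FastqRead] | str | Path, barcode_key: dict[str, str]
) -> list[tuple[str, FastqRead]]:
    """Assign reads to samples by exact barcode prefix and strip the barcode."""
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    by_barcode = {bc: s for s, bc in barcode_key.items()}
    lengths = sorted({len(bc) for bc in by_barcode})
    out: list[tuple[str, FastqRead]] = []
    for r in reads:
        for L in lengths:
            sample = by_barcode.get(r.seq[:L])
            if sample is not None:
                out.append((sample, FastqRead(id=r.id, seq=r.seq[L:], qual=r.qual[L:])))
                break
    return out


def call_tm(
    reads: list[FastqRead] | str | Path,
    barcode_key: dict[str, str],
    ref: ReferenceSet | dict[str, str],
    max_mismatch: int = 3,
    het_prior: float = 1e-3,
    apply_filters: bool = True,
    **filter_kwargs,
) -> TmCallSet:
    """Full mapping pipeline: demultiplex → quality trim → map → pileup →
    genotype likelihoods → site filters."""
    demuxed = demultiplex_reads(reads, barcode_key)
    # quality_trim drops reads, so pair samples with trimmed reads explicitly
    pairs: list[tuple[str, FastqRead]] = []
    for sample, read in demuxed:
        t = quality_trim([read])
        if t:
            pairs.append((sample, t[0]))
    alignments, mapped = map_reads(pairs, ref, max_mismatch)
    samples = list(barcode_key)
    callset = pileup_and_call(alignments, mapped, ref, samples, het_prior)
    callset.params.update({"max_mismatch": max_mismatch})
    if apply_filters and callset.n_sites:
        callset = filter_tm(callset, **filter_kwargs)
    return callset
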