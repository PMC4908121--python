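"""Reference-free SNP discovery from barcoded GBS reads (tag-pair network).

The procedure: perfect-barcode demultiplexing and 64-bp trimming, a tag
catalog of unique sequences seen at least ``min_total_count`` times across
all samples, reciprocal 1-bp-mismatch tag pairs as candidate SNPs, an
error-tolerance-rate (ETR) acceptance test on the minor tag's count
fraction, binomial-likelihood genotype calls, and the MAF / depth-median /
missingness site filters. One SNP per tag by construction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, SITE_COLUMNS, GenotypeMatrix
from .io import FastqRead, _check_barcodes, read_fastq


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------


def demultiplex_and_trim(
    reads: list[FastqRead] | str | Path,
    barcode_key: dict[str, str],
    tag_length: int = 64,
) -> dict[str, Counter]:
    """Per-sample tag multisets from barcoded reads.

    A read is kept iff its prefix exactly matches one barcode and the
    following ``tag_length`` bases contain no N; kept reads are trimmed to
    exactly ``tag_length`` bases after the barcode. Reads too short after the
    barcode are discarded.
    """
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    _check_barcodes(list(barcode_key.values()))
    by_barcode = {bc: sample for sample, bc in barcode_key.items()}
    lengths = sorted({len(bc) for bc in by_barcode})
    tags: dict[str, Counter] = {sample: Counter() for sample in barcode_key}
    for read in reads:
        for L in lengths:
            sample = by_barcode.get(read.seq[:L])
            if sample is None:
                continue
            tag = read.seq[L : L + tag_length]
            if len(tag) == tag_length and "N" not in tag:
                tags[sample][tag] += 1
            break  # non-prefix property: at most one barcode can match
    return tags


# ---------------------------------------------------------------------------
# Tag catalog
# ---------------------------------------------------------------------------


@dataclass
class TagCatalog:
    """Unique fixed-length tags with per-sample counts.

    Every stored tag's total count is at least ``min_total_count``; tags are
    kept in lexicographic order for reproducibility.
    """

    tags: list[str]
    counts: np.ndarray  # n_tags × n_samples
    samples: list[str]
    min_total_count: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.tags), len(self.samples)):
            raise ValueError("counts shape inconsistent with tags × samples")
        if self.tags:
            L = len(self.tags[0])
            if any(len(t) != L for t in self.tags):
                raise ValueError("mixed tag lengths in catalog")
            if (self.counts.sum(axis=1) < self.min_total_count).any():
                raise ValueError("catalog contains a tag below min_total_count")

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def tag_length(self) -> int:
        return len(self.tags[0]) if self.tags else 0

    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tags)}


def build_tag_catalog(
    per_sample_tags: dict[str, Counter], min_total_count: int = 5
) -> TagCatalog:
    """Merge per-sample tag multisets, dropping tags seen fewer than
    ``min_total_count`` times across all samples."""
    samples = list(per_sample_tags)
    totals: Counter = Counter()
    for c in per_sample_tags.values():
        totals.update(c)
    lengths = {len(t) for t in totals}
    if len(lengths) > 1:
        raise ValueError(f"mixed tag lengths: {sorted(lengths)}")
    kept = sorted(t for t, n in totals.items() if n >= min_total_count)
    counts = np.zeros((len(kept), len(samples)), dtype=np.int64)
    pos = {t: i for i, t in enumerate(kept)}
    for j, sample in enumerate(samples):
        for tag, n in per_sample_tags[sample].items():
            i = pos.get(tag)
            if i is not None:
                counts[i, j] = n
    return TagCatalog(tags=kept, counts=counts, samples=samples, min_total_count=min_total_count)


# ---------------------------------------------------------------------------
# Reciprocal tag pairs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagPair:
    """A reciprocal pair of tags differing at exactly one position.

    ``tag_a`` is the lexicographically smaller tag; its base at the mismatch
    position is ``allele_a``.
    """

    index_a: int
    index_b: int
    tag_a: str
    tag_b: str
    mismatch_position: int
    allele_a: str
    allele_b: str


def find_reciprocal_pairs(catalog: TagCatalog) -> list[TagPair]:
    """All reciprocal 1-mismatch tag pairs in the catalog.

    Masked-position indexing (tag with position p blanked) buckets every
    pair of tags at Hamming distance 1 exactly once, giving near-linear
    search. A pair is reciprocal iff each member's only distance-1 partner
    in the catalog is the other member.
    """
    if not catalog.tags:
        raise ValueError("empty catalog")
    n = len(catalog.tags)
    L = catalog.tag_length
    neighbor_count = np.zeros(n, dtype=np.int64)
    partner = np.full(n, -1, dtype=np.int64)
    edges: set[tuple[int, int]] = set()
    for p in range(L):
        buckets: dict[str, list[int]] = {}
        for i, t in enumerate(catalog.tags):
            buckets.setdefault(t[:p] + t[p + 1 :], []).append(i)
        for members in buckets.values():
            k = len(members)
            if k < 2:
                continue
            for i in members:
                neighbor_count[i] += k - 1
            if k == 2:
                a, b = members
                partner[a], partner[b] = b, a
                edges.add((min(a, b), max(a, b)))

    pairs: list[TagPair] = []
    for a, b in sorted(edges):
        if neighbor_count[a] == 1 and neighbor_count[b] == 1 and partner[a] == b:
            ta, tb = catalog.tags[a], catalog.tags[b]
            mm = next(i for i in range(L) if ta[i] != tb[i])
            pairs.append(
                TagPair(
                    index_a=a,
                    index_b=b,
                    tag_a=ta,
                    tag_b=tb,
                    mismatch_position=mm,
                    allele_a=ta[mm],
                    allele_b=tb[mm],
                )
            )
    return pairs


def etr_accept(total_a: int, total_b: int, etr: float) -> bool:
    """Error-tolerance-rate test: the minor tag's fraction of the pair's
    total count must reach ``etr``, otherwise the pair is attributed to
    sequencing error. This is the mechanism that discards rare variants."""
    total = total_a + total_b
    if total == 0:
        raise ValueError("pair with zero total count")
    return min(total_a, total_b) / total >= etr


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------


def call_genotypes_uneak(
    k_a: np.ndarray, k_b: np.ndarray, error_rate: float = 0.01
) -> np.ndarray:
    """Binomial-likelihood genotypes from per-sample tag counts.

    For counts (k_a, k_b), n = k_a + k_b:
    L(hom_a) = C(n, k_b)·(1−e)^k_a·e^k_b, L(hom_b) symmetric,
    L(het) = C(n, k_a)·(1/2)^n. The most likely genotype is assigned
    (0 = hom_a, 1 = het, 2 = hom_b); ties break toward het; n = 0 is missing.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must lie in (0, 0.5)")
    k_a = np.asarray(k_a, dtype=np.int64)
    k_b = np.asarray(k_b, dtype=np.int64)
    if (k_a < 0).any() or (k_b < 0).any():
        raise ValueError("negative counts")
    n = k_a + k_b
    log_choose = gammaln(n + 1) - gammaln(k_a + 1) - gammaln(k_b + 1)
    log_e, log_1me = np.log(error_rate), np.log1p(-error_rate)
    ll = np.stack(
        [
            log_choose + k_a * log_1me + k_b * log_e,  # hom_a
            log_choose - n * np.log(2.0),  # het
            log_choose + k_b * log_1me + k_a * log_e,  # hom_b
        ]
    )
    best = ll.max(axis=0)
    geno = np.where(
        np.isclose(ll[1], best, rtol=0.0, atol=1e-12), 1, np.argmax(ll, axis=0)
    ).astype(np.int8)
    geno[n == 0] = MISSING
    return geno


# ---------------------------------------------------------------------------
# Call set and filters
# ---------------------------------------------------------------------------


@dataclass
class UneakCallSet:
    """Called tag-pair SNPs: genotypes, depths, tag table, filter report.

    Site coordinates use the synthetic contig name "TAGPAIR" with the
    in-tag mismatch offset as position; ``pairs`` retains the tag sequences
    so sites can later be lifted onto a reference.
    """

    genotypes: GenotypeMatrix
    depths: np.ndarray  # samples × sites, k_a + k_b
    pairs: pd.DataFrame  # pair_id, tag_a, tag_b, offset, alleles, totals
    params: dict = field(default_factory=dict)
    report: pd.DataFrame | None = None

    @property
    def n_sites(self) -> int:
        return self.genotypes.n_sites

    def take_sites(self, index: np.ndarray) -> "UneakCallSet":
        index = np.asarray(index)
        return UneakCallSet(
            genotypes=self.genotypes.take_sites(index),
            depths=self.depths[:, index].copy(),
            pairs=self.pairs.iloc[index].reset_index(drop=True),
            params=dict(self.params),
            report=self.report,
        )


PAIR_COLUMNS = [
    "pair_id", "tag_a", "tag_b", "offset", "allele_a", "allele_b", "total_a", "total_b",
]


def genotype_tag_pairs(
    catalog: TagCatalog,
    pairs: list[TagPair],
    etr: float = 0.03,
    error_rate: float = 0.01,
) -> UneakCallSet:
    """ETR-accept candidate pairs and call per-sample genotypes."""
    accepted = [
        p for p in pairs if etr_accept(int(catalog.totals[p.index_a]), int(catalog.totals[p.index_b]), etr)
    ]
    rows, geno_cols, depth_cols = [], [], []
    for i, p in enumerate(accepted):
        ka = catalog.counts[p.index_a]
        kb = catalog.counts[p.index_b]
        g = call_genotypes_uneak(ka, kb, error_rate)
        pair_id = f"TP{i:06d}"
        rows.append(
            {
                "pair_id": pair_id,
                "tag_a": p.tag_a,
                "tag_b": p.tag_b,
                "offset": p.mismatch_position,
                "allele_a": p.allele_a,
                "allele_b": p.allele_b,
                "total_a": int(catalog.totals[p.index_a]),
                "total_b": int(catalog.totals[p.index_b]),
            }
        )
        geno_cols.append(g)
        depth_cols.append(ka + kb)
    pair_df = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    sites = pd.DataFrame(
        {
            "site_id": pair_df["pair_id"],
            "contig": "TAGPAIR",
            "pos": pair_df["offset"],
            "ref": pair_df["allele_a"],
            "alt": pair_df["allele_b"],
        },
        columns=SITE_COLUMNS,
    )
    n_samples = len(catalog.samples)
    G = np.asarray(geno_cols, dtype=np.int8).T if geno_cols else np.zeros((n_samples, 0), np.int8)
    D = np.asarray(depth_cols, dtype=np.int64).T if depth_cols else np.zeros((n_samples, 0), np.int64)
    return UneakCallSet(
        genotypes=GenotypeMatrix(samples=list(catalog.samples), sites=sites, G=G),
        depths=D,
        pairs=pair_df,
        params={"etr": etr, "error_rate": error_rate},
    )


def filter_uneak(
    callset: UneakCallSet,
    maf_min: float = 0.05,
    na_max: float = 0.1,
) -> UneakCallSet:
    """Site filters in order: MAF, depth median, missingness.

    (1) minor allele frequency ≥ ``maf_min`` on called genotypes;
    (2) site total depth ≤ median depth over sites surviving (1);
    (3) missing genotype fraction strictly below ``na_max``.
    Per-stage removal counts land in the returned set's ``report``.
    """
    n0 = callset.n_sites
    maf = callset.genotypes.minor_allele_freq()
    keep1 = np.flatnonzero(np.nan_to_num(maf) >= maf_min)
    cs1 = callset.take_sites(keep1)

    site_dp = cs1.depths.sum(axis=0)
    dp_max = float(np.median(site_dp)) if len(site_dp) else float("nan")
    keep2 = np.flatnonzero(site_dp <= dp_max)
    cs2 = cs1.take_sites(keep2)

    na = cs2.genotypes.missing_fraction()
    keep3 = np.flatnonzero(na < na_max)
    cs3 = cs2.take_sites(keep3)

    report = pd.DataFrame(
        [
            {"stage": "input", "removed": 0, "remaining": n0},
            {"stage": f"MAF<{maf_min}", "removed": n0 - cs1.n_sites, "remaining": cs1.n_sites},
            {"stage": f"DP>{dp_max:g}", "removed": cs1.n_sites - cs2.n_sites, "remaining": cs2.n_sites},
            {"stage": f"NA>={na_max}", "removed": cs2.n_sites - cs3.n_sites, "remaining": cs3.n_sites},
        ]
    )
    cs3.params = {**callset.params, "maf_min": maf_min, "na_max": na_max, "dp_max": dp_max}
    cs3.report = report
    return cs3


def call_uneak(
    reads: list[FastqRead] | str | Path,
    barcode_key: dict[str, str],
    tag_length: int = 64,
    min_tag_count: int = 5,
    etr: float = 0.03,
    error_rate: float = 0.01,
    maf_min: float = 0.05,
    na_max: float = 0.1,
    apply_filters: bool = True,
) -> UneakCallSet:
    """Full reference-free pipeline: demultiplex → catalog → pairs → ETR →
    genotypes → site filters."""
    per_sample = demultiplex_and_trim(reads, barcode_key, tag_length)
    catalog = build_tag_catalog(per_sample, min_tag_count)
    if not catalog.tags:
        raise ValueError("no tags reached the catalog count threshold")
    pairs = find_reciprocal_pairs(catalog)
    callset = genotype_tag_pairs(catalog, pairs, etr=etr, error_rate=error_rate)
    callset.params.update({"tag_length": tag_length, "min_tag_count": min_tag_count})
    if apply_filters and callset.n_sites:
        callset = filter_uneak(callset, maf_min=maf_min, na_max=na_max)
    return callset
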