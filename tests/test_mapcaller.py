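"""Mapping caller: trimming, exhaustive ungapped alignment, pileup
likelihoods, site filters."""

import math

import numpy as np
import pandas as pd
import pytest

from gbscompare.genotypes import MISSING
from gbscompare.io import FastqRead
from gbscompare.mapcaller import (
    ReadMapper,
    TmCallSet,
    filter_tm,
    map_reads,
    pileup_and_call,
    quality_trim,
    snp_cluster_mask,
)
from gbscompare.mapcaller import revcomp_codes
from gbscompare.sim import decode_seq, encode_seq


def _q(chars):
    return FastqRead(id="r", seq="A" * len(chars), qual=chars)


class TestQualityTrim:
    def test_clean_read_kept_unchanged(self):
        r = FastqRead(id="r", seq="A" * 64, qual="?" * 64)  # Q30
        out = quality_trim([r])
        assert out == [r]

    def test_trimmed_below_min_length_dropped(self):
        # 34 good bases flanked by Q10 ('+') tails
        qual = "+" * 5 + "?" * 34 + "+" * 5
        assert quality_trim([_q(qual)]) == []

    def test_low_mean_quality_dropped(self):
        # alternating Q20/Q39 -> mean 29.5 < 30
        qual = ("5H" * 32)  # '5'=Q20, 'H'=Q39
        assert quality_trim([_q(qual)]) == []

    def test_end_trimming_keeps_core(self):
        qual = "+" * 3 + "?" * 40 + "+" * 2
        out = quality_trim([_q(qual)])
        assert len(out) == 1 and len(out[0].seq) == 40


def _random_contig(rng, n):
    return decode_seq(rng.integers(0, 4, size=n).astype(np.uint8))


class TestMapping:
    rng = np.random.default_rng(0)
    c1 = _random_contig(rng, 400)
    c2 = _random_contig(rng, 400)
    contigs = {"c1": c1, "c2": c2}

    def test_unique_exact_read(self):
        mapper = ReadMapper(self.contigs)
        read = self.c1[100:164]
        (ci, start, strand, mm), n_best = mapper.map_read(read)
        assert (ci, start, strand, mm, n_best) == (0, 100, "+", 0, 1)

    def test_reverse_strand_read(self):
        mapper = ReadMapper(self.contigs)
        read = decode_seq(revcomp_codes(encode_seq(self.c1[100:164])))
        (ci, start, strand, mm), n_best = mapper.map_read(read)
        assert (ci, start, strand, mm) == (0, 100, "-", 0)

    def test_duplicated_region_counts_both_placements(self):
        dup = self.c1[50:150]
        contigs = {"c1": self.c1, "c2": self.c2[:200] + dup + self.c2[200:]}
        mapper = ReadMapper(contigs)
        _, n_best = mapper.map_read(self.c1[60:124])
        assert n_best == 2

    def test_too_many_mismatches_unmapped(self):
        mapper = ReadMapper(self.contigs)
        read = list(self.c1[100:164])
        for i in (5, 20, 40, 60):
            read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
        assert mapper.map_read("".join(read)) is None

    def test_three_mismatches_found_anywhere(self):
        # pigeonhole exhaustiveness: mutate any 3 positions, still mapped
        mapper = ReadMapper(self.contigs)
        rng = np.random.default_rng(5)
        for _ in range(20):
            read = list(self.c1[200:264])
            for i in rng.choice(64, size=3, replace=False):
                read[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[i]]
            hit = mapper.map_read("".join(read))
            assert hit is not None
            (ci, start, _, mm), _ = hit
            assert (ci, start, mm) == (0, 200, 3)


def _call_single_site(n_ref, n_alt, qual_char="?"):
    """One sample, reads covering one 64-bp window with an alt base at 32."""
    rng = np.random.default_rng(1)
    contig = _random_contig(rng, 200)
    ref = {"c": contig}
    window = contig[50:114]
    alt_base = {"A": "C", "C": "G", "G": "T", "T": "A"}[window[32]]
    reads = []
    for _ in range(n_ref):
        reads.append(("s0", FastqRead(id="r", seq=window, qual=qual_char * 64)))
    alt_read = window[:32] + alt_base + window[33:]
    for _ in range(n_alt):
        reads.append(("s0", FastqRead(id="r", seq=alt_read, qual=qual_char * 64)))
    alns, mapped = map_reads(reads, ref)
    return pileup_and_call(alns, mapped, ref, ["s0"])


def _oracle_loglik(n_ref, n_alt, e):
    """Direct likelihood arithmetic for a single diploid sample."""
    l0 = n_ref * math.log(1 - e) + n_alt * math.log(e / 3)
    l1 = (n_ref + n_alt) * math.log((1 - e) / 2 + e / 6)
    l2 = n_alt * math.log(1 - e) + n_ref * math.log(e / 3)
    return l0, l1, l2


class TestPileupCall:
    def test_all_alt_reads_give_hom_alt_high_qual(self):
        cs = _call_single_site(0, 10)
        assert cs.n_sites == 1
        assert cs.genotypes.G[0, 0] == 2
        assert cs.site_info["QUAL"][0] > 60
        # QUAL agrees with the normalized-likelihood oracle
        l0, l1, l2 = _oracle_loglik(0, 10, 1e-3)
        m = max(l0, l1, l2)
        p0 = math.exp(l0 - m) / sum(math.exp(x - m) for x in (l0, l1, l2))
        assert cs.site_info["QUAL"][0] == pytest.approx(-10 * math.log10(p0), rel=1e-6)

    def test_balanced_reads_give_het(self):
        cs = _call_single_site(5, 5)
        assert cs.genotypes.G[0, 0] == 1
        l0, l1, l2 = _oracle_loglik(5, 5, 1e-3)
        assert l1 > max(l0, l2)  # oracle agrees het is ML

    def test_no_alt_reads_no_site(self):
        cs = _call_single_site(10, 0)
        assert cs.n_sites == 0

    def test_qd_bounded_by_qual(self):
        cs = _call_single_site(3, 7)
        assert cs.site_info["QD"][0] <= cs.site_info["QUAL"][0]


def _toy_callset(positions, mq0=None, qual=None, dp=None, missing_col=None, n_samples=5):
    n = len(positions)
    sites = pd.DataFrame(
        {
            "site_id": [f"c:{p}" for p in positions],
            "contig": "c",
            "pos": positions,
            "ref": "A",
            "alt": "G",
        }
    )
    info = sites.copy()
    info["DP"] = dp if dp is not None else [20] * n
    info["MQ0"] = mq0 if mq0 is not None else [0] * n
    info["QUAL"] = qual if qual is not None else [100.0] * n
    info["QD"] = info["QUAL"] / info["DP"]
    G = np.ones((n_samples, n), dtype=np.int8)
    if missing_col is not None:
        G[0, missing_col] = MISSING
    from gbscompare.genotypes import GenotypeMatrix

    gm = GenotypeMatrix(samples=[f"s{i}" for i in range(n_samples)], sites=sites, G=G)
    D = np.full((n_samples, n), 4)
    return TmCallSet(genotypes=gm, depths=D, site_info=info)


class TestFilters:
    def test_cluster_rule_voids_dense_window(self):
        cs = _toy_callset([100, 102, 104, 108, 300])
        out = filter_tm(cs, qual_min=0, qd_quantile=0, na_max=1.0)
        assert list(out.site_info["pos"]) == [300]

    def test_cluster_filter_idempotent(self):
        cs = _toy_callset([100, 102, 104, 108, 300, 305, 311])
        m1 = snp_cluster_mask(cs.site_info)
        survivors = cs.take_sites(np.flatnonzero(~m1))
        m2 = snp_cluster_mask(survivors.site_info)
        assert not m2.any()

    def test_mq0_rule_requires_both_conditions(self):
        # MQ0=4, DP=20 -> 0.2 > 0.1 removed; MQ0=3, DP=10 -> kept
        cs = _toy_callset([100, 300], mq0=[4, 3], dp=[20, 10])
        out = filter_tm(cs, qual_min=0, qd_quantile=0, na_max=1.0)
        assert list(out.site_info["pos"]) == [300]

    def test_qual_boundary_inclusive_removal(self):
        cs = _toy_callset([100, 300], qual=[60.0, 61.0], dp=[1, 1])
        out = filter_tm(cs, qd_quantile=0, na_max=1.0)
        assert list(out.site_info["pos"]) == [300]

    def test_qd_quantile_removes_lowest(self):
        quals = [100.0 + i for i in range(40)]
        cs = _toy_callset(list(range(0, 40 * 20, 20)), qual=quals, dp=[10] * 40)
        out = filter_tm(cs, qd_quantile=0.05, na_max=1.0)
        assert len(out.site_info) < 40
        assert out.site_info["QD"].min() > out.params["qd_threshold"]

    def test_dp_median_and_missingness(self):
        cs = _toy_callset([0, 100, 200], dp=[10, 20, 30], missing_col=0)
        out = filter_tm(cs, qual_min=0, qd_quantile=0, na_max=0.1)
        # DP 30 removed (median 20); site 0 has 1/5 missing = 0.2 > 0.1
        assert list(out.site_info["pos"]) == [100]
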