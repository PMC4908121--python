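"""Head-to-head comparison of the two call sets, optionally against truth.

Lifts tag-pair sites onto the reference by aligning their tag sequences,
identifies SNPs shared by both call sets (same contig, position and
unordered allele pair), correlates allele frequencies and per-sample
missing rates, and assembles the full comparison report: diversity
statistics with rank-sum p-values, observed vs expected folded SFS,
per-filter attrition, and truth-benchmarked concordance and rare-variant
recall.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .mapcaller import ReadMapper, TmCallSet
from .popgen import (
    FoldedSFS,
    expected_neutral_folded_sfs,
    folded_sfs,
    heterozygosity,
    tajimas_d,
)
from .sim import ReferenceSet, Truth, truth_at_tag_loci
from .tagcaller import UneakCallSet

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TAGHIT_COLUMNS = ["tag_id", "contig", "start", "strand", "mismatches", "n_best_placements", "perfect"]


def align_tags_to_reference(
    tags: dict[str, str] | pd.DataFrame,
    ref: ReferenceSet | dict[str, str],
    max_mismatch: int = 3,
) -> pd.DataFrame:
    """Exhaustive ≤``max_mismatch`` alignment of tag sequences to the reference.

    ``tags`` is a mapping tag_id -> sequence (or an UneakCallSet ``pairs``
    frame, whose ``tag_a`` is aligned). Returns one row per tag that hits,
    with unique/perfect flags; the frame's ``attrs`` carry the summary
    fractions (hit rate, unique among hits, perfect among unique).
    """
    if isinstance(tags, pd.DataFrame):
        tags = dict(zip(tags["pair_id"], tags["tag_a"]))
    if not tags:
        raise ValueError("empty tag set")
    contigs = ref.contigs if isinstance(ref, ReferenceSet) else ref
    mapper = ReadMapper(contigs, max_mismatch)
    rows = []
    for tag_id, seq in tags.items():
        hit = mapper.map_read(seq)
        if hit is None:
            continue
        (ci, start, strand, mm), n_best = hit
        rows.append(
            {
                "tag_id": tag_id,
                "contig": mapper.contig_names[ci],
                "start": start,
                "strand": strand,
                "mismatches": mm,
                "n_best_placements": n_best,
                "perfect": mm == 0,
            }
        )
    hits = pd.DataFrame(rows, columns=TAGHIT_COLUMNS)
    n = len(tags)
    n_hit = len(hits)
    n_unique = int((hits["n_best_placements"] == 1).sum()) if n_hit else 0
    uniq = hits[hits["n_best_placements"] == 1]
    n_perfect = int(uniq["perfect"].sum()) if n_unique else 0
    hits.attrs["fraction_hit"] = n_hit / n
    hits.attrs["fraction_unique_among_hits"] = n_unique / n_hit if n_hit else float("nan")
    hits.attrs["fraction_perfect_among_unique"] = n_perfect / n_unique if n_unique else float("nan")
    return hits


def lift_uneak_sites(uneak: UneakCallSet, hits: pd.DataFrame) -> pd.DataFrame:
    """Reference coordinates and alleles for tag-pair sites with a unique hit.

    On the plus strand the SNP sits at hit start + in-tag offset; on the
    minus strand at start + (tag_length − 1 − offset), with alleles
    complemented.
    """
    uniq = hits[hits["n_best_placements"] == 1].set_index("tag_id")
    rows = []
    tag_len = len(uneak.pairs["tag_a"].iloc[0]) if len(uneak.pairs) else 0
    for j, pr in enumerate(uneak.pairs.itertuples(index=False)):
        if pr.pair_id not in uniq.index:
            continue
        h = uniq.loc[pr.pair_id]
        if h["strand"] == "+":
            pos = int(h["start"]) + int(pr.offset)
            a, b = pr.allele_a, pr.allele_b
        else:
            pos = int(h["start"]) + (tag_len - 1 - int(pr.offset))
            a, b = pr.allele_a.translate(_COMPLEMENT), pr.allele_b.translate(_COMPLEMENT)
        rows.append(
            {
                "site_index": j,
                "pair_id": pr.pair_id,
                "contig": h["contig"],
                "pos": pos,
                "allele_a": a,
                "allele_b": b,
            }
        )
    return pd.DataFrame(
        rows, columns=["site_index", "pair_id", "contig", "pos", "allele_a", "allele_b"]
    )


SHARED_COLUMNS = [
    "uneak_id", "tm_id", "contig", "pos", "alleles",
    "freq_uneak", "freq_tm", "missing_uneak", "missing_tm",
]


def shared_snps(
    uneak: UneakCallSet, hits: pd.DataFrame, tm: TmCallSet
) -> pd.DataFrame:
    """SNPs present in both call sets: same contig, position and allele pair.

    Reported frequencies are of the minor allele as defined on the pooled
    genotypes of both call sets; ``pos`` is 1-based for reporting.
    """
    lifted = lift_uneak_sites(uneak, hits)
    tm_sites = tm.genotypes.sites
    tm_lookup = {
        (r.contig, int(r.pos)): (j, frozenset((r.ref, r.alt)))
        for j, r in enumerate(tm_sites.itertuples(index=False))
    }
    u_miss = uneak.genotypes.missing_fraction()
    t_miss = tm.genotypes.missing_fraction()
    rows = []
    for r in lifted.itertuples(index=False):
        entry = tm_lookup.get((r.contig, int(r.pos)))
        if entry is None:
            continue
        tj, tm_alleles = entry
        if frozenset((r.allele_a, r.allele_b)) != tm_alleles:
            continue
        uj = int(r.site_index)
        # allele_a dosage: UNEAK genotypes count allele_b copies
        u_freq_b = uneak.genotypes.allele_freq()[uj]
        tm_ref = tm_sites.iloc[tj]["ref"]
        t_freq_alt = tm.genotypes.allele_freq()[tj]
        freq_of = {
            r.allele_b: (u_freq_b, t_freq_alt if tm_ref != r.allele_b else 1 - t_freq_alt),
            r.allele_a: (1 - u_freq_b, 1 - t_freq_alt if tm_ref != r.allele_b else t_freq_alt),
        }
        # minor allele on the pooled sets
        pooled = {al: (fu + ft) / 2 for al, (fu, ft) in freq_of.items()}
        minor = min(sorted(pooled), key=lambda al: pooled[al])
        fu, ft = freq_of[minor]
        rows.append(
            {
                "uneak_id": r.pair_id,
                "tm_id": tm_sites.iloc[tj]["site_id"],
                "contig": r.contig,
                "pos": int(r.pos) + 1,
                "alleles": "/".join(sorted(tm_alleles)),
                "freq_uneak": float(fu),
                "freq_tm": float(ft),
                "missing_uneak": float(u_miss[uj]),
                "missing_tm": float(t_miss[tj]),
            }
        )
    return pd.DataFrame(rows, columns=SHARED_COLUMNS)


def correlation_report(
    shared: pd.DataFrame,
    sample_missing_uneak: np.ndarray,
    sample_missing_tm: np.ndarray,
) -> dict:
    """Pearson correlations over shared SNPs and per-sample missing rates.

    The UNEAK:TM per-sample missing-rate ratio excludes samples whose TM
    rate is zero (count reported).
    """
    if len(shared) < 2:
        raise ValueError("need at least two shared SNPs")
    freq_r = float(stats.pearsonr(shared["freq_uneak"], shared["freq_tm"])[0])
    miss_r = (
        float(stats.pearsonr(sample_missing_uneak, sample_missing_tm)[0])
        if len(sample_missing_uneak) >= 2
        else float("nan")
    )
    ok = sample_missing_tm > 0
    ratios = sample_missing_uneak[ok] / sample_missing_tm[ok]
    return {
        "n_shared": len(shared),
        "freq_r": freq_r,
        "missing_rate_r": miss_r,
        "missing_ratio_mean": float(np.mean(ratios)) if ratios.size else float("nan"),
        "missing_ratio_sd": float(np.std(ratios, ddof=1)) if ratios.size > 1 else float("nan"),
        "n_tm_zero_excluded": int((~ok).sum()),
        "shared_maf_distribution": shared[["freq_uneak", "freq_tm"]].describe(),
    }


# ---------------------------------------------------------------------------
# Truth benchmarking
# ---------------------------------------------------------------------------


def match_sites_to_truth(
    sites: pd.DataFrame, truth: Truth
) -> np.ndarray:
    """For each row of ``sites`` (contig, pos, ref, alt — reference
    coordinates), the index of the matching truth variant or −1.

    Matching requires the same contig, position and unordered allele pair.
    """
    lookup = {
        (r.contig, int(r.pos)): (i, frozenset((r.ref, r.alt)))
        for i, r in enumerate(truth.variants.itertuples(index=False))
    }
    out = np.full(len(sites), -1, dtype=int)
    for j, r in enumerate(sites.itertuples(index=False)):
        entry = lookup.get((r.contig, int(r.pos)))
        if entry and frozenset((r.ref, r.alt)) == entry[1]:
            out[j] = entry[0]
    return out


def genotype_concordance(
    called: GenotypeMatrix, called_idx: np.ndarray, truth: Truth, truth_idx: np.ndarray,
    flip: np.ndarray | None = None,
) -> float:
    """Fraction of non-missing called genotypes equal to truth at matched sites.

    ``flip`` marks called sites whose allele coding is reversed relative to
    the truth (dosage g becomes 2−g)."""
    if len(called_idx) == 0:
        return float("nan")
    Gc = called.G[:, called_idx].astype(int)
    if flip is not None:
        Gc = np.where(flip[None, :], np.where(Gc == MISSING, MISSING, 2 - Gc), Gc)
    Gt = truth.genotypes.G[:, truth_idx].astype(int)
    ok = Gc != MISSING
    if not ok.any():
        return float("nan")
    return float((Gc[ok] == Gt[ok]).mean())


def rare_bin_recall(
    truth_tags: GenotypeMatrix, matched_truth_ids: set[str], max_minor_count: int = 2
) -> float:
    """Fraction of tag-locus truth variants with folded count ≤
    ``max_minor_count`` that appear in the final call set."""
    alt = truth_tags.alt_counts()
    n = truth_tags.called_chroms()
    minor = np.minimum(alt, n - alt)
    rare = (minor >= 1) & (minor <= max_minor_count)
    if not rare.any():
        return float("nan")
    ids = truth_tags.sites["site_id"].to_numpy()
    return float(np.mean([sid in matched_truth_ids for sid in ids[rare]]))


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------


@dataclass
class ComparisonReport:
    """All paired summaries of the two call sets (and truth, when given)."""

    diversity: pd.DataFrame  # Table-1-style: statistic × (uneak, tm, p)
    sfs_tables: dict[str, pd.DataFrame]
    correlations: dict | None
    attrition: dict[str, pd.DataFrame]
    truth_metrics: dict | None
    metadata: dict = field(default_factory=dict)

    def render_text(self) -> str:
        lines = ["# Two-pipeline comparison report", "", "## Diversity statistics"]
        lines.append(self.diversity.to_string())
        if self.correlations:
            lines += ["", "## Shared-SNP correlations"]
            for k, v in self.correlations.items():
                if not isinstance(v, pd.DataFrame):
                    lines.append(f"{k}: {v}")
        for name, table in self.attrition.items():
            lines += ["", f"## Filter attrition: {name}", table.to_string(index=False)]
        if self.truth_metrics:
            lines += ["", "## Truth benchmarks"]
            for k, v in self.truth_metrics.items():
                lines.append(f"{k}: {v}")
        lines += ["", "## Metadata"]
        for k, v in self.metadata.items():
            lines.append(f"{k}: {v}")
        return "\n".join(lines) + "\n"


def _per_locus_stats(gm: GenotypeMatrix) -> dict[str, np.ndarray]:
    het = heterozygosity(gm)
    return {"H_exp": het.h_exp, "H_obs": het.h_obs}


def build_report(
    uneak: UneakCallSet,
    tm: TmCallSet,
    ref: ReferenceSet | None = None,
    truth: Truth | None = None,
    demes: list[str] | None = None,
) -> ComparisonReport:
    """Assemble the full two-pipeline comparison.

    Per-locus statistics are compared with a two-sided Wilcoxon rank-sum
    test (the choice of test is this package's; no multiple-testing
    correction is applied — four descriptive statistics). Truth sections
    are omitted when ``truth`` is None.
    """
    if set(uneak.genotypes.samples) != set(tm.genotypes.samples):
        raise ValueError("call sets cover different sample sets")

    stats_u = _per_locus_stats(uneak.genotypes)
    stats_t = _per_locus_stats(tm.genotypes)
    if demes is not None:
        from .popgen import f_statistics

        fs_u = f_statistics(uneak.genotypes, demes)
        fs_t = f_statistics(tm.genotypes, demes)
        for name in ("fst", "fis"):
            stats_u[name.upper()] = fs_u.loci[name].to_numpy()
            stats_t[name.upper()] = fs_t.loci[name].to_numpy()
    rows = {}
    for name in stats_u:
        u = stats_u[name][np.isfinite(stats_u[name])]
        t = stats_t[name][np.isfinite(stats_t[name])]
        if u.size and t.size:
            if u.size == t.size and np.allclose(np.sort(u), np.sort(t)):
                p = 1.0
            else:
                p = float(stats.ranksums(u, t).pvalue)
        else:
            p = float("nan")
        rows[name] = {
            "uneak_mean": float(np.mean(u)) if u.size else float("nan"),
            "uneak_median": float(np.median(u)) if u.size else float("nan"),
            "uneak_sd": float(np.std(u, ddof=1)) if u.size > 1 else float("nan"),
            "tm_mean": float(np.mean(t)) if t.size else float("nan"),
            "tm_median": float(np.median(t)) if t.size else float("nan"),
            "tm_sd": float(np.std(t, ddof=1)) if t.size > 1 else float("nan"),
            "p_value": p,
        }
    div_u = tajimas_d(uneak.genotypes)
    div_t = tajimas_d(tm.genotypes)
    for label, d in (("uneak", div_u), ("tm", div_t)):
        rows.setdefault("Tajimas_D", {})[f"{label}_mean"] = d.tajimas_d
        rows.setdefault("Theta_w", {})[f"{label}_mean"] = d.theta_w
        rows.setdefault("Theta_pi", {})[f"{label}_mean"] = d.theta_pi
    diversity = pd.DataFrame(rows).T

    sfs_tables = {}
    for label, gm in (("uneak", uneak.genotypes), ("tm", tm.genotypes)):
        sfs = folded_sfs(gm)
        tab = sfs.to_frame()
        tab["expected_neutral"] = expected_neutral_folded_sfs(sfs.n_chrom, sfs.S)
        sfs_tables[label] = tab

    correlations = None
    attrition = {}
    if uneak.report is not None:
        attrition["uneak"] = uneak.report
    if tm.report is not None:
        attrition["tm"] = tm.report

    truth_metrics = None
    hits = None
    if ref is not None and len(uneak.pairs):
        hits = align_tags_to_reference(uneak.pairs, ref)
        shared = shared_snps(uneak, hits, tm)
        if len(shared) >= 2:
            correlations = correlation_report(
                shared,
                uneak.genotypes.sample_missing_rate(),
                tm.genotypes.sample_missing_rate(),
            )

    if truth is not None and ref is not None:
        truth_tags = truth_at_tag_loci(truth, ref)
        tm_match = match_sites_to_truth(tm.genotypes.sites, truth)
        tm_called = np.flatnonzero(tm_match >= 0)
        conc_tm = genotype_concordance(tm.genotypes, tm_called, truth, tm_match[tm_called])
        matched_tm_ids = {truth.variants.iloc[i]["site_id"] for i in tm_match[tm_called]}

        u_sites, u_match, u_flip = uneak_sites_in_truth_coords(uneak, hits, truth)
        u_called = np.flatnonzero(u_match >= 0)
        conc_u = genotype_concordance(
            uneak.genotypes, u_sites[u_called], truth, u_match[u_called], u_flip[u_called]
        )
        matched_u_ids = {truth.variants.iloc[i]["site_id"] for i in u_match[u_called]}

        d_truth_tags = tajimas_d(truth_tags)
        truth_metrics = {
            "concordance_uneak": conc_u,
            "concordance_tm": conc_tm,
            "rare_recall_uneak": rare_bin_recall(truth_tags, matched_u_ids),
            "rare_recall_tm": rare_bin_recall(truth_tags, matched_tm_ids),
            "tajimas_d_truth_tag_loci": d_truth_tags.tajimas_d,
            "h_exp_truth_tag_loci_mean": float(
                np.nanmean(heterozygosity(truth_tags.drop_monomorphic()).h_exp)
            )
            if truth_tags.drop_monomorphic().n_sites
            else float("nan"),
        }

    return ComparisonReport(
        diversity=diversity,
        sfs_tables=sfs_tables,
        correlations=correlations,
        attrition=attrition,
        truth_metrics=truth_metrics,
        metadata={
            "paired_test": "two-sided Wilcoxon rank-sum on per-locus values",
            "multiple_testing": "none (descriptive report)",
            "fstat_estimator": "Weir-Cockerham 1984 variance components",
        },
    )


def pc_congruence(coords_a: np.ndarray, coords_b: np.ndarray, k: int = 2) -> list[float]:
    """Per-axis Pearson correlation of two PCA solutions after alignment.

    Principal axes are only identified up to sign — and up to rotation
    within a subspace when eigenvalues are close (three symmetric clusters
    make PC1/PC2 nearly degenerate) — so the second solution's leading ``k``
    axes are first aligned to the first's by orthogonal Procrustes rotation.
    """
    from scipy.linalg import orthogonal_procrustes

    A, B = coords_a[:, :k], coords_b[:, :k]
    R, _ = orthogonal_procrustes(B, A)
    B = B @ R
    return [float(stats.pearsonr(A[:, c], B[:, c])[0]) for c in range(k)]


def uneak_sites_in_truth_coords(
    uneak: UneakCallSet, hits: pd.DataFrame | None, truth: Truth
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match tag-pair sites to truth variants via their unique tag hits.

    Returns (call-set site indices, matching truth index or −1, flip flag)
    where flip means the pair's allele_a is the truth alt allele, so called
    dosages must be reversed before comparison with truth.
    """
    if hits is None or not len(uneak.pairs):
        z = np.zeros(0, dtype=int)
        return z, z, z.astype(bool)
    lifted = lift_uneak_sites(uneak, hits)
    lookup = {
        (r.contig, int(r.pos)): (i, r.ref, r.alt)
        for i, r in enumerate(truth.variants.itertuples(index=False))
    }
    site_idx, match, flip = [], [], []
    for r in lifted.itertuples(index=False):
        site_idx.append(int(r.site_index))
        entry = lookup.get((r.contig, int(r.pos)))
        if entry and {r.allele_a, r.allele_b} == {entry[1], entry[2]}:
            match.append(entry[0])
            flip.append(r.allele_a == entry[2])  # allele_a is the alt allele
        else:
            match.append(-1)
            flip.append(False)
    return np.asarray(site_idx), np.asarray(match), np.asarray(flip, dtype=bool)
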