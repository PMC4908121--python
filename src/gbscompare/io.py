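"""Shared file I/O: FASTQ, barcode key files, VCF, run manifests.

All writers are deterministic given fixed inputs; internal coordinates are
0-based half-open and converted to each format's own convention on output
(VCF positions are 1-based).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, SITE_COLUMNS, GenotypeMatrix

PHRED_OFFSET = 33


@dataclass(frozen=True)
class FastqRead:
    """One single-end read: identifier, sequence, Phred+33 quality string."""

    id: str
    seq: str
    qual: str

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def qualities(self) -> np.ndarray:
        """Per-base Phred scores."""
        return np.frombuffer(self.qual.encode(), dtype=np.uint8).astype(int) - PHRED_OFFSET


def write_fastq(path: str | Path, reads: list[FastqRead]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{r.qual}\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    """Parse a 4-line FASTQ file; raises on truncated or malformed records."""
    reads: list[FastqRead] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ ({len(lines)} lines)")
    for i in range(0, len(lines), 4):
        header, seq, plus, qual = lines[i : i + 4]
        if not header.startswith("@") or not plus.startswith("+"):
            raise ValueError(f"{path}: malformed record at line {i + 1}")
        reads.append(FastqRead(id=header[1:].split()[0] if header[1:] else "", seq=seq, qual=qual))
    return reads


def write_barcode_key(path: str | Path, barcodes: dict[str, str]) -> None:
    """Write a minimal tab-separated barcode key: sample_id <TAB> barcode."""
    with open(path, "w") as fh:
        fh.write("sample_id\tbarcode\n")
        for sample, bc in barcodes.items():
            fh.write(f"{sample}\t{bc}\n")


def read_barcode_key(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "barcode"}.issubset(df.columns):
        raise ValueError(f"{path}: expected columns sample_id, barcode")
    key = dict(zip(df["sample_id"], df["barcode"]))
    _check_barcodes(list(key.values()))
    return key


def _check_barcodes(barcodes: list[str]) -> None:
    """Barcodes must be pairwise non-prefix, else demultiplexing is ambiguous."""
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes in key")
    for a in barcodes:
        for b in barcodes:
            if a != b and b.startswith(a):
                raise ValueError(f"barcode {a!r} is a prefix of {b!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth at the site">',
    '##INFO=<ID=MQ0,Number=1,Type=Integer,Description="Reads with zero mapping confidence (multiple equally best placements)">',
    '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant confidence divided by depth of variant-carrying samples">',
    '##FILTER=<ID=SnpCluster,Description="More than 3 variant sites in a 10 bp window">',
    '##FILTER=<ID=HardToValidate,Description="MQ0 >= 4 and MQ0/DP > 0.1">',
    '##FILTER=<ID=LowQual,Description="QUAL <= 60">',
    '##FILTER=<ID=LowQD,Description="QD at or below the empirical 5% quantile">',
    '##FILTER=<ID=HighDP,Description="Site depth above the median over retained sites">',
    '##FILTER=<ID=HighNA,Description="Missing genotype fraction above threshold">',
    '##FILTER=<ID=LowMAF,Description="Minor allele frequency below threshold">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
]

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    path: str | Path,
    gm: GenotypeMatrix,
    *,
    depths: np.ndarray | None = None,
    qual: np.ndarray | None = None,
    info: pd.DataFrame | None = None,
    filters: list[str] | None = None,
    contig_lengths: dict[str, int] | None = None,
    source: str = "gbscompare",
) -> None:
    """Write a GenotypeMatrix as VCF v4.2 (GT, optionally DP per sample).

    ``info`` may carry per-site DP/MQ0/QD columns; ``filters`` a per-site
    semicolon-joined FILTER string ("PASS"/"." if clean).
    """
    sites = gm.sites
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source={source}\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        else:
            for name in pd.unique(sites["contig"]):
                fh.write(f"##contig=<ID={name}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        fmt = "GT:DP" if depths is not None else "GT"
        for j in range(gm.n_sites):
            row = sites.iloc[j]
            q = "." if qual is None or not np.isfinite(qual[j]) else f"{qual[j]:.2f}"
            flt = "PASS" if filters is None else (filters[j] or "PASS")
            if info is not None:
                parts = []
                for col in info.columns:
                    v = info.iloc[j][col]
                    parts.append(f"{col}={v:.4g}" if isinstance(v, float) else f"{col}={v}")
                info_str = ";".join(parts) if parts else "."
            else:
                info_str = "."
            cells = []
            for i in range(gm.n_samples):
                gt = _GT_STR[int(gm.G[i, j])]
                if depths is not None:
                    cells.append(f"{gt}:{int(depths[i, j])}")
                else:
                    cells.append(gt)
            fh.write(
                f"{row['contig']}\t{int(row['pos']) + 1}\t{row['site_id']}\t"
                f"{row['ref']}\t{row['alt']}\t{q}\t{flt}\t{info_str}\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path, *, pass_only: bool = False) -> GenotypeMatrix:
    """Read a biallelic VCF into a GenotypeMatrix via cyvcf2.

    Multiallelic records are skipped (counted in the returned matrix's
    ``sites.attrs['n_multiallelic_skipped']``); ``pass_only`` drops records
    whose FILTER column names a failed filter.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, gts = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if pass_only and var.FILTER is not None:  # cyvcf2: None means PASS/.
            continue
        rows.append(
            {
                "site_id": var.ID or f"{var.CHROM}:{var.POS}",
                "contig": var.CHROM,
                "pos": var.POS - 1,
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        gts.append(g)
    sites = pd.DataFrame(rows, columns=SITE_COLUMNS)
    G = np.vstack(gts).T if gts else np.zeros((len(samples), 0), dtype=np.int8)
    gm = GenotypeMatrix(samples=samples, sites=sites, G=G)
    gm.sites.attrs["n_multiallelic_skipped"] = n_multi
    return gm


def write_manifest(out_dir: str | Path, params: dict) -> Path:
    """Echo all run parameters (incl. seed and package version) as JSON."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"gbscompare_version": __version__, **params}
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path
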