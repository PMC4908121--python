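"""Diploid genotype matrix — the shared currency of both callers and all statistics.

Genotypes are stored as ``int8`` alternate-allele dosages (0, 1, 2) with a
dedicated :data:`MISSING` sentinel; arithmetic never touches the sentinel
directly — use :meth:`GenotypeMatrix.missing_mask` / :meth:`masked`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype. Never used in arithmetic.
MISSING: int = -9

SITE_COLUMNS = ["site_id", "contig", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Samples × sites matrix of diploid alternate-allele dosages.

    Parameters
    ----------
    samples :
        Sample identifiers, one per row of ``G``.
    sites :
        Site metadata table with columns ``site_id, contig, pos, ref, alt``
        (``pos`` 0-based; writers convert to the 1-based VCF convention).
    G :
        ``(n_samples, n_sites)`` int8 array of {0, 1, 2, MISSING}.
    demes :
        Optional per-sample deme labels (for F-statistics and structure).
    """

    samples: list[str]
    sites: pd.DataFrame
    G: np.ndarray
    demes: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=np.int8)
        if self.G.shape != (len(self.samples), len(self.sites)):
            raise ValueError(
                f"G shape {self.G.shape} inconsistent with "
                f"{len(self.samples)} samples × {len(self.sites)} sites"
            )
        valid = np.isin(self.G, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotypes must be 0, 1, 2 or MISSING")
        if self.demes is not None and len(self.demes) != len(self.samples):
            raise ValueError("demes must align with samples")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def missing_mask(self) -> np.ndarray:
        """Boolean mask, True where the genotype is missing."""
        return self.G == MISSING

    def masked(self) -> np.ma.MaskedArray:
        """Float masked-array view suitable for arithmetic."""
        return np.ma.masked_array(self.G.astype(float), mask=self.missing_mask())

    def alt_counts(self) -> np.ndarray:
        """Per-site alternate allele count over non-missing chromosomes."""
        return np.asarray(self.masked().sum(axis=0).filled(0), dtype=int)

    def called_chroms(self) -> np.ndarray:
        """Per-site number of non-missing chromosomes (2 × called samples)."""
        return 2 * (~self.missing_mask()).sum(axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-site alternate allele frequency among non-missing chromosomes."""
        n = self.called_chroms()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, self.alt_counts() / n, np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing genotypes."""
        return self.missing_mask().mean(axis=0)

    def sample_missing_rate(self) -> np.ndarray:
        """Per-sample fraction of missing genotypes across sites."""
        return self.missing_mask().mean(axis=1)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset to the given site indices (order preserved)."""
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            sites=self.sites.iloc[index].reset_index(drop=True),
            G=self.G[:, index].copy(),
            demes=None if self.demes is None else list(self.demes),
        )

    def polymorphic_mask(self) -> np.ndarray:
        """True for sites segregating among non-missing genotypes."""
        maf = self.minor_allele_freq()
        return np.nan_to_num(maf) > 0

    def drop_monomorphic(self) -> "GenotypeMatrix":
        return self.take_sites(np.flatnonzero(self.polymorphic_mask()))
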