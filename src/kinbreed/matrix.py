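"""Genotype matrix container for biallelic SNP panels.

Individuals are rows, loci are columns.  Dosages count copies of the ALT
allele (0, 1, 2) with ``-1`` marking a missing call.  Per-call read depth
(DP) and allelic depths (AD ref/alt) are optional and carried alongside;
locus metadata (chrom, pos, ref, alt, qual, tag) lives in a DataFrame so
standard pandas selection works on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

LOCUS_COLUMNS = ["chrom", "pos", "ref", "alt", "qual", "tag"]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic-loci dosage matrix with optional depths.

    Parameters
    ----------
    ids : list of str
        Individual identifiers (row order).
    loci : pandas.DataFrame
        One row per locus with columns ``chrom, pos, ref, alt, qual, tag``.
        ``pos`` is 1-based as in VCF; ``tag`` is the RAD-tag identifier.
    dosage : ndarray of int8, shape (n_individuals, n_loci)
        ALT-allele dosage, ``-1`` for missing.
    dp : ndarray of int32 or None
        Per-call read depth.
    ad_ref, ad_alt : ndarray of int32 or None
        Per-call allelic depths.
    """

    ids: list[str]
    loci: pd.DataFrame
    dosage: np.ndarray
    dp: np.ndarray | None = None
    ad_ref: np.ndarray | None = None
    ad_alt: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        missing_cols = [c for c in LOCUS_COLUMNS if c not in self.loci.columns]
        if missing_cols:
            raise ValueError(f"loci table lacks columns {missing_cols}")
        self.loci = self.loci.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.dosage != MISSING

    # -- per-locus statistics -------------------------------------------

    def alt_freq(self) -> np.ndarray:
        """ALT allele frequency per locus over called genotypes (NaN if none)."""
        called = self.called
        n = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, alt / (2.0 * n), np.nan)

    def maf(self) -> np.ndarray:
        p = self.alt_freq()
        return np.minimum(p, 1.0 - p)

    def minor_allele_count(self) -> np.ndarray:
        called = self.called
        n = called.sum(axis=0)
        alt = np.where(called, self.dosage, 0).sum(axis=0)
        return np.minimum(alt, 2 * n - alt)

    def locus_missingness(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return 1.0 - self.called.mean(axis=1)

    def obs_het(self) -> np.ndarray:
        """Observed heterozygosity per locus over called genotypes."""
        called = self.called
        n = called.sum(axis=0)
        het = (self.dosage == 1).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, het / n, np.nan)

    # -- subsetting ------------------------------------------------------

    def take_loci(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = index.astype(np.int64)
        return GenotypeMatrix(
            ids=list(self.ids),
            loci=self.loci.iloc[index].reset_index(drop=True),
            dosage=self.dosage[:, index].copy(),
            dp=None if self.dp is None else self.dp[:, index].copy(),
            ad_ref=None if self.ad_ref is None else self.ad_ref[:, index].copy(),
            ad_alt=None if self.ad_alt is None else self.ad_alt[:, index].copy(),
            meta=dict(self.meta),
        )

    def take_individuals(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = index.astype(np.int64)
        return GenotypeMatrix(
            ids=[self.ids[i] for i in index],
            loci=self.loci.copy(),
            dosage=self.dosage[index, :].copy(),
            dp=None if self.dp is None else self.dp[index, :].copy(),
            ad_ref=None if self.ad_ref is None else self.ad_ref[index, :].copy(),
            ad_alt=None if self.ad_alt is None else self.ad_alt[index, :].copy(),
            meta=dict(self.meta),
        )

    def select_ids(self, wanted: list[str]) -> "GenotypeMatrix":
        lookup = {x: i for i, x in enumerate(self.ids)}
        missing = [w for w in wanted if w not in lookup]
        if missing:
            raise KeyError(f"individuals absent from matrix: {missing[:5]}")
        return self.take_individuals([lookup[w] for w in wanted])

    def copy(self) -> "GenotypeMatrix":
        return self.take_loci(np.arange(self.n_loci))

    def equals(self, other: "GenotypeMatrix") -> bool:
        """Equality of ids, locus table (chrom/pos/alleles/tag), dosage, DP, AD."""
        if self.ids != other.ids:
            return False
        cols = ["chrom", "pos", "ref", "alt", "tag"]
        if not self.loci[cols].equals(other.loci[cols]):
            return False
        if not np.array_equal(self.dosage, other.dosage):
            return False
        for a, b in ((self.dp, other.dp), (self.ad_ref, other.ad_ref),
                     (self.ad_alt, other.ad_alt)):
            if (a is None) != (b is None):
                return False
            if a is not None and not np.array_equal(a, b):
                return False
        return True
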