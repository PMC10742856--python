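"""Core in-memory containers shared across the pipeline.

Coordinates are 1-based and intervals are closed (VCF convention)
throughout the package; genotype dosages count copies of the ALT allele
(0, 1, 2) with ``numpy.nan`` marking a missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = np.nan

#: length of the upstream regulatory window treated as the promoter (bp)
PROMOTER_LENGTH = 2000


class HaploPhenoError(Exception):
    """Base class for user-facing errors raised by this package."""


class ConfigurationError(HaploPhenoError):
    """A configuration value violates its documented constraints."""


@dataclass(frozen=True)
class Variant:
    """One biallelic SNP or indel.

    ``info`` carries the caller annotations used by hard filtering
    (QD, FS, MQ); keys may be absent.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float | None = None
    info: Mapping[str, float] = field(default_factory=dict)
    id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles identical at {self.chrom}:{self.pos}")
        if not self.id:
            object.__setattr__(self, "id", f"{self.chrom}_{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp


class GenotypeMatrix:
    """Accessions x variants dosage table with variant metadata.

    Dosages are ALT-allele counts: 0 and 2 for the homozygotes of a
    fully inbred panel, 1 for residual heterozygotes, nan for missing.
    Variants are kept sorted by (chrom, pos).
    """

    def __init__(
        self,
        accessions: Sequence[str],
        variants: Sequence[Variant],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=float)
        if dosage.shape != (len(accessions), len(variants)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(accessions)} accessions x {len(variants)} variants"
            )
        order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
        self.accessions: list[str] = list(accessions)
        self.variants: list[Variant] = [variants[i] for i in order]
        self.dosage: np.ndarray = dosage[:, order]
        if len(set(self.accessions)) != len(self.accessions):
            raise ValueError("duplicate accession ids")

    # ------------------------------------------------------------------
    @property
    def n_accessions(self) -> int:
        return len(self.accessions)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.id for v in self.variants]

    def variant_index(self, variant_id: str) -> int:
        try:
            return self.variant_ids.index(variant_id)
        except ValueError:
            raise KeyError(f"variant {variant_id!r} not in matrix") from None

    def allele_frequency(self) -> np.ndarray:
        """Per-variant ALT allele frequency over non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def minor_allele_frequency(self) -> np.ndarray:
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def subset_variants(self, variant_ids: Iterable[str]) -> "GenotypeMatrix":
        keep = set(variant_ids)
        idx = [i for i, v in enumerate(self.variants) if v.id in keep]
        return GenotypeMatrix(
            self.accessions, [self.variants[i] for i in idx], self.dosage[:, idx]
        )

    def subset_accessions(self, accessions: Sequence[str]) -> "GenotypeMatrix":
        pos = {a: i for i, a in enumerate(self.accessions)}
        idx = [pos[a] for a in accessions]
        return GenotypeMatrix(list(accessions), self.variants, self.dosage[idx, :])

    def variant_frame(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (one row per variant)."""
        return pd.DataFrame(
            {
                "id": self.variant_ids,
                "chrom": [v.chrom for v in self.variants],
                "pos": [v.pos for v in self.variants],
                "ref": [v.ref for v in self.variants],
                "alt": [v.alt for v in self.variants],
                "qual": [v.qual for v in self.variants],
            }
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.accessions == other.accessions
            and [(v.chrom, v.pos, v.ref, v.alt) for v in self.variants]
            == [(v.chrom, v.pos, v.ref, v.alt) for v in other.variants]
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


@dataclass(frozen=True)
class GeneModel:
    """One gene's coordinates on the forward genomic axis.

    ``tx_start``/``tx_end`` and ``cds_start``/``cds_end`` are genomic
    (strand-independent) 1-based closed bounds; ``exons`` are sorted,
    non-overlapping closed intervals. The promoter is the 2000 bp window
    upstream of the strand-aware transcription start, truncated at the
    contig start.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene_id}: CDS span must lie within transcript span")
        prev_end = 0
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.gene_id}: exon ({s},{e}) reversed")
            if s <= prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or are unsorted")
            prev_end = e
        if not self.exons or self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError(f"{self.gene_id}: exons must tile the transcript bounds")
        if not any(s <= self.cds_start <= e for s, e in self.exons) or not any(
            s <= self.cds_end <= e for s, e in self.exons
        ):
            raise ValueError(f"{self.gene_id}: CDS bounds must fall inside exons")

    @property
    def promoter(self) -> tuple[int, int]:
        """Closed genomic interval of the promoter (strand-aware upstream)."""
        if self.strand == "+":
            return (max(1, self.tx_start - PROMOTER_LENGTH), self.tx_start - 1)
        return (self.tx_end + 1, self.tx_end + PROMOTER_LENGTH)

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        """Exon pieces clipped to the CDS span, in genomic order."""
        out = []
        for s, e in self.exons:
            lo, hi = max(s, self.cds_start), min(e, self.cds_end)
            if lo <= hi:
                out.append((lo, hi))
        return tuple(out)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_intervals)

    @property
    def span_with_promoter(self) -> tuple[int, int]:
        """[promoter, transcript] envelope used for gene assignment."""
        p0, p1 = self.promoter
        return (min(p0, self.tx_start), max(p1, self.tx_end))

    def contains(self, chrom: str, pos: int) -> bool:
        lo, hi = self.span_with_promoter
        return chrom == self.chrom and lo <= pos <= hi
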