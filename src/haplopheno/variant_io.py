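"""Variant and gene-model I/O, hard filtering and minimal annotation.

Hard-filter thresholds default to the GATK-style criteria used for the
targeted-capture variant set: a record is removed when QUAL < 30,
QD < 4.0, FS > 60.0 or MQ < 40.0 (strict inequalities; boundary values
are retained). Region annotation distinguishes promoter (2000 bp
upstream, strand-aware), UTRs, coding exons, introns and intergenic
positions; the coding-effect classifier covers the classes relevant to
candidate-gene curation (synonymous / nonsynonymous / premature stop /
frameshift / in-frame indel) and is deliberately not a full
variant-effect predictor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq
from cyvcf2 import VCF

from .datatypes import GeneModel, GenotypeMatrix, HaploPhenoError, Variant

logger = logging.getLogger(__name__)

#: default hard-filter thresholds; a record failing any criterion is removed
DEFAULT_HARD_FILTER = {"QUAL": 30.0, "QD": 4.0, "FS": 60.0, "MQ": 40.0}

REGION_LABELS = ("promoter", "5UTR", "exon_cds", "intron", "3UTR", "intergenic")

EFFECT_LABELS = (
    "synonymous",
    "nonsynonymous",
    "stop_gain",
    "frameshift",
    "inframe_indel",
    "non_coding",
)


class VcfParseError(HaploPhenoError):
    pass


# ----------------------------------------------------------------------
# VCF reading / writing
# ----------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    Biallelic records are retained; multiallelic records are dropped
    with a logged count. GT semantics: 0/0 -> 0, 0/1 -> 1, 1/1 -> 2,
    ./. -> missing (nan).
    """
    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise VcfParseError(f"cannot parse VCF header of {path}: {exc}") from exc
    accessions = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_multi = 0
    for line_no, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        info = {}
        for key in ("QD", "FS", "MQ"):
            val = rec.INFO.get(key)
            if val is not None:
                info[key] = float(val)
        try:
            variants.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    qual=rec.QUAL,
                    info=info,
                    id=rec.ID or "",
                )
            )
        except ValueError as exc:
            raise VcfParseError(f"malformed record #{line_no} in {path}: {exc}") from exc
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(rec.gt_types, dtype=float)
        dos = np.where(gt == 0, 0.0, np.where(gt == 1, 1.0, np.where(gt == 3, 2.0, np.nan)))
        rows.append(dos)
    if n_multi:
        logger.warning("dropped %d multiallelic record(s) from %s", n_multi, path)
    dosage = (
        np.column_stack(rows) if rows else np.empty((len(accessions), 0))
    )
    return GenotypeMatrix(accessions, variants, dosage)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF 4.2 file (GT format, QD/FS/MQ INFO fields)."""
    path = Path(path)
    contigs = sorted({v.chrom for v in matrix.variants})
    lines = [
        "##fileformat=VCFv4.2",
        "##source=haplopheno",
        '##INFO=<ID=QD,Number=1,Type=Float,Description="Variant quality by depth">',
        '##INFO=<ID=FS,Number=1,Type=Float,Description="Fisher strand bias (phred)">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(matrix.accessions)
    )
    for j, v in enumerate(matrix.variants):
        info = ";".join(f"{k}={v.info[k]:.4g}" for k in ("QD", "FS", "MQ") if k in v.info) or "."
        qual = "." if v.qual is None else f"{v.qual:.4g}"
        gts = []
        for d in matrix.dosage[:, j]:
            if np.isnan(d):
                gts.append("./.")
            elif d == 0:
                gts.append("0/0")
            elif d == 1:
                gts.append("0/1")
            else:
                gts.append("1/1")
        lines.append(
            f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t{qual}\tPASS\t{info}\tGT\t"
            + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Hard filtering
# ----------------------------------------------------------------------

@dataclass
class FilterReport:
    """Per-criterion removal counts from :func:`hard_filter`."""

    n_input: int = 0
    n_removed: int = 0
    removed_by: dict[str, int] = field(default_factory=dict)
    skipped_criteria: dict[str, int] = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [{"criterion": k, "n_removed": v} for k, v in sorted(self.removed_by.items())]
            + [{"criterion": "TOTAL", "n_removed": self.n_removed}]
        )


def _fails(v: Variant, thresholds: Mapping[str, float], report: FilterReport) -> list[str]:
    failed = []
    if "QUAL" in thresholds:
        if v.qual is None:
            report.skipped_criteria["QUAL"] = report.skipped_criteria.get("QUAL", 0) + 1
        elif v.qual < thresholds["QUAL"]:
            failed.append("QUAL")
    for key, low in (("QD", True), ("MQ", True), ("FS", False)):
        if key not in thresholds:
            continue
        val = v.info.get(key)
        if val is None:
            report.skipped_criteria[key] = report.skipped_criteria.get(key, 0) + 1
        elif (low and val < thresholds[key]) or (not low and val > thresholds[key]):
            failed.append(key)
    return failed


def hard_filter(
    matrix: GenotypeMatrix,
    thresholds: Mapping[str, float] | None = None,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove variants failing any hard-filter criterion.

    A record is removed iff QUAL < 30 OR QD < 4.0 OR FS > 60.0 OR
    MQ < 40.0 (defaults; strict inequalities). Absent INFO keys skip
    that criterion for that record, with the decision logged.
    """
    thr = dict(DEFAULT_HARD_FILTER if thresholds is None else thresholds)
    report = FilterReport(n_input=matrix.n_variants)
    keep = []
    for v in matrix.variants:
        failed = _fails(v, thr, report)
        if failed:
            report.n_removed += 1
            for k in failed:
                report.removed_by[k] = report.removed_by.get(k, 0) + 1
        else:
            keep.append(v.id)
    for key, n in report.skipped_criteria.items():
        logger.info("hard_filter: %s absent on %d record(s); criterion skipped there", key, n)
    logger.info(
        "hard_filter: removed %d/%d records (%s)",
        report.n_removed,
        report.n_input,
        report.removed_by or "none",
    )
    return matrix.subset_variants(keep), report


# ----------------------------------------------------------------------
# Region annotation
# ----------------------------------------------------------------------

def annotate_region(v: Variant, gene: GeneModel) -> str:
    """Label a variant's position relative to one gene model.

    Returns one of ``promoter, 5UTR, exon_cds, intron, 3UTR,
    intergenic``. UTR = exonic but outside the CDS span, with the 5'/3'
    side decided by strand. Indels are assigned by their left-anchored
    VCF position.
    """
    if v.chrom != gene.chrom:
        raise ValueError(
            f"variant {v.id} on {v.chrom} but gene {gene.gene_id} on {gene.chrom}"
        )
    pos = v.pos
    p0, p1 = gene.promoter
    if p0 <= pos <= p1:
        return "promoter"
    if not (gene.tx_start <= pos <= gene.tx_end):
        return "intergenic"
    in_exon = any(s <= pos <= e for s, e in gene.exons)
    if not in_exon:
        return "intron"
    if gene.cds_start <= pos <= gene.cds_end:
        return "exon_cds"
    upstream_of_cds = pos < gene.cds_start
    if gene.strand == "+":
        return "5UTR" if upstream_of_cds else "3UTR"
    return "3UTR" if upstream_of_cds else "5UTR"


# ----------------------------------------------------------------------
# Coding-effect classification
# ----------------------------------------------------------------------

def _cds_offset(gene: GeneModel, pos: int) -> int | None:
    """Genomic position -> 0-based offset along the genomic-order CDS."""
    off = 0
    for s, e in gene.cds_intervals:
        if s <= pos <= e:
            return off + (pos - s)
        off += e - s + 1
    return None


def classify_coding_effect(v: Variant, gene: GeneModel, cds_sequence: str) -> str:
    """Classify a variant's effect on the gene's coding sequence.

    ``cds_sequence`` is the spliced CDS read 5'->3' on the coding strand
    and must match the gene's CDS length (a multiple of 3). SNPs inside
    the CDS are classified by translating the affected codon before and
    after; CDS indels are frameshift iff the length difference is not a
    multiple of 3; everything outside the CDS is ``non_coding``.
    """
    cds_len = gene.cds_length
    if cds_len % 3 != 0:
        raise ValueError(f"{gene.gene_id}: CDS length {cds_len} not a multiple of 3")
    if len(cds_sequence) != cds_len:
        raise ValueError(
            f"{gene.gene_id}: CDS sequence length {len(cds_sequence)} != model length {cds_len}"
        )
    offset = _cds_offset(gene, v.pos)
    if offset is None:
        return "non_coding"
    if v.is_indel:
        return "frameshift" if (len(v.ref) - len(v.alt)) % 3 != 0 else "inframe_indel"
    # SNP: locate the base in coding orientation
    if gene.strand == "+":
        idx = offset
        ref_base, alt_base = v.ref, v.alt
    else:
        idx = cds_len - 1 - offset
        ref_base = str(Seq(v.ref).reverse_complement())
        alt_base = str(Seq(v.alt).reverse_complement())
    if cds_sequence[idx].upper() != ref_base.upper():
        raise ValueError(
            f"{gene.gene_id}: CDS base {cds_sequence[idx]} at offset {idx} "
            f"does not match REF allele {ref_base} of {v.id}"
        )
    codon_i = idx // 3
    codon = cds_sequence[3 * codon_i : 3 * codon_i + 3]
    mutated = codon[: idx % 3] + alt_base + codon[idx % 3 + 1 :]
    aa_before = str(Seq(codon).translate())
    aa_after = str(Seq(mutated).translate())
    if aa_after == "*" and aa_before != "*":
        return "stop_gain"
    return "synonymous" if aa_before == aa_after else "nonsynonymous"


# ----------------------------------------------------------------------
# Gene-model table I/O
# ----------------------------------------------------------------------

GENE_TABLE_COLUMNS = [
    "gene",
    "chrom",
    "strand",
    "tx_start",
    "tx_end",
    "cds_start",
    "cds_end",
    "exon_starts",
    "exon_ends",
]


def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for g in genes:
        rows.append(
            {
                "gene": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tx_start": g.tx_start,
                "tx_end": g.tx_end,
                "cds_start": g.cds_start,
                "cds_end": g.cds_end,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            }
        )
    pd.DataFrame(rows, columns=GENE_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> list[GeneModel]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    missing = set(GENE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise HaploPhenoError(f"gene-model table {path} lacks columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        starts = [int(x) for x in str(row.exon_starts).split(",")]
        ends = [int(x) for x in str(row.exon_ends).split(",")]
        genes.append(
            GeneModel(
                gene_id=row.gene,
                chrom=row.chrom,
                strand=row.strand,
                tx_start=int(row.tx_start),
                tx_end=int(row.tx_end),
                cds_start=int(row.cds_start),
                cds_end=int(row.cds_end),
                exons=tuple(zip(starts, ends)),
            )
        )
    return genes


def assign_gene(v: Variant, genes: Sequence[GeneModel]) -> GeneModel | None:
    """Gene whose [promoter, transcript] envelope contains the variant."""
    for g in genes:
        if g.contains(v.chrom, v.pos):
            return g
    return None
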