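"""Shared fixtures: toy gene models and small simulated panels."""

import numpy as np
import pytest

from haplopheno.datatypes import GeneModel, GenotypeMatrix, Variant
from haplopheno.synthetic_data import (
    CausalGene,
    SimulationConfig,
    TraitSpec,
    simulate,
)


@pytest.fixture(scope="session")
def toy_gene_plus() -> GeneModel:
    """Plus-strand two-exon gene: tx 5001..5900, CDS 5101..5750.

    Exons 5001-5400 and 5501-5900; CDS pieces 5101-5400 (300 bp) and
    5501-5750 (250 bp, trimmed to keep total 549 -> adjusted): total
    CDS = 300 + 249 = 549 = 183 codons.
    """
    return GeneModel(
        gene_id="toy+",
        chrom="chr1",
        strand="+",
        tx_start=5001,
        tx_end=5900,
        cds_start=5101,
        cds_end=5749,
        exons=((5001, 5400), (5501, 5900)),
    )


@pytest.fixture(scope="session")
def toy_gene_minus() -> GeneModel:
    return GeneModel(
        gene_id="toy-",
        chrom="chr1",
        strand="-",
        tx_start=5001,
        tx_end=5900,
        cds_start=5101,
        cds_end=5749,
        exons=((5001, 5400), (5501, 5900)),
    )


def make_matrix(dosage, positions=None, chrom="chr1", ref="A", alt="G", quals=None, infos=None):
    """Helper: build a GenotypeMatrix from a dosage array."""
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    positions = positions or list(range(100, 100 + m))
    variants = [
        Variant(
            chrom=chrom,
            pos=positions[j],
            ref=ref,
            alt=alt,
            qual=None if quals is None else quals[j],
            info={} if infos is None else infos[j],
        )
        for j in range(m)
    ]
    return GenotypeMatrix([f"a{i}" for i in range(n)], variants, dosage)


def crafted_qc_matrix():
    """20 records probing every hard-filter criterion and its boundary.

    Returns (matrix, expected_removed_ids). Boundary values (QUAL=30,
    QD=4.0, FS=60.0, MQ=40.0) must be retained: the criteria are
    strict inequalities.
    """
    ok = {"QD": 20.0, "FS": 5.0, "MQ": 55.0}
    rows = [
        # (qual, info, removed?)
        (100.0, dict(ok), False),
        (25.0, dict(ok), True),  # QUAL < 30
        (30.0, dict(ok), False),  # boundary retained
        (29.999, dict(ok), True),
        (100.0, {**ok, "QD": 3.9}, True),  # QD < 4
        (100.0, {**ok, "QD": 4.0}, False),  # boundary retained
        (100.0, {**ok, "QD": 0.5}, True),
        (100.0, {**ok, "FS": 60.1}, True),  # FS > 60
        (100.0, {**ok, "FS": 60.0}, False),  # boundary retained
        (100.0, {**ok, "FS": 200.0}, True),
        (100.0, {**ok, "MQ": 39.9}, True),  # MQ < 40
        (100.0, {**ok, "MQ": 40.0}, False),  # boundary retained
        (100.0, {**ok, "MQ": 10.0}, True),
        (25.0, {**ok, "QD": 3.0}, True),  # two criteria at once
        (31.0, dict(ok), False),
        (100.0, {"FS": 5.0, "MQ": 55.0}, False),  # QD absent -> skipped
        (100.0, {"QD": 20.0, "MQ": 55.0}, False),  # FS absent -> skipped
        (100.0, {"QD": 20.0, "FS": 5.0}, False),  # MQ absent -> skipped
        (100.0, {**ok, "QD": 4.0001}, False),
        (5.0, {**ok, "FS": 61.0}, True),
    ]
    dosage = np.tile([0.0, 2.0], (len(rows), 1)).T  # 2 accessions
    matrix = make_matrix(
        dosage,
        positions=list(range(1000, 1000 + len(rows))),
        quals=[q for q, _, _ in rows],
        infos=[i for _, i, _ in rows],
    )
    removed = {f"chr1_{1000 + k}" for k, (_, _, bad) in enumerate(rows) if bad}
    return matrix, removed


@pytest.fixture(scope="session")
def small_sim():
    """Small structured panel with one planted causal gene."""
    config = SimulationConfig(
        n_accessions=100,
        n_genes=20,
        founders_per_gene=2,
        sites_per_gene=4,
        n_subpops=2,
        subpop_divergence=0.1,
        causal_spec=(CausalGene("gene02", "T", (0.0, 1.5)),),
        trait_spec={"T": TraitSpec(10.0, 0.3, (0.2, -0.2), 0.05, 0.1)},
        founder_freqs=(0.5, 0.5),
        missing_rate=0.0,
        seed=11,
    )
    matrix, genes, pheno, truth = simulate(config)
    return config, matrix, genes, pheno, truth
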