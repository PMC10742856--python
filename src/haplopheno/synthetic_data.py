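"""Synthetic inbred diversity panels with planted haplotype effects.

The generator emulates a targeted-capture candidate-gene study in a
selfing crop: ~180 fully inbred accessions from 3 subpopulations,
~42 genes each carrying a handful of founder haplotypes over their
promoter (2 kb upstream) and gene body, and multi-environment grain
traits with high broad-sense heritability. Each accession carries one
founder haplotype per gene (no intra-gene recombination — haplotypes
are gene-local in inbred lines); subpopulation divergence perturbs the
founder frequencies Balding-Nichols style; phenotypes follow

    y_ijk = mu + g_i + h_i + E_j + (gE)_ij + eps_ijk

with a polygenic background g ~ N(0, Vg_bg * K) drawn on the true
kinship of the simulated genotypes, planted haplotype effects h, fixed
year effects E_j, interaction (gE) and replicate error eps. The truth
table records founder haplotypes, per-accession assignments, causal
genes, planted superior haplotypes and the realized heritability, and
is the oracle for end-to-end recovery tests.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, GeneModel, GenotypeMatrix, Variant
from .pheno_stats import PhenotypeTable
from .variant_io import read_gene_models, read_vcf, write_gene_models, write_vcf

logger = logging.getLogger(__name__)

BASES = "ACGT"
STOP_CODONS = ("TAA", "TAG", "TGA")
NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES
    for b in BASES
    for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class TraitSpec:
    """Generative parameters for one trait (units: the trait's own)."""

    mean: float
    vg_bg: float  # background polygenic variance
    env_effects: tuple[float, ...]  # fixed effect per environment (year)
    vge: float
    ve: float
    replicates: int = 1  # pooled-plant measurement: one value per env
    direction: str = "maximize"

    def __post_init__(self) -> None:
        if min(self.vg_bg, self.vge, self.ve) < 0:
            raise ConfigurationError("trait variances must be non-negative")
        if len(self.env_effects) < 1:
            raise ConfigurationError("need at least one environment")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.direction not in {"maximize", "minimize"}:
            raise ConfigurationError("direction must be maximize|minimize")

    @property
    def n_envs(self) -> int:
        return len(self.env_effects)


@dataclass(frozen=True)
class CausalGene:
    """Planted per-haplotype additive effects of one gene on one trait."""

    gene: str
    trait: str
    effects: tuple[float, ...]  # one effect per founder haplotype


@dataclass(frozen=True)
class SimulationConfig:
    """Shape and generative truth of a simulated panel."""

    n_accessions: int = 180
    n_genes: int = 42
    founders_per_gene: int = 3
    sites_per_gene: int = 65
    n_subpops: int = 3
    subpop_divergence: float = 0.15
    causal_spec: tuple[CausalGene, ...] = ()
    trait_spec: dict[str, TraitSpec] = field(default_factory=dict)
    inbreeding: float = 1.0
    missing_rate: float = 0.0
    qc_fail_fraction: float = 0.0
    founder_freqs: tuple[float, ...] | None = None
    subpop_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders_per_gene < 2:
            raise ConfigurationError("founders_per_gene must be >= 2")
        if self.founders_per_gene > self.n_accessions:
            raise ConfigurationError("founders_per_gene must be <= n_accessions")
        for frac, name in (
            (self.subpop_divergence, "subpop_divergence"),
            (self.inbreeding, "inbreeding"),
            (self.missing_rate, "missing_rate"),
            (self.qc_fail_fraction, "qc_fail_fraction"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {frac}")
        known_genes = {f"gene{g + 1:02d}" for g in range(self.n_genes)}
        for c in self.causal_spec:
            if c.gene not in known_genes:
                raise ConfigurationError(
                    f"causal gene {c.gene} outside the simulated panel of {self.n_genes} genes"
                )
            if c.trait not in self.trait_spec:
                raise ConfigurationError(
                    f"causal gene {c.gene} targets trait {c.trait!r} absent from trait_spec"
                )
            if len(c.effects) != self.founders_per_gene:
                raise ConfigurationError(
                    f"causal gene {c.gene}: {len(c.effects)} effects for "
                    f"{self.founders_per_gene} founders"
                )
        if self.founder_freqs is not None:
            if len(self.founder_freqs) != self.founders_per_gene:
                raise ConfigurationError("founder_freqs length must equal founders_per_gene")
            if abs(sum(self.founder_freqs) - 1.0) > 1e-9 or min(self.founder_freqs) <= 0:
                raise ConfigurationError("founder_freqs must be positive and sum to 1")
        if self.subpop_proportions is not None and len(self.subpop_proportions) != self.n_subpops:
            raise ConfigurationError("subpop_proportions length must equal n_subpops")


@dataclass
class TruthTable:
    """Generative truth recorded for recovery oracles."""

    subpop: dict[str, int]
    founder_strings: dict[str, list[str]]  # gene -> allele string per founder
    acc_founder: dict[str, dict[str, int]]  # gene -> accession -> founder id
    causal: dict[str, list[CausalGene]]  # trait -> planted genes
    superior_founder: dict[str, dict[str, int]]  # trait -> gene -> founder id
    realized_h2: dict[str, float] = field(default_factory=dict)
    cds_sequences: dict[str, str] = field(default_factory=dict)
    kinship: np.ndarray | None = None  # true normalized kinship (not serialized)
    founder_pairs: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subpop": self.subpop,
            "founder_strings": self.founder_strings,
            "acc_founder": self.acc_founder,
            "causal": {
                t: [dataclasses.asdict(c) for c in genes] for t, genes in self.causal.items()
            },
            "superior_founder": self.superior_founder,
            "realized_h2": self.realized_h2,
            "cds_sequences": self.cds_sequences,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        raw = json.loads(Path(path).read_text())
        return cls(
            subpop=raw["subpop"],
            founder_strings=raw["founder_strings"],
            acc_founder=raw["acc_founder"],
            causal={
                t: [CausalGene(c["gene"], c["trait"], tuple(c["effects"])) for c in genes]
                for t, genes in raw["causal"].items()
            },
            superior_founder=raw["superior_founder"],
            realized_h2=raw["realized_h2"],
            cds_sequences=raw["cds_sequences"],
        )


# ----------------------------------------------------------------------
# Default study conditions
# ----------------------------------------------------------------------

def default_trait_spec() -> dict[str, TraitSpec]:
    """Grain traits of an inbred rice panel over two years (r = 1).

    Means and spreads are typical of Indica grain phenotypes (GL/GW in
    mm, L/W dimensionless, TGW in g); variance components are set so
    the entry-mean heritabilities land near 0.94/0.86/0.91/0.80.
    """
    return {
        "GL": TraitSpec(9.0, 0.33, (0.15, -0.15), 0.020, 0.026),
        "GW": TraitSpec(2.6, 0.04, (0.02, -0.02), 0.005, 0.008),
        "LW": TraitSpec(3.5, 0.16, (0.05, -0.05), 0.014, 0.018),
        "TGW": TraitSpec(25.0, 9.0, (0.5, -0.5), 2.0, 2.5),
    }


def default_causal_spec() -> tuple[CausalGene, ...]:
    """1-5 causal genes per trait with shared (pleiotropic) genes.

    Effect magnitudes are a fraction of each trait's genetic SD,
    mirroring the size of single-gene haplotype contrasts in grain
    traits (tenths of a mm for GL, grams for TGW).
    """
    return (
        CausalGene("gene01", "GL", (0.0, -0.70, -0.35)),
        CausalGene("gene02", "GL", (0.0, -1.10, -0.55)),
        CausalGene("gene03", "GW", (0.0, 0.25, 0.12)),
        CausalGene("gene01", "LW", (0.0, -0.25, -0.12)),
        CausalGene("gene03", "LW", (0.0, -0.15, -0.07)),
        CausalGene("gene03", "TGW", (0.0, 2.50, 1.20)),
        CausalGene("gene04", "TGW", (0.0, -3.00, -1.50)),
        CausalGene("gene05", "TGW", (0.0, 3.00, 1.50)),
        CausalGene("gene06", "TGW", (0.0, -2.50, -1.20)),
        CausalGene("gene07", "TGW", (0.0, 2.00, 1.00)),
    )


def default_config(seed: int = 0) -> SimulationConfig:
    """The study-scale panel: 180 accessions, 42 genes, 3 subpops."""
    return SimulationConfig(
        causal_spec=default_causal_spec(),
        trait_spec=default_trait_spec(),
        missing_rate=0.01,
        subpop_proportions=(39 / 180, 58 / 180, 83 / 180),
        seed=seed,
    )


# ----------------------------------------------------------------------
# Panel simulation
# ----------------------------------------------------------------------

def _make_gene_model(gene_id: str, chrom: str, tx_start: int, rng: np.random.Generator) -> GeneModel:
    n_ex = int(rng.integers(1, 5))
    exon_lens = rng.integers(400, 900, n_ex)
    intron_lens = rng.integers(100, 800, max(n_ex - 1, 0))
    exons = []
    pos = tx_start
    for i in range(n_ex):
        exons.append((pos, pos + int(exon_lens[i]) - 1))
        pos = exons[-1][1] + 1 + (int(intron_lens[i]) if i < n_ex - 1 else 0)
    tx_end = exons[-1][1]
    utr5 = int(rng.integers(30, 150))
    utr3 = int(rng.integers(30, 150))
    cds_start = exons[0][0] + utr5
    cds_end = exons[-1][1] - utr3
    strand = "+" if rng.random() < 0.5 else "-"
    model = GeneModel(
        gene_id=gene_id,
        chrom=chrom,
        strand=strand,
        tx_start=tx_start,
        tx_end=tx_end,
        cds_start=cds_start,
        cds_end=cds_end,
        exons=tuple(exons),
    )
    extra = model.cds_length % 3
    if extra:
        model = dataclasses.replace(model, cds_end=cds_end - extra)
    return model


def _make_cds(length: int, rng: np.random.Generator) -> str:
    n_codons = length // 3
    mids = rng.integers(0, len(NON_STOP_CODONS), max(n_codons - 2, 0))
    return (
        "ATG" + "".join(NON_STOP_CODONS[i] for i in mids) + STOP_CODONS[int(rng.integers(3))]
    )


def _genomic_ref_base(gene: GeneModel, cds_seq: str, pos: int) -> str | None:
    """Forward-strand reference base at a CDS position, else None."""
    off = 0
    for s, e in gene.cds_intervals:
        if s <= pos <= e:
            o = off + (pos - s)
            if gene.strand == "+":
                return cds_seq[o]
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            return comp[cds_seq[len(cds_seq) - 1 - o]]
        off += e - s + 1
    return None


def _gene_sites(
    gene: GeneModel, cds_seq: str, m: int, rng: np.random.Generator
) -> list[Variant]:
    lo, hi = gene.span_with_promoter
    pos = rng.choice(np.arange(lo, hi + 1), size=m, replace=False)
    pos.sort()
    variants = []
    for p in pos:
        ref_cds = _genomic_ref_base(gene, cds_seq, int(p))
        in_cds = ref_cds is not None
        ref = ref_cds if in_cds else BASES[int(rng.integers(4))]
        if not in_cds and rng.random() < 0.2:  # indel (kept out of the CDS)
            extra = "".join(BASES[int(i)] for i in rng.integers(0, 4, int(rng.integers(1, 4))))
            if rng.random() < 0.5:
                alt, ref = ref, ref + extra  # deletion
            else:
                alt = ref + extra  # insertion
        else:
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        variants.append(
            Variant(chrom=gene.chrom, pos=int(p), ref=ref, alt=alt, id=f"{gene.chrom}_{p}")
        )
    return variants


def _founder_alleles(k: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """k x m binary founder matrix: every site segregates, founders distinct."""
    H = (rng.random((k, m)) < 0.5).astype(int)
    for j in range(m):
        if H[:, j].min() == H[:, j].max():
            H[int(rng.integers(k)), j] ^= 1
    seen: dict[tuple, int] = {}
    for f in range(k):
        while tuple(H[f]) in seen:
            H[f, int(rng.integers(m))] ^= 1
        seen[tuple(H[f])] = f
    return H


def _qc_fields(n: int, frac: float, rng: np.random.Generator):
    qual = rng.uniform(60, 2000, n)
    qd = rng.uniform(8, 30, n)
    fs = rng.uniform(0, 20, n)
    mq = rng.uniform(50, 60, n)
    for arr, bad in (
        (qual, lambda s: rng.uniform(1, 29.9, s)),
        (qd, lambda s: rng.uniform(0.1, 3.9, s)),
        (fs, lambda s: rng.uniform(60.1, 200, s)),
        (mq, lambda s: rng.uniform(10, 39.9, s)),
    ):
        mask = rng.random(n) < frac
        arr[mask] = bad(int(mask.sum()))
    return qual, qd, fs, mq


def simulate_panel(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, list[GeneModel], TruthTable]:
    """Simulate genotypes, gene models and the generative truth table."""
    rng = np.random.default_rng([config.seed, 0])
    n, k, m = config.n_accessions, config.founders_per_gene, config.sites_per_gene
    accessions = [f"acc{i + 1:04d}" for i in range(n)]

    # subpopulation assignment (largest-remainder apportionment)
    props = (
        np.asarray(config.subpop_proportions)
        if config.subpop_proportions is not None
        else np.full(config.n_subpops, 1.0 / config.n_subpops)
    )
    counts = np.floor(props * n).astype(int)
    frac_order = np.argsort(-(props * n - counts))
    for i in range(n - counts.sum()):
        counts[frac_order[i % len(counts)]] += 1
    subpop_of = np.repeat(np.arange(config.n_subpops), counts)

    genes: list[GeneModel] = []
    all_variants: list[Variant] = []
    dosage_cols: list[np.ndarray] = []
    truth = TruthTable(
        subpop={a: int(s) for a, s in zip(accessions, subpop_of)},
        founder_strings={},
        acc_founder={},
        causal={},
        superior_founder={},
        founder_pairs={},
    )

    for g in range(config.n_genes):
        gene_id = f"gene{g + 1:02d}"
        chrom = f"chr{(g % 12) + 1:02d}"
        tx_start = 100_000 + (g // 12) * 100_000
        gene = _make_gene_model(gene_id, chrom, tx_start, rng)
        cds_seq = _make_cds(gene.cds_length, rng)
        variants = _gene_sites(gene, cds_seq, m, rng)
        H = _founder_alleles(k, m, rng)

        if config.founder_freqs is not None:
            base = np.asarray(config.founder_freqs)
        else:
            # Dirichlet spread with a 5% floor: every founder haplotype is
            # present at panel scale (rarest analyzable groups sit near 5%)
            base = (1.0 - 0.05 * k) * rng.dirichlet(2.0 * np.ones(k)) + 0.05
        base = np.clip(base, 1e-3, None)
        base = base / base.sum()
        F = config.subpop_divergence
        if F <= 0:
            subpop_freqs = np.tile(base, (config.n_subpops, 1))
        else:
            subpop_freqs = np.vstack(
                [rng.dirichlet(base * (1.0 - F) / F) for _ in range(config.n_subpops)]
            )

        f1 = np.empty(n, dtype=int)
        f2 = np.empty(n, dtype=int)
        for i in range(n):
            p = subpop_freqs[subpop_of[i]]
            f1[i] = rng.choice(k, p=p)
            f2[i] = f1[i] if rng.random() < config.inbreeding else rng.choice(k, p=p)
        dose = H[f1] + H[f2]  # n x m in {0,1,2}
        dosage_cols.append(dose.astype(float))

        genes.append(gene)
        all_variants.extend(variants)
        truth.cds_sequences[gene_id] = cds_seq
        truth.founder_strings[gene_id] = [
            "|".join(v.alt if H[f, j] else v.ref for j, v in enumerate(variants))
            for f in range(k)
        ]
        truth.acc_founder[gene_id] = {a: int(f) for a, f in zip(accessions, f1)}
        truth.founder_pairs[gene_id] = {
            a: (int(x), int(y)) for a, x, y in zip(accessions, f1, f2)
        }

    dosage = np.hstack(dosage_cols)
    if config.missing_rate > 0:
        mask = rng.random(dosage.shape) < config.missing_rate
        dosage[mask] = np.nan

    qual, qd, fs, mq = _qc_fields(len(all_variants), config.qc_fail_fraction, rng)
    all_variants = [
        dataclasses.replace(
            v, qual=float(qual[i]), info={"QD": float(qd[i]), "FS": float(fs[i]), "MQ": float(mq[i])}
        )
        for i, v in enumerate(all_variants)
    ]
    matrix = GenotypeMatrix(accessions, all_variants, dosage)

    # causal bookkeeping
    for c in config.causal_spec:
        truth.causal.setdefault(c.trait, []).append(c)
        direction = config.trait_spec[c.trait].direction
        eff = np.asarray(c.effects)
        best = int(np.argmax(eff) if direction == "maximize" else np.argmin(eff))
        truth.superior_founder.setdefault(c.trait, {})[c.gene] = best

    # true kinship (normalized to unit mean diagonal) for the polygenic term
    col_mean = np.nanmean(dosage, axis=0)
    idx = np.where(np.isnan(dosage))
    X = dosage.copy()
    X[idx] = col_mean[idx[1]]
    W = X - X.mean(axis=0, keepdims=True)
    K = W @ W.T / W.shape[1]
    mean_diag = np.mean(np.diag(K))
    truth.kinship = K / mean_diag if mean_diag > 0 else np.eye(n)
    return matrix, genes, truth


# ----------------------------------------------------------------------
# Phenotype simulation
# ----------------------------------------------------------------------

def simulate_phenotypes(config: SimulationConfig, truth: TruthTable) -> PhenotypeTable:
    """Draw multi-environment phenotypes under the planted model."""
    if not config.trait_spec:
        raise ConfigurationError("trait_spec is empty")
    rng = np.random.default_rng([config.seed, 1])
    accessions = list(truth.subpop)
    n = len(accessions)
    if truth.kinship is None:
        K = np.eye(n)
    else:
        K = truth.kinship
    L = np.linalg.cholesky(K + 1e-8 * np.eye(n))

    rows = []
    for trait, spec in config.trait_spec.items():
        e, r = spec.n_envs, spec.replicates
        g_bg = np.sqrt(spec.vg_bg) * (L @ rng.standard_normal(n))
        h = np.zeros(n)
        for c in truth.causal.get(trait, []):
            pairs = truth.founder_pairs.get(c.gene)
            if pairs is None:  # truth loaded from JSON: inbred, single founder id
                ids = truth.acc_founder[c.gene]
                h += np.array([c.effects[ids[a]] for a in accessions])
            else:
                eff = np.asarray(c.effects)
                h += np.array(
                    [(eff[pairs[a][0]] + eff[pairs[a][1]]) / 2.0 for a in accessions]
                )
        ge = rng.normal(0.0, np.sqrt(spec.vge), (n, e)) if spec.vge > 0 else np.zeros((n, e))
        eps = (
            rng.normal(0.0, np.sqrt(spec.ve), (n, e, r)) if spec.ve > 0 else np.zeros((n, e, r))
        )
        for j in range(e):
            for kk in range(r):
                vals = spec.mean + g_bg + h + spec.env_effects[j] + ge[:, j] + eps[:, j, kk]
                for i, acc in enumerate(accessions):
                    rows.append(
                        {
                            "accession": acc,
                            "trait": trait,
                            "environment": f"env{j + 1}",
                            "replicate": kk + 1,
                            "value": float(vals[i]),
                        }
                    )
        genetic = g_bg + h
        vg_real = float(np.var(genetic, ddof=1))
        vge_real = float(np.var(ge, ddof=1)) if e * n > 1 else 0.0
        ve_real = float(np.var(eps, ddof=1)) if eps.size > 1 else 0.0
        denom = vg_real + vge_real / e + ve_real / (r * e)
        truth.realized_h2[trait] = vg_real / denom if denom > 0 else np.nan

    directions = {t: s.direction for t, s in config.trait_spec.items()}
    return PhenotypeTable(pd.DataFrame(rows), directions)


def simulate(config: SimulationConfig):
    """Convenience: panel + phenotypes in one call."""
    matrix, genes, truth = simulate_panel(config)
    pheno = simulate_phenotypes(config, truth)
    return matrix, genes, pheno, truth


# ----------------------------------------------------------------------
# Fixture I/O
# ----------------------------------------------------------------------

FIXTURE_FILES = {
    "vcf": "panel.vcf",
    "genes": "gene_models.tsv",
    "pheno": "phenotypes.tsv",
    "directions": "trait_directions.tsv",
    "truth": "truth.json",
    "cds": "cds_sequences.fa",
}


def write_fixture(
    outdir: str | Path,
    matrix: GenotypeMatrix,
    genes: list[GeneModel],
    phenotypes: PhenotypeTable,
    truth: TruthTable,
) -> dict[str, Path]:
    """Write the full fixture file set; read-back is lossless."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {k: outdir / v for k, v in FIXTURE_FILES.items()}
    write_vcf(matrix, paths["vcf"])
    write_gene_models(genes, paths["genes"])
    phenotypes.write(paths["pheno"], paths["directions"])
    truth.to_json(paths["truth"])
    with open(paths["cds"], "w") as fh:
        for gene_id, seq in truth.cds_sequences.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    logger.info("fixture written to %s", outdir)
    return paths


def read_fixture(outdir: str | Path):
    """Read back (matrix, genes, phenotypes, truth) from a fixture dir."""
    outdir = Path(outdir)
    paths = {k: outdir / v for k, v in FIXTURE_FILES.items()}
    matrix = read_vcf(paths["vcf"])
    genes = read_gene_models(paths["genes"])
    pheno = PhenotypeTable.read(paths["pheno"], paths["directions"])
    truth = TruthTable.from_json(paths["truth"])
    return matrix, genes, pheno, truth
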