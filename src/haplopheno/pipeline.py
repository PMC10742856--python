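"""End-to-end pipeline stages and their file products.

Stages: simulate -> qc -> assoc -> haplo -> markers. Each stage reads
the previous stage's products from the output directory, so they can
be run one at a time or via :func:`run_all`, which also writes a
manifest (package version, config hash, per-stage record counts).
Thresholds default to the analysis constants of the candidate-gene
protocol: hard filters QUAL/QD/FS/MQ = 30/4.0/60.0/40.0, pruning
100/50/0.2, association alpha = 0.01, minimum haplotype group size 4.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .association import (
    annotate_associations,
    associated_by_gene,
    consistent_associations,
    gene_summary,
    lmm_scan,
    scan_frame,
)
from .datatypes import GenotypeMatrix, HaploPhenoError
from .haplotypes import (
    analyze_groups,
    call_haplotypes,
    combine_haplotypes,
    results_table,
)
from .markers import discriminating_sites, genotype_panel, panel_table
from .pheno_stats import (
    PhenotypeTable,
    blup,
    heritability_report,
    trait_correlations,
    variance_components,
)
from .population import centered_kinship, ld_prune, prune_report
from .synthetic_data import (
    SimulationConfig,
    default_config,
    simulate,
    write_fixture,
)
from .variant_io import hard_filter, read_gene_models, read_vcf, write_vcf

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All paths, thresholds and modes of one pipeline run."""

    vcf: str | None = None
    genes: str | None = None
    phenotypes: str | None = None
    directions: str | None = None
    outdir: str = "haplopheno_out"
    alpha: float = 0.01
    hard_filter: dict = field(
        default_factory=lambda: {"QUAL": 30.0, "QD": 4.0, "FS": 60.0, "MQ": 40.0}
    )
    prune_window: int = 100
    prune_step: int = 50
    prune_r2: float = 0.2
    min_hap_count: int = 4
    min_hap_percent: float | None = None
    maf_min: float = 0.01
    per_variant_lambda: bool = True
    use_pruned_for_assoc: bool = False
    duncan_alpha: float = 0.05
    seed: int = 0
    simulate: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("alpha", "prune_window", "prune_step", "prune_r2", "min_hap_count"):
            if getattr(self, name) <= 0:
                raise HaploPhenoError(f"{name} must be positive")

    # ------------------------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path, overrides: list[str] | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw, overrides)

    @classmethod
    def from_dict(cls, raw: dict, overrides: list[str] | None = None) -> "PipelineConfig":
        raw = dict(raw)
        for item in overrides or []:
            if "=" not in item:
                raise HaploPhenoError(f"--set expects key=value, got {item!r}")
            key, val = item.split("=", 1)
            target = raw
            parts = key.split(".")
            for p in parts[:-1]:
                target = target.setdefault(p, {})
            target[parts[-1]] = yaml.safe_load(val)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise HaploPhenoError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _outdir(config: PipelineConfig, stage: str) -> Path:
    p = Path(config.outdir) / stage
    p.mkdir(parents=True, exist_ok=True)
    return p


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise HaploPhenoError(
            f"missing upstream artifact {path}; run the '{stage}' stage first"
        )
    return path


# ----------------------------------------------------------------------
# Stages
# ----------------------------------------------------------------------

def run_simulate(config: PipelineConfig) -> dict:
    """Generate the synthetic fixture the remaining stages consume."""
    sim_kwargs = dict(config.simulate)
    sim_kwargs.setdefault("seed", config.seed)
    if sim_kwargs.keys() <= {"seed"}:
        sim_config = default_config(seed=sim_kwargs["seed"])
    else:
        base = _rehydrate(dataclasses.asdict(default_config(seed=sim_kwargs["seed"])))
        merged = {**base, **sim_kwargs}
        if "causal_spec" not in sim_kwargs:
            # defaults reference gene01..gene07; drop any outside a
            # user-shrunk panel
            n = merged["n_genes"]
            merged["causal_spec"] = tuple(
                c for c in merged["causal_spec"] if int(c.gene.removeprefix("gene")) <= n
            )
        sim_config = SimulationConfig(**merged)
    matrix, genes, pheno, truth = simulate(sim_config)
    fixture = _outdir(config, "fixture")
    write_fixture(fixture, matrix, genes, pheno, truth)
    config.vcf = str(fixture / "panel.vcf")
    config.genes = str(fixture / "gene_models.tsv")
    config.phenotypes = str(fixture / "phenotypes.tsv")
    config.directions = str(fixture / "trait_directions.tsv")
    return {
        "n_accessions": matrix.n_accessions,
        "n_variants": matrix.n_variants,
        "n_genes": len(genes),
        "n_traits": len(pheno.traits),
    }


def _rehydrate(base: dict) -> dict:
    # dataclasses.asdict flattens nested dataclasses into dicts; rebuild them
    from .synthetic_data import CausalGene, TraitSpec

    base["causal_spec"] = tuple(
        CausalGene(c["gene"], c["trait"], tuple(c["effects"])) for c in base["causal_spec"]
    )
    base["trait_spec"] = {
        t: TraitSpec(**{**s, "env_effects": tuple(s["env_effects"])})
        for t, s in base["trait_spec"].items()
    }
    return base


def _input_vcf(config: PipelineConfig) -> Path:
    if config.vcf:
        return _require(Path(config.vcf), "simulate")
    return _require(Path(config.outdir) / "fixture" / "panel.vcf", "simulate")


def _input_path(config: PipelineConfig, attr: str, fixture_name: str) -> Path:
    val = getattr(config, attr)
    if val:
        return _require(Path(val), "simulate")
    return _require(Path(config.outdir) / "fixture" / fixture_name, "simulate")


def run_qc(config: PipelineConfig) -> dict:
    """Hard-filter the variant set and write the filtered VCF."""
    matrix = read_vcf(_input_vcf(config))
    filtered, report = hard_filter(matrix, config.hard_filter)
    out = _outdir(config, "qc")
    write_vcf(filtered, out / "filtered.vcf")
    report.to_frame().to_csv(out / "filter_report.tsv", sep="\t", index=False)
    return {
        "n_input": report.n_input,
        "n_removed": report.n_removed,
        "n_retained": filtered.n_variants,
    }


def run_assoc(config: PipelineConfig) -> dict:
    """Kinship, BLUPs and the three-dataset association scan per trait."""
    out = _outdir(config, "assoc")
    matrix = read_vcf(_require(Path(config.outdir) / "qc" / "filtered.vcf", "qc"))
    genes = read_gene_models(_input_path(config, "genes", "gene_models.tsv"))
    pheno = PhenotypeTable.read(
        _input_path(config, "phenotypes", "phenotypes.tsv"),
        _input_path(config, "directions", "trait_directions.tsv"),
    )

    retained = ld_prune(matrix, config.prune_window, config.prune_step, config.prune_r2)
    prune_report(matrix, retained).to_csv(out / "prune_report.tsv", sep="\t", index=False)
    kin_matrix = matrix.subset_variants(retained)
    kinship = centered_kinship(kin_matrix)
    kinship.write(out / "kinship.tsv")
    scan_matrix = kin_matrix if config.use_pruned_for_assoc else matrix

    heritability_report(pheno).to_csv(out / "heritability.tsv", sep="\t", index=False)
    blups = {}
    n_assoc_total = 0
    for trait in pheno.traits:
        vc = variance_components(pheno, trait)
        blups[trait] = blup(pheno, trait, vc)
        records = pheno.trait_records(trait)
        envs = sorted(records["environment"].unique())
        datasets: dict[str, pd.Series] = {}
        for env in envs:
            sub = records[records["environment"] == env]
            datasets[env] = sub.groupby("accession")["value"].mean()
        datasets["BLUP"] = blups[trait].values
        frames = {}
        for name, y in datasets.items():
            missing = set(scan_matrix.accessions) - set(y.index)
            if missing:
                raise HaploPhenoError(
                    f"trait {trait}: {len(missing)} accession(s) lack {name} values"
                )
            fits = lmm_scan(
                y,
                scan_matrix,
                kinship,
                maf_min=config.maf_min,
                per_variant_lambda=config.per_variant_lambda,
            )
            frames[name] = scan_frame(fits)
            frames[name].to_csv(out / f"scan_{trait}_{name}.tsv", sep="\t", index=False)
        consistent = consistent_associations(frames, alpha=config.alpha)
        annotated = annotate_associations(consistent, scan_matrix, genes)
        annotated.to_csv(out / f"associated_{trait}.tsv", sep="\t", index=False)
        gene_summary(annotated).to_csv(out / f"gene_summary_{trait}.tsv", sep="\t", index=False)
        n_assoc_total += int(annotated["consistent"].sum())

    blup_frame = pd.DataFrame({t: b.values for t, b in blups.items()})
    blup_frame.index.name = "accession"
    blup_frame.to_csv(out / "blups.tsv", sep="\t")
    if len(blups) >= 2:
        r, p = trait_correlations(blups)
        r.to_csv(out / "correlations_r.tsv", sep="\t")
        p.to_csv(out / "correlations_p.tsv", sep="\t")
    return {
        "n_variants_scanned": scan_matrix.n_variants,
        "n_pruned_for_kinship": len(retained),
        "n_consistent_associations": n_assoc_total,
    }


def run_haplo(config: PipelineConfig) -> dict:
    """Haplotype groups, combinations and superior labels per trait."""
    out = _outdir(config, "haplo")
    assoc_dir = Path(config.outdir) / "assoc"
    matrix = read_vcf(_require(Path(config.outdir) / "qc" / "filtered.vcf", "qc"))
    pheno = PhenotypeTable.read(
        _input_path(config, "phenotypes", "phenotypes.tsv"),
        _input_path(config, "directions", "trait_directions.tsv"),
    )
    blups = pd.read_csv(
        _require(assoc_dir / "blups.tsv", "assoc"), sep="\t", index_col="accession"
    )

    n_results = 0
    assignment_rows = []
    for trait in pheno.traits:
        annotated = pd.read_csv(_require(assoc_dir / f"associated_{trait}.tsv", "assoc"), sep="\t")
        by_gene = associated_by_gene(annotated)
        direction = pheno.direction(trait)
        values = blups[trait]
        gene_results = []
        assignments = []
        for gene_id, vids in sorted(by_gene.items()):
            assignment = call_haplotypes(matrix, gene_id, vids)
            assignments.append(assignment)
            assignment_rows.append(assignment.to_frame().assign(trait=trait))
            try:
                gene_results.append(
                    analyze_groups(
                        assignment,
                        values,
                        trait,
                        direction=direction,
                        min_count=config.min_hap_count,
                        min_percent=config.min_hap_percent,
                        alpha=config.duncan_alpha,
                    )
                )
            except HaploPhenoError as exc:
                logger.info("trait %s gene %s: %s; skipped", trait, gene_id, exc)
        table = results_table(gene_results) if gene_results else pd.DataFrame()
        table.to_csv(out / f"haplotypes_{trait}.tsv", sep="\t", index=False)
        n_results += len(gene_results)

        if len(assignments) >= 2:
            combo = combine_haplotypes(assignments)
            try:
                combo_result = analyze_groups(
                    combo,
                    values,
                    trait,
                    direction=direction,
                    min_count=config.min_hap_count,
                    min_percent=config.min_hap_percent,
                    alpha=config.duncan_alpha,
                )
            except HaploPhenoError as exc:
                logger.info("trait %s combinations: %s; skipped", trait, exc)
            else:
                results_table([combo_result]).to_csv(
                    out / f"combinations_{trait}.tsv", sep="\t", index=False
                )
                combo.to_frame().assign(trait=trait).to_csv(
                    out / f"combination_assignments_{trait}.tsv", sep="\t", index=False
                )
        # boxplot-ready long table: one value per (accession, group)
        if assignments:
            long_rows = []
            for assignment in assignments:
                for acc, lab in assignment.labels.items():
                    if lab is not None and acc in values.index:
                        long_rows.append(
                            {
                                "trait": trait,
                                "gene": assignment.gene,
                                "haplotype": lab,
                                "accession": acc,
                                "value": values[acc],
                            }
                        )
            pd.DataFrame(long_rows).to_csv(out / f"boxplot_{trait}.tsv", sep="\t", index=False)
    if assignment_rows:
        pd.concat(assignment_rows).to_csv(out / "assignments.tsv", sep="\t", index=False)
    return {"n_gene_results": n_results}


def run_markers(config: PipelineConfig) -> dict:
    """Discriminating marker panel for each trait's superior group."""
    out = _outdir(config, "markers")
    haplo_dir = Path(config.outdir) / "haplo"
    matrix = read_vcf(_require(Path(config.outdir) / "qc" / "filtered.vcf", "qc"))
    pheno = PhenotypeTable.read(
        _input_path(config, "phenotypes", "phenotypes.tsv"),
        _input_path(config, "directions", "trait_directions.tsv"),
    )
    blups = pd.read_csv(
        _require(Path(config.outdir) / "assoc" / "blups.tsv", "assoc"),
        sep="\t",
        index_col="accession",
    )
    n_panels = 0
    for trait in pheno.traits:
        combo_path = haplo_dir / f"combinations_{trait}.tsv"
        single_path = haplo_dir / f"haplotypes_{trait}.tsv"
        use_combo = combo_path.exists()
        table_path = combo_path if use_combo else _require(single_path, "haplo")
        table = pd.read_csv(table_path, sep="\t") if table_path.stat().st_size > 1 else pd.DataFrame()
        if table.empty:
            continue
        # rebuild the assignment the table came from
        annotated = pd.read_csv(
            _require(Path(config.outdir) / "assoc" / f"associated_{trait}.tsv", "assoc"), sep="\t"
        )
        by_gene = associated_by_gene(annotated)
        assignments = [
            call_haplotypes(matrix, g, vids) for g, vids in sorted(by_gene.items())
        ]
        if not assignments:
            continue
        assignment = (
            combine_haplotypes(assignments) if use_combo and len(assignments) >= 2 else assignments[0]
        )
        try:
            result = analyze_groups(
                assignment,
                blups[trait],
                trait,
                direction=pheno.direction(trait),
                min_count=config.min_hap_count,
                min_percent=config.min_hap_percent,
                alpha=config.duncan_alpha,
            )
        except HaploPhenoError as exc:
            logger.info("trait %s markers: %s; skipped", trait, exc)
            continue
        retained = [g.label for g in result.groups]
        if len(retained) < 2:
            logger.info("trait %s: single retained group, no panel needed", trait)
            continue
        panel = discriminating_sites(assignment, result.superior, retained=retained)
        panel_table(panel, matrix).to_csv(out / f"panel_{trait}.tsv", sep="\t", index=False)
        calls = genotype_panel(matrix, panel)
        calls.rename("call").to_frame().rename_axis("accession").to_csv(
            out / f"calls_{trait}.tsv", sep="\t"
        )
        n_panels += 1
    return {"n_panels": n_panels}


STAGES = {
    "simulate": run_simulate,
    "qc": run_qc,
    "assoc": run_assoc,
    "haplo": run_haplo,
    "markers": run_markers,
}


def run_all(config: PipelineConfig) -> dict:
    """Run every stage in order and write the manifest."""
    counts = {}
    for name, stage in STAGES.items():
        if name == "simulate" and config.vcf and Path(config.vcf).exists():
            logger.info("input VCF provided; skipping simulation")
            continue
        logger.info("stage %s", name)
        counts[name] = stage(config)
    manifest = {
        "package": "haplopheno",
        "version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "stages": counts,
    }
    Path(config.outdir).mkdir(parents=True, exist_ok=True)
    (Path(config.outdir) / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
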