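"""Haplotype-specific discriminating marker panels.

Given the retained haplotype (or haplotype-combination) groups at a
gene set, a marker panel for a target group is a small set of variant
sites whose diagnostic alleles jointly separate the target from every
other retained group — the sites an allele-specific PCR assay (KASP or
PARMS chemistry) would genotype. Site selection is a set-cover
problem: each candidate site "covers" the non-target groups that carry
a different allele there. The default greedy cover is exchanged for an
exhaustive minimal cover when the candidate list is small.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import pandas as pd

from .datatypes import GenotypeMatrix, HaploPhenoError
from .haplotypes import HaplotypeAssignment

logger = logging.getLogger(__name__)

EXACT_MAX_SITES = 15


@dataclass
class MarkerPanel:
    """Discriminating sites and their diagnostic (target) alleles."""

    target: str
    variant_ids: list[str]
    diagnostic_alleles: dict[str, str]
    coverage: dict[str, list[str]]  # non-target group -> separating panel sites

    def __post_init__(self) -> None:
        for group, sites in self.coverage.items():
            if not sites:
                raise ValueError(f"group {group} not separated by any panel site")


def discriminating_sites(
    assignment: HaplotypeAssignment,
    target: str,
    retained: list[str] | None = None,
    method: str = "auto",
) -> MarkerPanel:
    """Select a small site set separating ``target`` from all other groups.

    ``retained`` restricts the groups that must be separated (default:
    all labelled groups). ``method``: "greedy" (default for large
    candidate lists), "exact" (minimal cover by subset enumeration), or
    "auto" (exact when <= 15 candidate sites). Greedy ties prefer the
    earlier genomic position (list order).
    """
    groups = retained if retained is not None else sorted(assignment.alleles)
    if target not in groups:
        raise HaploPhenoError(f"target {target!r} is not a retained group")
    others = [g for g in groups if g != target]
    t_alleles = assignment.alleles[target]
    vids = assignment.variant_ids
    if not others:
        raise HaploPhenoError("no non-target groups to separate")

    separates: dict[int, set[str]] = {}
    for i, vid in enumerate(vids):
        cov = {g for g in others if assignment.alleles[g][i] != t_alleles[i]}
        if cov:
            separates[i] = cov
    clones = [g for g in others if assignment.alleles[g] == t_alleles]
    if clones:
        raise HaploPhenoError(
            f"target {target!r} not discriminable: group(s) {clones} share its haplotype string"
        )

    candidates = sorted(separates)
    if method == "auto":
        method = "exact" if len(candidates) <= EXACT_MAX_SITES else "greedy"
    if method == "exact":
        chosen = _exact_cover(candidates, separates, set(others))
    elif method == "greedy":
        chosen = _greedy_cover(candidates, separates, set(others))
    else:
        raise HaploPhenoError(f"unknown method {method!r}")

    panel_vids = [vids[i] for i in chosen]
    coverage = {
        g: [vids[i] for i in chosen if g in separates[i]] for g in others
    }
    panel = MarkerPanel(
        target=target,
        variant_ids=panel_vids,
        diagnostic_alleles={vids[i]: t_alleles[i] for i in chosen},
        coverage=coverage,
    )
    logger.info(
        "marker panel for %s: %d site(s) separating %d group(s)",
        target,
        len(panel_vids),
        len(others),
    )
    return panel


def _greedy_cover(candidates, separates, uncovered: set[str]) -> list[int]:
    chosen: list[int] = []
    remaining = set(uncovered)
    while remaining:
        best = max(candidates, key=lambda i: (len(separates[i] & remaining), -i))
        gain = separates[best] & remaining
        if not gain:
            raise HaploPhenoError("set cover stalled; groups not separable")
        chosen.append(best)
        remaining -= gain
    return chosen


def _exact_cover(candidates, separates, uncovered: set[str]) -> list[int]:
    """Smallest covering subset by size-ordered enumeration.

    Among equal-size covers the lexicographically earliest candidate
    tuple (genomic order) wins.
    """
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            covered = set().union(*(separates[i] for i in combo))
            if uncovered <= covered:
                return list(combo)
    raise HaploPhenoError("no covering subset exists")


def genotype_panel(
    matrix: GenotypeMatrix,
    panel: MarkerPanel,
    accessions: list[str] | None = None,
) -> pd.Series:
    """Call accessions against a marker panel.

    ``target``: homozygous for the diagnostic allele at every panel
    site; ``non-target``: a non-missing mismatch at any site;
    ``inconclusive``: no mismatch but at least one missing or
    heterozygous site.
    """
    accs = accessions if accessions is not None else matrix.accessions
    by_id = {v.id: (i, v) for i, v in enumerate(matrix.variants)}
    for vid in panel.variant_ids:
        if vid not in by_id:
            raise HaploPhenoError(f"panel variant {vid} absent from genotype matrix")
    acc_idx = {a: i for i, a in enumerate(matrix.accessions)}
    calls = {}
    for acc in accs:
        if acc not in acc_idx:
            raise HaploPhenoError(f"accession {acc} absent from genotype matrix")
        a = acc_idx[acc]
        mismatch = False
        incomplete = False
        for vid in panel.variant_ids:
            j, v = by_id[vid]
            d = matrix.dosage[a, j]
            if d == 0:
                allele = v.ref
            elif d == 2:
                allele = v.alt
            else:
                incomplete = True
                continue
            if allele != panel.diagnostic_alleles[vid]:
                mismatch = True
        if mismatch:
            calls[acc] = "non-target"
        elif incomplete:
            calls[acc] = "inconclusive"
        else:
            calls[acc] = "target"
    return pd.Series(calls, name=f"call_{panel.target}")


def panel_table(panel: MarkerPanel, matrix: GenotypeMatrix) -> pd.DataFrame:
    """Panel as a report table (site, alleles, diagnostic allele)."""
    by_id = {v.id: v for v in matrix.variants}
    rows = []
    for vid in panel.variant_ids:
        v = by_id[vid]
        rows.append(
            {
                "variant": vid,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "diagnostic_allele": panel.diagnostic_alleles[vid],
                "target": panel.target,
            }
        )
    return pd.DataFrame(rows)
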