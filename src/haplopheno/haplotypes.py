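"""Haplo-pheno analysis: haplotype calling, group statistics, superior
haplotypes and multi-gene haplotype combinations.

In a fully inbred panel the haplotype an accession carries at a gene is
simply the string of alleles at the gene's trait-associated variant
sites, read off the homozygous dosages — no phasing is required.
Accessions sharing a string form a haplotype group; groups are labelled
H1, H2, ... by descending frequency. Rare groups (fewer than four
accessions by default) are excluded from the statistics but still count
in panel-percent denominators. Group trait values (BLUPs by default)
are compared with a pooled-variance Student's t (two groups) or with
Duncan's multiple range test (more), the percent of variation explained
is the one-way ANOVA eta-squared, and the superior haplotype is the
retained group whose mean is most favourable for the trait's breeding
direction. Multi-gene haplotype combinations (HC1, HC2, ...) are
tuples of per-gene labels analysed with exactly the same machinery.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import GenotypeMatrix, HaploPhenoError

logger = logging.getLogger(__name__)

MISSING_LABEL = None
RARE_MIN_COUNT = 4  # "more than three accessions"


@dataclass
class HaplotypeAssignment:
    """Per-accession haplotype labels at one gene (or gene set).

    ``alleles`` maps each label to the tuple of allele strings at
    ``variant_ids`` (for gene sets: the concatenation over genes);
    ``labels`` maps accession -> label, with None for accessions whose
    haplotype could not be called (missing or heterozygous sites).
    """

    gene: str
    variant_ids: list[str]
    labels: dict[str, str | None]
    alleles: dict[str, tuple[str, ...]]
    label_prefix: str = "H"

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for lab in self.labels.values():
            if lab is not None:
                out[lab] = out.get(lab, 0) + 1
        return out

    @property
    def n_accessions(self) -> int:
        return len(self.labels)

    def members(self, label: str) -> list[str]:
        return [a for a, l in self.labels.items() if l == label]

    def haplotype_string(self, label: str) -> str:
        return "|".join(self.alleles[label])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": list(self.labels),
                "gene": self.gene,
                "haplotype": [l if l is not None else "NA" for l in self.labels.values()],
            }
        )


@dataclass
class HaploGroup:
    """One retained haplotype group with its trait summary."""

    label: str
    members: list[str]
    count: int
    percent: float
    mean: float


@dataclass
class HaploPhenoResult:
    """Group statistics for one gene (or gene set) and one trait."""

    trait: str
    genes: tuple[str, ...]
    groups: list[HaploGroup]
    r2: float
    overall_p: float
    superior: str
    pairwise_p: float | None = None  # two groups
    letters: dict[str, str] = field(default_factory=dict)  # > 2 groups

    def to_rows(self) -> list[dict]:
        rows = []
        for g in self.groups:
            rows.append(
                {
                    "trait": self.trait,
                    "gene": "+".join(self.genes),
                    "haplotype": g.label,
                    "n": g.count,
                    "percent": g.percent,
                    "mean": g.mean,
                    "letters": self.letters.get(g.label, ""),
                    "R2_percent": self.r2,
                    "p": self.pairwise_p if self.pairwise_p is not None else self.overall_p,
                    "superior": g.label == self.superior,
                }
            )
        return rows


# ----------------------------------------------------------------------
# Haplotype calling
# ----------------------------------------------------------------------

def call_haplotypes(
    matrix: GenotypeMatrix, gene: str, variant_ids: list[str]
) -> HaplotypeAssignment:
    """Call per-accession haplotypes from homozygous dosages.

    Dosage 0 reads the REF allele, 2 the ALT allele; a missing or
    heterozygous call at any site makes the accession's haplotype
    missing (logged). Labels H1, H2, ... are assigned by descending
    group frequency, ties broken by lexicographic allele string.
    """
    if not variant_ids:
        raise HaploPhenoError(f"gene {gene}: empty associated-variant list")
    idx = [matrix.variant_index(vid) for vid in variant_ids]
    variants = [matrix.variants[i] for i in idx]
    strings: dict[str, tuple[str, ...] | None] = {}
    n_uncalled = 0
    for a, acc in enumerate(matrix.accessions):
        alleles = []
        ok = True
        for i, v in zip(idx, variants):
            d = matrix.dosage[a, i]
            if d == 0:
                alleles.append(v.ref)
            elif d == 2:
                alleles.append(v.alt)
            else:  # missing or heterozygous
                ok = False
                break
        strings[acc] = tuple(alleles) if ok else None
        n_uncalled += 0 if ok else 1
    if n_uncalled:
        logger.info(
            "gene %s: %d accession(s) with missing/het sites -> haplotype missing",
            gene,
            n_uncalled,
        )
    observed: dict[tuple[str, ...], int] = {}
    for s in strings.values():
        if s is not None:
            observed[s] = observed.get(s, 0) + 1
    ordered = sorted(observed, key=lambda s: (-observed[s], s))
    label_of = {s: f"H{k + 1}" for k, s in enumerate(ordered)}
    labels = {a: (label_of[s] if s is not None else None) for a, s in strings.items()}
    alleles = {label_of[s]: s for s in ordered}
    return HaplotypeAssignment(gene=gene, variant_ids=list(variant_ids), labels=labels, alleles=alleles)


def filter_rare_haplotypes(
    assignment: HaplotypeAssignment,
    min_count: int = RARE_MIN_COUNT,
    min_percent: float | None = None,
) -> list[str]:
    """Labels of groups large enough to analyse.

    Default: count >= ``min_count`` (i.e. more than three accessions).
    If ``min_percent`` is given it replaces the count rule with
    count/panel >= min_percent/100.
    """
    counts = assignment.counts
    n = assignment.n_accessions
    if min_percent is not None:
        retained = [l for l, c in counts.items() if 100.0 * c / n >= min_percent]
    else:
        retained = [l for l, c in counts.items() if c >= min_count]
    retained.sort(key=lambda l: (-counts[l], l))
    if not retained:
        raise HaploPhenoError(f"gene {assignment.gene}: no analyzable haplotype groups")
    dropped = sorted(set(counts) - set(retained))
    if dropped:
        logger.info(
            "gene %s: excluded rare group(s) %s (counts %s)",
            assignment.gene,
            dropped,
            [counts[d] for d in dropped],
        )
    return retained


# ----------------------------------------------------------------------
# Group statistics
# ----------------------------------------------------------------------

def two_group_test(g1: np.ndarray, g2: np.ndarray, welch: bool = False) -> float:
    """Two-sided Student's t-test p-value (pooled variance by default).

    ``welch=True`` switches to the unequal-variance form.
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if len(g1) < 2 or len(g2) < 2:
        raise HaploPhenoError("both groups need >= 2 values for a t-test")
    sp2 = (
        (len(g1) - 1) * g1.var(ddof=1) + (len(g2) - 1) * g2.var(ddof=1)
    ) / (len(g1) + len(g2) - 2)
    if sp2 == 0:
        if g1.mean() == g2.mean():
            return 1.0
        logger.warning("zero pooled variance with unequal means; p -> 0")
        return 0.0
    _, p = stats.ttest_ind(g1, g2, equal_var=not welch)
    return float(p)


def _anova_sums(groups: list[np.ndarray]) -> tuple[float, float, int, int]:
    """(SS_between, SS_within, df_between, df_within)."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_b = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_w = sum(((g - g.mean()) ** 2).sum() for g in groups)
    return float(ss_b), float(ss_w), len(groups) - 1, len(allv) - len(groups)


def variance_explained(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA eta-squared (percent) and overall F-test p.

    R2 = 100 * SS_between / SS_total over the retained accessions.
    """
    if len(groups) < 2:
        raise HaploPhenoError("need >= 2 groups for variance explained")
    groups = [np.asarray(g, dtype=float) for g in groups]
    ss_b, ss_w, df_b, df_w = _anova_sums(groups)
    ss_t = ss_b + ss_w
    if ss_t == 0:
        raise HaploPhenoError("zero total sum of squares; R2 undefined")
    r2 = 100.0 * ss_b / ss_t
    if ss_w == 0 or df_w == 0:
        p = 0.0 if ss_b > 0 else 1.0
    else:
        f = (ss_b / df_b) / (ss_w / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return r2, p


def duncan_letters(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> dict[str, str]:
    """Duncan's multiple range test compact letter display.

    Means are sorted descending; a span of p consecutive means is
    declared homogeneous when its range does not exceed the critical
    range R_p = q(1 - alpha_p, p, df_err) * sqrt(MSE / n_h), with the
    protection level alpha_p = 1 - (1 - alpha)^(p-1) and n_h the
    harmonic mean of the group sizes. Spans inside an already
    homogeneous span are not retested (the step-down protection).
    Groups sharing a letter are not significantly different.
    """
    if len(groups) < 3:
        raise HaploPhenoError("duncan_letters needs >= 3 groups; use two_group_test")
    labels = list(groups)
    vals = [np.asarray(groups[l], dtype=float) for l in labels]
    _, ss_w, _, df_w = _anova_sums(vals)
    if df_w <= 0:
        raise HaploPhenoError("no residual degrees of freedom for Duncan's test")
    mse = ss_w / df_w
    n_h = len(vals) / sum(1.0 / len(g) for g in vals)
    means = np.array([g.mean() for g in vals])
    order = np.argsort(-means)  # descending
    k = len(labels)
    sorted_means = means[order]

    homogeneous: list[tuple[int, int]] = []  # inclusive index spans (sorted order)
    for p in range(k, 1, -1):
        alpha_p = 1.0 - (1.0 - alpha) ** (p - 1)
        if mse == 0:
            crit = 0.0
        else:
            q = stats.studentized_range.ppf(1.0 - alpha_p, p, df_w)
            crit = float(q) * np.sqrt(mse / n_h)
        for s in range(0, k - p + 1):
            e = s + p - 1
            if any(hs <= s and e <= he for hs, he in homogeneous):
                continue
            if sorted_means[s] - sorted_means[e] <= crit:
                homogeneous.append((s, e))

    # compact letter display from maximal homogeneous spans
    spans = [sp for sp in homogeneous if not any(
        other != sp and other[0] <= sp[0] and sp[1] <= other[1] for other in homogeneous
    )]
    covered = {i for s, e in spans for i in range(s, e + 1)}
    spans += [(i, i) for i in range(k) if i not in covered]
    spans.sort()
    letters_sorted: list[str] = ["" for _ in range(k)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for li, (s, e) in enumerate(spans):
        for i in range(s, e + 1):
            letters_sorted[i] += alphabet[li % len(alphabet)]
    out = {}
    for rank, gi in enumerate(order):
        out[labels[gi]] = letters_sorted[rank]
    return out


def superior_haplotype(
    means: dict[str, float], counts: dict[str, int], direction: str = "maximize"
) -> str:
    """Retained group with the most favourable mean for the trait.

    Ties are broken toward the larger group (logged), then by label.
    """
    if not means:
        raise HaploPhenoError("no retained groups")
    sign = 1.0 if direction == "maximize" else -1.0
    best = sorted(means, key=lambda l: (-sign * means[l], -counts.get(l, 0), l))
    if len(best) > 1 and means[best[0]] == means[best[1]]:
        logger.info("superior haplotype tie between %s and %s; chose larger group", best[0], best[1])
    return best[0]


# ----------------------------------------------------------------------
# Combinations
# ----------------------------------------------------------------------

def combine_haplotypes(assignments: list[HaplotypeAssignment]) -> HaplotypeAssignment:
    """Tuple of per-gene labels per accession, labelled HC1, HC2, ...

    An accession missing at any component gene is missing in the
    combination. Labels are assigned by descending combination
    frequency (ties: lexicographic tuple of component labels). A
    single-gene "combination" degenerates to the input assignment with
    HC labels.
    """
    if not assignments:
        raise HaploPhenoError("no assignments to combine")
    accs = set(assignments[0].labels)
    for a in assignments[1:]:
        accs &= set(a.labels)
    if not accs:
        raise HaploPhenoError("assignments cover disjoint accession sets")
    combo: dict[str, tuple[str, ...] | None] = {}
    for acc in accs:
        labs = tuple(a.labels[acc] for a in assignments)
        combo[acc] = None if any(l is None for l in labs) else labs
    counts: dict[tuple[str, ...], int] = {}
    for c in combo.values():
        if c is not None:
            counts[c] = counts.get(c, 0) + 1
    if not counts:
        raise HaploPhenoError("no accession has a complete haplotype combination")
    ordered = sorted(counts, key=lambda c: (-counts[c], c))
    label_of = {c: f"HC{k + 1}" for k, c in enumerate(ordered)}
    labels = {acc: (label_of[c] if c is not None else None) for acc, c in combo.items()}
    alleles = {
        label_of[c]: tuple(
            itertools.chain.from_iterable(a.alleles[lab] for a, lab in zip(assignments, c))
        )
        for c in ordered
    }
    return HaplotypeAssignment(
        gene="+".join(a.gene for a in assignments),
        variant_ids=list(itertools.chain.from_iterable(a.variant_ids for a in assignments)),
        labels=labels,
        alleles=alleles,
        label_prefix="HC",
    )


# ----------------------------------------------------------------------
# Full haplo-pheno analysis for one gene (or gene set)
# ----------------------------------------------------------------------

def analyze_groups(
    assignment: HaplotypeAssignment,
    values: pd.Series,
    trait: str,
    direction: str = "maximize",
    min_count: int = RARE_MIN_COUNT,
    min_percent: float | None = None,
    alpha: float = 0.05,
) -> HaploPhenoResult:
    """Group statistics, R2 and superior label for one assignment.

    ``values`` are per-accession trait values (BLUPs by default in the
    pipeline), indexed by accession id.
    """
    retained = filter_rare_haplotypes(assignment, min_count=min_count, min_percent=min_percent)
    n_panel = assignment.n_accessions
    groups: list[HaploGroup] = []
    arrays: dict[str, np.ndarray] = {}
    for lab in retained:
        members = [a for a in assignment.members(lab) if a in values.index]
        vals = values.loc[members].to_numpy(dtype=float)
        arrays[lab] = vals
        groups.append(
            HaploGroup(
                label=lab,
                members=members,
                count=len(members),
                percent=100.0 * assignment.counts[lab] / n_panel,
                mean=float(vals.mean()) if len(vals) else np.nan,
            )
        )
    means = {g.label: g.mean for g in groups}
    counts = {g.label: g.count for g in groups}
    pairwise_p = None
    letters: dict[str, str] = {}
    if len(groups) == 1:
        r2, overall_p = np.nan, np.nan
    else:
        r2, overall_p = variance_explained(list(arrays.values()))
        if len(groups) == 2:
            labs = list(arrays)
            pairwise_p = two_group_test(arrays[labs[0]], arrays[labs[1]])
        else:
            letters = duncan_letters(arrays, alpha=alpha)
    sup = superior_haplotype(means, counts, direction=direction)
    return HaploPhenoResult(
        trait=trait,
        genes=tuple(assignment.gene.split("+")),
        groups=groups,
        r2=r2,
        overall_p=overall_p,
        superior=sup,
        pairwise_p=pairwise_p,
        letters=letters,
    )


def results_table(results: list[HaploPhenoResult]) -> pd.DataFrame:
    """Stack per-gene results into a report table (one row per group)."""
    rows: list[dict] = []
    for r in results:
        rows.extend(r.to_rows())
    return pd.DataFrame(rows)
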