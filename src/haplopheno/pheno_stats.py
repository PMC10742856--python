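"""Multi-environment trait statistics.

The design emulated here is a multi-environment trial of fully inbred
accessions: each accession is phenotyped in ``e`` environments (years)
with ``r`` replicates per environment. Variance components come from
the classical two-way ANOVA expected-mean-squares decomposition, and
broad-sense heritability on an entry-mean basis is

    h2 = Vg / (Vg + Vge/e + Ve/(r*e))

With a single pooled value per environment (r = 1) the interaction and
residual variances are confounded; the interaction mean square is then
reported as Ve and Vge is set to 0, which leaves h2 and the BLUP
shrinkage unchanged because only the sum Vge/e + Ve/(re) enters them.

BLUPs use the balanced closed form: environments are treated as fixed
and removed by per-environment centering, and each accession mean is
shrunk toward the grand mean by s = Vg / (Vg + Vge/e + Ve/(re)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import HaploPhenoError

logger = logging.getLogger(__name__)

PHENO_COLUMNS = ["accession", "trait", "environment", "replicate", "value"]


class PhenotypeTable:
    """Long-format accession x trait x environment observations."""

    def __init__(self, records: pd.DataFrame, directions: Mapping[str, str] | None = None):
        missing = set(PHENO_COLUMNS) - set(records.columns)
        if missing:
            raise HaploPhenoError(f"phenotype table lacks columns: {sorted(missing)}")
        records = records.loc[:, PHENO_COLUMNS].copy()
        if records.duplicated(["accession", "trait", "environment", "replicate"]).any():
            raise HaploPhenoError("duplicate (accession, trait, environment, replicate) keys")
        if not np.isfinite(records["value"]).all():
            raise HaploPhenoError("non-finite phenotype values")
        self.records = records
        self.directions = dict(directions or {})
        for trait, d in self.directions.items():
            if d not in {"maximize", "minimize"}:
                raise HaploPhenoError(f"direction for {trait} must be maximize|minimize")

    @property
    def traits(self) -> list[str]:
        return sorted(self.records["trait"].unique())

    @property
    def accessions(self) -> list[str]:
        return sorted(self.records["accession"].unique())

    def trait_records(self, trait: str) -> pd.DataFrame:
        sub = self.records[self.records["trait"] == trait]
        if sub.empty:
            raise HaploPhenoError(f"trait {trait!r} not in phenotype table")
        return sub

    def direction(self, trait: str) -> str:
        return self.directions.get(trait, "maximize")

    # ------------------------------------------------------------------
    def write(self, path: str | Path, directions_path: str | Path | None = None) -> None:
        self.records.to_csv(path, sep="\t", index=False)
        if directions_path is not None:
            pd.DataFrame(
                {"trait": list(self.directions), "direction": list(self.directions.values())}
            ).to_csv(directions_path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path, directions_path: str | Path | None = None) -> "PhenotypeTable":
        records = pd.read_csv(path, sep="\t", dtype={"accession": str, "trait": str})
        directions = None
        if directions_path is not None:
            d = pd.read_csv(directions_path, sep="\t")
            directions = dict(zip(d["trait"], d["direction"]))
        return cls(records, directions)


@dataclass(frozen=True)
class VarianceComponents:
    """EMS variance-component estimates for one trait."""

    Vg: float
    Vge: float
    Ve: float
    e: int
    r: int

    def __post_init__(self) -> None:
        if min(self.Vg, self.Vge, self.Ve) < 0:
            raise ValueError("variance components must be non-negative")


@dataclass
class BlupVector:
    """Per-accession predicted genotypic values for one trait."""

    values: pd.Series  # index: accession
    grand_mean: float
    shrinkage: float

    def deviations(self) -> pd.Series:
        return self.values - self.grand_mean


# ----------------------------------------------------------------------

def _balanced_cells(records: pd.DataFrame, trait: str) -> tuple[pd.DataFrame, int, int]:
    """Cell means and (e, r) after enforcing complete env coverage."""
    envs = sorted(records["environment"].unique())
    e = len(envs)
    if e < 2:
        raise HaploPhenoError(
            f"trait {trait!r}: a single environment cannot separate Vg from Vge; "
            "use per-environment analysis instead"
        )
    cover = records.groupby("accession")["environment"].nunique()
    complete = cover[cover == e].index
    dropped = set(records["accession"]) - set(complete)
    if dropped:
        logger.info(
            "trait %s: excluded %d accession(s) without complete environment coverage",
            trait,
            len(dropped),
        )
    sub = records[records["accession"].isin(complete)]
    reps = sub.groupby(["accession", "environment"])["value"].size()
    r = int(reps.min())
    if reps.nunique() > 1:
        logger.info(
            "trait %s: unequal replicate counts; analysing per-cell means with r=1", trait
        )
        r = 1
    return sub, e, r


def variance_components(pheno: PhenotypeTable, trait: str) -> VarianceComponents:
    """Method-of-moments variance components from the two-way ANOVA.

    With r > 1 replicates: Vg = (MS_G - MS_GE)/(r e), Vge =
    (MS_GE - MS_err)/r, Ve = MS_err. With r = 1 the interaction and
    residual are confounded: Vg = (MS_G - MS_GE)/e, Ve = MS_GE, Vge = 0.
    Negative moment estimates are truncated at zero (logged).
    """
    records = pheno.trait_records(trait)
    sub, e, r = _balanced_cells(records, trait)
    cell = sub.groupby(["accession", "environment"])["value"].mean().unstack()
    g = cell.shape[0]
    if g < 2:
        raise HaploPhenoError(f"trait {trait!r}: need >= 2 accessions with full coverage")
    grand = float(cell.to_numpy().mean())
    acc_means = cell.mean(axis=1).to_numpy()
    env_means = cell.mean(axis=0).to_numpy()
    ss_g = r * e * float(((acc_means - grand) ** 2).sum())
    resid = cell.to_numpy() - acc_means[:, None] - env_means[None, :] + grand
    ss_ge = r * float((resid**2).sum())
    ms_g = ss_g / (g - 1)
    ms_ge = ss_ge / ((g - 1) * (e - 1))
    if r > 1:
        within = sub.groupby(["accession", "environment"])["value"].transform("mean")
        ss_err = float(((sub["value"] - within) ** 2).sum())
        ms_err = ss_err / (g * e * (r - 1))
        vg = (ms_g - ms_ge) / (r * e)
        vge = (ms_ge - ms_err) / r
        ve = ms_err
    else:
        vg = (ms_g - ms_ge) / e
        vge = 0.0
        ve = ms_ge
        logger.info("trait %s: r=1, Vge confounded with Ve (reported as Ve)", trait)
    clipped = {k: v for k, v in {"Vg": vg, "Vge": vge, "Ve": ve}.items() if v < 0}
    if clipped:
        logger.info("trait %s: truncated negative estimates to 0: %s", trait, clipped)
    return VarianceComponents(Vg=max(vg, 0.0), Vge=max(vge, 0.0), Ve=max(ve, 0.0), e=e, r=r)


def heritability(vc: VarianceComponents) -> float:
    """Broad-sense heritability h2 = Vg / (Vg + Vge/e + Ve/(r e))."""
    denom = vc.Vg + vc.Vge / vc.e + vc.Ve / (vc.r * vc.e)
    if denom == 0:
        raise HaploPhenoError("all variance components are zero; h2 undefined")
    return vc.Vg / denom


def blup(pheno: PhenotypeTable, trait: str, vc: VarianceComponents) -> BlupVector:
    """Balanced closed-form BLUP: shrink env-adjusted accession means.

    BLUP_i = mu + s (ybar_i - mu), with shrinkage s equal to the
    entry-mean heritability. Environments are removed as fixed effects
    by centering each environment at the grand mean.
    """
    records = pheno.trait_records(trait)
    sub, e, _ = _balanced_cells(records, trait)
    cell = sub.groupby(["accession", "environment"])["value"].mean().unstack()
    grand = float(cell.to_numpy().mean())
    centered = cell - cell.mean(axis=0) + grand
    acc_means = centered.mean(axis=1)
    denom = vc.Vg + vc.Vge / vc.e + vc.Ve / (vc.r * vc.e)
    if denom == 0:
        raise HaploPhenoError("all variance components are zero")
    s = vc.Vg / denom
    if vc.Vg == 0:
        logger.warning("trait %s: Vg = 0, all BLUPs collapse to the grand mean", trait)
    values = grand + s * (acc_means - grand)
    values.name = trait
    return BlupVector(values=values, grand_mean=grand, shrinkage=s)


def trait_correlations(
    blups: Mapping[str, BlupVector | pd.Series],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-sided p between per-accession BLUPs."""
    series = {
        t: (b.values if isinstance(b, BlupVector) else b) for t, b in blups.items()
    }
    traits = list(series)
    common = series[traits[0]].index
    for t in traits[1:]:
        common = common.intersection(series[t].index)
    if len(common) < 3:
        raise HaploPhenoError("need >= 3 common accessions for correlations")
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j in range(i + 1, len(traits)):
            b = traits[j]
            x, y = series[a].loc[common], series[b].loc[common]
            if x.std() == 0 or y.std() == 0:
                raise HaploPhenoError(f"zero-variance trait in correlation: {a} vs {b}")
            rr, pp = stats.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return r, p


def significance_stars(p: float) -> str:
    """Figure-style annotation: ** for p<0.01, *** for p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    return ""


def heritability_report(pheno: PhenotypeTable) -> pd.DataFrame:
    """Per-trait Vg, Vge, Ve and h2 as a tidy table."""
    rows = []
    for trait in pheno.traits:
        vc = variance_components(pheno, trait)
        rows.append(
            {
                "trait": trait,
                "Vg": vc.Vg,
                "Vge": vc.Vge,
                "Ve": vc.Ve,
                "e": vc.e,
                "r": vc.r,
                "h2": heritability(vc),
            }
        )
    return pd.DataFrame(rows)
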