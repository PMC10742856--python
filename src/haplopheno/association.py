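"""Per-variant mixed-model association scan with kinship correction.

The model for each variant is the standard single-marker LMM

    y = W a + x b + u + eps,   u ~ N(0, lambda * tau^-1 * K),
                               eps ~ N(0, tau^-1 * I)

with W an intercept (plus optional covariates), x the variant dosage
and K the centered relatedness matrix. K is eigendecomposed once; per
variant the REML log-likelihood is maximized over the variance ratio
lambda by a log-grid bracket followed by Brent refinement, beta is the
GLS estimate at lambda-hat, and the two-sided Wald p comes from the t
distribution with n - c degrees of freedom (c = number of fixed
effects, 2 by default) — the small-sample calibration that reduces
exactly to the OLS t-test when K is the identity.

A variant is "associated" with a trait when its p-value is below alpha
in every dataset scanned (each environment and the BLUP values) — the
cross-environment consistency rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datatypes import GenotypeMatrix, HaploPhenoError
from .population import KinshipMatrix, impute_missing
from .variant_io import annotate_region, assign_gene

logger = logging.getLogger(__name__)

LAMBDA_MIN = 1e-5
LAMBDA_MAX = 1e5
#: points per decade of the bracketing log-grid
GRID_PER_DECADE = 6

DATASETS = ("env1", "env2", "BLUP")


@dataclass
class LmmFit:
    """Single-variant fit: effect, Wald test and variance ratio."""

    variant_id: str
    beta: float = np.nan
    se: float = np.nan
    wald: float = np.nan
    p: float = np.nan
    lam: float = np.nan
    loglik: float = np.nan
    skipped: str | None = None


def reml_loglik(lam: float, d: np.ndarray, Uty: np.ndarray, UtX: np.ndarray) -> float:
    """REML log-likelihood of the variance ratio ``lam``.

    ``d`` are the kinship eigenvalues and ``Uty``/``UtX`` the response
    and design rotated into the eigenbasis.
    """
    n, c = UtX.shape
    v = lam * d + 1.0
    w = 1.0 / v
    wX = UtX * w[:, None]
    XtHX = UtX.T @ wX
    XtHy = wX.T @ Uty
    ytHy = float(w @ (Uty * Uty))
    try:
        beta = np.linalg.solve(XtHX, XtHy)
    except np.linalg.LinAlgError:
        return -np.inf
    ytPy = ytHy - float(XtHy @ beta)
    if ytPy <= 0:
        return -np.inf
    sign, logdet_XtHX = np.linalg.slogdet(XtHX)
    if sign <= 0:
        return -np.inf
    _, logdet_XtX = np.linalg.slogdet(UtX.T @ UtX)
    df = n - c
    return 0.5 * (
        df * np.log(df / (2.0 * np.pi))
        - df
        - float(np.log(v).sum())
        - logdet_XtHX
        + logdet_XtX
        - df * np.log(ytPy)
    )


def optimize_lambda(
    d: np.ndarray, Uty: np.ndarray, UtX: np.ndarray
) -> tuple[float, float]:
    """Maximize the REML log-likelihood over lambda in [1e-5, 1e5].

    Coarse log10 grid to bracket the optimum, then Brent refinement
    between the bracketing neighbours. Returns (lambda_hat, loglik).
    """
    n_pts = int(np.log10(LAMBDA_MAX / LAMBDA_MIN)) * GRID_PER_DECADE + 1
    grid = np.logspace(np.log10(LAMBDA_MIN), np.log10(LAMBDA_MAX), n_pts)
    vals = np.array([reml_loglik(l, d, Uty, UtX) for l in grid])
    i = int(np.argmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_pts - 1)]
    if lo == hi:
        return float(grid[i]), float(vals[i])
    res = optimize.minimize_scalar(
        lambda x: -reml_loglik(10.0**x, d, Uty, UtX),
        bounds=(np.log10(lo), np.log10(hi)),
        method="bounded",
        options={"xatol": 1e-7},
    )
    lam = float(10.0**res.x)
    ll = float(-res.fun)
    if vals[i] > ll:  # refinement never worsens the grid optimum
        return float(grid[i]), float(vals[i])
    return lam, ll


def _wald(lam: float, d: np.ndarray, Uty: np.ndarray, UtX: np.ndarray) -> tuple[float, float, float, float]:
    """GLS beta, se, t and two-sided p for the last design column."""
    n, c = UtX.shape
    w = 1.0 / (lam * d + 1.0)
    wX = UtX * w[:, None]
    XtHX = UtX.T @ wX
    XtHy = wX.T @ Uty
    XtHX_inv = np.linalg.inv(XtHX)
    beta = XtHX_inv @ XtHy
    ytPy = float(w @ (Uty * Uty)) - float(XtHy @ beta)
    df = n - c
    tau_inv = ytPy / df
    se = float(np.sqrt(max(tau_inv * XtHX_inv[-1, -1], 0.0)))
    b = float(beta[-1])
    if se == 0:
        return b, se, np.inf, 0.0
    t = b / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return b, se, t, float(p)


def lmm_scan(
    y: np.ndarray | pd.Series,
    matrix: GenotypeMatrix,
    kinship: KinshipMatrix,
    maf_min: float = 0.01,
    covariates: np.ndarray | None = None,
    per_variant_lambda: bool = True,
) -> list[LmmFit]:
    """Scan every variant for association with ``y``.

    ``y`` must be aligned to the matrix accessions (a Series is
    reindexed by accession id). Monomorphic variants and variants with
    MAF below ``maf_min`` are skipped with a reason. When
    ``per_variant_lambda`` is False, lambda is estimated once under the
    null (covariates-only) model and reused — the fast approximation.
    """
    if isinstance(y, pd.Series):
        y = y.reindex(matrix.accessions).to_numpy()
    y = np.asarray(y, dtype=float)
    n = matrix.n_accessions
    if y.shape != (n,):
        raise HaploPhenoError(f"phenotype length {y.shape} != {n} accessions")
    if not np.isfinite(y).all():
        raise HaploPhenoError("non-finite phenotype values in scan")
    if kinship.accessions != matrix.accessions:
        raise HaploPhenoError("kinship accession order does not match genotype matrix")

    dvals, U = np.linalg.eigh(kinship.values)
    n_floored = int((dvals < 0).sum())
    if n_floored:
        logger.info("floored %d negative kinship eigenvalues at 0", n_floored)
    dvals = np.maximum(dvals, 0.0)
    Uty = U.T @ y
    ones = np.ones((n, 1))
    W = ones if covariates is None else np.column_stack([ones, covariates])
    UtW = U.T @ W

    X = impute_missing(matrix.dosage)
    maf = matrix.minor_allele_frequency()

    lam_null = None
    if not per_variant_lambda:
        lam_null, _ = optimize_lambda(dvals, Uty, UtW)

    fits: list[LmmFit] = []
    for j, v in enumerate(matrix.variants):
        if np.isnan(maf[j]) or maf[j] == 0:
            fits.append(LmmFit(variant_id=v.id, skipped="monomorphic"))
            continue
        if maf[j] < maf_min:
            fits.append(LmmFit(variant_id=v.id, skipped=f"MAF {maf[j]:.4f} < {maf_min}"))
            continue
        UtX = np.column_stack([UtW, U.T @ X[:, j]])
        if per_variant_lambda:
            lam, ll = optimize_lambda(dvals, Uty, UtX)
        else:
            lam, ll = lam_null, reml_loglik(lam_null, dvals, Uty, UtX)
        b, se, t, p = _wald(lam, dvals, Uty, UtX)
        fits.append(
            LmmFit(variant_id=v.id, beta=b, se=se, wald=t, p=p, lam=lam, loglik=ll)
        )
    return fits


def scan_frame(fits: list[LmmFit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant": [f.variant_id for f in fits],
            "beta": [f.beta for f in fits],
            "se": [f.se for f in fits],
            "wald": [f.wald for f in fits],
            "p": [f.p for f in fits],
            "lambda": [f.lam for f in fits],
            "skipped": [f.skipped for f in fits],
        }
    )


def consistent_associations(
    frames: dict[str, pd.DataFrame], alpha: float = 0.01
) -> pd.DataFrame:
    """Variants with p < alpha in every dataset (the consistency rule).

    ``frames`` maps dataset name (e.g. env1/env2/BLUP) to a scan frame.
    Returns one row per variant with per-dataset p-values and a
    ``consistent`` flag; raises if the datasets cover different
    variants.
    """
    if len(frames) < 2:
        raise HaploPhenoError("need at least two datasets for the consistency rule")
    names = list(frames)
    base = list(frames[names[0]]["variant"])
    for name in names[1:]:
        if list(frames[name]["variant"]) != base:
            raise HaploPhenoError(f"dataset {name!r} covers different variants")
    out = pd.DataFrame({"variant": base})
    for name in names:
        out[f"p_{name}"] = frames[name]["p"].to_numpy()
        out[f"beta_{name}"] = frames[name]["beta"].to_numpy()
    pmat = out[[f"p_{n}" for n in names]].to_numpy()
    with np.errstate(invalid="ignore"):
        out["consistent"] = np.all(pmat < alpha, axis=1) & ~np.isnan(pmat).any(axis=1)
    return out


def annotate_associations(
    consistent: pd.DataFrame, matrix: GenotypeMatrix, genes
) -> pd.DataFrame:
    """Attach gene id, region label and variant class to a scan summary."""
    by_id = {v.id: v for v in matrix.variants}
    gene_ids, regions, vclass = [], [], []
    for vid in consistent["variant"]:
        v = by_id[vid]
        g = assign_gene(v, genes)
        gene_ids.append(g.gene_id if g else "intergenic")
        regions.append(annotate_region(v, g) if g else "intergenic")
        vclass.append("SNP" if v.is_snp else "Indel")
    out = consistent.copy()
    out["gene"] = gene_ids
    out["region"] = regions
    out["class"] = vclass
    return out


def associated_by_gene(annotated: pd.DataFrame) -> dict[str, list[str]]:
    """Consistent variants grouped per gene, in genomic order."""
    sub = annotated[annotated["consistent"]]
    groups: dict[str, list[str]] = {}
    for _, row in sub.iterrows():
        if row["gene"] != "intergenic":
            groups.setdefault(row["gene"], []).append(row["variant"])
    return groups


def gene_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    """Per-gene counts of associated SNPs/indels by region."""
    sub = annotated[annotated["consistent"]]
    if sub.empty:
        return pd.DataFrame(columns=["gene", "region", "class", "n"])
    return (
        sub.groupby(["gene", "region", "class"])
        .size()
        .rename("n")
        .reset_index()
        .sort_values(["gene", "region", "class"])
        .reset_index(drop=True)
    )
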