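"""Kinship construction and LD pruning.

The relatedness matrix is the centered form used by mixed-model
association tools: K = W W' / p over column-centered dosages, p being
the number of variants. LD pruning follows the sliding-window scheme
`--indep-pairwise 100 50 0.2`: windows of 100 variants advanced by 50,
greedily removing one variant of every pair whose dosage r-squared
exceeds 0.2 (the variant with the smaller minor-allele frequency;
ties remove the later position).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, HaploPhenoError

logger = logging.getLogger(__name__)


@dataclass
class KinshipMatrix:
    """Symmetric relatedness matrix with its accession order."""

    values: np.ndarray
    accessions: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.accessions)
        if v.shape != (n, n):
            raise ValueError(f"kinship shape {v.shape} != ({n},{n})")
        if not np.isfinite(v).all():
            raise ValueError("non-finite kinship entries")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("kinship matrix not symmetric")
        self.values = (v + v.T) / 2.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accessions, columns=self.accessions)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read(cls, path) -> "KinshipMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df.to_numpy(), [str(a) for a in df.columns])


def impute_missing(dosage: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-variant mean (logged)."""
    out = dosage.astype(float, copy=True)
    n_missing = int(np.isnan(out).sum())
    if n_missing:
        col_mean = np.nanmean(out, axis=0)
        idx = np.where(np.isnan(out))
        out[idx] = col_mean[idx[1]]
        logger.info("mean-imputed %d missing dosage entries", n_missing)
    return out


def centered_kinship(matrix: GenotypeMatrix) -> KinshipMatrix:
    """Centered relatedness K = W W' / p from column-centered dosages."""
    if matrix.n_variants < 2:
        raise HaploPhenoError("need >= 2 variants to build a kinship matrix")
    X = impute_missing(matrix.dosage)
    W = X - X.mean(axis=0, keepdims=True)
    if not np.any(W != 0):
        raise HaploPhenoError("all variants monomorphic; kinship undefined")
    K = W @ W.T / matrix.n_variants
    return KinshipMatrix(values=K, accessions=list(matrix.accessions))


# ----------------------------------------------------------------------
# LD pruning
# ----------------------------------------------------------------------

def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (complete pairs)."""
    ok = ~np.isnan(x) & ~np.isnan(y)
    if ok.sum() < 2:
        return 0.0
    xv, yv = x[ok], y[ok]
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = float(np.corrcoef(xv, yv)[0, 1])
    return r * r


def ld_prune(
    matrix: GenotypeMatrix,
    window: int = 100,
    step: int = 50,
    r2_max: float = 0.2,
) -> list[str]:
    """Greedy sliding-window LD pruning; returns retained variant ids.

    Windows are counted in variants (the unitless form of the
    parameters). Within each window, while any retained pair exceeds
    ``r2_max``, the member with the smaller minor-allele frequency is
    removed (ties: later genomic position). Pruning is per chromosome.
    """
    if window < 1 or step < 1:
        raise HaploPhenoError("window and step must be positive")
    maf = matrix.minor_allele_frequency()
    removed: set[int] = set()
    chroms: dict[str, list[int]] = {}
    for i, v in enumerate(matrix.variants):
        chroms.setdefault(v.chrom, []).append(i)
    for chrom_idx in chroms.values():
        start = 0
        while start < len(chrom_idx):
            win = [i for i in chrom_idx[start : start + window] if i not in removed]
            changed = True
            while changed:
                changed = False
                for a_pos in range(len(win)):
                    i = win[a_pos]
                    if i in removed:
                        continue
                    for b_pos in range(a_pos + 1, len(win)):
                        j = win[b_pos]
                        if j in removed:
                            continue
                        r2 = _pairwise_r2(matrix.dosage[:, i], matrix.dosage[:, j])
                        if r2 > r2_max:
                            if maf[i] < maf[j]:
                                drop = i
                            elif maf[j] < maf[i]:
                                drop = j
                            else:  # tie: later position
                                drop = max(i, j)
                            removed.add(drop)
                            changed = True
                            break
                    if changed:
                        break
                if changed:
                    win = [i for i in win if i not in removed]
            if start + window >= len(chrom_idx):
                break
            start += step
    retained = [v.id for i, v in enumerate(matrix.variants) if i not in removed]
    logger.info("ld_prune: retained %d/%d variants", len(retained), matrix.n_variants)
    return retained


def prune_report(matrix: GenotypeMatrix, retained: list[str]) -> pd.DataFrame:
    kept = set(retained)
    return pd.DataFrame(
        {
            "variant": matrix.variant_ids,
            "retained": [v in kept for v in matrix.variant_ids],
        }
    )
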