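"""Between-sample normalization: TMM scaling factors, FPKM, log-CPM and
per-gene median centering.

The TMM implementation follows the published defaults of the trimmed mean of
M-values method: reference column chosen by upper-quartile proximity to the
mean upper-quartile, double trimming of M (30% per tail) and A (5% per tail),
inverse asymptotic-variance weights, and a final rescaling of all factors to
geometric mean 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError, ValidationError

__all__ = [
    "ExpressionStudy",
    "NormalizedExpression",
    "tmm_factors",
    "fpkm",
    "log_cpm",
    "median_center",
    "normalize_study",
]


@dataclass
class ExpressionStudy:
    """Raw input of the pipeline: a count matrix plus its metadata.

    Attributes
    ----------
    counts : DataFrame
        Non-negative integer matrix, genes x samples.
    gene_length : Series
        Length in bp per gene, indexed like ``counts``.
    design : DataFrame
        One row per sample with columns ``organ`` and ``replicate``.
    """

    counts: pd.DataFrame
    gene_length: pd.Series
    design: pd.DataFrame

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            bad = np.argwhere(self.counts.values < 0)[0]
            raise ValidationError(
                f"negative count at gene {self.counts.index[bad[0]]!r}, "
                f"sample {self.counts.columns[bad[1]]!r}"
            )
        missing = [s for s in self.counts.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")
        if not self.gene_length.index.equals(self.counts.index):
            reidx = self.gene_length.reindex(self.counts.index)
            if reidx.isna().any():
                absent = list(reidx.index[reidx.isna()][:5])
                raise ValidationError(f"genes missing a length: {absent}")
            self.gene_length = reidx
        if (self.gene_length <= 0).any():
            bad = list(self.gene_length.index[self.gene_length <= 0][:5])
            raise ValidationError(f"non-positive gene length for: {bad}")

    @property
    def organ_labels(self) -> pd.Series:
        return self.design.loc[self.counts.columns, "organ"]


@dataclass
class NormalizedExpression:
    tmm_factor: pd.Series
    effective_libsize: pd.Series
    fpkm: pd.DataFrame
    log_cpm: pd.DataFrame
    centered: pd.DataFrame


def _upper_quartile(col: np.ndarray, libsize: float) -> float:
    """75th percentile of count/libsize over the column's nonzero genes."""
    nz = col[col > 0]
    if nz.size == 0:
        raise DegenerateInputError("sample has all-zero counts")
    return float(np.quantile(nz / libsize, 0.75))


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.30,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factor per sample.

    Returns factors rescaled so their geometric mean is exactly 1.
    """
    if counts.shape[1] < 2:
        raise DegenerateInputError("TMM requires at least 2 samples")
    mat = counts.to_numpy(dtype=float)
    libsize = mat.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(counts.columns[libsize <= 0])
        raise DegenerateInputError(f"sample(s) with all-zero counts: {bad}")

    uq = np.array([_upper_quartile(mat[:, j], libsize[j]) for j in range(mat.shape[1])])
    ref_j = int(np.argmin(np.abs(uq - uq.mean())))
    ref = mat[:, ref_j]
    n_ref = libsize[ref_j]

    factors = np.ones(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref_j:
            factors[j] = 1.0
            continue
        obs = mat[:, j]
        n_obs = libsize[j]
        keep = (obs > 0) & (ref > 0)
        if not keep.any():
            factors[j] = 1.0
            continue
        y, y_r = obs[keep], ref[keep]
        m = np.log2((y / n_obs) / (y_r / n_ref))
        a = 0.5 * np.log2((y / n_obs) * (y_r / n_ref))
        w = (n_obs - y) / (n_obs * y) + (n_ref - y_r) / (n_ref * y_r)

        n = m.size
        lo_l = np.floor(n * logratio_trim) + 1
        hi_l = n - np.floor(n * logratio_trim)
        lo_s = np.floor(n * sum_trim) + 1
        hi_s = n - np.floor(n * sum_trim)
        rm = rankdata(m)
        ra = rankdata(a)
        trimmed = (rm >= lo_l) & (rm <= hi_l) & (ra >= lo_s) & (ra <= hi_s)
        if not trimmed.any() or w[trimmed].sum() == 0:
            factors[j] = 1.0
            continue
        inv_w = 1.0 / w[trimmed]
        f = np.sum(inv_w * m[trimmed]) / np.sum(inv_w)
        factors[j] = 2.0 ** f if np.isfinite(f) else 1.0

    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def fpkm(
    counts: pd.DataFrame,
    gene_length: pd.Series,
    effective_libsize: pd.Series,
) -> pd.DataFrame:
    """Fragments per kilobase of feature per million mapped fragments:
    ``1e9 * count / (effective_libsize * length)``."""
    lengths = gene_length.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        bad = list(lengths.index[(lengths.isna()) | (lengths <= 0)][:5])
        raise ValidationError(f"missing or non-positive length for gene(s): {bad}")
    libs = effective_libsize.reindex(counts.columns)
    if (libs <= 0).any():
        bad = list(libs.index[libs <= 0])
        raise ValidationError(f"non-positive effective library size: {bad}")
    out = 1e9 * counts.to_numpy(dtype=float)
    out /= libs.to_numpy()[None, :]
    out /= lengths.to_numpy()[:, None]
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def log_cpm(
    counts: pd.DataFrame,
    effective_libsize: pd.Series,
    prior: float = 0.5,
) -> pd.DataFrame:
    """log2 counts per million with a prior count:
    ``log2((count + prior) / (libsize + 2*prior) * 1e6)``."""
    if prior <= 0:
        raise ValidationError(f"prior must be > 0, got {prior}")
    libs = effective_libsize.reindex(counts.columns).to_numpy()
    out = np.log2(
        (counts.to_numpy(dtype=float) + prior) / (libs[None, :] + 2 * prior) * 1e6
    )
    return pd.DataFrame(out, index=counts.index, columns=counts.columns)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract the row median from every row."""
    if matrix.shape[1] < 1:
        raise ValidationError("median_center requires at least one column")
    med = np.median(matrix.to_numpy(dtype=float), axis=1, keepdims=True)
    return pd.DataFrame(
        matrix.to_numpy(dtype=float) - med, index=matrix.index, columns=matrix.columns
    )


def normalize_study(study: ExpressionStudy, prior: float = 0.5) -> NormalizedExpression:
    """Run the full normalization stage.

    FPKM uses TMM-adjusted library sizes; ``centered`` is the per-gene
    median-centered log2(FPKM + 1) matrix used for cluster profiles.
    """
    study.validate()
    factor = tmm_factors(study.counts)
    raw_lib = study.counts.sum(axis=0).astype(float)
    eff_lib = (raw_lib * factor).rename("effective_libsize")
    fpkm_mat = fpkm(study.counts, study.gene_length, eff_lib)
    lcpm = log_cpm(study.counts, eff_lib, prior=prior)
    centered = median_center(np.log2(fpkm_mat + 1.0))
    return NormalizedExpression(
        tmm_factor=factor,
        effective_libsize=eff_lib,
        fpkm=fpkm_mat,
        log_cpm=lcpm,
        centered=centered,
    )
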