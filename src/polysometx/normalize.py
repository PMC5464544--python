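"""Between-sample normalization and the expression filter.

Implements trimmed-mean-of-M-values (TMM) scaling factors, counts per
million on TMM-effective library sizes, and the expression filter used to
call a gene "sufficiently expressed" (CPM strictly greater than a threshold
in at least a given fraction of libraries).

TMM assumes most genes are not differentially expressed between samples.
For sample k against reference r, each co-expressed gene contributes a
log2 fold change M_g and mean abundance A_g:

    M_g = log2((y_gk / N_k) / (y_gr / N_r))
    A_g = 0.5 * log2((y_gk / N_k) * (y_gr / N_r))

Genes in the extreme tails of M (30% each side) and A (5% each side) are
trimmed; the remaining M values are averaged with weights 1/v_g, the
inverse of the delta-method (binomial) variance

    v_g = (N_k - y_gk) / (N_k * y_gk) + (N_r - y_gr) / (N_r * y_gr)

and the factor is 2**(weighted mean). Factors are rescaled to geometric
mean 1 so the effective library sizes N_k * f_k stay on the raw-depth
scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .io import CountMatrix, ValidationError

__all__ = ["NormFactors", "CPMMatrix", "tmm_factors", "cpm", "filter_expressed"]


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors and effective library sizes."""

    factors: pd.Series
    effective_lib_sizes: pd.Series
    ref_sample: str

    def __post_init__(self):
        if (self.factors <= 0).any():
            raise ValidationError("TMM factors must be positive")
        gm = float(np.exp(np.mean(np.log(self.factors))))
        if abs(gm - 1.0) > 1e-8:
            raise ValidationError(f"TMM factors have geometric mean {gm}, expected 1")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tmm_factor": self.factors,
                "effective_lib_size": self.effective_lib_sizes,
            }
        )


@dataclass
class CPMMatrix:
    """Counts-per-million matrix; ``log`` flags log2(CPM + 0.5) scale."""

    values: pd.DataFrame
    log: bool = False

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    f75 = np.array(
        [np.quantile(counts[:, j] / lib_sizes[j], 0.75) for j in range(counts.shape[1])]
    )
    return int(np.argmin(np.abs(f75 - f75.mean())))


def _pair_factor(
    y_k: np.ndarray,
    y_r: np.ndarray,
    n_k: float,
    n_r: float,
    trim_m: float,
    trim_a: float,
) -> float:
    """Unscaled TMM factor of sample k against reference r (log2 space -> 2**f)."""
    ok = (y_k > 0) & (y_r > 0)
    if not np.any(ok):
        raise ValidationError("sample shares no co-expressed genes with the reference")
    pk = y_k[ok] / n_k
    pr = y_r[ok] / n_r
    m = np.log2(pk / pr)
    a = 0.5 * np.log2(pk * pr)
    # delta-method variance of M; weights below are its inverse
    v = (n_k - y_k[ok]) / (n_k * y_k[ok]) + (n_r - y_r[ok]) / (n_r * y_r[ok])

    n = m.size
    lo_m = math.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = math.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rm = rankdata(m)
    ra = rankdata(a)
    keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not np.any(keep) or np.sum(1.0 / v[keep]) == 0:
        return 1.0
    f = float(np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    if not np.isfinite(f) or abs(f) < 1e-10:
        return 1.0
    return 2.0**f


def tmm_factors(
    cm: CountMatrix,
    ref_sample: str | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> NormFactors:
    """TMM scaling factors for every sample of a count matrix.

    ``trim_m``/``trim_a`` are the per-tail trim fractions on the M and A
    statistics. The reference defaults to the sample whose 75th-percentile
    count fraction is closest to the across-sample mean. Factors are
    rescaled to geometric mean 1.
    """
    counts = cm.values.astype(float)
    if cm.n_samples < 2:
        raise ValidationError("TMM requires at least 2 samples")
    lib = counts.sum(axis=0)
    if np.any(lib == 0):
        empty = cm.sample_ids[lib == 0].tolist()
        raise ValidationError(f"samples with zero total counts: {empty}")
    if ref_sample is None:
        ref = _choose_reference(counts, lib)
    else:
        if ref_sample not in cm.sample_ids:
            raise ValidationError(f"reference sample {ref_sample!r} not in matrix")
        ref = int(cm.sample_ids.get_loc(ref_sample))

    raw = np.array(
        [
            _pair_factor(counts[:, j], counts[:, ref], lib[j], lib[ref], trim_m, trim_a)
            for j in range(cm.n_samples)
        ]
    )
    factors = raw / np.exp(np.mean(np.log(raw)))
    fs = pd.Series(factors, index=cm.sample_ids, name="tmm_factor")
    eff = fs * cm.lib_sizes.astype(float)
    eff.name = "effective_lib_size"
    return NormFactors(factors=fs, effective_lib_sizes=eff, ref_sample=str(cm.sample_ids[ref]))


def cpm(cm: CountMatrix, nf: NormFactors | None = None, log: bool = False) -> CPMMatrix:
    """Counts per million on effective (TMM-scaled) library sizes.

    With ``nf=None`` raw library sizes are used (factors of 1). ``log``
    returns log2(CPM + 0.5).
    """
    if nf is None:
        eff = cm.lib_sizes.astype(float)
    else:
        missing = [s for s in cm.sample_ids if s not in nf.effective_lib_sizes.index]
        if missing:
            raise ValidationError(f"normalization factors missing for samples: {missing}")
        eff = nf.effective_lib_sizes.loc[cm.sample_ids].astype(float)
    if (eff <= 0).any():
        raise ValidationError("effective library sizes must be positive")
    vals = cm.frame.astype(float).div(eff, axis=1) * 1e6
    if log:
        vals = np.log2(vals + 0.5)
    return CPMMatrix(values=vals, log=log)


def filter_expressed(
    cpm_mat: CPMMatrix, min_cpm: float = 2.0, min_sample_frac: float = 0.5
) -> pd.Series:
    """Expression mask: CPM strictly > ``min_cpm`` in at least
    ``ceil(min_sample_frac * n_samples)`` libraries.

    The threshold is strict, so a gene sitting exactly at ``min_cpm``
    everywhere fails. All libraries (both fractions, all cell lines) count
    toward the denominator.
    """
    if cpm_mat.log:
        raise ValidationError("filter_expressed requires linear-scale CPM")
    n = cpm_mat.values.shape[1]
    need = math.ceil(min_sample_frac * n)
    mask = (cpm_mat.values > min_cpm).sum(axis=1) >= need
    mask.name = "expressed"
    return mask
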