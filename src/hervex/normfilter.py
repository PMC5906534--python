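"""cpm conversion, low-expression filtering, and TMM normalization factors.

Order of operations follows the standard count-pipeline convention: raw counts
-> cpm -> keep elements with >= 1 cpm in at least half the samples -> trimmed
mean of M-values (TMM) factors on the retained counts.

TMM follows the Robinson–Oshlack definition: for sample k against a reference
r, over elements positive in both, M = log2((y_gk/N_k)/(y_gr/N_r)) and
A = 0.5*log2((y_gk/N_k)(y_gr/N_r)); the top and bottom 30% by M and 5% by A
are trimmed; the factor is 2 to the precision-weighted mean of the surviving
M values, with weights the inverse binomial delta-method variances; factors
are rescaled so their geometric mean is 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizedMatrix",
    "compute_cpm",
    "filter_low_expression",
    "tmm_factors",
    "normalize",
]


def compute_cpm(
    counts: pd.DataFrame, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """counts per million of library size: cpm[g,i] = counts[g,i]/N_i * 1e6.

    The default denominator is the column sum (total assigned reads); an
    external per-sample denominator (e.g. genome-mapped totals) may be passed
    instead.
    """
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    zero = library_sizes[library_sizes <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return counts.div(library_sizes, axis=1) * 1e6


def filter_low_expression(
    cpm: pd.DataFrame, min_cpm: float = 1.0, min_fraction: float = 0.5
) -> pd.Index:
    """Ids of elements with >= min_cpm in at least ceil(min_fraction * n) samples."""
    if min_cpm <= 0 or min_fraction <= 0:
        raise ValueError("thresholds must be positive")
    need = int(np.ceil(min_fraction * cpm.shape[1]))
    keep = (cpm >= min_cpm).sum(axis=1) >= need
    return cpm.index[keep]


def _choose_reference(counts: pd.DataFrame, library_sizes: pd.Series) -> str:
    """Sample whose upper-quartile count fraction is closest to the mean."""
    uq = counts.div(library_sizes, axis=1).quantile(0.75, axis=0)
    return (uq - uq.mean()).abs().idxmin()


def _tmm_pair(
    yk: np.ndarray,
    yr: np.ndarray,
    nk: float,
    nr: float,
    logratio_trim: float,
    abs_trim: float,
    min_kept: int,
) -> float:
    """log2 TMM factor of sample k against reference r."""
    pos = (yk > 0) & (yr > 0)
    yk, yr = yk[pos].astype(float), yr[pos].astype(float)
    if yk.size == 0:
        return 0.0
    m = np.log2((yk / nk) / (yr / nr))
    a = 0.5 * np.log2((yk / nk) * (yr / nr))
    w = 1.0 / ((nk - yk) / (nk * yk) + (nr - yr) / (nr * yr))
    n = m.size
    # doubly trimmed: keep elements whose 1-based rank survives both trims
    rank_m = m.argsort().argsort() + 1
    rank_a = a.argsort().argsort() + 1
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n + 1 - lo_a
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if keep.sum() < min_kept:
        warnings.warn(
            f"only {int(keep.sum())} elements survive TMM trimming "
            f"(< {min_kept}); falling back to factor 1",
            stacklevel=3,
        )
        return 0.0
    return float(np.sum(w[keep] * m[keep]) / np.sum(w[keep]))


def tmm_factors(
    counts: pd.DataFrame,
    reference_sample: str | None = None,
    logratio_trim: float = 0.3,
    abs_trim: float = 0.05,
    min_kept: int = 10,
) -> pd.Series:
    """Per-sample TMM normalization factors (geometric mean 1).

    The reference defaults to the sample whose upper-quartile count fraction
    is closest to the across-sample mean.  Effective library size is
    ``library size x factor``.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    if (counts.sum(axis=0) <= 0).any():
        raise ValueError("every sample needs at least one positive count")
    lib = counts.sum(axis=0).astype(float)
    ref = reference_sample if reference_sample is not None else _choose_reference(counts, lib)
    yr = counts[ref].to_numpy()
    log2f = {}
    for s in counts.columns:
        if s == ref:
            log2f[s] = 0.0
        else:
            log2f[s] = _tmm_pair(
                counts[s].to_numpy(), yr, lib[s], lib[ref], logratio_trim, abs_trim, min_kept
            )
    f = pd.Series({s: 2.0 ** v for s, v in log2f.items()})[counts.columns]
    f /= np.exp(np.log(f).mean())  # geometric mean 1
    f.name = "tmm_factor"
    return f


@dataclass
class NormalizedMatrix:
    """Filtered counts plus the quantities downstream models consume."""

    counts: pd.DataFrame  # retained elements x samples (raw integers)
    cpm: pd.DataFrame  # pre-filter cpm of the retained elements
    retained: pd.Index
    library_sizes: pd.Series
    tmm: pd.Series

    @property
    def effective_library_sizes(self) -> pd.Series:
        return self.library_sizes * self.tmm

    @property
    def offsets(self) -> np.ndarray:
        """Natural-log effective library sizes (NB-GLM offsets)."""
        return np.log(self.effective_library_sizes.to_numpy())


def normalize(
    counts: pd.DataFrame,
    library_sizes: pd.Series | None = None,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
) -> NormalizedMatrix:
    """cpm -> low-expression filter -> TMM on the retained counts."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0).astype(float)
    cpm = compute_cpm(counts, library_sizes)
    retained = filter_low_expression(cpm, min_cpm=min_cpm, min_fraction=min_fraction)
    kept = counts.loc[retained]
    tmm = tmm_factors(kept)
    return NormalizedMatrix(
        counts=kept,
        cpm=cpm.loc[retained],
        retained=retained,
        library_sizes=library_sizes,
        tmm=tmm,
    )
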