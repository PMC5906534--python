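"""Donor-paired negative-binomial GLM differential expression.

Model: counts y_gi ~ NB(mu_gi, phi_g) with log link
``log mu_gi = x_i' beta_g + offset_i`` where the design holds an intercept,
donor indicators (absorbing the paired structure) and a treatment indicator,
and the offset is the natural log of the effective (TMM-scaled) library size.

Dispersions are estimated by Cox–Reid adjusted profile likelihood (APL):
a common value maximizing the summed APL; an abundance-dependent trend from a
binned, moving-average-smoothed APL interpolated at each element's average
abundance; and per-element (tagwise) values from weighted-likelihood empirical
Bayes, maximizing ``APL_g(phi) + prior_n * APL_shared(phi)`` with
``prior_n = prior_df / residual_df``, which shrinks the genewise maxima toward
the trend with strength ``prior_df`` (default 10).

The treatment effect is tested per element with a likelihood-ratio test of
the full against the treatment-free model, referred to chi-square(1);
Benjamini–Hochberg controls the FDR; elements are classed up/down when
FDR < alpha and |log2FC| exceeds the effect-size threshold (default 3, i.e.
eightfold).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2, wilcoxon

__all__ = [
    "DesignMatrix",
    "DispersionModel",
    "build_design",
    "fit_nb_glm",
    "nb_deviance",
    "nb_loglik",
    "adjusted_profile_loglik",
    "estimate_dispersions",
    "lrt",
    "adjust_bh",
    "classify",
    "lfc_to_fold",
    "summarize_families",
    "run_de",
    "wilcoxon_signed_rank",
]

_LN2 = math.log(2.0)
_ETA_CAP = 30.0  # |linear predictor - offset| bound; keeps exp() finite


@dataclass
class DesignMatrix:
    """Design for the paired two-condition comparison.

    Columns: intercept, donor indicators (n_donors - 1), treatment indicator
    (last).  Residual df = n_samples - n_donors - 1; with 4 donors and 8
    samples that is 3.
    """

    matrix: np.ndarray  # samples x p
    columns: list[str]
    samples: list[str]

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    @property
    def residual_df(self) -> int:
        return self.matrix.shape[0] - self.matrix.shape[1]

    @property
    def treatment_index(self) -> int:
        return self.n_params - 1

    def reduced(self) -> np.ndarray:
        """Design without the treatment column (the null model)."""
        return self.matrix[:, :-1]


def build_design(design_table: pd.DataFrame) -> DesignMatrix:
    """Build the paired design from a sample table (donor, condition columns).

    A sample is treated when its condition label differs from ``untreated``
    or its ``dose_um`` is positive.  Every donor must contribute exactly one
    treated and one untreated sample.
    """
    donors = sorted(design_table["donor"].unique())
    cond = design_table["condition"].astype(str)
    dose = design_table.get("dose_um", pd.Series(0.0, index=design_table.index))
    treated = ((cond != "untreated") | (dose > 0)).astype(float)
    for d in donors:
        sub = treated[design_table["donor"] == d]
        if len(sub) != 2 or sub.sum() != 1:
            raise ValueError(
                f"donor {d!r} is not paired (needs exactly one treated and one "
                "untreated sample)"
            )
    n = len(design_table)
    cols = ["intercept"] + [f"donor_{d}" for d in donors[1:]] + ["treatment"]
    X = np.zeros((n, len(cols)))
    X[:, 0] = 1.0
    for j, d in enumerate(donors[1:], start=1):
        X[:, j] = (design_table["donor"] == d).astype(float)
    X[:, -1] = treated.to_numpy()
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return DesignMatrix(matrix=X, columns=cols, samples=list(design_table.index))


# --------------------------------------------------------------------------
# NB likelihood pieces (vectorized over elements: y is (m, n))
# --------------------------------------------------------------------------


def _as_2d(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    return y[None, :] if y.ndim == 1 else y


def _phi_col(phi, m: int) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 0:
        phi = np.full(m, float(phi))
    return phi[:, None]


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-element residual deviance 2*[l(saturated) - l(mu)]; phi=0 -> Poisson."""
    y = _as_2d(y)
    mu = np.maximum(_as_2d(mu), 1e-300)
    ph = _phi_col(phi, y.shape[0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        pois = t1 - (y - mu)
        # NB unit deviance: y log(y/mu) - (y + 1/phi) log((1+phi y)/(1+phi mu))
        with_od = t1 - (y + 1.0 / np.maximum(ph, 1e-300)) * np.log1p(
            ph * (y - mu) / (1.0 + ph * mu)
        )
    unit = np.where(ph > 0, with_od, pois)
    return 2.0 * unit.sum(axis=1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-element NB log-likelihood (Poisson at phi = 0)."""
    y = _as_2d(y)
    mu = np.maximum(_as_2d(mu), 1e-300)
    ph = _phi_col(phi, y.shape[0])
    out = np.empty(y.shape[0])
    pois_rows = ph[:, 0] <= 0
    if pois_rows.any():
        yy, mm = y[pois_rows], mu[pois_rows]
        out[pois_rows] = (yy * np.log(mm) - mm - gammaln(yy + 1.0)).sum(axis=1)
    nb_rows = ~pois_rows
    if nb_rows.any():
        yy, mm, pp = y[nb_rows], mu[nb_rows], ph[nb_rows]
        r = 1.0 / pp
        out[nb_rows] = (
            gammaln(yy + r)
            - gammaln(r)
            - gammaln(yy + 1.0)
            + yy * np.log(pp * mm / (1.0 + pp * mm))
            - r * np.log1p(pp * mm)
        ).sum(axis=1)
    return out


def fit_nb_glm(
    y: np.ndarray,
    design: np.ndarray,
    offsets: np.ndarray,
    phi,
    max_iter: int = 100,
    tol: float = 1e-8,
):
    """Fisher-scoring fit of the NB GLM with log link, vectorized over rows.

    Parameters
    ----------
    y : (m, n) or (n,) counts
    design : (n, p) design matrix
    offsets : (n,) natural-log effective library sizes
    phi : scalar or (m,) NB dispersion(s); 0 means Poisson

    Returns a dict with ``beta`` (m, p), ``mu`` (m, n), ``deviance`` (m,),
    ``converged`` (m,) and ``all_zero`` (m,) flags.  All-zero rows sit at the
    boundary (mean -> 0) and are flagged with deviance 0.
    """
    y = _as_2d(y)
    m, n = y.shape
    X = np.asarray(design, dtype=float)
    p = X.shape[1]
    off = np.broadcast_to(np.asarray(offsets, dtype=float), (n,))
    ph = _phi_col(phi, m)

    all_zero = y.sum(axis=1) == 0

    # start from a weighted least-squares fit to log counts
    z0 = np.log(np.maximum(y, 0.5)) - off
    beta, *_ = np.linalg.lstsq(X, z0.T, rcond=None)
    beta = beta.T  # (m, p)

    def _mu(b):
        eta = np.clip(b @ X.T, -_ETA_CAP, _ETA_CAP)
        return np.exp(eta + off), eta

    # all-zero rows sit at the boundary: push the linear predictor to the
    # cap (mean -> 0) and report exact zero deviance
    if all_zero.any():
        b_boundary, *_ = np.linalg.lstsq(X, -_ETA_CAP - off, rcond=None)
        beta[all_zero] = b_boundary

    mu, eta = _mu(beta)
    dev = nb_deviance(y, mu, ph[:, 0])
    dev[all_zero] = 0.0
    converged = np.zeros(m, dtype=bool)
    converged[all_zero] = True

    eye = np.eye(p)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        ya, mua, etaa, pha = y[active], mu[active], eta[active], ph[active]
        w = mua / (1.0 + pha * mua)  # Fisher weights for log link
        z = etaa + (ya - mua) / np.maximum(mua, 1e-300)
        xtwx = np.einsum("kn,np,nq->kpq", w, X, X)
        xtwz = np.einsum("np,kn,kn->kp", X, w, z)
        try:
            beta_new = np.linalg.solve(xtwx + 1e-10 * eye, xtwz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta_new = np.einsum(
                "kpq,kq->kp", np.linalg.pinv(xtwx + 1e-8 * eye), xtwz
            )
        # step-halving where the deviance would increase
        step = beta_new - beta[active]
        dev_a = dev[active]
        b_try = beta[active] + step
        for _half in range(8):
            eta_t = np.clip(b_try @ X.T, -_ETA_CAP, _ETA_CAP)
            mu_t = np.exp(eta_t + off)
            dev_t = nb_deviance(ya, mu_t, pha[:, 0])
            worse = dev_t > dev_a + 1e-10
            if not worse.any():
                break
            step[worse] *= 0.5
            b_try = beta[active] + step
        rel = np.abs(dev_t - dev_a) / (np.abs(dev_a) + 1.0)
        beta_act = b_try
        idx = np.flatnonzero(active)
        beta[idx] = beta_act
        mu[idx], eta[idx] = np.exp(eta_t + off), eta_t
        dev[idx] = dev_t
        converged[idx[rel < tol]] = True

    return {
        "beta": beta,
        "mu": mu,
        "deviance": dev,
        "converged": converged,
        "all_zero": all_zero,
    }


def adjusted_profile_loglik(
    y: np.ndarray, design: np.ndarray, offsets: np.ndarray, phi
) -> np.ndarray:
    """Cox–Reid APL per element at dispersion(s) ``phi``.

    APL_g = l_g(beta_hat; phi) - 0.5 * log det(X' W X), the profile
    log-likelihood penalized for estimating the mean parameters.
    """
    y = _as_2d(y)
    m = y.shape[0]
    ph = _phi_col(phi, m)[:, 0]
    fit = fit_nb_glm(y, design, offsets, ph)
    mu = np.maximum(fit["mu"], 1e-10)
    ll = nb_loglik(y, mu, ph)
    w = mu / (1.0 + ph[:, None] * mu)
    X = np.asarray(design, dtype=float)
    xtwx = np.einsum("kn,np,nq->kpq", w, X, X)
    sign, logdet = np.linalg.slogdet(xtwx + 1e-12 * np.eye(X.shape[1]))
    return ll - 0.5 * logdet


@dataclass
class DispersionModel:
    """Common, trended and empirically shrunk (tagwise) NB dispersions."""

    common: float
    trended: np.ndarray  # per element, at its abundance
    tagwise: np.ndarray  # per element, shrunk genewise
    genewise: np.ndarray  # unshrunk genewise APL maxima
    abundance: np.ndarray  # average log2 cpm per element
    prior_df: float

    def __post_init__(self):
        if self.common < 0 or (self.trended < 0).any() or (self.tagwise < 0).any():
            raise ValueError("dispersions must be >= 0")


def average_log2_cpm(counts: np.ndarray, lib_sizes: np.ndarray, prior: float = 0.5) -> np.ndarray:
    """log2 of the mean cpm with a small prior count (abundance axis A)."""
    counts = _as_2d(counts)
    cpm = (counts + prior) / (lib_sizes + 1.0) * 1e6
    return np.log2(cpm.mean(axis=1))


def _interp_max(log2_grid: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Argmax over a log2-phi grid with parabolic refinement, per row."""
    values = np.atleast_2d(values)
    j = values.argmax(axis=1)
    x = log2_grid
    out = x[j].astype(float)
    inner = (j > 0) & (j < len(x) - 1)
    if inner.any():
        ji = j[inner]
        rows = np.flatnonzero(inner)
        y0 = values[rows, ji - 1]
        y1 = values[rows, ji]
        y2 = values[rows, ji + 1]
        denom = y0 - 2 * y1 + y2
        shift = np.where(np.abs(denom) > 1e-12, 0.5 * (y0 - y2) / denom, 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = x[1] - x[0]
        out[rows] = x[ji] + shift * step
    return out


def estimate_dispersions(
    counts: pd.DataFrame | np.ndarray,
    design: DesignMatrix | np.ndarray,
    offsets: np.ndarray,
    prior_df: float = 10.0,
    grid_log2: tuple[float, float, int] = (-16.0, 6.0, 23),
) -> DispersionModel:
    """Estimate common, trended, and tagwise dispersions via Cox–Reid APL.

    The genewise APL is evaluated on a log2-spaced dispersion grid.  The
    common value maximizes the grid-summed APL.  The shared (trend) curve is
    built by binning elements on average abundance (``min(20, m // 50 + 2)``
    bins), averaging APL per bin, smoothing across bins with a moving average,
    and interpolating at each element's abundance; its per-element argmax is
    the trended dispersion.  Tagwise values maximize
    ``APL_g + (prior_df / residual_df) * shared`` and are clipped to the
    interval between the genewise and trended argmaxes, so ``prior_df = 0``
    returns the genewise maxima and ``prior_df -> inf`` returns the trend.
    """
    X = design.matrix if isinstance(design, DesignMatrix) else np.asarray(design)
    y = counts.to_numpy() if isinstance(counts, pd.DataFrame) else _as_2d(counts)
    m, n = y.shape
    resid_df = n - X.shape[1]
    if resid_df < 1:
        raise ValueError("residual df < 1: dispersion is unidentifiable")

    lo, hi, npts = grid_log2
    log2_grid = np.linspace(lo, hi, int(npts))
    grid = 2.0**log2_grid
    apl = np.empty((m, len(grid)))
    for j, ph in enumerate(grid):
        apl[:, j] = adjusted_profile_loglik(y, X, offsets, ph)

    common = float(2.0 ** _interp_max(log2_grid, apl.sum(axis=0))[0])

    lib = np.exp(np.asarray(offsets, dtype=float))
    A = average_log2_cpm(y, lib)

    # shared APL: abundance bins -> per-bin mean curve -> moving average ->
    # linear interpolation at each element's abundance
    nbins = max(1, min(20, m // 50 + 2))
    order = np.argsort(A)
    bins = np.array_split(order, nbins)
    bin_a = np.array([A[b].mean() for b in bins])
    bin_curves = np.stack([apl[b].mean(axis=0) for b in bins])  # nbins x G
    if nbins >= 3:
        sm = bin_curves.copy()
        sm[1:-1] = (bin_curves[:-2] + bin_curves[1:-1] + bin_curves[2:]) / 3.0
        bin_curves = sm
    shared = np.empty_like(apl)
    if nbins == 1:
        shared[:] = bin_curves[0]
    else:
        for j in range(apl.shape[1]):
            shared[:, j] = np.interp(A, bin_a, bin_curves[:, j])

    trended = 2.0 ** _interp_max(log2_grid, shared)
    genewise = 2.0 ** _interp_max(log2_grid, apl)
    prior_n = prior_df / resid_df
    tagwise = 2.0 ** _interp_max(log2_grid, apl + prior_n * shared)
    lo_clip = np.minimum(genewise, trended)
    hi_clip = np.maximum(genewise, trended)
    tagwise = np.clip(tagwise, lo_clip, hi_clip)

    return DispersionModel(
        common=common,
        trended=trended,
        tagwise=tagwise,
        genewise=genewise,
        abundance=A,
        prior_df=prior_df,
    )


def lrt(
    counts: pd.DataFrame | np.ndarray,
    design: DesignMatrix,
    offsets: np.ndarray,
    phi,
) -> pd.DataFrame:
    """Likelihood-ratio test of the treatment term, per element.

    LR = deviance(reduced) - deviance(full) >= 0 (clipped at tiny negative
    numerical slack), referred to chi-square with 1 df.  Nonconverged fits
    yield NaN p-values (excluded from FDR by :func:`adjust_bh`).
    """
    y = counts.to_numpy() if isinstance(counts, pd.DataFrame) else _as_2d(counts)
    idx = counts.index if isinstance(counts, pd.DataFrame) else pd.RangeIndex(y.shape[0])
    full = fit_nb_glm(y, design.matrix, offsets, phi)
    red = fit_nb_glm(y, design.reduced(), offsets, phi)
    lr = red["deviance"] - full["deviance"]
    lr = np.where(lr < -1e-6, np.nan, np.maximum(lr, 0.0))
    pvals = chi2.sf(lr, df=1)
    ok = full["converged"] & red["converged"]
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} element(s) failed to converge; p set to NaN",
            stacklevel=2,
        )
        pvals = np.where(ok, pvals, np.nan)
    logfc = full["beta"][:, design.treatment_index] / _LN2
    lib = np.exp(np.asarray(offsets, dtype=float))
    return pd.DataFrame(
        {
            "logFC": logfc,
            "logCPM": average_log2_cpm(y, lib),
            "LR": lr,
            "PValue": pvals,
        },
        index=idx,
    )


def adjust_bh(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``adj_(i) = min_{j >= i} m * p_(j) / j`` capped at 1.  NaNs are excluded
    from m and preserved in place.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if ((pv < 0) | (pv > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[ok] = res
    return out


def classify(
    results: pd.DataFrame, alpha: float = 0.05, lfc_threshold: float = 3.0
) -> pd.Series:
    """up / down / ns classes: significant (FDR < alpha) AND |log2FC| > threshold."""
    sig = results["FDR"] < alpha
    up = sig & (results["logFC"] > lfc_threshold)
    down = sig & (results["logFC"] < -lfc_threshold)
    cls = pd.Series("ns", index=results.index, name="class")
    cls[up] = "up"
    cls[down] = "down"
    return cls


def lfc_to_fold(log2fc: float) -> int:
    """Linear fold change 2**lfc, rounded half away from zero for reporting."""
    fold = 2.0 ** float(log2fc)
    return int(math.floor(abs(fold) + 0.5) * (1 if fold >= 0 else -1))


def summarize_families(results: pd.DataFrame) -> pd.DataFrame:
    """Per-family tallies of up/down classified elements (families with any).

    Expects ``family`` and ``class`` columns; returns n_up / n_down sorted by
    total modulation, empty when nothing is classified.
    """
    hit = results[results["class"].isin(["up", "down"])]
    if hit.empty:
        return pd.DataFrame(columns=["n_up", "n_down"]).rename_axis("family")
    tally = (
        hit.groupby("family")["class"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down"], fill_value=0)
        .rename(columns={"up": "n_up", "down": "n_down"})
    )
    tally.columns.name = None
    return tally.sort_values(["n_up", "n_down"], ascending=False)


def plot_family_summary(summary: pd.DataFrame, path) -> None:
    """Paired bar chart of per-family up (white) / down (black) counts."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(summary)), 4))
    x = np.arange(len(summary))
    ax.bar(x - 0.2, summary["n_up"], width=0.4, color="white", edgecolor="black", label="up")
    ax.bar(x + 0.2, summary["n_down"], width=0.4, color="black", label="down")
    ax.set_xticks(x)
    ax.set_xticklabels(summary.index, rotation=60, ha="right")
    ax.set_ylabel("modulated elements")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_de(
    counts: pd.DataFrame,
    design_table: pd.DataFrame,
    families: dict[str, str] | None = None,
    library_sizes: pd.Series | None = None,
    min_cpm: float = 1.0,
    min_fraction: float = 0.5,
    alpha: float = 0.05,
    lfc_threshold: float = 3.0,
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Full DE pass: filter + TMM -> dispersions -> LRT -> BH -> classes.

    ``counts`` columns must match ``design_table`` rows.  Returns the
    per-element results table (logFC, logCPM, LR, PValue, FDR, class, family).
    """
    from hervex.normfilter import normalize

    counts = counts[design_table.index]
    norm = normalize(
        counts, library_sizes=library_sizes, min_cpm=min_cpm, min_fraction=min_fraction
    )
    design = build_design(design_table)
    offsets = norm.offsets
    disp = estimate_dispersions(norm.counts, design, offsets, prior_df=prior_df)
    res = lrt(norm.counts, design, offsets, disp.tagwise)
    res["FDR"] = adjust_bh(res["PValue"].to_numpy())
    if families is not None:
        res.insert(0, "family", [families.get(e, "NA") for e in res.index])
    res["class"] = classify(res, alpha=alpha, lfc_threshold=lfc_threshold)
    return res


def wilcoxon_signed_rank(
    log_cpm: pd.DataFrame, design_table: pd.DataFrame
) -> pd.DataFrame:
    """Exact Wilcoxon signed-rank on within-donor log-cpm differences.

    Provided for comparison with the GLM path only; with few donors its
    smallest attainable p-value is far above typical significance thresholds.
    """
    cond = design_table["condition"].astype(str)
    dose = design_table.get("dose_um", pd.Series(0.0, index=design_table.index))
    treated_mask = (cond != "untreated") | (dose > 0)
    donors = sorted(design_table["donor"].unique())
    diffs = []
    for d in donors:
        rows = design_table[design_table["donor"] == d]
        t = rows.index[treated_mask.loc[rows.index]][0]
        u = rows.index[~treated_mask.loc[rows.index]][0]
        diffs.append(log_cpm[t] - log_cpm[u])
    dmat = pd.concat(diffs, axis=1)
    out = []
    for _, row in dmat.iterrows():
        vals = row.to_numpy()
        if np.allclose(vals, 0):
            out.append((0.0, 1.0))
        else:
            stat, p = wilcoxon(vals, mode="exact" if len(vals) <= 25 else "auto")
            out.append((float(stat), float(p)))
    return pd.DataFrame(out, index=dmat.index, columns=["W", "PValue"])
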