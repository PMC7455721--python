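"""Negative-binomial differential expression for two-group count designs.

The engine mirrors the classic count-based DE workflow for a simple
control-vs-knockout comparison: expression filtering on counts-per-million,
TMM (trimmed mean of M-values) between-sample normalization, per-gene
dispersion estimation with empirical-Bayes shrinkage toward a mean-dispersion
trend, and an exact-style conditional NB test on group sums with pseudo-counts
equalized to a common library size. p-values are corrected by
Benjamini-Hochberg step-up.

The NB is parameterized by its mean mu and dispersion phi with
``var = mu + phi * mu**2`` (phi = 0 is the Poisson limit).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import gmean
from statsmodels.stats.multitest import multipletests

from .io import ConfigError, CountMatrix


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every gene."""


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------

def cpm(counts: pd.DataFrame, lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Counts per million mapped reads, using raw library sizes by default."""
    lib = counts.sum(axis=0) if lib_sizes is None else lib_sizes
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ConfigError(f"samples with zero library size: {bad}")
    return counts / lib * 1e6


def filter_expressed(
    cm: CountMatrix, cpm_min: float = 1.0, min_samples: int = 3
) -> CountMatrix:
    """Keep genes with CPM >= ``cpm_min`` in at least ``min_samples`` samples.

    CPM is computed on raw (pre-normalization) library sizes; gene order is
    preserved. Raises :class:`EmptyResultError` if nothing survives.
    """
    keep = (cpm(cm.counts) >= cpm_min).sum(axis=1) >= min_samples
    if not keep.any():
        raise EmptyResultError(
            f"no gene has CPM >= {cpm_min} in >= {min_samples} samples"
        )
    return CountMatrix(cm.counts.loc[keep], cm.groups, cm.feature_class)


def tmm_factors(
    counts: pd.DataFrame | CountMatrix,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
    ref: str | None = None,
) -> pd.Series:
    """Weighted trimmed-mean-of-M-values scaling factors.

    For each sample, gene-wise log ratios M against a reference sample are
    trimmed (``trim_m`` of the M distribution and ``trim_a`` of the average
    log intensity A, each side) and averaged with inverse asymptotic-variance
    weights. Factors are normalized to geometric mean 1; effective library
    size = raw library size x factor.
    """
    if isinstance(counts, CountMatrix):
        counts = counts.counts
    if counts.shape[1] < 2:
        raise ConfigError("TMM needs at least two samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ConfigError(f"zero-total sample: {lib.index[lib <= 0].tolist()}")
    if ref is None:
        # sample whose upper-quartile CPM is closest to the across-sample mean
        q75 = (counts / lib).quantile(0.75)
        ref = (q75 - q75.mean()).abs().idxmin()
    xr = counts[ref].to_numpy(float)
    nr = lib[ref]
    factors = {}
    for s in counts.columns:
        if s == ref:
            factors[s] = 1.0
            continue
        xi = counts[s].to_numpy(float)
        ni = lib[s]
        ok = (xi > 0) & (xr > 0)
        if ok.sum() < 1:
            factors[s] = 1.0
            continue
        pi, pr = xi[ok] / ni, xr[ok] / nr
        m = np.log2(pi / pr)
        a = 0.5 * np.log2(pi * pr)
        w = (ni - xi[ok]) / (ni * xi[ok]) + (nr - xr[ok]) / (nr * xr[ok])
        # double trim: keep genes inside both the M and the A trim windows
        lo_m, hi_m = np.quantile(m, [trim_m, 1.0 - trim_m])
        lo_a, hi_a = np.quantile(a, [trim_a, 1.0 - trim_a])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, bool)
        f = np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[s] = float(2.0 ** f) if np.isfinite(f) else 1.0
    fac = pd.Series(factors).loc[counts.columns]
    return fac / gmean(fac)


# ---------------------------------------------------------------------------
# dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    cm: CountMatrix,
    factors: pd.Series | None = None,
    prior_df: float = 20.0,
    n_bins: int = 20,
    lib_sizes: pd.Series | None = None,
) -> pd.Series:
    """Per-gene NB dispersion phi with shrinkage toward a mean-dispersion trend.

    Per gene, a pooled within-group method-of-moments estimate
    ``(s^2 - xbar) / xbar^2`` is computed on counts scaled to a common
    library size. A trend is fit as binned means of the raw (un-floored)
    estimates against the log gene mean, and each gene is shrunk toward the
    trend with weight ``prior_df`` against its residual df. The shrunk value
    is floored at 0 (Poisson floor).
    """
    groups = cm.groups
    sizes = groups.value_counts()
    if (sizes < 2).all():
        raise ConfigError("dispersion estimation needs replicates in at least one group")
    lib = (cm.lib_sizes if lib_sizes is None else lib_sizes.loc[cm.samples]).astype(float)
    eff = lib * (factors.loc[cm.samples] if factors is not None else 1.0)
    scaled = cm.counts / eff * gmean(eff)

    resid_df = 0
    ss = np.zeros(cm.counts.shape[0])
    mean_of_means = np.zeros(cm.counts.shape[0])
    total_n = 0
    for g, idx in groups.groupby(groups).groups.items():
        sub = scaled[list(idx)]
        n = sub.shape[1]
        mu = sub.mean(axis=1).to_numpy()
        mean_of_means += mu * n
        total_n += n
        if n >= 2:
            ss += ((sub.to_numpy() - mu[:, None]) ** 2).sum(axis=1)
            resid_df += n - 1
    xbar = mean_of_means / total_n
    s2 = ss / resid_df
    with np.errstate(divide="ignore", invalid="ignore"):
        phi_raw = np.where(xbar > 0, (s2 - xbar) / np.maximum(xbar, 1e-300) ** 2, 0.0)

    # trend: binned means of raw estimates vs log mean
    order = np.argsort(xbar)
    n_genes = len(xbar)
    n_bins = max(1, min(n_bins, n_genes // 10 or 1))
    bins = np.array_split(order, n_bins)
    bx = np.array([np.log(np.maximum(xbar[b].mean(), 1e-8)) for b in bins])
    by = np.array([phi_raw[b].mean() for b in bins])
    if n_bins > 1:
        trend = np.interp(np.log(np.maximum(xbar, 1e-8)), bx, by)
    else:
        trend = np.full(n_genes, by[0])
    trend = np.maximum(trend, 0.0)

    shrunk = (resid_df * phi_raw + prior_df * trend) / (resid_df + prior_df)
    return pd.Series(np.maximum(shrunk, 0.0), index=cm.gene_ids, name="dispersion")


# ---------------------------------------------------------------------------
# exact-style conditional NB test
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray, size: float, mean: float) -> np.ndarray:
    """log pmf of NB with shape ``size`` (=1/dispersion) and mean ``mean``."""
    if mean <= 0:
        out = np.full_like(k, -np.inf, dtype=float)
        out[k == 0] = 0.0
        return out
    logp = size * np.log(size / (size + mean)) + k * np.log(mean / (size + mean))
    return gammaln(k + size) - gammaln(size) - gammaln(k + 1) + logp


def exact_nb_p(s1: float, s2: float, n1: int, n2: int, phi: float) -> float:
    """Two-sided conditional exact p-value for equal means, given group sums.

    Group sums of n i.i.d. NB(mu, phi) counts are NB(n*mu, phi/n). The test
    conditions on the total S = s1 + s2, evaluates the conditional probability
    of every split k + (S - k), and doubles the smaller tail (capped at 1).
    phi = 0 reduces to the conditional binomial (Poisson limit).
    """
    s1, s2 = float(s1), float(s2)
    total = s1 + s2
    if total <= 0:
        return 1.0
    S = int(round(total))
    k = np.arange(S + 1)
    if phi <= 1e-12:
        # Binomial(S, n1/(n1+n2)) via exact log-pmf
        p1 = n1 / (n1 + n2)
        logp = (
            gammaln(S + 1) - gammaln(k + 1) - gammaln(S - k + 1)
            + k * np.log(p1) + (S - k) * np.log1p(-p1)
        )
    else:
        mu = total / (n1 + n2)
        logp = _nb_logpmf(k, n1 / phi, n1 * mu) + _nb_logpmf(S - k, n2 / phi, n2 * mu)
        logp = logp - logsumexp(logp)
    obs = int(round(s1))
    lower = np.exp(logsumexp(logp[: obs + 1]))
    upper = np.exp(logsumexp(logp[obs:]))
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_test(
    cm: CountMatrix,
    dispersion: pd.Series | float,
    factors: pd.Series | None = None,
    ref_group: str = "control",
    prior_count: float = 0.125,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene exact-style NB test of the non-reference group vs ``ref_group``.

    Returns a DataFrame with columns ``gene_id, logFC, logCPM, PValue, FDR,
    direction`` where logFC is log2(non-reference / reference) computed on
    library-size-equalized pseudo-counts with ``prior_count`` added per
    library. ``lib_sizes`` overrides the matrix column totals, e.g. with a
    sample's full mapped-read total when the matrix holds only one feature
    class of a library.
    """
    groups = cm.groups
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ConfigError(f"need exactly two groups, got {levels}")
    if ref_group not in levels:
        raise ConfigError(f"reference group {ref_group!r} not in {levels}")
    trt_group = next(g for g in levels if g != ref_group)
    if isinstance(dispersion, (int, float)):
        phi = np.full(cm.counts.shape[0], float(dispersion))
    else:
        if len(dispersion) != cm.counts.shape[0]:
            raise ConfigError("dispersion vector length != gene count")
        phi = dispersion.loc[cm.gene_ids].to_numpy(float)
    if (phi < 0).any():
        raise ConfigError("negative dispersion")

    lib = (cm.lib_sizes if lib_sizes is None else lib_sizes.loc[cm.samples]).astype(float)
    eff = lib * (factors.loc[cm.samples] if factors is not None else 1.0)
    common = gmean(eff)
    # continuous pseudo-counts for fold changes; the exact test rounds its
    # group sums to the integer conditional support
    pseudo = cm.counts.to_numpy(float) * (common / eff.to_numpy())[None, :]

    ref_cols = np.asarray(groups == ref_group)
    n1, n2 = int(ref_cols.sum()), int((~ref_cols).sum())
    s1 = pseudo[:, ref_cols].sum(axis=1)
    s2 = pseudo[:, ~ref_cols].sum(axis=1)

    pvals = np.array(
        [
            exact_nb_p(round(a), round(b), n1, n2, ph)
            for a, b, ph in zip(s1, s2, phi)
        ]
    )
    log_fc = np.log2((s2 / n2 + prior_count) / (s1 / n1 + prior_count))
    log_cpm = np.log2(((s1 + s2) / (n1 + n2) + prior_count) / common * 1e6)
    fdr = bh_fdr(pvals)
    return pd.DataFrame(
        {
            "gene_id": cm.gene_ids,
            "logFC": log_fc,
            "logCPM": log_cpm,
            "PValue": pvals,
            "FDR": fdr,
            "direction": np.where(log_fc >= 0, "up", "down"),
        }
    ).reset_index(drop=True)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-value passed to bh_fdr")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_pipeline(
    cm: CountMatrix,
    cpm_min: float = 1.0,
    min_samples: int = 3,
    ref_group: str = "control",
    prior_df: float = 20.0,
    factors: pd.Series | None = None,
    lib_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Filter -> TMM -> dispersion -> exact NB test, returning the DE table.

    ``factors`` / ``lib_sizes`` allow normalization shared across feature
    classes of the same libraries (see :func:`deadstab.stability.stability_pipeline`);
    by default TMM factors are estimated from this matrix alone.
    """
    filtered = filter_expressed(cm, cpm_min=cpm_min, min_samples=min_samples)
    if factors is None:
        factors = tmm_factors(filtered)
    phi = estimate_dispersion(
        filtered, factors=factors, prior_df=prior_df, lib_sizes=lib_sizes
    )
    return nb_test(
        filtered, phi, factors=factors, ref_group=ref_group, lib_sizes=lib_sizes
    )
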