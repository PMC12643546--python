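"""Aggregation of per-scale odds ratios into summary statistics.

The central object is the "polypharmacy null": the empirical distribution
of ORs across pseudoscales.  Summaries per outcome and sampling pool are
the 95% simulation interval (empirical 2.5th-97.5th percentiles), median
and IQR, the two-sided Wilcoxon rank-sum contrast between the general and
anticholinergic pools, the overlap coefficient of the two OR densities
(Gaussian KDE with Sheather-Jones solve-the-equation bandwidths), the
fraction of significantly positive associations, and the Pearson
correlation between OR and scale size (Fisher-z CI).  Each real ABS is
located within its matched within-sampling null by its cumulative
probability: the fraction of matched pseudoscale ORs below the ABS's OR.

Quantiles use linear interpolation (type 7) throughout.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .scale_registry import ValidationError

__all__ = [
    "simulation_interval",
    "median_iqr",
    "rank_sum_test",
    "sheather_jones_bandwidth",
    "kde_overlap",
    "size_or_correlation",
    "cumulative_probability",
    "proportion_significant",
    "summarize",
    "write_report",
    "table2_frame",
]


def simulation_interval(ors, level: float = 0.95) -> tuple[float, float]:
    """Empirical central interval containing ``level`` of the values."""
    v = np.asarray(ors, dtype=float)
    if v.size < 2:
        raise ValidationError("need at least 2 values for a simulation interval")
    if not 0 <= level <= 1:
        raise ValidationError("level must be in [0, 1]")
    tail = 100 * (1 - level) / 2
    lo, hi = np.percentile(v, [tail, 100 - tail])
    return float(lo), float(hi)


def median_iqr(ors) -> tuple[float, float]:
    """Median and interquartile range (type-7 quantiles)."""
    v = np.asarray(ors, dtype=float)
    if v.size == 0:
        raise ValidationError("empty input")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    return float(q50), float(q75 - q25)


def rank_sum_test(ors_a, ors_b) -> float:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum p-value.

    Exact enumeration for small tie-free samples (both n <= 20), otherwise
    the normal approximation with tie correction and continuity correction.
    """
    a = np.asarray(ors_a, dtype=float)
    b = np.asarray(ors_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("non-finite values in rank-sum input")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 20 and b.size <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# Sheather-Jones bandwidth and density overlap
# ---------------------------------------------------------------------------

def _phi_sums(x: np.ndarray, nb: int):
    """Binned pair-distance counts for the plug-in functionals."""
    n = x.size
    xmin = x.min()
    rang = (x.max() - xmin) * 1.01
    if rang <= 0:
        raise ValidationError("zero-variance sample")
    d = rang / nb
    bins = np.minimum((np.floor((x - xmin) / d)).astype(int), nb - 1)
    c = np.bincount(bins, minlength=nb).astype(float)
    cnt = np.array([c[m:] @ c[: nb - m] for m in range(nb)])
    cnt[0] = (cnt[0] - n) / 2.0  # unordered within-bin pairs
    return n, d, cnt


def sheather_jones_bandwidth(x, nb: int = 1000) -> float:
    """Sheather-Jones solve-the-equation plug-in bandwidth for a Gaussian
    kernel, using binned approximations of the pairwise sums (bin count
    ``nb``) and Brent root finding."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 observations")
    sd = x.std(ddof=1)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if not np.isfinite(scale) or scale <= 0:
        raise ValidationError("zero-variance sample")
    n, d, cnt = _phi_sums(x, nb)
    sqrt2pi = math.sqrt(2 * math.pi)
    m = np.arange(nb)

    def phi4(h: float) -> float:
        delta = m * d / h
        term = np.exp(-0.5 * delta**2) * (delta**4 - 6 * delta**2 + 3)
        return (2 * (term @ cnt) + n * 3) / (n * (n - 1) * h**5 * sqrt2pi)

    def phi6(h: float) -> float:
        delta = m * d / h
        term = np.exp(-0.5 * delta**2) * (
            delta**6 - 15 * delta**4 + 45 * delta**2 - 15
        )
        return (2 * (term @ cnt) - n * 15) / (n * (n - 1) * h**7 * sqrt2pi)

    a = 1.24 * scale * n ** (-1 / 7)
    b = 1.23 * scale * n ** (-1 / 9)
    c1 = 1.0 / (2 * math.sqrt(math.pi) * n)
    td = -phi6(b)
    sda = phi4(a)
    if td <= 0 or sda <= 0:
        raise ValidationError("sample too sparse for Sheather-Jones estimate")
    alph2 = 1.357 * (sda / td) ** (1 / 7)

    def f(h: float) -> float:
        return (c1 / phi4(alph2 * h ** (5 / 7))) ** 0.2 - h

    hmax = 1.144 * sd * n ** (-0.2)
    lo, hi = 0.1 * hmax, hmax
    for _ in range(40):  # expand until the root is bracketed
        if f(lo) > 0:
            break
        lo /= 2
    for _ in range(40):
        if f(hi) < 0:
            break
        hi *= 1.3
    if f(lo) <= 0 or f(hi) >= 0:
        raise ValidationError("no Sheather-Jones bandwidth solution found")
    from scipy.optimize import brentq

    return float(brentq(f, lo, hi, xtol=1e-6 * hmax))


def _gaussian_kde_on_grid(x: np.ndarray, h: float, grid: np.ndarray) -> np.ndarray:
    """Gaussian KDE with fixed bandwidth evaluated on a grid (chunked)."""
    dens = np.empty_like(grid)
    step = max(1, int(4e7 // max(x.size, 1)))
    c = 1.0 / (x.size * h * math.sqrt(2 * math.pi))
    for i in range(0, grid.size, step):
        g = grid[i : i + step]
        z = (g[:, None] - x[None, :]) / h
        dens[i : i + step] = c * np.exp(-0.5 * z**2).sum(axis=1)
    return dens


def kde_overlap(ors_a, ors_b, n_grid: int = 2048) -> float:
    """Overlap coefficient of two OR distributions.

    Each sample gets a Gaussian KDE with its own Sheather-Jones bandwidth;
    the overlap is the trapezoidal integral of min(f, g) over a shared grid
    spanning both samples plus 3 bandwidths on each side.  1 means
    identical distributions, 0 disjoint ones.
    """
    a = np.asarray(ors_a, dtype=float)
    b = np.asarray(ors_b, dtype=float)
    if a.size < 10 or b.size < 10:
        raise ValidationError("need at least 10 observations per sample")
    ha = sheather_jones_bandwidth(a)
    hb = sheather_jones_bandwidth(b)
    pad = 3 * max(ha, hb)
    grid = np.linspace(
        min(a.min(), b.min()) - pad, max(a.max(), b.max()) + pad, max(n_grid, 2048)
    )
    fa = _gaussian_kde_on_grid(a, ha, grid)
    fb = _gaussian_kde_on_grid(b, hb, grid)
    return float(np.trapezoid(np.minimum(fa, fb), grid))


def size_or_correlation(results) -> tuple[float, tuple[float, float]]:
    """Pearson r between scale size and OR, with a 95% Fisher-z CI.

    ``results`` may be a DataFrame with columns scale_size / or_per_sd or a
    pair of sequences (sizes, ors).
    """
    if isinstance(results, pd.DataFrame):
        sizes = results["scale_size"].to_numpy(dtype=float)
        ors = results["or_per_sd"].to_numpy(dtype=float)
    else:
        sizes, ors = (np.asarray(v, dtype=float) for v in results)
    if sizes.size < 4:
        raise ValidationError("need at least 4 points for a correlation")
    if np.unique(sizes).size < 2 or np.unique(ors).size < 2:
        raise ValidationError("constant input to correlation")
    r = float(stats.pearsonr(sizes, ors).statistic)
    z = math.atanh(min(max(r, -1 + 1e-15), 1 - 1e-15))
    half = 1.959963984540054 / math.sqrt(sizes.size - 3)
    return r, (math.tanh(z - half), math.tanh(z + half))


def cumulative_probability(abs_or: float, pseudo_ors) -> float:
    """Fraction of pseudoscale ORs strictly below the ABS's OR: where the
    ABS sits within its polypharmacy null."""
    v = np.asarray(pseudo_ors, dtype=float)
    if v.size == 0:
        raise ValidationError("empty pseudoscale OR sample")
    return float(np.mean(v < abs_or))


def proportion_significant(results: pd.DataFrame, alpha: float = 0.05) -> float:
    """Fraction of converged models with two-sided p < alpha and OR > 1."""
    if len(results) == 0:
        raise ValidationError("empty results")
    ok = results["converged"] if "converged" in results else pd.Series(True, index=results.index)
    sub = results.loc[ok.astype(bool)]
    if len(sub) == 0:
        raise ValidationError("no converged models")
    hits = (sub["p_value"] < alpha) & (sub["or_per_sd"] > 1.0)
    return float(hits.mean())


# ---------------------------------------------------------------------------
# Full report
# ---------------------------------------------------------------------------

def summarize(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Build the summary report from a flat model-results table.

    Expects the columns produced by :func:`outcome_models.results_frame`.
    Returns a JSON-serializable dict: per outcome, across-sampling pool
    summaries with the general-vs-anticholinergic contrast, and per-ABS
    cumulative probabilities against matched within-sampling nulls.
    """
    res = results.loc[results["converged"].astype(bool)].copy()
    report: dict = {
        "alpha": alpha,
        "n_models": int(len(results)),
        "n_nonconverged": int(len(results) - len(res)),
        "outcomes": {},
    }
    for outcome, group in res.groupby("outcome", sort=True):
        entry: dict = {"across": {}, "abs": {}}
        across = group.loc[(group["mode"] == "across")]
        pools = {}
        for pool, sub in across.groupby("pool", sort=True):
            ors = sub["or_per_sd"].to_numpy()
            if len(ors) < 2:
                continue
            si = simulation_interval(ors)
            med, iqr = median_iqr(ors)
            pool_entry = {
                "n_scales": int(len(ors)),
                "si_low": si[0],
                "si_high": si[1],
                "median_or": med,
                "iqr_or": iqr,
                "prop_significant": proportion_significant(sub, alpha),
            }
            try:
                r, ci = size_or_correlation(sub)
                pool_entry["size_or_correlation"] = {
                    "r": r,
                    "ci_low": ci[0],
                    "ci_high": ci[1],
                }
            except ValidationError:
                pass
            pools[pool] = pool_entry
        entry["across"] = pools
        if {"general", "anticholinergic"} <= set(pools):
            ga = across.loc[across["pool"] == "general", "or_per_sd"].to_numpy()
            aa = across.loc[across["pool"] == "anticholinergic", "or_per_sd"].to_numpy()
            entry["rank_sum_p"] = rank_sum_test(ga, aa)
            try:
                entry["overlap"] = kde_overlap(ga, aa)
            except ValidationError:
                entry["overlap"] = None

        within = group.loc[group["mode"] == "within"]
        for scale_id, abs_row in (
            group.loc[group["kind"] == "abs"].groupby("scale_id", sort=True)
        ):
            abs_or = float(abs_row["or_per_sd"].iloc[0])
            abs_entry: dict = {"or": abs_or, "cumulative_probability": {}}
            for pool, sub in within.loc[
                within["template_scale_id"] == scale_id
            ].groupby("pool", sort=True):
                abs_entry["cumulative_probability"][pool] = cumulative_probability(
                    abs_or, sub["or_per_sd"].to_numpy()
                )
            entry["abs"][scale_id] = abs_entry
        report["outcomes"][outcome] = entry
    return report


def table2_frame(report: dict) -> pd.DataFrame:
    """Flat table mirroring the published summary layout: one row per
    outcome x pool with SI, median, IQR and the rank-sum contrast."""
    rows = []
    for outcome, entry in report["outcomes"].items():
        for pool, p in entry.get("across", {}).items():
            rows.append(
                {
                    "outcome": outcome,
                    "pool": pool,
                    "si_low": p["si_low"],
                    "si_high": p["si_high"],
                    "median_or": p["median_or"],
                    "iqr_or": p["iqr_or"],
                    "prop_significant": p["prop_significant"],
                    "rank_sum_p": entry.get("rank_sum_p"),
                    "overlap": entry.get("overlap"),
                }
            )
    return pd.DataFrame(rows)


def write_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
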