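"""TEM granule morphometrics: volumes, per-cell summaries, ECDF bands, tests.

Granule diameters measured manually on transmission electron micrographs are
converted to volumes under a spherical model (V = πd³/6).  Per-cell
summaries (count, largest-granule volume, total granular volume) feed
empirical CDFs with bootstrap pointwise confidence bands and the standard
nonparametric group comparisons: Mann-Whitney for two groups,
Kruskal-Wallis followed by Dunn's post hoc pairwise tests with Bonferroni
correction for three or more.

Zero-granule cells count toward the count distributions but are excluded
from all volume distributions (no granule, no volume).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EcdfWithCI",
    "GroupComparison",
    "volume_from_diameter",
    "summarize_cells",
    "ecdf_bootstrap",
    "dunn_posthoc",
    "compare_groups",
]


def volume_from_diameter(d):
    """Sphere volume V = π d³ / 6 for diameter(s) d (> 0)."""
    d = np.asarray(d, dtype=float)
    if (d <= 0).any():
        raise ValueError("diameter must be > 0")
    v = np.pi * d**3 / 6.0
    return float(v) if v.ndim == 0 else v


def summarize_cells(
    granules: pd.DataFrame,
    cells: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-cell granule count, largest-granule volume and total volume.

    Parameters
    ----------
    granules
        One row per granule: ``cell_id``, ``group``, ``diameter_nm``.
    cells
        Optional companion table of all imaged cells (``cell_id``,
        ``group``), needed so zero-granule cells appear with count 0;
        their ``largest_volume``/``total_volume`` are NaN.

    Volumes are in nm³ under the spherical model.
    """
    if not granules.empty and (granules["diameter_nm"] <= 0).any():
        raise ValueError("diameter_nm must be > 0")
    per_cell = (
        granules.assign(volume=lambda df: volume_from_diameter(df["diameter_nm"]))
        .groupby(["cell_id", "group"], sort=False)["volume"]
        .agg(count="size", largest_volume="max", total_volume="sum")
        .reset_index()
    )
    if cells is not None and not cells.empty:
        base = cells[["cell_id", "group"]].drop_duplicates()
        per_cell = base.merge(per_cell, on=["cell_id", "group"], how="left")
        per_cell["count"] = per_cell["count"].fillna(0).astype(int)
    return per_cell


@dataclass(frozen=True)
class EcdfWithCI:
    """ECDF on the sorted sample with a pointwise bootstrap band."""

    grid: np.ndarray      # sorted sample values
    ecdf: np.ndarray      # F̂(grid), non-decreasing, ends at 1
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    ci_level: float
    seed: int


def ecdf_bootstrap(
    sample,
    n_boot: int = 1000,
    ci_level: float = 0.95,
    seed: int = 0,
) -> EcdfWithCI:
    """ECDF with a pointwise percentile bootstrap confidence band.

    The band at each grid point (the sorted sample values) is the
    percentile interval of the ECDFs of ``n_boot`` resamples drawn with
    replacement.  Pointwise, not simultaneous: joint coverage over the
    whole curve is below ``ci_level``.
    """
    sample = np.sort(np.asarray(sample, dtype=float))
    if sample.size < 5:
        raise ValueError("sample size must be >= 5")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile bands",
                      stacklevel=2)
    n = sample.size
    ecdf = stats.ecdf(sample).cdf.evaluate(sample)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, n))
    for b in range(n_boot):
        resample = np.sort(rng.choice(sample, size=n, replace=True))
        # F̂_b at each grid point = fraction of resample ≤ grid value
        boot[b] = np.searchsorted(resample, sample, side="right") / n
    alpha = 1.0 - ci_level
    lower, upper = np.quantile(boot, [alpha / 2, 1 - alpha / 2], axis=0)
    return EcdfWithCI(grid=sample, ecdf=ecdf,
                      lower=np.minimum(lower, ecdf),
                      upper=np.maximum(upper, ecdf),
                      n_boot=n_boot, ci_level=ci_level, seed=seed)


def dunn_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's post hoc pairwise z-tests on joint ranks, Bonferroni adjusted.

    For groups i, j with mean joint ranks R̄ᵢ, R̄ⱼ over N pooled values,
    z = (R̄ᵢ − R̄ⱼ) / sqrt[(N(N+1)/12 − T) (1/nᵢ + 1/nⱼ)] where
    T = Σ(t³ − t)/(12(N−1)) corrects for ties.  Two-sided p from the normal
    distribution; adjusted p = min(1, p × number of pairs).
    """
    names = list(samples)
    pooled = np.concatenate([np.asarray(samples[g], dtype=float) for g in names])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for g in names:
        n_g = len(samples[g])
        mean_ranks[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({
            "group1": g1, "group2": g2, "z": z,
            "p_raw": p, "p_adjusted": min(1.0, p * n_pairs),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class GroupComparison:
    """Report of a nonparametric comparison of ≥2 independent groups."""

    test: str                      # "mann-whitney" or "kruskal-wallis"
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None  # Dunn table for >= 3 groups
    groups: tuple[str, ...]
    warning: str | None = None


def compare_groups(samples: dict[str, np.ndarray]) -> GroupComparison:
    """Mann-Whitney (2 groups) or Kruskal-Wallis + Dunn-Bonferroni (≥3).

    All tests two-sided on independent samples; each group needs n ≥ 3.
    Degenerate all-tied input yields p = 1 with a warning in the report
    rather than an exception.
    """
    names = tuple(samples)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(samples[g], dtype=float) for g in names]
    for g, a in zip(names, arrays):
        if a.size < 3:
            raise ValueError(f"group {g!r} has n < 3")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return GroupComparison(
            test="mann-whitney" if len(names) == 2 else "kruskal-wallis",
            statistic=np.nan, p_value=1.0, pairwise=None, groups=names,
            warning="all values tied; tests are undefined",
        )
    if len(names) == 2:
        res = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return GroupComparison(test="mann-whitney",
                               statistic=float(res.statistic),
                               p_value=float(res.pvalue),
                               pairwise=None, groups=names)
    kw = stats.kruskal(*arrays)
    return GroupComparison(test="kruskal-wallis",
                           statistic=float(kw.statistic),
                           p_value=float(kw.pvalue),
                           pairwise=dunn_posthoc(samples),
                           groups=names)
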