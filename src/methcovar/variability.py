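"""Dispersion estimates and the differential-variability (DVP) scan.

A differentially variable position (DVP) is a site where Levene's test —
a one-way ANOVA on absolute deviations from each group's center — rejects
equality of dispersion across the sample types. The classical (mean-
centered) form is the default; the median-centered Brown-Forsythe variant
is available via ``center="median"``.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from methcovar.core_io import (
    BetaMatrix,
    SampleRecord,
    SampleType,
    ValidationError,
)

__all__ = [
    "ALPHA_DVP",
    "groupwise_sd",
    "levene_multi",
    "levene_multi_matrix",
    "run_dvp_scan",
    "sd_correlation",
]

#: Genome-wide significance threshold for the DVP scan (as published; it
#: intentionally differs from the DMP threshold).
ALPHA_DVP = 9.42e-8


def _type_indices(
    m: BetaMatrix, records: Sequence[SampleRecord]
) -> dict[SampleType, np.ndarray]:
    by_type: dict[SampleType, list[int]] = {}
    for r in records:
        if r.sample_id in m._sample_index:
            by_type.setdefault(r.sample_type, []).append(m.sample_index(r.sample_id))
    return {t: np.asarray(ix) for t, ix in by_type.items()}


def groupwise_sd(
    m: BetaMatrix, records: Sequence[SampleRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-site, per-sample-type sample SD (n-1 denominator).

    Returns ``(sd_table, summary)``: the sites x types SD table and a
    per-type summary with the mean SD and the SD of SDs. Types with fewer
    than two non-missing values at a site get a missing SD there.
    """
    by_type = _type_indices(m, records)
    sd_table = pd.DataFrame(index=pd.Index(m.site_ids, name="site_id"))
    for t in sorted(by_type, key=lambda t: t.value):
        sub = m.values[:, by_type[t]]
        n_ok = np.isfinite(sub).sum(axis=1)
        with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
            warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(sub, axis=1, ddof=1)
        sd[n_ok < 2] = np.nan
        sd_table[t.value] = sd
    summary = pd.DataFrame(
        {
            "mean_sd": sd_table.mean(axis=0),
            "sd_of_sd": sd_table.std(axis=0, ddof=1),
            "n_sites": sd_table.notna().sum(axis=0),
        }
    )
    summary.index.name = "sample_type"
    return sd_table, summary


def levene_multi(
    values: np.ndarray, groups: Sequence, center: str = "mean"
) -> tuple[float, float]:
    """k-group Levene test: one-way ANOVA F on absolute deviations from
    each group's center. Returns (W, p) with p from F(k-1, N-k).

    Degenerate inputs (all absolute deviations zero) return (nan, nan);
    groups of size < 2 raise.
    """
    if center not in ("mean", "median"):
        raise ValidationError(f"center must be mean or median, got {center!r}")
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ok = np.isfinite(values)
    values, groups = values[ok], groups[ok]
    samples = []
    for g in pd.unique(groups):
        v = values[groups == g]
        if v.size < 2:
            raise ValidationError(f"group {g!r} has fewer than 2 observations")
        samples.append(v)
    if len(samples) < 2:
        raise ValidationError("need at least 2 groups")
    devs = np.concatenate(
        [
            np.abs(v - (np.mean(v) if center == "mean" else np.median(v)))
            for v in samples
        ]
    )
    if np.ptp(devs) == 0:
        return np.nan, np.nan
    W, p = stats.levene(*samples, center=center)
    return float(W), float(p)


def levene_multi_matrix(
    values: np.ndarray,
    group_codes: np.ndarray,
    n_groups: int,
    center: str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized k-group Levene over a sites x samples array.

    ``group_codes`` are 0..n_groups-1 per sample; missing values are
    excluded per site. Returns per-site (W, p) arrays; degenerate sites
    (all deviations equal, or any group with < 2 usable values) get NaN.

    The arithmetic mirrors :func:`levene_multi` and is cross-checked
    against ``scipy.stats.levene`` in the test suite.
    """
    values = np.asarray(values, dtype=float)
    n_sites, n_samples = values.shape
    finite = np.isfinite(values)
    onehot = np.zeros((n_samples, n_groups))
    onehot[np.arange(n_samples), group_codes] = 1.0
    counts = finite @ onehot  # sites x groups
    filled = np.where(finite, values, 0.0)
    sums = filled @ onehot
    with np.errstate(invalid="ignore", divide="ignore"):
        if center == "mean":
            centers = sums / counts
        else:
            centers = np.empty((n_sites, n_groups))
            for g in range(n_groups):
                col = np.where(
                    finite[:, group_codes == g], values[:, group_codes == g], np.nan
                )
                centers[:, g] = np.nanmedian(col, axis=1)
    dev = np.abs(values - centers[:, group_codes])
    dev = np.where(finite, dev, 0.0)
    dev_sums = dev @ onehot
    dev_sumsq = (dev**2) @ onehot
    N = counts.sum(axis=1)
    k = (counts > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        group_means = dev_sums / counts
        grand_mean = dev_sums.sum(axis=1) / N
        ss_between = np.nansum(counts * (group_means - grand_mean[:, None]) ** 2, axis=1)
        ss_within = np.nansum(dev_sumsq - counts * group_means**2, axis=1)
        df1 = k - 1
        df2 = N - k
        W = (ss_between / df1) / (ss_within / df2)
    p = stats.f.sf(W, df1, df2)
    bad = (
        (counts < 2).any(axis=1)
        | (k < 2)
        | ~np.isfinite(W)
        | (np.abs(ss_within) <= 1e-300)
    )
    W = np.where(bad, np.nan, W)
    p = np.where(bad, np.nan, p)
    return W, p


def run_dvp_scan(
    m: BetaMatrix,
    records: Sequence[SampleRecord],
    alpha_dvp: float = ALPHA_DVP,
    center: str = "mean",
) -> tuple[pd.DataFrame, dict]:
    """Per-site k-group Levene scan across sample types.

    Returns (table, summary); the table carries per-type SDs, the Levene W
    statistic and p-value, and the significance flag at ``alpha_dvp``.
    """
    by_type = _type_indices(m, records)
    if len(by_type) < 2:
        raise ValidationError("need >= 2 sample types for a DVP scan")
    types = sorted(by_type, key=lambda t: t.value)
    group_codes = np.empty(m.n_samples, dtype=int)
    group_codes.fill(-1)
    for g, t in enumerate(types):
        group_codes[by_type[t]] = g
    used = group_codes >= 0
    W, p = levene_multi_matrix(
        m.values[:, used], group_codes[used], len(types), center=center
    )
    sd_table, _ = groupwise_sd(m, records)
    table = sd_table.add_prefix("sd_")
    table["levene_W"] = W
    table["levene_p"] = p
    table["significant"] = pd.Series(p, index=table.index) < alpha_dvp
    n_tested = int(np.isfinite(p).sum())
    summary = {
        "n_sites": m.n_sites,
        "n_tested": n_tested,
        "n_significant": int(table["significant"].sum()),
        "alpha_dvp": alpha_dvp,
        "center": center,
    }
    return table, summary


def sd_correlation(sd_table: pd.DataFrame, min_sites: int = 3) -> pd.DataFrame:
    """Pairwise Pearson correlation of per-site SDs between sample types.

    Pairwise-complete over sites; symmetric with unit diagonal; entries
    with fewer than ``min_sites`` shared sites or a constant SD vector are
    missing.
    """
    cols = list(sd_table.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pair = sd_table[[a, b]].dropna()
            if (
                len(pair) < min_sites
                or np.ptp(pair[a].to_numpy()) == 0
                or np.ptp(pair[b].to_numpy()) == 0
            ):
                r = np.nan
            else:
                r = float(np.corrcoef(pair[a], pair[b])[0, 1])
            out.loc[a, b] = out.loc[b, a] = r
    return out
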