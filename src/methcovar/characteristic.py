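"""Characteristic scores: which single cell type drives a site's variance.

Procedure: restrict to the five purified cell types, remove each type's
mean per site (residuals of DNAm regressed on cell type), then for every
site and cell type run a one-sided two-group Levene test of that type's
residual dispersion against the pooled other four, upper tail. A site is
*characteristic of* a cell type when exactly one of the five tests passes
the genome-wide threshold. Characteristic sites annotate EWAS hits, and
per-trait enrichment is summarized as observed/expected fold changes
against the genome-wide composition of characteristic sites.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from methcovar.core_io import (
    CONSTITUENT_TYPES,
    BetaMatrix,
    EwasCatalogRecord,
    SampleRecord,
    SampleType,
    ValidationError,
)

__all__ = [
    "ALPHA_CHAR",
    "residualize_by_celltype",
    "one_sided_levene",
    "compute_characteristic_scores",
    "annotate_ewas",
    "enrichment_fold_change",
]

#: Genome-wide threshold for calling a site characteristic of a cell type.
ALPHA_CHAR = 9e-8

EWAS_P_THRESHOLD = 1e-7
MIN_TRAIT_SITES = 5


def _constituent_indices(
    m: BetaMatrix, records: Sequence[SampleRecord]
) -> dict[SampleType, np.ndarray]:
    by_type: dict[SampleType, list[int]] = {c: [] for c in CONSTITUENT_TYPES}
    for r in records:
        if r.sample_type in by_type and r.sample_id in m._sample_index:
            by_type[r.sample_type].append(m.sample_index(r.sample_id))
    missing = [c.value for c, ix in by_type.items() if not ix]
    if missing:
        raise ValidationError(f"constituent cell types absent: {missing}")
    return {c: np.asarray(ix) for c, ix in by_type.items()}


def residualize_by_celltype(
    m: BetaMatrix, records: Sequence[SampleRecord]
) -> tuple[np.ndarray, np.ndarray]:
    """Mean-center each site within cell type over the five constituents.

    Equivalent to taking residuals from a per-site regression of beta on
    cell type. Returns ``(residuals, type_codes)`` where residuals is a
    sites x (constituent samples) array ordered monocytes, granulocytes,
    CD4+ T, CD8+ T, B cells, and type_codes gives the 0-4 constituent
    index per column.
    """
    by_type = _constituent_indices(m, records)
    blocks = []
    codes = []
    for g, c in enumerate(CONSTITUENT_TYPES):
        sub = m.values[:, by_type[c]]
        with np.errstate(invalid="ignore"):
            centered = sub - np.nanmean(sub, axis=1, keepdims=True)
        blocks.append(centered)
        codes.extend([g] * sub.shape[1])
    return np.concatenate(blocks, axis=1), np.asarray(codes)


def one_sided_levene(
    target: np.ndarray, others: np.ndarray, center: str = "mean"
) -> tuple[float, float]:
    """One-sided two-group Levene: is the target group *more* dispersed?

    Reduces to a pooled-variance t-test on absolute deviations from each
    group's own center: returns the signed t (positive when the target's
    mean absolute deviation exceeds the pooled others') and the upper-tail
    p with ``n_target + n_others - 2`` df. Degenerate dispersion (all
    deviations equal) yields (nan, nan).
    """
    if center not in ("mean", "median"):
        raise ValidationError(f"center must be mean or median, got {center!r}")
    target = np.asarray(target, dtype=float)
    others = np.asarray(others, dtype=float)
    target = target[np.isfinite(target)]
    others = others[np.isfinite(others)]
    if target.size < 2 or others.size < 2:
        raise ValidationError("both groups need >= 2 observations")
    loc = np.mean if center == "mean" else np.median
    dev_t = np.abs(target - loc(target))
    dev_o = np.abs(others - loc(others))
    if np.ptp(np.concatenate([dev_t, dev_o])) == 0:
        return np.nan, np.nan
    res = stats.ttest_ind(dev_t, dev_o, equal_var=True, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def _one_sided_levene_matrix(
    residuals: np.ndarray, codes: np.ndarray, center: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized target-vs-pooled-rest one-sided Levene for all five
    constituents at once.

    Returns (stat, p) arrays of shape sites x 5. Mirrors
    :func:`one_sided_levene`; cross-checked against it in the tests.
    """
    n_sites = residuals.shape[0]
    k = len(CONSTITUENT_TYPES)
    stat = np.full((n_sites, k), np.nan)
    pval = np.full((n_sites, k), np.nan)
    finite = np.isfinite(residuals)
    for g in range(k):
        t_mask = codes == g
        o_mask = ~t_mask
        t_vals = residuals[:, t_mask]
        o_vals = residuals[:, o_mask]
        t_fin = finite[:, t_mask]
        o_fin = finite[:, o_mask]
        n1 = t_fin.sum(axis=1).astype(float)
        n2 = o_fin.sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            if center == "mean":
                c1 = np.nansum(np.where(t_fin, t_vals, 0.0), axis=1) / n1
                c2 = np.nansum(np.where(o_fin, o_vals, 0.0), axis=1) / n2
            else:
                c1 = np.nanmedian(np.where(t_fin, t_vals, np.nan), axis=1)
                c2 = np.nanmedian(np.where(o_fin, o_vals, np.nan), axis=1)
            d1 = np.where(t_fin, np.abs(t_vals - c1[:, None]), np.nan)
            d2 = np.where(o_fin, np.abs(o_vals - c2[:, None]), np.nan)
            m1 = np.nanmean(d1, axis=1)
            m2 = np.nanmean(d2, axis=1)
            v1 = np.nanvar(d1, axis=1, ddof=1)
            v2 = np.nanvar(d2, axis=1, ddof=1)
            df = n1 + n2 - 2.0
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
            se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
            t = (m1 - m2) / se
        p = stats.t.sf(t, df)
        bad = (n1 < 2) | (n2 < 2) | ~np.isfinite(t)
        stat[:, g] = np.where(bad, np.nan, t)
        pval[:, g] = np.where(bad, np.nan, p)
    return stat, pval


def compute_characteristic_scores(
    m: BetaMatrix,
    records: Sequence[SampleRecord],
    alpha_char: float = ALPHA_CHAR,
    center: str = "mean",
) -> pd.DataFrame:
    """Per-site characteristic scores for the five constituents.

    Returns a table with ``stat_<type>`` and ``p_<type>`` per constituent,
    ``n_passing`` (tests with p < alpha) and ``characteristic_of`` (set
    when exactly one passes). Degenerate sites carry missing entries.
    """
    residuals, codes = residualize_by_celltype(m, records)
    stat, pval = _one_sided_levene_matrix(residuals, codes, center=center)
    table = pd.DataFrame(index=pd.Index(m.site_ids, name="site_id"))
    for g, c in enumerate(CONSTITUENT_TYPES):
        table[f"stat_{c.value}"] = stat[:, g]
        table[f"p_{c.value}"] = pval[:, g]
    passing = np.where(np.isfinite(pval), pval < alpha_char, False)
    n_passing = passing.sum(axis=1)
    first = np.argmax(passing, axis=1)
    labels = np.asarray([c.value for c in CONSTITUENT_TYPES], dtype=object)
    table["n_passing"] = n_passing
    table["characteristic_of"] = np.where(n_passing == 1, labels[first], "")
    return table


def annotate_ewas(
    hits: Sequence[EwasCatalogRecord],
    scores: pd.DataFrame,
    p_threshold: float = EWAS_P_THRESHOLD,
    tissue_filter: Optional[str] = "whole blood",
) -> pd.DataFrame:
    """Join EWAS catalog hits onto characteristic scores.

    Hits are filtered to ``p_value < p_threshold`` and (case-insensitive)
    tissue match, then joined on site id; hits absent from the score table
    are flagged ``not_assessed``.
    """
    rows = []
    for h in hits:
        if h.p_value >= p_threshold:
            continue
        if tissue_filter is not None and h.tissue.strip().lower() != tissue_filter.strip().lower():
            continue
        assessed = h.site_id in scores.index
        char_of = (
            str(scores.at[h.site_id, "characteristic_of"]) if assessed else ""
        )
        rows.append(
            {
                "site_id": h.site_id,
                "trait": h.trait,
                "p_value": h.p_value,
                "tissue": h.tissue,
                "study_id": h.study_id,
                "assessed": assessed,
                "characteristic_of": char_of,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "site_id",
            "trait",
            "p_value",
            "tissue",
            "study_id",
            "assessed",
            "characteristic_of",
        ],
    )


def global_characteristic_shares(scores: pd.DataFrame) -> dict[str, float]:
    """Genome-wide composition of characteristic sites per cell type."""
    counts = (
        scores.loc[scores["characteristic_of"] != "", "characteristic_of"]
        .value_counts()
        .to_dict()
    )
    total = sum(counts.values())
    if total == 0:
        raise ValidationError("no characteristic sites; shares undefined")
    return {c.value: counts.get(c.value, 0) / total for c in CONSTITUENT_TYPES}


def enrichment_fold_change(
    annotated: pd.DataFrame,
    global_shares: dict[str, float],
    min_sites: int = MIN_TRAIT_SITES,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-trait, per-cell-type observed/expected fold changes.

    Expected count for cell type c in a trait = trait's characteristic-hit
    total x the genome-wide share of c. Traits with fewer than
    ``min_sites`` characteristic hits are skipped (returned separately);
    cells with zero expected are undefined (NaN).
    """
    total_share = sum(global_shares.values())
    if abs(total_share - 1.0) > 1e-9:
        raise ValidationError(f"global shares sum to {total_share}, expected 1")
    char_hits = annotated[annotated["characteristic_of"] != ""]
    rows = []
    skipped: list[str] = []
    for trait, grp in char_hits.groupby("trait"):
        n_total = len(grp)
        if n_total < min_sites:
            skipped.append(str(trait))
            continue
        obs = grp["characteristic_of"].value_counts().to_dict()
        row: dict = {"trait": trait, "n_characteristic": n_total}
        for cell, share in global_shares.items():
            expected = n_total * share
            row[f"fc_{cell}"] = obs.get(cell, 0) / expected if expected > 0 else np.nan
        rows.append(row)
    columns = ["trait", "n_characteristic"] + [f"fc_{c}" for c in global_shares]
    table = pd.DataFrame(rows, columns=columns).set_index("trait")
    return table, sorted(skipped)
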