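"""Per-site covariation between whole blood and its constituent cell types.

For each site the single-type statistic is the squared Pearson correlation
between whole-blood and cell-type beta values over matched individuals,
times 100 ("% variance explained"); the combined statistic is 100 * R^2
from an OLS fit of whole blood on all five constituents jointly. By the
nested-model property the combined value dominates every single-type value
on complete cases.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from methcovar.core_io import (
    CONSTITUENT_TYPES,
    AnnotationTable,
    BetaMatrix,
    SampleRecord,
    SampleType,
    ValidationError,
    align_by_individual,
)

__all__ = [
    "pairwise_variance_explained",
    "pairwise_variance_explained_matrix",
    "combined_variance_explained",
    "combined_variance_explained_matrix",
    "run_covariation_scan",
    "stratified_summary",
    "count_single_dominant",
]

DOMINANT_THRESHOLD_PCT = 20.0
MIN_PAIRS = 3
# joint model needs 5 slopes + intercept + 1 residual df
MIN_JOINT_N = 7


def pairwise_variance_explained(
    wb: np.ndarray, other: np.ndarray
) -> tuple[float, float]:
    """Pearson r and 100*r^2 between two matched per-individual vectors.

    Pairwise-complete; returns (nan, nan) with fewer than 3 complete pairs
    or a constant vector.
    """
    wb = np.asarray(wb, dtype=float)
    other = np.asarray(other, dtype=float)
    ok = np.isfinite(wb) & np.isfinite(other)
    if ok.sum() < MIN_PAIRS:
        return np.nan, np.nan
    a, b = wb[ok], other[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan, np.nan
    r = float(np.corrcoef(a, b)[0, 1])
    return r, 100.0 * r * r


def pairwise_variance_explained_matrix(
    wb: np.ndarray, other: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site Pearson r over sites x individuals arrays.

    Returns (r, pct, n_pairs) per site; pairwise-complete per site.
    """
    wb = np.asarray(wb, dtype=float)
    other = np.asarray(other, dtype=float)
    ok = np.isfinite(wb) & np.isfinite(other)
    a = np.where(ok, wb, 0.0)
    b = np.where(ok, other, 0.0)
    n = ok.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = a.sum(axis=1) / n
        mean_b = b.sum(axis=1) / n
        ca = np.where(ok, wb - mean_a[:, None], 0.0)
        cb = np.where(ok, other - mean_b[:, None], 0.0)
        cov = (ca * cb).sum(axis=1)
        var_a = (ca**2).sum(axis=1)
        var_b = (cb**2).sum(axis=1)
        r = cov / np.sqrt(var_a * var_b)
    bad = (n < MIN_PAIRS) | (var_a <= 0) | (var_b <= 0)
    r = np.where(bad, np.nan, r)
    r = np.clip(r, -1.0, 1.0)
    return r, 100.0 * r**2, n


def combined_variance_explained(
    wb: np.ndarray, constituents: np.ndarray
) -> tuple[float, bool]:
    """100 * R^2 of OLS with intercept: whole blood ~ five constituents.

    ``constituents`` is (5, n_individuals). Complete cases across all six
    vectors; with a rank-deficient design the collinear predictors are
    effectively dropped (minimum-norm least squares) and the fit is
    flagged. Returns (pct, collinear_flag); (nan, False) when fewer than
    7 complete cases or constant whole blood.
    """
    wb = np.asarray(wb, dtype=float)
    Xc = np.asarray(constituents, dtype=float)
    ok = np.isfinite(wb) & np.isfinite(Xc).all(axis=0)
    if ok.sum() < MIN_JOINT_N:
        return np.nan, False
    y = wb[ok]
    X = np.column_stack([np.ones(ok.sum()), Xc[:, ok].T])
    if np.ptp(y) == 0:
        return np.nan, False
    rank = np.linalg.matrix_rank(X)
    coef, _res, _rank, _sv = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return 100.0 * max(r2, 0.0), bool(rank < X.shape[1])


def combined_variance_explained_matrix(
    wb: np.ndarray, constituents: dict[SampleType, np.ndarray]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site joint R^2 over aligned sites x individuals arrays.

    Returns (pct, collinear_flag) arrays. Sites with any missing value in
    the six aligned vectors are fit on their complete cases.
    """
    cells = [np.asarray(constituents[c], dtype=float) for c in CONSTITUENT_TYPES]
    n_sites = wb.shape[0]
    pct = np.full(n_sites, np.nan)
    flag = np.zeros(n_sites, dtype=bool)
    for s in range(n_sites):
        X = np.stack([c[s] for c in cells])
        pct[s], flag[s] = combined_variance_explained(wb[s], X)
    return pct, flag


def run_covariation_scan(
    m: BetaMatrix,
    records: Sequence[SampleRecord],
    comparison_types: Optional[Sequence[SampleType]] = None,
    reference: SampleType = SampleType.WHOLE_BLOOD,
) -> tuple[pd.DataFrame, dict]:
    """Full covariation scan: per-type r/pct plus the joint model.

    ``comparison_types`` defaults to every non-reference type present in
    the sheet. The joint five-constituent model is fit whenever all five
    constituents are present. Returns (per-site table, summary).
    """
    present = {r.sample_type for r in records if r.sample_id in m._sample_index}
    if reference not in present:
        raise ValidationError(f"reference {reference.value} absent from matrix")
    if comparison_types is None:
        comparison_types = sorted(
            (t for t in present if t is not reference), key=lambda t: t.value
        )
    table = pd.DataFrame(index=pd.Index(m.site_ids, name="site_id"))
    aligned: dict[SampleType, tuple[np.ndarray, np.ndarray, list[str]]] = {}
    for t in comparison_types:
        wb_vals, other_vals, individuals = align_by_individual(m, records, reference, t)
        aligned[t] = (wb_vals, other_vals, individuals)
        r, pct, n = pairwise_variance_explained_matrix(wb_vals, other_vals)
        table[f"r_{t.value}"] = r
        table[f"pct_{t.value}"] = pct
        table[f"n_{t.value}"] = n.astype(int)

    have_all = all(c in aligned for c in CONSTITUENT_TYPES)
    if have_all:
        shared = sorted(
            set.intersection(*(set(aligned[c][2]) for c in CONSTITUENT_TYPES))
        )
        wb_idx = {ind: k for k, ind in enumerate(aligned[CONSTITUENT_TYPES[0]][2])}
        wb_vals = aligned[CONSTITUENT_TYPES[0]][0][:, [wb_idx[i] for i in shared]]
        cons = {}
        for c in CONSTITUENT_TYPES:
            _wb, vals, inds = aligned[c]
            pos = {ind: k for k, ind in enumerate(inds)}
            cons[c] = vals[:, [pos[i] for i in shared]]
        pct, flag = combined_variance_explained_matrix(wb_vals, cons)
        table["combined_r2_pct"] = pct
        table["combined_collinear"] = flag
        table["n_joint"] = len(shared)

    dominant, hist = count_single_dominant(table)
    table["dominant_single"] = dominant

    summary: dict = {"per_type": {}, "n_sites": m.n_sites}
    for t in comparison_types:
        col = table[f"pct_{t.value}"]
        summary["per_type"][t.value] = {
            "mean_pct": float(col.mean()),
            "sd_pct": float(col.std(ddof=1)),
            "n_over_80": int((col > 80).sum()),
            "n_assessed": int(col.notna().sum()),
        }
    if have_all:
        comb = table["combined_r2_pct"]
        summary["combined"] = {
            "mean_pct": float(comb.mean()),
            "sd_pct": float(comb.std(ddof=1)),
            "n_over_80": int((comb > 80).sum()),
            "n_assessed": int(comb.notna().sum()),
        }
    summary["dominant_single"] = hist
    return table, summary


def count_single_dominant(
    table: pd.DataFrame, threshold_pct: float = DOMINANT_THRESHOLD_PCT
) -> tuple[pd.Series, dict]:
    """Assign each site the constituent whose variance-explained exceeds
    the threshold when *exactly one* does.

    Returns (per-site assignment, histogram report). The report also
    carries the count of sites with at least one constituent above the
    threshold, since the exactly-one convention is not the only reading.
    """
    cols = [
        (c, f"pct_{c.value}") for c in CONSTITUENT_TYPES if f"pct_{c.value}" in table.columns
    ]
    if not cols:
        return pd.Series("", index=table.index, dtype=object), {}
    mat = np.column_stack([table[col].to_numpy() for _c, col in cols])
    over = np.where(np.isfinite(mat), mat > threshold_pct, False)
    n_over = over.sum(axis=1)
    first = np.argmax(over, axis=1)
    labels = np.asarray([c.value for c, _col in cols], dtype=object)
    assignment = np.where(n_over == 1, labels[first], "")
    hist = {int(k): int(v) for k, v in zip(*np.unique(n_over, return_counts=True))}
    report = {
        "threshold_pct": threshold_pct,
        "n_exactly_one": int((n_over == 1).sum()),
        "n_at_least_one": int((n_over >= 1).sum()),
        "histogram_n_types_over": hist,
        "per_type_exactly_one": {
            label: int(np.sum((n_over == 1) & (assignment == label)))
            for label in labels
        },
    }
    return pd.Series(assignment, index=table.index, name="dominant_single"), report


def stratified_summary(
    table: pd.DataFrame,
    site_classes: Optional[pd.DataFrame] = None,
    annotations: Optional[AnnotationTable] = None,
    strata: Optional[dict[str, pd.Series]] = None,
    low_n: int = 10,
) -> pd.DataFrame:
    """Mean/SD of per-type and combined variance-explained per stratum.

    Built-in strata (when inputs provide them): methylation bands, the
    ``0.4-0.5`` fine band, the variable flag, ``A > 0.8``, ``E > 0.8`` and
    ``has_mqtl``. Extra boolean masks can be passed via ``strata``. Strata
    with fewer than ``low_n`` sites are flagged.
    """
    masks: dict[str, pd.Series] = {"all_sites": pd.Series(True, index=table.index)}
    if site_classes is not None:
        sc = site_classes.reindex(table.index)
        for band in ("low", "intermediate", "high"):
            masks[f"band_{band}"] = sc["band"] == band
        masks["fine_band_0.4-0.5"] = sc["fine_band"] == "0.4-0.5"
        masks["variable"] = sc["variable"] == 1.0
        masks["not_variable"] = sc["variable"] == 0.0
    if annotations is not None:
        ann = annotations.frame.reindex(table.index)
        if "A" in ann.columns:
            masks["A>0.8"] = ann["A"] > 0.8
        if "E" in ann.columns:
            masks["E>0.8"] = ann["E"] > 0.8
        if "has_mqtl" in ann.columns:
            masks["has_mqtl"] = ann["has_mqtl"].fillna(False).astype(bool)
    if strata:
        for name, mask in strata.items():
            if name not in table.columns and not isinstance(mask, pd.Series):
                raise ValidationError(f"stratum {name!r} must be a boolean Series")
            masks[name] = mask.reindex(table.index).fillna(False)

    value_cols = [c for c in table.columns if c.startswith("pct_")]
    if "combined_r2_pct" in table.columns:
        value_cols.append("combined_r2_pct")
    rows = []
    for name, mask in masks.items():
        mask = mask.fillna(False).astype(bool)
        sub = table.loc[mask, value_cols]
        row: dict = {"stratum": name, "n_sites": int(mask.sum()), "low_n": bool(mask.sum() < low_n)}
        for col in value_cols:
            row[f"mean_{col}"] = float(sub[col].mean()) if len(sub) else np.nan
            row[f"sd_{col}"] = float(sub[col].std(ddof=1)) if len(sub) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")
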