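"""Descriptive stages: beta-band summaries, variable-site flags,
top-variable-site selection, clustering order and principal components."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from methcovar.core_io import (
    BetaMatrix,
    SampleRecord,
    SampleType,
    ValidationError,
)

__all__ = [
    "summarize_beta_bands",
    "classify_variable",
    "variable_flags",
    "site_level_classes",
    "select_top_variable_sites",
    "hierarchical_cluster_order",
    "principal_components",
]

# Band boundaries: low is strictly < 0.20 and high strictly > 0.80, so the
# intermediate band is the closed interval [0.20, 0.80].
LOW_CUT = 0.20
HIGH_CUT = 0.80

#: Sites are "variable" when the spread of the middle 80% of samples
#: (Q90 - Q10) exceeds this, in beta units.
VARIABLE_RANGE_CUT = 0.05
_MIN_VARIABLE_N = 10


def _group_sample_indices(
    m: BetaMatrix, records: Sequence[SampleRecord], group: set[SampleType]
) -> list[int]:
    idx = [
        m.sample_index(r.sample_id)
        for r in records
        if r.sample_type in group and r.sample_id in m._sample_index
    ]
    return idx


def summarize_beta_bands(
    m: BetaMatrix,
    records: Sequence[SampleRecord],
    group: set[SampleType] | Sequence[SampleType],
) -> pd.DataFrame:
    """Count sites per mean-methylation band over one group of sample types.

    Returns a frame indexed low/intermediate/high with ``count`` and
    ``fraction`` columns; means with no data are excluded from both.
    """
    group = set(group)
    if not group:
        raise ValidationError("empty sample-type group")
    idx = _group_sample_indices(m, records, group)
    if not idx:
        raise ValidationError("no samples of the requested types in the matrix")
    with np.errstate(invalid="ignore"):
        means = np.nanmean(m.values[:, idx], axis=1)
    ok = np.isfinite(means)
    low = int(np.sum(ok & (means < LOW_CUT)))
    high = int(np.sum(ok & (means > HIGH_CUT)))
    inter = int(ok.sum()) - low - high
    total = max(int(ok.sum()), 1)
    frame = pd.DataFrame(
        {"count": [low, inter, high]},
        index=pd.Index(["low", "intermediate", "high"], name="band"),
    )
    frame["fraction"] = frame["count"] / total
    return frame


def band_of(mean_beta: float) -> str:
    if not np.isfinite(mean_beta):
        return "missing"
    if mean_beta < LOW_CUT:
        return "low"
    if mean_beta > HIGH_CUT:
        return "high"
    return "intermediate"


def classify_variable(values: np.ndarray) -> Optional[bool]:
    """Flag a site as variable when Q90 - Q10 of its samples exceeds 5%.

    Quantiles use linear interpolation. Returns None (missing flag) with
    fewer than 10 non-missing values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < _MIN_VARIABLE_N:
        return None
    q10, q90 = np.quantile(values, [0.10, 0.90])
    return bool(q90 - q10 > VARIABLE_RANGE_CUT)


def variable_flags(values: np.ndarray) -> np.ndarray:
    """Vectorized :func:`classify_variable` over a sites x samples array.

    Returns a float array: 1.0 variable, 0.0 not, NaN undefined.
    """
    values = np.asarray(values, dtype=float)
    n_ok = np.isfinite(values).sum(axis=1)
    with np.errstate(invalid="ignore"):
        q = np.nanquantile(values, [0.10, 0.90], axis=1)
    out = np.where(q[1] - q[0] > VARIABLE_RANGE_CUT, 1.0, 0.0)
    out[n_ok < _MIN_VARIABLE_N] = np.nan
    return out


def site_level_classes(
    m: BetaMatrix,
    records: Sequence[SampleRecord],
    band_reference: SampleType = SampleType.WHOLE_BLOOD,
) -> pd.DataFrame:
    """Per-site banding and variability flags.

    Bands come from the mean over ``band_reference`` samples; the variable
    flag uses the same samples. ``fine_band`` is the decile bin of that
    mean (e.g. "0.4-0.5"), supporting mid-band stratifications.
    """
    idx = _group_sample_indices(m, records, {band_reference})
    if not idx:
        raise ValidationError(f"no {band_reference.value} samples in matrix")
    sub = m.values[:, idx]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(sub, axis=1)
    deciles = np.clip(np.floor(means * 10), 0, 9)
    fine = [
        f"{d / 10:.1f}-{(d + 1) / 10:.1f}" if np.isfinite(mu) else ""
        for d, mu in zip(deciles, means)
    ]
    return pd.DataFrame(
        {
            "mean_beta": means,
            "band": [band_of(mu) for mu in means],
            "fine_band": fine,
            "variable": variable_flags(sub),
        },
        index=pd.Index(m.site_ids, name="site_id"),
    )


def select_top_variable_sites(m: BetaMatrix, k: int) -> list[str]:
    """Site ids of the k most variable sites (SD across all samples,
    descending; ties broken by lexicographic site id)."""
    if k <= 0:
        raise ValidationError(f"k must be positive, got {k}")
    if k > m.n_sites:
        raise ValidationError(f"k={k} exceeds {m.n_sites} sites")
    with np.errstate(invalid="ignore", divide="ignore"):
        sds = np.nanstd(m.values, axis=1, ddof=1)
    sds = np.where(np.isfinite(sds), sds, -np.inf)
    order = sorted(range(m.n_sites), key=lambda i: (-sds[i], m.site_ids[i]))
    return [m.site_ids[i] for i in order[:k]]


def hierarchical_cluster_order(
    m: BetaMatrix, method: str = "average", metric: str = "euclidean"
) -> tuple[list[str], list[str]]:
    """Deterministic leaf orders (rows = sites, columns = samples) from
    hierarchical clustering of complete-case data."""
    if m.n_sites < 1 or m.n_samples < 2:
        raise ValidationError("need at least 1 site and 2 samples to cluster")
    values = m.values
    complete = np.isfinite(values).all(axis=1)
    values = values[complete]
    kept_sites = [s for s, ok in zip(m.site_ids, complete) if ok]
    if values.shape[0] == 0:
        raise ValidationError("no complete-case sites to cluster")

    def _order(matrix: np.ndarray, labels: list[str]) -> list[str]:
        if len(labels) == 1:
            return list(labels)
        dist = pdist(matrix, metric=metric)
        if dist.size and np.all(dist == 0):
            raise ValidationError("degenerate (all-constant) distance matrix")
        link = linkage(dist, method=method)
        return [labels[i] for i in leaves_list(link)]

    row_order = _order(values, kept_sites)
    col_order = _order(values.T, list(m.sample_ids))
    return row_order, col_order


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray
    loadings: pd.DataFrame  # sites x components


def principal_components(m: BetaMatrix, n_components: int) -> PcaResult:
    """SVD principal components of the centered, complete-case matrix.

    Samples are observations. Sign convention: each loading vector sums to
    a non-negative value, making scores deterministic under permutation of
    samples.
    """
    if m.n_samples < 2:
        raise ValidationError("need >= 2 samples for PCA")
    if n_components > m.n_samples:
        raise ValidationError(
            f"requested {n_components} components from {m.n_samples} samples"
        )
    complete = np.isfinite(m.values).all(axis=1)
    values = m.values[complete]
    if values.shape[0] == 0:
        raise ValidationError("no complete-case sites for PCA")
    kept_sites = [s for s, ok in zip(m.site_ids, complete) if ok]
    X = values.T  # samples x sites
    X = X - X.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    total_var = float(np.sum(s**2))
    k = n_components
    signs = np.where(vt[:k].sum(axis=1) >= 0, 1.0, -1.0)
    scores = u[:, :k] * s[:k] * signs
    loadings = (vt[:k].T) * signs
    frac = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=list(m.sample_ids), columns=comp_names),
        variance_fraction=frac,
        loadings=pd.DataFrame(loadings, index=kept_sites, columns=comp_names),
    )
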