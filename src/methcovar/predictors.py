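"""Coefficient-based DNAm predictors (epigenetic age, smoking score) and
within-individual cross-sample-type comparisons of their outputs."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from methcovar.core_io import (
    BetaMatrix,
    CoefficientModel,
    SampleRecord,
    SampleType,
    ValidationError,
)
from methcovar.mixedlm import NestedInterceptModel

__all__ = [
    "PredictionResult",
    "apply_linear_predictor",
    "predict_all_samples",
    "horvath_forward_transform",
    "horvath_inverse_transform",
    "compare_to_reference",
    "per_individual_range",
]


@dataclass
class PredictionResult:
    sample_id: str
    model_id: str
    raw_linear: float
    value: float
    n_missing_probes: int
    missing_fraction: float


def horvath_inverse_transform(x: float, adult_age: float = 20.0) -> float:
    """Map the clock's transformed scale back to age in years.

    ``age = (adult_age + 1) * exp(x) - 1`` for x <= 0 and
    ``age = (adult_age + 1) * x + adult_age`` for x > 0; continuous and
    strictly increasing, with x = 0 mapping to ``adult_age``.
    """
    x = float(x)
    if not np.isfinite(x):
        raise ValidationError("non-finite predictor value")
    if x <= 0:
        return (adult_age + 1.0) * float(np.exp(x)) - 1.0
    return (adult_age + 1.0) * x + adult_age


def horvath_forward_transform(age: float, adult_age: float = 20.0) -> float:
    """Inverse of :func:`horvath_inverse_transform` (age -> clock scale)."""
    age = float(age)
    if age <= adult_age:
        return float(np.log(age + 1.0) - np.log(adult_age + 1.0))
    return (age - adult_age) / (adult_age + 1.0)


def apply_linear_predictor(
    betas: dict[str, float] | pd.Series,
    model: CoefficientModel,
    max_missing: float = 0.2,
    sample_id: str = "sample",
) -> PredictionResult:
    """Score one sample: intercept + sum of weight x beta over model probes.

    Probes missing from the sample (or with missing values) contribute
    zero and are counted; the call is refused when the missing fraction
    exceeds ``max_missing``.
    """
    if isinstance(betas, pd.Series):
        betas = betas.to_dict()
    total = len(model.weights)
    raw = model.intercept
    n_missing = 0
    for probe, weight in model.weights.items():
        v = betas.get(probe)
        if v is None or not np.isfinite(v):
            n_missing += 1
            continue
        raw += weight * float(v)
    missing_fraction = n_missing / total
    if n_missing == total:
        raise ValidationError(
            f"sample {sample_id!r}: no overlap with model {model.model_id!r} probes"
        )
    if missing_fraction > max_missing:
        raise ValidationError(
            f"sample {sample_id!r}: {n_missing}/{total} model probes missing "
            f"(fraction {missing_fraction:.2f} > {max_missing})"
        )
    if model.transform_id == "horvath_age":
        value = horvath_inverse_transform(raw, adult_age=model.adult_age)
    else:
        value = raw
    return PredictionResult(
        sample_id=sample_id,
        model_id=model.model_id,
        raw_linear=raw,
        value=value,
        n_missing_probes=n_missing,
        missing_fraction=missing_fraction,
    )


def predict_all_samples(
    m: BetaMatrix, model: CoefficientModel, max_missing: float = 0.2
) -> pd.DataFrame:
    """Apply a predictor to every sample of a beta matrix."""
    row_of = {p: m.site_index(p) for p in model.weights if p in m._site_index}
    rows = []
    for j, sample_id in enumerate(m.sample_ids):
        betas = {
            probe: m.values[row_of[probe], j] if probe in row_of else np.nan
            for probe in model.weights
        }
        res = apply_linear_predictor(
            betas, model, max_missing=max_missing, sample_id=sample_id
        )
        rows.append(
            {
                "sample_id": res.sample_id,
                "model_id": res.model_id,
                "raw_linear": res.raw_linear,
                "value": res.value,
                "n_missing_probes": res.n_missing_probes,
                "missing_fraction": res.missing_fraction,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def compare_to_reference(
    predictions: pd.DataFrame,
    records: Sequence[SampleRecord],
    reference: SampleType = SampleType.WHOLE_BLOOD,
    ddf: str = "satterthwaite",
) -> pd.DataFrame:
    """Mixed-model contrasts of predictions per sample type vs reference.

    Model: value ~ sample_type with random intercepts for family and
    individual nested in family (the DMP engine's model, applied to one
    prediction per sample). Returns a per-type table of mean differences,
    t statistics and p-values.
    """
    rec_of = {r.sample_id: r for r in records}
    missing = [s for s in predictions.index if s not in rec_of]
    if missing:
        raise ValidationError(f"predictions without sheet records: {missing[:5]}")
    recs = [rec_of[s] for s in predictions.index]
    types = sorted({r.sample_type for r in recs}, key=lambda t: t.value)
    if reference not in types:
        raise ValidationError(f"reference {reference.value} has no predictions")
    if len(types) < 2:
        raise ValidationError("only one sample type; nothing to compare")
    others = [t for t in types if t is not reference]
    X = np.ones((len(recs), 1 + len(others)))
    for j, t in enumerate(others):
        X[:, 1 + j] = np.asarray([r.sample_type is t for r in recs], dtype=float)
    model = NestedInterceptModel(
        X,
        [r.family_id for r in recs],
        [r.individual_id for r in recs],
    )
    y = predictions["value"].to_numpy(dtype=float)
    fit = model.fit(y)
    cache = model.satterthwaite_cache(fit, y) if ddf == "satterthwaite" else None
    rows = []
    for j, t in enumerate(others):
        c = np.zeros(X.shape[1])
        c[1 + j] = 1.0
        est, tval, df, p = model.contrast_test(fit, c, y, ddf=ddf, cache=cache)
        rows.append(
            {
                "sample_type": t.value,
                "mean_difference": est,
                "t_stat": tval,
                "df": df,
                "p_value": p,
            }
        )
    return pd.DataFrame(rows).set_index("sample_type")


def per_individual_range(
    predictions: pd.DataFrame, records: Sequence[SampleRecord]
) -> tuple[pd.DataFrame, dict]:
    """Within-individual range of predictions across sample types.

    Returns (per-individual table, summary). Individuals with a single
    predicted sample type are excluded and counted. The summary also
    carries per-sample-type between-individual ranges.
    """
    rec_of = {r.sample_id: r for r in records}
    missing = [s for s in predictions.index if s not in rec_of]
    if missing:
        raise ValidationError(f"predictions without sheet records: {missing[:5]}")
    frame = predictions.copy()
    frame["individual_id"] = [rec_of[s].individual_id for s in frame.index]
    frame["sample_type"] = [rec_of[s].sample_type.value for s in frame.index]
    per_ind = (
        frame.groupby("individual_id")["value"]
        .agg(n_types="count", min="min", max="max")
        .assign(range=lambda f: f["max"] - f["min"])
    )
    eligible = per_ind[per_ind["n_types"] >= 2]
    per_type_range = (
        frame.groupby("sample_type")["value"].agg(lambda v: v.max() - v.min()).to_dict()
    )
    summary = {
        "n_individuals": int(len(eligible)),
        "n_excluded_single_type": int((per_ind["n_types"] < 2).sum()),
        "mean_range": float(eligible["range"].mean()) if len(eligible) else np.nan,
        "sd_range": float(eligible["range"].std(ddof=1)) if len(eligible) > 1 else np.nan,
        "per_type_between_individual_range": per_type_range,
    }
    return per_ind, summary
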