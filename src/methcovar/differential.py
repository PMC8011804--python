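"""Per-site mixed-effects ANOVA scan for differentially methylated
positions (DMPs) across sample types, with whole-blood-referenced
contrasts and sharing classification.

The per-site model is ``beta ~ sample_type`` with nested random intercepts
for family and individual, fit by REML (:mod:`methcovar.mixedlm`). The
ANOVA F-test covers the sample-type factor; t contrasts compare every
non-reference type to whole blood. Sites where the REML fit fails fall
back to OLS with family-clustered robust errors and are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from methcovar.core_io import (
    BetaMatrix,
    SampleRecord,
    SampleType,
    ValidationError,
)
from methcovar.mixedlm import NestedInterceptModel

__all__ = [
    "ALPHA_DMP",
    "DmpResult",
    "SiteAnovaEngine",
    "fit_site_anova",
    "run_dmp_scan",
    "classify_sharing",
]

#: Genome-wide significance threshold for the DMP ANOVA scan.
ALPHA_DMP = 9e-8

#: Nominal threshold used for per-type contrast membership.
NOMINAL_P = 0.05


@dataclass
class DmpResult:
    site_id: str
    anova_F: float
    anova_p: float
    df_num: float
    df_den: float
    effects: dict[SampleType, tuple[float, float, float]]  # type -> (effect, t, p)
    significant: bool
    n_types_nominal: int
    unique_type: Optional[SampleType]
    method: str = "mixed"  # mixed | ols | degenerate


class SiteAnovaEngine:
    """Pre-compiled per-site ANOVA for one sample sheet.

    Builds the treatment-coded design (reference = whole blood) once and
    reuses it for every site without missing values; sites with missing
    cells get a design subset on the fly.
    """

    def __init__(
        self,
        records: Sequence[SampleRecord],
        sample_ids: Sequence[str],
        reference: SampleType = SampleType.WHOLE_BLOOD,
        ddf: str = "satterthwaite",
    ) -> None:
        by_id = {r.sample_id: r for r in records}
        missing = [s for s in sample_ids if s not in by_id]
        if missing:
            raise ValidationError(f"samples missing from sheet: {missing[:5]}")
        recs = [by_id[s] for s in sample_ids]
        types_present = sorted({r.sample_type for r in recs}, key=lambda t: t.value)
        if reference not in types_present:
            raise ValidationError(
                f"reference type {reference.value} absent from the matrix"
            )
        if len(types_present) < 2:
            raise ValidationError("need >= 2 sample types for an ANOVA")
        counts = pd.Series([r.sample_type for r in recs]).value_counts()
        thin = [t.value for t, n in counts.items() if n < 2]
        if thin:
            raise ValidationError(f"sample types with < 2 samples: {thin}")
        self.reference = reference
        self.ddf = ddf
        self.types = [t for t in types_present if t is not reference]
        self.type_of = np.asarray([r.sample_type.value for r in recs], dtype=object)
        self.family = np.asarray([r.family_id for r in recs], dtype=object)
        self.individual = np.asarray([r.individual_id for r in recs], dtype=object)
        self.X = self._design(self.type_of, self.types)
        self._model = NestedInterceptModel(self.X, self.family, self.individual)

    @staticmethod
    def _design(type_of: np.ndarray, types: list[SampleType]) -> np.ndarray:
        X = np.ones((len(type_of), 1 + len(types)))
        for j, t in enumerate(types):
            X[:, 1 + j] = type_of == t.value
        return X

    # ------------------------------------------------------------------

    def fit_site(self, site_id: str, values: np.ndarray, alpha_dmp: float = ALPHA_DMP) -> DmpResult:
        y = np.asarray(values, dtype=float)
        keep = np.isfinite(y)
        if keep.all():
            model, X = self._model, self.X
            active_types = list(self.types)
            family = self.family
        else:
            type_of = self.type_of[keep]
            family = self.family[keep]
            present = set(type_of)
            if self.reference.value not in present or len(present) < 2:
                return self._degenerate(site_id)
            active_types = [t for t in self.types if t.value in present]
            X = self._design(type_of, active_types)
            model = NestedInterceptModel(X, family, self.individual[keep])
            y = y[keep]
        if np.ptp(y) == 0:
            return self._degenerate(site_id)

        q = len(active_types)
        C = np.zeros((q, X.shape[1]))
        C[:, 1:] = np.eye(q)

        method = "mixed"
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(y)
            if not np.isfinite(fit.beta).all():
                raise np.linalg.LinAlgError("non-finite fixed effects")
            cache = (
                model.satterthwaite_cache(fit, y)
                if self.ddf == "satterthwaite"
                else None
            )
            F, df_num, df_den, p_anova = model.joint_f_test(
                fit, C, y, ddf=self.ddf, cache=cache
            )
            effects: dict[SampleType, tuple[float, float, float]] = {}
            for j, t in enumerate(active_types):
                c = np.zeros(X.shape[1])
                c[1 + j] = 1.0
                est, tval, _df, pval = model.contrast_test(
                    fit, c, y, ddf=self.ddf, cache=cache
                )
                effects[t] = (est, tval, pval)
        except (np.linalg.LinAlgError, ValueError):
            F, df_num, df_den, p_anova, effects = self._ols_fallback(
                y, X, family, active_types
            )
            method = "ols"
        if not np.isfinite(p_anova):
            return self._degenerate(site_id)
        nominal = [t for t, (_e, _t, p) in effects.items() if np.isfinite(p) and p < NOMINAL_P]
        return DmpResult(
            site_id=site_id,
            anova_F=F,
            anova_p=p_anova,
            df_num=df_num,
            df_den=df_den,
            effects=effects,
            significant=bool(p_anova < alpha_dmp),
            n_types_nominal=len(nominal),
            unique_type=nominal[0] if len(nominal) == 1 else None,
            method=method,
        )

    def _ols_fallback(
        self,
        y: np.ndarray,
        X: np.ndarray,
        family: np.ndarray,
        active_types: list[SampleType],
    ):
        """OLS with family-clustered robust errors."""
        res = sm.OLS(y, X).fit(
            cov_type="cluster", cov_kwds={"groups": pd.factorize(family)[0]}
        )
        q = len(active_types)
        R = np.zeros((q, X.shape[1]))
        R[:, 1:] = np.eye(q)
        ftest = res.f_test(R)
        effects = {}
        for j, t in enumerate(active_types):
            effects[t] = (
                float(res.params[1 + j]),
                float(res.tvalues[1 + j]),
                float(res.pvalues[1 + j]),
            )
        return (
            float(ftest.fvalue),
            float(q),
            float(ftest.df_denom),
            float(ftest.pvalue),
            effects,
        )

    def _degenerate(self, site_id: str) -> DmpResult:
        return DmpResult(
            site_id=site_id,
            anova_F=np.nan,
            anova_p=np.nan,
            df_num=np.nan,
            df_den=np.nan,
            effects={},
            significant=False,
            n_types_nominal=0,
            unique_type=None,
            method="degenerate",
        )


def fit_site_anova(
    values: np.ndarray,
    records: Sequence[SampleRecord],
    alpha_dmp: float = ALPHA_DMP,
    reference: SampleType = SampleType.WHOLE_BLOOD,
    ddf: str = "satterthwaite",
    site_id: str = "site",
) -> DmpResult:
    """Fit the mixed-model ANOVA for one site.

    ``values`` must be ordered like ``records``. Convenience wrapper around
    :class:`SiteAnovaEngine`; use the engine directly for scans.
    """
    engine = SiteAnovaEngine(
        records, [r.sample_id for r in records], reference=reference, ddf=ddf
    )
    return engine.fit_site(site_id, values, alpha_dmp=alpha_dmp)


def run_dmp_scan(
    m: BetaMatrix,
    records: Sequence[SampleRecord],
    alpha_dmp: float = ALPHA_DMP,
    reference: SampleType = SampleType.WHOLE_BLOOD,
    ddf: str = "satterthwaite",
) -> tuple[pd.DataFrame, dict]:
    """Scan every site; returns (per-site table, summary).

    Summary counts per-type DMPs as sites passing BOTH the genome-wide
    ANOVA threshold and the type's nominal (p < 0.05) contrast.
    """
    engine = SiteAnovaEngine(records, m.sample_ids, reference=reference, ddf=ddf)
    rows = []
    for i, site_id in enumerate(m.site_ids):
        res = engine.fit_site(site_id, m.values[i], alpha_dmp=alpha_dmp)
        row = {
            "site_id": res.site_id,
            "anova_F": res.anova_F,
            "anova_p": res.anova_p,
            "df_num": res.df_num,
            "df_den": res.df_den,
            "significant": res.significant,
            "n_types_nominal": res.n_types_nominal,
            "unique_type": res.unique_type.value if res.unique_type else "",
            "method": res.method,
        }
        for t in engine.types:
            eff = res.effects.get(t)
            row[f"effect_{t.value}"] = eff[0] if eff else np.nan
            row[f"t_{t.value}"] = eff[1] if eff else np.nan
            row[f"p_{t.value}"] = eff[2] if eff else np.nan
        rows.append(row)
    table = pd.DataFrame(rows).set_index("site_id")
    tested = table["anova_p"].notna()
    n_tested = int(tested.sum())
    n_sig = int(table.loc[tested, "significant"].sum())
    per_type = {}
    for t in engine.types:
        col = table[f"p_{t.value}"]
        per_type[t.value] = int(
            (table["significant"] & col.notna() & (col < NOMINAL_P)).sum()
        )
    summary = {
        "n_sites": m.n_sites,
        "n_tested": n_tested,
        "n_significant": n_sig,
        "fraction_significant": n_sig / n_tested if n_tested else np.nan,
        "alpha_dmp": alpha_dmp,
        "per_type_dmp_counts": per_type,
        "n_ols_fallback": int((table["method"] == "ols").sum()),
    }
    return table, summary


def classify_sharing(table: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Classify significant DMPs as unique to one type or shared, and build
    the asymmetric pairwise overlap matrix.

    ``overlap.loc[a, b]`` = |DMP_a and DMP_b| / |DMP_a| where DMP_t is the
    set of significant sites with a nominal contrast for type t (the row
    type's set is the denominator).
    """
    p_cols = [c for c in table.columns if c.startswith("p_")]
    types = [c[2:] for c in p_cols]
    sig = table["significant"].fillna(False).to_numpy(dtype=bool)
    nominal = {
        t: (sig & table[f"p_{t}"].notna().to_numpy() & (table[f"p_{t}"] < NOMINAL_P).to_numpy())
        for t in types
    }
    n_nominal = np.sum(np.column_stack(list(nominal.values())), axis=1)
    labels = np.where(
        ~sig, "not_significant", np.where(n_nominal == 1, "unique", "shared")
    )
    labels = np.where(sig & (n_nominal == 0), "no_nominal_contrast", labels)
    sharing = pd.Series(labels, index=table.index, name="sharing")
    overlap = pd.DataFrame(index=types, columns=types, dtype=float)
    for a in types:
        denom = int(nominal[a].sum())
        for b in types:
            if denom == 0:
                overlap.loc[a, b] = np.nan
            else:
                overlap.loc[a, b] = float(np.sum(nominal[a] & nominal[b])) / denom
    return sharing, overlap
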