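"""Domain types, file I/O and sample alignment shared by every analysis stage.

File formats
------------
* Beta matrix: TSV, first column ``site_id``, remaining columns one per
  sample; cells are proportions in [0, 1], missing encoded as ``NA`` (or an
  empty cell on read).
* Sample sheet: CSV with columns ``sample_id, individual_id, family_id,
  sample_type`` and optional ``zygosity, sex``.
* Coefficient table: CSV with columns ``site_id, weight``; the intercept and
  transform are supplied separately (config or CLI flags).
* EWAS catalog: TSV with columns ``site_id, trait, p_value, tissue,
  study_id``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleType",
    "CONSTITUENT_TYPES",
    "SampleRecord",
    "BetaMatrix",
    "CoefficientModel",
    "EwasCatalogRecord",
    "AnnotationTable",
    "ValidationError",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_coefficient_model",
    "read_ewas_catalog",
    "read_annotation_table",
    "align_by_individual",
    "sheet_to_frame",
]

NA_TOKEN = "NA"


class ValidationError(ValueError):
    """Raised when an input file or object violates a documented invariant."""


class SampleType(str, enum.Enum):
    """The eight assayed sample types.

    Exactly five members are *constituents* (the FACS-purified blood cell
    types that mix to form whole blood) and exactly one member — whole
    blood — is the *reference* tissue for all contrasts.
    """

    WHOLE_BLOOD = "whole_blood"
    BUCCAL = "buccal"
    NASAL = "nasal"
    MONOCYTES = "monocytes"
    GRANULOCYTES = "granulocytes"
    CD4T = "cd4t"
    CD8T = "cd8t"
    BCELL = "bcell"

    @property
    def is_constituent(self) -> bool:
        return self in CONSTITUENT_TYPES

    @property
    def is_reference(self) -> bool:
        return self is SampleType.WHOLE_BLOOD

    @classmethod
    def parse(cls, label: str) -> "SampleType":
        try:
            return cls(str(label).strip().lower())
        except ValueError:
            raise ValidationError(
                f"unknown sample_type label {label!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


#: Canonical constituent ordering used throughout (mixture weights, truth
#: tables, characteristic scores).
CONSTITUENT_TYPES: tuple[SampleType, ...] = (
    SampleType.MONOCYTES,
    SampleType.GRANULOCYTES,
    SampleType.CD4T,
    SampleType.CD8T,
    SampleType.BCELL,
)

EPITHELIAL_TYPES: tuple[SampleType, ...] = (SampleType.BUCCAL, SampleType.NASAL)


@dataclass(frozen=True)
class SampleRecord:
    """One assayed sample: which individual, family and sample type."""

    sample_id: str
    individual_id: str
    family_id: str
    sample_type: SampleType
    zygosity: str = "unknown"  # MZ | DZ | unknown
    sex: str = "unknown"  # F | M | unknown

    def __post_init__(self) -> None:
        if self.zygosity not in ("MZ", "DZ", "unknown"):
            raise ValidationError(
                f"sample {self.sample_id}: zygosity must be MZ/DZ/unknown, "
                f"got {self.zygosity!r}"
            )
        if self.sex not in ("F", "M", "unknown"):
            raise ValidationError(
                f"sample {self.sample_id}: sex must be F/M/unknown, got {self.sex!r}"
            )


def validate_sheet(records: Sequence[SampleRecord]) -> None:
    """Enforce sheet-level invariants: unique sample ids, unique
    (individual, sample_type) pairs, one family per individual."""
    seen_samples: set[str] = set()
    seen_pairs: set[tuple[str, SampleType]] = set()
    fam_of: dict[str, str] = {}
    for rec in records:
        if rec.sample_id in seen_samples:
            raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
        seen_samples.add(rec.sample_id)
        key = (rec.individual_id, rec.sample_type)
        if key in seen_pairs:
            raise ValidationError(
                f"individual {rec.individual_id!r} has more than one "
                f"{rec.sample_type.value} sample"
            )
        seen_pairs.add(key)
        prev = fam_of.setdefault(rec.individual_id, rec.family_id)
        if prev != rec.family_id:
            raise ValidationError(
                f"individual {rec.individual_id!r} mapped to two families "
                f"({prev!r}, {rec.family_id!r})"
            )


class BetaMatrix:
    """Site x sample matrix of methylation proportions (beta values).

    Rows are probes/sites, columns are samples; values live in [0, 1] with
    NaN for missing. This orientation (sites as rows) matches array-data
    convention since sites vastly outnumber samples.
    """

    def __init__(
        self,
        site_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray,
    ) -> None:
        site_ids = [str(s) for s in site_ids]
        sample_ids = [str(s) for s in sample_ids]
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape != (len(site_ids), len(sample_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(site_ids)} sites x {len(sample_ids)} samples"
            )
        if len(set(site_ids)) != len(site_ids):
            raise ValidationError("site_ids are not unique")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("sample_ids are not unique")
        finite = values[np.isfinite(values)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            bad = np.argwhere(
                np.isfinite(values) & ((values < 0.0) | (values > 1.0))
            )[0]
            raise ValidationError(
                f"beta value out of [0, 1] at site {site_ids[bad[0]]!r}, "
                f"sample {sample_ids[bad[1]]!r}: {values[bad[0], bad[1]]}"
            )
        self.site_ids = site_ids
        self.sample_ids = sample_ids
        self.values = values
        self._site_index = {s: i for i, s in enumerate(site_ids)}
        self._sample_index = {s: i for i, s in enumerate(sample_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        return self._sample_index[sample_id]

    def site_index(self, site_id: str) -> int:
        return self._site_index[site_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = [self._sample_index[s] for s in sample_ids]
        return BetaMatrix(self.site_ids, list(sample_ids), self.values[:, idx])

    def subset_sites(self, site_ids: Sequence[str]) -> "BetaMatrix":
        idx = [self._site_index[s] for s in site_ids]
        return BetaMatrix(list(site_ids), self.sample_ids, self.values[idx, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.site_ids, name="site_id"),
            columns=self.sample_ids,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"BetaMatrix({self.n_sites} sites x {self.n_samples} samples)"


@dataclass
class CoefficientModel:
    """A linear DNAm predictor: intercept + sum of per-probe weights.

    ``transform_id`` selects the post-hoc transform of the linear score:
    ``identity`` (smoking-score style) or ``horvath_age`` (piecewise
    log-linear age calibration with anchor ``adult_age``).
    """

    model_id: str
    intercept: float
    weights: dict[str, float]
    transform_id: str = "identity"
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if not self.weights:
            raise ValidationError(f"model {self.model_id!r}: empty weight table")
        if self.transform_id not in ("identity", "horvath_age"):
            raise ValidationError(
                f"model {self.model_id!r}: unknown transform {self.transform_id!r}"
            )


@dataclass(frozen=True)
class EwasCatalogRecord:
    """One trait association from an EWAS catalog export."""

    site_id: str
    trait: str
    p_value: float
    tissue: str = ""
    study_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"EWAS record {self.site_id!r}/{self.trait!r}: "
                f"p_value must be in (0, 1], got {self.p_value}"
            )


class AnnotationTable:
    """Optional per-site annotations: additive-genetic (A) and non-shared
    environment (E) variance fractions plus an mQTL flag.

    Backed by a DataFrame indexed by site_id; all columns optional.
    """

    COLUMNS = ("A", "E", "has_mqtl")

    def __init__(self, frame: pd.DataFrame) -> None:
        frame = frame.copy()
        if frame.index.name != "site_id":
            if "site_id" in frame.columns:
                frame = frame.set_index("site_id")
            else:
                raise ValidationError("annotation table needs a site_id column")
        for col in ("A", "E"):
            if col in frame.columns:
                vals = frame[col].dropna()
                if len(vals) and ((vals < 0).any() or (vals > 1).any()):
                    raise ValidationError(
                        f"annotation column {col} outside [0, 1]"
                    )
        if "has_mqtl" in frame.columns:
            frame["has_mqtl"] = frame["has_mqtl"].astype(bool)
        self.frame = frame

    def __contains__(self, site_id: str) -> bool:
        return site_id in self.frame.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_beta_matrix(path: str | Path, dialect: str = "tsv") -> BetaMatrix:
    """Read a TSV beta matrix (first column site ids, header sample ids).

    Out-of-range values raise :class:`ValidationError` (they are never
    clamped); ``NA`` and empty cells become missing.
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, sep="\t", index_col=0, na_values=[NA_TOKEN, ""],
            keep_default_na=False,
        )
    except Exception as exc:  # pandas error types vary
        raise ValidationError(f"cannot parse beta matrix {path}: {exc}") from exc
    if frame.index.name is None or frame.shape[1] == 0:
        raise ValidationError(f"{path}: malformed header (need site_id + samples)")
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValidationError(f"{path}: non-numeric cell ({exc})") from exc
    return BetaMatrix(frame.index.astype(str), frame.columns.astype(str), values)


def write_beta_matrix(m: BetaMatrix, path: str | Path) -> Path:
    """Write a beta matrix as TSV; NaNs become the ``NA`` token.

    Uses repr-precision floats so a read-back round-trips values exactly.
    """
    if m.n_sites == 0:
        raise ValidationError("refusing to write a beta matrix with no sites")
    path = Path(path)
    frame = m.to_frame()
    frame.to_csv(path, sep="\t", na_rep=NA_TOKEN, float_format="%.17g")
    return path


_SHEET_REQUIRED = ("sample_id", "individual_id", "family_id", "sample_type")


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Read and validate a CSV sample sheet into SampleRecords."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _SHEET_REQUIRED if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            SampleRecord(
                sample_id=row.sample_id,
                individual_id=row.individual_id,
                family_id=row.family_id,
                sample_type=SampleType.parse(row.sample_type),
                zygosity=getattr(row, "zygosity", "unknown") or "unknown",
                sex=getattr(row, "sex", "unknown") or "unknown",
            )
        )
    validate_sheet(records)
    return records


def sheet_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "individual_id": [r.individual_id for r in records],
            "family_id": [r.family_id for r in records],
            "sample_type": [r.sample_type.value for r in records],
            "zygosity": [r.zygosity for r in records],
            "sex": [r.sex for r in records],
        }
    )


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> Path:
    path = Path(path)
    sheet_to_frame(records).to_csv(path, index=False)
    return path


def read_coefficient_model(
    path: str | Path,
    model_id: str,
    intercept: float = 0.0,
    transform_id: str = "identity",
    adult_age: float = 20.0,
) -> CoefficientModel:
    """Read a two-column (site_id, weight) CSV into a CoefficientModel."""
    frame = pd.read_csv(path)
    for col in ("site_id", "weight"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: coefficient table needs column {col!r}")
    if frame["site_id"].duplicated().any():
        dup = frame.loc[frame["site_id"].duplicated(), "site_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate coefficient for site {dup!r}")
    weights = dict(zip(frame["site_id"].astype(str), frame["weight"].astype(float)))
    return CoefficientModel(
        model_id=model_id, intercept=float(intercept), weights=weights,
        transform_id=transform_id, adult_age=adult_age,
    )


def read_ewas_catalog(path: str | Path) -> list[EwasCatalogRecord]:
    """Read a TSV EWAS catalog export."""
    frame = pd.read_csv(path, sep="\t", dtype={"site_id": str})
    for col in ("site_id", "trait", "p_value"):
        if col not in frame.columns:
            raise ValidationError(f"{path}: EWAS table needs column {col!r}")
    records = []
    for row in frame.itertuples(index=False):
        records.append(
            EwasCatalogRecord(
                site_id=str(row.site_id),
                trait=str(row.trait),
                p_value=float(row.p_value),
                tissue=str(getattr(row, "tissue", "")),
                study_id=str(getattr(row, "study_id", "")),
            )
        )
    return records


def read_annotation_table(path: str | Path) -> AnnotationTable:
    frame = pd.read_csv(path, sep="\t")
    return AnnotationTable(frame)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def samples_of_type(
    records: Sequence[SampleRecord], sample_type: SampleType
) -> list[SampleRecord]:
    return [r for r in records if r.sample_type is sample_type]


def align_by_individual(
    m: BetaMatrix,
    records: Sequence[SampleRecord],
    type_a: SampleType,
    type_b: SampleType,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pair samples of two types by individual.

    Returns ``(values_a, values_b, individual_ids)`` where both value arrays
    are sites x individuals with identical, deterministically sorted
    individual ordering; only individuals with a sample of each type *that
    is present in the matrix* are retained.
    """
    by_ind_a = {
        r.individual_id: r.sample_id
        for r in samples_of_type(records, type_a)
        if r.sample_id in m._sample_index
    }
    by_ind_b = {
        r.individual_id: r.sample_id
        for r in samples_of_type(records, type_b)
        if r.sample_id in m._sample_index
    }
    shared = sorted(set(by_ind_a) & set(by_ind_b))
    if not shared:
        raise ValidationError(
            f"no individuals have both {type_a.value} and {type_b.value} samples"
        )
    idx_a = [m.sample_index(by_ind_a[i]) for i in shared]
    idx_b = [m.sample_index(by_ind_b[i]) for i in shared]
    return m.values[:, idx_a], m.values[:, idx_b], shared
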