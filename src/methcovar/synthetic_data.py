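"""Twin-cohort multi-sample-type methylation simulator with known truth.

The generative model composes whole blood as a proportion-weighted mixture
of five constituent cell types, on top of a per-site variance structure with
four site classes:

``null``
    baseline mean + individual noise only.
``mean_shift``
    per-sample-type mean offsets (true DMPs).
``genetic``
    adds a twin-shared deviation (identical within MZ pairs, correlation
    0.5 within DZ pairs) common to all sample types of an individual.
``environmental``
    individual x cell-type noise only (like ``null``; kept as a separate
    label so covariation can be contrasted against ``genetic``).
``single_cell:<type>``
    one flagged constituent's noise SD is inflated (true characteristic
    sites).

Per assayed value: ``beta = clip(mu + g + e + m, 0.001, 0.999)`` where ``m``
is measurement noise. Whole blood mixes the *pre-measurement-noise* cell
signals and then receives its own measurement noise, so with
``sigma_measure = 0`` the mixture identity is exact before clipping.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from methcovar.core_io import (
    CONSTITUENT_TYPES,
    EPITHELIAL_TYPES,
    AnnotationTable,
    BetaMatrix,
    SampleRecord,
    SampleType,
    ValidationError,
    validate_sheet,
)

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "SimulatedDataset",
    "SITE_CLASSES",
    "draw_proportions",
    "simulate_cell_betas",
    "compose_whole_blood",
    "simulate_dataset",
]

CLIP_LO = 0.001
CLIP_HI = 0.999

#: Non-flagged site classes; ``single_cell:<constituent>`` labels extend this.
SITE_CLASSES = ("null", "mean_shift", "genetic", "environmental")


def single_cell_class(cell: SampleType) -> str:
    return f"single_cell:{cell.value}"


def default_class_fractions() -> dict[str, float]:
    fractions = {
        "null": 0.40,
        "mean_shift": 0.20,
        "genetic": 0.15,
        "environmental": 0.15,
    }
    for cell in CONSTITUENT_TYPES:
        fractions[single_cell_class(cell)] = 0.02
    return fractions


@dataclass
class SimulationConfig:
    """All knobs of the generative model; validated on construction.

    ``dirichlet_alpha`` orders the constituents (monocytes, granulocytes,
    CD4+ T, CD8+ T, B cells); its default echoes granulocyte dominance in
    whole blood. ``fixed_proportions``, when set, replaces the Dirichlet
    draw with one shared proportion vector (useful for exact mixture
    checks). The measurement-noise default (0.01) is a free parameter: no
    assay-noise magnitude is published for this platform.
    """

    n_families: int = 15
    prop_mz: float = 14 / 15
    n_sites: int = 2000
    class_fractions: dict[str, float] = field(default_factory=default_class_fractions)
    sigma_g: float = 0.05
    sigma_e: float = 0.02
    sigma_e_per_cell: Optional[tuple[float, ...]] = None  # overrides sigma_e per constituent
    sigma_cell_inflate: float = 5.0
    sigma_measure: float = 0.01
    dirichlet_alpha: tuple[float, ...] = (12.0, 60.0, 18.0, 10.0, 8.0)
    fixed_proportions: Optional[tuple[float, ...]] = None
    mean_beta_weights: tuple[float, float, float] = (0.28, 0.46, 0.26)
    mean_beta_ranges: tuple[tuple[float, float], ...] = (
        (0.05, 0.20),
        (0.20, 0.80),
        (0.80, 0.95),
    )
    mean_shift_sd: float = 0.1
    include_epithelial: bool = False
    epithelial_sd_multiplier: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_families < 1 or self.n_sites < 1:
            raise ValidationError("n_families and n_sites must be positive")
        if not (0.0 <= self.prop_mz <= 1.0):
            raise ValidationError("prop_mz must be in [0, 1]")
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"class_fractions sum to {total}, expected 1")
        if any(f < 0 for f in self.class_fractions.values()):
            raise ValidationError("class_fractions must be non-negative")
        valid = set(SITE_CLASSES) | {single_cell_class(c) for c in CONSTITUENT_TYPES}
        unknown = set(self.class_fractions) - valid
        if unknown:
            raise ValidationError(f"unknown site classes {sorted(unknown)}")
        if len(self.dirichlet_alpha) != len(CONSTITUENT_TYPES):
            raise ValidationError("dirichlet_alpha needs 5 entries")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValidationError("dirichlet_alpha entries must be > 0")
        if self.fixed_proportions is not None:
            w = np.asarray(self.fixed_proportions, dtype=float)
            if w.shape != (len(CONSTITUENT_TYPES),) or (w < 0).any():
                raise ValidationError("fixed_proportions must be 5 non-negatives")
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValidationError("fixed_proportions must sum to 1")
        if abs(sum(self.mean_beta_weights) - 1.0) > 1e-9:
            raise ValidationError("mean_beta_weights must sum to 1")
        if self.sigma_e_per_cell is not None:
            if len(self.sigma_e_per_cell) != len(CONSTITUENT_TYPES):
                raise ValidationError("sigma_e_per_cell needs 5 entries")
            if any(s < 0 for s in self.sigma_e_per_cell):
                raise ValidationError("sigma_e_per_cell entries must be >= 0")
        if self.epithelial_sd_multiplier <= 1.0 and self.include_epithelial:
            raise ValidationError("epithelial_sd_multiplier must be > 1")

    def generated_types(self) -> list[SampleType]:
        types = [SampleType.WHOLE_BLOOD, *CONSTITUENT_TYPES]
        if self.include_epithelial:
            types.extend(EPITHELIAL_TYPES)
        return types


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated dataset.

    ``sites``: per-site class label, flagged cell type and per-sample-type
    true mean / true SD (analytic, pre-clipping, including measurement
    noise). ``proportions``: per-individual mixture weights over the five
    constituents. ``genetic_effects``: the twin-shared deviations actually
    drawn (sites x individuals; zero rows for non-genetic sites).
    """

    sites: pd.DataFrame
    proportions: pd.DataFrame
    genetic_effects: pd.DataFrame

    def to_annotation_table(self) -> AnnotationTable:
        """Analytic A/E variance fractions implied by each site class."""
        cls = self.sites["site_class"]
        frame = pd.DataFrame(index=self.sites.index)
        frame.index.name = "site_id"
        is_gen = (cls == "genetic").to_numpy()
        frame["A"] = np.where(is_gen, 1.0, 0.0)
        frame["E"] = np.where(is_gen, 0.0, 1.0)
        frame["has_mqtl"] = is_gen
        return AnnotationTable(frame)


@dataclass
class SimulatedDataset:
    beta: BetaMatrix
    sheet: list[SampleRecord]
    truth: SimulatedTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# cohort structure
# ---------------------------------------------------------------------------


def _build_cohort(config: SimulationConfig) -> pd.DataFrame:
    """One row per individual: individual_id, family_id, zygosity, sex."""
    n_mz = int(round(config.prop_mz * config.n_families))
    rows = []
    for f in range(config.n_families):
        family_id = f"fam{f + 1:02d}"
        zygosity = "MZ" if f < n_mz else "DZ"
        sex = "F" if f % 5 < 3 else "M"  # ~60% female pairs, deterministic
        for t in (1, 2):
            rows.append(
                {
                    "individual_id": f"{family_id}_t{t}",
                    "family_id": family_id,
                    "zygosity": zygosity,
                    "sex": sex,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# generative pieces
# ---------------------------------------------------------------------------


def draw_proportions(
    config: SimulationConfig, n_individuals: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-individual constituent proportions, shape (n_individuals, 5).

    Dirichlet by default; a shared fixed vector when
    ``config.fixed_proportions`` is set.
    """
    if config.fixed_proportions is not None:
        w = np.asarray(config.fixed_proportions, dtype=float)
        return np.tile(w, (n_individuals, 1))
    return rng.dirichlet(np.asarray(config.dirichlet_alpha), size=n_individuals)


def _draw_baseline_means(
    config: SimulationConfig, n_sites: int, rng: np.random.Generator
) -> np.ndarray:
    """Mixture of uniforms favouring the low/high rails with an
    intermediate component."""
    comp = rng.choice(len(config.mean_beta_weights), size=n_sites,
                      p=np.asarray(config.mean_beta_weights))
    lo = np.array([r[0] for r in config.mean_beta_ranges])[comp]
    hi = np.array([r[1] for r in config.mean_beta_ranges])[comp]
    return rng.uniform(lo, hi)


def _draw_genetic_effects(
    cohort: pd.DataFrame,
    site_is_genetic: np.ndarray,
    sigma_g: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Twin-shared deviations, sites x individuals.

    MZ co-twins share the full deviation; DZ co-twins get
    ``sqrt(.5)*shared + sqrt(.5)*own`` so their correlation is 0.5 at equal
    marginal variance. Non-genetic sites get zero rows.
    """
    n_sites = site_is_genetic.shape[0]
    g = np.zeros((n_sites, len(cohort)))
    n_gen = int(site_is_genetic.sum())
    if n_gen == 0 or sigma_g == 0:
        return g
    gen_rows = np.flatnonzero(site_is_genetic)
    for family_id, members in cohort.groupby("family_id", sort=False).groups.items():
        idx = list(members)
        zygosity = cohort.loc[idx[0], "zygosity"]
        shared = rng.normal(0.0, sigma_g, size=n_gen)
        if zygosity == "MZ":
            for i in idx:
                g[gen_rows, i] = shared
        else:
            for i in idx:
                own = rng.normal(0.0, sigma_g, size=n_gen)
                g[gen_rows, i] = np.sqrt(0.5) * shared + np.sqrt(0.5) * own
    return g


def simulate_cell_betas(
    config: SimulationConfig,
    baseline_means: dict[SampleType, np.ndarray],
    genetic_effects: np.ndarray,
    flagged_inflate: dict[SampleType, np.ndarray],
    n_individuals: int,
    rng: np.random.Generator,
) -> tuple[dict[SampleType, np.ndarray], dict[SampleType, np.ndarray]]:
    """Draw per-individual signals for every non-whole-blood sample type.

    Returns ``(signal, observed)`` dicts mapping sample type to a
    sites x individuals array: ``signal = mu + g + e`` (what whole blood
    mixes) and ``observed = clip(signal + measurement noise)`` (what the
    assay reports).
    """
    signal: dict[SampleType, np.ndarray] = {}
    observed: dict[SampleType, np.ndarray] = {}
    per_cell_sd = {
        c: (config.sigma_e_per_cell[k] if config.sigma_e_per_cell else config.sigma_e)
        for k, c in enumerate(CONSTITUENT_TYPES)
    }
    for cell, mu in baseline_means.items():
        sd = np.full(mu.shape[0], per_cell_sd.get(cell, config.sigma_e), dtype=float)
        if cell in EPITHELIAL_TYPES:
            sd = sd * config.epithelial_sd_multiplier
        inflate = flagged_inflate.get(cell)
        if inflate is not None:
            sd = np.where(inflate, sd * config.sigma_cell_inflate, sd)
        e = rng.normal(0.0, 1.0, size=(mu.shape[0], n_individuals)) * sd[:, None]
        sig = mu[:, None] + genetic_effects + e
        m = (
            rng.normal(0.0, config.sigma_measure, size=sig.shape)
            if config.sigma_measure > 0
            else 0.0
        )
        signal[cell] = sig
        observed[cell] = np.clip(sig + m, CLIP_LO, CLIP_HI)
    return signal, observed


def compose_whole_blood(
    cell_betas: np.ndarray,
    w: np.ndarray,
    sigma_measure: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Mix constituent signals into whole blood per site.

    ``cell_betas`` is sites x 5 (one individual) or sites x 5 x individuals;
    ``w`` is the matching proportion vector (5,) or matrix (5, individuals).
    Returns ``clip(sum_c w_c * beta_c + m, 0.001, 0.999)``.
    """
    cell_betas = np.asarray(cell_betas, dtype=float)
    w = np.asarray(w, dtype=float)
    if (w < -1e-12).any() or np.abs(w.sum(axis=0) - 1.0).max() > 1e-9:
        raise ValidationError("proportion vector is not on the simplex")
    if cell_betas.ndim == 2:
        mixed = cell_betas @ w
    else:
        mixed = np.einsum("sci,ci->si", cell_betas, w)
    if sigma_measure > 0:
        if rng is None:
            raise ValidationError("sigma_measure > 0 requires an rng")
        mixed = mixed + rng.normal(0.0, sigma_measure, size=mixed.shape)
    return np.clip(mixed, CLIP_LO, CLIP_HI)


# ---------------------------------------------------------------------------
# full dataset
# ---------------------------------------------------------------------------


def _assign_classes(
    config: SimulationConfig, n_sites: int, rng: np.random.Generator
) -> list[str]:
    labels = sorted(config.class_fractions)
    p = np.array([config.class_fractions[k] for k in labels])
    return list(np.asarray(labels, dtype=object)[rng.choice(len(labels), size=n_sites, p=p)])


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset (beta matrix, sample sheet, truth).

    Deterministic for a fixed ``config.seed``. Always generates whole blood
    plus the five constituents; buccal/nasal are added when
    ``config.include_epithelial`` (independent baselines, noise SD times
    ``epithelial_sd_multiplier``).
    """
    rng = np.random.default_rng(config.seed)
    cohort = _build_cohort(config)
    n_ind = len(cohort)
    n_sites = config.n_sites
    site_ids = [f"cg{i:07d}" for i in range(n_sites)]

    classes = _assign_classes(config, n_sites, rng)
    class_arr = np.asarray(classes, dtype=object)
    flagged_type: list[str] = [
        c.split(":", 1)[1] if c.startswith("single_cell:") else "" for c in classes
    ]

    base_mu = np.clip(_draw_baseline_means(config, n_sites, rng), 0.02, 0.98)
    is_shift = class_arr == "mean_shift"

    cell_types = [*CONSTITUENT_TYPES]
    if config.include_epithelial:
        cell_types.extend(EPITHELIAL_TYPES)

    baseline_means: dict[SampleType, np.ndarray] = {}
    for cell in cell_types:
        if cell in EPITHELIAL_TYPES:
            mu = np.clip(_draw_baseline_means(config, n_sites, rng), 0.02, 0.98)
        else:
            mu = base_mu.copy()
        if is_shift.any():
            shift = rng.normal(0.0, config.mean_shift_sd, size=int(is_shift.sum()))
            mu = mu.copy()
            mu[is_shift] = np.clip(mu[is_shift] + shift, 0.02, 0.98)
        baseline_means[cell] = mu

    genetic_effects = _draw_genetic_effects(
        cohort, class_arr == "genetic", config.sigma_g, rng
    )

    flagged_inflate = {
        cell: np.asarray([f == cell.value for f in flagged_type])
        for cell in CONSTITUENT_TYPES
    }
    signal, observed = simulate_cell_betas(
        config, baseline_means, genetic_effects, flagged_inflate, n_ind, rng
    )

    w = draw_proportions(config, n_ind, rng)  # (n_ind, 5)
    constituent_signal = np.stack(
        [signal[c] for c in CONSTITUENT_TYPES], axis=1
    )  # sites x 5 x individuals
    wb = compose_whole_blood(
        constituent_signal, w.T, sigma_measure=config.sigma_measure, rng=rng
    )

    # assemble matrix + sheet, one sample per (individual, type)
    observed_by_type = dict(observed)
    observed_by_type[SampleType.WHOLE_BLOOD] = wb
    sample_ids: list[str] = []
    columns: list[np.ndarray] = []
    records: list[SampleRecord] = []
    for stype in config.generated_types():
        for i, row in cohort.iterrows():
            sample_id = f"{row.individual_id}_{stype.value}"
            sample_ids.append(sample_id)
            columns.append(observed_by_type[stype][:, i])
            records.append(
                SampleRecord(
                    sample_id=sample_id,
                    individual_id=row.individual_id,
                    family_id=row.family_id,
                    sample_type=stype,
                    zygosity=row.zygosity,
                    sex=row.sex,
                )
            )
    validate_sheet(records)
    beta = BetaMatrix(site_ids, sample_ids, np.column_stack(columns))

    truth = SimulatedTruth(
        sites=_truth_sites(
            config, site_ids, classes, flagged_type, baseline_means, w
        ),
        proportions=pd.DataFrame(
            w,
            index=pd.Index(cohort["individual_id"], name="individual_id"),
            columns=[c.value for c in CONSTITUENT_TYPES],
        ),
        genetic_effects=pd.DataFrame(
            genetic_effects,
            index=pd.Index(site_ids, name="site_id"),
            columns=list(cohort["individual_id"]),
        ),
    )
    return SimulatedDataset(beta=beta, sheet=records, truth=truth, config=config)


def _truth_sites(
    config: SimulationConfig,
    site_ids: list[str],
    classes: list[str],
    flagged_type: list[str],
    baseline_means: dict[SampleType, np.ndarray],
    w: np.ndarray,
) -> pd.DataFrame:
    """Analytic per-site, per-type true means and SDs (pre-clipping)."""
    class_arr = np.asarray(classes, dtype=object)
    n_sites = len(site_ids)
    frame = pd.DataFrame(index=pd.Index(site_ids, name="site_id"))
    frame["site_class"] = classes
    frame["flagged_type"] = flagged_type
    g_var = np.where(class_arr == "genetic", config.sigma_g**2, 0.0)
    m_var = config.sigma_measure**2
    w_mean = w.mean(axis=0)
    for k, cell in enumerate(CONSTITUENT_TYPES):
        base_sd = (
            config.sigma_e_per_cell[k] if config.sigma_e_per_cell else config.sigma_e
        )
        e_sd = np.full(n_sites, base_sd)
        e_sd = np.where(
            np.asarray(flagged_type, dtype=object) == cell.value,
            e_sd * config.sigma_cell_inflate,
            e_sd,
        )
        frame[f"true_mean_{cell.value}"] = baseline_means[cell]
        frame[f"true_sd_{cell.value}"] = np.sqrt(g_var + e_sd**2 + m_var)
    if config.include_epithelial:
        for cell in EPITHELIAL_TYPES:
            e_sd = config.sigma_e * config.epithelial_sd_multiplier
            frame[f"true_mean_{cell.value}"] = baseline_means[cell]
            frame[f"true_sd_{cell.value}"] = np.sqrt(g_var + e_sd**2 + m_var)
    wb_mean = np.zeros(n_sites)
    for k, cell in enumerate(CONSTITUENT_TYPES):
        wb_mean += w_mean[k] * baseline_means[cell]
    frame["true_mean_whole_blood"] = wb_mean
    return frame


# ---------------------------------------------------------------------------
# serialization helpers for the CLI
# ---------------------------------------------------------------------------


def config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["dirichlet_alpha"] = list(config.dirichlet_alpha)
    if config.fixed_proportions is not None:
        out["fixed_proportions"] = list(config.fixed_proportions)
    if config.sigma_e_per_cell is not None:
        out["sigma_e_per_cell"] = list(config.sigma_e_per_cell)
    out["mean_beta_weights"] = list(config.mean_beta_weights)
    out["mean_beta_ranges"] = [list(r) for r in config.mean_beta_ranges]
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    for key in (
        "dirichlet_alpha",
        "fixed_proportions",
        "mean_beta_weights",
        "sigma_e_per_cell",
    ):
        if data.get(key) is not None:
            data[key] = tuple(data[key])
    if data.get("mean_beta_ranges") is not None:
        data["mean_beta_ranges"] = tuple(tuple(r) for r in data["mean_beta_ranges"])
    return SimulationConfig(**data)
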