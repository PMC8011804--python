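import numpy as np
import pytest

from methcovar.core_io import CONSTITUENT_TYPES, SampleType, ValidationError
from methcovar.synthetic_data import (
    SimulationConfig,
    compose_whole_blood,
    config_from_dict,
    config_to_dict,
    default_class_fractions,
    draw_proportions,
    simulate_dataset,
)
from tests.conftest import null_fractions


class TestConfigValidation:
    def test_default_fractions_sum_to_one(self):
        assert sum(default_class_fractions().values()) == pytest.approx(1.0)

    def test_bad_fraction_sum_rejected(self):
        with pytest.raises(ValidationError, match="sum"):
            SimulationConfig(class_fractions={"null": 0.5})

    def test_unknown_class_rejected(self):
        with pytest.raises(ValidationError, match="unknown site classes"):
            SimulationConfig(class_fractions={"null": 0.5, "weird": 0.5})

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValidationError, match="dirichlet_alpha"):
            SimulationConfig(dirichlet_alpha=(1, 1, 1, 1, 0))

    def test_fixed_proportions_off_simplex_rejected(self):
        with pytest.raises(ValidationError, match="sum to 1"):
            SimulationConfig(fixed_proportions=(0.5, 0.5, 0.5, 0, 0))

    def test_round_trip_through_dict(self):
        cfg = SimulationConfig(n_sites=10, fixed_proportions=(0.2,) * 5)
        assert config_from_dict(config_to_dict(cfg)) == cfg


class TestDrawProportions:
    def test_degenerate_concentration(self):
        cfg = SimulationConfig(dirichlet_alpha=(1e6, 1e-6, 1e-6, 1e-6, 1e-6))
        w = draw_proportions(cfg, 50, np.random.default_rng(0))
        np.testing.assert_allclose(w[:, 0], 1.0, atol=1e-3)
        np.testing.assert_allclose(w[:, 1:], 0.0, atol=1e-3)

    def test_mean_matches_normalized_alpha(self):
        # Dirichlet mean is alpha / sum(alpha); Monte-Carlo check
        alpha = (60.0, 30.0, 5.0, 3.0, 2.0)
        cfg = SimulationConfig(dirichlet_alpha=alpha)
        w = draw_proportions(cfg, 10_000, np.random.default_rng(1))
        expected = np.asarray(alpha) / sum(alpha)
        np.testing.assert_allclose(w.mean(axis=0), expected, atol=0.01)

    def test_simplex_constraint(self):
        cfg = SimulationConfig()
        w = draw_proportions(cfg, 200, np.random.default_rng(2))
        assert (w >= 0).all()
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_fixed_proportions_tiled(self):
        cfg = SimulationConfig(fixed_proportions=(0.1, 0.6, 0.15, 0.1, 0.05))
        w = draw_proportions(cfg, 7, np.random.default_rng(3))
        assert w.shape == (7, 5)
        assert (w == w[0]).all()


class TestComposeWholeBlood:
    def test_equal_betas_identity(self):
        betas = np.full((4, 5), 0.4)
        w = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        np.testing.assert_allclose(compose_whole_blood(betas, w), 0.4)

    def test_degenerate_weight_selects_cell(self):
        rng = np.random.default_rng(0)
        betas = rng.uniform(0.2, 0.8, size=(10, 5))
        w = np.array([1.0, 0, 0, 0, 0])
        np.testing.assert_allclose(compose_whole_blood(betas, w), betas[:, 0])

    def test_equal_weights_arithmetic_mean(self):
        betas = np.array([[0.2, 0.4, 0.6, 0.8, 1.0]])
        wb = compose_whole_blood(betas, np.full(5, 0.2))
        assert wb[0] == pytest.approx(0.6)

    def test_off_simplex_rejected(self):
        with pytest.raises(ValidationError, match="simplex"):
            compose_whole_blood(np.full((1, 5), 0.5), np.full(5, 0.3))

    def test_noise_requires_rng(self):
        with pytest.raises(ValidationError, match="rng"):
            compose_whole_blood(np.full((1, 5), 0.5), np.full(5, 0.2), sigma_measure=0.1)


class TestSimulateDataset:
    def test_deterministic_for_seed(self):
        cfg = SimulationConfig(n_sites=25, seed=5)
        d1 = simulate_dataset(cfg)
        d2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(d1.beta.values, d2.beta.values)
        assert d1.beta.sample_ids == d2.beta.sample_ids
        assert d1.truth.sites.equals(d2.truth.sites)

    def test_cohort_structure(self, small_dataset):
        sheet = small_dataset.sheet
        individuals = {r.individual_id for r in sheet}
        assert len(individuals) == 30
        zyg = {r.family_id: r.zygosity for r in sheet}
        assert sum(z == "MZ" for z in zyg.values()) == 14
        assert sum(z == "DZ" for z in zyg.values()) == 1

    def test_one_sample_per_individual_type(self, small_dataset):
        pairs = {(r.individual_id, r.sample_type) for r in small_dataset.sheet}
        assert len(pairs) == len(small_dataset.sheet)
        types = {r.sample_type for r in small_dataset.sheet}
        assert types == {SampleType.WHOLE_BLOOD, *CONSTITUENT_TYPES}

    def test_epithelial_types_added(self, epithelial_dataset):
        types = {r.sample_type for r in epithelial_dataset.sheet}
        assert SampleType.BUCCAL in types and SampleType.NASAL in types
        assert len(types) == 8

    def test_truth_covers_every_site(self, small_dataset):
        assert list(small_dataset.truth.sites.index) == small_dataset.beta.site_ids
        assert not small_dataset.truth.sites.index.duplicated().any()

    def test_zero_noise_reproduces_means(self):
        cfg = SimulationConfig(
            n_sites=20,
            seed=3,
            class_fractions=null_fractions(),
            sigma_e=0.0,
            sigma_measure=0.0,
            sigma_g=0.0,
        )
        ds = simulate_dataset(cfg)
        for cell in CONSTITUENT_TYPES:
            cols = [
                ds.beta.sample_index(r.sample_id)
                for r in ds.sheet
                if r.sample_type is cell
            ]
            diff = (
                ds.beta.values[:, cols]
                - ds.truth.sites[f"true_mean_{cell.value}"].to_numpy()[:, None]
            )
            assert np.abs(diff).max() < 1e-12

    def test_mixture_identity_exact_without_noise(self):
        # whole blood must be an exact convex combination of constituents
        cfg = SimulationConfig(
            n_sites=200, seed=9, sigma_measure=0.0,
            fixed_proportions=(0.1, 0.6, 0.15, 0.1, 0.05),
        )
        ds = simulate_dataset(cfg)
        w = np.asarray(cfg.fixed_proportions)
        by_type = {
            t: [
                ds.beta.sample_index(r.sample_id)
                for r in sorted(ds.sheet, key=lambda r: r.individual_id)
                if r.sample_type is t
            ]
            for t in (SampleType.WHOLE_BLOOD, *CONSTITUENT_TYPES)
        }
        wb = ds.beta.values[:, by_type[SampleType.WHOLE_BLOOD]]
        mix = sum(
            w[k] * ds.beta.values[:, by_type[c]]
            for k, c in enumerate(CONSTITUENT_TYPES)
        )
        interior = (ds.beta.values > 0.001 + 1e-9).all(axis=1) & (
            ds.beta.values < 0.999 - 1e-9
        ).all(axis=1)
        assert interior.sum() > 100
        np.testing.assert_allclose(wb[interior], mix[interior], atol=1e-12)

    def test_mz_within_pair_correlation_exceeds_dz(self):
        # genetic-class sites: MZ co-twins share g fully, DZ at 0.5
        cfg = SimulationConfig(
            n_sites=600,
            seed=17,
            prop_mz=0.5,
            class_fractions=null_fractions(genetic=1.0),
            sigma_g=0.05,
            sigma_e=0.005,
            sigma_measure=0.005,
        )
        ds = simulate_dataset(cfg)
        g = ds.truth.genetic_effects
        mz_cols = [
            (f"fam{f:02d}_t1", f"fam{f:02d}_t2") for f in range(1, 8)
        ]
        dz_cols = [(f"fam{f:02d}_t1", f"fam{f:02d}_t2") for f in range(9, 16)]

        def pair_corr(cols):
            rs = []
            for a, b in cols:
                rs.append(np.corrcoef(g[a], g[b])[0, 1])
            return np.mean(rs)

        assert pair_corr(mz_cols) == pytest.approx(1.0, abs=1e-12)
        assert abs(pair_corr(dz_cols) - 0.5) < 0.25
        assert pair_corr(mz_cols) > pair_corr(dz_cols)

    def test_single_cell_inflation_sd_ratio(self):
        # closed form: SD ratio = sqrt((5 s_e)^2 + s_m^2) / sqrt(s_e^2 + s_m^2)
        s_e, s_m, infl = 0.02, 0.01, 5.0
        cfg = SimulationConfig(
            n_sites=1000,
            seed=29,
            class_fractions=null_fractions(**{"single_cell:bcell": 1.0}),
            sigma_e=s_e,
            sigma_measure=s_m,
            sigma_cell_inflate=infl,
            mean_beta_weights=(0.0, 1.0, 0.0),  # keep away from clipping
        )
        ds = simulate_dataset(cfg)
        cols = {
            t: [
                ds.beta.sample_index(r.sample_id)
                for r in ds.sheet
                if r.sample_type is t
            ]
            for t in (SampleType.BCELL, SampleType.MONOCYTES)
        }
        sd_b = np.std(ds.beta.values[:, cols[SampleType.BCELL]], axis=1, ddof=1)
        sd_m = np.std(ds.beta.values[:, cols[SampleType.MONOCYTES]], axis=1, ddof=1)
        expected = np.sqrt((infl * s_e) ** 2 + s_m**2) / np.sqrt(s_e**2 + s_m**2)
        observed = sd_b.mean() / sd_m.mean()
        assert abs(observed - expected) / expected < 0.10

    def test_variance_propagation_fixed_w(self):
        # Var(wb) = sum w_c^2 Var(cell_c) at independent-deviation sites
        w = (0.1, 0.6, 0.15, 0.1, 0.05)
        cfg = SimulationConfig(
            n_sites=2000,
            seed=31,
            class_fractions=null_fractions(),
            sigma_e=0.02,
            sigma_measure=0.0,
            fixed_proportions=w,
            mean_beta_weights=(0.0, 1.0, 0.0),
        )
        ds = simulate_dataset(cfg)
        wb_cols = [
            ds.beta.sample_index(r.sample_id)
            for r in ds.sheet
            if r.sample_type is SampleType.WHOLE_BLOOD
        ]
        var_wb = np.var(ds.beta.values[:, wb_cols], axis=1, ddof=1).mean()
        expected = sum(wk**2 for wk in w) * cfg.sigma_e**2
        assert abs(var_wb - expected) / expected < 0.10


class TestAnnotationExport:
    def test_genetic_sites_marked(self, small_dataset):
        ann = small_dataset.truth.to_annotation_table().frame
        cls = small_dataset.truth.sites["site_class"]
        assert (ann.loc[cls == "genetic", "A"] == 1.0).all()
        assert (ann.loc[cls != "genetic", "E"] == 1.0).all()
        assert ann["has_mqtl"].equals(cls == "genetic")
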