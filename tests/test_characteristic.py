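import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methcovar.characteristic import (
    annotate_ewas,
    compute_characteristic_scores,
    enrichment_fold_change,
    global_characteristic_shares,
    one_sided_levene,
    residualize_by_celltype,
)
from methcovar.core_io import (
    CONSTITUENT_TYPES,
    EwasCatalogRecord,
    SampleType,
    ValidationError,
)
from methcovar.synthetic_data import (
    SimulationConfig,
    simulate_dataset,
    single_cell_class,
)
from tests.conftest import null_fractions


class TestResidualize:
    def test_type_means_removed(self, small_dataset):
        residuals, codes = residualize_by_celltype(
            small_dataset.beta, small_dataset.sheet
        )
        for g in range(5):
            means = np.nanmean(residuals[:, codes == g], axis=1)
            np.testing.assert_allclose(means, 0.0, atol=1e-10)

    def test_between_type_spread_irrelevant(self):
        # distinct type means with zero within-type noise -> all residuals 0
        ds = simulate_dataset(
            SimulationConfig(
                n_sites=10, seed=1, sigma_e=0.0, sigma_measure=0.0, sigma_g=0.0,
                class_fractions=null_fractions(mean_shift=1.0),
            )
        )
        residuals, _ = residualize_by_celltype(ds.beta, ds.sheet)
        np.testing.assert_allclose(residuals, 0.0, atol=1e-12)

    def test_location_invariance(self, small_dataset):
        residuals, codes = residualize_by_celltype(
            small_dataset.beta, small_dataset.sheet
        )
        shifted = small_dataset.beta.to_frame().copy()
        bcell_samples = [
            r.sample_id for r in small_dataset.sheet
            if r.sample_type is SampleType.BCELL
        ]
        shifted[bcell_samples] = np.clip(shifted[bcell_samples] + 0.001, 0, 1)
        from methcovar.core_io import BetaMatrix

        m2 = BetaMatrix(
            small_dataset.beta.site_ids,
            small_dataset.beta.sample_ids,
            shifted.values,
        )
        residuals2, _ = residualize_by_celltype(m2, small_dataset.sheet)
        np.testing.assert_allclose(residuals, residuals2, atol=1e-9)

    def test_idempotent(self, small_dataset):
        # residualizing already-centered data changes nothing
        residuals, codes = residualize_by_celltype(
            small_dataset.beta, small_dataset.sheet
        )
        for g in range(5):
            block = residuals[:, codes == g]
            centered = block - np.nanmean(block, axis=1, keepdims=True)
            np.testing.assert_allclose(block, centered, atol=1e-12)


class TestOneSidedLevene:
    def test_identical_multisets_symmetry_point(self):
        vals = np.array([1, 2, 3, 4.0])
        stat, p = one_sided_levene(vals, vals)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(0.5)

    def test_monotone_in_dispersion(self):
        rng = np.random.default_rng(0)
        others = rng.normal(0, 1, 20)
        target = rng.normal(0, 1, 20)
        _s1, p1 = one_sided_levene(target, others)
        scaled = (target - target.mean()) * 10 + target.mean()
        _s2, p2 = one_sided_levene(scaled, others)
        assert p2 < p1

    def test_matches_permutation_oracle(self):
        target = np.array([1, 2, 3, 4, 5.0])
        others = np.array([2, 3, 4.0])
        stat, p = one_sided_levene(target, others)
        pooled = np.concatenate([target, others])
        rng = np.random.default_rng(1)
        n_perm = 10_000
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            s_perm, _ = one_sided_levene(perm[:5], perm[5:])
            if s_perm >= stat - 1e-12:
                count += 1
        p_perm = count / n_perm
        # tiny groups: permutation null is coarse, so agreement is loose
        assert abs(p - p_perm) < 0.10

    def test_half_two_sided_identity(self):
        # one-tailed p == half of two-sided Levene p when stat > 0
        rng = np.random.default_rng(2)
        target = rng.normal(0, 3, 15)
        others = rng.normal(0, 1, 25)
        stat, p = one_sided_levene(target, others)
        assert stat > 0
        _W, p_two = stats.levene(target, others, center="mean")
        assert p == pytest.approx(p_two / 2, abs=1e-10)
        # and 1 - half when the target is the *less* dispersed group
        stat2, p2 = one_sided_levene(others, target)
        assert stat2 < 0
        assert p2 == pytest.approx(1 - p_two / 2, abs=1e-10)

    def test_degenerate_dispersion(self):
        stat, p = one_sided_levene(np.full(5, 1.0), np.full(4, 2.0))
        assert np.isnan(stat) and np.isnan(p)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            one_sided_levene(np.array([1.0]), np.array([1.0, 2.0]))


class TestCharacteristicScores:
    def test_vectorized_matches_scalar(self, small_dataset):
        scores = compute_characteristic_scores(small_dataset.beta, small_dataset.sheet)
        residuals, codes = residualize_by_celltype(
            small_dataset.beta, small_dataset.sheet
        )
        rng = np.random.default_rng(3)
        for s in rng.choice(len(scores), size=10, replace=False):
            for g, c in enumerate(CONSTITUENT_TYPES):
                stat, p = one_sided_levene(
                    residuals[s, codes == g], residuals[s, codes != g]
                )
                assert scores.iloc[s][f"stat_{c.value}"] == pytest.approx(stat, rel=1e-9)
                assert scores.iloc[s][f"p_{c.value}"] == pytest.approx(p, rel=1e-9)

    def test_null_no_characteristic_sites(self):
        ds = simulate_dataset(
            SimulationConfig(n_sites=5000, seed=4, class_fractions=null_fractions())
        )
        scores = compute_characteristic_scores(ds.beta, ds.sheet)
        assert (scores["characteristic_of"] == "").all()

    def test_inflated_cell_recovered_at_relaxed_alpha(self):
        # bcell residual SD 5x others at n=28/type -> detected at 1e-4
        ds = simulate_dataset(
            SimulationConfig(
                n_sites=200, seed=5,
                class_fractions=null_fractions(**{single_cell_class(SampleType.BCELL): 1.0}),
                sigma_cell_inflate=5.0, sigma_e=0.02, sigma_measure=0.005,
            )
        )
        scores = compute_characteristic_scores(ds.beta, ds.sheet, alpha_char=1e-4)
        rate = (scores["characteristic_of"] == "bcell").mean()
        assert rate >= 0.90

    def test_classification_requires_exactly_one(self):
        frame = pd.DataFrame(
            {
                "characteristic_of": ["", ""],
            }
        )
        # constructed directly through the scoring path: a site with two
        # inflated types must not be classified
        ds = simulate_dataset(
            SimulationConfig(
                n_sites=50, seed=6,
                class_fractions=null_fractions(**{single_cell_class(SampleType.BCELL): 1.0}),
                sigma_cell_inflate=8.0, sigma_e=0.02, sigma_measure=0.0,
            )
        )
        scores = compute_characteristic_scores(ds.beta, ds.sheet, alpha_char=0.4)
        multi = scores[scores["n_passing"] >= 2]
        assert (multi["characteristic_of"] == "").all()


class TestAnnotateEwas:
    def _scores(self):
        return pd.DataFrame(
            {
                "characteristic_of": ["bcell", "", "cd4t"],
            },
            index=pd.Index(["cg1", "cg2", "cg3"], name="site_id"),
        )

    def _hit(self, site, trait="bmi", p=1e-9, tissue="whole blood"):
        return EwasCatalogRecord(site_id=site, trait=trait, p_value=p, tissue=tissue)

    def test_join_semantics(self):
        hits = [self._hit("cg1"), self._hit("cg2"), self._hit("cg9")]
        out = annotate_ewas(hits, self._scores())
        assert len(out) == 3
        assert out.set_index("site_id").loc["cg1", "characteristic_of"] == "bcell"
        assert out.set_index("site_id").loc["cg2", "characteristic_of"] == ""
        assert not out.set_index("site_id").loc["cg9", "assessed"]

    def test_p_and_tissue_filters(self):
        hits = [
            self._hit("cg1", p=1e-6),  # above threshold
            self._hit("cg1", tissue="saliva"),
            self._hit("cg3"),
        ]
        out = annotate_ewas(hits, self._scores())
        assert list(out["site_id"]) == ["cg3"]

    def test_empty_intersection(self):
        out = annotate_ewas([self._hit("cgX")], self._scores().iloc[:0])
        assert len(out) == 1 and not out["assessed"].iloc[0]


class TestEnrichment:
    def _annotated(self, counts: dict[str, int], trait="t1"):
        rows = []
        i = 0
        for cell, n in counts.items():
            for _ in range(n):
                rows.append({"site_id": f"cg{i}", "trait": trait,
                             "characteristic_of": cell})
                i += 1
        return pd.DataFrame(rows)

    def test_matching_shares_give_unit_fold_change(self):
        shares = {"monocytes": 0.5, "bcell": 0.25, "cd4t": 0.25}
        annotated = self._annotated({"monocytes": 8, "bcell": 4, "cd4t": 4})
        table, skipped = enrichment_fold_change(annotated, shares)
        assert skipped == []
        for cell in shares:
            assert table.loc["t1", f"fc_{cell}"] == pytest.approx(1.0)

    def test_concentrated_trait(self):
        shares = {"monocytes": 0.25, "bcell": 0.75}
        annotated = self._annotated({"monocytes": 10})
        table, _ = enrichment_fold_change(annotated, shares)
        assert table.loc["t1", "fc_monocytes"] == pytest.approx(4.0)
        assert table.loc["t1", "fc_bcell"] == 0.0

    def test_small_trait_skipped(self):
        shares = {"monocytes": 1.0}
        annotated = self._annotated({"monocytes": 3})
        table, skipped = enrichment_fold_change(annotated, shares)
        assert len(table) == 0
        assert skipped == ["t1"]

    def test_share_weighted_fold_changes_average_to_one(self):
        rng = np.random.default_rng(7)
        shares = {c.value: s for c, s in zip(CONSTITUENT_TYPES, (0.3, 0.3, 0.2, 0.1, 0.1))}
        frames = []
        for t in range(4):
            counts = {c.value: int(n) for c, n in
                      zip(CONSTITUENT_TYPES, rng.integers(1, 10, size=5))}
            frames.append(self._annotated(counts, trait=f"trait{t}"))
        annotated = pd.concat(frames, ignore_index=True)
        table, _ = enrichment_fold_change(annotated, shares)
        for trait, row in table.iterrows():
            total = sum(shares[c] * row[f"fc_{c}"] for c in shares)
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_global_shares_from_scores(self):
        scores = pd.DataFrame(
            {"characteristic_of": ["bcell", "bcell", "cd4t", ""]},
            index=pd.Index([f"cg{i}" for i in range(4)], name="site_id"),
        )
        shares = global_characteristic_shares(scores)
        assert shares["bcell"] == pytest.approx(2 / 3)
        assert shares["cd4t"] == pytest.approx(1 / 3)
        assert sum(shares.values()) == pytest.approx(1.0)

    def test_bad_shares_rejected(self):
        with pytest.raises(ValidationError, match="shares"):
            enrichment_fold_change(self._annotated({"bcell": 6}), {"bcell": 0.5})
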