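"""Synthetic cohort generator: sampling, threshold law, ascertainment, missingness."""

import numpy as np
import pandas as pd
import pytest

from mfim import (
    SimulationConfig,
    apply_diagnosis_filter,
    generate_cohort,
    inject_missingness,
    reading_from_factors,
    sample_factors,
)
from mfim.simulate import READING_COMPONENTS, exchangeable_correlation


class TestConfig:
    def test_defaults_match_target_cohort_structure(self):
        cfg = SimulationConfig()
        assert cfg.n_total == 266
        assert cfg.n_complete == 55
        assert len(cfg.factor_names) == 5
        assert cfg.diagnosis_cutoff == -2.0

    def test_non_positive_definite_matrix_rejected(self):
        bad = np.ones((5, 5))  # rank 1, unit diagonal
        cfg = SimulationConfig(factor_correlation=bad)
        with pytest.raises(ValueError, match="positive definite"):
            sample_factors(cfg)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SimulationConfig(gamma=2.5, tau=-0.5, seed=9)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = SimulationConfig.from_yaml(p)
        assert back.gamma == cfg.gamma
        assert back.tau == cfg.tau
        assert back.seed == cfg.seed
        np.testing.assert_array_equal(back.factor_correlation, cfg.factor_correlation)

    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(gamma=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(n_complete=300)


class TestFactors:
    def test_identity_correlation_uncorrelated_at_large_n(self):
        cfg = SimulationConfig(n_total=10_000, n_complete=10_000,
                               factor_correlation=np.eye(5), seed=3)
        z = sample_factors(cfg)
        emp = np.corrcoef(z.to_numpy(), rowvar=False)
        off = emp[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_near_unit_correlation_recovered(self):
        r = np.eye(5)
        r[0, 1] = r[1, 0] = 0.99
        cfg = SimulationConfig(n_total=1000, n_complete=1000,
                               factor_correlation=r, seed=4)
        z = sample_factors(cfg)
        assert np.corrcoef(z.iloc[:, 0], z.iloc[:, 1])[0, 1] > 0.9

    def test_fixed_seed_bit_identical(self):
        cfg = SimulationConfig(seed=5)
        pd.testing.assert_frame_equal(sample_factors(cfg), sample_factors(cfg))


class TestReading:
    def test_additive_degenerate_case_is_the_first_factor(self):
        cfg = SimulationConfig(
            n_total=50, n_complete=50, gamma=0.0,
            true_weights={"iq": 1.0, "phonological_awareness": 0.0, "ran_speed": 0.0,
                          "visual_search_speed": 0.0, "memory": 0.0},
            noise_sd=1e-12, component_noise_sd=0.0, seed=6,
        )
        factors = sample_factors(cfg)
        comps, mfi = reading_from_factors(factors, cfg)
        np.testing.assert_allclose(mfi, factors["iq"], atol=1e-12)
        for c in READING_COMPONENTS:
            np.testing.assert_allclose(comps[c], factors["iq"], atol=1e-6)

    def test_hinge_is_zero_at_the_threshold(self):
        """A child exactly at tau gets no amplification regardless of gamma."""
        for gamma in (0.0, 1.0, 5.0):
            assert gamma * min(0.0, 0.7 - 0.7) == 0.0
        cfg_a = SimulationConfig(n_total=200, n_complete=200, tau=-100.0, gamma=5.0,
                                 seed=7)
        cfg_b = SimulationConfig(n_total=200, n_complete=200, tau=-100.0, gamma=0.0,
                                 seed=7)
        comps_a, _ = reading_from_factors(sample_factors(cfg_a), cfg_a)
        comps_b, _ = reading_from_factors(sample_factors(cfg_b), cfg_b)
        # nobody is below a threshold of -100, so gamma is inert
        pd.testing.assert_frame_equal(comps_a, comps_b)

    def test_population_interaction_coefficient_is_negative(self):
        """Brute-force population regression under the hinge law: b3 < 0."""
        cfg = SimulationConfig(n_total=50_000, n_complete=50_000, seed=8)
        factors = sample_factors(cfg)
        comps, mfi = reading_from_factors(factors, cfg)
        y = comps[list(READING_COMPONENTS[:3])].mean(axis=1).to_numpy()
        x = factors["memory"].to_numpy()
        others = [f for f in cfg.factor_names if f != "memory"]
        w = cfg.true_weights
        of = sum(w[f] * factors[f].to_numpy() for f in others)
        X = np.column_stack([np.ones(len(y)), x, of, x * of])
        b = np.linalg.solve(X.T @ X, X.T @ y)
        assert b[3] < 0


class TestAscertainment:
    def _table(self):
        cfg = SimulationConfig(seed=9)
        factors = sample_factors(cfg)
        comps, _ = reading_from_factors(factors, cfg)
        return pd.concat([factors, comps], axis=1), cfg

    def test_unimpaired_child_excluded_and_impaired_retained(self):
        df = pd.DataFrame(
            {c: [0.0, -0.5] for c in READING_COMPONENTS},
            index=pd.Index(["ok", "low"], name="child_id"),
        )
        df.loc["low", "word_speed"] = -2.5
        kept = apply_diagnosis_filter(df)
        assert list(kept.index) == ["low"]

    def test_no_retained_child_violates_the_cutoff(self):
        table, cfg = self._table()
        kept = apply_diagnosis_filter(table, cfg.diagnosis_cutoff)
        assert (kept[list(READING_COMPONENTS)].min(axis=1) <= cfg.diagnosis_cutoff).all()

    def test_retained_fraction_strictly_inside_unit_interval(self):
        cfg = SimulationConfig(n_total=10_000, n_complete=10_000, seed=10)
        factors = sample_factors(cfg)
        comps, _ = reading_from_factors(factors, cfg)
        kept = apply_diagnosis_filter(pd.concat([factors, comps], axis=1))
        assert 0 < len(kept) < 10_000


class TestMissingness:
    def _table(self, n=80, seed=11):
        cfg = SimulationConfig(n_total=n, n_complete=55, seed=seed)
        factors = sample_factors(cfg)
        comps, _ = reading_from_factors(factors, cfg)
        return pd.concat([factors, comps], axis=1), cfg

    def test_complete_case_count_is_exact(self):
        table, cfg = self._table()
        out = inject_missingness(table, cfg)
        complete = out[list(cfg.factor_names)].notna().all(axis=1)
        assert complete.sum() == 55

    def test_n_complete_equal_to_size_means_no_missingness(self):
        table, cfg = self._table(n=55)
        out = inject_missingness(table, cfg)
        assert not out.isna().any().any()

    def test_reading_columns_never_deleted(self):
        table, cfg = self._table()
        out = inject_missingness(table, cfg)
        assert out[list(READING_COMPONENTS)].notna().all().all()

    def test_incomplete_children_lose_a_nonempty_predictor_subset(self):
        table, cfg = self._table()
        out = inject_missingness(table, cfg)
        incomplete = out[out[list(cfg.factor_names)].isna().any(axis=1)]
        assert (incomplete[list(cfg.factor_names)].isna().sum(axis=1) >= 1).all()

    def test_fixed_seed_identical_mask(self):
        table, cfg = self._table()
        pd.testing.assert_frame_equal(
            inject_missingness(table, cfg), inject_missingness(table, cfg)
        )

    def test_n_complete_exceeding_cohort_is_hard_error(self):
        table, cfg = self._table(n=80)
        with pytest.raises(ValueError, match="exceeds"):
            inject_missingness(table.iloc[:10], cfg)


class TestGenerateCohort:
    def test_default_config_yields_complete_case_subsample(self):
        cohort = generate_cohort(SimulationConfig(seed=12))
        t = cohort.table
        complete = t.data[list(cohort.config.factor_names)].notna().all(axis=1)
        assert complete.sum() == 55
        assert set(READING_COMPONENTS) <= set(t.columns)
        assert len(cohort.latent_mfi) == t.n_children

    def test_same_seed_identical_cohort(self):
        a = generate_cohort(SimulationConfig(seed=13))
        b = generate_cohort(SimulationConfig(seed=13))
        pd.testing.assert_frame_equal(a.table.data, b.table.data)
        pd.testing.assert_series_equal(a.latent_mfi, b.latent_mfi)

    def test_different_seeds_differ(self):
        a = generate_cohort(SimulationConfig(seed=14))
        b = generate_cohort(SimulationConfig(seed=15))
        assert not a.table.data.equals(b.table.data)

    def test_truth_record_written(self, tmp_path):
        cohort = generate_cohort(SimulationConfig(seed=16))
        p = tmp_path / "truth.yaml"
        cohort.write_truth(p)
        assert p.exists() and p.with_suffix(".config.yaml").exists()


def test_exchangeable_correlation_shape():
    r = exchangeable_correlation(4, 0.2)
    assert r.shape == (4, 4)
    assert (np.diag(r) == 1.0).all()
    assert r[0, 1] == 0.2
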