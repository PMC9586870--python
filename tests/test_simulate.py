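"""Generator behaviour: genome structure, spiked effects, forward model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cfmethyl import SimConfig, small_config
from cfmethyl.containers import derive_rng
from cfmethyl.simulate import (capture_mean, density_response, mixed_beta,
                               simulate_array, simulate_cfdna_sample,
                               simulate_cohort, simulate_counts,
                               simulate_genome, simulate_methylomes,
                               simulate_survival)


class TestGenome:
    def test_windows_are_contiguous_half_open_300bp(self):
        w = simulate_genome(small_config(seed=0))
        assert (w["end"] - w["start"] == 300).all()
        assert (w["start"].to_numpy() == np.arange(len(w)) * 300).all()

    def test_no_islands_means_background_rate_everywhere(self):
        cfg = small_config(seed=1, cgi_fraction=0.0)
        w = simulate_genome(cfg)
        assert not w["cgi"].any()
        # Poisson(2) mean over 4,000 windows
        assert w["cpg_count"].mean() == pytest.approx(cfg.cpg_rate_bg, abs=0.15)

    def test_same_seed_gives_identical_window_table(self):
        cfg = small_config(seed=5)
        pd.testing.assert_frame_equal(simulate_genome(cfg), simulate_genome(cfg))

    def test_cpg_tail_matches_exact_mixture_probability(self):
        """Fraction of CpG-dense windows equals the Poisson-mixture tail."""
        cfg = SimConfig(n_windows=10_000, cgi_fraction=0.1, seed=3)
        w = simulate_genome(cfg)
        expected = (cfg.cgi_fraction * stats.poisson.sf(9, cfg.cpg_rate_cgi)
                    + (1 - cfg.cgi_fraction) * stats.poisson.sf(9, cfg.cpg_rate_bg))
        observed = (w["cpg_count"] >= 10).mean()
        se = np.sqrt(expected * (1 - expected) / len(w))
        # island membership is correlated in runs, so allow a wide multiple
        assert abs(observed - expected) < 8 * se

    def test_qc_subset_flagged_on_background_windows(self):
        cfg = small_config(seed=2)
        w = simulate_genome(cfg)
        assert w["qc_always_methylated"].sum() == cfg.n_qc_windows
        assert not (w["qc_always_methylated"] & w["cgi"]).any()

    def test_too_few_windows_rejected(self):
        with pytest.raises(Exception, match="n_windows"):
            simulate_genome(small_config(n_windows=50, n_qc_windows=5))


class TestMethylomes:
    def test_hyper_hypo_split_matches_configured_fraction(self):
        cfg = small_config(seed=4, n_dmrs=100)
        w = simulate_genome(cfg)
        _, truth = simulate_methylomes(w, cfg)
        pan = truth[truth["role"] == "pan"]
        assert (pan["direction"] == 1).sum() == 69
        assert (pan["direction"] == -1).sum() == 31

    def test_no_pan_dmrs_means_tumor_equals_normal_outside_blocks(self):
        cfg = small_config(seed=4, n_dmrs=0)
        w = simulate_genome(cfg)
        meth, truth = simulate_methylomes(w, cfg)
        block = np.zeros(len(w), dtype=bool)
        block[truth["window"].to_numpy()] = True
        for s in ("ASCL1", "NEUROD1", "DN"):
            np.testing.assert_allclose(meth[f"tumor_{s}"].beta[~block],
                                       meth["normal"].beta[~block])

    def test_subtype_blocks_separate_the_discriminated_classes(self):
        cfg = small_config(seed=4)
        w = simulate_genome(cfg)
        meth, truth = simulate_methylomes(w, cfg)
        eff = cfg.dmr_effect_size
        for s in ("ASCL1", "NEUROD1", "DN"):
            rows = truth[truth["role"] == s]
            others = [t for t in ("ASCL1", "NEUROD1", "DN") if t != s]
            for _, r in rows.iterrows():
                j = int(r["window"])
                for o in others:
                    gap = meth[f"tumor_{s}"].beta[j] - meth[f"tumor_{o}"].beta[j]
                    assert abs(gap) >= eff - 1e-9
                    assert np.sign(gap) == r["direction"]

    def test_dmr_mask_marks_exactly_the_spiked_windows(self):
        cfg = small_config(seed=4)
        w = simulate_genome(cfg)
        meth, truth = simulate_methylomes(w, cfg)
        for s in ("ASCL1", "NEUROD1", "DN"):
            mask = meth[f"tumor_{s}"].dmr_mask
            spiked = set(truth.loc[truth["role"].isin(["pan", s]), "window"])
            assert set(np.flatnonzero(mask != 0)) == spiked

    def test_dmr_demand_beyond_genome_raises(self):
        cfg = small_config(seed=4, n_dmrs=3000)
        w = simulate_genome(cfg)
        with pytest.raises(Exception, match="DMR demand"):
            simulate_methylomes(w, cfg)


class TestCounts:
    def test_unmethylated_genome_expects_uniform_background_capture(self):
        cfg = small_config(seed=6, excluded_fraction=0.0)
        w = simulate_genome(cfg)
        mu = capture_mean(np.zeros(len(w)), w, cfg)
        np.testing.assert_allclose(mu, cfg.library_size / len(w))

    def test_expected_ratio_methylated_vs_not_matches_closed_form(self):
        cfg = small_config(seed=6, excluded_fraction=0.0)
        w = simulate_genome(cfg).iloc[:2].copy()
        w["cpg_count"] = 10
        g = density_response(np.array([10.0]), cfg)[0]
        mu = capture_mean(np.array([1.0, 0.0]), w, cfg)
        assert mu[0] / mu[1] == pytest.approx(
            (cfg.background_capture + g) / cfg.background_capture)

    def test_monte_carlo_mean_matches_model_mean(self):
        cfg = small_config(seed=6, n_windows=300, library_size=30_000,
                           n_dmrs=20, n_subtype_dmrs_per_contrast=5,
                           n_qc_windows=10)
        w = simulate_genome(cfg)
        meth, _ = simulate_methylomes(w, cfg)
        mu = capture_mean(meth["normal"].beta, w, cfg)
        rng = derive_rng(0, 77)
        reps = np.vstack([simulate_counts(meth["normal"].beta, w, cfg, rng)
                          for _ in range(200)])
        se = np.sqrt((mu + cfg.dispersion * mu ** 2) / 200)
        z = (reps.mean(axis=0) - mu) / np.maximum(se, 1e-9)
        # all but a handful of 300 windows within 3 s.e.
        assert (np.abs(z) < 3).mean() > 0.98

    def test_realized_totals_near_library_size(self):
        cfg = small_config(seed=6)
        w = simulate_genome(cfg)
        meth, _ = simulate_methylomes(w, cfg)
        counts = simulate_counts(meth["normal"].beta, w, cfg, 1)
        mu = capture_mean(meth["normal"].beta, w, cfg)
        sd_total = np.sqrt((mu + cfg.dispersion * mu ** 2).sum())
        assert abs(counts.sum() - cfg.library_size) < 4 * sd_total


class TestCfdnaMixture:
    def test_mixture_beta_is_exact_convex_combination(self):
        t, n = np.array([1.0, 0.3]), np.array([0.0, 0.5])
        np.testing.assert_allclose(mixed_beta(t, n, 0.5), [0.5, 0.4])

    @pytest.mark.parametrize("tf", [-0.1, 1.2])
    def test_tumor_fraction_outside_unit_interval_rejected(self, tf):
        with pytest.raises(ValueError, match="tumor fraction"):
            mixed_beta(np.array([1.0]), np.array([0.0]), tf)

    def test_extreme_fractions_reproduce_pure_samples_in_expectation(self):
        cfg = small_config(seed=6)
        w = simulate_genome(cfg)
        meth, _ = simulate_methylomes(w, cfg)
        t, n = meth["tumor_ASCL1"].beta, meth["normal"].beta
        np.testing.assert_allclose(capture_mean(mixed_beta(t, n, 0.0), w, cfg),
                                   capture_mean(n, w, cfg))
        np.testing.assert_allclose(capture_mean(mixed_beta(t, n, 1.0), w, cfg),
                                   capture_mean(t, w, cfg))
        counts, truth = simulate_cfdna_sample(t, n, 0.25, w, cfg, 3)
        assert truth["tumor_fraction"] == 0.25
        assert counts.sum() > 0


class TestArray:
    def test_zero_noise_probes_equal_window_beta(self):
        cfg = small_config(seed=7, array_noise_sd=0.0)
        w = simulate_genome(cfg)
        meth, _ = simulate_methylomes(w, cfg)
        prof = simulate_array(meth["normal"], w, cfg, 1)
        np.testing.assert_allclose(prof["beta"].to_numpy(),
                                   meth["normal"].beta[prof["window"]])

    def test_probe_multiplicity_follows_the_configured_law(self):
        cfg = small_config(seed=7, probes_per_window=(0.0, 0.0, 1.0))
        w = simulate_genome(cfg)
        meth, _ = simulate_methylomes(w, cfg)
        prof = simulate_array(meth["normal"], w, cfg, 1)
        per_window = prof.groupby("window").size()
        assert (per_window == 3).all()
        assert len(per_window) == (~w["excluded"]).sum()

    def test_probe_error_matches_folded_normal_mean(self):
        cfg = small_config(seed=7, array_noise_sd=0.05)
        w = simulate_genome(cfg)
        beta = np.full(len(w), 0.5)  # interior, so truncation never bites
        prof = simulate_array(beta, w, cfg, 2)
        observed = np.abs(prof["beta"] - 0.5).mean()
        expected = cfg.array_noise_sd * np.sqrt(2 / np.pi)
        assert observed == pytest.approx(expected, rel=0.05)


class TestSurvival:
    def _samples(self, n, rng):
        return pd.DataFrame({"tumor_fraction": rng.uniform(0.05, 0.5, n)},
                            index=[f"p{i}" for i in range(n)])

    def test_null_hazard_is_independent_of_tumor_fraction(self):
        cfg = small_config(seed=8, surv_log_hr=0.0, censor_rate=0.0)
        out = simulate_survival(self._samples(3000, derive_rng(1, 1)), cfg, 2)
        r = np.corrcoef(out["tumor_fraction"], out["os_months"])[0, 1]
        assert abs(r) < 0.05

    def test_zero_censoring_observes_every_event(self):
        cfg = small_config(seed=8, censor_rate=0.0)
        out = simulate_survival(self._samples(200, derive_rng(1, 2)), cfg, 3)
        assert (out["os_event"] == 1).all()

    def test_higher_burden_shortens_survival(self):
        cfg = small_config(seed=8, censor_rate=0.0)
        out = simulate_survival(self._samples(3000, derive_rng(1, 3)), cfg, 4)
        hi = out["tumor_fraction"] > 0.3
        assert out.loc[hi, "os_months"].median() < out.loc[~hi, "os_months"].median()


class TestCohort:
    def test_every_sample_has_a_truth_record(self, cohort_small):
        c = cohort_small
        assert set(c.counts.samples) <= set(c.samples.index)
        for sid in c.samples.index[c.samples["sample_type"] == "cfdna_sclc"]:
            assert 0 <= c.samples.loc[sid, "tumor_fraction"] <= 1
            assert c.true_beta(sid).shape == (len(c.windows),)
        arr_samples = set(c.arrays["sample_id"])
        cl = set(c.samples.index[c.samples["sample_type"] == "cell_line_array"])
        assert arr_samples == cl
        assert set(c.expression.index) >= cl

    def test_same_seed_reproduces_the_cohort(self, tiny_config):
        a, b = simulate_cohort(tiny_config), simulate_cohort(tiny_config)
        pd.testing.assert_frame_equal(a.counts.counts, b.counts.counts)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        np.testing.assert_array_equal(a.methylomes["normal"].beta,
                                      b.methylomes["normal"].beta)
        pd.testing.assert_frame_equal(a.arrays, b.arrays)
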