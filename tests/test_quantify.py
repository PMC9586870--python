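"""TMM normalization, blind calibration, beta estimation, QC, PCA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from cfmethyl import small_config
from cfmethyl.containers import CalibrationTable, CountMatrix, derive_rng
from cfmethyl.quantify import (estimate_beta, fit_calibration,
                               pca_variable_windows, pooled_reference,
                               qc_always_methylated, qc_sample,
                               relative_enrichment, tmm_factor, tmm_normalize)
from cfmethyl.simulate import (capture_mean, density_response,
                               simulate_genome, simulate_methylomes)


def _count_matrix(cols: dict) -> CountMatrix:
    df = pd.DataFrame(cols)
    return CountMatrix(df, df.sum(axis=0).astype(float))


class TestTMM:
    def test_sample_identical_to_reference_gets_factor_one(self):
        rng = derive_rng(0, 1)
        ref = rng.poisson(50, 2000)
        assert tmm_factor(ref, ref) == pytest.approx(1.0, abs=1e-12)

    def test_doubling_counts_leaves_nrpm_invariant(self):
        rng = derive_rng(0, 2)
        ref = rng.poisson(50, 2000) + 1
        cm = _count_matrix({"ref": ref, "x2": ref * 2})
        cm = tmm_normalize(cm, reference="ref")
        nrpm = cm.nrpm()
        np.testing.assert_allclose(nrpm["x2"], nrpm["ref"], rtol=1e-9)

    def test_factor_matches_brute_force_trimmed_mean_oracle(self):
        rng = derive_rng(0, 3)
        ref = rng.poisson(80, 1000) + 1
        obs = rng.poisson(80, 1000) + 1
        de = rng.choice(1000, 50, replace=False)
        obs[de] = obs[de] * 6  # 5% differential windows

        # independent oracle: unweighted trimmed mean of M over the A-trimmed set
        n_obs, n_ref = obs.sum(), ref.sum()
        m = np.log2((obs / n_obs) / (ref / n_ref))
        a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
        keep = np.ones(1000, bool)
        for vals, frac in ((m, 0.30), (a, 0.05)):
            lo, hi = np.quantile(vals, [frac, 1 - frac])
            keep &= (vals >= lo) & (vals <= hi)
        oracle = 2 ** m[keep].mean()

        fitted = tmm_factor(obs, ref)
        assert fitted == pytest.approx(oracle, rel=0.02)

    def test_no_overlap_yields_factor_one_with_warning(self):
        obs = np.array([0, 0, 5, 5])
        ref = np.array([5, 5, 0, 0])
        with pytest.warns(UserWarning, match="factor set to 1"):
            assert tmm_factor(obs, ref) == 1.0


@pytest.fixture(scope="module")
def genome():
    cfg = small_config(seed=11)
    w = simulate_genome(cfg)
    meth, _ = simulate_methylomes(w, cfg)
    return cfg, w, meth


class TestCalibration:
    def test_true_anchor_calibration_inverts_exactly(self, genome):
        """With the forward model's own anchors, beta comes back exactly."""
        cfg, w, meth = genome
        beta_true = meth["normal"].beta
        mu = capture_mean(beta_true, w, cfg, library_size=4e6)
        cm = CountMatrix(pd.DataFrame({"ref": mu}),
                         pd.Series({"ref": float(mu.sum())}))
        g = density_response(w["cpg_count"].to_numpy(), cfg)
        use = ~w["excluded"].to_numpy()
        total_w = (cfg.background_capture + beta_true * g)[use].sum()
        d_vals = np.unique(w["cpg_count"][use])
        g_d = density_response(d_vals, cfg)
        cal = CalibrationTable(pd.DataFrame({
            "d_min": d_vals, "d_max": d_vals, "d_mean": d_vals.astype(float),
            "bg": 1e6 * cfg.background_capture / total_w,
            "full": 1e6 * (cfg.background_capture + g_d) / total_w,
            "n": 1}))
        beta = estimate_beta(cm, cal, w, min_expected=0.1)["ref"].to_numpy()
        ok = use & (w["cpg_count"].to_numpy() >= 1)
        np.testing.assert_allclose(beta[ok], beta_true[ok], atol=1e-9)

    def test_blind_calibration_recovers_beta_up_to_anchor_bias(self, genome):
        """Blind anchors carry a small systematic bias, nothing more.

        The most-enriched decile per stratum sits slightly above the
        assumed calibration level (always-methylated windows land there),
        so the noiseless inversion is biased low by a bounded amount while
        remaining tightly correlated with the truth.
        """
        cfg, w, meth = genome
        beta_true = meth["normal"].beta
        mu = capture_mean(beta_true, w, cfg, library_size=4e6)
        cm = CountMatrix(pd.DataFrame({"ref": np.rint(mu).astype(int)}),
                         pd.Series({"ref": float(np.rint(mu).sum())}))
        cal = fit_calibration(cm, w, pool=["ref"])
        beta = estimate_beta(cm, cal, w)["ref"].to_numpy()
        d = w["cpg_count"].to_numpy()
        ok = (d >= 3) & ~np.isnan(beta)
        err = beta[ok] - beta_true[ok]
        assert np.sqrt(np.mean(err ** 2)) < 0.12
        assert np.corrcoef(beta[ok], beta_true[ok])[0, 1] > 0.98

    def test_span_tracks_the_density_response(self, genome):
        cfg, w, meth = genome
        mu = capture_mean(meth["normal"].beta, w, cfg, library_size=4e6)
        cm = CountMatrix(pd.DataFrame({"ref": np.rint(mu).astype(int)}),
                         pd.Series({"ref": float(np.rint(mu).sum())}))
        cal = fit_calibration(cm, w, pool=["ref"])
        from scipy.stats import spearmanr
        g = density_response(cal.strata["d_mean"].to_numpy(), cfg)
        span = (cal.strata["full"] - cal.strata["bg"]).to_numpy()
        assert spearmanr(span, g).statistic >= 0.95

    def test_zero_density_stratum_has_negligible_span(self, genome):
        cfg, w, meth = genome
        mu = capture_mean(meth["normal"].beta, w, cfg, library_size=4e6)
        cm = CountMatrix(pd.DataFrame({"ref": np.rint(mu).astype(int)}),
                         pd.Series({"ref": float(np.rint(mu).sum())}))
        cal = fit_calibration(cm, w, pool=["ref"])
        row0 = cal.strata.iloc[0]
        assert row0["d_min"] == 0
        span0 = row0["full"] - row0["bg"]
        top_span = (cal.strata["full"] - cal.strata["bg"]).max()
        assert span0 < 0.1 * top_span

    def test_full_is_monotone_and_above_background(self, genome):
        cfg, w, meth = genome
        mu = capture_mean(meth["normal"].beta, w, cfg, library_size=4e6)
        cm = CountMatrix(pd.DataFrame({"ref": np.rint(mu).astype(int)}),
                         pd.Series({"ref": float(np.rint(mu).sum())}))
        cal = fit_calibration(cm, w, pool=["ref"])
        full = cal.strata["full"].to_numpy()
        assert (np.diff(full) >= -1e-9).all()
        assert (full >= cal.strata["bg"].to_numpy() - 1e-9).all()


class TestEstimateBeta:
    @pytest.fixture
    def setup(self):
        windows = pd.DataFrame({
            "contig": "c", "start": [0, 300, 600], "end": [300, 600, 900],
            "cpg_count": [10, 10, 10], "excluded": [False, False, True],
            "qc_always_methylated": False, "cgi": False})
        cal = CalibrationTable(pd.DataFrame(
            {"d_min": [10], "d_max": [10], "d_mean": [10.0],
             "bg": [10.0], "full": [110.0], "n": [100]}))
        return windows, cal

    def test_anchors_map_to_zero_and_one(self, setup):
        windows, cal = setup
        lib = 1e6
        counts = CountMatrix(pd.DataFrame({"s": [10, 110, 60]}),
                             pd.Series({"s": lib}))
        beta = estimate_beta(counts, cal, windows)["s"]
        assert beta.iloc[0] == pytest.approx(0.0)
        assert beta.iloc[1] == pytest.approx(1.0)
        assert np.isnan(beta.iloc[2])  # excluded window

    def test_small_dynamic_range_returns_missing(self, setup):
        windows, cal = setup
        cal.strata.loc[0, "full"] = 10.5  # span below the 1-nrpm default
        counts = CountMatrix(pd.DataFrame({"s": [10, 11, 10]}),
                             pd.Series({"s": 1e6}))
        beta = estimate_beta(counts, cal, windows)["s"]
        assert beta.isna().all()


class TestQC:
    @pytest.fixture
    def windows(self):
        w = simulate_genome(small_config(seed=12))
        return w

    def test_uniform_counts_give_unit_enrichment(self, windows):
        counts = np.ones(len(windows))
        assert relative_enrichment(counts, windows) == pytest.approx(1.0)

    def test_all_mass_on_densest_window_gives_dmax_over_mean(self, windows):
        use = ~windows["excluded"].to_numpy()
        d = windows["cpg_count"].to_numpy().astype(float)
        j = np.flatnonzero(use)[np.argmax(d[use])]
        counts = np.zeros(len(windows))
        counts[j] = 500
        assert relative_enrichment(counts, windows) == pytest.approx(
            d[use].max() / d[use].mean())

    def test_density_proportional_counts_match_closed_form(self, windows):
        use = ~windows["excluded"].to_numpy()
        d = windows["cpg_count"].to_numpy().astype(float)
        counts = np.where(use, d, 0.0)
        expected = (d[use] ** 2).sum() / (d[use].sum() * d[use].mean())
        assert relative_enrichment(counts, windows) == pytest.approx(expected)

    def test_zero_counts_fail_with_undefined_ratio(self, windows):
        assert np.isnan(relative_enrichment(np.zeros(len(windows)), windows))

    def test_always_methylated_fraction_and_edge_cases(self, windows):
        beta = pd.Series(1.0, index=range(len(windows)))
        assert qc_always_methylated(beta, windows) == 1.0
        beta[:] = np.nan
        assert qc_always_methylated(beta, windows) == 0.0
        bare = windows.copy()
        bare["qc_always_methylated"] = False
        with pytest.raises(ValueError, match="QC windows"):
            qc_always_methylated(beta, bare)

    def test_good_sample_passes_and_shuffled_sample_fails(self, quant_small):
        q = quant_small
        windows = q.cohort.windows
        sid = q.counts.samples[0]
        rep = qc_sample(q.counts, q.beta, windows, sid)
        assert rep.pass_enrichment and rep.pass_always_methylated
        for seed in range(5):
            rng = derive_rng(seed, 55)
            shuffled = q.beta.copy()
            shuffled[sid] = rng.permutation(q.beta[sid].to_numpy())
            frac = qc_always_methylated(shuffled[sid], windows)
            assert frac < 0.40  # QC windows lose their methylated status


class TestPCA:
    def test_identical_samples_are_degenerate(self):
        beta = pd.DataFrame(np.tile(np.linspace(0, 1, 50)[:, None], (1, 4)),
                            columns=list("abcd"))
        out = pca_variable_windows(beta, k_windows=50)
        assert out["degenerate"]

    def test_constant_batch_offset_removed_exactly(self):
        rng = derive_rng(0, 9)
        base = rng.random((200, 6))
        beta = pd.DataFrame(base, columns=list("abcdef"))
        shifted = beta.copy()
        shifted[list("abc")] += 0.2  # batch 1 offset
        batch = pd.Series(["b1"] * 3 + ["b2"] * 3, index=list("abcdef"))
        ref = pca_variable_windows(beta, batch=batch, k_windows=200)
        got = pca_variable_windows(shifted, batch=batch, k_windows=200)
        np.testing.assert_allclose(np.abs(got["coordinates"].to_numpy()),
                                   np.abs(ref["coordinates"].to_numpy()),
                                   atol=1e-8)

    def test_three_subtype_cohort_separates_on_first_components(self, quant_small):
        q = quant_small
        s = q.cohort.samples
        tumors = s.index[s["sample_type"] == "tissue_tumor"]
        labels = s.loc[tumors, "class_label"].to_numpy()
        out = pca_variable_windows(q.beta[list(tumors)],
                                   batch=s.loc[tumors, "batch"],
                                   k_windows=2000, n_components=3)
        coords = out["coordinates"].iloc[:, :2].to_numpy()
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(coords)
        assert adjusted_rand_score(labels, km.labels_) >= 0.9
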