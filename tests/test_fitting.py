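"""Staged-fit, model-selection and bootstrap tests."""

import numpy as np
import pytest

from allokin import fitting, synth


def relerr(a, b):
    return abs(a / b - 1)


class TestGoodnessOfFit:
    def test_perfect_prediction(self):
        r2, rss = fitting.goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (r2, rss) == (1.0, 0.0)

    def test_mean_prediction(self):
        obs = np.array([1.0, 2.0, 3.0])
        r2, rss = fitting.goodness_of_fit(obs, np.full(3, 2.0))
        assert r2 == pytest.approx(0.0)
        assert rss == pytest.approx(2.0)  # = TSS

    def test_hand_arithmetic(self):
        r2, rss = fitting.goodness_of_fit([1.0, 2.0, 3.0], [1.0, 2.0, 4.0])
        assert rss == pytest.approx(1.0)
        assert r2 == pytest.approx(0.5)

    def test_zero_tss_sentinel(self):
        r2, rss = fitting.goodness_of_fit([2.0, 2.0], [2.0, 2.1])
        assert np.isnan(r2)


class TestTurnoverStage:
    def test_noiseless_parameter_recovery(self, h20s):
        profile = synth.model_profile(h20s)
        stage = fitting.fit_turnover_stage(profile, h20s.n)
        for name in ("kcat_A", "kcat_B", "K_AL", "K_BL", "L_L"):
            assert relerr(stage.params[name], getattr(h20s, name)) < 0.01

    def test_flat_profile_degenerates(self, a3dn):
        profile = synth.model_profile(a3dn)  # equal turnover numbers
        stage = fitting.fit_turnover_stage(profile, a3dn.n)
        assert stage.degenerate
        assert stage.params["kcat_A"] == stage.params["kcat_B"]
        assert stage.params["kcat_A"] == pytest.approx(a3dn.kcat_A, rel=1e-9)
        assert stage.status["K_BL"] == "degenerate"

    def test_requires_modulator_free_point(self, h20s):
        profile = synth.model_profile(h20s, modulator_uM=[0.1, 0.3, 1, 3, 10])
        with pytest.raises(ValueError, match="L = 0"):
            fitting.fit_turnover_stage(profile, 3)


class TestAffinityStage:
    def test_noiseless_recovery_h20s(self, h20s):
        profile = synth.model_profile(h20s)
        stage1 = fitting.fit_turnover_stage(profile, h20s.n)
        stage2 = fitting.fit_affinity_stage(profile, stage1, h20s.n, h20s.m)
        for name in ("K_AU", "K_BU", "L_U"):
            assert relerr(stage2.params[name], getattr(h20s, name)) < 0.02

    def test_noiseless_recovery_y20s_inhibitory_constant(self, y20s):
        profile = synth.model_profile(y20s)
        stage1 = fitting.fit_turnover_stage(profile, y20s.n)
        stage2 = fitting.fit_affinity_stage(profile, stage1, y20s.n, y20s.m)
        assert relerr(stage2.params["K_BI"], y20s.K_BI) < 0.02

    def test_symmetric_scheme_stages_agree(self, h20s):
        scheme = h20s.replace(
            K_AU=h20s.K_AL, K_BU=h20s.K_BL, L_U=h20s.L_L, m=0, K_BI=0.0
        )
        profile = synth.model_profile(scheme)
        stage1 = fitting.fit_turnover_stage(profile, scheme.n)
        stage2 = fitting.fit_affinity_stage(profile, stage1, scheme.n, scheme.m)
        assert relerr(stage2.params["K_AU"], stage1.params["K_AL"]) < 0.01
        assert relerr(stage2.params["K_BU"], stage1.params["K_BL"]) < 0.01
        assert relerr(stage2.params["L_U"], stage1.params["L_L"]) < 0.01

    def test_stage_one_parameters_frozen_bit_identical(self, h20s):
        profile = synth.model_profile(h20s)
        stage1 = fitting.fit_turnover_stage(profile, h20s.n)
        result = fitting.fit_scheme(profile, h20s.n, h20s.m)
        for name in ("kcat_A", "kcat_B", "K_AL", "K_BL", "L_L"):
            assert getattr(result.scheme, name) == stage1.params[name]


class TestSiteNumberSelection:
    def test_human_like_minimum_model(self, h20s_selection):
        assert (h20s_selection.n, h20s_selection.m) == (3, 0)

    def test_yeast_like_minimum_model(self, y20s_selection):
        assert (y20s_selection.n, y20s_selection.m) == (2, 1)

    def test_single_site_scheme_recovered(self, h20s):
        scheme = h20s.replace(n=1)
        profile = synth.model_profile(scheme)
        selection = fitting.select_site_numbers(
            profile, n_candidates=(1, 2, 3), m_candidates=(0, 1)
        )
        assert (selection.n, selection.m) == (1, 0)

    def test_rss_monotone_in_site_number(self, h20s_selection):
        # on noiseless cooperative data, under-parameterized n fits worse
        table = h20s_selection.table
        rss_by_n = table[table["m"] == 0].set_index("n")["rss_turnover"]
        assert rss_by_n[3] < rss_by_n[2] < rss_by_n[1]

    def test_gate_disrupted_mutant_with_known_bindings(self, a3dn):
        profile = synth.model_profile(a3dn)
        known = {
            k: getattr(a3dn, k) for k in ("K_AU", "K_BU", "K_AL", "K_BL", "K_BI")
        }
        selection = fitting.select_site_numbers(
            profile, equal_kcat=True, fixed_params=known
        )
        assert (selection.n, selection.m) == (2, 1)
        fit = selection.best_fit
        for name in ("kcat_A", "km_0", "km_B", "L_U", "L_L"):
            assert relerr(getattr(fit.scheme, name), getattr(a3dn, name)) < 0.01

    def test_empty_candidates_rejected(self, h20s):
        profile = synth.model_profile(h20s)
        with pytest.raises(ValueError):
            fitting.select_site_numbers(profile, n_candidates=())


class TestFitResult:
    def test_statuses_and_serialization(self, h20s_selection, tmp_path):
        fit = h20s_selection.best_fit
        assert fit.status["K_AI"] == "fixed"
        assert fit.status["kcat_A"] == "stage1:fitted"
        assert fit.status["K_AU"] == "stage2:fitted"
        assert fit.status["km_A"] == "tied:km_0"
        path = tmp_path / "fit.json"
        fit.to_json(path)
        doc = __import__("json").loads(path.read_text())
        assert doc["n"] == 3 and doc["m"] == 0
        assert doc["rss"]["total"] >= 0


class TestBootstrap:
    def test_noiseless_intervals_are_tight(self, h20s):
        profile = synth.model_profile(h20s)
        fit = fitting.fit_scheme(profile, h20s.n, h20s.m)
        ci = fitting.bootstrap_confidence(profile, fit, n_boot=100, seed=5, n_starts=1)
        for name, interval in ci.items():
            if name.startswith("_"):
                continue
            lo, hi = interval
            scale = abs(getattr(fit.scheme, name))
            assert hi - lo < 1e-6 * scale

    def test_seed_reproducibility(self, h20s):
        rng = np.random.default_rng(21)
        profile = synth.model_profile(h20s)
        for col in ("kcat_obs_per_s", "km_obs_uM", "eff_obs"):
            profile[col] = profile[col] * (1 + rng.normal(0, 0.02, len(profile)))
        fit = fitting.fit_scheme(profile, h20s.n, h20s.m)
        ci1 = fitting.bootstrap_confidence(profile, fit, n_boot=100, seed=9, n_starts=1)
        ci2 = fitting.bootstrap_confidence(profile, fit, n_boot=100, seed=9, n_starts=1)
        assert ci1 == ci2

    def test_minimum_replicates_enforced(self, h20s):
        profile = synth.model_profile(h20s)
        fit = fitting.fit_scheme(profile, h20s.n, h20s.m)
        with pytest.raises(ValueError):
            fitting.bootstrap_confidence(profile, fit, n_boot=50)

    def test_noisy_intervals_cover_well_identified_parameters(self, h20s):
        # scaled-down coverage check on the turnover parameters
        covered = total = 0
        for outer_seed in range(3):
            rng = np.random.default_rng(outer_seed)
            profile = synth.model_profile(h20s)
            for col in ("kcat_obs_per_s", "km_obs_uM", "eff_obs"):
                profile[col] = profile[col] * (1 + rng.normal(0, 0.05, len(profile)))
            fit = fitting.fit_scheme(profile, h20s.n, h20s.m)
            ci = fitting.bootstrap_confidence(
                profile, fit, n_boot=100, seed=outer_seed, n_starts=1
            )
            for name in ("kcat_A", "kcat_B", "km_0"):
                if name in ci:
                    lo, hi = ci[name]
                    covered += lo <= getattr(h20s, name) <= hi
                    total += 1
        assert covered / total >= 0.5
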