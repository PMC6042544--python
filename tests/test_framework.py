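"""The eight-step workflow: scoping, sweeps, selection, plots, sensitivity."""

import dataclasses
import filecmp

import numpy as np
import pandas as pd
import pytest

import lctmflow as lf
from lctmflow.adequacy import adequacy_report
from lctmflow.framework import SweepRecord, SweepResult
from conftest import make_fitted


@pytest.fixture(scope="module")
def fw_config():
    return lf.FrameworkConfig(fit=lf.FitConfig(n_starts=2, seed=3, max_iter=300))


class TestStep1Scoping:
    @pytest.mark.parametrize("code,expected", [("C", 0), ("E", 2)])
    def test_detects_generating_random_effect_order(self, code, expected, fw_config):
        sim = lf.simulate(lf.two_class_config(n_subjects=400, structure_code=code,
                                              seed=17))
        res = lf.step1_scoping(sim.dataset, 2, fw_config)
        assert res.suggestion == expected

    def test_pure_fixed_effect_data_reports_flat(self, fw_config):
        sim = lf.simulate(lf.two_class_config(n_subjects=400, structure_code="A",
                                              seed=17))
        res = lf.step1_scoping(sim.dataset, 2, fw_config)
        assert res.suggestion is None
        assert np.nanmax(res.variance_ratios) < fw_config.scoping_ratio_threshold


class TestSweeps:
    def test_class_sweep_anchors_k1_and_marks_best(self, three_class_sim, fw_config):
        cfg, sim = three_class_sim
        sweep = lf.sweep_classes(sim.dataset, "F", (1, 2, 3, 4), fw_config)
        assert [r.key for r in sweep.records] == [1, 2, 3, 4]
        assert sweep.record(1).converged  # K=1 always converges
        assert sweep.best_key == 3
        frame = sweep.to_frame()
        assert frame.loc[frame["candidate"] == 3, "selected"].item()

    def test_structure_sweep_rows_ordered_a_to_g(self, three_class_sim, fw_config):
        cfg, sim = three_class_sim
        sweep = lf.sweep_structures(sim.dataset, 2, ("D", "A", "C"), fw_config)
        assert [r.key for r in sweep.records] == ["A", "C", "D"]

    def test_true_structure_beats_fixed_effects_on_bic(self, three_class_sim, fw_config):
        cfg, sim = three_class_sim
        sweep = lf.sweep_structures(sim.dataset, 3, ("A", "F"), fw_config)
        assert sweep.record("F").bic < sweep.record("A").bic

    def test_nested_structures_with_unit_scales_differ_by_penalty(self, fw_config):
        """E and F coincide when all omega_k = 1, so BIC differs ~ by the
        extra K-1 scale parameters' penalty."""
        cfg = lf.two_class_config(n_subjects=500, structure_code="E", seed=29)
        sim = lf.simulate(cfg)
        sweep = lf.sweep_structures(sim.dataset, 2, ("E", "F"), fw_config)
        dbic = sweep.record("F").bic - sweep.record("E").bic
        penalty = np.log(sim.dataset.n_subjects)  # one extra parameter
        assert abs(dbic - penalty) < 0.5 * penalty + 2.0

    def test_failures_are_recorded_not_dropped(self, fw_config):
        # 2 observations per subject cannot support a random quadratic (q=3)
        rng = np.random.default_rng(0)
        frame = pd.DataFrame({
            "id": np.repeat(np.arange(40), 2),
            "time": np.tile([18.0, 50.0], 40),
            "y": rng.normal(25, 2, 80)})
        ds = lf.TrajectoryDataset(frame)
        sweep = lf.sweep_structures(ds, 1, ("A", "E"), fw_config)
        rec = sweep.record("E")
        assert not rec.converged
        assert rec.error is not None
        assert sweep.best_key == "A"


class TestSelectFavoured:
    def _record(self, key, bic_value, posterior, pi=None):
        K = posterior.shape[1]
        model = make_fitted(n_classes=K, pi=pi, posterior=posterior,
                            loglik=-bic_value / 2)
        rec = SweepRecord(key=key, structure=model.structure, model=model,
                          converged=True, bic=bic_value,
                          proportions=model.pi.tolist(), appa=None,
                          relative_entropy=None, dos=None,
                          adequacy=adequacy_report(model))
        return rec

    def test_single_passing_candidate_selected(self):
        sharp = np.tile([[0.98, 0.02], [0.02, 0.98]], (10, 1))
        sweep = SweepResult([self._record("F", 100.0, sharp)], best_key="F")
        sel = lf.select_favoured(sweep)
        assert sel.key == "F"
        assert sel.adequacy_passed

    def test_adequacy_overrides_lower_bic(self):
        sharp = np.tile([[0.98, 0.02], [0.02, 0.98]], (10, 1))
        fuzzy = np.tile([[0.55, 0.45], [0.45, 0.55]], (10, 1))
        sweep = SweepResult([self._record("A", 90.0, fuzzy),
                             self._record("F", 100.0, sharp)], best_key="A")
        sel = lf.select_favoured(sweep)
        assert sel.key == "F"
        assert sel.override_reason is not None

    def test_all_failing_returns_lowest_bic_with_flags(self):
        fuzzy = np.tile([[0.55, 0.45], [0.45, 0.55]], (10, 1))
        sweep = SweepResult([self._record("A", 90.0, fuzzy),
                             self._record("F", 100.0, fuzzy)], best_key="A")
        sel = lf.select_favoured(sweep)
        assert sel.key == "A"
        assert not sel.adequacy_passed
        assert sel.violations

    def test_no_converged_candidates_is_an_error(self):
        rec = SweepRecord(key="E", structure=lf.ModelStructure("E", 2), model=None,
                          converged=False, bic=None, proportions=None, appa=None,
                          relative_entropy=None, dos=None, error="failed")
        with pytest.raises(lf.NonConvergenceError):
            lf.select_favoured(SweepResult([rec], best_key=None))

    def test_sub_one_percent_class_flagged_never_deleted(self):
        post = np.vstack([np.tile([0.995, 0.005], (199, 1)),
                          [[0.005, 0.995]]])
        rec = self._record("F", 50.0, post, pi=[0.995, 0.005])
        sel = lf.select_favoured(SweepResult([rec], best_key="F"))
        assert sel.small_classes == [1]
        assert sel.model.n_classes == 2


class TestPlotData:
    def test_model_A_bands_have_constant_width(self, two_class_F):
        cfg, sim, _ = two_class_F
        model = make_fitted(n_classes=2, beta=[[20.0], [30.0]], sigma2=(4.0,),
                            posterior=np.tile([0.5, 0.5], (sim.dataset.n_subjects, 1)))
        out = lf.plot_data(model, sim.dataset, grid=[18.0, 35.0, 50.0])
        bands = out["bands"]
        width = bands["upper"] - bands["lower"]
        np.testing.assert_allclose(width, 2 * 1.96 * 2.0)

    def test_model_F_bands_widen_with_marginal_variance(self, two_class_F):
        cfg, sim, model = two_class_F
        grid = np.linspace(18, 62.5, 7)
        out = lf.plot_data(model, sim.dataset, grid=grid)
        bands = out["bands"][out["bands"]["class"] == 1]
        width = (bands["upper"] - bands["lower"]).to_numpy()
        s = model.structure
        X = np.vander(s.time_transform.apply(grid), 3, increasing=True)
        V = lf.marginal_covariance(model, X, 0)
        np.testing.assert_allclose(width, 2 * 1.96 * np.sqrt(np.diag(V)), rtol=1e-10)
        assert width.max() > width.min() + 1e-6

    def test_spaghetti_sample_is_seed_deterministic(self, two_class_F):
        cfg, sim, model = two_class_F
        a = lf.plot_data(model, sim.dataset, spaghetti_sample=10, seed=5)["spaghetti"]
        b = lf.plot_data(model, sim.dataset, spaghetti_sample=10, seed=5)["spaghetti"]
        c = lf.plot_data(model, sim.dataset, spaghetti_sample=10, seed=6)["spaghetti"]
        assert a.equals(b)
        assert not a.equals(c)


class TestConcordanceVsCategories:
    def test_classes_defined_by_categories_give_kappa_one(self):
        rng = np.random.default_rng(1)
        cats = rng.integers(0, 3, 200)
        post = np.eye(3)[cats]
        model = make_fitted(n_classes=3, posterior=post)
        rep = lf.concordance_vs_categories(model, cats, n_categories=3)
        assert rep.kappa == pytest.approx(1.0)
        assert rep.kappa_weighted == pytest.approx(1.0)

    def test_independent_categories_near_zero(self):
        rng = np.random.default_rng(2)
        post = np.eye(3)[rng.integers(0, 3, 5000)]
        cats = rng.integers(0, 3, 5000)
        model = make_fitted(n_classes=3, posterior=post)
        rep = lf.concordance_vs_categories(model, cats, n_categories=3)
        assert abs(rep.kappa) < 0.05

    def test_category_count_mismatch_rejected(self, two_class_F):
        _, _, model = two_class_F
        with pytest.raises(lf.DataError):
            lf.concordance_vs_categories(model, np.array([0, 1, 2]))

    def test_bmi_band_cut_points(self):
        vals = np.array([17.0, 18.5, 24.9, 25.0, 32.0, 40.0])
        np.testing.assert_array_equal(lf.bmi_categories(vals), [0, 1, 1, 2, 3, 4])


class TestSensitivity:
    def test_complete_cases_on_balanced_data_identical_to_main(self, two_class_F):
        cfg, sim, model = two_class_F
        recs = lf.sensitivity_refit(sim.dataset, cfg.structure, model,
                                    min_obs_list=(4,),
                                    fit_config=lf.FitConfig(n_starts=2, seed=5))
        rec = recs[0]
        assert not rec["failed"]
        assert rec["kappa_vs_main"] == pytest.approx(1.0)
        assert max(rec["max_trajectory_deviation"]) == pytest.approx(0.0, abs=1e-9)

    def test_random_thinning_preserves_trajectories(self):
        cfg = lf.two_class_config(n_subjects=500, structure_code="C", seed=37)
        cfg = dataclasses.replace(cfg, retention=0.7)
        sim = lf.simulate(cfg)
        fc = lf.FitConfig(n_starts=2, seed=5)
        model = lf.fit(sim.dataset, cfg.structure, fc)
        recs = lf.sensitivity_refit(sim.dataset, cfg.structure, model,
                                    min_obs_list=(2, 3), fit_config=fc)
        sigma = np.sqrt(cfg.sigma2[0])
        for rec in recs:
            assert not rec["failed"]
            assert rec["kappa_vs_main"] > 0.8
            assert max(rec["max_trajectory_deviation"]) < sigma

    def test_impossible_subset_recorded_as_failure(self, two_class_F):
        cfg, sim, model = two_class_F
        recs = lf.sensitivity_refit(sim.dataset, cfg.structure, model,
                                    min_obs_list=(9,))
        assert recs[0]["failed"]
        assert "error" in recs[0]


@pytest.fixture(scope="module")
def small_run(tmp_path_factory):
    cfg = lf.two_class_config(n_subjects=250, structure_code="C", seed=9)
    sim = lf.simulate(cfg)
    fw = lf.FrameworkConfig(k_range=(1, 2, 3), structures=("A", "C", "D"),
                            scoping_k=2, sensitivity_min_obs=(2,),
                            fit=lf.FitConfig(n_starts=2, seed=3, max_iter=200))
    out = tmp_path_factory.mktemp("run1")
    res = lf.run_pipeline(sim.dataset, fw, out_dir=out)
    return sim, fw, out, res


class TestPipeline:
    def test_end_to_end_emits_every_report(self, small_run):
        _, _, out, res = small_run
        expected = {"step2_classes.csv", "step3_structures.csv", "adequacy.json",
                    "selection.json", "trajectories.csv", "bands.csv",
                    "spaghetti.csv", "discrimination.json", "envelope.csv",
                    "concordance_categories.json", "sensitivity.json", "log.json",
                    "favoured_model.json", "posterior.csv", "scoping.json"}
        assert expected.issubset({p.name for p in out.iterdir()})
        assert res.selection.key == "C"  # the generating structure wins
        assert res.log["selected_k"] == 2

    def test_pipeline_is_byte_deterministic(self, small_run, tmp_path_factory):
        sim, fw, out, _ = small_run
        out2 = tmp_path_factory.mktemp("run2")
        lf.run_pipeline(sim.dataset, fw, out_dir=out2)
        for p in sorted(out.iterdir()):
            other = out2 / p.name
            assert other.exists()
            assert filecmp.cmp(p, other, shallow=False), p.name

    def test_selection_never_returns_non_converged(self, small_run):
        _, _, _, res = small_run
        assert res.selection.model.converged
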