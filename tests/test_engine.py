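"""Budget combination, scenario sampling/enumeration and the evaluation loop."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

import brachyrobust as br
from brachyrobust.budget import UncertaintyBudget, combine_quadrature
from brachyrobust.engine import (
    enumerate_worst_case,
    p4_mode_vectors,
    run_evaluation,
    run_scenario,
    sample_probabilistic,
)


class TestQuadrature:
    def test_published_totals(self):
        assert round(combine_quadrature([1.1, 0.34, 1.0]), 1) == 1.5
        assert round(combine_quadrature([1.0, 3.0, 3.0]), 1) == 4.4
        assert round(combine_quadrature([1.2, 0.86]), 1) == 1.5

    def test_pythagorean(self):
        assert combine_quadrature([3.0, 4.0]) == pytest.approx(5.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            combine_quadrature([])

    def test_budget_defaults_reproduce_program_inputs(self):
        b = UncertaintyBudget()
        assert round(b.p1_sd, 1) == 1.5
        assert round(b.p4_sd, 1) == 1.5
        assert round(b.p5_percent_sd, 1) == 4.4
        assert b.p2_sd == 2.0
        assert b.p3_rectum_sd == 1.0
        # diameter convention: published 0.5 mm diameter → 0.25 mm radial
        assert b.p3_urethra_sd == 0.25
        assert UncertaintyBudget(urethra_value_is_diameter=False).p3_urethra_sd == 0.5


def truncated_normal_sd(sd, m=1.65):
    """Oracle: SD of a ±m·sd truncated normal by numerical integration."""
    pdf = lambda x: norm.pdf(x, scale=sd)
    z, _ = quad(pdf, -m * sd, m * sd)
    second, _ = quad(lambda x: x**2 * pdf(x), -m * sd, m * sd)
    return np.sqrt(second / z)


class TestProbabilisticSampling:
    def test_draws_respect_truncation(self):
        b = UncertaintyBudget()
        rng = np.random.default_rng(7)
        for _ in range(200):
            p = sample_probabilistic(b, n_needles=4, seed=rng)
            assert abs(p.p1_shift) <= 1.65 * b.p1_sd
            assert abs(p.p2_prostate) <= 1.65 * b.p2_sd
            assert abs(p.p3_urethra) <= 1.65 * b.p3_urethra_sd
            assert abs(p.p3_rectum) <= 1.65 * b.p3_rectum_sd
            assert np.all(np.abs(p.p4_transverse) <= 1.65 * b.p4_sd)
            assert abs(p.p5_scale - 1.0) * 100 <= 1.65 * b.p5_percent_sd + 1e-9
            assert abs(p.p5_offset) <= 1.65 * b.p5_offset_sd_s
            np.testing.assert_array_less(np.abs(p.p6_rigid), 1.65 * b.p6_sd + 1e-12)

    def test_zero_budget_gives_zero_params(self):
        b = UncertaintyBudget(
            p1_components_mm=(0.0,), p2_sd_mm=0.0, p3_urethra_value_mm=0.0,
            p3_rectum_sd_mm=0.0, p4_components_mm=(0.0,),
            p5_percent_components=(0.0,), p5_offset_sd_s=0.0,
            p6_sd_mm=(0.0, 0.0, 0.0),
        )
        p = sample_probabilistic(b, n_needles=3, seed=0)
        assert p.p1_shift == 0 and p.p2_prostate == 0
        assert p.p5_scale == 1.0 and p.p5_offset == 0.0
        assert np.all(p.p4_transverse == 0) and np.all(p.p6_rigid == 0)

    def test_empirical_sd_matches_truncated_normal(self):
        b = UncertaintyBudget()
        rng = np.random.default_rng(3)
        draws = np.array(
            [sample_probabilistic(b, 1, rng).p1_shift for _ in range(10_000)]
        )
        assert draws.std() == pytest.approx(truncated_normal_sd(b.p1_sd), rel=0.03)

    def test_deterministic_given_seed(self):
        b = UncertaintyBudget()
        a = sample_probabilistic(b, 4, seed=11)
        c = sample_probabilistic(b, 4, seed=11)
        assert a.p1_shift == c.p1_shift
        np.testing.assert_array_equal(a.p4_transverse, c.p4_transverse)


class TestWorstCaseEnumeration:
    def test_zero_budget_single_scenario(self, small_case):
        b = UncertaintyBudget(
            p1_components_mm=(0.0,), p2_sd_mm=0.0, p3_urethra_value_mm=0.0,
            p3_rectum_sd_mm=0.0, p4_components_mm=(0.0,),
            p5_percent_components=(0.0,), p5_offset_sd_s=0.0,
            p6_sd_mm=(0.0, 0.0, 0.0),
        )
        scens = enumerate_worst_case(b, small_case)
        assert len(scens) == 1
        p = scens[0]
        assert p.p1_shift == 0 and p.p5_scale == 1.0 and p.p4_transverse is None

    def test_exhaustive_vs_product_oracle(self, small_case):
        import itertools

        b = UncertaintyBudget()
        scens = enumerate_worst_case(b, small_case)
        lv = lambda sd: (-1.65 * sd, 0.0, 1.65 * sd)
        scales = tuple(1.0 + s * 1.65 * b.p5_percent_sd / 100.0 for s in (-1, 0, 1))
        expected = {
            tuple(round(v, 9) for v in t)
            for t in itertools.product(lv(b.p1_sd), lv(b.p2_sd),
                                       lv(b.p3_urethra_sd), lv(b.p3_rectum_sd),
                                       scales)
        }
        got = {tuple(round(v, 9) for v in
                     (p.p1_shift, p.p2_prostate, p.p3_urethra, p.p3_rectum,
                      p.p5_scale)) for p in scens}
        assert got == expected
        # 3 scalar levels ^5 × 5 rigid levels × 3 transverse modes
        assert len(scens) == 3**5 * 5 * 3

    def test_p6_levels_are_one_axis_at_a_time(self, small_case):
        b = UncertaintyBudget()
        scens = enumerate_worst_case(b, small_case)
        p6 = {tuple(np.round(p.p6_rigid, 6)) for p in scens}
        assert p6 == {(0.0, 0.0, 0.0), (0.165, 0.0, 0.0), (-0.165, 0.0, 0.0),
                      (0.0, 0.825, 0.0), (0.0, -0.825, 0.0)}

    def test_p4_modes_geometry(self, small_case):
        centre = small_case.contours["prostate"].centroid()[:2]
        vecs = p4_mode_vectors(small_case, "out", 2.47)
        for i, pos in enumerate(small_case.dwells.positions):
            d = pos[:, :2].mean(axis=0) - centre
            assert np.dot(vecs[i], d) > 0            # radially outward
            assert np.linalg.norm(vecs[i]) == pytest.approx(2.47)
        post = p4_mode_vectors(small_case, "posterior", 0.82)
        np.testing.assert_allclose(post, np.tile([0.0, 0.82], (len(post), 1)))
        assert p4_mode_vectors(small_case, "none", 2.47) is None

    def test_deterministic_order(self, small_case):
        b = UncertaintyBudget()
        a = enumerate_worst_case(b, small_case)
        c = enumerate_worst_case(b, small_case)
        assert [p.p1_shift for p in a] == [p.p1_shift for p in c]


class TestRunScenario:
    def test_zero_params_equals_nominal(self, small_case, small_paths, source):
        m0, _, _ = run_scenario(small_case, small_paths, source,
                                br.ScenarioParams(), grid_spacing=2.0)
        m1, _, _ = run_scenario(small_case, small_paths, source,
                                br.ScenarioParams(), grid_spacing=2.0)
        assert m0 == m1

    def test_time_scale_multiplies_dose_metrics(self, small_case, small_paths, source):
        m0, _, _ = run_scenario(small_case, small_paths, source,
                                br.ScenarioParams(), grid_spacing=2.0)
        m1, _, _ = run_scenario(small_case, small_paths, source,
                                br.ScenarioParams(p5_scale=1.072), grid_spacing=2.0)
        for k in ("prostate_D90", "urethra_D10", "urethra_D0.01cc", "rectum_D0.1cc"):
            assert m1[k] == pytest.approx(1.072 * m0[k], rel=1e-9)

    def test_sampled_params_give_finite_physical_metrics(
            self, small_case, small_paths, source):
        b = UncertaintyBudget()
        params = sample_probabilistic(b, small_case.dwells.n_needles, seed=5)
        m, flags, curves = run_scenario(small_case, small_paths, source, params,
                                        grid_spacing=2.0)
        for k, v in m.items():
            assert np.isfinite(v) and v >= 0
            if "_V1" in k or "_V2" in k:
                assert v <= 100.0
        assert set(flags) == set(m)


class TestRunEvaluation:
    def test_determinism(self, small_case, source):
        kw = dict(n_probabilistic=2, seed=99, worst_case=False, grid_spacing=2.5)
        a = run_evaluation(small_case, source, **kw)
        b = run_evaluation(small_case, source, **kw)
        metric_cols = [c for c in a.scenario_table.columns if c != "elapsed_s"]
        assert a.scenario_table[metric_cols].equals(b.scenario_table[metric_cols])
        assert a.summary.table.equals(b.summary.table)

    def test_summary_has_eight_metric_rows(self, small_case, source):
        res = run_evaluation(small_case, source, n_probabilistic=3, seed=0,
                             worst_case=False, grid_spacing=2.5)
        assert len(res.summary.table) == 8
        assert res.summary.n_probabilistic == 3
        assert res.summary.n_failed == 0
        for s in ("prostate", "urethra", "rectum"):
            assert res.summary.sd_areas[s] >= 0.0

    def test_time_parameter_folding_matches_direct_evaluation(
            self, small_case, small_paths, source):
        # the engine folds p5 analytically; a direct scenario run must agree
        params = br.ScenarioParams(p1_shift=1.0, p2_prostate=0.8,
                                   p5_scale=1.05, p5_offset=0.03)
        direct_case = br.apply_scenario(small_case, small_paths, params)
        from brachyrobust.dvh import compute_metrics, sample_structure_points
        from brachyrobust.tg43 import accumulate_dose

        dose_by, w_by = {}, {}
        for name in ("prostate", "urethra", "rectum"):
            pts, w = sample_structure_points(direct_case.contours[name], 2.0)
            dose_by[name] = accumulate_dose(direct_case.dwells, small_paths,
                                            source, pts, w).dose
            w_by[name] = w
        direct = compute_metrics(small_case, dose_by, w_by)
        folded, _, _ = run_scenario(small_case, small_paths, source, params,
                                    grid_spacing=2.0)
        for k in direct:
            assert folded[k] == pytest.approx(direct[k], rel=1e-9, abs=1e-9)
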