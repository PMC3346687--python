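"""Membership construction, FCM, rule bases, Mamdani inference, defuzzification."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seizonset.fuzzy import (FuzzyCMeans, MembershipFunction, build_input_mfs,
                             defuzz_centroid, fcm, make_rulebase, mamdani_defuzz_batch,
                             mamdani_infer, minmax_normalize, output_grid,
                             three_level_variable, two_level_variable)

# the published rule tables, row for row
STAGE1_RULES = [
    ("HHHH", "H"), ("HHHL", "H"), ("HHLH", "H"), ("HLHH", "H"), ("LHHH", "H"),
    ("HHLL", "M"), ("HLLH", "M"), ("LLHH", "M"), ("LHLH", "M"), ("LHHL", "M"),
    ("HLHL", "M"),
    ("HLLL", "L"), ("LHLL", "L"), ("LLHL", "L"), ("LLLH", "L"), ("LLLL", "L"),
]
STAGE2_RULES = [
    ("HHHH", "H"), ("HHHL", "H"), ("HHLH", "H"), ("HLHH", "H"), ("LHHH", "H"),
    ("HHLL", "H"), ("HLLH", "H"), ("LLHH", "H"), ("HLHL", "H"), ("LHLH", "H"),
    ("LHHL", "H"),
    ("HLLL", "L"), ("LHLL", "L"), ("LLHL", "L"), ("LLLH", "L"), ("LLLL", "L"),
]
STAGE3_RULES = [("HH", "H"), ("HL", "M"), ("LH", "M"), ("LL", "L")]


class TestMembershipFunctions:
    def test_trapezoid_evaluation(self):
        mf = MembershipFunction.trapezoidal(0.1, 0.3, 0.6, 0.8)
        np.testing.assert_allclose(mf(np.array([0.0, 0.2, 0.45, 0.7, 0.9])),
                                   [0.0, 0.5, 1.0, 0.5, 0.0])

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ValueError):
            MembershipFunction(0.5, 0.3, 0.6, 0.8)

    def test_input_pair_midpoint(self):
        var = build_input_mfs(0.3, 0.7)
        assert var.membership("L", 0.5) == pytest.approx(0.5)
        assert var.membership("H", 0.5) == pytest.approx(0.5)
        assert var.membership("L", 0.0) == 1.0
        assert var.membership("H", 1.0) == 1.0

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_partition_of_unity(self, x):
        var = build_input_mfs(0.25, 0.65)
        assert var.membership("L", x) + var.membership("H", x) == pytest.approx(1.0)

    def test_coincident_centers_warn(self):
        with pytest.warns(UserWarning):
            two_level_variable("v", 0.4, 0.4)

    def test_three_level_anchors(self):
        var = three_level_variable("op")
        assert var.membership("L", 0.0) == 1.0
        assert var.membership("M", 0.5) == 1.0
        assert var.membership("H", 1.0) == 1.0
        assert var.membership("M", 0.3) == 0.0 and var.membership("M", 0.7) == 0.0


class TestMinMax:
    def test_simple(self):
        np.testing.assert_allclose(minmax_normalize(np.array([2.0, 4.0, 6.0])),
                                   [0.0, 0.5, 1.0])

    def test_identity_on_unit_range(self):
        x = np.array([0.0, 0.25, 1.0])
        np.testing.assert_allclose(minmax_normalize(x), x)

    def test_constant_warns(self):
        with pytest.warns(UserWarning):
            out = minmax_normalize(np.full(5, 3.0))
        np.testing.assert_allclose(out, 0.5)

    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30, unique=True))
    @settings(deadline=None, max_examples=50)
    def test_order_preserving(self, values):
        # monotone map: sorted inputs give (weakly) sorted outputs, and the
        # extremes land exactly on 0 and 1
        v = np.array(values)
        out = minmax_normalize(v)
        assert np.all(np.diff(out[np.argsort(v)]) >= 0)
        assert out[np.argmin(v)] == 0.0 and out[np.argmax(v)] == 1.0


class TestFuzzyCMeans:
    def test_bimodal_center_recovery(self, rng):
        x = np.concatenate([rng.normal(0.2, 0.02, 500), rng.normal(0.8, 0.02, 500)])
        centers, memb = fcm(x, seed=0)
        assert abs(centers[0] - 0.2) < 0.03 and abs(centers[1] - 0.8) < 0.03
        np.testing.assert_allclose(memb.sum(axis=1), 1.0, atol=1e-9)

    def test_objective_non_increasing(self, rng):
        x = rng.random(200)[:, None]
        est = FuzzyCMeans(random_state=1).fit(x)
        traj = np.array(est.objective_trajectory_)
        assert np.all(np.diff(traj) <= 1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            FuzzyCMeans().fit(np.ones((10, 1)))

    def test_sklearn_get_set_params_roundtrip(self):
        est = FuzzyCMeans(m=1.8, max_iter=50)
        est2 = FuzzyCMeans(**est.get_params())
        assert est2.m == 1.8 and est2.max_iter == 50

    def test_objective_matches_reference_implementation(self, rng):
        """Converged FCM objective agrees with e1071::cmeans on the same data."""
        x = np.concatenate([rng.normal(0.25, 0.04, 150), rng.normal(0.75, 0.04, 150)])
        est = FuzzyCMeans(n_clusters=2, m=2.0, max_iter=500, tol=1e-12,
                          random_state=0).fit(x[:, None])
        with tempfile.TemporaryDirectory() as td:
            data = Path(td) / "x.csv"
            np.savetxt(data, x)
            script = (
                f'x <- matrix(scan("{data}")); set.seed(1); '
                'r <- e1071::cmeans(x, centers=2, m=2, iter.max=1000, method="cmeans"); '
                'cat(sprintf("%.12f\\n", r$withinerror)); '
                'cat(sprintf("%.8f\\n", sort(r$centers)))'
            )
            out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                                 text=True, check=True).stdout.split()
        ref_obj, ref_centers = float(out[0]), [float(v) for v in out[1:]]
        # e1071 reports the objective as a per-point mean
        assert abs(est.objective_ / len(x) - ref_obj) < 1e-6
        np.testing.assert_allclose(est.cluster_centers_[:, 0], ref_centers, atol=1e-4)


class TestRuleBases:
    @pytest.mark.parametrize("stage,expected", [(1, STAGE1_RULES), (2, STAGE2_RULES),
                                                (3, STAGE3_RULES)])
    def test_tables_row_for_row(self, stage, expected):
        rb = make_rulebase(stage)
        assert len(rb.rules) == len(expected)
        for ant_str, cons in expected:
            assert rb.consequent(tuple(ant_str)) == cons

    def test_unknown_stage_rejected(self):
        with pytest.raises(ValueError):
            make_rulebase(4)

    @pytest.mark.parametrize("stage,ant,cons", [
        (1, "HHLH", "H"), (2, "HLLH", "H"), (3, "LL", "L"),
    ])
    def test_spot_rows(self, stage, ant, cons):
        assert make_rulebase(stage).consequent(tuple(ant)) == cons


def _stage1_setup():
    input_vars = [build_input_mfs(0.3, 0.7, name=f"f{i}") for i in range(4)]
    return make_rulebase(1), input_vars, three_level_variable("op1")


class TestMamdani:
    def test_all_high_saturates_h_set(self):
        rb, ivars, ovar = _stage1_setup()
        grid, curve = mamdani_infer(rb, [1.0] * 4, ivars, ovar)
        np.testing.assert_allclose(curve, ovar.membership("H", grid))

    def test_all_low_saturates_l_set(self):
        rb, ivars, ovar = _stage1_setup()
        grid, curve = mamdani_infer(rb, [0.0] * 4, ivars, ovar)
        np.testing.assert_allclose(curve, ovar.membership("L", grid))

    def test_matches_brute_force_rule_evaluation(self, rng):
        """Aggregate curve == naive per-rule min/clip/max on the same grid."""
        rb, ivars, ovar = _stage1_setup()
        grid = output_grid(1001)
        for _ in range(10):
            x = rng.random(4)
            _, curve = mamdani_infer(rb, x, ivars, ovar)
            brute = np.zeros_like(grid)
            for ant, cons in rb.rules:
                firing = min(ivars[j].membership(lbl, x[j]) for j, lbl in enumerate(ant))
                brute = np.maximum(brute, np.minimum(firing, ovar.membership(cons, grid)))
            assert np.max(np.abs(curve - brute)) < 1e-9

    def test_batch_equals_single(self, rng):
        rb, ivars, ovar = _stage1_setup()
        X = rng.random((20, 4))
        batch = mamdani_defuzz_batch(rb, X, ivars, ovar)
        single = [defuzz_centroid(mamdani_infer(rb, x, ivars, ovar)[1]) for x in X]
        np.testing.assert_allclose(batch, single, atol=1e-12)

    def test_out_of_range_inputs_clamped(self):
        rb, ivars, ovar = _stage1_setup()
        with pytest.warns(UserWarning):
            _, curve = mamdani_infer(rb, [1.2, -0.1, 0.5, 0.5], ivars, ovar)
        assert curve.max() <= 1.0

    def test_stage1_output_monotone_in_high_input_count(self):
        # centroid defuzzification is not pointwise monotone in each input
        # (the aggregated curve's mass shifts non-monotonically near set
        # crossovers), but more high-core inputs never lower the output
        rb, ivars, ovar = _stage1_setup()
        outs = []
        for n_high in range(5):
            x = np.array([1.0] * n_high + [0.0] * (4 - n_high))
            outs.append(mamdani_defuzz_batch(rb, x[None, :], ivars, ovar)[0])
        assert np.all(np.diff(outs) >= 0)
        assert outs[0] < 0.5 < outs[-1]


class TestCentroid:
    def test_symmetric_triangle(self):
        grid = output_grid(1001)
        tri = MembershipFunction.triangular(0.2, 0.5, 0.8)
        assert defuzz_centroid(tri(grid), grid) == pytest.approx(0.5, abs=1e-9)

    def test_rectangle(self):
        grid = output_grid(1001)
        curve = ((grid >= 0.6) & (grid <= 1.0)).astype(float)
        assert defuzz_centroid(curve, grid) == pytest.approx(0.8, abs=1e-3)

    def test_zero_area_warns(self):
        with pytest.warns(UserWarning):
            assert defuzz_centroid(np.zeros(101)) == 0.5

    def test_fine_grid_riemann_oracle(self, rng):
        """1001-point trapezoid centroid vs 100001-point Riemann sum."""
        for _ in range(5):
            a, b, c = np.sort(rng.random(3))
            mf = MembershipFunction.triangular(a, b, c)
            coarse = defuzz_centroid(mf(output_grid(1001)), output_grid(1001))
            fine = output_grid(100_001)
            mu = mf(fine)
            riemann = float(np.sum(fine * mu) / np.sum(mu))
            assert abs(coarse - riemann) < 1e-3

    def test_grid_refinement_stability(self, rng):
        rb, ivars, ovar = _stage1_setup()
        x = rng.random(4)
        c1 = defuzz_centroid(mamdani_infer(rb, x, ivars, ovar, grid_n=1001)[1],
                             output_grid(1001))
        c2 = defuzz_centroid(mamdani_infer(rb, x, ivars, ovar, grid_n=10_001)[1],
                             output_grid(10_001))
        assert abs(c1 - c2) < 1e-3
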