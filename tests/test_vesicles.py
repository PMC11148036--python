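import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipopore import synth
from lipopore.vesicles import (
    auc_cell_death,
    classify_mechanism,
    degree_of_filling,
    endpoint_release,
    percent_permeabilized,
    percent_release,
    pore_stability,
    size_selectivity,
    threshold_sensitivity,
    vesicle_table,
)


class TestPercentRelease:
    def test_detergent_control_is_hundred(self):
        assert percent_release(np.array([110.0]), fi=10.0, fm=110.0)[0] == 100.0

    def test_baseline_is_zero(self):
        assert percent_release(np.array([10.0]), fi=10.0, fm=110.0)[0] == 0.0

    def test_midpoint(self):
        assert percent_release(np.array([60.0]), fi=10.0, fm=110.0)[0] == 50.0

    def test_inverted_references_rejected(self):
        with pytest.raises(ValueError):
            percent_release(np.array([5.0]), fi=10.0, fm=10.0)

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-100.0, 100.0),
        ff=st.floats(10.0, 110.0),
    )
    def test_affine_invariance(self, a, b, ff):
        base = percent_release(np.array([ff]), 10.0, 110.0)[0]
        scaled = percent_release(
            np.array([a * ff + b]), a * 10.0 + b, a * 110.0 + b
        )[0]
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


class TestEndpointRelease:
    def test_constant_series(self):
        t = np.array([0.0, 30.0, 60.0, 90.0])
        assert endpoint_release(t, np.full(4, 40.0)) == 40.0

    def test_interpolation_between_flanking_points(self):
        assert endpoint_release(
            np.array([59.0, 61.0]), np.array([48.0, 52.0]), t_end=60.0
        ) == pytest.approx(50.0)

    def test_dose_ordering_preserved(self):
        t = np.linspace(0, 90, 10)
        doses = [10.0, 30.0, 60.0]
        ends = [endpoint_release(t, np.linspace(0, top, 10)) for top in doses]
        assert ends == sorted(ends)

    def test_endpoint_outside_range_rejected(self):
        with pytest.raises(ValueError):
            endpoint_release(np.array([0.0, 30.0]), np.array([0.0, 10.0]))


class TestDegreeOfFilling:
    @pytest.mark.parametrize(
        "lumen,expected,clamped",
        [(110.0, 1.0, False), (10.0, 0.0, False), (5.0, 0.0, True)],
    )
    def test_values_and_clamping(self, lumen, expected, clamped):
        df, flag = degree_of_filling(lumen, exterior=110.0, background=10.0)
        assert df == expected and flag == clamped

    def test_exterior_below_background_rejected(self):
        with pytest.raises(ValueError):
            degree_of_filling(50.0, exterior=5.0, background=10.0)


class TestPercentPermeabilized:
    def _table(self, dfs, dye="dye1"):
        rows = [
            {"vesicle_id": i, "dye": dye, "lumen": 10.0 + d * 100.0,
             "exterior": 110.0, "background": 10.0}
            for i, d in enumerate(dfs)
        ]
        return vesicle_table(rows)

    def test_threshold_split(self):
        tab = self._table([0.9, 0.1, 0.95, 0.05])
        assert percent_permeabilized(tab, "dye1") == 50.0

    def test_all_filled(self):
        assert percent_permeabilized(self._table([1.0, 1.0]), "dye1") == 100.0

    def test_zero_threshold_counts_everything(self):
        tab = self._table([0.0, 0.3, 0.9])
        assert percent_permeabilized(tab, "dye1", threshold=0.0) == 100.0

    def test_sensitivity_is_monotone_in_threshold(self):
        tab = self._table(np.linspace(0, 1, 21))
        sens = threshold_sensitivity(tab, "dye1")
        assert list(sens) == sorted(sens, reverse=True)

    def test_missing_dye_rejected(self):
        with pytest.raises(ValueError):
            percent_permeabilized(self._table([0.5]), "dye9")


class TestClassifyMechanism:
    def test_recovers_generator_truth(self):
        hits = 0
        n_sim = 500
        for i in range(n_sim):
            mech = "all_or_none" if i % 2 == 0 else "graded"
            table, truth = synth.gen_vesicle_population(
                50, mechanism=mech, seed=1000 + i
            )
            dfs = table[table["dye"] == "dye1"]["lumen"].to_numpy()
            dfs = (dfs - 10.0) / 100.0
            res = classify_mechanism(dfs)
            hits += res.mechanism == truth["mechanism"]
        assert hits / n_sim >= 0.95

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            classify_mechanism(np.full(5, 0.5))

    def test_intermediate_fraction_reported(self):
        dfs = np.concatenate([np.zeros(45), np.full(5, 0.5), np.ones(50)])
        res = classify_mechanism(dfs)
        assert res.intermediate_fraction == pytest.approx(0.05)
        assert res.mechanism == "all_or_none"


class TestPoreStability:
    def _two_dye_table(self, df1, df2):
        rows = []
        for i, (a, b) in enumerate(zip(df1, df2)):
            for dye, d in (("dye1", a), ("dye2", b)):
                rows.append(
                    {"vesicle_id": i, "dye": dye, "lumen": 10 + d * 100,
                     "exterior": 110.0, "background": 10.0}
                )
        return vesicle_table(rows)

    def test_perfect_stability(self):
        tab = self._two_dye_table([0.9, 0.95, 0.1], [0.9, 0.9, 0.1])
        res = pore_stability(tab, "dye1", "dye2")
        assert res.conditional == 1.0

    def test_partial_stability(self):
        df1 = [0.9] * 10 + [0.1] * 5
        df2 = [0.9] * 8 + [0.1] * 2 + [0.1] * 5
        res = pore_stability(self._two_dye_table(df1, df2), "dye1", "dye2")
        assert res.conditional == pytest.approx(0.8)
        assert res.joint[0] == (8, 2)

    def test_no_first_dye_positive_undefined(self):
        res = pore_stability(
            self._two_dye_table([0.1, 0.2], [0.9, 0.9]), "dye1", "dye2"
        )
        assert res.undefined

    def test_generator_stability_parameter_recovered(self):
        raw, truth = synth.gen_vesicle_population(
            400, mechanism="all_or_none", stability=1.0, seed=9
        )
        res = pore_stability(vesicle_table(raw), "dye1", "dye2")
        assert res.conditional == pytest.approx(1.0, abs=0.02)


class TestSizeSelectivity:
    def _marker_table(self, small, large):
        rows = []
        for i, (s, l) in enumerate(zip(small, large)):
            for dye, d in (("small_12kDa", s), ("large_104kDa", l)):
                rows.append(
                    {"vesicle_id": i, "dye": dye, "lumen": 10 + d * 100,
                     "exterior": 110.0, "background": 10.0}
                )
        return vesicle_table(rows)

    def test_class_assignment(self):
        tab = self._marker_table([0.95, 0.9, 0.05], [0.05, 0.9, 0.02])
        classes, fractions = size_selectivity(tab)
        assert list(classes) == ["size_limited", "large_pore", "impermeable"]
        assert fractions.sum() == pytest.approx(1.0)

    def test_partition_is_exact(self):
        rng = np.random.default_rng(4)
        tab = self._marker_table(rng.random(60), rng.random(60))
        classes, fractions = size_selectivity(tab)
        assert len(classes) == 60
        assert fractions.sum() == pytest.approx(1.0)

    def test_size_limited_generator(self):
        raw, _ = synth.gen_vesicle_population(
            100, mechanism="all_or_none", p_perm=0.8, size_limited=True,
            include_size_markers=True, seed=10,
        )
        classes, fractions = size_selectivity(vesicle_table(raw))
        assert fractions["size_limited"] > fractions["large_pore"]


class TestAucCellDeath:
    def test_constant_level(self):
        t = np.linspace(0, 24, 25)
        assert auc_cell_death(t, np.full(25, 50.0)) == pytest.approx(1200.0)

    def test_all_zero(self):
        assert auc_cell_death(np.array([0.0, 24.0]), np.zeros(2)) == 0.0

    def test_linear_ramp_triangle_area(self):
        t = np.linspace(0, 24, 25)
        assert auc_cell_death(t, np.linspace(0, 100, 25)) == pytest.approx(1200.0)

    def test_additive_over_subintervals(self):
        rng = np.random.default_rng(6)
        t = np.sort(rng.random(30)) * 24
        y = rng.random(30) * 100
        full = auc_cell_death(t, y)
        split = auc_cell_death(t[:15], y[:15]) + auc_cell_death(t[14:], y[14:])
        assert full == pytest.approx(split)

    def test_unsorted_time_rejected(self):
        with pytest.raises(ValueError):
            auc_cell_death(np.array([0.0, 2.0, 1.0]), np.zeros(3))
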