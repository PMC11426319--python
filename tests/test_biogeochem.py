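"""Deterministic derivation arithmetic: fumigation biomass, titration CO2-C,
qCO2, pool changes, ratios, specific enzyme activity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soilstoich.biogeochem import (
    accumulate_mineralization,
    derive_replicates,
    element_ratio,
    fumigation_biomass,
    metabolic_quotient,
    net_change,
    net_nitrification,
    specific_enzyme_activity,
    summarize_treatments,
    titration_co2c,
)
from soilstoich.experiment_model import TitrationSeries

finite = st.floats(min_value=0.01, max_value=1e4, allow_nan=False)


class TestFumigationBiomass:
    @pytest.mark.parametrize(
        "fum, unfum, k, expected",
        [
            (100.0, 55.0, 0.45, 100.0),
            (7.0, 7.0, 0.54, 0.0),
            (2.0, 1.82, 0.4, 0.45),
        ],
    )
    def test_known_values(self, fum, unfum, k, expected):
        assert fumigation_biomass(fum, unfum, k) == pytest.approx(expected)

    def test_negative_difference_returned_not_clamped(self):
        assert fumigation_biomass(1.0, 2.0, 0.45) < 0

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            fumigation_biomass(1.0, 0.5, 0.0)

    @given(fum=finite, unfum=finite, k=st.floats(min_value=0.05, max_value=1.0),
           c=st.floats(min_value=0.1, max_value=10))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_difference_and_reciprocal_in_k(self, fum, unfum, k, c):
        base = fumigation_biomass(fum, unfum, k)
        scaled = fumigation_biomass(c * fum, c * unfum, k)
        assert scaled == pytest.approx(c * base, rel=1e-9, abs=1e-9)
        halved_k = fumigation_biomass(fum, unfum, k / 2)
        assert halved_k == pytest.approx(2 * base, rel=1e-9, abs=1e-9)


def _series(intervals, molarity=1.0, mass=100.0):
    return TitrationSeries(intervals=tuple(intervals), hcl_molarity=molarity,
                           naoh_volume=10.0, soil_dry_mass=mass)


class TestTitration:
    def test_two_ml_difference_gives_120_ug_per_g(self):
        out = titration_co2c(_series([(3, 10.0, 8.0)]))
        assert out[0] == pytest.approx(120.0)

    def test_equal_volumes_give_zero(self):
        assert titration_co2c(_series([(3, 10.0, 10.0)]))[0] == 0.0

    def test_zero_molarity_gives_zero(self):
        assert titration_co2c(_series([(3, 10.0, 8.0)], molarity=0.0))[0] == 0.0

    def test_negative_interval_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            out = titration_co2c(_series([(3, 8.0, 10.0)]))
        assert out[0] == 0.0

    def test_split_interval_invariance(self):
        whole = titration_co2c(_series([(6, 10.0, 6.0)])).sum()
        split = titration_co2c(_series([(3, 10.0, 8.0), (6, 10.0, 8.0)])).sum()
        assert split == pytest.approx(whole)


class TestAccumulation:
    def test_constructed_control_total(self):
        per = [739.0 / 7] * 7
        total, partial = accumulate_mineralization(per)
        assert total == pytest.approx(739.0)
        assert len(partial) == 7

    def test_zeros(self):
        total, _ = accumulate_mineralization([0.0, 0.0, 0.0])
        assert total == 0.0

    def test_partial_sums_nondecreasing_for_nonnegative_input(self):
        _, partial = accumulate_mineralization([5.0, 0.0, 3.0, 1.0])
        assert (np.diff(partial) >= 0).all()


class TestQuotientsAndRatios:
    def test_qco2_is_plain_division(self):
        assert metabolic_quotient(739.0, 1283.0) == pytest.approx(0.576, abs=5e-4)
        assert metabolic_quotient(0.0, 10.0) == 0.0
        assert metabolic_quotient(7.0, 7.0) == 1.0

    def test_qco2_undefined_for_nonpositive_cmic(self):
        with pytest.warns(UserWarning):
            assert np.isnan(metabolic_quotient(5.0, 0.0))

    @pytest.mark.parametrize(
        "post, pre, expected",
        [(164.0, 28.0, 136.0), (5.0, 5.0, 0.0), (36.95, 5.0, 31.95)],
    )
    def test_net_change(self, post, pre, expected):
        assert net_change(post, pre) == pytest.approx(expected)

    @given(a=finite, b=finite)
    @settings(max_examples=50, deadline=None)
    def test_net_change_antisymmetric(self, a, b):
        assert net_change(a, b) == -net_change(b, a)

    @pytest.mark.parametrize(
        "post, pre, expected", [(135.0, 15.0, 120.0), (102.0, 15.0, 87.0), (9.0, 9.0, 0.0)]
    )
    def test_net_nitrification(self, post, pre, expected):
        assert net_nitrification(post, pre) == pytest.approx(expected)

    def test_element_ratio_pre_incubation_cmic_nmic(self):
        assert element_ratio(1190.0, 70.0) == pytest.approx(17.0)

    def test_element_ratio_edge_cases(self):
        assert element_ratio(3.0, 3.0) == 1.0
        assert element_ratio(0.0, 4.0) == 0.0
        assert np.isnan(element_ratio(1.0, 0.0))


class TestSpecificEnzymeActivity:
    def test_control_bg_sea(self):
        assert specific_enzyme_activity(0.0885, 1283.0) == pytest.approx(0.069, abs=5e-4)

    def test_zero_activity(self):
        assert specific_enzyme_activity(0.0, 1000.0) == 0.0

    def test_activity_equal_to_cmic_in_mg_gives_one(self):
        assert specific_enzyme_activity(1.5, 1500.0) == pytest.approx(1.0)

    @given(act=finite, cmic=finite, c=st.floats(min_value=0.5, max_value=5))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_degree_minus_one_in_cmic(self, act, cmic, c):
        assert specific_enzyme_activity(act, c * cmic) == pytest.approx(
            specific_enzyme_activity(act, cmic) / c, rel=1e-9
        )


class TestDatasetDerivation:
    def test_full_synthetic_dataset_derives_all_stages(self, dataset):
        derived = derive_replicates(dataset)
        assert len(derived) == 30  # 6 treatments x 5 replicates
        for col in ("co2_c_accum", "qco2", "net_nitrification",
                    "delta_doc", "ratio_cmic_pmic", "sea_bg"):
            assert col in derived.columns
            assert derived[col].notna().all()

    def test_accumulated_co2_matches_generating_targets(self, default_experiment):
        dataset, truth = default_experiment
        derived = derive_replicates(dataset).sort_values(["treatment", "replicate"])
        for t, tt in truth["per_treatment"].items():
            got = derived.loc[derived["treatment"] == t, "co2_c_accum"].to_numpy()
            assert got == pytest.approx(np.array(tt["co2_accum_drawn"]), rel=1e-9)

    def test_summary_is_mean_of_per_replicate_values(self, dataset):
        derived = derive_replicates(dataset)
        summary = summarize_treatments(derived)
        manual = derived[derived["treatment"] == "control"]["qco2"].mean()
        assert summary.loc["control", ("qco2", "mean")] == pytest.approx(manual)
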