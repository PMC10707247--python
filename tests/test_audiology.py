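import numpy as np
import pytest

import earmech as em
from earmech.audiology import (
    Audiogram,
    LossCurve,
    ab_gap,
    classify_slope,
    compare_curves,
    pta4,
    rank_scenarios,
    simulate_loss_curve,
    vsf_ratio_db,
)
from earmech.errors import DataError
from earmech.mechanics import TransmissionCurve

OCTAVES = [500.0, 1000.0, 2000.0, 4000.0]


def curve(values, freqs=None, name=""):
    if freqs is None:
        grid = [125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0]
        freqs = OCTAVES[: len(values)] if len(values) <= 4 else grid[: len(values)]
    return LossCurve(frequencies=freqs, loss_db=list(values), scenario_name=name)


class TestVsfRatio:
    def test_identical_curves_give_zero_loss(self):
        tc = TransmissionCurve(frequencies=(500.0, 1000.0), vsf_magnitude=(1e-9, 2e-9))
        loss = vsf_ratio_db(tc, tc)
        assert loss.loss_db == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_hundredfold_drop_is_40_db(self):
        normal = TransmissionCurve(frequencies=(1000.0,), vsf_magnitude=(1e-9,))
        diseased = TransmissionCurve(frequencies=(1000.0,), vsf_magnitude=(1e-11,))
        assert vsf_ratio_db(normal, diseased).loss_db[0] == pytest.approx(40.0)

    def test_gain_reports_negative_loss(self):
        normal = TransmissionCurve(frequencies=(1000.0,), vsf_magnitude=(1e-9,))
        diseased = TransmissionCurve(frequencies=(1000.0,), vsf_magnitude=(1e-8,))
        assert vsf_ratio_db(normal, diseased).loss_db[0] == pytest.approx(-20.0)

    def test_zero_diseased_magnitude_warns_with_sentinel(self):
        normal = TransmissionCurve(frequencies=(1000.0,), vsf_magnitude=(1e-9,))
        diseased = TransmissionCurve(frequencies=(1000.0,), vsf_magnitude=(0.0,))
        with pytest.warns(UserWarning, match="sentinel"):
            loss = vsf_ratio_db(normal, diseased)
        assert loss.loss_db[0] >= 1e5

    def test_mismatched_grids_rejected(self):
        a = TransmissionCurve(frequencies=(500.0,), vsf_magnitude=(1e-9,))
        b = TransmissionCurve(frequencies=(1000.0,), vsf_magnitude=(1e-9,))
        with pytest.raises(DataError):
            vsf_ratio_db(a, b)

    def test_level_invariance_of_loss_ratio(self, normal_model, catalog):
        scenario = {s.name: s for s in catalog}["patient2"]
        diseased_model = em.compose_scenario(normal_model, scenario)
        reference = None
        for level in (60.0, 80.0, 100.0):
            p = em.spl_to_pressure(level)
            freqs = normal_model.frequency_grid
            vn = [abs(em.footplate_volume_velocity(
                normal_model, em.harmonic_response(normal_model, f, pressure_pa=p)))
                for f in freqs]
            vd = [abs(em.footplate_volume_velocity(
                diseased_model, em.harmonic_response(diseased_model, f, pressure_pa=p)))
                for f in freqs]
            loss = vsf_ratio_db(
                TransmissionCurve(frequencies=tuple(freqs), vsf_magnitude=tuple(vn)),
                TransmissionCurve(frequencies=tuple(freqs), vsf_magnitude=tuple(vd)),
            )
            if reference is None:
                reference = loss.loss_db
            else:
                assert loss.loss_db == pytest.approx(reference, rel=1e-9, abs=1e-9)


class TestPta4:
    def test_mean4_is_arithmetic_mean(self):
        audiogram = Audiogram(frequencies=OCTAVES, air_db_hl=[30, 30, 35, 40])
        assert pta4(audiogram) == pytest.approx(33.75)

    def test_flat_audiogram_invariant_under_convention(self):
        audiogram = Audiogram(frequencies=OCTAVES, air_db_hl=[25, 25, 25, 25])
        assert pta4(audiogram, "mean4") == pytest.approx(25.0)
        assert pta4(audiogram, "japanese_weighted") == pytest.approx(25.0)

    def test_japanese_weighted_doubles_1khz(self):
        audiogram = Audiogram(frequencies=[500.0, 1000.0, 2000.0], air_db_hl=[20, 30, 40])
        assert pta4(audiogram, "japanese_weighted") == pytest.approx(30.0)

    def test_missing_frequency_named_in_error(self):
        audiogram = Audiogram(frequencies=[500.0, 1000.0, 2000.0], air_db_hl=[20, 30, 40])
        with pytest.raises(DataError, match="4000"):
            pta4(audiogram, "mean4")


class TestAbGap:
    def test_constant_gap(self):
        audiogram = Audiogram(
            frequencies=OCTAVES, air_db_hl=[50] * 4, bone_db_hl=[20] * 4
        )
        gap, mean = ab_gap(audiogram)
        assert gap.loss_db == pytest.approx([30.0] * 4)
        assert mean == pytest.approx(30.0)

    def test_air_equals_bone_gives_zero(self):
        audiogram = Audiogram(
            frequencies=OCTAVES, air_db_hl=[15] * 4, bone_db_hl=[15] * 4
        )
        _, mean = ab_gap(audiogram)
        assert mean == pytest.approx(0.0)

    def test_mean_of_varying_gaps(self):
        audiogram = Audiogram(
            frequencies=[500.0, 1000.0, 2000.0],
            air_db_hl=[40, 50, 60],
            bone_db_hl=[10, 20, 30],
        )
        _, mean = ab_gap(audiogram)
        assert mean == pytest.approx(30.0)

    def test_missing_bone_curve_rejected(self):
        audiogram = Audiogram(frequencies=OCTAVES, air_db_hl=[50] * 4)
        with pytest.raises(DataError):
            ab_gap(audiogram)


class TestClassifySlope:
    @pytest.mark.parametrize(
        "values, label",
        [
            ([40, 30, 20, 10], "up_sloping"),
            ([10, 20, 30, 40], "down_sloping"),
            ([25, 25, 25, 25], "flat"),
            ([10, 10, 30, 10, 10], "peaked"),
            ([30, 30, 10, 30, 30], "dipped"),
        ],
    )
    def test_canonical_shapes(self, values, label):
        assert classify_slope(curve(values)) == label

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            classify_slope(LossCurve(frequencies=[500.0, 1000.0, 2000.0],
                                     loss_db=[1.0, 2.0, 3.0]))


class TestCompareCurves:
    def test_identical_curves(self):
        a = curve([10, 20, 30, 40])
        report = compare_curves(a, a)
        assert report.rms_db == pytest.approx(0.0)
        assert report.pearson_r == pytest.approx(1.0)

    def test_constant_offset_preserves_correlation(self):
        a = curve([10, 20, 30, 40])
        b = curve([15, 25, 35, 45])
        report = compare_curves(b, a)
        assert report.rms_db == pytest.approx(5.0)
        assert report.pearson_r == pytest.approx(1.0)

    def test_antimonotone_pair_has_negative_correlation(self):
        report = compare_curves(curve([40, 30, 20, 10]), curve([10, 20, 30, 40]))
        assert report.pearson_r < 0

    def test_insufficient_overlap_rejected(self):
        a = curve([10, 20, 30, 40], freqs=[500.0, 1000.0, 2000.0, 4000.0])
        b = curve([10, 20, 30, 40], freqs=[505.0, 1010.0, 2020.0, 4040.0])
        with pytest.raises(DataError):
            compare_curves(a, b)


class TestRankScenarios:
    def test_noise_free_self_recovery(self, normal_model, catalog):
        scenario = {s.name: s for s in catalog}["patient2"]
        measured = simulate_loss_curve(normal_model, scenario)
        ranking = rank_scenarios(measured, catalog, normal_model)
        best, report = ranking[0]
        assert best.name == "patient2"
        assert report.rms_db == pytest.approx(0.0, abs=1e-9)

    def test_single_scenario_list_returned_regardless_of_fit(self, normal_model, catalog):
        scenario = {s.name: s for s in catalog}["patient4"]
        measured = curve([0, 0, 0, 0])
        ranking = rank_scenarios(measured, [scenario], normal_model)
        assert len(ranking) == 1
        assert ranking[0][0].name == "patient4"

    def test_cord_scenarios_slope_down_sal_ossification_slopes_up(self, normal_model):
        cord = em.apply_cord_replacement(normal_model, 1e-4, "Ver2")
        sal = em.apply_sal_modification(normal_model, "ossified")
        normal = em.transmission_curve(normal_model)
        cord_loss = vsf_ratio_db(normal, em.transmission_curve(cord, normal.frequencies))
        sal_loss = vsf_ratio_db(normal, em.transmission_curve(sal, normal.frequencies))
        assert classify_slope(cord_loss) == "down_sloping"
        assert classify_slope(sal_loss) == "up_sloping"

    def test_noisy_recovery_majority_of_seeded_replicates(self, normal_model, catalog):
        scenario = {s.name: s for s in catalog}["patient2"]
        base = np.array(simulate_loss_curve(normal_model, scenario).loss_db)
        freqs = list(normal_model.frequency_grid)
        rng = np.random.default_rng(202312)
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            noisy = LossCurve(
                frequencies=freqs, loss_db=(base + rng.normal(0.0, 3.0, base.size)).tolist()
            )
            if rank_scenarios(noisy, catalog, normal_model)[0][0].name == "patient2":
                hits += 1
        assert hits > n_rep // 2
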