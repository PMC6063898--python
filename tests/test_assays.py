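"""Assay calculators: formula identities, invariances, fits, recovery."""

import numpy as np
import pandas as pd
import pytest

from diffenh.assays import (
    AssayError,
    CtMeasurement,
    DoseResponseFitError,
    ddct_fold_change,
    dual_luciferase,
    fit_dose_response,
    four_param_logistic,
    gated_positive_fraction,
    growth_rate,
    interaction_frequency,
    nuclear_signal,
    percent_input,
    positive_fraction,
    proliferation_rate,
    signal_table,
    threshold_from_negative,
)
from diffenh.simulate import AssayScenario, simulate_assays


class TestInteractionFrequency:
    def test_ct_parity_gives_unity(self):
        res = interaction_frequency([23.0, 23.0, 23.0], [23.0, 23.0, 23.0])
        assert res.frequency == pytest.approx(1.0, abs=1e-12)

    def test_three_cycle_lag_gives_one_eighth(self):
        res = interaction_frequency([23.0], [20.0])
        assert res.frequency == pytest.approx(0.125, abs=1e-12)

    def test_each_extra_cycle_halves_frequency(self):
        for base in np.arange(18.0, 30.0, 0.7):
            f0 = interaction_frequency([base], [20.0]).frequency
            f1 = interaction_frequency([base + 1.0], [20.0]).frequency
            assert f1 == pytest.approx(f0 / 2.0, rel=1e-12)

    def test_machine_offset_invariance(self):
        a = interaction_frequency([24.1, 24.3], [21.0, 21.2])
        b = interaction_frequency([27.1, 27.3], [24.0, 24.2])
        assert a.frequency == pytest.approx(b.frequency, rel=1e-12)

    def test_se_variants_ordered(self):
        res = interaction_frequency(
            CtMeasurement("F4", "3C", (23.0, 23.4, 22.8), "test_3C"),
            CtMeasurement("BAC", "3C", (20.0, 20.3, 19.9), "control_BAC"),
        )
        assert res.se_with_bac >= res.se_without_bac > 0
        assert len(res.replicate_frequencies) == 3

    def test_missing_bac_rejected(self):
        with pytest.raises(AssayError):
            interaction_frequency([23.0], None)


class TestPercentInput:
    def test_chip_equal_to_adjusted_input_gives_hundred_percent(self):
        frac = 0.01
        adjusted = 25.0 - np.log2(1.0 / frac)
        assert percent_input([adjusted], [25.0], frac) == pytest.approx(100.0, rel=1e-12)

    def test_five_cycles_after_adjusted_input_gives_one_thirtysecond(self):
        frac = 0.01
        adjusted = 25.0 - np.log2(1.0 / frac)
        assert percent_input([adjusted + 5.0], [25.0], frac) == pytest.approx(100.0 / 32.0, rel=1e-12)

    def test_invalid_fraction_rejected(self):
        with pytest.raises(AssayError):
            percent_input([20.0], [25.0], 0.0)


class TestDualLuciferase:
    def test_ratio_of_ratios(self):
        assert dual_luciferase(200.0, 100.0, 50.0, 100.0) == pytest.approx(4.0, abs=1e-12)

    def test_identity_when_test_equals_vector(self):
        assert dual_luciferase(80.0, 40.0, 80.0, 40.0) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance_in_instrument_units(self):
        base = dual_luciferase(200.0, 100.0, 50.0, 100.0)
        for scale in (1e-3, 0.5, 7.0, 1e4):
            assert dual_luciferase(
                200.0 * scale, 100.0 * scale, 50.0 * scale, 100.0 * scale
            ) == pytest.approx(base, rel=1e-12)

    def test_zero_renilla_rejected(self):
        with pytest.raises(AssayError):
            dual_luciferase(200.0, 0.0, 50.0, 100.0)


class TestDdct:
    def test_delta_delta_of_two_gives_four(self):
        # sample dCt 2, control dCt 4 -> 2^(4-2) = 4
        assert ddct_fold_change(22.0, 20.0, 24.0, 20.0) == pytest.approx(4.0, abs=1e-12)

    def test_sample_equal_control_gives_one(self):
        assert ddct_fold_change(22.0, 20.0, 22.0, 20.0) == pytest.approx(1.0, abs=1e-12)

    def test_machine_offset_invariance(self):
        a = ddct_fold_change(22.0, 20.0, 24.0, 19.5)
        b = ddct_fold_change(25.0, 23.0, 27.0, 22.5)
        assert a == pytest.approx(b, rel=1e-12)

    def test_recovers_planted_template_ratio(self):
        tables = simulate_assays(AssayScenario(ddct_fold_change=16.0, ct_noise_sd=0.0, seed=1))
        rt = tables["rt_qpcr"]
        ct_cols = [c for c in rt.columns if c.startswith("ct")]

        def cts(sample, target):
            row = rt[(rt["sample"] == sample) & (rt["target"] == target)].iloc[0]
            return row[ct_cols].to_numpy(dtype=float)

        fold = ddct_fold_change(
            cts("test", "gene"), cts("test", "reference"),
            cts("control", "gene"), cts("control", "reference"),
        )
        assert fold == pytest.approx(16.0, rel=1e-9)


class TestNuclearSignal:
    def test_area_times_intensity(self):
        assert nuclear_signal(100.0, 2.0) == 200.0

    def test_all_below_threshold_gives_zero_fraction(self):
        df = pd.DataFrame(
            {
                "nucleus_id": ["n1", "n2"],
                "channel": ["MGMT", "MGMT"],
                "area": [100.0, 120.0],
                "mean_intensity": [1.0, 1.1],
            }
        )
        assert positive_fraction(df, "MGMT", threshold=1e9) == 0.0

    def test_planted_positive_fraction_recovered(self):
        tables = simulate_assays(AssayScenario(positive_fraction=0.24, n_nuclei=100, seed=5))
        nuclei = tables["nuclei"]
        neg = signal_table(nuclei[nuclei["channel"] == "control"])["signal"]
        thr = threshold_from_negative(neg, k=3.0)
        estimated = positive_fraction(nuclei, "MGMT", thr)
        assert abs(estimated - 0.24) <= 0.10  # binomial noise at n=100
        # and the classifier matches the actually drawn labels closely
        drawn = nuclei.attrs["true_positive"].mean()
        assert abs(estimated - drawn) <= 0.05

    def test_gated_fraction_uses_positive_and_negative_gates(self):
        rows = []
        # two proliferating tumor cells (Ki67+/CD45-), one MGMT+; one immune cell
        spec = [
            ("n1", {"Ki67": 10.0, "CD45": 0.1, "MGMT": 10.0}),
            ("n2", {"Ki67": 10.0, "CD45": 0.1, "MGMT": 0.1}),
            ("n3", {"Ki67": 10.0, "CD45": 10.0, "MGMT": 10.0}),
        ]
        for nid, channels in spec:
            for ch, inten in channels.items():
                rows.append(
                    {"nucleus_id": nid, "channel": ch, "area": 100.0, "mean_intensity": inten}
                )
        df = pd.DataFrame(rows)
        thr = {"Ki67": 100.0, "CD45": 100.0, "MGMT": 100.0}
        assert gated_positive_fraction(df, "MGMT", thr) == pytest.approx(0.5)

    def test_unknown_channel_rejected(self):
        df = pd.DataFrame(
            {"nucleus_id": ["n1"], "channel": ["MGMT"], "area": [10.0], "mean_intensity": [1.0]}
        )
        with pytest.raises(AssayError):
            positive_fraction(df, "Ki67", 1.0)


class TestDoseResponse:
    def test_noiseless_self_consistency(self):
        doses = np.logspace(-2, 2, 10) * 10.0
        responses = four_param_logistic(doses, 0.0, 1.0, 1.0, np.log(10.0))
        fit = fit_dose_response(doses, responses)
        assert fit.ic50 == pytest.approx(10.0, rel=1e-6)
        assert fit.bottom == pytest.approx(0.0, abs=1e-8)
        assert fit.top == pytest.approx(1.0, abs=1e-8)
        assert fit.hill == pytest.approx(1.0, rel=1e-6)

    def test_flat_response_is_fit_failure(self):
        with pytest.raises(DoseResponseFitError):
            fit_dose_response([1.0, 10.0, 100.0, 1000.0], [0.8, 0.8, 0.8, 0.8])

    def test_too_few_distinct_doses_rejected(self):
        with pytest.raises(AssayError):
            fit_dose_response([1.0, 1.0, 10.0, 10.0], [1.0, 1.0, 0.2, 0.2])

    def test_log2_ic50_shift_between_sensitive_and_resistant(self):
        # resistant line IC50 100, sensitive 5: log2 shift is log2(20)
        doses = np.logspace(-1, 3, 12)
        resistant = fit_dose_response(doses, four_param_logistic(doses, 0, 1, 1.2, np.log(100.0)))
        sensitive = fit_dose_response(doses, four_param_logistic(doses, 0, 1, 1.2, np.log(5.0)))
        shift = resistant.log2_ic50 - sensitive.log2_ic50
        assert shift == pytest.approx(np.log2(20.0), rel=1e-4)

    def test_recovery_under_measurement_noise(self):
        hits = 0
        for seed in range(25):
            tables = simulate_assays(
                AssayScenario(ic50=100.0, response_cv=0.05, seed=seed)
            )
            dr = tables["dose_response"]
            fit = fit_dose_response(dr["dose"], dr["response"])
            hits += abs(fit.ic50 - 100.0) / 100.0 <= 0.10
        assert hits >= 23


class TestProliferation:
    def test_constant_series_is_flat_one(self):
        rate = proliferation_rate([0, 1, 2, 3], [40.0, 40.0, 40.0, 40.0])
        np.testing.assert_allclose(rate, 1.0)

    def test_daily_doubling(self):
        rate = proliferation_rate([0, 1, 2, 3], [5.0, 10.0, 20.0, 40.0])
        np.testing.assert_allclose(rate, [1.0, 2.0, 4.0, 8.0])

    def test_missing_day_zero_rejected(self):
        with pytest.raises(AssayError):
            proliferation_rate([1, 2], [10.0, 20.0])

    def test_zero_day_zero_rejected(self):
        with pytest.raises(AssayError):
            proliferation_rate([0, 1], [0.0, 20.0])

    def test_growth_rate_recovered_from_noisy_exponential(self, rng):
        days = np.arange(0.0, 6.0, 0.25)
        true_rate = 0.8  # doublings per day
        series = 5.0 * 2.0 ** (true_rate * days) * rng.lognormal(0, 0.05, size=len(days))
        assert abs(growth_rate(days, series) - true_rate) / true_rate <= 0.10
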