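"""Generators are exact forward models: analyze(generate(truth)) == truth."""

import math
from dataclasses import replace

import numpy as np
import pytest

from lipolyzer import (
    CalibrationCurve,
    backscatter_rate,
    default_config,
    ffa_release_percent,
    initial_rate,
    sauter_mean_diameter,
    simulate_peak_tables,
    simulate_psd,
    simulate_scan,
    simulate_titration,
    species_lipolysis_rates,
    total_rate_config,
)
from lipolyzer.elsd import lipolysis_rate
from lipolyzer.errors import CalibrationError, ValidationError
from lipolyzer.synthetic import (
    OIL_CALIBRATIONS,
    SPECIES_LIPOLYSIS_RATES,
    TOTAL_LIPOLYSIS_RATES,
)


def curves_of(cfg):
    return {k: CalibrationCurve(a=a, b=b) for k, (a, b) in cfg.calibration.items()}


class TestTitration:
    def test_round_trip_recovers_first_order_curve(self):
        cfg = default_config("SBO", seed=3)
        series = simulate_titration(cfg)
        ffa = ffa_release_percent(series, cfg.digestion_spec)
        expected = cfg.f_max_percent * (
            1.0 - np.exp(-cfg.k_per_min * series.times / 60.0)
        )
        np.testing.assert_allclose(ffa, expected, atol=1e-9)

    def test_fast_kinetics_step_to_fmax(self):
        cfg = default_config("SBO", k_per_min=1e4)
        series = simulate_titration(cfg)
        ffa = ffa_release_percent(series, cfg.digestion_spec)
        assert ffa[1] == pytest.approx(cfg.f_max_percent, rel=1e-6)

    def test_deterministic(self):
        a = simulate_titration(default_config("PGO", seed=7))
        b = simulate_titration(default_config("PGO", seed=7))
        np.testing.assert_array_equal(a.volumes, b.volumes)

    @pytest.mark.parametrize(
        "oil, ffa10, rate",
        [
            ("SBO", 93.8, 0.134),
            ("PGO", 71.8, 0.094),
            ("PHY", 85.4, 0.118),
            ("IO", 92.2, 0.124),
        ],
    )
    def test_design_endpoints(self, oil, ffa10, rate):
        """Default kinetics hit the reported 10-min release and initial rate."""
        cfg = default_config(oil)
        series = simulate_titration(cfg)
        ffa = ffa_release_percent(series, cfg.digestion_spec)
        assert ffa[-1] == pytest.approx(ffa10, abs=0.5)
        assert initial_rate(series, cfg.digestion_spec) == pytest.approx(
            rate, abs=0.004
        )


class TestPeakTables:
    @pytest.mark.parametrize("oil", ["SBO", "PGO"])
    def test_zero_noise_species_round_trip(self, oil):
        cfg = default_config(oil, seed=11)
        obs0, obst = simulate_peak_tables(cfg)
        rates = species_lipolysis_rates(obs0, obst, curves_of(cfg))
        for label, truth in cfg.true_rates.items():
            assert rates[label] == pytest.approx(truth, abs=1e-9)

    @pytest.mark.parametrize("oil", sorted(TOTAL_LIPOLYSIS_RATES))
    def test_zero_noise_total_round_trip(self, oil):
        cfg = total_rate_config(oil, seed=11)
        obs0, obst = simulate_peak_tables(cfg)
        curve = CalibrationCurve(*OIL_CALIBRATIONS[oil])
        rate = lipolysis_rate(obs0, obst, curve)
        assert rate == pytest.approx(TOTAL_LIPOLYSIS_RATES[oil], abs=1e-9)

    def test_zero_rates_identical_concentration_ratios(self):
        cfg = default_config("PGO", true_rates={"CLn-CLn-CLn": 0.0,
                                                "CLn-CLn-P": 0.0})
        obs0, obst = simulate_peak_tables(cfg)
        for p0, pt in zip(obs0.peaks, obst.peaks):
            r0 = p0.area / obs0.is_area
            rt = pt.area / obst.is_area
            # equal concentration ratios need not mean equal areas: the
            # weighed product masses differ between the two time points
            curve = curves_of(cfg)[p0.annotation]
            c0 = curve.invert(r0) * obs0.m_lp_mg / obs0.m_a_mg
            ct = curve.invert(rt) * obst.m_lp_mg / obst.m_a_mg
            assert ct == pytest.approx(c0, rel=1e-12)

    def test_missing_calibration_is_error(self):
        cfg = default_config("PGO")
        cfg = replace(cfg, true_rates={**cfg.true_rates, "X-X-X": 50.0})
        with pytest.raises(CalibrationError, match="X-X-X"):
            simulate_peak_tables(cfg)

    def test_seeded_noise_reproducible(self):
        cfg = default_config("SBO", seed=5, noise_cv=0.02)
        a0, at = simulate_peak_tables(cfg)
        b0, bt = simulate_peak_tables(cfg)
        assert [p.area for p in a0.peaks] == [p.area for p in b0.peaks]
        assert [p.area for p in at.peaks] == [p.area for p in bt.peaks]

    def test_one_percent_noise_mean_error_below_one_point(self):
        """200 noisy replicates: mean absolute rate error <= 1 point."""
        errors = []
        for rep in range(200):
            cfg = default_config("PGO", seed=1000 + rep, noise_cv=0.01)
            obs0, obst = simulate_peak_tables(cfg)
            rates = species_lipolysis_rates(obs0, obst, curves_of(cfg))
            errors.extend(
                abs(rates[lb] - truth) for lb, truth in cfg.true_rates.items()
            )
        assert np.mean(errors) <= 1.0

    def test_retention_times_follow_pn_order(self):
        cfg = default_config("SBO")
        obs0, _ = simulate_peak_tables(cfg)
        from lipolyzer import parse_tag_label

        pns = [parse_tag_label(p.annotation).pn for p in obs0.peaks]
        assert pns == sorted(pns)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ValidationError):
            default_config("PGO", true_rates={"CLn-CLn-CLn": 120.0})


class TestPsdAndScan:
    def test_zero_width_distribution_d32_is_median(self):
        cfg = default_config("PGO", psd_gsd=1.0, psd_median_um=0.30)
        assert sauter_mean_diameter(simulate_psd(cfg)) == pytest.approx(0.30)

    def test_lognormal_d32_near_analytic_value(self):
        cfg = default_config("PGO", seed=2, psd_n_particles=200_000)
        d32 = sauter_mean_diameter(simulate_psd(cfg))
        sigma = math.log(cfg.psd_gsd)
        analytic = cfg.psd_median_um * math.exp(2.5 * sigma**2)
        assert d32 == pytest.approx(analytic, rel=0.02)

    def test_scan_slopes_recovered(self):
        cfg = default_config("PGO", seed=4)
        scan = simulate_scan(cfg)
        assert backscatter_rate(scan, "creaming") == pytest.approx(7.06, abs=1e-9)
        assert backscatter_rate(scan, "clarification") == pytest.approx(
            -2.12, abs=1e-9
        )

    def test_noisy_scan_slope_within_sampling_tolerance(self):
        cfg = default_config("PGO", seed=9, scan_noise_sd=0.3)
        scan = simulate_scan(cfg)
        # OLS slope sd for white noise of sd s averaged over m height samples:
        # s / sqrt(m) / sqrt(sum((t - tbar)^2)) with t in hours
        hours = scan.times_min / 60.0
        m = int((scan.heights_mm >= scan.heights_mm.max() - 3.0).sum())
        slope_sd = cfg.scan_noise_sd / math.sqrt(m) / math.sqrt(
            ((hours - hours.mean()) ** 2).sum()
        )
        rate = backscatter_rate(scan, "creaming")
        assert rate == pytest.approx(7.06, abs=3 * slope_sd)

    def test_same_seed_reproducible(self):
        cfg = default_config("IO", seed=6, scan_noise_sd=0.2)
        np.testing.assert_array_equal(
            simulate_scan(cfg).dbs_percent, simulate_scan(cfg).dbs_percent
        )
        np.testing.assert_array_equal(
            simulate_psd(cfg).counts, simulate_psd(cfg).counts
        )


def test_default_config_species_have_published_curves():
    for oil, rates in SPECIES_LIPOLYSIS_RATES.items():
        cfg = default_config(oil)
        assert set(rates) <= set(cfg.calibration)
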