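"""Synthetic waveforms, plates, Hill datasets and uptake traces."""

import numpy as np
import pytest

from flthts import (
    Contaminant,
    DecayGroundTruth,
    HillGroundTruth,
    IRFModel,
    NoiseSpec,
    PlantedEffect,
    PlateLayout,
    TimeGrid,
    fit_decay,
    hill_curve,
    simulate_hill_dataset,
    simulate_plate,
    simulate_uptake_trace,
    simulate_waveform,
)
from flthts.dose_response import uptake_initial_rate

NOISELESS = NoiseSpec("none")


class TestSimulateWaveform:
    def test_delta_irf_single_exponential_is_exact(self, delta_irf):
        truth = DecayGroundTruth(x=(1.0,), tau_ns=(2.5,))
        w1, _ = simulate_waveform(truth, delta_irf, NOISELESS)
        t = delta_irf.grid.times()
        expected = np.exp(-t / 2.5)
        expected *= truth.total_intensity / expected.sum()
        assert np.allclose(w1.intensity, expected, rtol=1e-12)

    @pytest.mark.parametrize("shape", ["gaussian", "delta"])
    @pytest.mark.parametrize("tau", [(1.0,), (2.5, 1.25)])
    def test_channel_ratio_equals_spectral_fraction(self, shape, tau):
        # noiseless, contaminant-free: integral(Ch2)/integral(Ch1) = 0.43,
        # independent of lifetimes and IRF shape
        irf = IRFModel(shape=shape, center=10.0, width=1.0)
        x = tuple(1.0 / len(tau) for _ in tau)
        truth = DecayGroundTruth(x=x, tau_ns=tau, channel2_fraction=0.43)
        w1, w2 = simulate_waveform(truth, irf, NOISELESS)
        assert w2.integral() / w1.integral() == pytest.approx(0.43, rel=1e-12)

    def test_mixture_linearity(self, irf):
        # mixture model equals the amplitude-weighted sum of single-component
        # models, noiseless, to 1e-10 relative
        from flthts import convolve_model

        x, tau = (0.6, 0.4), (2.5, 1.0)
        m_mix = convolve_model(np.array(x), np.array(tau), irf)
        m_sum = sum(xi * convolve_model([1.0], [taui], irf) for xi, taui in zip(x, tau))
        assert np.max(np.abs(m_mix - m_sum)) <= 1e-10 * np.max(m_sum)

    def test_contaminant_shifts_integrated_ratio_as_constructed(self, irf):
        c = Contaminant(frac_ch1=0.1, frac_ch2=0.3, tau_ns=3.5)
        truth = DecayGroundTruth(contaminant=c)
        w1, w2 = simulate_waveform(truth, irf, NOISELESS)
        expected = (0.43 + 0.3) / (1.0 + 0.1)
        assert w2.integral() / w1.integral() == pytest.approx(expected, rel=1e-6)

    def test_grid_too_short_raises(self):
        irf = IRFModel(shape="gaussian", center=10.0, width=1.0,
                       grid=TimeGrid(0.0, 0.25, 60))  # 5 ns after the IRF centre
        with pytest.raises(ValueError, match="5x the longest lifetime"):
            simulate_waveform(DecayGroundTruth(), irf, NOISELESS)

    def test_amplitude_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            DecayGroundTruth(x=(0.6, 0.5), tau_ns=(2.0, 1.0))


class TestSimulatePlate:
    def test_all_dmso_when_no_compounds(self):
        plate = simulate_plate(PlateLayout(format=384, n_compounds=0), seed=0)
        assert set(plate.plate_map["role"]) == {"dmso"}
        assert len(plate.plate_map) == 384

    def test_1536_control_columns(self):
        pmap = PlateLayout(format=1536, n_compounds=1280).build_map()
        for col in (1, 2, 47, 48):
            assert (pmap.loc[pmap["col"] == col, "role"] == "dmso").all()
        assert (pmap["role"] == "compound").sum() == 1280
        assert len(pmap) == 1536

    def test_seed_determinism_bit_identical(self):
        layout = PlateLayout(format=384, n_compounds=16)
        a = simulate_plate(layout, seed=42)
        b = simulate_plate(layout, seed=42)
        assert np.array_equal(a.ch1, b.ch1) and np.array_equal(a.ch2, b.ch2)
        c = simulate_plate(layout, seed=43)
        assert not np.array_equal(a.ch1, c.ch1)

    def test_planted_shift_moves_noiseless_lifetime_exactly(self, irf):
        truth = DecayGroundTruth()
        shifted = truth.shifted(-0.1)
        assert shifted.mean_tau_ns == pytest.approx(truth.mean_tau_ns - 0.1, abs=1e-12)
        w1, _ = simulate_waveform(shifted, irf, NOISELESS)
        fit = fit_decay(w1, irf, n_components=2)
        assert fit.mean_tau_ns == pytest.approx(truth.mean_tau_ns - 0.1, abs=1e-3)

    def test_effect_on_control_well_rejected(self):
        layout = PlateLayout(format=384, n_compounds=16)
        with pytest.raises(ValueError, match="control well"):
            simulate_plate(layout, effects={"A1": PlantedEffect("shift", -0.1)}, seed=0)

    def test_effect_on_unknown_well_rejected(self):
        with pytest.raises(KeyError):
            simulate_plate(PlateLayout(format=384), effects={"Z99": PlantedEffect("shift", -0.1)})

    def test_tool_wells_share_shifted_truth(self):
        plate = simulate_plate(
            PlateLayout(format=384, n_compounds=0, tool_cols=(2,)),
            noise=NOISELESS, seed=0, tool_dtau_ns=-0.15,
        )
        pmap = plate.plate_map
        assert (pmap.loc[pmap["col"] == 2, "role"] == "tool").all()
        i_tool = pmap.index[pmap["role"] == "tool"][0]
        i_dmso = pmap.index[pmap["role"] == "dmso"][0]
        # shifted lifetimes decay faster: smaller tail, larger peak fraction
        assert not np.allclose(plate.ch1[i_tool], plate.ch1[i_dmso])

    def test_planted_effect_json_round_trip(self):
        for eff in (PlantedEffect("shift", -0.066),
                    PlantedEffect("contaminant", contaminant=Contaminant(0.1, 0.3, 3.5))):
            assert PlantedEffect.from_json(eff.to_json()) == eff


class TestHillDataset:
    def test_zero_noise_lies_on_curve(self):
        truth = HillGroundTruth(midpoint=6.5, n_hill=2.0, noise_sd=0.0)
        x = np.linspace(7.5, 5.5, 9)
        df = simulate_hill_dataset(truth, x, seed=0)
        mu = hill_curve(df["x_value"].to_numpy(), 6.5, 2.0, 0.0, 1.0, "pCa")
        assert np.allclose(df["response"].to_numpy(), mu)

    def test_warns_when_grid_misses_midpoint(self):
        truth = HillGroundTruth(midpoint=6.5, noise_sd=0.0)
        with pytest.warns(UserWarning, match="one side"):
            simulate_hill_dataset(truth, np.linspace(6.4, 5.0, 8), seed=0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5 distinct"):
            simulate_hill_dataset(HillGroundTruth(midpoint=6.5), np.array([7, 6.6, 6.5, 6.0]))


class TestUptakeTrace:
    def test_zero_rate_is_flat(self):
        df = simulate_uptake_trace(rate=0.0, baseline=2.0, duration_s=900.0)
        assert np.allclose(df["fluorescence"], 2.0)

    def test_noiseless_initial_slope_equals_minus_rate(self):
        df = simulate_uptake_trace(rate=1e-3, baseline=1.0, duration_s=900.0, n_points=2000)
        r = uptake_initial_rate(df, window_s=10.0)
        assert r.rate == pytest.approx(1e-3, rel=1e-2)

    def test_expected_trace_monotone_decreasing(self):
        df = simulate_uptake_trace(rate=5e-4, baseline=1.0, duration_s=900.0)
        assert np.all(np.diff(df["fluorescence"]) <= 0)

    def test_full_inhibition_rate_ratio_near_zero(self):
        # a saturating pump inhibitor abolishes uptake: rate ratio -> 0
        control = uptake_initial_rate(simulate_uptake_trace(1e-3, n_points=2000))
        inhibited = uptake_initial_rate(simulate_uptake_trace(0.0, n_points=2000))
        assert abs(inhibited.rate) / control.rate < 1e-6
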