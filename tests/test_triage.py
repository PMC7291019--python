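"""Flagging, hit selection, counter-screen, MAD and robust Z-prime."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flthts import (
    ControlSummary,
    WellStat,
    channel_ratio_percent_diff,
    counter_screen,
    flag_fluorescent,
    mad,
    robust_zprime,
    select_hits,
)


def make_wells(dmso_taus, dmso_ratios=None, compounds=()):
    """Build a WellStat list: DMSO wells plus (tau, ratio[, cid]) compound wells."""
    wells = []
    ratios = dmso_ratios if dmso_ratios is not None else [0.43] * len(dmso_taus)
    for i, (tau, r) in enumerate(zip(dmso_taus, ratios)):
        wells.append(WellStat(f"D{i}", "dmso", tau, 1000.0, 1000.0 * r))
    for i, spec in enumerate(compounds):
        tau, r = spec[0], spec[1]
        cid = spec[2] if len(spec) > 2 else f"C{i:04d}"
        wells.append(WellStat(f"X{i}", "compound", tau, 1000.0, 1000.0 * r, cid))
    return wells


def gaussian_dmso(rng, n=64, tau=2.0, tau_sd=0.0066, ratio=0.43, ratio_sd=0.001):
    return list(rng.normal(tau, tau_sd, n)), list(rng.normal(ratio, ratio_sd, n))


class TestMad:
    def test_constant_input_is_zero(self):
        assert mad([1, 1, 1]) == 0.0

    def test_hand_arithmetic(self):
        assert mad([1, 2, 3, 4, 5]) == pytest.approx(1.4826)

    def test_empty_and_singleton_rejected(self):
        with pytest.raises(ValueError):
            mad([])
        with pytest.raises(ValueError):
            mad([1.0])

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=2, max_size=8))
    def test_matches_brute_force_oracle_on_short_inputs(self, values):
        # independent oracle via explicit sorted-median arithmetic
        def med(v):
            s = sorted(v)
            n = len(s)
            return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])

        center = med(values)
        expected = 1.4826 * med([abs(v - center) for v in values])
        assert mad(values) == pytest.approx(expected, rel=1e-12, abs=1e-9)

    def test_consistent_for_gaussian_sd(self, rng):
        x = rng.normal(0.0, 3.0, 200_000)
        assert mad(x) == pytest.approx(3.0, rel=0.02)


class TestRobustZPrime:
    def test_zero_mads_give_one(self):
        assert robust_zprime(ControlSummary("tool", 1.8, 0.0),
                             ControlSummary("dmso", 2.0, 0.0)) == 1.0

    def test_equal_medians_raise(self):
        with pytest.raises(ValueError, match="dynamic range"):
            robust_zprime(ControlSummary("tool", 2.0, 0.1),
                          ControlSummary("dmso", 2.0, 0.1))

    @pytest.mark.parametrize("sep_sd,expected", [(12.0, 0.5), (6.0, 0.0)])
    def test_gaussian_separation_calibration(self, sep_sd, expected):
        # equal-sigma Gaussian controls separated by sep_sd pooled SDs;
        # Monte-Carlo average over seeds
        vals = []
        for s in range(200):
            r = np.random.default_rng(s)
            a = r.normal(0.0, 1.0, 64)
            b = r.normal(sep_sd, 1.0, 64)
            vals.append(robust_zprime(ControlSummary.from_values("tool", b),
                                      ControlSummary.from_values("dmso", a)))
        assert np.mean(vals) == pytest.approx(expected, abs=0.05)

    def test_affine_invariance(self, rng):
        a = rng.normal(2.0, 0.01, 64)
        b = rng.normal(1.85, 0.01, 64)
        z1 = robust_zprime(ControlSummary.from_values("t", b),
                           ControlSummary.from_values("d", a))
        scale, offset = 3.7, -1.2
        z2 = robust_zprime(ControlSummary.from_values("t", scale * b + offset),
                           ControlSummary.from_values("d", scale * a + offset))
        assert z1 == pytest.approx(z2, rel=1e-12)


class TestChannelRatio:
    def test_zero_at_dmso_mean(self):
        assert channel_ratio_percent_diff(0.43, 0.43) == 0.0

    def test_plus_ten_percent(self):
        assert channel_ratio_percent_diff(0.473, 0.43) == pytest.approx(10.0)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            channel_ratio_percent_diff(0.43, 0.0)

    def test_null_distribution_centered_at_zero(self, rng):
        taus, ratios = gaussian_dmso(rng, n=500)
        pd_ = channel_ratio_percent_diff(np.array(ratios), float(np.mean(ratios)))
        assert abs(pd_.mean()) < 3 * pd_.std(ddof=1) / np.sqrt(len(ratios))


class TestFlagFluorescent:
    def test_strong_contaminants_all_flagged(self, rng):
        taus, ratios = gaussian_dmso(rng)
        sd_pd = 100 * np.std(ratios, ddof=1) / np.mean(ratios)
        wells = make_wells(taus, ratios,
                           compounds=[(2.0, 0.43 * (1 + 10 * sd_pd / 100)) for _ in range(5)])
        flags = flag_fluorescent(wells)
        assert all(flags.values()) and len(flags) == 5

    def test_clean_compounds_not_flagged(self, rng):
        taus, ratios = gaussian_dmso(rng)
        wells = make_wells(taus, ratios, compounds=[(2.0, 0.43)] * 5)
        assert not any(flag_fluorescent(wells).values())

    def test_too_few_dmso_wells_raise(self):
        wells = make_wells([2.0] * 5)
        with pytest.raises(ValueError, match="DMSO"):
            flag_fluorescent(wells)


class TestSelectHits:
    def test_threshold_bracketing(self, rng):
        taus, ratios = gaussian_dmso(rng)
        sd = np.std(taus, ddof=1)
        med = np.median(taus)
        wells = make_wells(taus, ratios,
                           compounds=[(med - 8 * sd, 0.43, "eight"),
                                      (med - 6 * sd, 0.43, "six"),
                                      (med - 1 * sd, 0.43, "one")])
        h5 = select_hits(wells, threshold_sd=5.0).set_index("compound_id")["hit"]
        h7 = select_hits(wells, threshold_sd=7.0).set_index("compound_id")["hit"]
        assert h5["eight"] and h7["eight"]
        assert h5["six"] and not h7["six"]
        assert not h5["one"] and not h7["one"]

    def test_direction_recorded(self, rng):
        taus, ratios = gaussian_dmso(rng)
        sd, med = np.std(taus, ddof=1), np.median(taus)
        wells = make_wells(taus, ratios,
                           compounds=[(med - 8 * sd, 0.43, "down"), (med + 8 * sd, 0.43, "up")])
        t = select_hits(wells, 5.0).set_index("compound_id")
        assert t.loc["down", "direction"] == "fret_increase"
        assert t.loc["up", "direction"] == "fret_decrease"

    def test_flagged_wells_never_hits(self, rng):
        taus, ratios = gaussian_dmso(rng)
        sd, med = np.std(taus, ddof=1), np.median(taus)
        # strong lifetime shift AND strong ratio shift -> flagged, not a hit
        wells = make_wells(taus, ratios, compounds=[(med - 10 * sd, 0.6, "fc")])
        flags = flag_fluorescent(wells)
        t = select_hits(wells, 5.0, fluorescent_flags=flags)
        assert flags["X0"] and not t.loc[0, "hit"]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(-12, 12), min_size=1, max_size=30))
    def test_hit_sets_nested_across_thresholds(self, shifts):
        rng = np.random.default_rng(0)
        taus, ratios = gaussian_dmso(rng)
        sd, med = np.std(taus, ddof=1), np.median(taus)
        wells = make_wells(taus, ratios,
                           compounds=[(med + s * sd, 0.43) for s in shifts])
        hit_sets = []
        for thr in (3.0, 5.0, 7.0):
            t = select_hits(wells, thr)
            hit_sets.append(set(t.loc[t["hit"], "well"]))
        assert hit_sets[2] <= hit_sets[1] <= hit_sets[0]

    def test_zero_dmso_sd_raises(self):
        wells = make_wells([2.0] * 10, compounds=[(1.5, 0.43)])
        with pytest.raises(ValueError, match="SD"):
            select_hits(wells, 5.0)


class TestCounterScreen:
    def make_linker(self, rng, compound_shifts):
        taus, ratios = gaussian_dmso(rng)
        sd, med = np.std(taus, ddof=1), np.median(taus)
        comps = [(med + s * sd, 0.43, cid) for cid, s in compound_shifts.items()]
        return make_wells(taus, ratios, compounds=comps)

    def test_specific_hit_passes_promiscuous_fails(self, rng):
        linker = self.make_linker(rng, {"specific": 0.0, "promiscuous": 6.0})
        out = counter_screen(["specific", "promiscuous"], linker)
        assert out == {"specific": "pass", "promiscuous": "fail"}

    def test_absent_compound_is_untested(self, rng):
        linker = self.make_linker(rng, {"a": 0.0})
        assert counter_screen(["missing"], linker)["missing"] == "untested"

    def test_borderline_four_sd_fails(self, rng):
        linker = self.make_linker(rng, {"b": 4.0})
        assert counter_screen(["b"], linker)["b"] == "fail"
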