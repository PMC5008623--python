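"""Forward simulator: analytic fractions, Poisson sampling, activity series."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plasmidbreaks import (
    FractionTriple,
    SimulationConfig,
    activity_series,
    analytic_fractions,
    render_lane,
    sample_observed_fractions,
    simulate_conformations,
    simulate_replicates,
)
from plasmidbreaks.tables import compound_fractions, scavenger_fractions

IB_POINT = dict(x_ssb=1.7789, x_dsb=0.26136)  # exact-Poisson Ib operating point


class TestAnalyticFractions:
    def test_no_damage_all_supercoiled(self):
        f = analytic_fractions(0.0, 0.0)
        assert f.as_tuple() == (1.0, 0.0, 0.0)

    def test_ib_operating_point(self):
        """The Ib condition inverts to (SC, OC, L) = (0.13, 0.64, 0.23)."""
        f = analytic_fractions(**IB_POINT)
        assert f.f_l == pytest.approx(0.23, abs=1e-4)
        assert f.f_sc == pytest.approx(0.13, abs=1e-4)
        assert f.f_oc == pytest.approx(0.64, abs=1e-4)

    def test_ln2_dsb_splits_half_linear(self):
        f = analytic_fractions(0.0, math.log(2.0))
        assert f.f_l == pytest.approx(0.5)
        assert f.f_sc == pytest.approx(0.5)
        assert f.f_oc == pytest.approx(0.0, abs=1e-12)

    def test_negative_means_rejected(self):
        with pytest.raises(ValueError):
            analytic_fractions(-0.1, 0.0)

    @settings(derandomize=True, max_examples=50)
    @given(x_ssb=st.floats(0.0, 4.0), x_dsb=st.floats(0.0, 3.0))
    def test_valid_triple_everywhere(self, x_ssb, x_dsb):
        f = analytic_fractions(x_ssb, x_dsb)
        assert sum(f.as_tuple()) == pytest.approx(1.0, abs=1e-9)


class TestSimulateConformations:
    def test_zero_yields_all_supercoiled(self):
        cfg = SimulationConfig(0.0, 0.0, n_plasmids=1000, seed=1)
        c = simulate_conformations(cfg)
        assert (c.n_sc, c.n_oc, c.n_l) == (1000, 0, 0)

    def test_counts_conserve_plasmids(self):
        cfg = SimulationConfig(0.3, 0.05, n_plasmids=12345, seed=2)
        c = simulate_conformations(cfg)
        assert c.n_total == 12345

    def test_no_dsb_channel_no_linear(self):
        cfg = SimulationConfig(50.0, 0.0, n_plasmids=5000, seed=3)
        c = simulate_conformations(cfg)
        assert c.n_l == 0
        assert c.n_sc == 0  # saturated SSB channel relaxes everything

    def test_million_plasmids_match_analytic_fractions(self):
        """Empirical fractions land within 4 binomial SEs of the Poisson map."""
        d = 6.37
        cfg = SimulationConfig(
            IB_POINT["x_ssb"] / d, IB_POINT["x_dsb"] / d,
            decays_per_plasmid=d, n_plasmids=10**6, seed=4,
        )
        c = simulate_conformations(cfg)
        truth = analytic_fractions(**IB_POINT)
        got = c.fractions()
        n = cfg.n_plasmids
        for g, w in zip(got.as_tuple(), truth.as_tuple()):
            se = math.sqrt(w * (1 - w) / n)
            assert abs(g - w) < 4 * se

    def test_multi_dsb_diagnostic_counted(self):
        cfg = SimulationConfig(0.0, 0.5, decays_per_plasmid=6.0,
                               n_plasmids=2000, seed=5)
        c = simulate_conformations(cfg)
        assert 0 < c.n_multi_dsb <= c.n_l

    def test_seeded_determinism(self):
        cfg = SimulationConfig(0.28, 0.047, n_plasmids=10000, seed=7)
        assert simulate_conformations(cfg) == simulate_conformations(cfg)


class TestSampleObservedFractions:
    def test_large_n_converges(self):
        f = FractionTriple(0.13, 0.64, 0.23)
        g = sample_observed_fractions(f, 10**6, rng=0)
        for got, want in zip(g.as_tuple(), f.as_tuple()):
            se = math.sqrt(want * (1 - want) / 10**6)
            assert abs(got - want) < 4 * se

    def test_degenerate_triple_fixed_point(self):
        f = FractionTriple(1.0, 0.0, 0.0)
        assert sample_observed_fractions(f, 17, rng=1).as_tuple() == (1.0, 0.0, 0.0)

    def test_mean_over_seeds_unbiased(self):
        f = FractionTriple(0.13, 0.64, 0.23)
        n = 300
        draws = np.array(
            [sample_observed_fractions(f, n, rng=s).as_tuple() for s in range(1000)]
        )
        se = np.sqrt(np.array(f.as_tuple()) * (1 - np.array(f.as_tuple())) / (n * 1000))
        assert np.all(np.abs(draws.mean(axis=0) - f.as_tuple()) < 3 * se)


class TestActivitySeries:
    def test_five_step_series_monotone_sc(self, setup):
        df = activity_series([3, 6, 9, 12, 15], setup, y_ssb=0.28, y_dsb=0.047)
        assert len(df) == 5
        assert df["F_SC"].is_monotonic_decreasing
        assert df["F_SC"].nunique() == 5

    def test_zero_yields_keep_sc_at_one(self, setup):
        df = activity_series([3, 6, 9, 12, 15], setup, y_ssb=0.0, y_dsb=0.0)
        assert (df["F_SC"] == 1.0).all()

    def test_break_means_linear_in_activity(self, setup):
        """d at 3 MBq is one fifth of d at 15 MBq, so X scales 1:5."""
        df = activity_series([3, 15], setup, y_ssb=0.1, y_dsb=0.01)
        d3, d15 = df["decays_per_plasmid"]
        assert d15 == pytest.approx(5 * d3, rel=1e-12)


class TestRenderLane:
    def test_band_areas_proportional_to_fractions(self):
        from plasmidbreaks import GelRenderConfig, integrate_bands

        f = FractionTriple(0.13, 0.64, 0.23)
        g = GelRenderConfig(baseline=0.0, noise_sd=0.0)
        lane = render_lane(f, g, rng=0)
        areas = integrate_bands(lane, g.band_windows())
        total = sum(areas.values())
        for conf, want in (("SC", 0.13), ("OC", 0.64), ("L", 0.23)):
            assert areas[conf] / total == pytest.approx(want, rel=0.01)

    def test_no_linear_band_when_fraction_zero(self):
        from plasmidbreaks import GelRenderConfig, integrate_bands

        f = FractionTriple(0.5, 0.5, 0.0)
        g = GelRenderConfig(baseline=0.0, noise_sd=0.0)
        areas = integrate_bands(render_lane(f, g, rng=0), g.band_windows())
        # only far Gaussian tails of the OC/SC bands leak into the L window
        assert areas["L"] / sum(areas.values()) < 1e-6

    def test_same_seed_identical_profiles(self):
        f = FractionTriple(0.2, 0.5, 0.3)
        a = render_lane(f, rng=42)
        b = render_lane(f, rng=42)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_overlapping_bands_rejected(self):
        from plasmidbreaks import GelRenderConfig

        with pytest.raises(ValueError, match="overlap"):
            GelRenderConfig(centers={"OC": 30.0, "L": 32.0, "SC": 80.0})


class TestSimulateReplicates:
    def test_replicate_streams_differ_but_rerun_identically(self):
        cfg = SimulationConfig(0.28, 0.047, n_plasmids=5000, n_replicates=3, seed=11)
        a = simulate_replicates(cfg)
        b = simulate_replicates(cfg)
        pd.testing.assert_frame_equal(a, b)
        assert a["F_SC"].nunique() == 3  # replicates are independent draws

    def test_parameter_recovery_over_seeds(self):
        """Inversion recovers the SSB yield within 5% and the DSB yield within
        5% of its known first-order target across 20 seeded studies."""
        from plasmidbreaks import PlasmidBreakModel

        d = 6.37
        y_ssb_true, y_dsb_true = 0.279, 0.041
        dsb_target = math.expm1(y_dsb_true * d) / d  # first-order estimator's limit
        for seed in range(20):
            cfg = SimulationConfig(
                y_ssb_true, y_dsb_true, decays_per_plasmid=d,
                n_plasmids=10**5, n_replicates=3, seed=seed,
            )
            res = PlasmidBreakModel.from_simulation(cfg).fit()
            row = res.table.iloc[0]
            assert row["Y_SSB_mean"] == pytest.approx(y_ssb_true, rel=0.05)
            assert row["Y_DSB_mean"] == pytest.approx(dsb_target, rel=0.05)


class TestFixtureTables:
    def test_compound_table_reference_rows(self):
        df = compound_fractions().set_index(["compound", "dmso"])
        tco4 = df.loc[("TcO4-", False)]
        assert (tco4["oc_pct"], tco4["l_pct"]) == (89.0, 10.0)
        iii = df.loc[("III", True)]
        assert iii["oc_pct"] == 4.0 and iii["censored_L"]
        ia = df.loc[("Ia", False)]
        assert ia["censored_SC"]  # OC 84 + L 16 leave no supercoiled band

    def test_scavenger_table_reference_row(self):
        df = scavenger_fractions().set_index(["compound", "activity_MBq"])
        row = df.loc[("TcO4- + DMSO", 3.0)]
        assert row["oc_pct"] == 3.0 and row["censored_L"]

    def test_fraction_columns_sum_to_one(self):
        for df in (compound_fractions(), scavenger_fractions()):
            total = df["F_SC"] + df["F_OC"] + df["F_L"]
            assert np.allclose(total, 1.0)
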