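"""Cytometry statistics: hand-computed oracles, partitions, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spermflow.config import Thresholds
from spermflow.cytometry import (
    EmptyGateError,
    Gate,
    cma3_statistics,
    default_gate,
    gate_events,
    gate_fractions,
    mbbr_statistics,
    median_fluorescence,
    oxodg_statistics,
    physiology_statistics,
    reference_bounds,
    scsa_statistics,
)
from spermflow.synthdata import (
    Cma3Truth,
    OxoDgTruth,
    Phys1Truth,
    Phys2Truth,
    simulate_cma3_events,
    simulate_phys1_events,
    simulate_phys2_events,
)
from spermflow.tables import EventTable


def make_events(assay="SCSA", channel_max=1023.0, **channels) -> EventTable:
    return EventTable(
        sample_id="s", assay=assay, data=pd.DataFrame(channels),
        channel_max=channel_max,
    )


class TestGating:
    def test_no_debris_passes_everything_through(self):
        ev = make_events(green=[500.0, 400.0], red=[200.0, 150.0])
        gated, report = gate_events(ev, Gate(("green", "red"), 100.0), min_events=1)
        assert report.n_debris == 0
        assert gated.n_events == 2
        pd.testing.assert_frame_equal(gated.data, ev.data)

    def test_accounting_is_exact(self):
        ev = make_events(green=[500.0, 50.0, 20.0], red=[200.0, 60.0, 600.0])
        gated, report = gate_events(ev, Gate(("green", "red"), 100.0), min_events=1)
        assert report.n_total == report.n_debris + report.n_sperm
        assert gated.n_events == report.n_sperm == 2  # AO double-negative out

    def test_empty_gate_raises(self):
        ev = make_events(green=[10.0], red=[20.0])
        with pytest.raises(EmptyGateError):
            gate_events(ev, Gate(("green", "red"), 100.0), min_events=1)

    def test_unknown_channel_is_an_error(self):
        ev = make_events(green=[500.0], red=[100.0])
        with pytest.raises(ValueError, match="fitc"):
            gate_events(ev, Gate(("fitc",), 100.0), min_events=1)

    def test_low_count_flagged_not_dropped(self):
        ev = make_events(green=[500.0] * 10, red=[100.0] * 10)
        with pytest.warns(UserWarning, match="gated events"):
            gated, report = gate_events(
                ev, Gate(("green",), 100.0), min_events=5000
            )
        assert gated.n_events == 10
        assert report.warnings

    def test_synthetic_debris_fraction_recovered(self, scsa_sample, thresholds):
        _, report = gate_events(
            scsa_sample, default_gate("SCSA", thresholds), min_events=1
        )
        p_true = scsa_sample.truth["debris"] / 100.0
        se = np.sqrt(p_true * (1 - p_true) / report.n_total)
        assert abs(report.n_debris / report.n_total - p_true) < 3 * se

    def test_unknown_assay_has_no_default_gate(self):
        with pytest.raises(ValueError):
            default_gate("SPECTRAL")


class TestScsaStatistics:
    def test_boundary_dfi_not_counted(self):
        # red=1, green=3 -> DFI exactly 250; the threshold is strict
        ev = make_events(green=[3.0], red=[1.0])
        res = scsa_statistics(ev, hds_threshold=665.0)
        assert res.pct_dfi == 0.0

    def test_ten_event_hand_oracle(self):
        """Nine (green=180, red=20) plus one (green=50, red=150): DFIs are
        nine 100s and one 750, so %DFI = 10 and sample SD = 205.548..."""
        green = [180.0] * 9 + [50.0]
        red = [20.0] * 9 + [150.0]
        ev = make_events(green=green, red=red)
        res = scsa_statistics(ev, hds_threshold=665.0)
        dfis = np.array([100.0] * 9 + [750.0])
        assert res.pct_dfi == pytest.approx(10.0)
        assert res.sd_dfi == pytest.approx(np.std(dfis, ddof=1))
        assert res.sd_dfi == pytest.approx(205.548, abs=1e-3)
        assert res.pct_hds == 0.0

    def test_hds_counts_cells_above_channel_cut(self, thresholds):
        assert thresholds.hds_cut == pytest.approx(0.65 * 1023)
        ev = make_events(green=[700.0, 600.0], red=[50.0, 50.0])
        res = scsa_statistics(ev, hds_threshold=thresholds.hds_cut)
        assert res.pct_hds == pytest.approx(50.0)

    def test_zero_total_fluorescence_is_an_error(self):
        ev = make_events(green=[0.0], red=[0.0])
        with pytest.raises(ValueError, match="debris"):
            scsa_statistics(ev, hds_threshold=665.0)

    def test_dfi_scale_invariance_and_monotonicity(self):
        ev1 = make_events(green=[300.0], red=[100.0])
        ev2 = make_events(green=[600.0], red=[200.0])
        r1 = scsa_statistics(ev1, hds_threshold=1e9)
        r2 = scsa_statistics(ev2, hds_threshold=1e9)
        assert r1.pct_dfi == r2.pct_dfi  # joint rescale leaves DFI unchanged
        # increasing red with green fixed never decreases DFI
        lo = scsa_statistics(make_events(green=[300.0], red=[100.0]), 1e9)
        hi = scsa_statistics(make_events(green=[300.0], red=[200.0]), 1e9)
        assert hi.pct_dfi >= lo.pct_dfi


class TestMedianFluorescence:
    def test_reference_normalisation(self):
        ev = make_events(x=[400.0, 500.0, 600.0])
        assert median_fluorescence(ev, "x", 500.0) == pytest.approx(1.0)

    def test_odd_count_median(self):
        ev = make_events(x=[1.0, 2.0, 9.0])
        assert median_fluorescence(ev, "x", 1.0) == pytest.approx(2.0)

    def test_nonpositive_reference_rejected(self):
        ev = make_events(x=[1.0])
        with pytest.raises(ValueError):
            median_fluorescence(ev, "x", 0.0)

    @given(scale=st.floats(min_value=0.01, max_value=50.0))
    def test_scale_equivariance(self, scale):
        """Scaling all channel values and the reference together leaves the
        normalised statistic unchanged."""
        base = np.array([100.0, 150.0, 320.0, 80.0, 210.0])
        ev = make_events(x=base, channel_max=1e9)
        ev_s = make_events(x=base * scale, channel_max=1e9)
        a = median_fluorescence(ev, "x", 150.0)
        b = median_fluorescence(ev_s, "x", 150.0 * scale)
        assert a == pytest.approx(b, rel=1e-9)


class TestGateFractions:
    def test_all_below_low_cut(self):
        ev = make_events(x=[10.0, 20.0])
        assert gate_fractions(ev, "x", (50.0, 100.0)) == (100.0, 0.0, 0.0)

    def test_partition_sums_to_100(self):
        rng = np.random.default_rng(0)
        ev = make_events(x=rng.uniform(0, 1000, 777))
        low, mod, high = gate_fractions(ev, "x", (110.0, 360.0))
        assert low + mod + high == pytest.approx(100.0)

    def test_inverted_bounds_rejected(self):
        ev = make_events(x=[1.0])
        with pytest.raises(ValueError):
            gate_fractions(ev, "x", (100.0, 50.0))

    def test_generator_truth_recovered(self, thresholds):
        truth = Cma3Truth(frac_low=0.10, frac_high=0.10)
        ev = simulate_cma3_events(truth, 5000, seed=21, thresholds=thresholds)
        gated, _ = gate_events(ev, default_gate("CMA3", thresholds), min_events=1)
        low, mod, high = gate_fractions(gated, "cma3", thresholds.cma3_bounds)
        rec = ev.truth
        n = gated.n_events
        for est, true_pct in ((low, rec["pct_low"]), (high, rec["pct_high"])):
            p = true_pct / 100
            se = 100 * np.sqrt(p * (1 - p) / n)
            assert abs(est - true_pct) < 3 * se

    def test_reference_bounds_are_percentiles(self):
        vals = np.arange(1.0, 101.0)
        lo, hi = reference_bounds(vals)
        assert lo == pytest.approx(np.percentile(vals, 5))
        assert hi == pytest.approx(np.percentile(vals, 95))


class TestMbbrStatistics:
    def test_equal_medians_give_zero_index(self):
        u = make_events(assay="MBBR", mbbr=[200.0, 210.0, 190.0])
        d = make_events(assay="MBBR_DTT", mbbr=[190.0, 200.0, 210.0])
        res = mbbr_statistics(u, d, bounds=(110.0, 360.0))
        assert res.disulfide_index == pytest.approx(0.0)
        assert not res.flags

    def test_normalised_index_arithmetic(self):
        # normalised medians 10 and 4 -> index 3
        u = make_events(assay="MBBR", mbbr=[400.0])
        d = make_events(assay="MBBR_DTT", mbbr=[1000.0])
        res = mbbr_statistics(u, d, reference_mfi=100.0, bounds=(110.0, 360.0))
        assert res.disulfide_index == pytest.approx(3.0)
        assert res.mfi_norm == pytest.approx(4.0)

    def test_negative_index_flagged(self):
        u = make_events(assay="MBBR", mbbr=[400.0])
        d = make_events(assay="MBBR_DTT", mbbr=[300.0])
        res = mbbr_statistics(u, d, bounds=(110.0, 360.0))
        assert res.disulfide_index < 0
        assert "negative_disulfide_index" in res.flags

    def test_mismatched_sample_ids_rejected(self):
        u = make_events(assay="MBBR", mbbr=[400.0])
        d = EventTable("other", "MBBR_DTT", pd.DataFrame({"mbbr": [300.0]}))
        with pytest.raises(ValueError, match="mismatched"):
            mbbr_statistics(u, d, bounds=(110.0, 360.0))

    def test_fraction_partition(self, mbbr_pair, thresholds):
        u, d = mbbr_pair
        gu, _ = gate_events(u, default_gate("MBBR", thresholds), min_events=1)
        gd, _ = gate_events(d, default_gate("MBBR_DTT", thresholds), min_events=1)
        res = mbbr_statistics(gu, gd, bounds=thresholds.mbbr_bounds)
        assert res.pct_low + res.pct_moderate + res.pct_high == pytest.approx(100.0)


class TestCma3AndOxoDg:
    def test_uniform_population_is_all_moderate(self):
        ev = make_events(assay="CMA3", cma3=[200.0, 250.0, 300.0])
        res = cma3_statistics(ev, bounds=(110.0, 360.0))
        assert (res.pct_low, res.pct_moderate, res.pct_high) == (0.0, 100.0, 0.0)

    def test_reference_equal_to_median_gives_unity(self):
        ev = make_events(assay="CMA3", cma3=[150.0, 200.0, 250.0])
        res = cma3_statistics(ev, reference_mfi=200.0, bounds=(110.0, 360.0))
        assert res.mfi_norm == pytest.approx(1.0)

    def test_oxodg_all_below_cut(self):
        ev = make_events(assay="OXODG", fitc=[50.0, 100.0])
        res = oxodg_statistics(ev, high_cut=220.0)
        assert res.pct_high == 0.0

    def test_oxodg_cut_at_median_splits_population(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(np.log(150), 0.3, 5001)
        ev = make_events(assay="OXODG", fitc=np.clip(x, 0, 1023))
        res = oxodg_statistics(ev, high_cut=float(np.median(x)))
        assert res.pct_high == pytest.approx(50.0, abs=0.1)

    def test_oxodg_day_shift_raises_mfi(self, thresholds):
        from spermflow.synthdata import simulate_oxodg_events

        lo = simulate_oxodg_events(
            OxoDgTruth(level=1.0), 4000, seed=5, thresholds=thresholds
        )
        hi = simulate_oxodg_events(
            OxoDgTruth(level=1.10), 4000, seed=6, thresholds=thresholds
        )
        glo, _ = gate_events(lo, default_gate("OXODG", thresholds), min_events=1)
        ghi, _ = gate_events(hi, default_gate("OXODG", thresholds), min_events=1)
        assert (
            oxodg_statistics(ghi, high_cut=thresholds.oxodg_high_cut).mfi_norm
            > oxodg_statistics(glo, high_cut=thresholds.oxodg_high_cut).mfi_norm
        )


class TestPhysiology:
    def make_panels(self, pi, yp, m540, pna, h258, mx, mtdr, cfda):
        p1 = make_events(assay="PHYS1", h342=[500.0] * len(pi),
                         pi=pi, yp=yp, m540=m540, pna=pna)
        p2 = make_events(assay="PHYS2", ssc=[400.0] * len(h258),
                         h258=h258, cfda=cfda, mx=mx, mtdr=mtdr)
        return p1, p2

    def test_all_viable(self):
        p1, p2 = self.make_panels(
            pi=[10.0, 10.0], yp=[10.0, 10.0], m540=[10.0, 10.0],
            pna=[10.0, 10.0], h258=[10.0, 10.0], mx=[10.0, 10.0],
            mtdr=[500.0, 500.0], cfda=[100.0, 120.0],
        )
        res = physiology_statistics(p1, p2)
        assert res.pct_viable == 100.0
        assert res.pct_active_mitochondria == 100.0
        assert res.cytoplasmic_ros_mfi == pytest.approx(110.0)

    def test_empty_denominator_flagged_not_fatal(self):
        # every cell apoptotic -> non-apoptotic denominators are empty
        p1, p2 = self.make_panels(
            pi=[10.0], yp=[500.0], m540=[10.0], pna=[10.0],
            h258=[500.0], mx=[10.0], mtdr=[10.0], cfda=[100.0],
        )
        res = physiology_statistics(p1, p2)
        assert np.isnan(res.pct_capacitated_of_nonapoptotic)
        assert any("empty_denominator" in f for f in res.flags)

    def test_generator_truth_recovered(self, thresholds):
        t1 = Phys1Truth(viable=0.90, capacitated_of_nonapoptotic=0.15)
        t2 = Phys2Truth()
        p1 = simulate_phys1_events(t1, 5000, seed=31, thresholds=thresholds)
        p2 = simulate_phys2_events(t2, 5000, seed=32, thresholds=thresholds)
        g1, _ = gate_events(p1, default_gate("PHYS1", thresholds), min_events=1)
        g2, _ = gate_events(p2, default_gate("PHYS2", thresholds), min_events=1)
        res = physiology_statistics(g1, g2, thresholds=thresholds)
        n = g1.n_events
        se_v = 100 * np.sqrt(0.9 * 0.1 / n)
        assert abs(res.pct_viable - 90.0) < 3 * se_v
        n_nonapo = int(
            np.sum(g1.data["yp"].to_numpy() <= thresholds.positivity_cut)
        )
        se_c = 100 * np.sqrt(0.15 * 0.85 / n_nonapo)
        assert abs(res.pct_capacitated_of_nonapoptotic - 15.0) < 3 * se_c
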