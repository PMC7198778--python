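"""Acetylene-inhibition partitioning: estimators, propagation, bootstrap."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from n2oflux.partition import (
    C2H2Triplet, PartitionError, aggregate_cell, bootstrap_infer,
    consumption_fraction, gross_rates, nitrate_buildup_fraction,
    nitrification_share, partition_rates_table, triplets_from_rates,
)


def _triplet(r0, r10, r10k, rep=1, fert="CT", temp=25, day=3):
    return C2H2Triplet(fert, temp, day, rep, r0=r0, r10=r10, r10k=r10k)


class TestGrossRates:
    @pytest.mark.parametrize(
        "r0, r10, r10k, exp_pro, exp_con",
        [
            (2.0, 3.0, 5.0, 4.0, 2.0),     # direct substitution
            (2.0, 3.0, 3.0, 2.0, 0.0),     # no inhibitable consumption
            (1.0, 5.0, 3.0, -1.0, -2.0),   # estimator may go negative
        ],
    )
    def test_arithmetic(self, r0, r10, r10k, exp_pro, exp_con):
        pro, con, net = gross_rates(_triplet(r0, r10, r10k))
        assert (pro, con, net) == (exp_pro, exp_con, r0)

    @given(
        r0=st.floats(-10, 50), r10=st.floats(-10, 50), r10k=st.floats(-10, 50)
    )
    def test_identity_production_minus_consumption_is_net(self, r0, r10, r10k):
        pro, con, net = gross_rates(_triplet(r0, r10, r10k))
        assert pro - con == pytest.approx(net, abs=1e-12)

    def test_incomplete_triplet_rejected(self):
        with pytest.raises(PartitionError):
            _triplet(1.0, float("nan"), 2.0)


class TestAggregateCell:
    def test_identical_triplets_have_zero_se(self):
        trips = [_triplet(2.0, 3.0, 5.0, rep=r) for r in range(1, 5)]
        for mode in ("paired", "propagated"):
            est = aggregate_cell(trips, mode=mode)
            assert est.se_consumption == pytest.approx(0.0)
            assert est.se_production == pytest.approx(0.0)

    def test_paired_mean_and_se(self):
        # per-replicate consumptions 1,2,3,4: mean 2.5, sd 1.291, SE 0.6455
        trips = [_triplet(1.0, 3.0, 3.0 + c, rep=i + 1)
                 for i, c in enumerate([1.0, 2.0, 3.0, 4.0])]
        est = aggregate_cell(trips, mode="paired")
        assert est.gross_consumption == pytest.approx(2.5)
        assert est.se_consumption == pytest.approx(1.2909944 / 2, rel=1e-6)

    def test_propagated_quadrature(self):
        # SE(r10k)=3, SE(r10)=4 -> SE(consumption)=5 (3-4-5 triangle)
        rng = np.random.default_rng(0)
        r10k = np.array([10.0, 10.0, 16.0, 16.0]) * 1.0  # sd 3.464, se 1.732
        # build rates with exact treatment-level SEs via direct construction
        r10 = np.array([0.0, 8.0, 0.0, 8.0])
        trips = [_triplet(1.0, r10[i], r10k[i], rep=i + 1) for i in range(4)]
        est = aggregate_cell(trips, mode="propagated")
        se10k = np.std(r10k, ddof=1) / 2
        se10 = np.std(r10, ddof=1) / 2
        assert est.se_consumption == pytest.approx(np.hypot(se10k, se10))
        del rng

    def test_cells_must_match(self):
        with pytest.raises(PartitionError):
            aggregate_cell([_triplet(1, 2, 3, temp=15), _triplet(1, 2, 3, temp=25)])
        with pytest.raises(PartitionError):
            aggregate_cell([])


class TestConsumptionFraction:
    def test_half(self):
        est = aggregate_cell([_triplet(2.0, 3.0, 5.0)])
        assert consumption_fraction(est) == pytest.approx(0.5)

    def test_zero_consumption(self):
        est = aggregate_cell([_triplet(2.0, 3.0, 3.0)])
        assert consumption_fraction(est) == 0.0

    def test_undefined_for_nonpositive_production(self):
        est = aggregate_cell([_triplet(1.0, 5.0, 3.0)])
        with pytest.raises(PartitionError):
            consumption_fraction(est)


class TestNitrificationShare:
    def test_full_overlap_is_zero_share(self):
        out = nitrification_share(4.0, 4.0)
        assert out["share_of_net"] == 0.0 and not out["censored_flag"]

    def test_quarter_share(self):
        out = nitrification_share(4.0, 3.0)
        assert out["nitrification_rate"] == pytest.approx(1.0)
        assert out["share_of_net"] == pytest.approx(0.25)

    def test_negative_raw_is_censored_and_flagged(self):
        out = nitrification_share(3.0, 4.0)
        assert out["nitrification_rate_raw"] == pytest.approx(-1.0)
        assert out["nitrification_rate"] == 0.0
        assert out["censored_flag"]


class TestNitrateBuildup:
    def test_no_ammonium_source(self):
        assert nitrate_buildup_fraction(0.0, 68.0) == 100.0

    def test_literature_style_values(self):
        # 13.05 ug/g initial ammonium against a 101 ug/g nitrate build-up
        assert nitrate_buildup_fraction(13.05, 101.0) == pytest.approx(87.08, abs=0.01)

    def test_full_attribution_floors_at_zero(self):
        assert nitrate_buildup_fraction(50.0, 50.0) == 0.0
        assert nitrate_buildup_fraction(80.0, 50.0) == 0.0

    def test_domain_errors(self):
        with pytest.raises(PartitionError):
            nitrate_buildup_fraction(1.0, 0.0)


def _rates_frame(cells):
    """cells: dict (fert, temp, day) -> list of (r0, r10, r10k) per replicate."""
    rows = []
    for (fert, temp, day), reps in cells.items():
        for i, (r0, r10, r10k) in enumerate(reps, start=1):
            for level, val in (("P0", r0), ("P10", r10), ("KP10", r10k)):
                rows.append({
                    "fertilization": fert, "temperature_C": temp, "day": day,
                    "replicate": i, "c2h2_level": level, "rate_ngN_g_d": val,
                })
    return pd.DataFrame(rows)


class TestBootstrapInfer:
    def _degenerate(self):
        return _rates_frame({
            ("CT", 15, 3): [(2.0, 3.0, 5.0)] * 4,
            ("CT", 25, 3): [(2.0, 3.0, 5.0)] * 4,
        })

    def test_degenerate_cells_zero_width_ci_p_one(self):
        res = bootstrap_infer(self._degenerate(), B=500, mc_sd=0.0, seed=0)
        assert (res.cells["ci_hi"] - res.cells["ci_lo"]).abs().max() == 0.0
        assert (res.pairwise["p"] == 1.0).all()

    def test_fixed_seed_reproducible(self):
        a = bootstrap_infer(self._degenerate(), B=500, mc_sd=0.3, seed=11)
        b = bootstrap_infer(self._degenerate(), B=500, mc_sd=0.3, seed=11)
        assert np.array_equal(a.draws, b.draws)
        pd.testing.assert_frame_equal(a.pairwise, b.pairwise)

    def test_identity_holds_in_every_draw(self):
        rng = np.random.default_rng(5)
        cells = {
            ("CT", t, 3): [tuple(rng.normal(5, 1, 3)) for _ in range(4)]
            for t in (15, 25, 35)
        }
        frame = _rates_frame(cells)
        pro = bootstrap_infer(frame, "gross_production", B=400, mc_sd=0.2, seed=3)
        con = bootstrap_infer(frame, "gross_consumption", B=400, mc_sd=0.2, seed=3)
        net = bootstrap_infer(frame, "net", B=400, mc_sd=0.2, seed=3)
        # same seed -> same resamples/noise -> the identity is exact draw-wise
        assert np.allclose(pro.draws - con.draws, net.draws, atol=1e-12)

    def test_small_B_rejected(self):
        with pytest.raises(PartitionError):
            bootstrap_infer(self._degenerate(), B=50)

    def test_single_replicate_without_noise_rejected(self):
        frame = _rates_frame({("CT", 15, 3): [(2.0, 3.0, 5.0)]})
        with pytest.raises(PartitionError):
            bootstrap_infer(frame, B=500, mc_sd=0.0)

    def test_ci_brackets_point_for_noisy_cells(self):
        rng = np.random.default_rng(2)
        cells = {("CT", t, 15): [tuple(rng.normal(6, 1, 3)) for _ in range(4)]
                 for t in (15, 25, 35)}
        res = bootstrap_infer(_rates_frame(cells), B=2000, mc_sd=0.1, seed=1)
        assert (res.cells["ci_lo"] <= res.cells["point"] + 1e-9).all()
        assert (res.cells["ci_hi"] >= res.cells["point"] - 1e-9).all()


class TestTripletsFromRates:
    def test_pivot_and_partition(self):
        frame = _rates_frame({("NPK", 25, 15): [(2.0, 1.5, 6.0)] * 3})
        trips = triplets_from_rates(frame)
        assert len(trips) == 3
        table = partition_rates_table(frame)
        assert table.loc[0, "gross_consumption_ngN_g_d"] == pytest.approx(4.5)
        assert table.loc[0, "gross_production_ngN_g_d"] == pytest.approx(6.5)

    def test_incomplete_triplet_rejected(self):
        frame = _rates_frame({("NPK", 25, 15): [(2.0, 1.5, 6.0)] * 3})
        with pytest.raises(PartitionError):
            triplets_from_rates(frame[frame["c2h2_level"] != "P10"])
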