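import math
import warnings

import numpy as np
import pytest

from sgt import (
    DeltaSGT,
    GrowthCurve,
    EstimationError,
    PlateMap,
    PlateMapEntry,
    ReplicateStats,
    SGTResult,
    UsageError,
    ValidationError,
    aggregate_replicates,
    compute_sgt,
    delta_delta_sgt,
    delta_sgt,
    estimate_doubling_time,
)


class TestComputeSGT:
    def test_linear_interpolation_between_bracketing_reads(self):
        curve = GrowthCurve("A1", [1.0, 2.0], [0.10, 0.20])
        r = compute_sgt(curve, threshold=0.15)
        assert r.sgt_hours == pytest.approx(1.5)
        assert r.interpolated and not r.censored

    def test_never_reaching_threshold_is_censored_at_last_time(self):
        curve = GrowthCurve("A1", np.arange(4) * 0.25, [0.05] * 4)
        r = compute_sgt(curve, threshold=0.15)
        assert r.censored
        assert r.sgt_hours == pytest.approx(0.75)

    def test_already_above_threshold_at_first_read(self):
        curve = GrowthCurve("A1", [0.0, 0.5, 1.0], [0.2, 0.3, 0.4])
        r = compute_sgt(curve, threshold=0.15)
        assert r.sgt_hours == 0.0
        assert not r.interpolated

    def test_matches_closed_form_on_noiseless_exponential(self, exp_curve, oracle_sgt):
        # oracle: sgt = td * log2(N_thr / N0), independent of the crossing code
        curve = exp_curve(n0=1e6, td=0.5)
        r = compute_sgt(curve, threshold=0.15)
        assert r.sgt_hours == pytest.approx(oracle_sgt(1e6, 0.5), abs=1e-3)
        assert r.sgt_hours == pytest.approx(4.114, abs=5e-3)

    def test_consecutive_reads_reject_an_isolated_spike(self):
        t = np.arange(8) * 0.25
        od = np.array([0.05, 0.05, 0.30, 0.05, 0.05, 0.16, 0.18, 0.20])
        spike_time = compute_sgt(GrowthCurve("A1", t, od), 0.15, consecutive=1)
        robust = compute_sgt(GrowthCurve("A1", t, od), 0.15, consecutive=2)
        assert spike_time.sgt_hours < 0.5
        assert robust.sgt_hours > 1.0  # crossing confirmed only at the real rise

    def test_run_clipped_by_series_end_counts_as_crossing(self):
        curve = GrowthCurve("A1", [0.0, 1.0], [0.10, 0.20])
        r = compute_sgt(curve, threshold=0.15, consecutive=3)
        assert not r.censored

    def test_smoothing_flag_suppresses_spike_with_consecutive_one(self):
        t = np.arange(8) * 0.25
        od = np.array([0.05, 0.05, 0.30, 0.05, 0.05, 0.16, 0.18, 0.20])
        r = compute_sgt(GrowthCurve("A1", t, od), 0.15, consecutive=1, smooth=True)
        assert r.sgt_hours > 1.0

    @pytest.mark.parametrize("threshold", [0.0, -0.15])
    def test_nonpositive_threshold_is_usage_error(self, threshold):
        curve = GrowthCurve("A1", [0.0, 1.0], [0.1, 0.2])
        with pytest.raises(UsageError):
            compute_sgt(curve, threshold=threshold)

    def test_monotone_in_inoculum(self, exp_curve):
        # more cells at start -> strictly earlier threshold crossing
        sgts = [
            compute_sgt(exp_curve(n0=n0), 0.15).sgt_hours
            for n0 in (1e4, 1e5, 1e6, 1e7)
        ]
        assert all(a > b for a, b in zip(sgts, sgts[1:]))


class TestAggregateReplicates:
    @staticmethod
    def pmap(wells, group=None):
        return PlateMap.from_entries(
            [PlateMapEntry(w, "s1", "treated", replicate_group=group) for w in wells]
        )

    def test_mean_sd_n(self):
        results = [SGTResult(w, v, 0.15) for w, v in
                   zip("ABC", (4.0, 4.2, 4.4))]
        pmap = self.pmap("ABC")
        (stats,) = aggregate_replicates(results, pmap).values()
        assert stats.mean == pytest.approx(4.2)
        assert stats.sd == pytest.approx(0.2)
        assert stats.n == 3

    def test_single_member_sd_is_missing_not_zero(self):
        (stats,) = aggregate_replicates(
            [SGTResult("A", 4.0, 0.15)], self.pmap("A")
        ).values()
        assert stats.n == 1
        assert math.isnan(stats.sd)

    def test_censored_member_excluded_with_warning(self):
        results = [SGTResult("A", 4.0, 0.15),
                   SGTResult("B", 12.0, 0.15, censored=True)]
        with pytest.warns(UserWarning, match="censored"):
            (stats,) = aggregate_replicates(results, self.pmap("AB")).values()
        assert stats.mean == pytest.approx(4.0)
        assert stats.n == 1 and stats.n_censored == 1

    def test_all_censored_group_reported_censored(self):
        results = [SGTResult(w, 12.0, 0.15, censored=True) for w in "AB"]
        (stats,) = aggregate_replicates(results, self.pmap("AB")).values()
        assert stats.censored and stats.n == 0

    def test_explicit_replicate_group_label_used(self):
        results = [SGTResult(w, 4.0, 0.15) for w in "AB"]
        out = aggregate_replicates(results, self.pmap("AB", group="g1"))
        assert set(out) == {"g1"}

    def test_unmapped_well_rejected(self):
        with pytest.raises(ValidationError, match="Z9"):
            aggregate_replicates([SGTResult("Z9", 4.0, 0.15)], self.pmap("A"))


class TestDeltaSGT:
    def test_difference_with_quadrature_sd(self):
        t = ReplicateStats("t", 10.0, 0.2, 3)
        n = ReplicateStats("n", 4.0, 0.1, 3)
        d = delta_sgt(t, n, "s1")
        assert d.value == pytest.approx(6.0)
        assert d.sd == pytest.approx(math.sqrt(0.2**2 + 0.1**2))

    def test_identical_means_give_zero(self):
        s = ReplicateStats("x", 5.0, 0.1, 3)
        assert delta_sgt(s, s, "s1").value == 0.0

    def test_censored_arm_flags_result(self):
        t = ReplicateStats("t", 12.0, float("nan"), 0, n_censored=3)
        n = ReplicateStats("n", 4.0, 0.1, 3)
        d = delta_sgt(t, n, "s1")
        assert d.censored and math.isnan(d.value)


class TestDeltaDeltaSGT:
    @staticmethod
    def dsgt(value, sd=0.1, sample="s"):
        return DeltaSGT(sample, value, sd, 3, 3)

    def test_zero_ddsgt_gives_fold_one(self):
        r = delta_delta_sgt(self.dsgt(3.0), self.dsgt(3.0, sample="cal"))
        assert r.fold == 1.0 and r.log2_fold == 0.0

    def test_paper_mode_exponentiates_hours_directly(self):
        r = delta_delta_sgt(self.dsgt(7.0), self.dsgt(4.0, sample="cal"))
        assert r.ddsgt == pytest.approx(3.0)
        assert r.fold == pytest.approx(0.125)
        assert r.log2_fold == pytest.approx(-3.0)

    def test_doublings_mode_divides_by_doubling_time(self):
        r = delta_delta_sgt(
            self.dsgt(3.0), self.dsgt(4.0, sample="cal"),
            mode="doublings", doubling_time_hours=0.5,
        )
        assert r.ddsgt == pytest.approx(-2.0)
        assert r.fold == pytest.approx(4.0)

    def test_doublings_mode_requires_doubling_time(self):
        with pytest.raises(UsageError, match="doubling_time"):
            delta_delta_sgt(self.dsgt(3.0), self.dsgt(4.0), mode="doublings")

    def test_antisymmetry_inverts_fold(self):
        a, b = self.dsgt(6.2, sample="a"), self.dsgt(4.1, sample="b")
        fwd = delta_delta_sgt(a, b)
        rev = delta_delta_sgt(b, a)
        assert fwd.ddsgt == pytest.approx(-rev.ddsgt)
        assert fwd.fold * rev.fold == pytest.approx(1.0)

    def test_censored_input_propagates_flag(self):
        censored = DeltaSGT("s", float("nan"), float("nan"), 0, 3, censored=True)
        r = delta_delta_sgt(censored, self.dsgt(4.0, sample="cal"))
        assert r.censored and math.isnan(r.fold)

    def test_sd_propagates_in_quadrature_and_scales_with_mode(self):
        a = self.dsgt(6.0, sd=0.3)
        b = self.dsgt(4.0, sd=0.4, sample="cal")
        hours = delta_delta_sgt(a, b)
        doublings = delta_delta_sgt(a, b, mode="doublings", doubling_time_hours=0.5)
        assert hours.sd == pytest.approx(0.5)
        assert doublings.sd == pytest.approx(1.0)
        assert hours.sd_fold == pytest.approx(hours.fold * math.log(2) * 0.5)


class TestEstimateDoublingTime:
    def test_recovers_known_doubling_time(self, exp_curve):
        td = estimate_doubling_time(exp_curve(n0=1e6, td=0.5))
        assert td == pytest.approx(0.5, abs=1e-6)

    def test_sampling_density_does_not_change_estimate(self, exp_curve):
        coarse = estimate_doubling_time(exp_curve(n0=1e6, td=0.7, dt=0.02))
        fine = estimate_doubling_time(exp_curve(n0=1e6, td=0.7, dt=0.01))
        assert coarse == pytest.approx(fine, rel=1e-9)

    def test_flat_curve_has_no_in_window_points(self):
        curve = GrowthCurve("A1", np.arange(5) * 0.25, [0.05] * 5)
        with pytest.raises(EstimationError, match="fewer than 3"):
            estimate_doubling_time(curve)
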