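"""Cut-point classification, daily accumulation and sedentary-bout lengths."""

import numpy as np
import pandas as pd
import pytest

from todacc.classification import (
    CUT_POINT_SETS,
    ActivityLevel,
    CutPointSet,
    classify_epoch,
    classify_series,
    daily_summaries,
    longest_sb_bout,
)
from todacc.ingest import CountsTimeSeries, reintegrate
from todacc.nonwear import NonwearInterval, apply_nonwear_mask

T0 = np.datetime64("2024-05-06T00:00:00", "s")


def epoch_series(y_per_second, epoch_len):
    y = np.asarray(y_per_second, dtype=int)
    ts = CountsTimeSeries("s1", T0, y, np.zeros_like(y), np.zeros_like(y))
    return reintegrate(ts, epoch_len)


def brute_label(value, cps):
    if value <= cps.sb_max:
        return "SB"
    elif value <= cps.lpa_max:
        return "LPA"
    else:
        return "MVPA"


class TestClassifyEpoch:
    @pytest.mark.parametrize(
        "set_name, count, expected",
        [
            ("trost_va", 25, "SB"),
            ("trost_va", 26, "LPA"),
            ("trost_va", 419, "LPA"),
            ("trost_va", 420, "MVPA"),
            ("costa_va", 5, "SB"),
            ("costa_va", 6, "LPA"),
            ("costa_va", 164, "LPA"),
            ("costa_va", 165, "MVPA"),
            ("costa_vm", 96, "SB"),
            ("costa_vm", 97, "LPA"),
            ("costa_vm", 361, "LPA"),
            ("costa_vm", 362, "MVPA"),
        ],
    )
    def test_published_boundaries(self, set_name, count, expected):
        assert classify_epoch(count, CUT_POINT_SETS[set_name]) == ActivityLevel(expected)

    @pytest.mark.parametrize("set_name", list(CUT_POINT_SETS))
    def test_zero_is_sedentary(self, set_name):
        assert classify_epoch(0, CUT_POINT_SETS[set_name]) is ActivityLevel.SB

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_epoch(-1, CUT_POINT_SETS["trost_va"])


class TestClassifySeries:
    def test_epoch_length_mismatch_is_configuration_error(self):
        ep5 = epoch_series(np.ones(60, dtype=int), 5)
        with pytest.raises(ValueError, match="15"):
            classify_series(ep5, CUT_POINT_SETS["trost_va"])

    def test_costa_va_boundary_fixture(self):
        # one count value per 5-s epoch, bracketing both thresholds
        per_epoch = [0, 5, 6, 100, 164, 165, 400, 5, 164, 165, 1, 1000]
        y = np.repeat(0, 5 * len(per_epoch)).copy()
        y[::5] = per_epoch  # first second of each epoch carries the sum
        ep = epoch_series(y, 5)
        labels = classify_series(ep, CUT_POINT_SETS["costa_va"])["label"].tolist()
        assert labels == [
            "SB", "SB", "LPA", "LPA", "LPA", "MVPA",
            "MVPA", "SB", "LPA", "MVPA", "SB", "MVPA",
        ]

    def test_agrees_with_per_epoch_comparator(self, rng):
        values = rng.integers(0, 1200, size=20000)
        for cps in CUT_POINT_SETS.values():
            y = np.zeros(len(values) * cps.epoch_len_s, dtype=int)
            y[:: cps.epoch_len_s] = values
            ep = epoch_series(y, cps.epoch_len_s)
            got = classify_series(ep, cps)["label"].tolist()
            want = [brute_label(v, cps) for v in ep.axis_values(cps.axis)]
            assert got == want

    def test_nonwear_epochs_unlabeled(self):
        ep = epoch_series(np.ones(60, dtype=int), 15)
        masked = apply_nonwear_mask(
            ep, [NonwearInterval(T0, T0 + np.timedelta64(30, "s"))]
        )
        out = classify_series(masked, CUT_POINT_SETS["trost_va"])
        assert out["label"].isna().tolist() == [True, True, False, False]

    def test_vm_axis_never_more_sb_than_va_at_equal_thresholds(self, rng):
        n = 5000
        ts = CountsTimeSeries(
            "s1", T0, rng.integers(0, 40, n), rng.integers(0, 40, n), rng.integers(0, 40, n)
        )
        ep = reintegrate(ts, 5)
        cps_va = CutPointSet("va", "VA", 5, 96, 361)
        cps_vm = CutPointSet("vm", "VM", 5, 96, 361)
        sb_va = (classify_series(ep, cps_va)["label"] == "SB").sum()
        sb_vm = (classify_series(ep, cps_vm)["label"] == "SB").sum()
        assert sb_vm <= sb_va

    def test_threshold_monotonicity(self, rng):
        values = rng.integers(0, 600, size=3000)
        y = np.zeros(len(values) * 5, dtype=int)
        y[::5] = values
        ep = epoch_series(y, 5)
        sb = []
        for sb_max in (5, 50, 96, 200):
            cps = CutPointSet("c", "VA", 5, sb_max, 361)
            sb.append((classify_series(ep, cps)["label"] == "SB").sum())
        assert sb == sorted(sb)


class TestDailySummaries:
    def test_all_sb_day(self):
        y = np.ones(2400 * 15, dtype=int)  # 2400 epochs of y_sum 15 <= 25
        labeled = classify_series(epoch_series(y, 15), CUT_POINT_SETS["trost_va"])
        (day,) = daily_summaries(labeled, "s1", 15).to_dict("records")
        assert day["sb_min"] == 600.0
        assert day["weartime_min"] == 600.0
        assert day["tpa_min"] == 0.0

    def test_empty_input(self):
        assert daily_summaries(pd.DataFrame(), "s1", 15).empty

    def test_partition_and_mixed_fixture(self):
        # 40 SB epochs, 20 LPA epochs, 12 MVPA epochs at 15 s
        per_epoch = [10] * 40 + [100] * 20 + [500] * 12
        y = np.zeros(len(per_epoch) * 15, dtype=int)
        y[::15] = per_epoch
        labeled = classify_series(epoch_series(y, 15), CUT_POINT_SETS["trost_va"])
        (day,) = daily_summaries(labeled, "s1", 15).to_dict("records")
        assert day["sb_min"] == 40 * 15 / 60
        assert day["lpa_min"] == 20 * 15 / 60
        assert day["mvpa_min"] == 12 * 15 / 60
        assert day["weartime_min"] == day["sb_min"] + day["lpa_min"] + day["mvpa_min"]
        assert day["tpa_min"] == day["lpa_min"] + day["mvpa_min"]


class TestLongestSbBout:
    def labeled(self, per_epoch, wear=None):
        y = np.zeros(len(per_epoch) * 15, dtype=int)
        y[::15] = per_epoch
        ep = epoch_series(y, 15)
        if wear is not None:
            ep.wear = np.asarray(wear, dtype=bool)
        return classify_series(ep, CUT_POINT_SETS["trost_va"])

    def test_no_sb(self):
        assert longest_sb_bout(self.labeled([100, 100, 500]), 15) == 0.0

    def test_240_epochs_is_60_minutes(self):
        assert longest_sb_bout(self.labeled([0] * 240), 15) == 60.0

    def test_interrupted_at_midpoint(self):
        per_epoch = [0] * 120 + [100] + [0] * 120
        assert longest_sb_bout(self.labeled(per_epoch), 15) == 30.0

    def test_broken_by_nonwear(self):
        per_epoch = [0] * 8
        wear = [True] * 4 + [False] + [True] * 3
        assert longest_sb_bout(self.labeled(per_epoch, wear), 15) == 1.0
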