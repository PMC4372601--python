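import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirsig import (
    ArrayScan,
    ExpressionMatrix,
    NormalizationConfig,
    call_presence,
    global_normalize,
    heatmap_filter,
    normalize_scan,
    subtract_background,
    trimmed_blank_stats,
)
from mirsig.errors import (
    AbsentSpotError,
    EmptyProfileError,
    InsufficientBlanksError,
    ValidationError,
)
from oracles import oracle_normalize_scan, oracle_trimmed_stats


class TestTrimmedBlankStats:
    def test_constant_blanks(self):
        stats = trimmed_blank_stats([10.0] * 20)
        assert stats.trimmed_mean == 10.0
        assert stats.trimmed_sd == 0.0
        assert stats.detection_threshold == 10.0
        assert stats.n_blanks_used == 18

    def test_integers_one_to_twenty(self):
        # floor(0.05*20)=1 per tail: stats over {2..19}
        stats = trimmed_blank_stats(list(range(1, 21)))
        assert stats.trimmed_mean == pytest.approx(10.5)
        assert stats.trimmed_sd == pytest.approx(math.sqrt(28.5))
        assert stats.detection_threshold == pytest.approx(
            10.5 + 2 * math.sqrt(28.5))
        assert stats.n_blanks_used == 18

    def test_no_trimming_below_twenty_blanks(self):
        stats = trimmed_blank_stats(list(range(1, 20)))
        assert stats.n_blanks_used == 19

    def test_matches_oracle_on_lognormal_draws(self):
        rng = np.random.default_rng(42)
        blanks = rng.lognormal(2.0, 0.5, 200)
        stats = trimmed_blank_stats(blanks)
        mean, sd, threshold = oracle_trimmed_stats(blanks)
        assert stats.trimmed_mean == pytest.approx(mean)
        assert stats.trimmed_sd == pytest.approx(sd)
        assert stats.detection_threshold == pytest.approx(threshold)

    def test_too_few_retained_blanks(self):
        with pytest.raises(InsufficientBlanksError):
            trimmed_blank_stats([1.0, 2.0])

    def test_negative_blank_rejected(self):
        with pytest.raises(ValidationError):
            trimmed_blank_stats([1.0, -2.0, 3.0])


class TestPresenceCall:
    def test_boundary_is_strict(self):
        stats = trimmed_blank_stats([8.0, 10.0, 12.0])  # mean 10, sd 2
        assert stats.detection_threshold == pytest.approx(14.0)
        assert not call_presence(14.0, stats)
        assert call_presence(14.000001, stats)
        assert not call_presence(0.0, stats)

    @given(x=st.floats(0, 1e6), y=st.floats(0, 1e6))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_intensity(self, x, y):
        stats = trimmed_blank_stats([8.0, 10.0, 12.0])
        lo, hi = min(x, y), max(x, y)
        if call_presence(lo, stats):
            assert call_presence(hi, stats)


class TestBackgroundSubtraction:
    def test_simple_subtraction(self):
        stats = trimmed_blank_stats([10.0] * 10)
        assert subtract_background(100.0, stats) == pytest.approx(90.0)

    def test_just_above_threshold(self):
        stats = trimmed_blank_stats([8.0, 10.0, 12.0])  # mean 10, sd 2
        assert subtract_background(14.5, stats) == pytest.approx(4.5)

    def test_present_spot_positive_output(self):
        stats = trimmed_blank_stats([8.0, 10.0, 12.0])
        assert subtract_background(stats.detection_threshold + 1e-9, stats) > 0

    def test_absent_spot_rejected(self):
        stats = trimmed_blank_stats([8.0, 10.0, 12.0])
        with pytest.raises(AbsentSpotError):
            subtract_background(10.0, stats)


class TestGlobalNormalize:
    def test_hand_example(self):
        prof = global_normalize({"a": 10.0, "b": 20.0, "c": 30.0}, 25.0)
        assert prof.values.to_dict() == pytest.approx(
            {"a": 12.5, "b": 25.0, "c": 37.5})
        assert prof.scale_factor == pytest.approx(1.25)

    def test_constant_profile_maps_to_target(self):
        prof = global_normalize({f"m{i}": 7.5 for i in range(9)}, 25.0)
        assert set(np.round(prof.values, 12)) == {25.0}

    def test_empty_profile_rejected(self):
        with pytest.raises(EmptyProfileError):
            global_normalize({}, 25.0)

    @given(st.lists(st.floats(0.01, 1e5), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_median_always_hits_target(self, values):
        prof = global_normalize({f"m{i}": v for i, v in enumerate(values)})
        med = float(np.median(prof.values))
        assert med == pytest.approx(25.0, rel=1e-9)


def build_scan(blanks, ids, intensities, sample_id="S"):
    n_b, n_p = len(blanks), len(ids)
    spots = pd.DataFrame({
        "probe_id": list(ids) + [f"BLANK_{j}" for j in range(n_b)],
        "spot_class": ["probe"] * n_p + ["blank"] * n_b,
        "intensity": np.concatenate([np.asarray(intensities, float),
                                     np.asarray(blanks, float)]),
    })
    return ArrayScan(sample_id, spots)


class TestNormalizeScan:
    def test_all_probes_below_threshold(self):
        scan = build_scan([10.0, 11.0, 12.0], ["a", "b"], [5.0, 9.0])
        with pytest.raises(EmptyProfileError):
            normalize_scan(scan)

    def test_matches_composed_oracle(self):
        rng = np.random.default_rng(11)
        blanks = rng.lognormal(np.log(10), 0.3, 25)
        ids = [f"m{i}" for i in range(10)]
        inten = rng.lognormal(np.log(30), 1.0, 10)
        scan = build_scan(blanks, ids, inten)
        prof = normalize_scan(scan)
        expected_values, expected_present = oracle_normalize_scan(
            blanks, ids, inten)
        for pid in ids:
            assert prof.present[pid] == expected_present[pid]
            assert prof.values[pid] == pytest.approx(expected_values[pid])

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=40, deadline=None)
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(3)
        blanks = rng.lognormal(np.log(10), 0.2, 20)
        ids = [f"m{i}" for i in range(8)]
        inten = rng.lognormal(np.log(60), 0.8, 8)
        base = normalize_scan(build_scan(blanks, ids, inten))
        scaled = normalize_scan(build_scan(blanks * c, ids, inten * c))
        assert np.allclose(base.values, scaled.values, rtol=1e-9)
        assert (base.present == scaled.present).all()

    def test_absent_policy_missing(self):
        scan = build_scan([10.0] * 5, ["lo", "hi"], [5.0, 100.0])
        prof = normalize_scan(
            scan, NormalizationConfig(absent_policy="set_missing"))
        assert np.isnan(prof.values["lo"])
        assert prof.values["hi"] == pytest.approx(25.0)


class TestHeatmapFilter:
    def make(self, c_vals, fm_vals):
        values = pd.DataFrame({"C1": c_vals, "FM1": fm_vals})
        return ExpressionMatrix(values, {"C1": "control", "FM1": "FM"})

    def test_either_group_mean_qualifies(self):
        m = self.make({"a": 6.0}, {"a": 0.0})
        assert heatmap_filter(m).mirna_ids == ["a"]

    def test_boundary_is_strict(self):
        m = self.make({"a": 5.0, "b": 5.01}, {"a": 5.0, "b": 0.0})
        assert heatmap_filter(m).mirna_ids == ["b"]

    def test_all_zero_dropped(self):
        m = self.make({"a": 0.0, "b": 99.0}, {"a": 0.0, "b": 99.0})
        assert heatmap_filter(m).mirna_ids == ["b"]

    def test_subset_and_idempotent(self, default_matrix):
        once = heatmap_filter(default_matrix)
        twice = heatmap_filter(once)
        assert set(once.mirna_ids) <= set(default_matrix.mirna_ids)
        assert once.mirna_ids == twice.mirna_ids
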