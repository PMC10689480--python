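"""Data hygiene and standardization rules, checked against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rangesqueeze import preprocessing as pp
from rangesqueeze.preprocessing import (
    MountainGradient,
    PipelineState,
    StandardizationConfig,
)

from conftest import make_records


def recs(*rows, state=PipelineState.FILTERED):
    out = make_records(
        [(f"sp{i}", "M0", lo, hi) for i, (lo, hi) in enumerate(rows)], state=state
    )
    return out


class TestRangeSize:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(1200.0, 3400.0, 2200.0), (900.0, 900.0, 0.0), (0.0, 6500.0, 6500.0)],
    )
    def test_range_is_max_minus_min(self, lo, hi, expected):
        assert pp.compute_range_size({"min_elev": lo, "max_elev": hi}) == expected

    def test_inverted_record_rejected(self):
        with pytest.raises(ValueError):
            pp.compute_range_size({"min_elev": 2500.0, "max_elev": 1800.0})


class TestValidateRecords:
    def test_rejection_reasons(self):
        df = make_records(
            [
                ("a", "M0", 2500.0, 1800.0),  # inverted
                ("b", "M0", 100.0, 6700.0),  # above ceiling
                ("c", "M0", np.nan, 500.0),  # non-finite
                ("d", "M0", 100.0, 900.0),  # fine
            ]
        )
        kept, log = pp.validate_records(df)
        assert list(kept["species_id"]) == ["d"]
        reasons = dict(zip(log["species_id"], log["reason"]))
        assert reasons == {"a": "min_gt_max", "b": "above_6500", "c": "non_finite"}

    def test_all_valid_is_identity(self):
        df = make_records([("a", "M0", 0.0, 1000.0), ("b", "M0", 50.0, 50.0)])
        kept, log = pp.validate_records(df)
        assert len(log) == 0
        pd.testing.assert_frame_equal(kept[df.columns], df)


class TestSingletonFraction:
    @pytest.mark.parametrize(
        "n_single,n_total,expected", [(25, 100, 0.25), (0, 10, 0.0), (5, 5, 1.0)]
    )
    def test_fraction(self, n_single, n_total, expected):
        rows = [(100.0, 100.0)] * n_single + [(0.0, 500.0)] * (n_total - n_single)
        assert pp.singleton_fraction(recs(*rows)) == pytest.approx(expected)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            pp.singleton_fraction(recs())


class TestSamplingGaps:
    def test_gap_above_threshold_detected(self):
        gaps = pp.detect_sampling_gaps(recs((0, 1000), (1600, 3000)))
        assert gaps == [(1000.0, 1600.0)]

    def test_gap_at_or_below_threshold_ignored(self):
        assert pp.detect_sampling_gaps(recs((0, 1000), (1400, 3000))) == []
        assert pp.detect_sampling_gaps(recs((0, 1000), (1500, 3000))) == []

    def test_single_range_continuous(self):
        assert pp.detect_sampling_gaps(recs((0, 3000))) == []

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 5000, allow_nan=False), st.floats(0, 2000, allow_nan=False)
            ),
            min_size=1,
            max_size=12,
        ),
        st.floats(50, 800),
    )
    def test_matches_transitive_merge_oracle(self, spans, threshold):
        """Gap detection equals a quadratic transitive interval merge."""
        rows = [(lo, lo + w) for lo, w in spans]
        got = pp.detect_sampling_gaps(recs(*rows), gap_threshold=threshold)
        # oracle: repeatedly merge any two overlapping intervals until stable
        sections = [list(r) for r in rows]
        changed = True
        while changed:
            changed = False
            for i in range(len(sections)):
                for j in range(i + 1, len(sections)):
                    a, b = sections[i], sections[j]
                    if a[0] <= b[1] and b[0] <= a[1]:
                        sections[i] = [min(a[0], b[0]), max(a[1], b[1])]
                        del sections[j]
                        changed = True
                        break
                if changed:
                    break
        sections.sort()
        expected = [
            (a[1], b[0])
            for a, b in zip(sections[:-1], sections[1:])
            if b[0] - a[1] > threshold
        ]
        assert got == expected


class TestFilterMountains:
    def _two_mountains(self, frac_a):
        rows = []
        n = 50
        n_single = int(round(frac_a * n))
        for i in range(n):
            lo = 100.0 * (i % 30)
            hi = lo if i < n_single else lo + 400.0
            rows.append((f"a{i}", "MA", lo, hi))
        for i in range(n):
            lo = 100.0 * (i % 30)
            rows.append((f"b{i}", "MB", lo, lo + 400.0))
        df = make_records(rows, state=PipelineState.VALIDATED)
        return df

    def test_over_25pct_singletons_excluded(self):
        kept, log = pp.filter_mountains(self._two_mountains(0.26))
        assert set(kept["mountain_id"]) == {"MB"}
        assert log.iloc[0]["reason"] == "singleton_fraction"

    def test_exactly_25pct_singletons_kept(self):
        kept, log = pp.filter_mountains(self._two_mountains(0.25))
        assert set(kept["mountain_id"]) == {"MA", "MB"}

    def test_gap_excludes_regardless_of_singletons(self):
        rows = [(f"a{i}", "MA", 0.0, 1000.0) for i in range(10)]
        rows += [(f"a{i+10}", "MA", 1700.0, 3000.0) for i in range(10)]
        df = make_records(rows, state=PipelineState.VALIDATED)
        kept, log = pp.filter_mountains(df)
        assert len(kept) == 0
        assert "sampling_gap" in log.iloc[0]["reason"]


@pytest.fixture
def gradient():
    return MountainGradient("M0", "continental", 0.0, 5100.0)


class TestStandardizeGradient:
    def test_worked_example_top_anchor(self, gradient):
        """A 0-5100 m gradient standardized to 2000 m keeps 3100-5100 m."""
        cfg = StandardizationConfig(length=2000.0, exclusion_zone=0.0, anchor="top")
        out, (lo, hi) = pp.standardize_gradient(recs((3200, 4000)), gradient, cfg)
        assert (lo, hi) == (3100.0, 5100.0)

    def test_crossing_range_truncated(self, gradient):
        cfg = StandardizationConfig(length=2000.0, exclusion_zone=0.0)
        out, _ = pp.standardize_gradient(recs((2500, 3600)), gradient, cfg)
        assert (out.loc[0, "min_elev"], out.loc[0, "max_elev"]) == (3100.0, 3600.0)

    def test_outside_range_dropped(self, gradient):
        cfg = StandardizationConfig(length=2000.0, exclusion_zone=0.0)
        out, _ = pp.standardize_gradient(recs((1200, 2900)), gradient, cfg)
        assert len(out) == 0

    def test_bottom_anchor_mirrors(self, gradient):
        cfg = StandardizationConfig(length=2000.0, exclusion_zone=0.0, anchor="bottom")
        out, (lo, hi) = pp.standardize_gradient(recs((1500, 2500)), gradient, cfg)
        assert (lo, hi) == (0.0, 2000.0)
        assert (out.loc[0, "min_elev"], out.loc[0, "max_elev"]) == (1500.0, 2000.0)

    def test_short_gradient_raises(self):
        short = MountainGradient("M1", "island", 0.0, 1800.0)
        cfg = StandardizationConfig(length=2500.0, exclusion_zone=0.0)
        with pytest.raises(pp.GradientTooShortError):
            pp.standardize_gradient(recs((0, 1000)), short, cfg)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 5100), st.floats(0, 3000)),
            min_size=1,
            max_size=20,
        )
    )
    def test_idempotent_and_contained(self, spans):
        gradient = MountainGradient("M0", "continental", 0.0, 5100.0)
        cfg = StandardizationConfig(length=2500.0, exclusion_zone=0.0)
        df = recs(*[(lo, min(lo + w, 5100.0)) for lo, w in spans])
        once, dom = pp.standardize_gradient(df, gradient, cfg)
        assert dom[1] - dom[0] == cfg.length
        assert (once["min_elev"] >= dom[0]).all() and (once["max_elev"] <= dom[1]).all()
        assert len(once) <= len(df)
        once.attrs["pipeline_state"] = PipelineState.FILTERED
        twice, dom2 = pp.standardize_gradient(once, gradient, cfg)
        assert dom2 == dom
        pd.testing.assert_frame_equal(once, twice)


class TestExclusionZones:
    def kept_ids(self, rows, ez, lo=3100.0, hi=5100.0):
        df = recs(*rows, state=PipelineState.STANDARDIZED)
        out = pp.apply_exclusion_zones(df, lo, hi, ez)
        return set(out["species_id"])

    def test_species_inside_top_zone_dropped(self):
        assert self.kept_ids([(4900, 5050)], 250.0) == set()

    def test_species_crossing_zone_boundary_kept(self):
        assert self.kept_ids([(3200, 3500)], 250.0) == {"sp0"}

    def test_zero_exclusion_is_identity(self):
        df = recs((3200, 3400), (4900, 5050), state=PipelineState.STANDARDIZED)
        out = pp.apply_exclusion_zones(df, 3100.0, 5100.0, 0.0)
        pd.testing.assert_frame_equal(out[df.columns], df)

    def test_touching_inner_edge_kept(self):
        # bottom zone is [3100, 3350]; a range ending exactly at 3350 stays
        assert self.kept_ids([(3150, 3350)], 250.0) == {"sp0"}

    def test_zone_covering_domain_rejected(self):
        df = recs((3200, 3400), state=PipelineState.STANDARDIZED)
        with pytest.raises(ValueError):
            pp.apply_exclusion_zones(df, 3100.0, 5100.0, 1000.0)

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 2500), st.floats(0, 2500)), min_size=1, max_size=15
        ),
        st.sampled_from([0.0, 250.0, 500.0]),
    )
    def test_matches_containment_oracle(self, spans, ez):
        lo, hi = 0.0, 2500.0
        rows = [(a, min(a + w, hi)) for a, w in spans]
        got = self.kept_ids(rows, ez, lo, hi)
        expected = set()
        for i, (a, b) in enumerate(rows):
            in_bottom = a >= lo and b < lo + ez
            in_top = a > hi - ez and b <= hi
            if not (in_bottom or in_top):
                expected.add(f"sp{i}")
        assert got == expected


class TestTransform:
    def test_singleton_floor_is_ln10(self):
        out = pp.transform_range_sizes([0.0])
        assert out[0] == pytest.approx(np.log(10.0), abs=1e-12)

    def test_ten_meters_matches_singleton(self):
        a = pp.transform_range_sizes([0.0])[0]
        b = pp.transform_range_sizes([10.0])[0]
        assert a == b

    def test_log_of_positive_range(self):
        assert pp.transform_range_sizes([1000.0])[0] == pytest.approx(np.log(1000.0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pp.transform_range_sizes([-1.0])

    def test_output_always_finite(self, rng):
        sizes = rng.uniform(0, 6500, 1000)
        sizes[::7] = 0.0
        out = pp.transform_range_sizes(sizes)
        assert np.all(np.isfinite(out))


class TestStageOrdering:
    def test_stages_refuse_to_run_out_of_order(self, gradient):
        raw = make_records([("a", "M0", 100.0, 900.0)])
        cfg = StandardizationConfig(length=2500.0, exclusion_zone=0.0)
        with pytest.raises(RuntimeError):
            pp.filter_mountains(raw)
        with pytest.raises(RuntimeError):
            pp.standardize_gradient(raw, gradient, cfg)
        with pytest.raises(RuntimeError):
            pp.apply_exclusion_zones(raw, 0.0, 2500.0, 250.0)
        with pytest.raises(RuntimeError):
            pp.transform_records(raw)

    def test_full_chain_runs_in_order(self, gradient):
        raw = make_records(
            [(f"s{i}", "M0", 100.0 * i, 100.0 * i + 800.0) for i in range(40)]
        )
        v, _ = pp.validate_records(raw)
        f, _ = pp.filter_mountains(v)
        s, (lo, hi) = pp.standardize_gradient(
            f, gradient, StandardizationConfig(length=2500.0, exclusion_zone=250.0)
        )
        e = pp.apply_exclusion_zones(s, lo, hi, 250.0)
        t = pp.transform_records(e)
        assert "log_range" in t.columns
        assert len(t) <= len(raw)
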