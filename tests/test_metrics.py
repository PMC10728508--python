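"""Six CIN metrics: worked examples, naive-loop oracle, and invariants."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import cinscore as cs
from cinscore.metrics import METRIC_NAMES, MetricConfig

from conftest import make_segments

CFG = MetricConfig()  # t = d = 0.2, TAI over aberrant segments, inclusive lengths


def naive_metrics(df: pd.DataFrame, cfg: MetricConfig = CFG) -> dict:
    """Deliberately naive per-segment loop over one sample's sorted segments.

    Kept independent of the production implementation: plain Python loops,
    no vectorization, no shared helpers.
    """
    segs = [
        (str(r.chromosome), int(r.start_bp), int(r.end_bp), float(r.segment_mean))
        for r in df.itertuples()
    ]
    t, d = cfg.aberration_threshold, cfg.adjacency_difference
    length = lambda s: (s[2] - s[1] + 1) if cfg.length_convention == "inclusive" else s[2] - s[1]

    total = sum(length(s) for s in segs)
    ab = [abs(s[3]) >= t for s in segs]
    base = sum(length(s) for s, a in zip(segs, ab) if a)
    n_ab = sum(ab)

    if cfg.tai_aberrant_only:
        den = sum(length(s) for s, a in zip(segs, ab) if a)
        num = sum(length(s) * s[3] for s, a in zip(segs, ab) if a)
        tai = num / den if den > 0 else 0.0
    else:
        tai = sum(length(s) * s[3] for s in segs) / total
    mtai = sum(length(s) * abs(s[3]) for s in segs) / total

    cna = 0
    for i, (s, a) in enumerate(zip(segs, ab)):
        if not a:
            continue
        prev = segs[i - 1] if i > 0 and segs[i - 1][0] == s[0] else None
        nxt = segs[i + 1] if i + 1 < len(segs) and segs[i + 1][0] == s[0] else None
        if cfg.cna_neighbor_rule == "previous":
            if prev is not None and abs(s[3] - prev[3]) > d:
                cna += 1
        else:
            ok_prev = prev is None or abs(s[3] - prev[3]) > d
            ok_next = nxt is None or abs(s[3] - nxt[3]) > d
            if ok_prev and ok_next:
                cna += 1

    return {
        "tai": tai,
        "modified_tai": mtai,
        "cna": cna,
        "break_points": 2 * n_ab,
        "base_segments": base,
        "fga": base / total,
    }


class TestWorkedExamples:
    def test_signed_tai_cancels_opposite_arms(self, toy_segments):
        assert cs.tai(toy_segments) == pytest.approx(0.0)

    def test_modified_tai_keeps_magnitude(self, toy_segments):
        assert cs.modified_tai(toy_segments) == pytest.approx(0.5)

    def test_single_aberrant_segment_identity(self):
        seg = make_segments([("S1", "1", 1, 999, 0.5)])
        assert cs.tai(seg) == pytest.approx(0.5)
        assert cs.modified_tai(seg) == pytest.approx(0.5)

    def test_negative_single_segment_absolute(self):
        seg = make_segments([("S1", "1", 1, 100, -0.3)])
        assert cs.modified_tai(seg) == pytest.approx(0.3)

    def test_cna_isolated_middle_segment(self):
        seg = make_segments(
            [("S1", "1", 1, 100, 0.0), ("S1", "1", 101, 200, 0.5), ("S1", "1", 201, 300, 0.0)]
        )
        assert cs.cna(seg) == 1
        assert cs.cna(seg, MetricConfig(cna_neighbor_rule="both")) == 1

    def test_cna_flat_aberrant_run_not_counted(self):
        seg = make_segments([("S1", "1", 1, 100, 0.5), ("S1", "1", 101, 200, 0.5)])
        assert cs.cna(seg) == 0
        assert cs.cna(seg, MetricConfig(cna_neighbor_rule="both")) == 0

    def test_cna_neighbor_rules_differ_on_opposite_pair(self, toy_segments):
        # +0.5 / -0.5: previous-only counts the second segment; the
        # both-neighbors variant counts both (chromosome ends unconstrained).
        assert cs.cna(toy_segments) == 1
        assert cs.cna(toy_segments, MetricConfig(cna_neighbor_rule="both")) == 2

    def test_break_points_two_per_aberrant_segment(self):
        seg = make_segments(
            [("S1", "1", 1, 100, 0.0), ("S1", "1", 101, 200, 0.5), ("S1", "1", 201, 300, 0.0)]
        )
        assert cs.count_break_points(seg) == 2

    def test_base_segments_counts_aberrant_bases_only(self):
        seg = make_segments([("S1", "1", 1, 100, 0.5), ("S1", "1", 101, 200, 0.0)])
        assert cs.count_base_segments(seg) == 100
        assert cs.fga(seg) == pytest.approx(0.5)

    def test_flat_profile_all_zero(self, flat_segments):
        row = cs.compute_all(flat_segments).iloc[0]
        assert all(row[m] == 0 for m in METRIC_NAMES)

    def test_saturated_profile(self):
        seg = make_segments([("S1", "1", 1, 100, 0.5), ("S1", "2", 1, 50, -0.9)])
        assert cs.fga(seg) == pytest.approx(1.0)
        assert cs.count_base_segments(seg) == 150

    @pytest.mark.parametrize("fn", [cs.tai, cs.modified_tai, cs.cna, cs.count_break_points, cs.count_base_segments, cs.fga])
    def test_empty_input_is_an_error(self, fn):
        empty = make_segments([("S1", "1", 1, 10, 0.0)]).df.iloc[:0]
        with pytest.raises(ValueError, match="empty"):
            fn(empty)


def random_sample_frame(rng: np.random.Generator, sample_id: str = "S") -> pd.DataFrame:
    """A small random sorted segment frame with occasional ties at the threshold."""
    rows = []
    for chrom in ("1", "2"):
        n = int(rng.integers(1, 8))
        bounds = np.sort(rng.choice(np.arange(1, 10_000), size=n + 1, replace=False))
        means = rng.choice([-0.5, -0.2, 0.0, 0.05, 0.2, 0.3, 0.8], size=n)
        for i in range(n):
            rows.append((sample_id, chrom, int(bounds[i]), int(bounds[i + 1] - 1) if i < n - 1 else int(bounds[i + 1]), float(means[i])))
    return make_segments(rows).df


class TestOracleEquivalence:
    @pytest.mark.parametrize("cfg", [CFG, MetricConfig(tai_aberrant_only=False), MetricConfig(cna_neighbor_rule="both"), MetricConfig(length_convention="half_open")])
    def test_production_matches_naive_loop(self, cfg, rng):
        frames = [random_sample_frame(rng, f"S{i}") for i in range(50)]
        table = cs.SegmentTable.from_frame(pd.concat(frames, ignore_index=True))
        prod = cs.compute_all(table, cfg).set_index("sample_id")
        for sid, sub in table.per_sample():
            expect = naive_metrics(sub, cfg)
            got = prod.loc[sid]
            for m in ("tai", "modified_tai", "fga"):
                assert got[m] == pytest.approx(expect[m], abs=1e-12)
            for m in ("cna", "break_points", "base_segments"):
                assert int(got[m]) == expect[m]

    def test_single_sample_functions_match_compute_all(self, toy_segments):
        row = cs.compute_all(toy_segments).iloc[0]
        sub = toy_segments.df
        assert row["tai"] == cs.tai(sub)
        assert row["modified_tai"] == cs.modified_tai(sub)
        assert row["cna"] == cs.cna(sub)
        assert row["break_points"] == cs.count_break_points(sub)
        assert row["base_segments"] == cs.count_base_segments(sub)
        assert row["fga"] == cs.fga(sub)


mean_values = st.floats(min_value=-2, max_value=2, allow_nan=False, width=32)


@st.composite
def segment_frames(draw):
    n = draw(st.integers(min_value=1, max_value=10))
    starts = sorted(draw(st.sets(st.integers(min_value=1, max_value=10_000), min_size=n + 1, max_size=n + 1)))
    rows = [("S1", "1", starts[i], starts[i + 1] - 1, draw(mean_values)) for i in range(n)]
    return make_segments(rows).df


class TestProperties:
    @given(segment_frames())
    def test_fga_is_base_segments_over_covered_length(self, df):
        total = int((df["end_bp"] - df["start_bp"] + 1).sum())
        assert cs.fga(df) == pytest.approx(cs.count_base_segments(df) / total, abs=1e-15)

    @given(segment_frames())
    def test_tai_bounded_by_modified_tai_over_all_segments(self, df):
        cfg = MetricConfig(tai_aberrant_only=False)
        assert abs(cs.tai(df, cfg)) <= cs.modified_tai(df, cfg) + 1e-12

    @given(segment_frames())
    def test_tai_equals_modified_tai_for_nonnegative_means(self, df):
        cfg = MetricConfig(tai_aberrant_only=False)
        df = df.assign(segment_mean=df["segment_mean"].abs())
        assert cs.tai(df, cfg) == pytest.approx(cs.modified_tai(df, cfg), abs=1e-12)

    @given(segment_frames(), st.integers(min_value=2, max_value=100))
    def test_coordinate_scaling(self, df, k):
        # lengths x k: ratios and counts unchanged, base_segments scales by k
        scaled = df.assign(
            start_bp=(df["start_bp"] - 1) * k + 1, end_bp=df["end_bp"] * k
        )
        for fn in (cs.tai, cs.modified_tai, cs.fga):
            assert fn(scaled) == pytest.approx(fn(df), abs=1e-12)
        assert cs.cna(scaled) == cs.cna(df)
        assert cs.count_break_points(scaled) == cs.count_break_points(df)
        assert cs.count_base_segments(scaled) == k * cs.count_base_segments(df)

    @given(segment_frames())
    def test_cna_at_most_aberrant_count(self, df):
        assert cs.cna(df) <= cs.count_break_points(df) // 2

    def test_permuting_input_rows_does_not_change_output(self, rng):
        df = random_sample_frame(rng)
        shuffled = cs.SegmentTable.from_frame(df.sample(frac=1, random_state=1))
        pd.testing.assert_frame_equal(
            cs.compute_all(cs.SegmentTable.from_frame(df)), cs.compute_all(shuffled)
        )
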