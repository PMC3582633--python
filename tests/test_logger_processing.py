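"""Block parsing, night assignment, aggregation, and bout detection."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import linregress

import lunarsea as ls
from lunarsea.logger_processing import BoutSummary

TZ = dt.timezone(dt.timedelta(hours=-6))


def _block(bird, iso, count):
    return ls.BlockRecord(bird, dt.datetime.fromisoformat(iso).replace(tzinfo=TZ), count)


def _night_blocks(bird, date, counts, start_hour=18):
    """Consecutive 10-min blocks for one night starting at start_hour."""
    t0 = dt.datetime.combine(date, dt.time(start_hour, 0), tzinfo=TZ)
    return [
        ls.BlockRecord(bird, t0 + dt.timedelta(minutes=10 * i), int(c))
        for i, c in enumerate(counts)
    ]


class TestReadWrite:
    def test_valid_csv_sorted(self, tmp_path):
        p = tmp_path / "blocks.csv"
        p.write_text(
            "bird_id,timestamp,wet_count\n"
            "b1,2010-03-05T18:20:00-06:00,5\n"
            "b1,2010-03-05T18:00:00-06:00,0\n"
            "b1,2010-03-05T18:10:00-06:00,200\n"
        )
        recs = ls.read_block_records(p)
        assert len(recs) == 3
        assert [r.wet_count for r in recs] == [0, 200, 5]  # timestamp order

    def test_count_out_of_bounds_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "bird_id,timestamp,wet_count\nb1,2010-03-05T18:00:00,201\n"
        )
        with pytest.raises(ls.LoggerParseError, match="line 2"):
            ls.read_block_records(p)

    def test_malformed_timestamp_names_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "bird_id,timestamp,wet_count\n"
            "b1,2010-03-05T18:00:00,3\n"
            "b1,not-a-time,3\n"
        )
        with pytest.raises(ls.LoggerParseError, match="line 3"):
            ls.read_block_records(p)

    def test_misaligned_block_start_rejected(self):
        with pytest.raises(ls.LoggerParseError, match="10-min grid"):
            _block("b1", "2010-03-05T18:05:00", 3)

    def test_generator_roundtrip_lossless(self, tmp_path):
        spec = ls.SimulationSpec(
            n_birds=2, n_nights=2, seed=3, include_daytime=True, day_rest_rate=0.0
        )
        records, _, _ = ls.simulate_deployment(spec)
        assert len(records) == 2 * 2 * 144  # nights + daytime, 2 birds x 2 days
        p = tmp_path / "rt.csv"
        ls.write_block_records(records, p)
        back = ls.read_block_records(p)
        assert back == sorted(records, key=lambda r: (r.bird_id, r.block_start))


class TestAssignNight:
    @pytest.mark.parametrize(
        "iso, expected",
        [
            ("2010-03-05T18:00:00", dt.date(2010, 3, 5)),  # window start
            ("2010-03-05T23:50:00", dt.date(2010, 3, 5)),
            ("2010-03-06T05:50:00", dt.date(2010, 3, 5)),  # pre-dawn -> prior evening
            ("2010-03-06T00:00:00", dt.date(2010, 3, 5)),
            ("2010-03-06T12:00:00", None),  # daytime
            ("2010-03-06T06:00:00", None),  # window end is exclusive
            ("2010-03-06T17:50:00", None),
        ],
    )
    def test_examples(self, iso, expected):
        t = dt.datetime.fromisoformat(iso).replace(tzinfo=TZ)
        assert ls.assign_night(t) == expected

    def test_window_must_span_midnight(self):
        t = dt.datetime(2010, 3, 5, 18, 0, tzinfo=TZ)
        with pytest.raises(ValueError):
            ls.assign_night(t, (dt.time(6, 0), dt.time(18, 0)))


class TestAggregateNights:
    def test_saturated_night(self):
        recs = _night_blocks("b1", dt.date(2010, 3, 5), [200] * 72)
        (obs,) = ls.aggregate_nights(recs)
        assert (obs.y, obs.n, obs.proportion) == (14_400, 14_400, 1.0)

    def test_all_dry_night(self):
        recs = _night_blocks("b1", dt.date(2010, 3, 5), [0] * 72)
        (obs,) = ls.aggregate_nights(recs)
        assert (obs.y, obs.proportion) == (0, 0.0)

    def test_alternating_blocks(self):
        counts = [0, 100] * 36
        recs = _night_blocks("b1", dt.date(2010, 3, 5), counts)
        (obs,) = ls.aggregate_nights(recs)
        assert obs.y == sum(counts) == 3_600
        assert obs.proportion == pytest.approx(0.25)

    def test_complete_night_has_full_trial_count(self):
        recs = _night_blocks("b1", dt.date(2010, 3, 5), list(range(72)))
        (obs,) = ls.aggregate_nights(recs)
        assert obs.n == ls.MAX_NIGHT_COUNT == 72 * 200
        assert obs.n_blocks == ls.BLOCKS_PER_NIGHT

    def test_partial_night_shrinks_trials(self):
        recs = _night_blocks("b1", dt.date(2010, 3, 5), [50] * 10)
        (obs,) = ls.aggregate_nights(recs)
        assert (obs.n, obs.n_blocks, obs.y) == (2_000, 10, 500)

    def test_min_blocks_filter(self):
        recs = _night_blocks("b1", dt.date(2010, 3, 5), [50] * 10)
        assert ls.aggregate_nights(recs, min_blocks=11) == []

    def test_duplicate_block_is_hard_error(self):
        recs = _night_blocks("b1", dt.date(2010, 3, 5), [1, 2])
        with pytest.raises(ls.AggregationError, match="duplicate"):
            ls.aggregate_nights(recs + [recs[0]])

    def test_daytime_blocks_ignored(self):
        recs = _night_blocks("b1", dt.date(2010, 3, 5), [9] * 6, start_hour=10)
        assert ls.aggregate_nights(recs) == []

    @given(
        counts=st.lists(st.integers(0, 200), min_size=1, max_size=72),
        perm_seed=st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariance_and_bounds(self, counts, perm_seed):
        """Nightly aggregate is order-free; y and proportion respect bounds."""
        recs = _night_blocks("b1", dt.date(2010, 3, 5), counts)
        perm = np.random.default_rng(perm_seed).permutation(len(recs))
        (a,) = ls.aggregate_nights(recs)
        (b,) = ls.aggregate_nights([recs[i] for i in perm])
        assert (a.y, a.n, a.n_blocks) == (b.y, b.n, b.n_blocks)
        assert 0 <= a.y <= 200 * a.n_blocks
        assert 0.0 <= a.proportion <= 1.0

    def test_additivity_across_disjoint_subsets(self):
        counts = list(np.random.default_rng(0).integers(0, 201, size=72))
        recs = _night_blocks("b1", dt.date(2010, 3, 5), counts)
        (whole,) = ls.aggregate_nights(recs)
        (first,) = ls.aggregate_nights(recs[:30])
        (second,) = ls.aggregate_nights(recs[30:])
        assert whole.y == first.y + second.y
        assert whole.n == first.n + second.n


def brute_force_bouts(seq):
    """Independent run-length oracle: count maximal runs of wet blocks."""
    bouts, in_bout = 0, False
    for c in seq:
        if c >= 1 and not in_bout:
            bouts += 1
        in_bout = c >= 1
    return bouts


class TestDetectWetBouts:
    @pytest.mark.parametrize(
        "seq, n_bouts, n_fly",
        [
            ([0, 5, 10, 0, 0, 3], 2, 3),
            ([0, 0, 0, 0], 0, 4),
            ([1] * 72, 1, 0),
            ([], 0, 0),
            ([7], 1, 0),
        ],
    )
    def test_examples(self, seq, n_bouts, n_fly):
        s = ls.detect_wet_bouts(seq)
        assert (s.n_wet_bouts, s.n_flying_blocks) == (n_bouts, n_fly)

    @given(st.lists(st.integers(0, 200), max_size=72))
    @settings(max_examples=300, deadline=None)
    def test_matches_run_length_oracle(self, seq):
        s = ls.detect_wet_bouts(seq)
        assert s.n_wet_bouts == brute_force_bouts(seq)
        assert s.n_flying_blocks == sum(1 for c in seq if c == 0)
        # alternating-pattern maximum
        assert s.n_wet_bouts <= (len(seq) + 1) // 2


class TestProportionBoutRegression:
    @staticmethod
    def _fixture(y_by_bouts):
        date = dt.date(2010, 3, 5)
        nights, bouts = [], []
        for i, (nb, y) in enumerate(y_by_bouts):
            d = date + dt.timedelta(days=i)
            nights.append(ls.NightObservation("b1", d, int(y), 14_400, 72))
            bouts.append(BoutSummary("b1", d, nb, 72 - nb))
        return nights, bouts

    def test_exact_linearity(self):
        nights, bouts = self._fixture([(1, 100), (2, 200), (3, 300), (5, 500)])
        slope, intercept, r2 = ls.proportion_bout_regression(nights, bouts)
        assert slope == pytest.approx(100.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r2 == pytest.approx(1.0)

    def test_constant_response_has_zero_r2(self):
        nights, bouts = self._fixture([(1, 50), (2, 50), (3, 50)])
        _, _, r2 = ls.proportion_bout_regression(nights, bouts)
        assert r2 == 0.0

    def test_zero_bout_variance_is_error(self):
        nights, bouts = self._fixture([(2, 10), (2, 20), (2, 30)])
        with pytest.raises(ValueError, match="zero variance"):
            ls.proportion_bout_regression(nights, bouts)

    def test_too_few_nights_is_error(self):
        nights, bouts = self._fixture([(1, 10), (2, 20)])
        with pytest.raises(ValueError, match=">=3"):
            ls.proportion_bout_regression(nights, bouts)

    def test_matches_least_squares_oracle_on_synthetic_data(self, small_deployment):
        _, records, _, _ = small_deployment
        nights = ls.aggregate_nights(records)
        bouts = ls.bouts_by_night(records)
        slope, intercept, r2 = ls.proportion_bout_regression(nights, bouts)
        key = {(o.bird_id, o.night_date): o.y for o in nights}
        x = np.array([b.n_wet_bouts for b in bouts], dtype=float)
        y = np.array([key[(b.bird_id, b.night_date)] for b in bouts], dtype=float)
        ref = linregress(x, y)
        assert slope == pytest.approx(ref.slope, rel=1e-10)
        assert intercept == pytest.approx(ref.intercept, rel=1e-10)
        assert r2 == pytest.approx(ref.rvalue**2, rel=1e-10)
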