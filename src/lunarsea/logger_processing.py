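"""Immersion-logger block processing.

Leg-mounted immersion loggers test for seawater contact every 3 s and sum
the results over 10-min blocks, so each block carries an integer 0-200: the
number of wet 3-s sub-periods. This module parses decoded block streams,
assigns blocks to 12-h nights (18:00-06:00 local time), aggregates them into
per-night binomial counts (y out of n = 200 x observed blocks, at most
14,400 = 72 x 200 for a complete night), and detects wet bouts -- maximal
runs of consecutive blocks with any water contact.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: wet 3-s sub-periods in one 10-min block (600 s / 3 s)
MAX_WET_COUNT = 200
#: 10-min blocks in a 12-h night
BLOCKS_PER_NIGHT = 72
#: maximum nightly aggregate count (72 x 200)
MAX_NIGHT_COUNT = BLOCKS_PER_NIGHT * MAX_WET_COUNT

#: default night window, local study time (equatorial: no DST)
NIGHT_START = dt.time(18, 0)
NIGHT_END = dt.time(6, 0)


class LoggerParseError(ValueError):
    """A block-stream row failed to parse or validate."""


class AggregationError(ValueError):
    """Nightly aggregation hit inconsistent input (e.g. duplicate blocks)."""


@dataclass(frozen=True)
class BlockRecord:
    """One decoded 10-min logger block."""

    bird_id: str
    block_start: dt.datetime
    wet_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.wet_count <= MAX_WET_COUNT:
            raise LoggerParseError(
                f"wet_count {self.wet_count} outside [0, {MAX_WET_COUNT}] "
                f"for bird {self.bird_id!r} at {self.block_start}"
            )
        if (self.block_start.minute % 10, self.block_start.second,
                self.block_start.microsecond) != (0, 0, 0):
            raise LoggerParseError(
                f"block_start {self.block_start} not aligned to 10-min grid"
            )


@dataclass(frozen=True)
class NightObservation:
    """Aggregated wet count for one bird-night: the binomial datum y of n."""

    bird_id: str
    night_date: dt.date
    y: int
    n: int
    n_blocks: int

    @property
    def proportion(self) -> float:
        return self.y / self.n

    def __post_init__(self) -> None:
        if not (0 <= self.y <= self.n <= MAX_NIGHT_COUNT):
            raise AggregationError(
                f"invalid night counts y={self.y}, n={self.n} "
                f"for bird {self.bird_id!r} on {self.night_date}"
            )
        if self.n != MAX_WET_COUNT * self.n_blocks:
            raise AggregationError(
                f"n={self.n} inconsistent with n_blocks={self.n_blocks}"
            )


@dataclass(frozen=True)
class BoutSummary:
    """Wet-bout and flying-block counts for one bird-night.

    A wet bout is a maximal run of consecutive blocks each with at least
    3 s of water contact (wet_count >= 1); every block of a flying bout is
    completely dry.
    """

    bird_id: str
    night_date: dt.date
    n_wet_bouts: int
    n_flying_blocks: int


def read_block_records(path, tz_offset_hours: float = -6.0) -> list[BlockRecord]:
    """Read a decoded block stream from CSV ``bird_id,timestamp,wet_count``.

    Timestamps are ISO-8601; naive timestamps are stamped with the fixed
    local study offset (default UTC-6, Galapagos; no DST). Records are
    returned sorted by (bird_id, block_start).

    Raises
    ------
    LoggerParseError
        On a malformed row (the message names the offending line) or a
        wet_count outside [0, 200].
    """
    tz = dt.timezone(dt.timedelta(hours=tz_offset_hours))
    df = pd.read_csv(path, dtype={"bird_id": str})
    expected = ["bird_id", "timestamp", "wet_count"]
    if list(df.columns) != expected:
        raise LoggerParseError(
            f"expected header {expected}, got {list(df.columns)}"
        )
    records: list[BlockRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            ts = dt.datetime.fromisoformat(str(row.timestamp))
            count = int(row.wet_count)
        except (ValueError, TypeError) as exc:
            raise LoggerParseError(f"line {i}: cannot parse row: {exc}") from exc
        if ts.tzinfo is None:
            ts = ts.replace(tzinfo=tz)
        try:
            records.append(BlockRecord(str(row.bird_id), ts, count))
        except LoggerParseError as exc:
            raise LoggerParseError(f"line {i}: {exc}") from exc
    records.sort(key=lambda r: (r.bird_id, r.block_start))
    return records


def write_block_records(records: Iterable[BlockRecord], path) -> None:
    """Write block records to the CSV dialect `read_block_records` accepts."""
    df = pd.DataFrame(
        {
            "bird_id": [r.bird_id for r in records],
            "timestamp": [r.block_start.isoformat() for r in records],
            "wet_count": [r.wet_count for r in records],
        }
    )
    df.to_csv(path, index=False)


def assign_night(
    block_start: dt.datetime,
    night_window: tuple[dt.time, dt.time] = (NIGHT_START, NIGHT_END),
) -> dt.date | None:
    """Map a block start time to the night (evening date) it belongs to.

    The window spans midnight: blocks starting in [start, 24:00) belong to
    that evening's date, blocks in [00:00, end) to the previous evening's.
    Daytime blocks map to None.
    """
    start, end = night_window
    if not start > end:
        raise ValueError("night window must span midnight (start > end)")
    t = block_start.time()
    if t >= start:
        return block_start.date()
    if t < end:
        return block_start.date() - dt.timedelta(days=1)
    return None


def aggregate_nights(
    records: Sequence[BlockRecord],
    night_window: tuple[dt.time, dt.time] = (NIGHT_START, NIGHT_END),
    min_blocks: int = 1,
) -> list[NightObservation]:
    """Aggregate block records into per-bird-night binomial counts.

    For each (bird, night) with at least ``min_blocks`` observed night
    blocks, y is the sum of wet counts and the trial count is
    n = 200 x n_blocks (14,400 when all 72 blocks are present). Nights with
    missing blocks keep a proportionally smaller n rather than being
    dropped; raise ``min_blocks`` to filter thin nights.

    Raises
    ------
    AggregationError
        If one bird has two blocks with the same timestamp (a logger fault
        that silent last-wins handling would hide).
    """
    seen: set[tuple[str, dt.datetime]] = set()
    acc: dict[tuple[str, dt.date], list[int]] = {}
    for rec in records:
        key_ts = (rec.bird_id, rec.block_start)
        if key_ts in seen:
            raise AggregationError(
                f"duplicate block for bird {rec.bird_id!r} at {rec.block_start}"
            )
        seen.add(key_ts)
        night = assign_night(rec.block_start, night_window)
        if night is None:
            continue
        acc.setdefault((rec.bird_id, night), []).append(rec.wet_count)
    out = []
    for (bird, night), counts in sorted(acc.items()):
        if len(counts) < min_blocks:
            continue
        out.append(
            NightObservation(
                bird_id=bird,
                night_date=night,
                y=int(sum(counts)),
                n=MAX_WET_COUNT * len(counts),
                n_blocks=len(counts),
            )
        )
    return out


def detect_wet_bouts(
    night_blocks: Sequence[int],
    bird_id: str = "",
    night_date: dt.date | None = None,
) -> BoutSummary:
    """Count wet bouts and flying blocks in one night's ordered block sequence.

    A wet bout is a maximal run of blocks with wet_count >= 1 (at least 3 s
    on the water); a flying block is completely dry (wet_count == 0). An
    empty sequence yields zero bouts and zero flying blocks.
    """
    wet = np.asarray(night_blocks, dtype=int) >= 1
    if wet.size == 0:
        n_bouts = 0
        n_fly = 0
    else:
        # a bout starts where wet turns on
        starts = wet & ~np.concatenate(([False], wet[:-1]))
        n_bouts = int(starts.sum())
        n_fly = int((~wet).sum())
    return BoutSummary(
        bird_id=bird_id,
        night_date=night_date or dt.date(1970, 1, 1),
        n_wet_bouts=n_bouts,
        n_flying_blocks=n_fly,
    )


def bouts_by_night(
    records: Sequence[BlockRecord],
    night_window: tuple[dt.time, dt.time] = (NIGHT_START, NIGHT_END),
) -> list[BoutSummary]:
    """Run `detect_wet_bouts` on every bird-night in a block stream."""
    acc: dict[tuple[str, dt.date], list[tuple[dt.datetime, int]]] = {}
    for rec in records:
        night = assign_night(rec.block_start, night_window)
        if night is None:
            continue
        acc.setdefault((rec.bird_id, night), []).append(
            (rec.block_start, rec.wet_count)
        )
    out = []
    for (bird, night), blocks in sorted(acc.items()):
        blocks.sort()
        seq = [c for _, c in blocks]
        out.append(detect_wet_bouts(seq, bird_id=bird, night_date=night))
    return out


def proportion_bout_regression(
    nights: Sequence[NightObservation], bouts: Sequence[BoutSummary]
) -> tuple[float, float, float]:
    """OLS of nightly aggregate wet count on wet-bout count.

    Diagnostic regression of time-on-water against the number of landings:
    the two should be strongly, linearly related if both processing steps
    are sound. Returns (slope, intercept, r_squared).

    Raises
    ------
    ValueError
        With fewer than 3 matched bird-nights, or zero variance in bout
        counts (undefined fit).
    """
    night_map = {(o.bird_id, o.night_date): o.y for o in nights}
    pairs = [
        (b.n_wet_bouts, night_map[(b.bird_id, b.night_date)])
        for b in bouts
        if (b.bird_id, b.night_date) in night_map
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >=3 matched bird-nights, got {len(pairs)}")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0.0:
        raise ValueError("zero variance in bout counts: undefined fit")
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    slope = sxy / sxx
    intercept = float(y.mean() - slope * x.mean())
    syy = float(np.sum((y - y.mean()) ** 2))
    r_squared = 0.0 if syy == 0.0 else sxy**2 / (sxx * syy)
    return slope, intercept, r_squared


def nights_to_frame(
    nights: Sequence[NightObservation],
    bouts: Sequence[BoutSummary] | None = None,
) -> pd.DataFrame:
    """Export nights (optionally with bout counts) as the audit CSV table."""
    df = pd.DataFrame(
        {
            "bird_id": [o.bird_id for o in nights],
            "night_date": [o.night_date.isoformat() for o in nights],
            "y": [o.y for o in nights],
            "n": [o.n for o in nights],
            "n_blocks": [o.n_blocks for o in nights],
            "proportion": [o.proportion for o in nights],
        }
    )
    if bouts is not None:
        bout_map = {
            (b.bird_id, b.night_date.isoformat()): b.n_wet_bouts for b in bouts
        }
        df["n_wet_bouts"] = [
            bout_map.get((r.bird_id, r.night_date), 0)
            for r in df.itertuples(index=False)
        ]
    return df
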