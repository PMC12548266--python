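"""Daily location histories.

Converts time-stamped receiver detections into per-fish calendar-day state
sequences at two levels of spatial resolution:

* **habitat** — ``river``, ``lake``, or (where configured) ``lake_st_clair``,
  the hydrological unit the receiver sits in;
* **region** — a named waterbody label such as ``LM`` (Lake Michigan) or
  ``MR`` (Menominee River).

Days without a detection are imputed by last-observation-carried-forward
(LOCF): a fish is assumed to remain at its last detected location until it
is detected somewhere else.  On days with detections at several locations
the *first* detection of the day supplies the day's state, while
carry-forward for the following undetected days starts from the *last*
detection of the day.  Days before the first detection are coded MISSING;
days after the final detection, when the analysis timeframe extends beyond
it, are coded VOID (a contiguous suffix).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Sentinel state for days before a fish's first detection ("left-missing").
MISSING = "*"
#: Sentinel state for days after a fish's final detection ("right-missing").
VOID = "%"

RIVER = "river"
LAKE = "lake"
LAKE_ST_CLAIR = "lake_st_clair"
HABITATS = (RIVER, LAKE, LAKE_ST_CLAIR)
#: Habitat states counted as "lake" time in residency calculations.
LAKE_LIKE = frozenset({LAKE, LAKE_ST_CLAIR})


@dataclass(frozen=True)
class ReceiverStation:
    """An acoustic receiver with its habitat class and regional label."""

    receiver_id: str
    habitat: str
    region: str
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(
                f"habitat {self.habitat!r} for receiver {self.receiver_id!r} "
                f"not one of {HABITATS}"
            )
        if not self.receiver_id or not self.region:
            raise ValueError("receiver_id and region must be non-empty")


def stations_to_frame(stations) -> pd.DataFrame:
    """Normalize a station table (frame or iterable of ReceiverStation)."""
    if isinstance(stations, pd.DataFrame):
        df = stations.copy()
    else:
        df = pd.DataFrame(
            [
                {
                    "receiver_id": s.receiver_id,
                    "habitat": s.habitat,
                    "region": s.region,
                    "lat": s.lat,
                    "lon": s.lon,
                }
                for s in stations
            ]
        )
    required = {"receiver_id", "habitat", "region"}
    if not required.issubset(df.columns):
        raise ValueError(f"station table needs columns {sorted(required)}")
    if df["receiver_id"].duplicated().any():
        dupes = df.loc[df["receiver_id"].duplicated(), "receiver_id"].tolist()
        raise ValueError(f"duplicate receiver ids: {dupes}")
    return df


def classify_receiver(receiver_id: str, stations) -> tuple[str, str]:
    """Look up ``(habitat, region)`` for one receiver.

    Bays are classified as their parent lake in the station table itself
    (e.g. a Green Bay receiver carries ``habitat='lake', region='LM'``);
    the split between river and lake happens where the river meets the lake.
    """
    df = stations_to_frame(stations)
    row = df.loc[df["receiver_id"] == receiver_id]
    if row.empty:
        raise KeyError(f"unknown receiver id: {receiver_id!r}")
    r = row.iloc[0]
    return str(r["habitat"]), str(r["region"])


def region_habitat_map(stations) -> dict[str, str]:
    """Region label -> habitat class mapping implied by a station table."""
    df = stations_to_frame(stations)
    out: dict[str, str] = {}
    for region, habitat in zip(df["region"], df["habitat"]):
        if region in out and out[region] != habitat:
            raise ValueError(f"region {region!r} maps to multiple habitats")
        out[region] = habitat
    return out


@dataclass
class DailyStateSequence:
    """Per-fish vector of daily states over consecutive calendar days."""

    fish_id: str
    start_date: dt.date
    states: np.ndarray  # object dtype, values in alphabet | {MISSING, VOID}
    alphabet: tuple[str, ...]

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=object)
        self.alphabet = tuple(self.alphabet)

    def __len__(self) -> int:
        return len(self.states)

    @property
    def end_date(self) -> dt.date:
        return self.start_date + dt.timedelta(days=len(self) - 1)

    def dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(len(self))]

    def state_on(self, day: dt.date) -> str:
        i = (day - self.start_date).days
        if not 0 <= i < len(self):
            raise IndexError(f"{day} outside sequence for {self.fish_id}")
        return self.states[i]

    def observed_mask(self) -> np.ndarray:
        return (self.states != MISSING) & (self.states != VOID)

    def strip_void(self) -> "DailyStateSequence":
        """Drop the trailing VOID run (used before edit-distance work)."""
        n = len(self.states)
        while n > 0 and self.states[n - 1] == VOID:
            n -= 1
        return replace(self, states=self.states[:n].copy())

    def to_series(self) -> pd.Series:
        return pd.Series(
            self.states, index=pd.to_datetime(self.dates()), name=self.fish_id
        )


def _event_days(events: pd.DataFrame, label: pd.Series) -> pd.DataFrame:
    """First/last label per UTC calendar day, from chronologically sorted events."""
    ts = pd.to_datetime(events["timestamp"], utc=True)
    df = pd.DataFrame({"day": ts.dt.date, "ts": ts, "label": label.values})
    df = df.sort_values("ts", kind="stable")
    g = df.groupby("day", sort=True)["label"]
    return pd.DataFrame({"first": g.first(), "last": g.last()})


def build_daily_sequence(
    events: pd.DataFrame,
    stations,
    timeframe: tuple[dt.date, dt.date],
    level: str = "habitat",
) -> DailyStateSequence:
    """Build one fish's daily state sequence over ``timeframe``.

    ``events`` must contain detections of a single fish (columns
    ``fish_id``, ``timestamp``, ``receiver_id``); timestamps are treated as
    UTC and a detection belongs to the UTC date of its timestamp.
    """
    if level not in ("habitat", "region"):
        raise ValueError("level must be 'habitat' or 'region'")
    start, end = timeframe
    if end < start:
        raise ValueError("inverted timeframe")
    if events.empty:
        raise ValueError("no events supplied")
    fish = events["fish_id"].unique()
    if len(fish) != 1:
        raise ValueError(f"events span multiple fish: {fish.tolist()}")

    df = stations_to_frame(stations)
    lut = df.set_index("receiver_id")[level]
    unknown = set(events["receiver_id"]) - set(lut.index)
    if unknown:
        raise KeyError(f"detections at unclassified stations: {sorted(unknown)}")
    label = events["receiver_id"].map(lut)
    daily = _event_days(events, label)

    if level == "habitat":
        alphabet = tuple(h for h in HABITATS if h in set(df["habitat"]))
    else:
        alphabet = tuple(sorted(df["region"].unique()))

    n = (end - start).days + 1
    states = np.full(n, MISSING, dtype=object)
    carry: str | None = None
    last_day: dt.date | None = None
    first_by_idx: dict[int, str] = {}
    carry_by_idx: dict[int, str] = {}
    for day, row in daily.iterrows():
        last_day = day
        if day < start:
            carry = row["last"]  # seeds LOCF at the window start
            continue
        if day > end:
            break
        i = (day - start).days
        first_by_idx[i] = row["first"]
        carry_by_idx[i] = row["last"]

    state = carry
    for i in range(n):
        if i in first_by_idx:
            states[i] = first_by_idx[i]
            state = carry_by_idx[i]
        elif state is not None:
            states[i] = state
    # Right-missing: the timeframe extends beyond the fish's final detection.
    final_day = daily.index[-1]
    if final_day < end:
        cut = max((final_day - start).days + 1, 0)
        states[cut:] = VOID

    return DailyStateSequence(str(fish[0]), start, states, alphabet)


def build_daily_sequences(
    events: pd.DataFrame,
    stations,
    timeframe: tuple[dt.date, dt.date],
    level: str = "habitat",
) -> dict[str, DailyStateSequence]:
    """``build_daily_sequence`` for every fish in an event table."""
    return {
        str(fid): build_daily_sequence(sub, stations, timeframe, level)
        for fid, sub in events.groupby("fish_id", sort=True)
    }


def truncate_to_timeframe(
    seq: DailyStateSequence, window: tuple[dt.date, dt.date]
) -> DailyStateSequence:
    """Restrict a sequence to ``window``, preserving temporal alignment.

    Leading days of the window that precede the sequence (or its first
    observation) stay MISSING — sequences are never re-anchored to the
    window start — and trailing days past the sequence become VOID.
    """
    start, end = window
    if end < start:
        raise ValueError("inverted window")
    if end < seq.start_date or start > seq.end_date:
        raise ValueError("window does not overlap sequence")
    n = (end - start).days + 1
    states = np.full(n, MISSING, dtype=object)
    lo = max(start, seq.start_date)
    hi = min(end, seq.end_date)
    src = (lo - seq.start_date).days
    dst = (lo - start).days
    span = (hi - lo).days + 1
    states[dst : dst + span] = seq.states[src : src + span]
    if end > seq.end_date:
        states[dst + span :] = VOID
    return DailyStateSequence(seq.fish_id, start, states, seq.alphabet)


def sequences_to_wide(seqs: dict[str, DailyStateSequence]) -> pd.DataFrame:
    """One row per fish, one ISO-dated column per day (serialization form)."""
    if not seqs:
        return pd.DataFrame()
    rows = {fid: s.to_series() for fid, s in seqs.items()}
    wide = pd.DataFrame(rows).T
    wide.columns = [c.date().isoformat() for c in wide.columns]
    wide.index.name = "fish_id"
    return wide


def wide_to_sequences(
    wide: pd.DataFrame, alphabet: tuple[str, ...]
) -> dict[str, DailyStateSequence]:
    start = dt.date.fromisoformat(wide.columns[0])
    return {
        str(fid): DailyStateSequence(
            str(fid), start, row.to_numpy(dtype=object), alphabet
        )
        for fid, row in wide.iterrows()
    }
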