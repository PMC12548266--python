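"""Synthetic acoustic-telemetry data with known behavioral ground truth.

Real multi-year sturgeon detection histories are not redistributable, so
every downstream stage of the package is exercised against simulated
cohorts instead.  The generator emulates the seven migratory-behavior
archetypes observed in Great Lakes lake sturgeon:

* ``annual_spring_river`` / ``intermittent_spring_river`` — short (~3 week)
  river migrations overlapping the April–June spawning season, every year
  or every ``period_years`` years;
* ``intermittent_two_step`` — fall entry into the spawning river,
  overwintering near the spawning site, spring spawning, return to the lake
  (biennial by default; a year-long-stay variant produces ~50:50
  lake:river residency);
* ``river_resident`` — year-round residence in one river;
* ``annual_summer_river`` — spring river entry with residence extending
  through the summer, lake overwintering;
* ``annual_winter_river`` — the inverse: fall river entry, overwintering in
  the river, spring return to the lake;
* ``annual_interlake`` — overwintering in Lake St. Clair, transiting a
  connecting river each spring to summer in a different Great Lake.

Movement is modeled as a deterministic per-fish calendar of daily true
regions (transition dates = archetype window midpoints plus optional
Gaussian jitter per cycle).  Detection is a Bernoulli draw per fish-day;
a detected day emits a short burst of pings (300 s apart) at one station of
the occupied region, mimicking the ping trains a fish parked near a
receiver produces and ensuring synthetic data survive the min-lag
false-detection filter.  With ``detection_prob=1`` and zero jitter the
induced daily sequence reproduces the archetype calendar exactly, so the
full pipeline can be inverted against ground truth.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sequences import HABITATS, LAKE, LAKE_ST_CLAIR, RIVER, ReceiverStation

Window = tuple[tuple[int, int], tuple[int, int]]  # ((month, day), (month, day))

ARCHETYPE_NAMES = (
    "annual_spring_river",
    "intermittent_spring_river",
    "intermittent_two_step",
    "river_resident",
    "annual_summer_river",
    "annual_winter_river",
    "annual_interlake",
)


@dataclass(frozen=True)
class BehaviorArchetype:
    """Calendar template for one migratory behavior.

    ``route`` lists the regions in the order a migratory cycle uses them;
    ``route[0]`` is the home unit and, for simple migrants, ``route[1]`` the
    spawning/overwinter river.  Entry/exit windows are (month, day) ranges;
    the simulator uses their midpoints as base transition dates.  A
    ``period_years`` of 1 is annual, >= 2 intermittent.
    """

    name: str
    route: tuple[str, ...]
    river_entry_window: Window | None = None
    river_exit_window: Window | None = None
    period_years: int = 1
    overwinter_unit: str | None = None

    def __post_init__(self) -> None:
        if self.period_years < 1:
            raise ValueError("period_years must be >= 1")
        if "intermittent" in self.name and self.period_years < 2:
            raise ValueError(f"{self.name}: intermittent archetypes need period_years >= 2")
        if self.name == "river_resident":
            if self.river_entry_window or self.river_exit_window:
                raise ValueError("river_resident has empty entry/exit windows")
        if not self.route:
            raise ValueError("route must be non-empty")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the detection simulation; the seed fully determines output."""

    n_fish_per_archetype: int = 10
    years: int = 6
    detection_prob: float = 1.0
    transition_jitter_days: float = 0.0
    seed: int = 0
    start_date: dt.date = dt.date(2015, 1, 1)
    tagging_spread_days: int = 0  # tagging dates uniform in [start, start+spread]
    fish_length_range: tuple[float, float] = (1.1, 2.0)  # meters
    tag_life_years: float = 10.0
    multi_station_prob: float = 0.0  # extra morning ping at yesterday's region
    pings_per_day: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_prob <= 1.0:
            raise ValueError("detection_prob must be in [0, 1]")
        if self.years < 2:
            raise ValueError("years must be >= 2 (two-year history filter)")
        if self.pings_per_day < 1:
            raise ValueError("pings_per_day must be >= 1")

    @property
    def end_date(self) -> dt.date:
        return dt.date(self.start_date.year + self.years, 1, 1) - dt.timedelta(days=1)


def _mid(window: Window, year: int) -> dt.date:
    (m1, d1), (m2, d2) = window
    a = dt.date(year, m1, d1)
    b = dt.date(year, m2, d2)
    if b < a:
        b = dt.date(year + 1, m2, d2)
    return a + (b - a) // 2


def default_archetypes(two_step_exit: Window = ((6, 10), (6, 20))) -> list[BehaviorArchetype]:
    """The seven-behavior reference set on the default network regions."""
    spring_entry: Window = ((4, 24), (5, 8))
    spring_exit: Window = ((5, 15), (5, 29))
    return [
        BehaviorArchetype("annual_spring_river", ("LM", "MR"), spring_entry, spring_exit, 1),
        BehaviorArchetype("intermittent_spring_river", ("LM", "MR"), spring_entry, spring_exit, 2),
        BehaviorArchetype(
            "intermittent_two_step", ("LM", "MR"), ((9, 24), (10, 8)), two_step_exit, 2
        ),
        BehaviorArchetype("river_resident", ("MR",)),
        BehaviorArchetype(
            "annual_summer_river", ("LM", "MR"), ((4, 24), (5, 8)), ((9, 8), (9, 22)), 1
        ),
        BehaviorArchetype(
            "annual_winter_river", ("LM", "MR"), ((9, 8), (9, 22)), ((4, 8), (4, 22)), 1
        ),
        BehaviorArchetype(
            "annual_interlake",
            ("LSC", "DR", "LE"),
            ((4, 18), (5, 2)),
            ((9, 10), (9, 24)),
            1,
            overwinter_unit="LSC",
        ),
    ]


def two_step_fifty_fifty() -> BehaviorArchetype:
    """Biennial two-step variant with a year-long river stay (~50:50 residency)."""
    return BehaviorArchetype(
        "intermittent_two_step", ("LM", "MR"), ((9, 24), (10, 8)), ((9, 24), (10, 8)), 2
    )


def two_step_two_transition() -> BehaviorArchetype:
    """Two-step variant transiting a river to overwinter in Lake St. Clair."""
    return BehaviorArchetype(
        "intermittent_two_step",
        ("LH", "SCR"),
        ((9, 24), (10, 8)),
        ((6, 10), (6, 20)),
        2,
        overwinter_unit="LSC",
    )


DEFAULT_LAYOUT: dict[str, tuple[str, int]] = {
    "LM": (LAKE, 3),
    "MR": (RIVER, 2),
    "LSC": (LAKE_ST_CLAIR, 2),
    "DR": (RIVER, 2),
    "LE": (LAKE, 2),
}


def make_network(layout: dict[str, tuple[str, int]]) -> list[ReceiverStation]:
    """Build a receiver network from ``{region: (habitat, station_count)}``."""
    if not layout:
        raise ValueError("empty network layout")
    habitats = {h for h, _ in layout.values()}
    if RIVER not in habitats or not habitats & {LAKE, LAKE_ST_CLAIR}:
        raise ValueError("layout needs at least one river and one lake region")
    stations = []
    for region, (habitat, count) in layout.items():
        if habitat not in HABITATS:
            raise ValueError(f"unknown habitat {habitat!r} for region {region!r}")
        if count < 1:
            raise ValueError(f"region {region!r} needs >= 1 station")
        for i in range(count):
            stations.append(ReceiverStation(f"{region}-{i + 1:02d}", habitat, region))
    return stations


def default_network() -> list[ReceiverStation]:
    return make_network(DEFAULT_LAYOUT)


def _daily_regions(
    arch: BehaviorArchetype, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """True region per day from start_date to end_date inclusive."""
    n = (cfg.end_date - cfg.start_date).days + 1
    days = np.array([cfg.start_date + dt.timedelta(days=i) for i in range(n)])
    regions = np.full(n, arch.route[0], dtype=object)

    def jitter() -> dt.timedelta:
        if cfg.transition_jitter_days <= 0:
            return dt.timedelta(0)
        return dt.timedelta(days=int(round(rng.normal(0.0, cfg.transition_jitter_days))))

    def mark(a: dt.date, b: dt.date, region: str) -> None:
        lo = max((a - cfg.start_date).days, 0)
        hi = min((b - cfg.start_date).days, n - 1)
        if hi >= lo:
            regions[lo : hi + 1] = region

    if arch.name == "river_resident":
        return regions

    if arch.name == "annual_interlake":
        # Overwinter in LSC; spring transit via river to a summer lake; fall
        # transit back.  route = (overwinter lake, transit river, summer lake)
        lsc, river, summer = arch.route
        for year in range(cfg.start_date.year - 1, cfg.end_date.year + 1):
            out_start = _mid(arch.river_entry_window, year) + jitter()
            in_end = _mid(arch.river_exit_window, year) + jitter()
            transit = dt.timedelta(days=14)
            mark(out_start, out_start + transit, river)
            mark(out_start + transit + dt.timedelta(days=1), in_end - transit, summer)
            mark(in_end - transit + dt.timedelta(days=1), in_end, river)
        return regions

    river = arch.route[1]
    for year in range(cfg.start_date.year - arch.period_years, cfg.end_date.year + 1):
        if (year - cfg.start_date.year) % arch.period_years != 0:
            continue
        entry = _mid(arch.river_entry_window, year)
        exit_ = _mid(arch.river_exit_window, year)
        if exit_ <= entry:  # cycle spans the year boundary (fall/winter entries)
            exit_ = _mid(arch.river_exit_window, year + 1)
        entry = entry + jitter()
        exit_ = max(exit_ + jitter(), entry)  # jitter never inverts the cycle
        if arch.overwinter_unit is not None and arch.overwinter_unit != arch.route[0]:
            # two-transition two-step: fall transit, overwinter elsewhere,
            # short spring stay in the spawning river
            transit = dt.timedelta(days=10)
            mark(entry, entry + transit, river)
            spawn_start = dt.date(entry.year + 1, 4, 25)
            mark(entry + transit + dt.timedelta(days=1), spawn_start - dt.timedelta(days=1),
                 arch.overwinter_unit)
            mark(spawn_start, exit_, river)
        else:
            mark(entry, exit_, river)
    return regions


def simulate_individual(
    arch: BehaviorArchetype,
    cfg: SimulationConfig,
    fish_id: str,
    stations=None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, str]:
    """Simulate one fish; returns (detections, true behavior label)."""
    if stations is None:
        stations = default_network()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    by_region: dict[str, list[str]] = {}
    for s in stations:
        by_region.setdefault(s.region, []).append(s.receiver_id)
    missing = set(arch.route) - set(by_region)
    if arch.overwinter_unit and arch.overwinter_unit not in by_region:
        missing.add(arch.overwinter_unit)
    if missing:
        raise ValueError(f"route references unknown regions: {sorted(missing)}")

    regions = _daily_regions(arch, cfg, rng)
    tag_offset = int(rng.integers(0, cfg.tagging_spread_days + 1))
    tagging_date = cfg.start_date + dt.timedelta(days=tag_offset)

    rows = []
    n = len(regions)
    detected = rng.random(n) < cfg.detection_prob
    for i in range(tag_offset, n):
        if not detected[i]:
            continue
        day = cfg.start_date + dt.timedelta(days=i)
        region = regions[i]
        rid = by_region[region][int(rng.integers(len(by_region[region])))]
        base = dt.datetime(day.year, day.month, day.day, 10, 0, tzinfo=dt.timezone.utc)
        if (
            cfg.multi_station_prob > 0
            and i > tag_offset
            and regions[i - 1] != region
            and rng.random() < cfg.multi_station_prob
        ):
            prev_rid = by_region[regions[i - 1]][0]
            rows.append((fish_id, base.replace(hour=6), prev_rid))
        for p in range(cfg.pings_per_day):
            rows.append((fish_id, base + dt.timedelta(seconds=300 * p), rid))
    det = pd.DataFrame(rows, columns=["fish_id", "timestamp", "receiver_id"])
    return det, arch.name


def simulate_cohort(
    cfg: SimulationConfig,
    archetypes: list[BehaviorArchetype] | None = None,
    stations=None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate ``n_fish_per_archetype`` fish per archetype.

    Returns ``(detections, metadata, truth)`` tables; the same config (and
    seed) always reproduces byte-identical tables.
    """
    if archetypes is None:
        archetypes = default_archetypes()
    if stations is None:
        stations = default_network()
    rng = np.random.default_rng(cfg.seed)
    dets, meta, truth = [], [], []
    for arch in archetypes:
        for i in range(cfg.n_fish_per_archetype):
            fid = f"{arch.name}_{i:02d}"
            d, label = simulate_individual(arch, cfg, fid, stations, rng)
            dets.append(d)
            lo, hi = cfg.fish_length_range
            tagging = (
                d["timestamp"].min().date() if not d.empty else cfg.start_date
            )
            meta.append(
                {
                    "fish_id": fid,
                    "total_length": round(float(rng.uniform(lo, hi)), 3),
                    "sex": str(rng.choice(["male", "female"])),
                    "tagging_date": tagging,
                    "tag_life_years": cfg.tag_life_years,
                }
            )
            truth.append(
                {
                    "fish_id": fid,
                    "behavior": label,
                    "contingent_route": "→".join(dict.fromkeys(arch.route)),
                }
            )
    detections = pd.concat(dets, ignore_index=True) if dets else pd.DataFrame(
        columns=["fish_id", "timestamp", "receiver_id"]
    )
    return detections, pd.DataFrame(meta), pd.DataFrame(truth)
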