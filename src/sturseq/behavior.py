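"""Rule-based classification of migratory behaviors.

In field studies, behavioral groups suggested by clustering are refined by
visually inspecting each fish's sequence.  This module replaces that
manual step with a deterministic, ordered rule cascade over the river
episodes extracted from a fish's habitat/region sequences:

1. **river_resident** — lake residency at or below a small threshold;
2. **annual_interlake** — repeated annual cycles of overwintering in Lake
   St. Clair, transiting a connecting river, and summering in a different
   Great Lake;
3. **annual_winter_river** — river entry in late summer/fall, river
   overwintering, spring exit, repeated near-annually;
4. **annual_summer_river** — spring entry, residence extending past the
   spawning season, late-summer/fall exit, repeated near-annually;
5. **intermittent_two_step** — fall river entry with the stay spanning the
   following spawning season;
6. **spring-river migrant** — short river trips overlapping the April–June
   spawning window, split into annual vs intermittent by the periodicity
   ratio (observed years per spring trip; <= 1.5 means annual);
7. **UNCLASSIFIED** — sequences conforming to none of the patterns.

The first matching rule wins.  "Annual" rules tolerate one missed year
(detection gaps truncate first/last cycles).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .sequences import LAKE, LAKE_LIKE, LAKE_ST_CLAIR, MISSING, RIVER, VOID, DailyStateSequence

DAYS_PER_YEAR = 365.25

UNCLASSIFIED = "UNCLASSIFIED"
BEHAVIORS = (
    "annual_spring_river",
    "intermittent_spring_river",
    "intermittent_two_step",
    "river_resident",
    "annual_summer_river",
    "annual_winter_river",
    "annual_interlake",
)

Window = tuple[tuple[int, int], tuple[int, int]]


def in_window(day: dt.date, window: Window) -> bool:
    """Is (month, day) of ``day`` inside the window?  Handles year wrap."""
    (m1, d1), (m2, d2) = window
    md = (day.month, day.day)
    lo, hi = (m1, d1), (m2, d2)
    if lo <= hi:
        return lo <= md <= hi
    return md >= lo or md <= hi


@dataclass(frozen=True)
class RuleConfig:
    """Seasonal windows and thresholds of the classification cascade.

    Windows are ((month, day), (month, day)); fractions in [0, 1];
    the periodicity threshold is 1.5 observed-years-per-trip.
    """

    spawning_window: Window = ((4, 1), (6, 30))
    spring_trip_max_days: int = 45
    summer_exit_window: Window = ((8, 1), (10, 31))
    winter_entry_window: Window = ((7, 1), (10, 31))
    winter_exit_window: Window = ((3, 1), (5, 31))
    fall_entry_window: Window = ((9, 1), (12, 31))
    resident_max_lake_fraction: float = 0.10
    fifty_fifty_band: tuple[float, float] = (0.35, 0.60)
    periodicity_threshold: float = 1.5


@dataclass(frozen=True)
class RiverEpisode:
    """A maximal run of consecutive river days."""

    region: str
    entry: dt.date
    exit: dt.date
    duration_days: int
    overlaps_spawning_window: bool

    def __post_init__(self) -> None:
        if self.exit < self.entry:
            raise ValueError("episode exit precedes entry")


@dataclass
class BehaviorAssignment:
    """Per-fish classification output."""

    fish_id: str
    behavior: str
    periodicity_ratio: float | None
    lake_residency: float
    residency_class: str  # lake_dominant | river_dominant | fifty_fifty
    cluster_id: int | None = None


def extract_river_episodes(
    habitat_seq: DailyStateSequence,
    regional_seq: DailyStateSequence,
    spawning_window: Window = ((4, 1), (6, 30)),
) -> list[RiverEpisode]:
    """Maximal consecutive-river-day runs, with modal region per run.

    A MISSING/VOID day inside a run breaks the episode (runs are over
    observed-or-imputed states only).
    """
    if (
        habitat_seq.fish_id != regional_seq.fish_id
        or habitat_seq.start_date != regional_seq.start_date
        or len(habitat_seq) != len(regional_seq)
    ):
        raise ValueError("habitat and regional sequences are misaligned")
    states = habitat_seq.states
    episodes: list[RiverEpisode] = []
    i, n = 0, len(states)
    while i < n:
        if states[i] != RIVER:
            i += 1
            continue
        j = i
        while j < n and states[j] == RIVER:
            j += 1
        entry = habitat_seq.start_date + dt.timedelta(days=i)
        exit_ = habitat_seq.start_date + dt.timedelta(days=j - 1)
        regions = [r for r in regional_seq.states[i:j] if r not in (MISSING, VOID)]
        vals, counts = np.unique(np.asarray(regions, dtype=object), return_counts=True)
        region = str(vals[np.argmax(counts)]) if len(vals) else ""
        overlaps = any(
            in_window(entry + dt.timedelta(days=k), spawning_window)
            for k in range(j - i)
        )
        episodes.append(RiverEpisode(region, entry, exit_, j - i, overlaps))
        i = j
    return episodes


def periodicity_ratio(
    history_years: float, n_spring_trips: int, threshold: float = 1.5
) -> tuple[float, str]:
    """Observed years per spring river trip; <= threshold classifies annual."""
    if n_spring_trips < 1:
        raise ValueError("periodicity undefined with zero spring trips")
    if history_years <= 0:
        raise ValueError("history_years must be positive")
    ratio = history_years / n_spring_trips
    return ratio, ("annual" if ratio <= threshold else "intermittent")


def lake_residency(habitat_seq: DailyStateSequence) -> float:
    """Fraction of observed-or-imputed days spent in lake states.

    Lake St. Clair counts as lake time; MISSING/VOID days are excluded
    from both numerator and denominator.
    """
    observed = habitat_seq.states[habitat_seq.observed_mask()]
    if len(observed) == 0:
        raise ValueError("sequence has no observed days")
    lake_days = sum(1 for s in observed if s in LAKE_LIKE)
    return lake_days / len(observed)


def _observed_span_years(seq: DailyStateSequence) -> float:
    idx = np.nonzero(seq.observed_mask())[0]
    if len(idx) == 0:
        raise ValueError("sequence has no observed days")
    return (idx[-1] - idx[0] + 1) / DAYS_PER_YEAR


def _spawn_years(ep: RiverEpisode, window: Window) -> set[int]:
    """Calendar years in which the episode touches the spawning window."""
    years = set()
    day = ep.entry
    while day <= ep.exit:
        if in_window(day, window):
            years.add(day.year)
        day += dt.timedelta(days=1)
    return years


def _residency_class(frac: float, band: tuple[float, float]) -> str:
    lo, hi = band
    if frac < lo:
        return "river_dominant"
    if frac > hi:
        return "lake_dominant"
    return "fifty_fifty"


def classify_behavior(
    habitat_seq: DailyStateSequence,
    regional_seq: DailyStateSequence,
    rules: RuleConfig = RuleConfig(),
) -> BehaviorAssignment:
    """Assign one of the seven migratory behaviors (first matching rule wins)."""
    frac = lake_residency(habitat_seq)
    res_class = _residency_class(frac, rules.fifty_fifty_band)
    episodes = extract_river_episodes(habitat_seq, regional_seq, rules.spawning_window)
    years_obs = _observed_span_years(habitat_seq)
    required_annual = max(1, int(years_obs) - 1)

    def done(behavior: str, ratio: float | None = None) -> BehaviorAssignment:
        return BehaviorAssignment(habitat_seq.fish_id, behavior, ratio, frac, res_class)

    # (1) river resident
    if frac <= rules.resident_max_lake_fraction:
        return done("river_resident")

    # (2) annual interlake: LSC winter, river transit, summer in another lake
    if LAKE_ST_CLAIR in habitat_seq.alphabet:
        cycles = 0
        for year in range(habitat_seq.start_date.year, habitat_seq.end_date.year + 1):
            try:
                winter = habitat_seq.state_on(dt.date(year, 2, 1))
                summer = habitat_seq.state_on(dt.date(year, 7, 15))
            except IndexError:
                continue
            transit = any(
                ep.entry.year == year or ep.exit.year == year for ep in episodes
            )
            if winter == LAKE_ST_CLAIR and summer == LAKE and transit:
                cycles += 1
        if cycles >= 2:
            return done("annual_interlake")

    # (3) annual winter river: fall entry, river overwinter, spring exit
    winter_eps = [
        ep
        for ep in episodes
        if in_window(ep.entry, rules.winter_entry_window)
        and in_window(ep.exit, rules.winter_exit_window)
    ]
    if len(winter_eps) >= required_annual:
        return done("annual_winter_river")

    # (4) annual summer river: spring entry persisting past spawning season
    spring_start = (3, 1)
    summer_eps = [
        ep
        for ep in episodes
        if in_window(ep.entry, (spring_start, rules.spawning_window[1]))
        and in_window(ep.exit, rules.summer_exit_window)
    ]
    if len(summer_eps) >= required_annual:
        return done("annual_summer_river")

    # (5) intermittent two-step: fall entry spanning the next spawning season
    for ep in episodes:
        if in_window(ep.entry, rules.fall_entry_window) and ep.exit >= dt.date(
            ep.entry.year + 1, *rules.spawning_window[0]
        ):
            return done("intermittent_two_step")

    # (6) spring river migrants, annual vs intermittent by periodicity
    spring_eps = [ep for ep in episodes if ep.overlaps_spawning_window]
    if spring_eps and all(
        ep.duration_days <= rules.spring_trip_max_days for ep in spring_eps
    ):
        trip_years: set[int] = set()
        for ep in spring_eps:
            trip_years |= _spawn_years(ep, rules.spawning_window)
        ratio, cls = periodicity_ratio(
            years_obs, len(trip_years), rules.periodicity_threshold
        )
        return done(f"{cls}_spring_river", ratio)

    return done(UNCLASSIFIED)


def classify_cohort(
    sequences: dict[str, tuple[DailyStateSequence, DailyStateSequence]],
    dissim=None,
    rules: RuleConfig = RuleConfig(),
    kmax: int = 10,
    benchmark: float = 0.5,
) -> tuple[list[BehaviorAssignment], dict]:
    """Classify every fish, using clustering as a recorded initial guide.

    ``sequences`` maps fish id -> (habitat sequence, regional sequence).
    When a dissimilarity matrix is supplied, the Ward tree is cut at the
    ASW-selected k and each fish's cluster id is recorded alongside its
    rule-based label; the report includes the disagreement rate between a
    cluster's majority rule-label and individual rule labels.
    """
    from .cluster import cut_tree, select_group_number, ward_tree

    assignments = [
        classify_behavior(hab, reg, rules) for hab, reg in sequences.values()
    ]
    report: dict = {"n": len(assignments), "rule_order": list(BEHAVIORS)}
    if dissim is not None:
        ids = list(getattr(dissim, "ids", sequences.keys()))
        if set(ids) != set(sequences.keys()):
            raise ValueError("dissimilarity matrix ids do not match sequences")
        try:
            selection = select_group_number(dissim, kmax=kmax, benchmark=benchmark)
            labels = cut_tree(ward_tree(dissim), selection.chosen_k)
        except ValueError as e:  # degenerate cohorts (n < 3, one group, ...)
            report["cluster_guide"] = {"error": str(e)}
        else:
            by_fish = dict(zip(ids, labels))
            for a in assignments:
                a.cluster_id = int(by_fish[a.fish_id])
            majority: dict[int, str] = {}
            for c in set(labels):
                labs = [a.behavior for a in assignments if a.cluster_id == c]
                majority[c] = max(set(labs), key=labs.count)
            disagree = sum(
                1 for a in assignments if majority[a.cluster_id] != a.behavior
            )
            report["cluster_guide"] = {
                "selection": selection.to_dict(),
                "disagreement_rate": disagree / len(assignments),
            }
    return assignments, report
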