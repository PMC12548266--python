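import datetime as dt
from functools import lru_cache

import numpy as np
import pandas as pd
import pytest

import sturseq as ss


def make_seq(labels, fish_id="f1", start=dt.date(2020, 1, 1), alphabet=None):
    """Construct a DailyStateSequence from a plain label list."""
    if alphabet is None:
        alphabet = tuple(
            sorted({x for x in labels if x not in (ss.MISSING, ss.VOID)})
        )
    return ss.DailyStateSequence(fish_id, start, np.array(labels, dtype=object), alphabet)


def om_bruteforce(a, b, cost):
    """Independent OM oracle: naive memoized edit-distance recursion."""
    a, b = list(a), list(b)

    @lru_cache(maxsize=None)
    def d(i, j):
        if i == 0 and j == 0:
            return 0.0
        opts = []
        if i > 0:
            opts.append(d(i - 1, j) + cost.indel)
        if j > 0:
            opts.append(d(i, j - 1) + cost.indel)
        if i > 0 and j > 0:
            opts.append(d(i - 1, j - 1) + cost.cost(a[i - 1], b[j - 1]))
        return min(opts)

    return d(len(a), len(b))


def random_cost_model(rng, max_states=5):
    """Random alphabet + random symmetric adjacency, geographic costs."""
    k = int(rng.integers(2, max_states + 1))
    alphabet = tuple(f"S{i}" for i in range(k))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            if rng.random() < 0.4:
                pairs.append((alphabet[i], alphabet[j]))
    return ss.build_cost_matrix(alphabet, pairs)


def random_labels(rng, cost, max_len=12, p_missing=0.15):
    n = int(rng.integers(1, max_len + 1))
    labels = [str(rng.choice(cost.alphabet)) for _ in range(n)]
    for i in range(n):
        if rng.random() < p_missing:
            labels[i] = ss.MISSING
    return labels


@pytest.fixture(scope="session")
def stations():
    return ss.default_network()


@pytest.fixture(scope="session")
def stations_df(stations):
    return pd.DataFrame(
        [
            {"receiver_id": s.receiver_id, "habitat": s.habitat, "region": s.region}
            for s in stations
        ]
    )


@pytest.fixture(scope="session")
def small_cohort(stations):
    """Noise-free 7-archetype cohort, 2 fish each, 4 years."""
    cfg = ss.SimulationConfig(n_fish_per_archetype=2, years=4, seed=7)
    detections, metadata, truth = ss.simulate_cohort(cfg, stations=stations)
    return cfg, detections, metadata, truth


@pytest.fixture(scope="session")
def small_sequences(small_cohort, stations_df):
    cfg, detections, metadata, _ = small_cohort
    timeframe = (cfg.start_date, cfg.end_date)
    events, _, _ = ss.apply_filter_cascade(detections, metadata, stations_df, timeframe)
    hab = ss.build_daily_sequences(events, stations_df, timeframe, "habitat")
    reg = ss.build_daily_sequences(events, stations_df, timeframe, "region")
    return hab, reg
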