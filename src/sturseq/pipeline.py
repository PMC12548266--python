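"""End-to-end orchestration: filters → sequences → distances → clustering →
classification → summary tables, with every stage's artifacts written to a
run directory so any downstream stage can be re-run from saved outputs.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import behavior as bh
from . import cluster as cl
from . import distance as di
from . import filters as fl
from . import sequences as sq
from . import stats as st


def default_habitat_adjacency() -> list[tuple[str, str]]:
    # rivers border both lake units; open lake and Lake St. Clair are
    # separated by connecting rivers, hence non-adjacent (cost 2)
    return [(sq.RIVER, sq.LAKE), (sq.RIVER, sq.LAKE_ST_CLAIR)]


def default_regional_adjacency() -> list[tuple[str, str]]:
    """Adjacency of the default synthetic network's regions."""
    return [("LM", "MR"), ("LSC", "DR"), ("DR", "LE")]


@dataclass
class RunConfig:
    """One reproducible analysis run."""

    detections: str | Path
    stations: str | Path
    metadata: str | Path
    population: str = "synthetic"
    timeframe: tuple[dt.date, dt.date] | None = None  # default: data extent
    habitat_adjacency: list = field(default_factory=default_habitat_adjacency)
    regional_adjacency: list = field(default_factory=default_regional_adjacency)
    rules: bh.RuleConfig = field(default_factory=bh.RuleConfig)
    kmax: int = 10
    benchmark: float = 0.5
    tf_seconds: float = 3600.0
    min_length: float = 1.0
    min_years: float = 2.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("detections", "stations", "metadata"):
            if key not in raw:
                raise ValueError(f"config missing required path {key!r}")
        if "timeframe" in raw and raw["timeframe"] is not None:
            a, b = raw["timeframe"]
            raw["timeframe"] = (dt.date.fromisoformat(str(a)), dt.date.fromisoformat(str(b)))
        if "rules" in raw and isinstance(raw["rules"], dict):
            rules = raw["rules"]
            for k, v in list(rules.items()):
                if k.endswith("window"):
                    rules[k] = tuple(tuple(x) for x in v)
                if k == "fifty_fifty_band":
                    rules[k] = tuple(v)
            raw["rules"] = bh.RuleConfig(**rules)
        for k in ("habitat_adjacency", "regional_adjacency"):
            if k in raw:
                raw[k] = [tuple(p) for p in raw[k]]
        return cls(**raw)


def _read_events(path: str | Path) -> pd.DataFrame:
    ev = pd.read_csv(path)
    ev["timestamp"] = pd.to_datetime(ev["timestamp"], utc=True)
    return ev


def _read_meta(path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(path)
    meta["tagging_date"] = pd.to_datetime(meta["tagging_date"]).dt.date
    return meta


def stage_filter(cfg: RunConfig, out: Path) -> None:
    events = _read_events(cfg.detections)
    stations = pd.read_csv(cfg.stations)
    meta = _read_meta(cfg.metadata)
    timeframe = cfg.timeframe
    if timeframe is None:
        days = events["timestamp"].dt.date
        timeframe = (days.min(), days.max())
    ev, fish, reports = fl.apply_filter_cascade(
        events,
        meta,
        stations,
        timeframe,
        tf_seconds=cfg.tf_seconds,
        min_length=cfg.min_length,
        min_years=cfg.min_years,
        spawning_window=cfg.rules.spawning_window,
    )
    ev.to_csv(out / "filtered_detections.csv", index=False)
    (out / "filter_reports.json").write_text(
        json.dumps([r.to_dict() for r in reports], indent=2)
    )
    (out / "timeframe.json").write_text(
        json.dumps({"start": timeframe[0].isoformat(), "end": timeframe[1].isoformat()})
    )


def _load_timeframe(out: Path) -> tuple[dt.date, dt.date]:
    tfr = json.loads((out / "timeframe.json").read_text())
    return dt.date.fromisoformat(tfr["start"]), dt.date.fromisoformat(tfr["end"])


def stage_sequences(cfg: RunConfig, out: Path) -> None:
    ev = _read_events(out / "filtered_detections.csv")
    stations = pd.read_csv(cfg.stations)
    timeframe = _load_timeframe(out)
    alphabets = {}
    for level in ("habitat", "region"):
        seqs = sq.build_daily_sequences(ev, stations, timeframe, level)
        wide = sq.sequences_to_wide(seqs)
        wide.to_csv(out / f"sequences_{level}.csv")
        alphabets[level] = list(next(iter(seqs.values())).alphabet)
    (out / "alphabets.json").write_text(json.dumps(alphabets, indent=2))


def _load_sequences(out: Path, level: str) -> dict[str, sq.DailyStateSequence]:
    alphabets = json.loads((out / "alphabets.json").read_text())
    wide = pd.read_csv(out / f"sequences_{level}.csv", index_col=0, dtype=str)
    return sq.wide_to_sequences(wide, tuple(alphabets[level]))


def stage_distances(cfg: RunConfig, out: Path) -> None:
    alphabets = json.loads((out / "alphabets.json").read_text())
    seqs = _load_sequences(out, "habitat")
    adj = [p for p in cfg.habitat_adjacency if set(p) <= set(alphabets["habitat"])]
    cost = di.build_cost_matrix(alphabets["habitat"], adj)
    mat = di.dissimilarity_matrix(seqs, cost)
    mat.to_dataframe().to_csv(out / "dissimilarity_habitat.csv")


def stage_cluster(cfg: RunConfig, out: Path) -> None:
    mat = di.DissimilarityMatrix.from_dataframe(
        pd.read_csv(out / "dissimilarity_habitat.csv", index_col=0)
    )
    selection = cl.select_group_number(mat, kmax=cfg.kmax, benchmark=cfg.benchmark)
    labels = cl.cut_tree(cl.ward_tree(mat), selection.chosen_k)
    (out / "group_selection.json").write_text(json.dumps(selection.to_dict(), indent=2))
    pd.DataFrame({"fish_id": mat.ids, "cluster_id": labels}).to_csv(
        out / "cluster_labels.csv", index=False
    )


def stage_classify(cfg: RunConfig, out: Path) -> None:
    hab = _load_sequences(out, "habitat")
    reg = _load_sequences(out, "region")
    mat_path = out / "dissimilarity_habitat.csv"
    mat = (
        di.DissimilarityMatrix.from_dataframe(pd.read_csv(mat_path, index_col=0))
        if mat_path.exists()
        else None
    )
    pairs = {fid: (hab[fid], reg[fid]) for fid in hab}
    assignments, report = bh.classify_cohort(
        pairs, mat, cfg.rules, kmax=cfg.kmax, benchmark=cfg.benchmark
    )
    rows = []
    for a in assignments:
        sig = st.route_signature(reg[a.fish_id], a.behavior)
        rows.append(
            {
                "fish_id": a.fish_id,
                "population": cfg.population,
                "behavior": a.behavior,
                "periodicity_ratio": a.periodicity_ratio,
                "lake_residency": a.lake_residency,
                "residency_class": a.residency_class,
                "cluster_id": a.cluster_id,
                "signature": sig,
            }
        )
    pd.DataFrame(rows).to_csv(out / "assignments.csv", index=False)
    (out / "classification_report.json").write_text(json.dumps(report, indent=2))


def stage_report(cfg: RunConfig, out: Path) -> None:
    assignments = pd.read_csv(out / "assignments.csv")
    freq = st.behavior_frequency_table(assignments)
    freq.formatted().to_csv(out / "frequency_table.csv")
    contingents, totals = st.tabulate_contingents(assignments)
    contingents.to_csv(out / "contingents.csv", index=False)
    residency = st.lake_residency_summary(assignments)
    residency.to_csv(out / "residency_summary.csv", index=False)
    report = {
        "population": cfg.population,
        "n_classified": int(freq.grand_total),
        "behavior_totals": {str(k): int(v) for k, v in freq.row_totals.items()},
        "n_contingents": {str(k): int(v) for k, v in totals.items()},
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))


STAGES = {
    "filter": stage_filter,
    "sequences": stage_sequences,
    "distances": stage_distances,
    "cluster": stage_cluster,
    "classify": stage_classify,
    "report": stage_report,
}


def run_pipeline(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage in order, writing all artifacts under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {
        "population": cfg.population,
        "seed": cfg.seed,
        "kmax": cfg.kmax,
        "benchmark": cfg.benchmark,
        "tf_seconds": cfg.tf_seconds,
        "min_length": cfg.min_length,
        "min_years": cfg.min_years,
        "rules": asdict(cfg.rules),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    for name, stage in STAGES.items():
        try:
            stage(cfg, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
    return out
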