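"""End-to-end orchestration of the simulation and analysis stages.

A run directory holds one subdirectory per protocol day plus pooled
outputs and a manifest recording the config hash, seed, package version and
per-file checksums.  Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import fearscope
from fearscope import behavior as beh
from fearscope import classify as cls
from fearscope import io
from fearscope import population as pop
from fearscope import state as st
from fearscope import stats as fstats
from fearscope import synthetic as syn
from fearscope.core import DataError, DependencyError, EventSeries

STAGES = ("simulate", "deconvolve", "behavior", "classify", "state", "population", "stats")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "days": ["habituation", "training", "recall"],
    "behavior": {},
    "population": {"n_neurons": 30, "n_us_responders": 4, "n_cs_responders": 3,
                   "n_movon_responders": 3},
    "classification": {"exclusion_window": cls.EXCLUSION_WINDOW},
    "state": {"exclude_us": True},
    "stages": {name: True for name in STAGES},
}


def config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def merge_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    merged["days"] = list(DEFAULT_CONFIG["days"])
    for key, value in (config or {}).items():
        if isinstance(value, dict) and isinstance(merged.get(key), dict):
            merged[key].update(value)
        else:
            merged[key] = value
    return merged


@dataclass
class RunPaths:
    root: Path

    def day_dir(self, day: str) -> Path:
        return self.root / f"day_{day}"

    def require(self, path: Path, stage: str) -> Path:
        if not path.exists():
            raise DependencyError(
                f"stage {stage!r} requires missing file {path.name}; "
                "run the upstream stage first"
            )
        return path


def _day_seed(base_seed: int, day: str, offset: int) -> int:
    return base_seed * 1000 + STAGES.index("simulate") + offset + list(syn.DAY_KINDS).index(day) * 10


def stage_simulate(paths: RunPaths, config: dict) -> None:
    seed = int(config["seed"])
    for day in config["days"]:
        day_dir = paths.day_dir(day)
        day_dir.mkdir(parents=True, exist_ok=True)
        schedule = syn.build_schedule(day, seed=_day_seed(seed, day, 1))
        bspec = syn.BehaviorSpec(seed=_day_seed(seed, day, 2), **config["behavior"])
        sim_beh = syn.simulate_behavior(schedule, bspec)
        pspec = syn.PopulationSpec(seed=_day_seed(seed, day, 3), **config["population"])
        traceset, truth = syn.simulate_population(schedule, sim_beh, pspec)

        io.write_schedule(day_dir / "schedule.csv", schedule)
        io.write_behavior(
            day_dir / "behavior_raw.csv", sim_beh.movement_index, None, bspec.frame_rate
        )
        io.write_traceset(day_dir / "traces.h5", traceset)
        io.write_json(
            day_dir / "ground_truth.json",
            {
                "counts": truth.counts(),
                "us_responder": truth.us_responder.tolist(),
                "cs_responder": truth.cs_responder.tolist(),
                "movon_responder": truth.movon_responder.tolist(),
                "duplicate_map": {str(k): v for k, v in truth.duplicate_map.items()},
            },
        )


def stage_deconvolve(paths: RunPaths, config: dict) -> None:
    from fearscope.deconvolution import deconvolve_ar1

    for day in config["days"]:
        day_dir = paths.day_dir(day)
        traceset = io.read_traceset(paths.require(day_dir / "traces.h5", "deconvolve"))
        rows = []
        for i in range(traceset.n_neurons):
            result = deconvolve_ar1(traceset.traces[i], rate=traceset.rate)
            for t, a in zip(result.event_times, result.event_amplitudes):
                rows.append(
                    {
                        "neuron": int(traceset.neuron_ids[i]),
                        "time_s": t,
                        "amplitude_sigma": a,
                    }
                )
        table = pd.DataFrame(rows, columns=list(EventSeries.COLUMNS))
        io.write_events(day_dir / "events.csv", EventSeries(table) if len(table) else EventSeries.empty())


def stage_behavior(paths: RunPaths, config: dict) -> None:
    for day in config["days"]:
        day_dir = paths.day_dir(day)
        raw = io.read_behavior(paths.require(day_dir / "behavior_raw.csv", "behavior"))
        frame_rate = 1.0 / float(raw["time_s"].diff().median())
        freezing = beh.detect_freezing(
            raw["movement_index"].to_numpy(), frame_rate=frame_rate
        )
        io.write_behavior(
            day_dir / "behavior.csv",
            raw["movement_index"].to_numpy(),
            freezing,
            frame_rate,
        )
        schedule = io.read_schedule(day_dir / "schedule.csv")
        epochs = beh.build_epochs(schedule)
        epochs.to_frame().to_csv(day_dir / "epochs.csv", index=False)
        pct = beh.percent_freezing(freezing, frame_rate=frame_rate)
        pd.DataFrame(
            {"bin_start_s": np.arange(pct.size) * beh.PERCENT_FREEZING_BIN,
             "percent_freezing": pct}
        ).to_csv(day_dir / "percent_freezing.csv", index=False)


def stage_classify(paths: RunPaths, config: dict) -> None:
    from fearscope.deconvolution import zscore_trace

    all_tables = []
    for day in config["days"]:
        day_dir = paths.day_dir(day)
        traceset = io.read_traceset(paths.require(day_dir / "traces.h5", "classify"))
        behavior_csv = io.read_behavior(paths.require(day_dir / "behavior.csv", "classify"))
        schedule = io.read_schedule(paths.require(day_dir / "schedule.csv", "classify"))

        deduped, removed = cls.remove_duplicates(traceset)
        frame_rate = 1.0 / float(behavior_csv["time_s"].diff().median())
        freezing = behavior_csv["freezing"].to_numpy()
        movons = beh.movement_on_events(freezing, frame_rate)
        w = float(config["classification"].get("exclusion_window", cls.EXCLUSION_WINDOW))
        clean_beeps, clean_movons, fractions = cls.exclude_confounded(
            schedule.beep_onsets, movons, w
        )
        in_block = np.zeros(clean_movons.size, dtype=bool)
        for s, e in schedule.block_intervals:
            in_block |= (clean_movons >= s) & (clean_movons < e)

        z = np.vstack([zscore_trace(tr) for tr in deduped.traces])
        aligned = []
        kinds = [("CS_beep", clean_beeps),
                 ("movON_CS", clean_movons[in_block]),
                 ("movON_noCS", clean_movons[~in_block])]
        if schedule.us_onsets.size:
            kinds.insert(0, ("US", schedule.us_onsets))
        for kind, times in kinds:
            if times.size == 0:
                continue
            aligned.extend(
                cls.align_events(
                    z, deduped.rate, times, event_kind=kind,
                    neuron_ids=deduped.neuron_ids,
                )
            )
        table = cls.classify_responders(aligned, day=day)
        table.to_csv(day_dir / "responders.csv", index=False)
        io.write_json(
            day_dir / "exclusions.json",
            {"removed_duplicates": removed.tolist(), "excluded_fractions": fractions},
        )
        all_tables.append(table)
    pd.concat(all_tables, ignore_index=True).to_csv(
        paths.root / "responders_all_days.csv", index=False
    )


def stage_state(paths: RunPaths, config: dict) -> None:
    frames = []
    for day in config["days"]:
        day_dir = paths.day_dir(day)
        schedule = io.read_schedule(paths.require(day_dir / "schedule.csv", "state"))
        behavior_csv = io.read_behavior(paths.require(day_dir / "behavior.csv", "state"))
        events = io.read_events(paths.require(day_dir / "events.csv", "state"))
        frame_rate = 1.0 / float(behavior_csv["time_s"].diff().median())
        labels = st.label_state_intervals(
            behavior_csv["freezing"].to_numpy(),
            frame_rate,
            schedule,
            exclude_us=bool(config["state"].get("exclude_us", True)),
        )
        activity = st.amplitude_weighted_frequency(events, labels)
        activity.insert(1, "day", day)
        activity.to_csv(day_dir / "state_activity.csv", index=False)
        frames.append(activity)
    pd.concat(frames, ignore_index=True).to_csv(
        paths.root / "state_activity_all_days.csv", index=False
    )


def stage_population(paths: RunPaths, config: dict) -> None:
    table_path = paths.require(paths.root / "responders_all_days.csv", "population")
    table = pd.read_csv(table_path)
    fractions = pop.fractions_by_day(table)
    fractions.to_csv(paths.root / "fractions_by_day.csv", index=False)
    if "training" in set(table["day"]):
        counts = pop.overlap_counts(table, "training")
        io.write_json(paths.root / "overlap_training.json", counts)


def stage_stats(paths: RunPaths, config: dict) -> None:
    fractions = pd.read_csv(
        paths.require(paths.root / "fractions_by_day.csv", "stats")
    )
    results: dict = {}
    tone = fractions[fractions["kind"] == "CS_beep"].sort_values("day")
    if len(tone) >= 2:
        contingency = np.column_stack(
            [tone["n_responders"], tone["n_total"] - tone["n_responders"]]
        )
        try:
            res = fstats.chi_square_independence(contingency)
            results["tone_responders_chi2"] = {
                "statistic": res.statistic, "p_value": res.p_value, "df": res.df,
            }
        except (fstats.DegenerateInputError, ValueError) as exc:
            results["tone_responders_chi2"] = {"error": str(exc)}

    activity = pd.read_csv(
        paths.require(paths.root / "state_activity_all_days.csv", "stats")
    )
    groups = [
        grp["freq_sigma_per_s"].dropna().to_numpy()
        for _, grp in activity.groupby(["day", "state"], observed=True)
    ]
    groups = [g for g in groups if g.size]
    if len(groups) >= 2:
        try:
            kw = fstats.kruskal_wallis(*groups)
            results["state_activity_kw"] = {
                "statistic": kw.statistic, "p_value": kw.p_value, "df": kw.df,
            }
        except fstats.DegenerateInputError as exc:
            results["state_activity_kw"] = {"error": str(exc)}
    io.write_json(paths.root / "stats_summary.json", results)


STAGE_FUNCTIONS = {
    "simulate": stage_simulate,
    "deconvolve": stage_deconvolve,
    "behavior": stage_behavior,
    "classify": stage_classify,
    "state": stage_state,
    "population": stage_population,
    "stats": stage_stats,
}


def run_pipeline(config: dict | None, outdir) -> Path:
    """Run the enabled stages in order; returns the run directory.

    The manifest lists the config hash, seed, package version, completed
    stages and a sha256 checksum per output file.
    """
    config = merge_config(config)
    unknown = set(config.get("stages", {})) - set(STAGES)
    if unknown:
        raise DataError(f"unknown stages in config: {sorted(unknown)}")
    for day in config["days"]:
        if day not in syn.DAY_KINDS:
            raise DataError(f"unknown day kind {day!r}")
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    paths = RunPaths(root)

    completed = []
    for stage in STAGES:
        if not config["stages"].get(stage, True):
            continue
        STAGE_FUNCTIONS[stage](paths, config)
        completed.append(stage)

    checksums = {}
    for path in sorted(root.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            checksums[str(path.relative_to(root))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    io.write_json(
        root / "manifest.json",
        {
            "config_hash": config_hash(config),
            "seed": config["seed"],
            "version": fearscope.__version__,
            "stages": completed,
            "checksums": checksums,
        },
    )
    return root
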