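"""End-to-end study orchestration: simulate → detect → spectra → stats.

:func:`run_study` reproduces the analysis workflow of a three-group
(kindle / LFSK / KLFS) kindling study on synthetic sessions:

1. per-animal 7 s baselines, decomposed into LFB/MFB/HFB fractions and
   compared across groups (one-way ANOVA per band);
2. one session per group with the profile's event counts; ADs detected by
   the 2.5× / 6 s rule, matched to annotations, and reduced to band powers;
3. per-phase fraction tables with one-way ANOVA + Bonferroni post hoc
   (generalized-stage statistics only when every group has enough events —
   descriptive otherwise, as small unbalanced cells make the tests
   unreliable);
4. per-sub-band two-way (group × phase) ANOVA including the theta/alpha
   ratio;
5. Pearson correlations between AD duration and aggregate band powers, for
   the kindle group and for the pooled LFS-treated (LFSK + KLFS) animals.

Everything is deterministic for a fixed seed.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .addetect import baseline_stats, detect_ad_events, label_segments
from .exceptions import ConfigurationError, DegenerateInputError
from .groupstats import (
    StatResult,
    bonferroni_pairwise,
    one_way_anova,
    pearson_r,
    two_way_anova,
)
from .records import PHASES
from .spectral import AGGREGATES, DEFAULT_BANDS, SUB_BANDS, band_fractions, welch_psd
from .synthgen import DEFAULT_PROFILES, GroupProfile, PhaseProfile, SimConfig, generate_baseline, simulate_session

log = logging.getLogger("kindleeg")

GROUP_ORDER = ("Kindle", "LFSK", "KLFS")


@dataclass
class StudyConfig:
    """One self-contained study description (simulator + analysis knobs)."""

    sim: SimConfig = field(default_factory=SimConfig)
    profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    detect_ratio: float = 2.5
    min_duration: float = 6.0
    gss_min_events: int = 3
    # statistics on individual events, or on per-animal phase means; the
    # choice changes the error degrees of freedom and is deliberately exposed
    aggregation: str = "per_event"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.aggregation not in ("per_event", "per_animal"):
            raise ConfigurationError("aggregation must be 'per_event' or 'per_animal'")

    def to_yaml(self) -> str:
        doc = {
            "seed": self.seed,
            "detect_ratio": self.detect_ratio,
            "min_duration": self.min_duration,
            "gss_min_events": self.gss_min_events,
            "aggregation": self.aggregation,
            "sim": dataclasses.asdict(self.sim),
            "profiles": {
                label: {
                    "n_animals": prof.n_animals,
                    "phases": {
                        ph: {
                            "target_fractions": list(entry.target_fractions),
                            "add_mean": entry.add_mean,
                            "add_sd": entry.add_sd,
                            "event_count": entry.event_count,
                        }
                        for ph, entry in prof.phases.items()
                    },
                }
                for label, prof in self.profiles.items()
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "StudyConfig":
        doc = yaml.safe_load(text)
        if not isinstance(doc, dict):
            raise ConfigurationError("study config YAML must be a mapping")
        sim = SimConfig(**doc.get("sim", {}))
        profiles = {}
        for label, p in doc.get("profiles", {}).items():
            profiles[label] = GroupProfile(
                group_label=label,
                n_animals=int(p.get("n_animals", 6)),
                phases={
                    ph: PhaseProfile(
                        target_fractions=tuple(e["target_fractions"]),
                        add_mean=float(e["add_mean"]),
                        add_sd=float(e["add_sd"]),
                        event_count=int(e["event_count"]),
                    )
                    for ph, e in p["phases"].items()
                },
            )
        if not profiles:
            profiles = dict(DEFAULT_PROFILES)
        return cls(
            sim=sim,
            profiles=profiles,
            detect_ratio=float(doc.get("detect_ratio", 2.5)),
            min_duration=float(doc.get("min_duration", 6.0)),
            gss_min_events=int(doc.get("gss_min_events", 3)),
            aggregation=str(doc.get("aggregation", "per_event")),
            seed=int(doc.get("seed", 0)),
        )


@dataclass
class StudyReport:
    """All study outputs in memory; see :func:`write_report` for files."""

    events: pd.DataFrame
    baseline: pd.DataFrame
    baseline_stats: dict
    phase_tables: dict
    phase_stats: dict
    twoway: dict
    correlations: pd.DataFrame
    counts: pd.DataFrame
    misses: dict
    seed: int
    config_yaml: str


def _stat_to_dict(res) -> dict | None:
    if res is None:
        return None
    d = {
        "test": res.test_name,
        "statistic": res.statistic,
        "df": list(res.df) if isinstance(res.df, tuple) else res.df,
        "p_value": res.p_value,
        "labels": list(res.group_labels),
    }
    if res.p_raw is not None:
        d["p_raw"] = res.p_raw
    if res.flag:
        d["flag"] = res.flag
    return d


def _analyze_segments(record, annotations, config: StudyConfig) -> tuple[pd.DataFrame, int]:
    """Detect, label and spectrally decompose one session; rows per matched AD."""
    base = baseline_stats(record, window=config.sim.baseline_duration)
    events = detect_ad_events(
        record, base, ratio=config.detect_ratio, min_duration=config.min_duration
    )
    segments = label_segments(events, annotations)
    rows = []
    for seg in segments:
        if not seg.matched:
            continue
        cut = record.slice_seconds(seg.onset, seg.add)
        fr = band_fractions(welch_psd(cut), DEFAULT_BANDS)
        row = {
            "group": seg.group,
            "animal_id": seg.animal_id,
            "racine_stage": seg.racine_stage,
            "phase": seg.phase,
            "onset_s": seg.onset,
            "add_s": seg.add,
            "theta_alpha_ratio": fr.theta_alpha_ratio,
        }
        for name in SUB_BANDS + AGGREGATES:
            row[f"frac_{name}"] = fr.fraction[name]
            row[f"power_{name}"] = fr.absolute[name]
        rows.append(row)
    misses = len(annotations) - sum(1 for s in segments if s.matched)
    return pd.DataFrame(rows), misses


def run_study(config: StudyConfig | None = None) -> StudyReport:
    """Run the full simulated study; deterministic for a fixed seed."""
    config = StudyConfig() if config is None else config
    t0 = time.time()
    group_labels = [g for g in GROUP_ORDER if g in config.profiles] + [
        g for g in config.profiles if g not in GROUP_ORDER
    ]
    seeds = np.random.SeedSequence(config.seed).spawn(len(group_labels) + 1)
    baseline_rows = []
    event_frames = []
    misses: dict = {}

    # per-animal baselines (one stream for all groups keeps them exchangeable:
    # no group effect is built into baseline activity)
    base_rng = np.random.default_rng(seeds[0])
    for label in group_labels:
        prof = config.profiles[label]
        for i in range(prof.n_animals):
            rec = generate_baseline(config.sim, rng=base_rng)
            fr = band_fractions(welch_psd(rec), DEFAULT_BANDS)
            row = {"group": label, "animal_id": f"{label}-{i + 1:02d}"}
            row.update({name: fr.fraction[name] for name in AGGREGATES})
            baseline_rows.append(row)

    for label, seed_seq in zip(group_labels, seeds[1:]):
        prof = config.profiles[label]
        session_seed = int(seed_seq.generate_state(1)[0] % (2**31))
        record, annotations = simulate_session(prof, config=config.sim, seed=session_seed)
        frame, n_missed = _analyze_segments(record, annotations, config)
        event_frames.append(frame)
        misses[label] = n_missed
        log.info(
            "group %s: %d annotated, %d analyzed, %d missed (%.1f s elapsed)",
            label, len(annotations), len(frame), n_missed, time.time() - t0,
        )

    event_columns = (
        ["group", "animal_id", "racine_stage", "phase", "onset_s", "add_s", "theta_alpha_ratio"]
        + [f"{kind}_{name}" for name in SUB_BANDS + AGGREGATES for kind in ("frac", "power")]
    )
    nonempty = [f for f in event_frames if len(f)]
    events = (
        pd.concat(nonempty, ignore_index=True)
        if nonempty
        else pd.DataFrame(columns=event_columns)
    )
    baseline = pd.DataFrame(baseline_rows, columns=["group", "animal_id", *AGGREGATES])

    # statistics frame: raw events, or per-animal phase means
    if config.aggregation == "per_animal" and len(events):
        numeric = [c for c in events.columns
                   if c not in ("group", "animal_id", "phase", "racine_stage", "onset_s")]
        stats_events = events.groupby(
            ["group", "animal_id", "phase"], as_index=False, sort=True
        )[numeric].mean()
    else:
        stats_events = events

    # baseline band comparison across groups
    baseline_results = {}
    for name in AGGREGATES:
        groups = [baseline.loc[baseline.group == g, name].to_numpy() for g in group_labels]
        if all(len(g) >= 2 for g in groups) and len(groups) >= 2:
            baseline_results[name] = one_way_anova(groups, labels=group_labels)

    # per-phase fraction tables + stats
    phase_tables: dict = {}
    phase_stats: dict = {}
    for phase in PHASES:
        sub = stats_events[stats_events.phase == phase]
        raw_sub = events[events.phase == phase] if len(events) else events
        rows = []
        for label in group_labels:
            cell = sub[sub.group == label]
            n_raw = int((raw_sub.group == label).sum()) if len(raw_sub) else 0
            for name in AGGREGATES:
                vals = cell[f"frac_{name}"].to_numpy() if len(cell) else np.array([])
                rows.append(
                    {
                        "phase": phase,
                        "band": name,
                        "group": label,
                        "n_events": n_raw,
                        "mean": float(vals.mean()) if vals.size else np.nan,
                        "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
                        "add_mean": float(cell["add_s"].mean()) if len(cell) else np.nan,
                    }
                )
        table = pd.DataFrame(rows, columns=["phase", "band", "group", "n_events", "mean", "sd", "add_mean"])
        phase_tables[phase] = table
        if len(group_labels) < 2:
            phase_stats[phase] = {"skipped": "fewer than two groups"}
            continue
        counts_ok = len(raw_sub) > 0 and all(
            (raw_sub.group == g).sum() >= config.gss_min_events for g in group_labels
        )
        if phase == "GSS" and not counts_ok:
            phase_stats[phase] = {"skipped": "insufficient events for reliable statistics"}
            log.warning("phase GSS: statistics skipped (sparse unbalanced cells)")
            continue
        stats_for_phase = {}
        for name in AGGREGATES:
            groups = [
                sub.loc[sub.group == g, f"frac_{name}"].to_numpy() for g in group_labels
            ]
            if any(len(g) < 2 for g in groups):
                stats_for_phase[name] = {"skipped": "empty or singleton cell"}
                continue
            omnibus = one_way_anova(groups, labels=group_labels)
            posthoc = bonferroni_pairwise(groups, labels=group_labels)
            stats_for_phase[name] = {
                "anova": _stat_to_dict(omnibus),
                "posthoc": [_stat_to_dict(r) for r in posthoc],
            }
        phase_stats[phase] = stats_for_phase

    # two-way group x phase ANOVA per sub-band and theta/alpha ratio
    twoway: dict = {}
    se = stats_events
    if len(se) and se.group.nunique() >= 2 and se.phase.nunique() >= 2:
        for name in SUB_BANDS:
            res = two_way_anova(se[f"frac_{name}"], se.group, se.phase)
            twoway[name] = {k: _stat_to_dict(v) for k, v in res.items()}
        res = two_way_anova(se["theta_alpha_ratio"], se.group, se.phase)
        twoway["theta_alpha"] = {k: _stat_to_dict(v) for k, v in res.items()}

    # ADD vs band-power correlations, kindle vs pooled LFS-treated
    corr_rows = []
    pools = [("Kindle", ["Kindle"]), ("LFS-treated", ["LFSK", "KLFS"])]
    for pool_label, members in pools:
        sub = stats_events[stats_events.group.isin(members)]
        for phase in PHASES:
            cell = sub[sub.phase == phase] if len(sub) else sub
            for name in AGGREGATES:
                row = {
                    "pool": pool_label,
                    "phase": phase,
                    "band": name,
                    "n": int(len(cell)),
                    "r": np.nan,
                    "p_value": np.nan,
                }
                if len(cell) >= 3:
                    try:
                        res = pearson_r(cell["add_s"], cell[f"power_{name}"])
                        row["r"], row["p_value"] = res.r, res.p_value
                    except DegenerateInputError:
                        pass
                corr_rows.append(row)
    correlations = pd.DataFrame(
        corr_rows, columns=["pool", "phase", "band", "n", "r", "p_value"]
    )

    counts = (
        events.groupby(["group", "phase"], sort=True).size().rename("n_events").reset_index()
        if len(events)
        else pd.DataFrame(columns=["group", "phase", "n_events"])
    )
    log.info("study complete in %.1f s", time.time() - t0)
    return StudyReport(
        events=events,
        baseline=baseline,
        baseline_stats={k: _stat_to_dict(v) for k, v in baseline_results.items()},
        phase_tables=phase_tables,
        phase_stats=phase_stats,
        twoway=twoway,
        correlations=correlations,
        counts=counts,
        misses=misses,
        seed=config.seed,
        config_yaml=config.to_yaml(),
    )


@dataclass
class CellRecovery:
    """Pipeline-recovered summary of one simulated group × phase cell."""

    group: str
    phase: str
    n_scheduled: int
    n_detected: int
    mean_fractions: dict
    mean_add: float


def recover_phase_cell(
    group: str = "Kindle",
    phase: str = "ISS",
    n_events: int = 61,
    seed: int = 0,
    config: SimConfig | None = None,
    add_sd: float | None = None,
) -> CellRecovery:
    """Closed-loop recovery of one cell: simulate → detect → band fractions.

    Builds a single-phase session from the default calibration for ``group``
    (optionally overriding the AD-duration SD), runs the detector and the
    spectral decomposition, and returns the mean recovered LFB/MFB/HFB
    fractions and the mean detected AD duration.
    """
    config = SimConfig() if config is None else config
    base_profile = DEFAULT_PROFILES[group]
    entry = base_profile.phases[phase]
    cell_entry = PhaseProfile(
        target_fractions=entry.target_fractions,
        add_mean=entry.add_mean,
        add_sd=entry.add_sd if add_sd is None else add_sd,
        event_count=n_events,
    )
    profile = GroupProfile(
        group_label=group, phases={phase: cell_entry}, n_animals=base_profile.n_animals
    )
    record, annotations = simulate_session(profile, config=config, seed=seed)
    base = baseline_stats(record, window=config.baseline_duration)
    detected = detect_ad_events(record, base)
    segments = [s for s in label_segments(detected, annotations) if s.matched]
    fracs = []
    adds = []
    for seg in segments:
        cut = record.slice_seconds(seg.onset, seg.add)
        fr = band_fractions(welch_psd(cut), DEFAULT_BANDS)
        fracs.append([fr.fraction[name] for name in AGGREGATES])
        adds.append(seg.add)
    mean_fracs = dict(zip(AGGREGATES, np.mean(fracs, axis=0))) if fracs else {}
    return CellRecovery(
        group=group,
        phase=phase,
        n_scheduled=len(annotations),
        n_detected=len(segments),
        mean_fractions={k: float(v) for k, v in mean_fracs.items()},
        mean_add=float(np.mean(adds)) if adds else float("nan"),
    )


def write_report(report: StudyReport, out_dir) -> list[Path]:
    """Write the report as TSV tables, a JSON stats bundle and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    def _tsv(frame: pd.DataFrame, name: str):
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        written.append(path)

    _tsv(report.events, "events.tsv")
    _tsv(report.baseline, "baseline_fractions.tsv")
    for phase, table in report.phase_tables.items():
        _tsv(table, f"fractions_{phase}.tsv")
    _tsv(report.correlations, "correlations.tsv")
    _tsv(report.counts, "event_counts.tsv")

    stats_bundle = {
        "baseline": report.baseline_stats,
        "phase": report.phase_stats,
        "two_way": report.twoway,
        "misses": report.misses,
    }
    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(stats_bundle, indent=1, sort_keys=True) + "\n")
    written.append(stats_path)

    manifest = {
        "seed": report.seed,
        "config_sha256": hashlib.sha256(report.config_yaml.encode()).hexdigest(),
        "kindleeg_version": __version__,
        "numpy_version": np.__version__,
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    written.append(manifest_path)
    config_path = out / "config.yaml"
    config_path.write_text(report.config_yaml)
    written.append(config_path)
    return written
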