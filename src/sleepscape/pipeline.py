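"""Configuration-driven end-to-end orchestration.

``run_pipeline`` drives: (simulated or loaded) sleep/wake series -> bout
smoothing -> noon-to-noon segmentation and the record-inclusion filter ->
daily window metrics and rhythm indexes -> 21-index table -> divisive
embedding/density clustering with Ward regrouping -> percentile outlier
branch -> artifacts (CSV tables, JSON tree and report).  Every artifact
carries the configuration hash so mismatched stages are detectable, and the
whole run is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as aio
from . import landscape, rhythm, scoring, simulate, windows
from .series import SleepWakeSeries
from .windows import INDEX_NAMES

log = logging.getLogger("sleepscape")


@dataclass
class PipelineConfig:
    """All numeric thresholds and stage parameters of the pipeline."""

    epoch_len: int = 30  # s
    min_bout: float = 10.0  # min, bout-smoothing threshold
    max_gap: float = 60.0  # min, window-merging gap
    long_short_threshold: float = 3.75  # h
    max_nonwear: float = 5.0  # h per noon-to-noon day
    min_consecutive_days: int = 4
    max_days: int = 7
    bin_len: float = 10.0  # min, wake binning
    period_min: float = 5.0  # h
    period_max: float = 35.0  # h
    alpha: float = 0.01  # periodogram significance level
    mu: float = 1.0  # van der Pol damping
    phase_grid_min: float = 1.0  # min, phase shift-search resolution
    pct: float = 2.28  # outlier percentile
    min_child_size: int = 20
    max_depth: int = 3
    ward_groups: int = 2
    embed_method: str = "umap"
    n_neighbors: int = 50
    min_dist: float = 0.0
    eps: object = "auto"  # DBSCAN radius; "auto" = k-distance heuristic
    min_samples: int = 20
    seed: int = 0
    outlier_indexes: list = field(default_factory=lambda: list(landscape.DEFAULT_OUTLIER_INDEXES))

    def __post_init__(self) -> None:
        checks = [
            self.epoch_len > 0,
            self.min_bout >= 0,
            self.max_gap >= 0,
            self.long_short_threshold > 0,
            0 < self.max_nonwear <= 24,
            self.min_consecutive_days >= 1,
            self.max_days >= self.min_consecutive_days,
            5.0 <= self.period_min < self.period_max <= 35.0,
            0 < self.alpha < 1,
            self.mu > 0,
            0 < self.pct <= 50,
            self.min_child_size >= 2,
            self.max_depth >= 1,
        ]
        if not all(checks):
            raise ValueError("configuration value outside its documented domain")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """Per-stage record counts plus provenance of one pipeline run."""

    counts: dict
    config_hash: str
    seed: int
    wall_time_s: float

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "counts": self.counts,
                "config_hash": self.config_hash,
                "seed": self.seed,
                "wall_time_s": round(self.wall_time_s, 3),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def extract_indexes(series: SleepWakeSeries, config: PipelineConfig) -> windows.SleepIndexVector | None:
    """One subject: smooth, segment, filter, and compute the 21 indexes.

    Returns None when the record fails the inclusion filter (no run of
    ``min_consecutive_days`` consecutive days with nonwear below the cap).
    """
    smoothed = scoring.smooth_series(series, config.min_bout)
    days = aio.segment_noon_days(smoothed, max_nonwear=config.max_nonwear)
    span = aio.select_valid_span(
        days, config.max_nonwear, config.min_consecutive_days, config.max_days
    )
    if not span:
        return None
    selected = [d for d in days if d.day_index in set(span)]
    wins = windows.label_windows(
        windows.build_windows(smoothed, config.max_gap), config.long_short_threshold
    )
    daily = [windows.daily_metrics(d, wins, smoothed) for d in selected]
    rr = rhythm.rhythm_summary(
        smoothed,
        selected,
        bin_len=config.bin_len,
        p_min=config.period_min,
        p_max=config.period_max,
        alpha=config.alpha,
        mu=config.mu,
        grid_min=config.phase_grid_min,
    )
    return windows.compute_index_vector(daily, rr)


def build_index_table(
    series_list: list[SleepWakeSeries],
    config: PipelineConfig,
    subject_ids: list | None = None,
) -> tuple[pd.DataFrame, list]:
    """Index vectors for a cohort; returns (table, ids of excluded subjects)."""
    ids = subject_ids or [f"s{i:05d}" for i in range(len(series_list))]
    rows, excluded = {}, []
    for sid, sw in zip(ids, series_list):
        vec = extract_indexes(sw, config)
        if vec is None:
            excluded.append(sid)
        else:
            rows[sid] = vec.to_series()
    table = pd.DataFrame(rows).T
    if not table.empty:
        table = table[INDEX_NAMES]
    table.index.name = "subject_id"
    return table, excluded


def _write_csv_with_hash(df: pd.DataFrame, path: Path, config_hash: str, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=index)


def read_artifact_csv(path, expected_hash: str | None = None, **kwargs) -> pd.DataFrame:
    """Read a pipeline CSV artifact, warning on a config-hash mismatch."""
    with open(path) as fh:
        first = fh.readline()
    skip = 0
    if first.startswith("# config_hash="):
        skip = 1
        found = first.strip().split("=", 1)[1]
        if expected_hash is not None and found != expected_hash:
            import warnings

            warnings.warn(f"config hash mismatch: artifact {found}, expected {expected_hash}")
    return pd.read_csv(path, skiprows=skip, **kwargs)


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    input_dir=None,
    simulate_spec: list[tuple[simulate.ArchetypeSpec, int]] | None = None,
    n_days: int = 6,
    write_series: bool = False,
) -> RunReport:
    """Run the full pipeline and write artifacts under ``out_dir``.

    Input is either a directory of sleep/wake CSVs or a simulation spec
    (list of (archetype, count)).  Artifacts: index_table.csv, labels.csv,
    profiles.csv, tree.json, outlier_labels.csv, report.json.
    """
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.hash()
    counts: dict = {}

    if (input_dir is None) == (simulate_spec is None):
        raise ValueError("provide exactly one of input_dir or simulate_spec")
    truth_labels = None
    if simulate_spec is not None:
        log.info("simulating cohort")
        series_list, truths = simulate.generate_cohort(
            simulate_spec, n_days=n_days, seed=config.seed, epoch_len=config.epoch_len
        )
        ids = [f"s{i:05d}" for i in range(len(series_list))]
        truth_labels = pd.Series([t.archetype for t in truths], index=ids, name="archetype")
        if write_series:
            sw_dir = out / "sleepwake"
            sw_dir.mkdir(exist_ok=True)
            for sid, sw in zip(ids, series_list):
                aio.write_sleepwake(sw, sw_dir / f"{sid}.csv")
    else:
        paths = sorted(Path(input_dir).glob("*.csv"))
        if not paths:
            raise ValueError(f"no sleep/wake CSVs under {input_dir}")
        series_list = [aio.read_sleepwake(p) for p in paths]
        ids = [p.stem for p in paths]
    counts["subjects_in"] = len(series_list)

    log.info("extracting indexes for %d subjects", len(series_list))
    table, excluded = build_index_table(series_list, config, ids)
    counts["subjects_valid"] = len(table)
    counts["subjects_excluded"] = len(excluded)
    _write_csv_with_hash(table, out / "index_table.csv", chash)
    if truth_labels is not None:
        truth_labels = truth_labels.loc[table.index]
        _write_csv_with_hash(truth_labels.to_frame(), out / "truth_labels.csv", chash)

    if len(table) < 2 * config.min_child_size:
        counts["subjects_clustered"] = 0
        report = RunReport(counts, chash, config.seed, time.perf_counter() - t0)
        report.to_json(out / "report.json")
        log.warning("too few valid subjects to cluster; stopping after indexing")
        return report

    log.info("clustering %d subjects", len(table))
    zm = landscape.zscore(table)
    tree = landscape.divisive_cluster(
        table,
        max_depth=config.max_depth,
        min_child_size=config.min_child_size,
        seed=config.seed,
        method=config.embed_method,
        eps=config.eps,
        min_samples=config.min_samples,
        n_neighbors=config.n_neighbors,
        min_dist=config.min_dist,
    )
    leaves = tree.leaves()
    groups = {
        top.node_id: min(
            config.ward_groups,
            sum(1 for lf in leaves if landscape._descends(top, lf)),
        )
        for top in tree.first_layer()
    }
    labels = landscape.ward_regroup(tree, zm, groups)
    counts["subjects_clustered"] = int((labels != "noise").sum())
    counts["noise"] = int((labels == "noise").sum())
    _write_csv_with_hash(labels.to_frame(), out / "labels.csv", chash)
    (out / "tree.json").write_text(json.dumps(tree.to_dict(), indent=2))

    profiles = landscape.cluster_profiles(labels, zm)
    prof_df = pd.DataFrame(
        [
            {"cluster": p.label, "size": p.size, "representative": p.representative, **p.mean_z.to_dict()}
            for p in profiles
        ]
    )
    _write_csv_with_hash(prof_df, out / "profiles.csv", chash, index=False)

    outlier_mask = landscape.select_outliers(table, config.outlier_indexes, config.pct)
    counts["outliers"] = int(outlier_mask.sum())
    if outlier_mask.sum() >= config.min_samples:
        out_labels = landscape.outlier_cluster(
            table.loc[outlier_mask],
            seed=config.seed,
            method=config.embed_method,
            eps=config.eps,
            min_samples=config.min_samples,
            n_neighbors=config.n_neighbors,
            min_dist=config.min_dist,
        )
        _write_csv_with_hash(out_labels.to_frame(), out / "outlier_labels.csv", chash)
        counts["outlier_clusters"] = int(len(set(out_labels) - {-1}))

    report = RunReport(counts, chash, config.seed, time.perf_counter() - t0)
    report.to_json(out / "report.json")
    return report
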