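"""Configuration handling and end-to-end analysis orchestration.

`run_analyze` takes traced tracks + contexts + manifest and writes:

* per-track classifications and motility metrics,
* per-microtubule metrics (landing rate, processive events, event frequency),
* superplot summaries per condition,
* the statistics battery across conditions,
* a run log with the config hash and library versions.

`run_simulate` writes a simulated dataset in the same CSV dialects, plus
ground truth as JSON.  Both are deterministic under fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from kymotility import __version__
from kymotility.io_model import (
    ExperimentManifest,
    KymographContext,
    Track,
    orient_track,
    read_contexts,
    read_manifest,
    read_tracks,
    write_contexts,
    write_manifest,
    write_tracks,
)
from kymotility.metrics import (
    detect_processive_events,
    event_frequency,
    landing_rate,
    track_metrics,
)
from kymotility.segmentation import classify_track, compute_segments, segment_runs
from kymotility.stats import aggregate, directionality_proportions, motility_battery
from kymotility.synthetic import preset, simulate_trackset

log = logging.getLogger("kymotility")

__all__ = ["PipelineConfig", "run_analyze", "run_simulate", "analyze_tracks"]

_THRESHOLD_KEYS = {
    "static_speed_nm_s": 25.0,
    "static_total_nm": 1000.0,
    "bidirectional_nm": 1500.0,
    "min_dwell_s": 1.2,
    "min_disp_nm": 525.0,
}
_STATS_KEYS = {"level": "mt", "gate_alpha": 0.05, "posthoc": "conover", "metric": "landing_rate_um_min"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (YAML-loadable, unknown keys rejected)."""

    tracks: str | None = None
    contexts: str | None = None
    manifest: str | None = None
    out_dir: str = "results"
    seed: int = 0
    preset: str | None = None
    thresholds: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.thresholds) - set(_THRESHOLD_KEYS)
        if bad:
            raise ValueError(f"unknown threshold key(s): {sorted(bad)}")
        bad = set(self.stats) - set(_STATS_KEYS)
        if bad:
            raise ValueError(f"unknown stats key(s): {sorted(bad)}")
        merged = {**_THRESHOLD_KEYS, **self.thresholds}
        nonpos = [k for k, v in merged.items() if not v > 0]
        if nonpos:
            raise ValueError(f"threshold(s) must be positive: {nonpos}")
        self.thresholds = merged
        self.stats = {**_STATS_KEYS, **self.stats}

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config key(s): {sorted(bad)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def analyze_tracks(
    tracks: list[Track],
    contexts: dict[str, KymographContext],
    manifest: ExperimentManifest,
    thresholds: dict | None = None,
) -> dict[str, pd.DataFrame]:
    """Core analysis: orient, segment, classify and summarize all tracks.

    Returns DataFrames: ``per_track`` (classification + metrics) and
    ``per_mt`` (landing rate and processive-event frequency per
    microtubule, including microtubules with zero tracks).
    """
    thr = {**_THRESHOLD_KEYS, **(thresholds or {})}
    rows = []
    events_per_ctx: dict[str, int] = {c: 0 for c in contexts}
    tracks_per_ctx: dict[str, int] = {c: 0 for c in contexts}
    for tr in tracks:
        ctx = contexts[tr.context_id]
        oriented = orient_track(tr, ctx)
        segs = compute_segments(oriented)
        runs, pauses = segment_runs(segs, static_speed_nm_s=thr["static_speed_nm_s"])
        cls = classify_track(runs, static_total_nm=thr["static_total_nm"], bidirectional_nm=thr["bidirectional_nm"])
        met = track_metrics(oriented, runs, pauses)
        events = detect_processive_events(
            oriented,
            min_dwell_s=thr["min_dwell_s"],
            min_disp_nm=thr["min_disp_nm"],
            static_speed_nm_s=thr["static_speed_nm_s"],
        )
        tracks_per_ctx[tr.context_id] += 1
        events_per_ctx[tr.context_id] += len(events)
        rows.append(
            {
                "track_id": tr.track_id,
                "context_id": tr.context_id,
                "label": cls.label,
                "plus_total_nm": cls.plus_total_nm,
                "minus_total_nm": cls.minus_total_nm,
                "total_run_length_nm": met.total_run_length_nm,
                "dwell_time_s": met.dwell_time_s,
                "average_speed_nm_s": met.average_speed_nm_s,
                "time_plus_s": met.time_plus_s,
                "time_minus_s": met.time_minus_s,
                "time_paused_s": met.time_paused_s,
                "n_runs": len(runs),
                "n_pauses": len(pauses),
                "is_processive_event": bool(events),
                "event_velocity_nm_s": events[0].velocity_nm_s if events else np.nan,
            }
        )
    per_track = pd.DataFrame(rows)
    mt_rows = []
    for cid, ctx in contexts.items():
        n = tracks_per_ctx[cid]
        lr = landing_rate(n, ctx)
        ne = events_per_ctx[cid]
        mt_rows.append(
            {
                "context_id": cid,
                "n_tracks": n,
                "landing_rate_um_min": lr.rate_um_min,
                "n_processive_events": ne,
                "event_freq_um_s": event_frequency(ne, ctx),
            }
        )
    return {"per_track": per_track, "per_mt": pd.DataFrame(mt_rows)}


def run_analyze(config: PipelineConfig) -> dict:
    """Full analysis from files on disk to a results bundle on disk."""
    if not (config.tracks and config.contexts and config.manifest):
        raise ValueError("analyze requires tracks, contexts and manifest paths")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    contexts = read_contexts(config.contexts)
    tracks = read_tracks(config.tracks, contexts)
    manifest = read_manifest(config.manifest)
    log.info("read %d tracks over %d kymographs", len(tracks), len(contexts))

    res = analyze_tracks(tracks, contexts, manifest, config.thresholds)
    per_track, per_mt = res["per_track"], res["per_mt"]
    counts = per_track["label"].value_counts().to_dict() if not per_track.empty else {}
    log.info("classified tracks: %s", counts)

    per_track.to_csv(out / "per_track.csv", index=False)
    per_mt.to_csv(out / "per_mt.csv", index=False)

    # condition of each microtubule, for grouping
    ctx_cond = manifest.table.drop_duplicates("context_id").set_index("context_id")["condition"]
    per_mt_cond = per_mt.assign(condition=per_mt["context_id"].map(ctx_cond))

    bundle: dict = {"per_track": per_track, "per_mt": per_mt}
    if not per_track.empty:
        props = directionality_proportions(
            pd.Series(per_track["label"].values, index=per_track["track_id"].values), manifest
        )
        props.to_csv(out / "directionality.csv", index_label="class")
        bundle["directionality"] = props

        metric = config.stats["metric"]
        summary = aggregate(
            pd.Series(per_mt_cond[metric].values, index=per_mt_cond["context_id"].values),
            manifest,
            level="experiment",
        )
        pd.DataFrame(
            {
                "level": [summary.level],
                "n_values": [summary.n_values],
                "n_groups": [summary.n_groups],
                "pooled_median": [summary.pooled_median],
                "quartile1": [summary.quartile1],
                "quartile3": [summary.quartile3],
                "p10": [summary.p10],
                "p90": [summary.p90],
            }
        ).to_csv(out / "superplot_summary.csv", index=False)
        bundle["superplot"] = summary

        by_cond = {
            str(cond): aggregate(
                pd.Series(grp[metric].values, index=grp["context_id"].values), manifest, "experiment"
            )
            for cond, grp in per_mt_cond.dropna(subset=["condition"]).groupby("condition")
        }
        try:
            from kymotility.plotting import superplot as draw_superplot

            ax = draw_superplot(by_cond, ylabel=metric)
            ax.figure.savefig(out / "superplot.png", dpi=120, bbox_inches="tight")
        except Exception as exc:  # plotting is diagnostic only
            log.warning("superplot rendering skipped: %s", exc)

        groups = {
            cond: grp[metric].to_numpy()
            for cond, grp in per_mt_cond.dropna(subset=["condition"]).groupby("condition")
        }
        if len(groups) >= 2:
            battery = motility_battery(
                groups, gate_alpha=config.stats["gate_alpha"], posthoc=config.stats["posthoc"]
            )
            report = {
                "metric": metric,
                "method": battery["method"],
                "omnibus": (
                    {"statistic": battery["omnibus"].statistic, "p": battery["omnibus"].p, "df": battery["omnibus"].df}
                    if battery["omnibus"]
                    else None
                ),
                "comparisons": [
                    {"pair": list(pair), "statistic": c.statistic, "p_raw": c.p, "p_holm": c.p_adjusted}
                    for pair, c in zip(battery["pairs"], battery["comparisons"])
                ],
            }
            (out / "stats_report.json").write_text(json.dumps(report, indent=2))
            bundle["stats"] = battery

    runlog = {
        "config_sha256": config.digest(),
        "kymotility_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_tracks": len(tracks),
        "n_kymographs": len(contexts),
        "class_counts": {k: int(v) for k, v in counts.items()},
    }
    (out / "run_log.json").write_text(json.dumps(runlog, indent=2))
    return bundle


def run_simulate(config: PipelineConfig, render: bool = True) -> dict:
    """Simulate a dataset from a preset and write it in the standard dialects.

    With ``render=True`` the first kymograph is also rendered to TIFF
    (Gaussian PSF + Poisson photon noise) for visual inspection.
    """
    if not config.preset:
        raise ValueError("simulate requires a preset name")
    params = preset(config.preset, seed=config.seed)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tracks, contexts, manifest, truths = simulate_trackset(params)
    if render and contexts:
        import tifffile

        from kymotility.synthetic import render_kymograph

        cid = next(iter(contexts))
        img = render_kymograph(
            [t for t in tracks if t.context_id == cid], contexts[cid], seed=config.seed
        )
        tifffile.imwrite(out / f"{cid}_kymograph.tif", img.astype(np.float32))
    write_tracks(tracks, out / "tracks.csv")
    write_contexts(contexts, out / "contexts.csv")
    write_manifest(manifest, out / "manifest.csv")
    gt = [
        {
            "track_id": g.track_id,
            "context_id": g.context_id,
            "population": g.population,
            "detached": g.detached,
            "left_microtubule": g.left_microtubule,
            "observed": g.observed,
            "true_label": None,
        }
        for g in truths
    ]
    from kymotility.synthetic import true_class

    for rec, g in zip(gt, truths):
        rec["true_label"] = true_class(g).label
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=2))
    log.info("simulated %d tracks (%d landings) over %d kymographs", len(tracks), len(truths), len(contexts))
    return {"tracks": tracks, "contexts": contexts, "manifest": manifest, "ground_truth": truths}
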