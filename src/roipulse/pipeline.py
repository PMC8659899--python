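"""End-to-end orchestration: dataset -> traces -> pulse -> metrics -> ranking.

``run_pipeline`` walks a dataset directory (synthetic or compatible real
layout), runs the requested extraction methods per region, scores every
(video, method, region) against ground truth and produces the tidy metric
table, the rBS table, the median ranking and optional combined-region
records (TOP5 / BOT5 / FACE_SKIN).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from roipulse import __version__
from roipulse.datasets import (
    DatasetError,
    list_subjects,
    read_fps,
    read_frames,
    read_ground_truth,
    read_region_specs,
)
from roipulse.geometry import combine_regions, extract_rgb_trace, skin_mask
from roipulse.metrics import (
    MetricRecord,
    MetricsError,
    UndefinedCorrelationError,
    build_rbs_table,
    mae,
    median_rank,
    pcc,
    rmse,
    thickness_pixel_correlation,
    top_bottom,
)
from roipulse.rppg import RPPGError, estimate_bpm, extract

__all__ = ["RunManifest", "run_pipeline", "report_tables", "PipelineError"]

log = logging.getLogger("roipulse.pipeline")

COMBO_LABELS = ("TOP5", "BOT5", "FACE_SKIN")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    dataset_dir: str
    methods: tuple[str, ...] = ("POS", "CHROM")
    dataset_label: str = "synthetic"
    window_s: float = 10.0
    hop_s: float = 1.0
    combos: bool = False
    combo_k: int = 5
    seed: int = 0
    version: str = __version__
    created: float = field(default_factory=time.time)

    @property
    def hash(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items() if k != "created"}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def write(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        payload["hash"] = self.hash
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _bpm_vs_truth(bvp, truth_times, truth_bpm, window_s, hop_s):
    series = estimate_bpm(bvp, window_s=window_s, hop_s=hop_s)
    ref = np.interp(series.window_centers, truth_times, truth_bpm)
    return series.bpm, ref


def _score(manifest, video, region_label, est, ref) -> MetricRecord:
    try:
        p = pcc(ref, est)
    except UndefinedCorrelationError:
        log.warning("video %s region %s: undefined PCC (zero variance)", video, region_label)
        p = None
    return MetricRecord(dataset=manifest.dataset_label, method="", video=video,
                        region=region_label, mae=mae(ref, est), rmse=rmse(ref, est), pcc=p)


def _process_subject(manifest: RunManifest, subject: Path) -> list[MetricRecord]:
    frames = read_frames(subject).astype(float)
    fps = read_fps(subject)
    pulse, bpm, times = read_ground_truth(subject / "ground_truth.txt")
    specs = read_region_specs(subject)
    if specs is None:
        raise DatasetError(f"{subject}: no regions.json; landmark-driven runs "
                           "must pre-rasterize masks into region specs")
    frame_size = (frames.shape[2], frames.shape[1])
    masks = {s.region_id: s.to_mask(frame_size) for s in specs}
    need_pixels = "SSR" in manifest.methods

    records: list[MetricRecord] = []
    video = subject.name

    def run_on_mask(region_label, mask):
        trace = extract_rgb_trace(frames, [mask], fps, keep_pixels=need_pixels,
                                  seed=manifest.seed)
        for method in manifest.methods:
            try:
                bvp = extract(method, trace)
                est, ref = _bpm_vs_truth(bvp, times, bpm, manifest.window_s, manifest.hop_s)
            except (RPPGError, ValueError) as exc:
                log.warning("video %s region %s method %s skipped: %s",
                            video, region_label, method, exc)
                continue
            rec = _score(manifest, video, region_label, est, ref)
            records.append(dataclasses.replace(rec, method=method))

    for rid, mask in masks.items():
        run_on_mask(rid, mask)

    if manifest.combos:
        base_records = [r for r in records if isinstance(r.region, int)]
        table = build_rbs_table(base_records)
        ranked = median_rank(table)
        top, bot = top_bottom(ranked, min(manifest.combo_k, len(ranked)))
        run_on_mask("TOP5", combine_regions(masks.values(), top, new_id=-11))
        run_on_mask("BOT5", combine_regions(masks.values(), bot, new_id=-12))
        run_on_mask("FACE_SKIN", skin_mask(frames[0]))
    return records


def run_pipeline(manifest: RunManifest, out_dir: str | Path) -> dict:
    """Run every subject under the manifest's dataset; write tidy CSV outputs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    subjects = list_subjects(manifest.dataset_dir)
    if not subjects:
        raise PipelineError(f"no subjects under {manifest.dataset_dir}")

    records: list[MetricRecord] = []
    skipped = []
    for subject in subjects:
        try:
            records.extend(_process_subject(manifest, subject))
        except DatasetError as exc:
            log.warning("subject %s skipped: %s", subject.name, exc)
            skipped.append(subject.name)
    if not records:
        raise PipelineError("every video was skipped")

    metrics_df = pd.DataFrame([r.__dict__ for r in records])
    base = [r for r in records if not (isinstance(r.region, str) and r.region in COMBO_LABELS)]
    rbs_df = build_rbs_table(base)
    ranked = median_rank(rbs_df)

    metrics_df.to_csv(out / "metrics.csv", index=False)
    rbs_df.to_csv(out / "rbs.csv", index=False)
    ranked.to_csv(out / "ranked.csv", index=False)
    manifest.write(out / "manifest.json")
    results = {"metrics": metrics_df, "rbs": rbs_df, "ranked": ranked,
               "skipped": skipped, "manifest": manifest}
    report_tables(results, out)
    return results


def report_tables(results: dict, out_dir: str | Path) -> dict[str, Path]:
    """Render summary tables: median-rBS ranking, thickness/pixels/rank, combos."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ranked: pd.DataFrame = results.get("ranked")
    metrics: pd.DataFrame = results.get("metrics")
    if ranked is None or ranked.empty or metrics is None or metrics.empty:
        raise PipelineError("empty results; nothing to report")
    paths = {}

    t6 = ranked.rename(columns={"median_rbs": "median_rBS"})
    t6.to_csv(out / "summary_median_rank.csv", index=False)
    paths["median_rank"] = out / "summary_median_rank.csv"

    # thickness / pixel-count / rank table with correlation footer
    from roipulse.anatomy import load_proposed_regions

    thickness = {r.region_id: r.combined_thickness for r in load_proposed_regions()}
    specs_rows = []
    pixel_counts = {}
    manifest: Optional[RunManifest] = results.get("manifest")
    if manifest is not None:
        for subject in list_subjects(manifest.dataset_dir):
            specs = read_region_specs(subject)
            if specs:
                for s in specs:
                    if s.rect is not None:
                        x0, y0, x1, y1 = s.rect
                        pixel_counts[s.region_id] = (x1 - x0) * (y1 - y0)
                    thickness.setdefault(s.region_id, s.thickness_um)
                    thickness[s.region_id] = thickness.get(s.region_id) or s.thickness_um
                break
    for _, row in ranked.iterrows():
        rid = row["region"]
        specs_rows.append({
            "region": rid,
            "thickness_um": thickness.get(rid),
            "pixel_count": pixel_counts.get(rid),
            "rank": int(row["rank"]),
        })
    t7 = pd.DataFrame(specs_rows)
    footer = ""
    usable = t7.dropna(subset=["pixel_count"])
    try:
        r_th, r_px = thickness_pixel_correlation(
            {r["region"]: r["rank"] for r in specs_rows},
            {r["region"]: r["thickness_um"] for r in specs_rows},
            {int(r["region"]): int(r["pixel_count"]) for _, r in usable.iterrows()},
        )
        footer = f"correlation (thickness, rank) = {r_th:.2f}; (pixels, rank) = {r_px:.2f}"
    except MetricsError as exc:
        footer = f"correlation unavailable: insufficient data ({exc})"
    t7.to_csv(out / "summary_thickness_pixels.csv", index=False)
    with open(out / "summary_thickness_pixels.txt", "w", encoding="utf-8") as fh:
        fh.write(t7.to_string(index=False) + "\n" + footer + "\n")
    paths["thickness_pixels"] = out / "summary_thickness_pixels.csv"

    combos = metrics[metrics["region"].isin(COMBO_LABELS)]
    if not combos.empty:
        t8 = combos.pivot_table(index="video", columns=["method", "region"],
                                values=["mae", "pcc"], aggfunc="mean")
        t8.to_csv(out / "summary_combos.csv")
        paths["combos"] = out / "summary_combos.csv"
    return paths


def plot_bvp_overlay(bvps: dict[str, np.ndarray], fps: float, path: str | Path,
                     truth: Optional[np.ndarray] = None) -> Path:
    """Overlay plot of extracted pulse waveforms against the ground truth."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.2))
    if truth is not None:
        t = np.arange(truth.size) / fps
        ax.plot(t, truth / (np.abs(truth).max() or 1), color="green", lw=1.2, label="ground truth")
    for name, x in bvps.items():
        t = np.arange(x.size) / fps
        ax.plot(t, x / (np.abs(x).max() or 1), lw=0.9, label=name)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("normalised pulse")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
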