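"""On-disk dataset adapter: one directory per subject, video + ground truth.

The ground-truth dialect is three whitespace-separated lines: pulse waveform,
per-frame BPM, per-frame timestamps.  Video may be a PNG frame sequence under
``vid/`` or a single video file readable by imageio.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["list_subjects", "read_ground_truth", "read_frames", "read_region_specs"]


class DatasetError(ValueError):
    pass


def list_subjects(root: str | Path) -> list[Path]:
    """Subject directories containing a ground-truth file, sorted by name."""
    root = Path(root)
    if not root.is_dir():
        raise DatasetError(f"dataset root {root} is not a directory")
    return sorted(p for p in root.iterdir() if p.is_dir() and (p / "ground_truth.txt").exists())


def read_ground_truth(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse a 3-line ground-truth file -> (pulse, bpm, timestamps)."""
    with open(path, "r", encoding="utf-8") as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    if len(lines) != 3:
        raise DatasetError(f"{path}: expected 3 non-empty lines, found {len(lines)}")
    rows = []
    for i, ln in enumerate(lines):
        try:
            rows.append(np.array([float(tok) for tok in ln.split()]))
        except ValueError as exc:
            raise DatasetError(f"{path}: line {i + 1} is not numeric") from exc
    if not (rows[0].size == rows[1].size == rows[2].size) or rows[0].size == 0:
        raise DatasetError(f"{path}: line lengths differ or are empty")
    return rows[0], rows[1], rows[2]


def read_frames(subject_dir: str | Path) -> np.ndarray:
    """Load the subject's frames as a (T, H, W, 3) uint8 array."""
    import imageio.v3 as iio

    subject_dir = Path(subject_dir)
    vid_dir = subject_dir / "vid"
    if vid_dir.is_dir():
        files = sorted(vid_dir.glob("*.png"))
        if not files:
            raise DatasetError(f"{vid_dir}: no PNG frames")
        return np.stack([iio.imread(f)[..., :3] for f in files])
    for pattern in ("*.avi", "*.mp4"):
        hits = sorted(subject_dir.glob(pattern))
        if hits:
            return np.asarray(iio.imread(hits[0], plugin="pyav"))[..., :3]
    raise DatasetError(f"{subject_dir}: no video found")


def read_fps(subject_dir: str | Path, default: float = 30.0) -> float:
    meta = Path(subject_dir) / "meta.json"
    if meta.exists():
        with open(meta, "r", encoding="utf-8") as fh:
            return float(json.load(fh).get("fps", default))
    return default


def read_region_specs(subject_dir: str | Path):
    """Load the subject's stored region specs, or None when absent."""
    from roipulse.synth import RegionSpec

    path = Path(subject_dir) / "regions.json"
    if not path.exists():
        return None
    with open(path, "r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return [
        RegionSpec(
            region_id=int(r["region_id"]), thickness_um=float(r["thickness_um"]),
            rect=tuple(r["rect"]) if r.get("rect") else None,
            polygon=tuple(tuple(p) for p in r["polygon"]) if r.get("polygon") else None,
        )
        for r in raw
    ]
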