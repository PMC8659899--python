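"""Face-mesh region geometry: polygon rasterization, masks, color traces.

Region polygons are defined over a 468-point landmark topology via a packaged
JSON map (region id -> ordered landmark indices), together with a canonical
frontal landmark layout used by tests and the synthetic renderer.  The layout
is a stylised approximation of a frontal face; it is data, editable without
code changes.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "LandmarkSet",
    "RegionMask",
    "RGBTrace",
    "rasterize_polygon",
    "build_region_masks",
    "extract_rgb_trace",
    "combine_regions",
    "skin_mask",
    "load_region_polygons",
    "canonical_landmarks",
    "CsvLandmarkProvider",
    "export_mask_png",
    "N_LANDMARKS",
    "DEFAULT_SKIN_BOUNDS",
]

N_LANDMARKS = 468

#: YCbCr chrominance bounds for the baseline skin mask (classic detector range).
DEFAULT_SKIN_BOUNDS = {"cb": (77.0, 127.0), "cr": (133.0, 173.0)}

SSR_MAX_PIXELS = 2000


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class LandmarkSet:
    """468 (x, y) pixel coordinates for one frame."""

    points: np.ndarray  # (468, 2) float
    frame_size: tuple[int, int]  # (width, height)
    frame_index: int = 0

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.shape != (N_LANDMARKS, 2):
            raise GeometryError(f"expected ({N_LANDMARKS}, 2) landmarks, got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise GeometryError("landmark coordinates must be finite")
        object.__setattr__(self, "points", pts)


@dataclass
class RegionMask:
    """Boolean pixel mask for one region in one frame."""

    region_id: int
    mask: np.ndarray  # (height, width) bool

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())

    @property
    def pixels(self) -> set[tuple[int, int]]:
        """Set of (row, col) coordinates; convenience for small masks."""
        rr, cc = np.nonzero(self.mask)
        return set(zip(rr.tolist(), cc.tolist()))

    @property
    def is_empty(self) -> bool:
        return not self.mask.any()


@dataclass
class RGBTrace:
    """Per-frame spatial mean color of one region (channel order R, G, B)."""

    values: np.ndarray  # (T, 3) float
    fps: float
    region_id: int = -1
    pixel_samples: Optional[list[np.ndarray]] = None  # per-frame (n, 3), for SSR
    held_frames: list[int] = field(default_factory=list)  # empty-mask frames filled by hold

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 3 or self.values.shape[0] < 1:
            raise GeometryError(f"trace must be (T, 3) with T >= 1, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("trace contains non-finite values")
        if not self.fps > 0:
            raise GeometryError("fps must be positive")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps


def rasterize_polygon(
    vertices: Sequence[tuple[float, float]],
    frame_size: tuple[int, int],
    region_id: int = -1,
) -> RegionMask:
    """Fill a polygon over pixel centers with the even-odd rule.

    Coordinates are 0-based with origin at the top-left; the pixel at
    (row, col) has center (col + 0.5, row + 0.5).  Vertices outside the frame
    are allowed; the mask is clipped to the frame.
    """
    verts = np.asarray(vertices, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
        raise GeometryError(f"polygon needs >= 3 (x, y) vertices, got shape {verts.shape}")
    width, height = int(frame_size[0]), int(frame_size[1])
    xs = np.arange(width) + 0.5
    ys = np.arange(height) + 0.5
    gx = xs[np.newaxis, :]  # (1, W)
    gy = ys[:, np.newaxis]  # (H, 1)
    inside = np.zeros((height, width), dtype=bool)
    n = verts.shape[0]
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edge never crosses a horizontal ray parity test
        straddles = (y1 > gy) != (y2 > gy)  # (H, 1)
        x_cross = x1 + (gy - y1) * (x2 - x1) / (y2 - y1)  # (H, 1)
        inside ^= straddles & (gx < x_cross)
    return RegionMask(region_id=region_id, mask=inside)


def load_region_polygons() -> dict[int, list[int]]:
    """Packaged region id -> ordered landmark-index polygon."""
    ref = resources.files("roipulse.data").joinpath("region_polygons.json")
    with ref.open("r", encoding="utf-8") as fh:
        raw = json.load(fh)
    return {int(k): list(map(int, v)) for k, v in raw.items()}


def build_region_masks(landmarks: LandmarkSet) -> list[RegionMask]:
    """Rasterize all 31 region polygons for one frame.

    Empty masks (degenerate or off-frame polygons) are permitted and simply
    have ``pixel_count == 0``.
    """
    polys = load_region_polygons()
    out = []
    for region_id in sorted(polys):
        verts = landmarks.points[polys[region_id]]
        out.append(rasterize_polygon(verts, landmarks.frame_size, region_id=region_id))
    return out


def combine_regions(masks: Iterable[RegionMask], region_ids: Sequence[int],
                    new_id: int = -1) -> RegionMask:
    """Set union of the masks whose region_id is in ``region_ids``."""
    ids = set(region_ids)
    if not ids:
        raise GeometryError("empty region selection")
    selected = [m for m in masks if m.region_id in ids]
    if not selected:
        raise GeometryError(f"no masks found for regions {sorted(ids)}")
    union = np.zeros_like(selected[0].mask, dtype=bool)
    for m in selected:
        union |= m.mask
    return RegionMask(region_id=new_id, mask=union)


def extract_rgb_trace(
    frames: Sequence[np.ndarray],
    masks: Sequence[RegionMask],
    fps: float,
    keep_pixels: bool = False,
    max_pixels: int = SSR_MAX_PIXELS,
    seed: int = 0,
) -> RGBTrace:
    """Spatially average each frame's color over its mask.

    ``masks`` may hold one mask per frame (tracked) or a single mask reused
    for every frame (static).  Frames whose mask is empty are filled by
    previous-value hold (leading empties are back-filled from the first valid
    frame) and recorded in ``held_frames``.  With ``keep_pixels`` a uniform
    random subsample of at most ``max_pixels`` pixel colors per frame is
    retained for subspace methods.
    """
    frames = list(frames)
    if len(masks) == 1:
        masks = list(masks) * len(frames)
    if len(masks) != len(frames):
        raise GeometryError("need one mask per frame or a single static mask")
    region_id = masks[0].region_id
    if any(m.region_id != region_id for m in masks):
        raise GeometryError("masks must belong to a single region")
    if all(m.is_empty for m in masks):
        raise GeometryError(f"region {region_id}: mask empty in every frame")

    rng = np.random.default_rng(seed)
    T = len(frames)
    values = np.empty((T, 3), dtype=float)
    samples: Optional[list] = [] if keep_pixels else None
    held: list[int] = []
    for t, (frame, m) in enumerate(zip(frames, masks)):
        frame = np.asarray(frame, dtype=float)
        if frame.ndim != 3 or frame.shape[2] != 3:
            raise GeometryError("frames must be (H, W, 3)")
        if m.is_empty:
            held.append(t)
            values[t] = np.nan
            if keep_pixels:
                samples.append(None)
            continue
        px = frame[m.mask]  # (n, 3)
        values[t] = px.mean(axis=0)
        if keep_pixels:
            if px.shape[0] > max_pixels:
                idx = rng.choice(px.shape[0], size=max_pixels, replace=False)
                px = px[idx]
            samples.append(px.copy())
    # previous-value hold; leading gap back-filled from first valid frame
    first_valid = next(t for t in range(T) if t not in set(held))
    for t in range(T):
        if np.isnan(values[t]).any():
            src = t - 1 if t > first_valid else first_valid
            values[t] = values[src]
            if keep_pixels:
                samples[t] = samples[src]
    return RGBTrace(values=values, fps=fps, region_id=region_id,
                    pixel_samples=samples, held_frames=held)


def skin_mask(frame: np.ndarray, bounds: Optional[dict] = None) -> RegionMask:
    """Chrominance-threshold skin mask (YCbCr bounds), for the face+skin baseline."""
    from skimage.color import rgb2ycbcr

    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[2] != 3:
        raise GeometryError("skin_mask needs an (H, W, 3) frame")
    b = bounds or DEFAULT_SKIN_BOUNDS
    # rgb2ycbcr expects uint8 or floats in [0, 1]
    ycbcr = rgb2ycbcr(np.clip(frame, 0, 255).astype(np.uint8))
    cb, cr = ycbcr[..., 1], ycbcr[..., 2]
    m = (cb >= b["cb"][0]) & (cb <= b["cb"][1]) & (cr >= b["cr"][0]) & (cr <= b["cr"][1])
    return RegionMask(region_id=-2, mask=m)


def canonical_landmarks(frame_size: tuple[int, int], frame_index: int = 0,
                        face_box: Optional[tuple[float, float, float, float]] = None) -> LandmarkSet:
    """Canonical frontal landmark layout scaled into ``face_box`` (x0, y0, x1, y1).

    By default the face box is the full frame.  Used as the test fixture and
    by the synthetic scene renderer when polygon regions are requested.
    """
    ref = resources.files("roipulse.data").joinpath("canonical_landmarks.csv")
    with ref.open("r", encoding="utf-8", newline="") as fh:
        rows = list(csv.DictReader(fh))
    pts = np.zeros((N_LANDMARKS, 2), dtype=float)
    for r in rows:
        pts[int(r["point_index"])] = (float(r["x"]), float(r["y"]))
    w, h = frame_size
    x0, y0, x1, y1 = face_box if face_box is not None else (0.0, 0.0, float(w), float(h))
    pts[:, 0] = x0 + pts[:, 0] * (x1 - x0)
    pts[:, 1] = y0 + pts[:, 1] * (y1 - y0)
    return LandmarkSet(points=pts, frame_size=(int(w), int(h)), frame_index=frame_index)


class CsvLandmarkProvider:
    """File-based landmark provider: CSV columns frame_index, point_index, x, y.

    Calling the provider with a frame index returns a LandmarkSet, or None if
    that frame has no (complete) landmark record — the failure flag of the
    provider contract.
    """

    def __init__(self, path: str | Path, frame_size: tuple[int, int]):
        self.frame_size = (int(frame_size[0]), int(frame_size[1]))
        self._frames: dict[int, np.ndarray] = {}
        with open(path, "r", encoding="utf-8", newline="") as fh:
            for row in csv.DictReader(fh):
                fi = int(row["frame_index"])
                arr = self._frames.setdefault(fi, np.full((N_LANDMARKS, 2), np.nan))
                arr[int(row["point_index"])] = (float(row["x"]), float(row["y"]))

    def frame_indices(self) -> list[int]:
        return sorted(self._frames)

    def __call__(self, frame_index: int) -> Optional[LandmarkSet]:
        arr = self._frames.get(frame_index)
        if arr is None or not np.all(np.isfinite(arr)):
            return None
        return LandmarkSet(points=arr, frame_size=self.frame_size, frame_index=frame_index)


def export_mask_png(mask: RegionMask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit PNG for visual inspection."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), (mask.mask.astype(np.uint8) * 255))
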