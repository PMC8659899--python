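"""Synthetic facial scenes with a planted blood-volume pulse.

Each scene contains disjoint region masks whose pixels share a pulsatile
diffuse color component.  The planted amplitude per region decreases with a
configured skin-thickness parameter, emulating depth-dependent diffuse
reflection.  Confounds: achromatic illumination flicker, achromatic specular
noise, per-pixel sensor noise, mask jitter and intensity quantization.  A
single seed expands into independent substreams per noise source, so scenes
are byte-reproducible and toggling one confound does not shift the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np

from roipulse.anatomy import load_proposed_regions
from roipulse.geometry import RegionMask, rasterize_polygon

__all__ = [
    "NoiseParams",
    "RegionSpec",
    "SceneConfig",
    "GroundTruth",
    "NOISE_PRESETS",
    "make_bvp",
    "render_scene",
    "write_ubfc_layout",
    "grid_region_specs",
    "synthesize_dataset",
]

HRProfile = Union[float, Sequence[float], Callable[[np.ndarray], np.ndarray]]

#: Default pulsatile channel coupling (green dominant), unit norm.
DEFAULT_COUPLING = np.array([0.33, 0.78, 0.53]) / np.linalg.norm([0.33, 0.78, 0.53])

#: Synthetic skin tone; chosen to sit inside the default chrominance skin bounds.
DEFAULT_BASE_COLOR = (190.0, 130.0, 110.0)


class SceneConfigError(ValueError):
    pass


@dataclass(frozen=True)
class NoiseParams:
    sensor_sd: float = 0.0  # per-pixel gaussian noise, intensity levels
    flicker_amp: float = 0.0  # achromatic sinusoidal illumination, levels
    flicker_freq: float = 0.1  # Hz
    specular_amp: float = 0.0  # achromatic broadband noise std, levels
    jitter_px: int = 0  # max per-frame mask translation
    quantization_step: float = 0.0  # 0 disables quantization
    albedo_sd: float = 0.0  # static per-pixel chromatic texture (relative gain sd)


NOISE_PRESETS: dict[str, NoiseParams] = {
    "none": NoiseParams(),
    "mild": NoiseParams(sensor_sd=8.0, flicker_amp=2.0, flicker_freq=0.1,
                        specular_amp=4.0, jitter_px=0, quantization_step=1.0,
                        albedo_sd=0.03),
    "harsh": NoiseParams(sensor_sd=6.0, flicker_amp=4.0, flicker_freq=0.3,
                         specular_amp=3.0, jitter_px=1, quantization_step=4.0,
                         albedo_sd=0.08),
}


@dataclass(frozen=True)
class RegionSpec:
    """One synthetic region: a rectangle (x0, y0, x1, y1) or a polygon."""

    region_id: int
    thickness_um: float
    rect: Optional[tuple[int, int, int, int]] = None
    polygon: Optional[tuple[tuple[float, float], ...]] = None

    def to_mask(self, frame_size: tuple[int, int]) -> RegionMask:
        if (self.rect is None) == (self.polygon is None):
            raise SceneConfigError("specify exactly one of rect/polygon")
        if self.rect is not None:
            x0, y0, x1, y1 = self.rect
            m = np.zeros((frame_size[1], frame_size[0]), dtype=bool)
            m[y0:y1, x0:x1] = True
            return RegionMask(region_id=self.region_id, mask=m)
        return rasterize_polygon(self.polygon, frame_size, region_id=self.region_id)


@dataclass
class SceneConfig:
    regions: list[RegionSpec]
    frame_size: tuple[int, int] = (64, 64)
    fps: float = 30.0
    duration: float = 30.0
    base_color: tuple[float, float, float] = DEFAULT_BASE_COLOR
    coupling: np.ndarray = field(default_factory=lambda: DEFAULT_COUPLING.copy())
    amplitude_law: str = "inverse"  # or "exp"
    amplitude_scale: float = 0.02  # relative modulation of the thinnest region
    hr_profile: HRProfile = 72.0
    noise: NoiseParams = field(default_factory=NoiseParams)
    background_color: tuple[float, float, float] = (40.0, 40.0, 80.0)
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted pulse, per-second heart rate and per-region amplitudes."""

    bvp: np.ndarray  # waveform at fps
    hr: np.ndarray  # BPM, one sample per second
    fps: float
    region_amplitudes: dict[int, float] = field(default_factory=dict)

    def hr_at(self, times: np.ndarray) -> np.ndarray:
        t = np.arange(self.hr.size, dtype=float)
        return np.interp(np.asarray(times, dtype=float), t, self.hr)


def _hr_per_frame(profile: HRProfile, fps: float, duration: float) -> np.ndarray:
    T = int(round(fps * duration))
    t = np.arange(T) / fps
    if callable(profile):
        hr = np.asarray(profile(t), dtype=float)
    elif np.isscalar(profile):
        hr = np.full(T, float(profile))
    else:
        arr = np.asarray(profile, dtype=float)  # one value per second
        hr = np.interp(t, np.arange(arr.size, dtype=float), arr)
    if hr.shape != (T,):
        raise SceneConfigError(f"hr profile evaluated to shape {hr.shape}, want ({T},)")
    if np.any(hr < 40.0) or np.any(hr > 180.0):
        raise SceneConfigError("hr profile must stay within [40, 180] BPM")
    return hr


def make_bvp(hr_profile: HRProfile, fps: float, duration: float,
             seed: int = 0) -> GroundTruth:
    """Phase-continuous pulse waveform: fundamental plus 30% second harmonic."""
    hr = _hr_per_frame(hr_profile, fps, duration)
    phase = 2.0 * np.pi * np.cumsum(hr / 60.0) / fps
    bvp = np.sin(phase) + 0.3 * np.sin(2.0 * phase)
    n_sec = int(np.ceil(hr.size / fps))
    sec_idx = np.minimum((np.arange(n_sec) * fps).astype(int), hr.size - 1)
    return GroundTruth(bvp=bvp, hr=hr[sec_idx], fps=fps)


def amplitude_for_thickness(thickness: np.ndarray, law: str, scale: float) -> np.ndarray:
    """Relative pulsatile amplitude per region, strictly decreasing in thickness."""
    th = np.asarray(thickness, dtype=float)
    if np.any(th <= 0):
        raise SceneConfigError("thickness must be positive")
    tmin = th.min()
    if law == "inverse":
        return scale * tmin / th
    if law == "exp":
        return scale * np.exp(-(th - tmin) / 500.0)
    raise SceneConfigError(f"unknown amplitude law {law!r}")


def _smooth_noise(rng: np.random.Generator, T: int, fps: float, sd: float) -> np.ndarray:
    """Broadband achromatic noise trace, lightly smoothed, std ``sd``."""
    x = rng.standard_normal(T + int(fps))
    k = max(3, int(fps) // 6)
    x = np.convolve(x, np.ones(k) / k, mode="same")[: T]
    s = x.std()
    return x / s * sd if s > 0 else x


def render_scene(config: SceneConfig) -> tuple[np.ndarray, dict[int, list[RegionMask]], GroundTruth]:
    """Render frames (T, H, W, 3 float), per-frame masks, and ground truth."""
    W, H = config.frame_size
    T = int(round(config.fps * config.duration))
    if T < 1:
        raise SceneConfigError("scene must contain at least one frame")
    if not config.regions:
        raise SceneConfigError("scene needs at least one region")

    base_masks = {r.region_id: r.to_mask((W, H)) for r in config.regions}
    occupancy = np.zeros((H, W), dtype=int)
    for m in base_masks.values():
        occupancy += m.mask
    if occupancy.max() > 1:
        raise SceneConfigError("region masks overlap")

    truth = make_bvp(config.hr_profile, config.fps, config.duration, seed=config.seed)
    thick = np.array([r.thickness_um for r in config.regions])
    amps = amplitude_for_thickness(thick, config.amplitude_law, config.amplitude_scale)
    truth.region_amplitudes = {r.region_id: float(a) for r, a in zip(config.regions, amps)}

    ss = np.random.SeedSequence(config.seed)
    rng_sensor, rng_jitter, rng_spec, rng_albedo = (
        np.random.default_rng(s) for s in ss.spawn(4))

    noise = config.noise
    t = np.arange(T) / config.fps
    flicker = noise.flicker_amp * np.sin(2.0 * np.pi * noise.flicker_freq * t)
    specular = (_smooth_noise(rng_spec, T, config.fps, noise.specular_amp)
                if noise.specular_amp > 0 else np.zeros(T))

    base = np.asarray(config.base_color, dtype=float)
    coupling = np.asarray(config.coupling, dtype=float)
    coupling = coupling / np.linalg.norm(coupling)
    bg = np.asarray(config.background_color, dtype=float)

    # static per-pixel chromatic skin texture; unit mean so region means are unbiased
    if noise.albedo_sd > 0:
        albedo = rng_albedo.normal(1.0, noise.albedo_sd, size=(H, W, 3)).astype(np.float32)
    else:
        albedo = None

    if noise.jitter_px > 0:
        offsets = rng_jitter.integers(-noise.jitter_px, noise.jitter_px + 1, size=(T, 2))
    else:
        offsets = np.zeros((T, 2), dtype=int)

    frames = np.empty((T, H, W, 3), dtype=np.float32)
    masks: dict[int, list[RegionMask]] = {rid: [] for rid in base_masks}
    for k in range(T):
        frame = np.broadcast_to(bg, (H, W, 3)).astype(np.float32).copy()
        dy, dx = int(offsets[k, 0]), int(offsets[k, 1])
        ach = flicker[k] + specular[k]
        for spec, a in zip(config.regions, amps):
            bm = base_masks[spec.region_id].mask
            m = np.roll(bm, (dy, dx), axis=(0, 1)) if (dy or dx) else bm
            color = base * (1.0 + a * truth.bvp[k] * coupling)
            if albedo is not None:
                frame[m] = color.astype(np.float32) * albedo[m] + ach
            else:
                frame[m] = color.astype(np.float32) + ach
            masks[spec.region_id].append(RegionMask(region_id=spec.region_id, mask=m))
        if noise.sensor_sd > 0:
            frame += rng_sensor.normal(0.0, noise.sensor_sd, size=frame.shape).astype(np.float32)
        if noise.quantization_step > 0:
            frame = np.round(frame / noise.quantization_step) * noise.quantization_step
        frames[k] = np.clip(frame, 0.0, 255.0)
    return frames, masks, truth


def grid_region_specs(frame_size: tuple[int, int], region_ids: Sequence[int],
                      margin: int = 2, gap: int = 2,
                      pixel_weights: Union[str, dict, None] = "reference") -> list[RegionSpec]:
    """Disjoint rectangle specs for the requested proposed-region ids.

    Regions are laid out on a near-square grid with published thickness
    values; eye regions (no thickness) are rejected.  ``pixel_weights``
    controls rectangle area within each grid cell: "reference" sizes regions
    proportionally to the published per-region pixel counts, a dict maps
    region_id -> relative weight, None gives equal full-cell rectangles.
    """
    table = {r.region_id: r for r in load_proposed_regions()}
    for rid in region_ids:
        if rid not in table:
            raise SceneConfigError(f"unknown region id {rid}")
        if table[rid].combined_thickness is None:
            raise SceneConfigError(f"region {rid} has no thickness; not usable here")
    if pixel_weights == "reference":
        from roipulse.metrics import load_reference_scores

        ref = load_reference_scores()
        pixel_weights = dict(zip(ref["region_id"], ref["pixel_count"].astype(float)))
    n = len(region_ids)
    cols = int(np.ceil(np.sqrt(n)))
    rows = int(np.ceil(n / cols))
    W, H = frame_size
    cw = (W - 2 * margin - (cols - 1) * gap) // cols
    ch = (H - 2 * margin - (rows - 1) * gap) // rows
    if cw < 2 or ch < 2:
        raise SceneConfigError("frame too small for requested region count")
    if pixel_weights is not None:
        wmax = max(pixel_weights[rid] for rid in region_ids)
        scale = {rid: float(np.sqrt(pixel_weights[rid] / wmax)) for rid in region_ids}
    else:
        scale = {rid: 1.0 for rid in region_ids}
    specs = []
    for i, rid in enumerate(region_ids):
        r, c = divmod(i, cols)
        x0 = margin + c * (cw + gap)
        y0 = margin + r * (ch + gap)
        w = max(2, int(round(cw * scale[rid])))
        h = max(2, int(round(ch * scale[rid])))
        specs.append(RegionSpec(region_id=rid, thickness_um=table[rid].combined_thickness,
                                rect=(x0, y0, x0 + w, y0 + h)))
    return specs


def write_ubfc_layout(frames: np.ndarray, truth: GroundTruth, out_dir: str | Path,
                      regions: Optional[Sequence[RegionSpec]] = None) -> Path:
    """Write one synthetic subject in the on-disk layout of the benchmark sets.

    ``out_dir`` receives a lossless PNG frame sequence under ``vid/`` and a
    3-line ground-truth text file (pulse waveform, per-frame BPM, per-frame
    timestamps).  Region specs, when given, are stored as ``regions.json`` so
    the pipeline can rebuild the exact masks.
    """
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "vid").mkdir(parents=True, exist_ok=True)
    T = frames.shape[0]
    for k in range(T):
        u8 = np.clip(np.round(frames[k]), 0, 255).astype(np.uint8)
        iio.imwrite(out / "vid" / f"frame_{k:05d}.png", u8)
    times = np.arange(T) / truth.fps
    hr_frames = truth.hr_at(times)
    with open(out / "ground_truth.txt", "w", encoding="utf-8") as fh:
        for row in (truth.bvp, hr_frames, times):
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
    meta = {"fps": truth.fps, "n_frames": int(T)}
    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=1)
    if regions is not None:
        payload = [
            {"region_id": s.region_id, "thickness_um": s.thickness_um,
             "rect": list(s.rect) if s.rect is not None else None,
             "polygon": [list(p) for p in s.polygon] if s.polygon is not None else None}
            for s in regions
        ]
        with open(out / "regions.json", "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
    return out


def synthesize_dataset(out_root: str | Path, n_subjects: int, region_ids: Sequence[int],
                       preset: str = "mild", frame_size: tuple[int, int] = (64, 64),
                       fps: float = 30.0, duration: float = 30.0, seed: int = 0,
                       amplitude_scale: float = 0.02) -> list[Path]:
    """Render ``n_subjects`` seeded scenes into a dataset directory tree."""
    if preset not in NOISE_PRESETS:
        raise SceneConfigError(f"unknown preset {preset!r}")
    out_root = Path(out_root)
    paths = []
    rng = np.random.default_rng(seed)
    for i in range(n_subjects):
        hr0 = float(rng.uniform(60.0, 90.0))
        hr1 = float(np.clip(hr0 + rng.uniform(-15.0, 15.0), 50.0, 110.0))
        specs = grid_region_specs(frame_size, region_ids)
        cfg = SceneConfig(regions=specs, frame_size=frame_size, fps=fps,
                          duration=duration, noise=NOISE_PRESETS[preset],
                          amplitude_scale=amplitude_scale,
                          hr_profile=lambda t, a=hr0, b=hr1: a + (b - a) * t / max(t[-1], 1e-9),
                          seed=int(seed * 1000 + i))
        frames, _, truth = render_scene(cfg)
        paths.append(write_ubfc_layout(frames, truth, out_root / f"subject{i + 1}",
                                       regions=specs))
    return paths
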