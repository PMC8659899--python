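import pytest

from roipulse.geometry import canonical_landmarks, extract_rgb_trace
from roipulse.synth import (
    NOISE_PRESETS,
    NoiseParams,
    SceneConfig,
    grid_region_specs,
    render_scene,
)

SCENE_REGION_IDS = [27, 10, 3, 0, 28, 16, 12, 14]


@pytest.fixture(scope="session")
def frontal_landmarks():
    return canonical_landmarks((128, 128))


@pytest.fixture(scope="session")
def textured_scene():
    """Noise-free scene with static skin texture only (rank-3 pixel stats)."""
    specs = grid_region_specs((64, 64), SCENE_REGION_IDS, pixel_weights=None)
    cfg = SceneConfig(regions=specs, frame_size=(64, 64), fps=30.0, duration=60.0,
                      hr_profile=72.0, noise=NoiseParams(albedo_sd=0.05), seed=1)
    frames, masks, truth = render_scene(cfg)
    return cfg, frames, masks, truth


@pytest.fixture(scope="session")
def textured_trace(textured_scene):
    cfg, frames, masks, truth = textured_scene
    trace = extract_rgb_trace(frames, masks[27], cfg.fps, keep_pixels=True, seed=0)
    return trace, truth


@pytest.fixture(scope="session")
def mild_scene():
    specs = grid_region_specs((96, 96), SCENE_REGION_IDS)
    cfg = SceneConfig(regions=specs, frame_size=(96, 96), fps=30.0, duration=30.0,
                      hr_profile=72.0, amplitude_scale=0.008,
                      noise=NOISE_PRESETS["mild"], seed=3)
    frames, masks, truth = render_scene(cfg)
    return cfg, frames, masks, truth


def brute_force_point_in_polygon(x, y, verts):
    """Scalar crossing-number test over a +x ray; independent oracle."""
    inside = False
    n = len(verts)
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_cross:
                inside = not inside
    return inside
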