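"""Synthetic crystal scenes, growth sequences and kinetics datasets.

These generators emulate the study conditions of a reflective-light growth
cell: a single bright convex hexagonal crystal on a darker, unevenly
illuminated, noisy background, imaged at constant time intervals while its
facet normal distances grow linearly.  Every generator is a pure function of
its seed, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import HexTemplate, render_hard_mask

__all__ = [
    "SceneParams",
    "SequenceParams",
    "SIGMA_GRID_DEFAULT",
    "KINETICS_FACE_DEFAULTS",
    "render_crystal_image",
    "generate_growth_sequence",
    "generate_kinetics_dataset",
    "default_sequence_params",
    "write_sequence",
]

#: Nine relative supersaturations spanning 0.28-1.21, the standard design
#: for growth-cell kinetics measurements of beta-L-glutamic acid.
SIGMA_GRID_DEFAULT = np.array(
    [1.21, 1.05, 0.91, 0.78, 0.66, 0.53, 0.40, 0.32, 0.28]
)

#: Default generating conditions for per-face synthetic kinetics datasets,
#: emulating beta-L-glutamic acid: the fast {101} capping faces grow by a
#: Birth & Spread mechanism with a nucleation barrier placing the 1%
#: detectability dead zone near sigma_c ~ 0.23; the slow {021} prismatic
#: faces follow a BCF spiral mechanism.  k_mt values put the mass-transfer
#: resistance on the 1e7-1e8 s/m scale typical of stagnant growth cells
#: (MT-limited capping, GSI-limited prismatic); A1 sets the surface
#: integration resistance scale and A2 sits in the tanh/exp transition band
#: where each mechanism's curvature is identifiable on the default sigma
#: grid.
KINETICS_FACE_DEFAULTS = {
    "capping": {
        "model": "birth_spread",
        "params": {"A1": 1.157e-6, "A2": 1.387},
        "k_mt": 7.85e-6,
    },
    "prismatic": {
        "model": "bcf",
        "params": {"A1": 8.807e-9, "A2": 1.0},
        "k_mt": 9.83e-7,
    },
}


@dataclass
class SceneParams:
    """One rendered frame: ground-truth template plus imaging conditions.

    Intensities are on a [0, 1] scale.  ``illum_gradient`` is the linear
    intensity slope per pixel (x, y) about the frame centre, emulating
    uneven illumination; ``blur_sigma`` the optical blur (px); ``noise_sd``
    the additive Gaussian sensor noise.
    """

    template: HexTemplate
    shape: tuple[int, int] = (256, 256)
    fg: float = 0.75
    bg: float = 0.30
    illum_gradient: tuple[float, float] = (2.5e-4, 1.5e-4)
    blur_sigma: float = 1.2
    noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fg <= self.bg:
            raise ValueError("foreground must be brighter than background")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def render_crystal_image(p: SceneParams) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame; returns ``(image, ground_truth_mask)``.

    The ground-truth mask is the unblurred, noise-free polygon raster.
    """
    mask = render_hard_mask(p.template, p.shape)
    img = p.bg + (p.fg - p.bg) * mask.astype(float)
    h, w = p.shape
    ys, xs = np.mgrid[0:h, 0:w]
    img = img + p.illum_gradient[0] * (xs - w / 2) + p.illum_gradient[1] * (
        ys - h / 2
    )
    if p.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, p.blur_sigma)
    rng = np.random.default_rng(p.seed)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0), mask


@dataclass
class SequenceParams:
    """A linear-growth time-lapse.

    ``rates`` holds six per-face normal growth rates in px/frame, in the
    ``dists`` layout (3 directions x {+, -}); negative rates model
    dissolve-back and distances are clipped at zero.
    """

    scene: SceneParams
    rates: np.ndarray
    n_frames: int = 20
    frame_interval_s: float = 60.0
    pixel_size_um: float = 0.5

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float).reshape(3, 2)
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")
        if not np.all(np.isfinite(self.rates)):
            raise ValueError("rates must be finite")


def default_sequence_params(seed: int = 0) -> SequenceParams:
    """The documented default growth sequence used throughout the tests.

    A 256x256 needle-habit crystal (short prismatic pair, long capping
    pairs) growing with fast capping and slow prismatic faces, mirroring
    the anisotropy of beta-L-glutamic acid.
    """
    template = HexTemplate(
        center=np.array([126.0, 130.0]),
        theta1=12.0,
        dists=np.array([[20.0, 22.0], [58.0, 61.0], [56.0, 59.0]]),
    )
    scene = SceneParams(template=template, seed=seed)
    rates = np.array([[0.10, 0.12], [1.05, 1.10], [1.00, 1.15]])
    return SequenceParams(scene=scene, rates=rates)


def generate_growth_sequence(
    p: SequenceParams,
) -> tuple[list[np.ndarray], list[HexTemplate], np.ndarray]:
    """Render the sequence; returns ``(images, true_templates, times_s)``.

    Frame t has distances ``clip(d0 + rate * t, 0)``; per-frame noise seeds
    are spawned deterministically from the scene seed.
    """
    seeds = np.random.SeedSequence(p.scene.seed).generate_state(p.n_frames)
    images, truths = [], []
    base = p.scene.template
    for t in range(p.n_frames):
        dists = np.clip(base.dists + p.rates * t, 0.0, None)
        tmpl = replace(base.copy(), dists=dists)
        scene_t = replace(p.scene, template=tmpl, seed=int(seeds[t] % (2**31)))
        img, _ = render_crystal_image(scene_t)
        images.append(img)
        truths.append(tmpl)
    times = np.arange(p.n_frames) * p.frame_interval_s
    return images, truths, times


def generate_kinetics_dataset(
    model: str,
    params: dict,
    k_mt: float,
    props,
    sigmas: Sequence[float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """(sigma, G) table from a known generating model.

    Noise is multiplicative Gaussian, ``G * (1 + eps)``; negative rates are
    clipped to zero.  With ``noise_sd=0`` the exact model curve is returned.
    """
    from .kinetics import model_growth_rate

    sig = SIGMA_GRID_DEFAULT if sigmas is None else np.asarray(sigmas, float)
    if np.any(sig < 0):
        raise ValueError("sigmas must be >= 0")
    g = model_growth_rate(model, params, k_mt, props, sig)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        g = g * (1.0 + rng.normal(0.0, noise_sd, size=g.shape))
    return sig, np.clip(g, 0.0, None)


def write_sequence(p: SequenceParams, out_dir: str | Path) -> Path:
    """Write numbered 16-bit PNG frames plus a CSV manifest.

    The manifest records filename, timestamp, pixel size and the
    ground-truth template parameters per frame; returns the manifest path.
    """
    import imageio.v3 as iio
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images, truths, times = generate_growth_sequence(p)
    rows = []
    for i, (img, tmpl, t) in enumerate(zip(images, truths, times)):
        name = f"frame_{i:04d}.png"
        iio.imwrite(out / name, (img * 65535).round().astype(np.uint16))
        d = tmpl.dists
        rows.append(
            {
                "frame": i,
                "filename": name,
                "time_s": t,
                "pixel_size_um": p.pixel_size_um,
                "true_cx": tmpl.center[0],
                "true_cy": tmpl.center[1],
                "true_theta1": tmpl.theta1,
                **{
                    f"true_d{i+1}{s}": d[i, j]
                    for i in range(3)
                    for j, s in enumerate("pm")
                },
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
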