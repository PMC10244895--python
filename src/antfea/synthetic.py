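"""Synthetic inputs: parametric head-like outlines and per-element stress tables.

Two independent generators make the whole pipeline testable offline:

* :func:`generate_head_outline` draws a radius-modulated closed curve
  ``r(theta)`` whose terms mimic the two extremes of *Pheidole* worker head
  morphology — broad, heart-shaped major heads (posterolateral lobes, vertex
  concavity, width > height) and narrow, rounded minor heads — then scales it
  anisotropically to a requested width/height ratio and area.
* :func:`generate_element_tables` draws per-element Tresca stresses from
  model-specific log-normal distributions (the heavy right tail motivates the
  top-2% artifact filter downstream) together with positive element areas.

Both are pure functions of their parameters and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import (Outline, OutlineError, RegionSpec, annotate_regions,
                       outline_area, polygon_signed_area)

logger = logging.getLogger(__name__)

# Fixed sculpting constants of the outline family (radians); not exposed as
# parameters because they define the family, not the morphospace position.
_LOBE_CENTERS = (np.deg2rad(45.0), np.deg2rad(135.0))
_LOBE_WIDTH = np.deg2rad(30.0)
_VERTEX_CENTER = np.deg2rad(90.0)
_VERTEX_WIDTH = np.deg2rad(18.0)
_BASE_CENTER = np.deg2rad(270.0)
_BASE_WIDTH = np.deg2rad(40.0)
_BASE_FLATTEN = 0.15  # mild narrowing at the mandibular base, all morphs


@dataclass(frozen=True)
class HeadShapeParams:
    """Morphospace coordinates of one synthetic head outline.

    width_height_ratio
        Target head width / head height (majors > 1, minors < 1).
    lobe_amplitude
        Posterolateral lobe strength ("heart-shapedness"), 0 for rounded heads.
    vertex_concavity
        Depth of the midline notch at the vertex (top of the head).
    harmonic_noise
        Amplitude of a low-order Fourier perturbation (breaks exact symmetry).
    scale
        Target outline area in mm^2.
    """

    width_height_ratio: float = 1.0
    lobe_amplitude: float = 0.0
    vertex_concavity: float = 0.0
    harmonic_noise: float = 0.0
    scale: float = 1.0
    seed: int = 0
    n_theta: int = 256

    def __post_init__(self) -> None:
        if self.scale <= 0 or self.width_height_ratio <= 0:
            raise ValueError("scale and width_height_ratio must be positive")
        if self.n_theta < 16 or self.n_theta % 2:
            raise ValueError("n_theta must be an even count >= 16")


def _angular_bump(theta: np.ndarray, center: float, width: float) -> np.ndarray:
    d = np.angle(np.exp(1j * (theta - center)))  # wrapped difference
    return np.exp(-0.5 * (d / width) ** 2)


def _radius(theta: np.ndarray, p: HeadShapeParams, rng: np.random.Generator,
            noise_scale: float) -> np.ndarray:
    r = np.ones_like(theta)
    for c in _LOBE_CENTERS:
        r += p.lobe_amplitude * _angular_bump(theta, c, _LOBE_WIDTH)
    r -= p.vertex_concavity * _angular_bump(theta, _VERTEX_CENTER, _VERTEX_WIDTH)
    r -= _BASE_FLATTEN * _angular_bump(theta, _BASE_CENTER, _BASE_WIDTH)
    if p.harmonic_noise > 0:
        for k in range(2, 6):
            amp = rng.normal(0.0, p.harmonic_noise / k) * noise_scale
            phase = rng.uniform(0.0, 2.0 * np.pi)
            r += amp * np.cos(k * theta + phase)
    return r


def generate_head_outline(params: HeadShapeParams, name: str | None = None,
                          region_spec: RegionSpec | None = None,
                          max_retries: int = 5) -> Outline:
    """Generate one head-like outline in the standard frame, regions annotated.

    The achieved area equals ``params.scale`` to rescaling precision and the
    achieved width/height ratio equals the request exactly (anisotropic
    scaling).  With ``harmonic_noise=0`` the outline is midline-symmetric to
    machine precision.  Raises :class:`OutlineError` if noise produces a
    self-intersecting curve after ``max_retries`` attenuated retries.
    """
    rng = np.random.default_rng(params.seed)
    theta = np.linspace(0.0, 2.0 * np.pi, params.n_theta, endpoint=False)
    last_err: Exception | None = None
    for attempt in range(max_retries):
        noise_scale = 0.5 ** attempt  # attenuate on retry
        r = _radius(theta, params, rng, noise_scale)
        if np.any(r <= 0.05):
            last_err = OutlineError("radius collapsed; parameters too extreme")
            continue
        x = r * np.cos(theta)
        y = r * np.sin(theta)
        # exact width/height ratio by anisotropic scaling
        width = x.max() - x.min()
        height = y.max() - y.min()
        x = x * (params.width_height_ratio * height / width)
        v = np.column_stack([x, y])
        if polygon_signed_area(v) <= 0:  # theta increases CCW, so always true
            v = v[::-1]
        # exact area by uniform rescale
        v *= np.sqrt(params.scale / polygon_signed_area(v))
        v[:, 0] -= 0.5 * (v[:, 0].min() + v[:, 0].max())  # midline at x=0
        try:
            out = Outline(v, name=name or f"head_seed{params.seed}")
            return annotate_regions(out, region_spec)
        except OutlineError as err:
            last_err = err
            if params.harmonic_noise == 0:
                raise
    raise OutlineError(
        f"could not generate a simple outline after {max_retries} retries: {last_err}"
    )


# Morph-specific parameter ranges for cohorts: majors are wide and
# heart-shaped, minors narrow and rounded; areas span the magnitudes of real
# worker heads (roughly 0.1-3.5 mm^2).
_MAJOR_RANGES = dict(width_height_ratio=(1.15, 1.35), lobe_amplitude=(0.15, 0.30),
                     vertex_concavity=(0.10, 0.20), scale=(0.6, 3.5))
_MINOR_RANGES = dict(width_height_ratio=(0.80, 0.95), lobe_amplitude=(0.0, 0.05),
                     vertex_concavity=(0.0, 0.05), scale=(0.14, 0.95))


def generate_cohort(n_major: int, n_minor: int, seed: int = 0,
                    harmonic_noise: float = 0.01,
                    area_range_major: tuple[float, float] | None = None,
                    area_range_minor: tuple[float, float] | None = None) -> list[Outline]:
    """Generate a cohort of uniquely named major and minor head outlines."""
    if n_major < 1 or n_minor < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    outlines: list[Outline] = []
    for morph, n, ranges, area_rng in (
        ("major", n_major, _MAJOR_RANGES, area_range_major),
        ("minor", n_minor, _MINOR_RANGES, area_range_minor),
    ):
        for i in range(n):
            draws = {k: rng.uniform(*v) for k, v in ranges.items()}
            if area_rng is not None:
                draws["scale"] = rng.uniform(*area_rng)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            p = HeadShapeParams(harmonic_noise=harmonic_noise, seed=sub_seed, **draws)
            outlines.append(generate_head_outline(p, name=f"{morph}_{i + 1:02d}"))
    return outlines


@dataclass(frozen=True)
class SyntheticStressParams:
    """Log-normal element-stress tables shaped like solver output.

    ``models`` maps model name -> (log-location mu, log-scale sigma) of its
    Tresca stress distribution in ln(MPa).  Defaults centre the filtered means
    near the ~0.7 MPa magnitude of real worker-head simulations, with a heavy
    right tail (sigma = 0.8).  Element areas are log-normal around
    ``mean_area`` mm^2 with mild spread.
    """

    models: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"model_a": (-0.8, 0.8), "model_b": (-0.5, 0.8)})
    n_elements: int = 5000
    mean_area: float = 4e-5
    area_sigma: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_elements < 1 or self.mean_area <= 0 or self.area_sigma < 0:
            raise ValueError("invalid SyntheticStressParams")


def generate_element_tables(params: SyntheticStressParams) -> pd.DataFrame:
    """Synthetic per-element table: columns model, element_id, tresca, area_mm2."""
    rng = np.random.default_rng(params.seed)
    frames = []
    for model, (mu, sigma) in params.models.items():
        stress = rng.lognormal(mu, sigma, params.n_elements)
        area = rng.lognormal(np.log(params.mean_area) - 0.5 * params.area_sigma**2,
                             params.area_sigma, params.n_elements)
        frames.append(pd.DataFrame({
            "model": model,
            "element_id": np.arange(1, params.n_elements + 1),
            "tresca": stress,
            "area_mm2": area,
        }))
    return pd.concat(frames, ignore_index=True)
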