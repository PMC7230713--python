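"""Synthetic Vis-NIR spectra and hypercubes of partially scaled fish surfaces.

The generator emulates the statistical structure the downstream analysis
assumes rather than any particular instrument:

* two smooth reflectance endmembers — scale and skin — with the scale curve
  everywhere brighter than skin and with absorption dips near 420 nm
  (porphyrins), in the 500–600 nm window (metmyoglobin) and near 960 nm
  (water overtone);
* linear areal mixing: the mean spectrum of a region with scaling rate
  ``P`` (percent of area scaled, i.e. skin exposed) is
  ``(1 - P/100) * scale + (P/100) * skin``, so reflectance decreases
  monotonically as ``P`` grows;
* per-sample multiplicative gain and additive baseline (the artifacts MSC
  and SNV remove) plus per-band white sensor noise (what SG smoothing
  removes).

All randomness flows through a single integer seed: identical seeds yield
bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import SpectralDataset, WavelengthAxis

__all__ = [
    "EndmemberPair",
    "ScenePhysics",
    "HypercubeScene",
    "generate_endmembers",
    "mixing_spectrum",
    "simulate_dataset",
    "simulate_cube",
]

# Absorption-dip windows (centre nm, width nm) shared by scale and skin.
_DIPS = ((420.0, 9.0), (545.0, 18.0), (960.0, 12.0))


@dataclass(frozen=True)
class EndmemberPair:
    """Reflectance endmembers (unitless fractions, 0–1) on a shared axis."""

    scale_spectrum: np.ndarray
    skin_spectrum: np.ndarray

    def __post_init__(self) -> None:
        scale = np.asarray(self.scale_spectrum, dtype=float)
        skin = np.asarray(self.skin_spectrum, dtype=float)
        object.__setattr__(self, "scale_spectrum", scale)
        object.__setattr__(self, "skin_spectrum", skin)
        if scale.shape != skin.shape or scale.ndim != 1:
            raise ValueError("endmember spectra must be 1-D and congruent")
        if np.any(scale < skin):
            raise ValueError("scale endmember must reflect at least as much as skin")


@dataclass(frozen=True)
class ScenePhysics:
    """Per-sample/pixel measurement artifacts and the RNG seed.

    ``scatter_slope_sd`` disperses a multiplicative gain around 1,
    ``baseline_sd`` an additive offset around 0 (percent-reflectance units),
    ``noise_sd`` is the per-band white-noise SD (percent reflectance).

    The default ``noise_sd`` describes ROI-mean sample spectra: averaging a
    2 x 2 cm region (>= ~10^3 pixels) over triplicate scans divides
    pixel-level sensor noise (~1 % reflectance) by
    sqrt(n_pixels * n_replicates), leaving a few hundredths of a percent per
    band; the default keeps a visible 0.05 % floor. Pass a larger value when
    simulating per-pixel cubes.
    """

    scatter_slope_sd: float = 0.1
    baseline_sd: float = 2.0
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scatter_slope_sd", "baseline_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class HypercubeScene:
    """Raw intensity cube with reference frames and the ground-truth mask.

    ``cube``, ``white_frame`` and ``dark_frame`` are ``(rows, cols, bands)``
    intensity arrays (the raw image and the white/dark reference images that
    feed reflectance correction); ``scale_mask`` is True where scales remain.
    """

    cube: np.ndarray
    white_frame: np.ndarray
    dark_frame: np.ndarray
    scale_mask: np.ndarray
    region_label: str
    axis: WavelengthAxis

    def __post_init__(self) -> None:
        if self.cube.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if self.white_frame.shape != self.cube.shape:
            raise ValueError("white frame shape must match the cube")
        if self.dark_frame.shape != self.cube.shape:
            raise ValueError("dark frame shape must match the cube")
        if self.scale_mask.shape != self.cube.shape[:2]:
            raise ValueError("scale mask must match the cube's spatial shape")
        if not np.all(self.white_frame > self.dark_frame):
            raise ValueError("white frame must exceed dark frame everywhere")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_endmembers(axis: WavelengthAxis, seed: int) -> EndmemberPair:
    """Draw a smooth scale/skin endmember pair.

    Both curves share a slowly rising base (reflectivity grows towards the
    NIR), Gaussian absorption dips at the three characteristic windows, and
    a small seed-dependent long-period undulation. The scale curve sits a
    strictly positive, smoothly varying gap above the skin curve.
    """
    lam = axis.values
    if lam.size < 10:
        raise ValueError("axis too short: endmember synthesis needs >= 10 bands")
    rng = np.random.default_rng(seed)

    base = 0.18 + 0.30 * _logistic((lam - 640.0) / 110.0)

    # Exposed skin absorbs more strongly at every characteristic window
    # (water, pigments) than the largely inorganic scale, so the skin dips
    # are deeper; the wavelength-dependent difference is what makes the
    # scaling-rate signature separable from flat gain/baseline artifacts.
    dips_skin = np.zeros_like(lam)
    dips_scale = np.zeros_like(lam)
    for centre, width in _DIPS:
        amp = 0.06 + 0.03 * rng.random()
        ratio = 0.4 + 0.2 * rng.random()  # scale dip depth relative to skin
        bump = np.exp(-0.5 * ((lam - centre) / width) ** 2)
        dips_skin += amp * bump
        dips_scale += ratio * amp * bump

    # Long-period undulation; amplitude kept well below the dip depths so the
    # three absorption minima survive.
    span = lam[-1] - lam[0]
    undulation = np.zeros_like(lam)
    for _ in range(3):
        period = span * (0.8 + 0.8 * rng.random())
        phase = 2.0 * np.pi * rng.random()
        undulation += 0.004 * rng.random() * np.cos(2.0 * np.pi * lam / period + phase)

    skin = base - dips_skin + undulation
    u = (lam - lam[0]) / span
    offset = (0.06 + 0.03 * rng.random()) + (0.03 * rng.random()) * u
    scale = skin + offset + (dips_skin - dips_scale)
    return EndmemberPair(scale_spectrum=scale, skin_spectrum=skin)


def mixing_spectrum(endmembers: EndmemberPair, rate_percent: float) -> np.ndarray:
    """Noise-free areal mixture (reflectance fraction) at scaling rate ``P``.

    ``P`` percent of the region area is scaled (skin exposed), so skin
    contributes with weight ``P/100``.
    """
    w = rate_percent / 100.0
    return (1.0 - w) * endmembers.scale_spectrum + w * endmembers.skin_spectrum


def _apply_physics(
    mix_fraction: np.ndarray,
    physics: ScenePhysics,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gain/offset/noise on top of noise-free mixtures; output in percent."""
    n = mix_fraction.shape[0]
    gains = 1.0 + physics.scatter_slope_sd * rng.standard_normal(n)
    offsets = physics.baseline_sd * rng.standard_normal(n)
    noise = physics.noise_sd * rng.standard_normal(mix_fraction.shape)
    return gains[:, None] * (100.0 * mix_fraction) + offsets[:, None] + noise


def simulate_dataset(
    n: int,
    axis: WavelengthAxis,
    physics: ScenePhysics,
    rate_range: tuple[float, float] = (0.0, 100.0),
    region: str = "back",
    endmembers: EndmemberPair | None = None,
) -> SpectralDataset:
    """Simulate ``n`` region-mean spectra with uniformly drawn scaling rates.

    Each sample is ``gain * (100 * mixture) + offset + noise`` in percent
    reflectance, with the paired true scaling rate stored in percent.
    Deterministic for a fixed ``physics`` (including its seed).
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    low, high = float(rate_range[0]), float(rate_range[1])
    if not (0.0 <= low <= high <= 100.0):
        raise ValueError("rate_range must be a non-empty subinterval of [0, 100]")
    rng = np.random.default_rng(physics.seed)
    if endmembers is None:
        endmembers = generate_endmembers(axis, seed=physics.seed)
    rates = rng.uniform(low, high, size=n)
    mix = np.stack([mixing_spectrum(endmembers, p) for p in rates])
    spectra = _apply_physics(mix, physics, rng)
    return SpectralDataset(
        axis=axis,
        spectra=spectra,
        responses=rates,
        region=region,
        reflectance_scale="percent",
    )


def simulate_cube(
    rows: int,
    cols: int,
    coverage_fraction: float,
    axis: WavelengthAxis,
    physics: ScenePhysics,
    region: str = "back",
    endmembers: EndmemberPair | None = None,
) -> HypercubeScene:
    """Simulate a raw intensity cube with white/dark frames and a truth mask.

    ``coverage_fraction`` is the fraction of pixels still covered by scales,
    so the scene's true scaling rate is ``100 * (1 - coverage_fraction)``.
    Raw intensities are synthesised so that white/dark reflectance correction
    recovers each pixel's percent reflectance exactly.
    """
    if rows * cols == 0:
        raise ValueError("cube must contain at least one pixel")
    if not (0.0 <= coverage_fraction <= 1.0):
        raise ValueError("coverage_fraction must lie in [0, 1]")
    rng = np.random.default_rng(physics.seed)
    if endmembers is None:
        endmembers = generate_endmembers(axis, seed=physics.seed)

    n_pixels = rows * cols
    n_scale = int(round(coverage_fraction * n_pixels))
    flat_mask = np.zeros(n_pixels, dtype=bool)
    flat_mask[rng.permutation(n_pixels)[:n_scale]] = True
    mask = flat_mask.reshape(rows, cols)

    ends = np.where(
        flat_mask[:, None], endmembers.scale_spectrum, endmembers.skin_spectrum
    )
    reflect_pct = _apply_physics(ends, physics, rng).reshape(rows, cols, len(axis))

    lam = axis.values
    # Smooth lamp/sensor response; spatially constant reference frames.
    white_band = 2500.0 + 1500.0 * np.exp(-0.5 * ((lam - 700.0) / 250.0) ** 2)
    dark_band = 80.0 + 10.0 * (lam - lam[0]) / (lam[-1] - lam[0])
    white = np.broadcast_to(white_band, (rows, cols, len(axis))).copy()
    dark = np.broadcast_to(dark_band, (rows, cols, len(axis))).copy()

    cube = dark + (white - dark) * reflect_pct / 100.0
    return HypercubeScene(
        cube=cube,
        white_frame=white,
        dark_frame=dark,
        scale_mask=mask,
        region_label=region,
        axis=axis,
    )
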