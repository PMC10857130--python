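"""Synthetic gas-adsorbed sensor-array scans and labeled feature datasets.

The generator emulates what the physical measurement produces: an odor source
evaporating benzaldehyde (BZD) or 4-ethylbenzaldehyde (EBZD) creates a 2D
Gaussian concentration plume over the sensor array; each grid point's spectrum
is the plume-weighted gas signature plus a sensor baseline and noise.  Narrow
bands of points falling in the gaps between the individual sensors of the 3 × 3
array carry noise-only spectra.

Signature peaks follow the reference compounds: BZD at 1006 and 1603 cm⁻¹,
EBZD at 1614 cm⁻¹, and a sensor baseline with residual-chemistry peaks at
900, 1050 and 1400 cm⁻¹.  Lineshapes are Lorentzian by default (the standard
Raman line model); a Gaussian lineshape is selectable.

Every operation is deterministic under its seed, and the clean (noise-free)
scan is exactly the generative formula, so the simulator doubles as the
ground-truth oracle for unmixing, localization and identification tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from .scan import (
    GridGeometry,
    HyperspectralScan,
    LabeledSpectrumDataset,
    WavenumberAxis,
    pixel_center_mm,
)

__all__ = [
    "GasSignature",
    "SourceSpec",
    "NoiseModel",
    "BZD",
    "EBZD",
    "BASELINE",
    "DEFAULT_SIGNATURES",
    "make_axis",
    "default_axis",
    "signature_spectrum",
    "plume_field",
    "gap_mask",
    "simulate_scan",
    "simulate_feature_dataset",
]

Lineshape = Literal["lorentzian", "gaussian"]


@dataclass(frozen=True)
class GasSignature:
    """A compound's Raman signature as a list of (center cm⁻¹, FWHM cm⁻¹, amplitude)."""

    name: str
    peaks: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError("signature needs at least one peak")
        for c, fwhm, a in self.peaks:
            if fwhm <= 0:
                raise ValueError("peak FWHM must be positive")
            if a <= 0:
                raise ValueError("peak amplitude must be positive")


@dataclass(frozen=True)
class SourceSpec:
    """A single odor source: gas name, plume center/widths (mm) and strength."""

    gas: str
    center: tuple[float, float]  # (x_mm, y_mm)
    sigma: tuple[float, float]  # (σx_mm, σy_mm)
    strength: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma[0] <= 0 or self.sigma[1] <= 0:
            raise ValueError("plume sigmas must be positive")
        if self.strength < 0:
            raise ValueError("strength must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise settings.

    additive_sd is expressed as a fraction of the maximum clean signal;
    multiplicative_sd is the lognormal spread of the per-pixel adsorption
    multiplier (gas adsorption has a degree of randomness); gap_band_width is
    the width in pixels of the inter-sensor gap bands.
    """

    additive_sd: float = 0.01
    multiplicative_sd: float = 0.05
    gap_band_width: int = 1
    seed: int = 42

    def __post_init__(self) -> None:
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.gap_band_width < 0:
            raise ValueError("gap band width must be non-negative")


# Reference signatures (relative amplitudes; the stronger ring-breathing band
# of BZD at 1006 cm⁻¹ is taken as the unit).
BZD = GasSignature("BZD", ((1006.0, 20.0, 1.0), (1603.0, 20.0, 0.8)))
EBZD = GasSignature("EBZD", ((1614.0, 20.0, 1.0),))
BASELINE = GasSignature(
    "baseline", ((900.0, 25.0, 1.0), (1050.0, 25.0, 0.7), (1400.0, 25.0, 0.5))
)
DEFAULT_SIGNATURES: Mapping[str, GasSignature] = {"BZD": BZD, "EBZD": EBZD}


def make_axis(start: float = 602.0, step: float = 4.0, m: int = 308) -> WavenumberAxis:
    """Uniform wavenumber axis: values[k] = start + k·step, length m.

    The default spans 602–1830 cm⁻¹ in 4 cm⁻¹ steps (308 channels), covering
    all signature peaks.
    """
    if step <= 0:
        raise ValueError("axis step must be positive")
    if m < 2:
        raise ValueError("axis needs at least 2 channels")
    return WavenumberAxis(start + step * np.arange(m), resolution_hint=step)


def default_axis() -> WavenumberAxis:
    return make_axis()


def signature_spectrum(
    sig: GasSignature,
    axis: WavenumberAxis,
    lineshape: Lineshape = "lorentzian",
) -> np.ndarray:
    """Evaluate a signature on the axis.

    Lorentzian: S(ν) = Σ a / (1 + ((ν − c) / (fwhm/2))²); peaks reach exactly
    their amplitude at ν = c and half of it at ν = c ± fwhm/2.
    """
    nu = axis.values
    S = np.zeros_like(nu)
    for c, fwhm, a in sig.peaks:
        if lineshape == "lorentzian":
            S += a / (1.0 + ((nu - c) / (fwhm / 2.0)) ** 2)
        elif lineshape == "gaussian":
            S += a * np.exp(-4.0 * np.log(2.0) * ((nu - c) / fwhm) ** 2)
        else:
            raise ValueError(f"unknown lineshape {lineshape!r}")
    return S


def plume_field(source: SourceSpec, geometry: GridGeometry) -> np.ndarray:
    """2D Gaussian plume sampled at pixel centers, as an n_rows × n_cols grid.

    G(x, y) = strength · exp(−((x−x0)²/(2σx²) + (y−y0)²/(2σy²)))
    """
    x0, y0 = source.center
    sx, sy = source.sigma
    p = geometry.pitch
    x = (np.arange(geometry.n_cols) + 0.5) * p
    y = (np.arange(geometry.n_rows) + 0.5) * p
    X, Y = np.meshgrid(x, y)
    return source.strength * np.exp(
        -((X - x0) ** 2 / (2 * sx**2) + (Y - y0) ** 2 / (2 * sy**2))
    )


def gap_mask(
    geometry: GridGeometry,
    sensors_per_side: int = 3,
    band_width: int = 1,
) -> np.ndarray:
    """Boolean grid marking pixels in the gaps between individual sensors.

    The array is a sensors_per_side × sensors_per_side mosaic; a band of
    ``band_width`` pixels starting at each internal sensor boundary (rows and
    columns 12 and 24 for the 36-point, 3-sensor default) is marked.
    """
    if geometry.n_cols % sensors_per_side or geometry.n_rows % sensors_per_side:
        raise ValueError("grid size must be divisible by sensors_per_side")
    mask = np.zeros((geometry.n_rows, geometry.n_cols), dtype=bool)
    if band_width == 0:
        return mask
    row_pitch = geometry.n_rows // sensors_per_side
    col_pitch = geometry.n_cols // sensors_per_side
    for b in range(1, sensors_per_side):
        mask[b * row_pitch : b * row_pitch + band_width, :] = True
        mask[:, b * col_pitch : b * col_pitch + band_width] = True
    return mask


def simulate_scan(
    sources: Sequence[SourceSpec],
    signatures: Mapping[str, GasSignature] = DEFAULT_SIGNATURES,
    baseline: GasSignature = BASELINE,
    noise: NoiseModel = NoiseModel(),
    geometry: GridGeometry = GridGeometry(),
    axis: WavenumberAxis | None = None,
    baseline_strength: float = 0.3,
    background: float = 0.1,
    lineshape: Lineshape = "lorentzian",
) -> HyperspectralScan:
    """Simulate one full array scan.

    Each non-gap pixel p gets V[p] = Σ_g plume_g(p)·m_p·S_g + b·B + bg + ε_p,
    with m_p a per-pixel lognormal adsorption multiplier, b·B the sensor
    baseline, bg a flat broadband background (fluorescence pedestal) and ε
    additive white noise; gap pixels carry noise-only spectra.  All
    intensities are clipped to ≥ 0; the clipped fraction over signal-bearing
    pixels is recorded in metadata.  Deterministic under ``noise.seed``.
    """
    axis = axis or default_axis()
    for s in sources:
        if s.gas not in signatures:
            raise KeyError(f"no signature defined for gas {s.gas!r}")

    rng = np.random.default_rng(noise.seed)
    n, m = geometry.n_points, len(axis)
    B = signature_spectrum(baseline, axis, lineshape)

    clean = np.zeros((n, m))
    for s in sources:
        field_flat = plume_field(s, geometry).ravel()
        S = signature_spectrum(signatures[s.gas], axis, lineshape)
        mult = (
            rng.lognormal(mean=0.0, sigma=noise.multiplicative_sd, size=n)
            if noise.multiplicative_sd > 0
            else np.ones(n)
        )
        clean += np.outer(field_flat * mult, S)
    clean += baseline_strength * B + background

    scale = clean.max() if clean.max() > 0 else 1.0
    V = clean + (
        rng.normal(0.0, noise.additive_sd * scale, size=(n, m))
        if noise.additive_sd > 0
        else 0.0
    )

    gaps = gap_mask(geometry, band_width=noise.gap_band_width).ravel()
    if gaps.any():
        gap_sd = noise.additive_sd * scale if noise.additive_sd > 0 else 0.0
        V[gaps] = rng.normal(0.0, gap_sd, size=(int(gaps.sum()), m))

    clipped_signal = float((V[~gaps] < 0).mean()) if (~gaps).any() else 0.0
    V = np.clip(V, 0.0, None)
    meta = {
        "simulated": True,
        "seed": noise.seed,
        "sources": [
            {"gas": s.gas, "center": list(s.center), "sigma": list(s.sigma),
             "strength": s.strength}
            for s in sources
        ],
        "baseline_strength": baseline_strength,
        "background": background,
        "clipped_fraction_signal_pixels": clipped_signal,
    }
    return HyperspectralScan(geometry, axis, V, meta)


def simulate_feature_dataset(
    counts_per_class: tuple[int, int, int] = (68, 21, 13),
    jitter_cm: float = 2.0,
    amplitude_jitter: float = 0.1,
    noise_sd: float = 0.02,
    seed: int = 42,
    axis: WavenumberAxis | None = None,
    split_tag: str = "",
    lineshape: Lineshape = "lorentzian",
) -> LabeledSpectrumDataset:
    """Generate a labeled feature-spectrum dataset for classifier training.

    Class 1 spectra are jittered BZD signatures, class 2 jittered EBZD
    signatures, and class 0 (interference) is an even mix of jittered
    baseline-like spectra and pure-noise spectra.  Peak centers shift by
    U(−jitter_cm, +jitter_cm), amplitudes by a lognormal factor of spread
    ``amplitude_jitter``, and white noise of sd ``noise_sd`` (relative to the
    unit signature amplitude) is added.  Reproducible under ``seed``.

    counts_per_class is (n_interference, n_BZD, n_EBZD); the defaults are the
    reference training-set composition (68/21/13).
    """
    n0, n1, n2 = counts_per_class
    if n0 < 0 or n1 < 0 or n2 < 0:
        raise ValueError("class counts must be non-negative")
    if n0 + n1 + n2 == 0:
        raise ValueError("at least one class count must be positive")

    axis = axis or default_axis()
    rng = np.random.default_rng(seed)
    m = len(axis)

    def jittered(sig: GasSignature) -> np.ndarray:
        peaks = tuple(
            (
                c + rng.uniform(-jitter_cm, jitter_cm),
                fwhm,
                a * rng.lognormal(0.0, amplitude_jitter),
            )
            for c, fwhm, a in sig.peaks
        )
        s = signature_spectrum(GasSignature(sig.name, peaks), axis, lineshape)
        return np.clip(s + rng.normal(0.0, noise_sd, m), 0.0, None)

    spectra: list[np.ndarray] = []
    labels: list[int] = []
    for i in range(n0):
        if i % 2 == 0:
            spectra.append(jittered(BASELINE))
        else:  # pure noise, low amplitude relative to the unit signatures
            spectra.append(np.abs(rng.normal(0.0, 3 * noise_sd, m)))
        labels.append(0)
    for _ in range(n1):
        spectra.append(jittered(BZD))
        labels.append(1)
    for _ in range(n2):
        spectra.append(jittered(EBZD))
        labels.append(2)

    return LabeledSpectrumDataset(np.array(spectra), np.array(labels), split_tag)
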