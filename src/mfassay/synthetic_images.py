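"""Seeded generator of ground-truthed four-channel fluorescence spot images.

Each probe on a spot carries a Cy3/Cy5 FRET pair.  Before force application
every assembled probe contributes to both the direct-acceptor channel
("RED") and the FRET channel.  After the ramp, probes whose reference
duplex broke keep their Cy5 on the lower surface but lose FRET; probes
whose protein bond broke lose both; probes that were never coupled to the
upper surface (fraction ``1 - CE``) keep both.  Start/Final image pairs in
both channels therefore encode the rupture fraction ``q`` and the coupling
efficiency ``CE``:

    E[RED_final / RED_start]   = (1 - CE) + CE * q
    E[FRET_final / FRET_start] = (1 - CE)

The generator realizes these expectations per pixel with Poisson probe
counts, multinomial fate splitting, Gaussian illumination inhomogeneity,
distinct channel gains, optional bleaching, shot noise and read noise, and
writes 16-bit grayscale images.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

from mfassay.bond_kinetics import ForceRamp, SerialProbe, first_rupture_prob

__all__ = [
    "CHANNELS",
    "GaussianIllumination",
    "GroundTruth",
    "OpticalModel",
    "NoiseModel",
    "SpotImageSet",
    "ArrayExperiment",
    "circular_spot_mask",
    "expected_channel_images",
    "simulate_spot_imageset",
    "simulate_array_experiment",
]

CHANNELS = ("red_start", "fret_start", "red_final", "fret_final")

_U16_MAX = 65535


@dataclass(frozen=True)
class GroundTruth:
    """What the generator knows and the pipeline must recover."""

    q_ref_break: float
    coupling_efficiency: float
    probe_density: float = 50.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.q_ref_break <= 1.0:
            raise ValueError(f"q_ref_break must be in [0, 1], got {self.q_ref_break}")
        if not 0.0 <= self.coupling_efficiency <= 1.0:
            raise ValueError(
                f"coupling_efficiency must be in [0, 1], got {self.coupling_efficiency}"
            )
        if not self.probe_density > 0:
            raise ValueError(f"probe_density must be > 0, got {self.probe_density}")


@dataclass(frozen=True)
class GaussianIllumination:
    """Smooth 2-D Gaussian illumination field over the image.

    ``center`` is (row, col) in pixels; None centers the profile.  ``sigma``
    is (row, col) widths in pixels; None gives a flat field of height
    ``amplitude``.
    """

    center: tuple[float, float] | None = None
    sigma: tuple[float, float] | None = None
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude <= 0:
            raise ValueError(f"amplitude must be > 0, got {self.amplitude}")
        if self.sigma is not None and (self.sigma[0] <= 0 or self.sigma[1] <= 0):
            raise ValueError(f"sigma components must be > 0, got {self.sigma}")

    def field(self, shape: tuple[int, int]) -> np.ndarray:
        if self.sigma is None:
            return np.full(shape, self.amplitude)
        cr, cc = self.center if self.center is not None else (
            (shape[0] - 1) / 2.0,
            (shape[1] - 1) / 2.0,
        )
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        return self.amplitude * np.exp(
            -((rows - cr) ** 2) / (2 * self.sigma[0] ** 2)
            - ((cols - cc) ** 2) / (2 * self.sigma[1] ** 2)
        )


@dataclass(frozen=True)
class OpticalModel:
    """Gains, FRET efficiency, illumination and bleaching of the readout."""

    illumination: GaussianIllumination = field(default_factory=GaussianIllumination)
    gain_red: float = 50.0
    gain_fret: float = 40.0
    fret_factor: float = 0.6
    bleach_red: float = 1.0
    bleach_fret: float = 1.0

    def __post_init__(self) -> None:
        if self.gain_red <= 0 or self.gain_fret <= 0:
            raise ValueError("gains must be > 0")
        if not 0.0 < self.fret_factor <= 1.0:
            raise ValueError(f"fret_factor must be in (0, 1], got {self.fret_factor}")
        for name in ("bleach_red", "bleach_fret"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class NoiseModel:
    """Camera background offset, shot noise, and Gaussian read noise."""

    background_offset: float = 100.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True

    def __post_init__(self) -> None:
        if self.background_offset < 0:
            raise ValueError("background_offset must be >= 0")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")


@dataclass
class SpotImageSet:
    """The four registered 16-bit images of one spot plus its mask."""

    red_start: np.ndarray
    fret_start: np.ndarray
    red_final: np.ndarray
    fret_final: np.ndarray
    spot_mask: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {getattr(self, c).shape for c in CHANNELS}
        if len(shapes) != 1 or self.spot_mask.shape not in shapes:
            raise ValueError("all four images and the mask must share one shape")
        if not self.spot_mask.any():
            raise ValueError("spot_mask must be non-empty")

    def channels(self) -> dict[str, np.ndarray]:
        return {c: getattr(self, c) for c in CHANNELS}


def circular_spot_mask(shape: tuple[int, int], radius: float | None = None) -> np.ndarray:
    """Centered circular boolean mask; default radius 0.375 * min(shape)."""
    if radius is None:
        radius = 0.375 * min(shape)
    cr, cc = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return (rows - cr) ** 2 + (cols - cc) ** 2 <= radius**2


def expected_channel_images(
    truth: GroundTruth,
    optical: OpticalModel,
    shape: tuple[int, int] = (128, 128),
    spot_mask: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Noise-free expectation of each channel (no background, float).

    Useful for asserting the expectation identities exactly; the stochastic
    generator fluctuates around these fields.
    """
    if spot_mask is None:
        spot_mask = circular_spot_mask(shape)
    illum = optical.illumination.field(shape) * spot_mask
    n = truth.probe_density
    ce, q = truth.coupling_efficiency, truth.q_ref_break
    return {
        "red_start": optical.gain_red * illum * n,
        "fret_start": optical.gain_fret * optical.fret_factor * illum * n,
        "red_final": optical.gain_red
        * optical.bleach_red
        * illum
        * n
        * ((1.0 - ce) + ce * q),
        "fret_final": optical.gain_fret
        * optical.fret_factor
        * optical.bleach_fret
        * illum
        * n
        * (1.0 - ce),
    }


def simulate_spot_imageset(
    truth: GroundTruth,
    optical: OpticalModel,
    noise: NoiseModel,
    shape: tuple[int, int] = (128, 128),
    seed: int = 0,
    spot_mask: np.ndarray | None = None,
    metadata: dict | None = None,
) -> SpotImageSet:
    """Render one spot as four 16-bit images, reproducibly for a seed.

    Per pixel inside the spot mask the probe count is Poisson with mean
    ``probe_density`` and is split multinomially into unloaded / reference-
    broken / protein-broken fates; channel expectations follow the module
    docstring, then background offset, optional shot noise, Gaussian read
    noise, clipping to [0, 65535] and quantization are applied.
    """
    if shape[0] < 16 or shape[1] < 16:
        raise ValueError(f"shape must be at least 16x16, got {shape}")
    if spot_mask is None:
        spot_mask = circular_spot_mask(shape)
    if spot_mask.shape != tuple(shape):
        raise ValueError("spot_mask shape mismatch")

    rng = np.random.default_rng(seed)
    ce, q = truth.coupling_efficiency, truth.q_ref_break

    n_pix = int(spot_mask.sum())
    n_total = rng.poisson(truth.probe_density, size=n_pix)
    n_unloaded = rng.binomial(n_total, 1.0 - ce)
    n_loaded = n_total - n_unloaded
    n_ref_broken = rng.binomial(n_loaded, q)

    illum_in = optical.illumination.field(shape)[spot_mask]

    counts = {
        "red_start": optical.gain_red * illum_in * n_total,
        "fret_start": optical.gain_fret * optical.fret_factor * illum_in * n_total,
        "red_final": optical.gain_red
        * optical.bleach_red
        * illum_in
        * (n_unloaded + n_ref_broken),
        "fret_final": optical.gain_fret
        * optical.fret_factor
        * optical.bleach_fret
        * illum_in
        * n_unloaded,
    }

    images: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        signal = np.full(shape, 0.0)
        signal[spot_mask] = counts[channel]
        signal += noise.background_offset
        if noise.shot_noise:
            signal = rng.poisson(signal).astype(float)
        if noise.read_noise_sd > 0:
            signal = signal + rng.normal(0.0, noise.read_noise_sd, size=shape)
        images[channel] = np.clip(np.rint(signal), 0, _U16_MAX).astype(np.uint16)

    meta = {"seed": seed, "truth": truth}
    if metadata:
        meta.update(metadata)
    return SpotImageSet(spot_mask=spot_mask, metadata=meta, **images)


@dataclass
class ArrayExperiment:
    """Result of a simulated spot array: image sets plus bookkeeping tables."""

    image_sets: dict[str, SpotImageSet]
    manifest: pd.DataFrame
    ground_truth: pd.DataFrame


def simulate_array_experiment(
    layout: list[list[str | None]],
    probes: Mapping[str, SerialProbe],
    ramp: ForceRamp,
    optical: OpticalModel,
    noise: NoiseModel,
    seed: int,
    coupling_efficiency: float | Mapping[str, float] = 0.8,
    probe_density: float = 50.0,
    shape: tuple[int, int] = (128, 128),
    out_dir: str | Path | None = None,
) -> ArrayExperiment:
    """Simulate a (up to) 4x4 array of spots, one image set per occupied spot.

    ``layout`` is a 4x4 grid of condition names (``None`` = empty spot);
    every named condition must have a probe in ``probes``.  The rupture
    fraction ``q`` of each condition is computed from its probe by the
    first-rupture integral.  One master seed deterministically yields an
    independent stream per spot, so the whole array is reproducible while
    replicate spots stay statistically independent.

    When ``out_dir`` is given the four channels of every spot are written as
    uncompressed 16-bit grayscale TIFFs and ``manifest.csv`` /
    ``ground_truth.csv`` are written alongside.
    """
    if len(layout) > 4 or any(len(row) > 4 for row in layout):
        raise ValueError("layout must be at most 4x4")
    conditions = {c for row in layout for c in row if c is not None}
    missing = conditions - set(probes)
    if missing:
        raise ValueError(f"layout references undefined conditions: {sorted(missing)}")

    def ce_for(condition: str) -> float:
        if isinstance(coupling_efficiency, Mapping):
            return coupling_efficiency[condition]
        return float(coupling_efficiency)

    q_by_condition = {
        name: first_rupture_prob(probes[name], ramp) for name in sorted(conditions)
    }

    master = np.random.SeedSequence(seed)
    spot_seeds = master.spawn(16)

    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    image_sets: dict[str, SpotImageSet] = {}
    manifest_rows, truth_rows = [], []
    for row_idx, row in enumerate(layout):
        for col_idx, condition in enumerate(row):
            if condition is None:
                continue
            spot_id = f"r{row_idx}c{col_idx}"
            spot_seed = spot_seeds[row_idx * 4 + col_idx]
            truth = GroundTruth(
                q_ref_break=q_by_condition[condition],
                coupling_efficiency=ce_for(condition),
                probe_density=probe_density,
            )
            image_set = simulate_spot_imageset(
                truth,
                optical,
                noise,
                shape=shape,
                seed=spot_seed,
                metadata={"spot_id": spot_id, "condition": condition},
            )
            image_sets[spot_id] = image_set

            manifest_row = {
                "spot_id": spot_id,
                "row": row_idx,
                "col": col_idx,
                "condition": condition,
            }
            if out_path is not None:
                for channel, image in image_set.channels().items():
                    fname = f"{spot_id}_{channel}.tif"
                    tifffile.imwrite(out_path / fname, image)
                    manifest_row[channel] = fname
            manifest_rows.append(manifest_row)
            truth_rows.append(
                {
                    "spot_id": spot_id,
                    "condition": condition,
                    "q_ref_break": truth.q_ref_break,
                    "coupling_efficiency": truth.coupling_efficiency,
                    "probe_density": truth.probe_density,
                }
            )

    manifest = pd.DataFrame(manifest_rows)
    ground_truth = pd.DataFrame(truth_rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
        ground_truth.to_csv(out_path / "ground_truth.csv", index=False)
    return ArrayExperiment(image_sets, manifest, ground_truth)
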