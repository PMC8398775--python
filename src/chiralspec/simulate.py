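"""Synthetic two-block (MIR + NIR) solid-mixture spectra generator.

The original diffuse-reflectance NIR and KBr-pellet transmittance MIR
spectra of the DOPA mixtures are not deposited, so this module provides a
forward model with the statistical structure the downstream analysis
assumes:

* two near-collinear pure-component spectra per block — the enantiopure-L
  and the racemic crystal form — built as sums of Gaussian bands;
* Beer–Lambert mixing of the two pure spectra with the mass fractions of
  the mixture design;
* instrument artifacts: per-spectrum multiplicative scatter, additive
  offset, low-order polynomial baseline drift, a broad humidity (water)
  band of sample-varying amplitude, and i.i.d. measurement noise;
* conversion to the recorded intensity mode — reflectance (NIR) or
  transmittance (MIR) — via ``10**(-A)``.

In the MIR block the two crystal forms differ by 10–30% in band intensity
(NH-stretch bands stronger in the racemate, aliphatic CH bands stronger in
the pure L form, plus contrasting fingerprint bands); in the NIR block the
two forms are nearly collinear, with band contrast held at or below 2% of
the tallest band. These contrast magnitudes are tunable emulation
parameters, not measured facts.

Randomness is driven by a single integer seed expanded into independent
per-(block, sample, replicate) streams, so a spectrum does not depend on
generation order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "PureSpectrum",
    "InstrumentProfile",
    "SpectralBlock",
    "make_grid",
    "build_pure_spectra",
    "simulate_block",
    "default_profile",
    "write_block_csv",
    "read_block_csv",
    "MIR_RANGE",
    "NIR_RANGE",
    "NIR_SPACING",
]

# Nominal instrument ranges (cm^-1).  The MIR grid at 1 cm^-1 spacing gives
# 3601 points over 400-4000; the NIR spacing is chosen so the 4000-10000
# range holds exactly 3112 points.
MIR_RANGE = (400.0, 4000.0)
NIR_RANGE = (4000.0, 10000.0)
NIR_SPACING = 6000.0 / 3111.0


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform, strictly increasing wavenumber axis (cm^-1)."""

    start: float
    end: float
    spacing: float
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class PureSpectrum:
    """Absorbance spectrum of one crystal form on a grid."""

    grid: WavenumberGrid
    intensity: np.ndarray
    form: str  # "pure_L" | "racemic"


@dataclass(frozen=True)
class InstrumentProfile:
    """Artifact magnitudes of the simulated instrument.

    scatter_sd
        Log-scale sd of the per-spectrum multiplicative factor
        (``exp(N(0, scatter_sd))``), dimensionless.
    offset_sd
        Sd of the per-spectrum additive absorbance offset.
    baseline_order, baseline_sd
        Degree and coefficient sd of the random polynomial baseline
        (absorbance units, axis normalised to [-1, 1]).
    humidity_sd
        Dimensionless amplitude scale of the broad water band; the band
        contribution is ``humidity_sd * |N(1, humidity_sd)|`` times a fixed
        block-specific template, so 0 switches it off.
    noise_sd
        Per-point absorbance noise sd.
    replicates
        Analytical replicates per sample (>= 1).
    """

    scatter_sd: float = 0.05
    offset_sd: float = 0.01
    baseline_order: int = 2
    baseline_sd: float = 0.01
    humidity_sd: float = 0.2
    noise_sd: float = 0.005
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scatter_sd", "offset_sd", "baseline_sd", "humidity_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SpectralBlock:
    """A block of spectra: grid + intensity matrix + row labels.

    ``mode`` is one of ``reflectance``, ``transmittance``, ``absorbance``;
    reflectance/transmittance values lie in (0, 1].
    """

    grid: WavenumberGrid
    matrix: np.ndarray
    sample_ids: list[str]
    replicate_index: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != len(self.sample_ids):
            raise ValueError("row count must match sample_ids")
        if self.matrix.shape[1] != len(self.grid):
            raise ValueError("column count must match grid")
        if self.mode not in ("reflectance", "transmittance", "absorbance"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode in ("reflectance", "transmittance"):
            if not ((self.matrix > 0) & (self.matrix <= 1)).all():
                raise ValueError(f"{self.mode} values must lie in (0, 1]")
        elif not np.isfinite(self.matrix).all():
            raise ValueError("absorbance values must be finite")


def make_grid(start: float, end: float, spacing: float) -> WavenumberGrid:
    """Inclusive uniform grid: ``floor((end-start)/spacing) + 1`` points."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if end <= start:
        raise ValueError("end must exceed start")
    n = int(np.floor((end - start) / spacing + 1e-9)) + 1
    values = start + spacing * np.arange(n)
    return WavenumberGrid(start=start, end=end, spacing=spacing, values=values)


def mir_grid() -> WavenumberGrid:
    return make_grid(*MIR_RANGE, 1.0)


def nir_grid() -> WavenumberGrid:
    return make_grid(*NIR_RANGE, NIR_SPACING)


# Band tables: (center cm^-1, width cm^-1, amplitude pure-L, amplitude racemic).
# MIR: NH-stretch triplet stronger in the racemate, aliphatic CH stronger in
# pure L, a broad shared OH envelope, and fingerprint bands with mixed
# contrast (NH deformation / C=O 1560-1650, phenolic CO ~1120, aromatic CH
# out-of-plane 810-830).
_MIR_BANDS = [
    (3370.0, 30.0, 0.59, 0.66),
    (3206.0, 35.0, 0.54, 0.60),
    (3070.0, 25.0, 0.48, 0.53),
    (2960.0, 12.0, 0.285, 0.255),
    (2930.0, 18.0, 0.40, 0.35),
    (2870.0, 15.0, 0.33, 0.30),
    (2900.0, 380.0, 0.50, 0.50),  # broad OH envelope, shared
    (1640.0, 28.0, 0.595, 0.545),
    (1590.0, 22.0, 0.565, 0.595),
    (1520.0, 18.0, 0.42, 0.42),
    (1285.0, 20.0, 0.35, 0.35),
    (1120.0, 16.0, 0.48, 0.45),
    (820.0, 12.0, 0.47, 0.51),
    (640.0, 40.0, 0.30, 0.30),
]

# NIR: combination and overtone bands; the two forms nearly collinear
# (contrast <= 2% of the tallest band).
_NIR_BANDS = [
    (4600.0, 60.0, 0.500, 0.508),
    (4870.0, 70.0, 0.440, 0.433),
    (5020.0, 50.0, 0.380, 0.386),
    (5290.0, 80.0, 0.520, 0.512),
    (5950.0, 100.0, 0.360, 0.366),
    (6900.0, 150.0, 0.250, 0.250),
    (8400.0, 600.0, 0.120, 0.120),
]

# Water-band templates (center, width, peak absorbance at unit scale).
_HUMIDITY = {"MIR": (2900.0, 300.0, 0.6), "NIR": (5150.0, 120.0, 0.3)}

_BANDS = {"MIR": _MIR_BANDS, "NIR": _NIR_BANDS}
_MODE = {"MIR": "transmittance", "NIR": "reflectance"}


def _gaussians(values: np.ndarray, bands, col: int) -> np.ndarray:
    out = np.zeros_like(values)
    for center, width, amp_l, amp_r in bands:
        amp = (amp_l, amp_r)[col]
        out += amp * np.exp(-0.5 * ((values - center) / width) ** 2)
    return out


def build_pure_spectra(grid: WavenumberGrid, block: str) -> tuple[PureSpectrum, PureSpectrum]:
    """Pure-component absorbance spectra of the two crystal forms.

    Returns ``(pure_L, racemic)`` on the given grid. ``block`` is ``"MIR"``
    or ``"NIR"``.
    """
    if block not in _BANDS:
        raise ValueError(f"unknown block {block!r}")
    bands = _BANDS[block]
    pure_l = _gaussians(grid.values, bands, 0)
    racemic = _gaussians(grid.values, bands, 1)
    return (
        PureSpectrum(grid=grid, intensity=pure_l, form="pure_L"),
        PureSpectrum(grid=grid, intensity=racemic, form="racemic"),
    )


def default_profile(block: str, seed: int = 0) -> InstrumentProfile:
    """Default artifact profile for a block.

    Replicate counts are 2 (MIR) and 3 (NIR). NIR per-point noise gives a
    signal-to-noise ratio of ~200 at its tallest band; the MIR channel is
    substantially noisier relative to its bands, emulating the noisier,
    more humidity-sensitive KBr-pellet measurement.
    """
    if block == "MIR":
        return InstrumentProfile(noise_sd=0.040, replicates=2, seed=seed)
    if block == "NIR":
        return InstrumentProfile(noise_sd=0.0026, replicates=3, seed=seed)
    raise ValueError(f"unknown block {block!r}")


def simulate_block(
    design: pd.DataFrame,
    block: str,
    profile: InstrumentProfile,
    grid: WavenumberGrid | None = None,
) -> SpectralBlock:
    """Simulate raw (reflectance/transmittance) spectra for every design row.

    For each sample and replicate the ideal absorbance is the Beer-Lambert
    convex combination ``f_L * pure_L + f_rac * racemic`` of the two pure
    spectra with the design mass fractions; artifacts are then applied in
    order (multiplicative scatter, additive offset, polynomial baseline,
    humidity band, noise) and the result converted to intensity via
    ``10**(-A)``, clipped into (1e-6, 1].
    """
    if block not in _BANDS:
        raise ValueError(f"unknown block {block!r}")
    if grid is None:
        grid = mir_grid() if block == "MIR" else nir_grid()
    pure_l, racemic = build_pure_spectra(grid, block)
    hum_center, hum_width, hum_peak = _HUMIDITY[block]
    hum_template = hum_peak * np.exp(-0.5 * ((grid.values - hum_center) / hum_width) ** 2)
    x_norm = np.linspace(-1.0, 1.0, len(grid))
    vander = np.vander(x_norm, profile.baseline_order + 1, increasing=True)
    block_code = 0 if block == "MIR" else 1

    rows, ids, reps = [], [], []
    masses = design[["mass_rac_g", "mass_L_g"]].to_numpy(float)
    for i, sample_id in enumerate(design["sample_id"]):
        m_rac, m_l = masses[i]
        total = m_rac + m_l
        ideal = (m_l / total) * pure_l.intensity + (m_rac / total) * racemic.intensity
        # the water-band amplitude is a property of the specimen, shared by
        # its replicates; its own per-sample stream keeps it independent of
        # the replicate count
        sample_rng = np.random.default_rng(
            np.random.SeedSequence(profile.seed, spawn_key=(block_code, i))
        )
        hum_amp = (
            profile.humidity_sd * abs(sample_rng.normal(1.0, profile.humidity_sd))
            if profile.humidity_sd
            else 0.0
        )
        for r in range(profile.replicates):
            rng = np.random.default_rng(
                np.random.SeedSequence(profile.seed, spawn_key=(block_code, i, r))
            )
            scatter = np.exp(rng.normal(0.0, profile.scatter_sd)) if profile.scatter_sd else 1.0
            offset = rng.normal(0.0, profile.offset_sd) if profile.offset_sd else 0.0
            coeffs = rng.normal(0.0, profile.baseline_sd, profile.baseline_order + 1)
            baseline = vander @ coeffs if profile.baseline_sd else 0.0
            noise = rng.normal(0.0, profile.noise_sd, len(grid)) if profile.noise_sd else 0.0
            absorb = scatter * ideal + offset + baseline + hum_amp * hum_template + noise
            rows.append(np.clip(10.0 ** (-absorb), 1e-6, 1.0))
            ids.append(sample_id)
            reps.append(r)

    return SpectralBlock(
        grid=grid,
        matrix=np.asarray(rows),
        sample_ids=ids,
        replicate_index=np.asarray(reps),
        mode=_MODE[block],
    )


def write_block_csv(block: SpectralBlock, path, meta_path=None) -> None:
    """Write a block as wide CSV (sample_id, replicate, one column per
    wavenumber) with a JSON sidecar recording grid and mode."""
    path = Path(path)
    df = pd.DataFrame(block.matrix, columns=[f"{v:.6f}" for v in block.grid.values])
    df.insert(0, "replicate", block.replicate_index)
    df.insert(0, "sample_id", block.sample_ids)
    df.to_csv(path, index=False)
    meta = {
        "mode": block.mode,
        "grid": {
            "start": block.grid.start,
            "end": block.grid.end,
            "spacing": block.grid.spacing,
        },
    }
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    meta_path.write_text(json.dumps(meta, indent=2))


def read_block_csv(path, meta_path=None) -> SpectralBlock:
    """Read a block written by :func:`write_block_csv`."""
    path = Path(path)
    meta_path = Path(meta_path) if meta_path else path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    df = pd.read_csv(path)
    grid = make_grid(meta["grid"]["start"], meta["grid"]["end"], meta["grid"]["spacing"])
    matrix = df.iloc[:, 2:].to_numpy(float)
    return SpectralBlock(
        grid=grid,
        matrix=matrix,
        sample_ids=df["sample_id"].tolist(),
        replicate_index=df["replicate"].to_numpy(int),
        mode=meta["mode"],
    )
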