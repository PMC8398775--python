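"""Spectral signal conditioning.

Implements the pretreatment ladder used for solid-state IR calibration:
(pseudo-)absorbance transform, replicate averaging, range truncation,
standard normal variate (SNV), Savitzky-Golay derivatives, and mean
centering, together with the six named pretreatment variants (raw, first
derivative, second derivative, SNV, and the SNV + derivative combinations,
each followed by mean centering).

Fixed pipeline order: convert to absorbance -> average replicates ->
truncate (MIR only) -> SNV -> derivative -> mean-center. SNV and the
derivatives act row-wise, so they commute with any train/test partition;
mean centering is the only step carrying train-set state.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .simulate import SpectralBlock, WavenumberGrid

__all__ = [
    "PretreatmentSpec",
    "PRETREATMENTS",
    "to_absorbance",
    "average_replicates",
    "truncate",
    "snv",
    "sg_derivative",
    "mean_center",
    "apply_pretreatment",
]

SG_WINDOW = 19  # points; first derivative uses poly order 2, second uses 3


@dataclass(frozen=True)
class PretreatmentSpec:
    """An ordered pretreatment recipe.

    ``steps`` is a tuple drawn from ``"snv"``, ``("sg", deriv_order)`` and
    ``"mean_center"``; mean centering, if present, must be last.
    """

    label: str
    steps: tuple

    def __post_init__(self) -> None:
        for i, step in enumerate(self.steps):
            if step == "mean_center" and i != len(self.steps) - 1:
                raise ValueError("mean_center must be the last step")
            if isinstance(step, tuple):
                if step[0] != "sg" or step[1] not in (1, 2):
                    raise ValueError(f"bad derivative step {step!r}")
            elif step not in ("snv", "mean_center"):
                raise ValueError(f"unknown step {step!r}")

    def without_centering(self) -> "PretreatmentSpec":
        steps = tuple(s for s in self.steps if s != "mean_center")
        return replace(self, steps=steps)


#: The six standard variants, keyed by their report labels.
PRETREATMENTS: dict[str, PretreatmentSpec] = {
    spec.label: spec
    for spec in (
        PretreatmentSpec("Raw data (+MC)", ("mean_center",)),
        PretreatmentSpec("First derivative (+MC)", (("sg", 1), "mean_center")),
        PretreatmentSpec("Second derivative (+MC)", (("sg", 2), "mean_center")),
        PretreatmentSpec("SNV (+MC)", ("snv", "mean_center")),
        PretreatmentSpec("SNV + First derivative (+MC)", ("snv", ("sg", 1), "mean_center")),
        PretreatmentSpec("SNV + Second derivative (+MC)", ("snv", ("sg", 2), "mean_center")),
    )
}


def to_absorbance(block: SpectralBlock) -> SpectralBlock:
    """Base-10 (pseudo-)absorbance: ``A = log10(1/I)``.

    Reflectance gives pseudo-absorbance, transmittance gives absorbance;
    both are handled identically and the result mode is ``absorbance``.
    """
    if block.mode not in ("reflectance", "transmittance"):
        raise ValueError(f"expected reflectance or transmittance, got {block.mode!r}")
    bad = np.argwhere(block.matrix <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive intensity at row {i} ({block.sample_ids[i]}), "
            f"wavenumber {block.grid.values[j]:.2f}"
        )
    return SpectralBlock(
        grid=block.grid,
        matrix=-np.log10(block.matrix),
        sample_ids=list(block.sample_ids),
        replicate_index=block.replicate_index.copy(),
        mode="absorbance",
    )


def average_replicates(block: SpectralBlock, sample_order: list[str] | None = None) -> SpectralBlock:
    """Average replicate rows, yielding one spectrum per sample.

    Row order follows ``sample_order`` when given, else first appearance.
    """
    if block.mode != "absorbance":
        raise ValueError("average replicates on absorbance data")
    if sample_order is None:
        sample_order = list(dict.fromkeys(block.sample_ids))
    ids = np.asarray(block.sample_ids)
    rows = []
    for sid in sample_order:
        mask = ids == sid
        if not mask.any():
            raise ValueError(f"sample {sid!r} has no replicate rows")
        rows.append(block.matrix[mask].mean(axis=0))
    return SpectralBlock(
        grid=block.grid,
        matrix=np.asarray(rows),
        sample_ids=list(sample_order),
        replicate_index=np.zeros(len(sample_order), dtype=int),
        mode="absorbance",
    )


def truncate(block: SpectralBlock, max_wavenumber: float) -> SpectralBlock:
    """Keep wavenumbers <= ``max_wavenumber`` (drops the baseline-only
    high-wavenumber side)."""
    if block.mode != "absorbance":
        raise ValueError("truncate absorbance data")
    keep = block.grid.values <= max_wavenumber
    if not keep.any():
        raise ValueError("truncation removes every column")
    values = block.grid.values[keep]
    grid = WavenumberGrid(
        start=float(values[0]), end=float(values[-1]), spacing=block.grid.spacing, values=values
    )
    return SpectralBlock(
        grid=grid,
        matrix=block.matrix[:, keep],
        sample_ids=list(block.sample_ids),
        replicate_index=block.replicate_index.copy(),
        mode="absorbance",
    )


def snv(matrix: np.ndarray) -> np.ndarray:
    """Standard normal variate: each row centered and scaled to unit sd
    (n-1 convention). Removes multiplicative scatter and offsets."""
    matrix = np.asarray(matrix, float)
    sd = matrix.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant row: SNV undefined")
    return (matrix - matrix.mean(axis=1, keepdims=True)) / sd


def sg_derivative(matrix: np.ndarray, deriv_order: int) -> np.ndarray:
    """Savitzky-Golay derivative, 19-point window.

    First derivative with a second-order polynomial, second derivative with
    a third-order polynomial. Derivatives are per index step (the uniform
    grid makes the physical rescale a constant, absorbed by regression).
    Edges use the boundary-anchored window polynomial evaluated off-center,
    so the column count is unchanged.
    """
    matrix = np.asarray(matrix, float)
    if matrix.shape[1] < SG_WINDOW:
        raise ValueError(f"need at least {SG_WINDOW} columns")
    if deriv_order == 1:
        poly = 2
    elif deriv_order == 2:
        poly = 3
    else:
        raise ValueError("deriv_order must be 1 or 2")
    return savgol_filter(
        matrix, window_length=SG_WINDOW, polyorder=poly, deriv=deriv_order, delta=1.0,
        axis=1, mode="interp",
    )


def mean_center(
    train_matrix: np.ndarray, apply_matrix: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Subtract train-set column means from train and (optionally) apply
    matrices; returns ``(train_c, apply_c, column_means)``."""
    train_matrix = np.asarray(train_matrix, float)
    means = train_matrix.mean(axis=0)
    train_c = train_matrix - means
    apply_c = None
    if apply_matrix is not None:
        apply_matrix = np.asarray(apply_matrix, float)
        if apply_matrix.shape[1] != train_matrix.shape[1]:
            raise ValueError("column counts differ")
        apply_c = apply_matrix - means
    return train_c, apply_c, means


def apply_pretreatment(
    spec: PretreatmentSpec, matrix: np.ndarray, train_matrix: np.ndarray | None = None
) -> np.ndarray:
    """Apply a pretreatment recipe to a matrix, steps in listed order.

    Mean centering uses the column means of ``train_matrix`` after the same
    preceding steps (default: ``matrix`` itself). SNV and derivatives are
    row-wise, so they carry no train-set state.
    """
    out = np.asarray(matrix, float)
    ref = np.asarray(train_matrix, float) if train_matrix is not None else None
    for step in spec.steps:
        if step == "snv":
            out = snv(out)
            ref = snv(ref) if ref is not None else None
        elif step == "mean_center":
            if ref is None:
                out = out - out.mean(axis=0)
            else:
                out = out - ref.mean(axis=0)
        else:
            out = sg_derivative(out, step[1])
            ref = sg_derivative(ref, step[1]) if ref is not None else None
    return out
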