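"""Gaussian activation-probability kernels and modeled-activation (MA) maps.

Each reported focus is treated as the center of a 3-D Gaussian probability
distribution whose width reflects the spatial uncertainty of the report:
a fixed between-template component and a between-subject component that
shrinks with the experiment's sample size,

    FWHM_total^2 = FWHM_template^2 + FWHM_subject^2 / n_subjects,
    sigma = FWHM_total / (2 * sqrt(2 * ln 2)).

Two kernel normalizations are provided.  ``gaussian_3d`` is a true 3-D
density, exp(-d^2 / 2 sigma^2) / ((2 pi)^{3/2} sigma^3), which integrates to
one over volume and is the default.  ``printed_1d`` is the 1-D-normalized
form exp(-d^2 / 2 sigma^2) / ((2 pi)^{1/2} sigma) that appears throughout
the ALE literature; it is retained for formula-level fidelity.

An experiment's MA map evaluates every focus's kernel at each voxel center,
converts density to a per-voxel activation probability (density x voxel
volume, capped at 1) and combines across foci by voxelwise maximum (default)
or probabilistic union.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .corpus import Experiment
from .grid import StatMap, VolumeGrid

__all__ = [
    "FWHM_TO_SIGMA",
    "UncertaintyModel",
    "KernelSpec",
    "sigma_for_experiment",
    "focus_probability",
    "modeled_activation_map",
]

#: FWHM = 2 sqrt(2 ln 2) * sigma for a Gaussian.
FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

NORMALIZATIONS = ("printed_1d", "gaussian_3d")
COMBINE_RULES = ("max", "union")


@dataclass(frozen=True)
class UncertaintyModel:
    """Spatial-uncertainty components of a reported focus, as FWHM in mm.

    Defaults are the empirical between-template (5.7 mm) and between-subject
    (11.6 mm) values standard in the ALE literature.
    """

    fwhm_template_mm: float = 5.7
    fwhm_subject_mm: float = 11.6

    def __post_init__(self) -> None:
        if self.fwhm_template_mm < 0 or self.fwhm_subject_mm < 0:
            raise ValueError("FWHM components must be nonnegative")
        if self.fwhm_template_mm == 0 and self.fwhm_subject_mm == 0:
            raise ValueError("at least one FWHM component must be positive")


def sigma_for_experiment(model: UncertaintyModel, n_subjects: int) -> float:
    """Kernel sigma (mm) for an experiment with ``n_subjects`` subjects.

    Strictly decreasing in the subject count whenever the subject component
    is positive: larger studies localize their foci more reliably.
    """
    if n_subjects < 1:
        raise ValueError(f"n_subjects must be >= 1, got {n_subjects}")
    fwhm_sq = model.fwhm_template_mm**2 + model.fwhm_subject_mm**2 / n_subjects
    return float(np.sqrt(fwhm_sq) / FWHM_TO_SIGMA)


@dataclass(frozen=True)
class KernelSpec:
    """A concrete kernel: width, normalization and truncation radius."""

    sigma_mm: float
    normalization: str = "gaussian_3d"
    truncation_radius_mm: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_mm <= 0:
            raise ValueError("sigma_mm must be positive")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"normalization must be one of {NORMALIZATIONS}")
        if self.truncation_radius_mm is None:
            object.__setattr__(self, "truncation_radius_mm", 3.0 * self.sigma_mm)
        if self.truncation_radius_mm <= 0:
            raise ValueError("truncation_radius_mm must be positive")

    @classmethod
    def for_experiment(
        cls,
        model: UncertaintyModel,
        n_subjects: int,
        normalization: str = "gaussian_3d",
        truncation_sigmas: float = 3.0,
    ) -> "KernelSpec":
        sigma = sigma_for_experiment(model, n_subjects)
        return cls(
            sigma_mm=sigma,
            normalization=normalization,
            truncation_radius_mm=truncation_sigmas * sigma,
        )


def focus_probability(kernel: KernelSpec, d_mm) -> np.ndarray | float:
    """Kernel value at Euclidean distance ``d_mm`` from the focus.

    Strictly decreasing in distance; zero beyond the truncation radius.
    """
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be nonnegative")
    s = kernel.sigma_mm
    core = np.exp(-(d**2) / (2.0 * s**2))
    if kernel.normalization == "printed_1d":
        out = core / (np.sqrt(2.0 * np.pi) * s)
    else:
        out = core / ((2.0 * np.pi) ** 1.5 * s**3)
    out = np.where(d > kernel.truncation_radius_mm, 0.0, out)
    return float(out) if np.isscalar(d_mm) else out


def _voxel_probability_cube(kernel: KernelSpec, grid: VolumeGrid) -> np.ndarray:
    """Per-voxel activation probabilities at integer voxel offsets.

    Cube of shape (2r0+1, 2r1+1, 2r2+1) centered on the focus voxel, with
    density converted to probability by the voxel volume and capped at 1.
    Used when foci sit exactly on voxel centers (random-relocation nulls).
    """
    half = np.ceil(kernel.truncation_radius_mm / grid.voxel_size).astype(int)
    axes = [np.arange(-h, h + 1) * vs for h, vs in zip(half, grid.voxel_size)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    d = np.sqrt(dx**2 + dy**2 + dz**2)
    return np.minimum(focus_probability(kernel, d) * grid.voxel_volume, 1.0)


def modeled_activation_map(
    experiment: Experiment,
    grid: VolumeGrid,
    model: UncertaintyModel,
    combine_rule: str = "max",
    normalization: str = "gaussian_3d",
    truncation_sigmas: float = 3.0,
) -> StatMap:
    """MA map of one experiment: per-voxel probability that it activates there.

    Each focus contributes its kernel within the truncation radius; foci are
    combined voxelwise by ``max`` (default; several nearby peaks count once)
    or probabilistic ``union`` 1 - prod(1 - p).
    """
    if combine_rule not in COMBINE_RULES:
        raise ValueError(f"combine_rule must be one of {COMBINE_RULES}")
    kernel = KernelSpec.for_experiment(
        model, experiment.n_subjects, normalization=normalization, truncation_sigmas=truncation_sigmas
    )
    shape = np.asarray(grid.shape)
    if combine_rule == "max":
        acc = np.zeros(grid.shape)
    else:
        acc = np.ones(grid.shape)  # running product of (1 - p)

    lo_mm = grid.origin - 0.5 * grid.voxel_size
    hi_mm = grid.origin + (shape - 0.5) * grid.voxel_size
    for focus in experiment.foci:
        c = focus.xyz
        if np.any(c < lo_mm) or np.any(c > hi_mm):
            warnings.warn(
                f"{experiment.id}: focus {tuple(c)} outside grid bounding box; "
                "it still contributes within its truncation radius",
                stacklevel=2,
            )
        r = kernel.truncation_radius_mm
        lo = np.maximum(np.ceil((c - r - grid.origin) / grid.voxel_size), 0).astype(int)
        hi = np.minimum(
            np.floor((c + r - grid.origin) / grid.voxel_size), shape - 1
        ).astype(int)
        if np.any(lo > hi):
            continue
        axes = [
            (np.arange(l, h + 1) * vs + o - cc)
            for l, h, vs, o, cc in zip(lo, hi, grid.voxel_size, grid.origin, c)
        ]
        dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
        d = np.sqrt(dx**2 + dy**2 + dz**2)
        p = np.minimum(focus_probability(kernel, d) * grid.voxel_volume, 1.0)
        window = tuple(slice(l, h + 1) for l, h in zip(lo, hi))
        if combine_rule == "max":
            np.maximum(acc[window], p, out=acc[window])
        else:
            acc[window] *= 1.0 - p

    values = acc if combine_rule == "max" else 1.0 - acc
    values = np.where(grid.mask, values, 0.0)
    return StatMap(grid=grid, values=values, kind="ma")
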