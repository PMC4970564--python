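"""ALE maps, null distributions, thresholding and cluster tables.

The ALE (activation likelihood estimation) score of a voxel is the
probabilistic union of the per-experiment modeled-activation values,

    ALE = 1 - prod_i (1 - MA_i),

i.e. the probability that at least one experiment in the corpus activates
the voxel under independence.  Significance is assessed against the null
hypothesis of *no biological activity*: foci scattered uniformly at random
over the in-mask voxel centers.  Two interchangeable constructions of that
null are provided:

* ``monte_carlo`` — literally relocate every focus uniformly in the mask,
  recompute ALE, and pool all in-mask voxel values over iterations.
* ``analytic_histogram`` — the same pooled distribution computed without
  sampling.  The exact pooled distribution of a single focus's contribution
  follows from the mask autocorrelation (how many voxel/focus pairs realize
  each integer offset); within-experiment combination is a CDF power (max
  rule) or self-convolution (union rule); the across-experiment union
  becomes an ordinary convolution in L = -log(1 - ALE) space, done by FFT.

Voxelwise p-values (inclusive right tail) are corrected by Benjamini-
Hochberg FDR and the surviving map is filtered by a minimum cluster extent
(default 100 mm^3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .corpus import Corpus
from .grid import GridError, StatMap, VolumeGrid, write_stat_map
from .kernels import (
    COMBINE_RULES,
    KernelSpec,
    UncertaintyModel,
    modeled_activation_map,
    sigma_for_experiment,
    _voxel_probability_cube,
)

__all__ = [
    "NullDistribution",
    "AnalysisConfig",
    "Cluster",
    "ALEResult",
    "ALE",
    "ale_union",
    "build_null_monte_carlo",
    "build_null_analytic",
    "union_discrete_distributions",
    "ale_to_p",
    "fdr_select",
    "extract_clusters",
    "clusters_table",
    "run_ale",
]

NULL_METHODS = ("monte_carlo", "analytic_histogram")

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


# -- null distribution -----------------------------------------------------


@dataclass
class NullDistribution:
    """Distribution of the ALE score under uniform random foci placement.

    Represented as a histogram of atoms: ``probabilities[i]`` is the mass of
    the value bin ``[bin_edges[i], bin_edges[i+1])`` whose representative
    value is the atom ``values[i]``.  The Monte-Carlo builder additionally
    retains the pooled sample so p-values equal direct counting exactly.
    """

    method: str
    bin_edges: np.ndarray
    probabilities: np.ndarray
    values: np.ndarray = None  # type: ignore[assignment]
    n_iterations: int | None = None
    rng_seed: int | None = None
    _samples: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.values is None:
            self.values = 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if len(self.probabilities) != len(self.bin_edges) - 1:
            raise ValueError("need one probability per bin")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must sum to 1")
        # right-tail mass *including* each atom, for inclusive p-values;
        # anchor the full-distribution tail at exactly 1
        self._tail = np.concatenate([np.cumsum(self.probabilities[::-1])[::-1], [0.0]])
        self._tail[0] = 1.0

    def sf(self, ale_values) -> np.ndarray:
        """P(null >= value), inclusive; floored at the smallest tail mass."""
        v = np.asarray(ale_values, dtype=float)
        if self._samples is not None:
            n = len(self._samples)
            idx = np.searchsorted(self._samples, v, side="left")
            p = (n - idx) / n
            floor = 1.0 / n
        else:
            # first atom with value >= v (tiny slack for float round-trip)
            idx = np.searchsorted(self.values, v - 1e-15, side="left")
            p = self._tail[idx]
            pos = self.probabilities[self.probabilities > 0]
            floor = float(pos.min()) if len(pos) else 1e-300
        return np.minimum(np.maximum(p, floor), 1.0)

    def quantile(self, q) -> np.ndarray:
        """Left-continuous quantile of the null ALE value."""
        q = np.asarray(q, dtype=float)
        if self._samples is not None:
            return np.quantile(self._samples, q)
        cdf = np.cumsum(self.probabilities)
        idx = np.searchsorted(cdf, q, side="left")
        idx = np.minimum(idx, len(self.values) - 1)
        return self.values[idx]

    def to_json(self, path=None) -> str:
        obj = {
            "method": self.method,
            "bin_edges": self.bin_edges.tolist(),
            "probabilities": self.probabilities.tolist(),
            "values": self.values.tolist(),
            "n_iterations": self.n_iterations,
            "rng_seed": self.rng_seed,
        }
        text = json.dumps(obj)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "NullDistribution":
        if hasattr(source, "read"):
            obj = json.load(source)
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                obj = json.load(fh)
        return cls(
            method=obj["method"],
            bin_edges=np.asarray(obj["bin_edges"]),
            probabilities=np.asarray(obj["probabilities"]),
            values=np.asarray(obj["values"]),
            n_iterations=obj.get("n_iterations"),
            rng_seed=obj.get("rng_seed"),
        )


def _atoms_to_null(
    values: np.ndarray,
    probs: np.ndarray,
    method: str,
    n_iterations: int | None = None,
    rng_seed: int | None = None,
    samples: np.ndarray | None = None,
) -> NullDistribution:
    """Build a NullDistribution from value atoms, trimming empty tail bins."""
    keep = probs > 0
    keep[0] = True
    last = np.max(np.nonzero(keep)[0])
    values = values[: last + 1]
    probs = probs[: last + 1].copy()
    probs /= probs.sum()
    # edges: midpoints between consecutive atoms, closed below at 0
    mids = 0.5 * (values[:-1] + values[1:])
    lo = min(0.0, values[0] - 1e-12)
    hi = values[-1] + max(1e-12, values[-1] - mids[-1] if len(mids) else 1e-12)
    edges = np.concatenate([[lo], mids, [hi]])
    return NullDistribution(
        method=method,
        bin_edges=edges,
        probabilities=probs,
        values=values,
        n_iterations=n_iterations,
        rng_seed=rng_seed,
        _samples=samples,
    )


# -- analysis configuration ------------------------------------------------


@dataclass
class AnalysisConfig:
    """All knobs of one ALE analysis; serializable to/from JSON or YAML dicts."""

    uncertainty: UncertaintyModel = field(default_factory=UncertaintyModel)
    combine_rule: str = "max"
    kernel_normalization: str = "gaussian_3d"
    truncation_sigmas: float = 3.0
    fdr_q: float = 0.05
    min_cluster_mm3: float = 100.0
    null_method: str = "analytic_histogram"
    null_iterations: int = 1000
    null_bins: int = 2**16
    rng_seed: int = 0
    cluster_connectivity: int = 26

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_q < 1.0):
            raise ValueError("fdr_q must lie in (0, 1)")
        if self.min_cluster_mm3 <= 0:
            raise ValueError("min_cluster_mm3 must be positive")
        if self.null_method not in NULL_METHODS:
            raise ValueError(f"null_method must be one of {NULL_METHODS}")
        if self.combine_rule not in COMBINE_RULES:
            raise ValueError(f"combine_rule must be one of {COMBINE_RULES}")
        if self.cluster_connectivity not in _CONNECTIVITY_STRUCTS:
            raise ValueError("cluster_connectivity must be 6, 18 or 26")
        if self.null_iterations < 1:
            raise ValueError("null_iterations must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        u = d.pop("uncertainty")
        d["fwhm_template_mm"] = u["fwhm_template_mm"]
        d["fwhm_subject_mm"] = u["fwhm_subject_mm"]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        u = UncertaintyModel(
            fwhm_template_mm=d.pop("fwhm_template_mm", 5.7),
            fwhm_subject_mm=d.pop("fwhm_subject_mm", 11.6),
        )
        d.pop("uncertainty", None)
        return cls(uncertainty=u, **d)


# -- core operations -------------------------------------------------------


def ale_union(ma_maps: Sequence[StatMap]) -> StatMap:
    """Voxelwise probabilistic union 1 - prod(1 - MA) of MA maps."""
    if len(ma_maps) < 1:
        raise ValueError("need at least one MA map")
    grid = ma_maps[0].grid
    if len(ma_maps) == 1:  # exact identity, no float round-trip through 1-x
        return StatMap(grid=grid, values=ma_maps[0].values.copy(), kind="ale")
    one_minus = np.ones(grid.shape)
    for m in ma_maps:
        grid.check_compatible(m.grid)
        one_minus *= 1.0 - m.values
    values = np.where(grid.mask, 1.0 - one_minus, 0.0)
    return StatMap(grid=grid, values=values, kind="ale")


def _experiment_cubes(corpus: Corpus, grid: VolumeGrid, config: AnalysisConfig):
    """Per-experiment voxel-probability cubes (foci at voxel centers)."""
    cubes = []
    for exp in corpus:
        kernel = KernelSpec.for_experiment(
            config.uncertainty,
            exp.n_subjects,
            normalization=config.kernel_normalization,
            truncation_sigmas=config.truncation_sigmas,
        )
        cubes.append((_voxel_probability_cube(kernel, grid), len(exp.foci)))
    return cubes


def _paste_max(acc: np.ndarray, cube: np.ndarray, center: np.ndarray) -> None:
    half = (np.asarray(cube.shape) - 1) // 2
    lo = center - half
    hi = center + half + 1
    src_lo = np.maximum(-lo, 0)
    src_hi = np.asarray(cube.shape) - np.maximum(hi - np.asarray(acc.shape), 0)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(acc.shape))
    dst = tuple(slice(a, b) for a, b in zip(lo, hi))
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    np.maximum(acc[dst], cube[src], out=acc[dst])


def _paste_union(acc_one_minus: np.ndarray, cube: np.ndarray, center: np.ndarray) -> None:
    half = (np.asarray(cube.shape) - 1) // 2
    lo = center - half
    hi = center + half + 1
    src_lo = np.maximum(-lo, 0)
    src_hi = np.asarray(cube.shape) - np.maximum(hi - np.asarray(acc_one_minus.shape), 0)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(acc_one_minus.shape))
    dst = tuple(slice(a, b) for a, b in zip(lo, hi))
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    acc_one_minus[dst] *= 1.0 - cube[src]


def build_null_monte_carlo(
    corpus: Corpus, grid: VolumeGrid, config: AnalysisConfig
) -> NullDistribution:
    """Empirical ALE null: relocate all foci uniformly in the mask and pool.

    Each iteration keeps every experiment's foci count and subject count but
    draws the focus positions independently and uniformly over in-mask voxel
    centers; the resulting in-mask ALE values of all iterations are pooled
    into one distribution.  Deterministic given ``config.rng_seed``.
    """
    if not grid.mask.any():
        raise GridError("empty mask")
    rng = np.random.default_rng(config.rng_seed)
    cubes = _experiment_cubes(corpus, grid, config)
    mask_idx = grid.mask_indices()
    n_mask = len(mask_idx)
    mask = grid.mask
    pooled = np.empty(config.null_iterations * n_mask)
    for it in range(config.null_iterations):
        one_minus_ale = np.ones(grid.shape)
        for cube, n_foci in cubes:
            if config.combine_rule == "max":
                ma = np.zeros(grid.shape)
                for j in rng.integers(0, n_mask, size=n_foci):
                    _paste_max(ma, cube, mask_idx[j])
            else:
                om = np.ones(grid.shape)
                for j in rng.integers(0, n_mask, size=n_foci):
                    _paste_union(om, cube, mask_idx[j])
                ma = 1.0 - om
            one_minus_ale *= 1.0 - ma
        pooled[it * n_mask : (it + 1) * n_mask] = (1.0 - one_minus_ale)[mask]
    pooled.sort()
    # histogram representation for serialization; samples kept for exact p
    hi = max(pooled[-1], 1e-12)
    edges = np.linspace(0.0, hi * (1 + 1e-9), 4097)
    counts, _ = np.histogram(pooled, bins=edges)
    probs = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return NullDistribution(
        method="monte_carlo",
        bin_edges=edges,
        probabilities=probs,
        values=centers,
        n_iterations=config.null_iterations,
        rng_seed=config.rng_seed,
        _samples=pooled,
    )


def _single_focus_atoms(
    cube: np.ndarray, weights: np.ndarray, n_pairs_total: float
) -> tuple[np.ndarray, np.ndarray]:
    """Exact pooled distribution of one focus's per-voxel probability.

    Atoms are the distinct cube values with mass proportional to the number
    of (voxel, focus) pairs realizing each offset; all remaining pairs
    contribute value 0.
    """
    vals = cube.ravel()
    w = weights.ravel()
    uniq, inv = np.unique(vals, return_inverse=True)
    mass = np.bincount(inv, weights=w, minlength=len(uniq))
    if uniq[0] != 0.0:
        uniq = np.concatenate([[0.0], uniq])
        mass = np.concatenate([[0.0], mass])
    mass[0] += n_pairs_total - mass.sum()
    return uniq, mass / n_pairs_total


def _bin_to_l_grid(values: np.ndarray, probs: np.ndarray, dl: float, n: int) -> np.ndarray:
    """Deposit atoms at L = -log(1-v) onto a uniform L grid (lever rule)."""
    L = -np.log1p(-np.minimum(values, 1 - 1e-15))
    pos = L / dl
    i0 = np.floor(pos).astype(int)
    frac = pos - i0
    i0 = np.clip(i0, 0, n - 1)
    i1 = np.clip(i0 + 1, 0, n - 1)
    hist = np.zeros(n)
    np.add.at(hist, i0, probs * (1.0 - frac))
    np.add.at(hist, i1, probs * frac)
    return hist


def union_discrete_distributions(
    dists: Sequence[tuple[np.ndarray, np.ndarray]],
    n_bins: int = 2**14,
    l_max: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of 1 - prod(1 - X_i) for independent discrete X_i.

    Each ``(values, probs)`` pair is a distribution on [0, 1).  The union is
    an exact sum in L = -log(1 - x) space, computed by FFT convolution on a
    uniform L grid; returns ``(values, probs)`` atoms of the result.
    ``l_max`` may be supplied to force a common atom grid across calls.
    """
    if l_max is None:
        l_max = sum(
            float(-np.log1p(-np.minimum(np.max(v), 1 - 1e-15))) for v, _ in dists
        )
    if l_max <= 0:
        return np.array([0.0]), np.array([1.0])
    dl = l_max / (n_bins - 2)
    spectrum = None
    for values, probs in dists:
        v = np.asarray(values, dtype=float)
        p = np.asarray(probs, dtype=float)
        vmax = np.max(v)
        if vmax > 0 and -np.log1p(-min(vmax, 1 - 1e-15)) < dl:
            raise ValueError(
                "bin grid too coarse for one distribution's support; use finer bins"
            )
        hist = _bin_to_l_grid(v, p, dl, n_bins)
        f = np.fft.rfft(hist, n=n_bins)
        spectrum = f if spectrum is None else spectrum * f
    out = np.fft.irfft(spectrum, n=n_bins)
    out = np.maximum(out, 0.0)
    out /= out.sum()
    l_atoms = np.arange(n_bins) * dl
    return 1.0 - np.exp(-l_atoms), out


def _combine_within_experiment(
    vals: np.ndarray, probs: np.ndarray, n_foci: int, combine_rule: str, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    if n_foci == 1:
        return vals, probs
    if combine_rule == "max":
        cdf = np.cumsum(probs)
        cdf_prev = np.concatenate([[0.0], cdf[:-1]])
        return vals, cdf**n_foci - cdf_prev**n_foci
    return union_discrete_distributions([(vals, probs)] * n_foci, n_bins=n_bins)


def build_null_analytic(
    corpus: Corpus, grid: VolumeGrid, config: AnalysisConfig, n_strata: int = 16
) -> NullDistribution:
    """Pooled ALE null computed without sampling.

    The distribution of one relocated focus's per-voxel probability follows
    exactly from the number of (voxel, focus) pairs realizing each integer
    offset inside the mask.  Foci within an experiment combine by a CDF
    power (max rule) or self-convolution in L space (union rule);
    experiments combine by the union formula, i.e. a convolution in
    L = -log(1 - ALE) space.

    Because voxels near the mask boundary see truncated kernels, the pooled
    distribution is a *mixture* over voxel neighborhoods: in-mask voxels are
    stratified by local mask coverage within the largest kernel box
    (``n_strata`` strata), the convolution is done per stratum, and the
    strata are mixed by their voxel counts.  This reproduces the Monte-Carlo
    pooled null without its sampling noise.
    """
    if len(corpus) < 1:
        raise ValueError("empty corpus")
    cubes = _experiment_cubes(corpus, grid, config)
    mask = grid.mask
    n_mask = grid.n_mask_voxels
    n_bins = config.null_bins

    # common L grid across strata so mixtures share atoms
    l_max = 0.0
    for cube, n_foci in cubes:
        l_one = float(-np.log1p(-np.minimum(cube.max(), 1 - 1e-15)))
        l_max += l_one * (n_foci if config.combine_rule == "union" else 1)

    # stratify in-mask voxels by in-mask neighbor count within the largest cube
    max_half = np.max([np.asarray(c.shape) for c, _ in cubes], axis=0) // 2
    if n_strata > 1 and n_mask > n_strata:
        box = np.ones(tuple(2 * h + 1 for h in max_half))
        cov = signal.fftconvolve(mask.astype(float), box, mode="same")
        cov_in = np.rint(cov[mask])
        qs = np.quantile(cov_in, np.linspace(0, 1, n_strata + 1)[1:-1])
        strat_id = np.searchsorted(qs, cov_in, side="right")
    else:
        strat_id = np.zeros(n_mask, dtype=int)

    mask_idx = grid.mask_indices()
    total_probs: np.ndarray | None = None
    total_values: np.ndarray | None = None
    zero_mass = 0.0
    mask_rev = mask[::-1, ::-1, ::-1].astype(float)
    center = np.asarray(grid.shape) - 1
    for s in range(int(strat_id.max()) + 1):
        members = mask_idx[strat_id == s]
        n_s = len(members)
        if n_s == 0:
            continue
        ind = np.zeros(grid.shape)
        ind[tuple(members.T)] = 1.0
        corr = signal.fftconvolve(ind, mask_rev, mode="full")
        exp_atoms = []
        for cube, n_foci in cubes:
            half = (np.asarray(cube.shape) - 1) // 2
            w = np.zeros(cube.shape)
            lo = np.maximum(center - half, 0)
            hi = np.minimum(center + half + 1, np.asarray(corr.shape))
            dst = tuple(
                slice(a - (c - h), b - (c - h)) for a, b, c, h in zip(lo, hi, center, half)
            )
            w[dst] = np.rint(corr[tuple(slice(a, b) for a, b in zip(lo, hi))])
            vals, probs = _single_focus_atoms(cube, w, float(n_s) * n_mask)
            exp_atoms.append(
                _combine_within_experiment(vals, probs, n_foci, config.combine_rule, n_bins)
            )
        values, probs = union_discrete_distributions(exp_atoms, n_bins=n_bins, l_max=l_max)
        weight = n_s / n_mask
        if len(values) == 1:  # degenerate all-zero stratum
            zero_mass += weight
            continue
        if total_probs is None:
            total_values = values
            total_probs = weight * probs
        else:
            total_probs += weight * probs
    if total_probs is None:
        total_values = np.array([0.0, 1e-12])
        total_probs = np.array([1.0, 0.0])
        zero_mass = 0.0
    total_probs[0] += zero_mass
    return _atoms_to_null(total_values, total_probs, method="analytic_histogram")


def ale_to_p(ale_map: StatMap, null: NullDistribution) -> StatMap:
    """Voxelwise right-tail p-values P(null >= observed ALE), inclusive."""
    if ale_map.values.min() < 0 or ale_map.values.max() > 1:
        raise ValueError("ALE values must lie in [0, 1]")
    p = np.zeros(ale_map.grid.shape)
    mask = ale_map.grid.mask
    p[mask] = null.sf(ale_map.values[mask])
    return StatMap(grid=ale_map.grid, values=p, kind="p")


def fdr_select(p_map: StatMap, q: float) -> StatMap:
    """Benjamini-Hochberg step-up selection over in-mask voxels."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    mask = p_map.grid.mask
    reject, *_ = multipletests(p_map.values[mask], alpha=q, method="fdr_bh")
    out = np.zeros(p_map.grid.shape)
    out[mask] = reject.astype(float)
    return StatMap(grid=p_map.grid, values=out, kind="binary")


@dataclass
class Cluster:
    """One surviving suprathreshold component (a row of a cluster table)."""

    label: int
    n_voxels: int
    size_mm3: float
    peak_mm: np.ndarray
    weighted_center_mm: np.ndarray
    peak_ale: float


def extract_clusters(
    binary_map: StatMap, ale_map: StatMap, config: AnalysisConfig
) -> list[Cluster]:
    """Connected components of the thresholded map, extent-filtered.

    Components smaller than ``min_cluster_mm3`` (voxel count x voxel volume;
    survival is inclusive, >=) are discarded.  The peak is the member voxel
    of maximum ALE (ties broken toward the lexicographically smallest
    index); the weighted center is the ALE-weighted mean of member voxel mm
    coordinates.  Clusters are labeled in order of decreasing size.
    """
    binary_map.grid.check_compatible(ale_map.grid)
    grid = binary_map.grid
    struct = _CONNECTIVITY_STRUCTS[config.cluster_connectivity]
    labels, n_comp = ndimage.label(binary_map.values > 0, structure=struct)
    clusters: list[Cluster] = []
    vol = grid.voxel_volume
    slices = ndimage.find_objects(labels)
    for lab in range(1, n_comp + 1):
        sl = slices[lab - 1]
        member = labels[sl] == lab
        n_vox = int(member.sum())
        size = n_vox * vol
        if size < config.min_cluster_mm3:
            continue
        coords = np.argwhere(member) + np.array([s.start for s in sl])
        vals = ale_map.values[tuple(coords.T)]
        peak_i = int(np.argmax(vals))  # argwhere is C-ordered: first max is smallest index
        peak_mm = grid.voxel_to_mm(coords[peak_i])
        weights = vals if vals.sum() > 0 else np.ones(n_vox)
        mm = coords * grid.voxel_size + grid.origin
        center = (mm * weights[:, None]).sum(axis=0) / weights.sum()
        clusters.append(
            Cluster(
                label=0,
                n_voxels=n_vox,
                size_mm3=float(size),
                peak_mm=peak_mm,
                weighted_center_mm=center,
                peak_ale=float(vals[peak_i]),
            )
        )
    clusters.sort(key=lambda c: (-c.n_voxels, tuple(c.peak_mm)))
    for i, c in enumerate(clusters, start=1):
        c.label = i
    return clusters


def clusters_table(clusters: Sequence[Cluster]) -> pd.DataFrame:
    """Cluster table mirroring the usual report layout (one row per region)."""
    rows = [
        {
            "label": c.label,
            "n_voxels": c.n_voxels,
            "size_mm3": c.size_mm3,
            "peak_x": c.peak_mm[0],
            "peak_y": c.peak_mm[1],
            "peak_z": c.peak_mm[2],
            "center_x": c.weighted_center_mm[0],
            "center_y": c.weighted_center_mm[1],
            "center_z": c.weighted_center_mm[2],
            "peak_ale": c.peak_ale,
        }
        for c in clusters
    ]
    cols = [
        "label", "n_voxels", "size_mm3", "peak_x", "peak_y", "peak_z",
        "center_x", "center_y", "center_z", "peak_ale",
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ALEResult:
    """Everything one ALE analysis produces."""

    ale_map: StatMap
    p_map: StatMap
    threshold_mask: StatMap
    clusters: list[Cluster]
    null: NullDistribution
    config: AnalysisConfig

    def clusters_table(self) -> pd.DataFrame:
        return clusters_table(self.clusters)

    def save(self, out_dir, prefix: str = "ale") -> list[str]:
        """Write NIfTI maps, the TSV cluster table and the null JSON dump."""
        import os

        os.makedirs(out_dir, exist_ok=True)
        written = []
        for name, smap in (
            ("ale", self.ale_map),
            ("p", self.p_map),
            ("mask", self.threshold_mask),
        ):
            path = os.path.join(out_dir, f"{prefix}_{name}.nii")
            write_stat_map(smap, path)
            written.append(path)
        table_path = os.path.join(out_dir, f"{prefix}_clusters.tsv")
        self.clusters_table().to_csv(table_path, sep="\t", index=False)
        written.append(table_path)
        null_path = os.path.join(out_dir, f"{prefix}_null.json")
        self.null.to_json(null_path)
        written.append(null_path)
        return written


# -- the estimator ---------------------------------------------------------


class ALE(BaseEstimator):
    """Activation likelihood estimation meta-analysis.

    A scikit-learn-style estimator: configure in the constructor, then
    ``fit(corpus, grid)`` to run the full chain (per-experiment kernels ->
    MA maps -> ALE union -> null distribution -> voxelwise p -> FDR ->
    cluster-extent filter).  Fitted attributes carry the results.

    Parameters
    ----------
    fwhm_template_mm, fwhm_subject_mm : float
        Spatial-uncertainty components; the kernel FWHM of an experiment is
        sqrt(template^2 + subject^2 / n_subjects).
    kernel_normalization : {"gaussian_3d", "printed_1d"}
        True 3-D density (default) or the 1-D-normalized literature formula.
    combine_rule : {"max", "union"}
        Within-experiment combination across foci.
    null_method : {"analytic_histogram", "monte_carlo"}
    null_iterations : int
        Monte-Carlo iterations (ignored by the analytic method).
    fdr_q : float
        Benjamini-Hochberg false-discovery level.
    min_cluster_mm3 : float
        Cluster-extent threshold; surviving clusters have size >= this.
    cluster_connectivity : {6, 18, 26}
    random_state : int
        Seed for the Monte-Carlo null.

    Attributes
    ----------
    sigmas_ : dict
        Kernel sigma (mm) per experiment id.
    ale_map_, p_map_, threshold_mask_ : StatMap
    clusters_ : list of Cluster
    null_ : NullDistribution
    result_ : ALEResult
    """

    def __init__(
        self,
        fwhm_template_mm: float = 5.7,
        fwhm_subject_mm: float = 11.6,
        kernel_normalization: str = "gaussian_3d",
        combine_rule: str = "max",
        truncation_sigmas: float = 3.0,
        null_method: str = "analytic_histogram",
        null_iterations: int = 1000,
        null_bins: int = 2**16,
        fdr_q: float = 0.05,
        min_cluster_mm3: float = 100.0,
        cluster_connectivity: int = 26,
        random_state: int = 0,
    ):
        self.fwhm_template_mm = fwhm_template_mm
        self.fwhm_subject_mm = fwhm_subject_mm
        self.kernel_normalization = kernel_normalization
        self.combine_rule = combine_rule
        self.truncation_sigmas = truncation_sigmas
        self.null_method = null_method
        self.null_iterations = null_iterations
        self.null_bins = null_bins
        self.fdr_q = fdr_q
        self.min_cluster_mm3 = min_cluster_mm3
        self.cluster_connectivity = cluster_connectivity
        self.random_state = random_state

    # -- config plumbing --

    def _config(self) -> AnalysisConfig:
        return AnalysisConfig(
            uncertainty=UncertaintyModel(self.fwhm_template_mm, self.fwhm_subject_mm),
            combine_rule=self.combine_rule,
            kernel_normalization=self.kernel_normalization,
            truncation_sigmas=self.truncation_sigmas,
            fdr_q=self.fdr_q,
            min_cluster_mm3=self.min_cluster_mm3,
            null_method=self.null_method,
            null_iterations=self.null_iterations,
            null_bins=self.null_bins,
            rng_seed=self.random_state,
            cluster_connectivity=self.cluster_connectivity,
        )

    @classmethod
    def from_config(cls, config: AnalysisConfig) -> "ALE":
        return cls(
            fwhm_template_mm=config.uncertainty.fwhm_template_mm,
            fwhm_subject_mm=config.uncertainty.fwhm_subject_mm,
            kernel_normalization=config.kernel_normalization,
            combine_rule=config.combine_rule,
            truncation_sigmas=config.truncation_sigmas,
            null_method=config.null_method,
            null_iterations=config.null_iterations,
            null_bins=config.null_bins,
            fdr_q=config.fdr_q,
            min_cluster_mm3=config.min_cluster_mm3,
            cluster_connectivity=config.cluster_connectivity,
            random_state=config.rng_seed,
        )

    # -- fitting --

    def fit(self, corpus: Corpus, grid: VolumeGrid) -> "ALE":
        if len(corpus) < 1:
            raise ValueError("empty corpus")
        config = self._config()
        self.sigmas_ = {
            e.id: sigma_for_experiment(config.uncertainty, e.n_subjects) for e in corpus
        }
        ma_maps = [
            modeled_activation_map(
                e,
                grid,
                config.uncertainty,
                combine_rule=config.combine_rule,
                normalization=config.kernel_normalization,
                truncation_sigmas=config.truncation_sigmas,
            )
            for e in corpus
        ]
        self.ale_map_ = ale_union(ma_maps)
        if config.null_method == "monte_carlo":
            self.null_ = build_null_monte_carlo(corpus, grid, config)
        else:
            self.null_ = build_null_analytic(corpus, grid, config)
        self.p_map_ = ale_to_p(self.ale_map_, self.null_)
        fdr_mask = fdr_select(self.p_map_, config.fdr_q)
        self.clusters_ = extract_clusters(fdr_mask, self.ale_map_, config)
        surviving = np.zeros(grid.shape)
        labels, _ = ndimage.label(
            fdr_mask.values > 0, structure=_CONNECTIVITY_STRUCTS[config.cluster_connectivity]
        )
        sizes = np.bincount(labels.ravel())
        keep = np.zeros_like(sizes, dtype=bool)
        keep[1:] = sizes[1:] * grid.voxel_volume >= config.min_cluster_mm3
        surviving = keep[labels].astype(float)
        self.threshold_mask_ = StatMap(grid=grid, values=surviving, kind="binary")
        self.result_ = ALEResult(
            ale_map=self.ale_map_,
            p_map=self.p_map_,
            threshold_mask=self.threshold_mask_,
            clusters=self.clusters_,
            null=self.null_,
            config=config,
        )
        return self


def run_ale(corpus: Corpus, grid: VolumeGrid, config: AnalysisConfig | None = None) -> ALEResult:
    """Run the full ALE chain and return its result (functional front-end)."""
    config = config or AnalysisConfig()
    return ALE.from_config(config).fit(corpus, grid).result_
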