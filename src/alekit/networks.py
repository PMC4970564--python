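"""Conjunction networks over thresholded maps and seed-component labeling.

A construct-level network is built by counting, per voxel, how many of n
condition maps include it, then keeping voxels present in at least k of the
n conditions (k = 2 of 4 by default for the acquired-capability network).
Intersecting two such networks yields seed regions whose connected
components are labeled and summarized by weighted centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .grid import GridError, StatMap, VolumeGrid

__all__ = [
    "OverlapMap",
    "SeedComponent",
    "SeedSet",
    "overlap_count",
    "k_of_n_network",
    "intersect_networks",
    "label_seed_components",
    "partition_two_group",
]

_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class OverlapMap:
    """Per-voxel count of how many condition maps include the voxel."""

    grid: VolumeGrid
    counts: np.ndarray
    n_conditions: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != self.grid.shape:
            raise GridError("counts shape does not match grid shape")
        if self.counts.min() < 0 or self.counts.max() > self.n_conditions:
            raise ValueError("counts must lie in 0..n_conditions")
        if np.any(self.counts[~self.grid.mask] != 0):
            raise ValueError("counts outside the mask must be 0")


def overlap_count(binary_maps: Sequence[StatMap]) -> OverlapMap:
    """Sum binary membership maps voxelwise."""
    if len(binary_maps) < 2:
        raise ValueError("need at least two binary maps")
    grid = binary_maps[0].grid
    counts = np.zeros(grid.shape, dtype=int)
    for m in binary_maps:
        grid.check_compatible(m.grid)
        if m.kind != "binary":
            raise ValueError("overlap_count expects binary maps")
        counts += m.values.astype(int)
    return OverlapMap(grid=grid, counts=counts, n_conditions=len(binary_maps))


def k_of_n_network(overlap_map: OverlapMap, k: int) -> StatMap:
    """Voxels present in at least k of the n conditions.

    k=1 is the union of the maps, k=n their intersection; the networks are
    nested: raising k never adds voxels.
    """
    if not (1 <= k <= overlap_map.n_conditions):
        raise ValueError(
            f"k must lie in 1..{overlap_map.n_conditions}, got {k}"
        )
    values = (overlap_map.counts >= k).astype(float)
    values[~overlap_map.grid.mask] = 0.0
    return StatMap(grid=overlap_map.grid, values=values, kind="binary")


def intersect_networks(net_a: StatMap, net_b: StatMap) -> StatMap:
    """Voxelwise AND of two binary networks."""
    net_a.grid.check_compatible(net_b.grid)
    values = ((net_a.values > 0) & (net_b.values > 0)).astype(float)
    return StatMap(grid=net_a.grid, values=values, kind="binary")


@dataclass
class SeedComponent:
    label: int
    n_voxels: int
    weighted_center_mm: np.ndarray
    name: str | None = None


@dataclass
class SeedSet:
    """Labeled connected seed regions with their weighted centers."""

    grid: VolumeGrid
    component_labels: np.ndarray
    components: list[SeedComponent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)

    def binary_map(self) -> StatMap:
        return StatMap(
            grid=self.grid,
            values=(self.component_labels > 0).astype(float),
            kind="binary",
        )

    def to_table(self) -> pd.DataFrame:
        rows = [
            {
                "label": c.label,
                "n_voxels": c.n_voxels,
                "center_x": c.weighted_center_mm[0],
                "center_y": c.weighted_center_mm[1],
                "center_z": c.weighted_center_mm[2],
                "name": c.name if c.name is not None else "",
            }
            for c in self.components
        ]
        cols = ["label", "n_voxels", "center_x", "center_y", "center_z", "name"]
        return pd.DataFrame(rows, columns=cols)


def label_seed_components(
    binary_map: StatMap,
    weight_map: StatMap | None = None,
    connectivity: int = 26,
) -> SeedSet:
    """Label connected components of a binary map in decreasing size order.

    Each component's weighted center is the weight-weighted mean of its
    member voxel mm coordinates (weights usually the mean condition ALE
    values); uniform weights are used when no weight map is given or the
    weights vanish on the component.  An empty map yields an empty SeedSet.
    """
    grid = binary_map.grid
    if weight_map is not None:
        grid.check_compatible(weight_map.grid)
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError("connectivity must be 6, 18 or 26")
    labels, n_comp = ndimage.label(
        binary_map.values > 0, structure=_CONNECTIVITY_STRUCTS[connectivity]
    )
    comps = []
    for lab in range(1, n_comp + 1):
        coords = np.argwhere(labels == lab)
        n_vox = len(coords)
        if weight_map is not None:
            w = weight_map.values[tuple(coords.T)]
            if w.sum() <= 0:
                w = np.ones(n_vox)
        else:
            w = np.ones(n_vox)
        mm = coords * grid.voxel_size + grid.origin
        center = (mm * w[:, None]).sum(axis=0) / w.sum()
        comps.append((lab, n_vox, center, tuple(coords[0])))
    comps.sort(key=lambda t: (-t[1], t[3]))
    relabeled = np.zeros(grid.shape, dtype=int)
    out = []
    for new_lab, (old_lab, n_vox, center, _) in enumerate(comps, start=1):
        relabeled[labels == old_lab] = new_lab
        out.append(SeedComponent(label=new_lab, n_voxels=n_vox, weighted_center_mm=center))
    return SeedSet(grid=grid, component_labels=relabeled, components=out)


def partition_two_group(map_m: StatMap, map_f: StatMap) -> tuple[StatMap, StatMap, StatMap]:
    """Split two group networks into exclusive and shared parts.

    Returns ``(m_only, f_only, shared)`` — pairwise disjoint binary maps
    whose union equals the union of the inputs (the two-color-plus-overlap
    overlay of a two-group comparison).
    """
    map_m.grid.check_compatible(map_f.grid)
    a = map_m.values > 0
    b = map_f.values > 0
    grid = map_m.grid
    mk = lambda arr: StatMap(grid=grid, values=arr.astype(float), kind="binary")
    return mk(a & ~b), mk(b & ~a), mk(a & b)
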