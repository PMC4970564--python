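"""Meta-analytic connectivity modeling (MACM).

The premise: voxels that are statistically coactivated with a seed region
across many independent experiments are functionally connected to it.  The
procedure selects every experiment reporting at least one focus inside the
seed, then meta-analyzes that sub-corpus with ALE; the surviving clusters
form the seed's coactivation network.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .ale import ALE, ALEResult, AnalysisConfig
from .corpus import Corpus
from .grid import StatMap, VolumeGrid

__all__ = ["MACMResult", "MACM", "select_experiments", "macm_map"]


class EmptySeedError(ValueError):
    pass


class EmptySelectionError(ValueError):
    pass


def _dilate(seed: np.ndarray, grid: VolumeGrid, radius_mm: float) -> np.ndarray:
    if radius_mm <= 0:
        return seed
    half = np.ceil(radius_mm / grid.voxel_size).astype(int)
    axes = [np.arange(-h, h + 1) * vs for h, vs in zip(half, grid.voxel_size)]
    dx, dy, dz = np.meshgrid(*axes, indexing="ij", sparse=True)
    ball = np.sqrt(dx**2 + dy**2 + dz**2) <= radius_mm
    return ndimage.binary_dilation(seed, structure=ball)


def select_experiments(
    corpus: Corpus,
    seed_map: StatMap,
    grid: VolumeGrid,
    dilation_mm: float = 0.0,
) -> tuple[Corpus, list[str]]:
    """Sub-corpus of experiments with >= 1 focus inside the (dilated) seed.

    Foci are mapped to their nearest voxel; membership is literal — a focus
    outside the grid never selects.  Order is preserved.  An empty seed is
    an error; an empty selection returns an empty sub-corpus with a warning.
    """
    seed = seed_map.values > 0
    if not seed.any():
        raise EmptySeedError("empty seed")
    seed = _dilate(seed, grid, dilation_mm)
    selected = []
    for exp in corpus:
        idx, inside = grid.mm_to_voxel(exp.foci_mm)
        inside_idx = idx[inside]
        if len(inside_idx) and seed[tuple(inside_idx.T)].any():
            selected.append(exp.id)
    if not selected:
        warnings.warn("no experiment reports a focus inside the seed", stacklevel=2)
    return corpus.subset(selected), selected


@dataclass
class MACMResult:
    """Seed, the experiments it selected, and their coactivation ALE result."""

    seed: StatMap
    selected_ids: list[str]
    coactivation: ALEResult


class MACM(BaseEstimator):
    """Seed-based coactivation meta-analysis as an estimator.

    Shares all ALE parameters; ``dilation_mm`` optionally enlarges the seed
    before experiment selection (default 0: literal membership).

    Attributes
    ----------
    selected_ids_ : list of experiment ids with a focus in the seed
    coactivation_ : ALEResult of the selected sub-corpus
    result_ : MACMResult
    """

    def __init__(
        self,
        dilation_mm: float = 0.0,
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
        self.dilation_mm = dilation_mm
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

    @classmethod
    def from_config(cls, config: AnalysisConfig, dilation_mm: float = 0.0) -> "MACM":
        return cls(dilation_mm=dilation_mm, **ALE.from_config(config).get_params())

    def fit(self, corpus: Corpus, grid: VolumeGrid, seed_map: StatMap) -> "MACM":
        sub, ids = select_experiments(corpus, seed_map, grid, dilation_mm=self.dilation_mm)
        if len(sub) == 0:
            raise EmptySelectionError(
                "no experiments selected; enlarge the seed (dilation_mm) or the corpus"
            )
        params = {k: v for k, v in self.get_params().items() if k != "dilation_mm"}
        ale = ALE(**params).fit(sub, grid)
        self.selected_ids_ = ids
        self.coactivation_ = ale.result_
        self.result_ = MACMResult(seed=seed_map, selected_ids=ids, coactivation=ale.result_)
        return self


def macm_map(
    corpus: Corpus,
    seed_map: StatMap,
    grid: VolumeGrid,
    config: AnalysisConfig | None = None,
    dilation_mm: float = 0.0,
) -> MACMResult:
    """Functional front-end: select by seed membership, then run ALE."""
    config = config or AnalysisConfig()
    est = MACM.from_config(config, dilation_mm=dilation_mm)
    return est.fit(corpus, grid, seed_map).result_
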