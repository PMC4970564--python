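"""Synthetic foci corpora with planted condition networks.

Stands in for literature-database searches: each *condition* (e.g. emotion,
pain, reward, fear, depression) has a set of true activation centers; every
simulated experiment of that condition expresses each center independently
with some probability, displaces expressed centers by isotropic Gaussian
jitter (parameterized as FWHM, the same spatial vocabulary as the kernels),
and adds uniform noise foci drawn over in-mask voxel centers — exactly the
null model of the ALE significance test, so null-calibration simulations
are a true null.  Coactivation structure arises naturally: experiments of a
condition co-express that condition's centers, which is what seed-based
coactivation mapping detects.

Ground truth is carried alongside the corpus for recovery scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ale import Cluster
from .corpus import Corpus, Experiment, Focus
from .grid import StatMap, VolumeGrid, make_box_mask
from .kernels import FWHM_TO_SIGMA
from .networks import SeedSet

__all__ = [
    "ConditionSpec",
    "SynthSpec",
    "GroundTruth",
    "RecoveryReport",
    "generate_corpus",
    "evaluate_recovery",
    "make_box_mask",
]


@dataclass
class ConditionSpec:
    """One simulated search condition: named true centers with expression odds."""

    name: str
    centers: list  # list of (x, y, z) mm
    expression_prob: float | list = 1.0

    def probs(self) -> np.ndarray:
        p = np.asarray(self.expression_prob, dtype=float)
        if p.ndim == 0:
            p = np.repeat(p, len(self.centers))
        if len(p) != len(self.centers):
            raise ValueError(f"{self.name}: one expression_prob per center required")
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError(f"{self.name}: expression_prob must lie in [0, 1]")
        return p


@dataclass
class SynthSpec:
    """Parameters of one synthetic corpus.

    Defaults emulate a modest literature search: 40 experiments per
    condition, centers expressed with probability 0.7, 10 mm FWHM spatial
    jitter between studies, 2 uniform noise foci per experiment and subject
    counts uniform in 10..30 (typical fMRI group sizes).
    """

    grid: VolumeGrid
    conditions: list[ConditionSpec] = field(default_factory=list)
    n_experiments_per_condition: int = 40
    jitter_fwhm_mm: float = 10.0
    n_noise_foci: int = 2
    n_subjects_range: tuple[int, int] = (10, 30)
    metadata_assignments: dict = field(default_factory=dict)
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_experiments_per_condition < 1:
            raise ValueError("n_experiments_per_condition must be >= 1")
        if self.jitter_fwhm_mm < 0 or self.n_noise_foci < 0:
            raise ValueError("jitter and noise counts must be nonnegative")
        lo, hi = self.n_subjects_range
        if not (1 <= lo <= hi):
            raise ValueError("n_subjects_range must satisfy 1 <= min <= max")
        if not self.conditions:
            raise ValueError("at least one condition required")
        for cond in self.conditions:
            cond.probs()
            for c in cond.centers:
                idx, inside = self.grid.mm_to_voxel(np.asarray(c, dtype=float))
                if not inside or not self.grid.mask[tuple(idx)]:
                    raise ValueError(
                        f"condition {cond.name!r}: true center {tuple(c)} is outside the mask"
                    )

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        d = dict(d)
        g = d.pop("grid")
        grid = make_box_mask(g["shape"], g["voxel_size"], g["origin"])
        conds = [
            ConditionSpec(
                name=c["name"],
                centers=[tuple(p) for p in c["centers"]],
                expression_prob=c.get("expression_prob", 1.0),
            )
            for c in d.pop("conditions")
        ]
        if "n_subjects_range" in d:
            d["n_subjects_range"] = tuple(d["n_subjects_range"])
        return cls(grid=grid, conditions=conds, **d)


@dataclass
class GroundTruth:
    """Planted centers plus what each experiment actually expressed."""

    condition_centers: dict[str, list]  # name -> list of (x, y, z)
    realized: dict[str, list]  # experiment id -> list of (condition, center_idx, (x, y, z))
    params: dict

    def centers_of(self, *condition_names: str) -> np.ndarray:
        pts = []
        for name in condition_names:
            pts.extend(self.condition_centers[name])
        return np.asarray(pts, dtype=float)

    def to_json(self, path=None) -> str:
        text = json.dumps(
            {
                "condition_centers": self.condition_centers,
                "realized": self.realized,
                "params": self.params,
            },
            indent=1,
        )
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                obj = json.load(fh)
        return cls(
            condition_centers={k: [tuple(p) for p in v] for k, v in obj["condition_centers"].items()},
            realized={
                k: [(c, i, tuple(p)) for c, i, p in v] for k, v in obj["realized"].items()
            },
            params=obj["params"],
        )


def generate_corpus(spec: SynthSpec) -> tuple[Corpus, GroundTruth]:
    """Draw one corpus (and its ground truth) from a :class:`SynthSpec`.

    Deterministic given ``spec.rng_seed``: the same spec yields byte-
    identical Sleuth output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    grid = spec.grid
    mask_idx = grid.mask_indices()
    jitter_sigma = spec.jitter_fwhm_mm / FWHM_TO_SIGMA
    lo, hi = spec.n_subjects_range

    experiments: list[Experiment] = []
    realized: dict[str, list] = {}
    for cond in spec.conditions:
        centers = np.asarray(cond.centers, dtype=float)
        probs = cond.probs()
        for i in range(spec.n_experiments_per_condition):
            exp_id = f"{cond.name}-{i + 1:03d}"
            foci: list[Focus] = []
            hits: list = []
            expressed = rng.random(len(centers)) < probs
            for ci in np.nonzero(expressed)[0]:
                pt = centers[ci] + rng.normal(0.0, jitter_sigma, size=3)
                foci.append(Focus.from_xyz(pt))
                hits.append((cond.name, int(ci), tuple(float(v) for v in pt)))
            for j in rng.integers(0, len(mask_idx), size=spec.n_noise_foci):
                foci.append(Focus.from_xyz(grid.voxel_to_mm(mask_idx[j])))
            n_subjects = int(rng.integers(lo, hi + 1))
            metadata = {"domain": cond.name}
            for key, dist in spec.metadata_assignments.items():
                labels = sorted(dist)
                weights = np.array([dist[l] for l in labels], dtype=float)
                metadata[key] = labels[rng.choice(len(labels), p=weights / weights.sum())]
            if not foci:
                # an experiment must report something; an empty draw becomes
                # a single uniform noise focus
                j = int(rng.integers(0, len(mask_idx)))
                foci.append(Focus.from_xyz(grid.voxel_to_mm(mask_idx[j])))
            experiments.append(
                Experiment(id=exp_id, n_subjects=n_subjects, foci=foci, metadata=metadata)
            )
            realized[exp_id] = hits

    truth = GroundTruth(
        condition_centers={c.name: [tuple(map(float, p)) for p in c.centers] for c in spec.conditions},
        realized=realized,
        params={
            "n_experiments_per_condition": spec.n_experiments_per_condition,
            "jitter_fwhm_mm": spec.jitter_fwhm_mm,
            "n_noise_foci": spec.n_noise_foci,
            "n_subjects_range": list(spec.n_subjects_range),
            "rng_seed": spec.rng_seed,
        },
    )
    return Corpus(experiments=experiments, space_label="SYNTH"), truth


@dataclass
class RecoveryReport:
    """How well recovered clusters match planted centers."""

    sensitivity: float
    n_true: int
    n_clusters: int
    matches: list  # (center_idx, cluster_idx, distance_mm)
    false_positive_idx: list

    @property
    def n_false_positives(self) -> int:
        return len(self.false_positive_idx)


def _peaks_from(obj) -> np.ndarray:
    if isinstance(obj, SeedSet):
        return np.asarray([c.weighted_center_mm for c in obj.components], dtype=float).reshape(-1, 3)
    if isinstance(obj, StatMap):
        raise TypeError("pass clusters or a SeedSet, not a raw map")
    peaks = []
    for c in obj:
        peaks.append(c.peak_mm if isinstance(c, Cluster) else np.asarray(c, dtype=float))
    return np.asarray(peaks, dtype=float).reshape(-1, 3)


def evaluate_recovery(clusters_or_seeds, true_centers, match_radius_mm: float) -> RecoveryReport:
    """One-to-one matching of cluster peaks to planted centers.

    Matching is the optimal assignment (maximum number of pairs within
    ``match_radius_mm``, minimum total distance among those); a center
    counts as recovered when matched.  Clusters matching no center are
    false positives.
    """
    from scipy.optimize import linear_sum_assignment

    if match_radius_mm <= 0:
        raise ValueError("match_radius_mm must be positive")
    centers = np.asarray(true_centers, dtype=float).reshape(-1, 3)
    peaks = _peaks_from(clusters_or_seeds)
    n_true, n_cl = len(centers), len(peaks)
    matches: list = []
    matched_p: set = set()
    if n_true and n_cl:
        dist = np.linalg.norm(centers[:, None, :] - peaks[None, :, :], axis=2)
        # out-of-radius pairs get a cost large enough that the assignment
        # never trades an in-radius match away
        big = match_radius_mm * (n_true + n_cl + 1) * 1000.0
        cost = np.where(dist <= match_radius_mm, dist, big)
        rows, cols = linear_sum_assignment(cost)
        for ci, pi in zip(rows, cols):
            if dist[ci, pi] <= match_radius_mm:
                matches.append((int(ci), int(pi), float(dist[ci, pi])))
                matched_p.add(int(pi))
    fp = [i for i in range(n_cl) if i not in matched_p]
    sensitivity = len(matches) / n_true if n_true else 0.0
    return RecoveryReport(
        sensitivity=sensitivity,
        n_true=n_true,
        n_clusters=n_cl,
        matches=sorted(matches),
        false_positive_idx=fp,
    )
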