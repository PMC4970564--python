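"""Reproducible desk-scale benchmarks of the full pipeline.

Two standard studies, both on synthetic corpora:

* :func:`null_calibration_study` — corpora whose foci are purely uniform in
  the mask (a true null for the ALE significance test): measures the
  fraction of voxels declared at p < alpha and the realized false-discovery
  proportion after Benjamini-Hochberg.

* :func:`planted_network_study` — four construct conditions x three centers
  plus a target ("depression") condition, with one center shared by two
  constructs and the target.  Runs the full chain (per-condition ALE ->
  2-of-4 conjunction -> intersection with the target network -> seed
  labeling -> seed-based MACM) and scores how often the seed set recovers
  the planted shared center and how many co-expressed centers MACM finds.

The study geometry is a 96 mm box at 4 mm resolution (24^3 voxels) for the
planted-network study and a 40 mm box at 2 mm (20^3) for calibration —
small enough to run in seconds per replicate, large enough to host
well-separated centers.  MACM seed dilation is set to the planted
between-study jitter FWHM (10 mm) so selection tolerates the same spatial
scatter the generator applies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ale import AnalysisConfig, ale_to_p, ale_union, build_null_analytic, fdr_select, run_ale
from .corpus import Corpus
from .grid import make_box_mask
from .kernels import modeled_activation_map
from .macm import macm_map
from .networks import intersect_networks, k_of_n_network, label_seed_components, overlap_count
from .simulate import ConditionSpec, SynthSpec, evaluate_recovery, generate_corpus

__all__ = [
    "CalibrationResult",
    "PlantedNetworkResult",
    "null_calibration_study",
    "planted_network_study",
    "uniform_null_corpus",
    "planted_conditions",
]

SHARED_CENTER = (44.0, 44.0, 44.0)


def planted_conditions() -> dict[str, list[tuple[float, float, float]]]:
    """Benchmark layout: 4 constructs + target, 3 centers each, one shared.

    The shared center belongs to two constructs (emotion, pain) and to the
    target, so it — and only it — survives the 2-of-4 conjunction followed
    by intersection with the target network.  All centers are >= 24 mm
    apart and >= 20 mm from the box faces.
    """
    s = SHARED_CENTER
    return {
        "emotion": [s, (20.0, 20.0, 20.0), (72.0, 72.0, 72.0)],
        "pain": [s, (72.0, 20.0, 20.0), (20.0, 72.0, 72.0)],
        "reward": [(20.0, 44.0, 72.0), (72.0, 44.0, 20.0), (44.0, 20.0, 72.0)],
        "fear": [(44.0, 72.0, 20.0), (20.0, 20.0, 72.0), (72.0, 72.0, 20.0)],
        "depression": [s, (72.0, 44.0, 72.0), (44.0, 72.0, 72.0)],
    }


def uniform_null_corpus(grid, seed: int, n_experiments: int = 20, n_foci: int = 8) -> Corpus:
    """A global-null corpus: every focus uniform over in-mask voxel centers."""
    spec = SynthSpec(
        grid=grid,
        conditions=[ConditionSpec("uniform", [tuple(grid.voxel_to_mm(np.array(grid.shape) // 2))], 0.0)],
        n_experiments_per_condition=n_experiments,
        jitter_fwhm_mm=0.0,
        n_noise_foci=n_foci,
        n_subjects_range=(15, 30),
        rng_seed=seed,
    )
    return generate_corpus(spec)[0]


@dataclass
class CalibrationResult:
    alphas: tuple[float, ...]
    fractions: dict[float, float]  # pooled fraction of voxels with p < alpha
    band_halfwidths: dict[float, float]  # binomial 99% half-width at pooled n
    mean_fdp: float  # mean realized false-discovery proportion (BH, q)
    n_corpora: int
    n_voxels: int


def null_calibration_study(
    seed: int,
    n_corpora: int = 60,
    alphas: tuple[float, ...] = (0.05, 0.01),
    fdr_q: float = 0.05,
    config: AnalysisConfig | None = None,
) -> CalibrationResult:
    """p-value calibration and FDR control under the global null.

    Each corpus has 20 experiments of 8 uniform foci on a 20^3 2-mm grid;
    every discovery is false by construction, so the realized FDP of a
    corpus is 1 when anything is rejected and 0 otherwise.
    """
    grid = make_box_mask((20, 20, 20), (2.0, 2.0, 2.0), (0.0, 0.0, 0.0))
    config = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    corpus_seeds = rng.integers(0, 2**31 - 1, size=n_corpora)
    frac = {a: [] for a in alphas}
    fdp = []
    for cs in corpus_seeds:
        corpus = uniform_null_corpus(grid, int(cs))
        mas = [modeled_activation_map(e, grid, config.uncertainty,
                                      combine_rule=config.combine_rule,
                                      normalization=config.kernel_normalization,
                                      truncation_sigmas=config.truncation_sigmas)
               for e in corpus]
        ale = ale_union(mas)
        null = build_null_analytic(corpus, grid, config)
        p = ale_to_p(ale, null)
        pm = p.in_mask()
        for a in alphas:
            frac[a].append((pm < a).mean())
        rejected = fdr_select(p, fdr_q).in_mask().sum()
        fdp.append(1.0 if rejected > 0 else 0.0)
    n_pool = n_corpora * grid.n_mask_voxels
    return CalibrationResult(
        alphas=alphas,
        fractions={a: float(np.mean(frac[a])) for a in alphas},
        band_halfwidths={
            a: float(2.5758 * np.sqrt(a * (1 - a) / n_pool)) for a in alphas
        },
        mean_fdp=float(np.mean(fdp)),
        n_corpora=n_corpora,
        n_voxels=grid.n_mask_voxels,
    )


@dataclass
class PlantedNetworkResult:
    seed_hit_rate: float  # replicates whose seed set falls within radius of the shared center
    mean_macm_sensitivity: float  # co-expressed centers recovered by MACM
    macm_sensitivities: list[float]
    seed_distances_mm: list[float]
    n_replicates: int
    match_radius_mm: float


def planted_network_study(
    seed: int,
    n_replicates: int = 20,
    n_experiments: int = 40,
    expression_prob: float = 0.7,
    jitter_fwhm_mm: float = 10.0,
    n_noise_foci: int = 2,
    match_radius_mm: float = 10.0,
    k: int = 2,
    macm_dilation_mm: float = 10.0,
    config: AnalysisConfig | None = None,
) -> PlantedNetworkResult:
    """End-to-end recovery of the planted shared center and its co-network."""
    grid = make_box_mask((24, 24, 24), (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
    conds = planted_conditions()
    shared = np.asarray(SHARED_CENTER)
    co_centers = np.asarray(
        [c for n in ("emotion", "pain", "depression") for c in conds[n] if c != SHARED_CENTER]
    )
    base = config or AnalysisConfig()
    rng = np.random.default_rng(seed)
    rep_seeds = rng.integers(0, 2**31 - 1, size=(n_replicates, len(conds) + 1))
    seed_dist = []
    sens = []
    for rep in range(n_replicates):
        corpora = {}
        for ci, (name, centers) in enumerate(conds.items()):
            spec = SynthSpec(
                grid=grid,
                conditions=[ConditionSpec(name, centers, expression_prob)],
                n_experiments_per_condition=n_experiments,
                jitter_fwhm_mm=jitter_fwhm_mm,
                n_noise_foci=n_noise_foci,
                n_subjects_range=(10, 30),
                rng_seed=int(rep_seeds[rep, ci]),
            )
            corpora[name], _ = generate_corpus(spec)
        cfg = AnalysisConfig.from_dict(
            {**base.to_dict(), "rng_seed": int(rep_seeds[rep, -1])}
        )
        results = {n: run_ale(corpora[n], grid, cfg) for n in conds}
        acs = k_of_n_network(
            overlap_count([results[n].threshold_mask for n in ("emotion", "pain", "reward", "fear")]),
            k,
        )
        inter = intersect_networks(acs, results["depression"].threshold_mask)
        seeds = label_seed_components(inter, results["depression"].ale_map)
        d = min(
            (float(np.linalg.norm(np.asarray(c.weighted_center_mm) - shared)) for c in seeds.components),
            default=float("inf"),
        )
        seed_dist.append(d)
        if d <= match_radius_mm:
            pooled = Corpus([e for c in corpora.values() for e in c])
            macm = macm_map(pooled, seeds.binary_map(), grid, cfg, dilation_mm=macm_dilation_mm)
            rep_score = evaluate_recovery(
                macm.coactivation.clusters, co_centers, match_radius_mm
            )
            sens.append(rep_score.sensitivity)
    hit_rate = float(np.mean([d <= match_radius_mm for d in seed_dist]))
    return PlantedNetworkResult(
        seed_hit_rate=hit_rate,
        mean_macm_sensitivity=float(np.mean(sens)) if sens else 0.0,
        macm_sensitivities=[float(s) for s in sens],
        seed_distances_mm=seed_dist,
        n_replicates=n_replicates,
        match_radius_mm=match_radius_mm,
    )
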