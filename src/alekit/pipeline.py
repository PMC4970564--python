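"""One-config orchestration of the full meta-analytic chain.

Per group (e.g. males / females): ALE per construct condition, overlap
counting, the k-of-n construct network, ALE on the target (depression)
corpus, network intersection into seeds, seed labeling, and seed-based
coactivation mapping (MACM).  Across two groups, the seed networks are
partitioned into group-exclusive and shared parts.  Every run writes a
manifest declaring its outputs, the config hash, the seed and a stage log.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .ale import AnalysisConfig, run_ale
from .corpus import Corpus, filter_corpus, parse_sleuth
from .grid import StatMap, make_box_mask, read_stat_map, write_stat_map
from .macm import macm_map
from .networks import (
    intersect_networks,
    k_of_n_network,
    label_seed_components,
    overlap_count,
    partition_two_group,
)

__all__ = ["PipelineConfig", "run_pipeline", "ConfigError", "DataError"]


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    ``corpora`` maps condition names to Sleuth files; ``groups`` maps group
    names to metadata predicates applied to every corpus; ``acs_conditions``
    are the constructs entering the k-of-n conjunction and
    ``target_condition`` the network it is intersected with.
    """

    corpora: dict[str, str]
    acs_conditions: list[str]
    target_condition: str
    grid: dict
    groups: dict[str, dict] = field(default_factory=lambda: {"all": {}})
    k: int = 2
    analysis: dict = field(default_factory=dict)
    macm_dilation_mm: float = 0.0
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        missing = [c for c in self.acs_conditions + [self.target_condition] if c not in self.corpora]
        if missing:
            raise ConfigError(f"conditions without corpus files: {missing}")
        paths = list(self.corpora.values())
        if len(set(paths)) != len(paths):
            raise ConfigError("corpus paths must be distinct")
        if not (1 <= self.k <= len(self.acs_conditions)):
            raise ConfigError(
                f"k={self.k} outside 1..{len(self.acs_conditions)} conditions"
            )

    def analysis_config(self) -> AnalysisConfig:
        d = dict(self.analysis)
        d.setdefault("rng_seed", self.seed)
        return AnalysisConfig.from_dict(d)

    def make_grid(self):
        g = self.grid
        if "mask_path" in g:
            m = read_stat_map(g["mask_path"], kind="binary")
            grid = m.grid
            grid.mask = m.values > 0
            if not grid.mask.any():
                raise DataError(f"mask {g['mask_path']} is empty")
            return grid
        try:
            return make_box_mask(g["shape"], g["voxel_size"], g["origin"])
        except KeyError as e:
            raise ConfigError(f"grid config needs shape/voxel_size/origin or mask_path: {e}")

    def to_canonical_json(self) -> str:
        return json.dumps(
            {
                "corpora": self.corpora,
                "acs_conditions": self.acs_conditions,
                "target_condition": self.target_condition,
                "grid": self.grid,
                "groups": self.groups,
                "k": self.k,
                "analysis": self.analysis,
                "macm_dilation_mm": self.macm_dilation_mm,
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {
            "corpora", "acs_conditions", "target_condition", "grid",
            "groups", "k", "analysis", "macm_dilation_mm", "seed", "out_dir",
        }
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            if str(path).endswith((".yaml", ".yml")):
                d = yaml.safe_load(fh)
            else:
                d = json.load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(d)


def _mean_map(maps: list[StatMap]) -> StatMap:
    grid = maps[0].grid
    mean = np.mean([m.values for m in maps], axis=0)
    return StatMap(grid=grid, values=np.where(grid.mask, mean, 0.0), kind="ale")


def run_pipeline(cfg: PipelineConfig, out_dir: str | None = None) -> dict:
    """Execute the full chain and return the manifest (also written to disk)."""
    out_dir = out_dir or cfg.out_dir
    os.makedirs(out_dir, exist_ok=True)
    grid = cfg.make_grid()
    ana = cfg.analysis_config()

    try:
        raw_corpora = {name: parse_sleuth(path) for name, path in cfg.corpora.items()}
    except (OSError, ValueError) as e:
        raise DataError(f"loading corpora: {e}")

    manifest: dict = {
        "config_sha256": hashlib.sha256(cfg.to_canonical_json().encode()).hexdigest(),
        "seed": cfg.seed,
        "stages": [],
        "outputs": [],
    }
    stages = manifest["stages"]
    outputs = manifest["outputs"]

    def emit(paths):
        outputs.extend(os.path.relpath(p, out_dir) for p in paths)

    group_seed_maps: dict[str, StatMap] = {}
    for group, predicate in cfg.groups.items():
        gdir = os.path.join(out_dir, group)
        os.makedirs(gdir, exist_ok=True)
        corpora = {name: filter_corpus(c, predicate) for name, c in raw_corpora.items()}
        for name, c in corpora.items():
            if len(c) == 0:
                raise DataError(f"group {group!r}: condition {name!r} has no experiments")

        cond_results = {}
        for name in cfg.acs_conditions:
            res = run_ale(corpora[name], grid, ana)
            cond_results[name] = res
            emit(res.save(gdir, prefix=f"ale_{name}"))
            stages.append(
                {
                    "stage": f"{group}/ale/{name}",
                    "n_experiments": len(corpora[name]),
                    "sigmas_mm": {
                        e.id: round(
                            float(
                                np.sqrt(
                                    ana.uncertainty.fwhm_template_mm**2
                                    + ana.uncertainty.fwhm_subject_mm**2 / e.n_subjects
                                )
                                / (2 * np.sqrt(2 * np.log(2)))
                            ),
                            4,
                        )
                        for e in corpora[name]
                    },
                    "null_method": ana.null_method,
                    "fdr_q": ana.fdr_q,
                    "min_cluster_mm3": ana.min_cluster_mm3,
                    "n_clusters": len(res.clusters),
                }
            )

        overlap = overlap_count([cond_results[n].threshold_mask for n in cfg.acs_conditions])
        acs_net = k_of_n_network(overlap, cfg.k)
        opath = os.path.join(gdir, "overlap_count.nii")
        write_stat_map(StatMap(grid=grid, values=overlap.counts.astype(float), kind="count"), opath)
        npath = os.path.join(gdir, "acs_network.nii")
        write_stat_map(acs_net, npath)
        emit([opath, npath])
        stages.append(
            {
                "stage": f"{group}/k_of_n",
                "k": cfg.k,
                "n_conditions": len(cfg.acs_conditions),
                "n_network_voxels": int(acs_net.values.sum()),
            }
        )

        target_res = run_ale(corpora[cfg.target_condition], grid, ana)
        emit(target_res.save(gdir, prefix=f"ale_{cfg.target_condition}"))
        stages.append(
            {
                "stage": f"{group}/ale/{cfg.target_condition}",
                "n_experiments": len(corpora[cfg.target_condition]),
                "null_method": ana.null_method,
                "n_clusters": len(target_res.clusters),
            }
        )

        seeds_bin = intersect_networks(acs_net, target_res.threshold_mask)
        weight = _mean_map(
            [cond_results[n].ale_map for n in cfg.acs_conditions] + [target_res.ale_map]
        )
        seeds = label_seed_components(seeds_bin, weight, connectivity=ana.cluster_connectivity)
        group_seed_maps[group] = seeds_bin
        spath = os.path.join(gdir, "seed_labels.nii")
        write_stat_map(
            StatMap(grid=grid, values=seeds.component_labels.astype(float), kind="count"), spath
        )
        tpath = os.path.join(gdir, "seeds.tsv")
        seeds.to_table().to_csv(tpath, sep="\t", index=False)
        emit([spath, tpath])
        stages.append({"stage": f"{group}/seeds", "n_components": len(seeds)})

        if len(seeds) > 0:
            pooled = Corpus(
                experiments=[e for c in corpora.values() for e in c],
                space_label=next(iter(corpora.values())).space_label,
            )
            macm = macm_map(pooled, seeds.binary_map(), grid, ana, dilation_mm=cfg.macm_dilation_mm)
            emit(macm.coactivation.save(gdir, prefix="macm"))
            idpath = os.path.join(gdir, "macm_selected.tsv")
            with open(idpath, "w", encoding="utf-8") as fh:
                fh.write("experiment_id\n")
                for eid in macm.selected_ids:
                    fh.write(eid + "\n")
            emit([idpath])
            stages.append(
                {
                    "stage": f"{group}/macm",
                    "n_selected": len(macm.selected_ids),
                    "n_clusters": len(macm.coactivation.clusters),
                }
            )
        else:
            stages.append({"stage": f"{group}/macm", "skipped": "empty seed set"})

    if len(cfg.groups) == 2:
        g1, g2 = list(cfg.groups)
        only1, only2, shared = partition_two_group(group_seed_maps[g1], group_seed_maps[g2])
        for tag, smap in ((f"{g1}_only", only1), (f"{g2}_only", only2), ("shared", shared)):
            path = os.path.join(out_dir, f"seeds_{tag}.nii")
            write_stat_map(smap, path)
            emit([path])
        stages.append(
            {
                "stage": "two_group_partition",
                "groups": [g1, g2],
                "n_shared_voxels": int(shared.values.sum()),
            }
        )

    mpath = os.path.join(out_dir, "manifest.json")
    with open(mpath, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
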