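"""End-to-end simulation campaigns and tidy result tables.

A campaign crosses sampling frames (sea polygon vs route network), sampling
strategies (random vs regular) and sample sizes, simulating many replicate
surveys against the truth community: detection curves (how many species
reach the modelling threshold), stacked-SDM rebuilds (Pearson correlation of
the rebuilt richness surface with the truth), subnetwork comparisons, and
taxonomic-removal experiments.  Replicate seeds are derived from the master
seed by hashing the arm coordinates (frame, strategy, n, replicate), so
every arm is independent but the whole campaign is reproducible bit-for-bit
from (config, master seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bias import climatic_bias_index, env_variability_index, richness_correlation
from .errors import UndefinedCorrelationError
from .grid import EnvStack, RouteNetwork, TruthSSDM
from .routes import traversed_cells
from .sampling import (PointSet, detection_filter, extract_occurrences,
                       retained_records, sample_network, sample_polygon)
from .sdm import SDMConfig, StackedSDM


def derive_seed(master_seed: int, *parts) -> int:
    """Stable replicate seed: CRC32 of the arm coordinates, below 2**31."""
    key = "|".join([str(master_seed)] + [str(p) for p in parts])
    return zlib.crc32(key.encode()) % (2**31 - 1)


@dataclass(frozen=True)
class CampaignConfig:
    """Campaign parameters.

    Defaults are the full study conditions: sizes 25/50/100, 1000 detection
    replicates, 40 SSDM rebuilds per arm, species retained with more than 20
    occurrences, 10 subnetwork rebuilds at 50 regular points.  :meth:`fast`
    returns a reduced profile for desk-scale runs.
    """

    frames: tuple[str, ...] = ("polygon", "network")
    strategies: tuple[str, ...] = ("random", "regular")
    sizes: tuple[int, ...] = (25, 50, 100)
    n_detection_reps: int = 1000
    n_ssdm_reps: int = 40
    min_occ: int = 20
    sdm: SDMConfig = field(default_factory=SDMConfig)
    subnet_points: int = 50
    subnet_reps: int = 10
    subnet_strategy: str = "regular"

    @classmethod
    def fast(cls, **overrides) -> "CampaignConfig":
        base = dict(n_detection_reps=100, n_ssdm_reps=10, sdm=SDMConfig.fast())
        base.update(overrides)
        return cls(**base)


def _draw_points(frame: str, strategy: str, n: int, seed: int,
                 truth: TruthSSDM, net: RouteNetwork | None) -> PointSet:
    if frame == "polygon":
        return sample_polygon(truth.grid, strategy, n, seed)
    if frame == "network":
        if net is None:
            raise ValueError("network frame requires a route network")
        return sample_network(net, strategy, n, seed)
    raise ValueError(f"unknown frame {frame!r}")


def detection_curve(truth: TruthSSDM, net: RouteNetwork | None,
                    config: CampaignConfig, master_seed: int = 0,
                    sizes: tuple[int, ...] | None = None) -> pd.DataFrame:
    """Mean +/- SD species detected per frame/strategy/size arm.

    A species counts as detected in a replicate when it has strictly more
    than ``config.min_occ`` extracted occurrences.
    """
    rows = []
    sizes = sizes if sizes is not None else config.sizes
    for frame in config.frames:
        if frame == "network" and net is None:
            continue
        for strategy in config.strategies:
            for n in sizes:
                detected = np.empty(config.n_detection_reps)
                for rep in range(config.n_detection_reps):
                    seed = derive_seed(master_seed, "detect", frame, strategy, n, rep)
                    pts = _draw_points(frame, strategy, n, seed, truth, net)
                    counts = detection_filter(extract_occurrences(pts, truth),
                                              config.min_occ)
                    detected[rep] = int(counts["kept"].sum()) if len(counts) else 0
                rows.append({"frame": frame, "strategy": strategy, "n_points": n,
                             "mean_detected": detected.mean(),
                             "sd_detected": detected.std(ddof=1)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RebuildResult:
    richness: np.ndarray | None
    pearson_r: float  # NaN when no model could be built or r is undefined
    n_species_modeled: int
    n_points_realized: int


def rebuild_ssdm(occ: pd.DataFrame, env: EnvStack, truth: TruthSSDM,
                 sdm_config: SDMConfig, seed: int, min_occ: int = 20) -> RebuildResult:
    """Rebuild a stacked SDM from simulated occurrences and score it.

    Species with more than ``min_occ`` records are refit (no spatial
    thinning, matching the rebuild protocol); the stacked richness surface is
    compared with the truth richness by Pearson correlation over sea cells.
    Returns NaN correlation when no species can be modelled.
    """
    kept = retained_records(occ, min_occ)
    n_pts = occ[["lon", "lat"]].drop_duplicates().shape[0]
    if len(kept) == 0:
        return RebuildResult(None, float("nan"), 0, n_pts)
    results = StackedSDM(kept, env, sdm_config, min_records=min_occ + 1).fit(seed)
    if results.n_species_modeled == 0:
        return RebuildResult(None, float("nan"), 0, n_pts)
    rich = results.richness()
    try:
        r = richness_correlation(rich, truth.richness, truth.grid)
    except UndefinedCorrelationError:
        r = float("nan")
    return RebuildResult(rich, r, results.n_species_modeled, n_pts)


def run_campaign(env: EnvStack, truth: TruthSSDM, net: RouteNetwork,
                 config: CampaignConfig, master_seed: int = 0) -> pd.DataFrame:
    """Main frame x strategy x size rebuild campaign.

    One row per replicate: species detected, species modelled, Pearson r of
    the rebuilt richness surface (NaN where no model could be built), and
    the frame's climatic bias index.
    """
    evi = env_variability_index(env)
    cbi_by_frame = {"polygon": 0.0,
                    "network": climatic_bias_index(evi, network_cells(net, truth.grid)).cbi}
    rows = []
    for frame in config.frames:
        for strategy in config.strategies:
            for n in config.sizes:
                for rep in range(config.n_ssdm_reps):
                    seed = derive_seed(master_seed, "rebuild", frame, strategy, n, rep)
                    pts = _draw_points(frame, strategy, n, seed, truth, net)
                    occ = extract_occurrences(pts, truth)
                    counts = detection_filter(occ, config.min_occ)
                    res = rebuild_ssdm(occ, env, truth, config.sdm, seed,
                                       config.min_occ)
                    rows.append({
                        "frame": frame, "strategy": strategy, "n_points": n,
                        "replicate": rep,
                        "n_species_detected": int(counts["kept"].sum()) if len(counts) else 0,
                        "n_species_modeled": res.n_species_modeled,
                        "pearson_r": res.pearson_r,
                        "cbi": cbi_by_frame[frame],
                    })
    return pd.DataFrame(rows)


def network_cells(net: RouteNetwork, grid) -> np.ndarray:
    """Boolean grid mask of sea cells traversed by any route of the network."""
    mask = np.zeros_like(grid.sea_mask)
    for _, verts in net.routes:
        cells = traversed_cells(grid, verts)
        if len(cells):
            mask[cells[:, 0], cells[:, 1]] = True
    return mask & grid.sea_mask


def subnetwork_campaign(env: EnvStack, truth: TruthSSDM,
                        subnetworks: dict[str, RouteNetwork],
                        config: CampaignConfig, master_seed: int = 0) -> pd.DataFrame:
    """Rebuild campaign over route subnetworks at fixed regular sampling.

    For each subnetwork: ``config.subnet_reps`` rebuilds at
    ``config.subnet_points`` regular points along the subnetwork, plus the
    subnetwork's climatic bias index (computed once).
    """
    evi = env_variability_index(env)
    rows = []
    for name, sub in subnetworks.items():
        cbi = climatic_bias_index(evi, network_cells(sub, truth.grid)).cbi
        for rep in range(config.subnet_reps):
            seed = derive_seed(master_seed, "subnet", name, rep)
            pts = sample_network(sub, config.subnet_strategy,
                                 config.subnet_points, seed)
            occ = extract_occurrences(pts, truth)
            res = rebuild_ssdm(occ, env, truth, config.sdm, seed, config.min_occ)
            rows.append({"subnetwork": name, "n_routes": sub.n_routes,
                         "replicate": rep, "pearson_r": res.pearson_r,
                         "n_species_modeled": res.n_species_modeled, "cbi": cbi})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TaxonExperiment:
    """Removal experiment: drop one class, or a size-matched random subset.

    ``paired_seed`` drives the random subset draw so class-vs-random pairs
    share everything except the removed species set.
    """

    removal: str                 # 'class' | 'random_subset'
    target_class: str
    paired_seed: int = 0


def taxon_experiment(truth: TruthSSDM, binaries: np.ndarray | None,
                     experiment: TaxonExperiment) -> float:
    """Pearson r between a stack with species removed and the full richness.

    ``binaries`` is a boolean (n_species, rows, cols) occupancy array in the
    truth's species order (defaults to the truth occupancy itself, i.e. the
    perfect-knowledge rasters).  removal='class' drops every species of
    ``target_class``; 'random_subset' drops a uniformly drawn species set of
    the same size.
    """
    occ = truth.occupancy if binaries is None else np.asarray(binaries, dtype=bool)
    if occ.shape != truth.occupancy.shape:
        raise ValueError("binaries shape must match the truth community")
    labels = np.array(truth.labels)
    in_class = labels == experiment.target_class
    if experiment.removal == "class":
        remove = in_class
    elif experiment.removal == "random_subset":
        rng = np.random.default_rng(experiment.paired_seed)
        idx = rng.choice(truth.n_species, size=int(in_class.sum()), replace=False)
        remove = np.zeros(truth.n_species, dtype=bool)
        remove[idx] = True
    else:
        raise ValueError(f"unknown removal mode {experiment.removal!r}")
    kept = occ[~remove]
    rich = kept.sum(axis=0).astype(int)
    return richness_correlation(rich, truth.richness, truth.grid)


def class_stack_correlations(truth: TruthSSDM,
                             binaries: np.ndarray | None = None) -> pd.DataFrame:
    """Pearson r of each single-class stack against the full richness."""
    occ = truth.occupancy if binaries is None else np.asarray(binaries, dtype=bool)
    labels = np.array(truth.labels)
    rows = []
    for lab in dict.fromkeys(truth.labels):
        rich = occ[labels == lab].sum(axis=0).astype(int)
        try:
            r = richness_correlation(rich, truth.richness, truth.grid)
        except UndefinedCorrelationError:
            r = float("nan")
        rows.append({"class": lab, "n_species": int((labels == lab).sum()),
                     "pearson_r": r})
    return pd.DataFrame(rows)
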