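"""Orchestration of a full benchmarking study from one configuration.

A study enumerates every combination of baseline incidence and relative
risk (a "risk combination"), simulates m datasets for each of the n
SU-centered true clusters, scans each dataset, classifies the outcome
against the simulated truth, and aggregates per-cluster indicators — then
optionally renders performance maps.

Reproducibility contract: every dataset and every Monte Carlo inference
stream is keyed by (master seed, stream tag, combo index, cluster index,
replicate index), so outputs are identical for identical config + seed at
any worker count, and a resumed run reproduces an uninterrupted one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import __version__
from .region import StudyRegion, generate_synthetic_region, load_region, write_region
from .simulate import (
    STREAM_H1,
    STREAM_MC,
    SimulationDesign,
    build_cluster_collection,
    simulate_dataset,
    substream,
)
from .scan import ScanSpace, monte_carlo_test
from .metrics import (
    asymptotic_ratio,
    classify,
    diagnostic_curves,
    summarize,
)
from .mapping import build_map_layer, render_map

__all__ = ["StudyConfig", "enumerate_design", "design_size", "run_study"]

log = logging.getLogger("cdtbench")


@dataclass
class StudyConfig:
    """Full configuration of one benchmarking study."""

    region_csv: str | None = None        # path to a region table ...
    region_geojson: str | None = None
    synthetic_n_units: int | None = None  # ... or a synthetic region size
    synthetic_quartiles: tuple = (17.0, 35.0, 70.0)
    synthetic_layout: str = "jittered-grid"
    incidences: tuple = (0.0226, 0.0048)
    relative_risks: tuple = (3.0, 6.0)
    cluster_size: int = 4
    replicates: int = 1000
    max_pop_fraction: float = 0.5
    mc_replicates: int = 999
    alpha: float = 0.05
    baseline: str = "incidence"
    seed: int = 0
    output_dir: str = "study_output"
    archive_datasets: bool = False
    archive_results: bool = False
    render_maps: bool = True
    workers: int = 1

    def __post_init__(self):
        if (self.region_csv is None) == (self.synthetic_n_units is None):
            raise ValueError("give exactly one of region_csv or synthetic_n_units")
        if not self.incidences or not self.relative_risks:
            raise ValueError("need at least one incidence and one relative risk")

    # -- (de)serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic_quartiles"] = list(self.synthetic_quartiles)
        d["incidences"] = list(self.incidences)
        d["relative_risks"] = list(self.relative_risks)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        for key in ("synthetic_quartiles", "incidences", "relative_risks"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- derived --------------------------------------------------------------

    @property
    def combos(self) -> list[tuple[float, float]]:
        """Risk combinations in deterministic (incidence-major) order."""
        return [(i, r) for i in self.incidences for r in self.relative_risks]

    def load_or_generate_region(self) -> StudyRegion:
        if self.region_csv is not None:
            return load_region(self.region_csv, geometry=self.region_geojson)
        return generate_synthetic_region(
            n_units=self.synthetic_n_units,
            population_quartiles=self.synthetic_quartiles,
            layout=self.synthetic_layout,
            seed=self.seed,
            with_polygons=self.render_maps,
        )


def enumerate_design(config: StudyConfig, n_units: int):
    """Yield every (incidence, relative_risk, cluster_index, replicate) task.

    Deterministic order: risk combination, then cluster, then replicate.
    """
    for inc, rr in config.combos:
        for c in range(n_units):
            for j in range(config.replicates):
                yield (inc, rr, c, j)


def design_size(config: StudyConfig, n_units: int) -> int:
    """Total dataset count: n x #incidences x #RRs x m."""
    return n_units * len(config.combos) * config.replicates


def _combo_tag(incidence: float, rr: float) -> str:
    return f"I{incidence:g}_RR{rr:g}"


def _run_cluster(
    region, space, cluster, combo_idx, incidence, rr, cluster_idx, config,
    dataset_dir=None,
):
    """Simulate, scan and classify all replicates of one true cluster."""
    design = SimulationDesign(
        incidence=incidence,
        relative_risk=rr,
        replicates=config.replicates,
        seed=config.seed,
        cluster_size=config.cluster_size,
    )
    counts, flags, rows = [], [], []
    for j in range(config.replicates):
        rng_data = substream(config.seed, STREAM_H1, combo_idx, cluster_idx, j)
        dataset = simulate_dataset(region, cluster, design, rng_data)
        if dataset_dir is not None:
            dataset.to_csv(
                Path(dataset_dir) / f"c{cluster_idx:04d}_r{j:05d}.csv"
            )
        rng_mc = substream(config.seed, STREAM_MC, combo_idx, cluster_idx, j)
        result = monte_carlo_test(
            dataset,
            space,
            n_replicates=config.mc_replicates,
            alpha=config.alpha,
            rng=rng_mc,
            baseline=config.baseline,
        )
        cc = classify(cluster, result, region.n)
        counts.append(cc)
        flags.append(result.rejected)
        rows.append(
            {
                "combo": _combo_tag(incidence, rr),
                "center_id": cluster.center_id,
                "replicate": j,
                "detected_ids": ";".join(str(i) for i in sorted(result.mlc_member_ids)),
                "statistic": result.statistic,
                "p_value": result.p_value,
                "rejected": result.rejected,
                "TP": cc.TP,
                "FP": cc.FP,
                "TN": cc.TN,
                "FN": cc.FN,
            }
        )
    summary = summarize(cluster, counts, flags)
    curves = diagnostic_curves(counts, flags, cluster.size)
    ratio = asymptotic_ratio(curves)
    summary_row = {
        "combo": _combo_tag(incidence, rr),
        "incidence": incidence,
        "relative_risk": rr,
        "center_id": cluster.center_id,
        "m": summary.m,
        "q": summary.detections,
        "tc_a": summary.tc_a,
        "tc_c": summary.tc_c,
        "usual_power": summary.usual_power,
        "asymptotic_ratio": np.nan if ratio is None else ratio,
    }
    return summary, summary_row, rows


def run_study(config: StudyConfig) -> dict:
    """Execute the full study; returns paths of the written outputs.

    Writes one metrics CSV per risk combination (one row per SU-centered
    cluster), optional per-replicate result archives, optional map layers,
    and a run manifest. Combos whose metrics CSV already exists with the
    full row count are skipped, so an interrupted run can be resumed and
    still yields byte-identical outputs.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    region = config.load_or_generate_region()
    write_region(region, out / "region.csv")
    space = ScanSpace(region, config.max_pop_fraction)
    clusters = build_cluster_collection(region, config.cluster_size)

    outputs = {"metrics": [], "maps": [], "results": []}
    for combo_idx, (inc, rr) in enumerate(config.combos):
        tag = _combo_tag(inc, rr)
        metrics_path = out / f"metrics_{tag}.csv"
        if metrics_path.exists():
            existing = pd.read_csv(metrics_path)
            if len(existing) == region.n:
                log.info("combo %s already complete, skipping", tag)
                outputs["metrics"].append(metrics_path)
                continue
        dataset_dir = None
        if config.archive_datasets:
            dataset_dir = out / "datasets" / tag
            dataset_dir.mkdir(parents=True, exist_ok=True)
        results = Parallel(n_jobs=config.workers)(
            delayed(_run_cluster)(
                region, space, clusters[c], combo_idx, inc, rr, c, config,
                dataset_dir,
            )
            for c in range(region.n)
        )
        summaries = [r[0] for r in results]
        metrics = pd.DataFrame([r[1] for r in results])
        metrics.to_csv(metrics_path, index=False)
        outputs["metrics"].append(metrics_path)
        if config.archive_results:
            rows = [row for r in results for row in r[2]]
            rpath = out / f"results_{tag}.csv"
            pd.DataFrame(rows).to_csv(rpath, index=False)
            outputs["results"].append(rpath)
        if config.render_maps and region.polygons is not None:
            for indicator in ("tc_a", "tc_c", "power"):
                layer = build_map_layer(
                    region, summaries, indicator, incidence=inc, relative_risk=rr
                )
                img = out / f"map_{indicator}_{tag}.png"
                gj = out / f"map_{indicator}_{tag}.geojson"
                render_map(layer, region, img, gj)
                outputs["maps"].extend([img, gj])

    manifest = {
        "config": config.to_dict(),
        "version": __version__,
        "design_size": design_size(config, region.n),
        "n_units": region.n,
        "region_sha256": hashlib.sha256(
            region.to_frame().to_csv(index=False).encode()
        ).hexdigest(),
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    outputs["manifest"] = out / "run_manifest.json"
    return outputs
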