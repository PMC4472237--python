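"""Cluster collections and Poisson case-count simulation.

The truth model: for each spatial unit c of the region, one "true" cluster
is built from c and its D-1 nearest neighbours by Euclidean centroid
distance (D = 4 by default), so a region of n SUs yields a collection of n
clusters. Case counts are then simulated independently per SU as

    H0:  N_i ~ Poisson(eps_i),          eps_i = I * population_i
    H1:  N_i ~ Poisson(eps_i * [1 + 1{i in cluster} * (theta - 1)])

where I is the region-wide baseline incidence (a proportion of the at-risk
population) and theta >= 1 the relative risk applied inside the cluster.
In-cluster SUs therefore have Poisson mean theta * eps_i.

Reproducibility uses numpy ``SeedSequence`` spawn keys: every dataset gets
an independent substream keyed by (master seed; stream tag; combo, cluster,
replicate indices), so replicates are statistically independent and a
replicate's draw never depends on scheduling or on other replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .region import StudyRegion

__all__ = [
    "ClusterSpec",
    "SimulationDesign",
    "CaseDataset",
    "substream",
    "build_cluster_collection",
    "expected_counts",
    "simulate_dataset",
    "simulate_null_dataset",
]

# Stream tags keeping the three RNG uses disjoint for one master seed.
STREAM_H1 = 0      # alternative-hypothesis datasets
STREAM_H0 = 1      # null-calibration datasets
STREAM_MC = 2      # Monte Carlo inference inside the scan


def substream(master_seed, *key) -> np.random.Generator:
    """Independent generator for (master seed, integer key path)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(int(k) for k in key))
    return np.random.default_rng(ss)


@dataclass(frozen=True)
class ClusterSpec:
    """One simulated true cluster: a center SU plus its nearest neighbours."""

    center_id: object
    member_ids: frozenset

    def __post_init__(self):
        if self.center_id not in self.member_ids:
            raise ValueError("cluster center must be a member")

    @property
    def size(self) -> int:
        """Number of SUs in the cluster (the quantity D)."""
        return len(self.member_ids)


@dataclass(frozen=True)
class SimulationDesign:
    """Settings for one simulation arm.

    incidence
        Baseline annual incidence I, as a proportion of the at-risk
        population (e.g. 0.0226 for 2.26% of births).
    relative_risk
        Multiplicative excess risk theta >= 1 inside the true cluster.
    replicates
        Number m of datasets per cluster.
    seed
        Master RNG seed; all substreams derive from it.
    cluster_size
        Cluster size D in SUs.
    """

    incidence: float
    relative_risk: float = 1.0
    replicates: int = 1000
    seed: int = 0
    cluster_size: int = 4

    def __post_init__(self):
        if not 0 < self.incidence < 1:
            raise ValueError("incidence must be in (0, 1)")
        if self.relative_risk < 1:
            raise ValueError("relative_risk must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be >= 1")


@dataclass
class CaseDataset:
    """One simulated realization: observed/expected cases per SU.

    Mirrors the canonical 5-column table (x, y, observed cases, at-risk
    population, expected cases) plus provenance keys.
    """

    region: StudyRegion
    observed: np.ndarray       # integer case counts per SU
    expected: np.ndarray       # eps_i = incidence * population_i, exact
    incidence: float
    cluster_center: object = None
    replicate: int | None = None
    seed: int | None = None

    @property
    def total_cases(self) -> int:
        return int(self.observed.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.region.x,
                "y": self.region.y,
                "observed_cases": self.observed,
                "population": self.region.population,
                "expected_cases": self.expected,
            }
        )

    def to_csv(self, path) -> None:
        # shortest-round-trip floats: archived datasets re-read exactly
        self.to_frame().to_csv(path, index=False, float_format=lambda v: repr(float(v)))

    @classmethod
    def from_csv(cls, path, region: StudyRegion, incidence: float) -> "CaseDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        obs = df["observed_cases"].to_numpy(dtype=np.int64)
        exp = df["expected_cases"].to_numpy(dtype=float)
        if len(obs) != region.n:
            raise ValueError("dataset row count does not match region")
        return cls(region=region, observed=obs, expected=exp, incidence=incidence)


def build_cluster_collection(region: StudyRegion, cluster_size: int = 4) -> list[ClusterSpec]:
    """One cluster per SU: the center plus its D-1 nearest neighbours.

    Distance is Euclidean between centroids; ties are broken in favour of
    the SU appearing earlier in the region's order (i.e. the smaller id for
    id-sorted inputs), and the center always belongs to its own cluster.
    """
    d = cluster_size
    if d > region.n:
        raise ValueError(f"cluster_size {d} exceeds region size {region.n}")
    clusters = []
    for k in range(region.n):
        dist = region.distances_from(k)
        others = [i for i in range(region.n) if i != k]
        others.sort(key=lambda i: (dist[i], i))
        members = frozenset(region.ids[i] for i in [k] + others[: d - 1])
        clusters.append(ClusterSpec(center_id=region.ids[k], member_ids=members))
    return clusters


def expected_counts(region: StudyRegion, incidence: float) -> np.ndarray:
    """Per-SU expected case counts eps_i = I * population_i (exact)."""
    if not 0 < incidence < 1:
        raise ValueError("incidence must be in (0, 1)")
    return incidence * region.population


def simulate_dataset(
    region: StudyRegion,
    cluster: ClusterSpec | None,
    design: SimulationDesign,
    rng: np.random.Generator,
) -> CaseDataset:
    """Draw one dataset under H1 (or H0 when ``cluster`` is None).

    In-cluster SUs have Poisson mean eps_i * [1 + (theta - 1)] = theta*eps_i;
    all other SUs keep mean eps_i.
    """
    eps = expected_counts(region, design.incidence)
    means = eps.copy()
    if cluster is not None:
        member_idx = [region.index_of[i] for i in cluster.member_ids]
        if len(member_idx) != len(cluster.member_ids):
            raise ValueError("cluster members not all in region")
        means[member_idx] *= design.relative_risk
    observed = rng.poisson(means).astype(np.int64)
    return CaseDataset(
        region=region,
        observed=observed,
        expected=eps,
        incidence=design.incidence,
        cluster_center=None if cluster is None else cluster.center_id,
        seed=design.seed,
    )


def simulate_null_dataset(
    region: StudyRegion, design: SimulationDesign, rng: np.random.Generator
) -> CaseDataset:
    """Draw one dataset under the null hypothesis of risk homogeneity."""
    return simulate_dataset(region, None, design, rng)
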