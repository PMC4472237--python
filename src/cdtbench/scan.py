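"""Kulldorff's circular spatial scan statistic with Monte Carlo inference.

Candidate zones are circles: a center successively placed on each SU
centroid and a radius growing from 0, so that for one center the zones form
a nested chain of SU sets ordered by centroid distance. A zone is kept
while its at-risk population stays within ``max_pop_fraction`` of the
regional total (50% in the standard configuration).

For a zone z with n_z observed cases and population N_z, the likelihood
ratio under the Poisson model is proportional to

    (n_z / (lam*N_z))^n_z * ((n-n_z) / (lam*(N-N_z)))^(n-n_z)   if n_z > lam*N_z

and the zone is not a candidate otherwise; lam is the baseline annual
incidence, so lam*N_z is the expected count in z under risk homogeneity.
The statistic is computed and maximized in log space; the zone maximizing
it is the most likely cluster (MLC). Setting ``baseline="conditional"``
replaces lam by n/N, giving Kulldorff's fully conditional benchmark.

Significance is assessed by Monte Carlo: the observed total case count n is
redistributed over SUs with probabilities eps_i / sum(eps) (multinomial,
conditioning on n), the max statistic recomputed for each of R null
replicates, and p = (1 + #{null >= observed}) / (R + 1). Ties count toward
the numerator, so p-values are valid; detection is declared when p <= alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .region import StudyRegion
from .simulate import CaseDataset

__all__ = [
    "Zone",
    "ScanResult",
    "ScanSpace",
    "enumerate_zones",
    "log_likelihood_ratio",
    "most_likely_cluster",
    "monte_carlo_test",
]

@njit(cache=True)
def _scan_kernel(cases, order, candidate, log_in, log_out, lam_pop, tbl,
                 stats, centers, lengths):
    """Max log likelihood ratio per case vector, with argmax zone.

    For each batch row, walks every center's distance-ordered prefix chain,
    accumulating zone case counts, and evaluates the statistic at each
    admissible (deduplicated) zone whose cases exceed the expected count.
    ``tbl[k] = k*log(k)`` so the inner loop is lookup + arithmetic only.
    Ties prefer fewer SUs, then the earlier center.
    """
    B, n = cases.shape
    for b in range(B):
        ntot = 0
        for i in range(n):
            ntot += cases[b, i]
        best = -np.inf
        bc = -1
        bk = -1
        for c in range(n):
            nz = 0
            for k in range(n):
                nz += cases[b, order[c, k]]
                if not candidate[c, k]:
                    continue
                if nz <= lam_pop[c, k]:
                    continue
                rest = ntot - nz
                llr = (tbl[nz] - nz * log_in[c, k]
                       + tbl[rest] - rest * log_out[c, k])
                if llr > best or (
                    llr == best and (k < bk or (k == bk and c < bc))
                ):
                    best = llr
                    bc = c
                    bk = k
        stats[b] = best
        centers[b] = bc
        lengths[b] = bk


@dataclass(frozen=True)
class Zone:
    """A candidate circular zone: center SU plus all SUs inside the circle."""

    center_id: object
    member_ids: frozenset
    population: float          # N_z, at-risk population in the zone
    cases: int | None = None   # n_z, filled when evaluated against a dataset

    @property
    def size(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True)
class ScanResult:
    """Outcome of one scan: MLC member set, statistic, Monte Carlo p-value."""

    mlc_member_ids: frozenset
    statistic: float           # log-scale likelihood ratio, 0 if no candidate
    p_value: float
    alpha: float
    n_replicates: int

    @property
    def rejected(self) -> bool:
        return self.p_value <= self.alpha


class ScanSpace:
    """Precomputed zone geometry for one region and population constraint.

    Row c of ``order`` lists SU indices sorted by distance from center c
    (center first, distance ties broken by position); ``valid[c, k]`` marks
    the prefix of length k+1 as an admissible zone: population positive, at
    most ``max_pop_fraction`` of the total, and strictly below the total
    (the whole region is never a candidate cluster). ``first_occurrence``
    additionally deduplicates identical SU sets reachable from different
    centers, so zone counts are counts of distinct sets.
    """

    def __init__(self, region: StudyRegion, max_pop_fraction: float = 0.5):
        if not 0 < max_pop_fraction <= 1:
            raise ValueError("max_pop_fraction must be in (0, 1]")
        self.region = region
        self.max_pop_fraction = float(max_pop_fraction)
        n = region.n
        order = np.empty((n, n), dtype=np.intp)
        for c in range(n):
            dist = region.distances_from(c)
            dist = dist.copy()
            dist[c] = -1.0  # the center is always the first member
            order[c] = np.lexsort((np.arange(n), dist))
        self.order = order
        self.cum_pop = np.cumsum(region.population[order], axis=1)
        N = region.total_population
        cap = self.max_pop_fraction * N
        self.valid = (self.cum_pop > 0) & (self.cum_pop <= cap) & (self.cum_pop < N)
        # Deduplicate identical prefix sets across centers.
        first = np.zeros((n, n), dtype=bool)
        seen: set = set()
        for c in range(n):
            for k in range(n):
                if not self.valid[c, k]:
                    continue
                key = frozenset(order[c, : k + 1].tolist())
                if key not in seen:
                    seen.add(key)
                    first[c, k] = True
        self.first_occurrence = first
        self._denom_cache: dict = {}

    @property
    def n(self) -> int:
        return self.region.n

    def zone_members(self, c: int, k: int) -> frozenset:
        """SU ids of the zone given by center c and prefix length k+1."""
        return frozenset(self.region.ids[i] for i in self.order[c, : k + 1])

    def zones(self) -> list[Zone]:
        """All distinct admissible zones, in (center, radius) order."""
        out = []
        n = self.n
        for c in range(n):
            for k in range(n):
                if self.first_occurrence[c, k]:
                    out.append(
                        Zone(
                            center_id=self.region.ids[c],
                            member_ids=self.zone_members(c, k),
                            population=float(self.cum_pop[c, k]),
                        )
                    )
        return out

    # -- statistic evaluation -------------------------------------------------

    def _denominators(self, lam: float):
        """Per-zone log(lam*N_z), log(lam*(N-N_z)) and lam*N_z, cached."""
        cached = self._denom_cache.get(lam)
        if cached is not None:
            return cached
        with np.errstate(divide="ignore", invalid="ignore"):
            log_in = np.where(self.valid, np.log(lam * self.cum_pop), 0.0)
            rest = self.region.total_population - self.cum_pop
            log_out = np.where(self.valid, np.log(lam * rest), 0.0)
        out = (log_in, log_out, lam * self.cum_pop)
        self._denom_cache[lam] = out
        return out

    def batch_statistics(self, cases: np.ndarray, lam: float):
        """Max log statistic (and argmax zone) for a batch of case vectors.

        ``cases`` has shape (B, n) with integer counts. Returns
        ``(stats, centers, lengths)`` where ``stats[b]`` is the max log
        likelihood ratio over candidate zones (``-inf`` when no zone passes
        the excess-cases indicator — the "not a candidate" sentinel, which
        ranks below every candidate) and ``centers[b], lengths[b]`` locate
        the maximizing zone (-1 when none). Ties prefer fewer SUs, then the
        earlier center.
        """
        cases = np.asarray(cases, dtype=np.int64)
        if cases.ndim == 1:
            cases = cases[None, :]
        B, n = cases.shape
        max_n = int(cases.sum(axis=1).max(initial=0))
        # k*log(k) lookup with the 0*log0 := 0 convention; counts are small
        # integers so a table beats elementwise logs by a wide margin.
        ks = np.arange(max_n + 1, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            tbl = ks * np.log(ks)
        tbl[0] = 0.0
        log_in, log_out, lam_pop = self._denominators(lam)
        stats = np.empty(B, dtype=float)
        centers = np.empty(B, dtype=np.int64)
        lengths = np.empty(B, dtype=np.int64)
        _scan_kernel(
            cases, self.order, self.first_occurrence,
            log_in, log_out, lam_pop, tbl,
            stats, centers, lengths,
        )
        return stats, centers, lengths


def enumerate_zones(region: StudyRegion, max_pop_fraction: float = 0.5) -> list[Zone]:
    """All distinct candidate zones for a region (see :class:`ScanSpace`)."""
    return ScanSpace(region, max_pop_fraction).zones()


def log_likelihood_ratio(n_z: int, N_z: float, n: int, N: float, lam: float) -> float:
    """Log likelihood ratio of one zone, 0.0 when the indicator fails.

    Implements n_z*log(n_z/(lam*N_z)) + (n-n_z)*log((n-n_z)/(lam*(N-N_z)))
    for n_z > lam*N_z, with 0*log(0) := 0; returns 0.0 ("not a candidate")
    otherwise.
    """
    if N_z <= 0 or N_z >= N:
        raise ValueError("zone population must satisfy 0 < N_z < N")
    if not 0 <= n_z <= n:
        raise ValueError("zone cases must satisfy 0 <= n_z <= n")
    if lam <= 0:
        raise ValueError("baseline incidence must be positive")
    if n_z <= lam * N_z:
        return 0.0
    term_in = n_z * math.log(n_z / (lam * N_z)) if n_z > 0 else 0.0
    rest = n - n_z
    term_out = rest * math.log(rest / (lam * (N - N_z))) if rest > 0 else 0.0
    return term_in + term_out


def _resolve_lam(dataset: CaseDataset, baseline: str) -> float:
    if baseline == "incidence":
        return dataset.incidence
    if baseline == "conditional":
        return dataset.total_cases / dataset.region.total_population
    raise ValueError(f"unknown baseline: {baseline!r}")


def most_likely_cluster(
    dataset: CaseDataset,
    space: ScanSpace,
    baseline: str = "incidence",
):
    """The zone maximizing the scan statistic for one dataset.

    Returns ``(zone, statistic)``; ``zone`` is ``None`` with statistic 0.0
    when no zone shows excess cases. Ties prefer the zone with fewer SUs,
    then the earlier center.
    """
    lam = _resolve_lam(dataset, baseline)
    if lam <= 0:
        return None, 0.0
    stats, centers, lengths = space.batch_statistics(dataset.observed, lam)
    if centers[0] < 0:
        return None, 0.0
    c, k = int(centers[0]), int(lengths[0])
    zone = Zone(
        center_id=space.region.ids[c],
        member_ids=space.zone_members(c, k),
        population=float(space.cum_pop[c, k]),
        cases=int(dataset.observed[space.order[c, : k + 1]].sum()),
    )
    return zone, float(stats[0])


def monte_carlo_test(
    dataset: CaseDataset,
    space: ScanSpace,
    n_replicates: int = 999,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
    baseline: str = "incidence",
) -> ScanResult:
    """Scan one dataset and attach a Monte Carlo p-value.

    Null replicates redistribute the observed total case count over SUs
    with probabilities proportional to the expected counts (multinomial,
    conditional on the total); p = (1 + #{null stat >= observed}) / (R + 1).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    zone, stat = most_likely_cluster(dataset, space, baseline=baseline)
    obs_internal = -np.inf if zone is None else stat
    ntot = dataset.total_cases
    if ntot > 0:
        probs = dataset.expected / dataset.expected.sum()
        null_cases = rng.multinomial(ntot, probs, size=n_replicates)
        if baseline == "conditional":
            lam = ntot / dataset.region.total_population
        else:
            lam = dataset.incidence
        null_stats, _, _ = space.batch_statistics(null_cases, lam)
    else:
        # no cases at all: every null replicate is the same empty dataset
        null_stats = np.full(n_replicates, -np.inf)
    # -inf >= -inf holds, so a no-candidate observation ties with every
    # null replicate and yields p = 1.
    exceed = int((null_stats >= obs_internal).sum())
    p = (1 + exceed) / (n_replicates + 1)
    return ScanResult(
        mlc_member_ids=frozenset() if zone is None else zone.member_ids,
        statistic=0.0 if zone is None else stat,
        p_value=p,
        alpha=alpha,
        n_replicates=n_replicates,
    )
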