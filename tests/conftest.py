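import numpy as np
import pandas as pd
import pytest

from cdtbench import (
    ScanSpace,
    build_cluster_collection,
    generate_synthetic_region,
    load_region,
)


@pytest.fixture(scope="session")
def line_region():
    """Five SUs on a line at x = 0, 1, 3, 6, 10 with equal populations."""
    df = pd.DataFrame(
        {
            "id": [0, 1, 2, 3, 4],
            "x": [0.0, 1.0, 3.0, 6.0, 10.0],
            "y": [0.0] * 5,
            "population": [10.0] * 5,
        }
    )
    return load_region(df)


@pytest.fixture(scope="session")
def small_region():
    """A 25-SU synthetic region for oracle-equivalence checks."""
    return generate_synthetic_region(25, seed=11)


@pytest.fixture(scope="session")
def small_space(small_region):
    return ScanSpace(small_region, max_pop_fraction=0.5)


@pytest.fixture(scope="session")
def medium_region():
    """A 50-SU synthetic region for calibration experiments."""
    return generate_synthetic_region(50, seed=7)


def brute_force_mlc(dataset, region, max_pop_fraction, lam):
    """Independent maximizer: enumerate every center/radius pair naively.

    Recomputes the likelihood ratio with plain ``math`` calls for every
    distinct admissible zone and returns (member frozenset or None, max log
    statistic or -inf). Tie-break mirrors the scan convention: fewer SUs,
    then earlier center.
    """
    import math

    N = region.total_population
    n = int(dataset.observed.sum())
    cap = max_pop_fraction * N
    best = (-math.inf, None)
    seen = set()
    for c in range(region.n):
        dist = np.hypot(region.x - region.x[c], region.y - region.y[c])
        order = sorted(range(region.n), key=lambda i: (dist[i] if i != c else -1.0, i))
        members, pop, cases = [], 0.0, 0
        for i in order:
            members.append(i)
            pop += region.population[i]
            cases += int(dataset.observed[i])
            if pop <= 0 or pop > cap or pop >= N:
                continue
            key = frozenset(members)
            if key in seen:
                continue
            seen.add(key)
            if cases <= lam * pop:
                continue
            llr = cases * math.log(cases / (lam * pop))
            rest = n - cases
            if rest > 0:
                llr += rest * math.log(rest / (lam * (N - pop)))
            if best[1] is None:
                best = ((llr, len(members), c), key)
            else:
                b_llr, b_len, b_c = best[0]
                if llr > b_llr or (llr == b_llr and (len(members), c) < (b_len, b_c)):
                    best = ((llr, len(members), c), key)
    if best[1] is None:
        return None, -math.inf
    return frozenset(region.ids[i] for i in best[1]), best[0][0]
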