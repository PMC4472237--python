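import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cdtbench import (
    ClusterSpec,
    ConfusionCounts,
    ScanResult,
    asymptotic_ratio,
    classify,
    diagnostic_curves,
    summarize,
    tanimoto,
    tc_averaged,
    tc_cumulated,
    usual_power,
)

D = 4
N_SU = 221


def cc(tp, fp, fn, n=N_SU):
    return ConfusionCounts(TP=tp, FP=fp, TN=n - tp - fp - fn, FN=fn)


def scan_result(member_ids, p):
    return ScanResult(
        mlc_member_ids=frozenset(member_ids),
        statistic=1.0 if p <= 0.05 else 0.0,
        p_value=p,
        alpha=0.05,
        n_replicates=999,
    )


TRUE = ClusterSpec(center_id=1, member_ids=frozenset({1, 2, 3, 4}))


# -- classification -----------------------------------------------------------

def test_non_detection_convention():
    """p > alpha: all SUs negative -> TP=0, FP=0, TN=217, FN=4."""
    counts = classify(TRUE, scan_result({9, 10}, p=0.051), n=N_SU)
    assert counts == ConfusionCounts(TP=0, FP=0, TN=217, FN=4)


def test_perfect_detection():
    counts = classify(TRUE, scan_result({1, 2, 3, 4}, p=0.001), n=N_SU)
    assert counts == ConfusionCounts(TP=4, FP=0, TN=217, FN=0)


def test_disjoint_detection():
    counts = classify(TRUE, scan_result({50, 51, 52}, p=0.01), n=N_SU)
    assert counts == ConfusionCounts(TP=0, FP=3, TN=214, FN=4)


@given(
    detected=st.sets(st.integers(1, 30), max_size=10),
    p=st.floats(0.001, 1.0),
)
@settings(deadline=None, max_examples=200)
def test_classification_conserves_su_count(detected, p):
    counts = classify(TRUE, scan_result(detected, p), n=N_SU)
    assert counts.TP + counts.FP + counts.TN + counts.FN == N_SU
    assert counts.TP + counts.FN == D
    assert min(counts) >= 0


# -- Tanimoto coefficient and its two aggregates ------------------------------

@pytest.mark.parametrize(
    "counts,expected",
    [
        (cc(4, 0, 0), 1.0),
        (cc(0, 0, 4), 0.0),
        (cc(2, 3, 2), 2 / 7),
    ],
)
def test_tanimoto_closed_form(counts, expected):
    assert tanimoto(counts) == pytest.approx(expected, abs=1e-12)


def test_tanimoto_undefined_without_cluster_or_detection():
    with pytest.raises(ValueError):
        tanimoto(ConfusionCounts(TP=0, FP=0, TN=N_SU, FN=0))


def test_tc_averaged_examples():
    assert tc_averaged([cc(4, 0, 0), cc(0, 0, 4)]) == pytest.approx(0.5, abs=1e-12)
    assert tc_averaged([cc(2, 2, 2), cc(4, 0, 0)]) == pytest.approx(2 / 3, abs=1e-12)
    assert tc_averaged([cc(1, 2, 3)] * 7) == pytest.approx(1 / 6, abs=1e-12)


def test_tc_cumulated_examples():
    assert tc_cumulated([cc(4, 0, 0), cc(0, 0, 4)]) == pytest.approx(0.5, abs=1e-12)
    # pooling weights replicates by their denominators: 6/10, not 2/3
    assert tc_cumulated([cc(2, 2, 2), cc(4, 0, 0)]) == pytest.approx(0.6, abs=1e-12)


counts_lists = st.lists(
    st.tuples(st.integers(0, D), st.integers(0, 20)).map(
        lambda t: cc(t[0], t[1] if (t[0] or t[1]) else 1, D - t[0])
    ),
    min_size=1,
    max_size=60,
)


@given(counts_lists)
@settings(deadline=None, max_examples=200)
def test_equal_denominators_make_aggregates_agree(counts):
    """When every replicate has the same TP+FP+FN, TC_c equals TC_a."""
    k = counts[0].TP + counts[0].FP + counts[0].FN
    same = [c for c in counts if c.TP + c.FP + c.FN == k] or counts[:1]
    assert tc_cumulated(same) == pytest.approx(tc_averaged(same), abs=1e-12)


@given(counts_lists)
@settings(deadline=None, max_examples=200)
def test_aggregate_bounds(counts):
    a, c = tc_averaged(counts), tc_cumulated(counts)
    assert 0 <= a <= 1 and 0 <= c <= 1


# -- usual power --------------------------------------------------------------

def test_usual_power_counts_rejections():
    results = [scan_result({1}, 0.01), scan_result({1}, 0.5), scan_result({1}, 0.04)]
    assert usual_power(results) == pytest.approx(2 / 3)
    assert usual_power([True, True]) == 1.0
    assert usual_power([False]) == 0.0


def test_power_bounds_both_indicators():
    """Power >= TC_a and TC_c: a detection adds 1 to power, at most 1 to TC."""
    rng = np.random.default_rng(3)
    for _ in range(50):
        m = rng.integers(1, 40)
        counts, flags = [], []
        for _ in range(m):
            if rng.random() < 0.5:
                counts.append(cc(0, 0, D))
                flags.append(False)
            else:
                tp = int(rng.integers(0, D + 1))
                fp = int(rng.integers(0, 8)) if tp else int(rng.integers(1, 8))
                counts.append(cc(tp, fp, D - tp))
                flags.append(True)
        s = summarize(TRUE, counts, flags)
        assert s.tc_a <= s.usual_power + 1e-12
        assert s.tc_c <= s.usual_power + 1e-12


# -- diagnostic curves --------------------------------------------------------

def random_replicates(rng, m, detect_prob=0.6):
    counts, flags = [], []
    for _ in range(m):
        if rng.random() < detect_prob:
            tp = int(rng.integers(0, D + 1))
            fp = int(rng.integers(0, 10)) if tp else int(rng.integers(1, 10))
            counts.append(cc(tp, fp, D - tp))
            flags.append(True)
        else:
            counts.append(cc(0, 0, D))
            flags.append(False)
    return counts, flags


def test_curves_end_at_the_aggregates():
    """f(m') = TC_a and g(m') = TC_c on 1000 random count lists."""
    rng = np.random.default_rng(12)
    for _ in range(1000):
        counts, flags = random_replicates(rng, int(rng.integers(1, 30)))
        curves = diagnostic_curves(counts, flags, D)
        assert curves.f[-1] == pytest.approx(tc_averaged(counts), abs=1e-12)
        assert curves.g[-1] == pytest.approx(tc_cumulated(counts), abs=1e-12)


def test_curves_ordering_and_partition():
    rng = np.random.default_rng(5)
    counts, flags = random_replicates(rng, 50)
    curves = diagnostic_curves(counts, flags, D)
    fps = [counts[i].FP for i in curves.ordering[: curves.q]]
    assert fps == sorted(fps)
    assert all(not flags[i] for i in curves.ordering[curves.q:])
    assert set(curves.S0) | set(curves.S1) | set(curves.S2) == {
        i for i, r in enumerate(flags) if r
    }
    assert not (set(curves.S0) & set(curves.S1))
    # within a detection TP and FP are never both zero
    for i in curves.S0:
        assert counts[i].FP > 0


def test_fp_free_detections_superpose_curves():
    """With FP=0 everywhere, f(s) = g(s) up to the last detection."""
    counts = [cc(3, 0, 1), cc(4, 0, 0), cc(2, 0, 2), cc(0, 0, D)]
    flags = [True, True, True, False]
    curves = diagnostic_curves(counts, flags, D)
    np.testing.assert_allclose(curves.f[: curves.q], curves.g[: curves.q], atol=1e-12)


def test_tail_closed_forms():
    """Past the detections: f(s) = M/s and g(s) = A/(B + sD)."""
    rng = np.random.default_rng(9)
    counts, flags = random_replicates(rng, 40, detect_prob=0.4)
    curves = diagnostic_curves(counts, flags, D)
    for s in range(curves.q + 1, curves.m_prime + 1):
        assert curves.f[s - 1] == pytest.approx(curves.M / s, abs=1e-12)
        assert curves.g[s - 1] == pytest.approx(
            curves.A / (curves.B + s * D), abs=1e-12
        )


def test_asymptotic_ratio_examples_and_bound():
    # every detection exact: M = q, A = qD -> ratio 1
    exact = [cc(D, 0, 0)] * 5
    curves = diagnostic_curves(exact, [True] * 5, D)
    assert asymptotic_ratio(curves) == pytest.approx(1.0, abs=1e-12)
    # single detection TP=2, FP=2: M = 2/6, A = 2 -> (1/3)*4/2 = 2/3
    curves = diagnostic_curves([cc(2, 2, 2)], [True], D)
    assert asymptotic_ratio(curves) == pytest.approx(2 / 3, abs=1e-12)
    # no TP ever -> undefined
    curves = diagnostic_curves([cc(0, 3, D)], [True], D)
    assert asymptotic_ratio(curves) is None


def test_asymptotic_ratio_bounded_by_one():
    """M*D/A <= 1 on 1000 random lists, =1 iff all detections are exact."""
    rng = np.random.default_rng(21)
    for _ in range(1000):
        counts, flags = random_replicates(rng, int(rng.integers(1, 25)))
        curves = diagnostic_curves(counts, flags, D)
        ratio = asymptotic_ratio(curves)
        if ratio is None:
            continue
        assert ratio <= 1 + 1e-12
        exact = all(
            counts[i].FP == 0 and counts[i].TP == D
            for i in curves.ordering[: curves.q]
        )
        if exact:
            assert ratio == pytest.approx(1.0, abs=1e-12)
        # a detection mixing true and false positives strictly drags the
        # ratio below 1; FP-only detections leave both M and A untouched
        if curves.S2:
            assert ratio < 1
        else:
            assert ratio == pytest.approx(1.0, abs=1e-12)
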