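"""Performance indicators for cluster detection tests.

Each analyzed dataset is scored by superimposing the detected cluster on
the simulated (true) cluster, classifying every SU as TP, FP, FN or TN.
A non-significant scan (p above alpha) counts as "no cluster detected":
all SUs are negatives, so TP = FP = 0, FN = D, TN = n - D.

The per-dataset Tanimoto coefficient (Jaccard index of the two SU sets)

    TC = TP / (TP + FP + FN)

is aggregated over the m replicates of one true cluster in two ways:

    TC_a = mean_i TC_i                       (averaged TC)
    TC_c = sum_i TP_i / sum_i (TP+FP+FN)_i   (cumulated TC)

Both lie in [0, 1] and are bounded above by the usual power (the rejection
rate), since a detection contributes 1 to power but at most 1 to either TC
statistic. The systematic ordering between TC_a and TC_c is made visible
by the diagnostic curves f(s) and g(s): replicates are sorted detections
first (by increasing FP count), and f and g track the running value of
TC_a and TC_c along that order. Past the last detection (s > q) they decay
as f(s) = M/s and g(s) = A/(B + sD) with M = sum TP_s/(D+FP_s), A = sum
TP_s, B = sum FP_s over the detections, so f/g tends to M*D/A <= 1 —
strictly below 1 exactly when some detection mixes true and false
positives.

All aggregation is on exact integer counts; division happens last.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .simulate import ClusterSpec
from .scan import ScanResult

__all__ = [
    "ConfusionCounts",
    "PerformanceSummary",
    "DiagnosticCurves",
    "classify",
    "tanimoto",
    "tc_averaged",
    "tc_cumulated",
    "usual_power",
    "summarize",
    "diagnostic_curves",
    "asymptotic_ratio",
]


class ConfusionCounts(NamedTuple):
    """SU classification for one analyzed dataset."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def classify(true_cluster: ClusterSpec, result: ScanResult, n: int) -> ConfusionCounts:
    """Confront detected and simulated clusters over a region of n SUs.

    A non-significant result means no cluster was detected: every SU is a
    negative, giving TP = FP = 0, FN = D, TN = n - D.
    """
    d = true_cluster.size
    if not result.rejected:
        return ConfusionCounts(TP=0, FP=0, TN=n - d, FN=d)
    detected = result.mlc_member_ids
    true = true_cluster.member_ids
    tp = len(detected & true)
    fp = len(detected - true)
    fn = len(true - detected)
    return ConfusionCounts(TP=tp, FP=fp, TN=n - tp - fp - fn, FN=fn)


def tanimoto(counts: ConfusionCounts) -> float:
    """TC = TP / (TP + FP + FN), the Jaccard index of the two SU sets."""
    denom = counts.TP + counts.FP + counts.FN
    if denom == 0:
        raise ValueError(
            "TC undefined: TP + FP + FN = 0 (no simulated cluster and no detection)"
        )
    return counts.TP / denom


def tc_averaged(counts_list: Sequence[ConfusionCounts]) -> float:
    """Averaged TC: arithmetic mean of per-replicate TC values."""
    if len(counts_list) == 0:
        raise ValueError("need at least one replicate")
    return sum(tanimoto(c) for c in counts_list) / len(counts_list)


def tc_cumulated(counts_list: Sequence[ConfusionCounts]) -> float:
    """Cumulated TC: pooled ratio sum(TP) / sum(TP + FP + FN).

    This is the TC of the stacked results of all replicates, and inherits
    the original coefficient's interpretation as intersection over union.
    """
    if len(counts_list) == 0:
        raise ValueError("need at least one replicate")
    num = sum(c.TP for c in counts_list)
    den = sum(c.TP + c.FP + c.FN for c in counts_list)
    if den == 0:
        raise ValueError("pooled TC undefined: sum(TP + FP + FN) = 0")
    return num / den


def usual_power(results: Sequence[ScanResult] | Sequence[bool], alpha: float = 0.05) -> float:
    """Fraction of replicates rejecting the null, regardless of location."""
    if len(results) == 0:
        raise ValueError("need at least one result")
    flags = [
        (r.p_value <= alpha) if isinstance(r, ScanResult) else bool(r) for r in results
    ]
    return sum(flags) / len(flags)


@dataclass
class PerformanceSummary:
    """Aggregated indicators for one simulated cluster over m replicates."""

    cluster: ClusterSpec
    m: int
    counts: list[ConfusionCounts]
    rejected: list[bool]
    tc_values: list[float]
    tc_a: float
    tc_c: float
    usual_power: float

    @property
    def detections(self) -> int:
        """q, the number of replicates with null rejection."""
        return sum(self.rejected)


def summarize(
    cluster: ClusterSpec,
    counts_list: Sequence[ConfusionCounts],
    rejected_flags: Sequence[bool],
) -> PerformanceSummary:
    if len(counts_list) != len(rejected_flags):
        raise ValueError("counts and rejection flags must align")
    tcs = [tanimoto(c) for c in counts_list]
    return PerformanceSummary(
        cluster=cluster,
        m=len(counts_list),
        counts=list(counts_list),
        rejected=[bool(r) for r in rejected_flags],
        tc_values=tcs,
        tc_a=tc_averaged(counts_list),
        tc_c=tc_cumulated(counts_list),
        usual_power=sum(bool(r) for r in rejected_flags) / len(rejected_flags),
    )


@dataclass
class DiagnosticCurves:
    """Running f(s)/g(s) curves explaining the TC_a vs TC_c ordering.

    ``ordering`` is the replicate permutation (detections sorted by
    increasing FP, ties by replicate index, then non-detections); ``f`` and
    ``g`` are the running TC_a and TC_c values along it. ``S0``, ``S1``,
    ``S2`` partition the q detections into no-TP, no-FP, and mixed sets
    (positions refer to original replicate indices). M, A and B are the
    cumulative quantities sum TP/(D+FP), sum TP and sum FP over the
    detections.
    """

    ordering: list[int]
    f: np.ndarray
    g: np.ndarray
    q: int
    m_prime: int
    D: int
    M: float
    A: int
    B: int
    S0: list[int]
    S1: list[int]
    S2: list[int]


def diagnostic_curves(
    counts_list: Sequence[ConfusionCounts],
    rejected_flags: Sequence[bool],
    D: int,
) -> DiagnosticCurves:
    """Compute f(s), g(s) and the quantities governing their asymptotics."""
    m_prime = len(counts_list)
    if m_prime == 0 or len(rejected_flags) != m_prime:
        raise ValueError("counts and rejection flags must align and be nonempty")
    detected = [i for i, r in enumerate(rejected_flags) if r]
    detected.sort(key=lambda i: (counts_list[i].FP, i))
    others = [i for i, r in enumerate(rejected_flags) if not r]
    ordering = detected + others
    q = len(detected)

    tp = np.array([counts_list[i].TP for i in ordering], dtype=np.int64)
    fp = np.array([counts_list[i].FP for i in ordering], dtype=np.int64)
    fn = np.array([counts_list[i].FN for i in ordering], dtype=np.int64)
    s = np.arange(1, m_prime + 1, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tc = np.where(tp + fp + fn > 0, tp / np.maximum(tp + fp + fn, 1), 0.0)
    f = np.cumsum(tc) / s
    g = np.cumsum(tp) / np.cumsum(tp + fp + fn).astype(float)

    S0 = [i for i in detected if counts_list[i].TP == 0]
    S1 = [i for i in detected if counts_list[i].FP == 0]
    S2 = [i for i in detected if counts_list[i].TP != 0 and counts_list[i].FP != 0]
    M = float(sum(counts_list[i].TP / (D + counts_list[i].FP) for i in detected))
    A = int(sum(counts_list[i].TP for i in detected))
    B = int(sum(counts_list[i].FP for i in detected))
    return DiagnosticCurves(
        ordering=ordering,
        f=f,
        g=g,
        q=q,
        m_prime=m_prime,
        D=D,
        M=M,
        A=A,
        B=B,
        S0=S0,
        S1=S1,
        S2=S2,
    )


def asymptotic_ratio(curves: DiagnosticCurves) -> float | None:
    """Limit of f(s)/g(s) as s grows: M*D/A, always at most 1.

    Strictly below 1 exactly when some detection mixes true and false
    positives (S2 nonempty): a term with TP>0 and FP>0 has TP/(D+FP) <
    TP/D, while FP-only detections contribute 0 to both M and A. ``None``
    when no detection ever produced a true positive (A = 0, undefined).
    """
    if curves.A == 0:
        return None
    ratio = curves.M * curves.D / curves.A
    if ratio > 1 + 1e-12:
        raise AssertionError(f"asymptotic ratio {ratio} exceeds 1: internal error")
    return ratio
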