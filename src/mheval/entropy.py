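"""Exact and polynomial-approximated information measures.

C4.5 scores candidate splits by the information gain ratio, whose evaluation
calls ``log`` for every class/branch count. The TAM variant replaces every
logarithm with the third-order Maclaurin expansion of ln(x) about 1,

    ln x  ≈  (x−1) − (x−1)²/2 + (x−1)³/3,          0 < x ≤ 1,

which for a count fraction p = a/b collapses p·ln p to the closed rational
form a(a−b)(2a² − 7ab + 11b²)/(6b⁴). Candidate scoring then needs only the
four elementary arithmetic operations — no transcendental library calls — at
the cost of an approximation error that grows as any proportion approaches 0.

Every transcendental call made by the exact path goes through the module's
instrumented wrappers, so callers can assert that the approximated path is
log-free (see :func:`transcendental_call_count`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datasets import ClassCounts

__all__ = [
    "PartitionCounts",
    "SplitCandidate",
    "exact_entropy",
    "exact_gain_ratio",
    "maclaurin_ln",
    "approx_plogp",
    "approx_entropy",
    "approx_gain_ratio",
    "discretize_continuous",
    "gain_ratio_rank_agreement",
    "transcendental_call_count",
    "reset_transcendental_counter",
]

LN2 = math.log(2.0)
_ZERO_TOL = 1e-12

_transcendental_calls = 0


def transcendental_call_count() -> int:
    """Number of log calls made through this module since the last reset."""
    return _transcendental_calls


def reset_transcendental_counter() -> None:
    global _transcendental_calls
    _transcendental_calls = 0


def _log2(x: float) -> float:
    """log2 with call accounting; the only log the exact path uses."""
    global _transcendental_calls
    _transcendental_calls += 1
    return math.log2(x)


@dataclass(frozen=True)
class PartitionCounts:
    """Class counts per branch of a candidate split: shape (branches, classes)."""

    table: np.ndarray

    def __post_init__(self) -> None:
        tab = np.asarray(self.table, dtype=np.int64)
        if tab.ndim != 2:
            raise ValueError("partition table must be 2-D (branches x classes)")
        if (tab < 0).any():
            raise ValueError("partition counts must be non-negative")
        object.__setattr__(self, "table", tab)

    @property
    def n_branches(self) -> int:
        return self.table.shape[0]

    def branch_totals(self) -> np.ndarray:
        return self.table.sum(axis=1)

    def parent_counts(self) -> ClassCounts:
        return ClassCounts(counts=tuple(int(c) for c in self.table.sum(axis=0)))


@dataclass(frozen=True)
class SplitCandidate:
    """A scored split: information gain, split information, and their ratio.

    ``valid`` is False when the split information vanishes (all records in one
    branch) or the attribute admits no split at all; invalid candidates carry
    zero scores and must not win attribute selection.
    """

    gain: float
    split_info: float
    gain_ratio: float
    valid: bool = True
    attribute: str | None = None
    threshold: float | None = None

    @staticmethod
    def invalid(attribute: str | None = None) -> "SplitCandidate":
        return SplitCandidate(
            gain=0.0, split_info=0.0, gain_ratio=0.0, valid=False, attribute=attribute
        )


def _counts_array(c: ClassCounts | Sequence[int] | np.ndarray) -> np.ndarray:
    if isinstance(c, ClassCounts):
        return c.as_array()
    return np.asarray(c, dtype=np.int64)


def exact_entropy(c: ClassCounts | Sequence[int]) -> float:
    """Shannon entropy −Σ p_i log2 p_i in bits, with 0·log 0 := 0."""
    counts = _counts_array(c)
    total = int(counts.sum())
    if total < 1:
        raise ValueError("entropy needs at least one record")
    h = 0.0
    for s_i in counts:
        if s_i > 0:
            p = s_i / total
            h -= p * _log2(p)
    return max(h, 0.0)


def exact_gain_ratio(
    parent: ClassCounts | Sequence[int], part: PartitionCounts
) -> SplitCandidate:
    """Information gain and gain ratio of a partition, all in bits.

    gain = H(parent) − Σ_j (s_j/s)·H(branch_j); split information is the
    entropy of the branch sizes; their quotient is the C4.5 criterion.
    """
    pc = _counts_array(parent)
    if not np.array_equal(pc, part.table.sum(axis=0)):
        raise ValueError("branch counts do not sum to the parent counts")
    total = int(pc.sum())
    if total < 1:
        raise ValueError("empty parent")
    branch_totals = part.branch_totals()
    info_parent = exact_entropy(pc)
    remainder = 0.0
    split_info = 0.0
    for j in range(part.n_branches):
        s_j = int(branch_totals[j])
        if s_j == 0:
            continue
        w = s_j / total
        remainder += w * exact_entropy(part.table[j])
        split_info -= w * _log2(w)
    gain = info_parent - remainder
    if split_info <= _ZERO_TOL:
        return SplitCandidate.invalid()
    return SplitCandidate(gain=gain, split_info=split_info, gain_ratio=gain / split_info)


def maclaurin_ln(x: float) -> float:
    """Third-order Maclaurin surrogate for ln(x) on (0, 1]."""
    if x <= 0.0 or x > 1.0:
        raise ValueError(f"maclaurin_ln is defined on (0, 1], got {x!r}")
    u = x - 1.0
    return u - u * u / 2.0 + u * u * u / 3.0


def approx_plogp(a: int, b: int) -> float:
    """Closed polynomial form of (a/b)·maclaurin_ln(a/b), in nats.

    Equals a(a−b)(2a² − 7ab + 11b²)/(6b⁴); zero when a = 0 or a = b. Uses
    only elementary arithmetic — the TAM building block.
    """
    a = int(a)
    b = int(b)
    if b < 1:
        raise ValueError("denominator count must be >= 1")
    if a < 0 or a > b:
        raise ValueError(f"need 0 <= a <= b, got a={a}, b={b}")
    if a == 0 or a == b:
        return 0.0
    num = a * (a - b) * (2 * a * a - 7 * a * b + 11 * b * b)
    return num / (6.0 * b**4)


def approx_entropy(c: ClassCounts | Sequence[int]) -> float:
    """Maclaurin-approximated class entropy, −(1/ln 2)·Σ approx_plogp, in bits."""
    counts = _counts_array(c)
    total = int(counts.sum())
    if total < 1:
        raise ValueError("entropy needs at least one record")
    acc = 0.0
    for s_i in counts:
        acc += approx_plogp(int(s_i), total)
    return -acc / LN2


def approx_gain_ratio(
    parent: ClassCounts | Sequence[int], part: PartitionCounts
) -> SplitCandidate:
    """Gain ratio with every log replaced by the Maclaurin polynomial.

    numerator   = Info′(S) − Info′_A(S)
    denominator = Info′(A)   (split information, approximated the same way)

    The whole computation is log-free; the 1/ln 2 prefactor keeps the three
    terms in bits but cancels in the ratio regardless.
    """
    pc = _counts_array(parent)
    if not np.array_equal(pc, part.table.sum(axis=0)):
        raise ValueError("branch counts do not sum to the parent counts")
    total = int(pc.sum())
    if total < 1:
        raise ValueError("empty parent")
    info_parent = approx_entropy(pc)
    branch_totals = part.branch_totals()
    cond = 0.0
    split_info = 0.0
    for j in range(part.n_branches):
        s_j = int(branch_totals[j])
        if s_j == 0:
            continue
        inner = 0.0
        for s_ij in part.table[j]:
            inner += approx_plogp(int(s_ij), s_j)
        cond -= (s_j / total) * inner / LN2
        split_info -= approx_plogp(s_j, total) / LN2
    gain = info_parent - cond
    if split_info <= _ZERO_TOL:
        return SplitCandidate.invalid()
    return SplitCandidate(gain=gain, split_info=split_info, gain_ratio=gain / split_info)


def _partition_from_threshold(
    values: np.ndarray, label_idx: np.ndarray, n_classes: int, threshold: float
) -> PartitionCounts:
    left = values <= threshold
    table = np.zeros((2, n_classes), dtype=np.int64)
    table[0] = np.bincount(label_idx[left], minlength=n_classes)
    table[1] = np.bincount(label_idx[~left], minlength=n_classes)
    return PartitionCounts(table=table)


def discretize_continuous(
    values: Sequence[float],
    labels: Sequence[object],
    n_points: int = 10,
    mode: str = "exact",
    class_names: Sequence[object] | None = None,
    midpoint_candidates: bool = False,
) -> SplitCandidate:
    """Find the best binary threshold for a continuous attribute.

    Candidate thresholds are the interior equal-division points
    ``A_i = MIN + i·(MAX−MIN)/(n_points+1)`` for i = 1..n_points; each induces
    the partition [MIN, A_i] vs (A_i, MAX]. The candidate with the largest
    gain ratio wins, ties going to the smaller threshold. ``mode`` selects the
    exact or Maclaurin-approximated criterion. ``midpoint_candidates=True``
    switches to the classic candidate set (midpoints of consecutive distinct
    sorted values) instead of equal division; off by default.
    """
    if mode not in ("exact", "tam"):
        raise ValueError(f"unknown mode {mode!r}")
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    vals = np.asarray(values, dtype=float)
    labs = np.asarray(labels, dtype=object)
    if vals.shape[0] != labs.shape[0] or vals.shape[0] < 2:
        raise ValueError("values and labels must have equal length >= 2")
    if class_names is None:
        class_names = sorted(set(labs.tolist()))
    lut = {c: i for i, c in enumerate(class_names)}
    label_idx = np.array([lut[y] for y in labs], dtype=np.intp)
    n_classes = len(class_names)

    lo = float(vals.min())
    hi = float(vals.max())
    if hi - lo <= _ZERO_TOL:
        return SplitCandidate.invalid()

    if midpoint_candidates:
        distinct = np.unique(vals)
        thresholds = (distinct[:-1] + distinct[1:]) / 2.0
    else:
        step = (hi - lo) / (n_points + 1)
        thresholds = lo + step * np.arange(1, n_points + 1)

    score = exact_gain_ratio if mode == "exact" else approx_gain_ratio
    best: SplitCandidate | None = None
    for thr in thresholds:
        part = _partition_from_threshold(vals, label_idx, n_classes, float(thr))
        parent = part.parent_counts()
        cand = score(parent, part)
        if not cand.valid:
            continue
        cand = SplitCandidate(
            gain=cand.gain,
            split_info=cand.split_info,
            gain_ratio=cand.gain_ratio,
            threshold=float(thr),
        )
        if best is None or cand.gain_ratio > best.gain_ratio + _ZERO_TOL:
            best = cand
    if best is None:
        return SplitCandidate.invalid()
    return best


def gain_ratio_rank_agreement(seed: int, n_trials: int = 200) -> float:
    """Fraction of random attribute-selection problems on which the exact and
    Maclaurin-approximated gain ratios pick the same best attribute.

    Each trial draws a 2-class parent with class proportion in [0.2, 0.8] and
    three candidate binary partitions whose branch proportions also lie in
    [0.2, 0.8]; each candidate carries a random class association strength so
    the three genuinely differ. The rate is the diagnostic behind using the
    TAM criterion as a drop-in replacement for attribute selection.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_trials):
        n = int(rng.integers(40, 200))
        x = int(round(n * rng.uniform(0.2, 0.8)))
        x = min(max(x, 1), n - 1)
        parent = (x, n - x)
        best_exact, best_approx = None, None
        score_exact, score_approx = -np.inf, -np.inf
        for j in range(3):
            left = int(round(n * rng.uniform(0.2, 0.8)))
            left = min(max(left, 1), n - 1)
            strength = rng.uniform(0.0, 1.0)
            target = left * ((1.0 - strength) * (x / n) + strength)
            la = int(round(target))
            la = min(max(la, max(0, left - (n - x))), min(left, x))
            table = np.array(
                [[la, left - la], [x - la, (n - left) - (x - la)]], dtype=np.int64
            )
            part = PartitionCounts(table=table)
            ce = exact_gain_ratio(parent, part)
            ca = approx_gain_ratio(parent, part)
            if ce.valid and ce.gain_ratio > score_exact:
                score_exact, best_exact = ce.gain_ratio, j
            if ca.valid and ca.gain_ratio > score_approx:
                score_approx, best_approx = ca.gain_ratio, j
        agree += int(best_exact == best_approx)
    return agree / n_trials
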