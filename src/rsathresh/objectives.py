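"""Threshold-vector objectives: Otsu between-class variance and Kapur entropy.

A threshold vector ``t_1 < t_2 < … < t_{m−1}`` (integers in ``[1, L−1]``)
partitions the gray levels into ``m`` classes by the half-open rule: level
``p`` belongs to class ``i`` iff ``t_i ≤ p < t_{i+1}`` with ``t_0 = 0`` and
``t_m = L``.  Both objectives are maximized:

* Otsu: ``σ_B = Σ_i ω_i (μ_i − μ_T)²`` — the between-class variance, where
  ``ω_i`` is the probability mass of class ``i``, ``μ_i`` its mean level and
  ``μ_T`` the global mean.
* Kapur: ``Σ_i H_i`` with ``H_i = −Σ_{j∈class i} (p_j/ω_i)·ln(p_j/ω_i)`` —
  the sum of the Shannon entropies of the within-class distributions.

Empty classes (``ω_i = 0``) and zero-probability levels contribute 0 to
either objective.  ``exhaustive_search`` enumerates every strictly
increasing tuple and is the ground-truth oracle for the metaheuristic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from .histograms import N_LEVELS, ChannelHistogram

OBJECTIVES = ("otsu", "kapur")


@dataclass(frozen=True)
class ThresholdVector:
    """Strictly increasing integer thresholds partitioning the gray levels."""

    values: tuple[int, ...]

    def __post_init__(self) -> None:
        vals = tuple(int(v) for v in self.values)
        if len(vals) < 1:
            raise ValueError("need at least one threshold")
        if any(v < 1 or v > N_LEVELS - 1 for v in vals):
            raise ValueError(f"thresholds must lie in [1, {N_LEVELS - 1}]: {vals}")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {vals}")
        object.__setattr__(self, "values", vals)

    @property
    def class_count(self) -> int:
        return len(self.values) + 1

    def __iter__(self):
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def partition_levels(t: ThresholdVector, n_levels: int = N_LEVELS) -> np.ndarray:
    """Class index for every gray level under the half-open class rule."""
    edges = np.asarray(t.values)
    return np.searchsorted(edges, np.arange(n_levels), side="right")


@dataclass(frozen=True)
class ClassDecomposition:
    """Per-class quantities behind the objectives (mass, mean, entropy...)."""

    omega: np.ndarray          # class probability mass ω_i
    mu: np.ndarray             # class mean μ_i (0 where class empty)
    mu_total: float            # global mean μ_T
    sigma: np.ndarray          # Otsu contributions ω_i(μ_i − μ_T)²
    entropy: np.ndarray        # Kapur contributions H_i
    within_var: np.ndarray     # ω_i · Var_i, for the total-variance identity


def decompose(h: ChannelHistogram, t: ThresholdVector) -> ClassDecomposition:
    """Per-class masses, means, variance and entropy contributions."""
    p = h.probabilities
    levels = np.arange(N_LEVELS, dtype=float)
    edges = [0, *t.values, N_LEVELS]
    m = len(edges) - 1
    omega = np.empty(m)
    mu = np.zeros(m)
    entropy = np.zeros(m)
    within = np.zeros(m)
    mu_total = float(levels @ p)
    for i in range(m):
        lo, hi = edges[i], edges[i + 1]
        pi = p[lo:hi]
        w = pi.sum()
        omega[i] = w
        if w > 0.0:
            mu[i] = float(levels[lo:hi] @ pi) / w
            within[i] = float(((levels[lo:hi] - mu[i]) ** 2) @ pi)
            q = pi[pi > 0.0] / w
            entropy[i] = float(-(q * np.log(q)).sum())
    sigma = omega * (mu - mu_total) ** 2
    return ClassDecomposition(omega, mu, mu_total, sigma, entropy, within)


def otsu_score(h: ChannelHistogram, t: ThresholdVector) -> float:
    """Between-class variance σ_B of the thresholding (maximize)."""
    return float(decompose(h, t).sigma.sum())


def kapur_score(h: ChannelHistogram, t: ThresholdVector) -> float:
    """Sum of within-class Shannon entropies (natural log; maximize)."""
    return float(decompose(h, t).entropy.sum())


def score(h: ChannelHistogram, t: ThresholdVector, objective: str) -> float:
    if objective == "otsu":
        return otsu_score(h, t)
    if objective == "kapur":
        return kapur_score(h, t)
    raise ValueError(f"unknown objective {objective!r}; expected one of {OBJECTIVES}")


class ObjectiveEvaluator:
    """Fast repeated scoring of threshold tuples against one histogram.

    Precomputes prefix sums of ``p``, ``j·p`` and ``p·ln p`` so a tuple is
    scored in O(m) instead of O(L).  Used by both the exhaustive oracle and
    the metaheuristic's inner loop; it matches ``otsu_score``/``kapur_score``
    to floating-point accuracy by construction (same class rule, same
    empty-class convention).
    """

    def __init__(self, h: ChannelHistogram, objective: str):
        if objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {objective!r}")
        self.objective = objective
        p = h.probabilities
        levels = np.arange(N_LEVELS, dtype=float)
        self._cp = np.concatenate(([0.0], np.cumsum(p)))            # Σ p
        self._cs = np.concatenate(([0.0], np.cumsum(levels * p)))   # Σ j·p
        plogp = np.where(p > 0.0, p * np.log(np.where(p > 0.0, p, 1.0)), 0.0)
        self._ce = np.concatenate(([0.0], np.cumsum(plogp)))        # Σ p·ln p
        self._mu_total = self._cs[-1]

    def __call__(self, thresholds) -> float:
        edges = np.asarray([0, *thresholds, N_LEVELS])
        w = self._cp[edges[1:]] - self._cp[edges[:-1]]
        if self.objective == "otsu":
            s = self._cs[edges[1:]] - self._cs[edges[:-1]]
            nz = w > 0.0
            mu = np.zeros_like(w)
            mu[nz] = s[nz] / w[nz]
            return float((w[nz] * (mu[nz] - self._mu_total) ** 2).sum())
        e = self._ce[edges[1:]] - self._ce[edges[:-1]]
        nz = w > 0.0
        # H_i = −Σ (p/ω)ln(p/ω) = ln ω − (Σ p ln p)/ω
        return float((np.log(w[nz]) - e[nz] / w[nz]).sum())

    def score_matrix(self, tuples: np.ndarray) -> np.ndarray:
        """Score many tuples at once; ``tuples`` is (n, k) of ints."""
        n, k = tuples.shape
        edges = np.empty((n, k + 2), dtype=np.int64)
        edges[:, 0] = 0
        edges[:, 1:-1] = tuples
        edges[:, -1] = N_LEVELS
        w = self._cp[edges[:, 1:]] - self._cp[edges[:, :-1]]
        nz = w > 0.0
        if self.objective == "otsu":
            s = self._cs[edges[:, 1:]] - self._cs[edges[:, :-1]]
            mu = np.divide(s, w, out=np.zeros_like(s), where=nz)
            contrib = np.where(nz, w * (mu - self._mu_total) ** 2, 0.0)
        else:
            e = self._ce[edges[:, 1:]] - self._ce[edges[:, :-1]]
            safe_w = np.where(nz, w, 1.0)
            contrib = np.where(nz, np.log(safe_w) - e / safe_w, 0.0)
        return contrib.sum(axis=1)


def exhaustive_search(
    h: ChannelHistogram,
    k: int,
    objective: str = "otsu",
    max_combinations: int = 5_000_000,
    chunk: int = 262_144,
) -> tuple[ThresholdVector, float]:
    """Brute-force arg-max over every strictly increasing k-tuple in [1, L−1].

    Ground-truth oracle for the metaheuristic.  Ties break to the
    lexicographically smallest tuple.  Raises ``ValueError`` when the
    enumeration (``C(L−1, k)`` tuples) exceeds ``max_combinations``.
    """
    if k < 1:
        raise ValueError("k must be ≥ 1")
    n_tuples = comb(N_LEVELS - 1, k)
    if n_tuples > max_combinations:
        raise ValueError(
            f"C({N_LEVELS - 1},{k}) = {n_tuples} tuples exceeds the enumeration "
            f"budget of {max_combinations}"
        )
    ev = ObjectiveEvaluator(h, objective)
    it = itertools.combinations(range(1, N_LEVELS), k)
    best_score = -np.inf
    best_tuple: tuple[int, ...] | None = None
    while True:
        block = np.fromiter(
            itertools.chain.from_iterable(itertools.islice(it, chunk)),
            dtype=np.int64,
        ).reshape(-1, k)
        if block.size == 0:
            break
        scores = ev.score_matrix(block)
        i = int(np.argmax(scores))  # first occurrence → lexicographic tie-break
        if scores[i] > best_score:
            best_score = float(scores[i])
            best_tuple = tuple(int(v) for v in block[i])
    assert best_tuple is not None
    return ThresholdVector(best_tuple), best_score
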