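"""Crossover combinatorics on tandem loxP arrays.

A Tlox cassette is a tandem array of loxP units with a stop codon hidden in
the overlap of the second unit: the downstream reporter switches ON
permanently when (and only when) the array collapses to a single unit.
Cre cannot recombine the array in cis; it can cross the array over with its
sister chromatid after replication. An unequal exchange between unit ``i``
on one sister and unit ``j`` on the other produces arrays of ``i + n - j``
and ``j + n - i`` units, conserving the total of ``2n``.

This module provides the exact single-crossover model (uniform pairing over
the ``n**2`` cross-alignments, random segregation of the two products) and
the simplified per-cycle model in which each daughter of an unlabeled cell
becomes labeled independently with probability ``p`` per division
(``p = 1/4`` at full Cre activity, the maximal per-cycle labeling rate).

All probability computations are exact when called with
:class:`fractions.Fraction` inputs and float otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ModelError

__all__ = [
    "ModelParams",
    "LoxArray",
    "crossover_products",
    "daughter_size_pmf",
    "activation_probability",
    "multiplicity_transition_matrix",
    "cumulative_label_fraction",
    "label_fraction_curve",
]

VARIANTS = ("exact", "simplified")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the labeling model.

    Parameters
    ----------
    c:
        Probability that a sister-chromatid crossover occurs during one
        division, given that Cre is active. Absorbs Cre expression level,
        locus accessibility and S/G2 duration; ``c = 1`` gives the maximal
        labeling rate (25% of daughters in the first cycle).
    variant:
        ``"exact"`` — track the full loxP multiplicity Markov chain;
        ``"simplified"`` — per-daughter activation with fixed probability
        ``p_simplified`` each division (the per-cycle approximation used
        for all paper-facing numbers and for inference).
    p_simplified:
        Per-daughter, per-division activation probability of the simplified
        variant. Default 1/4, the exact first-cycle value at ``c = 1``.
    n_max:
        Truncation bound of the multiplicity chain; mass beyond ``n_max`` is
        accumulated onto the last state so rows stay stochastic. The default
        of 32 keeps the truncated mass below 1e-9 for ``c = 1`` out to 20
        divisions.
    seed:
        Root seed for stochastic consumers of these parameters.
    """

    c: float = 1.0
    variant: str = "simplified"
    p_simplified: float = 0.25
    n_max: int = 32
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.c <= 1:
            raise ModelError(f"crossover probability c={self.c!r} outside [0, 1]")
        if self.variant not in VARIANTS:
            raise ModelError(
                f"variant {self.variant!r} not one of {VARIANTS}"
            )
        if not 0 <= self.p_simplified < 1:
            raise ModelError(
                f"p_simplified={self.p_simplified!r} outside [0, 1)"
            )
        if int(self.n_max) != self.n_max or self.n_max < 3:
            raise ModelError(f"n_max={self.n_max!r} must be an integer >= 3")


@dataclass(frozen=True)
class LoxArray:
    """A tandem loxP array on one chromatid.

    The reporter is ON iff the array holds exactly one unit; crossovers
    merge one loxP pair per event and can never empty the array, so a
    1-unit array is an absorbing, permanently labeled state.
    """

    count: int = 2

    def __post_init__(self) -> None:
        if int(self.count) != self.count or self.count < 1:
            raise ModelError(f"lox count {self.count!r} must be an integer >= 1")

    @property
    def reporter_on(self) -> bool:
        return self.count == 1


def _check_count(n) -> int:
    if int(n) != n or n < 1:
        raise ModelError(f"lox count n={n!r} must be an integer >= 1")
    return int(n)


def _check_prob(c, name: str = "c"):
    if not 0 <= c <= 1:
        raise ModelError(f"{name}={c!r} outside [0, 1]")
    return c


def crossover_products(n: int, i: int, j: int) -> tuple[int, int]:
    """Sizes of the two arrays produced by a crossover at units (i, j).

    Unit ``i`` on sister A aligns with unit ``j`` on sister B; the exchange
    joins the first ``i`` units of A to the last ``n - j`` of B and vice
    versa, giving products of ``i + n - j`` and ``j + n - i`` units. Their
    sum is always ``2n`` and neither can be empty. ``i == j`` is the equal
    exchange leaving both sizes at ``n``.
    """
    n = _check_count(n)
    if not 1 <= i <= n:
        raise ModelError(f"pairing index i={i} outside 1..{n}")
    if not 1 <= j <= n:
        raise ModelError(f"pairing index j={j} outside 1..{n}")
    return (i + n - j, j + n - i)


def daughter_size_pmf(n: int, c) -> dict[int, float]:
    """Distribution of one daughter's lox count after a single division.

    With probability ``1 - c`` no crossover occurs and the daughter inherits
    ``n`` units. With probability ``c`` a single crossover happens at a
    pairing ``(i, j)`` uniform over the ``n**2`` cross-alignments, and the
    daughter receives either product with probability 1/2. Marginally::

        P(n + d) = c * (n - |d|) / n**2      for 1 <= |d| <= n - 1
        P(n)     = (1 - c) + c / n

    Exact (Fraction) arithmetic is preserved when ``c`` is a Fraction.
    """
    n = _check_count(n)
    c = _check_prob(c)
    pmf: dict = {n: (1 - c) + c / n}
    for d in range(1, n):
        mass = c * (n - d) / (n * n)
        if mass:
            pmf[n - d] = pmf.get(n - d, 0) + mass
            pmf[n + d] = pmf.get(n + d, 0) + mass
    # drop exact zeros (c == 0) but keep the certain state
    return {k: v for k, v in sorted(pmf.items()) if v != 0 or k == n}


def activation_probability(n: int, c) -> float:
    """Probability one daughter becomes labeled (size 1) in one division.

    Equals ``c / n**2``: the only pairing producing a 1-unit product is
    ``(1, n)``/``(n, 1)`` and each hands the short product to a given
    daughter half the time. At ``n = 2, c = 1`` this is the maximal
    first-cycle labeling rate of 25%.
    """
    n = _check_count(n)
    if n < 2:
        raise ModelError("array with a single loxP is already labeled")
    c = _check_prob(c)
    return c / (n * n)


def multiplicity_transition_matrix(c: float, n_max: int = 32) -> np.ndarray:
    """Row-stochastic transition matrix of the lox-multiplicity chain.

    States are lox counts ``1..n_max`` (index ``s - 1``). Row ``n`` is
    :func:`daughter_size_pmf` with mass beyond ``n_max`` lumped onto the
    last state; state 1 (labeled) is absorbing.
    """
    if int(n_max) != n_max or n_max < 3:
        raise ModelError(f"n_max={n_max!r} must be an integer >= 3")
    c = _check_prob(c)
    n_max = int(n_max)
    T = np.zeros((n_max, n_max))
    T[0, 0] = 1.0
    for n in range(2, n_max + 1):
        for size, mass in daughter_size_pmf(n, float(c)).items():
            T[n - 1, min(size, n_max) - 1] += mass
    return T


def _cumulative_exact(k: int, params: ModelParams) -> float:
    T = multiplicity_transition_matrix(params.c, params.n_max)
    v = np.zeros(params.n_max)
    v[1] = 1.0  # unlabeled 2-unit cassette
    for _ in range(k):
        v = v @ T
    return float(v[0])


def cumulative_label_fraction(k, params: ModelParams) -> float:
    """Expected labeled fraction of the population after ``k`` divisions.

    Simplified variant: ``1 - (1 - p)**k`` (valid for real-valued effective
    division numbers). Exact variant: ``k`` iterations of the multiplicity
    chain started from a 2-unit array, returning the absorbed mass; ``k``
    must be a non-negative integer here. Both vanish at ``k = 0`` and are
    non-decreasing in ``k``.
    """
    if k < 0:
        raise ModelError(f"division count k={k!r} must be >= 0")
    if params.variant == "simplified":
        return 1.0 - (1.0 - params.p_simplified) ** k
    if int(k) != k:
        raise ModelError(
            "exact variant requires an integer division count; "
            "use the simplified variant for fractional effective generations"
        )
    return _cumulative_exact(int(k), params)


def label_fraction_curve(ks, params: ModelParams) -> np.ndarray:
    """Vectorized :func:`cumulative_label_fraction` over division counts."""
    return np.array([cumulative_label_fraction(k, params) for k in ks])
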