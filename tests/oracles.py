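"""Independent brute-force oracles for the crossover combinatorics.

These enumerate outcomes directly from the mechanism (all pairings, both
segregations, explicit array construction) in exact rational arithmetic and
never call the closed forms they are used to check.
"""

from fractions import Fraction
from functools import lru_cache
from itertools import product


def build_products(n: int, i: int, j: int) -> tuple[tuple, tuple]:
    """Construct the two recombinant arrays explicitly as unit tuples.

    Sister A carries units a1..an, sister B units b1..bn. A crossover
    pairing unit i with unit j fuses them into one hybrid unit; one product
    keeps A's prefix before the fusion, the other keeps B's prefix.
    """
    A = tuple(f"a{u}" for u in range(1, n + 1))
    B = tuple(f"b{u}" for u in range(1, n + 1))
    fused_ij = (f"a{i}|b{j}",)
    fused_ji = (f"b{j}|a{i}",)
    prod1 = A[: i - 1] + fused_ij + B[j:]
    prod2 = B[: j - 1] + fused_ji + A[i:]
    return prod1, prod2


def enumerate_daughter_pmf(n: int, c: Fraction) -> dict[int, Fraction]:
    """Marginal daughter-size distribution by exhaustive enumeration of all
    n^2 pairings x 2 segregations, each pairing weight c/n^2, each product
    handed to the daughter with weight 1/2."""
    pmf: dict[int, Fraction] = {}
    if c != 1:
        pmf[n] = 1 - c
    w = Fraction(1, 2 * n * n)
    for i, j in product(range(1, n + 1), repeat=2):
        p1, p2 = build_products(n, i, j)
        for prod in (p1, p2):
            size = len(prod)
            pmf[size] = pmf.get(size, Fraction(0)) + c * w
    return {k: v for k, v in sorted(pmf.items()) if v != 0 or k == n}


@lru_cache(maxsize=None)
def population_label_fraction(n: int, k: int, c: Fraction) -> Fraction:
    """Expected labeled fraction of the population after k divisions of a
    single n-unit founder, by full recursion over every lineage outcome."""
    if n == 1:
        return Fraction(1)
    if k == 0:
        return Fraction(0)
    total = (1 - c) * population_label_fraction(n, k - 1, c)
    w = Fraction(1, n * n)
    for i, j in product(range(1, n + 1), repeat=2):
        a, b = i + n - j, j + n - i
        total += (
            c
            * w
            * (
                population_label_fraction(a, k - 1, c)
                + population_label_fraction(b, k - 1, c)
            )
            / 2
        )
    return total
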