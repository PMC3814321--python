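"""Branching-process simulation of label accumulation in dividing cells.

Three entry points, all seeded and deterministic:

* :func:`simulate_division` — one cell, one division, the primitive event.
* :func:`simulate_population` — synchronous generations at the population
  level, either with paired daughters (the anti-correlated products of a
  crossover stay together, suitable for lineage statistics) or with
  count-vector propagation sampling each daughter from the marginal pmf
  (valid for population fractions because daughter fates are exchangeable,
  and memory-safe at any size).
* :func:`simulate_culture` — asynchronous exponential growth with
  exponential inter-division times (mean ``doubling_time / ln 2``) and a
  Cre-activity window: divisions completing before ``cre_start`` can never
  activate the reporter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ModelError
from .recombination import (
    ModelParams,
    crossover_products,
    multiplicity_transition_matrix,
)

__all__ = [
    "CellState",
    "DivisionSchedule",
    "simulate_division",
    "simulate_population",
    "simulate_culture",
]


@dataclass(frozen=True)
class CellState:
    """One cell: lox multiplicity, permanent label flag, generation index."""

    lox_count: int = 2
    labeled: bool = False
    generation: int = 0
    stage_id: str | None = None

    def __post_init__(self) -> None:
        if int(self.lox_count) != self.lox_count or self.lox_count < 1:
            raise ModelError(f"lox_count {self.lox_count!r} must be an integer >= 1")
        if self.generation < 0:
            raise ModelError("generation must be >= 0")


@dataclass(frozen=True)
class DivisionSchedule:
    """Either a fixed number of divisions or an asynchronous culture window.

    Culture mode mirrors the in vitro experiment: unsynchronized cells with
    a known doubling time, transduced with Cre at time ``cre_start`` and
    sampled over ``duration`` hours.
    """

    k: int | None = None
    doubling_time: float | None = None
    duration: float | None = None
    cre_start: float = 0.0

    def __post_init__(self) -> None:
        if self.k is not None:
            if int(self.k) != self.k or self.k < 0:
                raise ModelError(f"k={self.k!r} must be an integer >= 0")
            return
        if self.doubling_time is None or self.duration is None:
            raise ModelError("schedule needs either k or (doubling_time, duration)")
        if self.doubling_time <= 0:
            raise ModelError("doubling_time must be > 0 hours")
        if self.duration < 0 or self.cre_start < 0:
            raise ModelError("durations must be >= 0 hours")


def simulate_division(
    cell: CellState, params: ModelParams, rng: np.random.Generator
) -> tuple[CellState, CellState]:
    """Divide one cell into two daughters.

    Exact variant: with probability ``c`` draw a pairing ``(i, j)`` uniform
    over the ``n**2`` cross-alignments and hand the two products to the
    daughters in random order; otherwise both daughters inherit ``n`` units.
    Simplified variant: each daughter of an unlabeled parent is labeled
    independently with probability ``p_simplified``; labeled parents breed
    labeled daughters. The label never reverts in either variant.
    """
    g = cell.generation + 1
    if params.variant == "simplified":
        if cell.labeled:
            flags = (True, True)
        else:
            flags = tuple(rng.random(2) < params.p_simplified)
        return tuple(
            CellState(cell.lox_count, f, g, cell.stage_id) for f in flags
        )
    n = cell.lox_count
    if n > 1 and rng.random() < params.c:
        i = int(rng.integers(1, n + 1))
        j = int(rng.integers(1, n + 1))
        a, b = crossover_products(n, i, j)
        if rng.random() < 0.5:
            a, b = b, a
    else:
        a = b = n
    return (
        CellState(a, a == 1, g, cell.stage_id),
        CellState(b, b == 1, g, cell.stage_id),
    )


def _population_counts(
    counts: np.ndarray, k: int, T: np.ndarray, rng: np.random.Generator
) -> list[np.ndarray]:
    """Propagate a lox-count histogram through k generations by sampling
    each daughter independently from the marginal daughter pmf."""
    hists = [counts.copy()]
    for _ in range(k):
        nxt = np.zeros_like(counts)
        for s in np.nonzero(counts)[0]:
            nxt += rng.multinomial(2 * int(counts[s]), T[s])
        counts = nxt
        hists.append(counts.copy())
    return hists


def _population_paired(
    loxes: np.ndarray, k: int, params: ModelParams, rng: np.random.Generator,
    max_explicit: int,
) -> tuple[list[np.ndarray], np.ndarray | None]:
    """Explicit paired-daughter propagation; returns histograms and the
    final cell array, or switches to count mode when too large."""
    n_max = params.n_max
    hists = [np.bincount(loxes, minlength=n_max + 1)[1:].astype(np.int64)]
    for g in range(k):
        if 2 * loxes.size > max_explicit:
            warnings.warn(
                f"population exceeds {max_explicit} cells at generation {g};"
                " switching to count-vector tracking",
                RuntimeWarning,
                stacklevel=3,
            )
            T = multiplicity_transition_matrix(params.c, n_max)
            rest = _population_counts(hists[-1], k - g, T, rng)
            return hists + rest[1:], None
        n = loxes
        cross = (n > 1) & (rng.random(n.size) < params.c)
        i = rng.integers(1, n + 1)
        j = rng.integers(1, n + 1)
        a = np.where(cross, i + n - j, n)
        b = np.where(cross, j + n - i, n)
        swap = rng.random(n.size) < 0.5
        a, b = np.where(swap, b, a), np.where(swap, a, b)
        loxes = np.concatenate([a, b])
        np.minimum(loxes, n_max, out=loxes)
        hists.append(np.bincount(loxes, minlength=n_max + 1)[1:].astype(np.int64))
    return hists, loxes


def simulate_population(
    n_cells: int,
    k: int,
    params: ModelParams,
    seed: int | None = None,
    mode: str = "counts",
    max_explicit: int = 2_000_000,
) -> pd.DataFrame:
    """Simulate ``n_cells`` unlabeled founder cells through ``k`` synchronous
    generations; return a per-generation summary.

    Columns: ``generation``, ``n_cells``, ``n_labeled``, ``labeled_fraction``
    plus one ``lox_<s>`` histogram column per multiplicity state (exact
    variant). ``mode="counts"`` samples daughters from the marginal pmf;
    ``mode="paired"`` keeps crossover products together (and falls back to
    counts with a warning beyond ``max_explicit`` cells).
    """
    if n_cells < 1:
        raise ModelError("n_cells must be >= 1")
    if int(k) != k or k < 0:
        raise ModelError(f"k={k!r} must be an integer >= 0")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    if params.variant == "simplified":
        rows = []
        unlabeled, labeled = n_cells, 0
        rows.append((0, n_cells, 0))
        p = params.p_simplified
        for g in range(1, k + 1):
            new_lab = rng.binomial(2 * unlabeled, p) if unlabeled else 0
            labeled = 2 * labeled + new_lab
            unlabeled = 2 * unlabeled - new_lab
            rows.append((g, labeled + unlabeled, labeled))
        df = pd.DataFrame(rows, columns=["generation", "n_cells", "n_labeled"])
        df["labeled_fraction"] = df["n_labeled"] / df["n_cells"]
        return df

    if mode not in ("counts", "paired"):
        raise ModelError(f"unknown population mode {mode!r}")
    if mode == "counts":
        counts = np.zeros(params.n_max, dtype=np.int64)
        counts[1] = n_cells
        T = multiplicity_transition_matrix(params.c, params.n_max)
        hists = _population_counts(counts, k, T, rng)
    else:
        hists, _ = _population_paired(
            np.full(n_cells, 2, dtype=np.int64), k, params, rng, max_explicit
        )
    hist_arr = np.vstack(hists)
    df = pd.DataFrame(
        {
            "generation": np.arange(k + 1),
            "n_cells": hist_arr.sum(axis=1),
            "n_labeled": hist_arr[:, 0],
        }
    )
    df["labeled_fraction"] = df["n_labeled"] / df["n_cells"]
    for s in range(params.n_max):
        df[f"lox_{s + 1}"] = hist_arr[:, s]
    return df


def simulate_culture(
    schedule: DivisionSchedule,
    params: ModelParams,
    n_initial: int = 10_000,
    seed: int | None = None,
    record_every: float = 2.0,
    max_cells: int = 5_000_000,
) -> pd.DataFrame:
    """Asynchronous culture: exponential inter-division times, Cre gating.

    Every cell divides after an Exponential(mean = doubling_time / ln 2)
    waiting time, so the population doubles every ``doubling_time`` hours in
    expectation. A division completing at time ``t < cre_start`` uses
    crossover probability 0 (no Cre yet); later divisions use ``params.c``
    (or ``p_simplified``). Returns a tidy time series with columns
    ``time_h``, ``n_cells``, ``n_labeled``, ``labeled_fraction``.
    """
    if schedule.doubling_time is None:
        raise ModelError("culture simulation needs a (doubling_time, duration) schedule")
    if n_initial < 1:
        raise ModelError("n_initial must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mean_wait = schedule.doubling_time / np.log(2.0)
    duration = schedule.duration
    simplified = params.variant == "simplified"

    # live intervals: birth time, division (or inf), label state at birth
    starts, ends, labels = [], [], []

    # iterate generations of the event cascade; cells whose next division
    # falls past `duration` are censored there
    birth = np.zeros(n_initial)
    lox = np.full(n_initial, 2, dtype=np.int64)
    lab = np.zeros(n_initial, dtype=bool)
    total = n_initial
    while birth.size:
        div = birth + rng.exponential(mean_wait, birth.size)
        done = div > duration
        starts.append(birth[done])
        ends.append(np.full(done.sum(), np.inf))
        labels.append(lab[done])

        birth, div, lox, lab = birth[~done], div[~done], lox[~done], lab[~done]
        if birth.size == 0:
            break
        starts.append(birth)
        ends.append(div)
        labels.append(lab)
        total += birth.size
        if total > max_cells:
            raise ModelError(
                f"culture exceeded {max_cells} cells; shorten the window or "
                "lower n_initial"
            )

        active = div >= schedule.cre_start
        if simplified:
            p = np.where(active & ~lab, params.p_simplified, 0.0)
            la = lab | (rng.random(lab.size) < p)
            lb = lab | (rng.random(lab.size) < p)
            a = b = lox
        else:
            cross = active & (lox > 1) & (rng.random(lox.size) < params.c)
            i = rng.integers(1, lox + 1)
            j = rng.integers(1, lox + 1)
            a = np.where(cross, i + lox - j, lox)
            b = np.where(cross, j + lox - i, lox)
            swap = rng.random(lox.size) < 0.5
            a, b = np.where(swap, b, a), np.where(swap, a, b)
            np.minimum(a, params.n_max, out=a)
            np.minimum(b, params.n_max, out=b)
            la, lb = a == 1, b == 1
        birth = np.concatenate([div, div])
        lox = np.concatenate([a, b])
        lab = np.concatenate([la, lb])

    s = np.concatenate(starts)
    e = np.concatenate(ends)
    l = np.concatenate(labels)
    times = np.arange(0.0, duration + 1e-9, record_every)
    if times[-1] < duration:
        times = np.append(times, duration)
    rows = []
    for t in times:
        alive = (s <= t) & (e > t)
        n = int(alive.sum())
        nl = int(l[alive].sum())
        rows.append((t, n, nl, nl / n if n else np.nan))
    return pd.DataFrame(rows, columns=["time_h", "n_cells", "n_labeled", "labeled_fraction"])
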