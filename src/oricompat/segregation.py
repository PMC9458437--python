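"""Stochastic plasmid segregation and serial-passage simulation.

The in-silico analogue of the microbiological compatibility assay: cells
carry integer copy counts of each origin; between divisions copy numbers
relax deterministically under the Lotka-Volterra dynamics; at division each
plasmid assorts independently (Binomial(n, 1/2) per origin per daughter);
antibiotic selection removes cells that have lost a selected origin; serial
passaging repeatedly dilutes the culture 1:100 and regrows it.

For an origin held at n copies, the chance that a single division strands
one daughter without it is exactly 2^(1-n) — stochastic segregation alone
makes high-copy origins essentially stable and low-copy origins fragile,
which is what gives compatibility its copy-number-dependent directionality.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .lv import LVParams, integrate_copy_numbers, simulate

__all__ = [
    "Population",
    "PassagingProtocol",
    "RetentionCurve",
    "divide",
    "divide_population",
    "replicate",
    "stochastic_round",
    "grow_generation",
    "serial_passage",
    "initial_population",
    "loss_probability_exact",
]


@dataclass
class Population:
    """A multiset of cells: an (n_cells, n_origins) integer copy matrix."""

    copies: NDArray[np.int64]

    def __post_init__(self):
        arr = np.atleast_2d(np.asarray(self.copies))
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("copy counts must be integers")
            arr = arr.astype(np.int64)
        if np.any(arr < 0):
            raise ValueError("copy counts must be non-negative")
        self.copies = arr.astype(np.int64)

    @property
    def n_cells(self) -> int:
        return self.copies.shape[0]

    @property
    def n_origins(self) -> int:
        return self.copies.shape[1]

    def retention_fractions(self) -> NDArray[np.float64]:
        """Per-origin fraction of cells carrying >= 1 copy."""
        if self.n_cells == 0:
            return np.zeros(self.n_origins)
        return (self.copies > 0).mean(axis=0)

    def fraction_all_retained(self) -> float:
        if self.n_cells == 0:
            return 0.0
        return float(np.all(self.copies > 0, axis=1).mean())


@dataclass(frozen=True)
class PassagingProtocol:
    """Serial-passaging schedule.

    dilution_factor -- 1:dilution inoculum into fresh medium (default 100,
        i.e. 1% v/v)
    passages -- number of 24 h dilution-regrowth cycles
    generations_per_passage -- doublings per cycle; defaults to
        log2(dilution_factor) (the culture must regrow the dilution)
    selection -- origin indices whose loss is lethal (antibiotic markers)
    population_cap -- maximum simulated cells; uniform subsampling beyond
    """

    dilution_factor: int = 100
    passages: int = 4
    generations_per_passage: float | None = None
    selection: FrozenSet[int] = frozenset()
    population_cap: int = 10_000

    def __post_init__(self):
        if self.dilution_factor <= 1:
            raise ValueError("dilution_factor must be > 1")
        if self.generations_per_passage is None:
            object.__setattr__(
                self, "generations_per_passage", math.log2(self.dilution_factor)
            )
        if self.generations_per_passage <= 0:
            raise ValueError("generations_per_passage must be positive")
        object.__setattr__(self, "selection", frozenset(self.selection))

    @property
    def rounds_per_passage(self) -> int:
        """Integer growth-division rounds per passage (rounded doublings)."""
        return max(1, round(self.generations_per_passage))


@dataclass
class RetentionCurve:
    """Per-passage plasmid retention, including the t=0 point.

    fractions[p, i] is the fraction of live cells carrying origin i at the
    end of passage p; all_retained[p] the fraction carrying every origin.
    ``extinct`` flags a population wiped out by selection (curve truncated).
    """

    passage: NDArray[np.int64]
    fractions: NDArray[np.float64]
    all_retained: NDArray[np.float64]
    origin_ids: tuple[str, ...] = ()
    extinct: bool = False
    final_population: Population | None = None

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (passage, origin_id, fraction) + 'all' rows."""
        ids = self.origin_ids or tuple(
            f"ori{i}" for i in range(self.fractions.shape[1])
        )
        rows = []
        for p, fr, fa in zip(self.passage, self.fractions, self.all_retained):
            for oid, f in zip(ids, fr):
                rows.append({"passage": int(p), "origin_id": oid, "fraction": float(f)})
            rows.append({"passage": int(p), "origin_id": "all", "fraction": float(fa)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# elementary events

def divide(
    cell: Sequence[int] | NDArray, rng: np.random.Generator
) -> tuple[NDArray[np.int64], NDArray[np.int64]]:
    """Split one cell's plasmids between two daughters.

    Each origin assorts independently: daughter 1 receives
    Binomial(n_i, 1/2) copies, daughter 2 the remainder.  Totals conserved.
    """
    copies = np.asarray(cell, dtype=np.int64)
    d1 = rng.binomial(copies, 0.5)
    return d1.astype(np.int64), (copies - d1).astype(np.int64)


def divide_population(
    pop: Population, rng: np.random.Generator
) -> Population:
    """Divide every cell; returns the 2x-sized daughter population."""
    d1 = rng.binomial(pop.copies, 0.5).astype(np.int64)
    d2 = pop.copies - d1
    return Population(np.vstack([d1, d2]))


def stochastic_round(
    X: NDArray[np.float64], rng: np.random.Generator
) -> NDArray[np.int64]:
    """floor + Bernoulli(fractional part): integer-valued, unbiased."""
    lo = np.floor(X)
    frac = X - lo
    return (lo + (rng.random(X.shape) < frac)).astype(np.int64)


def replicate(
    cell: Sequence[int] | NDArray,
    params: LVParams,
    duration: float,
    rng: np.random.Generator,
    exact: bool = False,
) -> NDArray[np.int64]:
    """Intracellular replication for ``duration`` generations.

    Integrates the LV dynamics from the cell's counts, then stochastically
    rounds back to integers.  Origins at zero stay zero (no spontaneous
    gain).  ``exact=True`` routes through the adaptive integrator instead
    of the fixed-step population path.
    """
    if duration < 0:
        raise ValueError("duration must be >= 0")
    copies = np.asarray(cell, dtype=float)
    if duration == 0:
        return copies.astype(np.int64)
    if exact:
        X = simulate(params, copies, duration).x[-1]
    else:
        X = integrate_copy_numbers(copies[None, :], params, duration)[0]
    X = np.where(copies == 0, 0.0, X)
    return stochastic_round(X, rng)


def grow_generation(
    pop: Population,
    params: LVParams,
    selection: FrozenSet[int] | Sequence[int],
    rng: np.random.Generator,
    population_cap: int = 10_000,
) -> Population:
    """One generation: replicate, divide, select, cap.

    Every cell replicates for one generation under the LV dynamics (with
    stochastic rounding), then divides binomially; daughters missing any
    selected origin are killed (instant antibiotic action at the generation
    boundary); the survivors are uniformly subsampled to ``population_cap``
    when they exceed it.
    """
    if pop.n_cells == 0:
        return pop
    X = pop.copies.astype(float)
    X = integrate_copy_numbers(X, params, 1.0)
    X[pop.copies == 0] = 0.0
    counts = stochastic_round(X, rng)
    daughters = divide_population(Population(counts), rng)
    sel = sorted(selection)
    if sel:
        keep = np.all(daughters.copies[:, sel] > 0, axis=1)
        daughters = Population(daughters.copies[keep])
    if daughters.n_cells > population_cap:
        idx = rng.choice(daughters.n_cells, size=population_cap, replace=False)
        daughters = Population(daughters.copies[idx])
    return daughters


# ---------------------------------------------------------------------------
# serial passaging

def serial_passage(
    initial: Population,
    protocol: PassagingProtocol,
    params: LVParams,
    rng: np.random.Generator,
) -> RetentionCurve:
    """Run the serial-passage compatibility assay.

    Per passage: subsample 1/dilution_factor of cells (at least one), run
    ``rounds_per_passage`` growth-division-selection generations, record
    per-origin retention among live cells.  The curve includes t=0 (after
    the initial selection plating) and one point per passage.  If selection
    wipes the population out, the curve is truncated and flagged extinct.
    """
    if initial.n_cells == 0:
        raise ValueError("initial population must be non-empty")
    if not protocol.selection <= set(range(initial.n_origins)):
        raise ValueError("selection indices out of range")

    pop = initial
    sel = sorted(protocol.selection)
    if sel:
        keep = np.all(pop.copies[:, sel] > 0, axis=1)
        pop = Population(pop.copies[keep])

    passages = [0]
    fracs = [pop.retention_fractions()]
    alls = [pop.fraction_all_retained()]
    extinct = pop.n_cells == 0

    for p in range(1, protocol.passages + 1):
        if extinct:
            break
        n_inoc = max(1, pop.n_cells // protocol.dilution_factor)
        idx = rng.choice(pop.n_cells, size=n_inoc, replace=False)
        pop = Population(pop.copies[idx])
        for _ in range(protocol.rounds_per_passage):
            pop = grow_generation(
                pop, params, protocol.selection, rng, protocol.population_cap
            )
            if pop.n_cells == 0:
                extinct = True
                break
        if extinct:
            break
        passages.append(p)
        fracs.append(pop.retention_fractions())
        alls.append(pop.fraction_all_retained())

    return RetentionCurve(
        passage=np.asarray(passages, dtype=np.int64),
        fractions=np.vstack(fracs),
        all_retained=np.asarray(alls),
        origin_ids=params.origin_ids,
        extinct=extinct,
        final_population=pop,
    )


def initial_population(
    n_cells: int, K: Sequence[float], rng: np.random.Generator
) -> Population:
    """Co-transformed starting culture: Poisson-around-K copies, min 1.

    Every cell carries every origin (a freshly double-selected colony).
    """
    K = np.asarray(K, dtype=float)
    copies = rng.poisson(K, size=(n_cells, K.size))
    return Population(np.maximum(copies, 1))


# ---------------------------------------------------------------------------
# closed forms

def loss_probability_exact(n: int) -> float:
    """P(at least one daughter of a division holds 0 copies | parent has n).

    Each daughter misses out with probability 2^-n; the two events are
    mutually exclusive for n >= 1 (both daughters empty is impossible),
    giving exactly 2^(1-n).  For n = 0 the origin is already lost (1.0).
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return 1.0
    return 2.0 ** (1 - n)
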