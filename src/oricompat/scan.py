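"""Interaction-parameter-space exploration.

Pairwise compatibility calls constrain, but do not pin down, the LV
cross-inhibition coefficients.  This module grids the non-positive
interaction space to (a) find the feasible region consistent with an
observed compatibility pattern, (b) search for three-origin parameter sets
where every pairwise subsystem coexists yet the triple loses an origin —
the model-level demonstration that pairwise cross-compatibility does not
predict higher-order inter-compatibility — and (c) fit interaction
coefficients to retention curves by grid least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .lv import (
    LVParams,
    classify_outcome,
    from_copy_numbers,
    integrate_copy_numbers,
    interior_equilibrium,
    jacobian,
    pairwise_closed_form,
)
from .segregation import PassagingProtocol, initial_population, serial_passage

__all__ = [
    "CompatPattern",
    "FeasibleRegion",
    "default_grid",
    "ordered_pair_calls",
    "pattern_from_interactions",
    "scan_interactions",
    "find_higher_order_counterexample",
    "simulate_candidate_curves",
    "fit_loss_curves",
    "FitResult",
]


@dataclass(frozen=True)
class CompatPattern:
    """Observed compatibility calls over a complete ordered-pair grid.

    ``pairwise[(i, j)]`` is the call with origin i on the reporter
    (selected) plasmid and origin j on the regulatory one:
    "compatible" (j retained) or "incompatible" (j lost).  ``triples``
    optionally maps an origin triple to the frozenset of indices stably
    retained when all three share a cell.
    """

    n: int
    pairwise: Mapping[tuple[int, int], str]
    triples: Mapping[tuple[int, ...], frozenset[int]] = field(default_factory=dict)

    def __post_init__(self):
        expected = {(i, j) for i in range(self.n) for j in range(self.n) if i != j}
        if set(self.pairwise) != expected:
            raise ValueError("pairwise calls must cover every ordered pair")
        bad = {v for v in self.pairwise.values()} - {"compatible", "incompatible"}
        if bad:
            raise ValueError(f"unknown calls: {bad}")


@dataclass
class FeasibleRegion:
    """Grid points consistent with a compatibility pattern."""

    points: list[NDArray[np.float64]]
    grid: NDArray[np.float64]
    mode: str

    def __len__(self) -> int:
        return len(self.points)

    def contains(self, interaction: NDArray[np.float64], atol: float = 1e-12) -> bool:
        return any(np.allclose(p, interaction, atol=atol) for p in self.points)

    def to_frame(self) -> pd.DataFrame:
        if not self.points:
            return pd.DataFrame()
        n = self.points[0].shape[0]
        cols = [f"c{i}{j}" for i in range(n) for j in range(n) if i != j]
        rows = [
            [p[i, j] for i in range(n) for j in range(n) if i != j]
            for p in self.points
        ]
        return pd.DataFrame(rows, columns=cols)


def default_grid(K: Sequence[float], steps: int = 21) -> NDArray[np.float64]:
    """Interaction values spanning [-2/K_min, 0].

    Zero is maximum compatibility; the exclusion boundary for equal-K pairs
    sits at -1/K, so the grid reaches twice past it.
    """
    K = np.asarray(K, dtype=float)
    return np.linspace(-2.0 / K.min(), 0.0, steps)


# ---------------------------------------------------------------------------
# pattern evaluation

def ordered_pair_calls(
    K_i: float, K_j: float, c_ij: float, c_ji: float
) -> tuple[str, str]:
    """Analytic calls for the ordered pairs (i, j) and (j, i).

    Mapping from the two-origin LV outcome to assay calls under
    reporter-side selection: coexistence -> both compatible; exclusion of
    the unselected origin -> that direction incompatible while the reverse
    (where the winner is unselected) stays compatible; bistable or
    degenerate -> incompatible both ways (the selected origin always wins,
    the other is lost).
    """
    params = from_copy_numbers([K_i, K_j], [[0.0, c_ij], [c_ji, 0.0]])
    label = pairwise_closed_form(params)
    if label == "coexistence":
        return ("compatible", "compatible")
    if label == "exclusion_of_1":  # origin j lost
        return ("incompatible", "compatible")
    if label == "exclusion_of_0":  # origin i lost
        return ("compatible", "incompatible")
    return ("incompatible", "incompatible")  # bistable / degenerate


def pattern_from_interactions(
    K: Sequence[float], interaction: NDArray[np.float64]
) -> CompatPattern:
    """The compatibility pattern a known interaction matrix generates
    (analytic route) — used to pose round-trip recovery problems."""
    K = np.asarray(K, dtype=float)
    n = K.size
    calls: dict[tuple[int, int], str] = {}
    for i, j in combinations(range(n), 2):
        cij, cji = ordered_pair_calls(K[i], K[j], interaction[i, j], interaction[j, i])
        calls[(i, j)] = cij
        calls[(j, i)] = cji
    return CompatPattern(n=n, pairwise=calls)


def _simulated_pair_call(
    K_i: float, K_j: float, c_ij: float, c_ji: float,
    protocol: PassagingProtocol, seed: int, n_cells: int, threshold: float,
) -> str:
    params = from_copy_numbers([K_i, K_j], [[0.0, c_ij], [c_ji, 0.0]])
    rng = np.random.default_rng(seed)
    pop0 = initial_population(n_cells, params.K, rng)
    curve = serial_passage(pop0, protocol, params, rng)
    ret = float(curve.fractions[-1, 1])
    return "compatible" if ret >= threshold else "incompatible"


def scan_interactions(
    K: Sequence[float],
    pattern: CompatPattern,
    grid: NDArray[np.float64] | None = None,
    mode: str = "analytic",
    protocol: PassagingProtocol | None = None,
    seed: int = 0,
    n_cells: int = 300,
    threshold: float = 0.5,
) -> FeasibleRegion:
    """All interaction matrices on the grid reproducing ``pattern``.

    ``grid`` is the 1-D array of candidate values applied to every
    off-diagonal axis (cartesian product).  Analytic mode uses the n=2
    closed-form outcome criteria per pair; simulation mode replays the
    serial-passage assay per ordered pair with a fixed seed, so the region
    is deterministic given the seed.
    """
    K = np.asarray(K, dtype=float)
    n = K.size
    if grid is None:
        grid = default_grid(K)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must not be empty")
    if np.any(grid > 0):
        raise ValueError("interaction grid values must be <= 0")
    if protocol is None:
        protocol = PassagingProtocol(selection=frozenset({0}), passages=3)

    axes = [(i, j) for i in range(n) for j in range(n) if i != j]
    feasible: list[NDArray[np.float64]] = []
    for values in product(grid, repeat=len(axes)):
        C = np.zeros((n, n))
        for (i, j), v in zip(axes, values):
            C[i, j] = v
        ok = True
        for i, j in combinations(range(n), 2):
            if mode == "analytic":
                call_ij, call_ji = ordered_pair_calls(K[i], K[j], C[i, j], C[j, i])
            elif mode == "simulation":
                call_ij = _simulated_pair_call(
                    K[i], K[j], C[i, j], C[j, i], protocol, seed, n_cells, threshold
                )
                call_ji = _simulated_pair_call(
                    K[j], K[i], C[j, i], C[i, j], protocol, seed, n_cells, threshold
                )
            else:
                raise ValueError(f"unknown mode {mode!r}")
            if pattern.pairwise[(i, j)] != call_ij or pattern.pairwise[(j, i)] != call_ji:
                ok = False
                break
        if ok and pattern.triples:
            for triple, retained in pattern.triples.items():
                idx = list(triple)
                sub = from_copy_numbers(K[idx], C[np.ix_(idx, idx)])
                outcome = classify_outcome(sub, np.random.default_rng(seed))
                kept = frozenset(
                    triple[k] for k in range(3)
                    if k not in outcome.excluded
                ) if outcome.label == "exclusion" else (
                    frozenset(triple) if outcome.label == "coexistence" else frozenset()
                )
                if kept != retained:
                    ok = False
                    break
        if ok:
            feasible.append(C)
    return FeasibleRegion(points=feasible, grid=grid, mode=mode)


# ---------------------------------------------------------------------------
# higher-order counterexample

def find_higher_order_counterexample(
    K: Sequence[float],
    grid: NDArray[np.float64] | None = None,
    seed: int = 0,
    n_starts: int = 10,
    t_end: float = 200.0,
    loss_frac: float = 1e-3,
) -> dict | None:
    """First 3-origin interaction matrix where every pairwise subsystem
    coexists but the triple loses at least one origin.

    Scans the cartesian grid in a fixed (deterministic) axis order
    (c01, c02, c10, c12, c20, c21).  A candidate passes the analytic
    pairwise-coexistence prefilter, then must lose an origin (below
    ``loss_frac`` of its K) in *every* long-run integration from
    ``n_starts`` randomized interior starts.  Returns a dict with the
    witness matrix, the per-start surviving sets and the pairwise labels,
    or None when the grid holds no witness at this resolution.
    """
    K = np.asarray(K, dtype=float)
    if K.size != 3:
        raise ValueError("counterexample search is defined for 3 origins")
    if grid is None:
        grid = np.linspace(-2.0 / K.min(), 0.0, 6)
    grid = np.asarray(grid, dtype=float)

    # axis order (c01, c02, c10, c12, c20, c21); meshgrid in 'ij' indexing
    # flattened C-style reproduces itertools.product's deterministic order.
    axes = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    mesh = np.meshgrid(*([grid] * 6), indexing="ij")
    V = np.stack([m.ravel() for m in mesh], axis=1)  # (grid**6, 6)
    a = 1.0 / K
    col = {pair: k for k, pair in enumerate(axes)}
    # closed-form pairwise coexistence: positive interior + det > 0
    mask = np.ones(V.shape[0], dtype=bool)
    for i, j in combinations(range(3), 2):
        cij, cji = V[:, col[(i, j)]], V[:, col[(j, i)]]
        det = a[i] * a[j] - cij * cji
        mask &= (det > 0) & (a[j] + cij > 0) & (a[i] + cji > 0)

    for flat_idx in np.flatnonzero(mask):
        C = np.zeros((3, 3))
        for (i, j), v in zip(axes, V[flat_idx]):
            C[i, j] = v
        params = from_copy_numbers(K, C)
        interior = interior_equilibrium(params)
        if interior is not None:
            eig_real = np.linalg.eigvals(jacobian(interior, params)).real
            if np.all(eig_real < -1e-9):
                continue  # stable triple coexistence: not a counterexample
        # verify by direct simulation from randomized interior starts
        rng = np.random.default_rng(seed)
        survivor_sets = []
        for _ in range(n_starts):
            x0 = K * rng.uniform(0.2, 1.5, size=3)
            X = integrate_copy_numbers(x0[None, :], params, t_end, dt=0.05)[0]
            survivor_sets.append(frozenset(np.flatnonzero(X > loss_frac * K)))
        if all(len(s) < 3 for s in survivor_sets):
            return {
                "interaction": C,
                "K": K,
                "survivor_sets": survivor_sets,
                "interior": interior,
            }
    return None


# ---------------------------------------------------------------------------
# curve fitting

@dataclass(frozen=True)
class FitResult:
    interaction: NDArray[np.float64]
    objective: float


def simulate_candidate_curves(
    K: Sequence[float],
    grid: NDArray[np.float64],
    protocols: Sequence[PassagingProtocol],
    seed: int = 0,
    n_cells: int = 200,
) -> dict[tuple[float, float], list[NDArray[np.float64]]]:
    """Retention curves for every (c01, c10) candidate under each protocol.

    Every candidate is simulated with the same seed, so differences between
    candidates reflect parameters, not sampling noise.  The cache can be
    passed to `fit_loss_curves` to amortise repeated fits against different
    observed data (e.g. noise-replicate studies).
    """
    K = np.asarray(K, dtype=float)
    if K.size != 2:
        raise ValueError("curve fitting is defined for 2-origin systems")
    cache: dict[tuple[float, float], list[NDArray[np.float64]]] = {}
    for c01 in grid:
        for c10 in grid:
            params = from_copy_numbers(K, [[0.0, c01], [c10, 0.0]])
            curves = []
            for prot in protocols:
                rng = np.random.default_rng(seed)
                pop0 = initial_population(n_cells, K, rng)
                curve = serial_passage(pop0, prot, params, rng)
                curves.append(curve.fractions.copy())
            cache[(float(c01), float(c10))] = curves
    return cache


def fit_loss_curves(
    observed: Sequence[NDArray[np.float64]],
    K: Sequence[float],
    grid: NDArray[np.float64],
    protocols: Sequence[PassagingProtocol],
    seed: int = 0,
    n_cells: int = 200,
    candidates: dict[tuple[float, float], list[NDArray[np.float64]]] | None = None,
) -> FitResult:
    """Grid least squares of simulated against observed retention curves.

    ``observed`` holds one fractions array (passages+1, 2) per protocol
    (e.g. the two selection arrangements of an ordered pair).  Candidates
    are compared under a common seed; ties in the objective break toward
    the weaker (closer-to-zero) interaction, the conservative choice when
    the data cannot tell interference strengths apart.
    """
    if candidates is None:
        candidates = simulate_candidate_curves(K, grid, protocols, seed, n_cells)
    best: FitResult | None = None
    order = sorted(candidates, key=lambda c: (abs(c[0]) + abs(c[1]), c))
    for key in order:
        sims = candidates[key]
        obj = 0.0
        for obs, sim in zip(observed, sims):
            m = min(obs.shape[0], sim.shape[0])
            obj += float(np.sum((obs[:m] - sim[:m]) ** 2))
            # truncated (extinct) candidate curves pay for missing points
            if sim.shape[0] < obs.shape[0]:
                obj += float(np.sum(obs[sim.shape[0]:] ** 2))
        if best is None or obj < best.objective - 1e-15:
            C = np.array([[0.0, key[0]], [key[1], 0.0]])
            best = FitResult(interaction=C, objective=obj)
    assert best is not None
    return best
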