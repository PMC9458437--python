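"""Competitive Lotka-Volterra model of intracellular plasmid copy number.

Two (or more) ColE1-type origins replicating in the same cell compete for
replication initiation: each origin's RNAI inhibits priming from any RNAII
it can pair with.  The model treats the copy number of origin *i*, X_i, as
a population with logistic self-limitation and non-positive cross terms:

    dX_i/dt = r_i * X_i * (1 - a_i * X_i + sum_{j != i} c_ij * X_j)

with a_i = 1/K_i the reciprocal of the expected copy number (carrying
capacity) and c_ij <= 0 the phenomenological cross-inhibition of origin i
by origin j.  c = 0 is maximum compatibility; increasingly negative c
drives competitive exclusion.  Interactions need not be symmetric — the
RNAI_A/RNAII_B duplex has no thermodynamic obligation to match
RNAI_B/RNAII_A — and directional compatibility follows from that asymmetry.

Time is measured in host generations; the default replication rate r = 5
per generation makes copy number re-equilibrate well within a cell cycle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml
from numpy.typing import ArrayLike, NDArray
from scipy.integrate import solve_ivp

__all__ = [
    "LVParams",
    "LVOutcome",
    "Trajectory",
    "from_copy_numbers",
    "derivatives",
    "jacobian",
    "simulate",
    "integrate_copy_numbers",
    "interior_equilibrium",
    "classify_outcome",
    "pairwise_closed_form",
    "save_params",
    "load_params",
]

#: Eigenvalue real parts inside (-MARGINAL_TOL, MARGINAL_TOL) are treated as
#: marginal and resolved by simulation.
MARGINAL_TOL = 1e-9


@dataclass(frozen=True)
class LVParams:
    """Parameters of the competitive LV system.

    r        -- per-origin intrinsic replication rates (per generation, > 0)
    self_lim -- 1/K_i, reciprocal expected copy numbers (> 0)
    interaction -- n x n cross-inhibition matrix, zero diagonal,
                   off-diagonal entries <= 0
    """

    r: NDArray[np.float64]
    self_lim: NDArray[np.float64]
    interaction: NDArray[np.float64]
    origin_ids: tuple[str, ...] = ()

    def __post_init__(self):
        r = np.atleast_1d(np.asarray(self.r, dtype=float))
        a = np.atleast_1d(np.asarray(self.self_lim, dtype=float))
        c = np.atleast_2d(np.asarray(self.interaction, dtype=float))
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "self_lim", a)
        object.__setattr__(self, "interaction", c)
        n = r.size
        if a.size != n or c.shape != (n, n):
            raise ValueError("inconsistent parameter dimensions")
        if not (np.all(np.isfinite(r)) and np.all(np.isfinite(a)) and np.all(np.isfinite(c))):
            raise ValueError("parameters must be finite")
        if not np.all(r > 0):
            raise ValueError("replication rates r must be positive")
        if not np.all(a > 0):
            raise ValueError("self-limitation terms must be positive")
        if np.any(np.diag(c) != 0):
            raise ValueError("interaction diagonal must be exactly zero")
        off = c[~np.eye(n, dtype=bool)]
        if np.any(off > 0):
            raise ValueError(
                "off-diagonal interactions must be <= 0 "
                "(zero = maximum compatibility, negative = interference)"
            )
        if not self.origin_ids:
            object.__setattr__(
                self, "origin_ids", tuple(f"ori{i}" for i in range(n))
            )
        elif len(self.origin_ids) != n:
            raise ValueError("origin_ids length mismatch")

    @property
    def n(self) -> int:
        return self.r.size

    @property
    def K(self) -> NDArray[np.float64]:
        """Expected copy numbers (carrying capacities)."""
        return 1.0 / self.self_lim

    def subsystem(self, idx: Sequence[int]) -> "LVParams":
        """Restriction of the system to a subset of origins."""
        idx = list(idx)
        return LVParams(
            r=self.r[idx],
            self_lim=self.self_lim[idx],
            interaction=self.interaction[np.ix_(idx, idx)],
            origin_ids=tuple(self.origin_ids[i] for i in idx),
        )


@dataclass(frozen=True)
class LVOutcome:
    """Long-run verdict of the competition.

    label -- "coexistence", "exclusion", "bistable" or "degenerate"
    excluded -- origin indices lost (exclusion only)
    interior_state -- the all-positive interior equilibrium when it exists
    """

    label: str
    excluded: tuple[int, ...] = ()
    interior_state: NDArray[np.float64] | None = None


@dataclass(frozen=True)
class Trajectory:
    t: NDArray[np.float64]
    x: NDArray[np.float64]  # shape (len(t), n)

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.x, columns=[f"X{i + 1}" for i in range(self.x.shape[1])])
        df.insert(0, "t", self.t)
        return df


# ---------------------------------------------------------------------------
# construction

def from_copy_numbers(
    K: ArrayLike,
    interaction: ArrayLike | None = None,
    r: ArrayLike | float = 5.0,
    origin_ids: Sequence[str] = (),
) -> LVParams:
    """Parameterise the system from expected copy numbers.

    self_lim_i = 1/K_i; interaction defaults to all-zero (maximum
    compatibility); r defaults to 5 per generation for every origin.
    """
    K = np.atleast_1d(np.asarray(K, dtype=float))
    if not np.all(K > 0):
        raise ValueError("copy numbers K must be positive")
    n = K.size
    if interaction is None:
        interaction = np.zeros((n, n))
    r_vec = np.full(n, float(r)) if np.isscalar(r) else np.asarray(r, dtype=float)
    return LVParams(
        r=r_vec, self_lim=1.0 / K, interaction=np.asarray(interaction, dtype=float),
        origin_ids=tuple(origin_ids),
    )


# ---------------------------------------------------------------------------
# vector field

def derivatives(state: ArrayLike, params: LVParams) -> NDArray[np.float64]:
    """dX/dt at a non-negative state."""
    x = np.atleast_1d(np.asarray(state, dtype=float))
    if np.any(x < 0):
        raise ValueError("state must be non-negative")
    growth = 1.0 - params.self_lim * x + params.interaction @ x
    return params.r * x * growth


def jacobian(state: ArrayLike, params: LVParams) -> NDArray[np.float64]:
    """Jacobian of the vector field at a state."""
    x = np.atleast_1d(np.asarray(state, dtype=float))
    a, c, r = params.self_lim, params.interaction, params.r
    growth = 1.0 - a * x + c @ x
    J = (r * x)[:, None] * c
    np.fill_diagonal(J, r * (growth - a * x))
    return J


# ---------------------------------------------------------------------------
# integration

def simulate(
    params: LVParams,
    x0: ArrayLike,
    t_end: float,
    n_points: int = 200,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> Trajectory:
    """Adaptive integration of the LV system over [0, t_end].

    Components are clamped at zero through event detection: when a
    coordinate decays through a small positive floor the integration stops,
    the coordinate is set to 0 (extinction is absorbing) and integration
    resumes — the integrator's error control never sees a truncation jump.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    if np.any(x < 0):
        raise ValueError("x0 must be non-negative")
    if x.size != params.n:
        raise ValueError("x0 dimension mismatch")

    floor = 1e-12

    def rhs(t, y):
        return derivatives(np.maximum(y, 0.0), params)

    def make_event(i):
        def ev(t, y):
            return y[i] - floor
        ev.terminal = True
        ev.direction = -1
        return ev

    t_grid = np.linspace(0.0, float(t_end), n_points)
    ts = [0.0]
    xs = [x.copy()]
    t0 = 0.0
    alive = x > floor
    while t0 < t_end:
        events = [make_event(i) for i in range(params.n) if alive[i]]
        wanted = t_grid[(t_grid > t0) & (t_grid <= t_end)]
        sol = solve_ivp(
            rhs, (t0, t_end), x, method="RK45", rtol=rtol, atol=atol,
            t_eval=wanted if wanted.size else None, events=events or None,
        )
        if not sol.success:
            raise RuntimeError(f"integration failed: {sol.message}")
        for tk, yk in zip(sol.t, sol.y.T):
            if tk > ts[-1]:
                ts.append(float(tk))
                xs.append(np.maximum(yk, 0.0))
        if sol.status == 1:  # extinction event
            t0 = float(sol.t[-1]) if sol.t.size else t0
            t_ev = min(float(te[0]) for te in sol.t_events if te.size)
            y_ev = next(ye[0] for ye in sol.y_events if ye.size)
            x = np.maximum(np.asarray(y_ev, dtype=float), 0.0)
            x[x <= floor] = 0.0
            alive = x > floor
            t0 = t_ev
        else:
            break
    return Trajectory(t=np.asarray(ts), x=np.vstack(xs))


def integrate_copy_numbers(
    X: NDArray[np.float64], params: LVParams, duration: float, dt: float = 0.05
) -> NDArray[np.float64]:
    """Fixed-step RK4 of the LV system for a whole population at once.

    ``X`` has shape (n_cells, n_origins); every row is integrated under the
    same parameters for ``duration`` generations.  Rows at zero stay zero
    (the vector field vanishes there) and states are clamped non-negative
    after each step.  This is the performance path used by the segregation
    simulator; `simulate` is the high-accuracy single-cell path.
    """
    X = np.asarray(X, dtype=float).copy()
    if duration <= 0:
        return X
    a, c, r = params.self_lim, params.interaction, params.r

    def f(Y):
        return r * Y * (1.0 - Y * a + Y @ c.T)

    n_steps = max(1, int(np.ceil(duration / dt)))
    h = duration / n_steps
    for _ in range(n_steps):
        k1 = f(X)
        k2 = f(np.maximum(X + 0.5 * h * k1, 0.0))
        k3 = f(np.maximum(X + 0.5 * h * k2, 0.0))
        k4 = f(np.maximum(X + h * k3, 0.0))
        X = np.maximum(X + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)
    return X


# ---------------------------------------------------------------------------
# equilibria and classification

def interior_equilibrium(params: LVParams) -> NDArray[np.float64] | None:
    """The all-positive interior equilibrium, or None.

    Solves ``(diag(self_lim) - interaction) X = 1``.  Returns the solution
    iff every component is strictly positive; a singular system (degenerate,
    e.g. a duplicated origin sharing one copy-number pool) returns None.
    """
    A = np.diag(params.self_lim) - params.interaction
    try:
        x = np.linalg.solve(A, np.ones(params.n))
    except np.linalg.LinAlgError:
        return None
    if np.linalg.cond(A) > 1e12:
        return None
    return x if np.all(x > 0) else None


def _boundary_equilibria(params: LVParams) -> list[tuple[tuple[int, ...], NDArray[np.float64]]]:
    """Feasible equilibria on every proper face (subset of origins present)."""
    from itertools import combinations

    n = params.n
    out: list[tuple[tuple[int, ...], NDArray[np.float64]]] = []
    for k in range(1, n):
        for subset in combinations(range(n), k):
            sub = params.subsystem(subset)
            A = np.diag(sub.self_lim) - sub.interaction
            try:
                xs = np.linalg.solve(A, np.ones(k))
            except np.linalg.LinAlgError:
                continue
            if np.linalg.cond(A) > 1e12 or not np.all(xs > 0):
                continue
            full = np.zeros(n)
            full[list(subset)] = xs
            out.append((subset, full))
    return out


def _survivors_by_integration(
    params: LVParams,
    rng: np.random.Generator,
    n_starts: int = 10,
    t_end: float = 200.0,
    loss_frac: float = 1e-3,
) -> list[frozenset[int]]:
    """Surviving origin sets from randomized interior starts.

    An origin is lost when it ends below ``loss_frac`` of its K.
    """
    K = params.K
    x0 = K[None, :] * rng.uniform(0.2, 1.5, size=(n_starts, params.n))
    X = integrate_copy_numbers(x0, params, t_end, dt=0.05)
    return [frozenset(np.flatnonzero(row > loss_frac * K)) for row in X]


def classify_outcome(
    params: LVParams, rng: np.random.Generator | None = None
) -> LVOutcome:
    """Classify the long-run outcome of the competition.

    Interior equilibrium present and linearly stable (all Jacobian
    eigenvalues with real part < -1e-9) -> coexistence.  Interior present
    but unstable -> bistable for n=2 (planar competitive LV: an unstable
    interior is a saddle between two stable boundary states); for n >= 3
    the verdict comes from long-run integration from randomized interior
    starts.  No interior -> exclusion, the excluded set read off the stable
    boundary equilibrium (integration breaks ambiguity).  Eigenvalues inside
    the marginal band are resolved by simulation.  A singular interior
    system (duplicated origin) is "degenerate".
    """
    if rng is None:
        rng = np.random.default_rng(0)
    n = params.n

    A = np.diag(params.self_lim) - params.interaction
    if np.linalg.cond(A) > 1e12:
        return LVOutcome(label="degenerate")

    interior = interior_equilibrium(params)
    if interior is not None:
        eig_real = np.linalg.eigvals(jacobian(interior, params)).real
        if np.all(eig_real < -MARGINAL_TOL):
            return LVOutcome(label="coexistence", interior_state=interior)
        if np.any(eig_real > MARGINAL_TOL):
            if n == 2:
                return LVOutcome(label="bistable", interior_state=interior)
            survivor_sets = _survivors_by_integration(params, rng)
            if len(set(survivor_sets)) > 1:
                return LVOutcome(label="bistable", interior_state=interior)
            lost = tuple(sorted(set(range(n)) - survivor_sets[0]))
            if not lost:
                return LVOutcome(label="coexistence", interior_state=interior)
            return LVOutcome(label="exclusion", excluded=lost, interior_state=interior)
        # marginal: fall through to boundary analysis / simulation

    # no (clean) interior: read the survivors off the stable boundary
    # equilibria — eigenvalues resolve even very slow exclusions that a
    # finite integration horizon would miss
    stable_subsets = []
    marginal = False
    for subset, x_eq in _boundary_equilibria(params):
        eig_real = np.linalg.eigvals(jacobian(x_eq, params)).real
        if np.all(eig_real < -MARGINAL_TOL):
            stable_subsets.append(subset)
        elif not np.any(eig_real > MARGINAL_TOL):
            marginal = True
    if interior is None and not marginal:
        if len(stable_subsets) == 1:
            lost = tuple(sorted(set(range(n)) - set(stable_subsets[0])))
            return LVOutcome(label="exclusion", excluded=lost)
        if len(stable_subsets) > 1:
            return LVOutcome(label="bistable")

    survivor_sets = _survivors_by_integration(params, rng)
    if len(set(survivor_sets)) > 1:
        return LVOutcome(label="bistable", interior_state=interior)
    survivors = survivor_sets[0]
    lost = tuple(sorted(set(range(n)) - survivors))
    if not lost:
        return LVOutcome(label="coexistence", interior_state=interior)
    return LVOutcome(label="exclusion", excluded=lost, interior_state=interior)


def pairwise_closed_form(params: LVParams) -> str:
    """Closed-form n=2 outcome criteria (analytic route, no eigenvalues).

    With a_i = self_lim and c_ij = interaction, the interior equilibrium is

        X1* = (a2 + c12) / (a1*a2 - c12*c21),
        X2* = (a1 + c21) / (a1*a2 - c12*c21).

    Both positive and a1*a2 > c12*c21  -> stable coexistence.
    Both positive and a1*a2 < c12*c21  -> bistable (saddle interior).
    Otherwise exclusion: the origin whose boundary state resists invasion
    survives.  Returns "coexistence", "bistable", "exclusion_of_0",
    "exclusion_of_1" or "degenerate".
    """
    if params.n != 2:
        raise ValueError("closed form applies to n=2 only")
    a1, a2 = params.self_lim
    c12, c21 = params.interaction[0, 1], params.interaction[1, 0]
    det = a1 * a2 - c12 * c21
    if abs(det) < 1e-15 * max(a1 * a2, abs(c12 * c21), 1e-30):
        return "degenerate"
    x1 = (a2 + c12) / det
    x2 = (a1 + c21) / det
    if x1 > 0 and x2 > 0:
        return "coexistence" if det > 0 else "bistable"
    # invasion rates: origin j invades boundary-i (X_i = K_i) at rate
    # r_j (1 + c_ji K_i); a negative rate means boundary-i repels j.
    K1, K2 = 1.0 / a1, 1.0 / a2
    inv2 = 1.0 + c21 * K1  # can origin 2 invade a pure-1 culture?
    inv1 = 1.0 + c12 * K2
    if inv2 < 0 and inv1 >= 0:
        return "exclusion_of_1"
    if inv1 < 0 and inv2 >= 0:
        return "exclusion_of_0"
    if inv1 < 0 and inv2 < 0:
        return "bistable"
    return "coexistence"


# ---------------------------------------------------------------------------
# serialization

def _params_to_dict(params: LVParams) -> dict:
    return {
        "origins": [
            {"id": oid, "K": float(K), "r": float(r)}
            for oid, K, r in zip(params.origin_ids, params.K, params.r)
        ],
        "interaction": params.interaction.tolist(),
    }


def _params_from_dict(d: dict) -> LVParams:
    origins = d["origins"]
    return from_copy_numbers(
        K=[o["K"] for o in origins],
        interaction=d["interaction"],
        r=np.array([o.get("r", 5.0) for o in origins]),
        origin_ids=[o["id"] for o in origins],
    )


def save_params(params: LVParams, path) -> None:
    """Write parameters as YAML (or JSON when the path ends in .json)."""
    d = _params_to_dict(params)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(d, fh, indent=2)
        else:
            yaml.safe_dump(d, fh, sort_keys=False)


def load_params(path) -> LVParams:
    path = str(path)
    with open(path) as fh:
        d = json.load(fh) if path.endswith(".json") else yaml.safe_load(fh)
    return _params_from_dict(d)
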