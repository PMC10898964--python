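"""Photophobic weighted random walks over 2D energy-density planes.

Walkers start on the southern edge of a walk region and try to reach its
northern edge.  Each iteration proposes a move to one of the four cardinal
neighbours with fixed weights; the move is rejected (position unchanged,
iteration still consumed) when the target pixel is outside the region or
its log10 energy density exceeds the walker's threshold.  A walk fails when
the iteration cap is reached.

Planes are row-major north-up: row 0 is the northern boundary, the last row
the southern start edge.  The exact absorbing-Markov-chain solution of the
same process (:func:`markov_oracle`) validates the stochastic ensembles.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from numba import njit

from ._kernels import pcg_init, pcg_next
from ._rng import stream_seed
from .errors import ConfigurationError

#: Cardinal move order used throughout: north, east, south, west.
CARDINALS = ("north", "east", "south", "west")
_DR = np.array([-1, 0, 1, 0], dtype=np.int64)
_DC = np.array([0, 1, 0, -1], dtype=np.int64)


@dataclass
class WalkConfig:
    """Ensemble configuration.

    weights: proposal probabilities for (north, east, south, west); the
    default (0.5, 0.2, 0.1, 0.2) encodes goal-directed photophobia with
    lateral and occasional backward movement.
    threshold: log10 energy density (dex, engine output scale) above which
    a pixel rejects entry; pixels exactly at the threshold are passable and
    zero-density pixels (log = -inf) always are.
    """

    weights: tuple = (0.5, 0.2, 0.1, 0.2)
    threshold: float = -8.0
    max_iterations: int = 1000
    n_walkers: int = 100_000
    margin_m: float = 100.0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (4,) or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be 4 non-negative numbers summing to 1")
        if self.max_iterations < 1 or self.n_walkers < 1:
            raise ValueError("max_iterations and n_walkers must be >= 1")
        self.weights = tuple(w)

    @property
    def weight_cdf(self) -> np.ndarray:
        c = np.cumsum(self.weights)
        c[-1] = 1.0
        return c


@dataclass
class WalkResult:
    success: bool
    steps: int
    visited: np.ndarray  # per-pixel visit counts


@dataclass
class EnsembleSummary:
    success_rate: float
    steps: np.ndarray            # per-walker consumed iterations
    step_histogram: np.ndarray   # counts over 1..max_iterations
    visit_heatmap: np.ndarray
    n_success: int
    config: WalkConfig
    seed: int
    extras: dict = field(default_factory=dict)


def log_plane(plane: np.ndarray) -> np.ndarray:
    """log10 of an energy-density plane; zeros map to -inf (always passable)."""
    plane = np.asarray(plane, dtype=float)
    if np.any(~np.isfinite(plane)) or np.any(plane < 0):
        raise ValueError("plane must be finite and non-negative")
    out = np.full(plane.shape, -np.inf)
    pos = plane > 0
    out[pos] = np.log10(plane[pos])
    return out


def cut_margins(plane: np.ndarray, margin_cells: int) -> np.ndarray:
    """Trim east/west margins (columns) from a plane before walking."""
    if margin_cells <= 0:
        return plane
    if plane.shape[1] <= 2 * margin_cells:
        raise ConfigurationError("margins leave no walkable columns")
    return plane[:, margin_cells:plane.shape[1] - margin_cells]


# ---------------------------------------------------------------------------
# reference path (single walker, any rng with .random())
# ---------------------------------------------------------------------------

def propose_and_move(state, logp: np.ndarray, config: WalkConfig, rng):
    """One iteration: weighted cardinal proposal, accept/reject.

    Returns ((row, col), accepted).  Rejection (outside region or target
    above threshold) leaves the position unchanged.
    """
    r, c = state
    u = float(rng.random())
    k = int(np.searchsorted(config.weight_cdf, u, side="right"))
    k = min(k, 3)
    nr, nc = r + int(_DR[k]), c + int(_DC[k])
    if not (0 <= nr < logp.shape[0] and 0 <= nc < logp.shape[1]):
        return (r, c), False
    if logp[nr, nc] > config.threshold:
        return (r, c), False
    return (nr, nc), True


def run_walk(plane: np.ndarray, config: WalkConfig, start, rng) -> WalkResult:
    """One walk from `start` (row, col on the southern edge) to the north."""
    plane = np.asarray(plane, dtype=float)
    logp = plane if _is_log(plane) else log_plane(plane)
    visited = np.zeros(logp.shape, dtype=np.int64)
    state = tuple(start)
    visited[state] += 1
    for it in range(1, config.max_iterations + 1):
        state, _ = propose_and_move(state, logp, config, rng)
        visited[state] += 1
        if state[0] == 0:
            return WalkResult(True, it, visited)
    return WalkResult(False, config.max_iterations, visited)


def _is_log(plane: np.ndarray) -> bool:
    """Heuristic: planes containing negatives or -inf are already log10."""
    return bool(np.any(plane < 0) or np.any(np.isneginf(plane)))


# ---------------------------------------------------------------------------
# compiled ensemble
# ---------------------------------------------------------------------------

@njit(cache=True)
def _walk_ensemble_kernel(logp, wcdf, threshold, max_iter, n_walkers,
                          seeds, steps, success, visits):
    R, C = logp.shape
    for w in range(n_walkers):
        state = pcg_init(seeds[w])
        state, u0 = pcg_next(state)
        col = int(u0 * C)
        if col >= C:
            col = C - 1
        r = R - 1
        c = col
        visits[r, c] += 1
        n = 0
        ok = False
        while n < max_iter:
            state, u = pcg_next(state)
            if u < wcdf[0]:
                dr = -1; dc = 0
            elif u < wcdf[1]:
                dr = 0; dc = 1
            elif u < wcdf[2]:
                dr = 1; dc = 0
            else:
                dr = 0; dc = -1
            nr = r + dr
            nc = c + dc
            n += 1
            if 0 <= nr < R and 0 <= nc < C and logp[nr, nc] <= threshold:
                r = nr; c = nc
            visits[r, c] += 1
            if r == 0:
                ok = True
                break
        steps[w] = n
        success[w] = ok


def run_ensemble(plane: np.ndarray, config: WalkConfig, master_seed: int) -> EnsembleSummary:
    """Run n_walkers independent walks with per-walker derived PCG streams.

    Start columns are uniform over the southern edge.  Deterministic for a
    fixed master seed, independent of execution order.
    """
    logp = np.ascontiguousarray(plane if _is_log(np.asarray(plane)) else log_plane(plane))
    if logp.size == 0 or logp.shape[0] < 2:
        raise ConfigurationError("walk region must have at least two rows")
    n = config.n_walkers
    seeds = np.empty(n, dtype=np.uint64)
    for w in range(n):
        seeds[w] = stream_seed(master_seed, w)
    steps = np.zeros(n, dtype=np.int64)
    success = np.zeros(n, dtype=np.bool_)
    visits = np.zeros(logp.shape, dtype=np.int64)
    _walk_ensemble_kernel(logp, config.weight_cdf, config.threshold,
                          config.max_iterations, n, seeds,
                          steps, success, visits)
    hist = np.bincount(steps, minlength=config.max_iterations + 1)[1:]
    return EnsembleSummary(
        success_rate=float(success.mean()),
        steps=steps,
        step_histogram=hist,
        visit_heatmap=visits,
        n_success=int(success.sum()),
        config=config,
        seed=master_seed,
    )


# ---------------------------------------------------------------------------
# exact absorbing-chain oracle
# ---------------------------------------------------------------------------

@dataclass
class OracleResult:
    """Exact per-pixel absorption statistics of the walk chain."""

    success_probability: np.ndarray  # (R, C); NaN on the absorbing north row? no: 1 there
    expected_steps: np.ndarray       # E[min(T, cap)] per start pixel (cap = inf -> E[T] where finite)

    def south_edge_mean(self) -> float:
        """Ensemble success rate for uniform starts on the southern edge."""
        return float(np.mean(self.success_probability[-1, :]))


def _transition_structure(logp: np.ndarray, config: WalkConfig):
    """Sparse transition matrix over all pixels; north row absorbing."""
    R, C = logp.shape
    n = R * C
    w = np.asarray(config.weights)
    rows, cols, vals = [], [], []
    passable = logp <= config.threshold

    def sid(r, c):
        return r * C + c

    for r in range(R):
        for c in range(C):
            s = sid(r, c)
            if r == 0:
                rows.append(s); cols.append(s); vals.append(1.0)
                continue
            stay = 0.0
            for k in range(4):
                nr, nc = r + int(_DR[k]), c + int(_DC[k])
                if 0 <= nr < R and 0 <= nc < C and passable[nr, nc]:
                    rows.append(s); cols.append(sid(nr, nc)); vals.append(w[k])
                else:
                    stay += w[k]
            if stay > 0:
                rows.append(s); cols.append(s); vals.append(stay)
    P = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return P


def markov_oracle(plane: np.ndarray, config: WalkConfig,
                  max_iterations: int | None = None) -> OracleResult:
    """Exact success probability and expected consumed iterations per start.

    With ``max_iterations=None`` the infinite-horizon absorption problem is
    solved as a sparse linear system after removing states that cannot
    reach the northern boundary (their probability is exactly 0, covering
    isolated or barrier-blocked regions that would make the naive system
    singular).  With a finite cap, truncated power iteration gives
    P(T <= cap) and E[min(T, cap)], the quantities the capped ensembles
    estimate.
    """
    logp = np.asarray(plane if _is_log(np.asarray(plane)) else log_plane(plane))
    R, C = logp.shape
    n = R * C
    P = _transition_structure(logp, config)
    north = np.zeros(n, dtype=bool)
    north[:C] = True

    if max_iterations is not None:
        p = north.astype(float)
        surv = 1.0 - p  # P(T > k) per start
        esteps = np.zeros(n)
        for _ in range(max_iterations):
            esteps += surv
            p = P @ p
            np.clip(p, 0.0, 1.0, out=p)
            surv = 1.0 - p
        return OracleResult(p.reshape(R, C), esteps.reshape(R, C))

    # infinite horizon: reachability reduction, then sparse solve
    radj = (P > 0).T.tocsr()
    reach = north.copy()
    frontier = north.copy()
    while frontier.any():
        nxt = np.zeros(n, dtype=bool)
        idx = np.where(frontier)[0]
        for s in idx:
            nxt[radj.indices[radj.indptr[s]:radj.indptr[s + 1]]] = True
        frontier = nxt & ~reach
        reach |= nxt
    transient = reach & ~north
    t_idx = np.where(transient)[0]
    p = np.zeros(n)
    p[north] = 1.0
    esteps = np.full(n, np.inf)
    esteps[north] = 0.0
    if t_idx.size:
        Q = P[t_idx][:, t_idx]
        b = np.asarray(P[t_idx][:, north].sum(axis=1)).ravel()
        A = sp.identity(t_idx.size, format="csc") - Q.tocsc()
        p[t_idx] = spla.spsolve(A, b)
        # expected steps conditioned on eventual absorption into the north
        # is not needed; report expected steps of the absorbed chain where
        # absorption is certain, else inf
        certain = np.abs(p[t_idx] - 1.0) < 1e-10
        if certain.all():
            esteps[t_idx] = spla.spsolve(A, np.ones(t_idx.size))
    np.clip(p, 0.0, 1.0, out=p)
    return OracleResult(p.reshape(R, C), esteps.reshape(R, C))


def threshold_ladder(start: float = -10.0, stop: float = -5.0, step: float = 0.5) -> np.ndarray:
    """The standard threshold sweep in log10 energy density (dex)."""
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)
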