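"""The camper-travel network transport model.

The aggregated trip table defines a sparse n×n travel-frequency matrix
**M** (zero diagonal).  Scaling every entry by a single parameter λ_t
gives per-segment transition values p_ij = λ_t·m_ij; the remainder of
each row, p_i_term = 1 − Σ_j p_ij, is the chance that no further travel
proceeds from cell i.  λ_t is chosen as ``safety / max row sum`` so that
every row sum of the transition matrix stays strictly below 1 and the
resulting random walk is absorbing.

Relative dispersal risk φ_ij is the fraction of simulated walks started
at i that ever visit j — intermediate and final destinations both count,
each walk at most once, so φ_ij ∈ [0, 1].  The same quantity has an
exact analytic counterpart (the hitting probability of j from i), which
this module also computes by solving a sparse linear system; it serves
as an oracle for the Monte Carlo estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .trips import SegmentTable

MAX_PATH_STEPS = 10_000  # guard against misconfigured row sums; unreachable in practice


@dataclass(frozen=True)
class TravelMatrix:
    """Validated matrix view of a SegmentTable: the travel-frequency matrix M."""

    nodes: tuple[int, ...]
    matrix: sp.csr_matrix  # n×n, zero diagonal, weights m_ij

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def index(self) -> dict[int, int]:
        return {c: k for k, c in enumerate(self.nodes)}


def build_travel_matrix(segments: SegmentTable) -> TravelMatrix:
    """Fix the node set and materialise M as a sparse matrix.

    Rows with no outgoing travel (destination-only cells) are legal and
    stay as zero rows.  A diagonal entry is a validation error.
    """
    for (i, j) in segments.entries:
        if i == j:
            raise ValueError(f"diagonal entry ({i}, {i}) in travel matrix")
    nodes = tuple(segments.nodes)
    idx = {c: k for k, c in enumerate(nodes)}
    n = len(nodes)
    if n == 0:
        return TravelMatrix(nodes=(), matrix=sp.csr_matrix((0, 0)))
    items = sorted(segments.entries.items())
    rows = np.array([idx[i] for (i, _), _ in items], dtype=np.int64)
    cols = np.array([idx[j] for (_, j), _ in items], dtype=np.int64)
    vals = np.array([w for _, w in items], dtype=float)
    m = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return TravelMatrix(nodes=nodes, matrix=m)


@dataclass(frozen=True)
class TransitionModel:
    """Scaled transition structure: p_ij, λ_t and per-row termination."""

    nodes: tuple[int, ...]
    p: sp.csr_matrix  # p_ij = lambda_t * m_ij
    lambda_t: float
    p_term: np.ndarray  # per-row termination probability, in (0, 1]

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def index(self) -> dict[int, int]:
        return {c: k for k, c in enumerate(self.nodes)}

    def row_sums(self) -> np.ndarray:
        return np.asarray(self.p.sum(axis=1)).ravel()

    def validate_conservation(self, tol: float = 1e-12) -> None:
        """Check p_i_term + Σ_j p_ij = 1 on every row."""
        resid = np.abs(self.p_term + self.row_sums() - 1.0)
        if resid.size and resid.max() > tol:
            raise AssertionError(f"row conservation violated by {resid.max():.3e}")


def scale_to_transition(travel: TravelMatrix | SegmentTable, safety: float = 0.9) -> TransitionModel:
    """Scale the travel matrix to transition values with row sums below 1.

    λ_t = safety / (max row sum of M); p_ij = λ_t·m_ij; the per-row
    remainder is the termination probability.  Rows with no outgoing
    entries get p_i_term = 1 (the cell is a destination only).
    """
    if isinstance(travel, SegmentTable):
        travel = build_travel_matrix(travel)
    if not (0.0 < safety < 1.0):
        raise ValueError("safety must be in (0, 1)")
    m = travel.matrix
    if travel.n == 0 or m.nnz == 0:
        raise ValueError("travel matrix has no entries; lambda_t is undefined")
    row_sums = np.asarray(m.sum(axis=1)).ravel()
    lam = safety / float(row_sums.max())
    p = (m * lam).tocsr()
    p_term = 1.0 - np.asarray(p.sum(axis=1)).ravel()
    return TransitionModel(nodes=travel.nodes, p=p, lambda_t=lam, p_term=p_term)


@dataclass(frozen=True)
class PathSample:
    """One simulated camper itinerary."""

    origin: int
    visited: tuple[int, ...]  # cells after the origin, in order
    termination: str  # "terminal_draw", "dead_end", or "capped"


def _row_cumulative(model: TransitionModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """CSR-style (indptr, dest-index, cumulative-probability) arrays.

    Row r's cumulative values end at 1 − p_r_term, so a uniform draw u
    lands on destination k when cum[k−1] ≤ u < cum[k] and terminates the
    walk when u ≥ 1 − p_r_term.
    """
    csr = model.p.tocsr()
    cum = csr.data.copy()
    indptr = csr.indptr
    for r in range(model.n):
        lo, hi = indptr[r], indptr[r + 1]
        if hi > lo:
            cum[lo:hi] = np.cumsum(cum[lo:hi])
    return indptr.astype(np.int64), csr.indices.astype(np.int64), cum


def simulate_path(
    model: TransitionModel, origin: int, rng: np.random.Generator
) -> PathSample:
    """Simulate one walk from ``origin`` through the network.

    At each cell k the next cell is drawn with probability p_kl and the
    walk stops with probability p_k_term; a cell with no outgoing travel
    ends the walk immediately.  A hard cap of ``MAX_PATH_STEPS`` guards
    against misconfiguration and is recorded in the termination mode.
    """
    idx = model.index
    if origin not in idx:
        raise KeyError(f"origin cell {origin} not in node set")
    indptr, dests, cum = _row_cumulative(model)
    cur = idx[origin]
    visited: list[int] = []
    for _ in range(MAX_PATH_STEPS):
        lo, hi = indptr[cur], indptr[cur + 1]
        if hi == lo:
            return PathSample(origin, tuple(visited), "dead_end")
        u = rng.random()
        k = lo + np.searchsorted(cum[lo:hi], u, side="right")
        if k == hi:  # u fell in the terminal remainder of the row
            return PathSample(origin, tuple(visited), "terminal_draw")
        cur = int(dests[k])
        visited.append(model.nodes[cur])
    return PathSample(origin, tuple(visited), "capped")


@dataclass
class RiskMatrix:
    """Monte Carlo estimates φ_ij = M_ij / M.

    ``counts[(i, j)]`` is M_ij, the number of walks from i that visited j
    at least once; ``sims_per_origin`` is M, the per-origin walk count.
    φ_ii is never stored (the origin does not count as visited).
    """

    counts: dict[tuple[int, int], int] = field(default_factory=dict)
    sims_per_origin: int = 0
    origins: tuple[int, ...] = ()
    nodes: tuple[int, ...] = ()
    seed: int | None = None
    capped_walks: int = 0

    @property
    def phi(self) -> dict[tuple[int, int], float]:
        m = self.sims_per_origin
        return {k: c / m for k, c in self.counts.items()}

    def phi_value(self, i: int, j: int) -> float:
        return self.counts.get((i, j), 0) / self.sims_per_origin

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        m = self.sims_per_origin
        return pd.DataFrame(
            {
                "cell_i": [i for (i, _), _ in rows],
                "cell_j": [j for (_, j), _ in rows],
                "phi": [c / m for _, c in rows],
                "count": [c for _, c in rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sims_per_origin: int | None = None) -> "RiskMatrix":
        df = pd.read_csv(path)
        if sims_per_origin is None:
            if "count" not in df.columns or df.empty:
                raise ValueError("sims_per_origin required when counts are absent")
            with np.errstate(divide="ignore"):
                ratios = df["count"] / df["phi"]
            sims_per_origin = int(round(float(ratios.dropna().iloc[0])))
        counts = {
            (int(r.cell_i), int(r.cell_j)): int(round(r.phi * sims_per_origin))
            if "count" not in df.columns
            else int(r.count)
            for r in df.itertuples(index=False)
        }
        origins = tuple(sorted({i for i, _ in counts}))
        nodes = tuple(sorted({c for ij in counts for c in ij}))
        return cls(
            counts=counts,
            sims_per_origin=sims_per_origin,
            origins=origins,
            nodes=nodes,
        )


def _walks_from_origin(
    indptr: np.ndarray,
    dests: np.ndarray,
    cum: np.ndarray,
    n: int,
    origin_idx: int,
    sims: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Vectorised batch of walks from one origin.

    Returns the per-node count of walks that visited each node at least
    once, and the number of walks cut off at the step cap.  Walks are
    advanced in lockstep; the flattened-cumulative trick (row r's
    cumulative values shifted by +r) resolves every active walk's next
    draw with a single searchsorted call.
    """
    # shifted global cumulative: row r occupies the interval (r, r+1]
    row_of_entry = np.repeat(np.arange(n), np.diff(indptr))
    shifted = cum + row_of_entry
    current = np.full(sims, origin_idx, dtype=np.int64)
    alive = np.arange(sims)
    visited = np.zeros((sims, n), dtype=bool)
    capped = 0
    for _ in range(MAX_PATH_STEPS):
        if alive.size == 0:
            break
        u = rng.random(alive.size)
        keys = current[alive] + u
        pos = np.searchsorted(shifted, keys, side="right")
        # a draw past the end of its row (u >= 1 - p_term) terminates;
        # zero-entry rows terminate unconditionally
        ended = pos >= indptr[current[alive] + 1]
        cont = ~ended
        walk_ids = alive[cont]
        nxt = dests[pos[cont]]
        visited[walk_ids, nxt] = True
        current[walk_ids] = nxt
        alive = walk_ids
    else:
        capped = int(alive.size)
    return visited.sum(axis=0, dtype=np.int64), capped


def estimate_phi(
    model: TransitionModel,
    origins=None,
    sims_per_origin: int = 10_000,
    seed: int = 0,
) -> RiskMatrix:
    """Estimate φ_ij by repeated stochastic pathway simulation.

    For each origin i, ``sims_per_origin`` independent walks are run and
    M_ij counts the walks that visited j at least once — intermediate and
    final destinations both count, whether or not the path ended at j.
    φ_ij = M_ij / sims_per_origin, so every estimate lies in [0, 1].

    Each origin draws from its own RNG substream derived from (seed,
    cell id), so results do not depend on origin processing order.
    """
    if sims_per_origin < 1:
        raise ValueError("sims_per_origin must be >= 1")
    idx = model.index
    if origins is None:
        origins = model.nodes
    origins = tuple(origins)
    unknown = [o for o in origins if o not in idx]
    if unknown:
        raise KeyError(f"origins not in node set: {unknown[:5]}")
    indptr, dests, cum = _row_cumulative(model)
    node_arr = np.asarray(model.nodes)
    counts: dict[tuple[int, int], int] = {}
    total_capped = 0
    for o in origins:
        rng = np.random.default_rng([seed, o])
        visit_counts, capped = _walks_from_origin(
            indptr, dests, cum, model.n, idx[o], sims_per_origin, rng
        )
        total_capped += capped
        visit_counts[idx[o]] = 0  # the origin itself is never counted as visited
        nz = np.nonzero(visit_counts)[0]
        for j in nz:
            counts[(o, int(node_arr[j]))] = int(visit_counts[j])
    return RiskMatrix(
        counts=counts,
        sims_per_origin=sims_per_origin,
        origins=origins,
        nodes=model.nodes,
        seed=seed,
        capped_walks=total_capped,
    )


def analytic_visit_probabilities(model: TransitionModel, target: int) -> dict[int, float]:
    """Exact probability of ever visiting ``target`` from every other node.

    Solves h(k) = p_k,target + Σ_{l≠target} p_kl·h(l) as a sparse linear
    system.  Because every row sum of the transition matrix is below 1
    the system (I − Q) is strictly diagonally dominant and non-singular.
    """
    idx = model.index
    if target not in idx:
        raise KeyError(f"target cell {target} not in node set")
    t = idx[target]
    keep = np.array([k for k in range(model.n) if k != t], dtype=np.int64)
    if keep.size == 0:
        return {}
    P = model.p.tocsc()
    Q = P[keep][:, keep]
    b = np.asarray(P[keep][:, [t]].todense()).ravel()
    A = sp.identity(keep.size, format="csc") - Q.tocsc()
    h = spla.spsolve(A, b)
    h = np.atleast_1d(h)
    return {int(model.nodes[k]): float(h[pos]) for pos, k in enumerate(keep)}


def analytic_visit_probability(model: TransitionModel, origin: int, target: int) -> float:
    """Exact hitting probability of ``target`` for a walk from ``origin``."""
    if origin == target:
        raise ValueError("origin and target must differ")
    if origin not in model.index:
        raise KeyError(f"origin cell {origin} not in node set")
    return analytic_visit_probabilities(model, target)[origin]
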