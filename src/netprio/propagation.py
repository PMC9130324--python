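"""Random walk with restart (RWR) on the heterogeneous network.

The walk iterates

    RG_t = r * W @ RG_{t-1} + (1 - r) * RG_0

where ``W`` is the column-normalized adjacency matrix of the merged
network, ``RG_0`` puts mass 1/n on each of the n seed nodes, and ``r``
is the restart probability (the probability of continuing the walk
rather than jumping back to the seeds).  The fixed point

    x = (1 - r) * (I - r W)^{-1} RG_0

exists and is unique for r < 1 because W is column-stochastic
(spectral radius 1), and the iteration contracts in L1 at rate r, so
the steady state is reached geometrically.  ``solve_direct`` computes
the fixed point by a sparse linear solve and serves as the exact
oracle for the iterative ``propagate``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import HeterogeneousNetwork, NetworkError, NodeId

logger = logging.getLogger(__name__)


@dataclass
class RestartConfig:
    """RWR parameters: restart probability, convergence tolerance, cap.

    ``r`` is the probability of continuing the walk at each step (0.4 by
    default, the value selected by the restart-probability sweep);
    iteration stops when the L1 change between successive iterates drops
    below ``tol``.
    """

    r: float = 0.4
    tol: float = 1e-10
    max_iter: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 < self.r < 1.0:
            raise ValueError(f"restart probability r must be in (0,1), got {self.r}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class TransitionMatrix:
    """Column-stochastic walk matrix sharing the network's node ordering."""

    W: sp.csc_array
    m: int
    nodes: list[NodeId] = field(repr=False)
    node_index: dict[NodeId, int] = field(repr=False)


def build_transition_matrix(network: HeterogeneousNetwork) -> TransitionMatrix:
    """Column-normalize the binary adjacency into the RWR walk matrix.

    Column j of W distributes a walker at node j uniformly over its
    neighbors (1/deg(j)); every column sums to 1 because assembly makes
    isolated nodes impossible.
    """
    if network.edge_count == 0:
        raise NetworkError("cannot build a walk matrix from a network with no edges")
    adj = network.adjacency()
    deg = np.asarray(adj.sum(axis=0)).ravel()
    if np.any(deg == 0):  # cannot happen post-assembly; guards hand-built inputs
        raise NetworkError("network contains isolated nodes")
    inv_deg = sp.diags_array(1.0 / deg)
    walk = sp.csc_array(adj @ inv_deg)
    return TransitionMatrix(
        W=walk, m=network.m, nodes=list(network.nodes), node_index=dict(network.node_index)
    )


@dataclass
class SeedSet:
    """Seed nodes with the 1/n restart vector RG_0."""

    seeds: tuple[NodeId, ...]
    n: int
    rg0: np.ndarray = field(repr=False)

    @classmethod
    def from_nodes(
        cls,
        matrix_or_network: TransitionMatrix | HeterogeneousNetwork,
        seed_nodes: Iterable[NodeId],
    ) -> "SeedSet":
        """Map seed nodes onto the network; unmapped seeds are dropped
        with a warning and the 1/n weights recomputed over the rest."""
        index = matrix_or_network.node_index
        m = matrix_or_network.m
        mapped, missing = [], []
        for node in dict.fromkeys(seed_nodes):  # dedupe, keep order
            (mapped if node in index else missing).append(node)
        if missing:
            warnings.warn(
                f"{len(missing)} seed(s) not present in the network were dropped: "
                + ", ".join(n.identifier for n in missing[:5])
                + ("..." if len(missing) > 5 else ""),
                stacklevel=2,
            )
        if not mapped:
            raise NetworkError("no seed node maps into the network")
        mapped = tuple(sorted(mapped))
        rg0 = np.zeros(m)
        rg0[[index[s] for s in mapped]] = 1.0 / len(mapped)
        return cls(seeds=mapped, n=len(mapped), rg0=rg0)


@dataclass
class PropagationResult:
    """Steady-state risk scores with convergence metadata."""

    scores: np.ndarray
    iterations: int
    residual: float
    converged: bool


def propagate(
    matrix: TransitionMatrix, seed_set: SeedSet, config: RestartConfig | None = None
) -> PropagationResult:
    """Iterate the RWR update from RG_0 until the L1 change is below tol.

    Non-convergence within ``max_iter`` produces a warning, not an
    error; the last iterate is returned with ``converged=False``.
    """
    config = config or RestartConfig()
    r = config.r
    rg = seed_set.rg0.copy()
    restart = (1.0 - r) * seed_set.rg0
    residual = np.inf
    iterations = 0
    for iterations in range(1, config.max_iter + 1):
        nxt = r * (matrix.W @ rg) + restart
        residual = float(np.abs(nxt - rg).sum())
        rg = nxt
        if residual < config.tol:
            break
    converged = residual < config.tol
    if not converged:
        warnings.warn(
            f"RWR did not converge in {config.max_iter} iterations "
            f"(residual {residual:.3e})",
            stacklevel=2,
        )
    return PropagationResult(
        scores=rg, iterations=iterations, residual=residual, converged=converged
    )


def solve_direct(
    matrix: TransitionMatrix, seed_set: SeedSet, r: float
) -> np.ndarray:
    """Exact RWR steady state via sparse solve of (I - rW) x = (1-r) RG_0."""
    if not 0.0 < r < 1.0:
        raise ValueError(f"restart probability r must be in (0,1), got {r}")
    system = sp.eye_array(matrix.m, format="csc") - r * matrix.W
    rhs = (1.0 - r) * seed_set.rg0
    return spla.spsolve(sp.csc_matrix(system), rhs)
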