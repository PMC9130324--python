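"""Leave-one-out cross-validation of the propagation ranking.

Each of the n seed genes is held out in turn; propagation runs from the
remaining n-1 seeds (reweighted to 1/(n-1)) and all non-seed nodes —
held-out gene included — are ranked by descending risk score.  The n
per-trial ranking lists are pooled into one ROC curve by varying the
rank threshold k: TPR(k) is the fraction of held-out genes retrieved at
rank <= k, FPR(k) the fraction of pooled non-held-out candidates at
rank <= k.  AUC is the trapezoidal area.  A sweep over the restart
probability selects the r maximizing this pooled AUC.

Ties in score are broken by (identifier, node_type) lexicographic order
so every ranking is deterministic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import HeterogeneousNetwork, NetworkError, NodeId
from .propagation import (
    RestartConfig,
    SeedSet,
    TransitionMatrix,
    build_transition_matrix,
    propagate,
)

logger = logging.getLogger(__name__)


@dataclass
class TrialRanking:
    """One LOOCV trial: the held-out gene's rank among all candidates."""

    held_out: NodeId
    candidate_ranks: list[tuple[NodeId, float, int]]
    rank_of_held_out: int
    converged: bool = True

    @property
    def n_candidates(self) -> int:
        return len(self.candidate_ranks)


@dataclass
class LOOCVResult:
    """Pooled LOOCV outcome: per-trial rankings, ROC points, AUC."""

    trials: list[TrialRanking]
    roc_points: list[tuple[float, float]]
    auc: float
    r: float


@dataclass
class SweepResult:
    """AUC as a function of restart probability; best_r is the argmax
    (ties broken toward smaller r)."""

    grid: list[tuple[float, float]]
    best_r: float


def rank_candidates(
    matrix: TransitionMatrix,
    scores: np.ndarray,
    exclude: set[NodeId],
) -> list[tuple[NodeId, float, int]]:
    """Rank all nodes outside ``exclude`` by descending score.

    Tie-break: (identifier, node_type) ascending.  Ranks run 1..#candidates.
    """
    candidates = [
        (node, float(scores[i])) for node, i in matrix.node_index.items()
        if node not in exclude
    ]
    candidates.sort(key=lambda item: (-item[1], item[0]))
    return [(node, score, rank) for rank, (node, score) in enumerate(candidates, start=1)]


def loocv_trial(
    network: HeterogeneousNetwork | TransitionMatrix,
    seeds: SeedSet,
    held_out: NodeId,
    config: RestartConfig | None = None,
) -> TrialRanking:
    """Hold out one seed, propagate from the rest, record its rank.

    The remaining n-1 seeds are reweighted to 1/(n-1); candidates are
    all nodes except those trial seeds (so the held-out gene competes
    with every non-seed node).
    """
    if held_out not in seeds.seeds:
        raise NetworkError(f"held-out node {held_out.identifier!r} is not a seed")
    if seeds.n < 2:
        raise NetworkError("LOOCV requires at least 2 seeds")
    matrix = (
        network if isinstance(network, TransitionMatrix)
        else build_transition_matrix(network)
    )
    trial_seeds = [s for s in seeds.seeds if s != held_out]
    trial_set = SeedSet.from_nodes(matrix, trial_seeds)
    result = propagate(matrix, trial_set, config)
    if not result.converged:
        logger.warning(
            "trial holding out %s: propagation not converged (residual %.3e); "
            "ranking on last iterate", held_out.identifier, result.residual,
        )
    ranks = rank_candidates(matrix, result.scores, set(trial_set.seeds))
    rank_of_held_out = next(r for node, _, r in ranks if node == held_out)
    return TrialRanking(
        held_out=held_out,
        candidate_ranks=ranks,
        rank_of_held_out=rank_of_held_out,
        converged=result.converged,
    )


def pooled_roc(trials: Sequence[TrialRanking]) -> tuple[list[tuple[float, float]], float]:
    """Combine trial ranking lists into one ROC curve by rank threshold.

    At threshold k, the positives retrieved are the held-out genes with
    rank <= k and the negatives retrieved are all other pooled
    candidates with rank <= k.  Returns the ROC points (starting at
    (0,0), ending at (1,1)) and the trapezoidal AUC.
    """
    n = len(trials)
    held_ranks = np.array([t.rank_of_held_out for t in trials])
    sizes = np.array([t.n_candidates for t in trials])
    total_neg = int((sizes - 1).sum())
    max_k = int(sizes.max())
    ks = np.arange(0, max_k + 1)
    tpr = (held_ranks[None, :] <= ks[:, None]).sum(axis=1) / n
    retrieved = np.minimum(ks[:, None], sizes[None, :]).sum(axis=1)
    neg_retrieved = retrieved - (held_ranks[None, :] <= ks[:, None]).sum(axis=1)
    if total_neg > 0:
        fpr = neg_retrieved / total_neg
    else:  # degenerate: every candidate list is just the held-out gene
        fpr = np.zeros_like(ks, dtype=float)
    points = list(zip(fpr.tolist(), tpr.tolist()))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = float(np.trapezoid([p[1] for p in points], [p[0] for p in points]))
    return points, auc


def run_loocv(
    network: HeterogeneousNetwork | TransitionMatrix,
    seeds: SeedSet,
    config: RestartConfig | None = None,
) -> LOOCVResult:
    """Run all n hold-out trials and pool them into a single ROC/AUC."""
    if seeds.n < 2:
        raise NetworkError("LOOCV requires at least 2 seeds")
    config = config or RestartConfig()
    matrix = (
        network if isinstance(network, TransitionMatrix)
        else build_transition_matrix(network)
    )
    trials = [loocv_trial(matrix, seeds, held_out, config) for held_out in seeds.seeds]
    points, auc = pooled_roc(trials)
    return LOOCVResult(trials=trials, roc_points=points, auc=auc, r=config.r)


def sweep_restart(
    network: HeterogeneousNetwork | TransitionMatrix,
    seeds: SeedSet,
    r_grid: Sequence[float],
    config: RestartConfig | None = None,
) -> SweepResult:
    """LOOCV AUC at each restart probability in ``r_grid``.

    ``config`` supplies tol/max_iter; its r is ignored.  Ties on AUC are
    broken toward smaller r for determinism.
    """
    if not len(r_grid):
        raise ValueError("r_grid must be non-empty")
    base = config or RestartConfig()
    matrix = (
        network if isinstance(network, TransitionMatrix)
        else build_transition_matrix(network)
    )
    grid: list[tuple[float, float]] = []
    for r in r_grid:
        cfg = RestartConfig(r=float(r), tol=base.tol, max_iter=base.max_iter)
        grid.append((float(r), run_loocv(matrix, seeds, cfg).auc))
    best_r = min(grid, key=lambda item: (-item[1], item[0]))[0]
    return SweepResult(grid=grid, best_r=best_r)
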