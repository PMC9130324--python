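"""Genome-wide candidate prioritization from the full seed set.

One propagation from all seeds scores every node; non-seed nodes are
ranked by descending risk score and the top k are called candidate
susceptibility genes (k = 50 in the default workflow).  Unreachable
nodes keep score 0 and sit at the bottom of the list rather than being
dropped, so output length is stable.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass

from .network import HeterogeneousNetwork, NetworkError, NodeId
from .propagation import (
    RestartConfig,
    SeedSet,
    TransitionMatrix,
    build_transition_matrix,
    propagate,
)
from .evaluation import rank_candidates

logger = logging.getLogger(__name__)


@dataclass
class RankedGeneList:
    """Non-seed nodes ordered by descending risk score; ranks from 1."""

    entries: list[tuple[NodeId, float, int]]
    r: float

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class CandidateSet:
    """The top-k prefix of a ranked list, with per-type tallies."""

    k: int
    members: list[tuple[NodeId, float, int]]
    type_tallies: dict[str, int]

    @property
    def nodes(self) -> list[NodeId]:
        return [node for node, _, _ in self.members]


def rank_genome_wide(
    network: HeterogeneousNetwork | TransitionMatrix,
    seeds: SeedSet,
    config: RestartConfig | None = None,
    include_seeds: bool = False,
) -> RankedGeneList:
    """Propagate from the full seed set and rank all non-seed nodes.

    ``include_seeds=True`` keeps seed nodes in the output for
    diagnostics; by default they are excluded (the workflow predicts
    novel genes).
    """
    config = config or RestartConfig()
    matrix = (
        network if isinstance(network, TransitionMatrix)
        else build_transition_matrix(network)
    )
    if seeds.n < 1:
        raise NetworkError("genome-wide ranking needs at least one mapped seed")
    result = propagate(matrix, seeds, config)
    exclude = set() if include_seeds else set(seeds.seeds)
    entries = rank_candidates(matrix, result.scores, exclude)
    return RankedGeneList(entries=entries, r=config.r)


def select_top_k(
    ranked: RankedGeneList,
    k: int,
    type_filter: str | None = None,
) -> CandidateSet:
    """First k entries of the ranked list, optionally restricted to one
    molecule type; per-type tallies are reported alongside."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    entries = ranked.entries
    if type_filter is not None:
        entries = [e for e in entries if e[0].node_type == type_filter]
    if k > len(entries):
        warnings.warn(
            f"requested top {k} but only {len(entries)} candidates available",
            stacklevel=2,
        )
    members = entries[:k]
    tallies = Counter(node.node_type for node, _, _ in members)
    return CandidateSet(k=k, members=members, type_tallies=dict(tallies))
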