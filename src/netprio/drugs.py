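"""Drug repositioning by hypergeometric target-set enrichment.

For each drug, the overlap k between its in-universe target set (size
K) and the candidate gene set (size n_c) is scored with the exact upper
hypergeometric tail P(X >= k), X ~ Hypergeometric(N, K, n_c), where N
is the analysis universe.  P-values are adjusted across drugs by
Benjamini-Hochberg; drugs with adjusted p <= alpha are called
significantly targeting the candidates.

The default universe is every network node that appears as a target of
at least one drug in the supplied tables; passing the full node set
switches the background to "all network nodes".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import false_discovery_control, hypergeom

from .network import NodeId

logger = logging.getLogger(__name__)


def _ident(x: "NodeId | str") -> str:
    return x.identifier if isinstance(x, NodeId) else x


@dataclass
class DrugTargetSet:
    """A drug and its target identifiers (combination products such as
    "carboplatin + docetaxel" are kept as single drug ids)."""

    drug_id: str
    targets: frozenset[str]

    @classmethod
    def make(cls, drug_id: str, targets: Iterable["NodeId | str"]) -> "DrugTargetSet":
        return cls(drug_id=drug_id, targets=frozenset(_ident(t) for t in targets))


@dataclass
class EnrichmentResult:
    """Hypergeometric enrichment of one drug's targets in the candidates."""

    drug_id: str
    overlap: int          # k
    n_targets: int        # K, drug targets inside the universe
    n_candidates: int     # n_c
    universe_size: int    # N
    p_value: float
    adjusted_p: float
    overlapping: frozenset[str]
    significant: bool


def hypergeometric_tail(k: int, K: int, n_c: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n_c).

    N is the universe size, K the number of marked elements (drug
    targets), n_c the draw size (candidate set), k the observed overlap.
    """
    if not (0 <= k <= min(K, n_c)):
        raise ValueError(f"need 0 <= k <= min(K, n_c); got k={k}, K={K}, n_c={n_c}")
    if not (0 <= K <= N and 0 <= n_c <= N):
        raise ValueError(f"need K, n_c <= N; got K={K}, n_c={n_c}, N={N}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n_c))


def read_drug_target_table(path: str | Path) -> list[DrugTargetSet]:
    """Parse a TSV of (drug_id, target_id) rows into drug target sets.

    A header row is auto-detected; target identifiers beginning with
    "hsa-" are lower-cased (miRNA convention), all others upper-cased.
    """
    frame = pd.read_csv(
        path, sep="\t", header=None, dtype=str, keep_default_na=False,
        skip_blank_lines=True,
    )
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: drug-target table needs >=2 columns")
    rows = list(frame.itertuples(index=False, name=None))
    if rows and rows[0][0].strip().lower() in {"drug", "drug_id", "compound"}:
        rows = rows[1:]
    by_drug: dict[str, set[str]] = {}
    for row in rows:
        drug, target = row[0].strip(), row[1].strip()
        if not drug or not target:
            continue
        target = target.lower() if target.lower().startswith("hsa-") else target.upper()
        by_drug.setdefault(drug, set()).add(target)
    return [
        DrugTargetSet(drug_id=d, targets=frozenset(t))
        for d, t in sorted(by_drug.items())
    ]


def target_universe(drug_sets: Sequence[DrugTargetSet],
                    network_nodes: Iterable["NodeId | str"]) -> frozenset[str]:
    """Default analysis universe: network nodes targeted by >=1 drug."""
    node_ids = {_ident(n) for n in network_nodes}
    targeted = set().union(*(d.targets for d in drug_sets)) if drug_sets else set()
    return frozenset(node_ids & targeted)


def test_drug_enrichment(
    drug_sets: Sequence[DrugTargetSet],
    candidates: Iterable["NodeId | str"],
    universe: Iterable["NodeId | str"],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric enrichment of every drug's targets in the candidates.

    Drug targets are intersected with the universe first; drugs with no
    in-universe target are skipped (logged).  BH adjustment runs across
    the tested drugs and results are sorted by (adjusted p, raw p,
    drug_id).

    Raises
    ------
    ValueError
        If the universe or the in-universe candidate set is empty, or a
        candidate lies outside the universe.
    """
    universe_ids = frozenset(_ident(u) for u in universe)
    if not universe_ids:
        raise ValueError("enrichment universe is empty")
    candidate_ids = frozenset(_ident(c) for c in candidates)
    outside = candidate_ids - universe_ids
    if outside:
        logger.info(
            "%d candidate(s) outside the universe are ignored: %s",
            len(outside), ", ".join(sorted(outside)[:5]),
        )
    candidate_ids = candidate_ids & universe_ids
    if not candidate_ids:
        raise ValueError("no candidate lies inside the enrichment universe")
    N, n_c = len(universe_ids), len(candidate_ids)
    tested: list[tuple[DrugTargetSet, frozenset[str], frozenset[str]]] = []
    skipped = []
    for drug in drug_sets:
        in_universe = drug.targets & universe_ids
        if not in_universe:
            skipped.append(drug.drug_id)
            continue
        tested.append((drug, in_universe, in_universe & candidate_ids))
    if skipped:
        logger.info("skipped %d drug(s) with no in-universe target: %s",
                    len(skipped), ", ".join(skipped[:5]))
    if not tested:
        return []
    raw_p = np.array([
        hypergeometric_tail(len(hit), len(tgt), n_c, N) for _, tgt, hit in tested
    ])
    adj_p = np.minimum(false_discovery_control(raw_p, method="bh"), 1.0)
    results = [
        EnrichmentResult(
            drug_id=drug.drug_id,
            overlap=len(hit),
            n_targets=len(tgt),
            n_candidates=n_c,
            universe_size=N,
            p_value=float(p),
            adjusted_p=float(q),
            overlapping=hit,
            significant=bool(q <= alpha),
        )
        for (drug, tgt, hit), p, q in zip(tested, raw_p, adj_p)
    ]
    results.sort(key=lambda res: (res.adjusted_p, res.p_value, res.drug_id))
    return results


# the name follows the API convention "test the enrichment", not pytest's
test_drug_enrichment.__test__ = False  # type: ignore[attr-defined]
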