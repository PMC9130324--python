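"""Synthetic multi-layer network fixtures with planted structure.

Generates layered edge tables mimicking the heterogeneous molecular
network: typed nodes (mRNA, miRNA, lncRNA, TF, protein) wired by
bipartite layers (lncRNA-mRNA, miRNA-mRNA, miRNA-lncRNA, TF-miRNA,
TF-mRNA) plus a protein-protein layer.  A planted cross-layer module of
``module_size`` nodes gets elevated internal edge probability ``p_in``
against a sparse background ``p_out``, and seeds are drawn from the
module — a positive control with known signal for propagation-based
recovery.  A companion generator plants one enriched drug inside a
random drug-target table so the repositioning stage is testable
end to end.

All sampling is driven by one explicit integer seed; outputs are
byte-identical across calls with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .network import (
    EdgeRecord,
    HeterogeneousNetwork,
    LAYER_TYPES,
    NodeId,
    assemble_network,
)

_DEFAULT_N_NODES: Mapping[str, int] = {
    "mRNA": 120, "miRNA": 60, "lncRNA": 50, "TF": 30, "protein": 40,
}

_NAME_PATTERNS = {
    "mRNA": "GENE{:04d}",
    "miRNA": "hsa-mir-{:04d}",
    "lncRNA": "LNC{:04d}",
    "TF": "TF{:04d}",
    "protein": "PROT{:04d}",
}


@dataclass
class SyntheticSpec:
    """Parameters of the planted-module multi-layer fixture.

    ``p_out`` is the background edge probability used for every layer
    unless overridden in ``layer_probs``; pairs with both endpoints in
    the planted module connect with probability ``p_in`` instead.
    """

    n_nodes: Mapping[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_NODES))
    p_in: float = 0.5
    p_out: float = 0.01
    layer_probs: Mapping[str, float] = field(default_factory=dict)
    module_size: int = 20
    n_seeds: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_out, *self.layer_probs.values()):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"edge probability {p} outside [0,1]")
        if any(c < 0 for c in self.n_nodes.values()):
            raise ValueError("node counts must be >= 0")
        total = sum(self.n_nodes.values())
        if self.module_size > total:
            raise ValueError(
                f"module size {self.module_size} exceeds node count {total}"
            )
        if self.n_seeds > self.module_size:
            raise ValueError("n_seeds cannot exceed module_size")


@dataclass
class SyntheticNetwork:
    """Generated fixture: per-layer edge records, module, and seeds."""

    layers: dict[str, list[EdgeRecord]]
    module: list[NodeId]
    seeds: list[NodeId]
    spec: SyntheticSpec

    def records(self) -> list[EdgeRecord]:
        return [rec for layer in self.layers.values() for rec in layer]

    def assemble(self) -> HeterogeneousNetwork:
        return assemble_network(self.records())

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write one TSV edge table per layer plus module/seed lists.

        Returns the mapping layer name -> file path; seeds.tsv and
        module.tsv carry (identifier, node_type) rows.
        """
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for layer, recs in self.layers.items():
            path = out_dir / f"{layer}.tsv"
            pd.DataFrame(
                [(r.source.identifier, r.target.identifier) for r in recs],
                columns=["source", "target"],
            ).to_csv(path, sep="\t", index=False)
            paths[layer] = path
        for name, nodes in (("seeds", self.seeds), ("module", self.module)):
            pd.DataFrame(
                [(n.identifier, n.node_type) for n in nodes],
                columns=["identifier", "node_type"],
            ).to_csv(out_dir / f"{name}.tsv", sep="\t", index=False)
        return paths


def _make_nodes(spec: SyntheticSpec) -> dict[str, list[NodeId]]:
    return {
        ntype: [NodeId(_NAME_PATTERNS[ntype].format(i), ntype) for i in range(count)]
        for ntype, count in spec.n_nodes.items()
    }


def generate_multilayer_network(spec: SyntheticSpec) -> SyntheticNetwork:
    """Sample the layered fixture with its planted module and seeds.

    Each layer only connects its allowed type pair (miRNA-mRNA edges
    join a miRNA to an mRNA, PPI stays within proteins, ...), so the
    typed-identifier code paths are exercised.  The module spans types
    and its internal pairs (where layer-compatible) use ``p_in``.
    Seeds are drawn without replacement from module nodes that carry at
    least one edge.
    """
    rng = np.random.default_rng(spec.rng_seed)
    nodes_by_type = _make_nodes(spec)
    all_nodes = [n for ntype in sorted(nodes_by_type) for n in nodes_by_type[ntype]]
    module_idx = rng.choice(len(all_nodes), size=spec.module_size, replace=False)
    module = sorted(all_nodes[i] for i in module_idx)
    in_module = set(module)

    layers: dict[str, list[EdgeRecord]] = {}
    touched: set[NodeId] = set()
    for layer in sorted(LAYER_TYPES):
        type_a, type_b = LAYER_TYPES[layer]
        src_nodes = nodes_by_type.get(type_a, [])
        tgt_nodes = nodes_by_type.get(type_b, [])
        if not src_nodes or not tgt_nodes:
            continue
        p_bg = spec.layer_probs.get(layer, spec.p_out)
        recs: list[EdgeRecord] = []
        if type_a == type_b:
            pairs = [
                (u, v) for i, u in enumerate(src_nodes) for v in src_nodes[i + 1:]
            ]
        else:
            pairs = [(u, v) for u in src_nodes for v in tgt_nodes]
        draws = rng.random(len(pairs))
        for (u, v), x in zip(pairs, draws):
            p = spec.p_in if (u in in_module and v in in_module) else p_bg
            if x < p:
                recs.append(EdgeRecord(u, v, layer))
                touched.add(u)
                touched.add(v)
        if recs:
            layers[layer] = recs

    eligible = [n for n in module if n in touched]
    if len(eligible) < spec.n_seeds:
        raise ValueError(
            f"only {len(eligible)} module nodes carry edges; cannot draw "
            f"{spec.n_seeds} seeds (raise p_in or module_size)"
        )
    seed_idx = rng.choice(len(eligible), size=spec.n_seeds, replace=False)
    seeds = sorted(eligible[i] for i in seed_idx)
    return SyntheticNetwork(layers=layers, module=module, seeds=seeds, spec=spec)


def generate_drug_target_table(
    universe: Iterable[NodeId],
    candidates: Iterable[NodeId],
    n_drugs: int = 20,
    planted_overlap: int = 8,
    targets_per_drug: tuple[int, int] = (5, 15),
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Random drug-target table with one planted enriched drug.

    ``n_drugs - 1`` decoy drugs draw their targets uniformly from the
    universe; the planted drug (``DRUG_PLANTED``) receives
    ``planted_overlap`` candidate genes plus random non-candidate
    padding up to the sampled target count.  Returns a two-column
    DataFrame (drug_id, target) whose TSV serialization is
    byte-identical for a fixed seed.
    """
    universe = sorted(set(universe))
    candidates = sorted(set(candidates))
    if planted_overlap > len(candidates):
        raise ValueError("planted_overlap exceeds the candidate set size")
    lo, hi = targets_per_drug
    if hi > len(universe):
        raise ValueError("universe smaller than the requested target counts")
    rng = np.random.default_rng(rng_seed)
    rows: list[tuple[str, str]] = []
    for d in range(n_drugs - 1):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=size, replace=False)
        for i in sorted(idx):
            rows.append((f"DRUG{d:03d}", universe[i].identifier))
    size = max(int(rng.integers(lo, hi + 1)), planted_overlap)
    hit_idx = rng.choice(len(candidates), size=planted_overlap, replace=False)
    targets = {candidates[i].identifier for i in hit_idx}
    non_candidates = [u for u in universe if u not in set(candidates)]
    pad = size - planted_overlap
    if pad > 0 and non_candidates:
        pad_idx = rng.choice(len(non_candidates), size=min(pad, len(non_candidates)),
                             replace=False)
        targets |= {non_candidates[i].identifier for i in pad_idx}
    for t in sorted(targets):
        rows.append(("DRUG_PLANTED", t))
    return pd.DataFrame(rows, columns=["drug_id", "target"])
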