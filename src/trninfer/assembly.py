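"""Assembly of per-core sub-networks into one three-layer hierarchical network.

Layers run upstream TFs -> core TFs -> middle SDETFs -> terminal GO-process
nodes.  A gene may belong to several layers (a core TF of one sub-network
can be a middle-layer SDETF of another); such nodes are represented once
with the union of their layer memberships.  Edges live strictly between
layers, are deduplicated by (source, target, layer_pair) with multiplicity
folded into provenance, and every process node carries the count of
distinct middle-layer TFs regulating it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .datatypes import (
    LAYER_CORE,
    LAYER_MIDDLE,
    LAYER_PROCESS,
    LAYER_UPSTREAM,
    LP_CORE_MIDDLE,
    LP_MIDDLE_PROCESS,
    LP_UPSTREAM_CORE,
    UNRESOLVED,
    PipelineParams,
    SignedEdge,
    ValidationError,
    logger,
)

_LAYER_OF_PAIR = {
    LP_UPSTREAM_CORE: (LAYER_UPSTREAM, LAYER_CORE),
    LP_CORE_MIDDLE: (LAYER_CORE, LAYER_MIDDLE),
    LP_MIDDLE_PROCESS: (LAYER_MIDDLE, LAYER_PROCESS),
}


@dataclass(frozen=True)
class NetworkNode:
    id: str
    name: str
    layers: frozenset[str]

    def __post_init__(self) -> None:
        bad = set(self.layers) - {LAYER_UPSTREAM, LAYER_CORE, LAYER_MIDDLE, LAYER_PROCESS}
        if bad:
            raise ValidationError(f"node {self.id!r}: unknown layer(s) {sorted(bad)}")


@dataclass
class HierarchicalNetwork:
    """The final layered signed graph plus the parameters that produced it."""

    nodes: dict[str, NetworkNode]
    edges: list[SignedEdge]
    params: PipelineParams
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.edges = sorted(self.edges,
                            key=lambda e: (e.source, e.target, e.layer_pair))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HierarchicalNetwork):
            return NotImplemented
        return (self.nodes == other.nodes and self.edges == other.edges
                and self.params == other.params)

    def validate(self, core_tfs: Iterable[str] | None = None) -> None:
        seen: set[tuple[str, str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in self.nodes:
                    raise ValidationError(f"edge endpoint {endpoint!r} missing from nodes")
            src_layer, tgt_layer = _LAYER_OF_PAIR[e.layer_pair]
            if src_layer not in self.nodes[e.source].layers:
                raise ValidationError(
                    f"edge {e.source}->{e.target}: source lacks layer {src_layer!r}")
            if tgt_layer not in self.nodes[e.target].layers:
                raise ValidationError(
                    f"edge {e.source}->{e.target}: target lacks layer {tgt_layer!r}")
            key = (e.source, e.target, e.layer_pair)
            if key in seen:
                raise ValidationError(f"duplicate edge {key}")
            seen.add(key)
        if core_tfs is not None:
            configured = set(core_tfs)
            actual = {n.id for n in self.nodes.values() if LAYER_CORE in n.layers}
            if actual != configured:
                raise ValidationError(
                    f"core layer {sorted(actual)} differs from configured "
                    f"{sorted(configured)}")

    def process_regulator_counts(self) -> dict[str, int]:
        """Distinct middle-layer TFs feeding each process node."""
        counts: dict[str, set[str]] = {}
        for e in self.edges:
            if e.layer_pair == LP_MIDDLE_PROCESS:
                counts.setdefault(e.target, set()).add(e.source)
        return {pid: len(regs) for pid, regs in counts.items()}


def assemble(core_networks: Mapping[str, Iterable[SignedEdge]],
             upstream_edges: Iterable[SignedEdge],
             core_tfs: Iterable[str],
             params: PipelineParams | None = None,
             provenance: Mapping | None = None) -> HierarchicalNetwork:
    """Merge per-core edge lists and upstream edges into one network.

    Nodes are deduplicated by id with layer-set union; duplicate
    (source, target, layer_pair) edges collapse to one edge whose provenance
    concatenates all rule firings.  Self-loops (within-layer candidates)
    are dropped with a logged note.  The merge canonicalizes ordering, so
    permuting the input sub-networks yields an identical network.
    """
    params = params or PipelineParams()
    core_set = set(core_tfs)
    layers: dict[str, set[str]] = {tf: {LAYER_CORE} for tf in core_set}

    all_edges: list[SignedEdge] = []
    for core in sorted(core_networks):
        all_edges.extend(core_networks[core])
    all_edges.extend(upstream_edges)
    all_edges.sort(key=lambda e: (e.source, e.target, e.layer_pair, e.sign, e.provenance))

    merged: dict[tuple[str, str, str], SignedEdge] = {}
    for e in all_edges:
        if e.source == e.target:
            logger.info("dropping within-layer self edge %s->%s", e.source, e.target)
            continue
        src_layer, tgt_layer = _LAYER_OF_PAIR[e.layer_pair]
        layers.setdefault(e.source, set()).add(src_layer)
        layers.setdefault(e.target, set()).add(tgt_layer)
        key = (e.source, e.target, e.layer_pair)
        if key in merged:
            prior = merged[key]
            sign = prior.sign
            if prior.sign != e.sign:
                # the same TF can be dissected under two core deletions with
                # opposite directions; collapse the contradiction explicitly
                logger.warning("conflicting signs for edge %s (%s vs %s); "
                               "collapsing to unresolved", key, prior.sign, e.sign)
                sign = UNRESOLVED
            merged[key] = SignedEdge(
                source=e.source, target=e.target, sign=sign,
                layer_pair=e.layer_pair,
                provenance=prior.provenance + " | " + e.provenance)
        else:
            merged[key] = e

    nodes = {
        node_id: NetworkNode(id=node_id, name=node_id.split("|")[0],
                             layers=frozenset(node_layers))
        for node_id, node_layers in layers.items()
    }
    network = HierarchicalNetwork(
        nodes=nodes,
        edges=list(merged.values()),
        params=params,
        provenance=dict(provenance or {}),
    )
    network.validate(core_tfs=core_set)
    return network


def summarize(network: HierarchicalNetwork) -> dict:
    """Tabular counterpart of the assembled network.

    Counts nodes per layer (multi-membership nodes count in each of their
    layers), edges per sign and per layer pair, and the distribution of
    process regulator counts; any coverage statistics recorded in the
    network's provenance are carried through.
    """
    layer_counts = {layer: 0 for layer in
                    (LAYER_UPSTREAM, LAYER_CORE, LAYER_MIDDLE, LAYER_PROCESS)}
    for node in network.nodes.values():
        for layer in node.layers:
            layer_counts[layer] += 1
    sign_counts: dict[str, int] = {}
    pair_counts: dict[str, int] = {}
    for e in network.edges:
        sign_counts[e.sign] = sign_counts.get(e.sign, 0) + 1
        pair_counts[e.layer_pair] = pair_counts.get(e.layer_pair, 0) + 1
    return {
        "n_nodes": len(network.nodes),
        "n_edges": len(network.edges),
        "layer_counts": layer_counts,
        "sign_counts": sign_counts,
        "layer_pair_counts": pair_counts,
        "process_regulator_counts": network.process_regulator_counts(),
        "coverage": network.provenance.get("coverage", {}),
    }
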