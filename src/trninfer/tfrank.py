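"""Heat-diffusion ranking of candidate regulators and upstream triangulation.

Candidate regulators of a gene list (the SDEG seeds) are scored by diffusing
heat from the seeds backwards along documented regulator->target edges: each
target splits its heat equally among its documented regulators, nodes
without documented regulators retain theirs, and the accumulated weight is
the truncated heat-kernel series

    w = sum_{j>=1} (alpha^j / j!) M^j s,      alpha = diffusion coefficient,

with M the reverse transition operator and s the uniform seed-heat vector.
On a single documented edge TF->g with seed {g} this reduces to the closed
form w(TF) = e^alpha - 1.

An upstream regulator of a core TF is then triangulated as a TF that (i)
ranks in the top k by weight while individually covering more than the
required fraction of the seeds, (ii) is documented to regulate the core TF,
and (iii) is not itself a downstream SDETF of that core TF; qPCR of the core
TF in the upstream-deletion strain can overrule the documented sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .datatypes import (
    ACTIVATES,
    INHIBITS,
    LP_UPSTREAM_CORE,
    SIGN_ACTIVATION,
    SIGN_INHIBITION,
    UNRESOLVED,
    PipelineParams,
    RegulonDB,
    SignedEdge,
    ValidationError,
    logger,
)

#: truncation tolerance on the max entry of a series term
SERIES_TOL = 1e-12
#: qPCR |fold| boundary for confirming or overriding a documented sign
QPCR_FOLD_CUTOFF = 2.0


@dataclass
class RegGraph:
    """Documented regulatory graph with its reverse diffusion operator."""

    nodes: list[str]                    # lexicographic order
    index: dict[str, int]
    tf_nodes: list[str]                 # nodes acting as regulators
    reverse_transition: sparse.csr_matrix   # M[i, j]: heat flow j -> i
    regulon: RegulonDB


@dataclass(frozen=True)
class TFWeight:
    """Diffusion weight and seed coverage of one candidate regulator."""

    tf: str
    weight: float
    seed_target_fraction: float


def build_graph(regulon: RegulonDB) -> RegGraph:
    """Build the reverse-normalized diffusion operator from a regulon.

    For every target with d documented regulators, each regulator receives
    1/d of the target's heat per step; a node with no documented regulators
    keeps its heat, so mass is conserved and per-target reverse weights sum
    to one.
    """
    if len(regulon) == 0:
        raise ValidationError("cannot build a graph from an empty regulon")
    nodes = sorted({a.regulator for a in regulon.associations}
                   | {a.target for a in regulon.associations})
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    regs_of: dict[str, list[str]] = {}
    for a in regulon.associations:
        regs_of.setdefault(a.target, []).append(a.regulator)

    rows, cols, vals = [], [], []
    for node in nodes:
        regs = regs_of.get(node)
        if regs:
            share = 1.0 / len(regs)
            for r in sorted(set(regs)):
                rows.append(index[r])
                cols.append(index[node])
                vals.append(share * regs.count(r))
        else:
            rows.append(index[node])
            cols.append(index[node])
            vals.append(1.0)
    M = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return RegGraph(
        nodes=nodes,
        index=index,
        tf_nodes=sorted(regulon.regulators()),
        reverse_transition=M,
        regulon=regulon,
    )


def tfrank(graph: RegGraph, seeds: set[str],
           params: PipelineParams | None = None) -> list[TFWeight]:
    """Rank candidate regulators of the seed genes by diffusion weight.

    Seeds start with uniform heat 1/|seeds|; the truncated exponential
    series accumulates the heat reaching each node.  Weights are reported
    for TF nodes only, sorted descending with lexicographic tie-break.  The
    seed-coverage fraction uses the full seed list as denominator, the way
    "percentage of target genes in the user set" is defined.
    """
    params = params or PipelineParams()
    seeds = set(seeds)
    if not seeds:
        raise ValidationError("tfrank requires a non-empty seed set")
    in_graph = seeds & set(graph.index)
    dropped = seeds - in_graph
    if dropped:
        logger.warning("%d seed gene(s) absent from the regulatory graph; dropped",
                       len(dropped))
    if not in_graph:
        raise ValidationError("no seed gene is present in the regulatory graph")

    s = np.zeros(len(graph.nodes))
    for g in in_graph:
        s[graph.index[g]] = 1.0 / len(seeds)

    alpha = params.diffusion_coefficient
    M = graph.reverse_transition
    weight = np.zeros_like(s)
    term = s.copy()
    j = 0
    while True:
        j += 1
        term = (alpha / j) * (M @ term)
        weight += term
        if term.max(initial=0.0) < SERIES_TOL or j > 200:
            break

    out = [
        TFWeight(
            tf=tf,
            weight=float(weight[graph.index[tf]]),
            seed_target_fraction=len(graph.regulon.targets_of(tf) & seeds) / len(seeds),
        )
        for tf in graph.tf_nodes
    ]
    out.sort(key=lambda w: (-w.weight, w.tf))
    return out


def top_ranked(weights: list[TFWeight], params: PipelineParams | None = None) -> list[str]:
    """Top-k TFs by weight among those covering > min_target_fraction of seeds.

    The coverage filter applies first (strictly more than the threshold, per
    "more than 40%"), then the k highest weights are taken; fewer are
    returned, with a logged shortfall, when candidates run out.
    """
    params = params or PipelineParams()
    qualified = [w.tf for w in weights
                 if w.seed_target_fraction > params.min_target_fraction]
    if len(qualified) < params.top_k:
        logger.warning("only %d of the requested top %d TFs pass the >%g seed-"
                       "coverage filter", len(qualified), params.top_k,
                       params.min_target_fraction)
    return qualified[: params.top_k]


def documented_regulators(core_tf: str, regulon: RegulonDB) -> set[str]:
    """TFs documented to regulate the core TF's own transcription."""
    return regulon.regulators_of(core_tf)


def select_upstream(top: set[str] | list[str], documented: set[str],
                    downstream_sdetfs: set[str], core_tf: str) -> set[str]:
    """Triangulate upstream regulators of a core TF.

    Keep TFs that are both top-ranked for the deletion's SDEGs and documented
    regulators of the core TF, excluding the core TF's own downstream SDETFs
    (and the core TF itself) to avoid circular attribution.
    """
    return (set(top) & set(documented)) - set(downstream_sdetfs) - {core_tf}


def upstream_edge_sign(upstream_tf: str, core_tf: str, documented_sign: str,
                       qpcr_fold: float | None = None) -> SignedEdge:
    """Sign the upstream->core edge, letting qPCR evidence overrule the database.

    A signed fold change of the core TF upon upstream-TF deletion at or
    beyond +2 means the upstream TF was inhibiting it; at or beyond -2,
    activating it.  Weaker evidence keeps the documented sign, flagged
    unconfirmed; with no qPCR at all the documented sign passes through.  An
    unknown documented sign with no qPCR yields an edge flagged unresolved.
    """
    doc_as_edge = {SIGN_ACTIVATION: ACTIVATES, SIGN_INHIBITION: INHIBITS}.get(documented_sign)
    if qpcr_fold is not None:
        if qpcr_fold >= QPCR_FOLD_CUTOFF:
            sign, note = INHIBITS, f"qPCR fold {qpcr_fold:+g} upon deletion => inhibitor"
            if doc_as_edge == ACTIVATES:
                note += " (overrides documented activation)"
        elif qpcr_fold <= -QPCR_FOLD_CUTOFF:
            sign, note = ACTIVATES, f"qPCR fold {qpcr_fold:+g} upon deletion => activator"
            if doc_as_edge == INHIBITS:
                note += " (overrides documented inhibition)"
        elif doc_as_edge is not None:
            sign = doc_as_edge
            note = (f"documented {documented_sign} retained; qPCR fold "
                    f"{qpcr_fold:+g} below the +/-{QPCR_FOLD_CUTOFF:g} boundary "
                    "(unconfirmed)")
        else:
            sign = UNRESOLVED
            note = f"documented sign unknown; qPCR fold {qpcr_fold:+g} inconclusive"
    elif doc_as_edge is not None:
        sign, note = doc_as_edge, f"documented {documented_sign} (no qPCR evidence)"
    else:
        sign, note = UNRESOLVED, "documented sign unknown and no qPCR evidence"
        logger.warning("upstream edge %s->%s emitted with unresolved sign",
                       upstream_tf, core_tf)
    logger.debug("rule upstream->core fired: %s -%s-> %s (%s)",
                 upstream_tf, sign, core_tf, note)
    return SignedEdge(
        source=upstream_tf,
        target=core_tf,
        sign=sign,
        layer_pair=LP_UPSTREAM_CORE,
        provenance=f"upstream sign rule: {note}",
    )
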