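"""Downstream network dissection: SDETFs, associations and sign logic.

A core-TF deletion perturbs a set of genes (the SDEGs).  The SDEGs that are
themselves transcription factors with documented targets — the SDETFs —
form the middle layer of the core TF's sub-network.  Two deterministic sign
rules orient the edges:

* core -> middle: a downstream TF whose expression *decreased* upon deletion
  was activated by the core TF; one whose expression increased was
  inhibited.
* middle -> process: the SDETF's associated SDEGs are split by direction and
  each group is enriched separately; when the SDETF and the gene group moved
  in the same direction the SDETF activates the enriched process, otherwise
  it inhibits it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .datatypes import (
    ACTIVATES,
    INHIBITS,
    LP_CORE_MIDDLE,
    LP_MIDDLE_PROCESS,
    GeneRecord,
    GOTermSet,
    PipelineParams,
    RegulonDB,
    SDEGSet,
    SignedEdge,
    logger,
    process_node_id,
)
from .setops import enrich


@dataclass
class SDETF:
    """A significantly differentially expressed TF under one core-TF deletion."""

    tf: str
    direction: str  # expression change upon core-TF deletion: "up" or "down"
    core_contrast: object
    associated_up: set[str] = field(default_factory=set)
    associated_down: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class CoverageStats:
    """How much of the SDEG sets the SDETF associations explain."""

    n_sdetfs: int
    frac_up_covered: float
    frac_down_covered: float


def find_sdetfs(sdegs: SDEGSet, regulon: RegulonDB,
                catalog: list[GeneRecord]) -> list[SDETF]:
    """SDEGs that are TFs with at least one documented regulatory target.

    Direction is the gene's own SDEG direction; associated target sets start
    empty and are filled by :func:`associate_targets`.
    """
    tf_ids = {g.gene_id for g in catalog if g.is_tf}
    out = []
    for gene in sorted(sdegs.all_genes):
        if gene in tf_ids and regulon.targets_of(gene):
            out.append(SDETF(tf=gene, direction=sdegs.direction_of(gene),
                             core_contrast=sdegs.contrast))
    return out


def associate_targets(sdetf: SDETF, sdegs: SDEGSet, regulon: RegulonDB) -> SDETF:
    """Intersect the SDETF's documented targets with the contrast's SDEGs.

    A TF documented to target itself never contributes itself, preventing
    degenerate self-loops downstream.
    """
    targets = regulon.targets_of(sdetf.tf) - {sdetf.tf}
    sdetf.associated_up = targets & sdegs.up
    sdetf.associated_down = targets & sdegs.down
    return sdetf


def core_to_middle_sign(core_tf: str, sdetf: SDETF) -> SignedEdge:
    """Orient the core->middle edge from the SDETF's expression change.

    Decreased expression upon core-TF deletion means the core TF was
    activating the SDETF; increased expression means it was inhibiting it.
    """
    sign = ACTIVATES if sdetf.direction == "down" else INHIBITS
    logger.debug("rule core->middle fired: %s -%s-> %s (direction=%s)",
                 core_tf, sign, sdetf.tf, sdetf.direction)
    return SignedEdge(
        source=core_tf,
        target=sdetf.tf,
        sign=sign,
        layer_pair=LP_CORE_MIDDLE,
        provenance=(
            f"core-to-middle rule: {sdetf.tf} {sdetf.direction} upon {core_tf} "
            f"deletion ({sdetf.core_contrast.label()})"
        ),
    )


def middle_to_process_edges(sdetf: SDETF, go_terms: list[GOTermSet],
                            universe: set[str],
                            params: PipelineParams | None = None) -> list[SignedEdge]:
    """Signed edges from an SDETF to the processes its associated SDEGs enrich.

    The up- and down-regulated associated genes are enriched separately.
    Same trend of SDETF and gene group => activates; opposite trend =>
    inhibits.  Process nodes are keyed by (term, gene-group direction) so one
    term can carry distinguishable edges from different TFs and groups.
    """
    params = params or PipelineParams()
    edges = []
    for group_direction, genes in (("up", sdetf.associated_up),
                                   ("down", sdetf.associated_down)):
        if not genes:
            continue
        for row in enrich(genes, go_terms, universe, params):
            if not row.significant:
                continue
            sign = ACTIVATES if sdetf.direction == group_direction else INHIBITS
            logger.debug("rule middle->process fired: %s -%s-> %s|%s "
                         "(tf=%s, group=%s)", sdetf.tf, sign, row.term_id,
                         group_direction, sdetf.direction, group_direction)
            edges.append(SignedEdge(
                source=sdetf.tf,
                target=process_node_id(row.term_id, group_direction),
                sign=sign,
                layer_pair=LP_MIDDLE_PROCESS,
                provenance=(
                    f"middle-to-process rule: {sdetf.tf} {sdetf.direction}, "
                    f"{group_direction}-group enriched {row.term_id} "
                    f"(k={row.k}/{row.K}, p_bonf={row.p_bonf:.3g})"
                ),
            ))
    return edges


def coverage(sdegs: SDEGSet, sdetfs: list[SDETF]) -> CoverageStats:
    """Fraction of up/down SDEGs associated with at least one SDETF."""
    covered_up: set[str] = set()
    covered_down: set[str] = set()
    for s in sdetfs:
        covered_up |= s.associated_up
        covered_down |= s.associated_down
    return CoverageStats(
        n_sdetfs=len(sdetfs),
        frac_up_covered=len(covered_up & sdegs.up) / len(sdegs.up) if sdegs.up else 0.0,
        frac_down_covered=(
            len(covered_down & sdegs.down) / len(sdegs.down) if sdegs.down else 0.0
        ),
    )
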