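"""Shared domain types for the regulatory-network inference pipeline.

The pipeline moves read counts from TF-deletion strains through differential
expression, set operations, sign-logic dissection and heat-diffusion ranking
into one layered signed network.  Every stage exchanges the types defined
here; validation happens at construction so downstream code can assume
well-formed objects.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("trninfer")

ACTIVATES = "activates"
INHIBITS = "inhibits"
UNRESOLVED = "unresolved"

#: sign vocabulary for documented regulations
SIGN_ACTIVATION = "activation"
SIGN_INHIBITION = "inhibition"
SIGN_UNKNOWN = "unknown"

EVIDENCE_DOCUMENTED = "documented_expression"
EVIDENCE_OTHER = "other"

LAYER_UPSTREAM = "upstream"
LAYER_CORE = "core"
LAYER_MIDDLE = "middle"
LAYER_PROCESS = "process"

LP_UPSTREAM_CORE = "upstream->core"
LP_CORE_MIDDLE = "core->middle"
LP_MIDDLE_PROCESS = "middle->process"


class ValidationError(ValueError):
    """Raised when an input object or file violates a documented invariant."""


@dataclass(frozen=True)
class GeneRecord:
    """One gene of the annotation catalog.

    ``length_bp`` feeds the RPKM denominator; ``is_tf`` marks candidate
    regulators for the SDETF search.
    """

    gene_id: str
    length_bp: int
    is_tf: bool = False

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValidationError("gene_id must be non-empty")
        if int(self.length_bp) < 1:
            raise ValidationError(
                f"gene {self.gene_id!r}: length_bp must be >= 1, got {self.length_bp}"
            )


@dataclass(frozen=True)
class SampleMeta:
    """One sequencing library: genotype ('WT' or deleted TF), temperature, replicate."""

    sample_id: str
    genotype: str
    temperature_c: float
    replicate: int

    def __post_init__(self) -> None:
        if self.temperature_c <= 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: temperature_c must be positive"
            )
        if int(self.replicate) < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )

    @property
    def condition(self) -> tuple[str, float]:
        return (self.genotype, self.temperature_c)


@dataclass
class CountMatrix:
    """Gene x sample matrix of raw, non-negative integer read counts.

    Counts stay integer and un-normalized here; RPKM and size-factor
    normalization live in :mod:`trninfer.diffexpr` so the raw matrix is exact.
    """

    genes: list[GeneRecord]
    samples: list[SampleMeta]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if self.counts.size and not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValidationError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.size and (self.counts < 0).any():
            g, s = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count {self.counts[g, s]} for gene "
                f"{self.genes[g].gene_id!r} in sample {self.samples[s].sample_id!r}"
            )
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate gene_id(s): {dup}")
        keys = [(s.genotype, s.temperature_c, s.replicate) for s in self.samples]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (genotype, temperature, replicate) in samples")
        self._gene_index = {g.gene_id: i for i, g in enumerate(self.genes)}

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def gene_row(self, gene_id: str) -> np.ndarray:
        return self.counts[self._gene_index[gene_id]]

    def columns_for(self, genotype: str, temperature_c: float) -> list[int]:
        return [
            j
            for j, s in enumerate(self.samples)
            if s.genotype == genotype and s.temperature_c == temperature_c
        ]

    def tf_ids(self) -> set[str]:
        return {g.gene_id for g in self.genes if g.is_tf}


@dataclass(frozen=True)
class Contrast:
    """A deletion-vs-wild-type comparison at one temperature."""

    deletion_genotype: str
    temperature_c: float
    reference_genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.deletion_genotype == self.reference_genotype:
            raise ValidationError("contrast must compare a deletion to a different reference")

    def label(self) -> str:
        return f"{self.deletion_genotype}_vs_{self.reference_genotype}_{self.temperature_c:g}C"


@dataclass(frozen=True)
class RegulatoryAssociation:
    """A documented regulator->target relation with optional sign."""

    regulator: str
    target: str
    evidence: str = EVIDENCE_DOCUMENTED
    documented_sign: str = SIGN_UNKNOWN

    def __post_init__(self) -> None:
        if self.evidence not in (EVIDENCE_DOCUMENTED, EVIDENCE_OTHER):
            raise ValidationError(f"unknown evidence token {self.evidence!r}")
        if self.documented_sign not in (SIGN_ACTIVATION, SIGN_INHIBITION, SIGN_UNKNOWN):
            raise ValidationError(f"unknown sign token {self.documented_sign!r}")


class RegulonDB:
    """Documented regulations, indexed both by regulator and by target.

    The local stand-in for a curated regulation database restricted to
    expression evidence.  Duplicate (regulator, target) pairs collapse to a
    single association; conflicting documented signs collapse to ``unknown``
    with a logged warning.
    """

    def __init__(self, associations: Iterable[RegulatoryAssociation] = ()) -> None:
        self._by_pair: dict[tuple[str, str], RegulatoryAssociation] = {}
        self._by_regulator: dict[str, set[str]] = {}
        self._by_target: dict[str, set[str]] = {}
        self.sign_conflicts: list[tuple[str, str]] = []
        for assoc in associations:
            self.add(assoc)

    def add(self, assoc: RegulatoryAssociation) -> None:
        key = (assoc.regulator, assoc.target)
        prior = self._by_pair.get(key)
        if prior is None:
            self._by_pair[key] = assoc
            self._by_regulator.setdefault(assoc.regulator, set()).add(assoc.target)
            self._by_target.setdefault(assoc.target, set()).add(assoc.regulator)
            return
        if prior.documented_sign != assoc.documented_sign:
            logger.warning(
                "sign conflict for %s->%s (%s vs %s); collapsing to unknown",
                assoc.regulator, assoc.target, prior.documented_sign, assoc.documented_sign,
            )
            self.sign_conflicts.append(key)
            self._by_pair[key] = dataclasses.replace(prior, documented_sign=SIGN_UNKNOWN)

    @property
    def associations(self) -> list[RegulatoryAssociation]:
        return list(self._by_pair.values())

    def __len__(self) -> int:
        return len(self._by_pair)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._by_pair

    def targets_of(self, regulator: str) -> set[str]:
        return set(self._by_regulator.get(regulator, ()))

    def regulators_of(self, target: str) -> set[str]:
        return set(self._by_target.get(target, ()))

    def sign_of(self, regulator: str, target: str) -> str:
        assoc = self._by_pair.get((regulator, target))
        return assoc.documented_sign if assoc is not None else SIGN_UNKNOWN

    def regulators(self) -> set[str]:
        return set(self._by_regulator)

    def validate_against_catalog(self, genes: Sequence[GeneRecord]) -> None:
        """Every regulator present in the catalog must be flagged is_tf."""
        flags = {g.gene_id: g.is_tf for g in genes}
        for reg in sorted(self.regulators()):
            if reg in flags and not flags[reg]:
                raise ValidationError(f"regulator {reg!r} is not flagged is_tf in the catalog")


@dataclass(frozen=True)
class GOTermSet:
    """A flat biological-process annotation: term id, name, member genes."""

    term_id: str
    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValidationError(f"GO term {self.term_id!r} has an empty gene set")


@dataclass(frozen=True)
class PipelineParams:
    """All thresholds of the inference chain, serialized with every run.

    Defaults are the study conditions: |fold change| >= 2.0 with FDR <= 0.05
    for SDEG calling, Bonferroni 0.05 for enrichment, heat-diffusion
    coefficient 0.25, top six ranked TFs each covering more than 40% of the
    seed SDEGs.
    """

    fc_threshold: float = 2.0
    fdr_alpha: float = 0.05
    enrich_alpha: float = 0.05
    diffusion_coefficient: float = 0.25
    top_k: int = 6
    min_target_fraction: float = 0.40
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValidationError("fc_threshold must be positive")
        for name in ("fdr_alpha", "enrich_alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValidationError(f"{name} must be in (0, 1]")
        if self.diffusion_coefficient <= 0:
            raise ValidationError("diffusion_coefficient must be positive")
        if self.top_k < 1:
            raise ValidationError("top_k must be a positive integer")
        if not (0 <= self.min_target_fraction <= 1):
            raise ValidationError("min_target_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SignedEdge:
    """A directed signed regulatory edge between network layers.

    ``provenance`` records the rule and inputs that produced the edge so the
    assembled network is auditable.  ``sign`` is ``activates`` or ``inhibits``;
    the single ``unresolved`` value is emitted only when a documented sign is
    unknown and no qPCR evidence exists to adjudicate it.
    """

    source: str
    target: str
    sign: str
    layer_pair: str
    provenance: str

    def __post_init__(self) -> None:
        if self.sign not in (ACTIVATES, INHIBITS, UNRESOLVED):
            raise ValidationError(f"unknown edge sign {self.sign!r}")
        if self.layer_pair not in (LP_UPSTREAM_CORE, LP_CORE_MIDDLE, LP_MIDDLE_PROCESS):
            raise ValidationError(f"unknown layer_pair {self.layer_pair!r}")
        if not self.provenance:
            raise ValidationError("edge provenance must be non-empty")


@dataclass
class SDEGSet:
    """Up/down significantly differentially expressed genes for one contrast."""

    contrast: Contrast
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValidationError(f"genes in both up and down sets: {sorted(overlap)[:5]}")

    @property
    def all_genes(self) -> set[str]:
        return self.up | self.down

    def direction_of(self, gene_id: str) -> str:
        if gene_id in self.up:
            return "up"
        if gene_id in self.down:
            return "down"
        raise KeyError(gene_id)


def process_node_id(term_id: str, group_direction: str) -> str:
    """Node id for an enriched process, keyed by (term, gene-group direction).

    The same term reached through an up-regulated and a down-regulated gene
    group stays distinguishable, mirroring how one biological process can be
    activated via one TF and inhibited via another.
    """
    return f"{term_id}|{group_direction}"
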