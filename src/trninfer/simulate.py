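"""Ground-truth network and count simulation for pipeline validation.

The generator plants a layered signed regulatory network — upstream TFs
documented to regulate the core TFs, core TFs causally regulating middle
TFs, middle TFs causally regulating disjoint blocks of target genes — and
draws negative-binomial read counts for wild-type and deletion strains at
two temperatures in biological duplicates.  Deleting a TF zeroes its own
transcript and shifts every downstream node by 2^(+-effect_log2fc) along
composed planted signs (activation of an activator propagates activation;
crossing an inhibitor flips the direction), to a propagation depth of two
levels below the deleted node.

Upstream TFs additionally carry *documented-only* regulations covering a
large random fraction of the gene universe.  These emulate how curated
regulation databases document far more targets than any one deletion
perturbs; they give the heat-diffusion ranking something to find without
injecting causal effects.

Everything is deterministic given the truth seed; per-strain count draws
re-seed from a stable hash of (seed, genotype, temperature).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    EVIDENCE_DOCUMENTED,
    SIGN_ACTIVATION,
    SIGN_INHIBITION,
    SIGN_UNKNOWN,
    CountMatrix,
    GeneRecord,
    GOTermSet,
    RegulatoryAssociation,
    RegulonDB,
    SampleMeta,
    ValidationError,
)

KIND_UPSTREAM_CORE = "upstream->core"
KIND_CORE_MIDDLE = "core->middle"
KIND_MIDDLE_GENE = "middle->gene"
KIND_DOCUMENTED_ONLY = "documented_only"

#: knockout residual expression (fraction of baseline) for a deleted TF
KNOCKOUT_FACTOR = 2.0**-10


@dataclass(frozen=True)
class PlantedEdge:
    """One planted regulation: documented sign plus its role in the truth."""

    regulator: str
    target: str
    sign: str  # activation / inhibition
    kind: str  # which layer pair, or documented-only


@dataclass
class SyntheticTruth:
    """Planted network, simulation parameters and derived per-gene baselines."""

    upstream_tfs: list[str]
    core_tfs: list[str]
    middle_tfs: list[str]
    genes: list[str]
    edges: list[PlantedEdge]
    go_modules: dict[str, frozenset[str]]
    effect_log2fc: float
    dispersion: float
    lib_size_mean: float
    replicates: int
    temperatures: tuple[float, ...]
    seed: int
    baseline_mean: dict[str, float] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)

    @property
    def all_ids(self) -> list[str]:
        return self.upstream_tfs + self.core_tfs + self.middle_tfs + self.genes

    @property
    def tf_ids(self) -> set[str]:
        return set(self.upstream_tfs) | set(self.core_tfs) | set(self.middle_tfs)

    def edges_of_kind(self, kind: str) -> list[PlantedEdge]:
        return [e for e in self.edges if e.kind == kind]

    def catalog(self) -> list[GeneRecord]:
        tfs = self.tf_ids
        return [GeneRecord(g, self.gene_lengths[g], g in tfs) for g in self.all_ids]


def sample_truth(
    n_genes: int = 2000,
    n_middle: int = 25,
    n_core: int = 3,
    n_upstream: int = 2,
    seed: int = 0,
    effect_log2fc: float = 3.0,
    dispersion: float = 0.05,
    replicates: int = 2,
    temperatures: tuple[float, ...] = (30.0, 40.0),
    lib_size_mean: float = 80.0,
    regulated_gene_fraction: float = 0.8,
    documented_coverage: float = 0.6,
    n_decoy_modules: int | None = None,
    force_activation: bool = False,
) -> SyntheticTruth:
    """Draw a random layered truth at the study's scale.

    Defaults mirror the study design: three profiled core TFs, a middle
    layer of 25 TFs, biological duplicates at 30 and 40 degC, and an
    8-fold (effect_log2fc = 3) planted shift at dispersion 0.05.  Each
    middle TF receives a disjoint block of target genes so two-level sign
    composition is unambiguous; ``force_activation`` makes every planted
    sign an activation (degenerate option for exact sign checks).
    """
    if n_genes < 10 * n_middle:
        raise ValidationError(
            f"infeasible sizes: need n_genes >= 10 x n_middle, got {n_genes} < "
            f"{10 * n_middle}")
    if min(n_genes, n_middle, n_core, n_upstream) < 1:
        raise ValidationError("all layer sizes must be >= 1")
    rng = np.random.default_rng(seed)

    upstream = [f"UTF{i+1:02d}" for i in range(n_upstream)]
    core = [f"CTF{i+1}" for i in range(n_core)]
    middle = [f"MTF{i+1:02d}" for i in range(n_middle)]
    genes = [f"G{i+1:04d}" for i in range(n_genes)]

    def draw_sign() -> str:
        if force_activation:
            return SIGN_ACTIVATION
        return SIGN_ACTIVATION if rng.random() < 0.5 else SIGN_INHIBITION

    edges: list[PlantedEdge] = []
    # upstream -> core: every upstream TF documents a signed regulation of
    # every core TF, so triangulation has a well-defined target set.
    for u in upstream:
        for c in core:
            edges.append(PlantedEdge(u, c, draw_sign(), KIND_UPSTREAM_CORE))
    # core -> middle: random non-empty regulator subset per middle TF
    for m in middle:
        regulators = [c for c in core if rng.random() < 0.5]
        if not regulators:
            regulators = [core[rng.integers(len(core))]]
        for c in regulators:
            edges.append(PlantedEdge(c, m, draw_sign(), KIND_CORE_MIDDLE))
    # middle -> gene: disjoint target blocks over a shuffled gene subset
    n_regulated = int(round(regulated_gene_fraction * n_genes))
    shuffled = list(rng.permutation(genes))
    blocks = np.array_split(np.array(shuffled[:n_regulated]), n_middle)
    module_map: dict[str, frozenset[str]] = {}
    for m, block in zip(middle, blocks):
        for g in block:
            edges.append(PlantedEdge(m, str(g), draw_sign(), KIND_MIDDLE_GENE))
        module_map[f"MOD:{m}"] = frozenset(str(g) for g in block)
    # documented-only coverage of the gene universe by upstream TFs
    for u in upstream:
        covered = rng.random(n_genes) < documented_coverage
        for g, hit in zip(genes, covered):
            if hit:
                edges.append(PlantedEdge(u, g, draw_sign(), KIND_DOCUMENTED_ONLY))
    # decoy GO modules of matched size, disjoint from nothing in particular
    if n_decoy_modules is None:
        n_decoy_modules = n_middle
    mean_block = max(2, n_regulated // n_middle)
    for d in range(n_decoy_modules):
        members = rng.choice(genes, size=mean_block, replace=False)
        module_map[f"DECOY:{d+1:02d}"] = frozenset(str(g) for g in members)

    truth = SyntheticTruth(
        upstream_tfs=upstream, core_tfs=core, middle_tfs=middle, genes=genes,
        edges=edges, go_modules=module_map, effect_log2fc=effect_log2fc,
        dispersion=dispersion, lib_size_mean=lib_size_mean,
        replicates=replicates, temperatures=tuple(temperatures), seed=seed,
    )
    # Baselines: TFs from a tighter, higher log-normal than bulk genes, so
    # regulator transcripts sit in the comfortably quantifiable range.
    for name in truth.all_ids:
        if name in truth.tf_ids:
            truth.baseline_mean[name] = float(
                np.exp(rng.normal(np.log(2.5 * lib_size_mean), 0.5)))
        else:
            truth.baseline_mean[name] = float(
                np.exp(rng.normal(np.log(lib_size_mean), 1.0)))
        truth.gene_lengths[name] = int(rng.integers(500, 4001))
    return truth


def _strain_seed(seed: int, genotype: str, temperature_c: float) -> int:
    return zlib.crc32(f"{seed}|{genotype}|{temperature_c:g}".encode()) & 0x7FFFFFFF


def _direction_factor(direction_up: bool, effect_log2fc: float) -> float:
    return 2.0**effect_log2fc if direction_up else 2.0**-effect_log2fc


def expected_shift_directions(truth: SyntheticTruth, genotype: str) -> dict[str, bool]:
    """Map node -> True if its expression rises upon deleting ``genotype``.

    Walks planted causal edges two levels below the deleted TF, composing
    signs: losing an activator lowers the target, losing an inhibitor
    raises it, and each inhibition crossed below flips the direction.
    """
    if genotype in truth.upstream_tfs:
        level_1, level_2 = KIND_UPSTREAM_CORE, KIND_CORE_MIDDLE
    elif genotype in truth.core_tfs:
        level_1, level_2 = KIND_CORE_MIDDLE, KIND_MIDDLE_GENE
    else:
        raise ValidationError(f"unknown deletion genotype {genotype!r}")
    by_regulator: dict[str, list[PlantedEdge]] = {}
    for e in truth.edges:
        if e.kind == level_2:
            by_regulator.setdefault(e.regulator, []).append(e)
    directions: dict[str, bool] = {}
    for e1 in truth.edges:
        if e1.kind != level_1 or e1.regulator != genotype:
            continue
        up1 = e1.sign == SIGN_INHIBITION  # lost inhibition => target rises
        directions[e1.target] = up1
        for e2 in by_regulator.get(e1.target, ()):
            directions[e2.target] = up1 ^ (e2.sign == SIGN_INHIBITION)
    return directions


def simulate_counts(truth: SyntheticTruth, genotype: str,
                    temperature_c: float) -> CountMatrix:
    """Negative-binomial replicate counts for one strain at one temperature.

    The deleted TF's own transcript drops to a residual 2^-10 of baseline;
    affected downstream means shift by 2^(+-effect_log2fc); counts follow
    NB(mean, phi) with variance mu + phi mu^2.  Deterministic under
    (truth.seed, genotype, temperature).
    """
    if genotype != "WT" and genotype not in truth.tf_ids:
        raise ValidationError(f"unknown genotype {genotype!r}")
    if genotype in truth.middle_tfs:
        raise ValidationError(
            f"deletion strains exist only for core and upstream TFs, not {genotype!r}")
    rng = np.random.default_rng(_strain_seed(truth.seed, genotype, temperature_c))

    means = np.array([truth.baseline_mean[g] for g in truth.all_ids])
    if genotype != "WT":
        idx = {g: i for i, g in enumerate(truth.all_ids)}
        means = means.copy()
        means[idx[genotype]] *= KNOCKOUT_FACTOR
        for node, rises in expected_shift_directions(truth, genotype).items():
            means[idx[node]] *= _direction_factor(rises, truth.effect_log2fc)

    phi = truth.dispersion
    r = 1.0 / phi
    p = r / (r + means)
    counts = rng.negative_binomial(r, p[:, None],
                                   size=(means.size, truth.replicates))
    samples = [
        SampleMeta(f"{genotype}_{temperature_c:g}C_r{k+1}", genotype,
                   temperature_c, k + 1)
        for k in range(truth.replicates)
    ]
    return CountMatrix(genes=truth.catalog(), samples=samples, counts=counts)


def simulate_experiment(truth: SyntheticTruth,
                        include_upstream_deletions: bool = False) -> CountMatrix:
    """Full count matrix: WT plus deletion strains at every temperature."""
    genotypes = ["WT"] + list(truth.core_tfs)
    if include_upstream_deletions:
        genotypes += list(truth.upstream_tfs)
    blocks, samples = [], []
    for temperature in truth.temperatures:
        for genotype in genotypes:
            cm = simulate_counts(truth, genotype, temperature)
            blocks.append(cm.counts)
            samples.extend(cm.samples)
    return CountMatrix(genes=truth.catalog(), samples=samples,
                       counts=np.hstack(blocks))


def emit_regulon(truth: SyntheticTruth, completeness: float = 1.0,
                 spurious_rate: float = 0.0, seed: int = 0) -> RegulonDB:
    """Documented regulations derived from the truth, optionally degraded.

    Every planted edge (causal and documented-only) is kept with probability
    ``completeness`` with its sign preserved; spurious TF->gene associations
    of unknown sign are added at ``spurious_rate`` x the true edge count,
    never duplicating a true pair.
    """
    if not (0 <= completeness <= 1):
        raise ValidationError("completeness must be in [0, 1]")
    if spurious_rate < 0:
        raise ValidationError("spurious_rate must be >= 0")
    rng = np.random.default_rng(seed)
    db = RegulonDB()
    true_pairs = {(e.regulator, e.target) for e in truth.edges}
    for e in truth.edges:
        if rng.random() < completeness:
            db.add(RegulatoryAssociation(e.regulator, e.target,
                                         EVIDENCE_DOCUMENTED, e.sign))
    n_spurious = int(round(spurious_rate * len(truth.edges)))
    tfs = sorted(truth.tf_ids)
    targets = truth.all_ids
    added = 0
    while added < n_spurious:
        pair = (tfs[rng.integers(len(tfs))], targets[rng.integers(len(targets))])
        if pair in true_pairs or pair[0] == pair[1] or pair in db:
            continue
        db.add(RegulatoryAssociation(pair[0], pair[1], EVIDENCE_DOCUMENTED,
                                     SIGN_UNKNOWN))
        added += 1
    return db


def truth_go_terms(truth: SyntheticTruth) -> list[GOTermSet]:
    """GO-style flat term sets from the planted modules (plus decoys)."""
    return [
        GOTermSet(term_id=name, name=name.replace(":", " module "), genes=members)
        for name, members in sorted(truth.go_modules.items())
    ]


def emit_dataset(truth: SyntheticTruth, out_dir,
                 completeness: float = 1.0, spurious_rate: float = 0.0,
                 include_upstream_deletions: bool = False) -> dict[str, str]:
    """Write counts/annotation/metadata/regulon/GMT files the readers accept."""
    from pathlib import Path

    from . import io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm = simulate_experiment(truth, include_upstream_deletions)
    paths = {
        "counts": out / "counts.tsv",
        "annotation": out / "annotation.tsv",
        "metadata": out / "samples.tsv",
        "regulon": out / "regulon.tsv",
        "gmt": out / "go_modules.gmt",
    }
    io.write_counts(cm, paths["counts"])
    io.write_annotation(cm.genes, paths["annotation"])
    io.write_sample_metadata(cm.samples, paths["metadata"])
    io.write_regulon(
        emit_regulon(truth, completeness, spurious_rate, seed=truth.seed),
        paths["regulon"])
    io.write_go_gmt(truth_go_terms(truth), paths["gmt"])
    return {k: str(v) for k, v in paths.items()}
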