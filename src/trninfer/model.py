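"""Model/Results interface over the full inference chain.

:class:`RegulatoryNetworkModel` holds the data (counts, documented regulon,
GO annotation) and the thresholds; :meth:`~RegulatoryNetworkModel.fit` runs
differential expression, Venn partitioning with enrichment, downstream
sign-logic dissection, heat-diffusion upstream ranking and network assembly,
returning a :class:`RegulatoryNetworkResults` that carries every
intermediate table, the assembled three-layer network and a printable
summary.

Example
-------
>>> from trninfer import simulate
>>> from trninfer.model import RegulatoryNetworkModel
>>> truth = simulate.sample_truth(n_genes=500, n_middle=10, seed=7)
>>> model = RegulatoryNetworkModel(
...     counts=simulate.simulate_experiment(truth),
...     regulon=simulate.emit_regulon(truth, seed=7),
...     go_terms=simulate.truth_go_terms(truth),
...     temperature_c=40.0,
... )
>>> results = model.fit()
>>> print(results.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import assembly, diffexpr, downstream, io, setops, tfrank
from .datatypes import (
    Contrast,
    CountMatrix,
    GOTermSet,
    PipelineParams,
    RegulonDB,
    SDEGSet,
    SignedEdge,
    ValidationError,
)


class RegulatoryNetworkModel:
    """Hierarchical regulatory-network model of TF-deletion transcriptomes.

    Parameters
    ----------
    counts
        Raw read counts for wild-type and deletion strains.
    regulon
        Documented regulator->target associations (expression evidence).
    go_terms
        Flat biological-process annotation.
    core_tfs
        The profiled deletion genotypes anchoring the sub-networks; default:
        every non-reference genotype present at the chosen temperature.
    temperature_c
        Temperature to analyze; inferred when the samples contain exactly one.
    qpcr_folds
        Optional {(upstream_tf, core_tf): signed fold change} measured in
        upstream-deletion strains, used to confirm or overrule documented
        upstream edge signs.
    """

    def __init__(
        self,
        counts: CountMatrix,
        regulon: RegulonDB,
        go_terms: list[GOTermSet],
        core_tfs: list[str] | None = None,
        temperature_c: float | None = None,
        params: PipelineParams | None = None,
        reference_genotype: str = "WT",
        qpcr_folds: dict[tuple[str, str], float] | None = None,
    ) -> None:
        self.counts = counts
        self.regulon = regulon
        self.go_terms = list(go_terms)
        self.params = params or PipelineParams()
        self.reference_genotype = reference_genotype
        self.qpcr_folds = dict(qpcr_folds or {})
        regulon.validate_against_catalog(counts.genes)

        temps = sorted({s.temperature_c for s in counts.samples})
        if temperature_c is None:
            if len(temps) != 1:
                raise ValidationError(
                    f"temperature_c must be given; samples span {temps}")
            temperature_c = temps[0]
        self.temperature_c = float(temperature_c)

        if core_tfs is None:
            core_tfs = sorted({
                s.genotype for s in counts.samples
                if s.genotype != reference_genotype
                and s.temperature_c == self.temperature_c
            })
        if not core_tfs:
            raise ValidationError("no deletion genotypes to analyze")
        self.core_tfs = list(core_tfs)

    @classmethod
    def from_files(cls, counts_path, annotation_path, metadata_path,
                   regulon_path, gmt_path, **kwargs) -> "RegulatoryNetworkModel":
        counts = io.read_counts(counts_path, annotation_path, metadata_path)
        return cls(
            counts=counts,
            regulon=io.read_regulon(regulon_path, catalog=counts.genes),
            go_terms=io.read_go_gmt(gmt_path),
            **kwargs,
        )

    def fit(self) -> "RegulatoryNetworkResults":
        """Run the full inference chain and return the results object."""
        params = self.params
        universe = set(self.counts.gene_ids)  # enrichment universe: all assayed genes
        catalog = self.counts.genes

        deg_tables: dict[str, pd.DataFrame] = {}
        sdeg_sets: dict[str, SDEGSet] = {}
        for core in self.core_tfs:
            contrast = Contrast(core, self.temperature_c, self.reference_genotype)
            table = diffexpr.de_test(self.counts, contrast)
            deg_tables[core] = table
            sdeg_sets[core] = diffexpr.sdeg_filter(table, contrast, params)

        venn = None
        region_enrichments: dict[str, list[setops.EnrichmentRow]] = {}
        if len(self.core_tfs) == 3:
            a, b, c = (sdeg_sets[t].all_genes for t in self.core_tfs)
            venn = setops.venn3(a, b, c, labels=tuple(self.core_tfs))
            for mask, genes in venn.regions.items():
                if genes:
                    region_enrichments[mask] = setops.enrich(
                        genes, self.go_terms, universe, params)

        sdetfs: dict[str, list[downstream.SDETF]] = {}
        coverage_stats: dict[str, downstream.CoverageStats] = {}
        core_edges: dict[str, list[SignedEdge]] = {}
        for core in self.core_tfs:
            sdegs = sdeg_sets[core]
            found = [
                downstream.associate_targets(s, sdegs, self.regulon)
                for s in downstream.find_sdetfs(sdegs, self.regulon, catalog)
                if s.tf != core  # the deleted gene itself is not its own SDETF
            ]
            sdetfs[core] = found
            coverage_stats[core] = downstream.coverage(sdegs, found)
            edges = [downstream.core_to_middle_sign(core, s) for s in found]
            for s in found:
                edges.extend(downstream.middle_to_process_edges(
                    s, self.go_terms, universe, params))
            core_edges[core] = edges

        graph = tfrank.build_graph(self.regulon)
        rankings: dict[str, list[tfrank.TFWeight]] = {}
        upstream_selected: dict[str, set[str]] = {}
        upstream_edges: list[SignedEdge] = []
        for core in self.core_tfs:
            seeds = sdeg_sets[core].all_genes
            if not seeds & set(graph.index):
                rankings[core] = []
                upstream_selected[core] = set()
                continue
            weights = tfrank.tfrank(graph, seeds, params)
            rankings[core] = weights
            top = tfrank.top_ranked(weights, params)
            documented = tfrank.documented_regulators(core, self.regulon)
            chosen = tfrank.select_upstream(
                top, documented, {s.tf for s in sdetfs[core]}, core)
            upstream_selected[core] = chosen
            for tf in sorted(chosen):
                upstream_edges.append(tfrank.upstream_edge_sign(
                    tf, core, self.regulon.sign_of(tf, core),
                    self.qpcr_folds.get((tf, core))))

        provenance = {
            "temperature_c": self.temperature_c,
            "reference_genotype": self.reference_genotype,
            "core_tfs": self.core_tfs,
            "enrichment_universe": "all genes in the count matrix",
            "bonferroni_factor": "number of terms with overlap >= 1",
            "upstream_rule": "coverage filter first, then top-k by weight",
            "coverage": {
                core: {
                    "n_sdetfs": cs.n_sdetfs,
                    "frac_up_covered": cs.frac_up_covered,
                    "frac_down_covered": cs.frac_down_covered,
                }
                for core, cs in coverage_stats.items()
            },
        }
        network = assembly.assemble(core_edges, upstream_edges, self.core_tfs,
                                    params, provenance)
        return RegulatoryNetworkResults(
            model=self,
            deg_tables=deg_tables,
            sdeg_sets=sdeg_sets,
            venn=venn,
            region_enrichments=region_enrichments,
            sdetfs=sdetfs,
            coverage_stats=coverage_stats,
            rankings=rankings,
            upstream_selected=upstream_selected,
            network=network,
        )


@dataclass
class RegulatoryNetworkResults:
    """Everything the fitted model produced, stage by stage."""

    model: RegulatoryNetworkModel
    deg_tables: dict[str, pd.DataFrame]
    sdeg_sets: dict[str, SDEGSet]
    venn: setops.VennPartition3 | None
    region_enrichments: dict[str, list[setops.EnrichmentRow]]
    sdetfs: dict[str, list[downstream.SDETF]]
    coverage_stats: dict[str, downstream.CoverageStats]
    rankings: dict[str, list[tfrank.TFWeight]]
    upstream_selected: dict[str, set[str]]
    network: assembly.HierarchicalNetwork
    summary_record: dict = field(init=False)

    def __post_init__(self) -> None:
        self.summary_record = assembly.summarize(self.network)

    def summary(self) -> str:
        """Human-readable run summary in the style of a fit report."""
        lines = [
            "Hierarchical regulatory network inference",
            "=" * 57,
            f"Temperature: {self.model.temperature_c:g} degC   "
            f"reference: {self.model.reference_genotype}",
            f"Core TFs: {', '.join(self.model.core_tfs)}",
            "",
            f"{'core TF':<10}{'SDEG up':>9}{'SDEG dn':>9}{'SDETFs':>8}"
            f"{'cov up':>8}{'cov dn':>8}{'upstream':>18}",
            "-" * 70,
        ]
        for core in self.model.core_tfs:
            s = self.sdeg_sets[core]
            cv = self.coverage_stats[core]
            ups = ",".join(sorted(self.upstream_selected.get(core, set()))) or "-"
            lines.append(
                f"{core:<10}{len(s.up):>9}{len(s.down):>9}{cv.n_sdetfs:>8}"
                f"{cv.frac_up_covered:>8.1%}{cv.frac_down_covered:>8.1%}{ups:>18}")
        if self.venn is not None:
            lines += ["", f"Venn union of SDEG sets: {self.venn.union_size} genes"]
            for mask in setops.VENN_MASKS:
                n = len(self.venn.regions[mask])
                lines.append(f"  region {mask}: {n:>5}  ({self.venn.region_percent(mask):.1f}%)")
        sm = self.summary_record
        lines += [
            "",
            f"Network: {sm['n_nodes']} nodes / {sm['n_edges']} edges "
            f"(layers {sm['layer_counts']})",
            f"Edge signs: {sm['sign_counts']}",
        ]
        return "\n".join(lines)

    def save(self, out_dir) -> None:
        """Write every stage's tables plus the network and params snapshot."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for core, table in self.deg_tables.items():
            io.write_deg_table(
                table.rename(columns={}), out / f"deg_{core}.tsv")
        sdeg_rows = [
            (g, direction, core)
            for core, s in self.sdeg_sets.items()
            for direction, genes in (("up", s.up), ("down", s.down))
            for g in sorted(genes)
        ]
        pd.DataFrame(sdeg_rows, columns=["gene_id", "direction", "contrast"]).to_csv(
            out / "sdegs.tsv", sep="\t", index=False)
        if self.venn is not None:
            pd.DataFrame(
                [
                    (mask, ";".join(self.venn.labels), len(genes),
                     self.venn.region_percent(mask), ";".join(sorted(genes)))
                    for mask, genes in self.venn.regions.items()
                ],
                columns=["mask", "labels", "size", "percent", "genes"],
            ).to_csv(out / "venn_regions.tsv", sep="\t", index=False)
        enr_rows = [
            (mask, r.term_id, r.name, r.k, r.K, r.n, r.N, r.p_raw, r.p_bonf,
             r.significant)
            for mask, rows in self.region_enrichments.items() for r in rows
        ]
        pd.DataFrame(enr_rows, columns=[
            "region", "term_id", "name", "k", "K", "n", "N", "p_raw", "p_bonf",
            "significant"]).to_csv(out / "region_enrichment.tsv", sep="\t",
                                   index=False)
        sdetf_rows = [
            (core, s.tf, s.direction, len(s.associated_up), len(s.associated_down))
            for core, lst in self.sdetfs.items() for s in lst
        ]
        pd.DataFrame(sdetf_rows, columns=[
            "core_tf", "tf", "direction", "n_assoc_up", "n_assoc_down"
        ]).to_csv(out / "sdetfs.tsv", sep="\t", index=False)
        rank_rows = [
            (core, i + 1, w.tf, w.weight, w.seed_target_fraction)
            for core, lst in self.rankings.items()
            for i, w in enumerate(lst)
        ]
        pd.DataFrame(rank_rows, columns=[
            "core_tf", "rank", "tf", "weight", "seed_target_fraction"
        ]).to_csv(out / "tfrank.tsv", sep="\t", index=False)
        pd.DataFrame(
            [(core, ",".join(sorted(tfs))) for core, tfs in
             self.upstream_selected.items()],
            columns=["core_tf", "upstream_tfs"],
        ).to_csv(out / "upstream_selection.tsv", sep="\t", index=False)
        edge_rows = [
            (e.source, e.target, e.sign, e.layer_pair, e.provenance)
            for e in self.network.edges
        ]
        pd.DataFrame(edge_rows, columns=[
            "source", "target", "sign", "layer_pair", "provenance"
        ]).to_csv(out / "edges.tsv", sep="\t", index=False)
        for fmt in ("json", "graphml", "dot"):
            io.write_network(self.network, out / f"network.{fmt}", fmt)
        (out / "params.json").write_text(
            json.dumps(self.model.params.to_dict(), indent=1, sort_keys=True))
        (out / "summary.txt").write_text(self.summary() + "\n")
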