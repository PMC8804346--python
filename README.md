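# trninfer

Hierarchical transcriptional-regulatory-network inference from TF-deletion
transcriptomes.

## The problem

When a transcription factor (TF) is deleted and the strain is profiled by
RNA-seq against the wild type, the genes that respond carry the signature of
the regulatory network beneath that TF.  `trninfer` turns a panel of such
deletion transcriptomes — e.g. yeast strains each lacking one
thermotolerance-associated regulator, fermented at elevated and normal
temperature in biological duplicates — into a three-layer signed regulatory
network:

    upstream TFs  →  core TFs  →  middle-layer SDETFs  →  GO biological processes

where the *core* TFs are the deletion-profiled regulators, the *middle*
layer holds the significantly differentially expressed TFs (SDETFs) each
deletion perturbs, and the terminal layer holds the biological processes
their target genes enrich.  Every edge carries a sign (activation or
inhibition) and a provenance record naming the rule that produced it.

It is written for systems-biology practitioners who have: a gene×sample
read-count table, a table of documented regulator→target associations with
expression evidence (e.g. a YEASTRACT-style export), and a flat GO
biological-process annotation (GMT).

## The method

1. **SDEG calling.** Counts are normalized by median-of-ratios size factors;
   each deletion-vs-WT contrast is tested per gene with a negative-binomial
   Wald test (method-of-moments dispersion moderated toward the genewise
   trend, floored at 0.01).  Genes with |fold change| ≥ 2 and
   Benjamini–Hochberg FDR ≤ 0.05 (both inclusive) are the significantly
   differentially expressed genes, split into up and down sets.  RPKM and
   the signed 2^−ΔΔCt qPCR fold change are provided alongside; externally
   computed DE tables are accepted through `trninfer.io.read_deg_table`.
2. **Set operations.** The three SDEG sets are partitioned into the seven
   Venn regions; each region (and later each SDETF-associated gene group)
   is tested for GO enrichment with the one-sided hypergeometric tail,
   Bonferroni-corrected over the terms actually tested, at α = 0.05.
3. **Downstream dissection.** SDEGs that are TFs with ≥ 1 documented target
   are the SDETFs.  Sign logic: an SDETF that *decreased* upon core-TF
   deletion was activated by the core TF, otherwise inhibited; an SDETF and
   an enriched gene group moving with the *same* trend means the SDETF
   activates that process, opposite trends mean inhibition.
4. **Upstream ranking.** Candidate regulators of each deletion's SDEGs are
   scored by heat diffusion over the documented graph: seeds get uniform
   heat, every target splits its heat equally among its documented
   regulators, and the weight is the truncated exponential series
   w = Σ_{j≥1} (α^j/j!) M^j s with diffusion coefficient α = 0.25.  The
   top six TFs that each cover more than 40 % of the seeds, intersected
   with the documented regulators of the core TF and cleared of its own
   downstream SDETFs, are the upstream candidates; qPCR fold changes of the
   core TF in upstream-deletion strains (|fold| ≥ 2) can confirm or
   overrule the documented sign.
5. **Assembly.** The per-core sub-networks and upstream edges merge into one
   `HierarchicalNetwork` with multi-layer node membership, per-edge
   provenance, and a regulator count per process node; export to GraphML,
   JSON (round-trippable) and DOT (solid arrow = activates, dashed =
   inhibits).

A synthetic-data generator (`trninfer.simulate`) plants a layered signed
truth and draws negative-binomial counts for all strains, so the whole
chain is testable and parameter recovery is measurable without any
download.

## Worked example

```python
from trninfer import simulate
from trninfer.model import RegulatoryNetworkModel

truth = simulate.sample_truth(n_genes=500, n_middle=10, n_core=3,
                              n_upstream=2, seed=7)
model = RegulatoryNetworkModel(
    counts=simulate.simulate_experiment(truth),
    regulon=simulate.emit_regulon(truth, seed=truth.seed),
    go_terms=simulate.truth_go_terms(truth),
    temperature_c=40.0,
)
results = model.fit()
print(results.summary())
results.save("out/")          # all stage tables + network.{json,graphml,dot}
```

prints

```
Hierarchical regulatory network inference
=========================================================
Temperature: 40 degC   reference: WT
Core TFs: CTF1, CTF2, CTF3

core TF     SDEG up  SDEG dn  SDETFs  cov up  cov dn          upstream
----------------------------------------------------------------------
CTF1            112      134       6   99.1%   95.5%       UTF01,UTF02
CTF2            122      123       6   97.5%   95.9%       UTF01,UTF02
CTF3             89       79       4   95.5%   94.9%       UTF01,UTF02

Venn union of SDEG sets: 411 genes
  region 100:    82  (20.0%)
  region 010:   121  (29.4%)
  region 001:    43  (10.5%)
  region 110:    40  (9.7%)
  region 101:    41  (10.0%)
  region 011:     1  (0.2%)
  region 111:    83  (20.2%)

Network: 36 nodes / 43 edges (layers {'upstream': 2, 'core': 3, 'middle': 10, 'process': 21})
Edge signs: {'activates': 19, 'inhibits': 18, 'unresolved': 6}
```

Reading: each row is one deletion strain's contrast against WT at 40 °C —
its up/down SDEG counts, how many of its SDEGs are themselves documented
TFs (the middle layer), what fraction of the SDEGs those SDETFs' documented
targets cover, and which upstream regulators the ranking + documentation
triangulation selected (here both planted upstream TFs, for every core).
The Venn block partitions the three SDEG sets by membership mask
(`100` = first set only, `111` = all three), with each region's share of
the union.  `unresolved` edge signs mark contradictions the data cannot
adjudicate (e.g. one TF dissected under two deletions with opposite
directions).

The same run is available from a shell:

```sh
trninfer run-all --config run.cfg --out out/
```

with a plain key–value config (`simulate.n_genes = 500`, or the five input
paths `counts/annotation/metadata/regulon/gmt`); stage subcommands
(`de`, `venn`, `enrich`, `network-down`, `rank`, `network-up`, `assemble`)
write one stage's tables each.

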