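"""Readers and writers for every on-disk format the pipeline touches.

All tabular formats are plain TSV; annotations use GMT; networks export to
GraphML (via networkx), JSON (round-trippable) and DOT (hand-written, with
solid arrows for activation and dashed for inhibition).  Validation is
total: malformed input raises :class:`~trninfer.datatypes.ValidationError`
naming the offending record, never silently coerces.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import networkx as nx
import pandas as pd

from .datatypes import (
    ACTIVATES,
    EVIDENCE_DOCUMENTED,
    SIGN_UNKNOWN,
    CountMatrix,
    GeneRecord,
    GOTermSet,
    PipelineParams,
    RegulatoryAssociation,
    RegulonDB,
    SampleMeta,
    SignedEdge,
    ValidationError,
    logger,
)

if TYPE_CHECKING:  # pragma: no cover
    from .assembly import HierarchicalNetwork

NETWORK_FORMATS = ("graphml", "json", "dot")


def _require(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"input file not found: {p}")
    return p


def read_annotation(path: str | Path) -> list[GeneRecord]:
    """Read the gene catalog TSV (gene_id, length_bp, is_tf)."""
    df = pd.read_csv(_require(path), sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "length_bp", "is_tf"):
        if col not in df.columns:
            raise ValidationError(f"annotation file missing column {col!r}")
    dup = df["gene_id"][df["gene_id"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate gene_id(s) in annotation: {sorted(set(dup))}")
    records = []
    for row in df.itertuples(index=False):
        flag = row.is_tf
        if isinstance(flag, str):
            token = flag.strip().lower()
            if token not in ("true", "false", "0", "1"):
                raise ValidationError(f"gene {row.gene_id!r}: bad is_tf token {flag!r}")
            flag = token in ("true", "1")
        records.append(GeneRecord(str(row.gene_id), int(row.length_bp), bool(flag)))
    return records


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata TSV (sample_id, genotype, temperature_c, replicate)."""
    df = pd.read_csv(_require(path), sep="\t", dtype={"sample_id": str, "genotype": str})
    for col in ("sample_id", "genotype", "temperature_c", "replicate"):
        if col not in df.columns:
            raise ValidationError(f"metadata file missing column {col!r}")
    return [
        SampleMeta(str(r.sample_id), str(r.genotype), float(r.temperature_c), int(r.replicate))
        for r in df.itertuples(index=False)
    ]


def read_counts(
    path: str | Path,
    annotation_path: str | Path,
    metadata_path: str | Path,
) -> CountMatrix:
    """Read a gene x sample count TSV into a validated :class:`CountMatrix`.

    The counts file has a header row of sample ids and a first column of
    gene ids.  Every gene must appear in the annotation catalog and every
    sample column in the metadata file; anything else fails loudly.
    """
    genes_catalog = {g.gene_id: g for g in read_annotation(annotation_path)}
    meta = {s.sample_id: s for s in read_sample_metadata(metadata_path)}
    df = pd.read_csv(_require(path), sep="\t", index_col=0)
    df.index = df.index.astype(str)

    missing = [g for g in df.index if g not in genes_catalog]
    if missing:
        raise ValidationError(f"genes absent from annotation: {missing[:5]}")
    unknown = [s for s in df.columns if s not in meta]
    if unknown:
        raise ValidationError(f"samples in counts header absent from metadata: {unknown}")

    for sample in df.columns:
        col = pd.to_numeric(df[sample], errors="coerce")
        if col.isna().any():
            gene = df.index[col.isna()][0]
            raise ValidationError(
                f"non-numeric count {df.loc[gene, sample]!r} for gene {gene!r} "
                f"in sample {sample!r}"
            )
        bad = col[(col < 0) | (col % 1 != 0)]
        if len(bad):
            gene = bad.index[0]
            raise ValidationError(
                f"invalid count {bad.iloc[0]:g} for gene {gene!r} in sample {sample!r}: "
                "counts must be non-negative integers"
            )
    return CountMatrix(
        genes=[genes_catalog[g] for g in df.index],
        samples=[meta[s] for s in df.columns],
        counts=df.to_numpy(dtype="int64"),
    )


def write_counts(matrix: CountMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.counts, index=matrix.gene_ids, columns=matrix.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def write_annotation(genes: Iterable[GeneRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene_id, g.length_bp, g.is_tf) for g in genes],
        columns=["gene_id", "length_bp", "is_tf"],
    ).to_csv(path, sep="\t", index=False)


def write_sample_metadata(samples: Iterable[SampleMeta], path: str | Path) -> None:
    pd.DataFrame(
        [(s.sample_id, s.genotype, s.temperature_c, s.replicate) for s in samples],
        columns=["sample_id", "genotype", "temperature_c", "replicate"],
    ).to_csv(path, sep="\t", index=False)


def read_regulon(path: str | Path, catalog: Iterable[GeneRecord] | None = None) -> RegulonDB:
    """Read documented regulations TSV (regulator, target, evidence, sign).

    A blank sign means ``unknown``.  Duplicate (regulator, target) rows
    collapse; conflicting signs collapse to unknown with a warning.  When a
    catalog is supplied, every regulator present in it must be flagged is_tf.
    """
    df = pd.read_csv(
        _require(path), sep="\t", dtype=str, keep_default_na=False, na_values=[]
    )
    for col in ("regulator", "target"):
        if col not in df.columns:
            raise ValidationError(f"regulon file missing column {col!r}")
    db = RegulonDB()
    for row in df.itertuples(index=False):
        evidence = getattr(row, "evidence", EVIDENCE_DOCUMENTED) or EVIDENCE_DOCUMENTED
        sign = getattr(row, "sign", "") or SIGN_UNKNOWN
        db.add(RegulatoryAssociation(row.regulator, row.target, evidence, sign))
    if catalog is not None:
        db.validate_against_catalog(list(catalog))
    return db


def write_regulon(db: RegulonDB, path: str | Path) -> None:
    rows = sorted(
        (a.regulator, a.target, a.evidence,
         "" if a.documented_sign == SIGN_UNKNOWN else a.documented_sign)
        for a in db.associations
    )
    pd.DataFrame(rows, columns=["regulator", "target", "evidence", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_go_gmt(path: str | Path) -> list[GOTermSet]:
    """Read GMT annotation: term_id <tab> description <tab> gene ids..."""
    terms = []
    with open(_require(path)) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}: line {lineno}: GMT line needs term, description and "
                    f">= 1 gene, got {len(fields)} field(s)"
                )
            genes = frozenset(g for g in fields[2:] if g)
            if not genes:
                raise ValidationError(f"{path}: line {lineno}: empty gene list")
            terms.append(GOTermSet(fields[0], fields[1], genes))
    return terms


def write_go_gmt(terms: Iterable[GOTermSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in terms:
            fh.write("\t".join([t.term_id, t.name, *sorted(t.genes)]) + "\n")


# ---------------------------------------------------------------------------
# DEG tables (also the entry point for externally computed statistics)

DEG_COLUMNS = ["gene_id", "log2_fc", "p_raw", "q_fdr", "mean_ref", "mean_test"]


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Load a differential-expression table computed here or externally.

    Columns: gene_id, log2_fc, p_raw, q_fdr, mean_ref, mean_test.  Accepting
    external tables lets the network stages run on statistics produced by
    other DE engines.
    """
    df = pd.read_csv(_require(path), sep="\t", dtype={"gene_id": str})
    for col in DEG_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"DEG table missing column {col!r}")
    for col in ("p_raw", "q_fdr"):
        if ((df[col] < 0) | (df[col] > 1)).any():
            raise ValidationError(f"DEG table column {col!r} outside [0, 1]")
    return df.set_index("gene_id")


def write_deg_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# Network serialization

def _network_to_jsonable(network: "HierarchicalNetwork") -> dict:
    return {
        "nodes": [
            {"id": n.id, "name": n.name, "layers": sorted(n.layers)}
            for n in sorted(network.nodes.values(), key=lambda n: n.id)
        ],
        "edges": [
            {
                "source": e.source,
                "target": e.target,
                "sign": e.sign,
                "layer_pair": e.layer_pair,
                "provenance": e.provenance,
            }
            for e in sorted(
                network.edges, key=lambda e: (e.source, e.target, e.layer_pair)
            )
        ],
        "params": network.params.to_dict(),
        "provenance": network.provenance,
    }


def write_network(network: "HierarchicalNetwork", path: str | Path, format: str = "json") -> None:
    """Serialize a hierarchical network to GraphML, JSON or DOT.

    Node attributes carry the layer-membership set; edge attributes carry the
    sign and provenance.  The JSON form round-trips through
    :func:`read_network_json`.
    """
    if format not in NETWORK_FORMATS:
        raise ValidationError(
            f"unknown network format {format!r}; expected one of {NETWORK_FORMATS}"
        )
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_network_to_jsonable(network), indent=1, sort_keys=True))
    elif format == "graphml":
        g = nx.DiGraph()
        for node in sorted(network.nodes.values(), key=lambda n: n.id):
            g.add_node(node.id, name=node.name, layers=",".join(sorted(node.layers)))
        for e in sorted(network.edges, key=lambda e: (e.source, e.target, e.layer_pair)):
            g.add_edge(e.source, e.target, sign=e.sign, layer_pair=e.layer_pair,
                       provenance=e.provenance)
        nx.write_graphml(g, path)
    else:  # dot, hand-written: solid arrow = activates, dashed = inhibits
        lines = ["digraph hierarchical_trn {", "  rankdir=TB;"]
        for node in sorted(network.nodes.values(), key=lambda n: n.id):
            layers = ",".join(sorted(node.layers))
            lines.append(f'  "{node.id}" [label="{node.name}", layers="{layers}"];')
        for e in sorted(network.edges, key=lambda e: (e.source, e.target, e.layer_pair)):
            style = "solid" if e.sign == ACTIVATES else "dashed"
            lines.append(f'  "{e.source}" -> "{e.target}" [style={style}, sign="{e.sign}"];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")


def read_network_json(path: str | Path) -> "HierarchicalNetwork":
    """Reconstruct a hierarchical network from its JSON serialization."""
    from .assembly import HierarchicalNetwork, NetworkNode

    payload = json.loads(Path(_require(path)).read_text())
    nodes = {
        n["id"]: NetworkNode(n["id"], n["name"], frozenset(n["layers"]))
        for n in payload["nodes"]
    }
    edges = [
        SignedEdge(e["source"], e["target"], e["sign"], e["layer_pair"], e["provenance"])
        for e in payload["edges"]
    ]
    return HierarchicalNetwork(
        nodes=nodes,
        edges=edges,
        params=PipelineParams(**payload["params"]),
        provenance=payload.get("provenance", {}),
    )
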