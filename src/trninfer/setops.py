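"""Three-set Venn partitioning and hypergeometric GO enrichment.

Localizes the two web-tool computations of the study design: partitioning
SDEG sets by membership mask, and one-sided hypergeometric enrichment of
biological-process terms with Bonferroni correction over the terms actually
tested.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

from scipy import stats

from .datatypes import GOTermSet, PipelineParams, ValidationError

VENN_MASKS = ("100", "010", "001", "110", "101", "011", "111")


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero (the convention behind printed percentages).

    Works on the decimal representation, so 34.95 rounds to 35.0 even though
    the nearest binary double sits fractionally below the half.
    """
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(decimal.Decimal(repr(value)).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass
class VennPartition3:
    """Exact partition of three gene sets by membership mask.

    Masks are strings over the three labels in order, e.g. ``110`` holds the
    genes in the first and second set but not the third.
    """

    labels: tuple[str, str, str]
    regions: dict[str, set[str]]

    @property
    def union_size(self) -> int:
        return sum(len(g) for g in self.regions.values())

    def region_percent(self, mask: str) -> float:
        """Region share of the union, one decimal, half away from zero."""
        if self.union_size == 0:
            return 0.0
        return round_half_away(100.0 * len(self.regions[mask]) / self.union_size, 1)

    def set_size(self, which: int) -> int:
        return sum(len(g) for mask, g in self.regions.items() if mask[which] == "1")


def venn3(a: set[str], b: set[str], c: set[str],
          labels: tuple[str, str, str] = ("A", "B", "C")) -> VennPartition3:
    """Partition three sets into the seven disjoint Venn regions."""
    a, b, c = set(a), set(b), set(c)
    universe = a | b | c
    regions: dict[str, set[str]] = {mask: set() for mask in VENN_MASKS}
    for g in universe:
        mask = f"{int(g in a)}{int(g in b)}{int(g in c)}"
        regions[mask].add(g)
    return VennPartition3(labels=tuple(labels), regions=regions)


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    X counts annotated genes in a draw of n from a universe of N containing
    K annotated genes; the tail is inclusive, so k = 0 gives 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValidationError(f"invalid parameters K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValidationError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class EnrichmentRow:
    """One tested GO term: overlap counts, raw and Bonferroni p, verdict."""

    term_id: str
    name: str
    k: int
    K: int
    n: int
    N: int
    p_raw: float
    p_bonf: float
    significant: bool


def enrich(query: set[str], terms: list[GOTermSet], universe: set[str],
           params: PipelineParams | None = None) -> list[EnrichmentRow]:
    """Hypergeometric enrichment of ``query`` against each term.

    Term gene sets are intersected with the universe before testing; only
    terms overlapping the query (k >= 1) are tested, and the Bonferroni
    factor is the number of terms tested, recorded per row as p_bonf =
    min(1, p_raw x tested).  Rows sort by p_raw ascending, ties by term_id.
    """
    params = params or PipelineParams()
    universe = set(universe)
    if not universe:
        raise ValidationError("enrichment universe is empty")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValidationError(f"query genes outside the universe: {sorted(stray)[:5]}")
    N = len(universe)
    n = len(query)

    tested: list[tuple[GOTermSet, int, int, float]] = []
    for term in terms:
        members = term.genes & universe
        k = len(members & query)
        if k >= 1:
            tested.append((term, k, len(members), hypergeom_tail(k, len(members), n, N)))

    m = len(tested)
    rows = [
        EnrichmentRow(
            term_id=term.term_id,
            name=term.name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_raw=p,
            p_bonf=min(1.0, p * m),
            significant=min(1.0, p * m) <= params.enrich_alpha,
        )
        for term, k, K, p in tested
    ]
    rows.sort(key=lambda r: (r.p_raw, r.term_id))
    return rows
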