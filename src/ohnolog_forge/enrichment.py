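"""Hypergeometric over/under-representation tests over any annotation map.

Given a selected gene set drawn from a universe of N genes, K of which carry a
term, the over-representation p-value of observing k hits among n selected is
P(X >= k) and the under-representation p-value P(X <= k), with
X ~ Hypergeometric(N, K, n).  The same machinery serves functional categories,
pathways, domains — and, with chromosomes (or sliding windows of gene order)
as terms, positional clustering along the genome: tandem-duplicate sets
cluster, whole-genome-duplication ohnologs do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .simulate import GenomeLayout


@dataclass
class EnrichmentResult:
    term: str
    description: str
    direction: str       # "over" | "under"
    k: int               # hits in selection
    n: int               # selection size
    K: int               # annotated genes in universe
    N: int               # universe size
    p_value: float
    adjusted_p: Optional[float] = None


def read_gmt(path) -> dict[str, tuple[str, set[str]]]:
    """GMT annotation file: term <tab> description <tab> gene..."""
    annot: dict[str, tuple[str, set[str]]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            term, desc, genes = parts[0], parts[1], set(parts[2:]) - {""}
            if term in annot:
                raise InputError(f"duplicate term id {term!r}")
            if genes:
                annot[term] = (desc, genes)
    return annot


def write_gmt(annot: dict[str, tuple[str, set[str]]], path) -> None:
    with open(path, "w") as fh:
        for term, (desc, genes) in annot.items():
            fh.write("\t".join([term, desc, *sorted(genes)]) + "\n")


def hypergeom_test(
    selected: Iterable[str],
    universe: Iterable[str],
    annot: dict[str, tuple[str, set[str]]],
    direction: str = "over",
    adjust: str = "BH",
) -> list[EnrichmentResult]:
    """Per-term hypergeometric tail tests, sorted by p-value.

    Annotation gene sets are intersected with the universe first; terms left
    empty are skipped.  ``adjust`` is "BH" (Benjamini-Hochberg) or "none".
    """
    universe = set(universe)
    selected = set(selected)
    if not universe or not selected:
        raise InputError("selected and universe must be non-empty")
    if not selected <= universe:
        raise InputError("selected set must be a subset of the universe")
    if direction not in ("over", "under"):
        raise InputError(f"direction must be 'over' or 'under', got {direction!r}")
    if adjust not in ("BH", "none"):
        raise InputError(f"unknown adjustment {adjust!r}")
    N, n = len(universe), len(selected)
    results: list[EnrichmentResult] = []
    for term, (desc, genes) in annot.items():
        term_genes = genes & universe
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & selected)
        if direction == "over":
            p = float(hypergeom.sf(k - 1, N, K, n))
        else:
            p = float(hypergeom.cdf(k, N, K, n))
        results.append(EnrichmentResult(term, desc, direction, k, n, K, N,
                                        min(p, 1.0)))
    if results and adjust == "BH":
        adjusted = multipletests([r.p_value for r in results], method="fdr_bh")[1]
        for r, ap in zip(results, adjusted):
            r.adjusted_p = float(ap)
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def chromosome_annotation(layout: GenomeLayout,
                          window: Optional[int] = None) -> dict[str, tuple[str, set[str]]]:
    """Chromosome-membership terms, optionally augmented with half-overlapping
    windows of ``window`` consecutive gene positions."""
    annot: dict[str, tuple[str, set[str]]] = {}
    for chrom, genes in layout.chromosomes.items():
        if genes:
            annot[chrom] = (f"genes on {chrom}", set(genes))
        if window and window >= 2:
            step = max(window // 2, 1)
            for start in range(0, max(len(genes) - 1, 0), step):
                block = genes[start:start + window]
                if len(block) >= 2:
                    annot[f"{chrom}:{start}-{start + len(block)}"] = (
                        f"window {chrom}[{start}, {start + len(block)})", set(block))
    return annot


def chromosome_clustering_test(
    gene_set: Iterable[str],
    layout: GenomeLayout,
    universe: Optional[Iterable[str]] = None,
    window: Optional[int] = 25,
    adjust: str = "BH",
) -> list[EnrichmentResult]:
    """Positional clustering: over-representation of the gene set on any
    chromosome (and, by default, 25-gene half-overlapping windows)."""
    universe = set(universe) if universe is not None else set(layout.position)
    gene_set = set(gene_set) & universe
    if not gene_set:
        raise InputError("empty gene set (after intersection with universe)")
    annot = chromosome_annotation(layout, window=window)
    return hypergeom_test(gene_set, universe, annot, direction="over", adjust=adjust)


def write_enrichment(results: list[EnrichmentResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tdirection\tk\tn\tK\tN\tp_value\tadjusted_p\tdescription\n")
        for r in results:
            ap = f"{r.adjusted_p:.4g}" if r.adjusted_p is not None else "NA"
            fh.write(f"{r.term}\t{r.direction}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t"
                     f"{r.p_value:.4g}\t{ap}\t{r.description}\n")
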