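"""Differentially methylated region (DMR) detection around candidate genes.

Candidate imprinting control regions are sought as intervals where
per-cytosine percent methylation differs between two conditions (e.g.
wild-type endosperm vs endosperm deficient for the DME demethylase) within
a gene's intergenic neighbourhood — the span between the gene bodies
immediately upstream and downstream of the candidate.

A cytosine is *differential* when |pct_b - pct_a| >= ``min_diff``
percentage points. Differential cytosines are chained while consecutive
ones lie within ``max_gap`` bp; chains with at least ``min_count``
differential cytosines are emitted as DMRs. All three parameters are
mandatory in report headers so results are self-describing; methylation
percentages alone (without read depths) support no significance test, so
none is attempted. Cytosine sequence context (CpG/CHG/CHH) is carried as
pass-through metadata and does not affect chaining.

Coordinates are 1-based in input and output (the convention of the
methylation-track and annotation formats consumed); intervals are closed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "MethylationRecord",
    "GeneAnnotation",
    "DMRParams",
    "GeneRelation",
    "DMR",
    "flank_region",
    "find_dmrs",
]


@dataclass(frozen=True)
class MethylationRecord:
    """Percent methylation of one cytosine under two conditions."""

    chromosome: str
    position: int  # 1-based
    pct_a: float   # condition A, e.g. wild-type endosperm
    pct_b: float   # condition B, e.g. dme endosperm
    context: str | None = None  # CpG/CHG/CHH pass-through, unused in chaining

    def __post_init__(self) -> None:
        for value in (self.pct_a, self.pct_b):
            if not 0 <= value <= 100:
                raise ValueError(
                    f"{self.chromosome}:{self.position}: methylation percentage "
                    f"{value} outside [0, 100]"
                )

    @property
    def difference(self) -> float:
        return self.pct_b - self.pct_a


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    start: int  # 1-based closed
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -")


@dataclass(frozen=True)
class DMRParams:
    min_diff: float = 20.0  # percentage points
    min_count: int = 5      # differential cytosines per region
    max_gap: int = 250      # bp between consecutive differential cytosines

    def __post_init__(self) -> None:
        if self.min_diff <= 0 or self.min_count <= 0 or self.max_gap <= 0:
            raise ValueError("DMR parameters must be positive")


@dataclass(frozen=True)
class GeneRelation:
    """Placement of a DMR relative to a gene body, on the gene's strand."""

    distance: int  # bp from the gene-body boundary to the nearest DMR edge
    side: str      # upstream | downstream | overlapping


@dataclass(frozen=True)
class DMR:
    chromosome: str
    start: int  # 1-based closed interval over the differential cytosines
    end: int
    n_cytosines: int      # all cytosines within [start, end]
    n_differential: int   # cytosines with |pct_b - pct_a| >= min_diff
    n_hyper_b: int        # cytosines with pct_b - pct_a >= min_diff
    mean_difference: float
    relation_to_gene: GeneRelation | None = None


def flank_region(
    gene: GeneAnnotation,
    all_genes: Sequence[GeneAnnotation],
    chromosome_length: int | None = None,
) -> tuple[str, int, int]:
    """Intergenic neighbourhood of ``gene``: (chromosome, start, end), 1-based closed.

    Spans from the end of the nearest gene body to the left to the start of
    the nearest gene body to the right, including the candidate's own gene
    body. With no neighbour on a side the region runs to position 1 or to
    ``chromosome_length`` (the candidate's own end when no length is
    given). Neighbours overlapping the candidate truncate the region at
    the overlap boundary, with a warning.
    """
    neighbours = [
        g for g in all_genes
        if g.chromosome == gene.chromosome and g.gene_id != gene.gene_id
    ]
    left = [g for g in neighbours if g.start < gene.start]
    right = [g for g in neighbours if g.end > gene.end]

    if left:
        left_gene = max(left, key=lambda g: g.end)
        start = left_gene.end
        if left_gene.end > gene.start:
            warnings.warn(
                f"{left_gene.gene_id} overlaps {gene.gene_id}; flank region "
                "truncated at the overlap boundary"
            )
            start = min(left_gene.end, gene.end)
    else:
        start = 1
    if right:
        right_gene = min(right, key=lambda g: g.start)
        end = right_gene.start
        if right_gene.start < gene.end:
            warnings.warn(
                f"{right_gene.gene_id} overlaps {gene.gene_id}; flank region "
                "truncated at the overlap boundary"
            )
            end = max(right_gene.start, gene.start)
    else:
        end = chromosome_length if chromosome_length is not None else gene.end
    return gene.chromosome, start, end


def _relate(start: int, end: int, gene: GeneAnnotation) -> GeneRelation:
    """Distance and strand-aware side of the interval nearest the gene body."""
    if end < gene.start:
        distance = gene.start - end
        left_side = True
    elif start > gene.end:
        distance = start - gene.end
        left_side = False
    else:
        return GeneRelation(0, "overlapping")
    if gene.strand == "+":
        side = "upstream" if left_side else "downstream"
    else:
        side = "downstream" if left_side else "upstream"
    return GeneRelation(distance, side)


def find_dmrs(
    records: Sequence[MethylationRecord],
    params: DMRParams = DMRParams(),
    gene: GeneAnnotation | None = None,
) -> list[DMR]:
    """Chain differential cytosines into DMRs.

    ``records`` must be position-sorted on a single chromosome. Emitted
    intervals span the first to the last differential cytosine of each
    qualifying chain; ``n_cytosines`` counts every cytosine inside the
    interval, ``n_hyper_b`` those hypermethylated in condition B by at
    least ``min_diff``, and ``mean_difference`` averages pct_b - pct_a over
    all cytosines in the interval. When ``gene`` is supplied each DMR is
    annotated with its strand-aware distance and side relative to the gene
    body.
    """
    if not records:
        return []
    chromosomes = {r.chromosome for r in records}
    if len(chromosomes) > 1:
        raise ValueError(f"records span multiple chromosomes: {sorted(chromosomes)}")
    positions = [r.position for r in records]
    if any(b <= a for a, b in zip(positions, positions[1:])):
        raise ValueError("methylation records must be sorted by position")

    differential = [r for r in records if abs(r.difference) >= params.min_diff]
    chains: list[list[MethylationRecord]] = []
    for record in differential:
        if chains and record.position - chains[-1][-1].position <= params.max_gap:
            chains[-1].append(record)
        else:
            chains.append([record])

    dmrs = []
    for chain in chains:
        if len(chain) < params.min_count:
            continue
        start, end = chain[0].position, chain[-1].position
        inside = [r for r in records if start <= r.position <= end]
        dmrs.append(
            DMR(
                chromosome=chain[0].chromosome,
                start=start,
                end=end,
                n_cytosines=len(inside),
                n_differential=len(chain),
                n_hyper_b=sum(1 for r in inside if r.difference >= params.min_diff),
                mean_difference=sum(r.difference for r in inside) / len(inside),
                relation_to_gene=_relate(start, end, gene) if gene else None,
            )
        )
    return dmrs
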