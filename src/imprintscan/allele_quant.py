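"""Allele-specific pyrosequencing (QUASEP) summaries.

Pyrosequencing a transcribed SNP in cDNA from reciprocal F1 hybrid seeds
yields, per cross direction, the percentage of transcript signal carried by
the maternal allele. The two reciprocal directions are averaged into a mean
maternal percentage and classified on explicit, configurable thresholds —
the qualitative labels (binary vs preferential vs biallelic imprinting) are
interpretive, so the thresholds are part of the configuration rather than a
claim of the method. The defaults place a fully imprinted MEG control
(mean ~95%) in ``maternal_binary``, a biallelic endosperm control (~46%) in
``biallelic``, and a preferentially paternal control (~21%) in
``paternal_preferential``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

__all__ = [
    "AlleleMeasurement",
    "ClassificationThresholds",
    "ImprintingSummary",
    "allele_fraction",
    "summarize_gene",
]


def allele_fraction(maternal_signal: float, paternal_signal: float) -> float | None:
    """Percentage of total allele signal attributable to the maternal allele.

    Returns ``None`` (missing) when both signals are zero, where the
    fraction is undefined.
    """
    if maternal_signal < 0 or paternal_signal < 0:
        raise ValueError("allele signals must be non-negative")
    total = maternal_signal + paternal_signal
    if total == 0:
        return None
    return 100.0 * maternal_signal / total


@dataclass(frozen=True)
class AlleleMeasurement:
    """Maternal-allele percentage in one cross direction."""

    gene_id: str
    cross_label: str  # which accession is the mother, e.g. "Col-0 x C24"
    maternal_pct: float
    source: str = "cDNA"  # cDNA | genomic_control

    def __post_init__(self) -> None:
        if not 0 <= self.maternal_pct <= 100:
            raise ValueError(
                f"{self.gene_id} ({self.cross_label}): maternal percentage "
                f"{self.maternal_pct} outside [0, 100]"
            )
        if self.source not in ("cDNA", "genomic_control"):
            raise ValueError(f"unknown measurement source {self.source!r}")


@dataclass(frozen=True)
class ClassificationThresholds:
    """Mean-maternal-percentage cutoffs, mirrored about 50%."""

    binary: float = 90.0
    preferential: float = 70.0

    def classify(self, mean_maternal_pct: float) -> str:
        m = mean_maternal_pct
        if m >= self.binary:
            return "maternal_binary"
        if m >= self.preferential:
            return "maternal_preferential"
        if m > 100 - self.preferential:
            return "biallelic"
        if m > 100 - self.binary:
            return "paternal_preferential"
        return "paternal_binary"


@dataclass(frozen=True)
class ImprintingSummary:
    gene_id: str
    mean_maternal_pct: float
    classification: str | None
    one_directional: bool = False


def summarize_gene(
    measurements: Iterable[AlleleMeasurement],
    thresholds: ClassificationThresholds = ClassificationThresholds(),
) -> ImprintingSummary:
    """Summarise the two reciprocal cDNA measurements of one gene.

    The mean maternal percentage is the arithmetic mean over the two cross
    directions (order-invariant). With only one direction available the
    summary is flagged ``one_directional`` and left unclassified; genomic
    controls are ignored.
    """
    cdna = [m for m in measurements if m.source == "cDNA"]
    if not cdna:
        raise ValueError("no cDNA measurements supplied")
    gene_ids = {m.gene_id for m in cdna}
    if len(gene_ids) != 1:
        raise ValueError(f"measurements span multiple genes: {sorted(gene_ids)}")
    if len({m.cross_label for m in cdna}) != len(cdna):
        raise ValueError("duplicate cross direction in measurements")
    if len(cdna) > 2:
        raise ValueError("expected at most one measurement per reciprocal direction")

    mean = sum(m.maternal_pct for m in cdna) / len(cdna)
    if len(cdna) == 1:
        return ImprintingSummary(cdna[0].gene_id, mean, None, one_directional=True)
    return ImprintingSummary(cdna[0].gene_id, mean, thresholds.classify(mean))
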