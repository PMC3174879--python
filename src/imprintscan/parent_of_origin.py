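"""Parent-of-origin calling from reciprocal-cross presence/absence tables.

A restriction-site polymorphism between two accessions makes a TDF
accession-specific: the allele amplifies from one accession (the *carrier*)
but not the other. Comparing the carrier allele's presence across the two
parental selfs (A x A, B x B) and the two reciprocal F1 hybrids (A x B,
B x A; mother listed first) over several developmental timepoints separates
parent-of-origin effects from allele effects:

* present in the F1 where the carrier is the mother, absent in the
  reciprocal -> the timepoint supports *maternal* expression;
* the mirror pattern supports *paternal* expression;
* present in both F1 directions -> biallelic at that timepoint.

A maternal (resp. paternal) call requires at least ``min_stages``
supporting timepoints (default 2, i.e. uniparental expression at two or
more of the stages sampled) and no timepoint supporting the opposite
direction. Mixed maternal/paternal support yields ``not_uniparental``;
all-biallelic patterns likewise. Anything below the evidence threshold is
``insufficient_evidence``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import pandas as pd

__all__ = [
    "CrossDesign",
    "Sample",
    "AlleleCallTable",
    "ParentOfOriginCall",
    "build_allele_table",
    "detect_polymorphic",
    "call_parent_of_origin",
    "call_all",
]

logger = logging.getLogger(__name__)

TdfKey = tuple[str, float]  # (primer combination label, bin center)


@dataclass(frozen=True)
class Sample:
    mother: str
    father: str
    timepoint: int

    @property
    def is_self(self) -> bool:
        return self.mother == self.father


@dataclass(frozen=True)
class CrossDesign:
    """Reciprocal-cross sample layout over developmental timepoints."""

    accessions: tuple[str, str]
    samples: Mapping[str, Sample]
    timepoints: tuple[int, ...]

    def __post_init__(self) -> None:
        a, b = self.accessions
        if a == b:
            raise ValueError("cross design requires two distinct accessions")
        for label, sample in self.samples.items():
            for parent in (sample.mother, sample.father):
                if parent not in self.accessions:
                    raise ValueError(
                        f"sample {label}: parent {parent!r} is not one of "
                        f"the design accessions {self.accessions}"
                    )

    def find(self, mother: str, father: str, timepoint: int) -> str | None:
        for label, sample in self.samples.items():
            if sample == Sample(mother, father, timepoint):
                return label
        return None

    def self_of(self, accession: str, timepoint: int) -> str | None:
        return self.find(accession, accession, timepoint)

    def require_selfs(self) -> None:
        """Error (naming the absent sample) if any self is missing."""
        for accession in self.accessions:
            for timepoint in self.timepoints:
                if self.self_of(accession, timepoint) is None:
                    raise ValueError(
                        f"missing self sample {accession} x {accession} "
                        f"at timepoint {timepoint}"
                    )


@dataclass
class AlleleCallTable:
    """Presence/absence of allele bins per sample.

    ``calls`` is indexed by (primer combination label, bin center) with one
    0/1 column per sample label. Bin centers derive from capillary sizes
    with a half-width of 0.5 bp by default (the binning convention of
    capillary allele calling).
    """

    calls: pd.DataFrame
    bin_halfwidth: float = 0.5
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.calls.index, pd.MultiIndex) or self.calls.index.nlevels != 2:
            raise ValueError(
                "allele table must be indexed by (primer_key, bin_center)"
            )
        self.calls = self.calls.astype(int)

    @property
    def keys(self) -> list[TdfKey]:
        return list(self.calls.index)

    def present(self, key: TdfKey, sample: str) -> bool:
        return bool(self.calls.at[key, sample])


def _cluster_centers(sizes: Iterable[float], halfwidth: float) -> list[float]:
    """Greedy left-to-right clustering of sorted sizes into +/-halfwidth bins."""
    centers: list[float] = []
    for size in sorted(sizes):
        if not centers or size > centers[-1] + halfwidth:
            centers.append(size)
    return centers


def build_allele_table(
    peaks: Mapping[str, Mapping[str, Iterable[float]]],
    design: CrossDesign,
    bin_halfwidth: float = 0.5,
) -> AlleleCallTable:
    """Bin per-sample capillary peaks into an allele call table.

    ``peaks`` maps sample label -> primer combination label -> iterable of
    observed peak sizes. Bin centers are seeded from the parental-self
    peaks; every sample's peaks are then assigned to the nearest center
    within ``bin_halfwidth``. F1 peaks matching no self-derived center
    cannot be a parental allele and are dropped (counted in provenance).
    """
    self_labels = {label for label, s in design.samples.items() if s.is_self}
    centers: dict[str, list[float]] = {}
    for label in self_labels & set(peaks):
        for primer_key, sizes in peaks[label].items():
            centers.setdefault(primer_key, []).extend(sizes)
    centers = {k: _cluster_centers(v, bin_halfwidth) for k, v in centers.items()}

    rows: dict[TdfKey, dict[str, int]] = {
        (primer_key, center): {label: 0 for label in design.samples}
        for primer_key, cs in centers.items()
        for center in cs
    }
    dropped = 0
    for label, by_primer in peaks.items():
        for primer_key, sizes in by_primer.items():
            for size in sizes:
                candidates = [
                    c for c in centers.get(primer_key, ())
                    if abs(size - c) <= bin_halfwidth
                ]
                if not candidates:
                    dropped += 1
                    continue
                center = min(candidates, key=lambda c: abs(size - c))
                rows[(primer_key, center)][label] = 1

    calls = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    calls.index = pd.MultiIndex.from_tuples(calls.index, names=["primer_key", "bin_center"])
    if dropped:
        logger.warning("%d F1 peak(s) matched no parental-self bin and were dropped", dropped)
    return AlleleCallTable(
        calls,
        bin_halfwidth=bin_halfwidth,
        provenance={"dropped_nonparental_peaks": dropped},
    )


def detect_polymorphic(table: AlleleCallTable, design: CrossDesign) -> dict[TdfKey, str]:
    """TDF keys whose allele is carried by exactly one accession's self.

    Returns a mapping from polymorphic TDF key to its carrier accession. A
    key qualifies iff the allele is present in every self sample of one
    accession (across the design timepoints) and absent from every self
    sample of the other; inconsistent presence is not polymorphic.
    """
    design.require_selfs()
    a, b = design.accessions
    selfs = {
        accession: [design.self_of(accession, tp) for tp in design.timepoints]
        for accession in design.accessions
    }
    carriers: dict[TdfKey, str] = {}
    for key in table.keys:
        in_self = {
            accession: [table.present(key, label) for label in labels]
            for accession, labels in selfs.items()
        }
        if all(in_self[a]) and not any(in_self[b]):
            carriers[key] = a
        elif all(in_self[b]) and not any(in_self[a]):
            carriers[key] = b
    return carriers


@dataclass(frozen=True)
class ParentOfOriginCall:
    key: TdfKey
    carrier_accession: str | None
    call: str  # maternal | paternal | not_uniparental | not_polymorphic | insufficient_evidence
    supporting_timepoints: tuple[int, ...] = ()


def call_parent_of_origin(
    key: TdfKey,
    table: AlleleCallTable,
    design: CrossDesign,
    min_stages: int = 2,
    carrier: str | None = None,
) -> ParentOfOriginCall:
    """Classify one polymorphic TDF as maternal/paternal/neither.

    ``carrier`` may be passed when already known (e.g. from
    :func:`detect_polymorphic`); otherwise it is re-derived. A timepoint
    missing any required F1 sample is uninformative rather than
    contradictory.
    """
    if carrier is None:
        carrier = detect_polymorphic(table, design).get(key)
    if carrier is None:
        raise ValueError(f"TDF {key}: carrier accession unknown (not polymorphic?)")
    other = next(acc for acc in design.accessions if acc != carrier)

    n_maternal = n_paternal = n_biallelic = 0
    supporting: list[int] = []
    for timepoint in design.timepoints:
        mat_label = design.find(carrier, other, timepoint)   # carrier is mother
        pat_label = design.find(other, carrier, timepoint)   # carrier is father
        if mat_label is None or pat_label is None:
            continue  # uninformative timepoint
        in_mat = table.present(key, mat_label)
        in_pat = table.present(key, pat_label)
        if in_mat and not in_pat:
            n_maternal += 1
            supporting.append(timepoint)
        elif in_pat and not in_mat:
            n_paternal += 1
            supporting.append(timepoint)
        elif in_mat and in_pat:
            n_biallelic += 1

    if n_maternal >= min_stages and n_paternal == 0:
        return ParentOfOriginCall(key, carrier, "maternal",
                                  tuple(supporting))
    if n_paternal >= min_stages and n_maternal == 0:
        return ParentOfOriginCall(key, carrier, "paternal",
                                  tuple(supporting))
    if (n_maternal and n_paternal) or n_biallelic:
        return ParentOfOriginCall(key, carrier, "not_uniparental")
    return ParentOfOriginCall(key, carrier, "insufficient_evidence")


def call_all(
    table: AlleleCallTable,
    design: CrossDesign,
    min_stages: int = 2,
) -> list[ParentOfOriginCall]:
    """Call every TDF in the table; non-polymorphic keys get ``not_polymorphic``."""
    carriers = detect_polymorphic(table, design)
    calls = []
    for key in table.keys:
        if key in carriers:
            calls.append(
                call_parent_of_origin(key, table, design, min_stages, carriers[key])
            )
        else:
            calls.append(ParentOfOriginCall(key, None, "not_polymorphic"))
    return calls
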