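"""TDF-to-gene matching against an in-silico fragment index.

An observed transcript-derived fragment (TDF) from a capillary run is
characterised by the primer combination that amplified it and its
fractionally sized length in base pairs. Matching proceeds by building an
index of every predicted fragment of a transcriptome keyed by primer
combination, then retrieving the genes whose predicted size lies within a
tolerance (default 1.0 bp, inclusive) of the observed size. Multiple
isoforms of one gene collapse to a single gene-level candidate; the status
of a match is ``unique`` (one gene), ``ambiguous`` (two or more) or
``unmatched`` (none), with the nearest out-of-tolerance candidates reported
as near misses.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal

from .digest import PredictedFragment, PrimerSpec, SizeModel, digest_transcript
from .enzymes import BSTYI, MSEI, RestrictionEnzyme, TranscriptRecord

__all__ = [
    "IndexEntry",
    "FragmentIndex",
    "ObservedTDF",
    "MatchCandidate",
    "MatchResult",
    "build_index",
    "match_tdf",
]

logger = logging.getLogger(__name__)

MatchStatus = Literal["unique", "ambiguous", "unmatched"]


@dataclass(frozen=True)
class IndexEntry:
    predicted_size: float
    gene_id: str
    transcript_id: str
    fragment: PredictedFragment


@dataclass(frozen=True)
class ObservedTDF:
    """One sized capillary observation of an amplified fragment."""

    tdf_id: str
    primer: PrimerSpec
    observed_size: float
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # The assay's detected range (50-500 bp) is advisory, not enforced.
        if self.observed_size <= 0:
            raise ValueError(f"TDF {self.tdf_id}: observed size must be positive")


@dataclass(frozen=True)
class MatchCandidate:
    gene_id: str
    predicted_size: float
    deviation: float


@dataclass(frozen=True)
class MatchResult:
    tdf_id: str
    status: MatchStatus
    matched_genes: tuple[MatchCandidate, ...]
    near_misses: tuple[MatchCandidate, ...]
    note: str = ""


class FragmentIndex:
    """Predicted fragments of a transcriptome keyed by primer combination.

    Per-key entry lists are kept sorted by predicted size so size-window
    queries are a bisect. ``settings`` records the digestion provenance
    (mode, selective lengths, size correction) so a mismatch between index
    and query settings is detectable downstream.
    """

    def __init__(self, settings: dict | None = None) -> None:
        self._entries: dict[tuple[str, str, str], list[IndexEntry]] = {}
        self.settings: dict = settings or {}

    def add(self, fragment: PredictedFragment) -> None:
        primer = fragment.primer
        if primer is None:  # unamplifiable under the configured selectivity
            return
        entry = IndexEntry(fragment.predicted_size, fragment.gene_id,
                           fragment.transcript_id, fragment)
        bisect.insort(
            self._entries.setdefault(primer.key, []),
            entry,
            key=lambda e: (e.predicted_size, e.gene_id, e.transcript_id),
        )

    def entries(self, primer: PrimerSpec) -> list[IndexEntry]:
        return self._entries.get(primer.key, [])

    def __len__(self) -> int:
        return sum(len(v) for v in self._entries.values())

    def __iter__(self) -> Iterable[IndexEntry]:
        for entries in self._entries.values():
            yield from entries

    @property
    def primer_keys(self) -> list[tuple[str, str, str]]:
        return sorted(self._entries)


def build_index(
    transcripts: Iterable[TranscriptRecord],
    enzymes: tuple[RestrictionEnzyme, RestrictionEnzyme] = (BSTYI, MSEI),
    mode: Literal["all", "last"] = "last",
    k5: int = 2,
    k3: int = 2,
    size_model: SizeModel | None = None,
) -> FragmentIndex:
    """Digest every transcript and index the products by primer combination.

    The default ``mode="last"`` indexes only the poly-A-proximal fragment
    of each transcript, matching the capillary protocol's isolation step.
    """
    size_model = size_model or SizeModel()
    index = FragmentIndex(
        settings={
            "enzymes": f"{enzymes[0].name}+{enzymes[1].name}",
            "mode": mode,
            "k5": k5,
            "k3": k3,
            "size_correction": size_model.correction_total,
        }
    )
    n = 0
    for transcript in transcripts:
        n += 1
        for fragment in digest_transcript(
            transcript, enzymes=enzymes, mode=mode, k5=k5, k3=k3, size_model=size_model
        ):
            index.add(fragment)
    if n == 0:
        logger.warning("building fragment index from an empty transcript set")
    return index


def match_tdf(
    tdf: ObservedTDF,
    index: FragmentIndex,
    tolerance: float = 1.0,
    n_near_misses: int = 3,
) -> MatchResult:
    """Identify the gene(s) behind one observed TDF.

    Candidates are index entries under the TDF's primer key whose predicted
    size deviates from the observed size by at most ``tolerance``
    (inclusive; the 1 bp default mirrors stringent capillary sizing).
    Isoforms collapse to genes, each gene reporting its minimal deviation.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    entries = index.entries(tdf.primer)
    note = ""
    if not entries:
        note = f"primer combination {tdf.primer.label} absent from index"

    per_gene: dict[str, MatchCandidate] = {}
    misses: list[MatchCandidate] = []
    for entry in entries:
        deviation = abs(entry.predicted_size - tdf.observed_size)
        candidate = MatchCandidate(entry.gene_id, entry.predicted_size, deviation)
        if deviation <= tolerance:
            best = per_gene.get(entry.gene_id)
            if best is None or deviation < best.deviation:
                per_gene[entry.gene_id] = candidate
        else:
            misses.append(candidate)

    matched = tuple(sorted(per_gene.values(), key=lambda c: (c.deviation, c.gene_id)))
    near = tuple(sorted(misses, key=lambda c: (c.deviation, c.gene_id))[:n_near_misses])
    if len(matched) == 1:
        status: MatchStatus = "unique"
    elif matched:
        status = "ambiguous"
    else:
        status = "unmatched"
    return MatchResult(tdf.tdf_id, status, matched, near, note=note)
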