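"""In-silico cDNA-AFLP digestion and selective amplification.

The wet protocol digests cDNA with BstYI and MseI, ligates adapters to both
cut ends and amplifies with primers carrying one or two extra 3' "selective"
nucleotides, so that only a subset of fragments amplifies per primer
combination. Only fragments with a BstYI end on the 5' side and an MseI end
on the 3' side are both amplified and detected. This module reproduces that
geometry on a transcript sequence:

* dual digestion at the union of both enzymes' cut sites;
* retention of BstYI->MseI fragments (optionally only the poly-A-proximal
  one, which is what the capillary protocol isolates);
* the Y-variant of the BstYI remnant plus both selective-nucleotide
  contexts, which together determine the unique primer combination that
  amplifies a fragment;
* the predicted migrated size: cut-to-cut length plus a constant primer
  tail correction.

The default size correction of 26 bp derives from the printed primer
geometry of the assay: the 18-nt BstYI primer extends 11 nt beyond the
fragment's 5' cut (its last 7 nt anneal inside: GATC + Y + 2 selective) and
the 18-nt MseI primer extends 15 nt beyond the 3' cut (3 nt inside: the
remnant-T complement + 2 selective). Capillary mobility and dye shifts make
the true offset assay-specific, so the correction is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

from .enzymes import (
    BSTYI,
    MSEI,
    ConfigurationError,
    RestrictionEnzyme,
    TranscriptRecord,
    reverse_complement,
)

__all__ = [
    "PrimerSpec",
    "SizeModel",
    "PredictedFragment",
    "FragmentTooShortError",
    "MIN_FRAGMENT_LENGTH",
    "digest_transcript",
    "selective_contexts",
    "matches_primer",
]

#: Shortest retained fragment: the 5-nt GATCY remnant plus the terminal T.
MIN_FRAGMENT_LENGTH = 6


class FragmentTooShortError(ValueError):
    """Fragment too short for the requested selective-context lengths."""


@dataclass(frozen=True)
class PrimerSpec:
    """One primer combination of the selective amplification.

    ``bst_variant`` is the single base read at the Y position of the BstYI
    recognition remnant (C or T, matching the two BstYI primer families);
    ``bst_selective`` and ``mse_selective`` are the 0-2 selective
    nucleotides appended to the BstYI and MseI primers respectively.
    """

    bst_variant: str
    bst_selective: str = ""
    mse_selective: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "bst_variant", self.bst_variant.upper())
        object.__setattr__(self, "bst_selective", self.bst_selective.upper())
        object.__setattr__(self, "mse_selective", self.mse_selective.upper())
        if self.bst_variant not in ("C", "T"):
            raise ConfigurationError(
                f"BstYI primer variant must be C or T, got {self.bst_variant!r}"
            )
        for label, sel in (("BstYI", self.bst_selective), ("MseI", self.mse_selective)):
            if len(sel) > 2 or set(sel) - set("ACGT"):
                raise ConfigurationError(
                    f"{label} selective nucleotides must be 0-2 of A/C/G/T, got {sel!r}"
                )

    @property
    def label(self) -> str:
        return f"BstYI+{self.bst_variant}{self.bst_selective} / MseI+{self.mse_selective}"

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.bst_variant, self.bst_selective, self.mse_selective)


@dataclass(frozen=True)
class SizeModel:
    """Constant correction from cut-to-cut length to migrated amplicon size.

    Either supply the split primer-tail extensions (defaults 11 + 15 = 26)
    or an explicit ``correction_total`` overriding them.
    """

    bst_tail: int = 11
    mse_tail: int = 15
    correction_total: int | None = None

    def __post_init__(self) -> None:
        if self.correction_total is None:
            object.__setattr__(self, "correction_total", self.bst_tail + self.mse_tail)
        if self.correction_total < 0:
            raise ConfigurationError("size correction must be >= 0")

    def predicted_size(self, fragment_length: int) -> int:
        return fragment_length + self.correction_total


@dataclass(frozen=True)
class PredictedFragment:
    """A BstYI->MseI digestion product of one transcript.

    ``start``/``end`` are the 0-based half-open cut-to-cut interval on the
    transcript; ``sequence`` is the sense strand of that interval, which by
    construction begins ``GATC`` + C/T and ends with the MseI remnant ``T``.
    ``bst_context``/``mse_context`` are the selective contexts the
    amplifying primers must carry (``None`` when the fragment is too short
    to amplify with the configured selective lengths).
    """

    transcript_id: str
    gene_id: str
    start: int
    end: int
    sequence: str
    bst_variant_observed: str
    bst_context: str | None
    mse_context: str | None
    predicted_size: int
    is_three_prime_most: bool = False
    flanks: tuple[str, str] = ("BstYI", "MseI")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def amplifiable(self) -> bool:
        return self.bst_context is not None and self.mse_context is not None

    @property
    def primer(self) -> PrimerSpec | None:
        """The unique primer combination that amplifies this fragment."""
        if not self.amplifiable:
            return None
        return PrimerSpec(self.bst_variant_observed, self.bst_context, self.mse_context)


def selective_contexts(fragment: "PredictedFragment | str", k5: int = 2, k3: int = 2) -> tuple[str, str]:
    """Selective-nucleotide contexts of a fragment.

    The BstYI context is read directly from the sense strand just inside
    the GATCY remnant (fragment positions ``[5, 5+k5)``). The MseI primer
    anneals to the sense strand from the other end, so its selective bases
    are the reverse complement of the ``k3`` sense bases immediately 5' of
    the terminal remnant ``T``.

    Raises
    ------
    FragmentTooShortError
        When the fragment is shorter than ``5 + k5 + 1 + k3`` bases, i.e.
        the two contexts would overlap each other or the remnants; such a
        fragment is unamplifiable for that primer set.
    """
    seq = fragment if isinstance(fragment, str) else fragment.sequence
    if not 0 <= k5 <= 2 or not 0 <= k3 <= 2:
        raise ConfigurationError("selective lengths must be 0, 1 or 2")
    if len(seq) < 5 + k5 + 1 + k3:
        raise FragmentTooShortError(
            f"fragment of length {len(seq)} cannot amplify with k5={k5}, k3={k3}"
        )
    bst_context = seq[5:5 + k5]
    mse_context = reverse_complement(seq[len(seq) - 1 - k3:len(seq) - 1])
    return bst_context, mse_context


def matches_primer(fragment: PredictedFragment, primer: PrimerSpec) -> bool:
    """True iff ``primer`` amplifies ``fragment``.

    The fragment amplifies iff the BstYI primer's Y variant equals the
    remnant base actually observed and both selective contexts equal the
    primer's selective nucleotides.
    """
    try:
        bst_context, mse_context = selective_contexts(
            fragment, len(primer.bst_selective), len(primer.mse_selective)
        )
    except FragmentTooShortError:
        return False
    return (
        fragment.bst_variant_observed == primer.bst_variant
        and bst_context == primer.bst_selective
        and mse_context == primer.mse_selective
    )


def _labelled_cuts(
    sequence: str, bst: RestrictionEnzyme, mse: RestrictionEnzyme
) -> list[tuple[int, set[str]]]:
    """Union of both enzymes' cut positions with per-position enzyme labels."""
    labels: dict[int, set[str]] = {}
    for role, enzyme in (("BstYI", bst), ("MseI", mse)):
        for pos in enzyme.find_cut_positions(sequence):
            labels.setdefault(pos, set()).add(role)
    return sorted(labels.items())


def digest_transcript(
    transcript: TranscriptRecord,
    enzymes: tuple[RestrictionEnzyme, RestrictionEnzyme] = (BSTYI, MSEI),
    mode: Literal["all", "last"] = "last",
    k5: int = 2,
    k3: int = 2,
    size_model: SizeModel | None = None,
    include_homoflanked: bool = False,
) -> list[PredictedFragment]:
    """Simulate the dual digestion of one transcript.

    Candidate fragments are the intervals between *consecutive* cuts in the
    union of both enzymes' cut positions whose 5' boundary is a BstYI cut
    and whose 3' boundary is an MseI cut — only those carry both adapters
    and amplify. ``mode="last"`` returns only the fragment with maximal
    start (the poly-A-proximal fragment the protocol isolates);
    ``mode="all"`` returns every candidate ordered by start. Products
    shorter than :data:`MIN_FRAGMENT_LENGTH` are discarded.

    ``include_homoflanked=True`` additionally reports BstYI/BstYI and
    MseI/MseI intervals (diagnostics only; they carry no contexts).
    """
    if mode not in ("all", "last"):
        raise ConfigurationError(f"mode must be 'all' or 'last', got {mode!r}")
    bst, mse = enzymes
    for enzyme in enzymes:
        if not enzyme.is_palindromic():
            raise ConfigurationError(
                f"{enzyme.name}: non-palindromic recognition sites require "
                "double-strand scanning, which this digestion engine does not "
                "support"
            )
    size_model = size_model or SizeModel()
    cuts = _labelled_cuts(transcript.sequence, bst, mse)

    fragments: list[PredictedFragment] = []
    extras: list[PredictedFragment] = []
    for (start, labels5), (end, labels3) in zip(cuts, cuts[1:]):
        is_dual = "BstYI" in labels5 and "MseI" in labels3
        if not is_dual and not include_homoflanked:
            continue
        if end - start < MIN_FRAGMENT_LENGTH:
            continue
        seq = transcript.sequence[start:end]
        if is_dual:
            try:
                bst_context, mse_context = selective_contexts(seq, k5, k3)
            except FragmentTooShortError:
                bst_context = mse_context = None
            fragments.append(
                PredictedFragment(
                    transcript_id=transcript.id,
                    gene_id=transcript.gene_id,
                    start=start,
                    end=end,
                    sequence=seq,
                    bst_variant_observed=seq[4],
                    bst_context=bst_context,
                    mse_context=mse_context,
                    predicted_size=size_model.predicted_size(end - start),
                    flanks=("BstYI", "MseI"),
                )
            )
        else:
            side5 = "BstYI" if "BstYI" in labels5 else "MseI"
            side3 = "MseI" if "MseI" in labels3 else "BstYI"
            extras.append(
                PredictedFragment(
                    transcript_id=transcript.id,
                    gene_id=transcript.gene_id,
                    start=start,
                    end=end,
                    sequence=seq,
                    bst_variant_observed="",
                    bst_context=None,
                    mse_context=None,
                    predicted_size=size_model.predicted_size(end - start),
                    flanks=(side5, side3),
                )
            )

    if fragments:
        last_start = fragments[-1].start
        fragments = [
            replace(f, is_three_prime_most=(f.start == last_start)) for f in fragments
        ]
    if mode == "last":
        fragments = [f for f in fragments if f.is_three_prime_most]
    if include_homoflanked:
        return sorted(fragments + extras, key=lambda f: f.start)
    return fragments
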