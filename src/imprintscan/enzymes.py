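"""Restriction enzymes with degenerate recognition sequences.

cDNA-AFLP relies on a pair of type II restriction enzymes. The pair used
throughout this package by default is BstYI (R/GATCY, where R = A/G and
Y = C/T) and MseI (T/TAA). Recognition sequences may contain any IUPAC
nucleotide ambiguity code; cut positions are located by scanning the sense
strand only, which is sufficient because both default enzymes recognise
sites that are their own reverse complement under IUPAC complementation.

Coordinates are 0-based and half-open everywhere in this package; a cut
position ``p`` means the phosphodiester backbone is severed immediately
before index ``p`` of the sense strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "IUPAC_CODES",
    "ConfigurationError",
    "RestrictionEnzyme",
    "TranscriptRecord",
    "BSTYI",
    "MSEI",
    "reverse_complement",
    "derive_gene_id",
    "find_cut_positions",
]

#: IUPAC nucleotide ambiguity codes mapped to the set of literal bases matched.
#: Note that N in a *transcript* never matches any recognition position: the
#: sets below contain only A/C/G/T, so a masked base cannot fire a site.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_ISOFORM_SUFFIX = re.compile(r"\.\d+$")


class ConfigurationError(ValueError):
    """Raised for invalid enzyme or run configuration."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a (possibly degenerate) nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def derive_gene_id(transcript_id: str) -> str:
    """Derive the locus identifier from a transcript identifier.

    A trailing ``.<number>`` isoform suffix (the locus.isoform convention of
    annotated transcriptomes, e.g. ``At3g09840.2``) is stripped; any other
    identifier is its own gene id.
    """
    return _ISOFORM_SUFFIX.sub("", transcript_id)


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A restriction enzyme defined by name, recognition site and cut offset.

    Parameters
    ----------
    name:
        Short display name, e.g. ``"BstYI"``.
    recognition:
        IUPAC recognition sequence on the sense strand, e.g. ``"RGATCY"``.
    cut_offset:
        0-based offset of the cut within the recognition site; BstYI cuts
        R/GATCY so its offset is 1.
    """

    name: str
    recognition: str
    cut_offset: int
    _pattern: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        recognition = self.recognition.upper()
        bad = set(recognition) - set(IUPAC_CODES)
        if bad:
            raise ConfigurationError(
                f"{self.name}: invalid IUPAC code(s) {sorted(bad)} in "
                f"recognition sequence {recognition!r}"
            )
        if not recognition:
            raise ConfigurationError(f"{self.name}: empty recognition sequence")
        if not 0 <= self.cut_offset <= len(recognition):
            raise ConfigurationError(
                f"{self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(recognition)}]"
            )
        object.__setattr__(self, "recognition", recognition)
        # Lookahead so overlapping matches are all reported.
        expanded = "".join(f"[{IUPAC_CODES[c]}]" for c in recognition)
        object.__setattr__(self, "_pattern", re.compile(f"(?=({expanded}))"))

    @property
    def site_length(self) -> int:
        return len(self.recognition)

    def is_palindromic(self) -> bool:
        """True iff the recognition site equals its own IUPAC reverse complement.

        For palindromic sites a sense-strand scan finds every duplex site, so
        single-strand scanning is exact. Non-palindromic enzymes are rejected
        by the digestion engine rather than silently mishandled.
        """
        return reverse_complement(self.recognition) == self.recognition

    def find_cut_positions(self, sequence: str) -> list[int]:
        """All cut positions on ``sequence`` (sense strand), strictly increasing.

        A position ``p`` is returned iff the recognition pattern matches the
        sense strand starting at ``p - cut_offset``. Overlapping site matches
        are all reported; a transcript ``N`` never matches.
        """
        return [m.start() + self.cut_offset for m in self._pattern.finditer(sequence)]


def find_cut_positions(sequence: str, enzyme: RestrictionEnzyme) -> list[int]:
    """Functional alias for :meth:`RestrictionEnzyme.find_cut_positions`."""
    return enzyme.find_cut_positions(sequence)


@dataclass(frozen=True)
class TranscriptRecord:
    """A sense-strand transcript sequence (5'->3', poly-A side at the 3' end)."""

    id: str
    sequence: str
    gene_id: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(
                f"transcript {self.id}: non-nucleotide character(s) {sorted(bad)}"
            )
        object.__setattr__(self, "sequence", seq)
        if not self.gene_id:
            object.__setattr__(self, "gene_id", derive_gene_id(self.id))

    def __len__(self) -> int:
        return len(self.sequence)


#: BstYI recognises R/GATCY.
BSTYI = RestrictionEnzyme("BstYI", "RGATCY", 1)
#: MseI recognises T/TAA.
MSEI = RestrictionEnzyme("MseI", "TTAA", 1)

# Palindromy sufficiency for sense-strand-only scanning, asserted at load time.
for _enzyme in (BSTYI, MSEI):
    assert _enzyme.is_palindromic(), f"{_enzyme.name} is not palindromic"
del _enzyme
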