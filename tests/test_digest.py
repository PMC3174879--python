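"""Dual digestion, selective contexts, primer matching and the PCR oracle."""

import itertools

import numpy as np
import pytest

from imprintscan import (
    BSTYI,
    MSEI,
    PrimerSpec,
    RestrictionEnzyme,
    SizeModel,
    TranscriptRecord,
    digest_transcript,
    matches_primer,
    reverse_complement,
    selective_contexts,
)
from imprintscan.digest import FragmentTooShortError, MIN_FRAGMENT_LENGTH
from imprintscan.enzymes import ConfigurationError

from conftest import random_transcript

WORKED_EXAMPLE = TranscriptRecord("toy.1", "AAAAGATCTCCGGATTAAGGG")


def test_worked_example_last_fragment():
    (fragment,) = digest_transcript(WORKED_EXAMPLE, mode="last")
    assert (fragment.start, fragment.end) == (4, 15)
    assert fragment.sequence == "GATCTCCGGAT"
    assert fragment.bst_variant_observed == "T"
    assert len(fragment) == 11
    assert fragment.predicted_size == 11 + 26
    assert fragment.is_three_prime_most
    assert fragment.gene_id == "toy"


def test_no_bst_site_yields_nothing():
    assert digest_transcript(TranscriptRecord("t", "CCCCTTAACCCC")) == []
    assert digest_transcript(TranscriptRecord("t", "CCCCTTAACCCC"), mode="all") == []


def test_bst_bst_interval_excluded():
    # BstYI cuts at b1 < b2, one MseI cut m > b2: only [b2, m) is a fragment
    seq = "AGATCC" + "CCC" + "GGATCT" + "CCCCCC" + "TTAA" + "CC"
    transcript = TranscriptRecord("t", seq)
    fragments = digest_transcript(transcript, mode="all")
    assert len(fragments) == 1
    assert fragments[0].sequence.startswith("GATCT")
    assert fragments[0].sequence.endswith("T")
    # diagnostics mode also surfaces the BstYI/BstYI interval
    with_extras = digest_transcript(transcript, mode="all", include_homoflanked=True)
    flanks = {f.flanks for f in with_extras}
    assert ("BstYI", "BstYI") in flanks and ("BstYI", "MseI") in flanks


def test_mode_last_is_maximal_start_member_of_all(small_transcriptome):
    records_a, _, _ = small_transcriptome
    for transcript in records_a:
        every = digest_transcript(transcript, mode="all")
        last = digest_transcript(transcript, mode="last")
        assert [f for f in every if f.is_three_prime_most] == last
        assert last[0].start == max(f.start for f in every)
        # partition property: candidate fragments never overlap
        spans = sorted((f.start, f.end) for f in every)
        assert all(a_end <= b_start for (_, a_end), (b_start, _) in zip(spans, spans[1:]))


def test_short_product_discarded():
    # overlapping sites RGATCT+TAA give a 5-bp product, below the minimum
    seq = "CCAGATCTTAACC"
    assert digest_transcript(TranscriptRecord("t", seq), mode="all") == []
    assert MIN_FRAGMENT_LENGTH == 6


@pytest.mark.parametrize(
    "fragment, k5, k3, expected",
    [
        ("GATCTCCGGAT", 2, 2, ("CC", "TC")),
        ("GATCTCCGGAT", 0, 0, ("", "")),
        ("GATCTCCGGAT", 1, 2, ("C", "TC")),
    ],
)
def test_selective_contexts(fragment, k5, k3, expected):
    assert selective_contexts(fragment, k5, k3) == expected


def test_selective_contexts_too_short():
    with pytest.raises(FragmentTooShortError):
        selective_contexts("GATCCAT", 2, 2)  # length 7 < 5+2+1+2


def test_unamplifiable_fragment_flagged():
    # 8-bp fragment digests fine but cannot carry 2+2 selective nucleotides
    seq = "CCAGATCTCCTTAACC"
    (fragment,) = digest_transcript(TranscriptRecord("t", seq), mode="all")
    assert len(fragment) == 8
    assert not fragment.amplifiable and fragment.primer is None


@pytest.mark.parametrize(
    "primer, expected",
    [
        (PrimerSpec("T", "CC", "TC"), True),
        (PrimerSpec("C", "CC", "TC"), False),
        (PrimerSpec("T", "CC", "AG"), False),
    ],
)
def test_matches_primer(primer, expected):
    (fragment,) = digest_transcript(WORKED_EXAMPLE, mode="last")
    assert matches_primer(fragment, primer) is expected


def test_primer_exhaustiveness(small_transcriptome):
    """Each amplifiable fragment matches exactly one of the 2x16x16 combinations."""
    panel = [
        PrimerSpec(variant, "".join(sel5), "".join(sel3))
        for variant in "CT"
        for sel5 in itertools.product("ACGT", repeat=2)
        for sel3 in itertools.product("ACGT", repeat=2)
    ]
    assert len(panel) == 2 * 16 * 16
    records_a, _, _ = small_transcriptome
    checked = 0
    for transcript in records_a[:10]:
        for fragment in digest_transcript(transcript, mode="all"):
            if not fragment.amplifiable:
                continue
            hits = [p for p in panel if matches_primer(fragment, p)]
            assert hits == [fragment.primer]
            checked += 1
    assert checked > 0


BST_PRIMER_COMMON = "GACTGCGTAGTGATC"   # 18-nt primer minus Y minus 2 selective
MSE_PRIMER_COMMON = "GATGAGTCCTGAGTAA"  # 18-nt primer minus 2 selective


def _amplicon(fragment) -> str:
    """Literal amplicon top strand: adapter tails around the fragment.

    The BstYI primer's first 11 nt extend beyond the 5' cut; the MseI
    primer's first 15 nt (reverse-complemented) extend beyond the 3' cut.
    """
    return BST_PRIMER_COMMON[:-4] + fragment.sequence + reverse_complement(
        MSE_PRIMER_COMMON[:-1]
    )


def _brute_force_amplifies(fragment, primer: PrimerSpec) -> bool:
    """Does the reconstructed amplicon carry both full primers at its ends?"""
    amplicon = _amplicon(fragment)
    bst_full = BST_PRIMER_COMMON + primer.bst_variant + primer.bst_selective
    mse_full = MSE_PRIMER_COMMON + primer.mse_selective
    return amplicon.startswith(bst_full) and reverse_complement(amplicon).startswith(
        mse_full
    )


def test_full_pcr_oracle(rng):
    """matches_primer agrees with literal amplicon reconstruction."""
    checked = 0
    for _ in range(100):
        transcript = TranscriptRecord("r", random_transcript(rng, 800))
        for fragment in digest_transcript(transcript, mode="all"):
            if not fragment.amplifiable:
                continue
            own = fragment.primer
            probes = [own] + [
                PrimerSpec(v, s5, s3)
                for v, s5, s3 in (
                    ("C" if own.bst_variant == "T" else "T",
                     own.bst_selective, own.mse_selective),
                    (own.bst_variant, "AA", own.mse_selective),
                    (own.bst_variant, own.bst_selective, "GG"),
                )
            ]
            for primer in probes:
                assert matches_primer(fragment, primer) == _brute_force_amplifies(
                    fragment, primer
                ), (fragment.sequence, primer)
                checked += 1
    assert checked > 100


def test_size_linearity(small_transcriptome):
    records_a, _, _ = small_transcriptome
    for model in (SizeModel(), SizeModel(correction_total=0), SizeModel(3, 4)):
        offsets = {
            f.predicted_size - len(f)
            for t in records_a[:5]
            for f in digest_transcript(t, mode="all", size_model=model)
        }
        assert offsets == {model.correction_total}


def test_size_model_defaults():
    assert SizeModel().correction_total == 26
    assert SizeModel(correction_total=30).correction_total == 30
    with pytest.raises(ConfigurationError):
        SizeModel(bst_tail=1, mse_tail=1, correction_total=-2)


def test_non_palindromic_enzyme_rejected():
    fok = RestrictionEnzyme("FokI", "GGATG", 0)
    with pytest.raises(ConfigurationError, match="palindromic"):
        digest_transcript(WORKED_EXAMPLE, enzymes=(fok, MSEI))


def test_primer_spec_validation_and_label():
    assert PrimerSpec("T", "CC", "AG").label == "BstYI+TCC / MseI+AG"
    with pytest.raises(ConfigurationError):
        PrimerSpec("A")
    with pytest.raises(ConfigurationError):
        PrimerSpec("C", "AAA", "")
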