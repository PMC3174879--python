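"""Seeded synthetic fixtures with planted ground truth.

Every generator here emulates one input surface of an imprinting screen so
the other modules can be tested end-to-end without external downloads:

* :func:`simulate_transcriptome` — paired-accession transcript sets with
  planted BstYI->MseI fragments and, for a configured fraction of genes, a
  single SNP destroying one restriction site of the poly-A-proximal
  fragment in one accession (the mechanism that makes a TDF
  accession-specific in a real screen);
* :func:`simulate_allele_table` — reciprocal-cross presence/absence tables
  over selfs and F1s at several timepoints, with known maternal genes;
* :func:`simulate_methylation` — two-condition percent-methylation tracks
  with planted DMRs over bounded baseline noise.

Planted fragments are built by concatenating literal site motifs around
random filler drawn from {A, C, G}. Excluding T from filler means TT (the
core of the MseI site) and GATC (the core of the BstYI site) can only
occur inside planted motifs, so fillers are site-free by construction at
any spacing; a post-scan asserts it. All outputs are byte-deterministic
under a fixed seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import PrimerSpec, SizeModel
from .dmr import MethylationRecord
from .enzymes import BSTYI, MSEI, ConfigurationError, TranscriptRecord, reverse_complement
from .parent_of_origin import AlleleCallTable, CrossDesign, Sample

__all__ = [
    "SimulationConfig",
    "simulate_transcriptome",
    "simulate_allele_table",
    "simulate_methylation",
]

_FILLER_ALPHABET = np.array(list("ACG"))


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic fixtures; defaults are the study conditions.

    ``site_disruption_fraction`` is the fraction of genes whose poly-A-
    proximal fragment loses a restriction site in one accession (~0.5,
    matching the roughly half-polymorphic TDF pool of a two-accession
    screen); of the polymorphic genes, ``maternal_fraction`` are planted as
    maternally expressed. Timepoints follow the 3/4/5 days-after-
    pollination sampling of silique screens.
    """

    seed: int = 0
    # transcriptome geometry
    n_genes: int = 200
    isoforms_per_gene: int = 1
    fragment_interior_range: tuple[int, int] = (30, 250)
    utr5_range: tuple[int, int] = (40, 120)
    utr3_range: tuple[int, int] = (20, 60)
    decoy_fragments: int = 1
    polya_length: int = 20
    site_disruption_fraction: float = 0.5
    # cross design
    accessions: tuple[str, str] = ("Col-0", "Ler-0")
    timepoints: tuple[int, ...] = (3, 4, 5)
    maternal_fraction: float = 0.2
    single_timepoint_fraction: float = 0.0
    dropout: float = 0.0
    # methylation track
    chromosome: str = "Chr1"
    track_length: int = 60_000
    cytosine_spacing: int = 25
    baseline_noise: float = 5.0
    n_planted_dmrs: int = 2
    dmr_n_cytosines: int = 8
    dmr_effect: float = 40.0
    # digestion settings the truth table is expressed in
    k5: int = 2
    k3: int = 2
    size_model: SizeModel = field(default_factory=SizeModel)

    def __post_init__(self) -> None:
        for name in ("site_disruption_fraction", "maternal_fraction",
                     "single_timepoint_fraction", "dropout"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.fragment_interior_range[0] < 4:
            raise ConfigurationError(
                "fragment interior must be >= 4 bases so two selective "
                "nucleotides fit on each side"
            )
        for lo, hi in (self.fragment_interior_range, self.utr5_range, self.utr3_range):
            if lo > hi or lo < 0:
                raise ConfigurationError(f"invalid range ({lo}, {hi})")
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")


def _filler(rng: np.random.Generator, length: int) -> str:
    """Site-free random filler: no T, hence no TTAA and no GATC possible."""
    return "".join(rng.choice(_FILLER_ALPHABET, size=length)) if length else ""


def _fragment_block(rng: np.random.Generator, interior_length: int) -> str:
    """One planted site pair: R GATC Y <interior> TTAA (interior is T-free)."""
    r = rng.choice(["A", "G"])
    y = rng.choice(["C", "T"])
    return r + "GATC" + y + _filler(rng, interior_length) + "TTAA"


def simulate_transcriptome(
    config: SimulationConfig,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord], pd.DataFrame]:
    """Generate paired-accession transcript sets with a planted truth table.

    Returns ``(records_a, records_b, truth)``. Every transcript carries at
    least one BstYI->MseI fragment; the 3'-most one is the planted *final*
    fragment whose primer key and predicted size the truth table records.
    For a ``site_disruption_fraction`` of genes, one accession (chosen at
    random) carries a SNP destroying the final fragment's BstYI or MseI
    site, so its poly-A-proximal TDF differs — the other accession is the
    *carrier* of the planted TDF. Isoforms of one gene share the 3' end and
    therefore the final fragment.
    """
    rng = np.random.default_rng(config.seed)
    records_a: list[TranscriptRecord] = []
    records_b: list[TranscriptRecord] = []
    truth_rows = []

    n_disrupted = round(config.n_genes * config.site_disruption_fraction)
    disrupted_genes = set(
        rng.choice(config.n_genes, size=n_disrupted, replace=False).tolist()
    )

    for g in range(config.n_genes):
        gene_id = f"SYN{g + 1:04d}"
        interior_len = int(rng.integers(*config.fragment_interior_range, endpoint=True))
        interior = _filler(rng, interior_len)
        r = rng.choice(["A", "G"])
        y = rng.choice(["C", "T"])
        final_block = r + "GATC" + y + interior + "TTAA"

        decoys = "".join(
            _fragment_block(rng, int(rng.integers(20, 120)))
            + _filler(rng, int(rng.integers(10, 40)))
            for _ in range(config.decoy_fragments)
        )
        utr3 = _filler(rng, int(rng.integers(*config.utr3_range, endpoint=True)))
        body = decoys + final_block + utr3 + "A" * config.polya_length

        disrupted_accession: str | None = None
        mutated_body = body
        if g in disrupted_genes:
            disrupted_accession = config.accessions[int(rng.integers(2))]
            block_start = len(decoys)
            if rng.random() < 0.5:
                # destroy the BstYI site: the C of GATC -> A (creates no new site)
                pos = block_start + 4
                assert body[pos] == "C"
                mutated_body = body[:pos] + "A" + body[pos + 1:]
            else:
                # destroy the MseI site: the first T of TTAA -> C
                pos = block_start + len(final_block) - 4
                assert body[pos] == "T"
                mutated_body = body[:pos] + "C" + body[pos + 1:]

        for isoform in range(1, config.isoforms_per_gene + 1):
            utr5 = _filler(rng, int(rng.integers(*config.utr5_range, endpoint=True)))
            transcript_id = f"{gene_id}.{isoform}"
            seq_a = utr5 + (body if disrupted_accession != config.accessions[0] else mutated_body)
            seq_b = utr5 + (body if disrupted_accession != config.accessions[1] else mutated_body)
            records_a.append(TranscriptRecord(transcript_id, seq_a))
            records_b.append(TranscriptRecord(transcript_id, seq_b))

            # planted final-fragment geometry on the intact allele
            intact = utr5 + body
            frag_start = len(utr5) + len(decoys) + 1          # cut after R
            frag_end = frag_start + 5 + interior_len + 1      # cut after first T of TTAA
            fragment_length = frag_end - frag_start
            bst_sel = interior[:config.k5]
            mse_sel = reverse_complement(interior[len(interior) - config.k3:])
            assert intact[frag_start:frag_start + 4] == "GATC"
            truth_rows.append(
                {
                    "gene_id": gene_id,
                    "transcript_id": transcript_id,
                    "bst_variant": y,
                    "bst_sel": bst_sel,
                    "mse_sel": mse_sel,
                    "fragment_length": fragment_length,
                    "predicted_size": config.size_model.predicted_size(fragment_length),
                    "polymorphic": disrupted_accession is not None,
                    "disrupted_accession": disrupted_accession,
                    "carrier_accession": (
                        None if disrupted_accession is None
                        else next(a for a in config.accessions if a != disrupted_accession)
                    ),
                }
            )

    # post-scan: filler construction must have planted every site deliberately
    expected_sites = config.decoy_fragments + 1
    for rec_a, rec_b, row in zip(records_a, records_b, truth_rows):
        n_sites = {
            acc: len(BSTYI.find_cut_positions(rec.sequence))
            + len(MSEI.find_cut_positions(rec.sequence))
            for acc, rec in zip(config.accessions, (rec_a, rec_b))
        }
        if row["disrupted_accession"] is None:
            assert all(n == 2 * expected_sites for n in n_sites.values())
        else:
            assert n_sites[row["carrier_accession"]] == 2 * expected_sites
            assert n_sites[row["disrupted_accession"]] == 2 * expected_sites - 1

    truth = pd.DataFrame(truth_rows)
    return records_a, records_b, truth


def _sample_label(mother: str, father: str, timepoint: int) -> str:
    return f"{mother}x{father}_{timepoint}dap"


def _build_design(config: SimulationConfig) -> CrossDesign:
    a, b = config.accessions
    samples = {}
    for timepoint in config.timepoints:
        for mother, father in ((a, a), (b, b), (a, b), (b, a)):
            samples[_sample_label(mother, father, timepoint)] = Sample(
                mother, father, timepoint
            )
    return CrossDesign(config.accessions, samples, tuple(config.timepoints))


def simulate_allele_table(
    truth: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[AlleleCallTable, CrossDesign, pd.DataFrame]:
    """Derive a reciprocal-cross allele table with known parent-of-origin truth.

    One table row per gene (its poly-A-proximal TDF, keyed by primer
    combination and predicted size). Non-polymorphic genes are present in
    every sample. Polymorphic genes are present in the carrier self only;
    of these, ``maternal_fraction`` are planted maternal (present in the F1
    where the carrier is the mother, absent in the reciprocal), the rest
    biallelic (present in both F1s). A ``single_timepoint_fraction`` of the
    maternal genes express their F1 pattern at one timepoint only, which is
    below the two-stage evidence rule — their expected call is
    ``insufficient_evidence``. ``dropout`` flips present->absent at the
    given rate. Expected calls per gene are returned as the truth labels.
    """
    rng = np.random.default_rng(config.seed + 1)
    design = _build_design(config)
    gene_truth = truth.drop_duplicates("gene_id").set_index("gene_id")

    polymorphic = [g for g, row in gene_truth.iterrows() if row.polymorphic]
    n_maternal = round(len(polymorphic) * config.maternal_fraction)
    shuffled = list(polymorphic)
    rng.shuffle(shuffled)
    maternal = set(shuffled[:n_maternal])
    n_single = round(len(maternal) * config.single_timepoint_fraction)
    single_stage = set(sorted(maternal)[:n_single])

    rows: dict[tuple[str, float], dict[str, int]] = {}
    label_rows = []
    for gene_id, row in gene_truth.iterrows():
        primer = PrimerSpec(row.bst_variant, row.bst_sel, row.mse_sel)
        key = (primer.label, float(row.predicted_size))
        cells = {label: 0 for label in design.samples}
        if not row.polymorphic:
            cells = {label: 1 for label in design.samples}
            expected = "not_polymorphic"
        else:
            carrier = row.carrier_accession
            other = next(a for a in config.accessions if a != carrier)
            active_timepoints = tuple(config.timepoints)
            if gene_id in single_stage:
                active_timepoints = (
                    config.timepoints[int(rng.integers(len(config.timepoints)))],
                )
            for timepoint in config.timepoints:
                cells[_sample_label(carrier, carrier, timepoint)] = 1
                if gene_id in maternal:
                    if timepoint in active_timepoints:
                        cells[_sample_label(carrier, other, timepoint)] = 1
                else:  # biallelic
                    cells[_sample_label(carrier, other, timepoint)] = 1
                    cells[_sample_label(other, carrier, timepoint)] = 1
            if gene_id in single_stage:
                expected = "insufficient_evidence"
            elif gene_id in maternal:
                expected = "maternal"
            else:
                expected = "not_uniparental"
        if config.dropout > 0:
            cells = {
                label: (0 if value and rng.random() < config.dropout else value)
                for label, value in cells.items()
            }
        rows[key] = cells
        label_rows.append(
            {
                "gene_id": gene_id,
                "primer_key": key[0],
                "bin_center": key[1],
                "carrier_accession": row.carrier_accession,
                "expected_call": expected,
            }
        )

    calls = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    calls.index = pd.MultiIndex.from_tuples(calls.index, names=["primer_key", "bin_center"])
    table = AlleleCallTable(calls, provenance={"seed": config.seed})
    return table, design, pd.DataFrame(label_rows)


def simulate_methylation(
    config: SimulationConfig,
) -> tuple[list[MethylationRecord], pd.DataFrame]:
    """Two-condition methylation track with planted DMRs.

    Baseline cytosines carry pct_b = pct_a plus noise bounded by
    ``baseline_noise`` (kept below any sensible detection threshold).
    Planted regions raise pct_b by ``dmr_effect`` over ``dmr_n_cytosines``
    consecutive cytosines, centred at evenly spaced anchors so regions
    cannot chain together. Returns the records and a truth table of
    planted intervals.
    """
    if config.dmr_effect <= config.baseline_noise:
        warnings.warn(
            "planted DMR effect does not exceed the baseline noise bound; "
            "planted regions will be undetectable"
        )
    rng = np.random.default_rng(config.seed + 2)
    spacing = config.cytosine_spacing
    gaps = rng.integers(max(1, spacing // 2), spacing * 3 // 2 + 1,
                        size=config.track_length // spacing * 2)
    positions = 1 + np.cumsum(gaps)
    positions = positions[positions <= config.track_length]

    pct_a = rng.uniform(20, 80, size=len(positions))
    pct_b = pct_a + rng.uniform(-config.baseline_noise, config.baseline_noise,
                                size=len(positions))

    truth_rows = []
    n = config.n_planted_dmrs
    for i in range(n):
        anchor = config.track_length * (i + 1) / (n + 1)
        center_idx = int(np.argmin(np.abs(positions - anchor)))
        lo = max(0, center_idx - config.dmr_n_cytosines // 2)
        idx = slice(lo, lo + config.dmr_n_cytosines)
        pct_a[idx] = rng.uniform(20, 55, size=config.dmr_n_cytosines)
        pct_b[idx] = pct_a[idx] + config.dmr_effect
        truth_rows.append(
            {
                "chromosome": config.chromosome,
                "start": int(positions[idx][0]),
                "end": int(positions[idx][-1]),
                "n_cytosines": config.dmr_n_cytosines,
                "effect": config.dmr_effect,
            }
        )

    records = [
        MethylationRecord(config.chromosome, int(pos), float(np.clip(a, 0, 100)),
                          float(np.clip(b, 0, 100)))
        for pos, a, b in zip(positions, pct_a, pct_b)
    ]
    return records, pd.DataFrame(truth_rows)
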