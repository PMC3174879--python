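"""Shared readers/writers and the run configuration.

Interchange conventions: FASTA for transcript sets (via Biopython), GFF3
(gene features only) for annotations, and tab-delimited UTF-8 TSV with a
header row and ``#``-prefixed provenance comments for every tabular
artifact. GFF3 coordinates are 1-based closed on disk and stay 1-based in
the annotation objects (the DMR module's convention); transcript-level
interval arithmetic is 0-based half-open internally.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable
from urllib.parse import unquote

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .digest import PredictedFragment, PrimerSpec, SizeModel
from .dmr import DMRParams, GeneAnnotation, MethylationRecord
from .enzymes import RestrictionEnzyme, TranscriptRecord
from .matching import MatchResult, ObservedTDF
from .parent_of_origin import AlleleCallTable, CrossDesign, ParentOfOriginCall, Sample
from .ranking import ExpressionRecord

__all__ = [
    "RunConfig",
    "read_fasta",
    "write_fasta",
    "read_tsv",
    "write_tsv",
    "read_gff3_genes",
    "read_methylation",
    "read_observed_tdfs",
    "read_expression",
    "read_allele_table",
    "write_allele_table",
    "read_cross_design",
    "fragments_to_frame",
    "match_results_to_frame",
    "calls_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Numeric run parameters, echoed into all output headers for provenance."""

    bst_enzyme: tuple[str, str, int] = ("BstYI", "RGATCY", 1)
    mse_enzyme: tuple[str, str, int] = ("MseI", "TTAA", 1)
    k5: int = 2
    k3: int = 2
    size_correction: int = SizeModel().correction_total
    mode: str = "last"
    tolerance: float = 1.0
    min_stages: int = 2
    bin_halfwidth: float = 0.5
    dmr_min_diff: float = 20.0
    dmr_min_count: int = 5
    dmr_max_gap: int = 250

    @property
    def enzymes(self) -> tuple[RestrictionEnzyme, RestrictionEnzyme]:
        return (RestrictionEnzyme(*self.bst_enzyme), RestrictionEnzyme(*self.mse_enzyme))

    @property
    def size_model(self) -> SizeModel:
        return SizeModel(correction_total=self.size_correction)

    @property
    def dmr_params(self) -> DMRParams:
        return DMRParams(self.dmr_min_diff, self.dmr_min_count, self.dmr_max_gap)

    def provenance(self) -> dict:
        d = asdict(self)
        d["bst_enzyme"] = "/".join(map(str, d["bst_enzyme"]))
        d["mse_enzyme"] = "/".join(map(str, d["mse_enzyme"]))
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("bst_enzyme", "mse_enzyme"):
            if key in data:
                name, recognition, offset = data[key]
                data[key] = (name, recognition, int(offset))
        return cls(**data)


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[TranscriptRecord]:
    """Read a (possibly line-wrapped, mixed-case) multi-FASTA transcript set.

    Record ids are the first whitespace-delimited header token; sequences
    are upper-cased. Empty records are rejected; an empty file yields an
    empty list with a warning.
    """
    records = []
    with open(path, encoding="utf-8") as handle:
        for seq_record in SeqIO.parse(handle, "fasta"):
            sequence = str(seq_record.seq)
            if not sequence:
                raise ValueError(f"{path}: empty sequence for record {seq_record.id!r}")
            records.append(TranscriptRecord(seq_record.id, sequence))
    if not records:
        logger.warning("%s: no FASTA records found", path)
    return records


def write_fasta(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


# ---------------------------------------------------------------------------
# TSV with provenance comments

def write_tsv(frame: pd.DataFrame, path: str | Path, provenance: dict | None = None,
              index: bool = False) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for key, value in (provenance or {}).items():
            handle.write(f"# {key}={value}\n")
        frame.to_csv(handle, sep="\t", index=index)


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# Domain-specific tables

def read_gff3_genes(path: str | Path) -> list[GeneAnnotation]:
    """Parse the gene features of a GFF3 file (1-based closed coordinates).

    Only ``gene``-type features are used; the gene id comes from the ID=
    (or gene_id=) attribute, falling back to a positional label.
    """
    genes = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(fields)}")
        chrom, _source, ftype, start, end, _score, strand, _phase, attributes = fields
        if ftype != "gene":
            continue
        attrs = dict(
            part.split("=", 1) for part in attributes.strip(";").split(";") if "=" in part
        )
        gene_id = unquote(attrs.get("ID", attrs.get("gene_id", f"gene_{lineno}")))
        genes.append(GeneAnnotation(gene_id, chrom, int(start), int(end), strand))
    return genes


def read_methylation(path: str | Path) -> list[MethylationRecord]:
    """BED-like methylation TSV: chrom, pos (1-based), pct_a, pct_b[, context]."""
    frame = read_tsv(path)
    has_context = "context" in frame.columns
    return [
        MethylationRecord(
            str(row.chrom), int(row.pos), float(row.pct_a), float(row.pct_b),
            context=str(row.context) if has_context else None,
        )
        for row in frame.itertuples()
    ]


def read_observed_tdfs(path: str | Path) -> list[ObservedTDF]:
    """Observed-TDF TSV: tdf_id, bst_variant, bst_sel, mse_sel, size."""
    frame = read_tsv(path, dtype={"bst_sel": str, "mse_sel": str}, keep_default_na=False)
    return [
        ObservedTDF(
            str(row.tdf_id),
            PrimerSpec(str(row.bst_variant), str(row.bst_sel), str(row.mse_sel)),
            float(row.size),
        )
        for row in frame.itertuples()
    ]


def read_expression(path: str | Path) -> list[ExpressionRecord]:
    """Seed-tissue expression TSV with optional presence/probe columns."""
    frame = read_tsv(path)
    records = []
    for row in frame.itertuples():
        records.append(
            ExpressionRecord(
                gene_id=str(row.gene_id),
                seed_coat=float(row.seed_coat),
                embryo=float(row.embryo),
                peripheral_endosperm=float(row.peripheral_endosperm),
                micropylar_endosperm=float(row.micropylar_endosperm),
                chalazal_endosperm=float(row.chalazal_endosperm),
                present_in_seed=bool(getattr(row, "present_in_seed", True)),
                probe_status=str(getattr(row, "probe_status", "ok")),
            )
        )
    return records


def read_allele_table(path: str | Path, bin_halfwidth: float = 0.5) -> AlleleCallTable:
    """Allele table TSV: primer_key, bin_center, then one 0/1 column per sample."""
    frame = read_tsv(path)
    frame = frame.set_index(["primer_key", "bin_center"])
    return AlleleCallTable(frame, bin_halfwidth=bin_halfwidth)


def write_allele_table(table: AlleleCallTable, path: str | Path,
                       provenance: dict | None = None) -> None:
    merged = dict(table.provenance)
    merged.update(provenance or {})
    merged["bin_halfwidth"] = table.bin_halfwidth
    write_tsv(table.calls.reset_index(), path, provenance=merged)


def read_cross_design(path: str | Path) -> CrossDesign:
    """Design TSV: sample, mother, father, timepoint."""
    frame = read_tsv(path)
    samples = {
        str(row.sample): Sample(str(row.mother), str(row.father), int(row.timepoint))
        for row in frame.itertuples()
    }
    accessions = sorted({s.mother for s in samples.values()}
                        | {s.father for s in samples.values()})
    if len(accessions) != 2:
        raise ValueError(
            f"cross design must involve exactly two accessions, found {accessions}"
        )
    timepoints = tuple(sorted({s.timepoint for s in samples.values()}))
    return CrossDesign((accessions[0], accessions[1]), samples, timepoints)


# ---------------------------------------------------------------------------
# Result serialisation

def fragments_to_frame(fragments: Iterable[PredictedFragment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "transcript_id": f.transcript_id,
                "gene_id": f.gene_id,
                "start": f.start,
                "end": f.end,
                "bst_variant": f.bst_variant_observed,
                "bst_sel": f.bst_context or "",
                "mse_sel": f.mse_context or "",
                "predicted_size": f.predicted_size,
                "is_three_prime_most": f.is_three_prime_most,
            }
            for f in fragments
        ],
        columns=["transcript_id", "gene_id", "start", "end", "bst_variant",
                 "bst_sel", "mse_sel", "predicted_size", "is_three_prime_most"],
    )


def match_results_to_frame(results: Iterable[MatchResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "tdf_id": r.tdf_id,
                "status": r.status,
                "gene_ids": ",".join(c.gene_id for c in r.matched_genes),
                "deviations": ",".join(f"{c.deviation:g}" for c in r.matched_genes),
                "near_misses": ",".join(
                    f"{c.gene_id}:{c.predicted_size:g}:{c.deviation:g}"
                    for c in r.near_misses
                ),
                "note": r.note,
            }
            for r in results
        ],
        columns=["tdf_id", "status", "gene_ids", "deviations", "near_misses", "note"],
    )


def calls_to_frame(calls: Iterable[ParentOfOriginCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "primer_key": c.key[0],
                "bin_center": c.key[1],
                "carrier_accession": c.carrier_accession or "",
                "call": c.call,
                "supporting_timepoints": ",".join(map(str, c.supporting_timepoints)),
            }
            for c in calls
        ],
        columns=["primer_key", "bin_center", "carrier_accession", "call",
                 "supporting_timepoints"],
    )
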