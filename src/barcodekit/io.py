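"""Reading, writing and summarising species-labelled barcode alignments.

A barcode reference library is an aligned FASTA (equal-length sequences over
the IUPAC DNA alphabet plus ``-`` gaps) together with a 5-column tab-separated
metadata table (``id``, ``species``, ``genus``, ``family``, ``higher_taxon``)
mapping every sequence to its taxonomic labels.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError, DuplicateIdError, MetadataError

#: Unambiguous nucleotide states.
BASES = ("A", "C", "G", "T")

#: Full IUPAC nucleotide alphabet accepted in aligned barcodes.
IUPAC_DNA = set("ACGTRYSWKMBDHVN-")

#: IUPAC ambiguity code for every non-empty subset of {A,C,G,T}.
AMBIGUITY_CODE = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G",
    frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}

METADATA_COLUMNS = ["id", "species", "genus", "family", "higher_taxon"]

#: Barcodes shorter (ungapped, unambiguous) than this raise a warning only;
#: the CBOL quality standard for a full barcode record.
MIN_BARCODE_LENGTH = 500


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned barcode sequence with its taxonomic labels."""

    id: str
    species: str
    genus: str
    family: str
    higher_taxon: str
    sequence: str

    def __post_init__(self) -> None:
        for name in ("id", "species", "genus", "family", "higher_taxon"):
            if not getattr(self, name):
                raise MetadataError(f"record field {name!r} must be non-empty")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise AlignmentError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )
        if not any(c in BASES for c in self.sequence):
            raise AlignmentError(
                f"record {self.id!r}: no unambiguous base in sequence"
            )

    @property
    def ungapped_length(self) -> int:
        """Number of unambiguous (A/C/G/T) sites in the sequence."""
        return sum(1 for c in self.sequence if c in BASES)


@dataclass
class AlignmentStats:
    """Library-level composition summary of an aligned barcode dataset."""

    base_frequencies: dict[str, float]
    gc_content: float
    n_conserved: int
    n_variable: int
    n_singleton: int
    n_sequences: int
    alignment_length: int
    min_length_ungapped: int

    def to_dict(self) -> dict:
        return {
            "base_frequencies": dict(self.base_frequencies),
            "gc_content": self.gc_content,
            "n_conserved": self.n_conserved,
            "n_variable": self.n_variable,
            "n_singleton": self.n_singleton,
            "n_sequences": self.n_sequences,
            "alignment_length": self.alignment_length,
            "min_length_ungapped": self.min_length_ungapped,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def read_alignment(
    fasta_path: str | Path, metadata_path: str | Path
) -> list[BarcodeRecord]:
    """Read an aligned FASTA plus its metadata TSV into BarcodeRecords.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  Records are
    returned in FASTA file order.

    Raises
    ------
    AlignmentError
        If sequences are not all the same length.
    MetadataError
        If a FASTA id is missing from the metadata table or the table lacks
        the required columns.
    DuplicateIdError
        If an id occurs more than once in the FASTA or the metadata.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise MetadataError(
            f"metadata table {metadata_path} lacks columns {missing_cols}"
        )
    if meta["id"].duplicated().any():
        dups = meta.loc[meta["id"].duplicated(), "id"].tolist()
        raise DuplicateIdError(f"duplicate ids in metadata: {dups}")
    meta = meta.set_index("id")

    records: list[BarcodeRecord] = []
    seen: set[str] = set()
    length: int | None = None
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise DuplicateIdError(f"duplicate id in FASTA: {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"sequence {rec.id!r} has length {len(seq)}, expected {length}"
            )
        if rec.id not in meta.index:
            raise MetadataError(f"FASTA id {rec.id!r} absent from metadata")
        row = meta.loc[rec.id]
        records.append(
            BarcodeRecord(
                id=rec.id,
                species=row["species"],
                genus=row["genus"],
                family=row["family"],
                higher_taxon=row["higher_taxon"],
                sequence=seq,
            )
        )
    return records


def write_alignment(
    records: Sequence[BarcodeRecord],
    fasta_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write records back to the FASTA + metadata TSV dialect read_alignment reads."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(fasta_path), "fasta")
    pd.DataFrame(
        [
            {
                "id": r.id,
                "species": r.species,
                "genus": r.genus,
                "family": r.family,
                "higher_taxon": r.higher_taxon,
            }
            for r in records
        ],
        columns=METADATA_COLUMNS,
    ).to_csv(metadata_path, sep="\t", index=False)


def _check_equal_lengths(records: Sequence[BarcodeRecord]) -> int:
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise AlignmentError(f"unequal sequence lengths: {sorted(lengths)}")
    return lengths.pop()


def composition_stats(records: Sequence[BarcodeRecord]) -> AlignmentStats:
    """Compute base composition and per-site conservation classes.

    Base frequencies are pooled over all unambiguous bases of all records;
    ambiguity codes and gaps are excluded from the counts.  A site is
    *conserved* when every unambiguous state present agrees (gaps and
    ambiguity codes do not contradict); *variable* otherwise; a variable
    site is additionally a *singleton* when exactly one sequence differs
    from the shared state of all the others.
    """
    if not records:
        raise ValueError("composition_stats requires at least one record")
    length = _check_equal_lengths(records)

    base_counts: Counter[str] = Counter()
    for r in records:
        base_counts.update(c for c in r.sequence if c in BASES)
    total = sum(base_counts.values())
    freqs = {b: base_counts[b] / total for b in BASES}

    n_conserved = n_variable = n_singleton = 0
    for j in range(length):
        column = [r.sequence[j] for r in records]
        states = Counter(c for c in column if c in BASES)
        if len(states) <= 1:
            n_conserved += 1
        else:
            n_variable += 1
            if len(states) == 2 and min(states.values()) == 1:
                n_singleton += 1

    return AlignmentStats(
        base_frequencies=freqs,
        gc_content=freqs["G"] + freqs["C"],
        n_conserved=n_conserved,
        n_variable=n_variable,
        n_singleton=n_singleton,
        n_sequences=len(records),
        alignment_length=length,
        min_length_ungapped=min(r.ungapped_length for r in records),
    )


@dataclass
class StopCodonReport:
    """Per-record internal stop-codon count under the vertebrate mitochondrial code."""

    id: str
    n_stops: int
    gap_in_codon: bool
    stop_positions: list[int] = field(default_factory=list)


def translation_check(
    records: Sequence[BarcodeRecord], frame: int = 0
) -> list[StopCodonReport]:
    """Count internal stop codons per record in the given reading frame.

    Translation uses the vertebrate mitochondrial genetic code (NCBI table
    2), under which AGA and AGG are stops in addition to TAA and TAG.  A
    quality screen for a protein-coding barcode: any internal stop usually
    indicates a pseudogene or a frame/alignment problem.  Report-only; no
    record is rejected.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame!r}")
    reports = []
    for r in records:
        seq = r.sequence[frame:]
        gap_in_codon = False
        stops: list[int] = []
        for i in range(0, len(seq) - 2, 3):
            codon = seq[i : i + 3]
            if "-" in codon:
                gap_in_codon = True
                continue
            if set(codon) <= set(BASES):
                aa = str(Seq(codon).translate(table=2))
                if aa == "*":
                    stops.append(frame + i)
        reports.append(
            StopCodonReport(
                id=r.id,
                n_stops=len(stops),
                gap_in_codon=gap_in_codon,
                stop_positions=stops,
            )
        )
    return reports


def short_sequence_warnings(
    records: Iterable[BarcodeRecord], min_length: int = MIN_BARCODE_LENGTH
) -> list[str]:
    """Ids of records whose ungapped length falls below the quality standard."""
    return [r.id for r in records if r.ungapped_length < min_length]
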