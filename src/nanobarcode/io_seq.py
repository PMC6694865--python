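"""Sequence I/O: FASTQ reads, FASTA, and the taxonomy-annotated reference dialect.

Reference barcodes travel in a plain FASTA whose headers carry the lineage as
five pipe-delimited fields::

    >accession|marker|family|genus|species

Only the ranks family/genus/species are modelled; they are the ranks the
multi-marker identification logic consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence, Tuple

from Bio.SeqIO.QualityIO import FastqGeneralIterator


class ParseError(ValueError):
    """Raised for malformed FASTQ/FASTA/reference records."""


_PHRED_OFFSET = 33

_COMPLEMENT = str.maketrans("ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
                            "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb")


def reverse_complement(sequence: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC-aware)."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: Sequence[int]

    def __post_init__(self) -> None:
        if not self.read_id:
            raise ValueError("read_id must be non-empty")
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def reverse_complement(self) -> "Read":
        return Read(self.read_id, reverse_complement(self.sequence),
                    list(self.qualities)[::-1])

    def slice(self, start: int, end: int) -> "Read":
        """Sub-read keeping sequence and qualities in register."""
        return Read(self.read_id, self.sequence[start:end],
                    list(self.qualities)[start:end])


@dataclass
class ReferenceRecord:
    """A reference barcode with its marker and three-rank lineage."""

    accession: str
    marker: str
    family: str
    genus: str
    species: str
    sequence: str

    @property
    def lineage(self) -> Tuple[str, str, str]:
        return (self.family, self.genus, self.species)


def decode_qualities(quality_string: str) -> list[int]:
    return [ord(c) - _PHRED_OFFSET for c in quality_string]


def encode_qualities(qualities: Iterable[int]) -> str:
    return "".join(chr(q + _PHRED_OFFSET) for q in qualities)


def read_fastq(path: str | os.PathLike) -> Iterator[Read]:
    """Yield reads from a Sanger Phred+33 FASTQ file, in file order."""
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                return
            except ValueError as exc:
                raise ParseError(f"malformed FASTQ record #{index}: {exc}") from exc
            if len(seq) != len(qual):
                raise ParseError(
                    f"malformed FASTQ record #{index} ({title.split()[0]!r}): "
                    f"sequence and quality lengths differ"
                )
            yield Read(title.split()[0], seq.upper(), decode_qualities(qual))
            index += 1


def write_fastq(reads: Iterable[Read], path: str | os.PathLike) -> None:
    with open(path, "w") as handle:
        for read in reads:
            handle.write(f"@{read.read_id}\n{read.sequence}\n+\n"
                         f"{encode_qualities(read.qualities)}\n")


def read_fasta(path: str | os.PathLike) -> list[Tuple[str, str]]:
    """Read a FASTA file as (id, sequence) pairs, in file order."""
    records: list[Tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].strip()
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
        if header is not None:
            records.append((header, "".join(chunks)))
    return records


def write_fasta(records: Iterable[Tuple[str, str]], path: str | os.PathLike,
                width: int = 0) -> None:
    """Write (id, sequence) pairs as FASTA. ``width`` 0 means unwrapped lines."""
    seen: set[str] = set()
    with open(path, "w") as handle:
        for rec_id, seq in records:
            if rec_id in seen:
                raise ValueError(f"duplicate FASTA id {rec_id!r}")
            seen.add(rec_id)
            handle.write(f">{rec_id}\n")
            if width and width > 0:
                for i in range(0, len(seq), width):
                    handle.write(seq[i:i + width] + "\n")
            else:
                handle.write(seq + "\n")


def read_reference_fasta(path: str | os.PathLike) -> list[ReferenceRecord]:
    """Parse a reference FASTA with ``accession|marker|family|genus|species`` headers."""
    out: list[ReferenceRecord] = []
    for header, seq in read_fasta(path):
        fields = header.split("|")
        if len(fields) != 5:
            raise ParseError(
                f"reference header {header!r} has {len(fields)} pipe-separated "
                f"fields; expected 5 (accession|marker|family|genus|species)"
            )
        accession, marker, family, genus, species = (f.strip() for f in fields)
        out.append(ReferenceRecord(accession, marker, family, genus, species,
                                   seq.upper()))
    return out


def write_reference_fasta(records: Iterable[ReferenceRecord],
                          path: str | os.PathLike) -> None:
    write_fasta(((f"{r.accession}|{r.marker}|{r.family}|{r.genus}|{r.species}",
                  r.sequence) for r in records), path)
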