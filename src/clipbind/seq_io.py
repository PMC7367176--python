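"""Sequence and interval I/O: FASTA, BED3/6, model bundles.

All genomic coordinates are 0-based half-open (BED convention).  Sequences
are normalized to the RNA alphabet on read: uppercase, ``T`` -> ``U``.
Ambiguity codes (``N`` etc.) are retained through I/O and handled at
encoding time.
"""

from __future__ import annotations

import io
import json
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VOCABULARY = ("A", "C", "G", "U")

_RNA_COMPLEMENT = str.maketrans("ACGUNRYSWKMBDHV", "UGCANYRSWMKVHDB")

BUNDLE_FORMAT_VERSION = 1


class ParseError(ValueError):
    """Raised for malformed FASTA/BED input."""


class CoordinateError(ValueError):
    """Raised when an interval falls outside its chromosome."""


class BundleVersionError(ValueError):
    """Raised when a model bundle was written by an incompatible format."""


def normalize_residues(residues: str) -> str:
    """Uppercase and convert DNA ``T`` to RNA ``U``."""
    return residues.upper().replace("T", "U")


def reverse_complement(residues: str) -> str:
    """Reverse complement in the RNA alphabet (A<->U, C<->G)."""
    return normalize_residues(residues).translate(_RNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicInterval:
    """Strand-aware 0-based half-open interval (peak, gene, background, site)."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_width(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class NamedSequence:
    """A named RNA sequence with an optional binary class label."""

    id: str
    residues: str
    label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label!r}")

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(path: str | os.PathLike | io.TextIOBase) -> list[NamedSequence]:
    """Read a multi-record FASTA file into normalized :class:`NamedSequence`.

    DNA input is converted to RNA (T->U); record order is preserved.
    Raises :class:`ParseError` on empty records or files without any record.
    """
    handle = path if isinstance(path, io.TextIOBase) else open(path)
    try:
        records = []
        for i, rec in enumerate(SeqIO.parse(handle, "fasta"), start=1):
            residues = normalize_residues(str(rec.seq))
            if not residues:
                raise ParseError(f"record {i} ({rec.id!r}) has an empty sequence")
            records.append(NamedSequence(id=rec.id, residues=residues))
    finally:
        if handle is not path:
            handle.close()
    if not records:
        raise ParseError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: Iterable[NamedSequence], path: str | os.PathLike) -> None:
    """Write sequences in RNA alphabet, one record per sequence."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs
    ]
    with open(path, "w") as handle:
        SeqIO.write(records, handle, "fasta")


def read_bed(path: str | os.PathLike) -> list[GenomicInterval]:
    """Read BED3+ intervals; strand from column 6 when present, else ``+``.

    Raises :class:`ParseError` with the offending record index on invalid
    coordinates.
    """
    intervals: list[GenomicInterval] = []
    with open(path) as handle:
        for i, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"BED record {i}: expected >= 3 columns")
            chrom, start_s, end_s = fields[:3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"BED record {i}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            strand = fields[5] if len(fields) > 5 else "+"
            if strand not in ("+", "-"):
                # tolerate the unicode minus some tools emit
                strand = "-" if strand in ("−",) else strand
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand=strand, name=name)
                )
            except ValueError as exc:
                raise ParseError(f"BED record {i}: {exc}") from exc
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path: str | os.PathLike) -> None:
    """Write intervals as BED6 (score column fixed to 0)."""
    with open(path, "w") as handle:
        for iv in intervals:
            name = iv.name if iv.name is not None else "."
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n"
            )


def extract_sequence(
    genome: Mapping[str, str], iv: GenomicInterval
) -> NamedSequence:
    """Extract the RNA sequence of ``iv`` from a chrom -> sequence mapping.

    Minus-strand intervals return the reverse complement, so the returned
    residues always read 5'->3' on the annotated strand.
    """
    if iv.chrom not in genome:
        raise CoordinateError(f"chromosome {iv.chrom!r} not in genome")
    chrom_seq = str(genome[iv.chrom])
    if iv.end > len(chrom_seq):
        raise CoordinateError(
            f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
            f"length {len(chrom_seq)}"
        )
    segment = chrom_seq[iv.start : iv.end]
    residues = (
        reverse_complement(segment)
        if iv.strand == "-"
        else normalize_residues(segment)
    )
    name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
    return NamedSequence(id=name, residues=residues)


def read_genome_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a genome FASTA into a chrom -> raw sequence dict (not normalized)."""
    with open(path) as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def save_model(bundle, path: str | os.PathLike) -> None:
    """Serialize a model bundle to a single ``.npz`` archive.

    Parameter tensors are stored as named float64 arrays (bit-exact
    round-trip); config, vocabulary and metadata are stored as a JSON string.
    """
    arrays = bundle.params.to_arrays()
    header = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "config": bundle.config,
        "vocabulary": list(bundle.vocabulary),
        "metadata": bundle.metadata,
        "filter_sizes": [int(m) for m in bundle.params.conv.sizes],
        "hidden_size": int(bundle.params.fwd.hidden_size),
        "output_weight": float(bundle.params.output_weight),
    }
    np.savez(
        path,
        __header__=np.frombuffer(
            json.dumps(header).encode("utf-8"), dtype=np.uint8
        ),
        **arrays,
    )


def load_model(path: str | os.PathLike):
    """Load a bundle written by :func:`save_model`.

    Raises :class:`BundleVersionError` on a format-version mismatch and a
    plain load error on truncated/invalid archives.
    """
    from clipbind.network import ModelBundle, ModelParams  # avoid import cycle

    with np.load(path, allow_pickle=False) as archive:
        if "__header__" not in archive:
            raise ParseError(f"{path} is not a model bundle (missing header)")
        header = json.loads(bytes(archive["__header__"]).decode("utf-8"))
        if header.get("format_version") != BUNDLE_FORMAT_VERSION:
            raise BundleVersionError(
                f"bundle format {header.get('format_version')!r} is not "
                f"supported (reader expects {BUNDLE_FORMAT_VERSION})"
            )
        arrays = {k: archive[k] for k in archive.files if k != "__header__"}
    params = ModelParams.from_arrays(
        arrays,
        filter_sizes=header["filter_sizes"],
        hidden_size=header["hidden_size"],
        output_weight=header["output_weight"],
    )
    return ModelBundle(
        params=params,
        config=header["config"],
        vocabulary=tuple(header["vocabulary"]),
        metadata=header["metadata"],
    )
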