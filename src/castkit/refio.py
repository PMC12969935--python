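"""Sequence I/O and exact k-mer indexing shared by the design and mapping stages.

Coordinates are 0-based half-open everywhere inside the library; every writer
converts to 1-based inclusive coordinates (and says so in its header).

Sequences are uppercase DNA over {A, C, G, T, N}. ``N`` is reserved for
ambiguity in references and for masked spacer positions; any other IUPAC
ambiguity code is rejected at load time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "ALPHABET",
    "FastaFormatError",
    "FastqFormatError",
    "Reference",
    "ReadRecord",
    "KmerIndex",
    "revcomp",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "build_kmer_index",
    "write_tsv",
]

ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: byte-level code table: A=0 C=1 G=2 T=3 N=4 (anything else maps to 255)
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_LUT[_b] = _i
_CODE_LUT[ord("N")] = 4

_BASE_LUT = np.frombuffer(b"ACGTN", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return _BASE_LUT[codes].tobytes().decode("ascii")


class FastaFormatError(ValueError):
    """Malformed FASTA input."""


class FastqFormatError(ValueError):
    """Malformed FASTQ input."""


@dataclass(frozen=True)
class Reference:
    """An ordered collection of named contigs (a genome, MAG, or vector).

    Parameters
    ----------
    contigs
        Ordered ``(contig_id, sequence)`` pairs. Sequences are uppercased on
        construction and must be over ``{A, C, G, T, N}``; contig ids must be
        unique and non-empty.
    """

    contigs: tuple[tuple[str, str], ...]

    def __init__(self, contigs: Iterable[tuple[str, str]]):
        normalized = []
        seen: set[str] = set()
        for cid, seq in contigs:
            if not cid:
                raise FastaFormatError("empty contig id")
            if cid in seen:
                raise FastaFormatError(f"duplicate contig id {cid!r}")
            seen.add(cid)
            seq = seq.upper()
            bad = set(seq) - ALPHABET
            if bad:
                raise FastaFormatError(
                    f"contig {cid!r} contains invalid characters {sorted(bad)!r} "
                    "(only A/C/G/T/N are accepted)"
                )
            normalized.append((cid, seq))
        object.__setattr__(self, "contigs", tuple(normalized))

    @property
    def contig_ids(self) -> tuple[str, ...]:
        return tuple(cid for cid, _ in self.contigs)

    @property
    def total_length(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)

    def sequence(self, contig_id: str) -> str:
        for cid, seq in self.contigs:
            if cid == contig_id:
                return seq
        raise KeyError(contig_id)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.contigs)

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class ReadRecord:
    """A single sequencing read with Phred quality scores.

    ``qualities`` is held as a uint8 numpy array (one score per base); list
    input is converted. Scores are Phred (Q = -10 log10 p_error), >= 0.
    """

    read_id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.qualities, dtype=np.uint8)
        if len(q) != len(self.sequence):
            raise FastqFormatError(
                f"read {self.read_id!r}: quality length {len(q)} != "
                f"sequence length {len(self.sequence)}"
            )
        self.qualities = q

    def __len__(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> Reference:
    """Read a (multi-record) FASTA file into a :class:`Reference`.

    Record order is preserved; lowercase sequence is uppercased. Raises
    :class:`FastaFormatError` for an empty file, a file that does not start
    with a ``>`` header (naming the offending line), or duplicate contig ids.
    """
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaFormatError(
                    f"{path}: line {lineno}: expected '>' FASTA header, "
                    f"got {line.strip()[:40]!r}"
                )
            break
        else:
            raise FastaFormatError(f"{path}: empty FASTA file")
    contigs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(path, "fasta")]
    if not contigs:
        raise FastaFormatError(f"{path}: no FASTA records")
    return Reference(contigs)


def write_fasta(ref: Reference, path: str | Path, width: int = 70) -> None:
    """Write a :class:`Reference` as FASTA with fixed line wrapping."""
    with open(path, "w") as out:
        for cid, seq in ref:
            out.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    """Stream Phred+33 FASTQ records as :class:`ReadRecord`.

    Raises :class:`FastqFormatError` on truncated records or a quality line
    whose length differs from the sequence, naming the read where possible.
    """
    path = Path(path)
    try:
        with open(path) as handle:
            for rec in SeqIO.parse(handle, "fastq"):
                yield ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    qualities=np.asarray(
                        rec.letter_annotations["phred_quality"], dtype=np.uint8
                    ),
                )
    except ValueError as exc:  # Biopython's parse error for bad FASTQ
        raise FastqFormatError(f"{path}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Write reads as Phred+33 FASTQ."""
    with open(path, "w") as out:
        for read in reads:
            qual = (read.qualities + 33).astype(np.uint8).tobytes().decode("ascii")
            out.write(f"@{read.read_id}\n{read.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Exact k-mer index
# ---------------------------------------------------------------------------

FWD = "fwd"
REV = "rev"


@dataclass
class KmerIndex:
    """Exact both-strand k-mer index over a :class:`Reference`.

    ``entries[kmer]`` lists every occurrence as ``(contig_id, start, strand)``
    where ``start`` is the 0-based fwd-strand offset of the matching interval
    ``[start, start + k)``. A ``rev`` entry means the k-mer (read 5'->3')
    equals the reverse complement of that fwd-strand interval. K-mers
    containing N are not indexed.
    """

    k: int
    entries: dict[str, list[tuple[str, int, str]]]

    def lookup(self, kmer: str) -> list[tuple[str, int, str]]:
        """All both-strand occurrences of ``kmer`` (empty list if none)."""
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != index k={self.k}")
        return self.entries.get(kmer, [])

    def occurrence_count(self, kmer: str) -> int:
        """Number of distinct genomic loci matching ``kmer`` on either strand.

        A palindromic k-mer matches one locus on both strands; that counts
        once (per occurrence, not per strand).
        """
        return len({(cid, start) for cid, start, _ in self.lookup(kmer)})


def build_kmer_index(ref: Reference, k: int) -> KmerIndex:
    """Index every k-mer occurrence of ``ref`` on both strands.

    Contigs shorter than ``k`` contribute nothing; k-mers containing N are
    skipped. Lookups agree exactly with a naive scan of both strands.
    """
    if k <= 0:
        raise ValueError(f"k must be >= 1, got {k}")
    entries: dict[str, list[tuple[str, int, str]]] = {}
    for cid, seq in ref:
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            entries.setdefault(kmer, []).append((cid, i, FWD))
            entries.setdefault(revcomp(kmer), []).append((cid, i, REV))
    return KmerIndex(k=k, entries=entries)


# ---------------------------------------------------------------------------
# TSV output
# ---------------------------------------------------------------------------

def write_tsv(df, path: str | Path, metadata: dict | None = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed metadata lines.

    Metadata always records that genomic coordinates in the table are
    1-based inclusive.
    """
    meta = {"coordinates": "1-based inclusive"}
    if metadata:
        meta.update(metadata)
    with open(path, "w") as out:
        for key, value in meta.items():
            out.write(f"#{key}={value}\n")
        df.to_csv(out, sep="\t", index=False)
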