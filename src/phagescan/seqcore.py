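"""Genome I/O and circular-coordinate arithmetic.

Everything downstream (ORF calling, RBS scanning, terminator detection,
composition statistics) works on a :class:`Genome` and addresses it with
1-based inclusive :class:`Interval` coordinates.  Features on a circular
genome may cross the origin; such intervals carry ``wraps=True`` and their
span is ``(L - start + 1) + end``.

DNA is stored as T.  Report-facing strings in an mRNA context (RBS
patterns, codons) are rendered with U by :func:`as_rna`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGT")
STOP_CODONS = ("TAA", "TAG", "TGA")
START_CODONS = ("ATG", "GTG", "TTG")

__all__ = [
    "Genome",
    "Interval",
    "read_fasta",
    "write_fasta",
    "subsequence",
    "span_length",
    "reverse_complement",
    "translate",
    "as_rna",
    "as_dna",
    "write_gff3",
    "STOP_CODONS",
    "START_CODONS",
]


class SequenceError(ValueError):
    """Raised for malformed sequence input (ambiguity codes, bad coordinates)."""


@dataclass(frozen=True)
class Genome:
    """A single DNA record with topology.

    Parameters
    ----------
    id : str
        Record identifier.
    seq : str
        Uppercase DNA over ``{A, C, G, T}``.  Ambiguity codes are rejected.
    topology : {"circular", "linear"}
        Phage genomes as replicated in the host are circular; the default
        everywhere in this package is circular.
    """

    id: str
    seq: str
    topology: str = "circular"

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", self.seq.upper())
        if self.topology not in ("circular", "linear"):
            raise ValueError(f"unknown topology {self.topology!r}")
        for i, base in enumerate(self.seq):
            if base not in VALID_BASES:
                raise SequenceError(
                    f"non-ACGT residue {base!r} at position {i + 1}"
                )
        if not self.seq:
            raise SequenceError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def circular(self) -> bool:
        return self.topology == "circular"


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval; ``wraps`` marks origin-crossing features."""

    start: int
    end: int
    wraps: bool = False

    def validate(self, length: int, topology: str = "circular") -> None:
        if not (1 <= self.start <= length and 1 <= self.end <= length):
            raise SequenceError(
                f"interval ({self.start}, {self.end}) outside 1..{length}"
            )
        if self.wraps and topology != "circular":
            raise SequenceError("wrapping interval on a linear genome")
        if not self.wraps and self.end < self.start:
            raise SequenceError(
                f"interval end {self.end} < start {self.start} without wraps"
            )

    def span(self, length: int) -> int:
        if self.wraps:
            return (length - self.start + 1) + self.end
        return self.end - self.start + 1


def read_fasta(path: str | Path, topology: str = "circular") -> Genome:
    """Read a single-record FASTA file into a :class:`Genome`.

    Residues are uppercased; a multi-record file or any non-ACGT residue is
    an error (the error names the offending 1-based position).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise SequenceError(
            f"expected single record in {path}, found {len(records)}"
        )
    rec = records[0]
    return Genome(id=rec.id, seq=str(rec.seq), topology=topology)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    rec = SeqRecord(Seq(genome.seq), id=genome.id, description=genome.topology)
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")
    # Re-wrap at the requested width (SeqIO uses 60 by default, which is fine;
    # width kept as a parameter for callers that care).


def subsequence(genome: Genome, interval: Interval) -> str:
    """Residues ``start..end``; wrapping intervals concatenate around the origin."""
    interval.validate(genome.length, genome.topology)
    if interval.wraps:
        return genome.seq[interval.start - 1 :] + genome.seq[: interval.end]
    return genome.seq[interval.start - 1 : interval.end]


def span_length(start: int, end: int, length: int, topology: str = "circular") -> int:
    """Nucleotide count of a 1-based inclusive span, circular-aware.

    A span given with ``end < start`` on a circular genome is taken to wrap
    the origin: ``(L - start + 1) + end``.
    """
    if not (1 <= start <= length and 1 <= end <= length):
        raise SequenceError(f"span ({start}, {end}) outside 1..{length}")
    if end >= start:
        return end - start + 1
    if topology != "circular":
        raise SequenceError("wrapping span on a linear genome")
    return (length - start + 1) + end


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(
    seq: str,
    *,
    to_stop: bool = True,
    initiator_met: bool = False,
) -> tuple[str, str | None]:
    """Translate a DNA coding sequence with the bacterial genetic code.

    Returns ``(protein, stop_codon)``.  The terminal stop codon, when
    present, is excluded from the protein and reported separately.  An
    internal stop raises with the offending codon index.  With
    ``initiator_met`` the first codon is translated as Met regardless of
    whether it is ATG, GTG or TTG (as annotated initiators are).
    """
    if len(seq) % 3:
        raise SequenceError(f"length {len(seq)} not divisible by 3")
    seq = seq.upper().replace("U", "T")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    stop: str | None = None
    if codons and codons[-1] in STOP_CODONS:
        stop = codons[-1]
        codons = codons[:-1]
    elif to_stop:
        raise SequenceError("sequence does not end in a stop codon")
    for idx, codon in enumerate(codons):
        if codon in STOP_CODONS:
            raise SequenceError(f"internal stop codon {codon} at codon index {idx}")
    protein = str(Seq("".join(codons)).translate(table=11))
    if initiator_met and protein:
        protein = "M" + protein[1:]
    return protein, stop


def as_rna(seq: str) -> str:
    """Render a DNA string in mRNA context (T -> U), preserving case."""
    return seq.replace("T", "U").replace("t", "u")


def as_dna(seq: str) -> str:
    return seq.replace("U", "T").replace("u", "t")


def _gff3_escape(value: str) -> str:
    for raw, esc in ((";", "%3B"), ("=", "%3D"), (",", "%2C")):
        value = value.replace(raw, esc)
    return value


def write_gff3(
    genome: Genome,
    features: Iterable[dict],
    path: str | Path,
    source: str = "phagescan",
) -> None:
    """Write features as GFF3 (1-based inclusive, 9 tab-separated columns).

    Each feature dict carries ``type``, ``interval`` (:class:`Interval`),
    ``strand`` ('+'/'-'), optional ``score`` and an ``attributes`` mapping.
    A wrapping feature is serialized as two part-lines sharing its ``ID``
    attribute (GFF3 has no native circular-span form).
    """
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {genome.length}"]
    for feat in features:
        iv: Interval = feat["interval"]
        ftype = feat["type"]
        strand = feat.get("strand", "+")
        score = feat.get("score")
        score_s = f"{score:.2f}" if score is not None else "."
        attrs = feat.get("attributes", {})
        attr_s = ";".join(
            f"{k}={_gff3_escape(str(v))}" for k, v in attrs.items()
        ) or "."
        segments = (
            [(iv.start, genome.length), (1, iv.end)]
            if iv.wraps
            else [(iv.start, iv.end)]
        )
        for seg_start, seg_end in segments:
            lines.append(
                "\t".join(
                    [
                        genome.id,
                        source,
                        ftype,
                        str(seg_start),
                        str(seg_end),
                        score_s,
                        strand,
                        str(feat.get("phase", ".")),
                        attr_s,
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
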