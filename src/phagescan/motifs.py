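"""Programmed ribosomal frameshift (slippery-site) detection.

Two recoding signals are recognized inside called ORFs:

* **+1 frameshift at a terminal CCC proline codon.**  Ribosomes pause at
  the rare CCC codon when it directly precedes a UAA stop (the CCCUAA
  arrangement) and slip forward onto the overlapping frequent CCU codon,
  reading through into the +1 frame.  The shifted product keeps the full
  unshifted protein sequence and gains a carboxyl-terminal extension.

* **-1 frameshift at a slippery heptamer.**  At a X XXY YYZ heptamer
  (the documented phage instance is UUUUUUC) the P- and A-site tRNAs can
  re-pair one nucleotide back, moving translation into the -1 frame.
  The two products share the amino-terminal region up to the slip codon.

Both detectors require the shifted frame to stay open for a minimum
extension (default 10 codons) before reaching a stop, filtering chance
motifs; the documented phage extensions are an order of magnitude longer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .orfcall import OrfCall, orf_sequence
from .seqcore import Genome, STOP_CODONS, translate

__all__ = [
    "SlipperySite",
    "find_plus1_sites",
    "find_minus1_sites",
    "predict_fusion_products",
    "GENERIC_SLIPPERY",
]

# classic X XXY YYZ slippery grammar with X, Y in {A, U}
GENERIC_SLIPPERY = re.compile(r"([AT])\1\1([AT])\2\2[ACGT]")


@dataclass(frozen=True)
class SlipperySite:
    kind: str  # "plus1" | "minus1"
    position: int  # 1-based genome coordinate of the motif start
    motif: str
    orf_id: str
    orf_offset: int  # 0-based nt offset of the motif within the ORF
    ext_codons: int  # codons gained in the shifted frame after the shared prefix
    shared_prefix_aa: int


def _genome_pos(orf: OrfCall, genome: Genome, offset: int) -> int:
    L = genome.length
    if orf.strand == "+":
        return (orf.start_nt - 1 + offset) % L + 1
    return (orf.start_nt - 1 - offset) % L + 1


def _frame_walk(genome: Genome, orf: OrfCall, from_offset: int, max_codons: int = 4000):
    """Codons read from ORF-relative nt offset ``from_offset`` in reading
    direction, continuing past the ORF end into the genome."""
    L = genome.length
    seq = genome.seq
    for k in range(max_codons):
        off = from_offset + 3 * k
        codon = ""
        for j in range(3):
            if orf.strand == "+":
                p = (orf.start_nt - 1 + off + j) % L
                if not genome.circular and orf.start_nt - 1 + off + j >= L:
                    return
                codon += seq[p]
            else:
                p0 = orf.start_nt - 1 - off - j
                if not genome.circular and p0 < 0:
                    return
                codon += {"A": "T", "T": "A", "G": "C", "C": "G"}[seq[p0 % L]]
        yield off, codon


def _open_extension(genome: Genome, orf: OrfCall, from_offset: int, min_ext: int) -> int | None:
    """Number of sense codons from ``from_offset`` to the next stop in that
    frame, or None if below ``min_ext`` or no stop is reachable."""
    n = 0
    for _, codon in _frame_walk(genome, orf, from_offset):
        if codon in STOP_CODONS:
            return n if n >= min_ext else None
        n += 1
    return None


def find_plus1_sites(orf: OrfCall, genome: Genome, min_ext: int = 10) -> list[SlipperySite]:
    """+1 sites: final sense codon CCC immediately followed by a TAA stop,
    with an open +1 frame of at least ``min_ext`` codons to a downstream stop."""
    seq = orf_sequence(orf, genome)
    if seq[-6:-3] != "CCC" or seq[-3:] != "TAA":
        return []
    last_sense = len(seq) - 6
    # after re-reading the proline as CCU in the +1 frame, extension codons
    # start one base into the original stop codon
    ext = _open_extension(genome, orf, last_sense + 4, min_ext)
    if ext is None:
        return []
    return [
        SlipperySite(
            kind="plus1",
            position=_genome_pos(orf, genome, last_sense),
            motif="CCCTAA",
            orf_id=orf.id,
            orf_offset=last_sense,
            ext_codons=ext,
            shared_prefix_aa=orf.length_aa,
        )
    ]


def find_minus1_sites(
    orf: OrfCall,
    genome: Genome,
    heptamers: tuple[str, ...] = ("TTTTTTC",),
    generic: bool = True,
    min_ext: int = 10,
) -> list[SlipperySite]:
    """-1 sites: a slippery heptamer inside the ORF body, aligned so its
    first base is the last base of a codon (X XXY YYZ), with the -1 frame
    open for at least ``min_ext`` codons to a stop."""
    seq = orf_sequence(orf, genome)
    body = seq[:-3]  # exclude the stop codon
    hept = {h.upper().replace("U", "T") for h in heptamers}
    hits: list[SlipperySite] = []
    for r in range(2, len(body) - 6):
        if r % 3 != 2:
            continue
        window = body[r : r + 7]
        if window not in hept and not (generic and GENERIC_SLIPPERY.fullmatch(window)):
            continue
        shared = (r + 1) // 3
        # post-slip reading resumes one base back: -1 frame from offset r
        total = _open_extension(genome, orf, r, min_ext)
        if total is None:
            continue
        hits.append(
            SlipperySite(
                kind="minus1",
                position=_genome_pos(orf, genome, r),
                motif=window,
                orf_id=orf.id,
                orf_offset=r,
                ext_codons=total,
                shared_prefix_aa=shared,
            )
        )
    return hits


def predict_fusion_products(
    orf: OrfCall, sites: list[SlipperySite], genome: Genome
) -> list[dict]:
    """Unshifted and shifted protein for each slippery site, with the length
    of their identical amino-terminal region."""
    seq = orf_sequence(orf, genome)
    protein_a, _ = translate(seq, initiator_met=True)
    out = []
    for site in sites:
        if site.kind == "plus1":
            shift_from = site.orf_offset + 4
            prefix = protein_a  # CCC re-read as CCU is still proline
        else:
            shift_from = site.orf_offset
            prefix = protein_a[: site.shared_prefix_aa]
        tail = []
        for _, codon in _frame_walk(genome, orf, shift_from):
            if codon in STOP_CODONS:
                break
            tail.append(codon)
        tail_protein, _ = translate("".join(tail) + "TAA") if tail else ("", None)
        out.append(
            {
                "site": site,
                "protein_a": protein_a,
                "protein_b": prefix + tail_protein,
                "shared_prefix_aa": site.shared_prefix_aa,
            }
        )
    return out
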