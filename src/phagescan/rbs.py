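"""Anti-Shine-Dalgarno ribosome-binding-site scanning.

The *B. subtilis* 16S rRNA 3' tail (written 3'->5': UCUUUCCUCCACUAG) base-
pairs with the mRNA just upstream of the initiation codon.  Its position-
wise Watson-Crick partner read 5'->3' on the mRNA is AGAAAGGAGGUGAUC, which
contains the canonical AGGAGG Shine-Dalgarno core.  The scanner slides
this mRNA-side template ungapped over a window upstream of each start
codon, scores placements by paired-base count, and accepts the best
placement whose anchor-derived spacing falls inside the allowed range
(8-14 nt by default).

Spacing is counted as the number of nucleotides strictly between the base
paired with the template *anchor* (the position pairing the central U of
the anti-SD CCUCC core; template index 8, configurable since the original
convention is ambiguous) and the nucleotide preceding the initiation
codon, exclusive on both sides.

Match patterns are rendered in the annotation-table style: the aligned
stretch from first to last paired base, paired bases uppercase, mismatches
lowercase, in RNA spelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

from .seqcore import Genome, SequenceError, as_dna, as_rna, reverse_complement

__all__ = ["SDModel", "RbsMatch", "scan_rbs", "render_pattern", "detect_dual_starts", "calibrate_anchor"]

_RNA_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _mrna_template(antisd_3to5: str) -> str:
    """Position-wise pairing partner of the printed (3'->5') 16S tail."""
    return "".join(_RNA_COMPLEMENT[b] for b in antisd_3to5)


@dataclass(frozen=True)
class SDModel:
    """Parameters of the anti-SD matching rule."""

    antisd_as_printed: str = "UCUUUCCUCCACUAG"
    anchor_index: int = 8  # 1-based template position pairing the anti-SD central U
    spacing_range: tuple[int, int] = (8, 14)
    min_paired: int = 4
    max_mismatch: int = 2
    window: int = 25

    @property
    def mrna_template(self) -> str:
        return _mrna_template(self.antisd_as_printed)

    @property
    def core_positions(self) -> range:
        """1-based template positions of the AGGAGG core."""
        i = self.mrna_template.find("AGGAGG")
        if i < 0:  # custom template without the canonical core
            return range(0)
        return range(i + 1, i + 7)


@dataclass(frozen=True)
class RbsMatch:
    """One anti-SD complementary match upstream of a start codon."""

    pattern: str  # table style: matched bases uppercase, mismatches lowercase
    n_paired: int
    n_mismatch: int
    spacing: int
    genome_offset: int  # 1-based genome position of the first pattern base
    category: str = "canonical"  # canonical | weak
    template_offset: int = 0  # 1-based template position aligned to pattern start


def _upstream_window(genome: Genome, start_pos: int, strand: str, window: int) -> tuple[str, list[int]]:
    """Window sequence 5'->3' ending just before the start codon, plus the
    1-based genome position of each window base."""
    L = genome.length
    positions: list[int] = []
    if strand == "+":
        for off in range(window, 0, -1):
            p = start_pos - off
            if genome.circular:
                p = (p - 1) % L + 1
                positions.append(p)
            elif p >= 1:
                positions.append(p)
    else:
        for off in range(window, 0, -1):
            p = start_pos + off
            if genome.circular:
                p = (p - 1) % L + 1
                positions.append(p)
            elif p <= L:
                positions.append(p)
    if len(positions) < window:
        warnings.warn(
            f"upstream window truncated to {len(positions)} nt at the genome edge",
            stacklevel=2,
        )
    bases = "".join(
        genome.seq[p - 1] if strand == "+" else _dna_complement(genome.seq[p - 1])
        for p in positions
    )
    return bases, positions


def _dna_complement(b: str) -> str:
    return {"A": "T", "T": "A", "G": "C", "C": "G"}[b]


def _alignments(window_rna: str, model: SDModel):
    """Yield candidate (offset, block) placements of the template.

    For each ungapped placement of the template inside the window, every
    contiguous block bounded by paired bases with at most ``max_mismatch``
    internal mismatches is a candidate; the reported pattern is that block
    (paired bases uppercase, internal mismatches lowercase), matching the
    annotation-table style.
    """
    tpl = model.mrna_template
    t_len = len(tpl)
    w_len = len(window_rna)
    for offset in range(w_len - t_len + 1):
        paired = [window_rna[offset + j] == tpl[j] for j in range(t_len)]
        idx = [j for j in range(t_len) if paired[j]]
        if not idx:
            continue
        for a_i, first in enumerate(idx):
            for last in idx[a_i:]:
                n_mismatch = (last - first + 1) - sum(
                    1 for j in idx if first <= j <= last
                )
                if n_mismatch > model.max_mismatch:
                    break
                n_paired = (last - first + 1) - n_mismatch
                yield offset, paired, first, last, n_paired, n_mismatch


def render_pattern(window_rna: str, offset: int, paired: list[bool], first: int, last: int) -> str:
    """Table-style pattern: aligned stretch, mismatches in lowercase."""
    out = []
    for j in range(first, last + 1):
        base = window_rna[offset + j]
        out.append(base if paired[j] else base.lower())
    return "".join(out)


def scan_rbs(
    genome: Genome,
    start_pos: int,
    strand: str = "+",
    model: SDModel | None = None,
    window: int | None = None,
) -> RbsMatch | None:
    """Best anti-SD match upstream of the start codon at ``start_pos``.

    Returns the highest paired-base-count placement whose spacing is in
    range; ties break toward fewer mismatches, then smaller spacing.
    ``None`` when no placement satisfies the thresholds.
    """
    model = model or SDModel()
    if window is not None:
        model = replace(model, window=window)
    win_dna, positions = _upstream_window(genome, start_pos, strand, model.window)
    if len(win_dna) < len(model.mrna_template):
        return None
    win_rna = as_rna(win_dna)
    w_len = len(win_rna)
    anchor_j = model.anchor_index - 1
    best: tuple | None = None
    for offset, paired, first, last, n_paired, n_mismatch in _alignments(win_rna, model):
        if n_mismatch > model.max_mismatch:
            continue
        # spacing: bases strictly between the anchor-aligned window position
        # and the base preceding the start codon (the window's final base),
        # exclusive on both sides; geometric, whether or not the anchor pairs
        spacing = (w_len - 1) - (offset + anchor_j) - 1
        lo, hi = model.spacing_range
        if not (lo <= spacing <= hi):
            continue
        # a ribosome-binding interaction must engage the SD core: require
        # at least 3 paired bases inside AGGAGG (an A-rich window pairing
        # only the template's 5' tail is not an RBS)
        core = set(model.core_positions)
        core_paired = sum(
            1 for j in range(first, last + 1) if paired[j] and (j + 1) in core
        )
        if core_paired < 3:
            continue
        category = "canonical" if n_paired >= model.min_paired else "weak"
        key = (-n_paired, n_mismatch, spacing, offset, first)
        if best is None or key < best[0]:
            pattern = render_pattern(win_rna, offset, paired, first, last)
            best = (
                key,
                RbsMatch(
                    pattern=pattern,
                    n_paired=n_paired,
                    n_mismatch=n_mismatch,
                    spacing=spacing,
                    genome_offset=positions[offset + first],
                    category=category,
                    template_offset=first + 1,
                ),
            )
    return best[1] if best else None


def detect_dual_starts(orf, genome: Genome, k: int = 15, model: SDModel | None = None) -> list[dict]:
    """In-frame internal starts within the first ``k`` codons that carry
    their own qualifying RBS.

    Dual-start genes (long and short product from the same frame, each
    with a canonical RBS a few codons apart) are how phage holin/antiholin
    pairs are encoded; the short form lacks the first few residues.
    """
    from .orfcall import orf_sequence  # local import to avoid a cycle

    model = model or SDModel()
    L = genome.length
    seq = orf_sequence(orf, genome)
    out = []
    for codon_idx in range(1, min(k, orf.length_aa)):
        codon = seq[3 * codon_idx : 3 * codon_idx + 3]
        if codon != "ATG":
            continue
        if orf.strand == "+":
            pos = (orf.start_nt - 1 + 3 * codon_idx) % L + 1
        else:
            pos = (orf.start_nt - 1 - 3 * codon_idx) % L + 1
        match = scan_rbs(genome, pos, orf.strand, model=model)
        if match is not None:
            out.append({"offset_aa": codon_idx, "start_nt": pos, "rbs": match})
    return out


def calibrate_anchor(
    examples: list[tuple[str, str, int]],
    model: SDModel | None = None,
) -> tuple[int, dict[int, int]]:
    """Choose the anchor index that best reproduces (pattern, spacing) pairs.

    ``examples`` are (upstream window sequence 5'->3' ending at the base
    preceding the start codon, expected pattern, expected spacing).  The
    printed convention for which anti-SD U anchors the spacing count is
    ambiguous; this scores every anchor position and returns the argmax
    with the full agreement tally.
    """
    model = model or SDModel()
    t_len = len(model.mrna_template)
    scores: dict[int, int] = {}
    for anchor in range(1, t_len + 1):
        m = replace(model, anchor_index=anchor)
        n_ok = 0
        for win, pattern, spacing in examples:
            g = Genome(id="w", seq=as_dna(win).upper() + "ATG" + "A" * 45, topology="linear")
            match = scan_rbs(g, start_pos=len(win) + 1, strand="+", model=replace(m, window=min(m.window, len(win))))
            if match and match.pattern == pattern and match.spacing == spacing:
                n_ok += 1
        scores[anchor] = n_ok
    best = max(scores, key=lambda a: (scores[a], -abs(a - model.anchor_index)))
    return best, scores
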