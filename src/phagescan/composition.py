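"""Composition statistics: GC and purine content, AT-rich islands, codon
usage bias, protein mass, and ORF-table summary statistics.

The heavy strand of a phage genome is operationalized here as the strand
with the higher purine (A+G) fraction — heaviness in isopycnic
centrifugation tracks purine content.  Codon usage is expressed as
within-synonymous-family fractions, with the stop codons forming their own
("End") family.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables
from .seqcore import (
    Genome,
    Interval,
    SequenceError,
    STOP_CODONS,
    as_rna,
    reverse_complement,
    span_length,
    subsequence,
)

WATER_MASS = 18.01524

# Synonymous families over the standard bacterial code, keyed by the family
# label used in reports; stop codons form the "End" family.
_CODON_FAMILY: dict[str, str] = {}


def _build_families() -> None:
    from Bio.Seq import Seq

    aa3 = {
        "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
        "E": "Glu", "Q": "Gln", "G": "Gly", "H": "His", "I": "Ile",
        "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
        "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
    }
    bases = "TCAG"
    for c1 in bases:
        for c2 in bases:
            for c3 in bases:
                codon = c1 + c2 + c3
                if codon in STOP_CODONS:
                    _CODON_FAMILY[codon] = "End"
                else:
                    _CODON_FAMILY[codon] = aa3[str(Seq(codon).translate(table=11))]


_build_families()


@dataclass
class CodonUsageTable:
    """Per-codon counts and within-family fractions (RNA codon keys)."""

    counts: dict[str, int]

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def family(self, codon_rna: str) -> str:
        return _CODON_FAMILY[codon_rna.replace("U", "T")]

    def family_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for codon, n in self.counts.items():
            out[self.family(codon)] = out.get(self.family(codon), 0) + n
        return out

    def fractions(self) -> dict[str, float]:
        fam_totals = self.family_counts()
        return {
            codon: (n / fam_totals[self.family(codon)] if fam_totals[self.family(codon)] else 0.0)
            for codon, n in self.counts.items()
        }

    def to_frame(self) -> pd.DataFrame:
        frac = self.fractions()
        rows = [
            {
                "family": self.family(c),
                "codon": c,
                "count": n,
                "fraction": frac[c],
            }
            for c, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


@dataclass
class CompositionReport:
    gc_pct: float
    purine_pct_fwd: float
    purine_pct_rev: float
    heavy_strand: str  # '+' or '-'
    at_islands: list[dict] = field(default_factory=list)


def gc_content(seq_or_genome) -> float:
    """GC percentage, 100*(G+C)/length."""
    seq = seq_or_genome.seq if isinstance(seq_or_genome, Genome) else seq_or_genome
    if not seq:
        raise SequenceError("empty sequence")
    return 100.0 * (seq.count("G") + seq.count("C")) / len(seq)


def purine_content(seq: str) -> float:
    """Purine (A+G) percentage of a strand."""
    if not seq:
        raise SequenceError("empty sequence")
    return 100.0 * (seq.count("A") + seq.count("G")) / len(seq)


def composition_report(genome: Genome, window: int = 50, threshold: float = 0.75) -> CompositionReport:
    fwd = purine_content(genome.seq)
    rev = purine_content(reverse_complement(genome.seq))
    return CompositionReport(
        gc_pct=gc_content(genome),
        purine_pct_fwd=fwd,
        purine_pct_rev=rev,
        heavy_strand="+" if fwd >= rev else "-",
        at_islands=at_islands(genome, window=window, threshold=threshold),
    )


def at_islands(genome: Genome, window: int = 50, threshold: float = 0.75) -> list[dict]:
    """Maximal merged runs of windows whose A+T fraction >= threshold.

    Windows are slid one nucleotide at a time; on a circular genome they
    wrap the origin, so the island set is rotation-invariant.  Each island
    is reported with its interval and overall AT fraction.
    """
    L = genome.length
    if window > L:
        return []
    is_at = np.frombuffer(genome.seq.encode(), dtype=np.uint8)
    is_at = ((is_at == ord("A")) | (is_at == ord("T"))).astype(np.int32)
    if genome.circular:
        ext = np.concatenate([is_at, is_at[: window - 1]])
        n_starts = L
    else:
        ext = is_at
        n_starts = L - window + 1
    cum = np.concatenate([[0], np.cumsum(ext)])
    counts = cum[window:] - cum[:-window]  # AT count of window starting at i
    hot = np.flatnonzero(counts[:n_starts] >= threshold * window)
    if hot.size == 0:
        return []
    # Merge windows into islands: a hot window at i covers [i, i+window-1].
    segments: list[list[int]] = []
    for i in hot:
        i = int(i)
        if segments and i <= segments[-1][1] + 1:
            segments[-1][1] = i
        else:
            segments.append([i, i])
    # circular join: last run touching origin joins first run at start 0
    if genome.circular and len(segments) > 1 and segments[0][0] == 0 and segments[-1][1] == L - 1:
        segments[0][0] = segments[-1][0] - L  # negative start marks wrap
        segments.pop()
    out = []
    for seg in segments:
        s, e = seg[0], seg[1] + window - 1  # nucleotide extent, 0-based
        if e - s + 1 >= L:
            iv = Interval(1, L)
        else:
            wraps = s < 0 or e >= L
            iv = Interval((s % L) + 1, (e % L) + 1, wraps=wraps and genome.circular)
        frac = _at_fraction(genome, iv)
        out.append({"interval": iv, "at_fraction": frac})
    return out


def _at_fraction(genome: Genome, iv: Interval) -> float:
    s = subsequence(genome, iv)
    return (s.count("A") + s.count("T")) / len(s)


def codon_usage(orf_sequences) -> CodonUsageTable:
    """Codon counts over a set of coding sequences, terminal stop included.

    Each sequence must have length divisible by 3 and end in a stop codon,
    so for an ORF set the total equals the summed (length_aa + 1).
    """
    counts: dict[str, int] = {}
    for seq in orf_sequences:
        seq = seq.upper().replace("U", "T")
        if len(seq) % 3:
            raise SequenceError(f"coding sequence length {len(seq)} not divisible by 3")
        if seq[-3:] not in STOP_CODONS:
            raise SequenceError("coding sequence does not end in a stop codon")
        for i in range(0, len(seq), 3):
            codon = as_rna(seq[i : i + 3])
            counts[codon] = counts.get(codon, 0) + 1
    return CodonUsageTable(counts=counts)


def compare_usage(
    a: CodonUsageTable | pd.DataFrame,
    b: CodonUsageTable | pd.DataFrame,
    diff: float = 0.1,
    rare: float = 0.1,
) -> pd.DataFrame:
    """Flag codons whose family fraction diverges between two usage tables.

    A codon is ``divergent`` when |fraction_a - fraction_b| > diff (strict),
    and ``rare`` per table when its fraction < rare.  Accepts
    :class:`CodonUsageTable` or a frame with codon/fraction columns.
    """

    def fracs(t) -> dict[str, float]:
        if isinstance(t, CodonUsageTable):
            return t.fractions()
        return dict(zip(t["codon"], t["fraction"]))

    fa, fb = fracs(a), fracs(b)
    rows = []
    for codon in sorted(set(fa) | set(fb)):
        va, vb = fa.get(codon, 0.0), fb.get(codon, 0.0)
        rows.append(
            {
                "codon": codon,
                "fraction_a": va,
                "fraction_b": vb,
                "divergent": abs(va - vb) > diff + 1e-12,
                "rare_a": va < rare,
                "rare_b": vb < rare,
            }
        )
    return pd.DataFrame(rows)


def protein_mass(aa_sequence: str) -> float:
    """Average molecular mass in Da: summed residue masses plus one water."""
    if not aa_sequence:
        raise SequenceError("empty protein sequence")
    masses = tables.load_residue_masses()
    total = WATER_MASS
    for i, aa in enumerate(aa_sequence):
        try:
            total += masses[aa]
        except KeyError:
            raise SequenceError(f"unknown residue {aa!r} at position {i + 1}") from None
    return total


def coverage_pct(intervals: list[Interval], length: int, topology: str = "circular") -> float:
    """Percent of the genome covered by the union of intervals (circular-aware)."""
    covered = np.zeros(length, dtype=bool)
    for iv in intervals:
        iv.validate(length, topology)
        if iv.wraps:
            covered[iv.start - 1 :] = True
            covered[: iv.end] = True
        else:
            covered[iv.start - 1 : iv.end] = True
    return 100.0 * covered.sum() / length


def summarize_orf_table(rows: pd.DataFrame, length: int, topology: str = "circular") -> dict:
    """Summary statistics over a Table-3-style ORF record set.

    Computes genome coverage of the interval union, start/stop codon
    tallies and fractions, and mean/SD (population) of product length and
    mass (sample SD, matching how annotation tables report spread).  ``rows`` needs columns start_nt, stop_nt, start_codon,
    stop_codon, length_aa, mm_kda (codons may be RNA or DNA spelling).
    """
    intervals = []
    for _, r in rows.iterrows():
        s, e = int(r["start_nt"]), int(r["stop_nt"])
        intervals.append(Interval(s, e, wraps=e < s))
    starts = {
        k: int(v)
        for k, v in rows["start_codon"].str.replace("T", "U").value_counts().items()
    }
    stops = {
        k: int(v)
        for k, v in rows["stop_codon"].str.replace("T", "U").value_counts().items()
    }
    n = len(rows)
    lengths = rows["length_aa"].astype(float)
    masses = rows["mm_kda"].astype(float)
    return {
        "n_orfs": n,
        "coverage_pct": coverage_pct(intervals, length, topology),
        "start_codon_tally": starts,
        "stop_codon_tally": stops,
        "stop_codon_fractions": {k: v / n for k, v in stops.items()},
        "mean_length_aa": float(lengths.mean()),
        "sd_length_aa": float(lengths.std(ddof=1)) if n > 1 else 0.0,
        "mean_mass_kda": float(masses.mean()),
        "sd_mass_kda": float(masses.std(ddof=1)) if n > 1 else 0.0,
    }
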