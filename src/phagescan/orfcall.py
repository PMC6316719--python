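"""ORF enumeration for small (circular) phage genomes.

The calling criteria follow the SPP1 re-annotation conventions: ORFs start
at ATG, GTG or TTG, encode at least 45 amino acids (initiator included,
stop excluded), and by default only the heavy (purine-rich, coding) strand
is scanned.  For every in-frame stop codon one *maximal* ORF is emitted —
the most-upstream valid start reachable without an intervening stop —
with any further in-frame starts kept as internal candidates for
embedded-ORF bookkeeping and dual-start detection.

Coordinates are 1-based inclusive and include the stop codon; ORFs on a
circular genome may wrap the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .seqcore import (
    Genome,
    Interval,
    SequenceError,
    START_CODONS,
    STOP_CODONS,
    reverse_complement,
    subsequence,
    translate,
)

__all__ = [
    "OrfCall",
    "scan_orfs",
    "filter_embedded",
    "detect_translational_coupling",
    "orf_sequence",
]


@dataclass
class OrfCall:
    """A called open reading frame.

    ``start_nt``/``stop_nt`` follow the annotation-table convention: first
    base of the start codon and last base of the stop codon *in reading
    direction* (so on the minus strand ``start_nt > stop_nt`` on the
    forward axis).  ``interval`` is the genomic footprint with
    ``start <= end`` unless it wraps the origin.
    """

    id: str
    start_nt: int
    stop_nt: int
    strand: str
    start_codon: str
    stop_codon: str
    length_aa: int
    interval: Interval
    internal_starts: list[int] = field(default_factory=list)
    embedded_in: str | None = None
    rbs: object | None = None
    flags: set = field(default_factory=set)

    def span_nt(self) -> int:
        return 3 * (self.length_aa + 1)


def _footprint(start_nt: int, stop_nt: int, strand: str, length: int) -> Interval:
    if strand == "+":
        left, right = start_nt, stop_nt
    else:
        left, right = stop_nt, start_nt
    return Interval(left, right, wraps=right < left)


def orf_sequence(orf: OrfCall, genome: Genome) -> str:
    """Coding sequence of an ORF (start through stop codon, reading strand)."""
    seq = subsequence(genome, orf.interval)
    if orf.strand == "-":
        seq = reverse_complement(seq)
    return seq


def _scan_strand(seq: str, circular: bool, min_aa: int, starts: tuple[str, ...]):
    """Yield (start0, stop0, start_codon, stop_codon, n_aa, internal0) on one
    strand, positions 0-based on that strand's sequence.

    On a circular sequence every position is a potential codon start (a
    circular genome whose length is not a multiple of 3 has a single
    reading cycle); the walk back from each stop codon is bounded by one
    full lap.
    """
    L = len(seq)
    max_codons = L // 3

    def codon_at(p: int) -> str:
        if circular:
            return seq[p % L] + seq[(p + 1) % L] + seq[(p + 2) % L]
        return seq[p : p + 3]

    limit = L if circular else L - 2
    seen = set()
    for p in range(limit):
        if codon_at(p) not in STOP_CODONS:
            continue
        # walk upstream in-frame until the previous stop (or sequence start)
        best_start = None
        internal: list[int] = []
        q = p - 3
        steps = 0
        while steps < max_codons - 1:
            if not circular and q < 0:
                break
            c = codon_at(q % L if circular else q)
            if c in STOP_CODONS:
                break
            if c in starts:
                if best_start is not None:
                    internal.append(best_start)
                best_start = q % L if circular else q
            q -= 3
            steps += 1
        if best_start is None:
            continue
        start0 = best_start
        dist = (p - start0) % L if circular else p - start0
        n_aa = dist // 3
        if n_aa < min_aa:
            # the maximal ORF is too short; a longer internal one cannot exist
            continue
        # internal candidates were collected upstream-to-downstream of
        # best_start replacements; rebuild as downstream in-frame starts
        internal = sorted(
            {s for s in internal},
            key=lambda s: ((s - start0) % L) if circular else s - start0,
        )
        key = (start0, p % L if circular else p)
        if key in seen:
            continue
        seen.add(key)
        yield start0, (p % L if circular else p), codon_at(start0), codon_at(p), n_aa, internal


def scan_orfs(
    genome: Genome,
    min_aa: int = 45,
    starts: tuple[str, ...] = START_CODONS,
    strand_mode: str = "heavy_only",
) -> list[OrfCall]:
    """Enumerate maximal ORFs meeting the calling criteria.

    ``strand_mode='heavy_only'`` scans the forward strand (the genome is
    expected oriented with its coding/heavy strand forward, as phage
    records are deposited); ``'both'`` also scans the reverse complement.
    Output is sorted by start coordinate.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    if strand_mode not in ("heavy_only", "both"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    starts = tuple(s.upper().replace("U", "T") for s in starts)
    L = genome.length
    calls: list[OrfCall] = []
    for strand in ("+", "-") if strand_mode == "both" else ("+",):
        seq = genome.seq if strand == "+" else reverse_complement(genome.seq)
        for s0, p0, sc, pc, n_aa, internal in _scan_strand(
            seq, genome.circular, min_aa, starts
        ):
            if strand == "+":
                start_nt = s0 + 1
                stop_nt = (p0 + 2) % L + 1 if genome.circular else p0 + 3
                internal_nt = [(i % L) + 1 for i in internal]
            else:
                start_nt = L - s0
                stop_nt = L - ((p0 + 2) % L) if genome.circular else L - (p0 + 2)
                internal_nt = [L - (i % L) for i in internal]
            iv = _footprint(start_nt, stop_nt, strand, L)
            calls.append(
                OrfCall(
                    id="",
                    start_nt=start_nt,
                    stop_nt=stop_nt,
                    strand=strand,
                    start_codon=sc,
                    stop_codon=pc,
                    length_aa=n_aa,
                    interval=iv,
                    internal_starts=internal_nt,
                )
            )
    calls.sort(key=lambda o: (o.interval.start, o.interval.end, o.strand))
    for i, orf in enumerate(calls, start=1):
        orf.id = f"orf_{i:04d}"
    return calls


def _contains(outer: OrfCall, inner: OrfCall, L: int) -> bool:
    """True when inner's footprint is fully inside outer's (circular-aware)."""
    o, i = outer.interval, inner.interval
    o_start0 = o.start - 1
    i_start0 = i.start - 1
    o_span = o.span(L)
    i_span = i.span(L)
    offset = (i_start0 - o_start0) % L
    return offset + i_span <= o_span


def filter_embedded(orfs: list[OrfCall], rbs_results: dict, genome: Genome) -> list[OrfCall]:
    """Apply the embedded-ORF elimination rule.

    An ORF whose footprint is fully contained in a longer retained ORF and
    which lacks an RBS is dropped (it is most likely never translated).
    Non-nested ORFs without an RBS are kept but flagged ``no_rbs`` — the
    SPP1 annotation keeps two such genes whose starts are confirmed
    experimentally.
    """
    L = genome.length
    by_len = sorted(orfs, key=lambda o: -o.length_aa)
    retained: list[OrfCall] = []
    removed: list[OrfCall] = []
    for orf in by_len:
        has_rbs = rbs_results.get(orf.id) is not None
        parent = next(
            (
                p
                for p in retained
                if p.strand == orf.strand
                and p.length_aa > orf.length_aa
                and _contains(p, orf, L)
            ),
            None,
        )
        if parent is not None and not has_rbs:
            orf.embedded_in = parent.id
            removed.append(orf)
            continue
        if not has_rbs:
            orf.flags.add("no_rbs")
        retained.append(orf)
    retained.sort(key=lambda o: (o.interval.start, o.interval.end))
    return retained


def detect_translational_coupling(
    orfs: list[OrfCall], genome: Genome, max_gap: int = 1
) -> list[tuple[str, str, str]]:
    """Report adjacent same-strand pairs arranged for translational coupling.

    Two arrangements are recognized: the downstream start codon overlapping
    the upstream stop codon by one base shift (the ATGA motif, reported as
    ``overlap -1``) and a start within ``max_gap`` nucleotides of the stop
    (``gap k``, e.g. the TAAGATG arrangement is ``gap 1``).
    """
    L = genome.length
    out = []
    plus = sorted((o for o in orfs if o.strand == "+"), key=lambda o: o.start_nt)
    for up in plus:
        stop_first = (up.stop_nt - 3) % L + 1  # first base of the stop codon
        for down in plus:
            if down is up:
                continue
            delta_overlap = (down.start_nt - stop_first) % L
            if delta_overlap == L - 1:  # start one base before the stop codon
                out.append((up.id, down.id, "overlap -1"))
                continue
            gap = (down.start_nt - up.stop_nt - 1) % L
            if gap <= max_gap and down.start_nt != up.start_nt:
                out.append((up.id, down.id, f"gap {gap}"))
    return out
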