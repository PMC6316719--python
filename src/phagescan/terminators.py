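"""Rho-independent transcription terminator detection.

A Rho-independent terminator is an mRNA stem-loop immediately followed by
a U-rich tract; the hairpin pulls the nascent transcript out of the RNA
polymerase while the weak rU:dA hybrid lets it dissociate.  The detector
enumerates every (stem, loop) decomposition inside a sliding window on
the coding strand, requires a downstream U tract, scores each hairpin
with a nearest-neighbor stacking model, and keeps candidates with
negative free energy, collapsing overlapping ones to the most stable.

Stems may contain G:U wobble pairs; at most one *internal* mismatch is
allowed (terminal stem pairs must pair) and bulges are not modeled —
terminator stems in small phage genomes are short and clean.  The energy
parameters ship as editable data files; the scorer is a sanity anchor
(sign and ordering of stabilities), not a full secondary-structure folder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import tables
from .seqcore import Genome, Interval, SequenceError, as_rna

__all__ = ["Terminator", "TerminatorParams", "find_terminators", "hairpin_energy", "u_tract_score"]

_RNA_PAIRS = {
    ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"),
}

MISMATCH_PENALTY = 1.0  # kcal/mol per internal mismatch (stack-breaking bubble)
_LOOP_EXTRAPOLATION = 1.08  # Jacobson-Stockmayer coefficient, kcal/mol


@dataclass(frozen=True)
class TerminatorParams:
    window: int = 60
    min_stem: int = 4
    max_stem: int = 15
    loop_range: tuple[int, int] = (3, 12)
    max_stem_mismatch: int = 1
    min_u: int = 3
    u_window: int = 8


@dataclass
class Terminator:
    interval: Interval  # stem-loop footprint (first stem base .. last stem base)
    stem_len: int
    loop_len: int
    mismatches_in_stem: int
    u_tract_len: int
    dG: float
    stem5: str = ""
    loop: str = ""
    stem3: str = ""


def _pairs(left: str, right: str) -> list[tuple[str, str] | None]:
    """Base pairs of a stem, outermost first; None marks a mismatch."""
    s = len(left)
    out: list[tuple[str, str] | None] = []
    for j in range(s):
        a, b = left[j], right[s - 1 - j]
        out.append((a, b) if (a, b) in _RNA_PAIRS else None)
    return out


def hairpin_energy(
    stem_pairs: list[tuple[str, str] | None],
    loop_len: int,
    stacks: dict | None = None,
    loops: dict | None = None,
) -> float:
    """Free energy (kcal/mol) of a hairpin: nearest-neighbor stack sum over
    consecutive paired positions, plus a loop-length initiation penalty and
    a fixed penalty per internal mismatch.

    Loops shorter than 3 nt are sterically impossible and raise.
    """
    if loop_len < 3:
        raise SequenceError(f"loop of {loop_len} nt is sterically impossible")
    if len(stem_pairs) < 2:
        raise SequenceError("stem must hold at least 2 base pairs")
    stacks = stacks if stacks is not None else tables.load_stack_energies()
    loops = loops if loops is not None else tables.load_loop_penalties()
    dg = 0.0
    for p1, p2 in zip(stem_pairs, stem_pairs[1:]):
        if p1 is not None and p2 is not None:
            key = (f"{p1[0]}:{p1[1]}", f"{p2[0]}:{p2[1]}")
            dg += stacks.get(key, -0.5)
    dg += MISMATCH_PENALTY * stem_pairs.count(None)
    if loop_len in loops:
        dg += loops[loop_len]
    else:
        ref = max(loops)
        dg += loops[ref] + _LOOP_EXTRAPOLATION * math.log(loop_len / ref)
    return dg


def u_tract_score(seq: str, window: int = 8) -> int:
    """Longest run of U (T) allowing a single interruption, within ``window``
    nt downstream of the stem."""
    s = as_rna(seq[:window].upper())
    best = 0
    runs: list[tuple[int, int]] = []  # (start, length) of U runs
    i = 0
    while i < len(s):
        if s[i] == "U":
            j = i
            while j < len(s) and s[j] == "U":
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    for idx, (start, ln) in enumerate(runs):
        best = max(best, ln)
        if idx + 1 < len(runs):
            nxt_start, nxt_len = runs[idx + 1]
            if nxt_start == start + ln + 1:  # single interruption
                best = max(best, ln + nxt_len)
    return best


def _enumerate_hairpins(seq: str, origin: int, params: TerminatorParams, stacks, loops):
    """Yield raw Terminator candidates anchored inside ``seq``; ``origin`` is
    the 0-based genome offset of seq[0]."""
    n = len(seq)
    lo_loop, hi_loop = params.loop_range
    # precompute U-tract score at every position
    u_at = [u_tract_score(seq[i:], params.u_window) for i in range(n)] + [0]
    for i in range(n):
        for stem in range(params.min_stem, params.max_stem + 1):
            for loop in range(lo_loop, hi_loop + 1):
                end = i + 2 * stem + loop
                if end > n or end - i > params.window:
                    break
                if u_at[end] < params.min_u:
                    continue
                left = seq[i : i + stem]
                loop_seq = seq[i + stem : i + stem + loop]
                right = seq[i + stem + loop : end]
                pairs = _pairs(as_rna(left), as_rna(right))
                if pairs[0] is None or pairs[-1] is None:
                    continue
                mism = pairs.count(None)
                if mism > params.max_stem_mismatch:
                    continue
                dg = hairpin_energy(pairs, loop, stacks, loops)
                if dg >= 0:
                    continue
                yield Terminator(
                    interval=Interval(origin + i + 1, origin + end),  # adjusted by caller for wrap
                    stem_len=stem,
                    loop_len=loop,
                    mismatches_in_stem=mism,
                    u_tract_len=u_at[end],
                    dG=dg,
                    stem5=left,
                    loop=loop_seq,
                    stem3=right,
                )


def find_terminators(
    genome_or_seq, params: TerminatorParams | None = None
) -> list[Terminator]:
    """Scan the coding strand for stem-loop + U-tract terminator candidates.

    Accepts a :class:`Genome` or a plain sequence string (treated as
    linear).  Overlapping candidates are collapsed to the lowest-energy
    representative; output is sorted by coordinate.
    """
    params = params or TerminatorParams()
    stacks = tables.load_stack_energies()
    loops = tables.load_loop_penalties()
    if isinstance(genome_or_seq, Genome):
        genome = genome_or_seq
        seq = genome.seq
        circular = genome.circular
    else:
        seq = str(genome_or_seq).upper()
        circular = False
    L = len(seq)
    scan_seq = seq + seq[: params.window + params.u_window] if circular else seq
    raw: list[Terminator] = []
    seen: set[tuple[int, int, int]] = set()
    for t in _enumerate_hairpins(scan_seq, 0, params, stacks, loops):
        start0 = (t.interval.start - 1) % L
        if t.interval.start - 1 >= L:  # duplicate of a non-wrapping hit
            continue
        end0 = (t.interval.end - 1) % L
        key = (start0, t.stem_len, t.loop_len)
        if key in seen:
            continue
        seen.add(key)
        wraps = t.interval.end > L
        t.interval = Interval(start0 + 1, end0 + 1, wraps=wraps)
        raw.append(t)
    return _collapse(raw, L)


def _collapse(candidates: list[Terminator], length: int) -> list[Terminator]:
    """Group overlapping candidates; keep the lowest-dG member of each group."""
    if not candidates:
        return []

    def extent(t: Terminator) -> tuple[int, int]:
        s = t.interval.start
        e = t.interval.end if not t.interval.wraps else t.interval.end + length
        return s, e

    candidates = sorted(candidates, key=lambda t: extent(t))
    groups: list[list[Terminator]] = []
    cur: list[Terminator] = [candidates[0]]
    cur_end = extent(candidates[0])[1]
    for t in candidates[1:]:
        s, e = extent(t)
        if s <= cur_end:
            cur.append(t)
            cur_end = max(cur_end, e)
        else:
            groups.append(cur)
            cur = [t]
            cur_end = e
    groups.append(cur)
    out = [min(g, key=lambda t: (t.dG, t.interval.start)) for g in groups]
    out.sort(key=lambda t: (t.interval.start, t.interval.end))
    return out
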