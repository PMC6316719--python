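"""Synthetic genomes with planted, ground-truthed features.

The generator emulates the statistical structure of a small circular
phage genome — GC near 43.7%, coding-strand purine excess near 58.4%,
Shine-Dalgarno sites at 8-14 nt spacings, stem-loop + U-tract
terminators — and plants features whose exact coordinates are known, so
every scanner can be scored for recall against a truth table without any
external data.

Background bases are i.i.d. (no dinucleotide structure); that is enough
to exercise the scanners but does not reproduce real coding-sequence
periodicity.  Plants are verified against the actual scanners at build
time and their local background is resampled (deterministically, from the
seeded generator) until recovery is exact, so truth tables are guaranteed
faithful for compliant plants.

Each planted ORF cassette carries an in-frame guard stop upstream of its
RBS so that the planted start is the maximal start for its stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import tables
from .orfcall import OrfCall, scan_orfs
from .rbs import SDModel, scan_rbs
from .seqcore import (
    Genome,
    Interval,
    STOP_CODONS,
    as_dna,
    reverse_complement,
    write_fasta,
    write_gff3,
)
from .terminators import TerminatorParams, find_terminators

GENERATOR_VERSION = "phagescan-synth/1"

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_START_CODONS = ("ATG", "GTG", "TTG")


@dataclass
class PlantedOrf:
    length_aa: int = 60
    start_codon: str = "ATG"
    stop_codon: str = "TAA"
    rbs_pattern: str = "AAGGAGGU"  # RNA spelling, substring of the SD template
    spacing: int = 10
    position: int | None = None  # 1-based start-codon coordinate


@dataclass
class PlantedTerminator:
    stem: str = "CCGACG"
    loop: str = "GCAA"  # loop ends must not pair (even G:U), or the detector
    # legitimately reports a longer stem than the planted one
    u_len: int = 7
    position: int | None = None  # 1-based first stem base


@dataclass
class PlantedSlippery:
    kind: str = "minus1"  # "minus1" | "plus1"
    orf_length_aa: int = 60
    shared_prefix_aa: int = 30  # minus1 only
    ext_codons: int = 20
    position: int | None = None


@dataclass
class GenomeSpec:
    length: int = 20000
    gc: float = 0.437
    purine: float = 0.584
    topology: str = "circular"
    seed: int = 0
    orfs: list[PlantedOrf] = field(default_factory=list)
    terminators: list[PlantedTerminator] = field(default_factory=list)
    slippery: list[PlantedSlippery] = field(default_factory=list)
    min_aa: int = 45


def _base_probs(gc: float, purine: float) -> np.ndarray:
    """P(A), P(C), P(G), P(T) hitting the GC and purine targets."""
    d = (purine - 0.5) / 2.0
    p = np.array(
        [(1 - gc) / 2 + d, gc / 2 - d, gc / 2 + d, (1 - gc) / 2 - d]
    )
    if (p < 0).any():
        raise ValueError("gc/purine targets are jointly infeasible")
    return p


class _Builder:
    def __init__(self, spec: GenomeSpec):
        self.spec = spec
        self.rng = np.random.default_rng(spec.seed)
        self.seq = self._background(spec.length)
        self.reserved = np.zeros(spec.length, dtype=bool)

    def _background(self, n: int) -> np.ndarray:
        p = _base_probs(self.spec.gc, self.spec.purine)
        return self.rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)

    def resample(self, positions: list[int]) -> None:
        p = _base_probs(self.spec.gc, self.spec.purine)
        draws = self.rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=len(positions), p=p)
        for pos, b in zip(positions, draws):
            self.seq[pos % self.spec.length] = b

    def write(self, pos: int, piece: str) -> None:
        L = self.spec.length
        for i, b in enumerate(piece):
            self.seq[(pos + i) % L] = b.encode()

    def reserve(self, pos: int, n: int, margin: int = 0) -> bool:
        L = self.spec.length
        idx = [(pos - margin + i) % L for i in range(n + 2 * margin)]
        if self.reserved[idx].any():
            return False
        self.reserved[idx] = True
        return True

    def auto_place(self, n: int, margin: int) -> int:
        for _ in range(500):
            pos = int(self.rng.integers(0, self.spec.length))
            if self.reserve(pos, n, margin):
                return pos
        raise ValueError("infeasible packing: planted features exceed genome capacity")

    def genome(self) -> Genome:
        return Genome(
            id=f"synthetic seed={self.spec.seed}",
            seq=self.seq.tobytes().decode(),
            topology=self.spec.topology,
        )


def _rbs_layout(pattern_rna: str, spacing: int, model: SDModel) -> tuple[int, int]:
    """(offset of pattern start relative to the start codon, template offset).

    The pattern must align to the SD mRNA template (uppercase = paired).
    Spacing counts bases strictly between the anchor-aligned position and
    the base preceding the start codon.
    """
    tpl = model.mrna_template
    probe = "".join(c if c.isupper() else "." for c in pattern_rna)
    import re

    m = re.search(probe, tpl)
    if not m:
        raise ValueError(f"pattern {pattern_rna!r} does not align to the SD template")
    t0 = m.start()  # 0-based template index of pattern start
    anchor_j = model.anchor_index - 1
    # genome: anchor position a, start codon at st:  spacing = st - a - 2
    # pattern start = a - (anchor_j - t0)
    rel_pattern_start = -(spacing + 2) - (anchor_j - t0)
    return rel_pattern_start, t0


def _sample_codons(rng, n: int, forbid_starts: bool = False) -> list[str]:
    pool = [c for c in _SENSE_CODONS if not (forbid_starts and c in _START_CODONS)]
    idx = rng.integers(0, len(pool), size=n)
    return [pool[i] for i in idx]


def _plant_orf(b: _Builder, plant: PlantedOrf, model: SDModel) -> dict:
    """Write one ORF cassette and verify scanner recovery."""
    spec = b.spec
    L = spec.length
    n_nt = 3 * (plant.length_aa + 1)
    rel_rbs, _ = _rbs_layout(plant.rbs_pattern, plant.spacing, model)
    lead = -rel_rbs + 6  # room upstream of start for guard + rbs
    # pad so the guard stop sits in frame with the start codon
    pad = (-(lead) ) % 3
    lead += pad
    total = lead + n_nt
    if plant.position is None:
        pos0 = b.auto_place(total, margin=40) + lead  # 0-based start codon pos
        start_nt = pos0 % L + 1
    else:
        start_nt = plant.position
        pos0 = start_nt - 1
        if not b.reserve((pos0 - lead) % L, total, margin=40):
            raise ValueError(f"planted ORF at {start_nt} overlaps another feature")

    body = _sample_codons(b.rng, plant.length_aa - 1, forbid_starts=True)
    cds = plant.start_codon + "".join(body) + plant.stop_codon
    b.write(pos0, cds)
    b.write(pos0 - lead, "TAA")  # in-frame guard stop
    pattern_dna = as_dna(plant.rbs_pattern).upper()
    b.write(pos0 + rel_rbs, pattern_dna)

    # Joint fix-up loop: (a) no in-frame start codon may survive between the
    # guard stop and the planted start (it would steal ORF maximality);
    # (b) the RBS scanner must recover exactly the planted pattern/spacing.
    # Offending bases outside the protected set are resampled; a start
    # codon buried inside the protected pattern is neutralized by writing
    # an in-frame stop in the free spacer downstream of it.
    protected = {(pos0 + rel_rbs + i) % L for i in range(len(pattern_dna))}
    protected |= {(pos0 - lead + i) % L for i in range(3)}
    expected = (plant.rbs_pattern, plant.spacing)
    for attempt in range(400):
        g = b.genome()
        dirty = False
        for off in range(-lead + 3, 0, 3):
            codon = "".join(g.seq[(pos0 + off + j) % L] for j in range(3))
            if codon in _START_CODONS:
                # harmless if an in-frame stop already sits between this
                # start and the planted start (its ORF ends there)
                blocked = any(
                    "".join(g.seq[(pos0 + w + j) % L] for j in range(3))
                    in STOP_CODONS
                    for w in range(off + 3, 0, 3)
                )
                if blocked:
                    continue
                free = [
                    pos0 + off + j
                    for j in range(3)
                    if (pos0 + off + j) % L not in protected
                ]
                if free:
                    b.resample(free)
                else:
                    placed = False
                    for w in range(off + 3, 0, 3):
                        idx = [(pos0 + w + j) % L for j in range(3)]
                        if not any(i in protected for i in idx):
                            b.write(pos0 + w, "TAA")
                            protected |= set(idx)
                            placed = True
                            break
                    if not placed:
                        raise ValueError(
                            f"RBS pattern {plant.rbs_pattern!r} at spacing "
                            f"{plant.spacing} buries an unremovable in-frame start"
                        )
                dirty = True
        if dirty:
            continue
        match = scan_rbs(g, start_nt, "+", model=model)
        if match is not None and (match.pattern, match.spacing) == expected:
            break
        window_positions = [
            (pos0 - k) % L
            for k in range(1, model.window + 1)
            if (pos0 - k) % L not in protected
        ]
        if not window_positions:
            raise RuntimeError(f"could not realize RBS plant {plant}")
        b.resample(window_positions)
    else:  # pragma: no cover - generation failure is a hard error
        raise RuntimeError(f"could not realize RBS plant {plant}")
    stop_nt = (pos0 + n_nt - 1) % L + 1
    return {
        "start_nt": start_nt,
        "stop_nt": stop_nt,
        "length_aa": plant.length_aa,
        "start_codon": plant.start_codon,
        "stop_codon": plant.stop_codon,
        "rbs_pattern": plant.rbs_pattern,
        "spacing": plant.spacing,
    }


_NO_PAIR_BEFORE = "C"  # cannot pair (even wobble) with the U-tract that follows


def _plant_terminator(b: _Builder, plant: PlantedTerminator) -> dict:
    spec = b.spec
    L = spec.length
    stem = plant.stem.upper()
    loop = plant.loop.upper()
    _PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
    if len(loop) >= 5 and (loop[0], loop[-1]) in _PAIRS:
        raise ValueError(
            f"loop {loop!r} ends can base-pair; the detector would extend the "
            "stem inward and the planted boundaries would never be recovered"
        )
    cassette = _NO_PAIR_BEFORE + stem + loop + reverse_complement(stem) + "T" * plant.u_len + "G"
    n = len(cassette)
    if plant.position is None:
        pos0 = b.auto_place(n, margin=70) + 1
        start_nt = pos0 % L + 1
    else:
        start_nt = plant.position
        pos0 = start_nt - 1
        if not b.reserve((pos0 - 1) % L, n, margin=70):
            raise ValueError(f"planted terminator at {start_nt} overlaps another feature")
    b.write(pos0 - 1, cassette)
    footprint = 2 * len(stem) + len(loop)
    end_nt = (pos0 + footprint - 1) % L + 1
    protected = {(pos0 - 1 + i) % L for i in range(n)}
    params = TerminatorParams()
    for attempt in range(200):
        g = b.genome()
        lo = pos0 - params.window
        ctx = "".join(g.seq[(lo + i) % L] for i in range(footprint + 2 * params.window))
        found = find_terminators(ctx, params)
        hit = [
            t
            for t in found
            if t.interval.start - 1 == params.window and t.stem_len == len(stem)
            and t.loop_len == len(loop)
        ]
        if hit:
            break
        free = [
            (lo + i) % L
            for i in range(footprint + 2 * params.window)
            if (lo + i) % L not in protected
        ]
        b.resample(free)
    else:  # pragma: no cover
        raise RuntimeError(f"could not realize terminator plant {plant}")
    return {
        "start_nt": start_nt,
        "end_nt": end_nt,
        "stem": stem,
        "loop": loop,
        "u_len": plant.u_len,
    }


def _plant_slippery(b: _Builder, plant: PlantedSlippery, model: SDModel) -> dict:
    from .motifs import find_minus1_sites, find_plus1_sites

    spec = b.spec
    L = spec.length
    n_aa = plant.orf_length_aa
    if plant.kind == "minus1":
        shift0 = 3 * (plant.shared_prefix_aa - 1) + 2
        if shift0 + 3 * plant.ext_codons <= 3 * (n_aa + 1):
            raise ValueError(
                "minus1 extension must run past the ORF stop: "
                f"need ext_codons > {(3 * (n_aa + 1) - shift0) // 3}"
            )
    orf_plant = PlantedOrf(length_aa=n_aa, rbs_pattern="AAGGAGGU", spacing=10)
    ext_nt = 3 * (plant.ext_codons + 2)

    # build the carrying ORF, then edit its body to hold the motif
    rel_rbs, _ = _rbs_layout(orf_plant.rbs_pattern, orf_plant.spacing, model)
    lead = -rel_rbs + 6
    lead += (-lead) % 3
    total = lead + 3 * (n_aa + 1) + ext_nt
    pos0 = b.auto_place(total, margin=40) + lead
    orf_plant.position = pos0 + 1
    # reserve() already done by auto_place; write cassette pieces directly
    body = _sample_codons(b.rng, n_aa - 1, forbid_starts=True)
    if plant.kind == "plus1":
        body[-1] = "CCC"
        stop = "TAA"
    else:
        shared = plant.shared_prefix_aa
        body[shared - 2] = body[shared - 2][:2] + "T"  # codon ending in T
        body[shared - 1] = "TTT"
        body[shared] = "TTC"
        stop = orf_plant.stop_codon
    cds = orf_plant.start_codon + "".join(body) + stop
    b.write(pos0, cds)
    b.write(pos0 - lead, "TAA")
    b.write(pos0 + rel_rbs, as_dna(orf_plant.rbs_pattern).upper())

    start_nt = pos0 % L + 1
    stop_nt = (pos0 + 3 * (n_aa + 1) - 1) % L + 1
    orf = OrfCall(
        id="plant",
        start_nt=start_nt,
        stop_nt=stop_nt,
        strand="+",
        start_codon=orf_plant.start_codon,
        stop_codon=stop,
        length_aa=n_aa,
        interval=Interval(start_nt, stop_nt, wraps=stop_nt < start_nt),
    )
    if plant.kind == "plus1":
        slip_offset = 3 * (n_aa - 1)
        shift_from = slip_offset + 4
        shared = n_aa
    else:
        slip_offset = 3 * (plant.shared_prefix_aa - 1) + 2
        shift_from = slip_offset
        shared = plant.shared_prefix_aa
    # carve the shifted frame: ext_codons sense codons then a stop
    for attempt in range(300):
        g = b.genome()
        bad = None
        for k, (off, codon) in enumerate(
            _walk(g, pos0, shift_from)
        ):
            if k < plant.ext_codons:
                if codon in STOP_CODONS:
                    bad = (off, codon)
                    break
            elif k == plant.ext_codons:
                if codon not in STOP_CODONS:
                    b.write(pos0 + off, "TAA")
                bad = None
                break
        if bad is None:
            sites = (
                find_plus1_sites(orf, g, min_ext=10)
                if plant.kind == "plus1"
                else find_minus1_sites(orf, g, min_ext=10)
            )
            mine = [s for s in sites if s.orf_offset == slip_offset]
            if len(mine) == 1 and len(sites) == 1:
                break
            # chance extra motifs in the body: break them and re-impose the plant
            for s in sites:
                if s.orf_offset != slip_offset:
                    b.resample([pos0 + s.orf_offset + 1])
            _repair_body(b, pos0, n_aa, slip_offset, plant.kind)
        else:
            off, _ = bad
            # premature stop in the shifted frame: resample it, then re-impose
            # sense codons (and the motif) on the unshifted frame
            b.resample([pos0 + off, pos0 + off + 1, pos0 + off + 2])
            _repair_body(b, pos0, n_aa, slip_offset, plant.kind)
    else:  # pragma: no cover
        raise RuntimeError(f"could not realize slippery plant {plant}")
    return {
        "kind": plant.kind,
        "orf_start_nt": start_nt,
        "orf_stop_nt": stop_nt,
        "position": (pos0 + slip_offset) % L + 1,
        "shared_prefix_aa": shared,
        "ext_codons": plant.ext_codons,
    }


def _walk(genome: Genome, pos0: int, from_offset: int, max_codons: int = 5000):
    L = genome.length
    for k in range(max_codons):
        off = from_offset + 3 * k
        codon = "".join(genome.seq[(pos0 + off + j) % L] for j in range(3))
        yield off, codon


def _repair_body(b: _Builder, pos0: int, n_aa: int, slip_offset: int, kind: str) -> None:
    """Re-impose sense codons (and the motif) on the unshifted frame after a
    resample touched ORF bases."""
    g = b.genome()
    L = b.spec.length
    for c in range(1, n_aa):
        off = 3 * c
        codon = "".join(g.seq[(pos0 + off + j) % L] for j in range(3))
        if codon in STOP_CODONS:
            b.write(pos0 + off, _SENSE_CODONS[int(b.rng.integers(0, len(_SENSE_CODONS)))])
    if kind == "plus1":
        b.write(pos0 + 3 * (n_aa - 1), "CCCTAA")
    else:
        b.write(pos0 + slip_offset, "TTTTTTC")


def generate(spec: GenomeSpec) -> tuple[Genome, dict[str, pd.DataFrame]]:
    """Build the genome and its truth tables.  Deterministic per seed."""
    b = _Builder(spec)
    model = SDModel()
    orf_rows = [_plant_orf(b, p, model) for p in spec.orfs]
    term_rows = [_plant_terminator(b, p) for p in spec.terminators]
    slip_rows = [_plant_slippery(b, p, model) for p in spec.slippery]
    genome = b.genome()
    truth = {
        "orfs": pd.DataFrame(orf_rows, columns=["start_nt", "stop_nt", "length_aa", "start_codon", "stop_codon", "rbs_pattern", "spacing"]),
        "terminators": pd.DataFrame(term_rows, columns=["start_nt", "end_nt", "stem", "loop", "u_len"]),
        "slippery": pd.DataFrame(slip_rows, columns=["kind", "orf_start_nt", "orf_stop_nt", "position", "shared_prefix_aa", "ext_codons"]),
    }
    return genome, truth


def default_spec(seed: int, length: int = 12000, n_orfs: int = 6, n_terms: int = 3, slippery: bool = True) -> GenomeSpec:
    """Study-condition defaults: SPP1-like GC and purine bias, SD spacings
    spread over the allowed 8-14 range, clean short-stem terminators."""
    rng = np.random.default_rng(seed)
    patterns = ["AAGGAGGU", "AGGAGG", "AAGGAGG", "GGAGG", "AGGAGGUGA", "GAGG"]
    orfs = [
        PlantedOrf(
            length_aa=int(rng.integers(46, 180)),
            start_codon=["ATG", "ATG", "ATG", "GTG", "TTG"][int(rng.integers(0, 5))],
            stop_codon=["TAA", "TGA", "TAG"][int(rng.integers(0, 3))],
            rbs_pattern=patterns[int(rng.integers(0, len(patterns)))],
            spacing=int(rng.integers(8, 15)),
        )
        for _ in range(n_orfs)
    ]
    stems = ["CCGACG", "GGCGCC", "GCCGC", "CGGGC", "GGCCGC"]
    loops = ["GCAA", "CTAA", "GAAAG", "GAAAAG"]
    terms = [
        PlantedTerminator(
            stem=stems[int(rng.integers(0, len(stems)))],
            loop=loops[int(rng.integers(0, len(loops)))],
            u_len=int(rng.integers(4, 9)),
        )
        for _ in range(n_terms)
    ]
    slips = (
        [
            PlantedSlippery(kind="minus1", orf_length_aa=80, shared_prefix_aa=40, ext_codons=50),
            PlantedSlippery(kind="plus1", orf_length_aa=70, ext_codons=30),
        ]
        if slippery
        else []
    )
    return GenomeSpec(length=length, seed=seed, orfs=orfs, terminators=terms, slippery=slips)


def make_fixture_suite(outdir: str | Path, seeds: tuple[int, ...] = (101, 102, 103)) -> list[Path]:
    """Write the packaged reference tables plus seeded synthetic genomes
    (FASTA + GFF3 + TSV truth) used by the test suite.  Re-running
    produces identical files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, loader in (
        ("table2_terminators.tsv", tables.load_terminator_table),
        ("table3_orfs.tsv", tables.load_orf_table),
        ("table4_codon_usage.tsv", tables.load_codon_usage_table),
    ):
        path = outdir / name
        loader().to_csv(path, sep="\t", index=False)
        written.append(path)
    for seed in seeds:
        spec = default_spec(seed)
        genome, truth = generate(spec)
        fasta = outdir / f"synthetic_{seed}.fasta"
        gname = f"synthetic_{seed}"
        Genome(id=gname, seq=genome.seq, topology=genome.topology)
        with open(fasta, "w") as fh:
            fh.write(f">{gname} {GENERATOR_VERSION} topology={spec.topology}\n")
            for i in range(0, len(genome.seq), 70):
                fh.write(genome.seq[i : i + 70] + "\n")
        written.append(fasta)
        for key, df in truth.items():
            path = outdir / f"synthetic_{seed}.{key}.tsv"
            df.to_csv(path, sep="\t", index=False)
            written.append(path)
        feats = [
            {
                "type": "CDS",
                "interval": Interval(int(r.start_nt), int(r.stop_nt), wraps=int(r.stop_nt) < int(r.start_nt)),
                "strand": "+",
                "phase": 0,
                "attributes": {"ID": f"planted_orf_{i+1}"},
            }
            for i, r in enumerate(truth["orfs"].itertuples())
        ]
        gff = outdir / f"synthetic_{seed}.truth.gff3"
        write_gff3(genome, feats, gff, source="phagescan-synth")
        written.append(gff)
    return written
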