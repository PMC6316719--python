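# phagescan

Annotation toolkit for small (circular) phage genomes: ORF calling under
explicit criteria, anti-Shine-Dalgarno ribosome-binding-site (RBS)
scanning, Rho-independent terminator detection with nearest-neighbor
hairpin free energies, codon-usage bias, genome composition statistics,
and programmed ribosomal frameshift motif discovery.

It is written for people annotating tailed-phage genomes of the
*Bacillus subtilis* phage SPP1 scale (~44 kb, circularly permuted,
heavy-strand coding), and ships the SPP1 re-annotation's reference
tables — 80 heavy-strand ORFs, 13 terminators, and the SPP1 vs
*B. subtilis* codon-usage table — as packaged fixtures so that every
analysis stage can be validated desk-side, without downloads.

## What it computes

**ORF calling.** ORFs start at AUG/GUG/UUG and must encode ≥ 45 amino
acids (initiator counted, stop excluded). For each in-frame stop codon
the *maximal* ORF (most-upstream reachable start) is emitted; further
in-frame starts are kept as candidates. ORFs fully nested inside a
longer ORF and lacking an RBS are eliminated — they are most likely
never translated. Coordinates are 1-based inclusive, stop codon
included, and may wrap the origin of a circular genome (the reference
genome's terminase gene runs 43,884 → 311, i.e. 444 nt = 3·(147+1)).

**RBS scanning.** The 16S rRNA 3′ tail (anti-SD), printed 3′→5′ as
`UCUUUCCUCCACUAG`, pairs position-wise with the mRNA template
`AGAAAGGAGGUGAUC` (5′→3′), which carries the canonical `AGGAGG` core.
The scanner slides this template ungapped over a 25-nt window upstream
of each start codon and reports the placement maximizing paired bases,
subject to ≤ 2 internal mismatches, ≥ 3 paired bases inside the core,
and an anchor-to-start spacing of 8–14 nt. Patterns are rendered
table-style: paired bases uppercase, mismatches lowercase (`GGgGGU`).

**Terminators.** A Rho-independent terminator is a stem-loop followed
by a U-rich tract. The detector enumerates every (stem ≥ 4 bp,
loop 3–12 nt) decomposition in a 60-nt window, allows G:U wobble pairs
and one internal stem mismatch, requires a U-tract (longest U run with
one interruption ≥ 3 within 8 nt), and scores hairpins as

ΔG° = Σ nearest-neighbor stacks + loop(ℓ) + mismatch penalty,

with the stack/loop tables shipped as editable data files. Candidates
with ΔG° ≥ 0 are discarded; overlapping candidates collapse to the most
stable.

**Composition & codon usage.** GC%, per-strand purine (A+G)% (the
heavy, denser strand is the purine-rich one), merged A+T-rich islands,
per-codon counts with within-synonymous-family fractions (stops form
the "End" family), average protein mass, and annotation-table summary
statistics (coverage of the genome by the ORF union, start/stop codon
tallies, mean ± SD length and mass).

**Frameshift motifs.** +1 sites: a terminal CCC proline codon directly
followed by UAA (the `CCCUAA` arrangement) with an open +1 extension;
−1 sites: a slippery heptamer (`UUUUUUC` or the generic X XXY YYZ
pattern with X,Y ∈ {A,U}) at a codon boundary with an open −1 frame.
Both report the fused product and the shared amino-terminal length.

**Synthetic genomes.** `phagescan.synthetic` generates seeded genomes
at chosen GC/purine bias with planted ORFs+RBSs, terminators and
slippery sites, verified at build time so the truth tables are exact.

## Worked example

```
$ phagescan summarize-table src/phagescan/data/table3_orfs.tsv
ORFs: 80
genome coverage: 94.1%
start codons: {'AUG': 72, 'GUG': 5, 'UUG': 3}
stop codons: {'UAA': 40, 'UGA': 31, 'UAG': 9}
mean length: 179 aa (SD 197)
mean mass: 20.3 kDa (SD 21.9)
```

This is the published picture of the SPP1 genome: the 80 heavy-strand
ORFs cover 94% of the 44,016-bp sequence (6% non-coding), AUG initiates
72 of them (90%), UGA terminates 39% and UAA 50%, and the encoded
proteins average 179 ± 197 aa and 20.3 ± 21.9 kDa.

Annotating a genome FASTA end to end:

```
$ phagescan annotate genome.fasta --topology circular --out annotation_out
```

writes `report.json`, a Table-3-style `orfs.tsv`, `terminators.tsv` and
`features.gff3` (origin-wrapping features become two GFF3 part-lines
sharing one ID). From Python:

```python
from phagescan import annotate, generate, GenomeSpec
from phagescan.synthetic import default_spec

genome, truth = generate(default_spec(seed=101))
report = annotate(genome)
print(len(report.orfs), "ORFs,", len(report.terminators), "terminator candidates")
```

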