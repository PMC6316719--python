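# Methods

This note records the models, parameter choices and numerical
conventions behind phagescan, and what the synthetic-data tests do and
do not demonstrate.

## Coordinate model

Genomes are single DNA records over {A,C,G,T}; ambiguity codes are
rejected at ingest because every downstream scanner assumes a definite
base. Topology defaults to circular: phage genomes that are terminally
redundant and circularly permuted circularize in the host, and the
deposited coordinate systems place genes across the packaging origin.
Intervals are 1-based inclusive with the stop codon included; an
origin-crossing feature carries `wraps=True` and spans
`(L − start + 1) + end` nucleotides. The reference genome's terminase
gene (43,884 → 311 on a 44,016-bp circle) spans 444 nt = 3·(147 + 1),
which fixes both the inclusive-stop convention and the wrap arithmetic.
GFF3 output keeps 1-based inclusive coordinates and serializes a
wrapping feature as two part-lines sharing an ID, because GFF3 has no
native circular-span form.

## ORF calling

Criteria: start ∈ {AUG, GUG, UUG}, product ≥ `min_aa` = 45 amino acids.
The threshold counts the initiator (length_aa = sense codons, stop
excluded), so span = 3·(length_aa + 1). The caller emits one maximal
ORF per in-frame stop codon — the most-upstream valid start with no
intervening stop — and records internal in-frame starts as candidates;
they are bookkeeping for embedded-ORF elimination and dual-start
detection, not separate records. On circular genomes every position is
a potential codon start (when L is not a multiple of 3 the circle has a
single 3L-periodic reading cycle), so the scan walks backwards from
each stop codon occurrence, bounded by one lap; the result is invariant
under genome rotation and was checked against an independent
per-position brute-force oracle.

Embedded elimination: an ORF whose footprint is fully contained in a
longer retained ORF *and* which lacks a canonical RBS is dropped.
Non-nested RBS-less ORFs are kept and flagged `no_rbs` — in the
reference annotation two such genes are real, their starts confirmed
experimentally, with translation presumably coupled to the upstream
gene (start overlapping the upstream stop in the AUGA arrangement, or
one nucleotide after it, UAAG AUG).

Frameshift-fusion records and internal-start (dual-start) records in
the reference table are not plain ORFs and are deliberately not
expected from the ORF caller; they come from the motif and RBS modules.
The pipeline therefore does not promise to regenerate exactly the 80
published records from sequence alone — that table also embeds manual
curation.

Scanning is restricted to the forward strand by default
(`strand_mode="heavy_only"`): the purine-rich heavy strand is the
coding strand in this genome family, and records are deposited with it
forward. `both` is available for general use.

## Anti-SD model

The printed 16S 3′ tail `UCUUUCCUCCACUAG` is interpreted as written
3′→5′; its position-wise Watson–Crick partner, read 5′→3′ on the mRNA,
is `AGAAAGGAGGUGAUC`. This orientation is forced by the data: it is the
only register containing an `AGGAGG`-complementary core, and it
reproduces the published patterns (AAGGAGGU, AGGAGGUGA, GGgGGU, …).

The scanner slides the template ungapped across a 25-nt upstream
window. For each placement, every contiguous block bounded by paired
bases with ≤ `max_mismatch` = 2 internal mismatches is a candidate;
the winner maximizes paired bases, breaking ties by fewer mismatches,
then smaller spacing (then placement position, for determinism). A
reportable match must pair ≥ 3 bases inside the AGGAGG core — without
core pairing there is no SD interaction, which is what rejects A-rich
windows that happen to pair the template's AGAAA tail. Matches pairing
≥ `min_paired` = 4 bases in total are "canonical"; core-engaging
matches below that (G-rich partial sites) are "weak" and do not protect
an embedded ORF from elimination.

Spacing is counted strictly between the anchor-aligned position and the
base preceding the initiation codon, exclusive on both sides, and must
lie in 8–14 nt. The anchor is template position 8, the A pairing the
central U of the anti-SD CCUCC core. Which U was originally intended is
typographically ambiguous, so the anchor is configurable and
`calibrate_anchor` scores every choice against (pattern, spacing)
examples; the shipped default maximizes agreement on constructed
examples and admits the published 8–14 range geometrically. Some
printed sites are compatible with several spacings — the ambiguity is
surfaced, not resolved.

Dual starts: an in-frame AUG within the first `k` = 15 codons carrying
its own qualifying match is reported with its amino-acid offset. Both
published arrangements are covered: a separate internal RBS (offset 9,
a 27-nt start shift), and one RBS serving both starts at spacings 8 and
14 (offset 2).

## Terminator model

Candidates are enumerated exhaustively: stem 4–15 bp, loop 3–12 nt,
whole hairpin within a 60-nt window, G:U wobble allowed, at most one
internal stem mismatch (terminal pairs must pair), no bulges — stems in
this genome class are short and clean. A U-tract (longest U run
tolerating one interruption, ≥ 3 within the 8 nt downstream of the
stem) is required, ΔG° must be negative, and overlapping candidates
collapse to the lowest-ΔG° representative.

The loop upper bound is 12 nt: one of the thirteen reference
terminators has an 11-nt printed loop and its only valid
stem/loop decomposition under these stem rules needs loops up to 12;
with a cap of 10 that sequence is undetectable.

Energies are a nearest-neighbor sum over consecutive intact pairs, plus
a tabulated hairpin-loop initiation penalty (Jacobson–Stockmayer
extrapolation beyond 12) and +1.0 kcal/mol per internal mismatch. The
Watson–Crick stack values follow the standard Turner free-energy set;
wobble-containing stacks are approximate. Both tables ship as editable
TSV data. The scorer is a *sanity anchor* — sign and stability
ordering — not a secondary-structure folder: the published ΔG° values
come from an external tool whose exact parameter set is unknown, so
equality with printed energies is not asserted anywhere; a ViennaRNA
cross-check test confirms sign and scale agreement on clean hairpins.

## Composition and codon usage

GC% and purine% are plain base fractions; the heavy strand is
operationalized as the strand with the higher purine fraction, since
buoyant density tracks purine content. A+T-rich islands are maximal
merged runs of 50-nt windows with AT ≥ 0.75, computed on wrapped
windows so the island set is rotation-invariant on circular genomes.

Codon usage counts every codon including the terminal stop (the "End"
family), so an ORF set totals Σ(length_aa + 1); fractions are
within-synonymous-family. Divergence between two tables is flagged at
|Δfraction| > 0.1 (strict) and rarity at fraction < 0.1, matching the
published table's bold/underline conventions.

Protein masses are average residue masses plus one water, from a
packaged table. Summary statistics over an annotation table use a
per-base bitmap for the circular-aware coverage union, and mean ± SD
with the *sample* SD (n−1): that convention reproduces the published
179 ± 197 aa / 20.3 ± 21.9 kDa exactly, where the population SD does
not. Coverage is rounded to the nearest integer percent for reporting.

## Frameshift motifs

+1: the final sense codon must be CCC immediately followed by UAA
(ribosomes pause at the rare proline codon and re-pair on the
overlapping CCU), and the +1 frame must stay open ≥ `min_ext` = 10
codons to a downstream stop. The shifted product keeps the complete
unshifted protein (the re-read proline is still proline) plus the
extension. −1: a slippery heptamer whose first base is the last base of
a codon (X XXY YYZ), from a configurable list defaulting to the
documented UUUUUUC plus the generic X,Y ∈ {A,U} grammar; after the
slip, reading resumes one base back and must stay open ≥ 10 codons.
`min_ext` = 10 filters chance motifs — the documented extensions are
87 and 185 amino acids, an order of magnitude larger. Shared-prefix
lengths follow from the slip position: (r + 1)/3 for a heptamer
starting at ORF offset r.

## Synthetic data

The generator emulates the study conditions: GC 0.437, forward-strand
purine fraction 0.584 (base probabilities split the GC and AT masses
asymmetrically to hit both targets), SD spacings drawn from 8–14,
planted ORFs of 46–180 aa with template-exact RBS patterns, short
GC-rich stems with 4–6-nt loops and 4–8-nt U-tracts, and one −1 and one
+1 slippery plant per genome (default genome 12 kb, 6 ORFs, 3
terminators).

Plants are written as cassettes and then *verified against the real
scanners*, with deterministic local resampling of background until
recovery is exact: an in-frame guard stop upstream of each RBS makes
the planted start maximal; buried in-frame starts inside an RBS pattern
are neutralized by an in-frame stop in the spacer; terminator cassettes
use a non-pairing base before the stem and loops whose ends cannot pair
(otherwise the detector would — correctly — report a longer stem, so
such loops are rejected with an error); slippery cassettes carve the
shifted frame open to a planted stop. Generation is deterministic per
seed and byte-identical across runs.

Limitations: the background is i.i.d. — no dinucleotide structure, no
codon bias in the background, no gene architecture. Passing recovery
tests therefore demonstrates scanner correctness and calibration of the
planted geometry, not performance on real genomes, where chance ORFs,
overlapping signals and curated judgment calls (the reference table's
80 records embed manual inspection) dominate the residual differences.

## Problem sizes in the shipped checks

The packaged validation uses the 80-row/13-row/64-row reference tables
as-is, brute-force oracle comparisons on 2-kb random sequences, and
recovery sweeps over six to eight 12-kb synthetic genomes plus one
44,016-bp background-only genome for the GC/purine calibration check
(3-binomial-SD bands). These sizes keep the whole suite in the
tens-of-seconds range while exercising every code path, including
origin-wrapping features.
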