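"""Anti-SD scanning: pattern recovery, spacing rule, oracle equivalence."""

import pytest

from phagescan.rbs import SDModel, scan_rbs, detect_dual_starts, calibrate_anchor
from phagescan.seqcore import Genome, as_rna

from conftest import sd_window, random_genome

MODEL = SDModel()
TPL = MODEL.mrna_template


def make_gene(window: str, body_codons: int = 50) -> Genome:
    return Genome(id="g", seq=window + "ATG" + "GCT" * body_codons + "TAA",
                  topology="linear")


class TestTemplateOrientation:
    def test_template_pairs_printed_16s_tail_positionwise(self):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        assert TPL == "".join(comp[b] for b in MODEL.antisd_as_printed)
        assert "AGGAGG" in TPL  # the canonical SD core exists in this register


class TestScanRbs:
    @pytest.mark.parametrize(
        "pattern_dna,t0,spacing,expected",
        [
            ("AAGGAGGT", TPL.find("AAGGAGGU"), 10, "AAGGAGGU"),
            ("AGGAGG", TPL.find("AGGAGG"), 9, "AGGAGG"),
            ("GAGG", TPL.find("GAGG"), 12, "GAGG"),
            ("AGGAGGTGA", TPL.find("AGGAGGUGA"), 11, "AGGAGGUGA"),
            ("AAGGAGG", TPL.find("AAGGAGG"), 8, "AAGGAGG"),
            ("AAGGAGG", TPL.find("AAGGAGG"), 14, "AAGGAGG"),
        ],
    )
    def test_planted_pattern_and_spacing_recovered(self, pattern_dna, t0, spacing, expected):
        g = make_gene(sd_window(pattern_dna, t0, spacing))
        m = scan_rbs(g, 26, "+", model=MODEL)
        assert m is not None
        assert (m.pattern, m.spacing, m.category) == (expected, spacing, "canonical")

    def test_internal_mismatch_rendered_lowercase(self):
        # genome GGGGGT against template GGAGGU: the non-pairing base prints
        # lowercase, exactly one of them
        g = make_gene(sd_window("GGGGGT", 5, 10))
        m = scan_rbs(g, 26, "+", model=MODEL)
        assert m is not None and m.pattern == "GGgGGU"
        assert sum(c.islower() for c in m.pattern) == m.n_mismatch == 1

    def test_poly_a_window_is_not_an_rbs(self):
        g = make_gene("A" * 25)
        assert scan_rbs(g, 26, "+", model=MODEL) is None

    def test_uppercase_positions_pair_the_printed_tail(self):
        g = make_gene(sd_window("GGGGGT", 5, 10))
        m = scan_rbs(g, 26, "+", model=MODEL)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        anti = MODEL.antisd_as_printed
        for k, ch in enumerate(m.pattern):
            t_pos = m.template_offset - 1 + k
            if ch.isupper():
                assert ch == comp[anti[t_pos]]
            else:
                assert ch.upper() != comp[anti[t_pos]]

    def test_spacing_always_in_range(self, rng):
        for _ in range(40):
            g = random_genome(rng, 120, topology="linear")
            m = scan_rbs(g, 100, "+", model=MODEL)
            if m is not None:
                assert 8 <= m.spacing <= 14

    def test_widening_spacing_range_never_loses_matches(self, rng):
        import dataclasses
        wide = dataclasses.replace(MODEL, spacing_range=(6, 16))
        for _ in range(40):
            g = random_genome(rng, 120, topology="linear")
            if scan_rbs(g, 100, "+", model=MODEL) is not None:
                assert scan_rbs(g, 100, "+", model=wide) is not None

    def test_equals_exhaustive_offset_argmax_oracle(self, rng):
        """Brute force over every placement and every paired-bounded block."""
        def oracle(win_rna):
            best = None
            t_len = len(TPL)
            w_len = len(win_rna)
            anchor_j = MODEL.anchor_index - 1
            for off in range(w_len - t_len + 1):
                paired = [win_rna[off + j] == TPL[j] for j in range(t_len)]
                idx = [j for j in range(t_len) if paired[j]]
                for ai, first in enumerate(idx):
                    for last in idx[ai:]:
                        block = list(range(first, last + 1))
                        mism = sum(1 for j in block if not paired[j])
                        if mism > MODEL.max_mismatch:
                            continue
                        n_paired = len(block) - mism
                        spacing = (w_len - 1) - (off + anchor_j) - 1
                        if not (8 <= spacing <= 14):
                            continue
                        core = set(MODEL.core_positions)
                        if sum(1 for j in block if paired[j] and j + 1 in core) < 3:
                            continue
                        key = (-n_paired, mism, spacing, off, first)
                        if best is None or key < best:
                            best = key
            return best

        for _ in range(60):
            g = random_genome(rng, 120, topology="linear")
            win = g.seq[100 - 25 : 100]
            m = scan_rbs(g, 100 + 1, "+", model=MODEL)
            # NB start_pos 101: window is seq[76:101]
            win = as_rna(g.seq[75:100])
            exp = oracle(win)
            if exp is None:
                assert m is None
            else:
                assert m is not None
                assert (-m.n_paired, m.n_mismatch, m.spacing) == exp[:3]


class TestDualStarts:
    def test_internal_start_with_own_rbs_reported(self):
        # holin-type dual start 9 codons in (cf. a 27-nt start offset): the
        # internal ATG carries its own SD pattern inside the coding region
        from phagescan.synthetic import GenomeSpec, PlantedOrf, generate
        from phagescan.orfcall import scan_orfs
        spec = GenomeSpec(length=4000, seed=11, orfs=[
            PlantedOrf(length_aa=80, rbs_pattern="AAGGAGG", spacing=9, position=1000)
        ])
        g, _ = generate(spec)
        seq = list(g.seq)
        internal0 = 999 + 27  # 0-based position of the internal ATG (codon 9)
        seq[internal0 : internal0 + 3] = "ATG"
        t0 = TPL.find("AGGAGGU")
        rel = -(10 + 2) - (MODEL.anchor_index - 1 - t0)  # spacing-10 layout
        seq[internal0 + rel : internal0 + rel + 7] = "AGGAGGT"
        g = Genome(id="dual", seq="".join(seq), topology="circular")
        orfs = [o for o in scan_orfs(g, min_aa=40) if o.start_nt == 1000]
        assert orfs, "planted ORF must survive the graft"
        duals = detect_dual_starts(orfs[0], g, k=15, model=MODEL)
        assert any(d["offset_aa"] == 9 for d in duals)

    def test_shared_rbs_serves_both_starts_a_few_codons_apart(self):
        # the two holin initiation codons of the reference phage share one
        # RBS read at spacings 8 and 14; an internal ATG 2 codons in is
        # reported off the same planted site
        from phagescan.synthetic import GenomeSpec, PlantedOrf, generate
        from phagescan.orfcall import scan_orfs
        spec = GenomeSpec(length=4000, seed=13, orfs=[
            PlantedOrf(length_aa=80, rbs_pattern="AAAGGAG", spacing=8, position=1000)
        ])
        g, _ = generate(spec)
        seq = list(g.seq)
        seq[1005:1008] = "ATG"  # codon 2 of the gene
        g = Genome(id="dual2", seq="".join(seq), topology="circular")
        orfs = [o for o in scan_orfs(g, min_aa=40) if o.start_nt == 1000]
        assert orfs
        duals = detect_dual_starts(orfs[0], g, k=15, model=MODEL)
        hits = [d for d in duals if d["offset_aa"] == 2]
        assert hits and hits[0]["rbs"].spacing == 14

    def test_gene_without_internal_atg_reports_nothing(self):
        g = Genome(id="g", seq="C" * 30 + "ATG" + "GCT" * 60 + "TAA" + "C" * 10,
                   topology="linear")
        from phagescan.orfcall import scan_orfs
        (orf,) = scan_orfs(g, min_aa=40)
        assert detect_dual_starts(orf, g, k=15, model=MODEL) == []


class TestAnchorCalibration:
    def test_recovers_the_generating_anchor(self):
        examples = []
        for pat, t0, sp in [
            ("AAGGAGGT", TPL.find("AAGGAGGU"), 10),
            ("AGGAGG", TPL.find("AGGAGG"), 9),
            ("GAGG", TPL.find("GAGG"), 12),
        ]:
            examples.append((sd_window(pat, t0, sp), as_rna(pat), sp))
        best, scores = calibrate_anchor(examples, MODEL)
        assert best == MODEL.anchor_index
        assert scores[best] == len(examples)
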