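"""Composition statistics, codon usage, protein mass, ORF-table summaries."""

import numpy as np
import pytest

from phagescan.composition import (
    at_islands,
    codon_usage,
    compare_usage,
    coverage_pct,
    gc_content,
    protein_mass,
    purine_content,
    summarize_orf_table,
)
from phagescan.seqcore import Genome, Interval, SequenceError

from conftest import random_genome


class TestBaseContent:
    def test_extremes(self):
        assert gc_content("GGCC") == 100.0
        assert gc_content("AATT") == 0.0
        assert purine_content("AGAG") == 100.0

    def test_against_counting_oracle(self, rng):
        for _ in range(20):
            g = random_genome(rng, 500)
            gc = sum(b in "GC" for b in g.seq) / 5.0
            pur = sum(b in "AG" for b in g.seq) / 5.0
            assert gc_content(g) == pytest.approx(gc)
            assert purine_content(g.seq) == pytest.approx(pur)

    def test_complementary_strands_sum_to_100(self, rng):
        from phagescan.seqcore import reverse_complement
        g = random_genome(rng, 801)
        assert purine_content(g.seq) + purine_content(reverse_complement(g.seq)) == pytest.approx(100.0)


class TestAtIslands:
    def test_planted_at_insert_found(self, rng):
        backbone = random_genome(rng, 2000, gc=0.5).seq
        insert = "AT" * 30
        seq = backbone[:1000] + insert + backbone[1000:]
        g = Genome(id="isl", seq=seq, topology="linear")
        islands = at_islands(g, window=50, threshold=0.75)
        cover = [i for i in islands
                 if i["interval"].start <= 1001 and i["interval"].end >= 1060]
        assert len(cover) == 1
        assert cover[0]["at_fraction"] >= 0.7

    def test_uniform_genome_high_threshold_empty(self, rng):
        hits = 0
        for _ in range(5):
            g = random_genome(rng, 3000, topology="circular", gc=0.5)
            hits += len(at_islands(g, window=50, threshold=0.9))
        assert hits == 0

    def test_rotation_invariance(self, rng):
        backbone = random_genome(rng, 1500, gc=0.45).seq
        seq = backbone[:700] + "AT" * 40 + backbone[700:]
        g = Genome(id="r", seq=seq, topology="circular")
        L = g.length
        base = {( (i["interval"].start - 1) % L, i["interval"].span(L))
                for i in at_islands(g)}
        for rot in (3, 777):
            g2 = Genome(id="r2", seq=seq[rot:] + seq[:rot], topology="circular")
            rotated = {(((i["interval"].start - 1) + rot) % L, i["interval"].span(L))
                       for i in at_islands(g2)}
            assert rotated == base


class TestCodonUsage:
    def test_minimal_orf(self):
        t = codon_usage(["ATGAAATAA"])
        f = t.fractions()
        assert f["AAA"] == 1.0  # sole Lys codon
        assert f["UAA"] == 1.0  # sole stop
        assert t.total_codons == 3

    def test_printed_lys_fraction(self):
        # AAA=760 vs AAG=460 gives the published 0.62
        from phagescan.composition import CodonUsageTable
        t = CodonUsageTable(counts={"AAA": 760, "AAG": 460})
        assert t.fractions()["AAA"] == pytest.approx(0.62, abs=0.005)

    def test_against_dictionary_oracle_and_family_sums(self, rng):
        from phagescan.seqcore import STOP_CODONS
        sense = [c for c in
                 ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
                 if c not in STOP_CODONS]
        seqs = []
        for _ in range(10):
            n = int(rng.integers(5, 60))
            body = [sense[i] for i in rng.integers(0, len(sense), size=n)]
            seqs.append("".join(body) + ["TAA", "TAG", "TGA"][int(rng.integers(0, 3))])
        t = codon_usage(seqs)
        # oracle: plain dictionary count
        from collections import Counter
        cnt = Counter()
        for s in seqs:
            for i in range(0, len(s), 3):
                cnt[s[i:i+3].replace("T", "U")] += 1
        assert t.counts == dict(cnt)
        assert t.total_codons == sum(len(s) // 3 for s in seqs)
        # within every family the fractions sum to 1
        fam_sums = {}
        for codon, frac in t.fractions().items():
            fam = t.family(codon)
            fam_sums[fam] = fam_sums.get(fam, 0.0) + frac
        for fam, s in fam_sums.items():
            assert s == pytest.approx(1.0, abs=1e-9)

    def test_requires_terminal_stop(self):
        with pytest.raises(SequenceError):
            codon_usage(["ATGAAA"])


class TestCompareUsage:
    def test_his_cau_divergent(self, codon_table):
        spp1 = codon_table.rename(columns={"spp1_fraction": "fraction"})
        bs = codon_table.rename(columns={"bs_fraction": "fraction"})
        flags = compare_usage(spp1, bs)
        row = flags.set_index("codon").loc["CAU"]
        assert bool(row["divergent"])  # 0.53 vs 0.67

    def test_identical_tables_have_no_divergence(self, codon_table):
        t = codon_table.rename(columns={"spp1_fraction": "fraction"})
        flags = compare_usage(t, t)
        assert not flags["divergent"].any()

    def test_flags_match_printed_annotations(self, codon_table):
        """Brute-force recomputation over the packaged table reproduces the
        published bold (divergent) markup; rare flags follow the <0.1 rule."""
        spp1 = codon_table.rename(columns={"spp1_fraction": "fraction"})
        bs = codon_table.rename(columns={"bs_fraction": "fraction"})
        flags = compare_usage(spp1, bs).set_index("codon")
        for _, row in codon_table.iterrows():
            assert flags.loc[row["codon"], "divergent"] == (row["divergent_printed"] == "yes")
            assert flags.loc[row["codon"], "rare_a"] == (row["spp1_fraction"] < 0.1)
            assert flags.loc[row["codon"], "rare_b"] == (row["bs_fraction"] < 0.1)


class TestProteinMass:
    def test_empty_sequence_rejected(self):
        with pytest.raises(SequenceError):
            protein_mass("")

    def test_unknown_residue_rejected(self):
        with pytest.raises(SequenceError, match="position 2"):
            protein_mass("MXK")

    def test_mk_hand_sum(self):
        # Met 131.1926 + Lys 128.1741 + water 18.01524
        assert protein_mass("MK") == pytest.approx(277.38194)

    def test_polyglycine_linear_in_n(self):
        from phagescan.tables import load_residue_masses
        gly = load_residue_masses()["G"]
        for n in (1, 7, 40):
            assert protein_mass("G" * n) == pytest.approx(n * gly + 18.01524)


class TestSummarizeOrfTable:
    def test_reference_table_reproduces_published_statistics(self, orf_table):
        s = summarize_orf_table(orf_table, 44016, "circular")
        assert s["n_orfs"] == 80
        assert round(s["coverage_pct"]) == 94
        assert s["start_codon_tally"]["AUG"] == 72
        assert round(100 * s["stop_codon_fractions"]["UGA"]) == 39
        assert round(100 * s["stop_codon_fractions"]["UAA"]) == 50
        assert round(s["mean_length_aa"]) == 179
        assert round(s["mean_mass_kda"], 1) == 20.3
        assert round(s["sd_length_aa"]) == 197
        assert round(s["sd_mass_kda"], 1) == 21.9

    def test_stop_tallies_match_usage_table_end_family(self, orf_table, codon_table):
        s = summarize_orf_table(orf_table, 44016, "circular")
        end = codon_table[codon_table["family"] == "End"].set_index("codon")
        for codon in ("UGA", "UAG", "UAA"):
            assert s["stop_codon_tally"][codon] == end.loc[codon, "spp1_count"]

    def test_single_full_genome_orf_covers_everything(self):
        import pandas as pd
        rows = pd.DataFrame([{"start_nt": 1, "stop_nt": 300, "start_codon": "AUG",
                              "stop_codon": "UAA", "length_aa": 99, "mm_kda": 11.0}])
        s = summarize_orf_table(rows, 300, "circular")
        assert s["coverage_pct"] == 100.0

    def test_union_against_bitmap_oracle_including_wraps(self, rng):
        L = 500
        for _ in range(25):
            ivs = []
            mask = np.zeros(L, dtype=bool)
            for _ in range(int(rng.integers(1, 8))):
                a = int(rng.integers(1, L + 1))
                span = int(rng.integers(1, L))
                bvec = [(a - 1 + k) % L for k in range(span)]
                mask[bvec] = True
                b = (a - 1 + span - 1) % L + 1
                ivs.append(Interval(a, b, wraps=b < a))
            got = coverage_pct(ivs, L, "circular")
            assert got == pytest.approx(100.0 * mask.sum() / L)
            # idempotence and bound
            assert got <= 100.0 + 1e-9

    def test_coverage_idempotent(self):
        ivs = [Interval(10, 200), Interval(150, 400), Interval(480, 20, wraps=True)]
        a = coverage_pct(ivs, 500, "circular")
        assert coverage_pct(ivs + ivs, 500, "circular") == a
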