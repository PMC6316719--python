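sequence	start_nt	end_nt	dg_printed
AAAAGCGAGTTAACCGACGTAAAAATGCGTCGGTTTTTTTCGTGCTTC	4718	4765	-12.20
GTGTCAGTGCGCGGGTTCAATTCCCGGAGTCCGTTTTTACCGCCC	6780	6824	-5.50
TAAAAAGAGAAGAGGGGCTAACGCCTCTCTTTTTTTGAAAG	8775	8815	-14.00
ATTGCCAGCAGAGAGCACGGGTTAATTCCCGCGCTCTTTTTTTGTATTCA	11255	11304	-9.20
TGAATTAGACAGGGCCGCGCAAGTGGCTCTTTTTAATAGGT	12009	12049	-15.20
TGAAAAGACGCGGCGCCGCTAACGGCGTCCGTTTTGAACATGA	16711	16753	-12.10
GATTGACGAAGTAAAGGGCCATGTGCCCTTTATTTTTTTGCAAA	21897	21940	-10.70
ACCTTCGCTTGCCGCCCGGCTGATGGGCGGTTTTTTATTTTT	24095	24136	-13.20
TGTCCTAAAATCGGCCCGTTCCCAGTCGGGCCACTTTTTTTATTTTA	27934	27980	-13.60
GACTTTGAAAGGAACCGTTCTCTAACGGTTCTTTTTTTATTTC	30205	30247	-9.90
TATTTTGATTGAGTCGGGGAAACCCGGCTTTTTTATTTTGGG	35232	35273	-14.90
ATCAAAGTTATGGTGGGAGTAATCCCGCCTTTTTCTATTTT	40466	40506	-14.40
AACACAGAGAGGCACCCTATTTGGGTGCTTTTTTGTTGTA	43774	43813	-11.90
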