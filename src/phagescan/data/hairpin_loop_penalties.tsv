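# Hairpin loop initiation free energies, kcal/mol at 37 C (Turner-style).
# Loops longer than the largest tabulated size are extrapolated as
# dG(n) = dG(9) + 1.08 * ln(n / 9)  (Jacobson-Stockmayer).
loop_len	dg
3	5.4
4	5.6
5	5.7
6	5.4
7	6.0
8	5.5
9	6.4
10	6.5
11	6.6
12	6.7
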