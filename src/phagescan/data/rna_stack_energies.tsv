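# Nearest-neighbor RNA stacking free energies, kcal/mol at 37 C.
# A stack is two adjacent base pairs; pair1 is 5'-side on the top strand,
# pair2 its 3' neighbor.  Pairs are written top-base:bottom-base.
# Watson-Crick values follow the Turner free-energy set; wobble (G:U)
# entries are approximate and editable.  Symmetry-related combinations
# (pair1,pair2) == (flip(pair2),flip(pair1)) are filled in by the loader.
pair1	pair2	dg
A:U	A:U	-0.93
A:U	U:A	-1.10
U:A	A:U	-1.33
C:G	U:A	-2.08
C:G	A:U	-2.11
G:C	U:A	-2.24
G:C	A:U	-2.35
C:G	G:C	-2.36
G:C	G:C	-3.26
G:C	C:G	-3.42
A:U	G:U	-0.55
A:U	U:G	-1.36
C:G	G:U	-1.41
C:G	U:G	-2.11
G:C	G:U	-1.53
G:C	U:G	-2.51
U:A	G:U	-1.20
U:A	U:G	-1.00
G:U	G:U	-0.50
U:G	U:G	-0.50
G:U	U:G	0.50
U:G	G:U	-0.60
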