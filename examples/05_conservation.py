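"""Cross-species positional conservation of antisense TSS.

Positions inside orthologous genes are compared on a length-normalized
0-100 scale (d = 0 at the start codon, 100 at the stop codon) binned in
tenths; an aTSS is conserved when both orthologs carry one in the same
tenth. D = |d_a - d_b| measures positional equivalence.
"""

from asmapper import conserved_atss

for d_a, d_b in [(42.0, 47.0), (38.0, 41.0), (77.0, 77.0)]:
    rec = conserved_atss(d_a, d_b)
    print(f"d_a={d_a:5.1f} d_b={d_b:5.1f}  partitions "
          f"({rec.partition_a},{rec.partition_b})  D={rec.D:4.1f}  "
          f"conserved={rec.conserved}")
# 42 vs 47 share tenth [40,50) -> conserved despite D=5; 38 vs 41 differ
# by only 3 but straddle the [30,40)/[40,50) boundary -> not conserved;
# D=0 is always conserved.
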