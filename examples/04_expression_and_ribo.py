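"""Expression candidacy and the ribosome-association (rancRNA) filter.

An asRNA is a candidate cis-regulator when its raw fragment count reaches
its cognate mRNA's in at least one library. A locus is a putative
rancRNA when pooled Ribo-seq coverage spans more than half of it and at
least 20 reads support it.
"""

from asmapper import expression_flags, is_rancrna

ratios, candidate = expression_flags([12, 3, 0], [9, 30, 4])
print("log2((a+1)/(m+1)) per library:", [round(float(r), 2) for r in ratios])
print("candidate cis-regulator:", candidate)  # library 1: 12 >= 9

for fraction, reads in [(0.6, 25), (0.5, 100), (0.9, 19)]:
    print(f"coverage {fraction:.0%}, {reads} reads -> rancRNA: "
          f"{is_rancrna(fraction, reads)}")
# 50% coverage fails (strictly greater than half required); 19 reads
# fails the 20-read floor regardless of coverage.
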