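"""Classify transcription start sites against a gene annotation.

A TSS inside a gene on the opposite strand is an antisense TSS (aTSS); a
TSS on the opposite strand within 200 nt past a gene's 3' end is a
downstream antisense TSS (daTSS); everything else is 'other'.
"""

from asmapper import Gene, classify_tss

genes = [
    Gene("VNG_RS00100", "chr", 1000, 2000, "+"),
    Gene("VNG_RS00105", "chr", 2600, 3400, "-"),
]

for position, strand in [(1500, "-"), (2100, "-"), (2250, "-"),
                         (2450, "+"), (3000, "+")]:
    cls, cognate = classify_tss(position, strand, genes, da_window_nt=200)
    tags = ",".join(g.locus_tag for g in cognate) or "-"
    print(f"TSS {position}({strand}): {cls:22s} cognate: {tags}")

# 1500(-) sits inside the + gene -> antisense; 2100(-) is 100 nt past its
# 3' end -> downstream_antisense; 2250(-) is beyond the 200 nt window;
# 2450(+) is within 200 nt of the - gene's 3' end (at 2600, leftwards);
# 3000(+) is inside the - gene -> antisense.
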