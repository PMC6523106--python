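"""Infer asRNA loci (minimum 3' ends) from fragment 3'-end accumulation.

Generates a synthetic dataset with planted asRNAs, classifies the planted
TSS, infers each locus's minimum 3' end (>= 10 pooled 3'-end observations
at the end, uninterrupted coverage in >= 4 libraries) and compares the
result with the planted truth.
"""

from asmapper import (PipelineConfig, SimConfig, Tss, build_loci,
                      classify_tss, simulate)

dataset = simulate(SimConfig(n_genes=15, n_asrnas=12, noise_rate=0.0),
                   seed=8, species_b=False)
sites = []
for i, planted in enumerate(dataset.truth.planted_asrnas):
    cls, cognate = classify_tss(planted.tss_position, planted.strand,
                                dataset.genes, 200)
    prefix = "aTSS" if cls == "antisense" else "daTSS"
    sites.append(Tss(f"{prefix}_{i + 1}", "chrA", planted.tss_position,
                     planted.strand, cls, [g.locus_tag for g in cognate]))

loci = build_loci(sites, dataset.three_prime, dataset.coverage,
                  PipelineConfig(), genes=dataset.genes)
truth = {(p.tss_position, p.strand): p for p in dataset.truth.planted_asrnas}
print(f"{len(loci)} loci inferred from {len(sites)} planted TSS")
print(f"{'asrna_id':24s}{'start':>8}{'end':>8}{'size':>6}{'end_ok':>8}")
for locus in loci[:8]:
    planted = truth[(locus.tss_position, locus.strand)]
    end3 = locus.end - 1 if locus.strand == "+" else locus.start
    ok = "yes" if end3 == planted.end_position else "no"
    print(f"{locus.asrna_id:24s}{locus.start:>8}{locus.end:>8}"
          f"{locus.size_nt:>6}{ok:>8}")
# size = end - start for every locus; at saturating depth with no noise
# the inferred minimum 3' ends coincide with the planted ends.
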