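# Methods

This note documents the models and conventions behind `asmapper`, the
choices made where the design was genuinely open, and what the synthetic
data does and does not establish about real data.

## Coordinates and naming

All internal coordinates are 0-based half-open `[start, end)`; GFF3 I/O
converts from the 1-based inclusive file convention at the boundary and
BED/bedGraph pass through unchanged. The published asRNA tables satisfy
`Size = End − Start`, which is the half-open length identity, so the
package anchors on that identity rather than on absolute genome
registration (printed table starts may be 0- or 1-based; only the
identity is certain). asRNA identifiers concatenate a class prefix with
the cognate gene tag suffix and the TSS ordinal: `VNG_RS12315` +
`aTSS_1568` → `VNG_as12315_1568`; legacy `VNG_OE`-style tags keep their
full suffix (`VNG_OE3105F` + `daTSS_36` → `VNG_da3105F_36`).

## TSS classification

A site is **antisense** when it lies in `[gene.start, gene.end)` of at
least one gene on the opposite strand, and **downstream antisense** when
it is not antisense but lies within the 200 nt window past a gene's 3′
end measured in gene orientation: `[end, end + 200)` for a + gene,
`[start − 200, start)` for a − gene (the TSS strand must be opposite the
gene's). The classes are disjoint and antisense takes precedence — a
site inside one gene and downstream of another is an aTSS. The source
text does not say whether a daTSS may simultaneously be antisense to a
different gene; treating antisense as absorbing is our reading, chosen
because the two classes are reported as disjoint sets. A site antisense
to two genes (possible only where two same-strand genes overlap) carries
both cognate tags. At the locus level, an asRNA that runs past its
anchor gene into a neighbour also gains that neighbour as a cognate.

The optional TSS caller is a deliberately simple stand-in for a full
dRNA-seq caller: a position is a candidate when its TEX+ 5′-end count is
≥ 4 and a one-sided Poisson test against a mean of max(TEX− count, 1)
gives p < 0.005; candidates within 5 nt are chained into clusters and
the maximal-count position (leftmost on ties, for determinism)
represents each cluster. It shares the published parameter surface but
not the published statistical model, and it is labelled accordingly.

## Structure filter

Stable secondary structure protects processed 5′ ends from the
terminator exonuclease, so structure-prone regions yield false-positive
TSS calls. The genome is tiled on both strands with 51-nt windows at a
10-nt offset (trailing partial windows skipped), each window is folded,
and the 33.3% empirical quantile (linear interpolation) of the pooled
MFE distribution is the cutoff. Each aTSS's downstream window starts at
the TSS base (window registration is unstated in the source; including
the TSS base is our choice) and the site is removed when its MFE is ≤
the cutoff — inclusive, so the degenerate all-equal distribution removes
everything loudly rather than nothing silently. Sites too close to the
replicon end for a full window are retained with a logged warning.

Two folding engines are provided. The default is ViennaRNA's
thermodynamic nearest-neighbour MFE (`RNA.fold`, default parameters),
which is the model this filter's science calls for; its continuous
energies also make the quantile cutoff well behaved. The alternative
`builtin` engine is a Nussinov-style weighted base-pair maximization
(pair weights GC=3, AU=2, GU=1, minimum hairpin loop 3, energy = −max
total weight): a fast, dependency-free scorer with exactly checkable
semantics, used by the test oracles and available wherever ViennaRNA is
not. Its integer-valued energies concentrate several percent of tile
mass on single values, so the fraction removed under a quantile cutoff
is seed-dependent with ties at the tertile — a caveat that does not
apply to the thermodynamic engine. Further engines can be registered at
run time (`register_folder`).

## Locus inference

For each retained aTSS/daTSS the scanner walks downstream in transcript
orientation up to `max_locus_span_nt` (default 2000 nt, nearly an order
of magnitude above the largest reference asRNA of 303 nt). The first position where the
**pooled** (summed over libraries) fragment 3′-end count reaches
`min_end_support` = 10 becomes the locus end — provided the interval
from the TSS to that position has nonzero fragment coverage at every
position in at least `min_lib_support` = 4 libraries. Two published
numbers are the only objective criteria available (the original
procedure also involved visual inspection), and codifying them this way
makes the annotation reproducible: the 10-observation rule is read as
pooled across libraries (per-library vs pooled is unstated), while the
four-library rule is read as coverage support for the locus extent,
matching the separation of the two criteria in the text. Taking the
*first* qualifying position yields the minimum 3′ end: later
accumulations never extend an already-qualified locus, and the locus
size is a lower bound on the molecule's true length.

## Characterization

Positions inside a CDS are normalized as `d = 100·o/(L−1)` where `o` is
the 0-based offset along gene orientation; the denominator `L−1` maps
the last base exactly to `d = 100`. Tenth partitions are
`[0,10), …, [90,100)` with `d = 100` clamped into partition 9 (it must
live somewhere and the printed partitions end at 100). The 5′-overlap
rule marks a locus when its interval intersects the 15-nt window
covering the cognate start codon plus 12 nt (four codons) downstream —
window *intersection*, not full coverage, which is the weaker and more
faithful reading of "overlap the start codon or at least 12 nt
downstream of it". Frequency matrices extract windows in transcript
orientation (reverse complement on −), offset 0 at the aligned base,
promoter −40..+10 (51 positions, TSS at 0) and 3′ window −10..+10 (21
positions, last transcribed base at 0).

Fragment counting is union-mode and strand-aware; fragments overlapping
more than one same-strand feature are discarded as ambiguous.
Expression candidacy uses raw counts (`asRNA ≥ mRNA` in ≥ 1 library), so
it is invariant to any within-library normalization; the exported log2
ratios use a pseudocount of 1, which never affects the flag. Downstream
differential-expression analysis is out of scope; the count matrix is
exported in a DESeq2-ready layout instead. The rancRNA rule is
`coverage_fraction > 0.5` (strict) **and** `reads ≥ 20`, with reads
counted as Ribo-seq read starts inside the locus (or an externally
supplied count), pooled across Ribo-seq libraries.

## Conservation

For each ortholog pair, every combination of (asRNA locus in species A
whose anchoring TSS lies inside the gene) × (aTSS inside the species-B
ortholog) is scored: `D = |d_A − d_B|`, conserved iff the tenth
partitions agree. A gene pair is conserved when at least one combination
is, and the pair's reported D is the minimum over combinations; the full
per-combination table is also emitted, together with a D histogram and
the count of positionally equivalent records (D < 3). The scan is
deliberately asymmetric (annotated locus required in A, bare aTSS
sufficient in B), mirroring how one species' annotation is typically
deeper than the other's. Partitions are half-open left-closed
throughout; the source alternates between `[0;10)` and `(0;10)` notation
and we use the former consistently.

## Synthetic data

The generator emulates the input structure of the study design: one
GC-rich replicon (default 50 kb, GC 0.65 — halophile-like), 40 genes
(300–1100 nt, ≥ 250 nt intergenic gaps so daTSS windows stay
intergenic), a few same-strand overlapping gene pairs to create
two-cognate sites, and 60 planted asRNAs (lognormal sizes ~40–300 nt,
most below 100 nt, the size range typical of primary asRNA annotations)
of which 5% are daTSS-anchored, 20% overlap the cognate 5′ window, 11%
are ribosome-associated and 30% are positionally conserved in the
companion species — the class composition this design emulates. Ten
libraries are sampled (four replicates plus biological duplicates of
three time points, mirroring the emulated library structure), with
per-asRNA per-library fragment counts negative binomial (dispersion 10)
around a lognormal expression level (mean 30 fragments, σ = 0.4); genes
receive their own mRNA fragments (mean 150, σ = 1.0) so expression
candidacy is non-trivial — about 12–15% of loci qualify, the same
low-minority regime seen in real annotations.

Fragments follow a simple fragmentation model: a molecule shorter than
the drawn fragment length (Gaussian, mean 150 sd 30) is sequenced whole;
otherwise 40% of fragments are 3′-terminal and the rest break uniformly
inside the transcript with the 5′ end clipped at the TSS. Fragment 5′
ends feed the 5′-accumulation track, 3′ ends the 3′-accumulation track.
This reproduces the load-bearing features — sharp 3′-end pileups at
true termini over a diffuse internal background, continuous coverage,
TEX+ enrichment at primary 5′ ends — but none of the nuisance structure
of real libraries: no sequencing error, mappability artifacts,
multimappers, processed 5′ ends, or transcription beyond the planted
molecules (background noise is i.i.d. fragments at a configurable rate,
default 0.1/kb/library/strand). Passing tests on these fixtures
therefore demonstrates that the *decision rules* are implemented and
composed correctly and are recoverable under the stated thresholds; it
does not certify performance on real libraries, where threshold
sensitivity is dominated by exactly the artifacts not modelled. The
species-B annotation is a positional control (gene lengths copied, aTSS
planted in controlled tenths), not an evolutionary simulation.

Everything is a pure function of (config, seed) via a single
`numpy.random.default_rng` stream; placements are validated against an
independent brute-force classifier at planting time, and infeasible
packings fail loudly after bounded retries.

## Pipeline and numerics

The pipeline runs classify → structure-filter → loci → analytics /
counts / ribo / conservation from a YAML config, writes plain-text
outputs plus a JSON manifest (config snapshot, SHA-256 input checksums,
per-stage counters), and is deterministic end to end: reruns with
unchanged inputs are byte-identical, and running stages individually
composes to the same outputs as a full run. When a previous manifest
matches the current inputs, the TSS and locus stages resume from disk;
the cheap downstream stages always recompute. Genome-scale totals (n
aTSS, n removed, n loci, n candidates, …) are surfaced as counters so a
full-data run can be compared against published figures; those totals
themselves require the original multi-gigabyte read data and are not
reproduced here.

Numerical choices worth noting: quantiles use linear interpolation
between order statistics (`numpy.quantile` default); Poisson tail
probabilities come from `scipy.stats.poisson.sf`; the Nussinov recursion
is O(n³) per window, JIT-compiled with numba when available with a pure
Python fallback; identical tile sequences are folded once (a cache that
matters on low-complexity genomes). Test problem sizes (50 kb genomes,
60 planted asRNAs, 10 libraries, 1000-site filter samples) were chosen
as the smallest sets on which the statistical checks have clear margins.
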