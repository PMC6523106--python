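"""Seeded generator of synthetic pipeline inputs with planted ground truth.

The generator emulates the input structure of a dRNA-seq / paired-end
RNA-seq study of a GC-rich haloarchaeal genome: annotated genes on both
strands, planted antisense RNAs with known TSS and 3' ends, multi-library
fragment sampling, TEX+/TEX- 5'-end profiles, Ribo-seq signal over a
subset of planted loci, and a companion "species B" annotation with
positionally controlled aTSS for conservation tests. Every output is a
pure function of (config, seed).

Study-shaped defaults: 10 RNA-seq libraries (four mid-log replicates plus
biological duplicates of three growth time points), a 0.65 GC genome,
~5% of planted antisense TSS downstream-anchored (daTSS), ~11% of loci
ribosome-associated, and a 30% positionally conserved fraction in
species B.

Fragment model: each sequenced fragment of a planted asRNA is the whole
molecule when the transcript is shorter than the drawn fragment length
(Gaussian, mean 150 sd 30, rounded); otherwise a fragment-length window
anchored at the 5' end, at the 3' end, or uniformly inside the transcript
(probabilities 0.35/0.35/0.30). Fragment 5' ends feed the 5'-accumulation
track, 3' ends the 3'-accumulation track, extents the coverage track.
Per-asRNA, per-library fragment counts are negative binomial around the
planted expression level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as aio
from .analytics import partition_index, relative_position
from .model import ANTISENSE, DOWNSTREAM_ANTISENSE, Gene, ProfileTrack, Tss


@dataclass
class SimConfig:
    """Generator configuration (all sizes in nt)."""

    genome_length: int = 50_000
    gc_fraction: float = 0.65
    replicon: str = "chrA"
    n_genes: int = 40
    n_asrnas: int = 60
    gene_min_len: int = 300
    gene_max_len: int = 1100
    gap_min: int = 250
    gap_max: int = 350
    asrna_min_len: int = 40
    asrna_max_len: int = 300
    frac_datss: float = 0.05
    frac_five_prime: float = 0.20
    frac_two_genes: float = 0.05
    frac_rancrna: float = 0.11
    frac_conserved: float = 0.30
    n_libraries: int = 10
    mean_depth: float = 30.0  # mean fragments per asRNA per library
    nb_dispersion: float = 10.0
    expression_sigma: float = 0.4  # lognormal spread of per-asRNA levels
    gene_mean_depth: float = 150.0  # mean mRNA fragments per gene per library
    gene_expression_sigma: float = 1.0
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 30.0
    end_jitter_sd: float = 0.0
    noise_rate: float = 0.1  # background fragments per kb per library per strand


@dataclass
class PlantedAsRna:
    """Ground truth for one planted antisense RNA.

    ``tss_position`` and ``end_position`` are both inclusive base
    coordinates; the half-open interval is derived from the strand.
    """

    tss_position: int
    strand: str
    end_position: int
    cognate_genes: list[str]
    tss_class: str
    expression_level: float
    is_rancrna: bool = False
    is_conserved_in_b: bool = False
    overlaps_five_prime: bool = False

    @property
    def interval(self) -> tuple[int, int]:
        if self.strand == "+":
            return self.tss_position, self.end_position + 1
        return self.end_position, self.tss_position + 1

    @property
    def size_nt(self) -> int:
        start, end = self.interval
        return end - start


@dataclass
class SimTruth:
    planted_genes: list[Gene]
    planted_asrnas: list[PlantedAsRna]
    library_params: dict
    seed: int
    gene_expression: dict[str, float] = field(default_factory=dict)


@dataclass
class SimDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimConfig
    genome: dict[str, str]
    genes: list[Gene]
    truth: SimTruth
    libraries: list[str]
    coverage: list[ProfileTrack]
    five_prime: list[ProfileTrack]
    three_prime: list[ProfileTrack]
    tex_plus: list[ProfileTrack]
    tex_minus: list[ProfileTrack]
    ribo_coverage: list[ProfileTrack]
    ribo_starts: list[ProfileTrack]
    fragments: dict[str, list[tuple[str, int, int, str]]]
    genes_b: list[Gene] = field(default_factory=list)
    atss_b: list[Tss] = field(default_factory=list)
    orthologs: Optional[pd.DataFrame] = None


def generate_genome(length: int, gc_fraction: float = 0.65,
                    seed: int = 0, replicon: str = "chrA") -> dict[str, str]:
    """I.i.d. random genome with the given GC content."""
    if length <= 0:
        raise ValueError("genome length must be positive")
    if not 0.0 < gc_fraction < 1.0:
        raise ValueError("gc_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    bases = rng.choice(np.array(list("ACGT")), size=length, p=[at, gc, gc, at])
    return {replicon: "".join(bases)}


def _exact_count_mask(n: int, fraction: float, rng: np.random.Generator) -> np.ndarray:
    """Boolean mask with exactly round(fraction * n) True entries, randomly
    placed. Exact composition keeps planted designs analyzable."""
    k = int(round(fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[rng.choice(n, size=k, replace=False)] = True
    return mask


def plant_features(genome: dict[str, str], cfg: SimConfig,
                   seed: int) -> tuple[list[Gene], SimTruth]:
    """Place genes and plant asRNAs with classes true by construction.

    Genes are packed left to right with intergenic gaps of at least
    ``gap_min`` (> the 200 nt daTSS window, so downstream windows stay
    intergenic). A fraction of genes receive an overlapping opposite-
    strand partner so some asRNAs are antisense to two genes. Planted
    asRNA intervals never overlap each other on the same strand, keeping
    each 3'-end signal attributable to one molecule.
    """
    rng = np.random.default_rng(seed)
    replicon = next(iter(genome))
    L = len(genome[replicon])

    n_pairs = int(round(cfg.frac_two_genes * cfg.n_asrnas))
    genes: list[Gene] = []
    # host tag -> (overlap_start, overlap_end): region shared by two
    # same-strand genes, so an aTSS there is antisense to both
    pair_overlaps: dict[str, tuple[int, int]] = {}
    partner_tags: set[str] = set()
    cursor = 300
    idx = 0
    while len(genes) < cfg.n_genes:
        length = int(rng.integers(cfg.gene_min_len, cfg.gene_max_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        if cursor + length > L - 500:
            raise ValueError(
                f"infeasible packing: {cfg.n_genes} genes do not fit in a "
                f"{L} nt genome; placed {len(genes)}")
        idx += 1
        tag = f"VNG_RS{idx * 5:05d}"
        host = Gene(tag, replicon, cursor, cursor + length, strand)
        genes.append(host)
        cursor = host.end
        if len(pair_overlaps) < n_pairs and length >= 600:
            overlap = int(rng.integers(100, 200))
            p_len = int(rng.integers(300, 500))
            idx += 1
            p_tag = f"VNG_RS{idx * 5:05d}"
            partner = Gene(p_tag, replicon, host.end - overlap,
                           host.end - overlap + p_len, host.strand)
            genes.append(partner)
            pair_overlaps[tag] = (partner.start, host.end)
            partner_tags.add(p_tag)
            cursor = max(cursor, partner.end)
        cursor += int(rng.integers(cfg.gap_min, cfg.gap_max + 1))

    is_datss = _exact_count_mask(cfg.n_asrnas, cfg.frac_datss, rng)
    wants_5p = _exact_count_mask(cfg.n_asrnas, cfg.frac_five_prime, rng)
    is_ranc = _exact_count_mask(cfg.n_asrnas, cfg.frac_rancrna, rng)
    is_cons = _exact_count_mask(cfg.n_asrnas, cfg.frac_conserved, rng)

    # hosts for aTSS: pair hosts first so two-gene cognates occur, then
    # cycle through the remaining genes
    paired_tags = set(pair_overlaps)
    singleton = [g for g in genes
                 if g.locus_tag not in paired_tags
                 and g.locus_tag not in partner_tags]
    hosts = [g for g in genes if g.locus_tag in paired_tags]
    if not singleton and len(hosts) < cfg.n_asrnas:
        raise ValueError("infeasible design: not enough host genes for asRNAs")
    while len(hosts) < cfg.n_asrnas:
        hosts.extend(singleton)
    occupied: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}

    def free(strand: str, start: int, end: int) -> bool:
        return all(e <= start or end <= s for s, e in occupied[strand])

    def class_of(position: int, strand: str) -> tuple[str, list[str]]:
        """Independent brute-force classification against the placed genes."""
        inside = [g.locus_tag for g in genes
                  if g.strand != strand and g.contains(position)]
        if inside:
            return ANTISENSE, inside
        down = []
        for g in genes:
            if g.strand == strand:
                continue
            if g.strand == "+" and g.end <= position < g.end + 200:
                down.append(g.locus_tag)
            elif g.strand == "-" and g.start - 200 <= position < g.start:
                down.append(g.locus_tag)
        if down:
            return DOWNSTREAM_ANTISENSE, down
        return "other", []

    def propose(gene: Gene, i: int) -> tuple[int, int, bool] | None:
        """One placement attempt in `gene`; returns (tss, end3, overlaps5)."""
        strand = "+" if gene.strand == "-" else "-"
        length = int(np.clip(round(rng.lognormal(np.log(90.0), 0.45)),
                             cfg.asrna_min_len, cfg.asrna_max_len))
        gl = len(gene)
        win = 3 + 12  # cognate 5' window length
        if is_datss[i]:
            off = int(rng.integers(0, 200))
            if gene.strand == "+":
                tss = gene.end + off
                end3 = tss - length + 1  # asRNA on -, runs leftwards
            else:
                tss = gene.start - 1 - off
                end3 = tss + length - 1
            return tss, end3, False
        if gene.locus_tag in pair_overlaps:
            # force the aTSS into the region shared by both genes
            lo, hi = pair_overlaps[gene.locus_tag]
            tss = int(rng.integers(lo, hi))
            if gene.strand == "+":
                end3 = tss - length + 1
            else:
                end3 = tss + length - 1
            return tss, end3, False
        if wants_5p[i]:
            dist = int(rng.integers(10, min(gl - 1, 120)))
            overshoot = int(rng.integers(0, 20))
            if gene.strand == "+":
                tss = gene.start + dist
                end3 = gene.start - overshoot
            else:
                tss = gene.end - 1 - dist
                end3 = gene.end - 1 + overshoot
            return tss, end3, True
        # keep the interval clear of the cognate 5' window
        lo_off = win + length - 1
        if lo_off >= gl:
            length = max(cfg.asrna_min_len, gl - win - 1)
            lo_off = win + length - 1
            if lo_off >= gl:
                return None
        o = int(rng.integers(lo_off, gl))
        if gene.strand == "+":
            tss = gene.start + o
            end3 = tss - length + 1
        else:
            tss = gene.end - 1 - o
            end3 = tss + length - 1
        return tss, end3, False

    planted: list[PlantedAsRna] = []
    levels = cfg.mean_depth * rng.lognormal(0.0, cfg.expression_sigma,
                                            size=cfg.n_asrnas)
    for i in range(cfg.n_asrnas):
        intended = DOWNSTREAM_ANTISENSE if is_datss[i] else ANTISENSE
        placedrec = None
        candidates = [hosts[i]] + [g for g in singleton if g is not hosts[i]]
        for gene in candidates:
            if placedrec is not None:
                break
            strand = "+" if gene.strand == "-" else "-"
            for _attempt in range(60):
                prop = propose(gene, i)
                if prop is None:
                    break
                tss, end3, overlaps5 = prop
                start, end = (min(tss, end3), max(tss, end3) + 1)
                if start < 50 or end > L - 50:
                    continue
                if not free(strand, start, end):
                    continue
                cls, cognate = class_of(tss, strand)
                if cls != intended or gene.locus_tag not in cognate:
                    continue
                occupied[strand].append((start, end))
                placedrec = PlantedAsRna(
                    tss_position=tss, strand=strand, end_position=end3,
                    cognate_genes=cognate, tss_class=cls,
                    expression_level=float(levels[i]),
                    is_rancrna=bool(is_ranc[i]),
                    is_conserved_in_b=bool(is_cons[i]) and cls == ANTISENSE,
                    overlaps_five_prime=overlaps5)
                break
        if placedrec is None:
            raise ValueError(f"infeasible packing: could not place asRNA {i} "
                             f"after bounded retries")
        planted.append(placedrec)

    gene_levels = {
        g.locus_tag: float(cfg.gene_mean_depth
                           * rng.lognormal(0.0, cfg.gene_expression_sigma))
        for g in genes}
    truth = SimTruth(planted_genes=genes, planted_asrnas=planted,
                     library_params={"n_libraries": cfg.n_libraries,
                                     "mean_depth": cfg.mean_depth,
                                     "fragment_length_mean": cfg.fragment_length_mean,
                                     "fragment_length_sd": cfg.fragment_length_sd},
                     seed=seed, gene_expression=gene_levels)
    return genes, truth


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    """Negative binomial with the given mean and size (dispersion) r."""
    p = dispersion / (dispersion + mean)
    return int(rng.negative_binomial(dispersion, p))


def simulate_libraries(genome: dict[str, str], truth: SimTruth,
                       cfg: SimConfig, seed: int) -> SimDataset:
    """Sample per-library fragment profiles (and TEX/Ribo tracks) from the
    planted truth. See the module docstring for the fragment model."""
    rng = np.random.default_rng(seed)
    replicon = next(iter(genome))
    L = len(genome[replicon])
    libs = [f"lib{i + 1}" for i in range(cfg.n_libraries)]

    def track(kind: str, strand: str, lib: str) -> ProfileTrack:
        return ProfileTrack(replicon=replicon, strand=strand, library_id=lib,
                            kind=kind, values=np.zeros(L, dtype=np.int64))

    coverage, five_prime, three_prime = [], [], []
    fragments: dict[str, list[tuple[str, int, int, str]]] = {l: [] for l in libs}
    by = {}
    for lib in libs:
        for strand in "+-":
            by[(lib, strand, "coverage")] = track("coverage", strand, lib)
            by[(lib, strand, "five_prime")] = track("five_prime", strand, lib)
            by[(lib, strand, "three_prime")] = track("three_prime", strand, lib)
    tex_plus = {s: track("five_prime", s, "tex_plus") for s in "+-"}
    tex_minus = {s: track("five_prime", s, "tex_minus") for s in "+-"}
    ribo_cov = {s: track("ribo", s, "ribo") for s in "+-"}
    ribo_start = {s: track("five_prime", s, "ribo") for s in "+-"}

    def add_fragment(lib: str, strand: str, p5: int, p3: int) -> None:
        start, end = (p5, p3 + 1) if strand == "+" else (p3, p5 + 1)
        start = max(0, start)
        end = min(L, end)
        if end <= start:
            return
        by[(lib, strand, "coverage")].values[start:end] += 1
        if 0 <= p5 < L:
            by[(lib, strand, "five_prime")].values[p5] += 1
        if 0 <= p3 < L:
            by[(lib, strand, "three_prime")].values[p3] += 1
        fragments[lib].append((replicon, start, end, strand))

    def sample_transcript(lib: str, strand: str, five_t: int, three_t: int,
                          level: float, jitter_sd: float = 0.0) -> None:
        """Sample one library's fragments of one transcript (5'..3' given
        as inclusive base coordinates in transcript orientation)."""
        sgn = 1 if strand == "+" else -1
        size = sgn * (three_t - five_t) + 1
        n = _nb_draw(rng, level, cfg.nb_dispersion)
        if n == 0:
            return
        flens = np.maximum(
            20, np.rint(rng.normal(cfg.fragment_length_mean,
                                   cfg.fragment_length_sd, size=n))
        ).astype(int)
        terminal = rng.random(n) < 0.4
        jitter = (np.rint(rng.normal(0, jitter_sd, size=n)).astype(int)
                  if jitter_sd > 0 else np.zeros(n, dtype=int))
        for k in range(n):
            flen = int(flens[k])
            if flen >= size:  # molecule shorter than a fragment: whole
                p5 = five_t
                p3 = three_t + sgn * int(jitter[k])
            elif terminal[k]:  # 3'-terminal fragment
                p3 = three_t + sgn * int(jitter[k])
                p5 = p3 - sgn * (flen - 1)
            else:  # internal breakpoint: 3' end uniform inside
                off = int(rng.integers(0, size - 1))
                p3 = five_t + sgn * off
                p5 = p3 - sgn * (flen - 1)
                if sgn * (p5 - five_t) < 0:  # clip to the transcript 5' end
                    p5 = five_t
            add_fragment(lib, strand, p5, p3)

    for asr in truth.planted_asrnas:
        for lib in libs:
            sample_transcript(lib, asr.strand, asr.tss_position,
                              asr.end_position, asr.expression_level,
                              cfg.end_jitter_sd)
        # dRNA-seq: TEX+ enriched at the primary 5' end, TEX- residual
        n_tex = _nb_draw(rng, asr.expression_level, cfg.nb_dispersion)
        tex_plus[asr.strand].values[asr.tss_position] += max(n_tex, 1)
        n_bg = rng.poisson(0.1 * asr.expression_level)
        if n_bg > 0:
            pos = rng.integers(min(*asr.interval), max(*asr.interval), size=n_bg)
            np.add.at(tex_minus[asr.strand].values, pos, 1)
        # Ribo-seq
        start, end = asr.interval
        size = asr.size_nt
        if asr.is_rancrna:
            n_r = 25 + int(rng.poisson(10))
            rlen = 30
            if size <= rlen:
                starts = np.full(n_r, start)
                rl = size
            else:
                starts = np.linspace(start, end - rlen, n_r).astype(int)
                rl = rlen
            for s in starts:
                ribo_cov[asr.strand].values[s : s + rl] += 1
                ribo_start[asr.strand].values[s] += 1
        else:
            n_r = int(rng.integers(0, 4))
            for _ in range(n_r):
                s = int(rng.integers(start, end))
                ribo_cov[asr.strand].values[s : min(s + 30, end)] += 1
                ribo_start[asr.strand].values[s] += 1

    # mRNA expression of the genes themselves (sense strand)
    for g in truth.planted_genes:
        level = truth.gene_expression.get(g.locus_tag, 0.0)
        if level <= 0:
            continue
        five_t = g.start if g.strand == "+" else g.end - 1
        three_t = g.end - 1 if g.strand == "+" else g.start
        for lib in libs:
            sample_transcript(lib, g.strand, five_t, three_t, level)
        n_tex = _nb_draw(rng, level, cfg.nb_dispersion)
        tex_plus[g.strand].values[five_t] += max(n_tex, 1)
        n_bg = rng.poisson(0.1 * level)
        if n_bg > 0:
            pos = rng.integers(g.start, g.end, size=n_bg)
            np.add.at(tex_minus[g.strand].values, pos, 1)

    # background noise fragments
    if cfg.noise_rate > 0:
        lam = cfg.noise_rate * L / 1000.0
        for lib in libs:
            for strand in "+-":
                sgn = 1 if strand == "+" else -1
                for _ in range(int(rng.poisson(lam))):
                    p5 = int(rng.integers(0, L))
                    flen = max(20, int(round(rng.normal(
                        cfg.fragment_length_mean, cfg.fragment_length_sd))))
                    p3 = int(np.clip(p5 + sgn * (flen - 1), 0, L - 1))
                    add_fragment(lib, strand, p5, p3)

    for lib in libs:
        for strand in "+-":
            coverage.append(by[(lib, strand, "coverage")])
            five_prime.append(by[(lib, strand, "five_prime")])
            three_prime.append(by[(lib, strand, "three_prime")])

    return SimDataset(
        config=cfg, genome=genome, genes=truth.planted_genes, truth=truth,
        libraries=libs, coverage=coverage, five_prime=five_prime,
        three_prime=three_prime,
        tex_plus=list(tex_plus.values()), tex_minus=list(tex_minus.values()),
        ribo_coverage=list(ribo_cov.values()),
        ribo_starts=list(ribo_start.values()), fragments=fragments)


def make_species_b(dataset: SimDataset, seed: int) -> None:
    """Attach a companion species-B annotation for conservation tests.

    Species B copies every species-A gene length (tags ``HVO_<n>``) onto
    its own replicon and plants one aTSS per antisense-class planted
    asRNA: in the same tenth partition as the species-A site when the
    truth marks it conserved, in a different tenth otherwise. This is a
    positional-control construction, not an evolutionary simulation.
    """
    rng = np.random.default_rng(seed)
    cursor = 200
    genes_b: list[Gene] = []
    a_to_b: dict[str, Gene] = {}
    for i, g in enumerate(dataset.genes):
        gb = Gene(f"HVO_{(i + 1) * 5:05d}", "chrB", cursor, cursor + len(g), "+")
        genes_b.append(gb)
        a_to_b[g.locus_tag] = gb
        cursor = gb.end + 200
    genes_a = {g.locus_tag: g for g in dataset.genes}
    atss_b: list[Tss] = []
    n = 0
    for asr in dataset.truth.planted_asrnas:
        if asr.tss_class != ANTISENSE:
            continue
        tag_a = asr.cognate_genes[0]
        gene_a = genes_a[tag_a]
        gb = a_to_b[tag_a]
        d_a = relative_position(asr.tss_position, gene_a)
        p_a = partition_index(d_a)
        Lb = len(gb)
        offsets = np.arange(Lb)
        d_all = 100.0 * offsets / (Lb - 1) if Lb > 1 else np.zeros(1)
        parts = np.minimum((d_all // 10).astype(int), 9)
        pool = offsets[parts == p_a] if asr.is_conserved_in_b else offsets[parts != p_a]
        o = int(rng.choice(pool))
        n += 1
        atss_b.append(Tss(id=f"HVO_aTSS_{n}", replicon="chrB",
                          position=gb.start + o, strand="-",
                          tss_class=ANTISENSE, cognate_genes=[gb.locus_tag],
                          read_support=10))
    dataset.genes_b = genes_b
    dataset.atss_b = atss_b
    dataset.orthologs = pd.DataFrame({
        "gene_a": [g.locus_tag for g in dataset.genes],
        "gene_b": [a_to_b[g.locus_tag].locus_tag for g in dataset.genes],
    })


def simulate(cfg: SimConfig | None = None, seed: int = 0,
             species_b: bool = True) -> SimDataset:
    """Generate a complete synthetic dataset from a single seed."""
    if cfg is None:
        cfg = SimConfig()
    genome = generate_genome(cfg.genome_length, cfg.gc_fraction, seed,
                             cfg.replicon)
    genes, truth = plant_features(genome, cfg, seed + 1)
    dataset = simulate_libraries(genome, truth, cfg, seed + 2)
    if species_b:
        make_species_b(dataset, seed + 3)
    return dataset


def truth_to_frame(truth: SimTruth) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "tss_position": a.tss_position, "strand": a.strand,
            "end_position": a.end_position, "tss_class": a.tss_class,
            "cognate_genes": ",".join(a.cognate_genes),
            "size_nt": a.size_nt, "expression_level": a.expression_level,
            "is_rancrna": a.is_rancrna,
            "is_conserved_in_b": a.is_conserved_in_b,
            "overlaps_five_prime": a.overlaps_five_prime,
        }
        for a in truth.planted_asrnas
    ])


def write_dataset(dataset: SimDataset, outdir: str | Path) -> dict[str, str]:
    """Write the dataset as plain-text standard formats; returns a manifest
    of logical name -> path."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def put(name: str, rel: str) -> Path:
        p = out / rel
        paths[name] = str(p)
        return p

    aio.write_genome(dataset.genome, put("genome", "genome.fasta"))
    aio.write_annotation(dataset.genes, put("annotation", "genes.gff3"))
    strand_tag = {"+": "fwd", "-": "rev"}
    for tr_list, kind in ((dataset.coverage, "coverage"),
                          (dataset.five_prime, "five_prime"),
                          (dataset.three_prime, "three_prime")):
        for t in tr_list:
            rel = f"{t.library_id}.{kind}.{strand_tag[t.strand]}.bedgraph"
            aio.write_profile(t, put(f"{t.library_id}.{kind}.{t.strand}", rel))
    for lib in dataset.libraries:
        aio.write_fragments_bed(dataset.fragments[lib],
                                put(f"{lib}.fragments", f"{lib}.fragments.bed"))
    for tr_list, name in ((dataset.tex_plus, "tex_plus"),
                          (dataset.tex_minus, "tex_minus"),
                          (dataset.ribo_coverage, "ribo_coverage"),
                          (dataset.ribo_starts, "ribo_starts")):
        for t in tr_list:
            rel = f"{name}.{strand_tag[t.strand]}.bedgraph"
            aio.write_profile(t, put(f"{name}.{t.strand}", rel))
    truth_to_frame(dataset.truth).to_csv(put("truth", "truth.tsv"),
                                         sep="\t", index=False)
    if dataset.orthologs is not None:
        aio.write_annotation(dataset.genes_b, put("annotation_b", "genes_b.gff3"))
        aio.write_tss_bed(dataset.atss_b, put("tss_b", "atss_b.bed"))
        dataset.orthologs.to_csv(put("orthologs", "orthologs.tsv"),
                                 sep="\t", index=False)
    return paths
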