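"""Positional and sequence characterization of aTSS and asRNA loci.

Positions inside a CDS are expressed on a length-normalized 0-100 scale
(``d`` = 0 at the first base of the start codon, 100 at the last base of
the stop codon) and binned into tenths [0,10), [10,20), ..., [90,100),
with d = 100 clamped into the last bin. Sequence context around aligned
sites (promoter windows around aTSS, termination windows around 3' ends)
is summarized as per-offset nucleotide count/frequency matrices.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import revcomp
from .model import AsRnaLocus, FrequencyMatrix, Gene, Tss

logger = logging.getLogger(__name__)


def relative_position(position: int, gene: Gene) -> float:
    """Length-normalized position ``d`` of a base inside a gene.

    The offset ``o`` runs 0..L-1 along the gene's orientation (o = 0 at
    the first base of the start codon); ``d = 100 * o / (L - 1)`` so the
    last base maps exactly to 100.
    """
    if not gene.contains(position):
        raise ValueError(
            f"position {position} outside gene {gene.locus_tag} "
            f"[{gene.start},{gene.end})")
    L = len(gene)
    if L == 1:
        return 0.0
    o = position - gene.start if gene.strand == "+" else (gene.end - 1) - position
    return 100.0 * o / (L - 1)


def partition_index(d: float, n_partitions: int = 10) -> int:
    """Tenth-partition index of ``d``: floor(d / (100/n)), with d = 100
    clamped into the last partition."""
    if not 0.0 <= d <= 100.0:
        raise ValueError(f"d = {d} outside [0, 100]")
    return min(int(d // (100.0 / n_partitions)), n_partitions - 1)


def five_prime_window_of(gene: Gene, ext: int = 12) -> tuple[int, int]:
    """Half-open genomic interval covering the start codon plus ``ext`` nt
    downstream of it in gene orientation (length 3 + ext)."""
    if gene.strand == "+":
        return gene.start, gene.start + 3 + ext
    return gene.end - 3 - ext, gene.end


def five_prime_overlap(locus: AsRnaLocus, gene: Gene, ext: int = 12) -> bool:
    """Whether an antisense locus intersects its cognate gene's 5' window
    (start codon + ``ext`` nt downstream; any shared base counts)."""
    lo, hi = five_prime_window_of(gene, ext)
    return locus.replicon == gene.replicon and locus.start < hi and lo < locus.end


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}


def frequency_matrix(sites: Sequence[tuple[str, int, str]],
                     genome: Mapping[str, str],
                     window_offsets: Sequence[int]) -> FrequencyMatrix:
    """Per-offset nucleotide counts over aligned site windows.

    Each site is ``(replicon, position, strand)``; offset 0 is the site
    base, negative offsets upstream and positive downstream *in transcript
    orientation* (minus-strand sequences are reverse-complemented). Sites
    whose window leaves the replicon are skipped with a warning.
    """
    sites = list(sites)
    if not sites:
        raise ValueError("frequency_matrix needs at least one site")
    offsets = list(window_offsets)
    counts = np.zeros((len(offsets), 4), dtype=np.int64)
    used = 0
    for replicon, position, strand in sites:
        seq = genome[replicon]
        if strand == "+":
            lo, hi = position + offsets[0], position + offsets[-1]
        else:
            lo, hi = position - offsets[-1], position - offsets[0]
        if lo < 0 or hi >= len(seq):
            logger.warning("site %s:%d(%s): window out of bounds; skipped",
                           replicon, position, strand)
            continue
        if strand == "+":
            window = seq[lo : hi + 1]
        else:
            window = revcomp(seq[lo : hi + 1])
        for row, off in enumerate(offsets):
            counts[row, _BASE_INDEX[window[off - offsets[0]]]] += 1
        used += 1
    return FrequencyMatrix(window_offsets=offsets, counts=counts, n_sites=used)


def position_histogram(atss: Iterable[Tss], genes: Mapping[str, Gene],
                       n_partitions: int = 10) -> np.ndarray:
    """Counts of aTSS per tenth partition of ``d`` relative to cognate
    genes. A site antisense to two genes contributes once per gene."""
    hist = np.zeros(n_partitions, dtype=np.int64)
    for t in atss:
        for tag in t.cognate_genes:
            gene = genes[tag]
            if not gene.contains(t.position):
                continue  # daTSS anchors lie outside the gene body
            d = relative_position(t.position, gene)
            hist[partition_index(d, n_partitions)] += 1
    return hist


def frequency_matrix_frame(fm: FrequencyMatrix):
    """Tabular (pandas) view: one row per offset with counts and
    frequencies per base, for TSV export."""
    import pandas as pd

    freq = fm.frequencies
    data = {"offset": fm.window_offsets}
    for j, base in enumerate(FrequencyMatrix.BASES):
        data[f"count_{base}"] = fm.counts[:, j]
    for j, base in enumerate(FrequencyMatrix.BASES):
        data[f"freq_{base}"] = freq[:, j]
    return pd.DataFrame(data)
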