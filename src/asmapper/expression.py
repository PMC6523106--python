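"""Fragment counting, asRNA:mRNA expression comparison, and the
ribosome-association (rancRNA) filter.

Counting is union-mode and strand-aware: a fragment counts toward a
feature when it overlaps it by at least one base on the same strand;
fragments overlapping more than one same-strand feature are discarded as
ambiguous. Expression candidacy follows the raw-count rule — an asRNA is
a candidate cis-regulator when its count is equal to or greater than its
cognate mRNA's in at least one library — so no normalization or
pseudocount choice can affect the flag. A locus is a putative
ribosome-associated ncRNA (rancRNA) when pooled Ribo-seq coverage spans
more than half of it and at least 20 reads support it.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .model import AsRnaLocus, PipelineConfig, ProfileTrack, pooled

logger = logging.getLogger(__name__)

#: a stranded interval: (replicon, start, end, strand)
Interval = tuple[str, int, int, str]


def count_fragments(features: Mapping[str, Interval],
                    fragments: Mapping[str, Sequence[Interval]]) -> pd.DataFrame:
    """Union-mode count matrix: rows = feature ids, columns = library ids.

    A fragment is assigned to the unique same-strand feature it overlaps;
    fragments hitting zero features are unassigned, fragments hitting two
    or more are ambiguous, and neither is counted.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for fid, (replicon, start, end, strand) in features.items():
        trees.setdefault((replicon, strand), IntervalTree()).addi(start, end, fid)
    matrix = pd.DataFrame(0, index=list(features), columns=list(fragments),
                          dtype=np.int64)
    for lib, frags in fragments.items():
        n_ambiguous = 0
        for replicon, start, end, strand in frags:
            tree = trees.get((replicon, strand))
            if tree is None:
                continue
            hits = tree.overlap(start, end)
            if len(hits) == 1:
                matrix.loc[next(iter(hits)).data, lib] += 1
            elif len(hits) > 1:
                n_ambiguous += 1
        if n_ambiguous:
            logger.info("count_fragments: %d ambiguous fragments discarded in %s",
                        n_ambiguous, lib)
    return matrix


def expression_flags(asrna_counts: Sequence[int],
                     mrna_counts: Sequence[int]) -> tuple[np.ndarray, bool]:
    """Per-library log2((a+1)/(m+1)) ratios and the candidacy flag.

    ``candidate`` is True when the asRNA count is >= the mRNA count in at
    least one library (the all-zero pair trivially satisfies this and is
    logged as degenerate).
    """
    a = np.asarray(asrna_counts, dtype=np.int64)
    m = np.asarray(mrna_counts, dtype=np.int64)
    if a.shape != m.shape:
        raise ValueError(f"count vector length mismatch: {a.shape} vs {m.shape}")
    ratios = np.log2((a + 1) / (m + 1))
    candidate = bool(np.any(a >= m))
    if candidate and not np.any((a > 0) | (m > 0)):
        logger.info("expression_flags: all-zero pair flagged as candidate "
                    "(degenerate 0 >= 0)")
    return ratios, candidate


def is_rancrna(coverage_fraction: float, reads: int,
               cfg: PipelineConfig | None = None) -> bool:
    """The rancRNA decision rule: coverage strictly greater than the
    minimum fraction (default 0.5) AND reads at or above the minimum
    (default 20)."""
    if cfg is None:
        cfg = PipelineConfig()
    return (coverage_fraction > cfg.rancrna_min_coverage_fraction
            and reads >= cfg.rancrna_min_reads)


def rancrna_filter(locus: AsRnaLocus, ribo_coverage: Sequence[ProfileTrack],
                   ribo_reads: Sequence[ProfileTrack] | int,
                   cfg: PipelineConfig | None = None) -> tuple[float, int, bool]:
    """Evaluate one locus against the rancRNA thresholds.

    ``ribo_coverage`` tracks (same replicon/strand as the locus) are
    pooled; the coverage fraction is the share of locus positions with
    pooled signal > 0. ``ribo_reads`` is either a pooled read count for
    the locus, or read-start (5'-end) tracks from which reads are counted
    as starts falling inside the locus.

    Returns ``(coverage_fraction, reads, is_rancrna)``.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if locus.size_nt <= 0:
        raise ValueError(f"zero-length locus {locus.asrna_id}")
    for t in ribo_coverage:
        if t.replicon != locus.replicon or t.strand != locus.strand:
            raise ValueError(f"ribo track {t.library_id} does not match locus "
                             f"{locus.asrna_id} replicon/strand")
    cov = pooled(ribo_coverage)[locus.start : locus.end]
    coverage_fraction = float(np.count_nonzero(cov)) / locus.size_nt
    if isinstance(ribo_reads, int):
        reads = ribo_reads
    else:
        reads = int(pooled(list(ribo_reads))[locus.start : locus.end].sum())
    return coverage_fraction, reads, is_rancrna(coverage_fraction, reads, cfg)


def expression_table(matrix: pd.DataFrame, loci: Iterable[AsRnaLocus]) -> pd.DataFrame:
    """Per-locus expression summary against the first cognate gene.

    Requires ``matrix`` rows for each locus asrna_id and cognate gene
    locus_tag (missing cognates are skipped with a warning). Returns one
    row per locus with per-library log2 ratios and the candidate flag.
    """
    rows = []
    for locus in loci:
        if locus.asrna_id not in matrix.index:
            logger.warning("expression_table: no counts for %s", locus.asrna_id)
            continue
        if not locus.cognate_genes or locus.cognate_genes[0] not in matrix.index:
            logger.warning("expression_table: no cognate counts for %s",
                           locus.asrna_id)
            continue
        a = matrix.loc[locus.asrna_id].to_numpy()
        m = matrix.loc[locus.cognate_genes[0]].to_numpy()
        ratios, candidate = expression_flags(a, m)
        row = {"asrna_id": locus.asrna_id, "cognate": locus.cognate_genes[0],
               "candidate": candidate}
        for lib, r in zip(matrix.columns, ratios):
            row[f"log2_ratio_{lib}"] = r
        rows.append(row)
    return pd.DataFrame(rows)
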