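"""asRNA locus inference from fragment 3'-end accumulation profiles.

An asRNA locus is anchored at a classified (and structure-filtered)
aTSS/daTSS and extends downstream in transcript orientation to the first
position where the fragment 3'-end count, pooled across libraries, reaches
``min_end_support`` (default 10) — provided the interval from the TSS to
that position has uninterrupted nonzero fragment coverage in at least
``min_lib_support`` libraries (default 4). The first qualifying position
demarcates the *minimum* 3' end: paired-end 3' evidence marks where
fragments preferentially terminate, and taking the first such position is
deliberately conservative about locus length.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np

from .model import (AsRnaLocus, PipelineConfig, ProfileTrack, Tss,
                    make_asrna_id, pooled)

logger = logging.getLogger(__name__)


def _check_tracks(tss: Tss, tracks: Sequence[ProfileTrack]) -> None:
    for t in tracks:
        if t.replicon != tss.replicon or t.strand != tss.strand:
            raise ValueError(
                f"track {t.library_id}/{t.kind} ({t.replicon}, {t.strand}) does "
                f"not match TSS {tss.id} ({tss.replicon}, {tss.strand})")


def _coverage_reach(values: np.ndarray, start: int, step: int, limit: int) -> int:
    """Length of the contiguous nonzero run from ``start`` walking by
    ``step`` (+1 or -1), capped at ``limit`` positions."""
    run = 0
    pos = start
    n = len(values)
    while run < limit and 0 <= pos < n and values[pos] > 0:
        run += 1
        pos += step
    return run


def infer_locus(tss: Tss, three_prime: Sequence[ProfileTrack],
                coverage: Sequence[ProfileTrack],
                cfg: PipelineConfig | None = None) -> AsRnaLocus | None:
    """Infer the minimum 3' end for one TSS; ``None`` when no position
    qualifies within ``max_locus_span_nt`` (or before the replicon end).

    The returned locus has ``start == tss.position`` on + (``end - 1`` on
    -) and ``size_nt == end - start``. ``end_support`` records the pooled
    3'-end count at the inferred end, ``lib_support`` the number of
    libraries whose coverage is nonzero at every locus position.
    """
    if cfg is None:
        cfg = PipelineConfig()
    _check_tracks(tss, list(three_prime) + list(coverage))
    pooled3 = pooled(three_prime)
    n = len(pooled3)
    if not 0 <= tss.position < n:
        raise ValueError(f"TSS {tss.id} position {tss.position} outside replicon")
    step = 1 if tss.strand == "+" else -1
    # per-library contiguous coverage run from the TSS in transcript orientation
    reaches = [_coverage_reach(c.values, tss.position, step, cfg.max_locus_span_nt)
               for c in coverage]
    span_limit = min(cfg.max_locus_span_nt,
                     n - tss.position if step == 1 else tss.position + 1)
    hit_boundary = span_limit < cfg.max_locus_span_nt
    for offset in range(span_limit):
        pos = tss.position + step * offset
        support = int(pooled3[pos])
        if support >= cfg.min_end_support:
            # locus covers offset+1 positions from the TSS through `pos`
            lib_support = sum(1 for r in reaches if r >= offset + 1)
            if lib_support >= cfg.min_lib_support:
                start = tss.position if step == 1 else pos
                end = pos + 1 if step == 1 else tss.position + 1
                return AsRnaLocus(
                    asrna_id="", tss_id=tss.id, replicon=tss.replicon,
                    start=start, end=end, strand=tss.strand,
                    cognate_genes=list(tss.cognate_genes),
                    end_support=support, lib_support=lib_support)
    if hit_boundary:
        logger.info("TSS %s: scan reached the replicon boundary without a "
                    "qualifying 3' end", tss.id)
    return None


def build_loci(sites: Iterable[Tss], three_prime: Sequence[ProfileTrack],
               coverage: Sequence[ProfileTrack],
               cfg: PipelineConfig | None = None,
               genes: Iterable | None = None) -> list[AsRnaLocus]:
    """Infer a locus for every classified TSS that has a qualifying end.

    Tracks are passed for both strands; each TSS uses the matching-strand
    subset. asRNA ids follow the ``VNG_as<gene>_<ordinal>`` /
    ``VNG_da<gene>_<ordinal>`` convention, derived from the first cognate
    gene of the anchoring TSS. When ``genes`` is given, each locus's
    cognate list is extended with every opposite-strand gene its interval
    overlaps (an asRNA can run past its anchor gene into a neighbour, and
    is then antisense to two genes).
    """
    if cfg is None:
        cfg = PipelineConfig()
    from .tss import GeneIndex

    index = None
    if isinstance(genes, GeneIndex):
        index = genes
    elif genes is not None:
        genes = list(genes)
        if genes:
            index = GeneIndex(genes)
    sites = list(sites)
    loci: list[AsRnaLocus] = []
    for tss in sites:
        tp = [t for t in three_prime
              if t.replicon == tss.replicon and t.strand == tss.strand]
        cov = [t for t in coverage
               if t.replicon == tss.replicon and t.strand == tss.strand]
        if not tp or not cov:
            logger.warning("TSS %s: no matching-strand tracks; skipped", tss.id)
            continue
        locus = infer_locus(tss, tp, cov, cfg)
        if locus is None:
            continue
        if index is not None:
            opp = "-" if locus.strand == "+" else "+"
            overlapped = index.overlapping(locus.replicon, opp,
                                           locus.start, locus.end)
            extra = [g.locus_tag for g in overlapped
                     if g.locus_tag not in locus.cognate_genes]
            locus.cognate_genes = list(locus.cognate_genes) + extra
        if tss.cognate_genes:
            try:
                locus.asrna_id = make_asrna_id(tss.cognate_genes[0], tss.id)
            except ValueError:
                locus.asrna_id = f"asRNA_{tss.id}"
        else:
            locus.asrna_id = f"asRNA_{tss.id}"
        loci.append(locus)
    logger.info("build_loci: %d TSS -> %d loci", len(sites), len(loci))
    return loci
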