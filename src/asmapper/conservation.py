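"""Cross-species positional conservation of antisense TSS.

Orthologous genes are compared on a length-normalized scale: an aTSS at
normalized position ``d_a`` in species A is conserved when some aTSS in
the ortholog sits in the same tenth partition (``d_b`` with the same
``floor(d/10)`` bin). ``D = |d_a - d_b|`` measures positional
equivalence; D = 0 means the identical relative position and D < 3 is
reported as "positionally equivalent". The scan is deliberately
asymmetric: species A must contribute an annotated asRNA locus (TSS plus
inferred 3' end), while a bare aTSS suffices in species B.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .analytics import partition_index, relative_position
from .model import AsRnaLocus, ConservationRecord, Gene, Tss

logger = logging.getLogger(__name__)


def conserved_atss(d_a: float, d_b: float, n_partitions: int = 10) -> ConservationRecord:
    """Score one (d_a, d_b) pair: partitions, D, and the conserved flag."""
    pa = partition_index(d_a, n_partitions)
    pb = partition_index(d_b, n_partitions)
    return ConservationRecord(
        gene_a="", gene_b="", d_a=d_a, d_b=d_b, partition_a=pa, partition_b=pb,
        D=abs(d_a - d_b), conserved=(pa == pb))


def conservation_scan(
    ortholog_pairs: pd.DataFrame,
    loci_a: Sequence[AsRnaLocus],
    atss_b: Sequence[Tss],
    genes_a: Mapping[str, Gene],
    genes_b: Mapping[str, Gene],
    n_partitions: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every (locus-in-A, aTSS-in-B) combination per ortholog pair.

    Only ortholog pairs with >= 1 annotated asRNA locus whose anchoring
    TSS lies inside the species-A gene and >= 1 aTSS inside the species-B
    gene enter the comparison. Returns ``(records, pairs)``:

    records
        one row per scored combination (gene_a, gene_b, asrna_id, tss_b,
        d_a, d_b, partitions, D, conserved);
    pairs
        one row per qualifying ortholog pair with the OR-over-combinations
        conserved flag and the minimum D.

    Pairs referencing unknown locus tags are skipped with a warning.
    """
    loci_by_gene: dict[str, list[AsRnaLocus]] = {}
    for locus in loci_a:
        for tag in locus.cognate_genes:
            loci_by_gene.setdefault(tag, []).append(locus)
    atss_by_gene: dict[str, list[Tss]] = {}
    for t in atss_b:
        for tag in t.cognate_genes:
            atss_by_gene.setdefault(tag, []).append(t)

    rec_rows, pair_rows = [], []
    for _, pair in ortholog_pairs.iterrows():
        tag_a, tag_b = pair["gene_a"], pair["gene_b"]
        if tag_a not in genes_a or tag_b not in genes_b:
            logger.warning("ortholog pair (%s, %s): unknown locus tag; skipped",
                           tag_a, tag_b)
            continue
        gene_a, gene_b = genes_a[tag_a], genes_b[tag_b]
        cand_a = [l for l in loci_by_gene.get(tag_a, ())
                  if gene_a.contains(l.tss_position)]
        cand_b = [t for t in atss_by_gene.get(tag_b, ())
                  if gene_b.contains(t.position)]
        if not cand_a or not cand_b:
            continue
        best_D = np.inf
        any_conserved = False
        for locus in cand_a:
            d_a = relative_position(locus.tss_position, gene_a)
            for t in cand_b:
                d_b = relative_position(t.position, gene_b)
                rec = conserved_atss(d_a, d_b, n_partitions)
                rec_rows.append({
                    "gene_a": tag_a, "gene_b": tag_b,
                    "asrna_id": locus.asrna_id, "tss_b": t.id,
                    "d_a": d_a, "d_b": d_b,
                    "partition_a": rec.partition_a, "partition_b": rec.partition_b,
                    "D": rec.D, "conserved": rec.conserved,
                })
                best_D = min(best_D, rec.D)
                any_conserved = any_conserved or rec.conserved
        pair_rows.append({"gene_a": tag_a, "gene_b": tag_b,
                          "n_combinations": len(cand_a) * len(cand_b),
                          "conserved": any_conserved, "min_D": best_D})
    records = pd.DataFrame(rec_rows, columns=[
        "gene_a", "gene_b", "asrna_id", "tss_b", "d_a", "d_b",
        "partition_a", "partition_b", "D", "conserved"])
    pairs = pd.DataFrame(pair_rows, columns=[
        "gene_a", "gene_b", "n_combinations", "conserved", "min_D"])
    return records, pairs


def conservation_summary(records: pd.DataFrame, pairs: pd.DataFrame) -> dict:
    """Headline numbers: conserved combinations/pairs and the D < 3
    positional-equivalence count among conserved records."""
    conserved_records = records[records["conserved"]]
    return {
        "n_pairs_scored": int(len(pairs)),
        "n_pairs_conserved": int(pairs["conserved"].sum()) if len(pairs) else 0,
        "n_records": int(len(records)),
        "n_records_conserved": int(len(conserved_records)),
        "n_equivalent_D_lt_3": int((conserved_records["D"] < 3).sum())
        if len(conserved_records) else 0,
    }


def d_histogram(records: pd.DataFrame, bin_width: float = 1.0) -> pd.DataFrame:
    """Histogram of D over conserved records (distribution of positional
    differences among conserved aTSS)."""
    conserved = records.loc[records["conserved"], "D"].to_numpy()
    edges = np.arange(0.0, 10.0 + bin_width, bin_width)
    counts, _ = np.histogram(conserved, bins=edges)
    return pd.DataFrame({"D_lo": edges[:-1], "D_hi": edges[1:], "count": counts})
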