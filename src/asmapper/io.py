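"""Readers and writers for the standard formats the pipeline touches.

GFF3 carries gene annotation in and asRNA loci out (1-based inclusive in
the file, converted to/from internal 0-based half-open at this boundary).
BED6 carries TSS positions, bedGraph carries stranded per-position count
profiles, FASTA carries the genome, and TSV carries ortholog tables and
matrices. bedGraph intervals that overlap are summed, not overwritten: the
format forbids overlaps but real exports contain them, and summation keeps
``read_profile`` linear in its input.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

from .model import AsRnaLocus, Gene, ProfileTrack, Tss

Source = Union[str, Path, TextIO]

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (result is DNA-alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _as_handle(source: Source, mode: str = "r"):
    if hasattr(source, "read") or hasattr(source, "write"):
        return source, False
    return open(source, mode), True


# ---------------------------------------------------------------------------
# FASTA

def read_genome(source: Source) -> dict[str, str]:
    """Read a FASTA file into a mapping replicon -> uppercase sequence."""
    handle, close = _as_handle(source)
    try:
        genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")}
    finally:
        if close:
            handle.close()
    if not genome:
        raise ValueError("empty genome: no FASTA records found")
    return genome


def write_genome(genome: Mapping[str, str], dest: Source, width: int = 70) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for name, seq in genome.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# GFF3

def _parse_gff_attributes(field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in field.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ValueError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        attrs[key] = value
    return attrs


def _format_gff_attributes(attrs: Mapping[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def read_annotation(source: Source,
                    feature_types: Sequence[str] = ("gene", "CDS")) -> list[Gene]:
    """Read gene records from GFF3 into 0-based half-open :class:`Gene`s.

    A feature is kept if its type is in ``feature_types`` (``gene``
    preferred; ``CDS`` rows are used only when no ``gene`` rows exist, so
    annotations exporting both do not double-count). Duplicate locus tags
    raise.
    """
    handle, close = _as_handle(source)
    by_type: dict[str, list[Gene]] = {t: [] for t in feature_types}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 record at line {lineno}: "
                                 f"expected 9 tab-separated fields, got {len(fields)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = fields
            if ftype not in by_type:
                continue
            if strand not in ("+", "-"):
                raise ValueError(f"unknown strand symbol {strand!r} at line {lineno}")
            try:
                start_1 = int(start_s)
                end_1 = int(end_s)
            except ValueError as exc:
                raise ValueError(f"non-integer coordinate at line {lineno}") from exc
            attrs = _parse_gff_attributes(attr_s)
            tag = attrs.get("locus_tag") or attrs.get("ID")
            if tag is None:
                raise ValueError(f"record at line {lineno} lacks locus_tag/ID")
            by_type[ftype].append(
                Gene(locus_tag=tag, replicon=seqid, start=start_1 - 1, end=end_1,
                     strand=strand, product=attrs.get("product"))
            )
    finally:
        if close:
            handle.close()
    genes: list[Gene] = []
    for t in feature_types:
        if by_type[t]:
            genes = by_type[t]
            break
    seen: set[str] = set()
    for g in genes:
        if g.locus_tag in seen:
            raise ValueError(f"duplicate locus_tag {g.locus_tag!r} in annotation")
        seen.add(g.locus_tag)
    return genes


def write_annotation(genes: Iterable[Gene], dest: Source,
                     source_name: str = "asmapper") -> None:
    """Write genes back to GFF3 (1-based inclusive coordinates)."""
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("##gff-version 3\n")
        for g in genes:
            attrs = {"ID": g.locus_tag, "locus_tag": g.locus_tag}
            if g.product is not None:
                attrs["product"] = g.product
            handle.write("\t".join([
                g.replicon, source_name, "gene", str(g.start + 1), str(g.end),
                ".", g.strand, ".", _format_gff_attributes(attrs),
            ]) + "\n")
    finally:
        if close:
            handle.close()


def write_loci_gff3(loci: Iterable[AsRnaLocus], dest: Source,
                    source_name: str = "asmapper") -> None:
    """Write asRNA loci as GFF3 ncRNA features with full attribute set."""
    handle, close = _as_handle(dest, "w")
    try:
        handle.write("##gff-version 3\n")
        for loc in loci:
            attrs = {
                "ID": loc.asrna_id,
                "tss_id": loc.tss_id,
                "size_nt": str(loc.size_nt),
                "cognate_genes": ",".join(loc.cognate_genes),
                "end_support": str(loc.end_support),
                "lib_support": str(loc.lib_support),
            }
            handle.write("\t".join([
                loc.replicon, source_name, "ncRNA", str(loc.start + 1),
                str(loc.end), ".", loc.strand, ".", _format_gff_attributes(attrs),
            ]) + "\n")
    finally:
        if close:
            handle.close()


def read_loci_gff3(source: Source) -> list[AsRnaLocus]:
    handle, close = _as_handle(source)
    loci: list[AsRnaLocus] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 record at line {lineno}")
            attrs = _parse_gff_attributes(fields[8])
            loci.append(AsRnaLocus(
                asrna_id=attrs["ID"], tss_id=attrs.get("tss_id", ""),
                replicon=fields[0], start=int(fields[3]) - 1, end=int(fields[4]),
                strand=fields[6],
                cognate_genes=[t for t in attrs.get("cognate_genes", "").split(",") if t],
                end_support=int(attrs.get("end_support", 0)),
                lib_support=int(attrs.get("lib_support", 0)),
            ))
    finally:
        if close:
            handle.close()
    return loci


# ---------------------------------------------------------------------------
# BED6 (TSS)

def read_tss_bed(source: Source) -> list[Tss]:
    """Read TSS sites from BED6. The name field holds ``<id>``,
    ``<id>|<class>`` or ``<id>|<class>|<cognate,tags>``; the score field
    holds read support."""
    handle, close = _as_handle(source)
    sites: list[Tss] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 record at line {lineno} has <6 fields")
            chrom, start_s, _end, name, score, strand = fields[:6]
            parts = name.split("|")
            tss_id = parts[0]
            tss_class = parts[1] if len(parts) > 1 and parts[1] else "other"
            cognates = [t for t in parts[2].split(",") if t] if len(parts) > 2 else []
            sites.append(Tss(
                id=tss_id, replicon=chrom, position=int(start_s), strand=strand,
                tss_class=tss_class, cognate_genes=cognates,
                read_support=int(float(score)) if score not in (".", "") else 0,
            ))
    finally:
        if close:
            handle.close()
    return sites


def write_tss_bed(sites: Iterable[Tss], dest: Source) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for t in sites:
            name = f"{t.id}|{t.tss_class}|{','.join(t.cognate_genes)}"
            handle.write("\t".join([
                t.replicon, str(t.position), str(t.position + 1), name,
                str(t.read_support), t.strand,
            ]) + "\n")
    finally:
        if close:
            handle.close()


def read_fragments_bed(source: Source) -> list[tuple[str, int, int, str]]:
    """Read stranded fragment intervals from BED6 (chrom, start, end, strand)."""
    handle, close = _as_handle(source)
    frags: list[tuple[str, int, int, str]] = []
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 record at line {lineno} has <6 fields")
            frags.append((fields[0], int(fields[1]), int(fields[2]), fields[5]))
    finally:
        if close:
            handle.close()
    return frags


def write_fragments_bed(fragments: Iterable[tuple[str, int, int, str]],
                        dest: Source) -> None:
    handle, close = _as_handle(dest, "w")
    try:
        for replicon, start, end, strand in fragments:
            handle.write(f"{replicon}\t{start}\t{end}\t.\t.\t{strand}\n")
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# bedGraph

def read_profile(source: Source, replicon_lengths: Mapping[str, int],
                 strand: str, library_id: str, kind: str,
                 replicon: str | None = None) -> ProfileTrack:
    """Read a stranded bedGraph into a dense per-position vector.

    One file per strand; the strand is supplied as metadata. Positions
    absent from the file are zero; overlapping intervals are summed.
    """
    handle, close = _as_handle(source)
    vectors = {name: np.zeros(length, dtype=np.int64)
               for name, length in replicon_lengths.items()}
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"malformed bedGraph record at line {lineno}")
            chrom, start_s, end_s, value_s = fields
            if chrom not in vectors:
                raise ValueError(f"unknown replicon {chrom!r} at line {lineno}")
            start, end = int(start_s), int(end_s)
            value = float(value_s)
            if value < 0:
                raise ValueError(f"negative value at line {lineno}")
            if end > len(vectors[chrom]) or start < 0 or end <= start:
                raise ValueError(
                    f"interval [{start},{end}) out of bounds for replicon "
                    f"{chrom!r} (length {len(vectors[chrom])}) at line {lineno}")
            vectors[chrom][start:end] += int(round(value))
    finally:
        if close:
            handle.close()
    if replicon is None:
        if len(vectors) != 1:
            raise ValueError("replicon must be named when several lengths are given")
        replicon = next(iter(vectors))
    return ProfileTrack(replicon=replicon, strand=strand, library_id=library_id,
                        kind=kind, values=vectors[replicon])


def write_profile(track: ProfileTrack, dest: Source) -> None:
    """Write a dense vector as run-length-encoded bedGraph (zeros omitted)."""
    handle, close = _as_handle(dest, "w")
    values = track.values
    try:
        n = len(values)
        i = 0
        while i < n:
            v = values[i]
            j = i + 1
            while j < n and values[j] == v:
                j += 1
            if v != 0:
                handle.write(f"{track.replicon}\t{i}\t{j}\t{int(v)}\n")
            i = j
    finally:
        if close:
            handle.close()


# ---------------------------------------------------------------------------
# TSV tables

def read_ortholog_table(source: Source) -> pd.DataFrame:
    """Read an ortholog pair table; the first two columns are the locus
    tags in species A and B, named ``gene_a``/``gene_b`` on return."""
    df = pd.read_csv(source, sep="\t", dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValueError("ortholog table needs at least two columns")
    df = df.rename(columns={df.columns[0]: "gene_a", df.columns[1]: "gene_b"})
    return df[["gene_a", "gene_b"]]


def loci_to_frame(loci: Sequence[AsRnaLocus]) -> pd.DataFrame:
    """Tabular view of loci (for TSV export), including the size column."""
    return pd.DataFrame([
        {
            "asrna_id": l.asrna_id, "tss_id": l.tss_id, "replicon": l.replicon,
            "start": l.start, "end": l.end, "strand": l.strand,
            "size_nt": l.size_nt, "cognate_genes": ",".join(l.cognate_genes),
            "end_support": l.end_support, "lib_support": l.lib_support,
        }
        for l in loci
    ])
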