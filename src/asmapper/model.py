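"""Core data model for the antisense transcriptome pipeline.

Coordinate convention
---------------------
All internal coordinates are 0-based, half-open ``[start, end)``. With this
convention the length of any feature is ``end - start``, which is the
identity the asRNA size bookkeeping relies on throughout. GFF3 input/output
converts from/to the 1-based inclusive file convention at the boundary;
BED and bedGraph records pass through unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

STRANDS = ("+", "-")

#: classification labels for transcription start sites
ANTISENSE = "antisense"
DOWNSTREAM_ANTISENSE = "downstream_antisense"
OTHER = "other"


@dataclass(frozen=True)
class Gene:
    """A stranded CDS interval on a named replicon.

    ``start``/``end`` are 0-based half-open; ``end > start``.
    """

    locus_tag: str
    replicon: str
    start: int
    end: int
    strand: str
    product: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.locus_tag}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"gene {self.locus_tag}: unknown strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, position: int) -> bool:
        return self.start <= position < self.end

    @property
    def three_prime_end(self) -> int:
        """Coordinate of the 3'-most base (inclusive) in gene orientation."""
        return self.end - 1 if self.strand == "+" else self.start


@dataclass
class Tss:
    """A single-base transcription start site with its antisense class.

    ``position`` is the 0-based coordinate of the first transcribed base.
    ``cognate_genes`` lists the locus tags of every gene that qualifies the
    site as antisense (inside the gene, opposite strand) or
    downstream-antisense (within the configured window past the gene's
    3' end, opposite strand). A site antisense to two overlapping genes
    carries both tags.
    """

    id: str
    replicon: str
    position: int
    strand: str
    tss_class: str = OTHER
    cognate_genes: list[str] = field(default_factory=list)
    read_support: int = 0

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"TSS {self.id}: unknown strand {self.strand!r}")
        if self.read_support < 0:
            raise ValueError(f"TSS {self.id}: negative read support")


@dataclass
class AsRnaLocus:
    """An antisense RNA locus anchored at an aTSS/daTSS with an inferred
    minimum 3' end.

    The anchoring TSS is the interval's 5' extremity: ``start`` for a +
    locus, ``end - 1`` for a - locus. ``end_support`` is the pooled
    fragment-3'-end count observed at the inferred end; ``lib_support`` is
    the number of libraries with uninterrupted nonzero coverage across the
    locus.
    """

    asrna_id: str
    tss_id: str
    replicon: str
    start: int
    end: int
    strand: str
    cognate_genes: list[str] = field(default_factory=list)
    end_support: int = 0
    lib_support: int = 0

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus {self.asrna_id}: end must exceed start")
        if self.strand not in STRANDS:
            raise ValueError(f"locus {self.asrna_id}: unknown strand {self.strand!r}")

    @property
    def size_nt(self) -> int:
        return self.end - self.start

    @property
    def tss_position(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


PROFILE_KINDS = ("coverage", "five_prime", "three_prime", "ribo")


@dataclass
class ProfileTrack:
    """Dense per-position count vector for one replicon/strand/library.

    ``kind`` distinguishes fragment coverage, fragment 5'-end accumulation,
    fragment 3'-end accumulation, and Ribo-seq signal. Values are
    non-negative and the vector spans the whole replicon.
    """

    replicon: str
    strand: str
    library_id: str
    kind: str
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"profile: unknown strand {self.strand!r}")
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"profile: unknown kind {self.kind!r}")
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("profile values must be one-dimensional")
        if np.any(self.values < 0):
            raise ValueError("profile values must be non-negative")

    def __len__(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class ConservationRecord:
    """One ortholog-pair aTSS comparison.

    ``d_a``/``d_b`` are length-normalized CDS positions in [0, 100]
    (0 = start codon, 100 = stop codon); ``D = |d_a - d_b|``. The site is
    conserved when both positions fall into the same tenth partition.
    """

    gene_a: str
    gene_b: str
    d_a: float
    d_b: float
    partition_a: int
    partition_b: int
    D: float
    conserved: bool


@dataclass
class FrequencyMatrix:
    """Per-offset nucleotide counts and frequencies around aligned sites."""

    window_offsets: list[int]
    counts: np.ndarray  # shape (n_offsets, 4), columns A,C,G,U
    n_sites: int

    BASES = ("A", "C", "G", "U")

    @property
    def frequencies(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(totals > 0, self.counts / totals, 0.0)
        return freq


@dataclass
class TssCallerParams:
    """Parameters of the simplified dRNA-seq TSS caller."""

    p_max: float = 0.005
    min_reads: int = 4
    cluster_nt: int = 5


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, with the study defaults.

    Defaults: 200 nt daTSS window; 51 nt folding window tiled every 10 nt
    with a 33.3% quantile cutoff; 3'-end demarcation at >= 10 pooled
    observations with coverage in >= 4 libraries; 12 nt (four codons)
    5'-overlap extension; rancRNA calls at coverage > 50% and >= 20 reads;
    promoter window -40..+10 and 3'-end window -10..+10; 10 conservation
    partitions.
    """

    da_window_nt: int = 200
    mfe_window_nt: int = 51
    mfe_offset_nt: int = 10
    mfe_quantile: float = 1.0 / 3.0
    folder: str = "vienna"
    min_end_support: int = 10
    min_lib_support: int = 4
    max_locus_span_nt: int = 2000
    five_prime_extension_nt: int = 12
    rancrna_min_coverage_fraction: float = 0.5
    rancrna_min_reads: int = 20
    promoter_window: tuple[int, int] = (-40, 10)
    three_prime_window: tuple[int, int] = (-10, 10)
    tss_caller: TssCallerParams = field(default_factory=TssCallerParams)
    n_partitions: int = 10

    def __post_init__(self) -> None:
        for name in ("da_window_nt",):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("mfe_window_nt", "mfe_offset_nt", "min_end_support",
                     "min_lib_support", "max_locus_span_nt", "n_partitions"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.mfe_quantile < 1.0:
            raise ValueError("mfe_quantile must lie in (0, 1)")
        if isinstance(self.tss_caller, dict):
            self.tss_caller = TssCallerParams(**self.tss_caller)
        if isinstance(self.promoter_window, (list, tuple)):
            self.promoter_window = tuple(self.promoter_window)
        if isinstance(self.three_prime_window, (list, tuple)):
            self.three_prime_window = tuple(self.three_prime_window)


_TSS_ID_RE = re.compile(r"^(a|da)TSS_(\d+)$")
_TAG_RE = re.compile(r"^VNG_(?:RS|OE)(\w+)$|^VNG_(\w+)$")


def make_asrna_id(gene_locus: str, tss_id: str) -> str:
    """Derive the asRNA identifier from its cognate gene tag and TSS id.

    An aTSS anchor yields ``VNG_as<suffix>_<ordinal>``, a daTSS anchor
    ``VNG_da<suffix>_<ordinal>``, where ``<suffix>`` is the numeric part of
    a ``VNG_RS`` tag or the trailing part of a legacy ``VNG_OE``-style tag:

    >>> make_asrna_id("VNG_RS12315", "aTSS_1568")
    'VNG_as12315_1568'
    >>> make_asrna_id("VNG_OE3105F", "daTSS_36")
    'VNG_da3105F_36'
    """
    m = _TSS_ID_RE.match(tss_id)
    if m is None:
        raise ValueError(f"unrecognized TSS id form: {tss_id!r}")
    prefix = "as" if m.group(1) == "a" else "da"
    ordinal = m.group(2)
    tm = _TAG_RE.match(gene_locus)
    if tm is None:
        raise ValueError(f"unrecognized locus tag form: {gene_locus!r}")
    suffix = tm.group(1) or tm.group(2)
    return f"VNG_{prefix}{suffix}_{ordinal}"


def opposite_strand(strand: str) -> str:
    if strand not in STRANDS:
        raise ValueError(f"unknown strand {strand!r}")
    return "-" if strand == "+" else "+"


def pooled(tracks: Sequence[ProfileTrack]) -> np.ndarray:
    """Sum a set of equal-length profile tracks into one vector."""
    if not tracks:
        raise ValueError("cannot pool an empty track list")
    lengths = {len(t) for t in tracks}
    if len(lengths) != 1:
        raise ValueError("cannot pool tracks of different lengths")
    out = np.zeros(lengths.pop(), dtype=np.int64)
    for t in tracks:
        out += t.values
    return out
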