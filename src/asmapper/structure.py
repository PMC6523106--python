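"""Secondary-structure filter for putative false-positive aTSS.

Genomic regions prone to stable RNA secondary structure produce spurious
5'-end enrichment in dRNA-seq (structured RNAs resist the terminator
exonuclease), so aTSS whose downstream sequence folds unusually well are
treated as likely artifacts. The genome is tiled with 51-nt windows every
10 nt, each window's minimum free energy (MFE) is computed, and the 33.3%
quantile of the genome-wide MFE distribution is the cutoff: an aTSS whose
downstream 51-nt window folds at or below the cutoff is removed.

Two folding engines are available:

``vienna``
    ViennaRNA's thermodynamic nearest-neighbour MFE (``RNA.fold`` with
    default parameters). This is the default.
``builtin``
    A weighted base-pair maximization score (Nussinov-style dynamic
    program): the energy is minus the maximum total pair weight over all
    nested structures with a minimum hairpin loop of 3 unpaired bases and
    pair weights GC=3, AU=2, GU=1. It is a fast, dependency-free scorer
    with exactly checkable semantics, not a thermodynamic model; its
    integer-valued energies produce heavy ties, so quantile-based cutoffs
    behave less smoothly than with ``vienna``.

Additional engines can be registered via :func:`register_folder`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .io import revcomp
from .model import PipelineConfig, Tss

logger = logging.getLogger(__name__)

_ENCODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# pair weights indexed by (base, base); GC=3, AU=2, GU=1
_PAIR_WEIGHT = np.zeros((4, 4), dtype=np.int32)
for _a, _b, _w in ((2, 1, 3), (0, 3, 2), (2, 3, 1)):
    _PAIR_WEIGHT[_a, _b] = _w
    _PAIR_WEIGHT[_b, _a] = _w

_MIN_LOOP = 3  # unpaired bases enclosed by any pair


def _nussinov_python(code: np.ndarray) -> int:
    n = code.shape[0]
    W = np.zeros((n, n), dtype=np.int64)
    for span in range(_MIN_LOOP + 1, n):
        for i in range(n - span):
            j = i + span
            best = W[i + 1, j]
            for k in range(i + _MIN_LOOP + 1, j + 1):
                w = _PAIR_WEIGHT[code[i], code[k]]
                if w:
                    s = w + W[i + 1, k - 1]
                    if k + 1 <= j:
                        s += W[k + 1, j]
                    if s > best:
                        best = s
            W[i, j] = best
    return int(W[0, n - 1])


try:  # numba accelerates the O(n^3) recursion ~100x; fall back if absent
    from numba import njit as _njit

    _nussinov_fast = _njit(cache=False)(_nussinov_python)
except ImportError:  # pragma: no cover
    _nussinov_fast = _nussinov_python


def encode_rna(seq: str) -> np.ndarray:
    """Map an A/C/G/U (or T) string to integer codes; reject anything else."""
    try:
        return np.array([_ENCODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"non-nucleotide character {exc.args[0]!r} in sequence") from None


def fold_energy(seq: str) -> float:
    """Built-in folding score: minus the maximum weighted number of nested
    base pairs (GC=3, AU=2, GU=1, minimum hairpin loop 3).

    Always <= 0; 0 when no pair can form.

    >>> fold_energy("AAAAAA")
    0.0
    >>> fold_energy("GAAAC")
    -3.0
    """
    if len(seq) == 0:
        raise ValueError("cannot fold an empty sequence")
    code = encode_rna(seq)
    if len(code) < _MIN_LOOP + 2:  # too short for any pair
        return 0.0
    score = _nussinov_fast(code)
    return -float(score) if score else 0.0


def _vienna_fold(seq: str) -> float:
    import RNA  # ViennaRNA python bindings

    rna = seq.upper().replace("T", "U")
    _structure, mfe = RNA.fold(rna)
    return round(float(mfe), 2)


_FOLDERS: dict[str, Callable[[str], float]] = {
    "builtin": fold_energy,
    "vienna": _vienna_fold,
}


def register_folder(name: str, func: Callable[[str], float]) -> None:
    """Register an alternative folding engine under ``name``."""
    _FOLDERS[name] = func


def get_folder(name: str) -> Callable[[str], float]:
    try:
        return _FOLDERS[name]
    except KeyError:
        raise ValueError(f"unknown folding engine {name!r}; "
                         f"available: {sorted(_FOLDERS)}") from None


@dataclass(frozen=True)
class MfeWindow:
    """One genome tile with its folding energy (transcript orientation)."""

    replicon: str
    start: int
    strand: str
    sequence: str
    mfe: float


def tile_genome_mfe(genome: Mapping[str, str], window: int = 51,
                    offset: int = 10,
                    folder: Callable[[str], float] | str = "vienna") -> list[MfeWindow]:
    """Tile every replicon on both strands with fixed windows and fold each.

    Windows start at 0, ``offset``, 2*``offset``, ...; a trailing partial
    window shorter than ``window`` is skipped. Minus-strand windows use the
    reverse complement of the same genomic slice.
    """
    if window <= 0 or offset <= 0:
        raise ValueError("window and offset must be positive")
    if not genome or all(len(s) == 0 for s in genome.values()):
        raise ValueError("empty genome")
    fold = get_folder(folder) if isinstance(folder, str) else folder
    # fold each distinct sequence once: tiles repeat in low-complexity regions
    cache: dict[str, float] = {}
    out: list[MfeWindow] = []
    for name, seq in genome.items():
        for start in range(0, len(seq) - window + 1, offset):
            sub = seq[start : start + window]
            for strand, s in (("+", sub), ("-", revcomp(sub))):
                if s not in cache:
                    cache[s] = fold(s)
                out.append(MfeWindow(name, start, strand, s, cache[s]))
    return out


def mfe_cutoff(mfe_values: Sequence[float], q: float = 1.0 / 3.0) -> float:
    """Empirical q-quantile (linear interpolation) of the MFE distribution."""
    values = np.asarray(mfe_values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot take a quantile of an empty list")
    return float(np.quantile(values, q))


def downstream_window(genome: Mapping[str, str], tss: Tss,
                      window: int = 51) -> str | None:
    """The ``window``-nt sequence starting at the TSS in transcript
    orientation (TSS base first); ``None`` if the replicon ends first."""
    seq = genome[tss.replicon]
    if tss.strand == "+":
        if tss.position + window > len(seq):
            return None
        return seq[tss.position : tss.position + window]
    if tss.position - window + 1 < 0:
        return None
    return revcomp(seq[tss.position - window + 1 : tss.position + 1])


def filter_structured_atss(
    atss: Iterable[Tss], genome: Mapping[str, str], cutoff: float,
    window: int = 51, folder: Callable[[str], float] | str = "vienna",
) -> tuple[list[Tss], list[Tss]]:
    """Partition aTSS into (retained, removed) by downstream-window MFE.

    A site is removed when its downstream window folds at ``mfe <= cutoff``
    (inclusive: lower energy means more structure-prone). Sites too close
    to the replicon end for a full window are retained with a warning.
    The two lists partition the input exactly.
    """
    fold = get_folder(folder) if isinstance(folder, str) else folder
    retained: list[Tss] = []
    removed: list[Tss] = []
    for tss in atss:
        sub = downstream_window(genome, tss, window)
        if sub is None:
            logger.warning(
                "TSS %s at %s:%d(%s): insufficient sequence for a %d-nt "
                "downstream window; retained unfiltered",
                tss.id, tss.replicon, tss.position, tss.strand, window)
            retained.append(tss)
            continue
        if fold(sub) <= cutoff:
            removed.append(tss)
        else:
            retained.append(tss)
    return retained, removed
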