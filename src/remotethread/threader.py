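"""Fold-recognition contract and the bundled surrogate backend.

A threading backend takes a query region and a structure library and returns
a complete Z-score-ranked hit list, one score per library structure.  The
bundled surrogate backend scores sequence-structure compatibility as a
length-normalized gapped local alignment of the query against each
structure's reference sequence (BLOSUM62), then standardizes the raw scores
across the library into per-query Z-scores.  It is deterministic, fast, and
exists so that the statistical scoring layer on top can be exercised without
external threading software; an adapter implementing the same contract can
wrap a physics-based threading program (see docs/methods.md for the adapter
contract).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .formats import (
    SequenceRecord,
    StructureEntry,
    read_fasta,
    read_structure_manifest,
)

#: Absolute top-window size used for libraries at full fold-library scale.
TOP_WINDOW_FLOOR = 60
#: Fraction of the library inspected for expected structures (0.5%).
TOP_WINDOW_FRACTION = 0.005
#: Library size above which the absolute floor applies.
FULL_LIBRARY_SIZE = 12000


class ThreadingError(RuntimeError):
    pass


@dataclass(frozen=True)
class ThreadingHit:
    structure_id: str
    zscore: float
    rank: int  # 1-based


@dataclass(frozen=True)
class ThreadingResult:
    """A total ranking of the structure library for one query region."""

    query_id: str
    hits: tuple[ThreadingHit, ...]
    backend: str

    def __post_init__(self):
        ids = [h.structure_id for h in self.hits]
        if len(set(ids)) != len(ids):
            raise ThreadingError("duplicate structure ids in threading result")
        for i, h in enumerate(self.hits, 1):
            if h.rank != i:
                raise ThreadingError("ranks must be consecutive from 1")

    def top_structures(self, window: int) -> set[str]:
        return {h.structure_id for h in self.hits[:window]}

    def zscore_of(self, structure_id: str) -> float:
        for h in self.hits:
            if h.structure_id == structure_id:
                return h.zscore
        raise KeyError(structure_id)


@dataclass
class StructureLibrary:
    """Structure entries plus, for the surrogate backend, reference sequences."""

    entries: tuple[StructureEntry, ...]
    reference_sequences: dict[str, str]

    def __post_init__(self):
        missing = [e.structure_id for e in self.entries if e.structure_id not in self.reference_sequences]
        if missing:
            raise ThreadingError(
                f"structures lacking reference sequences: {missing[:5]}"
            )

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def load(cls, manifest_path, fasta_path) -> "StructureLibrary":
        entries = tuple(read_structure_manifest(manifest_path))
        refs = {r.id: r.residues for r in read_fasta(fasta_path)}
        return cls(entries=entries, reference_sequences=refs)


class ThreadingBackend(Protocol):
    name: str

    def raw_scores(self, query: SequenceRecord, library: StructureLibrary) -> np.ndarray:
        """One raw compatibility score per library entry, in entry order."""


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


class SurrogateBackend:
    """Alignment-based stand-in for a threading energy function.

    Raw score = local BLOSUM62 alignment score of the query against the
    structure's reference sequence, divided by sqrt(query length x reference
    length) so long references do not dominate.
    """

    name = "surrogate"

    def __init__(self):
        self._aligner = _make_aligner()

    def raw_scores(self, query: SequenceRecord, library: StructureLibrary) -> np.ndarray:
        q = query.residues
        out = np.empty(len(library))
        for i, entry in enumerate(library.entries):
            ref = library.reference_sequences[entry.structure_id]
            s = self._aligner.score(q, ref)
            out[i] = s / math.sqrt(len(q) * len(ref))
        return out


def surrogate_score(query: SequenceRecord, library: StructureLibrary) -> np.ndarray:
    """Raw surrogate compatibility scores in library entry order."""
    return SurrogateBackend().raw_scores(query, library)


def thread(
    query: SequenceRecord,
    library: StructureLibrary,
    backend: Optional[ThreadingBackend] = None,
) -> ThreadingResult:
    """Thread one query region against the whole library.

    Raw backend scores are standardized into per-query Z-scores over the
    library ((s - mean) / sd) and ranked descending; ties break by
    structure_id ascending so the ranking is total and deterministic.  A
    degenerate query (all raw scores equal, e.g. fully masked) yields all-zero
    Z-scores.
    """
    if not len(query.residues):
        raise ThreadingError("empty query")
    if not len(library):
        raise ThreadingError("empty structure library")
    backend = backend or SurrogateBackend()
    try:
        raw = np.asarray(backend.raw_scores(query, library), dtype=float)
    except Exception as exc:  # surface backend diagnostics
        raise ThreadingError(f"backend {backend.name!r} failed: {exc}") from exc
    if raw.shape != (len(library),):
        raise ThreadingError(
            f"backend {backend.name!r} returned {raw.shape}, expected ({len(library)},)"
        )
    sd = raw.std()
    z = np.zeros_like(raw) if sd < 1e-12 else (raw - raw.mean()) / sd
    order = sorted(
        range(len(library)),
        key=lambda i: (-z[i], library.entries[i].structure_id),
    )
    hits = tuple(
        ThreadingHit(
            structure_id=library.entries[i].structure_id,
            zscore=float(z[i]),
            rank=rank,
        )
        for rank, i in enumerate(order, 1)
    )
    return ThreadingResult(query_id=query.id, hits=hits, backend=backend.name)


def top_window(
    library_size: int,
    fraction: float = TOP_WINDOW_FRACTION,
    floor: int = TOP_WINDOW_FLOOR,
) -> int:
    """Size of the top-hit window inspected for expected structures.

    At full fold-library scale (>= 12000 structures) the historical absolute
    window of 60 applies; smaller libraries scale by the 0.5% fraction with a
    minimum of 1.
    """
    if library_size < 1:
        raise ValueError("library_size must be >= 1")
    if library_size >= FULL_LIBRARY_SIZE:
        return floor
    return max(1, math.ceil(fraction * library_size))
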