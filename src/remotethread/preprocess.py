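"""Pre-processing of query proteins before fold recognition.

Low-complexity segments (entropy-based, SEG-style two-threshold trigger /
extension) and predicted coiled coils (heptad-register propensity scoring)
are replaced by the mask token X in a single collated sequence; the domain
envelope found by the relaxed search is then cut out of that masked sequence
and sent to the threading stage.  A hook accepts an externally computed
3-state secondary-structure string per protein; the bundled surrogate
threader does not consume it, but a real threading backend may.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .formats import MASK, SequenceRecord
from .search import DomainHit

#: SEG-style defaults: window length, trigger entropy, extension entropy (bits).
SEG_WINDOW = 12
SEG_K1 = 2.2
SEG_K2 = 2.5

#: Coiled-coil scoring defaults: window length and per-window score cutoff.
COIL_WINDOW = 28
COIL_CUTOFF = 0.5

# Per-residue log-propensities by heptad position (a b c d e f g).  The core
# positions a/d favour aliphatic hydrophobics, the flanking e/g favour the
# charged residues that form interhelical salt bridges; proline is strongly
# penalized everywhere, glycine mildly.  A compact, versioned stand-in for a
# full coiled-coil propensity table, adequate for masking purposes.
_COIL_DEFAULT = -0.3
COIL_PROPENSITIES: dict[str, tuple[float, ...]] = {
    #        a     b     c     d     e     f     g
    "L": (2.0, 0.3, 0.3, 2.0, 0.0, 0.0, 0.0),
    "I": (1.5, 0.0, 0.0, 1.5, -0.2, -0.2, -0.2),
    "V": (1.2, 0.0, 0.0, 1.2, -0.2, -0.2, -0.2),
    "M": (1.5, 0.1, 0.1, 1.5, 0.0, 0.0, 0.0),
    "A": (1.0, 0.3, 0.3, 1.0, 0.2, 0.2, 0.2),
    "F": (0.5, -0.2, -0.2, 0.5, -0.3, -0.3, -0.3),
    "E": (-0.5, 0.5, 0.5, -0.5, 1.5, 0.3, 1.2),
    "K": (-0.5, 0.5, 0.5, -0.5, 1.2, 0.3, 1.5),
    "Q": (-0.2, 0.4, 0.4, -0.2, 1.0, 0.3, 1.0),
    "R": (-0.4, 0.4, 0.4, -0.4, 1.0, 0.3, 1.0),
    "D": (-0.6, 0.3, 0.3, -0.6, 0.6, 0.2, 0.4),
    "N": (-0.4, 0.2, 0.2, -0.4, 0.3, 0.2, 0.3),
    "S": (-0.3, 0.1, 0.1, -0.3, 0.1, 0.1, 0.1),
    "T": (-0.3, 0.1, 0.1, -0.3, 0.1, 0.1, 0.1),
    "G": (-1.0, -1.0, -1.0, -1.0, -1.0, -1.0, -1.0),
    "P": (-3.0, -3.0, -3.0, -3.0, -3.0, -3.0, -3.0),
}

Interval = tuple[int, int, str]  # (start, end, source), 0-based half-open


class PreprocessError(ValueError):
    pass


@dataclass(frozen=True)
class MaskedSequence:
    """A protein with low-complexity / coiled-coil stretches replaced by X."""

    protein_id: str
    residues: str
    mask_intervals: tuple[Interval, ...]
    secondary_structure: Optional[str] = None


def _window_entropy(residues: str, window: int) -> np.ndarray:
    """Shannon entropy (bits) of each length-``window`` subsequence."""
    n = len(residues)
    if n < window:
        return np.empty(0)
    ent = np.empty(n - window + 1)
    counts: dict[str, int] = {}
    for c in residues[:window]:
        counts[c] = counts.get(c, 0) + 1

    def h() -> float:
        return -sum((k / window) * math.log2(k / window) for k in counts.values())

    ent[0] = h()
    for i in range(1, n - window + 1):
        out_c, in_c = residues[i - 1], residues[i + window - 1]
        counts[out_c] -= 1
        if not counts[out_c]:
            del counts[out_c]
        counts[in_c] = counts.get(in_c, 0) + 1
        ent[i] = h()
    return ent


def mask_low_complexity(
    seq: SequenceRecord,
    window: int = SEG_WINDOW,
    k1: float = SEG_K1,
    k2: float = SEG_K2,
) -> list[Interval]:
    """Entropy-based low-complexity intervals.

    A window with entropy below ``k1`` triggers a segment, which extends over
    adjacent windows while entropy stays below ``k2``; the reported interval
    covers the union of the contributing windows.
    """
    if window < 4:
        raise PreprocessError("window must be >= 4")
    ent = _window_entropy(seq.residues, window)
    if ent.size == 0:
        return []
    # windows touching an existing mask token are already masked territory;
    # excluding them keeps masking idempotent
    is_x = np.array([c == MASK for c in seq.residues])
    has_x = np.array([
        is_x[i : i + window].any() for i in range(ent.size)
    ])
    trigger = (ent < k1) & ~has_x
    extend = (ent < k2) & ~has_x
    intervals: list[Interval] = []
    i = 0
    n = ent.size
    while i < n:
        if not extend[i]:
            i += 1
            continue
        j = i
        while j < n and extend[j]:
            j += 1
        if trigger[i:j].any():
            intervals.append((i, j - 1 + window, "low_complexity"))
        i = j
    return intervals


def _coil_window_score(residues: str, register: int) -> float:
    total = 0.0
    for i, c in enumerate(residues):
        prop = COIL_PROPENSITIES.get(c)
        heptad = (i + register) % 7
        total += _COIL_DEFAULT if prop is None else prop[heptad]
    return total / len(residues)


def mask_coiled_coils(
    seq: SequenceRecord,
    window: int = COIL_WINDOW,
    score_cutoff: float = COIL_CUTOFF,
) -> list[Interval]:
    """Heptad-register propensity scan for coiled-coil stretches.

    Every window is scored under its best of the 7 possible heptad registers;
    windows above the cutoff merge into maximal intervals.
    """
    if window not in (14, 21, 28):
        raise PreprocessError("coiled-coil window must be one of 14, 21, 28")
    n = len(seq.residues)
    if n < window:
        return []
    above = np.zeros(n - window + 1, dtype=bool)
    for i in range(n - window + 1):
        sub = seq.residues[i : i + window]
        best = max(_coil_window_score(sub, r) for r in range(7))
        above[i] = best >= score_cutoff
    intervals: list[Interval] = []
    i = 0
    while i < above.size:
        if not above[i]:
            i += 1
            continue
        j = i
        while j < above.size and above[j]:
            j += 1
        intervals.append((i, j - 1 + window, "coiled_coil"))
        i = j
    return intervals


def collate(
    seq: SequenceRecord,
    *mask_lists: Sequence[Interval],
    secondary_structure: Optional[str] = None,
) -> MaskedSequence:
    """Apply the union of all mask intervals as X over the sequence."""
    n = len(seq.residues)
    masked = np.zeros(n, dtype=bool)
    all_intervals: list[Interval] = []
    for intervals in mask_lists:
        for start, end, source in intervals:
            if not (0 <= start < end <= n):
                raise PreprocessError(
                    f"{seq.id}: interval ({start}, {end}) out of bounds for length {n}"
                )
            masked[start:end] = True
            all_intervals.append((start, end, source))
    if secondary_structure is not None and len(secondary_structure) != n:
        raise PreprocessError(f"{seq.id}: secondary-structure string length mismatch")
    residues = "".join(
        MASK if masked[i] else c for i, c in enumerate(seq.residues)
    )
    return MaskedSequence(
        protein_id=seq.id,
        residues=residues,
        mask_intervals=tuple(all_intervals),
        secondary_structure=secondary_structure,
    )


def preprocess_sequence(
    seq: SequenceRecord, secondary_structure: Optional[str] = None
) -> MaskedSequence:
    """Default pre-processing: low-complexity plus coiled-coil masking."""
    return collate(
        seq,
        mask_low_complexity(seq),
        mask_coiled_coils(seq),
        secondary_structure=secondary_structure,
    )


def extract_domain_region(mseq: MaskedSequence, hit: DomainHit) -> SequenceRecord:
    """Cut the hit envelope out of the masked sequence for threading.

    The record id encodes protein, profile and the 1-based inclusive span.
    A fully masked region is returned with a warning flag rather than dropped.
    """
    n = len(mseq.residues)
    if not (0 <= hit.env_start < hit.env_end <= n):
        raise PreprocessError(
            f"{mseq.protein_id}: envelope ({hit.env_start}, {hit.env_end}) "
            f"out of bounds for length {n}"
        )
    sub = mseq.residues[hit.env_start : hit.env_end]
    warning = "fully-masked region" if set(sub) == {MASK} else None
    return SequenceRecord(
        id=f"{mseq.protein_id}/{hit.profile_accession}/{hit.env_start + 1}-{hit.env_end}",
        residues=sub,
        warning=warning,
    )
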