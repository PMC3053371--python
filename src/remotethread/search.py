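"""Relaxed conserved-domain search.

The built-in engine aligns a sequence to a per-position log-odds profile by
glocal dynamic programming (global in the profile, local in the sequence)
with linear gap penalties, and converts the resulting bit score to an
E-value through a per-profile extreme-value calibration:

    E(S) = db_size * exp(-lambda * (S - mu))

where (mu, lambda) are fitted to the maximal alignment scores of the profile
against i.i.d. random sequences.  This is deliberately a simplified profile
scorer rather than a full profile-HMM implementation: the statistics that sit
downstream (fold-recognition rescoring, validation) are the point of the
package, and the engine contract is pluggable so a production profile-HMM
search can stand in.

Hits are reported up to a deliberately permissive E-value ceiling (default
50) so that sub-significant, "remote" domain candidates survive into the
fold-recognition stage instead of being discarded at the usual 1e-4 cut.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gumbel_r

from .formats import ALPHABET, DomainProfile, SequenceRecord, residue_index

logger = logging.getLogger(__name__)

#: Linear gap penalties, bits.  gap_delete skips a profile match position,
#: gap_insert skips a sequence residue inside the aligned region.
GAP_DELETE = 4.0
GAP_INSERT = 4.0

#: Minimum sequence length worth searching.
MIN_SEQ_LEN = 5


class SearchError(RuntimeError):
    pass


@dataclass(frozen=True)
class DomainHit:
    """One profile match on one protein.

    The envelope is 0-based half-open on the protein.  ``alignment`` pairs
    (sequence position, profile match position), strictly increasing on both
    axes and contained in the envelope.
    """

    protein_id: str
    profile_accession: str
    env_start: int
    env_end: int
    bit_score: float
    evalue: float
    alignment: tuple[tuple[int, int], ...]
    db_version: str = "v1"

    def __post_init__(self):
        if not (0 <= self.env_start < self.env_end):
            raise ValueError(f"bad envelope ({self.env_start}, {self.env_end})")
        if not self.evalue > 0:
            raise ValueError("evalue must be > 0")

    def overlaps(self, other: "DomainHit") -> int:
        """Number of shared residues with another hit on the same protein."""
        return max(0, min(self.env_end, other.env_end) - max(self.env_start, other.env_start))


@dataclass(frozen=True)
class SearchConfig:
    """Thresholds of the relaxed search.

    ``report_threshold`` (default 50) is the permissive reporting ceiling;
    ``significant_threshold`` (1e-4) accepts a hit outright with no fold
    recognition; ``weak_threshold`` (0.1) is the line above which a hit needs
    cross-species validation on top of an accepted fold.
    """

    report_threshold: float = 50.0
    significant_threshold: float = 1e-4
    weak_threshold: float = 0.1
    overlap_mode: str = "all_overlapping"  # or "top_hit_only"
    overlap_tolerance: int = 0  # shared residues allowed between kept hits

    def __post_init__(self):
        if not (self.significant_threshold < self.weak_threshold < self.report_threshold):
            raise ValueError(
                "thresholds must satisfy significant < weak < report"
            )
        if self.overlap_mode not in ("all_overlapping", "top_hit_only"):
            raise ValueError(f"unknown overlap_mode {self.overlap_mode!r}")


# ---------------------------------------------------------------------------
# the glocal DP scorer


def _glocal_score_matrix(profile: DomainProfile, seq_idx: np.ndarray):
    """Run the glocal DP; return (H rows list, final row) for traceback.

    H[j][i] = best score after consuming profile rows 1..j with the alignment
    ending at sequence prefix i (i = 0..n; 0 means before the first residue).
    Row 0 is all zeros: the local start in the sequence is free.
    """
    n = seq_idx.size
    L = profile.length
    scores = profile.match_scores
    pos = np.arange(n + 1, dtype=float)
    Hprev = np.zeros(n + 1)
    rows = [Hprev]
    ops = []  # per row: int8 array, 0=match, 1=delete, 2=insert
    for j in range(L):
        srow = np.where(seq_idx >= 0, scores[j, np.clip(seq_idx, 0, None)], 0.0)
        match = np.full(n + 1, -np.inf)
        match[1:] = Hprev[:-1] + srow
        delete = Hprev - GAP_DELETE
        V = np.maximum(match, delete)
        op = np.where(match >= delete, np.int8(0), np.int8(1))
        # insert transition H[i] = max(V[i], H[i-1] - GAP_INSERT): decayed
        # running max, computed as a prefix max in a tilted frame.
        B = np.maximum.accumulate(V + GAP_INSERT * pos)
        H = B - GAP_INSERT * pos
        op = np.where(H > V + 1e-12, np.int8(2), op)
        rows.append(H)
        ops.append(op)
        Hprev = H
    return rows, ops


def _traceback(rows, ops, seq_idx: np.ndarray, end_i: int):
    """Recover the match-state alignment ending at sequence prefix end_i."""
    pairs: list[tuple[int, int]] = []
    j = len(ops)
    i = end_i
    while j > 0:
        op = ops[j - 1][i]
        if op == 0:  # match: profile row j-1 with sequence residue i-1
            pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
        elif op == 1:  # delete: profile row skipped
            j -= 1
        else:  # insert: sequence residue skipped
            i -= 1
    pairs.reverse()
    return tuple(pairs)


def score_sequence(profile: DomainProfile, seq: SequenceRecord):
    """Best glocal alignment of ``seq`` to ``profile``.

    Returns (bit_score, alignment pairs).  Alignment may be empty when the
    best path deletes every profile position (degenerate, heavily penalized).
    """
    seq_idx = residue_index(seq.residues)
    rows, ops = _glocal_score_matrix(profile, seq_idx)
    final = rows[-1]
    end_i = int(np.argmax(final))
    score = float(final[end_i])
    alignment = _traceback(rows, ops, seq_idx, end_i)
    return score, alignment


# ---------------------------------------------------------------------------
# calibration


def random_background_sequence(rng: np.random.Generator, length: int) -> str:
    """I.i.d. random sequence under uniform background residue frequencies."""
    return "".join(rng.choice(list(ALPHABET), size=length))


def calibrate_profile(
    profile: DomainProfile,
    n_random: int = 1000,
    seed: int = 0,
    random_length: Optional[int] = None,
) -> DomainProfile:
    """Fit the extreme-value (mu, lambda) calibration of a profile.

    Scores ``n_random`` i.i.d. random sequences (uniform residue background)
    and fits a Gumbel (right-skewed extreme value) distribution to the
    resulting maximal alignment bit scores; lambda is the reciprocal Gumbel
    scale.  Deterministic given the seed.
    """
    if n_random < 200:
        raise SearchError("calibration needs n_random >= 200")
    if profile.length < 2:
        raise SearchError(
            f"profile {profile.accession}: too short to calibrate (length < 2)"
        )
    rng = np.random.default_rng(seed)
    length = random_length or max(100, 2 * profile.length)
    scores = np.empty(n_random)
    for t in range(n_random):
        seq = SequenceRecord(id=f"rand{t}", residues=random_background_sequence(rng, length))
        scores[t], _ = score_sequence(profile, seq)
    if np.ptp(scores) < 1e-9:
        raise SearchError(
            f"profile {profile.accession}: degenerate score distribution"
        )
    mu, beta = gumbel_r.fit(scores)
    return replace(profile, calibration=(float(mu), float(1.0 / beta)))


def evalue_from_score(profile: DomainProfile, bit_score: float, db_size: int) -> float:
    if profile.calibration is None:
        raise SearchError(f"profile {profile.accession} is not calibrated")
    mu, lam = profile.calibration
    e = db_size * math.exp(-lam * (bit_score - mu))
    return max(e, 1e-300)  # keep strictly positive for downstream logs


# ---------------------------------------------------------------------------
# search + overlap handling


def search_domains(
    seq: SequenceRecord,
    db: Sequence[DomainProfile],
    cfg: SearchConfig = SearchConfig(),
    evalue_ceiling: Optional[float] = None,
) -> list[DomainHit]:
    """Search one sequence against a profile database.

    Returns hits with E-value <= the reporting ceiling, sorted ascending by
    E-value with ties broken by (accession, envelope start).  The optional
    ``evalue_ceiling`` overrides the config ceiling (the ortholog-validation
    pass searches at a looser 100).
    """
    if not db:
        raise SearchError("empty profile database")
    ceiling = cfg.report_threshold if evalue_ceiling is None else evalue_ceiling
    if len(seq) < MIN_SEQ_LEN:
        logger.warning("sequence %s shorter than %d residues; skipping", seq.id, MIN_SEQ_LEN)
        return []
    hits: list[DomainHit] = []
    for profile in db:
        if profile.calibration is None:
            raise SearchError(f"profile {profile.accession} is not calibrated")
        score, alignment = score_sequence(profile, seq)
        if not alignment:
            continue
        ev = evalue_from_score(profile, score, db_size=len(db))
        if ev > ceiling:
            continue
        env_start = alignment[0][0]
        env_end = alignment[-1][0] + 1
        hits.append(
            DomainHit(
                protein_id=seq.id,
                profile_accession=profile.accession,
                env_start=env_start,
                env_end=env_end,
                bit_score=score,
                evalue=ev,
                alignment=alignment,
                db_version=profile.db_version,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.profile_accession, h.env_start))
    return hits


def resolve_overlaps(hits: Sequence[DomainHit], tolerance: int = 0) -> list[DomainHit]:
    """Greedy best-E-value-first overlap removal.

    A hit is kept iff it shares at most ``tolerance`` residues with every
    already-kept hit; output is sorted by envelope start.
    """
    if not hits:
        return []
    proteins = {h.protein_id for h in hits}
    if len(proteins) != 1:
        raise SearchError("resolve_overlaps expects hits on a single protein")
    ordered = sorted(hits, key=lambda h: (h.evalue, h.profile_accession, h.env_start))
    kept: list[DomainHit] = []
    for h in ordered:
        if all(h.overlaps(k) <= tolerance for k in kept):
            kept.append(h)
    kept.sort(key=lambda h: h.env_start)
    return kept


def gate_by_structure(hit: DomainHit, structure_map) -> bool:
    """True iff the hit's profile has at least one mapped structure."""
    return bool(structure_map.get(hit.profile_accession))
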