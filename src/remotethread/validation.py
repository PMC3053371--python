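"""Cross-species and essential-residue validation of weak domain hits.

A hit whose search E-value exceeds 0.1 rests on very thin sequence evidence
even after its fold is accepted, so two orthogonal checks add confidence:

* the same domain is re-detected (at a looser E-value ceiling of 100) in the
  orthologs of up to three related species, and the fold is re-accepted there
  by the identical threading-and-scoring procedure; the validation level is
  the number of species in which both succeed, and level >= 2 is the default
  operating point for calling a hit validated;

* the residues the family annotates as functionally essential are compared
  between the query and the family consensus and classified as identity,
  similarity (positive BLOSUM62 score) or null, with a pass at >= 25%
  identity-or-similarity over the evaluable positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from Bio.Align import substitution_matrices

from .formats import DomainProfile, SequenceRecord
from .preprocess import extract_domain_region, preprocess_sequence
from .scoring import EmpiricalCDF, FoldScore, score_threading
from .search import DomainHit, SearchConfig, search_domains
from .threader import StructureLibrary, ThreadingBackend, thread, top_window

#: E-value ceiling of the ortholog-side domain search.
ORTHOLOG_EVALUE_CEILING = 100.0
#: Fraction of essential positions that must be identical or similar.
RESIDUE_PASS_FRACTION = 0.25

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


@dataclass(frozen=True)
class SpeciesOutcome:
    found_domain: bool
    fold_accepted: bool


@dataclass(frozen=True)
class ResidueClassification:
    """Counts of essential consensus positions by conservation category."""

    identity: int
    similarity: int
    null: int
    evaluable: bool  # False when the profile carries no annotation

    @property
    def total(self) -> int:
        return self.identity + self.similarity + self.null

    @property
    def passed(self) -> Optional[bool]:
        if not self.evaluable or self.total == 0:
            return None
        return (self.identity + self.similarity) / self.total >= RESIDUE_PASS_FRACTION


@dataclass(frozen=True)
class ValidationReport:
    per_species: Mapping[str, SpeciesOutcome]
    level: int
    no_data: bool = False
    residues: Optional[ResidueClassification] = None


def assign_level(per_species: Mapping[str, SpeciesOutcome]) -> int:
    """Number of species where the domain was both re-found and fold-accepted.

    Permutation-invariant in species order; an empty mapping (no orthologs
    available) yields level 0 and callers flag it as "no validation data".
    """
    return sum(
        1 for o in per_species.values() if o.found_domain and o.fold_accepted
    )


def validate_in_ortholog(
    ortholog: SequenceRecord,
    profile: DomainProfile,
    db: Sequence[DomainProfile],
    library: StructureLibrary,
    structure_map: Mapping[str, set],
    cdf: EmpiricalCDF,
    cfg: SearchConfig = SearchConfig(),
    expected_region: Optional[tuple[int, int]] = None,
    backend: Optional[ThreadingBackend] = None,
    evalue_ceiling: float = ORTHOLOG_EVALUE_CEILING,
    method: str = "product",
) -> SpeciesOutcome:
    """Re-detect one domain in one ortholog and re-score its fold.

    The ortholog is searched at the looser ceiling; a hit counts as the same
    domain when it carries the same profile accession and, if an expected
    region is given, overlaps it by at least one residue.  On re-detection
    the hit region is preprocessed, threaded and scored exactly as in the
    primary pipeline.
    """
    hits = search_domains(ortholog, db, cfg, evalue_ceiling=evalue_ceiling)
    match: Optional[DomainHit] = None
    for h in hits:
        if h.profile_accession != profile.accession:
            continue
        if expected_region is not None:
            lo = max(h.env_start, expected_region[0])
            hi = min(h.env_end, expected_region[1])
            if hi - lo < 1:
                continue
        match = h
        break
    if match is None:
        return SpeciesOutcome(found_domain=False, fold_accepted=False)
    expected = structure_map.get(profile.accession, set())
    if not expected:
        return SpeciesOutcome(found_domain=True, fold_accepted=False)
    mseq = preprocess_sequence(ortholog)
    region = extract_domain_region(mseq, match)
    result = thread(region, library, backend=backend)
    window = top_window(len(library))
    fs = score_threading(result, set(expected), cdf, window, method=method)
    return SpeciesOutcome(found_domain=True, fold_accepted=fs.accepted)


def classify_residues(
    hit: DomainHit,
    query: SequenceRecord,
    profile: DomainProfile,
    essentials: Optional[Sequence[tuple[int, str]]],
) -> ResidueClassification:
    """Classify annotated essential consensus positions against the query.

    ``essentials`` lists (0-based consensus/match position, expected residue)
    pairs; positions the hit alignment does not cover count as null.  A
    profile without annotation yields a "not evaluable" result, distinct
    from a failing one.
    """
    if not essentials:
        return ResidueClassification(0, 0, 0, evaluable=False)
    by_profile_pos = {ppos: spos for spos, ppos in hit.alignment}
    identity = similarity = null = 0
    for pos, expected in essentials:
        if not (0 <= pos < profile.length):
            raise ValueError(
                f"essential position {pos} outside profile {profile.accession}"
            )
        spos = by_profile_pos.get(pos)
        observed = query.residues[spos] if spos is not None else None
        if observed is None:
            null += 1
        elif observed == expected:
            identity += 1
        elif _blosum(observed, expected) > 0:
            similarity += 1
        else:
            null += 1
    return ResidueClassification(identity, similarity, null, evaluable=True)


def _blosum(a: str, b: str) -> float:
    try:
        return float(_BLOSUM62[a, b])
    except (KeyError, IndexError):
        return -1.0
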