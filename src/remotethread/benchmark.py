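"""Hide-and-seek benchmark framework for remote-domain detection.

The truth set exploits profile-database growth: a domain that scores weakly
(E > 0.1) under an older profile release but significantly (E < 0.1, with at
least a 10-fold E-value drop) under a newer one is a known remote member
under the old profiles — detectable in principle, missed by the old
sequence search alone.  Candidate regions are then classified against that
truth set by the method's decision statistic (combined p <= 0.001, or plain
presence/absence for engines without a p-value), with profiles sharing a
clan with the regional truth profile excluded from the counts entirely, and
the confusion table is reduced to precision / recall / accuracy / FPR / FNR
percentages (integer, half-up rounding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

#: Significance threshold of the new-release search in the truth-set rule.
TRUTH_EVALUE = 0.1
#: Minimum old/new E-value ratio in the truth-set rule.
TRUTH_FOLD_CHANGE = 10.0
#: Decision threshold on the method's combined p-value.
DECISION_P = 1e-3


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class RegionHit:
    """One (protein, profile, region) hit with its search E-value."""

    protein_id: str
    profile_accession: str
    start: int
    end: int
    evalue: float

    def overlaps(self, other: "RegionHit") -> bool:
        return (
            self.protein_id == other.protein_id
            and min(self.end, other.end) - max(self.start, other.start) >= 1
        )


@dataclass(frozen=True)
class TruthEntry:
    protein_id: str
    profile_accession: str
    start: int
    end: int
    evalue_old: float
    evalue_new: float


@dataclass(frozen=True)
class TruthSet:
    entries: tuple[TruthEntry, ...]
    old_version: str
    new_version: str

    def contains(self, protein_id: str, profile_accession: str, start: int, end: int) -> bool:
        for e in self.entries:
            if (
                e.protein_id == protein_id
                and e.profile_accession == profile_accession
                and min(e.end, end) - max(e.start, start) >= 1
            ):
                return True
        return False

    def truth_profiles_at(self, protein_id: str, start: int, end: int) -> set[str]:
        return {
            e.profile_accession
            for e in self.entries
            if e.protein_id == protein_id
            and min(e.end, end) - max(e.start, start) >= 1
        }


def select_truth(
    old_hits: Sequence[RegionHit],
    new_hits: Sequence[RegionHit],
    old_version: str = "old",
    new_version: str = "new",
    threshold: float = TRUTH_EVALUE,
    fold_change: float = TRUTH_FOLD_CHANGE,
    strict_fold: bool = False,
) -> TruthSet:
    """Select remote-domain truth entries from paired release searches.

    An entry qualifies when the old-release E-value exceeds ``threshold``,
    the new-release E-value is below it, and the old/new ratio reaches
    ``fold_change`` (>= by default; > with ``strict_fold``).  Old and new
    hits pair by (protein, profile) with overlapping regions.
    """
    if old_version == new_version:
        raise BenchmarkError("old and new database versions must differ")
    entries: list[TruthEntry] = []
    for new in new_hits:
        for old in old_hits:
            if (
                old.protein_id != new.protein_id
                or old.profile_accession != new.profile_accession
                or not old.overlaps(new)
            ):
                continue
            ratio = old.evalue / new.evalue
            passes_fold = ratio > fold_change if strict_fold else ratio >= fold_change
            if old.evalue > threshold and new.evalue < threshold and passes_fold:
                entries.append(
                    TruthEntry(
                        protein_id=new.protein_id,
                        profile_accession=new.profile_accession,
                        start=new.start,
                        end=new.end,
                        evalue_old=old.evalue,
                        evalue_new=new.evalue,
                    )
                )
    return TruthSet(entries=tuple(entries), old_version=old_version, new_version=new_version)


@dataclass(frozen=True)
class Candidate:
    """One candidate region with the method's best hit and decision statistic.

    ``p_value`` carries the combined probability; engines without one use
    ``present`` instead (presence/absence substitutes for the p-threshold).
    """

    protein_id: str
    profile_accession: str
    start: int
    end: int
    p_value: Optional[float] = None
    present: Optional[bool] = None

    def positive(self, p_threshold: float) -> bool:
        if self.p_value is not None:
            return self.p_value <= p_threshold
        if self.present is not None:
            return self.present
        return False


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fn: int
    fp: int
    tn: int
    excluded: int = 0

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn, self.excluded) < 0:
            raise BenchmarkError("confusion counts must be non-negative")


def classify(
    candidates: Sequence[Candidate],
    truth: TruthSet,
    clans: Optional[Mapping[str, str]] = None,
    p_threshold: float = DECISION_P,
) -> ConfusionTable:
    """Reduce candidate decisions against the truth set to a confusion table.

    Candidates whose profile shares a clan with a truth profile overlapping
    the same region are excluded from every count (clan-mates are neither
    false positives nor true negatives).  Order-invariant.
    """
    clans = clans or {}
    tp = fn = fp = tn = excluded = 0
    for cand in candidates:
        in_truth = truth.contains(
            cand.protein_id, cand.profile_accession, cand.start, cand.end
        )
        positive = cand.positive(p_threshold)
        if in_truth:
            if positive:
                tp += 1
            else:
                fn += 1
            continue
        cand_clan = clans.get(cand.profile_accession)
        if cand_clan is not None:
            regional = truth.truth_profiles_at(cand.protein_id, cand.start, cand.end)
            if any(clans.get(acc) == cand_clan for acc in regional):
                excluded += 1
                continue
        if positive:
            fp += 1
        else:
            tn += 1
    return ConfusionTable(tp=tp, fn=fn, fp=fp, tn=tn, excluded=excluded)


def _pct(num: int, den: int) -> Optional[int]:
    if den == 0:
        return None
    return int(
        (Decimal(num) * 100 / Decimal(den)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class Metrics:
    """Integer percentages (half-up); None marks an undefined ratio."""

    precision: Optional[int]
    recall: Optional[int]
    accuracy: Optional[int]
    fpr: Optional[int]
    fnr: Optional[int]


def metrics(ct: ConfusionTable) -> Metrics:
    """Precision TP/(TP+FP), recall TP/(TP+FN), accuracy (TP+TN)/all,
    FPR FP/(FP+TN), FNR FN/(TP+FN); each as a rounded integer percent."""
    return Metrics(
        precision=_pct(ct.tp, ct.tp + ct.fp),
        recall=_pct(ct.tp, ct.tp + ct.fn),
        accuracy=_pct(ct.tp + ct.tn, ct.tp + ct.tn + ct.fp + ct.fn),
        fpr=_pct(ct.fp, ct.fp + ct.tn),
        fnr=_pct(ct.fn, ct.tp + ct.fn),
    )
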