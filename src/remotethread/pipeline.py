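"""End-to-end orchestration, one protein at a time.

The decision table per reported hit:

===========  =================  =============  ================  ==================
E-value      structure mapped   fold accepted  validation level  tier
===========  =================  =============  ================  ==================
< 1e-4       (any)              (not run)      (not run)         significant
>= 1e-4      no                 --             --                rejected
1e-4..0.1    yes                yes            --                confirmed_weak
1e-4..0.1    yes                no             --                rejected
>= 0.1       yes                yes            >= required       remote_validated
>= 0.1       yes                yes            < required        remote_unvalidated
>= 0.1       yes                no             --                rejected
===========  =================  =============  ================  ==================

Hits at statistically significant E-values need no fold recognition at all;
everything weaker must have a mapped structure and an accepted fold, and
hits above E = 0.1 additionally go through cross-species validation (level =
number of species re-confirming both domain and fold; the default operating
point requires 2 of up to 3 species).
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import yaml

from .formats import (
    DomainProfile,
    ReportRow,
    SequenceRecord,
    write_hits_report,
)
from .preprocess import extract_domain_region, preprocess_sequence
from .scoring import ACCEPT_THRESHOLD, EmpiricalCDF, FoldScore, score_threading
from .search import (
    DomainHit,
    SearchConfig,
    gate_by_structure,
    resolve_overlaps,
    search_domains,
)
from .threader import StructureLibrary, ThreadingBackend, thread, top_window
from .validation import (
    ORTHOLOG_EVALUE_CEILING,
    SpeciesOutcome,
    ValidationReport,
    assign_level,
    classify_residues,
    validate_in_ortholog,
)

logger = logging.getLogger(__name__)

#: Profiles shorter than this many match positions are flagged as short
#: domains, which are empirically harder to call correctly.
SHORT_DOMAIN_LENGTH = 50


class Tier(str, enum.Enum):
    SIGNIFICANT = "significant"
    CONFIRMED_WEAK = "confirmed_weak"
    REMOTE_VALIDATED = "remote_validated"
    REMOTE_UNVALIDATED = "remote_unvalidated"
    REJECTED = "rejected"


class PipelineError(RuntimeError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    """Every threshold of a run, serializable so runs are reproducible."""

    search: SearchConfig = field(default_factory=SearchConfig)
    ortholog_evalue: float = ORTHOLOG_EVALUE_CEILING
    accept_threshold: float = ACCEPT_THRESHOLD
    required_level: int = 2
    combiner: str = "product"
    thread_significant: bool = False  # evaluation-only: thread E < 1e-4 hits too
    continue_on_error: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        data = {
            "report_threshold": self.search.report_threshold,
            "significant_threshold": self.search.significant_threshold,
            "weak_threshold": self.search.weak_threshold,
            "overlap_mode": self.search.overlap_mode,
            "overlap_tolerance": self.search.overlap_tolerance,
            "ortholog_evalue": self.ortholog_evalue,
            "accept_threshold": self.accept_threshold,
            "required_level": self.required_level,
            "combiner": self.combiner,
            "thread_significant": self.thread_significant,
            "continue_on_error": self.continue_on_error,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        search = SearchConfig(
            report_threshold=data.get("report_threshold", 50.0),
            significant_threshold=data.get("significant_threshold", 1e-4),
            weak_threshold=data.get("weak_threshold", 0.1),
            overlap_mode=data.get("overlap_mode", "all_overlapping"),
            overlap_tolerance=data.get("overlap_tolerance", 0),
        )
        return cls(
            search=search,
            ortholog_evalue=data.get("ortholog_evalue", ORTHOLOG_EVALUE_CEILING),
            accept_threshold=data.get("accept_threshold", ACCEPT_THRESHOLD),
            required_level=data.get("required_level", 2),
            combiner=data.get("combiner", "product"),
            thread_significant=data.get("thread_significant", False),
            continue_on_error=data.get("continue_on_error", True),
            seed=data.get("seed", 0),
        )


@dataclass
class PipelineResources:
    """Everything a run needs besides the query sequences."""

    profiles: Sequence[DomainProfile]
    library: StructureLibrary
    structure_map: Mapping[str, set]
    cdf: EmpiricalCDF
    orthologs: Optional[Mapping[str, Mapping[str, str]]] = None  # query -> species -> id
    ortholog_sequences: Optional[Mapping[str, SequenceRecord]] = None
    essentials: Optional[Mapping[str, list]] = None
    backend: Optional[ThreadingBackend] = None

    def profile_by_accession(self, accession: str) -> DomainProfile:
        for p in self.profiles:
            if p.accession == accession:
                return p
        raise KeyError(accession)


@dataclass(frozen=True)
class DomainCall:
    """One fully adjudicated domain hit."""

    hit: DomainHit
    tier: Tier
    fold_score: Optional[FoldScore] = None
    validation: Optional[ValidationReport] = None
    short_domain_flag: bool = False


def classify_evalue_band(evalue: float, cfg: SearchConfig) -> str:
    if evalue < cfg.significant_threshold:
        return "significant"
    if evalue < cfg.weak_threshold:
        return "weak"
    return "remote"


def decide_tier(
    e_band: str,
    structure_mapped: bool,
    fold_accepted: Optional[bool],
    level: Optional[int],
    required_level: int = 2,
) -> Tier:
    """Pure decision-table lookup; total over every input combination."""
    if e_band == "significant":
        return Tier.SIGNIFICANT
    if e_band not in ("weak", "remote"):
        raise PipelineError(f"unknown E-value band {e_band!r}")
    if not structure_mapped or not fold_accepted:
        return Tier.REJECTED
    if e_band == "weak":
        return Tier.CONFIRMED_WEAK
    lvl = level if level is not None else 0
    return Tier.REMOTE_VALIDATED if lvl >= required_level else Tier.REMOTE_UNVALIDATED


def _validate_hit(
    hit: DomainHit,
    resources: PipelineResources,
    cfg: PipelineConfig,
    query: SequenceRecord,
) -> ValidationReport:
    profile = resources.profile_by_accession(hit.profile_accession)
    residues = classify_residues(
        hit,
        query,
        profile,
        (resources.essentials or {}).get(hit.profile_accession),
    )
    if not resources.orthologs or query.id not in resources.orthologs:
        return ValidationReport(per_species={}, level=0, no_data=True, residues=residues)
    per_species: dict[str, SpeciesOutcome] = {}
    for species, oid in resources.orthologs[query.id].items():
        oseq = (resources.ortholog_sequences or {}).get(oid)
        if oseq is None:
            logger.warning("ortholog %s for %s not found; skipping", oid, query.id)
            continue
        per_species[species] = validate_in_ortholog(
            oseq,
            profile,
            resources.profiles,
            resources.library,
            resources.structure_map,
            resources.cdf,
            cfg.search,
            expected_region=(hit.env_start, hit.env_end),
            backend=resources.backend,
            evalue_ceiling=cfg.ortholog_evalue,
            method=cfg.combiner,
        )
    if not per_species:
        return ValidationReport(per_species={}, level=0, no_data=True, residues=residues)
    return ValidationReport(
        per_species=per_species,
        level=assign_level(per_species),
        no_data=False,
        residues=residues,
    )


def run_protein(
    seq: SequenceRecord,
    resources: PipelineResources,
    cfg: PipelineConfig = PipelineConfig(),
) -> list[DomainCall]:
    """Search, thread, score and validate every reported hit on one protein."""
    hits = search_domains(seq, resources.profiles, cfg.search)
    if cfg.search.overlap_mode == "top_hit_only":
        hits = resolve_overlaps(hits, tolerance=cfg.search.overlap_tolerance)
    mseq = None
    calls: list[DomainCall] = []
    for hit in hits:
        profile = resources.profile_by_accession(hit.profile_accession)
        short_flag = profile.length < SHORT_DOMAIN_LENGTH
        band = classify_evalue_band(hit.evalue, cfg.search)
        if band == "significant" and not cfg.thread_significant:
            calls.append(
                DomainCall(hit=hit, tier=Tier.SIGNIFICANT, short_domain_flag=short_flag)
            )
            continue
        mapped = gate_by_structure(hit, resources.structure_map)
        if not mapped:
            tier = decide_tier(band, False, None, None, cfg.required_level)
            calls.append(DomainCall(hit=hit, tier=tier, short_domain_flag=short_flag))
            continue
        if resources.cdf is None:
            raise PipelineError("threading required but no background CDF provided")
        if mseq is None:
            mseq = preprocess_sequence(seq)
        region = extract_domain_region(mseq, hit)
        result = thread(region, resources.library, backend=resources.backend)
        window = top_window(len(resources.library))
        fs = score_threading(
            result,
            set(resources.structure_map[hit.profile_accession]),
            resources.cdf,
            window,
            threshold=cfg.accept_threshold,
            method=cfg.combiner,
        )
        validation = None
        if band == "remote" and fs.accepted:
            validation = _validate_hit(hit, resources, cfg, seq)
        tier = decide_tier(
            band if band != "significant" else "weak",  # thread_significant mode
            True,
            fs.accepted,
            validation.level if validation else None,
            cfg.required_level,
        )
        if band == "significant":
            tier = Tier.SIGNIFICANT
        calls.append(
            DomainCall(
                hit=hit,
                tier=tier,
                fold_score=fs,
                validation=validation,
                short_domain_flag=short_flag,
            )
        )
    return calls


def calls_to_rows(calls: Sequence[DomainCall]) -> list[ReportRow]:
    rows = []
    for c in calls:
        fs = c.fold_score
        rows.append(
            ReportRow(
                protein_id=c.hit.protein_id,
                profile_accession=c.hit.profile_accession,
                start=c.hit.env_start,
                end=c.hit.env_end,
                evalue=c.hit.evalue,
                tier=c.tier.value,
                p_cdf=fs.p_cdf if fs else None,
                p_hyper=fs.p_hyper if fs else None,
                p_combined=fs.p_combined if fs else None,
                validation_level=c.validation.level if c.validation else None,
                no_validation_data=bool(c.validation and c.validation.no_data),
                short_domain=c.short_domain_flag,
            )
        )
    return rows


@dataclass
class ProteomeSummary:
    total_proteins: int = 0
    total_calls: int = 0
    significant: int = 0
    confirmed_weak: int = 0
    remote_calls: int = 0  # reported hits at E >= 0.1 with accepted fold
    validated_level: dict = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    rejected: int = 0
    errors: int = 0

    def as_dict(self) -> dict:
        return {
            "total_proteins": self.total_proteins,
            "total_calls": self.total_calls,
            "significant": self.significant,
            "confirmed_weak": self.confirmed_weak,
            "remote_calls": self.remote_calls,
            "validated_1_species": self.validated_level[1],
            "validated_2_species": self.validated_level[2],
            "validated_3_species": self.validated_level[3],
            "rejected": self.rejected,
            "errors": self.errors,
        }


def run_proteome(
    sequences: Sequence[SequenceRecord],
    resources: PipelineResources,
    cfg: PipelineConfig = PipelineConfig(),
    out_dir: Optional[Path] = None,
) -> tuple[list[DomainCall], ProteomeSummary]:
    """Run every protein, optionally writing the per-call report and config."""
    summary = ProteomeSummary()
    all_calls: list[DomainCall] = []
    for seq in sequences:
        summary.total_proteins += 1
        try:
            calls = run_protein(seq, resources, cfg)
        except PipelineError:
            raise
        except Exception as exc:
            if not cfg.continue_on_error:
                raise PipelineError(f"protein {seq.id}: {exc}") from exc
            logger.error("protein %s failed: %s", seq.id, exc)
            summary.errors += 1
            continue
        logger.info("protein %s: %d call(s)", seq.id, len(calls))
        for c in calls:
            summary.total_calls += 1
            if c.tier is Tier.SIGNIFICANT:
                summary.significant += 1
            elif c.tier is Tier.CONFIRMED_WEAK:
                summary.confirmed_weak += 1
            elif c.tier is Tier.REJECTED:
                summary.rejected += 1
            else:
                summary.remote_calls += 1
                lvl = c.validation.level if c.validation else 0
                for threshold in (1, 2, 3):
                    if lvl >= threshold:
                        summary.validated_level[threshold] += 1
        all_calls.extend(calls)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_hits_report(calls_to_rows(all_calls), out_dir / "calls.tsv")
        cfg.to_yaml(out_dir / "config.yaml")
        with open(out_dir / "summary.yaml", "w") as fh:
            yaml.safe_dump(summary.as_dict(), fh, sort_keys=True)
    return all_calls, summary
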